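"""Screen annotated CDS start codons for N-terminal truncation.

Automated gene callers frequently place a start codon downstream of the
true one when the encoded N-terminus has no similarity to model-organism
homologs — exactly the failure mode that truncates variable N-terminal
peptides.  Given a CDS with in-frame upstream genomic context and an
alignment of trusted homologs, the screen:

1. enumerates in-frame candidate starts (ATG/GTG/TTG) upstream of the
   annotated one, stopping at the first in-frame stop codon;
2. scores each candidate's would-be N-terminal peptide against the homolog
   alignment's N-terminal region (consensus similarity + length agreement);
3. proposes an extension only when some candidate beats the annotated
   start by at least a configured margin.

The scoring rule is this module's own construction (output headers say so):
there is no community-standard statistic for "the N-terminus looks
truncated".  No ribosome-binding-site model is used — a documented
limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import aligndist
from .aligndist import Alignment
from .errors import ComputationError, FrameError, ValidationError
from .regions import RegionPartition, blosum62, conservation_profile, nterm_length_profile, map_reference_regions

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

DEFAULT_MARGIN = 0.1

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(nt: str, initiator: bool = False) -> str:
    """Translate an in-frame nucleotide string; bacterial initiators read as M."""
    nt = nt.upper()
    if len(nt) % 3:
        raise FrameError(f"sequence length {len(nt)} is not a multiple of 3")
    aas = []
    for k in range(0, len(nt), 3):
        codon = nt[k : k + 3]
        aa = _CODON_TABLE.get(codon)
        if aa is None:
            raise ValidationError(f"unrecognized codon {codon!r} at position {k + 1}")
        if aa == "*":
            break
        if k == 0 and initiator and codon in START_CODONS:
            aa = "M"
        aas.append(aa)
    return "".join(aas)


@dataclass
class CdsRecord:
    """A CDS starting at its annotated start codon, plus in-frame upstream context."""

    id: str
    cds: str
    upstream: str

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        self.upstream = self.upstream.upper()
        if len(self.cds) % 3:
            raise FrameError(f"{self.id}: CDS length {len(self.cds)} not a multiple of 3")
        if len(self.upstream) % 3:
            raise FrameError(
                f"{self.id}: upstream length {len(self.upstream)} not a multiple of 3"
            )
        if self.cds[:3] not in START_CODONS:
            raise ValidationError(
                f"{self.id}: CDS begins with {self.cds[:3]!r}, not a recognized start codon"
            )


@dataclass
class CandidateStart:
    offset_nt: int       # nucleotides upstream of the annotated start (multiple of 3)
    codon: str

    @property
    def extension_aa(self) -> int:
        return self.offset_nt // 3


@dataclass
class ReannotationProposal:
    id: str
    extension_nt: int
    extension_aa: int
    candidate_start_codon: str
    score: float
    annotated_score: float
    verdict: str  # "keep" | "extend"


def enumerate_upstream_starts(rec: CdsRecord) -> list[CandidateStart]:
    """In-frame ATG/GTG/TTG upstream of the annotated start, nearest first,
    bounded by the first in-frame stop codon (or the end of the context)."""
    out = []
    up = rec.upstream
    offset = 3
    while offset <= len(up):
        codon = up[len(up) - offset : len(up) - offset + 3]
        if codon in STOP_CODONS:
            break
        if codon in START_CODONS:
            out.append(CandidateStart(offset_nt=offset, codon=codon))
        offset += 3
    return out


def length_agreement(n: int, median_length: float) -> float:
    """1 - |n - median| / median; 1 at the median, 0 at zero length, can go
    negative for absurdly long candidates (penalizing them)."""
    if median_length <= 0:
        raise ComputationError("median homolog region length must be positive")
    return 1.0 - abs(n - median_length) / median_length


def _region_consensus(homolog_aln: Alignment, region_columns: tuple[int, int]) -> str:
    start, end = region_columns
    sub = homolog_aln.columns(list(range(start, end + 1)))
    prof = conservation_profile(sub)
    return prof.consensus.replace(aligndist.GAP, "")


def score_extension(
    candidate_peptide: str,
    homolog_aln: Alignment,
    region_columns: tuple[int, int],
    median_region_length: float | None = None,
    weights: tuple[float, float] = (0.5, 0.5),
) -> float:
    """Similarity of a candidate N-terminal peptide to the homolog region.

    similarity = sum of BLOSUM62(candidate, consensus) over the candidate's
    residues aligned flush to the region's C-terminal edge, normalized by
    the consensus self-score over the FULL region — so a candidate that
    covers only part of the region is penalized for the uncovered part.
    The combined score is weights[0]*similarity + weights[1]*length_agreement.
    """
    if not candidate_peptide:
        raise ValidationError("candidate peptide is empty")
    cons = _region_consensus(homolog_aln, region_columns)
    if not cons:
        raise ComputationError("homolog region has no consensus residues")
    if median_region_length is None:
        median_region_length = float(len(cons))
    self_score = sum(blosum62(ch, ch) for ch in cons)
    k = min(len(candidate_peptide), len(cons))
    pairs = zip(candidate_peptide[len(candidate_peptide) - k :], cons[len(cons) - k :])
    sim = sum(blosum62(a, b) for a, b in pairs) / self_score
    lterm = length_agreement(len(candidate_peptide), median_region_length)
    return weights[0] * sim + weights[1] * lterm


def _locate_core_start(
    protein: str, core_probe: str, max_offset: int
) -> int:
    """Offset in ``protein`` where the conserved core begins, by best
    BLOSUM62 match of a consensus probe taken from just after the region."""
    best, best_off = -np.inf, 0
    for off in range(0, max(1, min(max_offset, len(protein) - len(core_probe)) + 1)):
        window = protein[off : off + len(core_probe)]
        if len(window) < len(core_probe):
            break
        s = sum(blosum62(a, b) for a, b in zip(window, core_probe))
        if s > best:
            best, best_off = s, off
    return best_off


def screen_annotation(
    rec: CdsRecord,
    homolog_aln: Alignment,
    partition: RegionPartition,
    threshold: float = DEFAULT_MARGIN,
    region_name: str = "nterm",
    probe_length: int = 15,
) -> ReannotationProposal:
    """Propose keeping or extending a CDS's annotated start.

    The best-scoring candidate (including the annotated start itself) wins;
    the verdict is "extend" only if a candidate beats the annotated start
    by at least ``threshold``.  Equal-scoring candidates resolve toward the
    SHORTER extension (conservative re-annotation).
    """
    colmap = map_reference_regions(homolog_aln, partition)
    region_cols = colmap[region_name]
    counts, stats = nterm_length_profile(homolog_aln, partition, region_name)
    median_len = stats["median"]
    # consensus probe from the columns just after the region locates the core
    start_col, end_col = region_cols
    probe_cols = (end_col + 1, min(end_col + probe_length, homolog_aln.length - 1))
    if probe_cols[1] <= probe_cols[0]:
        raise ComputationError(
            "homolog alignment has no columns after the N-terminal region; "
            "cannot locate the core in the query"
        )
    core_probe = _region_consensus(homolog_aln, probe_cols)
    annotated_protein = translate(rec.cds, initiator=True)
    n0 = _locate_core_start(
        annotated_protein, core_probe, max_offset=int(2 * median_len) + probe_length
    )
    annotated_nterm = annotated_protein[:n0]

    def peptide_score(peptide: str) -> float:
        if not peptide:
            return 0.0
        return score_extension(
            peptide, homolog_aln, region_cols, median_region_length=median_len
        )

    annotated_score = peptide_score(annotated_nterm)
    best_score = annotated_score
    best: CandidateStart | None = None
    for cand in enumerate_upstream_starts(rec):  # nearest (shortest) first
        ext = translate(rec.upstream[len(rec.upstream) - cand.offset_nt :], initiator=True)
        if len(ext) < cand.extension_aa:
            continue  # internal stop: candidate reading frame closed
        score = peptide_score(ext + annotated_nterm)
        if score > best_score:  # strict: ties keep the shorter extension
            best_score, best = score, cand
    if best is not None and best_score >= annotated_score + threshold:
        return ReannotationProposal(
            id=rec.id,
            extension_nt=best.offset_nt,
            extension_aa=best.extension_aa,
            candidate_start_codon=best.codon,
            score=best_score,
            annotated_score=annotated_score,
            verdict="extend",
        )
    return ReannotationProposal(
        id=rec.id,
        extension_nt=0,
        extension_aa=0,
        candidate_start_codon=rec.cds[:3],
        score=annotated_score,
        annotated_score=annotated_score,
        verdict="keep",
    )


def screen_batch(
    records: Sequence[CdsRecord],
    homolog_aln: Alignment,
    partition: RegionPartition,
    threshold: float = DEFAULT_MARGIN,
) -> list[ReannotationProposal]:
    return [
        screen_annotation(rec, homolog_aln, partition, threshold=threshold)
        for rec in records
    ]


def proposals_to_tsv(proposals: Sequence[ReannotationProposal]) -> str:
    lines = [
        "# start-codon screen; scoring rule is this tool's own construction "
        "(consensus similarity + length agreement)",
        "id\tverdict\textension_aa\textension_nt\tcandidate_start_codon\tscore\tannotated_score",
    ]
    for p in proposals:
        lines.append(
            f"{p.id}\t{p.verdict}\t{p.extension_aa}\t{p.extension_nt}\t"
            f"{p.candidate_start_codon}\t{p.score:.6f}\t{p.annotated_score:.6f}"
        )
    return "\n".join(lines) + "\n"
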