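"""Region partitions, per-region rates, N-terminal lengths, conservation.

A :class:`RegionPartition` names contiguous stretches of a *reference*
sequence in 1-based residue coordinates (the convention of protein region
diagrams).  Coordinates are lifted onto alignment columns gap-awarely: the
k-th reference residue maps to the alignment column holding the k-th
non-gap reference character.

The default FtsZ-style partition puts the variable N-terminal peptide at
residues 1-60 of the reference; core and downstream boundaries are user
config (their exact coordinates differ per protein family and reference).

Conservation classification follows the consensus/BLOSUM62 rule used in
alignment figures: a residue scores level 2 if it matches the column
consensus, level 1 if it differs but has a positive BLOSUM62 score against
the consensus, else level 0.  Columns that are >= 50% gaps get consensus
'-' and every residue level 0 (a conservative choice for gappy N-terminal
columns); consensus ties break alphabetically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from . import aligndist
from .aligndist import Alignment, distance_matrix, neighbor_joining, p_distance, correct_distance
from .constraint import BoxSummary, RelativeDistanceRecord, summarize
from .errors import (
    AlphabetError,
    ComputationError,
    CoordinateError,
    ReliabilityError,
    UnknownLabelError,
    ValidationError,
)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> float:
    """BLOSUM62 score of a residue pair (X scores as in the published matrix)."""
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        raise ValidationError(f"residue pair ({a!r}, {b!r}) not in BLOSUM62") from None


@dataclass
class Region:
    name: str
    start: int  # 1-based inclusive reference residue
    end: int    # 1-based inclusive


@dataclass
class RegionPartition:
    regions: list[Region]
    reference_label: str

    def __post_init__(self) -> None:
        names = set()
        prev_end = 0
        self.regions = [
            r if isinstance(r, Region) else Region(*r) for r in self.regions
        ]
        for r in sorted(self.regions, key=lambda r: r.start):
            if r.name in names:
                raise ValidationError(f"duplicate region name {r.name!r}")
            names.add(r.name)
            if r.start < 1 or r.end < r.start:
                raise ValidationError(
                    f"region {r.name!r}: invalid bounds {r.start}-{r.end}"
                )
            if r.start <= prev_end:
                raise ValidationError(f"region {r.name!r} overlaps its predecessor")
            prev_end = r.end

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise UnknownLabelError(f"no region named {name!r}")


def default_ftsz_partition(reference_label: str, reference_length: int) -> RegionPartition:
    """N-terminal peptide 1-60 plus a placeholder core (61-380 or to the
    reference end).  The core/spacer boundaries are NOT authoritative —
    supply your own partition for real analyses."""
    core_end = min(380, reference_length)
    return RegionPartition(
        [Region("nterm", 1, 60), Region("core", 61, core_end)], reference_label
    )


def map_reference_regions(
    aln: Alignment, partition: RegionPartition
) -> dict[str, tuple[int, int]]:
    """Lift 1-based reference residue ranges to 0-based alignment column
    ranges (inclusive)."""
    ref = aln.sequence(partition.reference_label)
    col_of_residue: list[int] = [c for c, ch in enumerate(ref) if ch != aligndist.GAP]
    nres = len(col_of_residue)
    out = {}
    for r in partition.regions:
        if r.end > nres:
            raise CoordinateError(
                f"region {r.name!r} ends at residue {r.end} but reference "
                f"{partition.reference_label!r} has only {nres} residues"
            )
        out[r.name] = (col_of_residue[r.start - 1], col_of_residue[r.end - 1])
    return out


def slice_region(aln: Alignment, partition: RegionPartition, region_name: str) -> Alignment:
    """Sub-alignment spanning a region's columns; all labels retained."""
    partition.region(region_name)
    start, end = map_reference_regions(aln, partition)[region_name]
    return aln.columns(list(range(start, end + 1)))


def nterm_length_profile(
    aln: Alignment, partition: RegionPartition, region_name: str = "nterm"
) -> tuple[dict[str, int], dict[str, float]]:
    """Ungapped residue count per sequence within the N-terminal region.

    A count of 0 marks sequences in which the region is totally missing.
    Returns (per-sequence counts, {min, max, median}).
    """
    sub = slice_region(aln, partition, region_name)
    counts = {
        label: sum(1 for ch in seq if ch != aligndist.GAP) for label, seq in sub.records
    }
    vals = np.array(list(counts.values()))
    stats = {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "median": float(np.median(vals)),
    }
    return counts, stats


def region_rate_ratio(
    aln: Alignment,
    partition: RegionPartition,
    region_a: str,
    region_b: str,
    root_tip: str,
    model: str = "jc20",
    mode: str = "nj",
    max_capped_fraction: float = 0.2,
    min_overlap: int = aligndist.DEFAULT_MIN_OVERLAP,
) -> tuple[list[RelativeDistanceRecord], BoxSummary]:
    """Per-tip ratio of evolutionary rates between two alignment regions.

    ``nj`` mode builds a per-region distance matrix and NJ tree, then takes
    K = patristic(root_tip, tip) on each; ``direct`` mode takes K as the
    corrected pairwise distance root_tip-to-tip within the region columns
    (more stable for short regions where NJ is noisy).
    """
    if mode not in ("nj", "direct"):
        raise ValidationError(f"unknown mode {mode!r}")
    ks: dict[str, dict[str, float]] = {}
    for region in (region_a, region_b):
        sub = slice_region(aln, partition, region)
        if mode == "nj":
            dm = distance_matrix(sub, model=model, min_overlap=min_overlap)
            if dm.capped_fraction > max_capped_fraction:
                raise ReliabilityError(
                    f"region {region!r}: {dm.capped_fraction:.0%} of pairs "
                    f"saturation-capped (limit {max_capped_fraction:.0%})"
                )
            tree = neighbor_joining(dm)
            ks[region] = {
                tip: tree.patristic(root_tip, tip)
                for tip in sub.labels()
                if tip != root_tip
            }
        else:
            ks[region] = {}
            for tip in sub.labels():
                if tip == root_tip:
                    continue
                est = p_distance(sub, root_tip, tip, min_overlap=min_overlap)
                ks[region][tip] = correct_distance(est, model=model)
    records = []
    for tip in sorted(ks[region_a]):
        ka, kb = ks[region_a][tip], ks[region_b][tip]
        if kb == 0.0:
            raise ComputationError(f"tip {tip!r}: region {region_b!r} rate is zero")
        records.append(
            RelativeDistanceRecord(tip=tip, K_protein=ka, K_marker=kb, ratio=ka / kb)
        )
    return records, summarize([r.ratio for r in records])


@dataclass
class ConservationProfile:
    consensus: str            # one char per column ('-' for gap-majority columns)
    levels: list[list[int]]   # per record, per column: 2 / 1 / 0
    labels: list[str]

    def to_tsv(self) -> str:
        lines = ["label\t" + "\t".join(self.consensus)]
        for label, row in zip(self.labels, self.levels):
            lines.append(label + "\t" + "\t".join(str(v) for v in row))
        return "\n".join(lines) + "\n"


def conservation_profile(aln: Alignment) -> ConservationProfile:
    """Consensus-match / positive-BLOSUM62 / other classification per cell."""
    if aln.alphabet != "protein":
        raise AlphabetError("conservation profiling requires a protein alignment")
    ncol = aln.length
    seqs = [seq for _, seq in aln.records]
    consensus_chars = []
    for c in range(ncol):
        column = [s[c] for s in seqs]
        gaps = sum(1 for ch in column if ch == aligndist.GAP)
        if gaps * 2 >= len(column):
            consensus_chars.append(aligndist.GAP)
            continue
        counts: dict[str, int] = {}
        for ch in column:
            if ch != aligndist.GAP:
                counts[ch] = counts.get(ch, 0) + 1
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        # alphabetical tie-break among equally frequent residues
        top = min(ch for ch, k in counts.items() if k == best[1])
        consensus_chars.append(top)
    consensus = "".join(consensus_chars)
    levels = []
    for seq in seqs:
        row = []
        for c in range(ncol):
            ch, cons = seq[c], consensus[c]
            if cons == aligndist.GAP or ch == aligndist.GAP:
                row.append(0)
            elif ch == cons:
                row.append(2)
            elif blosum62(ch, cons) > 0:
                row.append(1)
            else:
                row.append(0)
        levels.append(row)
    return ConservationProfile(consensus=consensus, levels=levels, labels=aln.labels())
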