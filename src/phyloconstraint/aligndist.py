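"""Alignment I/O, corrected evolutionary distances, and neighbor joining.

The distance corrections are the equal-rates closed forms:

* ``poisson``:  d = -ln(1 - p)
* ``jc20`` (amino acids):  d = -(19/20) ln(1 - (20/19) p)
* ``jc69`` (nucleotides):  d = -(3/4) ln(1 - (4/3) p)

``jc20`` is the default protein model because the bundled sequence simulator
uses a 20-state equal-rates substitution process, making estimator and
generator mutually consistent.  Pairs at or beyond a model's saturation
bound are capped (default 5.0 substitutions/site) with a logged warning.

Neighbor joining (Saitou–Nei Q criterion) is provided as a self-contained
stand-in for external ML tree inference: on an exactly tree-additive matrix
it recovers the generating topology and branch lengths.  Ties in Q are
broken toward the lexicographically smallest pair of cluster representative
labels so trees are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    AlphabetError,
    InsufficientOverlapError,
    UnknownLabelError,
    ValidationError,
)
from .treeio import Node, PhyloTree

logger = logging.getLogger(__name__)

PROTEIN_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDE_RESIDUES = set("ACGT")
GAP = "-"
PROTEIN_AMBIGUOUS = set("X")
NUCLEOTIDE_AMBIGUOUS = set("N")

DEFAULT_MIN_OVERLAP = 10
DEFAULT_SATURATION_CAP = 5.0

# p at which each correction saturates
_SATURATION_BOUND = {"poisson": 1.0, "jc20": 19.0 / 20.0, "jc69": 3.0 / 4.0}


@dataclass
class Alignment:
    """Equal-length labeled sequences over a declared alphabet."""

    records: list[tuple[str, str]]
    alphabet: str  # "protein" | "nucleotide"

    def __post_init__(self) -> None:
        if self.alphabet not in ("protein", "nucleotide"):
            raise AlphabetError(f"unknown alphabet {self.alphabet!r}")
        if not self.records:
            raise AlignmentError("alignment has no records")
        labels = set()
        length = len(self.records[0][1])
        allowed = self._allowed()
        norm: list[tuple[str, str]] = []
        for label, seq in self.records:
            seq = seq.upper()
            if label in labels:
                raise AlignmentError(f"duplicate record label {label!r}")
            labels.add(label)
            if len(seq) != length:
                raise AlignmentError(
                    f"record {label!r} has length {len(seq)}, expected {length}"
                )
            for pos, ch in enumerate(seq):
                if ch not in allowed:
                    raise AlignmentError(
                        f"record {label!r}: invalid {self.alphabet} residue {ch!r} "
                        f"at column {pos + 1}"
                    )
            norm.append((label, seq))
        self.records = norm
        self._index = {label: i for i, (label, _) in enumerate(self.records)}

    def _allowed(self) -> set[str]:
        if self.alphabet == "protein":
            return PROTEIN_RESIDUES | PROTEIN_AMBIGUOUS | {GAP}
        return NUCLEOTIDE_RESIDUES | NUCLEOTIDE_AMBIGUOUS | {GAP}

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def labels(self) -> list[str]:
        return [label for label, _ in self.records]

    def sequence(self, label: str) -> str:
        try:
            return self.records[self._index[label]][1]
        except KeyError:
            raise UnknownLabelError(f"no record labeled {label!r}") from None

    def columns(self, col_indices: list[int]) -> "Alignment":
        """Sub-alignment of the given 0-based columns, labels retained."""
        recs = [(lab, "".join(seq[c] for c in col_indices)) for lab, seq in self.records]
        return Alignment(recs, self.alphabet)


@dataclass
class DistanceEstimate:
    p: float
    n_sites: int
    d: float | None = None
    model: str | None = None
    capped: bool = False


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    capped_pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, rtol=0, atol=0):
            raise ValidationError("distance matrix must be exactly symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise ValidationError("distance matrix entries must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    @property
    def capped_fraction(self) -> float:
        n = len(self.labels)
        n_pairs = n * (n - 1) // 2
        return len(self.capped_pairs) / n_pairs if n_pairs else 0.0

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "  " + "  ".join(format(v, ".8f") for v in row))
        return "\n".join(lines) + "\n"

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab + "\t" + "\t".join(format(v, ".10g") for v in row))
        return "\n".join(lines) + "\n"


# -- FASTA I/O -------------------------------------------------------------------------


def read_fasta_alignment(path, alphabet: str = "protein") -> Alignment:
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    lengths = {len(seq) for _, seq in records}
    if len(lengths) > 1:
        bad = next(
            lab for lab, seq in records if len(seq) != len(records[0][1])
        )
        raise AlignmentError(
            f"{path}: ragged alignment; record {bad!r} differs in length"
        )
    return Alignment(records, alphabet)


def write_fasta_alignment(aln: Alignment, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=label, description="") for label, seq in aln.records
    ]
    SeqIO.write(recs, str(path), "fasta")


# -- distances -------------------------------------------------------------------------


def _skip_chars(alphabet: str) -> set[str]:
    if alphabet == "protein":
        return PROTEIN_AMBIGUOUS | {GAP}
    return NUCLEOTIDE_AMBIGUOUS | {GAP}


def p_distance(
    aln: Alignment, i: str, j: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceEstimate:
    """Proportion of differing sites under pairwise deletion.

    Columns where either sequence has a gap or ambiguity character are
    excluded from the comparison.
    """
    a, b = aln.sequence(i), aln.sequence(j)
    skip = _skip_chars(aln.alphabet)
    n = diff = 0
    for ca, cb in zip(a, b):
        if ca in skip or cb in skip:
            continue
        n += 1
        if ca != cb:
            diff += 1
    if n < min_overlap:
        raise InsufficientOverlapError(
            f"pair ({i!r}, {j!r}): only {n} comparable columns (minimum {min_overlap})"
        )
    return DistanceEstimate(p=diff / n, n_sites=n)


def correct_distance(
    est: DistanceEstimate,
    model: str = "jc20",
    saturation_cap: float = DEFAULT_SATURATION_CAP,
) -> float:
    """Closed-form distance correction; saturated pairs capped, never dropped."""
    if model not in _SATURATION_BOUND:
        raise ValidationError(f"unknown distance model {model!r}")
    p = est.p
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    bound = _SATURATION_BOUND[model]
    if p == 0.0:
        d = 0.0
    elif p >= bound:
        d = math.inf
    elif model == "poisson":
        d = -math.log1p(-p)
    elif model == "jc20":
        d = -(19.0 / 20.0) * math.log1p(-(20.0 / 19.0) * p)
    else:  # jc69
        d = -(3.0 / 4.0) * math.log1p(-(4.0 / 3.0) * p)
    if d > saturation_cap:
        warnings.warn(
            f"distance saturated under {model} (p={p:.4f}); capped at {saturation_cap}",
            stacklevel=2,
        )
        est.capped = True
        d = saturation_cap
    est.d = d
    est.model = model
    return d


def distance_matrix(
    aln: Alignment,
    model: str = "jc20",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    saturation_cap: float = DEFAULT_SATURATION_CAP,
) -> DistanceMatrix:
    labels = aln.labels()
    if len(labels) < 3:
        raise ValidationError("distance_matrix requires at least 3 sequences")
    n = len(labels)
    values = np.zeros((n, n))
    capped: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            try:
                est = p_distance(aln, labels[i], labels[j], min_overlap=min_overlap)
            except InsufficientOverlapError as exc:
                raise InsufficientOverlapError(
                    f"pair ({labels[i]!r}, {labels[j]!r}): {exc}"
                ) from exc
            d = correct_distance(est, model=model, saturation_cap=saturation_cap)
            if est.capped:
                capped.add((labels[i], labels[j]))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values, capped)


# -- neighbor joining ------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining; returns an unrooted tree.

    Clusters are keyed by their smallest member tip label; among equal Q
    minima the lexicographically smallest (key_i, key_j) pair is joined.
    Negative branch-length estimates are clamped to 0 with the deficit moved
    to the sibling branch (their sum is preserved).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")

    D = dm.values.astype(float).copy()
    nodes: dict[int, Node] = {}
    next_id = 0
    # active cluster: (representative key, node id)
    active: list[tuple[str, int]] = []
    for label in dm.labels:
        nodes[next_id] = Node(next_id, None, [], None, label)
        active.append((label, next_id))
        next_id += 1
    index = {nid: k for k, (_, nid) in enumerate(active)}  # row in D

    def clamp_pair(la: float, lb: float) -> tuple[float, float]:
        # clamp a negative estimate to 0, moving the deficit to the sibling
        # so that la + lb (the joined distance) is preserved
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return max(la, 0.0), max(lb, 0.0)

    while len(active) > 3:
        m = len(active)
        rows = [index[nid] for _, nid in active]
        sub = D[np.ix_(rows, rows)]
        r = sub.sum(axis=1)
        # evaluate Q on the upper triangle only: the naive broadcast form is
        # not exactly symmetric in floating point, which breaks tie detection
        qvals = {
            (i, j): (m - 2) * sub[i, j] - r[i] - r[j]
            for i in range(m)
            for j in range(i + 1, m)
        }
        qmin = min(qvals.values())
        # all argmins, tie-broken by representative label pair
        cands = []
        for (i, j), qv in qvals.items():
            if qv == qmin:
                ki, kj = active[i][0], active[j][0]
                pair = (ki, kj) if ki < kj else (kj, ki)
                cands.append((pair, i, j))
        _, i, j = min(cands)
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        ni, nj = active[i][1], active[j][1]
        new = Node(next_id, None, [ni, nj], None, None)
        nodes[next_id] = new
        nodes[ni].parent = next_id
        nodes[ni].length = li
        nodes[nj].parent = next_id
        nodes[nj].length = lj
        # distances from the new cluster to the others
        new_row = np.zeros(len(D) + 1)
        grown = np.zeros((len(D) + 1, len(D) + 1))
        grown[: len(D), : len(D)] = D
        D = grown
        ri, rj = index[ni], index[nj]
        for _, nid in active:
            if nid in (ni, nj):
                continue
            rk = index[nid]
            D[-1, rk] = D[rk, -1] = 0.5 * (D[ri, rk] + D[rj, rk] - dij)
        key = min(active[i][0], active[j][0])
        active = [(k, nid) for k, nid in active if nid not in (ni, nj)]
        active.append((key, next_id))
        active.sort()
        index[next_id] = len(D) - 1
        next_id += 1

    # resolve the final three clusters around a central node
    (ka, na), (kb, nb), (kc, nc) = sorted(active)
    ra, rb, rc = index[na], index[nb], index[nc]
    dab, dac, dbc = D[ra, rb], D[ra, rc], D[rb, rc]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    center = Node(next_id, None, [na, nb, nc], None, None)
    nodes[next_id] = center
    for nid, length in ((na, la), (nb, lb), (nc, lc)):
        nodes[nid].parent = next_id
        nodes[nid].length = length
    return PhyloTree(nodes, next_id, rooted=False)
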