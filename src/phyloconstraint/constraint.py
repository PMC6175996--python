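"""Lineage-constraint statistics on phylogenies.

Two statistics quantify lineage-specific evolutionary constraint on a
protein:

* **Lineage contribution ratio** — for each tip of a lineage, the fraction
  of its divergence from a fixed reference node that accrued *within* the
  lineage: ratio = (reference distance - d(reference node, lineage MRCA))
  / reference distance.  The lineage MRCA's own stem branch is excluded
  from the lineage distances: divergence "during lineage expansion" starts
  at the clade's origin node.

* **Relative distance ratio** — K_protein / K_marker, where K is the
  patristic distance from a designated basal tip (e.g. *Gloeobacter*) to
  each tip, measured on the protein tree and on an independently evolving
  marker tree (e.g. concatenated rRNAs).  The marker normalizes protein
  divergence by overall species divergence.

Clades are compared on these per-tip ratios with the Wilcoxon–Mann–Whitney
test; distributions are summarized with median/quartile/5-95 percentile
boxes (linear-interpolation percentiles, numpy default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import ranktest
from .errors import ComputationError, TopologyError, UnknownLabelError
from .ranktest import RankTestResult
from .treeio import NodeRef, PhyloTree

logger = logging.getLogger(__name__)


@dataclass
class LineageContributionRecord:
    tip: str
    reference_distance: float
    lineage_distance: float
    ratio: float


@dataclass
class RelativeDistanceRecord:
    tip: str
    K_protein: float
    K_marker: float
    ratio: float


@dataclass
class BoxSummary:
    median: float
    p25: float
    p75: float
    p05: float
    p95: float
    n: int


def resolve_reference_node(tree: PhyloTree, reference_tips: Iterable[str]) -> NodeRef:
    """MRCA of the reference tips (e.g. the branching point of the
    Yellowstone *Synechococcus* strains)."""
    tips = set(reference_tips)
    missing = [t for t in tips if t not in set(tree.tip_labels())]
    if missing:
        raise UnknownLabelError(f"reference tips absent from tree: {sorted(missing)}")
    ref = tree.mrca(tips)
    logger.info(
        "reference node %s at distance %.6g from root",
        ref.node_id,
        tree.depths()[ref.node_id],
    )
    return ref


def lineage_contribution(
    tree: PhyloTree,
    reference_tips: Iterable[str],
    lineage_tips: Iterable[str],
) -> list[LineageContributionRecord]:
    """Per-tip contribution of a lineage expansion to sequence divergence.

    For every lineage tip: reference_distance = d(reference node, tip);
    lineage_distance = reference_distance - d(reference node, lineage MRCA);
    ratio = lineage_distance / reference_distance.
    """
    lineage = sorted(set(lineage_tips))
    if not lineage:
        raise ComputationError("lineage tip set is empty")
    ref = resolve_reference_node(tree, reference_tips)
    lmrca = tree.mrca(lineage)
    # the reference node must be the lineage MRCA or one of its ancestors
    if ref.node_id not in tree.ancestor_path(lmrca.node_id):
        raise TopologyError(
            "reference node is not ancestral to the lineage MRCA; "
            "the lineage-distance subtraction is undefined"
        )
    stem = tree.node_distance(ref.node_id, lmrca.node_id)
    records = []
    for tip in lineage:
        refd = tree.node_distance(ref.node_id, tree.tip_id(tip))
        if refd == 0.0:
            raise ComputationError(
                f"tip {tip!r} has zero distance from the reference node; "
                "contribution ratio undefined"
            )
        lind = refd - stem
        records.append(
            LineageContributionRecord(
                tip=tip,
                reference_distance=refd,
                lineage_distance=lind,
                ratio=lind / refd,
            )
        )
    return records


def relative_distance_ratios(
    protein_tree: PhyloTree,
    marker_tree: PhyloTree,
    root_tip: str,
    tips: Iterable[str] | None = None,
    aliases: dict[str, str] | None = None,
) -> list[RelativeDistanceRecord]:
    """K_protein/K_marker per tip, both measured from a basal tip.

    ``aliases`` maps protein-tree tip labels to marker-tree labels where
    naming drifts between datasets; matching is otherwise exact after
    whitespace trimming.
    """
    aliases = aliases or {}
    prot_tips = {t.strip(): t for t in protein_tree.tip_labels()}
    mark_tips = {t.strip(): t for t in marker_tree.tip_labels()}
    rt = root_tip.strip()
    rt_marker = aliases.get(rt, rt)
    if rt not in prot_tips:
        raise UnknownLabelError(f"root tip {rt!r} absent from protein tree")
    if rt_marker not in mark_tips:
        raise UnknownLabelError(f"root tip {rt_marker!r} absent from marker tree")
    if tips is None:
        tips = [t for t in sorted(prot_tips) if t != rt]
    records = []
    for tip in sorted(set(t.strip() for t in tips)):
        marker_name = aliases.get(tip, tip)
        if tip not in prot_tips:
            raise UnknownLabelError(f"tip {tip!r} absent from protein tree")
        if marker_name not in mark_tips:
            raise UnknownLabelError(f"tip {marker_name!r} absent from marker tree")
        kp = protein_tree.patristic(prot_tips[rt], prot_tips[tip])
        km = marker_tree.patristic(mark_tips[rt_marker], mark_tips[marker_name])
        if km == 0.0:
            raise ComputationError(f"K_marker is zero for tip {tip!r}; ratio undefined")
        records.append(
            RelativeDistanceRecord(tip=tip, K_protein=kp, K_marker=km, ratio=kp / km)
        )
    return records


def compare_clades(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "two-sided",
) -> RankTestResult:
    """Wilcoxon–Mann–Whitney comparison of two clades' per-tip ratios."""
    return ranktest.wilcoxon(list(values_a), list(values_b), alternative=alternative)


def pairwise_clade_comparisons(
    clade_values: dict[str, Sequence[float]],
    alternative: str = "two-sided",
) -> list[dict]:
    """All pairwise comparisons with raw and Holm-adjusted p-values."""
    names = sorted(clade_values)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    results = [
        compare_clades(clade_values[a], clade_values[b], alternative) for a, b in pairs
    ]
    adjusted = ranktest.holm_adjust([r.p for r in results])
    return [
        {
            "clade_a": a,
            "clade_b": b,
            "U": r.U,
            "n": r.n,
            "m": r.m,
            "p": r.p,
            "p_holm": p_adj,
            "method": r.method,
        }
        for (a, b), r, p_adj in zip(pairs, results, adjusted)
    ]


def summarize(values: Sequence[float]) -> BoxSummary:
    """Median, quartiles and 5th/95th percentiles (linear interpolation)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ComputationError("cannot summarize an empty sample")
    p05, p25, med, p75, p95 = np.percentile(arr, [5, 25, 50, 75, 95])
    return BoxSummary(
        median=float(med), p25=float(p25), p75=float(p75),
        p05=float(p05), p95=float(p95), n=int(arr.size),
    )
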