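"""Replicated simulation experiments that validate the whole pipeline.

Each experiment generates data with the synthetic generator, runs the full
estimation path (simulate -> distances -> NJ -> root -> statistic), and
measures recovery of the known truth.  They are used by the test suite and
by the acceptance script; problem sizes default to the package's stated
study conditions.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass

import numpy as np

from .aligndist import distance_matrix, neighbor_joining
from .constraint import compare_clades, lineage_contribution, relative_distance_ratios
from .reannotate import screen_batch
from .regions import Region, RegionPartition, region_rate_ratio
from .synthetic_data import (
    SimulationConfig,
    apply_clade_multiplier,
    attach_outgroup,
    generate_paired_clade_tree,
    generate_yule_tree,
    make_misannotation_fixture,
    simulate_alignment,
    simulate_dataset,
)


def _child_seed(seed: int, tag: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, tag, rep)))


@dataclass
class ContributionRecovery:
    fraction_focal_below_control: float
    median_est_over_analytic: float
    n_replicates: int


def contribution_recovery_experiment(
    n_replicates: int = 100, seed: int = 0, cfg_kwargs: dict | None = None
) -> ContributionRecovery:
    """Estimate focal-clade contribution ratios from simulated alignments.

    Per replicate: simulate protein under a suppressed focal clade
    (r_clade), estimate an NJ tree, root by the outgroup, compute
    contribution ratios for focal and age-matched control clades, and
    compare the focal median against (a) the control median and (b) the
    analytic expectation r*d/((H-d)+r*d) from the true rate tree.
    """
    cfg_kwargs = dict(cfg_kwargs or {})
    below = 0
    ratios = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_replicates):
            rep_seed = int(np.random.SeedSequence((seed, 5, rep)).generate_state(1)[0] % (2**31))
            ds = simulate_dataset(SimulationConfig(seed=rep_seed, **cfg_kwargs))
            dm = distance_matrix(ds.protein, model="jc20")
            rooted = neighbor_joining(dm).root_by_outgroup({ds.config.outgroup_label})
            ingroup = set(rooted.tip_labels()) - {ds.config.outgroup_label}
            focal = lineage_contribution(rooted, ingroup, ds.truth.focal_tips)
            control = lineage_contribution(rooted, ingroup, ds.truth.control_tips)
            est = statistics.median(r.ratio for r in focal)
            analytic = statistics.median(ds.truth.expected_ratios.values())
            ratios.append(est / analytic)
            below += est < statistics.median(r.ratio for r in control)
    return ContributionRecovery(
        fraction_focal_below_control=below / n_replicates,
        median_est_over_analytic=float(statistics.median(ratios)),
        n_replicates=n_replicates,
    )


def region_rate_experiment(
    n_replicates: int = 50,
    seed: int = 0,
    n_tips: int = 24,
    tree_height: float = 0.2,
    nterm_len: int = 60,
    core_len: int = 320,
    rate_contrast: float = 4.0,
) -> dict:
    """Recover a known fast-region/slow-region rate contrast.

    Per replicate: ultrametric tree with basal outgroup, protein with an
    N-terminal region evolving ``rate_contrast`` times faster than the
    core, per-region NJ trees, per-tip K ratio from the outgroup; report
    the median of per-replicate median ratios.
    """
    partition = RegionPartition(
        [Region("nterm", 1, nterm_len), Region("core", nterm_len + 1, nterm_len + core_len)],
        "OUT",
    )
    medians = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_replicates):
            rng = _child_seed(seed, 6, rep)
            tree = attach_outgroup(
                generate_yule_tree(n_tips, tree_height, rng), "OUT", 0.25
            )
            aln, _ = simulate_alignment(
                tree,
                [("nterm", nterm_len, rate_contrast), ("core", core_len, 1.0)],
                rng,
                "protein",
            )
            _, summary = region_rate_ratio(
                aln, partition, "nterm", "core", root_tip="OUT", mode="nj"
            )
            medians.append(summary.median)
    return {
        "median_ratio": float(statistics.median(medians)),
        "true_contrast": rate_contrast,
        "n_replicates": n_replicates,
    }


def kratio_power_experiment(
    n_replicates: int = 100,
    seed: int = 0,
    r_clade: float = 0.3,
    n_per_clade: int = 8,
    alpha: float = 0.05,
    protein_regions: list[tuple[str, int, float]] | None = None,
    marker_length: int = 1500,
) -> dict:
    """Rejection rate of the focal-vs-sister Wilcoxon test on K ratios.

    The tree is a matched simultaneous radiation (two sister star clades,
    zero-length stems) so per-tip ratios are exchangeable units under the
    null; see generate_paired_clade_tree.  With r_clade = 1 this measures
    the empirical type-I error.
    """
    protein_regions = protein_regions or [("nterm", 60, 4.0), ("core", 340, 1.0)]
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_replicates):
            rng = _child_seed(seed, 7, rep)
            tree, a_tips, _ = generate_paired_clade_tree(n_per_clade)
            ptree = (
                apply_clade_multiplier(tree, a_tips, r_clade) if r_clade != 1.0 else tree
            )
            protein, _ = simulate_alignment(ptree, protein_regions, rng, "protein")
            marker, _ = simulate_alignment(
                tree, [("marker", marker_length, 1.0)], rng, "nucleotide"
            )
            pt = neighbor_joining(distance_matrix(protein, model="jc20"))
            mt = neighbor_joining(distance_matrix(marker, model="jc69"))
            recs = relative_distance_ratios(pt, mt, "OUT")
            ra = [r.ratio for r in recs if r.tip.startswith("A_")]
            rb = [r.ratio for r in recs if r.tip.startswith("B_")]
            rejections += compare_clades(ra, rb).p < alpha
    return {
        "rejection_rate": rejections / n_replicates,
        "r_clade": r_clade,
        "alpha": alpha,
        "n_replicates": n_replicates,
    }


def reannotation_screen_experiment(
    n_records: int = 200, seed: int = 0, truncation_aa_range: tuple[int, int] = (10, 40)
) -> dict:
    """Sensitivity and false-extend rate of the start-codon screen on
    fixtures with known truncations."""
    fx = make_misannotation_fixture(
        seed=seed, n_records=n_records, truncation_aa_range=truncation_aa_range
    )
    partition = RegionPartition([Region("nterm", *fx.nterm_region)], fx.reference_label)
    proposals = screen_batch(fx.records, fx.homologs, partition)
    tp = fn = fp = keeps = exact = 0
    for prop in proposals:
        truth = fx.truth[prop.id]
        if truth["verdict"] == "extend":
            if prop.verdict == "extend":
                tp += 1
                exact += prop.extension_aa == truth["extension_aa"]
            else:
                fn += 1
        else:
            keeps += 1
            fp += prop.verdict == "extend"
    return {
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "false_extend_rate": fp / keeps if keeps else float("nan"),
        "extensions_exact": exact,
        "extensions_proposed": tp,
        "n_records": n_records,
    }
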