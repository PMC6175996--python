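"""Generators for trees, rate-modified alignments, and screen fixtures.

The generative model mirrors the statistical structure the constraint
analysis assumes:

* an ultrametric species tree (pure-birth/Yule topology, branch lengths in
  expected substitutions per site at the baseline rate), optionally with a
  basal outgroup tip for rooting;
* a protein whose sites are partitioned into regions with per-region rate
  multipliers (e.g. a fast N-terminal peptide vs a slow core);
* a focal lineage whose branches — strictly below the lineage MRCA, the
  stem excluded — carry a rate multiplier ``r_clade`` on the protein only;
* an independently evolving marker locus simulated on the SAME tree at
  baseline rate (all multipliers 1).

Sequences evolve under equal-rates Markov processes (20-state for protein,
4-state for nucleotide): per site and branch, the number of substitution
events is Poisson with mean branch_length x rate multipliers, and each
event moves to a uniformly chosen different state.  These match the jc20 /
jc69 distance corrections exactly, so estimator consistency is a testable
property rather than an approximation.

One global seed drives a per-purpose seed sequence (tree, protein sites,
marker sites, fixtures) so components can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .aligndist import Alignment
from .errors import ValidationError
from .reannotate import CdsRecord, START_CODONS, STOP_CODONS, _CODON_TABLE
from .treeio import Node, PhyloTree, write_newick

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDE_ALPHABET = "ACGT"

DEFAULT_REGIONS = [("nterm", 60, 4.0), ("core", 340, 1.0)]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a deep within-phylum protein phylogeny: 16 ingroup
    tips under a basal outgroup, root-to-tip height 0.3 substitutions/site
    at baseline rate, a focal lineage covering ~1/4 of the tips whose
    protein rate is reduced to ``r_clade`` = 0.3, a 60-residue N-terminal
    region evolving 4x faster than the 340-residue core, and a 1500-nt
    marker at baseline rate.
    """

    n_tips: int = 16
    tree_height: float = 0.3
    seed: int = 0
    focal_fraction: float = 0.25
    r_clade: float = 0.3
    regions: list[tuple[str, int, float]] = field(
        default_factory=lambda: list(DEFAULT_REGIONS)
    )
    marker_length: int = 1500
    outgroup_label: str = "OUT"
    outgroup_stem_fraction: float = 0.5  # ingroup stem + outgroup branch sizing

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValidationError("n_tips must be >= 3")
        if self.r_clade <= 0:
            raise ValidationError("r_clade must be > 0")
        for name, length, mult in self.regions:
            if length < 1:
                raise ValidationError(f"region {name!r}: length must be >= 1")
            if mult <= 0:
                raise ValidationError(f"region {name!r}: multiplier must be > 0")


def _seed_sequence(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    keys = ("tree", "protein", "marker", "fixture", "misc")
    children = ss.spawn(len(keys))
    return {k: np.random.default_rng(c) for k, c in zip(keys, children)}


# -- tree generation ---------------------------------------------------------------


def generate_yule_tree(
    n_tips: int, height: float, seed: int | np.random.Generator = 0
) -> PhyloTree:
    """Ultrametric pure-birth tree; root-to-tip distance equals ``height``.

    Tips are labeled T01, T02, ... in birth order; identical seeds give
    byte-identical Newick.
    """
    if n_tips < 3:
        raise ValidationError("generate_yule_tree requires n_tips >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # the root is the first split: two lineages at time 0; thereafter split a
    # uniformly chosen extant lineage after Exp(number of lineages) waiting
    nodes: dict[int, Node] = {0: Node(0, None, [], None, None)}
    birth: dict[int, float] = {0: 0.0}
    extant: list[int] = []
    next_id = 1
    t = 0.0
    for _ in range(2):
        nodes[next_id] = Node(next_id, 0, [], None, None)
        nodes[0].children.append(next_id)
        birth[next_id] = 0.0
        extant.append(next_id)
        next_id += 1
    while len(extant) < n_tips:
        t += rng.exponential(1.0 / len(extant))
        k = int(rng.integers(len(extant)))
        parent = extant.pop(k)
        for _ in range(2):
            nodes[next_id] = Node(next_id, parent, [], None, None)
            nodes[parent].children.append(next_id)
            birth[next_id] = t
            extant.append(next_id)
            next_id += 1
    t_end = t + rng.exponential(1.0 / len(extant))
    scale = height / t_end if t_end > 0 else 0.0
    for nid, node in nodes.items():
        if node.parent is None:
            continue
        end = t_end if not node.children else birth[node.children[0]]
        node.length = (end - birth[nid]) * scale
    width = max(2, len(str(n_tips)))
    counter = 1
    for nid in sorted(nodes):
        if not nodes[nid].children:
            nodes[nid].label = f"T{counter:0{width}d}"
            counter += 1
    return PhyloTree(nodes, 0, rooted=True)


def attach_outgroup(
    tree: PhyloTree, label: str = "OUT", stem_fraction: float = 0.5
) -> PhyloTree:
    """New root above the ingroup with a basal outgroup tip.

    The ingroup (height h) hangs from a stem of ``stem_fraction * h``; the
    outgroup branch has length h * (1 + stem_fraction) so the whole tree
    stays ultrametric.
    """
    tree = tree.copy()
    h = max(tree.depths().values())
    stem = stem_fraction * h
    new_root = max(tree.nodes) + 1
    og = new_root + 1
    old_root = tree.nodes[tree.root_id]
    old_root.parent = new_root
    old_root.length = stem
    tree.nodes[new_root] = Node(new_root, None, [og, tree.root_id], None, None)
    tree.nodes[og] = Node(og, new_root, [], h + stem, label)
    return PhyloTree(tree.nodes, new_root, rooted=True)


def pick_focal_clade(tree: PhyloTree, fraction: float, exclude: set[str] | None = None) -> frozenset[str]:
    """Internal-node tip set whose size is closest to fraction * n_tips.

    Deterministic: ties resolve toward the lexicographically smallest tip
    set. ``exclude`` bars clades containing those labels (e.g. the outgroup).
    """
    exclude = exclude or set()
    n = tree.n_tips() - len(exclude)
    target = max(2, round(fraction * n))
    best: tuple[int, tuple, frozenset] | None = None
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.is_tip or nid == tree.root_id:
            continue
        ts = tree.tipset(nid)
        if ts & exclude or len(ts) >= n:
            continue
        key = (abs(len(ts) - target), tuple(sorted(ts)))
        if best is None or key < best[:2]:
            best = (key[0], key[1], ts)
    if best is None:
        raise ValidationError("tree has no internal clade to use as focal lineage")
    return best[2]


def apply_clade_multiplier(
    tree: PhyloTree, focal_tips: Sequence[str], r_clade: float
) -> PhyloTree:
    """Annotate branches strictly below the focal MRCA with ``r_clade``.

    The MRCA's own stem branch keeps multiplier 1, mirroring the convention
    that lineage expansion starts at the clade's origin node.
    """
    focal = frozenset(focal_tips)
    out = tree.copy()
    mrca = out.mrca(focal)
    if out.tipset(mrca.node_id) != focal:
        raise ValidationError(
            f"focal tips are not monophyletic: clade of their MRCA is "
            f"{sorted(out.tipset(mrca.node_id))}"
        )
    stack = list(out.nodes[mrca.node_id].children)
    while stack:
        nid = stack.pop()
        out.nodes[nid].rate = r_clade
        stack.extend(out.nodes[nid].children)
    return out


# -- sequence simulation ------------------------------------------------------------


def simulate_alignment(
    rate_tree: PhyloTree,
    regions: Sequence[tuple[str, int, float]],
    seed: int | np.random.Generator = 0,
    alphabet: str = "protein",
) -> tuple[Alignment, str]:
    """Simulate sequences down a rate-annotated tree.

    Per branch and region, the per-site expected substitution count is
    branch_length x branch rate multiplier x region multiplier.  Returns
    the tip alignment and the root sequence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    letters = PROTEIN_ALPHABET if alphabet == "protein" else NUCLEOTIDE_ALPHABET
    n_states = len(letters)
    lengths = [length for _, length, _ in regions]
    mults = np.concatenate(
        [np.full(length, mult) for _, length, mult in regions]
    )
    total = int(sum(lengths))
    root_states = rng.integers(0, n_states, size=total)
    states: dict[int, np.ndarray] = {rate_tree.root_id: root_states}
    for nid in rate_tree.preorder():
        if nid == rate_tree.root_id:
            continue
        node = rate_tree.nodes[nid]
        parent_states = states[node.parent]
        mean = (node.length or 0.0) * node.rate * mults
        child = parent_states.copy()
        n_events = rng.poisson(mean)
        hot = np.nonzero(n_events)[0]
        for site in hot:
            s = child[site]
            for _ in range(int(n_events[site])):
                s = (s + rng.integers(1, n_states)) % n_states
            child[site] = s
        states[nid] = child
    records = []
    for nid in rate_tree.preorder():
        node = rate_tree.nodes[nid]
        if node.is_tip:
            records.append((node.label, "".join(letters[s] for s in states[nid])))
    root_seq = "".join(letters[s] for s in root_states)
    return Alignment(records, alphabet), root_seq


# -- whole datasets ------------------------------------------------------------------


@dataclass
class SimulationTruth:
    seed: int
    true_tree: PhyloTree
    focal_tips: list[str]
    control_tips: list[str]
    r_clade: float
    regions: list[tuple[str, int, float]]
    expected_ratios: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "true_tree": write_newick(self.true_tree),
                "focal_tips": self.focal_tips,
                "control_tips": self.control_tips,
                "r_clade": self.r_clade,
                "regions": [list(r) for r in self.regions],
                "expected_ratios": self.expected_ratios,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    species_tree: PhyloTree       # baseline-rate tree, outgroup attached
    protein_rate_tree: PhyloTree  # clade multiplier applied
    protein: Alignment
    marker: Alignment
    truth: SimulationTruth


def expected_contribution_ratio(
    rate_tree: PhyloTree, reference_node_id: int, focal_mrca_id: int, tip_label: str
) -> float:
    """Analytic expected contribution ratio from a rate-annotated true tree.

    With baseline stem distance g = d(reference, MRCA) and within-lineage
    tip depth d at multiplier r, the expectation is r*d / (g + r*d); on a
    clock tree of height H from the reference this is r*d/((H-d) + r*d).
    """
    tid = rate_tree.tip_id(tip_label)
    # rate-weighted distances
    def weighted(a: int, b: int) -> float:
        m = rate_tree._mrca_ids([a, b])
        total = 0.0
        for start in (a, b):
            cur = start
            while cur != m:
                node = rate_tree.nodes[cur]
                total += (node.length or 0.0) * node.rate
                cur = node.parent
        return total

    g = weighted(reference_node_id, focal_mrca_id)
    rd = weighted(focal_mrca_id, tid)
    return rd / (g + rd)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate one protein + marker dataset with its truth record."""
    rngs = _seed_sequence(cfg.seed)
    ingroup = generate_yule_tree(cfg.n_tips, cfg.tree_height, rngs["tree"])
    tree = attach_outgroup(ingroup, cfg.outgroup_label, cfg.outgroup_stem_fraction)
    focal = pick_focal_clade(tree, cfg.focal_fraction, exclude={cfg.outgroup_label})
    control = _pick_control_clade(tree, focal, cfg.outgroup_label)
    prot_tree = apply_clade_multiplier(tree, focal, cfg.r_clade)
    protein, _ = simulate_alignment(prot_tree, cfg.regions, rngs["protein"], "protein")
    marker, _ = simulate_alignment(
        tree, [("marker", cfg.marker_length, 1.0)], rngs["marker"], "nucleotide"
    )
    ref_id = tree.mrca(set(tree.tip_labels()) - {cfg.outgroup_label}).node_id
    focal_mrca = prot_tree.mrca(focal).node_id
    expected = {
        tip: expected_contribution_ratio(prot_tree, ref_id, focal_mrca, tip)
        for tip in sorted(focal)
    }
    truth = SimulationTruth(
        seed=cfg.seed,
        true_tree=prot_tree,
        focal_tips=sorted(focal),
        control_tips=sorted(control),
        r_clade=cfg.r_clade,
        regions=list(cfg.regions),
        expected_ratios=expected,
    )
    return SimulatedDataset(cfg, tree, prot_tree, protein, marker, truth)


def _pick_control_clade(
    tree: PhyloTree, focal: frozenset[str], outgroup_label: str
) -> frozenset[str]:
    """Control lineage for the focal clade: disjoint from it (and the
    outgroup), matched on clade age first, then size.

    Age matching matters: a much younger control clade has a small
    contribution ratio regardless of rates, which would confound the
    focal-vs-control contrast the experiment is designed to expose.
    """
    best = None
    target = len(focal)
    n = tree.n_tips() - 1
    depths = tree.depths()
    focal_depth = depths[tree.mrca(focal).node_id]
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.is_tip or nid == tree.root_id:
            continue
        ts = tree.tipset(nid)
        if ts & focal or outgroup_label in ts or len(ts) >= n:
            continue
        key = (abs(depths[nid] - focal_depth), abs(len(ts) - target), tuple(sorted(ts)))
        if best is None or key < best[0]:
            best = (key, ts)
    if best is None:
        # fall back to the non-focal, non-outgroup tips as a paraphyletic control
        return frozenset(set(tree.tip_labels()) - focal - {outgroup_label})
    return best[1]


def generate_paired_clade_tree(
    n_per_clade: int,
    clade_height: float = 0.25,
    stem: float = 0.0,
    join_depth: float = 0.05,
    outgroup_label: str = "OUT",
) -> tuple[PhyloTree, frozenset[str], frozenset[str]]:
    """Two sister radiations of equal size under a basal outgroup.

    Each clade is a simultaneous radiation (star) of ``n_per_clade`` tips at
    depth ``clade_height`` below its origin; the two origins sit on sister
    stems of length ``stem`` (default 0: the clades split and radiate at
    once).  This matched design gives every tip its own independent
    evolutionary history below the split, so rank tests comparing per-tip
    statistics between the clades see exchangeable units: a long shared
    clade stem would act as a single random draw common to all of a clade's
    tips and confound the comparison.  Tips are prefixed A_/B_; returns
    (tree, clade A tips, clade B tips).  Deterministic (no randomness).
    """
    nodes: dict[int, Node] = {}
    root, join = 0, 1
    nodes[root] = Node(root, None, [join], None, None)
    nodes[join] = Node(join, root, [], join_depth, None)
    nid = 2
    for prefix in ("A", "B"):
        clade_root = nid
        nid += 1
        nodes[clade_root] = Node(clade_root, join, [], stem, None)
        nodes[join].children.append(clade_root)
        for k in range(n_per_clade):
            nodes[nid] = Node(nid, clade_root, [], clade_height, f"{prefix}_{k + 1:02d}")
            nodes[clade_root].children.append(nid)
            nid += 1
    h_in = join_depth + stem + clade_height
    nodes[nid] = Node(nid, root, [], h_in, outgroup_label)
    nodes[root].children.append(nid)
    tree = PhyloTree(nodes, root, rooted=True)
    a_tips = frozenset(t for t in tree.tip_labels() if t.startswith("A_"))
    b_tips = frozenset(t for t in tree.tip_labels() if t.startswith("B_"))
    return tree, a_tips, b_tips


# -- misannotation fixtures -----------------------------------------------------------

_AA_TO_CODON = {aa: codon for codon, aa in _CODON_TABLE.items() if aa != "*"}
# fix codon choices so that only Met codes ATG and no Val/Leu uses GTG/TTG:
# candidate starts inside fixture ORFs then correspond to Met positions only
_AA_TO_CODON.update({"M": "ATG", "V": "GTT", "L": "CTG"})

_SAFE_PAD_CODONS = [
    c for c, aa in _CODON_TABLE.items()
    if aa != "*" and c not in START_CODONS and c not in STOP_CODONS
]


@dataclass
class MisannotationFixture:
    records: list[CdsRecord]
    homologs: Alignment           # true peptides, N-termini flush right to the core
    reference_label: str
    nterm_region: tuple[int, int]  # 1-based residue range on the reference
    truth: dict[str, dict]        # id -> {"verdict": keep|extend, "extension_aa": int}


def _mutate(peptide: str, rate: float, rng: np.random.Generator, forbid: str = "") -> str:
    out = list(peptide)
    alphabet = [a for a in PROTEIN_ALPHABET if a not in forbid]
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in alphabet if a != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def reverse_translate(peptide: str) -> str:
    return "".join(_AA_TO_CODON[aa] for aa in peptide)


def make_misannotation_fixture(
    seed: int = 0,
    n_records: int = 50,
    truncation_aa_range: tuple[int, int] = (10, 40),
    truncated_fraction: float = 0.5,
    nterm_len_range: tuple[int, int] = (50, 60),
    core_len: int = 120,
    divergence: float = 0.1,
) -> MisannotationFixture:
    """A homolog family with known start-codon truncations.

    Each record derives from a shared ancestral N-terminal peptide + core
    (point mutations at ``divergence`` per site; N-terminal lengths vary by
    trimming the ancestral peptide's left edge).  A ``truncated_fraction``
    of records have their annotated start moved downstream by a known
    amount, the true start surviving in the upstream context.  Mutations
    never introduce Met in the N-terminal region, so the true extension is
    the unique in-frame candidate by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    lo, hi = truncation_aa_range
    nlo, nhi = nterm_len_range
    if lo < 1 or hi + 5 > nlo:
        raise ValidationError(
            "truncations must fit inside the N-terminal region (need "
            f"max truncation + 5 <= min N-terminal length, got {hi}+5 > {nlo})"
        )
    anc_nterm = "M" + "".join(
        PROTEIN_ALPHABET[i]
        for i in rng.integers(0, 20, size=nhi - 1)
    )
    anc_nterm = anc_nterm[0] + anc_nterm[1:].replace("M", "A")
    anc_core = "".join(PROTEIN_ALPHABET[i] for i in rng.integers(0, 20, size=core_len))

    records: list[CdsRecord] = []
    homolog_rows: list[tuple[str, str]] = []
    truth: dict[str, dict] = {}
    n_trunc = int(round(n_records * truncated_fraction))
    for k in range(n_records):
        rid = f"R{k + 1:03d}"
        # the last record is always full length so a gapless reference exists
        n_len = nhi if k == n_records - 1 else int(rng.integers(nlo, nhi + 1))
        nterm = "M" + _mutate(anc_nterm[nhi - n_len + 1 :], divergence, rng, forbid="M")
        core = _mutate(anc_core, divergence / 2.0, rng)
        homolog_rows.append((rid, "-" * (nhi - n_len) + nterm + core))
        truncate = k < n_trunc
        if truncate:
            t = int(rng.integers(lo, hi + 1))
            annotated_pep = "M" + nterm[t + 1 :] + core
            cds = reverse_translate(annotated_pep) + "TAA"
            true_ext_codons = reverse_translate(nterm[:t])
            pad = "".join(
                _SAFE_PAD_CODONS[int(rng.integers(len(_SAFE_PAD_CODONS)))]
                for _ in range(6)
            )
            upstream = pad + "TAA" + true_ext_codons
            truth[rid] = {"verdict": "extend", "extension_aa": t}
        else:
            cds = reverse_translate(nterm + core) + "TAA"
            pad = [
                _SAFE_PAD_CODONS[int(rng.integers(len(_SAFE_PAD_CODONS)))]
                for _ in range(12)
            ]
            if k % 2 == 0:
                # half the keep records carry a spurious in-frame start whose
                # extension is random peptide: the screen must reject it
                junk = "ATG" + "".join(pad[6:11])
                upstream = "".join(pad[:5]) + "TAA" + junk
            else:
                upstream = "".join(pad[:6]) + "TAA" + "".join(pad[6:])
            truth[rid] = {"verdict": "keep", "extension_aa": 0}
        records.append(CdsRecord(id=rid, cds=cds, upstream=upstream))
    homologs = Alignment(homolog_rows, "protein")
    # reference: a gapless (full N-terminal length) homolog, so region 1..nhi maps
    reference_label = next(lab for lab, seq in homolog_rows if "-" not in seq)
    return MisannotationFixture(
        records=records,
        homologs=homologs,
        reference_label=reference_label,
        nterm_region=(1, nhi),
        truth=truth,
    )
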