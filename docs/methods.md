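# Methods

## The statistics

### Lineage contribution ratio

All distance work reduces to patristic path sums on trees with branch
lengths in expected substitutions per site.  For a rooted tree, a
*reference node* R (the MRCA of a configured tip set, chosen to be present
in every tree under comparison) and a *lineage* with MRCA M, each lineage
tip t contributes one record:

    reference_distance = d(R, t)
    lineage_distance   = d(R, t) − d(R, M)
    ratio              = lineage_distance / reference_distance

The subtraction removes the divergence shared by the whole lineage; what
remains is the divergence accumulated during the lineage's own radiation.
Two conventions are fixed here:

* **Stem exclusion.**  The lineage MRCA's stem branch is *not* part of the
  lineage distance — expansion begins at the clade's origin node.  The
  synthetic generator applies clade rate multipliers with the same
  convention, so analytic expectations are exact.
* R must be M or one of its ancestors; otherwise the subtraction has no
  meaning and the operation raises a topology error.

With non-negative branch lengths the ratio lies in [0, 1], equals 1 when
M = R, 0 for a single-tip lineage, and is invariant under rescaling all
branch lengths.  On an ultrametric tree of height H from R with M at depth
H−d and a within-lineage rate multiplier r on the protein, the expected
estimated ratio is r·d/((H−d) + r·d); this closed form is used as the
recovery target in simulation tests.

### Relative genetic distances

K_protein/K_marker per tip, with K = patristic distance from a designated
basal tip (the rooting taxon; "OUT" in simulations) to the tip, measured on
the protein tree and on an independently evolving marker tree.  The marker
(in practice concatenated rRNAs) sets the expected pace of neutral species
divergence; a clade whose protein ratios sit below its sister's indicates
protein-specific constraint.  Tip labels are matched exactly after
whitespace trimming; a config alias map absorbs naming drift between
protein and marker datasets.

### Rank test

Self-contained Wilcoxon–Mann–Whitney.  U is reported for the first sample
with midranks for ties.  For n+m ≤ 20 the p-value is exact: all C(n+m, n)
assignments of the pooled values are enumerated (ties handled by
construction); two-sided p = min(1, 2·min(P≤, P≥)), the doubling
convention.  Larger samples use the normal approximation with tie-corrected
variance and continuity correction 0.5; all pooled values identical yields
p = 1 with a warning.  When more than two clades are compared pairwise,
raw and Holm-adjusted p-values are reported.

### Distances and neighbor joining

Pairwise p-distances use pairwise deletion (columns with a gap or
ambiguity character in either sequence are excluded; fewer than 10
comparable columns is an error).  Corrections:

* poisson: d = −ln(1−p)
* jc20 (amino acids, 20-state equal rates): d = −(19/20)·ln(1−(20/19)·p)
* jc69 (nucleotides): d = −(3/4)·ln(1−(4/3)·p)

computed with `log1p` for small-p accuracy.  At or beyond a model's
saturation bound the distance is capped (default 5.0 substitutions/site)
with a warning and the pair is flagged; region-rate estimation refuses to
proceed if more than 20% of pairs are capped.  jc20 is the default protein
model because the simulator uses the matching 20-state process — estimator
consistency is then a checkable property, not an approximation.  Empirical
exchangeability matrices (LG/JTT) and rate heterogeneity are out of scope
by design; the NJ/jc20 route is a self-contained stand-in for external ML
inference, so absolute branch lengths will differ from ML trees on the
same data.

Neighbor joining is the standard Saitou–Nei Q-criterion algorithm.  Two
determinism rules: among tied Q minima the pair whose cluster
representative labels (smallest member tip) sort lexicographically first is
joined; negative branch-length estimates are clamped to 0 with the deficit
moved to the sibling branch so the joined distance is preserved.  On an
exactly additive matrix NJ recovers the generating topology and branch
lengths to floating-point accuracy (checked to 1e−9 in tests).

### Regions and conservation

Region partitions are declared in 1-based residue coordinates of a named
reference sequence and lifted onto alignment columns gap-awarely (residue k
→ the column of the k-th non-gap reference character).  Per-region rates
come from per-region distance matrices → NJ trees → K from the root tip,
or a "direct" mode (corrected pairwise distance root-tip→tip) for short
regions where NJ is unstable.

Conservation classification per cell: 2 if the residue matches the column
consensus, 1 if it differs but scores positively against the consensus in
BLOSUM62, 0 otherwise (including gaps).  Consensus = most frequent non-gap
residue; ties break alphabetically; columns that are ≥ 50% gaps get
consensus '−' and all cells 0 — deliberately conservative in gappy
N-terminal columns.  No majority threshold beyond plurality is imposed;
this choice is documented rather than inherited, since figure-style
consensus definitions are rarely stated precisely.

### Start-codon screen

Candidate starts are in-frame ATG/GTG/TTG codons scanned upstream from the
annotated start, bounded by the first in-frame stop.  For each candidate,
the would-be N-terminal peptide (candidate extension + the annotated
N-terminus, located by sliding a post-region consensus probe over the
annotated protein) is scored against the homolog alignment's N-terminal
region:

    score = 0.5 · similarity + 0.5 · length_agreement
    similarity       = Σ BLOSUM62(candidate_i, consensus_i) / Σ BLOSUM62(consensus_i, consensus_i)
    length_agreement = 1 − |len − median homolog region length| / median

The candidate aligns flush to the region's C-terminal edge; the similarity
denominator runs over the *full* consensus, so a peptide covering only
part of the region is penalized for the uncovered part.  The verdict is
`extend` only when a candidate beats the annotated start by a margin
(default 0.1, configurable); ties resolve toward the shorter extension.
This scoring rule is the package's own construction — the screen it
formalizes is traditionally done by eye — and output headers say so.  No
ribosome-binding-site model is used; that is a known limitation.

## The synthetic generator

`synthetic_data` produces the structures the analysis assumes:

* **Species tree**: Yule (pure-birth) topology, branch lengths scaled so
  every root-to-tip distance equals the configured height exactly; a basal
  outgroup tip ("OUT") is attached for rooting, keeping the whole tree
  ultrametric.
* **Clade constraint**: a focal clade (≈ 1/4 of tips by default) whose
  branches strictly below its MRCA carry multiplier r_clade on the protein
  only; the stem is untouched (matching the contribution statistic's
  convention).
* **Regions**: the protein is a concatenation of regions with per-region
  multipliers; default 60 residues at 4× (a fast N-terminal peptide) plus
  340 at 1× (a conserved core).
* **Marker**: an independent locus simulated on the same tree at baseline
  rate (1500 nt, jc69 process).
* **Sequence evolution**: per site and branch, substitution events are
  Poisson with mean = branch length × branch multiplier × region
  multiplier; each event moves to a uniformly chosen different state
  (20-state protein, 4-state nucleotide).  This is exactly the process the
  jc20/jc69 corrections invert.
* **Misannotation fixtures**: a homolog family sharing an ancestral
  N-terminal peptide (lengths 50–60 aa, left-trimmed; ~10% point
  divergence, no Met introduced inside the region so the true start is the
  unique candidate) and core; a configured fraction of records have the
  annotated start moved 10–40 codons downstream with the true start
  preserved in the upstream context, and half of the intact records carry a
  spurious in-frame ATG whose extension is random peptide (the screen must
  reject it).

One global seed drives a per-purpose seed sequence (tree, protein sites,
marker sites, fixtures), so components regenerate independently and all
outputs are byte-identical under a fixed seed.

### Default study conditions and why

* Ingroup height 0.3 substitutions/site: deep within-phylum protein
  divergence, far from both the zero-information and saturation regimes.
* r_clade = 0.3: a strong but not degenerate constraint, the regime the
  contribution statistic is meant to expose.
* Protein 400 aa (60 + 340), marker 1500 nt: typical sizes for a bacterial
  cell-division protein and a concatenated rRNA fragment.
* Region-rate experiments use ingroup height 0.2 so that the 4×-accelerated
  region stays below the jc20 saturation cap along the longest paths.
* The K-ratio power experiment uses a *matched simultaneous radiation*: two
  sister star clades of 8 tips with zero-length stems under the outgroup.
  The rank test treats per-tip ratios as exchangeable units; a long shared
  clade stem is a single random draw common to all of a clade's tips
  (realized substitutions on it cannot be averaged away by adding sites)
  and badly inflates the test's type-I error.  With the matched radiation
  every tip's history below the split is independent and the measured null
  rejection rate sits at the nominal 5%.

### What passing tests do and do not show

The generator omits indels (alignments are gap-free; gap handling is
exercised by constructed fixtures), rate heterogeneity across sites within
a region, empirical amino-acid exchangeabilities, codon structure, and
horizontal transfer.  Recovery results therefore demonstrate correctness
of the estimators under their own model assumptions and sensible behavior
at realistic noise levels — not robustness to model misspecification on
real data.  On real datasets, ML trees under selected models should be
supplied as inputs in place of the NJ stand-in.

## Numerical and degenerate-input choices

* Percentiles: linear interpolation between order statistics (numpy
  default), stated because box figures rarely define one.
* Newick: internal values after ')' are labels, not lengths; quoted labels
  and bracketed comments supported; missing branch lengths default to 0
  with a warning; zero-length branches are legal and logged when they touch
  a reference/MRCA node.
* Outgroup rooting bisects the unrooted stem branch 50/50 (merging the two
  root edges when the stored root already sits on the stem), preserving
  all tip-to-tip distances; a degree-2 node left at the old root is
  suppressed.
* NJ Q values are evaluated on the upper triangle only (the broadcast form
  is not exactly symmetric in floating point, which would corrupt tie
  detection).
* Exact rank-test enumeration compares rank sums with a 1e−9 slack to
  absorb midrank floating-point error.

## Problem sizes used in validation

Validation experiments run at: 200 random trees (≤ 20 tips) for the
patristic oracle; 1,000 random rooted trees for contribution identities;
100 additive matrices (≤ 15 taxa) for NJ exactness; 5,000 null replicates
at n = m = 30 for rank-test calibration; 100 replicates of the 16-tip
clade-constraint recovery; 50 replicates of the 24-tip region-rate
contrast; 100 + 100 replicates (power + null) of the 8v8 K-ratio
experiment; and 200 screen fixtures.  The acceptance script re-runs the
same experiments at comparable sizes (50–2,000 replicates depending on the
experiment) from a user-supplied seed.
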