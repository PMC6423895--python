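# Methods

`acedhs` detects regulatory elements whose DNA sequence has evolved faster on
the human lineage than local neutral expectation. The unit of analysis is a
DNaseI hypersensitive site (DHS) paired with a nearby ancient repeat element
(ARE) — an old transposable-element relic assumed to evolve neutrally — in a
multi-species primate alignment. This note describes the model, the tests,
the synthetic data that stands in for the genomic resources a full-scale
study would download, and the design choices made where the design was open.

## Substitution model and likelihood engine

Sequences evolve under HKY85: transitions (A↔G, C↔T) are scaled by κ relative
to transversions, equilibrium frequencies are π. The rate matrix is
normalised so one unit of branch length equals one expected substitution per
site, so branch lengths are directly comparable across fits. HKY85 is the
simplest model with unequal base frequencies and a transition bias — the two
features of real substitution data that matter at this depth; more heavily
parameterised models (GTR, dinucleotide) add nothing testable at 1–10 kb.

Likelihoods are computed by Felsenstein pruning over unique site patterns,
with gap/N leaf states treated as missing data (partial-likelihood vector of
ones); columns that are missing in every species contribute exactly zero.
Transition matrices come from the symmetrised eigendecomposition, which is
exact for reversible models. The engine also exposes inside/outside
conditional likelihoods so that any single-branch profile
`lnL(t_branch | everything else)` can be evaluated in microseconds; all the
scalar optimisations below are built on this.

The default species tree is a trifurcating-root (unrooted) catarrhine
topology over human, chimp, gorilla, orangutan and macaque. With a
reversible model a rooted tree's two root-adjacent branches are confounded;
the trifurcation makes every branch length identifiable.

## Neutral calibration

Each element's neutral model is fitted on its own local ARE, topology fixed:
π is set to the observed base frequencies (floored at 1e-4), κ and all branch
lengths are maximised by bounded coordinate ascent (κ ∈ [0.05, 50], branch
lengths ∈ [0, 3]) until the log-likelihood improves by less than 1e-6 in a
sweep or 200 sweeps pass (then the fit is flagged unconverged and excluded
with a warning). Refitting at a stored optimum changes lnL by < 1e-6.

When the human ARE is more than twice the human DHS length, the ARE is cut
into sliding sub-ARE windows of exactly the DHS length with a step of 10% of
that length (full windows only, sliced along human non-gap positions), each
window is fitted separately, and the DHS is tested against every window.

## Acceleration tests

Two one-sided likelihood-ratio tests target the human terminal branch:

* **Sub-branch test (A)** — alternative: the DHS human branch is the shared
  neutral human branch scaled by ρ ≥ 1.
* **Sub-branch-given-tree test (B)** — a free factor ν > 0 rescales the whole
  DHS tree under both hypotheses (absorbing element-wide rate differences,
  e.g. regional mutation-rate variation); the alternative adds ρ ≥ 1 on the
  human branch on top.

Because ρ = 1 is a boundary point, p-values use the 50:50 mixture null
½δ₀ + ½χ²₁: p = 1 when ρ̂ sticks to the boundary, else 0.5·P(χ²₁ ≥ LR).

**Profiling the neutral human branch.** The neutral human-branch length is
itself an estimate from a short ARE. Treating it as exact inflates the null
variance of both statistics by a factor 1 + n_DHS/n_ARE; since the windowing
rule caps a single calibration window at twice the DHS length, that factor is
at least 1.5 and the tests become anti-conservative enough to break FDR
control — window voting does not rescue this, because the DHS's own sampling
noise and the heavily overlapping windows' calibration noise are shared
across the vote. Both tests therefore treat the human branch as a nuisance
parameter profiled in the **joint** ARE + DHS likelihood: under the null, ARE
and DHS share one human branch length (times ν for the DHS in test B); under
the alternative, the DHS human branch is additionally scaled by ρ ≥ 1. This
restores calibration — the type-I experiment in the test suite and
`scripts/acceptance.py` measures the null rejection rates — at a modest cost
in power. A `NeutralModel` that carries no
calibration alignment falls back to the fixed-neutral form — useful when the
neutral model is known exactly, as in oracle simulations.

ρ is profiled on [1, 100] and ν on [1e-3, 100], both on the log scale with
tolerance 1e-6. Elements with fewer than 50 non-missing alignment columns are
reported untestable and excluded, mirroring the ≥100 bp input filter.

**Calling.** Benjamini–Hochberg q-values are computed separately for the p_A
and p_B families, pooled across all (DHS, window) pairs — pooling maximises
comparability across elements. A window is significant iff both q-values fall
below α = 0.05; a DHS is accelerated iff its significant windows are a strict
majority of its windows (for a single window this reduces to that window
being significant).

## Pre-processing filters

DHSs pair with the closest ARE whose nearest edge lies within ±5 kb of the
DHS center (ties to the smaller start). Pairs then pass a fixed cascade, each
removal attributed to the first violated rule so the report reconciles
exactly: (1) human DHS or ARE shorter than 100 bp — applied to both element
classes; (2) orthologs in fewer than 4 species (human required); (3) ARE
further than 5 kb from the DHS center in any non-human genome with an
ortholog, measured the same way as on the human side; (4) DHS longer than its
ARE, or DHS/ARE overlap in any genome; (5) ARE overlapping ≥1 bp of the
merged union of coding exons, promoters, simple repeats, low-complexity
regions or segmental duplications — any of which would break the neutrality
assumption. A missing track is a configuration error, never silently skipped.

## Motif scanning and cross-species affinity

PWMs load from JASPAR PFM or minimal MEME files (via Bio.motifs); counts
become probabilities with a total pseudocount of 0.1 distributed by the
background. Scores are log₂ odds against a 0-order background (uniform by
default). P-values are exact: the distribution of the score discretised to
1/1000 bit is built by dynamic programming over columns and matches full 4^w
enumeration to < 1e-9 total variation; both strands are scanned and hits at
p ≤ 1e-4 reported. The relative profile score (score − min)/(max − min) on
the log-odds scale gives the JASPAR-style binding call at threshold 0.8.

For a human hit, the hit window is mapped through alignment columns to each
species and each species is scored by its best relative score over the
mapped window ± one motif width of flank (absorbing small indel slippage).
Classification: human_gain iff human ≥ 0.8 and all scored non-human species
< 0.8; human_loss is the mirror; conserved iff all ≥ 0.8; anything else —
including fewer than 3 scored non-human species — is unclassified.

## Downstream association

Elements link to target genes by Pearson correlation of element
accessibility against gene signal across shared samples, r > 0.7 strict,
within a configurable cis window (default 1 Mb); a DHS may link several
genes. Expression matrices are Z-score normalised per gene (n−1 denominator;
constant genes map to zero with a warning). Species contrasts use Welch's
two-sided t-test — chosen over Student's for robustness to unequal variance.
SNP membership in elements is the half-open point test; a SNP is concordant
when its reported gene is among the containing element's linked targets.
Allele-frequency filtering keeps minor-allele frequency strictly above 1%.
LD is the squared Pearson correlation of allele dosages (composite LD). qPCR
relative expression is 2^−ΔCt, with batch normalisation to a control group's
mean.

## Synthetic data: what it emulates and what it does not

The generator produces every input the pipeline consumes, with known ground
truth: ortholog alignments evolved down the tree (root drawn from π, each
branch applying P(t), the human terminal branch multiplied by ρ),
gene/DHS/ARE coordinates on one synthetic chromosome `chrS` (0-based
half-open), per-rule filter violators, planted motif gains/losses,
species-labelled expression matrices (baseline + species shift + Gaussian
noise on the log scale) and Hardy–Weinberg SNP tables. Identical seed and
configuration give bit-identical output; each fixture draws from one seeded
generator in a documented order.

Default study conditions, chosen once: DHS length 800 bp; ARE length 2,000 bp
(more than twice the DHS, so the windowing path is exercised: 16 windows per
element); κ = 4; 42% GC; human terminal branch 0.021 with a human–macaque
path of ≈ 0.36 substitutions/site. The tree keeps the catarrhine topology but
compresses time roughly three-fold relative to the real primates: the
relative error of a branch-length estimate scales as 1/√(n·t), and at strict
primate depth a single 1–2 kb element carries too few substitutions
(≈ 6 on the human branch) for per-element calibration to be informative —
per-element tests there are underpowered no matter the statistic. The
parameter-recovery experiments go further and use a compact 4-taxon tree
with uniform 0.1 branches: recovering every branch within a tight relative
tolerance on 10 kb requires n·t large enough that each estimate's standard
error (inflated by correlation between adjacent branches) leaves margin for
the worst of ~120 draws.

Consequences for interpretation: passing tests show the statistics are exact,
calibrated and powerful **under the model** — site-independent, gap-free HKY
evolution at informative depth. They do not demonstrate performance on real
shallow primate alignments with indels, alignment error, context-dependent
mutation (CpG), or non-equilibrium base composition. No indels are simulated
(gaps appear only where tests inject them) because the statistic operates on
aligned columns; repeat-family realism (LINE subfamilies) is likewise out of
scope.

## Numerical choices

Score discretisation 1/1000 bit; branch-length optimisation tolerance 1e-8
(coordinate ascent stop at 1e-6 log-likelihood); LR values clamped at 0 with
optimizer tolerance 1e-6; base frequencies floored at 1e-4; TSS-distance ties
broken by lexicographically smaller gene id; gene centers use floor division;
"other" feature annotation requires an explicitly supplied non-coding track;
a fully uniform PWM has zero score range and relative score 0 with a warning.
Seeds derived inside experiments stay below 2³¹.

## Known limitations

Per-element neutral calibration is intrinsically noisy at shallow divergence;
the profiled tests are calibrated but lose power when the ARE is short. The
window majority vote tames ARE heterogeneity but windows overlap 90% and are
not independent evidence. Expression/accessibility correlation is a proxy for
element–gene contact, not a chromatin-interaction model. The qPCR and LD
utilities are deliberately minimal (no population structure, no phasing).
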