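# Methods

This note documents the models, parameter choices and numerical decisions
behind fibromod, and what the synthetic validation does and does not
establish about real data.

## Pipeline overview

The package chains five stages in method order: synthetic data generation
(or user-supplied TSV matrices), CPM/log normalization and Welch
differential expression, weighted co-expression network construction and
module detection, phase-wise differential-activity (DA) selection, and
projection of the selected modules onto targeted-panel concentration-
response DEG tables. Annotation utilities (ortholog mapping, biomarker
overlap, Fisher over-representation against GMT collections) operate on any
module set.

## The synthetic in vivo generator

The generator emulates a treated-vs-control mouse time course: 7
post-exposure timepoints (days 1, 2, 7, 14, 21, 28, 35), 8 animals per
group and arm, with lung fibrosis developing through an inflammatory
(days 1–2), acute fibrotic (days 7–14) and late fibrotic (day ≥ 21) phase.
Each planted module `m` has a latent activity per sample `s`

    z_s = A · f_m(day_s) · (1 + cv · ε_s) + A · σ_lat · ε'_s ,

with amplitude `A` (default 1.5, log2 units), phase trajectory `f_m` (1 in
the module's phase, baseline 0.1 on other treated days so that phase
*specificity* — not mere on/off behaviour — is exercised, and 0 in
controls), between-animal response heterogeneity `cv` (default 3.0,
treated samples only) and a small residual wobble `σ_lat` (0.05). Gene `g`
of the module observes `loading_g · z_s` plus N(0, noise_sd²) noise
(noise_sd = 1); loadings are drawn from (0.4, 0.9) with random sign, so
modules contain both positively and negatively regulated members and the
network must be unsigned to group them.

Two deliberate properties of this construction:

* **Both latent noise terms scale with the amplitude.** An amplitude-0
  (null) module therefore carries no shared signal whatsoever, and null
  simulations are genuine global nulls.
* **The heterogeneity term is trajectory-coherent** (`cv · ε` multiplies
  `f_m`). Animals differ strongly in how hard a module responds while the
  module is active, but off-phase and control samples stay quiet. This is
  what makes the within-module correlation strong enough for network
  detection (mean within-module |cor| ≈ 0.4–0.5 at the defaults) while
  keeping the DA contrast clean: off-peak DA sits near 1 and control
  activity stays low. With heterogeneity shared across all treated samples
  instead, either module recovery or DA phase specificity degrades; with no
  heterogeneity at all, within-module correlation at these amplitudes is
  ~0.1 and no clustering method can recover the partition.

A consequence worth knowing: because treated animals vary around the mean
response, per-timepoint mean-shift differential expression (8 vs 8 Welch
tests) on the default in vivo data is underpowered and typically yields few
or no DEGs. The DEG machinery is validated on its own oracles and on the
in vitro data, where effects are planted as clean mean shifts.

The default module plan plants eight phase-peaked modules of 30–250 genes
(three inflammatory, three acute, two late) among 2000 genes. A constant
("general") profile is supported but not part of the default plan: after
per-gene standardization a module that is equally active on every treated
day places its controls far from the data mean, so its control EG score is
comparable to the treated score and DA ≥ 2.5 is unreachable by
construction — phase-peaked modules are the meaningful test case for the
selection statistic.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects, library-size variation in the in vivo arm, temporal
autocorrelation of per-animal trajectories, correlated background genes, or
cell-type composition shifts. Passing recovery tests therefore shows the
pipeline's correctness and its statistical behaviour under an idealized
factor model, not robustness to those real-data complications.

## The in vitro generator

The concentration series emulates a reduced-representation (targeted-panel)
assay on airway epithelial cells: a panel covering ~20% of each planted
module (clipped to 4–42 measured genes per module) plus ~200 background
genes, five concentrations, 3 treated vs 3 control replicates per
condition, negative-binomial counts (dispersion 0.1). Planted log2 fold
changes are drawn from U(2, 4) with random sign at the top concentration
and scale linearly in log10 concentration down to a floor of 0.25 at the
lowest level, so the planted module-score trend is exactly linear in log10
concentration. Fibrosis-class compounds shift the panel genes of every
planted module, inflammation-only compounds only those of
inflammatory-profile modules, inert compounds nothing. Active compounds
additionally shift 30% of off-module panel genes — the broad stress
response real exposures produce — without which the Benjamini-Hochberg
correction across the panel is so strict for narrowly acting compounds
that no module could ever activate under a 3 vs 3 design.

Effect sizes are deliberately large: with 3 replicates the Welch test has
~4 degrees of freedom, and the aim is to validate the projection logic
(activation fractions, module scores, trend calls), not the power limits of
tiny designs. One stochastic behaviour is inherited from the strict
">20% of measured genes" activation rule: for a module with only 4–8
measured genes a single false-positive DEG crosses the threshold, so an
occasional spurious activation of a small module by a narrowly acting
compound is expected — the same near-threshold behaviour reduced panels
show in practice.

## Network and module detection

* **Unsigned adjacency** `|cor|^β`, β = 4. Unsigned because modules contain
  anti-correlated members by construction; β configurable, and
  `scan_soft_threshold` reports the scale-free fit R² and mean connectivity
  per candidate power for users who want to pick β from their own data.
* **TOM** on by default; `use_tom=False` switches the dissimilarity to
  `1 − |cor|^β`.
* **Branch cutting.** The default is a recursive two-branch decomposition
  of the average-linkage dendrogram: descend while a child could still hold
  a module (≥ 30 leaves); terminal nodes and side branches of ≥ 10 genes
  become candidates. A candidate survives only if its first principal
  component explains at least twice the random-matrix noise floor
  `(1 + √(n_genes/n_samples))² / n_genes` — this is what keeps diffuse
  background branches out. Members with |kME| < 0.3 are stripped;
  after merging, unassigned genes with |kME| ≥ 0.4 against any module
  eigengene are rescued into their best module (under a global null a
  |kME| of 0.4 at 112 samples is a ≈ 4σ event, so false rescues are rare).
  The minimum module size (30) is enforced against the originating branch
  size, so a module whose weakest members were stripped is not spuriously
  discarded. A classic static cut at a fraction of the maximum merge
  height (`cut_method="static"`, default fraction 0.99) is provided as the
  simpler alternative; on data with a large unstructured background a
  single global cut height is unreliable — the top merge heights belong to
  background outliers — which is why the recursive strategy is the default.
* **Merging.** Iteratively merge the module pair with the largest absolute
  eigengene correlation while it exceeds 0.75, recomputing eigengenes after
  every merge; ties break towards the lowest module indices. Afterwards no
  pair of eigengenes correlates above the threshold.
* **Eigengenes.** First right-singular vector of the z-scored module
  submatrix (unit Euclidean norm, one entry per sample), sign-oriented so
  the mean member correlation is ≥ 0; the exact anticorrelated-pair tie
  falls back to making the first member's correlation positive. Variance
  explained is the first squared singular value over the total. Hub gene:
  maximal signed kME, ties broken lexicographically by gene id.
* Zero-variance genes are dropped before correlation, with the dropped ids
  reported; label 0 marks unassigned genes and is excluded from all
  downstream scoring.

## Phase activity and selection

Samples map to phases by day (treated: 1–2 inflammatory, 7–14 acute, ≥ 21
late); all control samples pool into a single control class. EG score:
mean |eigengene entry| per phase (absolute values prevent cancellation of
up- and down-regulated activity). DA: phase score over control score, with
the control denominator clamped at 1e-8 (and the module flagged unstable,
with a warning) should it vanish. Selection threshold 2.5, applied
*inclusively* (DA ≥ 2.5): the reported selection pattern this rule is
checked against treats 2.50 as selected, so the threshold is inclusive by
construction; both threshold and rule are configurable. DA is
scale-invariant in the eigengene, so the unit-norm convention does not
affect selection.

## Differential expression

CPM normalization (per-sample scaling to one million) followed by
log2(x + 1); the pseudocount of 1 keeps the transform invertible and exact
at zero. The built-in test is a two-sided Welch t-test per gene on the
log scale with Welch–Satterthwaite degrees of freedom; genes with zero
variance in both groups get p = 1 when means agree and p = 0 otherwise.
Benjamini-Hochberg adjustment is implemented as the literal step-up
arithmetic (`p·m/rank`, reverse cumulative minimum, clipped at 1) so that
results are bit-identical to the definition. DEG thresholds: padj < 0.05
(strict) and |log2FC| ≥ 1 (inclusive). The built-in engine deliberately
avoids variance moderation and count models — externally produced DEG
tables (e.g. from moderated or negative-binomial frameworks) are accepted
through `read_deg_table`, which recomputes the DEG flag under the stated
thresholds.

## Annotation

Ortholog mapping uses a static two-column file; one-to-many mappings expand
to all targets (de-duplicated per module) and unmapped genes are dropped
and counted. Over-representation is a one-sided Fisher exact test (upper
hypergeometric tail) with BH correction across gene sets within each
module. The default enrichment universe is the set of genes that entered
the network (assigned or not), matching the tested pool rather than a
whole-genome background; callers can pass any universe.

## Projection

Modules are first restricted to the measured panel; modules with fewer than
3 measured genes are flagged not-evaluable rather than scored (a 1–2-gene
"module" fraction is meaningless). Activation uses the strict rule
(fraction > 0.20). The module score is the plain mean |log2FC| over all
measured module genes; a kME-weighted variant is provided for users who
want eigengene-proximity weighting, but the unweighted mean is the default
and the score used in validation. Dose-responsiveness is operationalized
as OLS slope > 0 with two-sided p < 0.05 on log10 concentration — with
exactly two concentrations the slope is reported and inference flagged NA.
Recurrence: DEG at ≥ 2 concentrations of one compound; genes recurrent for
≥ 2 compounds carry a cross-compound flag.

## Problem sizes used in validation

The validation suite runs ten seeded end-to-end in vivo simulations at the
full default design (2000 genes, 112 samples), one hundred 500-gene null
simulations for the selection false-positive rate, and ten in vitro
projection experiments (three compounds × five concentrations, ~550-gene
panel); `scripts/acceptance.py` uses the same designs with fifty null
runs. These sizes give stable pass/fail behaviour for the property checks
(module recovery ARI ≥ 0.8, per-module Jaccard ≥ 0.6 in ≥ 9/10 seeds, and
so on) while keeping a full run in the minutes range on a single CPU.

## Known limitations

* The recursive branch cut is a deliberate simplification of full dynamic
  tree cutting (no PAM-like reassignment stage); its cohesion criterion is
  tuned for data with a clear module-vs-background contrast.
* The built-in DE engine is not appropriate for 2–3 replicate count data
  when effect sizes are small; use an external moderated/NB framework and
  feed the tables in.
* DA selection uses a plain threshold, not a significance test; with very
  few control samples the control EG score is itself noisy.
* Eigengene-based module scores on reduced panels are biased when panel
  coverage of a module is low; the DEG-fraction readout is the
  coverage-robust companion, which is why both are reported.
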