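# Methods

`mwsip` implements the analysis chain of a DNA stable isotope probing (SIP)
microcosm experiment: identification of ¹³C-incorporating taxa from
CsCl-gradient amplicon counts, growth/life-history traits of those
incorporators, carbon mineralization accounting, and the correlation of
phylogenetic with functional distance. A seeded generator emulates the whole
experiment so that every stage can be scored against known ground truth.
This note records the models, the defaults and why, and what the synthetic
benchmark does and does not establish about real data.

## Incorporator identification (MW-HR-SIP)

DNA that has assimilated ¹³C bands at higher buoyant density (BD). For each
of three overlapping heavy windows — 1.70–1.73, 1.72–1.75 and 1.74–1.77
g/mL, closed intervals, a fraction in an overlap used in both windows — the
¹³C-treatment fractions are compared against the corresponding
¹²C-control fractions of the same substrate × day × tillage comparison:

1. **Pruning.** Taxa with a summed count below 2 across all samples are
   removed.
2. **Sparsity sweep.** For each candidate prevalence cutoff (default grid
   {0, 0.15, 0.30}), taxa present in fewer than that fraction of the pooled
   samples are removed before testing; the cutoff that maximizes the number
   of Benjamini–Hochberg-significant taxa is kept, ties broken toward the
   smaller cutoff. The grid is a package default: the sweep procedure is
   standard in high-resolution SIP but no canonical grid exists.
3. **Normalization.** Median-of-ratios size factors (the DESeq estimator)
   across the pooled window table; when no taxon is positive in every
   sample the reference geometric mean is computed over positive entries
   only, with a logged warning.
4. **Test.** Per taxon, group means of normalized counts are treated as
   negative binomial with a pooled method-of-moments dispersion floored at
   0.01, and a pseudo-mean of 0.5 normalized counts is added to both group
   means. The statistic is a one-sided Wald test of
   H0: log₂(μ₁₃/μ₁₂) ≤ 0.25 against H1: > 0.25. This is deliberately a
   reimplementation of the *decision rule* embodied by DESeq2-based SIP
   wrappers, not of DESeq2 itself (no dispersion shrinkage across taxa);
   the contract preserved — calibrated one-sided testing of enrichment
   above 0.25 log₂ units — is verified by simulation (see Calibration).
5. **Decision.** BH adjustment within each window; a taxon is an
   incorporator when adjusted p < 0.1 and l2fc > 0.25 in at least one
   window. The 0.1 cutoff is configurable; it is the conventional default
   in high-resolution SIP software, since the l2fc rule itself does not fix
   an error rate.

`first_label_day` is the earliest sampling day with a positive call;
absence of a call at an interior day does not reset it. The **degree of
¹³C assimilation** of a taxon is the maximum per-window l2fc estimate over
the windows in which it was tested; the maximum (rather than a mean) is
used because windows where the labeled band does not fall carry no signal,
and the best-window estimate tracks the band's true enrichment.

## Growth traits

- **Normalized abundance** = (relative abundance / taxon rrn / sample mean
  rrn) × DNA yield. The sample mean rrn is the relative-abundance-weighted
  mean over detected taxa — the natural sample-level analogue of the
  per-taxon correction; an unweighted mean would let rare taxa dominate the
  correction. DNA yield (ng/µL) enters as a biomass proxy.
- **Max l2fc** = log₂(max over post-addition days of normalized abundance /
  baseline in the unamended control), floored at 0. Taxa absent from the
  control receive the control's smallest nonzero normalized abundance as a
  pseudo-baseline (the ratio is otherwise undefined; using the detection
  floor makes the resulting fold change an upper bound flagged by
  construction).
- **Latency** = max(0, first label day − peak mineralization day), per
  substrate × tillage, with the peak day taken from the mineralization
  module rather than hard-coded. Labeling before the peak is clamped to 0:
  such taxa assimilated the substrate during its main decomposition pulse.
- **Rarefaction** to an even depth (default 1,567 reads) by uniform
  subsampling without replacement; shallower samples are dropped.
- **Diversity.** Richness; Pielou's evenness = Shannon (nats) / ln
  richness, undefined at richness ≤ 1; Faith's PD as the branch-length sum
  of the subtree spanning present tips and the root (computed in-package so
  multifurcating trees are accepted; cross-checked against scikit-bio).
- **Group comparisons.** Wilcoxon rank-sum tests (exact for small untied
  samples, normal approximation with continuity correction otherwise),
  BH-adjusted across traits.

## Mineralization

Inputs are mg C respired per inter-flush interval (the headspace is assumed
fully reset at each measurement, so intervals are independent). Cumulative
curves are running sums per microcosm; rates are interval mass / interval
duration in hours, assigned to the interval's end; the peak day is the
interval end (in days) with the maximal replicate-mean rate, ties broken to
the earlier day. Peaks are defined on replicate means rather than pooled
rows so that unbalanced replication cannot shift the peak. GC-MS ion
counts and standard-curve conversion are upstream of this package.

## Phylogeny–function correlation

Functional profiles per incorporator: substrate indicators, day of first
label detection, degree of assimilation. Columns are range-scaled to [0, 1]
(constant columns to 0) — Gower-family distances presuppose comparable
column ranges, and range scaling is the least structured choice. Distance
is the modified Gower ("altGower") form: mean absolute difference over
columns not doubly zero. Phylogenetic distance is cophenetic (tip-to-tip
path length). The Spearman correlation of the two lower triangles is
reported with a Mantel-style permutation p (default 999 label permutations
of one matrix, two-sided on |rho|), because distance pairs are not
independent and a parametric p would be anticonservative.

## Synthetic experiment generator

The generator is the benchmark's ground truth, not a fitting device; its
defaults are fixed once and describe one realistic microcosm experiment.

- **Community.** n taxa with GC ~ U(0.35, 0.70), base abundances lognormal
  (σ = 0.8) normalized to sum 1, rrn log-uniform on [1, 12]. By default 10%
  of taxa are incorporators of each substrate, drawn independently (so dual
  incorporators occur). With the default rrn bias, xylose incorporators
  draw rrn from the upper half of the range and cellulose-only
  incorporators from the lower half, mirroring the ruderal/high-rrn
  association with labile carbon. The 10% default keeps the labeled
  biomass share low enough that the compositional inflation of unlabeled
  taxa in fraction-relative counts stays below the 0.25 l2fc decision
  threshold — with much larger labeled shares, one-sided testing against a
  fixed threshold is inherently at risk in any fraction-relative design.
- **Gradient.** BD = 1.660 + 0.098·GC g/mL (the classical linear GC–density
  relation) plus atom-excess × 0.036 g/mL at full labeling; 24 equal
  fractions tile 1.67–1.78 g/mL; within-taxon band spread is Gaussian with
  σ = 0.005 g/mL (≈ 3–5-fraction bands). Each taxon additionally spreads
  2% of its mass uniformly across the sampled range: real gradients carry a
  diffuse non-equilibrium smear in every fraction, and without it the
  heavy-tail control fractions contain essentially no DNA yet are still
  sequenced to full depth, collapsing to a degenerate single-taxon
  composition that no real experiment shows. Fraction counts are
  multinomial at 10,000 reads per fraction, with no extra overdispersion by
  default so the test's null behavior can be probed cleanly.
- **Labeling and growth.** Enrichment is per substrate (atom-fraction
  excess, default 1.0 for incorporators) and takes effect only at days ≥
  the taxon's lag — labeling requires growth, which makes the true first
  label day well defined. Bulk abundances follow lagged logistic growth
  (flat until the lag, then logistic toward base × max_fold, max_fold ~
  U(4, 32)); bulk counts are multinomial over 16S copy abundance (cells ×
  rrn), and DNA yield is proportional to total biomass. Xylose
  incorporators lag U(0, 4) days, cellulose incorporators U(2, 8) days,
  consistent with the substrates' mineralization peaks.
- **Mineralization.** Xylose follows a pulse rate curve (t/τ)·e^(1−t/τ)
  peaking at day 2; cellulose a lagged logistic-derivative (sech²) curve
  peaking at day 6; half of the added substrate C is respired by default.
  Interval masses are the instantaneous rate at the interval end times the
  interval duration (normalized), so the detected peak coincides with the
  rate function's peak on any grid containing it; this is a deliberate
  simplification of within-interval integration.
- **Trees and trait evolution.** Ultrametric trees by UPGMA on random
  coordinates; Brownian trait evolution via the tip covariance implied by
  the tree, for positive-control tests of the distance correlation.

**What the benchmark does not show.** The generator draws independent
multinomial counts (no spatial correlation along the gradient, no
overdispersion unless enabled), one gradient per treatment (real designs
replicate gradients), sharp hard-lag growth, and full labeling of
incorporators. Passing its calibration therefore demonstrates that the
decision rule is wired correctly and calibrated under its stated model —
not that real soil communities, with partial labeling, compositional
drift, and gradient-to-gradient variation, will yield the same error
rates.

## Numerical choices and problem sizes

Degenerate inputs: all-zero taxa are excluded from testing; a window with
fewer than two usable fractions per group is skipped with a warning, and an
analysis error is raised only if every window is empty; empty mineralization
selections return zeros; single-taxon samples have undefined evenness.
Standard errors are floored at 1e-12 to avoid division by zero in exact-tie
groups; BD values are written with 4 decimals.

Test-suite simulations use 30–100 taxa, 24 fractions at 10,000 reads,
200-replicate null/power ensembles and 10-seed end-to-end ensembles; these
sizes give binomial standard errors well below the asserted margins while
keeping the whole suite in seconds. All randomness flows from explicit
seeds (`numpy.random.default_rng`; the pipeline derives per-stage
substreams from one root seed via `SeedSequence`), so every reported number
is exactly reproducible.

## Known limitations

- No qSIP (atom-fraction-excess estimation) and no multi-isotope support.
- The NB Wald test has no cross-taxon dispersion shrinkage; at very small
  fraction counts per window it relies on the dispersion floor.
- Latency resolution is bounded by the sampling-day grid.
- Mixed-effects modeling, ordination/PERMANOVA and differential-abundance
  frameworks are intentionally out of scope.
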