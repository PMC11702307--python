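# Methods

This note documents the models implemented in `lynxkit`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Units and constants

All forces are pN, lengths nm (Å in the structural module), rates 1/s,
temperatures K. The Boltzmann constant is fixed at
k_B = 0.0138065 pN·nm/K and the default temperature is 298.15 K (25 °C,
the measurement temperature), so k_BT ≈ 4.1164 pN·nm.

## Bell–Evans model and dynamic-force-spectrum fitting

The force-dependent off-rate is k(f) = k₀·exp(fγ/k_BT). The rupture-force
density at constant loading rate r_f is used in its normalized
Evans–Ritchie form, with the 1/r_f prefactor, so that it integrates to 1
over f ∈ [0, ∞); the analytic CDF

&nbsp;&nbsp;CDF(f) = 1 − exp[(k₀k_BT/(γr_f)) (1 − e^{γf/k_BT})]

is inverted in closed form for sampling. The most probable force
f\* = (k_BT/γ)·ln(γr_f/(k₀k_BT)) is clamped to 0 when the analytic
expression is negative: below the crossover loading rate γr_f = k₀k_BT the
density is monotone decreasing and its mode sits at the f = 0 boundary.

`fit_dfs` regresses f\* on ln(r_f in pN/s). The default is ordinary least
squares; no weighting scheme is canonical for mode-based spectra, and inverse
half-bin-variance weighting is available as an option (with equal bin
widths it coincides with OLS). From the fitted slope m and intercept b,
γ = k_BT/m and k₀ = (1/m)·exp(−b/m), in 1/s under the pN/s loading-rate
convention. A non-positive slope is reported as a fit failure rather than
propagated into negative barrier widths.

No independent estimate of γ exists for these bonds; all
simulation defaults use γ = 0.5 nm, a typical receptor–ligand barrier
width consistent with the measured 60–90 pN forces over 30–4,000 pN/s.

The Poisson single-bond model treats bonds per contact as Poisson(⟨n⟩)
with adhesion frequency Pa = 1 − e^(−⟨n⟩); the single-bond probability
among adhesions is ⟨n⟩(1−Pa)/Pa, ≈ 83.2% at Pa = 0.30.

## Trace analysis

Cantilever stiffness is estimated by equipartition, k = k_BT/var(x), with
the sample variance (ddof = 1) about the series mean; at 10⁵ samples the
estimator's relative SD is ≈ 0.45%.

Rupture detection scans adjacent-sample force drops in the retract phase
and calls the largest drop if it exceeds 5× the baseline noise SD (a
robust threshold on the synthetic traces, exposed as configuration). The system spring constant is the
slope of a linear force-vs-displacement fit over the 50–95% window of the
pre-rupture ramp. The unbinding force is the fitted-ramp value at the last
loaded sample minus the post-rupture baseline (median of the final 25% of
the retract phase); reading the ramp fit instead of the single raw sample
suppresses single-point noise while agreeing exactly on clean traces.

Histograms use fixed 5 pN bins anchored at 0; the mode is the center of the maximal-count bin, ties breaking
toward lower force, with half-bin uncertainty. Spectra are assembled by
grouping events into equal-width bins in ln(loading rate) — default one
group per distinct retraction speed — each group contributing the
geometric-mean rate and the member-force histogram mode; groups with fewer
than 10 events are flagged.

## Replicated lifetime-recovery studies

A single simulated experiment (5 rates × 300 events) recovers the
zero-force lifetime only coarsely: each histogram mode carries ±2.5 pN
quantization plus sampling noise (per-point SD ≈ 2.5 pN), and the fit
back-transforms the intercept through an exponential, so single-run
lifetime errors of 30–60% are intrinsic at these event counts.
`pipeline.recover_lifetime_study` therefore runs many independent
replicate experiments (default 400, all under the stated 5 × 300 design)
and reports the geometric mean of the recovered lifetimes — the stable
central summary of this log-normal-like estimator. At 400 replicates the
study-level spread is a few percent for short lifetimes and ≈ 10% for the
1,470 s wild-type bond, with a small (+5%/−6%) residual bias from mode
quantization interacting with the log-scale fit.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (configuration, seed) via
`numpy.random.default_rng`, and every generator emits a truth record
sufficient for recovery testing.

* **Rupture forces** are exact inverse-CDF draws from the Evans–Ritchie
  density — no instrument drift, no multiple-bond events, no
  polymer-linker elasticity.
* **Pulling traces** ramp force linearly in displacement at the system
  spring constant with additive white Gaussian noise and a clean drop to a
  zero baseline; real traces show PEG-linker nonlinearity and baseline
  tilt, so passing round-trip tests demonstrates correctness of the
  detection logic, not robustness to instrument artifacts.
* **Thermal traces** are i.i.d. Gaussian with variance k_BT/k, i.e. an
  ideal single-mode cantilever without 1/f noise or filtering.
* **Cohorts** plant per-participant target sum scores drawn from group
  normals (clamped to the achievable range) and realize them as random
  integer item compositions within 1–4 bounds, with reverse-keyed items
  stored as raw responses; scoring recovers the targets exactly. The
  default calibration uses the study's published group summaries
  (e.g. STICSA totals 71.09 ± 1.04 SEM, n = 469 reference vs
  91.778 ± 6.184 SEM, n = 15 carriers; SD recovered as SEM·√n) and a
  carrier frequency of 14/624. No item-level covariance structure,
  demographics effects or missingness are simulated.
* **Mutant sequences** apply non-overlapping substitutions (optionally as
  IUPAC heterozygote codes), insertions and deletions to a reference CDS.
* **Toy complexes** plant inter-body atom pairs at distances chosen so the
  clash count decreases by construction along the outward offsets.

## Cohort statistics

Scoring follows the sum-score convention: reverse-keyed item weights are
(max + min − response), so weights always increase along the
anxiety-expressing continuum; subscale scores are member sums and the
total is state + trait. Participants missing any item of a subscale are
excluded from that subscale (missing-data policy "exclude") or rejected
("error", default).

Threshold classification uses ≥ (a score at the threshold counts as
high). The default t-test is Welch's — the carrier group (n ≈ 14) is far
smaller than the reference group (n ≈ 558), which makes pooled-variance
inference fragile — with Student's available. The two-tailed Fisher p is
the probability-mass convention (sum of same-margin tables no more
probable than observed), the behavior of `scipy.stats.fisher_exact`;
alternatives such as doubling the one-tail differ and are not offered.
Cohen's d from summaries uses SD = SEM·√n and the (n−1)-weighted pooled
SD. Note that under this standard formula the published discovery-cohort
summary row yields d ≈ 1.68 rather than the printed 1.64; the package
reports the formula value. No multiple-testing correction is applied.

## Variant annotation

Alignment is global Needleman–Wunsch with match +1, mismatch −1, gap open
−4, gap extend −1 (a gap of length L costs 4 + (L − 1)) and a
deterministic traceback preferring diagonal, then vertical, making the
reported alignment unique; indels in repeat runs are therefore reported
left-aligned. IUPAC-ambiguous sample bases match when the reference
allele is in their expansion; a substitution is heterozygous when the
expansion contains the reference plus a differing allele. Consequences
follow the standard genetic code; indels of length not divisible by 3 are
frameshifts annotated at the first shifted codon, in-frame indels are
labelled `inframe_indel`. Protein positions are 1-based; mature-protein
numbering subtracts the signal-peptide length (default 22, giving the
61 ↔ 39 correspondence), and positions inside the signal peptide return a
flag instead of a number. Genomic coordinates are carried as opaque
annotations only — no liftover, and no packaged human sequence.

## Structure tools

"Bad contacts" are inter-structure heavy-atom pairs strictly closer than
3.0 Å (configurable). The placement
search includes offset 0 (an outward move "≤ 2 Å" admits no movement),
scans 0..max_offset in 1 Å steps along the unit vector between
binding-surface centroids, and breaks ties toward the smallest offset.
Kabsch superposition is uniform-weight least squares with the reflection
corrected to a proper rotation; near-collinear point sets are rejected as
degenerate. Chain-aligned RMSD superposes on the alignment chains' Cα
atoms only and evaluates over the target chain, so it includes both
conformational change and relative displacement of the target.

Interaction energies are a desk-scale analog, not a force field: LJ 12-6
with one generic (σ, ε) per element (bundled YAML, user-overridable),
Lorentz–Berthelot combination, Coulomb 332.06·q₁q₂/r kcal/mol with unit
dielectric, a plain 12 Å cutoff and no switching function. Hydrogen bonds
and salt bridges are distance-only criteria (donor–acceptor ≤ 3.5 Å;
carboxylate-O to basic-N ≤ 4.0 Å, boundary inclusive) over residue
templates with implied hydrogens — no angle term is possible on
heavy-atom-only models, a documented limitation.

## Problem sizes

Default test and acceptance runs use: 300 events per loading rate across
5 rates with 200–400 replicate experiments for lifetime recovery; 10⁵
samples for thermal calibration and Poisson adhesion summaries; 624
participants for cohort generation; ≤ 200-atom toy complexes. These sizes
match the measurement designs the package emulates, and otherwise keep every
estimator's Monte Carlo error well inside the tolerances asserted in the
tests.

## Known limitations

* Mode-based DFS fitting is the only estimator offered (no
  maximum-likelihood rupture-force fitting, no Dudko–Hummer–Szabo or
  multiple-barrier models); mode fitting is the convention this
  package follows.
* The rupture detector handles a single rupture per trace and no
  drift/tilt or worm-like-chain corrections.
* Cohort simulation is marginal-distribution calibration only; it cannot
  validate item-level psychometrics (no IRT or factor structure).
* The structural module operates on static toys; it does not generate
  conformational ensembles or reproduce molecular-dynamics observables.
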