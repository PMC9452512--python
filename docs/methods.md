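# Methods

This note records the models implemented in `clusterbind`, their
assumptions, the defaults chosen where the design was genuinely open, and
what the synthetic generators do and do not emulate.

## Occupancy model

A cluster of $n$ specific binding sites on one DNA molecule is treated as
an equilibrium system whose microstates $\sigma$ are the subsets of bound
sites.  The statistical weight of a state is

$$w(\sigma)=\prod_{i\in\sigma}\frac{c}{K_{d,i}}\,
  \exp\!\big(-\varepsilon_\mathrm{clash}\,n_\mathrm{clash}(\sigma)\big),$$

with $c$ the free TF concentration (nM), $K_{d,i}$ the per-site
dissociation constant (nM) and $n_\mathrm{clash}(\sigma)$ the number of
bound pairs whose sites share at least one basepair.  The partition
function is $Z=\sum_\sigma w(\sigma)$ and the mean occupancy
$\langle N\rangle=\sum_\sigma |\sigma|\,w(\sigma)/Z$.

**Weight convention.**  The dimensionless per-site factor $c/K_d$ was
chosen so that a single site follows the Langmuir isotherm
$c/(K_d+c)$ exactly.  Energies are interchangeable with dissociation
constants through $\varepsilon_{bs}=\ln(K_d/c_\mathrm{ref})$ for an
explicit reference concentration $c_\mathrm{ref}$ (default 1 nM);
`kd_to_energy`/`energy_to_kd` are exact inverses.

**Modes.**  *Independent* ignores overlaps (closed-form site sum);
*exclusive* forbids states containing any clashing pair (the allowed
states are the independent sets of the overlap graph — 3 states for a
2-site overlapping cluster); *permissive* allows all $2^n$ states with a
repulsive penalty $\varepsilon_\mathrm{clash}\ge 0$ in $k_BT$ per
clashing bound pair.  $\varepsilon_\mathrm{clash}=0$ reduces permissive
to independent; $\varepsilon_\mathrm{clash}\to\infty$ reduces it to
exclusive (numerically indistinguishable at 30 $k_BT$ over
$c\in[10^{-2}K_d,10^{3}K_d]$).

**Clash counting.**  Any bound pair sharing ≥ 1 bp contributes one
penalty, additively in the exponent (multiplicatively in the weight).
Pair-additivity for ≥ 3 simultaneously clashing TFs is the minimal
extension of the two-body definition; nothing in the implementation
couples the penalty to the *extent* of overlap (1 vs 3 bp) — different
overlap classes are expected to be fitted separately.

**Enumeration.**  States are enumerated exhaustively; the cap of 16
specific sites (2¹⁶ states) is far above the ≤ 6-site clusters the
analysis targets.  NS-class sites carry no statistical weight and are
excluded before enumeration.  Weights are computed in plain product form
(not log-space): with $n\le16$ and $c/K_d\le10^6$ they stay far from
overflow, and exact agreement with closed forms is preserved to 1e-12.

## Geometry conventions

Coordinates are 0-based, half-open $[\,\mathrm{start},
\mathrm{start}+\mathrm{length})$.  Shared basepairs are the interval
intersection length; spacing $\Delta$ is the gap
$b_\mathrm{start}-a_\mathrm{end}$, negative exactly when sites overlap
(then $-\Delta$ equals the shared count).  The default motif length is
9 bp (zinc-finger-like); 6 bp (E-box) is used for the two-region
native-promoter style designs.  Sites are strand-agnostic.  FASTA output
fills a fixed neutral backbone constant and writes placeholder motifs
into site intervals; it is a geometric stand-in, not a reproduction of
any real library sequence.

## Saturation binding inference

The per-target model is $B(c)=B_\mathrm{max}c/(K_d+c)$, deliberately
2-parameter even for multi-site targets: the fitted $B_\mathrm{max}$ then
measures total saturating signal and $K_d$ an effective affinity.
Least-squares fitting uses a deterministic initialization ($K_d$ at the
concentration of half-maximal mean signal, $B_\mathrm{max}$ at the signal
maximum) so fits are reproducible without a seed.  Degenerate inputs
(fewer than 3 distinct concentrations, all-zero or non-finite signal, no
concentration dependence) raise distinct errors.

**Credible intervals.**  The posterior over
$(\ln K_d,\ln B_\mathrm{max},\ln\sigma)$ uses a Gaussian likelihood with
constant per-target variance and flat priors on the log-parameters within
broad declared bounds (±7 natural-log units around the data-derived
scales).  Sampling uses an affine-invariant ensemble (32 walkers, 700
steps, 200 burn-in by default, fully seeded).  The reported 5–95 %
intervals are posterior percentile (credible) intervals.  Convergence is
screened by a Gelman–Rubin R̂ computed over four walker groups with a
default threshold of 1.05; walker-group R̂ on short interacting-ensemble
chains is noisy, so the conventional 1.05 screen is used rather than a
stricter 1.01, and the threshold is an explicit argument.  On failure the
intervals are withheld and a `ConvergenceError` is raised.

**Calibration.**  $B_\mathrm{max}$ grows linearly with the number of
identical sites; the OLS slope (the "step", RFU per bound TF) converts
signal to mean occupancy.  The intercept is free by default (a
through-the-origin option exists), and the fit range can be restricted to
the linear regime — needed when a late-saturating very-weak site breaks
linearity at high site counts.  `to_occupancy` divides the raw signal by
the step; subtracting the intercept first is an explicit option rather
than the default, keeping zero signal at zero occupancy.

**Cross points.**  The root of
$\langle N\rangle_\mathrm{cluster}(c)-\langle N\rangle_\mathrm{ref}(c)$
is found by scanning a 241-point log grid over $[10^{-3},10^{6}]$ nM and
polishing each sign change with Brent's method on $\ln c$.  The first
root is reported; multiple crossings raise a warning carrying all roots.
Coincident curves and bracket-wide absence of a sign change raise
distinct errors.  For $n$ identical independent weak sites against one
strong site the solver agrees with $c^\*=(K_w-nK_s)/(n-1)$ to 1e-9
relative.

**Clash-energy fit and model selection.**  With per-site $K_d$s fixed
from independent single-site characterization, the permissive model fits
$(\varepsilon_\mathrm{clash}, \mathrm{scale})$ — the scale being the
signal per unit occupancy — by profiling
$\varepsilon_\mathrm{clash}$ on a grid over $[0,30]\,k_BT$ and refining
by bounded scalar minimization; the exclusive alternative fits the scale
only.  The $\varepsilon_\mathrm{clash}$ interval is a curvature-based
(Gaussian) 5–95 % approximation from the RSS profile.  AIC
$=n\ln(\mathrm{RSS}/n)+2k$ and BIC $=n\ln(\mathrm{RSS}/n)+k\ln n$ count
the noise variance in $k$ for both models (permissive $k=3$, exclusive
$k=2$), so criterion differences reflect only the extra clash parameter.

## In vivo analysis

Normalization follows the measurement chain: per time point,
$(\mathrm{GFP}-\mathrm{blank})/(\mathrm{OD}-\mathrm{blank})$, with points
below an OD floor of 0.01 masked to avoid division blow-ups.  The
response window [8.5 h, 9.5 h] after induction is closed at both ends; at
a 10-minute cadence aligned to induction time zero it contains 7
readings.  The TF-specific response is induced − uninduced window means;
the non-specific response is the uninduced difference against a
designated no-site (or ablated) reference strain and may be negative.
Replicates are paired positionally when counts match, otherwise the
unpaired difference of condition means is used.

Copies-per-cell convert to nuclear concentration as
$c=\mathrm{copies}/(N_A V)$; the nuclear volume is an explicit parameter
(default 4.2 fL, under which 538 copies ≈ 213 nM) rather than a hidden
constant, since published copy-number ranges leave the volume implicit.

**Threshold model.**  Expression vs. predicted occupancy is fitted as a
continuous hinge $y=\mathrm{baseline}+\mathrm{slope}\cdot\max(0,\langle
N\rangle-\theta)$.  θ is profiled over a grid of feasible candidates
(each must leave ≥ 1 promoter at/below and ≥ 2 above) and refined by
bounded minimization of the RSS, which recovers noiseless parameters to
1e-6; uncertainty comes from a seeded bootstrap over promoters.
Candidate thresholds start at 0.2 occupancy — activation at a small
fraction of one bound TF is indistinguishable from baseline, and data
entirely below this range raise a "threshold unidentifiable" error.
Occupancy predictions default to the independent model, switching to
permissive for designs with overlapping sites.

## Synthetic generators

`simulate_imitomi` emulates per-chamber equilibrium binding data: 8
log-spaced concentration sections spanning 1–10⁴ nM, 30 chambers per
section (inside the 20–84 per-sample range of such assays), bound signal
$= \mathrm{step}\cdot\langle N\rangle_\mathrm{true}(c)\cdot
(\mathrm{DNA}/\mathrm{DNA}_\mathrm{ref})$ plus Gaussian noise at 5 % of
the single-site saturation signal, and lognormal chamber-to-chamber DNA
variability (10 % CV).  Defaults: step 500 RFU per bound TF, consensus
$K_d$ 10 nM, DNA reference 1000 RFU.  Free concentrations are treated as
known exactly (the assay measures them; concentration error is out of
scope).  Ground truth (per-site $K_d$s, clash energy, step) is emitted
beside every table.

`simulate_platereader` produces OD/GFP/mScarlet readings every 10 min
over 20 h: logistic growth (OD₀ 0.15, capacity 1.2, rate 0.45 h⁻¹), GFP
accumulating at $\dot G = \mathrm{rate}\cdot\mathrm{OD}(t)$ where the
rate combines a baseline, a site-count-proportional non-specific leak
(both conditions) and a hinge response to the predicted occupancy at the
induced nuclear concentration (600 nM default, inside the plausible
213–1322 nM range); blank offsets and reading noise (10 % multiplicative
on fluorescence) are added per channel.  The GFP kinetic shape factor is
normalized so rate units equal window-mean GFP/OD units.

What the generators do **not** emulate: optics and photobleaching,
concentration-measurement error, chamber outliers beyond lognormal DNA
spread, cell-to-cell expression noise, growth differences between
strains, and nucleosome dynamics.  Passing recovery tests therefore
demonstrates correctness of the estimators under the declared noise
model, not robustness to every artefact of real data.

`fixture_library` provides the design families the analysis exercises:
multiplicity series (S1/S3/S6, W1–W6, V-3/V-6, W-6), mixed-affinity
clusters and a reordering (W3V-3, V-3W3), a two-site spacing series
(Δ = 0–20 bp), overlap chains of 2–4 strong or weak sites sharing exactly
1 or 3 bp, two-region native-promoter style N/A/C replacements with 6 bp
motifs, and a no-site NS control.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
1440 chambers for the six-target calibration pipeline, 16-concentration
clash-energy fits, 50-seed recovery/model-selection loops and a 100-
dataset interval-coverage study with 40-point datasets — enough for the
binomial tolerances asserted, while keeping the full suite under a few
minutes on one CPU.

## Known limitations

* The 2-parameter binding curve is intentionally mis-specified for
  mixed-affinity clusters (it is the measurement model, not the truth);
  its $K_d$ is an effective quantity.
* Clash penalties are pair-additive and overlap-extent-blind within one
  fit; heterotypic mixtures, kinetics/dwell times and nucleosome
  competition are out of scope.
* The curvature-based interval for $\varepsilon_\mathrm{clash}$ is a
  local Gaussian approximation and degrades when the estimate sits at
  the boundary (exclusive-like data).
* The hinge threshold model assumes a single global θ and linear
  post-threshold response; saturation of very strong promoters is not
  modeled.
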