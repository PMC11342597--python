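# Methods

## Overview

`stratmode` is a simulation laboratory for a single question: when a fossil
lineage is sampled through an incomplete stratigraphic section and the
resulting series is read as if deposition had been uninterrupted and constant,
how well can the *mode of evolution* — stasis, unbiased random walk (URW),
or biased/general random walk (GRW) — still be identified? The pipeline has
four stages, each usable on its own: trait simulation in continuous time,
forward modelling of a carbonate platform, height→time sampling through
age-depth models, and AICc-based model selection.

## Trait evolution in continuous time

Random walks are simulated as Brownian drift, `X_t = x0 + mu·t + sigma·B_t`,
so that a lineage can be evaluated *exactly* at arbitrary strictly increasing
times: the value over a gap `(t_i, t_{i+1})` is drawn as an independent
Gaussian increment with mean `mu·Δt` and variance `sigma²·Δt`. No
interpolation is ever used — interpolating would induce correlations that
contradict the independent-increments assumption, and exact increments make
the finite-dimensional distributions independent of the grid on which the
lineage is generated (simulating finely and sub-sampling is distributionally
identical to simulating coarsely). The process is anchored at `t = 0` with
value `x0` even when the first sampled time is later; the paper-style
statements "expected change after t" then hold for every sampled time.

Stasis is a sequence of i.i.d. `Normal(m, s²)` values, by construction
independent of the spacing of observation times.

Default parameters are the three study scenarios: stasis `(m=0, s=1)`,
Brownian motion `(mu=0, sigma=1)`, Brownian drift `(mu=5, sigma=1)` — the
drift and volatility chosen so that after 1 Myr the expected change is 5
trait units with SD 1.

Duplicate times are rejected at a tolerance of 1e-12 Myr (zero-duration
increments are degenerate). One root seed per lineage is spawned into
independent streams (lineage, specimen sampling) via `numpy` seed sequences;
generation on the union of several time grids lets the same realization be
observed in both the time and stratigraphic domains.

## Sea-level forcing

Two generators supply eustatic curves on a uniform grid (default step 1 kyr):

* a composite sinusoid, by default 20 m amplitude at 1 Myr period plus 2 m at
  0.112 Myr (phases default to 0 and are configurable);
* a glacioeustatic stand-in for Pleistocene forcing: 41 kyr oscillations whose
  peak-to-trough range ramps linearly from half of 50 m up to 50 m (the
  growth of Northern-Hemisphere ice volume), switching in the youngest
  0.8 Myr to 0.1 Myr cycles with a 140 m range, optionally reddened with an
  AR(1) noise term, and normalized to mean 0 after assembly. This emulates
  the *statistical structure* of published Pleistocene curves (periodicities,
  amplitudes, the mid-Pleistocene transition), not any specific record.

A loader accepts empirical two-column (age, elevation) tables in Myr or ka,
linearly interpolates onto the model grid and then (optionally) removes the
mean; normalization follows interpolation so the delivered curve has exactly
zero mean on the grid actually used.

## Carbonate-platform forward model

The platform model is a deliberately simple accommodation-driven simulator in
the spirit of cellular-automaton carbonate models. Grid: 10 (strike) × 150
(dip) cells of 100 m, 1 kyr steps, uniform subsidence 70 m/Myr, initial
linear ramp of 5.33 m/km (0 m at the shore to 80 m at 15 km, sampled at cell
centres). Water depth at each step is
`initial depth + subsidence·t + (SL(t) − SL(0)) − cumulative thickness`.

Three factories produce at `g_max` (500/160/150 m/Myr) down to a plateau
depth (30/40/40 m) and decay exponentially below it. The decay e-foldings
(10/20/40 m) are the package's own choice, set so the two deep factories
differ in how fast production shuts down with depth; they are exposed in the
configuration. In-situ deposition is capped at the current water depth, so
the platform top locks onto sea level; during lowstands exposure makes
production zero and forces hiatuses — the mechanism that generates the
record's gaps.

Occupancy follows minimal cellular-automaton rules: factories persist while
submerged, die on exposure, and re-flooded barren cells are recolonized by a
uniformly drawn factory after an optional lag (default 0 steps — instant
recolonization; a positive lag models the delayed return of carbonate
producers). An optional neighbor-count survival window exists but is off by
default. Downstream statistics were deliberately chosen not to depend on the
fine structure of these rules.

A fixed fraction (default 0.3) of each cell's production cascades down-dip to
the nearest local topographic low or the basinward boundary, where it
deposits as a "transported" secondary facies labelled by source factory. The
basin is closed — sediment reaching the edge stays — so total deposited
volume equals total produced volume to rounding error. Transported arrivals
are not depth-capped; they land in local lows by construction. The 0.3
fraction is a realistic export share for an attached platform with
significant lowstand shedding; it controls how much slope record exists but
not the platform-top gap structure that drives the inference results.

## Age-depth models and sampling

An age-depth model (ADM) stores cumulative height per 1 kyr step edge.
Completeness is the fraction of steps with positive increment, measured at
the native step; hiatus durations are maximal runs of zero-increment steps
(so single gap steps count as 1 kyr hiatuses and consecutive gaps merge), and
`completeness + Σ gaps / duration = 1` holds exactly at step resolution.
Within a depositing step accumulation is assumed uniform, so both directions
of the time↔height map interpolate linearly inside a step; a height attained
immediately before a hiatus maps to its *earliest* attainment (the deposition
time, not the re-flooding time).

Stratophenetic sampling places one sample every metre starting at 1 m (height
0 is the pre-simulation surface), maps heights to deposition times through
the ADM, simulates the lineage exactly at those times, and draws 100
specimens per sample from `Normal(true mean, 0.1)`; the stored series carries
the empirical mean and unbiased variance, mirroring real data. The
within-sample variance of 0.1 keeps population scatter small against the
Myr-scale evolutionary signal. Time-domain baselines use the same specimen
model at equidistant times including both endpoints.

## Model selection

The statistical core fits Stasis, URW and GRW to a series of sample means
`y_i` with sampling-error variances `eps_i = var_i / n_i` (by default the
sample variances are first pooled by their `(n_i − 1)`-weighted mean). Two
likelihood formulations are implemented:

* **joint** (default): all observations as one multivariate normal; with the
  time origin shifted to the first sample, random walks have mean
  `anc + mstep·t` (`mstep = 0` for URW) and covariance
  `vstep·min(t_i, t_j) + eps_i` on the diagonal;
* **ad** (ancestor–descendant): successive differences treated as independent
  Gaussians, a cheaper approximation.

Parameter counts are joint {Stasis 2, URW 2, GRW 3}, ad {Stasis 2, URW 1,
GRW 2}; the AICc sample size is the number of samples (joint) or differences
(ad). Model weights are Akaike weights of AICc; `n − K − 1 ≤ 0` yields an
infinite AICc and zero weight, which is what penalizes GRW out of contention
for 5-point series.

Numerics: for a fixed variance parameter (omega or vstep) the mean
parameters are profiled out in closed form by generalized least squares, so
each fit reduces to a one-dimensional bounded optimization. That scalar
problem is solved by a deterministic 17-point log-spaced grid scan over
`[1e-8, 100] ×` a moment-based scale, followed by bounded Brent refinement
around the best grid point — a deterministic superset of multi-start that
cannot miss a basin wider than one grid interval and makes fits
bit-reproducible. Variance parameters are floored at `1e-8 ×` the series
variance scale to avoid degenerate likelihoods; singular covariances return
`−inf` rather than raising. When stratigraphic series are fitted, sample
heights stand in for time (the uninterrupted-constant-accumulation reading);
AICc comparisons are invariant to the unknown linear time scale.

## Experiments and problem sizes

The drivers regenerate the study designs: the time-domain baseline grid
(series lengths 5–200, three modes, default 100 replicates), the
stratigraphic experiment at 2/6/8/10/12 km from shore with a matched-length
time-domain baseline, completeness/hiatus profiles along dip, lineage
triplet exports, and misselection rates. Routine runs in the test suite use
20–25 replicates, which is sufficient for the median-based summaries; the
acceptance script uses the full 100. A full platform simulation
(10 × 150 × 2000 steps) takes a few seconds; the complete acceptance run is
well under a minute on one CPU.

## What the synthetic data do and do not show

The generators emulate the statistical structure the analysis assumes:
Gaussian trait increments, i.i.d. specimen scatter, deterministic subsidence,
eustasy-driven gaps. They deliberately exclude erosion, pelagic production,
heterogeneous subsidence, time averaging, taphonomy and abundance gradients
— the model's platforms are conceptual end-members with exaggerated
completeness, and every lineage is equally sampleable everywhere. Passing
tests therefore demonstrate properties of the inference pipeline under these
idealized conditions, not the fidelity of any empirical record. Platform-level
numbers that depend on the internals of the original cellular-automaton
simulator (average completeness percentages, exact hiatus ratios,
misselection percentages) are reproduced qualitatively, not numerically; the
package's own platform yields the same *shape* of results (heavy-tailed gap
distributions, completeness peaks on the slope, stasis robustness, drift
punctuation over gaps).

## Known limitations

* The cellular-automaton rules are minimal stand-ins; facies maps are
  plausible but not calibrated against any published automaton.
* The ad likelihood treats differences as independent, ignoring their shared
  endpoints' sampling noise correlation structure beyond the adjacent terms.
* ADMs are treated as perfectly known ("perfect knowledge" setting);
  stochastic or inferred age-depth models are out of scope.
* Ornstein–Uhlenbeck and Lévy-process models are not fitted; the candidate
  set is exactly {Stasis, URW, GRW}.
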