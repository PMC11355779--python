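# Methods

This note records the models behind `clcphasor`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Phasor FLIM model

A pixel's decay histogram with counts *c_k* in bins centred at *t_k*
(bin width Δ = T/n_bins, laser period T = 1/f) is transformed at harmonic
*n* (default 1) to

    G = Σ c_k cos(2π n t_k / T) / Σ c_k ,
    S = Σ c_k sin(2π n t_k / T) / Σ c_k .

For an ideal (delta-IRF) single-exponential decay of lifetime τ wrapped
over the period, the continuous-time phasor is G = 1/(1+(ωτ)²),
S = ωτ/(1+(ωτ)²) on the universal semicircle; the bin-centre discrete sum
deviates from it by O((Δ/τ)²), about 4×10⁻⁵ at the defaults
(256 bins, 12.5 ns period, τ = 2.5 ns) — negligible against photon noise.
The phase lifetime is τ = S/(2πfG), exact for single-exponential decays
and used as the apparent lifetime for mixtures, as is conventional in
modal phasor analysis.

Pixels with zero photons have no phasor; they are flagged invalid and
excluded from histograms rather than mapped to (0, 0), so the phasor heat
map total always equals the number of informative ROI pixels.

**ROI selection.** "Medium fluorescence level" is operationalized as the
[0.30, 0.80] intensity-quantile band of nonzero pixels (configurable).
The band excludes dim background below and saturated aggregates above; the
exact quantiles matter little for homogeneous synthetic cells and are
recorded in the mask's provenance for real data.

**Modal phasor.** The (G, S) histogram (default 200×200 bins over
[0,1]×[0,0.6]) is searched for its peak bin; a 2-D Gaussian with
independent widths and a constant offset is fitted over a 7×7-bin window
around it, giving a sub-bin mode. A window this size spans roughly ±2.5
per-pixel phasor standard deviations at 10⁴ photons/pixel — wide enough to
constrain the fit, narrow enough not to be biased by the skewed far tails.
If the fit fails or its centre leaves the window, the count-weighted
window centroid is used instead and flagged (`fit_ok=False`). Ties between
equal peak bins resolve to the first in row-major order, with a warning.

**Calibration.** Real instruments add a phase delay and modulation loss;
`calibrate_phasor` rotates/scales phasors so a measured lifetime standard
lands on its theoretical semicircle point. Synthetic ideal-IRF data need
no calibration, so it is off by default.

**FRET.** τ_D is the modal lifetime pooled over all donor-only cells of
an experiment (per-cell matching is available via `pool_donor=False`);
each donor+acceptor cell contributes a modal τ_DA and E = 1 − τ_DA/τ_D.
Negative efficiencies are reported unclipped (with a warning) so the
estimator's distribution around zero is preserved for group statistics.

## Synthetic FLIM data

`simulate_flim_stack` draws independent Poisson counts per pixel and bin
around the expected histogram: a wrapped multi-exponential decay sampled
at bin centres, circularly convolved with a Gaussian IRF when
`irf_sigma > 0`, scaled to `photons_per_pixel` expected signal photons,
plus a uniform background. Defaults — 128×128 px, 256 bins/period, 80 MHz,
10⁴ photons/pixel, ideal IRF, no background — represent a good
photon-counting FLIM acquisition; bin count and photon budget are
acquisition settings that published work rarely states, so these are
deliberate, fixed choices rather than inferred values.

What the generator does **not** emulate: spatial structure (membranes,
vesicles, aggregates — intensity is statistically uniform, so ROI
quantile selection is exercised only against Poisson intensity spread),
detector afterpulsing and dead time, autofluorescence, acceptor
photophysics, and optical blur. Passing recovery tests therefore
demonstrate the estimator chain is unbiased under ideal counting
statistics, not robustness to those instrumental effects.

`simulate_fret_pair` models quenching as a lifetime shortened to
(1−E)·τ_D in a fraction `fret_fraction` of the donor population (default
1); partially interacting populations put the phasor on the chord between
the two component phasors, which the tests verify.

## Cell model and voltage-clamp processing

The simulated cell is a passive membrane — capacitance C (20 pF) charged
through a series resistance R_s (5 MΩ), ohmic leak g_leak (1 nS, reversal
0 mV) — in parallel with a transporter conductance g_max (10 nS) gated by
a Boltzmann steady state p∞(V) = 1/(1+exp(−(V−V½)/k)), V½ = +80 mV,
k = 25 mV. These gate parameters give the smooth, strongly outward
rectification characteristic of endosomal CLC transport currents. After
each voltage step the gate relaxes from its pre-step value toward p∞ with
a rising biexponential (defaults 21 ms and 120 ms, equal weights — the
slowed-activation phenotype). Voltage jumps add a series-RC transient
(ΔV/R_s)·exp(−t/R_sC). Noise is additive Gaussian on currents (per-sample,
default 10 pA) and Poisson on photons — standard rig and detector
statistics. Units: mV, nA, ms, nS, kHz everywhere.

**P/N subtraction** is implemented exactly as defined: corrected =
raw − pn/scale, with the companion recorded under the protocol whose
excursions from holding are scaled by 0.2. For a purely passive cell this
cancels identically (tested to machine precision). A physical caveat the
simulation makes visible: with a 0 mV holding and +200 mV test pulses, the
0.2× companion pulses reach +40 mV, where the default Boltzmann gate is
already ~17% open and the default kinetics leave a 5 ms pulse far from
steady state — so the corrected current is the *model-predicted* P/N
output (tested exactly against the forward model), not the pure
steady-state transporter current. Only for a rapidly gating, sharply
rectifying cell (τ ≪ pulse, k ≈ 10 mV) does the corrected steady current
at +200 mV approximate the transporter current to ~2%, and that case is
tested separately. Same-sign P/N pulses applied where the conductance is
partially active contaminate the correction in real recordings for the
same reason.

**Windows.** Steady-state I-V: mean over the last 20% of the test pulse
(avoids the settling transient). Baseline: final 2 ms of the holding
segment before the step. Both are conventions, exposed as arguments.

**Biexponential fitting** uses variable projection: for fixed (τ_f, τ_s)
the steady level and amplitudes are solved by linear least squares, and
only the log time constants are optimized (bounded trust-region), from a
log-spaced multi-start grid {1, 10, 30, 100, 300} ms; ties break by lowest
residual, then lowest τ_f. The first 1 ms after the step is excluded to
avoid residual capacitive artifacts. A second component is flagged
degenerate when its amplitude falls below 1% of the total rising amplitude
or the time constants are within a factor 1.5. Model choice between 1 and
2 components uses the small-sample corrected Akaike criterion, with the
parsimony rule that a degenerate 2-component fit never wins.

**Slope conductance** is the OLS slope of I on V over −40…+40 mV
(nA/mV → nS), offset-invariant by construction. Off-grid currents
interpolate linearly.

## Colocalization

Pearson r over the whole frame with no thresholding (optional boolean
mask), which is what "default parameters" of the common Fiji plugin do for
the Pearson statistic; per-cell coefficients summarize as mean ± SEM.
The synthetic pair scatters `n_puncta` Gaussian puncta (σ = 2 px, peak
amplitudes 0.5–1) and mixes a shared population into channel B with weight
`mixing` against an independent population — r is 1 at mixing 1 with no
noise, near 0 at mixing 0, and monotone in between (tested by Spearman
rank correlation over 10 levels).

## Statistics

All group comparisons are unpaired Student t-tests assuming equal
variance, two-tailed (the convention of the usual graphing software, and
the natural reading when a test's sidedness is unstated), computable
identically from raw samples or from printed (mean, SD, n) summaries —
the identity is tested to machine precision. Zero pooled variance returns
p = 1 for equal means and p → 0 (flagged) otherwise. The FRET group report
performs raw pairwise tests without multiple-testing correction, matching
figure-legend star conventions, and says so in its output column. One
known discrepancy: recomputing the ClC-3 current comparison from its
printed rounded summaries (2.06 ± 0.97, n=13 vs 0.64 ± 0.37, n=13) gives
p ≈ 5×10⁻⁶, smaller than the printed p = 0.0002; input rounding and/or a
test variant explains the gap, and no test asserts that value.

## Problem sizes and determinism

Recovery studies use 20 activation traces (500 ms at 10 kHz, noise SD 1%
of steady current) and 10 cells per FRET condition (128×128 px, 10⁴
photons/pixel) — sizes at which estimator means are stable to well under
the acceptance tolerances while a full run stays inside a minute on one
core. Every generator is deterministic given its parameters and seed;
`scripts/acceptance.py` derives all per-trace and per-cell seeds from a
single `--seed` via a master generator, and the pipeline driver embeds a
config hash and all seeds in its provenance record so reruns are
byte-identical apart from timestamps.

## Known limitations

* Modal (phase) lifetimes are exact only for single-exponential ROI
  decays; heterogeneous mixtures yield an apparent lifetime, as in any
  single-harmonic phasor analysis.
* The ROI selector operates on intensity quantiles only; it has no notion
  of spatial contiguity or organelle identity.
* The cell model's transporter is a minimal Boltzmann rectifier — no
  proton coupling, gating charge movement, or deactivation tails — and
  the leak reverses at 0 mV.
* Sweep noise is white; real rig noise is colored and line-frequency
  contaminated.
* `compare_exponential_models` stops at two components by design.
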