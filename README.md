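# clcphasor

Quantitative analysis of CLC chloride-transporter regulation by accessory
subunits: fit-free phasor-plot FLIM-FRET, voltage-clamp current processing,
Pearson colocalization, and the summary statistics that turn them into
figure-legend numbers — together with seeded synthetic-data generators that
stand in for the microscope and the patch-clamp rig.

## Who this is for

Studies of endosomal Cl⁻/H⁺ antiporters (ClC-3, ClC-4) and their candidate
accessory proteins combine three kinds of evidence: suppression of
transporter currents under voltage clamp, altered activation kinetics, and
direct physical interaction detected as Förster resonance energy transfer
(FRET) between fluorophore-tagged proteins via donor-lifetime quenching.
`clcphasor` implements the full analysis chain for all three, so each step
is reusable, testable, and reproducible on synthetic data with known ground
truth.

## The core methods

**Phasor FLIM.** Each pixel's time-binned photon decay histogram
(counts *c_k* at bin-center times *t_k* within the laser period) maps to a
point in the phasor plane,

    G = Σ c_k cos(ω t_k) / Σ c_k ,   S = Σ c_k sin(ω t_k) / Σ c_k ,

with ω = 2π·f and f the pulse repetition frequency (80 MHz by default).
Single-exponential decays fall on the universal semicircle
G² + S² = G; mixtures lie inside it on the chord between the component
phasors. The modal phasor of a region of interest — the (G, S) bin with
the most pixels, refined by a local 2-D Gaussian fit — gives the fit-free
lifetime

    τ = S / (2π f G) .

**FLIM-FRET.** FRET shortens the donor lifetime from τ_D (donor-only
cells) to τ_DA (donor + acceptor cells); the efficiency is
E = 1 − τ_DA / τ_D.

**Voltage clamp.** P/N subtraction removes leak and capacitive currents
(record the protocol scaled by 0.2×, rescale by 1/0.2, subtract — all
linear components cancel exactly), followed by baseline subtraction,
steady-state I-V construction, reference (non-injected cell) subtraction,
normalization, slope conductance over −40…+40 mV, and biexponential
fitting of the activation time course
I(t) = I_ss − A_f·e^(−t/τ_f) − A_s·e^(−t/τ_s) with small-sample-AIC model
comparison against the mono-exponential alternative.

**Colocalization.** Pixelwise Pearson correlation between two channels,
whole-frame by default (no thresholding), summarized per cell as
mean ± SEM.

## Worked example

Simulate five donor-only / donor+acceptor cell pairs at a true FRET
efficiency of 0.19 (τ_D = 2.5 ns, 10⁴ photons/pixel) and run the full
phasor pipeline:

```python
from clcphasor import (FlimSimParams, simulate_fret_pair,
                       analyze_fret_experiment)

donors, pairs = [], []
for i in range(5):
    params = FlimSimParams(width=64, height=64, photons_per_pixel=1e4,
                           seed=2 * i)
    d, p = simulate_fret_pair(params, efficiency=0.19)
    donors.append(d); pairs.append(p)

res = analyze_fret_experiment(donors, pairs)
print(f"tau_D = {res.tau_donor:.3f} ns")
print(res.table.round(4).to_string(index=False))
print(f"mean E = {res.mean_efficiency:.3f} +/- {res.sem_efficiency:.4f} "
      f"(SEM, n={res.n_cells})")
```

prints

```
tau_D = 2.500 ns
 cell  tau_donor_ns  tau_da_ns  efficiency
    0        2.5002     2.0240      0.1905
    1        2.5002     2.0264      0.1895
    2        2.5002     2.0241      0.1904
    3        2.5002     2.0255      0.1899
    4        2.5002     2.0253      0.1899
mean E = 0.190 +/- 0.0002 (SEM, n=5)
```

The pooled donor-only modal lifetime is 2.500 ns, each pair cell's modal
lifetime is quenched to ≈2.025 ns, and the recovered group-mean efficiency
matches the generating value 0.19. Comparing two current cohorts straight
from printed figure-legend summaries (mean ± SD, n) works the same way:

```python
from clcphasor import SummaryStats, ttest_from_summary
a = SummaryStats(n=5, mean=1.38, sd=0.58, sem=0.26)
b = SummaryStats(n=4, mean=1.19, sd=0.59, sem=0.295)
r = ttest_from_summary(a, b)
print(f"t = {r.t:.3f}, df = {r.df}, p = {r.p:.3f}")   # t = 0.485, df = 7, p = 0.643
```

A `clcphasor` command-line tool exposes the same steps
(`simulate-flim`, `phasor`, `fret`, `leak-subtract`, `iv`, `conductance`,
`fit-activation`, `coloc`, `ttest-summary`, `run`); see
`clcphasor --help`.

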