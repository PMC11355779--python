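"""Synthetic FLIM stacks, voltage-clamp sweeps and two-channel images.

This module stands in for the microscope and the patch-clamp rig: every
generator produces data with known ground truth, fully determined by its
parameters and seed.

* FLIM: per-pixel photon-count histograms drawn from Poisson statistics of a
  periodic multi-exponential decay under 80 MHz pulsed excitation, with an
  optional Gaussian instrument response and uniform background.
* Electrophysiology: passive RC membrane (capacitive transient + ohmic
  leak) plus an outwardly rectifying transporter current with a Boltzmann
  steady-state gate and rising biexponential activation kinetics.
* Colocalization: punctate two-channel images with a controllable fraction
  of shared structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .coloc import TwoChannelImage
from .ephys import SweepSet, VoltageProtocol
from .flim_phasor import FlimStack

logger = logging.getLogger(__name__)

__all__ = [
    "FlimSimParams",
    "CellModel",
    "ColocSimParams",
    "expected_decay",
    "simulate_flim_stack",
    "simulate_fret_pair",
    "model_current",
    "simulate_sweeps",
    "simulate_pn_pair",
    "simulate_activation_traces",
    "simulate_coloc_pair",
]


# ---------------------------------------------------------------------------
# FLIM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlimSimParams:
    """Parameters of a simulated FLIM acquisition.

    ``lifetimes`` (ns) and ``fractions`` describe the intensity-weighted
    decay components; ``photons_per_pixel`` is the mean signal photon count
    per pixel, on top of which ``background_rate`` counts/bin of uniform
    background are added.  ``irf_sigma`` (ns) widens the instrument
    response from an ideal delta (0) to a wrapped Gaussian.
    """

    width: int = 128
    height: int = 128
    n_bins: int = 256
    laser_freq: float = 80.0            # MHz
    lifetimes: tuple[float, ...] = (2.5,)
    fractions: tuple[float, ...] = (1.0,)
    photons_per_pixel: float = 1e4
    irf_sigma: float = 0.0              # ns
    background_rate: float = 0.0        # counts/bin
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lifetimes", tuple(self.lifetimes))
        object.__setattr__(self, "fractions", tuple(self.fractions))
        if self.n_bins < 16:
            raise ValueError("n_bins must be >= 16")
        if self.laser_freq <= 0:
            raise ValueError("laser_freq must be positive (MHz)")
        if any(tau <= 0 for tau in self.lifetimes):
            raise ValueError("lifetimes must be positive (ns)")
        if len(self.lifetimes) != len(self.fractions):
            raise ValueError("need one fraction per lifetime")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.photons_per_pixel <= 0:
            raise ValueError("photons_per_pixel must be positive")
        if self.irf_sigma < 0 or self.background_rate < 0:
            raise ValueError("irf_sigma and background_rate must be >= 0")

    @property
    def period(self) -> float:
        return 1000.0 / self.laser_freq

    @property
    def bin_width(self) -> float:
        return self.period / self.n_bins


def expected_decay(params: FlimSimParams) -> np.ndarray:
    """Expected photon count per time bin for one pixel (no Poisson noise).

    Each component is an exponential decay wrapped over the laser period
    (photons excited by earlier pulses pile into the current one), sampled
    at bin centers, convolved circularly with a Gaussian IRF when
    ``irf_sigma > 0``, and scaled so the signal sums to
    ``photons_per_pixel``; the uniform background adds
    ``background_rate`` per bin.
    """
    t = (np.arange(params.n_bins) + 0.5) * params.bin_width
    shape = np.zeros(params.n_bins)
    for tau, frac in zip(params.lifetimes, params.fractions):
        comp = np.exp(-t / tau) / (1.0 - np.exp(-params.period / tau))
        shape += frac * comp / comp.sum()
    if params.irf_sigma > 0:
        sigma_bins = params.irf_sigma / params.bin_width
        shape = gaussian_filter1d(shape, sigma_bins, mode="wrap")
    return params.photons_per_pixel * shape + params.background_rate


def simulate_flim_stack(params: FlimSimParams,
                        rng: np.random.Generator | None = None
                        ) -> tuple[FlimStack, np.ndarray]:
    """Draw a Poisson FLIM stack; returns the stack and the ground-truth
    (intensity-weighted mean) lifetime map in ns."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    lam = expected_decay(params)
    counts = rng.poisson(lam, size=(params.height, params.width,
                                    params.n_bins))
    tau_mean = float(np.dot(params.lifetimes, params.fractions))
    truth = np.full((params.height, params.width), tau_mean)
    stack = FlimStack(counts=counts, laser_freq=params.laser_freq,
                      bin_width=params.bin_width,
                      meta={"simulated": True,
                            "lifetimes_ns": list(params.lifetimes),
                            "fractions": list(params.fractions),
                            "photons_per_pixel": params.photons_per_pixel,
                            "seed": params.seed})
    return stack, truth


def simulate_fret_pair(params: FlimSimParams, efficiency: float,
                       fret_fraction: float = 1.0
                       ) -> tuple[FlimStack, FlimStack]:
    """Donor-only and donor+acceptor stacks for one FRET condition.

    The donor-only stack decays with ``tau_D = params.lifetimes[0]``; in
    the pair stack a fraction ``fret_fraction`` of the donor population is
    quenched to ``tau_DA = (1 - efficiency) * tau_D`` while the remainder
    keeps the unquenched lifetime.
    """
    if not (0 <= efficiency < 1):
        raise ValueError("efficiency must be in [0, 1)")
    if not (0 <= fret_fraction <= 1):
        raise ValueError("fret_fraction must be in [0, 1]")
    tau_d = params.lifetimes[0]
    donor_params = replace(params, lifetimes=(tau_d,), fractions=(1.0,))
    if efficiency == 0 or fret_fraction == 0:
        pair_params = replace(donor_params, seed=params.seed + 1)
    else:
        tau_da = (1.0 - efficiency) * tau_d
        if fret_fraction == 1:
            pair_params = replace(params, lifetimes=(tau_da,),
                                  fractions=(1.0,), seed=params.seed + 1)
        else:
            pair_params = replace(
                params, lifetimes=(tau_da, tau_d),
                fractions=(fret_fraction, 1.0 - fret_fraction),
                seed=params.seed + 1)
    donor, _ = simulate_flim_stack(donor_params)
    pair, _ = simulate_flim_stack(pair_params)
    return donor, pair


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellModel:
    """Electrical model of one cell under voltage clamp.

    A passive membrane (capacitance ``membrane_capacitance`` pF charged
    through ``series_resistance`` MOhm, ohmic ``leak_conductance`` nS) in
    parallel with an outwardly rectifying transporter conductance
    ``transporter_gmax`` nS gated by a Boltzmann steady state centred at
    ``v_half`` with slope ``v_slope`` (mV).  On a voltage step the gate
    relaxes with a rising biexponential (fast/slow time constants in ms,
    slow-component weight ``frac_slow``).  Gaussian current noise of SD
    ``noise_sd`` pA is added to every sample.
    """

    membrane_capacitance: float = 20.0   # pF
    leak_conductance: float = 1.0        # nS
    series_resistance: float = 5.0       # MOhm
    transporter_gmax: float = 10.0       # nS
    reversal_potential: float = 0.0      # mV
    v_half: float = 80.0                 # mV
    v_slope: float = 25.0                # mV
    tau_fast: float = 21.0               # ms
    tau_slow: float = 120.0              # ms
    frac_slow: float = 0.5
    noise_sd: float = 10.0               # pA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.membrane_capacitance < 0 or self.leak_conductance < 0 \
                or self.transporter_gmax < 0:
            raise ValueError("capacitance and conductances must be >= 0")
        if self.series_resistance <= 0:
            raise ValueError("series_resistance must be positive")
        if not (0 <= self.frac_slow <= 1):
            raise ValueError("frac_slow must be in [0, 1]")
        if self.tau_fast <= 0 or self.tau_slow <= 0:
            raise ValueError("time constants must be positive")
        if self.tau_fast > self.tau_slow:
            raise ValueError("tau_fast must not exceed tau_slow")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def boltzmann(self, v: float | np.ndarray) -> float | np.ndarray:
        """Steady-state open probability of the transporter gate."""
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - self.v_half)
                                   / self.v_slope))


def model_current(cell: CellModel, protocol: VoltageProtocol,
                  sweep: int) -> np.ndarray:
    """Deterministic (noise-free) model current for one sweep, in nA.

    Sum of the series-RC capacitive transient at every voltage jump, the
    ohmic leak, and the gated transporter current whose activation follows
    a rising biexponential after each step.
    """
    t = protocol.time
    current = np.zeros_like(t)
    tau_c = cell.series_resistance * cell.membrane_capacitance * 1e-3  # ms

    v_prev = protocol.holding_potential
    p_prev = float(cell.boltzmann(v_prev))
    t0 = 0.0
    for seg in protocol.segments:
        v = seg.voltage(sweep)
        sel = (t >= t0) & (t < t0 + seg.duration)
        ts = t[sel] - t0
        # capacitive transient of the jump into this segment
        dv = v - v_prev
        if dv != 0 and cell.membrane_capacitance > 0:
            current[sel] += (dv / cell.series_resistance) * np.exp(-ts / tau_c)
        # ohmic leak: nS * mV = pA -> nA
        current[sel] += cell.leak_conductance * v * 1e-3
        # transporter: gate relaxes from its pre-step level to steady state
        p_inf = float(cell.boltzmann(v))
        act = (1.0 - cell.frac_slow * np.exp(-ts / cell.tau_slow)
               - (1.0 - cell.frac_slow) * np.exp(-ts / cell.tau_fast))
        gate = p_prev + (p_inf - p_prev) * act
        current[sel] += (cell.transporter_gmax * gate
                         * (v - cell.reversal_potential) * 1e-3)
        p_prev = float(p_prev + (p_inf - p_prev)
                       * (1.0 - cell.frac_slow * np.exp(-seg.duration / cell.tau_slow)
                          - (1.0 - cell.frac_slow) * np.exp(-seg.duration / cell.tau_fast)))
        v_prev = v
        t0 += seg.duration
    return current


def simulate_sweeps(cell: CellModel, protocol: VoltageProtocol,
                    rng: np.random.Generator | None = None) -> SweepSet:
    """Simulate a full sweep family for one cell (model + Gaussian noise)."""
    if protocol.sampling_rate * cell.tau_fast < 5:
        logger.warning(
            "sampling rate %.3g kHz resolves tau_fast=%.3g ms with fewer "
            "than 5 samples; fitted kinetics will be unreliable",
            protocol.sampling_rate, cell.tau_fast)
    rng = np.random.default_rng(cell.seed) if rng is None else rng
    samples = np.column_stack([model_current(cell, protocol, i)
                               for i in range(protocol.n_sweeps)])
    if cell.noise_sd > 0:
        samples = samples + rng.normal(0.0, cell.noise_sd * 1e-3,
                                       samples.shape)
    return SweepSet(samples=samples, time=protocol.time, protocol=protocol,
                    provenance=("raw", "simulated"))


def simulate_pn_pair(cell: CellModel, protocol: VoltageProtocol,
                     rng: np.random.Generator | None = None
                     ) -> tuple[SweepSet, SweepSet]:
    """Simulate the measurement sweep set and its P/N companion.

    The companion is the same cell recorded under the protocol with all
    voltage excursions scaled down by ``protocol.pn_scale`` (independent
    noise), as acquired by an amplifier's P/N routine.
    """
    rng = np.random.default_rng(cell.seed) if rng is None else rng
    raw = simulate_sweeps(cell, protocol, rng=rng)
    pn = simulate_sweeps(cell, protocol.scaled(), rng=rng)
    pn = SweepSet(samples=pn.samples, time=pn.time, protocol=protocol,
                  provenance=("pn", "simulated"))
    return raw, pn


def simulate_activation_traces(n_traces: int = 20, i_ss: float = 1.0,
                               tau_fast: float = 21.0, tau_slow: float = 120.0,
                               frac_slow: float = 0.5,
                               noise_frac: float = 0.01,
                               duration: float = 500.0,
                               sampling_rate: float = 10.0,
                               seed: int = 42
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Bare activation time courses for kinetics-recovery studies.

    Each trace is ``I(t) = i_ss * (1 - frac_slow*exp(-t/tau_slow) -
    (1-frac_slow)*exp(-t/tau_fast))`` over ``duration`` ms at
    ``sampling_rate`` kHz, plus Gaussian noise of SD
    ``noise_frac * i_ss``.  Returns ``(time_ms, traces)`` with traces of
    shape ``(n_samples, n_traces)``.
    """
    rng = np.random.default_rng(seed)
    t = (np.arange(int(round(duration * sampling_rate))) + 0.5) / sampling_rate
    clean = i_ss * (1.0 - frac_slow * np.exp(-t / tau_slow)
                    - (1.0 - frac_slow) * np.exp(-t / tau_fast))
    traces = clean[:, None] + rng.normal(
        0.0, noise_frac * i_ss, (t.size, n_traces))
    return t, traces


# ---------------------------------------------------------------------------
# colocalization images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColocSimParams:
    """Parameters of a simulated two-channel punctate image pair.

    ``mixing`` controls the weight of the shared punctum population in
    channel B (1 = channel B sees exactly the channel-A structures,
    0 = fully independent structures).
    """

    width: int = 256
    height: int = 256
    n_puncta: int = 150
    mixing: float = 0.5
    puncta_sigma: float = 2.0          # px
    channel_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.mixing <= 1):
            raise ValueError("mixing must be in [0, 1]")
        if self.n_puncta < 1:
            raise ValueError("need at least one punctum")
        if self.channel_noise_sd < 0:
            raise ValueError("channel_noise_sd must be >= 0")


def _puncta_image(rng: np.random.Generator, params: ColocSimParams
                  ) -> np.ndarray:
    img = np.zeros((params.height, params.width))
    ys = rng.integers(0, params.height, params.n_puncta)
    xs = rng.integers(0, params.width, params.n_puncta)
    amps = rng.uniform(0.5, 1.0, params.n_puncta)
    np.add.at(img, (ys, xs), amps)
    # scale so each punctum keeps ~its drawn peak amplitude after blurring
    return gaussian_filter(img, params.puncta_sigma) * \
        (2.0 * np.pi * params.puncta_sigma ** 2)


def simulate_coloc_pair(params: ColocSimParams) -> TwoChannelImage:
    """Two-channel image with a controllable shared-structure fraction.

    Channel A holds the shared puncta; channel B mixes the shared set
    (weight ``mixing``) with an independent set (weight ``1 - mixing``).
    Pearson correlation between the channels rises monotonically with
    ``mixing``.
    """
    rng = np.random.default_rng(params.seed)
    shared = _puncta_image(rng, params)
    independent = _puncta_image(rng, params)
    noise_a = rng.normal(0.0, params.channel_noise_sd, shared.shape) \
        if params.channel_noise_sd > 0 else 0.0
    noise_b = rng.normal(0.0, params.channel_noise_sd, shared.shape) \
        if params.channel_noise_sd > 0 else 0.0
    channel_a = np.clip(shared + noise_a, 0.0, None)
    channel_b = np.clip(params.mixing * shared
                        + (1.0 - params.mixing) * independent + noise_b,
                        0.0, None)
    return TwoChannelImage(channel_a=channel_a, channel_b=channel_b)
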