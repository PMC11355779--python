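"""Voltage-clamp sweep processing for CLC transporter currents.

Covers the standard whole-cell / two-electrode voltage-clamp analysis chain:
P/N leak-and-capacitance subtraction, baseline subtraction, steady-state I-V
construction, reference (non-injected / untransfected) subtraction,
normalization, slope conductance, and biexponential fitting of the current
activation time course.

Units are mV for voltages, nA for currents, ms for time, nS for
conductances and kHz for sampling rates throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)

__all__ = [
    "ProtocolSegment",
    "VoltageProtocol",
    "SweepSet",
    "IVCurve",
    "BiexpFit",
    "pn_subtract",
    "baseline_subtract",
    "steady_state_iv",
    "subtract_reference_iv",
    "normalize_iv",
    "slope_conductance",
    "fit_biexponential",
    "compare_exponential_models",
    "current_at",
]


@dataclass(frozen=True)
class ProtocolSegment:
    """One segment of a voltage-clamp sweep.

    A fixed segment has ``level`` set; the stepped (family) segment instead
    has ``start`` and ``step`` so sweep ``i`` is held at ``start + i*step``.
    """

    duration: float  # ms
    level: float | None = None  # mV, fixed segment
    start: float | None = None  # mV, family segment
    step: float | None = None   # mV per sweep

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if (self.level is None) == (self.start is None):
            raise ValueError("segment needs either a fixed level or a "
                             "start/step family, not both")
        if self.start is not None and self.step is None:
            raise ValueError("family segment needs a step size")

    def voltage(self, sweep: int) -> float:
        if self.level is not None:
            return self.level
        return self.start + sweep * self.step


@dataclass(frozen=True)
class VoltageProtocol:
    """Step protocol: holding potential, per-sweep segments, sampling."""

    holding_potential: float          # mV
    segments: tuple[ProtocolSegment, ...]
    n_sweeps: int
    sampling_rate: float              # kHz
    pn_scale: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not (0 < self.pn_scale <= 1):
            raise ValueError("pn_scale must be in (0, 1]")
        if self.n_sweeps < 1:
            raise ValueError("need at least one sweep")

    @property
    def sweep_duration(self) -> float:
        return sum(seg.duration for seg in self.segments)

    @property
    def n_samples(self) -> int:
        return int(round(self.sweep_duration * self.sampling_rate))

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms (bin centers of the sampling grid)."""
        return (np.arange(self.n_samples) + 0.5) / self.sampling_rate

    def test_levels(self) -> np.ndarray:
        """Voltage of the (first) family segment for every sweep."""
        for seg in self.segments:
            if seg.start is not None:
                return np.array([seg.voltage(i) for i in range(self.n_sweeps)])
        raise ValueError("protocol has no stepped family segment")

    def segment_window(self, index: int) -> tuple[float, float]:
        """(start, end) time in ms of segment ``index``."""
        t0 = sum(seg.duration for seg in self.segments[:index])
        return t0, t0 + self.segments[index].duration

    def voltage_trace(self, sweep: int) -> np.ndarray:
        """Command voltage at every sample time for one sweep."""
        v = np.empty(self.n_samples)
        t = self.time
        t0 = 0.0
        for seg in self.segments:
            sel = (t >= t0) & (t < t0 + seg.duration)
            v[sel] = seg.voltage(sweep)
            t0 += seg.duration
        return v

    def scaled(self, scale: float | None = None) -> "VoltageProtocol":
        """P/N companion protocol: excursions from holding scaled down."""
        scale = self.pn_scale if scale is None else scale
        hold = self.holding_potential

        def sc(seg: ProtocolSegment) -> ProtocolSegment:
            if seg.level is not None:
                return replace(seg, level=hold + scale * (seg.level - hold))
            return replace(seg, start=hold + scale * (seg.start - hold),
                           step=scale * seg.step)

        return replace(self, segments=tuple(sc(s) for s in self.segments))

    # --- canonical protocols -------------------------------------------

    @classmethod
    def clc_patch_iv(cls, sampling_rate: float = 100.0) -> "VoltageProtocol":
        """HEK whole-cell I-V family: 5 ms pulses from 0 mV holding,
        +200 to -40 mV in 10 mV decrements, 0.2x P/N subtraction."""
        return cls(
            holding_potential=0.0,
            segments=(ProtocolSegment(duration=5.0, level=0.0),
                      ProtocolSegment(duration=5.0, start=200.0, step=-10.0),
                      ProtocolSegment(duration=5.0, level=0.0)),
            n_sweeps=25, sampling_rate=sampling_rate, pn_scale=0.2)

    @classmethod
    def clc_activation(cls, sampling_rate: float = 10.0) -> "VoltageProtocol":
        """Slow-activation family: 500 ms pulses from 0 mV holding,
        +140 to -80 mV in 20 mV decrements, -80 mV tail."""
        return cls(
            holding_potential=0.0,
            segments=(ProtocolSegment(duration=20.0, level=0.0),
                      ProtocolSegment(duration=500.0, start=140.0, step=-20.0),
                      ProtocolSegment(duration=100.0, level=-80.0)),
            n_sweeps=12, sampling_rate=sampling_rate, pn_scale=0.2)

    @classmethod
    def tevc_clc(cls, sampling_rate: float = 10.0) -> "VoltageProtocol":
        """Oocyte TEVC family: 10 ms pulses from -30 mV holding,
        +170 to -10 mV in 10 mV decrements."""
        return cls(
            holding_potential=-30.0,
            segments=(ProtocolSegment(duration=10.0, level=-30.0),
                      ProtocolSegment(duration=10.0, start=170.0, step=-10.0),
                      ProtocolSegment(duration=10.0, level=-30.0)),
            n_sweeps=19, sampling_rate=sampling_rate, pn_scale=0.2)


@dataclass
class SweepSet:
    """A matrix of current sweeps bound to the protocol that evoked them."""

    samples: np.ndarray          # (n_samples, n_sweeps) nA
    time: np.ndarray             # ms
    protocol: VoltageProtocol
    provenance: tuple[str, ...] = ("raw",)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (n_samples, n_sweeps)")
        if self.samples.shape[0] != self.time.size:
            raise ValueError("time base does not match sample matrix")
        if self.samples.shape[1] != self.protocol.n_sweeps:
            raise ValueError(
                f"sweep count {self.samples.shape[1]} does not match the "
                f"protocol family size {self.protocol.n_sweeps}")

    @property
    def n_sweeps(self) -> int:
        return self.samples.shape[1]

    def _window_index(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        if lo < self.time[0] - 1e-9 or hi > self.time[-1] + 1e-9:
            raise ValueError(f"window {window} lies outside the sweep "
                             f"({self.time[0]:.3g}..{self.time[-1]:.3g} ms)")
        idx = np.flatnonzero((self.time >= lo) & (self.time <= hi))
        if idx.size == 0:
            raise ValueError(f"window {window} contains no samples")
        return idx


@dataclass
class IVCurve:
    """Steady-state current-voltage relationship."""

    voltages: np.ndarray                 # mV, strictly monotone
    currents: np.ndarray                 # nA (or dimensionless if normalized)
    dispersion: np.ndarray | None = None
    n: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        dv = np.diff(self.voltages)
        if self.voltages.size > 1 and not (np.all(dv > 0) or np.all(dv < 0)):
            raise ValueError("voltages must be strictly monotone")
        if self.dispersion is not None:
            self.dispersion = np.asarray(self.dispersion, dtype=float)


@dataclass
class BiexpFit:
    """Rising biexponential fit of a current activation time course.

    Model: ``I(t) = I_ss - A_fast*exp(-t/tau_fast) - A_slow*exp(-t/tau_slow)``
    with t measured from the step onset; ``tau_fast <= tau_slow`` by
    convention.  ``n_components`` records whether the second component is
    degenerate (amplitude ~0 or indistinguishable time constants).
    """

    steady_amplitude: float
    amp_fast: float
    amp_slow: float
    tau_fast: float
    tau_slow: float
    residual_rms: float
    n_components: int = 2
    v_test: float = float("nan")


# ---------------------------------------------------------------------------
# sweep-level operations
# ---------------------------------------------------------------------------

def pn_subtract(raw: SweepSet, pn: SweepSet) -> SweepSet:
    """P/N leak and capacitance correction.

    The companion ``pn`` set is recorded with the same timing but with all
    voltage excursions scaled down by ``pn_scale``; rescaling it by
    ``1/pn_scale`` and subtracting cancels every linear (leak + capacitive)
    current component exactly.
    """
    if raw.samples.shape != pn.samples.shape or \
            not np.allclose(raw.time, pn.time):
        raise ValueError("raw and P/N sweep sets have mismatched timing")
    scale = raw.protocol.pn_scale
    if scale is None or scale <= 0:
        raise ValueError("protocol does not define a positive pn_scale")
    corrected = raw.samples - pn.samples / scale
    return SweepSet(samples=corrected, time=raw.time, protocol=raw.protocol,
                    provenance=raw.provenance + ("pn_subtracted",))


def baseline_subtract(sweeps: SweepSet,
                      window: tuple[float, float] | None = None) -> SweepSet:
    """Remove the per-sweep mean current over a holding window.

    Default window: the final 2 ms of the first (holding) segment.
    """
    if window is None:
        t0, t1 = sweeps.protocol.segment_window(0)
        window = (max(t0, t1 - 2.0), t1)
    idx = sweeps._window_index(window)
    baseline = sweeps.samples[idx].mean(axis=0, keepdims=True)
    return SweepSet(samples=sweeps.samples - baseline, time=sweeps.time,
                    protocol=sweeps.protocol,
                    provenance=sweeps.provenance + ("baseline_subtracted",))


def steady_state_iv(sweeps: SweepSet,
                    window: tuple[float, float] | None = None) -> IVCurve:
    """I-V curve from the mean current late in the test pulse.

    Default window: the last 20% of the stepped family segment, where the
    current has settled.
    """
    proto = sweeps.protocol
    fam = next(i for i, s in enumerate(proto.segments) if s.start is not None)
    t0, t1 = proto.segment_window(fam)
    if window is None:
        window = (t1 - 0.2 * (t1 - t0), t1)
    idx = sweeps._window_index(window)
    currents = sweeps.samples[idx].mean(axis=0)
    voltages = proto.test_levels()
    order = np.argsort(voltages)
    return IVCurve(voltages=voltages[order], currents=currents[order])


def subtract_reference_iv(iv: IVCurve, reference: IVCurve) -> IVCurve:
    """Subtract a reference I-V (e.g. non-injected oocytes) pointwise."""
    if iv.voltages.shape != reference.voltages.shape or \
            not np.allclose(iv.voltages, reference.voltages):
        raise ValueError("I-V voltage grids do not match")
    disp = None
    if iv.dispersion is not None and reference.dispersion is not None:
        disp = np.hypot(iv.dispersion, reference.dispersion)
    return IVCurve(voltages=iv.voltages,
                   currents=iv.currents - reference.currents,
                   dispersion=disp, normalized=iv.normalized)


def normalize_iv(iv: IVCurve, reference_value: float) -> IVCurve:
    """Divide all currents by a reference current (e.g. the wild-type
    current at +170 mV), yielding a dimensionless curve."""
    if reference_value == 0:
        raise ValueError("cannot normalize by a zero reference current")
    disp = None if iv.dispersion is None else iv.dispersion / abs(reference_value)
    return IVCurve(voltages=iv.voltages, currents=iv.currents / reference_value,
                   dispersion=disp, normalized=True)


def slope_conductance(iv: IVCurve,
                      v_range: tuple[float, float] = (-40.0, 40.0)) -> float:
    """Ordinary least-squares slope of I on V over ``v_range``, in nS.

    With currents in nA and voltages in mV the raw slope is nA/mV = uS, so
    it is converted to nS.  Invariant to any constant current offset.
    """
    sel = (iv.voltages >= v_range[0]) & (iv.voltages <= v_range[1])
    if sel.sum() < 3:
        raise ValueError("need at least 3 I-V points inside the voltage range")
    slope_uS = np.polyfit(iv.voltages[sel], iv.currents[sel], 1)[0]
    return float(slope_uS * 1e3)


def current_at(iv: IVCurve, v: float) -> float:
    """Current at voltage ``v`` (exact at grid points, linear between)."""
    vmin, vmax = iv.voltages.min(), iv.voltages.max()
    if not (vmin <= v <= vmax):
        raise ValueError(f"{v} mV is outside the I-V grid "
                         f"[{vmin:g}, {vmax:g}] mV")
    asc = np.argsort(iv.voltages)
    return float(np.interp(v, iv.voltages[asc], iv.currents[asc]))


# ---------------------------------------------------------------------------
# activation-kinetics fitting
# ---------------------------------------------------------------------------

_TAU_STARTS = (1.0, 10.0, 30.0, 100.0, 300.0)  # ms, log-spaced multi-start


def _exp_design(t: np.ndarray, taus: Sequence[float]) -> np.ndarray:
    cols = [np.ones_like(t)] + [-np.exp(-t / tau) for tau in taus]
    return np.column_stack(cols)


def _project_amplitudes(t, y, taus):
    """Best-fit (I_ss, amplitudes) for fixed time constants (linear LS)."""
    design = _exp_design(t, taus)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(np.sqrt(np.mean(resid ** 2)))


def _fit_n_exp(t, y, n_components):
    """Variable-projection fit of an n-component rising exponential."""
    best = None
    starts = ([(tf,) for tf in _TAU_STARTS] if n_components == 1 else
              [(tf, ts) for tf in _TAU_STARTS for ts in _TAU_STARTS
               if tf < ts])
    span = t[-1] - t[0]

    def residual(log_taus):
        taus = np.exp(log_taus)
        design = _exp_design(t, taus)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return y - design @ coef

    for start in starts:
        try:
            sol = least_squares(
                residual, np.log(start),
                bounds=(np.log(1e-3), np.log(50 * span)), method="trf")
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        taus = np.exp(sol.x)
        coef, rms = _project_amplitudes(t, y, taus)
        key = (round(rms, 12), round(float(np.min(taus)), 6))
        if best is None or key < best[0]:
            best = (key, taus, coef, rms)
    if best is None:
        raise RuntimeError("exponential fit failed to converge from every "
                           "starting point")
    _, taus, coef, rms = best
    return taus, coef, rms


def fit_biexponential(time: np.ndarray, current: np.ndarray,
                      v_test: float = float("nan"), t_start: float = 1.0,
                      degenerate_amp_frac: float = 0.01,
                      degenerate_tau_ratio: float = 1.5) -> BiexpFit:
    """Fit a rising biexponential to one activation trace.

    ``time`` is measured from the step onset (ms); samples before
    ``t_start`` (default 1 ms) are excluded to avoid residual capacitive
    artifacts.  Time constants use a log-spaced multi-start grid with the
    amplitudes solved linearly at each step (variable projection); ties are
    broken by lowest residual, then lowest fast time constant.  A second
    component with amplitude below ``degenerate_amp_frac`` of the total
    rising amplitude, or with time constants closer than
    ``degenerate_tau_ratio``, is flagged degenerate (``n_components=1``).
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    sel = time >= t_start
    if sel.sum() < 8:
        raise ValueError("too few samples after t_start to fit")
    t, y = time[sel], current[sel]
    taus, coef, rms = _fit_n_exp(t, y, 2)
    order = np.argsort(taus)
    tau_fast, tau_slow = float(taus[order[0]]), float(taus[order[1]])
    amp_fast, amp_slow = float(coef[1 + order[0]]), float(coef[1 + order[1]])
    total_amp = abs(amp_fast) + abs(amp_slow)
    n_comp = 2
    if total_amp > 0 and (min(abs(amp_fast), abs(amp_slow)) <
                          degenerate_amp_frac * total_amp):
        n_comp = 1
    if tau_slow < degenerate_tau_ratio * tau_fast:
        n_comp = 1
    if n_comp == 1:
        logger.warning("biexponential fit degenerate (amp_fast=%.3g, "
                       "amp_slow=%.3g, tau_fast=%.3g, tau_slow=%.3g); "
                       "a single component may suffice",
                       amp_fast, amp_slow, tau_fast, tau_slow)
    return BiexpFit(steady_amplitude=float(coef[0]), amp_fast=amp_fast,
                    amp_slow=amp_slow, tau_fast=tau_fast, tau_slow=tau_slow,
                    residual_rms=rms, n_components=n_comp, v_test=v_test)


def compare_exponential_models(time: np.ndarray, current: np.ndarray,
                               v_test: float = float("nan"),
                               t_start: float = 1.0,
                               max_components: int = 2):
    """Fit 1- and 2-component activation models and pick one by AICc.

    Returns ``(chosen_n, fits)`` where ``fits[n]`` is the fit with ``n``
    components.  The small-sample corrected Akaike criterion guards against
    preferring a redundant second exponential on mono-exponential data.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    sel = time >= t_start
    t, y = time[sel], current[sel]
    n = y.size
    fits: dict[int, BiexpFit] = {}
    aicc: dict[int, float] = {}
    for n_comp in range(1, max_components + 1):
        taus, coef, rms = _fit_n_exp(t, y, n_comp)
        order = np.argsort(taus)
        tau_sorted = [float(taus[i]) for i in order]
        amp_sorted = [float(coef[1 + i]) for i in order]
        if n_comp == 1:
            fit = BiexpFit(steady_amplitude=float(coef[0]),
                           amp_fast=amp_sorted[0], amp_slow=0.0,
                           tau_fast=tau_sorted[0], tau_slow=float("inf"),
                           residual_rms=rms, n_components=1, v_test=v_test)
        else:
            total_amp = abs(amp_sorted[0]) + abs(amp_sorted[1])
            degenerate = (
                (total_amp > 0 and min(abs(amp_sorted[0]), abs(amp_sorted[1]))
                 < 0.01 * total_amp)
                or tau_sorted[1] < 1.5 * tau_sorted[0])
            fit = BiexpFit(steady_amplitude=float(coef[0]),
                           amp_fast=amp_sorted[0], amp_slow=amp_sorted[1],
                           tau_fast=tau_sorted[0], tau_slow=tau_sorted[1],
                           residual_rms=rms,
                           n_components=1 if degenerate else 2,
                           v_test=v_test)
        k = 2 * n_comp + 2  # amplitudes + taus + steady level + noise sigma
        rss = max(n * rms ** 2, 1e-300)
        val = n * np.log(rss / n) + 2 * k
        if n - k - 1 > 0:
            val += 2 * k * (k + 1) / (n - k - 1)
        fits[n_comp] = fit
        aicc[n_comp] = val
    chosen = min(aicc, key=aicc.get)
    # parsimony: identical-tau or vanishing second component never wins
    if chosen == 2 and fits[2].n_components == 1:
        chosen = 1
    return chosen, fits


def cohort_current_at(ivs: Sequence[IVCurve], v: float):
    """Mean and SD of the current at ``v`` across a cohort of cells."""
    vals = np.array([current_at(iv, v) for iv in ivs])
    sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return float(vals.mean()), sd, vals.size
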