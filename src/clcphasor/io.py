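"""File formats and the pipeline driver.

FLIM stacks travel as multi-page TIFF (one page per time bin) with a JSON
metadata sidecar, or as a single HDF5 file; sweep sets as CSV (column 0 =
time in ms, remaining columns = sweeps in nA) with a JSON protocol sidecar.
Units everywhere: mV, nA, ms, ns, MHz, kHz.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .ephys import ProtocolSegment, SweepSet, VoltageProtocol
from .flim_phasor import FlimStack, analyze_fret_experiment
from .stats_report import fret_group_report
from .synthgen import FlimSimParams, simulate_fret_pair

logger = logging.getLogger(__name__)

__all__ = [
    "read_flim_stack", "write_flim_stack",
    "read_sweeps", "write_sweeps",
    "run_pipeline",
]

_REQUIRED_FLIM_KEYS = ("laser_freq_MHz", "bin_width_ns")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


# ---------------------------------------------------------------------------
# FLIM stacks
# ---------------------------------------------------------------------------

def write_flim_stack(stack: FlimStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF (+JSON sidecar) or HDF5, by suffix."""
    path = Path(path)
    meta = {"laser_freq_MHz": stack.laser_freq,
            "bin_width_ns": stack.bin_width, **stack.meta}
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("counts", data=stack.counts,
                                    compression="gzip")
            dset.attrs["axes"] = "YXT"
            f.attrs["meta"] = json.dumps(meta)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        pages = np.moveaxis(stack.counts, 2, 0).astype(np.uint32)
        tifffile.imwrite(path, pages)
        _sidecar(path).write_text(json.dumps(meta, indent=1))
    else:
        raise ValueError(f"unsupported stack container: {path.suffix}")
    return path


def read_flim_stack(path: str | Path) -> FlimStack:
    """Read a stack written by :func:`write_flim_stack` (or any multi-page
    TIFF with a compatible JSON sidecar)."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            counts = f["counts"][()]
            meta = json.loads(f.attrs["meta"])
    elif path.suffix.lower() in {".tif", ".tiff"}:
        sidecar = _sidecar(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"missing metadata sidecar {sidecar.name}: required keys "
                f"{list(_REQUIRED_FLIM_KEYS)}")
        meta = json.loads(sidecar.read_text())
        counts = np.moveaxis(tifffile.imread(path), 0, 2)
    else:
        raise ValueError(f"unsupported stack container: {path.suffix}")
    missing = [k for k in _REQUIRED_FLIM_KEYS if k not in meta]
    if missing:
        raise KeyError(f"stack metadata missing required keys: {missing}")
    extra = {k: v for k, v in meta.items() if k not in _REQUIRED_FLIM_KEYS}
    return FlimStack(counts=counts, laser_freq=meta["laser_freq_MHz"],
                     bin_width=meta["bin_width_ns"], meta=extra)


# ---------------------------------------------------------------------------
# sweep sets
# ---------------------------------------------------------------------------

def _protocol_to_dict(proto: VoltageProtocol) -> dict:
    return {
        "holding_potential_mV": proto.holding_potential,
        "segments": [dataclasses.asdict(s) for s in proto.segments],
        "n_sweeps": proto.n_sweeps,
        "sampling_rate_kHz": proto.sampling_rate,
        "pn_scale": proto.pn_scale,
    }


def _protocol_from_dict(d: dict) -> VoltageProtocol:
    return VoltageProtocol(
        holding_potential=d["holding_potential_mV"],
        segments=tuple(ProtocolSegment(**s) for s in d["segments"]),
        n_sweeps=d["n_sweeps"],
        sampling_rate=d["sampling_rate_kHz"],
        pn_scale=d.get("pn_scale", 0.2),
    )


def write_sweeps(sweeps: SweepSet, path: str | Path) -> Path:
    """Write a sweep set as CSV plus a JSON protocol sidecar."""
    path = Path(path)
    cols = {"time_ms": sweeps.time}
    for i in range(sweeps.n_sweeps):
        cols[f"sweep_{i:03d}_nA"] = sweeps.samples[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)
    side = {"protocol": _protocol_to_dict(sweeps.protocol),
            "provenance": list(sweeps.provenance)}
    _sidecar(path).write_text(json.dumps(side, indent=1))
    return path


def read_sweeps(path: str | Path) -> SweepSet:
    """Read a sweep set written by :func:`write_sweeps`."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing protocol sidecar {sidecar.name}")
    side = json.loads(sidecar.read_text())
    proto = _protocol_from_dict(side["protocol"])
    frame = pd.read_csv(path)
    time = frame.iloc[:, 0].to_numpy()
    samples = frame.iloc[:, 1:].to_numpy()
    if samples.shape[1] != proto.n_sweeps:
        raise ValueError(f"CSV has {samples.shape[1]} sweep columns but the "
                         f"protocol declares {proto.n_sweeps}")
    if samples.shape[0] != proto.n_samples:
        raise ValueError(f"CSV has {samples.shape[0]} rows but the protocol "
                         f"implies {proto.n_samples} samples")
    dt = np.diff(time)
    if dt.size and not np.allclose(dt, 1.0 / proto.sampling_rate, rtol=1e-6):
        raise ValueError("CSV time base does not match the sidecar "
                         "sampling rate")
    return SweepSet(samples=samples, time=time, protocol=proto,
                    provenance=tuple(side.get("provenance", ("raw",))))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_KNOWN_STAGES = {"simulate_fret", "analyze_fret", "report"}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run a config-driven synthetic FRET experiment end-to-end.

    ``config`` keys: ``stages`` (ordered subset of ``simulate_fret``,
    ``analyze_fret``, ``report``); ``flim`` (FlimSimParams overrides);
    ``groups`` (list of ``{name, efficiency, fret_fraction, n_cells,
    seed}``); ``roi`` (``low``/``high`` quantiles).  Outputs per-cell and
    group CSV/JSON plus a provenance record; reruns with the same config
    and seeds are identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", ["simulate_fret", "analyze_fret", "report"])
    unknown = set(stages) - _KNOWN_STAGES
    if unknown:
        raise ValueError(f"unknown pipeline stage(s): {sorted(unknown)}")

    provenance = {"config": config, "config_hash": _config_hash(config),
                  "package_version": __version__, "stages_run": []}
    state: dict = {}
    for stage in stages:
        logger.info("pipeline stage: %s", stage)
        try:
            if stage == "simulate_fret":
                state["experiments"] = _stage_simulate(config)
            elif stage == "analyze_fret":
                if "experiments" not in state:
                    raise ValueError("analyze_fret requires simulate_fret "
                                     "output")
                state["results"] = {
                    name: analyze_fret_experiment(
                        donors, pairs,
                        roi_low=config.get("roi", {}).get("low", 0.3),
                        roi_high=config.get("roi", {}).get("high", 0.8))
                    for name, (donors, pairs) in state["experiments"].items()}
            elif stage == "report":
                if "results" not in state:
                    raise ValueError("report requires analyze_fret output")
                state["report"] = _stage_report(state["results"], outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") \
                from exc
        provenance["stages_run"].append(stage)

    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1,
                                                       default=str))
    return state


def _stage_simulate(config: dict):
    flim_kwargs = dict(config.get("flim", {}))
    experiments = {}
    for group in config["groups"]:
        base_seed = int(group.get("seed", 0))
        donors, pairs = [], []
        for cell in range(int(group["n_cells"])):
            params = FlimSimParams(**{**flim_kwargs,
                                      "seed": base_seed + 2 * cell})
            d, p = simulate_fret_pair(
                params, efficiency=float(group["efficiency"]),
                fret_fraction=float(group.get("fret_fraction", 1.0)))
            donors.append(d)
            pairs.append(p)
        experiments[group["name"]] = (donors, pairs)
    return experiments


def _stage_report(results, outdir: Path) -> dict:
    tables = []
    for name, res in results.items():
        tbl = res.table.copy()
        tbl.insert(0, "group", name)
        tables.append(tbl)
    per_cell = pd.concat(tables, ignore_index=True)
    per_cell.to_csv(outdir / "fret_per_cell.csv", index=False)
    summary, tests = fret_group_report(
        {name: res.table["efficiency"].tolist()
         for name, res in results.items()})
    summary.to_csv(outdir / "fret_groups.csv", index=False)
    tests.to_csv(outdir / "fret_pairwise_tests.csv", index=False)
    return {"per_cell": per_cell, "summary": summary, "tests": tests}
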