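"""Shared engineering: config loading/validation, run manifests, CSV/JSON
readers and writers for all artifact types, and a canonical fixture bundle.

CSV dialect: comma-separated, UTF-8, header row, '.' decimal, times in
seconds as floats.  Every result file can echo the configuration and seed
that produced it via the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Type, TypeVar

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clamp_controller import ClampConfig, OpenLoopProtocol, PulseLog, run_session_protocol
from .synth_neuro import SpikeTrains, TraceSet, default_population
from .bci_task import BCIAgent, EnsembleSpec, run_session

__all__ = [
    "load_config",
    "save_config",
    "write_traceset_csv",
    "read_traceset_csv",
    "write_pulselog_csv",
    "read_pulselog_csv",
    "write_spiketrains_csv",
    "read_spiketrains_csv",
    "write_json_report",
    "read_json_report",
    "RunManifest",
    "file_digest",
    "make_fixtures",
]

T = TypeVar("T")


def load_config(path: str | Path, schema: Type[T]) -> T:
    """Load a YAML/JSON config into a dataclass schema.

    Unknown keys are rejected with a message listing them; missing keys take
    the schema defaults; the dataclass's own validation then applies.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(schema)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ValueError(f"unknown config keys for {schema.__name__}: {unknown}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return schema(**coerced)


def save_config(config: Any, path: str | Path) -> None:
    """Write a dataclass config as YAML (JSON if the suffix is .json)."""
    path = Path(path)
    data = dataclasses.asdict(config)
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


# ---------------------------------------------------------------------------
# tabular writers/readers


def write_traceset_csv(traces: TraceSet, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": traces.times})
    for i, roi in enumerate(traces.roi_ids):
        df[roi] = traces.data[i]
    df.to_csv(path, index=False)


def read_traceset_csv(path: str | Path) -> TraceSet:
    df = pd.read_csv(path)
    times = df.pop("time_s").to_numpy()
    if times.size < 2:
        raise ValueError("trace file must contain at least two samples")
    fs = 1.0 / float(np.median(np.diff(times)))
    return TraceSet(data=df.to_numpy().T, fs=fs, roi_ids=list(df.columns))


def write_pulselog_csv(log: PulseLog, path: str | Path) -> None:
    df = log.events.copy()
    df["mode"] = log.mode
    df.to_csv(path, index=False)


def read_pulselog_csv(path: str | Path) -> PulseLog:
    df = pd.read_csv(path)
    mode = str(df.pop("mode").iloc[0]) if "mode" in df and len(df) else "closed_loop"
    return PulseLog(events=df, mode=mode)


def write_spiketrains_csv(spikes: SpikeTrains, path: str | Path) -> None:
    rows = []
    for roi, train in enumerate(spikes.trains):
        for t in train:
            rows.append({"roi_id": roi, "time_s": t})
    pd.DataFrame(rows, columns=["roi_id", "time_s"]).to_csv(path, index=False)


def read_spiketrains_csv(path: str | Path, n_roi: int, duration: float) -> SpikeTrains:
    df = pd.read_csv(path)
    trains = [
        df.loc[df["roi_id"] == i, "time_s"].to_numpy() for i in range(n_roi)
    ]
    return SpikeTrains(trains=trains, duration=duration)


def write_json_report(obj: Any, path: str | Path) -> None:
    """Serialize a dataclass/dict report (numpy-aware) to JSON."""

    def default(o: Any):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON serializable: {type(o).__name__}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default), encoding="utf-8")


def read_json_report(path: str | Path) -> Any:
    return json.loads(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# manifests


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config echo, seed, version and file digests."""

    seed: int
    config: dict[str, Any] = field(default_factory=dict)
    version: str = __version__
    files: dict[str, str] = field(default_factory=dict)
    timestamp: str | None = None

    def add_file(self, path: str | Path) -> None:
        self.files[Path(path).name] = file_digest(path)

    def write(self, path: str | Path) -> None:
        write_json_report(dataclasses.asdict(self), path)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**read_json_report(path))


# ---------------------------------------------------------------------------
# canonical fixture bundle


def make_fixtures(seed: int, outdir: str | Path) -> RunManifest:
    """Emit a small canonical dataset bundle, deterministic per seed.

    Contents: a 46-ROI population clamp recording (ROI 5 clamped, 17 other
    ROIs coupled to it), one single-neuron clamp session with pre/post
    probes, and one 4-neuron BCI ensemble session.  Timestamps are omitted
    so identical seeds give byte-identical bundles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed)

    # --- 46-ROI population with 17 ROIs coupled to the clamped ROI 5 ------
    n_roi, clamped, n_coupled = 46, 5, 17
    rng = np.random.default_rng(seed)
    coupling = np.zeros((n_roi, n_roi))
    others = [i for i in range(n_roi) if i != clamped]
    driven = rng.choice(others, size=n_coupled, replace=False)
    coupling[driven, clamped] = 0.06
    model = default_population(n_roi=n_roi, coupling=coupling, seed=seed, clamped_index=clamped)
    cfg = ClampConfig(k_sd=5.0, t_cl=120.0, baseline_window_s=40.0)
    from .clamp_controller import run_closed_loop  # local to avoid cycle at import

    run = run_closed_loop(model, clamped, cfg, seed=seed)
    write_traceset_csv(run.traces, outdir / "population_traces.csv")
    write_pulselog_csv(run.pulses, outdir / "population_pulses.csv")
    save_config(cfg, outdir / "population_clamp_config.yaml")
    np.savetxt(outdir / "population_coupling.csv", coupling, delimiter=",", fmt="%.4g")

    # --- single-neuron full session protocol ------------------------------
    session_model = default_population(n_roi=1, seed=seed + 1)
    protocol = OpenLoopProtocol(post_offsets_s=(180.0,))
    session_cfg = ClampConfig(k_sd=5.0, t_cl=200.0)
    bundle = run_session_protocol(session_model, 0, session_cfg, protocol, seed=seed + 1)
    write_traceset_csv(bundle.traces, outdir / "session_traces.csv")
    write_pulselog_csv(bundle.clamp_pulses, outdir / "session_clamp_pulses.csv")
    write_json_report(
        {"segments": bundle.segments, "a_cl": bundle.a_cl, "seed": bundle.seed},
        outdir / "session_manifest.json",
    )

    # --- one BCI ensemble session -----------------------------------------
    agent = BCIAgent(seed=seed + 2)
    spec = EnsembleSpec()
    metrics, records, rates = run_session(agent, spec, n_trials=30, seed=seed + 2)
    trials = pd.DataFrame(
        {
            "trial": np.arange(len(records)),
            "success": [r.success for r in records],
            "tt": [r.tt for r in records],
            "start_pos": [r.start_pos for r in records],
        }
    )
    trials.to_csv(outdir / "bci_trials.csv", index=False)
    rates.to_csv(outdir / "bci_rates.csv", index=False)
    write_json_report(metrics, outdir / "bci_session_metrics.json")

    for name in sorted(p.name for p in outdir.iterdir() if p.suffix in {".csv", ".yaml", ".json"}):
        if name != "manifest.json":
            manifest.add_file(outdir / name)
    manifest.write(outdir / "manifest.json")
    return manifest
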