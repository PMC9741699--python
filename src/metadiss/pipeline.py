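"""Per-system orchestration and cross-system depth-Tm correlation.

A *system* is one protein complex with a set of repeated metadynamics
runs, each contributing a structural trajectory, a HILLS record and a
COLVAR series.  ``run_system`` chains the per-system stages: descriptors
-> state fits on a bound reference window -> transition detection per run
-> free-energy profiles truncated at each run's detected dissociation ->
combined depth with leave-one-out errors -> window-resolved contact
occurrence -> orientation variability.  ``run_panel`` repeats this across
systems and correlates the depths with experimental melting temperatures,
excluding systems without a Tm (they stay in the depth table, marked).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import contacts as contacts_mod
from . import descriptors as desc_mod
from . import free_energy as fe_mod
from . import orientation as orient_mod
from . import states as states_mod
from .errors import InsufficientReplicatesError, MetadissError

logger = logging.getLogger("metadiss.pipeline")

__all__ = ["RunPaths", "SystemRecord", "PipelineConfig", "run_system", "run_panel"]


@dataclass
class RunPaths:
    trajectory: str
    hills: str
    colvar: str


@dataclass
class SystemRecord:
    system_id: str
    runs: list[RunPaths]
    bound_region: tuple[float, float]
    tm_celsius: Optional[float] = None
    chain_a: str = "a"
    chain_b: str = "b"
    frame_spacing: float = 1.0

    def __post_init__(self):
        if not self.runs:
            raise MetadissError(f"system {self.system_id}: needs at least one run")
        self.runs = [
            RunPaths(**r) if isinstance(r, dict) else r for r in self.runs
        ]
        self.bound_region = tuple(self.bound_region)


@dataclass
class PipelineConfig:
    """All knobs of the stage chain, with the defaults of their modules."""

    native_cutoff: float = 4.5
    probe_radius: float = 1.4
    sasa_points: int = 240
    threshold_dissociation: float = 0.5
    threshold_unbound: float = 0.05
    min_dwell: Optional[int] = None
    bound_reference_fraction: float = 0.45  # first fraction of run 1 fits the sigmoids
    temperature: float = 300.0
    min_occurrence: float = 0.2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data.get("config", data))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def run_system(
    record: SystemRecord,
    config: Optional[PipelineConfig] = None,
    out_dir=None,
) -> dict:
    """Execute the full stage chain for one system; returns a manifest entry."""
    config = config or PipelineConfig()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    entry: dict = {"system_id": record.system_id, "tm_celsius": record.tm_celsius,
                   "runs": [], "warnings": []}

    fe_runs = []
    truncate_frames = []
    fits = None
    native = None
    all_contacts_by_window: dict[str, list] = {"bound": [], "encounter": []}
    orientation_summaries = []

    for i_run, run in enumerate(record.runs):
        logger.info("system %s: run %d descriptors", record.system_id, i_run)
        traj = desc_mod.load_trajectory(
            run.trajectory,
            chain_a=record.chain_a,
            chain_b=record.chain_b,
            frame_spacing=record.frame_spacing,
        )
        if native is None:
            native = desc_mod.define_native_contacts(
                traj.frame(0), config.native_cutoff, record.chain_a, record.chain_b
            )
        descriptors = desc_mod.descriptor_timeseries(
            traj, native, probe_radius=config.probe_radius,
            sasa_points=config.sasa_points,
            chain_a=record.chain_a, chain_b=record.chain_b,
        )
        if fits is None:
            n_ref = max(1, int(config.bound_reference_fraction * traj.n_frames))
            bound_window = {k: v.values[:n_ref] for k, v in descriptors.items()}
            fits = states_mod.fit_state_model(bound_window, min_samples=min(100, n_ref))

        labels, report = states_mod.classify_states(
            descriptors,
            fits,
            threshold_dissociation=config.threshold_dissociation,
            threshold_unbound=config.threshold_unbound,
            min_dwell=config.min_dwell,
        )
        run_entry = {
            "t_dissociation": report.t_dissociation,
            "t_unbound": report.t_unbound,
        }
        if report.t_dissociation is None:
            run_entry["flag"] = "no-dissociation"
            entry["warnings"].append(f"run {i_run}: no dissociation detected")
        entry["runs"].append(run_entry)

        cv = fe_mod.read_colvar(run.colvar)
        hills = fe_mod.read_hills(run.hills)
        fe_runs.append((cv, hills))
        if report.t_dissociation is None:
            truncate_frames.append(None)  # full run contributes
        else:
            # map the structural transition frame to the CV series by the
            # elapsed fraction of the trajectory
            frac = report.t_dissociation / traj.n_frames
            truncate_frames.append(max(1, int(frac * len(cv))))

        per_frame = contacts_mod.detect_contacts_trajectory(
            traj, chain_a=record.chain_a, chain_b=record.chain_b
        )
        t_d = report.t_dissociation or traj.n_frames
        t_u = report.t_unbound or traj.n_frames
        if t_d > 0:
            all_contacts_by_window["bound"].extend(per_frame[:t_d])
        if t_u > t_d:
            all_contacts_by_window["encounter"].extend(per_frame[t_d:t_u])

        dfd = orient_mod.define_reference_frames(
            traj.frame(0), chain_a=record.chain_a, chain_b=record.chain_b
        )
        metrics = orient_mod.orientation_timeseries(traj, dfd)
        window_labels = labels.copy()
        try:
            summary = orient_mod.variability_summary(
                metrics[list(orient_mod.METRIC_NAMES)], window_labels
            )
            orientation_summaries.append(summary.to_dict(orient="records"))
        except MetadissError as exc:
            entry["warnings"].append(f"run {i_run}: orientation summary: {exc}")

    # free energy: combined depth with LOO errors
    try:
        est = fe_mod.loo_depth(
            fe_runs,
            bound_region=record.bound_region,
            temperature=config.temperature,
            truncate_frames=truncate_frames,
        )
        entry["depth"] = {
            "mean_depth": est.mean_depth,
            "loo_min": est.loo_min,
            "loo_max": est.loo_max,
            "n_runs": est.n_runs,
        }
    except InsufficientReplicatesError as exc:
        entry["depth"] = None
        entry["warnings"].append(str(exc))

    for window, frames in all_contacts_by_window.items():
        if not frames:
            continue
        occ = contacts_mod.occurrence(frames, label=window)
        occ = contacts_mod.filter_occurrence(occ, config.min_occurrence)
        if out_dir is not None:
            contacts_mod.write_occurrence_csv(
                occ, out_dir / f"{record.system_id}_occurrence_{window}.csv"
            )
        entry[f"n_contacts_{window}"] = len(occ.entries)

    entry["orientation"] = orientation_summaries
    if out_dir is not None:
        with open(out_dir / f"{record.system_id}_manifest.json", "w") as fh:
            json.dump(entry, fh, indent=1, default=_json_default)
    return entry


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_panel(
    records: Sequence[SystemRecord],
    config: Optional[PipelineConfig] = None,
    out_dir=None,
) -> dict:
    """Run every system and correlate depths against melting temperatures."""
    config = config or PipelineConfig()
    manifest: dict = {"config_hash": config.digest(), "systems": {}, "warnings": []}
    for record in records:
        try:
            manifest["systems"][record.system_id] = run_system(record, config, out_dir)
        except MetadissError as exc:
            manifest["systems"][record.system_id] = {"error": f"{type(exc).__name__}: {exc}"}
            manifest["warnings"].append(f"system {record.system_id} failed: {exc}")
            logger.warning("system %s failed: %s", record.system_id, exc)

    depths, tms, ids = [], [], []
    for record in records:
        entry = manifest["systems"][record.system_id]
        if entry.get("depth"):
            depths.append(entry["depth"]["mean_depth"])
            tms.append(record.tm_celsius)
            ids.append(record.system_id)
    try:
        corr = fe_mod.correlate_depth_tm(depths, tms)
        manifest["correlation"] = {
            "pearson": corr.pearson,
            "spearman": corr.spearman,
            "n_used": corr.n_used,
            "excluded_systems": [ids[i] for i in corr.excluded],
        }
    except MetadissError as exc:
        manifest["correlation"] = None
        manifest["warnings"].append(f"correlation skipped: {exc}")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "panel_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=_json_default)
    return manifest


def load_panel_yaml(path) -> tuple[list[SystemRecord], PipelineConfig]:
    """Read a panel description: a YAML with `systems:` and optional `config:`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    config = PipelineConfig(**data.get("config", {}))
    records = [SystemRecord(**s) for s in data["systems"]]
    return records, config
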