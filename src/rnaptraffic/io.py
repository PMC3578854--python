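"""Reading and writing of run artefacts.

Event streams are plain TSV (one row per event: time, rnap, position,
mode, event); a JSON manifest captures the full run configuration for
provenance.  Experimental pause lists are 2-column TSV
(sequence name, 1-based position).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .energetics import TECGeometry, Template
from .engine import RunConfig, Trajectory
from .kinetics import KineticParams

__all__ = [
    "write_event_stream",
    "read_event_stream",
    "write_manifest",
    "read_pause_list",
    "config_from_yaml",
]

_COLUMNS = ["time", "rnap", "position", "mode", "event"]


def write_event_stream(trajs: list[Trajectory], path: str | Path) -> None:
    rows = []
    for traj in trajs:
        mode = "elongating"
        for t, kind, pos in traj.events:
            if kind == "backtrack_step":
                mode = "backtracked"
            elif kind in ("initiation", "incorporation"):
                mode = "elongating"
            elif kind == "forward_step":
                pass  # stays backtracked until re-entry shows as incorporation
            elif kind == "termination":
                mode = "terminated"
            rows.append((t, traj.rnap_index, pos, mode, kind))
    rows.sort(key=lambda r: (r[0], r[1]))
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_event_stream(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path, sep="\t")
    trajs = []
    for idx, grp in df.groupby("rnap"):
        grp = grp.sort_values("time", kind="stable")
        first = grp.iloc[0]
        traj = Trajectory(rnap_index=int(idx), t_init=float(first["time"]))
        for _, row in grp.iterrows():
            t, pos, kind = float(row["time"]), int(row["position"]), str(row["event"])
            traj.events.append((t, kind, pos))
            traj.breakpoints.append((t, float(pos)))
            if kind == "termination":
                traj.terminated = True
                traj.t_term = t
        trajs.append(traj)
    return sorted(trajs, key=lambda tr: tr.rnap_index)


def write_manifest(config: RunConfig, mode: str, path: str | Path) -> None:
    payload = {
        "mode": mode,
        "template": {"name": config.template.name, "length": config.template.length},
        "params": {
            "ntp_conc": config.params.ntp_conc,
            "vmax": config.params.vmax,
            "km": config.params.km,
            "k0": config.params.k0,
            "dg0": config.params.dg0,
            "force_pN": config.params.force,
            "collision_force_pN": config.params.collision_force,
            "temperature_K": config.params.temperature,
        },
        "n_rnap_max": config.n_rnap_max,
        "initiation_interval_s": config.initiation_interval,
        "n_replicates": config.n_replicates,
        "seed": config.seed,
        "t_max_s": config.t_max,
        "start_position": config.start_position,
        "backtracking": config.backtracking,
        "geometry": {
            "hybrid_len_post": config.geometry.hybrid_len_post,
            "hybrid_len_pre": config.geometry.hybrid_len_pre,
            "bubble_len": config.geometry.bubble_len,
            "delta_nm": config.geometry.delta,
            "d1": config.geometry.d1,
            "d2": config.geometry.d2,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_pause_list(path: str | Path) -> dict[str, list[int]]:
    """Experimental pause positions: TSV of (sequence name, 1-based position)."""
    out: dict[str, list[int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, pos = line.split("\t")[:2]
        out.setdefault(name, []).append(int(pos))
    return {name: sorted(v) for name, v in out.items()}


def config_from_yaml(path: str | Path, template: Template) -> RunConfig:
    """Build a RunConfig from a YAML key-value file plus a template."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    geom = TECGeometry(**raw.get("geometry", {}))
    pkeys = {
        "ntp_conc", "vmax", "km", "k0", "dg0", "force",
        "collision_force", "temperature",
    }
    params = KineticParams(**{k: v for k, v in raw.items() if k in pkeys})
    ckeys = {
        "n_rnap_max", "initiation_interval", "n_replicates", "seed",
        "t_max", "start_position", "backtracking",
    }
    return RunConfig(
        template=template,
        params=params,
        geometry=geom,
        **{k: v for k, v in raw.items() if k in ckeys},
    )
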