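"""File formats and reporting.

Canonical trial interchange is wide-format TSV, chosen so synthetic and
real data stay human-inspectable:

* ``markers.tsv`` — one row per camera frame: ``frame``, ``time_s`` and one
  ``<bone>_<marker>_<x|y|z>`` column per marker coordinate (mm); empty
  cells are marker gaps,
* ``grf.tsv`` — one row per force-plate frame: ``frame``, ``time_s``,
  ``fz_N``,
* ``meta.json`` — sampling rates, body weight and identifiers.

Floats are written with 17 significant digits so a write/read round trip is
bit-exact.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import PreprocessError, TrialRaw

__all__ = [
    "ParseError",
    "RunConfig",
    "read_trial",
    "write_trial",
    "read_mesh",
    "write_report",
]

_FLOAT_FMT = "%.17g"
_COL_RE = re.compile(r"^(?P<bone>[A-Za-z][A-Za-z0-9]*)_(?P<marker>[A-Za-z0-9]+)_(?P<axis>[xyz])$")


class ParseError(ValueError):
    """Malformed trial file."""


def write_trial(trial: TrialRaw, out_dir: str | Path) -> Path:
    """Write a trial as markers.tsv + grf.tsv + meta.json; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n = trial.n_frames
    data: dict[str, np.ndarray] = {
        "frame": np.arange(n),
        "time_s": trial.marker_times(),
    }
    for bone, (labels, arr) in trial.markers.items():
        for m, label in enumerate(labels):
            for a, ax in enumerate("xyz"):
                data[f"{bone}_{label}_{ax}"] = arr[:, m, a]
    pd.DataFrame(data).to_csv(
        out / "markers.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    grf = pd.DataFrame(
        {
            "frame": np.arange(len(trial.grf_z)),
            "time_s": trial.grf_times(),
            "fz_N": trial.grf_z,
        }
    )
    grf.to_csv(out / "grf.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    meta = {
        "marker_rate_hz": trial.marker_rate_hz,
        "grf_rate_hz": trial.grf_rate_hz,
        "body_weight_N": trial.body_weight_N,
        "participant": trial.participant,
        "trial": trial.trial,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def read_trial(path: str | Path, require_bones: tuple[str, ...] = ("tibia", "talus")) -> TrialRaw:
    """Read a trial directory (markers.tsv, grf.tsv, meta.json) into TrialRaw.

    Validates header structure, per-marker column completeness, monotone
    time stamps and the presence of the required bones. Missing cells
    become NaN gaps.
    """
    p = Path(path)
    markers_file = p / "markers.tsv"
    if not markers_file.exists():
        raise ParseError(f"missing markers.tsv in {p}")
    df = pd.read_csv(markers_file, sep="\t", float_precision="round_trip")
    if "frame" not in df.columns or "time_s" not in df.columns:
        raise ParseError("markers.tsv must have 'frame' and 'time_s' columns")
    if not np.all(np.diff(df["time_s"].to_numpy()) > 0):
        raise ParseError("markers.tsv: time_s is not strictly increasing")

    coord_cols: dict[str, dict[str, dict[str, str]]] = {}
    for col in df.columns:
        if col in ("frame", "time_s"):
            continue
        m = _COL_RE.match(col)
        if m is None:
            raise ParseError(f"unrecognized marker column {col!r}")
        coord_cols.setdefault(m["bone"], {}).setdefault(m["marker"], {})[m["axis"]] = col

    markers: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for bone, marker_map in coord_cols.items():
        labels = tuple(marker_map.keys())
        arrs = []
        for label in labels:
            axes = marker_map[label]
            for ax in "xyz":
                if ax not in axes:
                    raise ParseError(
                        f"missing column {bone}_{label}_{ax} in markers.tsv"
                    )
            arrs.append(
                np.column_stack([df[axes[ax]].to_numpy(dtype=float) for ax in "xyz"])
            )
        markers[bone] = (labels, np.stack(arrs, axis=1))

    for bone in require_bones:
        if bone not in markers:
            raise ParseError(f"required bone {bone!r} not found in markers.tsv")

    grf_file = p / "grf.tsv"
    if not grf_file.exists():
        raise ParseError(f"missing grf.tsv in {p}")
    grf_df = pd.read_csv(grf_file, sep="\t", float_precision="round_trip")
    if "fz_N" not in grf_df.columns:
        raise ParseError("grf.tsv must have an 'fz_N' column")

    meta_file = p / "meta.json"
    if not meta_file.exists():
        raise ParseError(f"missing meta.json in {p}")
    meta = json.loads(meta_file.read_text())
    try:
        return TrialRaw(
            markers=markers,
            marker_rate_hz=float(meta["marker_rate_hz"]),
            grf_z=grf_df["fz_N"].to_numpy(dtype=float),
            grf_rate_hz=float(meta["grf_rate_hz"]),
            body_weight_N=float(meta["body_weight_N"]),
            participant=str(meta.get("participant", "")),
            trial=str(meta.get("trial", p.name)),
        )
    except KeyError as exc:
        raise ParseError(f"meta.json missing key {exc}") from exc
    except PreprocessError as exc:
        raise ParseError(str(exc)) from exc


def read_mesh(path: str | Path):
    """Load an ASCII OBJ/PLY talus mesh into a TalusMesh."""
    import trimesh

    from .morphology import TalusMesh

    tm = trimesh.load(str(path), force="mesh", process=False)
    return TalusMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


_ALLOWED_KEYS = {
    "trials_dir",
    "reference",
    "mesh",
    "out_dir",
    "gate_deg",
    "window_pct",
    "step_pct",
    "slab_mm",
    "contact_threshold_N",
    "lowpass_cutoff_hz",
    "max_gap_frames",
    "seed",
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (all parameters defaulted)."""

    trials_dir: str = ""
    reference: str = ""
    mesh: str = ""
    out_dir: str = "out"
    gate_deg: float = 2.0
    window_pct: int = 10
    step_pct: int = 1
    slab_mm: float = 2.0
    contact_threshold_N: float = 10.0
    lowpass_cutoff_hz: float = 10.0
    max_gap_frames: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gate_deg < 360:
            raise ValueError(f"gate_deg must be in (0, 360), got {self.gate_deg}")
        if not 0 < self.window_pct <= 100:
            raise ValueError("window_pct must be in (0, 100]")
        if self.step_pct < 1:
            raise ValueError("step_pct must be >= 1")
        if self.slab_mm <= 0:
            raise ValueError("slab_mm must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_report(results, out_dir: str | Path, config: RunConfig | None = None) -> list[Path]:
    """Write the tidy CSV outputs of a fitted analysis plus provenance.

    *results* is an :class:`~ankleaxis.model.AnkleAxisResults`; empty result
    sets produce headers-only CSVs. Output is deterministic for identical
    inputs. Returns the list of files written.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        written.append(path)

    emit(results.window_table, "windows.csv")
    emit(results.trial_summary, "trial_summary.csv")
    emit(results.landmark_table, "grf_landmarks.csv")
    emit(results.period_table(), "period_summary.csv")
    emit(results.flexion_pair_table, "flexion_pairs.csv")
    if getattr(results, "morphology_table", None) is not None:
        emit(results.morphology_table, "morphology.csv")

    prov = {
        "tool": "ankleaxis",
        "version": __version__,
        "config_hash": config.content_hash() if config else None,
        "config": asdict(config) if config else None,
        "n_trials_included": len(results.trials),
        "n_trials_excluded": len(results.excluded),
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=2, sort_keys=True))
    written.append(prov_path)
    return written
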