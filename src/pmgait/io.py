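"""Reading marker kinematics and writing pipeline result tables.

Two input formats are supported: C3D motion-capture files (via the optional
``ezc3d`` dependency) and the pipeline's own long-format CSV
(``subject, condition, frame, marker, x, y, z``; millimetres, UTF-8, "."
decimal, mandatory header).  Trials with any gap (NaN) in a selected marker
are rejected outright — the analysis excludes incomplete trials rather than
gap-filling.  Age group and preferred speed come from a separate participant
metadata CSV, never from the motion files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MarkerGapError, MissingMarkerError, ValidationError
from .markers import MarkerTrajectorySet

COHORT_COLUMNS = ("subject", "condition", "frame", "marker", "x", "y", "z")
METADATA_COLUMNS = ("subject_id", "age_group", "preferred_speed_m_s")

#: Result-table schemas: column order and the sort keys that make writes
#: deterministic.
TABLE_SCHEMAS: dict[str, dict] = {
    "rvar_table": {
        "columns": ("subject", "age_group", "condition", "pm", "metric", "value"),
        "sort": ("subject", "condition", "pm", "metric"),
    },
    "lye_table": {
        "columns": ("subject", "age_group", "condition", "pm", "lye", "units",
                    "n_replacements", "speed_m_s", "status"),
        "sort": ("subject", "condition", "pm"),
    },
    "anova_table": {
        "columns": ("metric", "pm", "effect", "df1", "df2", "F", "p",
                    "p_uncorrected", "partial_eta_sq", "observed_power",
                    "epsilon_gg", "n_subjects", "n_dropped"),
        "sort": ("metric", "pm", "effect"),
    },
    "correlation_table": {
        "columns": ("condition", "pm", "n", "r", "p", "flag"),
        "sort": ("pm", "condition"),
    },
    "posthoc_table": {
        "columns": ("metric", "pm", "level_a", "level_b", "mean_diff", "t",
                    "df", "p", "significant", "significant_allpairs",
                    "alpha_adj", "flag"),
        "sort": ("metric", "pm", "level_a", "level_b"),
    },
    "robustness_table": {
        "columns": ("left_out", "pm", "similarity"),
        "sort": ("pm", "left_out"),
    },
}


def write_table(records: pd.DataFrame | list[dict], path: str | Path,
                schema: str) -> Path:
    """Write a result table in a declared schema, deterministically ordered."""
    if schema not in TABLE_SCHEMAS:
        raise ValidationError(
            f"unknown schema {schema!r}; expected one of {sorted(TABLE_SCHEMAS)}"
        )
    spec = TABLE_SCHEMAS[schema]
    df = pd.DataFrame(records)
    if df.empty:
        df = pd.DataFrame(columns=spec["columns"])
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise ValidationError(f"schema {schema!r}: missing columns {missing}")
    df = df.loc[:, list(spec["columns"])]
    if len(df):
        df = df.sort_values(list(spec["sort"]), kind="mergesort")
    path = Path(path)
    df.to_csv(path, index=False)
    return path


_STRING_KEYS = ("subject", "condition", "marker", "age_group", "metric",
                "left_out", "level_a", "level_b", "subject_id")


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read back a result table written by :func:`write_table`."""
    if schema not in TABLE_SCHEMAS:
        raise ValidationError(f"unknown schema {schema!r}")
    dtypes = {c: str for c in TABLE_SCHEMAS[schema]["columns"]
              if c in _STRING_KEYS}
    df = pd.read_csv(path, float_precision="round_trip", dtype=dtypes)
    expected = list(TABLE_SCHEMAS[schema]["columns"])
    if list(df.columns) != expected:
        raise ValidationError(
            f"{path}: columns {list(df.columns)} do not match schema "
            f"{schema!r} ({expected})"
        )
    return df


def read_participant_metadata(path: str | Path) -> pd.DataFrame:
    """Participant metadata CSV: subject_id, age_group, preferred_speed_m_s."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata file missing columns: {missing}")
    return df


def write_cohort_csv(trials: list[MarkerTrajectorySet],
                     path: str | Path) -> Path:
    """Write trials as the long-format cohort CSV (one file, many trials)."""
    parts = []
    for tr in sorted(trials, key=lambda t: t.key()):
        t_frames = tr.n_frames
        for label in tr.marker_labels:
            arr = tr.markers[label]
            parts.append(pd.DataFrame({
                "subject": tr.subject_id,
                "condition": tr.condition,
                "frame": np.arange(t_frames),
                "marker": label,
                "x": arr[:, 0], "y": arr[:, 1], "z": arr[:, 2],
            }))
    df = (pd.concat(parts, ignore_index=True) if parts
          else pd.DataFrame(columns=COHORT_COLUMNS))
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_metadata_csv(trials: list[MarkerTrajectorySet],
                       path: str | Path) -> Path:
    """Participant metadata for a (synthetic) cohort, one row per subject."""
    rows = {}
    for tr in trials:
        rows[tr.subject_id] = {
            "subject_id": tr.subject_id,
            "age_group": tr.age_group,
            "preferred_speed_m_s": tr.preferred_speed_m_s,
        }
    df = pd.DataFrame([rows[k] for k in sorted(rows)],
                      columns=list(METADATA_COLUMNS))
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def _select_markers(available: dict[str, np.ndarray],
                    selection: list[str] | tuple[str, ...] | None,
                    context: str) -> dict[str, np.ndarray]:
    if selection is None:
        return dict(available)
    missing = [m for m in selection if m not in available]
    if missing:
        raise MissingMarkerError(missing)
    out = {}
    for label in selection:  # configured canonical order, never file order
        arr = available[label]
        if not np.all(np.isfinite(arr)):
            raise MarkerGapError(
                f"{context}: marker {label!r} has gap frames; trial rejected"
            )
        out[label] = arr
    return out


def read_cohort_csv(
    path: str | Path,
    fs_hz: float = 150.0,
    marker_selection: list[str] | None = None,
    metadata: pd.DataFrame | None = None,
) -> list[MarkerTrajectorySet]:
    """Read every trial from a long-format cohort CSV.

    Markers are returned in ``marker_selection`` order when given; any NaN
    coordinate in a selected marker rejects the whole trial.  ``metadata``
    (see :func:`read_participant_metadata`) supplies age group and preferred
    speed.
    """
    df = pd.read_csv(path, float_precision="round_trip",
                     dtype={"subject": str, "condition": str, "marker": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: cohort CSV missing columns {missing}")
    meta_idx = (metadata.set_index("subject_id")
                if metadata is not None else None)
    trials = []
    for (subj, cond), g in df.groupby(["subject", "condition"], sort=True):
        markers_avail: dict[str, np.ndarray] = {}
        for label, mg in g.groupby("marker", sort=True):
            mg = mg.sort_values("frame")
            frames = mg["frame"].to_numpy()
            if not np.array_equal(frames, np.arange(len(frames))):
                raise ValidationError(
                    f"trial ({subj}, {cond}) marker {label!r}: frames are "
                    "not contiguous from 0"
                )
            markers_avail[label] = mg[["x", "y", "z"]].to_numpy(dtype=float)
        markers = _select_markers(markers_avail, marker_selection,
                                  f"trial ({subj}, {cond})")
        for label, arr in markers.items():
            if not np.all(np.isfinite(arr)):
                raise MarkerGapError(
                    f"trial ({subj}, {cond}): marker {label!r} has gap frames"
                )
        age_group, pws = "unknown", None
        if meta_idx is not None and str(subj) in meta_idx.index.astype(str):
            row = meta_idx.loc[meta_idx.index.astype(str) == str(subj)].iloc[0]
            age_group = str(row["age_group"])
            pws = float(row["preferred_speed_m_s"])
        trials.append(MarkerTrajectorySet(
            subject_id=str(subj),
            condition=str(cond),
            fs_hz=fs_hz,
            markers=markers,
            age_group=age_group,
            preferred_speed_m_s=pws,
        ))
    return trials


def _read_c3d(path: Path, marker_selection: list[str] | None):
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ValidationError(
            "reading C3D files requires the optional 'ezc3d' dependency "
            "(pip install pmgait[c3d]); convert to the long-format CSV "
            "otherwise"
        ) from exc
    c3d = ezc3d.c3d(str(path))
    labels = [s.strip() for s in
              c3d["parameters"]["POINT"]["LABELS"]["value"]]
    fs = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    units = "mm"
    try:
        units = str(c3d["parameters"]["POINT"]["UNITS"]["value"][0]).strip()
    except (KeyError, IndexError):
        pass
    scale = {"mm": 1.0, "cm": 10.0, "m": 1000.0}.get(units.lower(), 1.0)
    points = c3d["data"]["points"]  # 4 x n_markers x T
    available = {
        lab: (points[:3, i, :].T * scale) for i, lab in enumerate(labels)
    }
    markers = _select_markers(available, marker_selection, str(path))
    return markers, fs


def read_trial(
    path: str | Path,
    format: str = "csv",
    marker_selection: list[str] | None = None,
    subject_id: str | None = None,
    condition: str | None = None,
    fs_hz: float = 150.0,
    metadata: pd.DataFrame | None = None,
) -> MarkerTrajectorySet:
    """Read a single trial from a C3D or long-format CSV file.

    For CSV the file must contain exactly one (subject, condition) trial;
    for C3D, subject and condition are parsed from the filename stem
    (``<subject>_<condition>.c3d``) unless given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    if format == "csv":
        trials = read_cohort_csv(path, fs_hz=fs_hz,
                                 marker_selection=marker_selection,
                                 metadata=metadata)
        if len(trials) != 1:
            raise ValidationError(
                f"{path}: expected exactly one trial, found {len(trials)}"
            )
        return trials[0]
    if format == "c3d":
        markers, fs = _read_c3d(path, marker_selection)
        if subject_id is None or condition is None:
            stem_parts = path.stem.split("_")
            subject_id = subject_id or stem_parts[0]
            condition = condition or (stem_parts[1] if len(stem_parts) > 1
                                      else "unknown")
        age_group, pws = "unknown", None
        if metadata is not None:
            hit = metadata[metadata["subject_id"].astype(str) == subject_id]
            if len(hit):
                age_group = str(hit.iloc[0]["age_group"])
                pws = float(hit.iloc[0]["preferred_speed_m_s"])
        return MarkerTrajectorySet(
            subject_id=subject_id, condition=condition, fs_hz=fs,
            markers=markers, age_group=age_group, preferred_speed_m_s=pws,
        )
    raise ValidationError(f"unknown format {format!r}; expected 'csv' or 'c3d'")
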