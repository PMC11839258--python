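"""Posture vectors: assembly, centering/normalization, pooling.

A posture vector is the concatenation of the (x, y, z) coordinates of all
selected markers at one frame (39 coordinates for a 13-marker layout).  Each
trial is centered by subtracting its mean posture vector (removing marker
placement offsets) and scaled by the trial's mean Euclidean distance from
that mean posture (removing anthropometric size differences).  Preprocessed
trials are then stacked into the single input matrix on which the
principal-movement basis is fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .markers import MarkerTrajectorySet


@dataclass
class PostureMatrix:
    """T x D matrix of posture vectors for one trial, with provenance."""

    values: np.ndarray
    subject_id: str
    condition: str
    fs_hz: float
    layout: tuple[str, ...]
    age_group: str = "unknown"
    preferred_speed_m_s: float | None = None
    centering_vector: np.ndarray | None = None
    norm_scale: float | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dims(self) -> int:
        return self.values.shape[1]

    @property
    def is_preprocessed(self) -> bool:
        return self.centering_vector is not None

    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.condition)


@dataclass
class PooledMatrix:
    """Vertical concatenation of preprocessed trials, with a block index."""

    values: np.ndarray
    block_index: dict[tuple[str, str], tuple[int, int]]
    trials: list[PostureMatrix] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def dims(self) -> int:
        return self.values.shape[1]

    def block(self, subject_id: str, condition: str) -> np.ndarray:
        lo, hi = self.block_index[(subject_id, condition)]
        return self.values[lo:hi]

    def row_index(self) -> pd.DataFrame:
        """Long-format (subject, condition, frame) provenance of every row."""
        parts = []
        for (subj, cond), (lo, hi) in self.block_index.items():
            parts.append(pd.DataFrame({
                "subject": subj,
                "condition": cond,
                "frame": np.arange(hi - lo),
            }))
        return pd.concat(parts, ignore_index=True)


def assemble_posture(
    trial: MarkerTrajectorySet,
    layout: tuple[str, ...] | list[str] | None = None,
) -> PostureMatrix:
    """Stack marker coordinates into raw posture vectors.

    Row t is the concatenation of (x, y, z) of each marker in ``layout``
    order; column ``d`` holds axis ``d mod 3`` of marker ``d // 3``.
    """
    layout = tuple(layout) if layout is not None else trial.marker_labels
    missing = [m for m in layout if m not in trial.markers]
    if missing:
        raise ValidationError(
            f"trial {trial.key()} lacks layout markers: {missing}"
        )
    values = np.concatenate([trial.markers[m] for m in layout], axis=1)
    return PostureMatrix(
        values=values,
        subject_id=trial.subject_id,
        condition=trial.condition,
        fs_hz=trial.fs_hz,
        layout=layout,
        age_group=trial.age_group,
        preferred_speed_m_s=trial.preferred_speed_m_s,
    )


def center_and_normalize(posture: PostureMatrix) -> PostureMatrix:
    """Center on the trial's mean posture and scale by the mean Euclidean distance.

    Output rows are ``(p_t - p_mean) / s`` with
    ``s = mean_t ||p_t - p_mean||_2``; afterwards the column means are ~0 and
    the mean row norm is exactly 1.  Raises :class:`DegenerateInputError`
    when the trial has no postural variation (``s = 0``).
    """
    if posture.n_frames < 2:
        raise ValidationError("need at least 2 frames to center and normalize")
    mean = posture.values.mean(axis=0)
    centered = posture.values - mean
    scale = float(np.linalg.norm(centered, axis=1).mean())
    # treat variation at the floating-point level of the offsets as none
    floor = 1e-12 * max(1.0, float(np.linalg.norm(mean)))
    if scale <= floor or not np.isfinite(scale):
        raise DegenerateInputError(
            f"trial {posture.key()}: all posture vectors identical "
            "(zero mean Euclidean distance)"
        )
    prior_center = (posture.centering_vector
                    if posture.centering_vector is not None
                    else np.zeros_like(mean))
    prior_scale = posture.norm_scale if posture.norm_scale is not None else 1.0
    return PostureMatrix(
        values=centered / scale,
        subject_id=posture.subject_id,
        condition=posture.condition,
        fs_hz=posture.fs_hz,
        layout=posture.layout,
        age_group=posture.age_group,
        preferred_speed_m_s=posture.preferred_speed_m_s,
        centering_vector=prior_center + prior_scale * mean,
        norm_scale=prior_scale * scale,
    )


def preprocess_trial(
    trial: MarkerTrajectorySet,
    layout: tuple[str, ...] | list[str] | None = None,
) -> PostureMatrix:
    """Assemble then center/normalize one trial (the default per-trial scope)."""
    return center_and_normalize(assemble_posture(trial, layout))


def pool(trials: list[PostureMatrix]) -> PooledMatrix:
    """Stack preprocessed trials into the single PCA input matrix.

    Trials are concatenated in deterministic ``(subject, condition)`` sort
    order, with conditions ordered numerically when their labels parse as
    numbers.  The block index maps every trial to its half-open row range.
    """
    if not trials:
        raise ValidationError("cannot pool an empty trial list")
    dims = {p.dims for p in trials}
    if len(dims) != 1:
        raise ValidationError(f"trials have mixed posture dimensions: {sorted(dims)}")

    def sort_key(p: PostureMatrix):
        try:
            cond = (0, float(p.condition), p.condition)
        except ValueError:
            cond = (1, 0.0, p.condition)
        return (p.subject_id, cond)

    ordered = sorted(trials, key=sort_key)
    seen = set()
    for p in ordered:
        if p.key() in seen:
            raise ValidationError(f"duplicate trial {p.key()} in pool")
        seen.add(p.key())
    block_index: dict[tuple[str, str], tuple[int, int]] = {}
    lo = 0
    for p in ordered:
        block_index[p.key()] = (lo, lo + p.n_frames)
        lo += p.n_frames
    values = np.concatenate([p.values for p in ordered], axis=0)
    return PooledMatrix(values=values, block_index=block_index, trials=ordered)
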