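"""Labeled 3-D marker trajectories for one walking trial.

The container is shared by the file readers and the synthetic cohort
generator so that real and simulated data follow one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: One plausible bilateral expansion of the pelvis / lower-limb landmark set
#: into 13 labels.  The selection is configuration-driven everywhere; this
#: list is only a default for the synthetic generator.
DEFAULT_MARKER_LAYOUT: tuple[str, ...] = (
    "R_ASIS",
    "L_ASIS",
    "R_PSIS",
    "L_PSIS",
    "R_IliacCrest",
    "R_GreaterTrochanter",
    "L_GreaterTrochanter",
    "R_FibulaHead",
    "L_FibulaHead",
    "R_LatMalleolus",
    "L_LatMalleolus",
    "R_Heel",
    "L_Heel",
)


@dataclass
class MarkerTrajectorySet:
    """Marker kinematics of one subject x speed-condition trial.

    Parameters
    ----------
    subject_id
        Participant identifier.
    condition
        Speed label as percent of preferred walking speed ("40" ... "145").
    fs_hz
        Sampling rate in Hz (150 for the motion-capture protocol emulated
        here).
    markers
        Ordered mapping ``label -> (T, 3)`` coordinate array in millimetres.
    age_group
        ``"young"``, ``"older"`` or ``"unknown"``.
    preferred_speed_m_s
        The participant's self-selected comfortable speed, used by the
        speed-stability correlation stage; optional.
    """

    subject_id: str
    condition: str
    fs_hz: float
    markers: dict[str, np.ndarray]
    age_group: str = "unknown"
    preferred_speed_m_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValidationError(f"fs_hz must be positive, got {self.fs_hz}")
        if not self.markers:
            raise ValidationError("trial contains no markers")
        lengths = set()
        for label, arr in self.markers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(
                    f"marker {label!r}: expected (T, 3) array, got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(
                    f"marker {label!r} contains non-finite coordinates"
                )
            self.markers[label] = arr
            lengths.add(arr.shape[0])
        if len(lengths) != 1:
            raise ValidationError(
                f"marker series lengths differ: {sorted(lengths)}"
            )

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def marker_labels(self) -> tuple[str, ...]:
        return tuple(self.markers)

    @property
    def speed_m_s(self) -> float | None:
        """Belt speed of this condition, if preferred speed is known."""
        if self.preferred_speed_m_s is None:
            return None
        return self.preferred_speed_m_s * float(self.condition) / 100.0

    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.condition)
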