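"""Synthetic treadmill-gait cohorts with a known-divergence chaotic component.

The generator emulates the statistical structure that the principal-movement
pipeline assumes: 13 lower-body markers sampled at 150 Hz, quasi-periodic
stride harmonics whose fundamental frequency scales with the speed condition
(40%-145% of preferred speed, 8 conditions), additive measurement noise, and
an optional low-dimensional chaotic component injected along a fixed
posture-space direction.  The chaotic component is the x-coordinate of a
Lorenz system whose largest Lyapunov exponent is computed independently with
a Benettin variational integrator, giving a ground truth for
parameter-recovery tests of the Wolf estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrationError, ValidationError
from .markers import DEFAULT_MARKER_LAYOUT, MarkerTrajectorySet

DEFAULT_SPEED_FACTORS: tuple[float, ...] = (
    0.40, 0.55, 0.70, 0.85, 1.00, 1.15, 1.30, 1.45,
)

#: Fundamental oscillation amplitude per marker (mm); distal markers move
#: more than pelvis markers during walking.
_DEFAULT_MARKER_AMPLITUDE_MM = {
    "ASIS": 15.0, "PSIS": 15.0, "IliacCrest": 12.0,
    "GreaterTrochanter": 25.0, "FibulaHead": 45.0,
    "LatMalleolus": 65.0, "Heel": 70.0, "Metatarsal": 75.0,
}
#: Relative excursion along (x=AP, y=ML, z=vertical).
_AXIS_SCALE = np.array([1.0, 0.4, 0.7])

#: Rough standing positions (mm) used as static offsets; x anterior,
#: y left, z up.
_BASE_POSITION_MM = {
    "ASIS": (120.0, 120.0, 950.0),
    "PSIS": (-60.0, 50.0, 970.0),
    "IliacCrest": (0.0, 140.0, 1020.0),
    "GreaterTrochanter": (0.0, 160.0, 880.0),
    "FibulaHead": (30.0, 120.0, 480.0),
    "LatMalleolus": (0.0, 110.0, 80.0),
    "Heel": (-80.0, 90.0, 30.0),
    "Metatarsal": (150.0, 90.0, 40.0),
}


def _landmark(label: str) -> tuple[str, float]:
    """Split a bilateral label into (landmark, side sign); sides: R=-1, L=+1."""
    if label.startswith("R_"):
        return label[2:], -1.0
    if label.startswith("L_"):
        return label[2:], 1.0
    return label, 0.0


def default_harmonic_amplitudes(
    layout: tuple[str, ...] = DEFAULT_MARKER_LAYOUT,
    n_harmonics: int = 3,
) -> dict[str, tuple[float, ...]]:
    """Per-marker, per-harmonic amplitudes (mm) decaying as 1/h.

    Three harmonics of stride rates near 1-1.5 Hz concentrate signal power
    below ~4.5 Hz, matching the spectral profile the 7-Hz low-pass stage of
    the analysis is designed around.
    """
    out: dict[str, tuple[float, ...]] = {}
    for label in layout:
        name, _ = _landmark(label)
        base = _DEFAULT_MARKER_AMPLITUDE_MM.get(name, 30.0)
        out[label] = tuple(base / h for h in range(1, n_harmonics + 1))
    return out


@dataclass(frozen=True)
class LorenzParams:
    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0


@dataclass
class ChaoticReference:
    """Ground truth attached to a generated chaotic signal.

    ``oracle_lye`` is the largest Lyapunov exponent of the underlying system
    in nats per *system time unit*, computed by the Benettin variational
    oracle.  A signal generated with time compression ``timescale`` diverges
    at ``timescale * oracle_lye`` nats per second.
    """

    params: LorenzParams
    initial_state: tuple[float, float, float]
    dt: float
    timescale: float
    oracle_lye: float

    @property
    def injected_lye_per_s(self) -> float:
        return self.timescale * self.oracle_lye


def _lorenz_rhs(s: np.ndarray, p: LorenzParams) -> np.ndarray:
    x, y, z = s
    return np.array([
        p.sigma * (y - x),
        x * (p.rho - z) - y,
        x * y - p.beta * z,
    ])


def _rk4(f, s: np.ndarray, dt: float) -> np.ndarray:
    k1 = f(s)
    k2 = f(s + 0.5 * dt * k1)
    k3 = f(s + 0.5 * dt * k2)
    k4 = f(s + dt * k3)
    return s + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def benettin_lyapunov(
    params: LorenzParams = LorenzParams(),
    duration: float = 200.0,
    dt: float = 0.002,
    transient: float = 10.0,
    initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Largest Lyapunov exponent by the Benettin variational method.

    Integrates the system together with a tangent vector under the exact
    variational (Jacobian) dynamics, renormalizing the tangent vector each
    step; the exponent is the mean log growth rate in nats per time unit.
    Entirely independent of the Wolf trajectory-divergence estimator, which
    it serves as oracle for.
    """

    def rhs(s: np.ndarray) -> np.ndarray:
        x, y, z, dx, dy, dz = s
        p = params
        return np.array([
            p.sigma * (y - x),
            x * (p.rho - z) - y,
            x * y - p.beta * z,
            p.sigma * (dy - dx),
            dx * (p.rho - z) - x * dz - dy,
            dx * y + x * dy - p.beta * dz,
        ])

    s = np.array([*initial_state, 1.0, 0.0, 0.0], dtype=float)
    n_tr = int(round(transient / dt))
    n = int(round(duration / dt))
    for _ in range(n_tr):
        s = _rk4(rhs, s, dt)
        nv = np.linalg.norm(s[3:])
        if nv == 0.0 or not np.isfinite(nv):
            raise IntegrationError("tangent vector degenerated during burn-in")
        s[3:] /= nv
    acc = 0.0
    for _ in range(n):
        s = _rk4(rhs, s, dt)
        if not np.all(np.isfinite(s)):
            raise IntegrationError("non-finite state during Benettin integration")
        nv = np.linalg.norm(s[3:])
        acc += np.log(nv)
        s[3:] /= nv
    return acc / (n * dt)


def lorenz_trajectory(
    params: LorenzParams = LorenzParams(),
    duration_s: float = 60.0,
    fs_hz: float = 150.0,
    seed: int | None = None,
    timescale: float = 1.0,
    transient: float = 10.0,
    dt_max: float = 0.002,
    initial_state: tuple[float, float, float] | None = None,
    compute_oracle: bool = True,
    oracle_duration: float = 200.0,
) -> tuple[np.ndarray, ChaoticReference]:
    """x-component of a Lorenz trajectory sampled at ``fs_hz`` for ``duration_s``.

    The system's time axis is compressed by ``timescale`` (output sample i is
    x at system time ``transient + timescale * i / fs_hz``), so the signal
    diverges at ``timescale * oracle_lye`` nats per second of output time.
    The first ``transient`` system time units are discarded as burn-in to
    reach the attractor.  ``seed`` perturbs the default initial state by a
    small deterministic offset so different trials follow different
    trajectories of the same system.
    """
    if duration_s <= 0 or fs_hz <= 0 or timescale <= 0:
        raise ValidationError("duration_s, fs_hz and timescale must be positive")
    if initial_state is None:
        base = np.array([1.0, 1.0, 1.0])
        if seed is not None:
            rng = np.random.default_rng(seed)
            base = base + rng.uniform(-1e-2, 1e-2, size=3)
        initial_state = tuple(float(v) for v in base)

    outer_dt = timescale / fs_hz  # system-time step between output samples
    n_sub = max(1, int(np.ceil(outer_dt / dt_max)))
    dt = outer_dt / n_sub

    s = np.array(initial_state, dtype=float)
    rhs = lambda st: _lorenz_rhs(st, params)  # noqa: E731
    n_burn = int(np.ceil(transient / dt))
    for _ in range(n_burn):
        s = _rk4(rhs, s, dt)
        if not np.all(np.isfinite(s)):
            raise IntegrationError("non-finite state during Lorenz burn-in")

    n_out = int(round(duration_s * fs_hz))
    series = np.empty(n_out)
    for i in range(n_out):
        series[i] = s[0]
        for _ in range(n_sub):
            s = _rk4(rhs, s, dt)
        if not np.all(np.isfinite(s)):
            raise IntegrationError("non-finite state during Lorenz integration")

    oracle = np.nan
    if compute_oracle:
        oracle = benettin_lyapunov(
            params, duration=oracle_duration, dt=dt_max,
            transient=transient, initial_state=initial_state,
        )
    ref = ChaoticReference(
        params=params,
        initial_state=initial_state,
        dt=dt,
        timescale=timescale,
        oracle_lye=float(oracle),
    )
    return series, ref


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic gait cohort.

    Defaults mirror the emulated study design: 8 speed conditions from 40%
    to 145% of preferred speed, one trial per condition, 13 markers sampled
    at 150 Hz, stride fundamental 1.25 Hz at preferred speed.
    """

    n_subjects: int = 26
    speed_factors: tuple[float, ...] = DEFAULT_SPEED_FACTORS
    base_stride_freq_hz: float = 1.25
    duration_s: float = 30.0
    fs_hz: float = 150.0
    marker_layout: tuple[str, ...] = DEFAULT_MARKER_LAYOUT
    harmonic_amplitudes: dict[str, tuple[float, ...]] | None = None
    noise_sd_mm: float = 1.0
    phase_jitter_sd: float = 0.3
    amplitude_jitter_sd: float = 0.1
    chaos_gain: float = 0.0
    chaos_timescale: float = 2.0
    chaos_direction: np.ndarray | None = None
    lorenz_params: LorenzParams = field(default_factory=LorenzParams)
    preferred_speed_mean_m_s: float = 1.25
    preferred_speed_sd_m_s: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        self.speed_factors = tuple(float(f) for f in self.speed_factors)
        self.marker_layout = tuple(self.marker_layout)
        if self.harmonic_amplitudes is None:
            self.harmonic_amplitudes = default_harmonic_amplitudes(self.marker_layout)
        self.validate()

    @property
    def n_harmonics(self) -> int:
        return max(len(a) for a in self.harmonic_amplitudes.values())

    @property
    def dims(self) -> int:
        return 3 * len(self.marker_layout)

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValidationError(f"n_subjects must be >= 0, got {self.n_subjects}")
        if any(f <= 0 for f in self.speed_factors):
            raise ValidationError("speed_factors must all be > 0")
        if self.base_stride_freq_hz <= 0:
            raise ValidationError("base_stride_freq_hz must be > 0")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        if self.noise_sd_mm < 0:
            raise ValidationError("noise_sd_mm must be >= 0")
        if self.phase_jitter_sd < 0 or self.amplitude_jitter_sd < 0:
            raise ValidationError("jitter SDs must be >= 0")
        if self.chaos_gain < 0:
            raise ValidationError("chaos_gain must be >= 0")
        missing = [m for m in self.marker_layout if m not in self.harmonic_amplitudes]
        if missing:
            raise ValidationError(
                f"harmonic_amplitudes missing markers: {missing}"
            )
        highest = max(self.speed_factors) * self.base_stride_freq_hz * self.n_harmonics
        if self.fs_hz <= 2.0 * highest:
            raise ValidationError(
                f"fs_hz={self.fs_hz} must exceed twice the highest harmonic "
                f"frequency ({highest:.2f} Hz)"
            )
        if self.chaos_gain > 0 and self.chaos_direction is not None:
            d = np.asarray(self.chaos_direction, dtype=float)
            if d.shape != (self.dims,):
                raise ValidationError(
                    f"chaos_direction must have length {self.dims}, got {d.shape}"
                )
            if abs(np.linalg.norm(d) - 1.0) > 1e-8:
                raise ValidationError("chaos_direction must have unit Euclidean norm")


def _resolve_chaos_direction(spec: SyntheticCohortSpec) -> np.ndarray:
    if spec.chaos_direction is not None:
        return np.asarray(spec.chaos_direction, dtype=float)
    # Deterministic pseudo-random unit vector, independent of subject RNGs.
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))
    d = rng.standard_normal(spec.dims)
    return d / np.linalg.norm(d)


def generate_cohort(spec: SyntheticCohortSpec) -> list[MarkerTrajectorySet]:
    """Generate ``n_subjects x len(speed_factors)`` synthetic trials.

    Each marker coordinate is a static offset plus a sum of harmonics of the
    condition's stride frequency (``speed_factor * base_stride_freq_hz``),
    plus additive Gaussian measurement noise and, when ``chaos_gain > 0``,
    a standardized Lorenz x-signal of amplitude ``chaos_gain`` mm projected
    along ``chaos_direction``.  Harmonic phases are shared across the
    cohort with per-subject Gaussian jitter (``phase_jitter_sd`` rad) and
    per-subject log-normal amplitude jitter, so subjects share common
    movement synergies — the structure the pooled PCA assumes — while
    remaining individually distinct.  Left-side markers run half a stride
    out of phase with right-side ones.  Identical specs and seeds produce
    bit-identical cohorts.
    """
    spec.validate()
    trials: list[MarkerTrajectorySet] = []
    if spec.n_subjects == 0:
        return trials

    t = np.arange(int(round(spec.duration_s * spec.fs_hz))) / spec.fs_hz
    direction = _resolve_chaos_direction(spec) if spec.chaos_gain > 0 else None
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    n_young = (spec.n_subjects + 1) // 2
    cohort_rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 0xBA5E]))
    base_phases = cohort_rng.uniform(
        0.0, 2.0 * np.pi, size=(len(spec.marker_layout), 3, spec.n_harmonics))

    for s_idx in range(spec.n_subjects):
        rng = np.random.default_rng(subject_seeds[s_idx])
        subject_id = f"S{s_idx + 1:02d}"
        age_group = "young" if s_idx < n_young else "older"
        pws = float(rng.normal(spec.preferred_speed_mean_m_s,
                               spec.preferred_speed_sd_m_s))
        pws = max(pws, 0.5)
        # cohort-shared phases with subject-specific jitter and gains
        shape = (len(spec.marker_layout), 3, spec.n_harmonics)
        phases = base_phases + rng.normal(0.0, spec.phase_jitter_sd, shape)
        amp_gain = np.exp(rng.normal(0.0, spec.amplitude_jitter_sd, shape))
        for cond_idx, factor in enumerate(spec.speed_factors):
            f0 = factor * spec.base_stride_freq_hz
            cond_label = f"{factor * 100:g}"
            flat = np.empty((t.size, spec.dims))
            for m_idx, label in enumerate(spec.marker_layout):
                name, side = _landmark(label)
                base = np.array(_BASE_POSITION_MM.get(name, (0.0, 0.0, 500.0)))
                base = base * np.array([1.0, side if side != 0.0 else 1.0, 1.0])
                amps = spec.harmonic_amplitudes[label]
                for ax in range(3):
                    sig = np.full(t.size, base[ax])
                    for h_idx, amp in enumerate(amps):
                        h = h_idx + 1
                        side_shift = np.pi * h if side > 0 else 0.0
                        sig = sig + amp * amp_gain[m_idx, ax, h_idx] \
                            * _AXIS_SCALE[ax] * np.sin(
                                2.0 * np.pi * h * f0 * t
                                + phases[m_idx, ax, h_idx] + side_shift
                            )
                    flat[:, 3 * m_idx + ax] = sig
            if spec.chaos_gain > 0:
                chaos_seed = int(rng.integers(0, 2**31 - 1))
                sig, _ = lorenz_trajectory(
                    spec.lorenz_params, duration_s=spec.duration_s,
                    fs_hz=spec.fs_hz, seed=chaos_seed,
                    timescale=spec.chaos_timescale, compute_oracle=False,
                )
                sig = (sig - sig.mean()) / sig.std()
                flat = flat + spec.chaos_gain * np.outer(sig, direction)
            if spec.noise_sd_mm > 0:
                flat = flat + rng.normal(0.0, spec.noise_sd_mm, size=flat.shape)
            markers = {
                label: flat[:, 3 * i:3 * i + 3].copy()
                for i, label in enumerate(spec.marker_layout)
            }
            trials.append(MarkerTrajectorySet(
                subject_id=subject_id,
                condition=cond_label,
                fs_hz=spec.fs_hz,
                markers=markers,
                age_group=age_group,
                preferred_speed_m_s=pws,
                meta={"speed_factor": factor, "condition_index": cond_idx},
            ))
    return trials
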