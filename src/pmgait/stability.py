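"""Local dynamic stability of PM score series.

A score series PP_k(t) is delay-embedded into state space (delay tau,
dimension m) and the largest Lyapunov exponent is estimated with Wolf's
fiducial-trajectory algorithm: follow the observed trajectory, track the
separation from a nearby neighbor trajectory, accumulate log divergence
over short evolution intervals, and renormalize by replacing the neighbor
whenever the separation leaves the small-scale range.  A positive exponent
measures how fast naturally occurring micro-perturbations grow — lower
values mean higher local dynamic stability.

Embedding parameters default to the fixed values (tau=10, m=4) used for
150-Hz treadmill gait; average mutual information and false-nearest-neighbor
diagnostics are provided both to audit that choice and as an optional
adaptive selection mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.spatial import cKDTree

from .decomposition import PMScoreSeries
from .errors import DegenerateInputError, ValidationError


@dataclass(frozen=True)
class EmbeddingParameters:
    """Delay-embedding parameters; ``source`` records how they were chosen."""

    tau: int = 10
    m: int = 4
    source: str = "fixed"

    def validate(self, n_samples: int | None = None) -> None:
        if self.tau < 1:
            raise ValidationError(f"tau must be >= 1, got {self.tau}")
        if self.m < 1:
            raise ValidationError(f"m must be >= 1, got {self.m}")
        if n_samples is not None and (self.m - 1) * self.tau >= n_samples:
            raise ValidationError(
                f"embedding window (m-1)*tau = {(self.m - 1) * self.tau} "
                f"does not fit in {n_samples} samples"
            )

    @property
    def window(self) -> int:
        return (self.m - 1) * self.tau


@dataclass
class AMIResult:
    lags: np.ndarray
    ami: np.ndarray  # nats
    first_minimum: int | None  # None -> no local minimum up to max_lag


@dataclass
class FNNResult:
    dims: np.ndarray
    fraction: np.ndarray
    recommended_m: int | None
    threshold: float


@dataclass
class StabilityResult:
    """Wolf estimate for one embedded series."""

    lye: float
    units: str
    n_replacements: int
    n_epochs: int
    trajectory_length_used: int
    fallback_count: int
    subject_id: str | None = None
    condition: str | None = None
    pm: int | None = None


def average_mutual_information(
    series: np.ndarray,
    max_lag: int = 60,
    n_bins: int = 16,
) -> AMIResult:
    """Histogram-based average mutual information over lags 0..max_lag.

    AMI(0) is the marginal entropy estimate; the first local minimum of the
    AMI curve is the conventional delay choice, balancing redundancy
    (small lags) against decorrelation (large lags).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError("AMI expects a scalar series")
    if x.size < 10 * max_lag:
        raise ValidationError(
            f"series of {x.size} samples is too short for max_lag={max_lag} "
            "(need T >= 10 * max_lag)"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has zero entropy")
    edges = np.histogram_bin_edges(x, bins=n_bins)
    ami = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = x[: x.size - lag]
        b = x[lag:]
        joint, _, _ = np.histogram2d(a, b, bins=(edges, edges))
        p = joint / joint.sum()
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        mask = p > 0
        ami[lag] = float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))
    # Binned AMI curves of deterministic signals carry bin-resonance jitter;
    # detect the first local minimum on a lightly smoothed curve.
    w = min(5, max_lag) | 1
    smooth = np.convolve(ami, np.ones(w) / w, mode="valid")
    off = w // 2
    first_min = None
    for lag in range(1, smooth.size - 1):
        if smooth[lag] < smooth[lag - 1] and smooth[lag] <= smooth[lag + 1]:
            first_min = lag + off
            break
    return AMIResult(lags=np.arange(max_lag + 1), ami=ami, first_minimum=first_min)


def delay_embed(series: np.ndarray, params: EmbeddingParameters) -> np.ndarray:
    """Delay-coordinate embedding: row i = (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError("delay_embed expects a scalar series")
    params.validate(x.size)
    n = x.size - params.window
    cols = [x[j * params.tau: j * params.tau + n] for j in range(params.m)]
    return np.column_stack(cols)


def false_nearest_neighbors(
    series: np.ndarray,
    tau: int,
    max_m: int = 8,
    r_tol: float = 15.0,
    a_tol: float = 2.0,
    threshold: float = 0.01,
    theiler: int | None = None,
) -> FNNResult:
    """Kennel false-nearest-neighbor fractions for m = 1..max_m.

    A neighbor pair in dimension m is false when adding the (m+1)-th delay
    coordinate stretches it by more than ``r_tol`` relative to its m-dim
    distance, or when the extended distance exceeds ``a_tol`` times the
    attractor size (the loneliness criterion).  The recommended dimension is
    the first m whose false fraction drops below ``threshold``.
    """
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series cannot be embedded")
    if x.size <= (max_m + 1) * tau + 10:
        raise ValidationError(
            f"series of {x.size} samples too short for max_m={max_m}, tau={tau}"
        )
    attractor_size = float(x.std())
    dims = np.arange(1, max_m + 1)
    fractions = np.empty(max_m)
    for m_idx, m in enumerate(dims):
        # usable points must also have the (m+1)-th coordinate x[i + m*tau]
        emb = delay_embed(x, EmbeddingParameters(tau=tau, m=m, source="fnn"))
        n_use = x.size - m * tau
        emb = emb[:n_use]
        excl = theiler if theiler is not None else tau * m
        tree = cKDTree(emb)
        k_query = min(2 * excl + 3, n_use)
        dist, idx = tree.query(emb, k=k_query)
        n_false = 0
        n_pairs = 0
        for i in range(n_use):
            j = -1
            for cand, d in zip(idx[i], dist[i]):
                if cand != i and abs(int(cand) - i) > excl and d > 0:
                    j = int(cand)
                    rd = float(d)
                    break
            if j < 0:
                continue
            extra = abs(x[i + m * tau] - x[j + m * tau])
            n_pairs += 1
            if extra / rd > r_tol or np.hypot(rd, extra) / attractor_size > a_tol:
                n_false += 1
        fractions[m_idx] = n_false / n_pairs if n_pairs else np.nan
    recommended = None
    for m, frac in zip(dims, fractions):
        if np.isfinite(frac) and frac < threshold:
            recommended = int(m)
            break
    return FNNResult(dims=dims, fraction=fractions,
                     recommended_m=recommended, threshold=threshold)


def select_embedding(
    series: np.ndarray,
    max_lag: int = 60,
    max_m: int = 8,
    fnn_threshold: float = 0.01,
) -> EmbeddingParameters:
    """AMI/FNN-adaptive embedding selection (tau at first AMI minimum)."""
    ami = average_mutual_information(series, max_lag=max_lag)
    tau = ami.first_minimum if ami.first_minimum is not None else max_lag
    fnn = false_nearest_neighbors(series, tau=tau, max_m=max_m,
                                  threshold=fnn_threshold)
    if fnn.recommended_m is not None:
        m = fnn.recommended_m
    else:
        m = int(fnn.dims[np.nanargmin(fnn.fraction)])
    return EmbeddingParameters(tau=tau, m=m, source="ami_fnn")


def mean_pseudo_period(series: np.ndarray, fs_hz: float) -> float:
    """Dominant-oscillation period in samples.

    Estimated from the power-weighted mean frequency (spectral centroid) of
    the periodogram, which recovers the oscillation period for
    quasi-periodic signals and a representative orbital time for broadband
    chaotic ones — unlike the raw periodogram peak, which for chaotic
    signals can lock onto slow large-scale drifts.
    """
    x = np.asarray(series, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("series has no oscillatory power")
    freqs, psd = signal.periodogram(x, fs=fs_hz, detrend="constant")
    power = psd[1:]
    if power.sum() <= 0:
        raise DegenerateInputError("series has no oscillatory power")
    f_mean = float((freqs[1:] * power).sum() / power.sum())
    if f_mean <= 0:
        raise DegenerateInputError("no positive-frequency spectral power")
    return fs_hz / f_mean


def wolf_lyapunov(
    embedded: np.ndarray,
    fs_hz: float,
    evolve_steps: int,
    min_sep: float | None = None,
    max_sep: float | None = None,
    theta_max_deg: float = 30.0,
    theiler: int | None = None,
    settle_steps: int = 0,
    max_age_steps: int | None = None,
    units: str = "per_second",
) -> StabilityResult:
    """Largest Lyapunov exponent by Wolf's fiducial-trajectory method.

    Starting from the first point, the algorithm tracks the distance
    between the fiducial trajectory and a neighbor trajectory over
    ``evolve_steps``-sample intervals, accumulating log(d_end / d_start).
    When the separation leaves [``min_sep``, ``max_sep``] the neighbor is
    replaced by a point that restores a small separation while deviating
    from the current separation direction by at most ``theta_max_deg``
    (falling back to the best-angle candidate, then to the plain nearest
    neighbor, when the constrained search fails).  ``theiler`` excludes
    temporally adjacent samples from neighbor searches (default
    ``evolve_steps``; callers that know the embedding pass ``tau*(m-1)``).

    ``settle_steps`` discards accumulation during the first samples after
    every replacement: a freshly selected neighbor is conditioned on being
    unusually close, so its early separation growth is dominated by a
    selection-bias transient rather than the true divergence rate (the
    same transient that divergence-curve estimators skip by fitting the
    later linear region).  ``max_age_steps`` bounds how long one neighbor
    is followed, so each renormalization cycle samples the same
    pre-saturation stretch of the divergence curve; ``None`` means
    neighbors are followed until they outgrow ``max_sep`` (classic Wolf,
    which on benchmark systems runs 20-40% high).

    Default separation scales delimit the linear-scaling regime of the
    attractor: ``min_sep`` = 0.005 x RMS attractor radius (a floor for
    replacement candidates; raise it above the noise scale for noisy
    series) and ``max_sep`` = 0.5 x radius (below saturation at the
    attractor extent).  The estimate is the accumulated log divergence
    divided by the evolved time (nats per second), or per sample when
    ``units`` says so.
    """
    emb = np.asarray(embedded, dtype=float)
    if emb.ndim != 2:
        raise ValidationError("embedded trajectory must be 2-D (N x m)")
    n = emb.shape[0]
    if evolve_steps < 1:
        raise ValidationError("evolve_steps must be >= 1")
    if n <= 10 * evolve_steps:
        raise ValidationError(
            f"trajectory of {n} points too short for evolve_steps={evolve_steps}"
        )
    radius = float(np.sqrt(((emb - emb.mean(axis=0)) ** 2).sum(axis=1).mean()))
    if radius == 0:
        raise DegenerateInputError("embedded trajectory is a single point")
    if min_sep is None:
        min_sep = 0.005 * radius
    if max_sep is None:
        max_sep = 0.5 * radius
    if theiler is None:
        theiler = evolve_steps
    if max_age_steps is None:
        max_age_steps = n  # never expire: replace only on outgrowing max_sep
    cos_theta_min = np.cos(np.deg2rad(theta_max_deg))

    def _neighbor(i: int, direction: np.ndarray | None) -> tuple[int, bool]:
        """Pick a neighbor of point i; returns (index, used_fallback)."""
        d = np.linalg.norm(emb - emb[i], axis=1)
        valid = np.ones(n, dtype=bool)
        lo = max(0, i - theiler)
        hi = min(n, i + theiler + 1)
        valid[lo:hi] = False
        valid[n - evolve_steps:] = False  # neighbor must survive one epoch
        valid &= d > 0
        if not valid.any():
            raise DegenerateInputError("no admissible neighbor candidates")
        in_range = valid & (d >= min_sep) & (d <= max_sep)
        if direction is not None and in_range.any():
            vecs = emb[in_range] - emb[i]
            cos = (vecs @ direction) / (
                np.linalg.norm(vecs, axis=1) * np.linalg.norm(direction)
            )
            cand_idx = np.flatnonzero(in_range)
            ok = cos >= cos_theta_min
            if ok.any():
                sub = cand_idx[ok]
                return int(sub[np.argmin(d[sub])]), False
            # fall back to the candidate with the smallest angular deviation
            return int(cand_idx[np.argmax(cos)]), True
        if in_range.any():
            cand_idx = np.flatnonzero(in_range)
            return int(cand_idx[np.argmin(d[cand_idx])]), direction is not None
        # nothing in the separation range: plain nearest admissible neighbor
        cand_idx = np.flatnonzero(valid)
        return int(cand_idx[np.argmin(d[cand_idx])]), True

    i = 0
    j, _ = _neighbor(i, None)
    pair_age = 0
    n_replacements = 1
    fallback_count = 0
    acc = 0.0
    steps_total = 0
    n_epochs = 0
    while i + evolve_steps < n:
        if j + evolve_steps >= n:
            # neighbor runs off the record: renormalize before evolving
            try:
                j, fell_back = _neighbor(i, None)
            except DegenerateInputError:
                break
            n_replacements += 1
            fallback_count += int(fell_back)
            pair_age = 0
        d0 = float(np.linalg.norm(emb[i] - emb[j]))
        i2 = i + evolve_steps
        j2 = j + evolve_steps
        d1 = float(np.linalg.norm(emb[i2] - emb[j2]))
        if d0 > 0 and d1 > 0 and pair_age >= settle_steps:
            acc += np.log(d1 / d0)
            steps_total += evolve_steps
            n_epochs += 1
        pair_age += evolve_steps
        i = i2
        if i + evolve_steps >= n:
            break
        if 0 < d1 <= max_sep and pair_age < max_age_steps:
            j = j2  # separation still small: keep following the same neighbor
            continue
        direction = emb[j2] - emb[i] if d1 > 0 else None
        try:
            j, fell_back = _neighbor(i, direction)
        except DegenerateInputError:
            break
        n_replacements += 1
        if fell_back:
            fallback_count += 1
        pair_age = 0
    if n_epochs < 2:
        raise ValidationError("fewer than 2 Wolf evolution epochs completed")
    if fallback_count:
        warnings.warn(
            f"Wolf replacement search fell back {fallback_count} times "
            "(angle or separation constraints unsatisfiable)",
            stacklevel=2,
        )
    lye_per_s = acc / (steps_total / fs_hz)
    if units == "per_second":
        lye = lye_per_s
    elif units == "per_sample":
        lye = acc / steps_total
    else:
        raise ValidationError(f"unknown units {units!r} (per_stride is applied "
                              "by stability_table, which knows the period)")
    return StabilityResult(
        lye=float(lye),
        units=units,
        n_replacements=n_replacements,
        n_epochs=n_epochs,
        trajectory_length_used=steps_total,
        fallback_count=fallback_count,
    )


def series_lyapunov(
    series: np.ndarray,
    fs_hz: float,
    params: EmbeddingParameters | None = None,
    units: str = "per_second",
    **wolf_kwargs,
) -> StabilityResult:
    """Wolf LyE of one scalar series with the standard parameter policy.

    Embedding defaults to AMI/FNN selection when ``params`` is None.  The
    evolution interval, Theiler window, settle interval and neighbor age
    limit are all derived from the series' mean pseudo-period (period/8,
    max(embedding window, period/2), period/2 and 1.5 periods
    respectively), so periodic, gait-like and chaotic series share one
    policy.
    """
    x = np.asarray(series, dtype=float)
    if params is None:
        params = select_embedding(x)
    params.validate(x.size)
    emb = delay_embed(x, params)
    period = mean_pseudo_period(x, fs_hz)
    defaults = dict(
        evolve_steps=max(1, min(int(round(period / 8)),
                                (emb.shape[0] - 1) // 11)),
        theiler=max(params.window, int(round(0.5 * period))),
        settle_steps=int(round(0.5 * period)),
        max_age_steps=int(round(1.5 * period)),
    )
    defaults.update(wolf_kwargs)
    return wolf_lyapunov(emb, fs_hz, units=units, **defaults)


def stability_table(
    scores: list[PMScoreSeries],
    k_retained: int = 5,
    params: EmbeddingParameters | None = None,
    mode: str = "fixed",
    evolve_steps: int | None = None,
    units: str = "per_second",
    use_filtered: bool = False,
    cutoff_hz: float = 7.0,
) -> pd.DataFrame:
    """One Wolf LyE per subject x condition x PM.

    ``mode="fixed"`` (default) uses tau=10, m=4 throughout;
    ``mode="adaptive"`` re-selects (tau, m) per series via AMI/FNN.  The
    evolution interval defaults to half the series' mean pseudo-period.
    LyE is computed on raw position scores by default (``use_filtered``
    switches to the 7-Hz filtered series).  Per-trial failures are isolated:
    the row is emitted with NaN and a status message, and the run continues.
    """
    from .decomposition import lowpass_filter  # local import avoids cycle

    if mode not in ("fixed", "adaptive"):
        raise ValidationError(f"unknown embedding mode {mode!r}")
    if params is None:
        params = EmbeddingParameters()
    out_units = units
    rows = []
    for s in sorted(scores, key=lambda t: t.key()):
        for k in range(min(k_retained, s.n_components)):
            series = s.pp[:, k]
            if use_filtered:
                series = lowpass_filter(series, s.fs_hz, cutoff_hz)
            row = {
                "subject": s.subject_id,
                "age_group": s.age_group,
                "condition": s.condition,
                "pm": k + 1,
                "lye": np.nan,
                "units": out_units,
                "n_replacements": 0,
                "speed_m_s": (
                    s.preferred_speed_m_s * float(s.condition) / 100.0
                    if s.preferred_speed_m_s is not None else np.nan
                ),
                "status": "ok",
            }
            try:
                p = (select_embedding(series) if mode == "adaptive" else params)
                wolf_units = "per_second" if units == "per_stride" else units
                extra = {"evolve_steps": evolve_steps} if evolve_steps else {}
                res = series_lyapunov(series, s.fs_hz, params=p,
                                      units=wolf_units, **extra)
                lye = res.lye
                if units == "per_stride":
                    lye = res.lye * (mean_pseudo_period(series, s.fs_hz)
                                     / s.fs_hz)
                row.update(lye=float(lye), n_replacements=res.n_replacements)
            except (ValidationError, DegenerateInputError) as exc:
                row["status"] = f"failed: {exc}"
            rows.append(row)
    cols = ["subject", "age_group", "condition", "pm", "lye", "units",
            "n_replacements", "speed_m_s", "status"]
    return pd.DataFrame(rows, columns=cols)
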