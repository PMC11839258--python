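"""Principal movements: basis fitting, scores, rVAR, accelerations, diagnostics.

The principal-movement (PM) basis is the eigenbasis of the covariance of
the pooled posture matrix.  Projecting a trial's posture vectors onto
eigenvector k gives the PM's position score series PP_k(t); its second time
derivative, after zero-phase low-pass filtering, is the principal
acceleration PA_k(t).  Relative explained variance (rVAR) is a PM's share
of the total score variance within a scope (one trial, or all of one
subject's trials).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DegenerateInputError, ValidationError
from .posture import PooledMatrix, PostureMatrix


@dataclass
class PMBasis:
    """Orthonormal eigenvector basis of the pooled posture covariance.

    ``eigenvectors`` is D x K with columns sorted by descending eigenvalue;
    each column's sign is fixed so its largest-magnitude element is positive
    (the raw eigendecomposition sign is arbitrary, and downstream score
    series must be reproducible).
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    k_retained: int = 5

    @property
    def dims(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            raise DegenerateInputError("basis has zero total variance")
        return self.eigenvalues / total


@dataclass
class PMScoreSeries:
    """Per-trial PM score series: positions ``pp`` and accelerations ``pa``.

    ``pa`` is NaN until :func:`principal_accelerations` fills it; its first
    and last frames stay NaN (central differences are undefined there) and
    are excluded from downstream statistics.
    """

    subject_id: str
    condition: str
    fs_hz: float
    pp: np.ndarray
    pa: np.ndarray | None = None
    age_group: str = "unknown"
    preferred_speed_m_s: float | None = None

    @property
    def n_frames(self) -> int:
        return self.pp.shape[0]

    @property
    def n_components(self) -> int:
        return self.pp.shape[1]

    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.condition)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip columns so each column's largest-|.| element is positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def fit_basis(pooled: PooledMatrix | np.ndarray, k_retained: int = 5) -> PMBasis:
    """Eigendecompose the covariance of the pooled posture matrix.

    Uses a symmetric eigendecomposition of the D x D sample covariance
    (rows are frames), returning all K = min(D, rows - 1) components in
    descending eigenvalue order with the deterministic sign convention
    applied.  Zero eigenvalues from rank deficiency are retained.
    """
    values = pooled.values if isinstance(pooled, PooledMatrix) else np.asarray(pooled)
    n, d = values.shape
    if n < 2:
        raise ValidationError("need at least 2 pooled rows to fit a basis")
    centered = values - values.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _fix_signs(eigvecs[:, order])
    k = min(d, n - 1)
    return PMBasis(
        eigenvectors=eigvecs[:, :k],
        eigenvalues=eigvals[:k],
        k_retained=min(k_retained, k),
    )


def project(basis: PMBasis, posture: PostureMatrix) -> PMScoreSeries:
    """Project a preprocessed trial onto the PM basis (fills ``pp`` only)."""
    if posture.dims != basis.dims:
        raise ValidationError(
            f"dimension mismatch: posture D={posture.dims}, basis D={basis.dims}"
        )
    pp = posture.values @ basis.eigenvectors
    return PMScoreSeries(
        subject_id=posture.subject_id,
        condition=posture.condition,
        fs_hz=posture.fs_hz,
        pp=pp,
        age_group=posture.age_group,
        preferred_speed_m_s=posture.preferred_speed_m_s,
    )


def project_pooled(basis: PMBasis, pooled: PooledMatrix) -> list[PMScoreSeries]:
    """Project every trial of a pooled matrix, preserving trial metadata."""
    return [project(basis, trial) for trial in pooled.trials]


def reconstruct(basis: PMBasis, scores: PMScoreSeries,
                components: list[int] | None = None) -> np.ndarray:
    """Posture-space reconstruction from selected PMs (static inspection aid)."""
    k = components if components is not None else list(range(basis.n_components))
    return scores.pp[:, k] @ basis.eigenvectors[:, k].T


def _variance_shares(var: np.ndarray) -> np.ndarray:
    total = var.sum()
    if total <= 0 or not np.isfinite(total):
        raise DegenerateInputError("zero total score variance in rVAR scope")
    return 100.0 * var / total


def participant_rvar(
    scores: list[PMScoreSeries],
    k_retained: int = 5,
    scope: str = "trial",
    use_pa: bool = False,
) -> pd.DataFrame:
    """Relative explained variance per PM, per participant.

    ``scope="trial"`` computes rVAR per subject x condition from that
    trial's scores (the within-subject factor of the ANOVA stage);
    ``scope="subject"`` pools each subject's trials first (the pooled
    summary-table convention).  With ``use_pa`` the same formula is applied
    to the principal-acceleration series (NaN edge frames ignored).
    Shares are percentages of the total variance over *all* components and
    sum to 100; only the first ``k_retained`` PMs are reported.
    """
    if scope not in ("trial", "subject"):
        raise ValidationError(f"unknown rVAR scope {scope!r}")
    metric = "pa_rvar" if use_pa else "rvar"
    groups: dict[tuple, list[PMScoreSeries]] = {}
    for s in scores:
        key = s.key() if scope == "trial" else (s.subject_id,)
        groups.setdefault(key, []).append(s)
    rows = []
    for key, members in sorted(groups.items()):
        if use_pa:
            mats = []
            for s in members:
                if s.pa is None:
                    raise ValidationError(
                        f"trial {s.key()} has no principal accelerations"
                    )
                mats.append(s.pa)
            data = np.concatenate(mats, axis=0)
            var = np.nanvar(data, axis=0, ddof=1)
        else:
            data = np.concatenate([s.pp for s in members], axis=0)
            var = np.var(data, axis=0, ddof=1)
        shares = _variance_shares(var)
        first = members[0]
        for k in range(min(k_retained, shares.size)):
            row = {
                "subject": first.subject_id,
                "age_group": first.age_group,
                "pm": k + 1,
                "metric": metric,
                "value": shares[k],
            }
            row["condition"] = first.condition if scope == "trial" else "pooled"
            rows.append(row)
    cols = ["subject", "age_group", "condition", "pm", "metric", "value"]
    return pd.DataFrame(rows, columns=cols)


def lowpass_filter(x: np.ndarray, fs_hz: float, cutoff_hz: float = 7.0,
                   order: int = 3) -> np.ndarray:
    """Zero-phase (forward-backward) low-pass Butterworth filter.

    ``order`` is the per-pass design order; the forward-backward application
    squares the magnitude response and cancels the phase response.
    """
    if cutoff_hz >= fs_hz / 2:
        raise ValidationError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist ({fs_hz / 2} Hz)"
        )
    b, a = signal.butter(order, cutoff_hz / (fs_hz / 2.0), btype="low")
    padlen = 3 * max(len(a), len(b))
    if x.shape[0] <= padlen:
        raise ValidationError(
            f"series too short for zero-phase filtering: {x.shape[0]} <= {padlen}"
        )
    return signal.filtfilt(b, a, x, axis=0)


def second_derivative(x: np.ndarray, fs_hz: float) -> np.ndarray:
    """Second-order central-difference second derivative.

    Interior frames use (x[t+1] - 2 x[t] + x[t-1]) * fs^2; the first and
    last frames are NaN and excluded from downstream statistics.
    """
    out = np.full_like(np.asarray(x, dtype=float), np.nan)
    out[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) * fs_hz**2
    return out


def principal_accelerations(
    scores: PMScoreSeries,
    cutoff_hz: float = 7.0,
    order: int = 3,
    filter_scores: bool = True,
) -> PMScoreSeries:
    """Fill ``pa``: low-pass the position scores, then differentiate twice.

    Filtering before differentiation suppresses the high-frequency
    measurement noise that double differentiation would otherwise amplify;
    the zero-phase design keeps accelerations aligned in time with
    positions.
    """
    if scores.n_frames <= 6 * order:
        raise ValidationError(
            f"trial {scores.key()}: {scores.n_frames} frames is too short "
            f"for order-{order} filtering and differentiation"
        )
    pp_f = lowpass_filter(scores.pp, scores.fs_hz, cutoff_hz, order) \
        if filter_scores else scores.pp
    pa = second_derivative(pp_f, scores.fs_hz)
    return PMScoreSeries(
        subject_id=scores.subject_id,
        condition=scores.condition,
        fs_hz=scores.fs_hz,
        pp=scores.pp,
        pa=pa,
        age_group=scores.age_group,
        preferred_speed_m_s=scores.preferred_speed_m_s,
    )


def spectral_profile(
    scores: PMScoreSeries,
    bands: tuple[tuple[float, float], ...] = ((0, 2), (2, 4), (5, 7), (7, np.inf)),
) -> pd.DataFrame:
    """One-sided power spectrum and band powers per PM score series.

    Used to verify where score power concentrates before choosing the
    low-pass cutoff.  Band power is the integral of the periodogram density
    over the band, so the bands partition the series variance (Parseval).
    """
    if scores.n_frames < 64:
        raise ValidationError("need at least 64 frames for a spectral profile")
    freqs, psd = signal.periodogram(scores.pp, fs=scores.fs_hz, axis=0,
                                    detrend="constant", scaling="density")
    df = freqs[1] - freqs[0]
    rows = []
    for k in range(scores.n_components):
        peak = freqs[np.argmax(psd[:, k])]
        total = psd[:, k].sum() * df
        for lo, hi in bands:
            mask = (freqs >= lo) & (freqs < hi)
            rows.append({
                "pm": k + 1,
                "band_lo_hz": lo,
                "band_hi_hz": hi,
                "power": psd[mask, k].sum() * df,
                "total_power": total,
                "peak_hz": peak,
            })
    return pd.DataFrame(rows)


@dataclass
class RobustnessReport:
    """Leave-one-subject-out stability of each eigenvector.

    ``similarity`` holds |cosine| between the full-data and reduced-data
    eigenvector k for each left-out subject; a PM whose minimum similarity
    stays above the threshold is considered robust to any single
    participant.
    """

    similarity: pd.DataFrame  # columns: left_out, pm, similarity
    threshold: float

    def min_similarity(self) -> pd.Series:
        return self.similarity.groupby("pm")["similarity"].min()

    def robust_pms(self) -> list[int]:
        mins = self.min_similarity()
        return [int(pm) for pm, v in mins.items() if v >= self.threshold]


def loo_robustness(
    pooled: PooledMatrix,
    k_check: int = 5,
    threshold: float = 0.9,
) -> RobustnessReport:
    """Refit the basis with each subject left out; compare eigenvectors.

    Similarity is the absolute cosine between corresponding full-data and
    reduced-data eigenvectors, which is 1 for identical directions and
    insensitive to the arbitrary eigenvector sign.
    """
    subjects = sorted({subj for subj, _ in pooled.block_index})
    if len(subjects) < 3:
        raise ValidationError("leave-one-out needs at least 3 subjects")
    full = fit_basis(pooled)
    rows = []
    for left_out in subjects:
        keep = [tr for tr in pooled.trials if tr.subject_id != left_out]
        reduced_values = np.concatenate([tr.values for tr in keep], axis=0)
        reduced = fit_basis(reduced_values)
        k_max = min(k_check, full.n_components, reduced.n_components)
        for k in range(k_max):
            cos = abs(float(
                full.eigenvectors[:, k] @ reduced.eigenvectors[:, k]
            ))
            rows.append({
                "left_out": left_out,
                "pm": k + 1,
                "similarity": min(cos, 1.0),
            })
    return RobustnessReport(
        similarity=pd.DataFrame(rows, columns=["left_out", "pm", "similarity"]),
        threshold=threshold,
    )
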