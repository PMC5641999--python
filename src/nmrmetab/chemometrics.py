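"""Latent-variable chemometrics: PCA with Hotelling's T2 outlier gating,
PLS-DA, O-PLS-DA and back-scaled correlation loadings.

Conventions used throughout:

* class encoding is symmetric +1/-1, with the *reference* group (e.g.
  controls) at -1, so positive back-scaled loadings read as "up in the
  positive class relative to the reference";
* unit-variance scaling drops zero-variance columns (recorded on the
  :class:`ScaledMatrix`) because autoscaling is undefined for them;
* the O-PLS-DA model carries exactly one predictive and one orthogonal
  component (single-response Trygg-Wold orthogonal signal correction);
* bin-level significance uses the two-tailed critical Pearson
  correlation at P < 0.05 for the model's sample size, the same rule
  that yields cutoffs of 0.32 (n = 38) to 0.48 (n = 17).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .nmrproc import BinnedMatrix

__all__ = [
    "ScaledMatrix",
    "PcaModel",
    "PlsModel",
    "OplsModel",
    "LoadingProfile",
    "scale_matrix",
    "fit_pca",
    "hotelling_t2_limit",
    "hotelling_t2",
    "detect_outliers",
    "encode_labels",
    "fit_pls_da",
    "fit_opls_da",
    "backscaled_loadings",
    "correlation_cutoff",
    "significant_bins",
]


def _as_values(matrix) -> np.ndarray:
    if isinstance(matrix, BinnedMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


@dataclass(frozen=True)
class ScaledMatrix:
    """Centered (and optionally autoscaled) matrix with its parameters.

    ``kept`` is a boolean mask over the original columns; zero-variance
    columns are dropped in ``unit_variance`` mode.
    """

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    mode: str
    kept: np.ndarray

    def transform(self, raw) -> np.ndarray:
        """Apply the stored centering/scaling to new rows."""
        x = _as_values(raw)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.kept.size:
            raise ValueError(
                f"expected {self.kept.size} columns, got {x.shape[1]}"
            )
        x = x[:, self.kept] - self.column_means
        if self.mode == "unit_variance":
            x = x / self.column_sds
        return x


def scale_matrix(matrix, mode: str = "unit_variance") -> ScaledMatrix:
    """Center (and in ``unit_variance`` mode autoscale) each column.

    Sample standard deviations (ddof=1).  Columns with zero variance are
    dropped with a warning in ``unit_variance`` mode and kept (centered)
    in ``mean_center`` mode.
    """
    if mode not in ("unit_variance", "mean_center"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    x = _as_values(matrix)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to scale")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    kept = np.ones(x.shape[1], dtype=bool)
    if mode == "unit_variance":
        kept = sds > 0
        if not kept.all():
            warnings.warn(
                f"dropping {int((~kept).sum())} zero-variance columns",
                stacklevel=2,
            )
        values = (x[:, kept] - means[kept]) / sds[kept]
        return ScaledMatrix(values, means[kept], sds[kept], mode, kept)
    values = x - means
    return ScaledMatrix(values, means, sds, mode, kept)


# ---------------------------------------------------------------------------
# PCA and Hotelling's T2


@dataclass(frozen=True)
class PcaModel:
    scores: np.ndarray  # n x A
    loadings: np.ndarray  # p x A, orthonormal columns
    eigenvalues: np.ndarray  # score variances, descending

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def fit_pca(scaled: ScaledMatrix, n_components: int) -> PcaModel:
    """Top components by singular value decomposition of the scaled data."""
    x = scaled.values
    n = x.shape[0]
    max_a = min(n - 1, x.shape[1])
    if not 1 <= n_components <= max_a:
        raise ValueError(f"n_components must be in [1, {max_a}]")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic sign: largest-|loading| entry of each component positive
    for a in range(n_components):
        j = int(np.argmax(np.abs(vt[a])))
        if vt[a, j] < 0:
            vt[a] *= -1.0
            u[:, a] *= -1.0
    return PcaModel(
        scores=u * s,
        loadings=vt.T,
        eigenvalues=s**2 / (n - 1),
    )


def hotelling_t2_limit(n: int, n_components: int, alpha: float = 0.05) -> float:
    """F-based confidence limit for Hotelling's T2 of PCA scores.

    ``A(n-1)(n+1) / (n(n-A)) * F_{1-alpha}(A, n-A)`` — the exact limit
    for scores of a model fitted on the same n samples.
    """
    a = n_components
    if not (n > a >= 1):
        raise ValueError("need n > n_components >= 1")
    factor = a * (n - 1) * (n + 1) / (n * (n - a))
    return float(factor * stats.f.ppf(1.0 - alpha, a, n - a))


def hotelling_t2(pca: PcaModel) -> np.ndarray:
    """Per-sample T2 = sum_a t_a^2 / lambda_a over the model components."""
    lam = pca.eigenvalues
    if np.any(lam <= 0):
        raise ValueError("non-positive eigenvalue; reduce component count")
    return (pca.scores**2 / lam).sum(axis=1)


def detect_outliers(pca: PcaModel, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of samples outside the T2 confidence limit."""
    n = pca.scores.shape[0]
    limit = hotelling_t2_limit(n, pca.n_components, alpha)
    return hotelling_t2(pca) > limit


# ---------------------------------------------------------------------------
# PLS-DA / O-PLS-DA


def encode_labels(
    labels, positive: str, reference: str
) -> tuple[np.ndarray, dict[str, float]]:
    """Encode a two-class label vector as +1 (positive) / -1 (reference)."""
    labels = np.asarray(labels)
    present = set(np.unique(labels).tolist())
    if present != {positive, reference}:
        raise ValueError(
            f"labels {sorted(present)} do not match classes "
            f"({positive!r}, {reference!r})"
        )
    y = np.where(labels == positive, 1.0, -1.0)
    return y, {positive: 1.0, reference: -1.0}


def _check_two_class(y: np.ndarray):
    u = np.unique(y)
    if u.size != 2:
        raise ValueError("y must contain exactly two classes")


@dataclass(frozen=True)
class PlsModel:
    """NIPALS PLS1 model (weights W, scores T, loadings P, y-loadings c)."""

    weights: np.ndarray  # p x A
    scores: np.ndarray  # n x A
    loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    coef: np.ndarray  # p, regression vector on scaled X
    scaling: ScaledMatrix
    y_encoding: dict[str, float] | None = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def predict(self, raw) -> np.ndarray:
        """Predicted y for new (unscaled) rows; no intercept, so the
        training-mean row predicts 0."""
        return self.scaling.transform(raw) @ self.coef

    def fitted(self) -> np.ndarray:
        return self.scores @ self.y_loadings


def fit_pls_da(
    scaled: ScaledMatrix, y: np.ndarray, n_components: int = 2
) -> PlsModel:
    """Single-response NIPALS PLS with X and y deflation."""
    y = np.asarray(y, dtype=float)
    _check_two_class(y)
    x = scaled.values.copy()
    yr = y.copy()
    n, p = x.shape
    ws, ts, ps, cs = [], [], [], []
    for _ in range(n_components):
        w = x.T @ yr
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = x @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p_vec = x.T @ t / tt
        c = float(yr @ t / tt)
        x = x - np.outer(t, p_vec)
        yr = yr - c * t
        ws.append(w)
        ts.append(t)
        ps.append(p_vec)
        cs.append(c)
    if not ws:
        raise ValueError("y carries no covariance with X; cannot fit")
    w_mat = np.column_stack(ws)
    p_mat = np.column_stack(ps)
    c_vec = np.array(cs)
    coef = w_mat @ np.linalg.solve(p_mat.T @ w_mat, c_vec)
    return PlsModel(
        weights=w_mat,
        scores=np.column_stack(ts),
        loadings=p_mat,
        y_loadings=c_vec,
        coef=coef,
        scaling=scaled,
    )


@dataclass(frozen=True)
class OplsModel:
    """O-PLS-DA with one predictive and one orthogonal component.

    ``w`` is the unit predictive weight vector, ``w_orth``/``p_orth``
    define the orthogonal signal-correction filter, and ``b`` regresses
    y on the predictive score.
    """

    w: np.ndarray
    t_pred: np.ndarray
    p_pred: np.ndarray
    w_orth: np.ndarray
    t_orth: np.ndarray
    p_orth: np.ndarray
    b: float
    scaling: ScaledMatrix
    y_encoding: dict[str, float] | None = None

    def filter(self, x_scaled: np.ndarray) -> np.ndarray:
        """Remove the orthogonal component from scaled rows.

        Idempotent: the filtered matrix has zero projection on
        ``w_orth``, so re-applying the filter is the identity.
        """
        if np.linalg.norm(self.w_orth) == 0:
            return x_scaled
        t_o = x_scaled @ self.w_orth
        return x_scaled - np.outer(t_o, self.p_orth)

    def predict_scores(self, raw) -> np.ndarray:
        """Predictive scores t_pred for new (unscaled) rows."""
        x = self.scaling.transform(raw)
        return self.filter(x) @ self.w

    def predict(self, raw) -> np.ndarray:
        """Predicted y = b * t_pred; class is its sign."""
        return self.b * self.predict_scores(raw)

    def classify(self, raw, encoding: dict[str, float] | None = None):
        enc = encoding or self.y_encoding
        if enc is None:
            raise ValueError("no label encoding stored")
        inv = {v: k for k, v in enc.items()}
        return [inv[1.0] if s >= 0 else inv[-1.0] for s in self.predict(raw)]


def fit_opls_da(
    scaled: ScaledMatrix, y: np.ndarray, y_encoding: dict[str, float] | None = None
) -> OplsModel:
    """Trygg-Wold single-y O-PLS-DA (one orthogonal component).

    The orthogonal weight is the part of the first PLS loading not
    aligned with the predictive weight; its score is uncorrelated with y
    by construction.  After deflating the orthogonal component the
    predictive component is refitted on the filtered matrix.
    """
    y = np.asarray(y, dtype=float)
    _check_two_class(y)
    x = scaled.values
    if x.shape[1] < 2:
        raise ValueError("need at least 2 variables for O-PLS")
    w = x.T @ y
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("y carries no covariance with X; cannot fit")
    w /= nw
    t = x @ w
    p_vec = x.T @ t / float(t @ t)
    w_orth = p_vec - float(w @ p_vec) * w
    n_orth = np.linalg.norm(w_orth)
    if n_orth > 1e-10:
        w_orth = w_orth / n_orth
        t_orth = x @ w_orth
        p_orth = x.T @ t_orth / float(t_orth @ t_orth)
        x_filt = x - np.outer(t_orth, p_orth)
    else:  # no structured y-orthogonal variation
        w_orth = np.zeros_like(w)
        t_orth = np.zeros(x.shape[0])
        p_orth = np.zeros_like(w)
        x_filt = x
    # Xf' y == X' y because t_orth is y-orthogonal, so w is unchanged;
    # recompute the score and loading on the filtered matrix.
    t_pred = x_filt @ w
    p_pred = x_filt.T @ t_pred / float(t_pred @ t_pred)
    b = float(y @ t_pred / (t_pred @ t_pred))
    return OplsModel(
        w=w,
        t_pred=t_pred,
        p_pred=p_pred,
        w_orth=w_orth,
        t_orth=t_orth,
        p_orth=p_orth,
        b=b,
        scaling=scaled,
        y_encoding=y_encoding,
    )


# ---------------------------------------------------------------------------
# Back-scaled correlation loadings


@dataclass(frozen=True)
class LoadingProfile:
    """Per-bin back-scaled loadings with correlation significance."""

    bin_ppm: np.ndarray
    backscaled: np.ndarray
    r: np.ndarray
    r_crit: float
    significant: np.ndarray
    direction: np.ndarray  # sign of backscaled: +1 up, -1 down

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ppm": self.bin_ppm,
                "backscaled": self.backscaled,
                "r": self.r,
                "significant": self.significant,
                "direction": np.where(self.direction > 0, "up", "down"),
            }
        )


def correlation_cutoff(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical Pearson correlation at significance ``alpha``.

    ``r_crit = t_q / sqrt(t_q^2 + n - 2)`` with ``t_q`` the
    ``1 - alpha/2`` Student-t quantile on ``n - 2`` degrees of freedom;
    e.g. 0.32 at n = 38 and 0.48 at n = 17.
    """
    if n < 4:
        raise ValueError("need n >= 4 for a correlation cutoff")
    tq = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(tq / np.sqrt(tq**2 + n - 2))


def backscaled_loadings(
    model: OplsModel,
    unscaled_matrix,
    bin_ppm: np.ndarray | None = None,
    alpha: float = 0.05,
) -> LoadingProfile:
    """Back-scaled predictive loadings with correlation colour-coding.

    Each loading is multiplied back by its column's standard deviation
    so the profile reads like a spectrum; ``r`` is the Pearson
    correlation between the predictive score and each (unscaled) bin
    column, thresholded at the critical value for the model's n.
    """
    x = _as_values(unscaled_matrix)
    if bin_ppm is None:
        if isinstance(unscaled_matrix, BinnedMatrix):
            bin_ppm = unscaled_matrix.bin_centers
        else:
            raise ValueError("bin_ppm required for a bare matrix")
    kept = model.scaling.kept
    x = x[:, kept]
    ppm = np.asarray(bin_ppm)[kept]
    t = model.t_pred
    n = x.shape[0]
    backscaled = model.p_pred * model.scaling.column_sds
    xc = x - x.mean(axis=0)
    tc = t - t.mean()
    denom = np.sqrt((xc**2).sum(axis=0)) * np.sqrt(float(tc @ tc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc.T @ tc / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    r_crit = correlation_cutoff(n, alpha)
    return LoadingProfile(
        bin_ppm=ppm,
        backscaled=backscaled,
        r=r,
        r_crit=r_crit,
        significant=np.abs(r) >= r_crit,
        direction=np.where(backscaled >= 0, 1, -1),
    )


def significant_bins(
    profile: LoadingProfile,
    assignments: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Table of significantly changed bins (the up/down metabolite list).

    ``assignments`` optionally maps metabolite names to ppm intervals;
    a significant bin falling inside an interval is annotated with the
    name.  Direction follows the class encoding: "up" means higher in
    the positive class than in the reference class.
    """
    mask = profile.significant
    ppm = profile.bin_ppm[mask]
    names = np.full(ppm.shape, "", dtype=object)
    if assignments:
        for name, (lo, hi) in assignments.items():
            inside = (ppm >= min(lo, hi)) & (ppm <= max(lo, hi))
            names[inside] = name
    return pd.DataFrame(
        {
            "ppm": ppm,
            "metabolite": names,
            "direction": np.where(profile.direction[mask] > 0, "up", "down"),
            "r": profile.r[mask],
            "backscaled": profile.backscaled[mask],
        }
    ).reset_index(drop=True)
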