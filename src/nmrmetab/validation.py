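"""Model-validity machinery: sevenfold cross-validated Q2/R2, the
200-permutation test, CV-ANOVA on cross-validated residuals, ROC/AUC on
cross-validated scores, and the combined verdict.

A discrimination model is declared *valid* only when the permutation
test and the CV-ANOVA test pass at the same time; either alone is not
sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chemometrics import ScaledMatrix, fit_opls_da, fit_pls_da, scale_matrix

__all__ = [
    "ValidationReport",
    "PermutationResult",
    "stratified_folds",
    "cross_validated_q2",
    "training_r2",
    "permutation_test",
    "cv_anova",
    "roc_auc",
    "model_verdict",
    "validate_contrast",
]


def stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold assignment stratified by class.

    Indices within each class are shuffled and dealt round-robin into
    ``k`` folds, so class proportions are as equal as possible per fold
    and every training fold contains both classes.
    """
    y = np.asarray(y)
    n = y.size
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= n folds")
    folds = np.empty(n, dtype=int)
    start = 0
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        folds[idx] = (start + np.arange(idx.size)) % k
        start += idx.size  # offset so small classes spread over all folds
    for f in range(k):
        if np.unique(y[folds != f]).size < 2:
            raise ValueError(f"training fold {f} lost a class; lower k")
    return folds


def _fit_predict(x_train, y_train, x_test, method, n_components, scale_mode):
    scaled = scale_matrix(x_train, scale_mode)
    if method == "opls":
        model = fit_opls_da(scaled, y_train)
    elif method == "pls":
        model = fit_pls_da(scaled, y_train, n_components)
    else:
        raise ValueError(f"unknown method {method!r}")
    return model.predict(x_test)


def cross_validated_q2(
    x: np.ndarray,
    y: np.ndarray,
    k: int = 7,
    seed: int = 0,
    method: str = "opls",
    n_components: int = 2,
    scale_mode: str = "unit_variance",
):
    """K-fold cross-validated predictive ability.

    Each fold is left out, the model (including its scaling) is refitted
    on the rest, and the held-out samples are predicted back.
    ``Q2 = 1 - PRESS / SS_y`` with ``SS_y`` about the overall mean.

    Returns ``(q2, residuals, cv_scores)`` with per-sample
    cross-validated residuals ``y - yhat`` and predicted scores.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    folds = stratified_folds(y, k, rng)
    yhat = np.empty(y.size)
    for f in range(k):
        train = folds != f
        yhat[~train] = _fit_predict(
            x[train], y[train], x[~train], method, n_components, scale_mode
        )
    press = float(((y - yhat) ** 2).sum())
    ss_y = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss_y, y - yhat, yhat


def training_r2(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "opls",
    n_components: int = 2,
    scale_mode: str = "unit_variance",
) -> float:
    """Explained variance of the training fit, ``1 - SS_res / SS_y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    yhat = _fit_predict(x, y, x, method, n_components, scale_mode)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_y = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_y


@dataclass(frozen=True)
class PermutationResult:
    q2_real: float
    perm_q2: np.ndarray
    passed: bool

    @property
    def q2_max(self) -> float:
        return float(self.perm_q2.max())


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 200,
    k: int = 7,
    seed: int = 0,
    method: str = "pls",
    n_components: int = 2,
) -> PermutationResult:
    """Randomised-classification overfit check.

    The class vector is permuted ``n_perm`` times (uniformly over
    orderings, identity not excluded) and the full cross-validated Q2 is
    recomputed each time.  The model passes when the real Q2 exceeds the
    maximum permuted Q2.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    q2_real, _, _ = cross_validated_q2(
        x, y, k=k, seed=int(rng.integers(2**31)), method=method,
        n_components=n_components,
    )
    perm_q2 = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        perm_q2[i], _, _ = cross_validated_q2(
            x, y_perm, k=k, seed=int(rng.integers(2**31)), method=method,
            n_components=n_components,
        )
    return PermutationResult(
        q2_real=q2_real, perm_q2=perm_q2, passed=bool(q2_real > perm_q2.max())
    )


def cv_anova(
    cv_residuals: np.ndarray, y: np.ndarray, model_df: int = 2
) -> tuple[float, float]:
    """ANOVA of the cross-validated residuals.

    ``F = ((SS_y - PRESS) / df1) / (PRESS / df2)`` with ``df1`` the
    number of fitted components (predictive + orthogonal = 2 for the
    O-PLS-DA models here) and ``df2 = n - model_df - 1``.  When the
    cross-validated predictions explain nothing (PRESS >= SS_y) the test
    reports ``p = 1``.
    """
    res = np.asarray(cv_residuals, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    df1 = model_df
    df2 = n - model_df - 1
    if df1 < 1 or df2 < 1:
        raise ValueError("invalid degrees of freedom")
    press = float((res**2).sum())
    ss_y = float(((y - y.mean()) ** 2).sum())
    f_stat = ((ss_y - press) / df1) / (press / df2)
    p = float(stats.f.sf(f_stat, df1, df2)) if f_stat > 0 else 1.0
    return float(f_stat), p


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney U identity.

    Ties between a positive and a negative score count one half.
    """
    y = np.asarray(y_true, dtype=float)
    s = np.asarray(scores, dtype=float)
    pos = y > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = float(ranks[pos].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


@dataclass(frozen=True)
class ValidationReport:
    """Table-style validation record for one group contrast."""

    q2: float  # O-PLS-DA cross-validated Q2
    r2: float  # O-PLS-DA training R2
    q2_pls: float  # PLS-DA cross-validated Q2
    perm_q2: np.ndarray
    perm_pass: bool
    cv_anova_F: float
    cv_anova_p: float
    cv_anova_pass: bool
    auc: float
    seeds: dict = field(default_factory=dict)

    @property
    def perm_q2_max(self) -> float:
        return float(np.max(self.perm_q2))

    @property
    def verdict(self) -> bool:
        return model_verdict(self)


def model_verdict(report: ValidationReport) -> bool:
    """Valid only when permutation test AND CV-ANOVA pass together."""
    return bool(report.perm_pass and report.cv_anova_pass)


def validate_contrast(
    x: np.ndarray,
    y: np.ndarray,
    k: int = 7,
    n_perm: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    pls_components: int = 2,
) -> ValidationReport:
    """Full validation of one two-class contrast.

    O-PLS-DA supplies Q2/R2, the CV-ANOVA residuals and the
    cross-validated scores for the AUC; the permutation test runs on the
    PLS-DA model.  All randomness (folds, permutations) derives from
    ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seed_cv, seed_perm = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    q2, residuals, cv_scores = cross_validated_q2(
        x, y, k=k, seed=seed_cv, method="opls"
    )
    r2 = training_r2(x, y, method="opls")
    q2_pls, _, _ = cross_validated_q2(
        x, y, k=k, seed=seed_cv, method="pls", n_components=pls_components
    )
    perm = permutation_test(
        x, y, n_perm=n_perm, k=k, seed=seed_perm, method="pls",
        n_components=pls_components,
    )
    f_stat, p = cv_anova(residuals, y, model_df=2)
    auc = roc_auc(y, cv_scores)
    return ValidationReport(
        q2=q2,
        r2=r2,
        q2_pls=q2_pls,
        perm_q2=perm.perm_q2,
        perm_pass=perm.passed,
        cv_anova_F=f_stat,
        cv_anova_p=p,
        cv_anova_pass=bool(p < alpha),
        auc=auc,
        seeds={"seed": seed, "cv": seed_cv, "permutation": seed_perm},
    )
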