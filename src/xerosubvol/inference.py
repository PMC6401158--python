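"""Outcome derivation and statistical modelling of xerostomia injury/recovery.

Implements the analysis stages downstream of feature extraction:

* CTCAE timeline -> injury/recovery labels (injury = any grade >=2 within
  6 months of radiotherapy; recovery = injury followed by a drop below
  grade 2 within 18 months);
* prevalence curves over follow-up windows and per-group feature summaries;
* single-step max-T permutation testing of dose features with family-wise
  error control;
* ridge-penalized logistic regression (unpenalized intercept, internal
  per-column standardization) with nested cross-validation: inner folds
  select the penalty, outer folds estimate generalization, and the whole
  split is resampled over iterations to attach standard deviations to
  AUC, sensitivity and specificity;
* ridge-coefficient importance normalized to [-100, 100] over the dose
  features for spatial visualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .dosimetry import dose_feature_columns, predictor_columns
from .errors import ConvergenceError, ValidationError

logger = logging.getLogger(__name__)

#: 6-month boundary for injury, days post-RT
INJURY_WINDOW_DAYS = 183
#: 18-month boundary for recovery, days post-RT
RECOVERY_WINDOW_DAYS = 548

#: follow-up windows for the prevalence curve, days post-RT (inclusive)
DEFAULT_VISIT_WINDOWS: dict[str, tuple[int, int]] = {
    "OTV": (0, 60),
    "3mo": (61, 135),
    "6mo": (136, 225),
    "9mo": (226, 315),
    "12mo": (316, 410),
    "18mo": (500, 600),
}

#: default ridge-penalty grid: 30 log-spaced values on standardized features
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 3, 30))


@dataclass
class AssessmentTimeline:
    """Longitudinal CTCAE xerostomia assessments for one patient."""

    patient_id: str
    assessments: list[tuple[int, int]]  # (days_post_rt, ctcae_grade)

    def __post_init__(self) -> None:
        days = [d for d, _ in self.assessments]
        if any(d < 0 for d in days):
            raise ValidationError(f"{self.patient_id}: negative days_post_rt")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValidationError(f"{self.patient_id}: days must be strictly increasing")
        if any(g not in (0, 1, 2, 3) for _, g in self.assessments):
            raise ValidationError(f"{self.patient_id}: grades must be in 0..3")


@dataclass(frozen=True)
class OutcomeLabels:
    """Binary injury label plus recovery label (defined only when injured)."""

    injury: int
    recovery: int | None

    def __post_init__(self) -> None:
        if self.injury not in (0, 1):
            raise ValidationError("injury must be 0/1")
        if self.injury == 0 and self.recovery is not None:
            raise ValidationError("recovery must be undefined when injury = 0")
        if self.injury == 1 and self.recovery not in (0, 1):
            raise ValidationError("recovery must be 0/1 when injury = 1")


def derive_outcomes(timeline: AssessmentTimeline) -> OutcomeLabels | None:
    """Derive injury/recovery labels from a CTCAE timeline.

    Injury: any grade >=2 assessment at <= 183 days post-RT.  Recovery
    (injured patients only): the last assessment at <= 548 days has grade
    < 2.  Returns ``None`` (exclusion signal, not an error) for a patient
    with no assessment inside the 18-month window.
    """
    in_window = [(d, g) for d, g in timeline.assessments if d <= RECOVERY_WINDOW_DAYS]
    if not in_window:
        return None
    injury = int(any(g >= 2 for d, g in in_window if d <= INJURY_WINDOW_DAYS))
    if not injury:
        return OutcomeLabels(0, None)
    last_grade = in_window[-1][1]
    return OutcomeLabels(1, int(last_grade < 2))


def prevalence_curve(
    timelines: list[AssessmentTimeline],
    visit_windows: dict[str, tuple[int, int]] | None = None,
) -> dict[str, float | None]:
    """Fraction of assessed patients with grade >=2 per follow-up window.

    The denominator of each window counts patients with at least one
    assessment inside it; a window nobody attended yields ``None``.
    """
    if not timelines:
        raise ValidationError("empty cohort")
    windows = visit_windows or DEFAULT_VISIT_WINDOWS
    out: dict[str, float | None] = {}
    for name, (lo, hi) in windows.items():
        assessed = 0
        positive = 0
        for tl in timelines:
            grades = [g for d, g in tl.assessments if lo <= d <= hi]
            if grades:
                assessed += 1
                positive += int(max(grades) >= 2)
        out[name] = positive / assessed if assessed else None
    return out


GROUP_DEFS = {
    "no_xerostomia": lambda df: df["injury"] == 0,
    "injury_recovery": lambda df: (df["injury"] == 1) & (df["recovery"] == 1),
    "injury_no_recovery": lambda df: (df["injury"] == 1) & (df["recovery"] == 0),
}


def group_summaries(features: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-group mean and coefficient of variation of every dose feature.

    Groups: no xerostomia, injury followed by recovery, injury without
    recovery.  CV uses the sample standard deviation (ddof=1) divided by
    the mean; it is NaN where the mean is zero.
    """
    dose_cols = [c for c in dose_feature_columns() if c in features.columns]
    out: dict[str, pd.DataFrame] = {}
    for name, sel in GROUP_DEFS.items():
        sub = features.loc[sel(features), dose_cols]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        cv = sd / mean.where(mean != 0)
        out[name] = pd.DataFrame({"mean": mean, "cv": cv, "n": len(sub)})
    return out


# ---------------------------------------------------------------------------
# max-T permutation test
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Single-step max-T permutation test output."""

    features: list[str]
    t_observed: np.ndarray
    p_adjusted: np.ndarray
    p_unadjusted: np.ndarray
    n_permutations: int
    seed: int
    direction: str
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.p_adjusted < self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "T": self.t_observed,
                "p_adjusted": self.p_adjusted,
                "p_unadjusted": self.p_unadjusted,
                "significant": self.significant,
            }
        ).set_index("feature")


def _t_statistics(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pooled-SE two-sample statistics for one or many label columns.

    ``labels`` is (n,) or (n, B) of 0/1; returns (p,) or (p, B).
    """
    single = labels.ndim == 1
    L = labels[:, None] if single else labels
    n, p = X.shape
    n1 = L[:, 0].sum()
    n0 = n - n1
    S = X.sum(axis=0)[:, None]
    Q = (X * X).sum(axis=0)[:, None]
    S1 = X.T @ L
    Q1 = (X * X).T @ L
    m1 = S1 / n1
    m0 = (S - S1) / n0
    ss1 = Q1 - n1 * m1 * m1
    ss0 = (Q - Q1) - n0 * m0 * m0
    sp2 = (ss1 + ss0) / (n - 2)
    se = np.sqrt(np.maximum(sp2, 0.0) * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m0) / np.where(se > 0, se, 1.0), 0.0)
    return t[:, 0] if single else t


def maxT_permutation_test(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    direction: str = "greater",
    seed: int = 0,
    alpha: float = 0.05,
) -> PermutationResult:
    """Single-step max-T permutation test over all dose features.

    The observed per-feature statistic is the two-sample mean difference
    (positive class minus negative class) over its pooled standard error.
    For each label permutation the maximum statistic across features is
    recorded; the one-sided adjusted p-value of feature j is
    ``(1 + #{b : M_b >= T_j}) / (1 + n_perm)``, which controls the
    family-wise error rate at level alpha in a single step.

    ``direction="greater"`` tests for higher feature values in the
    positive class; ``"less"`` tests the opposite one-sided alternative.
    """
    if direction not in ("greater", "less"):
        raise ValidationError(f"direction must be 'greater' or 'less', got {direction!r}")
    if isinstance(X, pd.DataFrame):
        features = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        features = [f"f{j}" for j in range(Xv.shape[1])]
    yv = np.asarray(y).astype(int)
    if set(np.unique(yv)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    if yv.sum() == 0 or yv.sum() == yv.size:
        raise ValidationError("both classes must be nonempty")
    if np.isnan(Xv).any():
        raise ValidationError("feature matrix contains missing values")
    sign = 1.0 if direction == "greater" else -1.0

    const = Xv.std(axis=0) == 0
    if const.any():
        logger.warning(
            "%d constant feature(s); their statistics set to 0", int(const.sum())
        )

    t_obs = sign * _t_statistics(Xv, yv)
    t_obs[const] = 0.0

    rng = np.random.default_rng(seed)
    perms = np.empty((yv.size, n_perm), dtype=float)
    for b in range(n_perm):
        perms[:, b] = rng.permutation(yv)
    t_perm = sign * _t_statistics(Xv, perms)
    t_perm[const, :] = 0.0
    m_max = t_perm.max(axis=0)

    p_adj = (1 + (m_max[None, :] >= t_obs[:, None]).sum(axis=1)) / (1 + n_perm)
    p_unadj = (1 + (t_perm >= t_obs[:, None]).sum(axis=1)) / (1 + n_perm)
    return PermutationResult(
        features=features,
        t_observed=t_obs,
        p_adjusted=p_adj,
        p_unadjusted=p_unadj,
        n_permutations=n_perm,
        seed=seed,
        direction=direction,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# ridge logistic regression
# ---------------------------------------------------------------------------


@dataclass
class RidgeModel:
    """Fitted ridge logistic regression with its standardization state.

    Coefficients live on the standardized-predictor scale; the intercept
    is unpenalized.  ``predict_proba`` applies the stored training means
    and standard deviations, so no refitting information leaks from data
    scored later.
    """

    intercept: float
    coef: np.ndarray
    lam: float
    feature_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    n_iter: int = 0
    grad_norm: float = np.nan

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        Z = (Xv - self.x_mean) / self.x_sd
        eta = self.intercept + Z @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))


def fit_ridge_logistic(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    lam: float,
    max_iter: int = 200,
    tol: float = 1e-6,
    feature_names: list[str] | None = None,
    init: tuple[float, np.ndarray] | None = None,
) -> RidgeModel:
    """Fit ridge-penalized logistic regression by damped Newton iteration.

    Minimizes the penalized negative log-likelihood
    ``-l(b) + (lam/2) * ||b||^2`` with the intercept excluded from the
    penalty.  Predictors are standardized internally to mean 0, sd 1
    (binary dummies included; constant columns are left unscaled).
    Iterates until the gradient norm falls below ``tol``.
    """
    if lam <= 0:
        raise ValidationError(f"lam must be > 0, got {lam}")
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        feature_names = feature_names or [f"f{j}" for j in range(Xv.shape[1])]
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    mean = Xv.mean(axis=0)
    sd = Xv.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Xv - mean) / sd

    if init is not None:
        b0 = float(init[0])
        beta = np.asarray(init[1], dtype=float).copy()
    else:
        beta = np.zeros(p)
        b0 = 0.0
        pbar = yv.mean()
        if 0 < pbar < 1:
            b0 = float(np.log(pbar / (1 - pbar)))

    def objective(b0_, beta_):
        eta = b0_ + Z @ beta_
        # log(1+exp(eta)) - y*eta, numerically stable
        ll = np.logaddexp(0.0, eta) - yv * eta
        return ll.sum() + 0.5 * lam * beta_ @ beta_

    obj = objective(b0, beta)
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        eta = b0 + Z @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        g_beta = Z.T @ (mu - yv) + lam * beta
        g_b0 = float((mu - yv).sum())
        grad_norm = float(np.sqrt(g_b0 * g_b0 + g_beta @ g_beta))
        if grad_norm < tol:
            return RidgeModel(
                intercept=float(b0), coef=beta, lam=float(lam),
                feature_names=feature_names, x_mean=mean, x_sd=sd,
                n_iter=it - 1, grad_norm=grad_norm,
            )
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        Zw = Z * w[:, None]
        H = np.empty((p + 1, p + 1))
        H[0, 0] = w.sum()
        H[0, 1:] = w @ Z
        H[1:, 0] = H[0, 1:]
        H[1:, 1:] = Z.T @ Zw
        H[1:, 1:][np.diag_indices(p)] += lam
        g = np.concatenate(([g_b0], g_beta))
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # backtracking line search on the penalized objective
        t = 1.0
        for _ in range(40):
            b0_new = b0 - t * step[0]
            beta_new = beta - t * step[1:]
            obj_new = objective(b0_new, beta_new)
            if obj_new <= obj + 1e-12:
                break
            t *= 0.5
        b0, beta, obj = b0_new, beta_new, obj_new
    # final gradient check after the loop
    eta = b0 + Z @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    g_beta = Z.T @ (mu - yv) + lam * beta
    g_b0 = float((mu - yv).sum())
    grad_norm = float(np.sqrt(g_b0 * g_b0 + g_beta @ g_beta))
    if grad_norm >= tol:
        raise ConvergenceError(
            f"ridge logistic fit did not converge: gradient norm {grad_norm:.3e} "
            f"after {max_iter} Newton iterations (lam={lam}, n={n}, p={p})"
        )
    return RidgeModel(
        intercept=float(b0), coef=beta, lam=float(lam),
        feature_names=feature_names, x_mean=mean, x_sd=sd,
        n_iter=max_iter, grad_norm=grad_norm,
    )


def normalized_importance(model: RidgeModel) -> pd.Series:
    """Ridge dose-feature coefficients rescaled to [-100, 100].

    ``importance_j = 100 * beta_j / max_k |beta_k|`` with the maximum over
    dose-feature coefficients only (standardized scale); the largest
    absolute importance is exactly 100 whenever any dose coefficient is
    nonzero.  Clinical coefficients are not part of the normalization.
    """
    dose_cols = [c for c in dose_feature_columns() if c in model.feature_names]
    idx = [model.feature_names.index(c) for c in dose_cols]
    beta = model.coef[idx]
    m = np.abs(beta).max() if len(beta) else 0.0
    vals = np.zeros_like(beta) if m == 0 else 100.0 * beta / m
    return pd.Series(vals, index=dose_cols, name="importance")


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------


@dataclass
class EvalMetrics:
    """Resampled nested-CV performance plus normalized importance."""

    auc_mean: float
    auc_sd: float
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    n_iterations: int
    importance: pd.Series
    final_model: RidgeModel
    lambda_final: float
    auc_per_iteration: np.ndarray = field(default_factory=lambda: np.array([]))
    auc_sd_folds: float = np.nan
    clinical_coefficients: pd.Series | None = None

    def summary(self) -> dict[str, float]:
        return {
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "sensitivity_mean": self.sensitivity_mean,
            "sensitivity_sd": self.sensitivity_sd,
            "specificity_mean": self.specificity_mean,
            "specificity_sd": self.specificity_sd,
            "n_iterations": self.n_iterations,
            "lambda_final": self.lambda_final,
        }


def _model_population(table: pd.DataFrame, outcome: str) -> tuple[pd.DataFrame, np.ndarray]:
    cols = [c for c in predictor_columns() if c in table.columns]
    if outcome == "injury":
        rows = table
        y = table["injury"].to_numpy(dtype=int)
    elif outcome == "recovery":
        rows = table[table["recovery"].notna()]
        y = rows["recovery"].to_numpy(dtype=int)
    else:
        raise ValidationError(f"outcome must be 'injury' or 'recovery', got {outcome!r}")
    if len(set(np.unique(y))) < 2:
        raise ValidationError(f"outcome {outcome!r} has a single class")
    return rows[cols], y


def _stratified_folds(y, n_splits, rng, max_attempts=20):
    """Stratified fold indices; re-drawn (logged) if a fold lacks a class."""
    for attempt in range(max_attempts):
        state = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=state)
        folds = list(skf.split(np.zeros_like(y), y))
        ok = all(
            len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
            for tr, te in folds
        )
        if ok:
            return folds
        logger.warning("fold draw %d produced a single-class fold; re-drawing", attempt)
    raise ValidationError(
        f"could not draw {n_splits} stratified folds with both classes "
        f"after {max_attempts} attempts (class counts {np.bincount(y)})"
    )


def _youden_threshold(y_true: np.ndarray, scores: np.ndarray) -> float:
    fpr, tpr, thr = roc_curve(y_true, scores)
    j = tpr - fpr
    return float(thr[int(np.argmax(j))])


def nested_cv_evaluate(
    table: pd.DataFrame,
    outcome: str,
    outer_folds: int = 5,
    inner_folds: int = 5,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    n_iterations: int = 50,
    seed: int = 0,
) -> EvalMetrics:
    """Nested cross-validation of the ridge logistic outcome model.

    Per iteration: a stratified outer split; for each outer training set
    the penalty is chosen by inner cross-validation maximizing validation
    AUC; the model is refit on the outer training set and scored on the
    held-out outer test set.  Outer-test scores are pooled into a single
    AUC per iteration, and sensitivity/specificity are read off at the
    Youden-optimal threshold on the pooled scores.  Means and standard
    deviations are taken over iterations.  The final importance vector
    comes from a model refit on all data at the modal selected penalty.
    """
    if not lambda_grid:
        raise ValidationError("lambda_grid must be nonempty")
    X, y = _model_population(table, outcome)
    lam_sorted = sorted(set(float(l) for l in lambda_grid))

    ss = np.random.SeedSequence([int(seed), 0xCE5])
    iter_seqs = ss.spawn(n_iterations)
    aucs, sens, specs = [], [], []
    fold_aucs: list[float] = []
    selected_lams: list[float] = []
    Xv = X.to_numpy(dtype=float)
    for it in range(n_iterations):
        rng = np.random.default_rng(iter_seqs[it])
        outer = _stratified_folds(y, outer_folds, rng)
        pooled_scores = np.empty_like(y, dtype=float)
        for tr_idx, te_idx in outer:
            X_tr, y_tr = Xv[tr_idx], y[tr_idx]
            inner = _stratified_folds(y_tr, inner_folds, rng)
            lam_auc = np.zeros(len(lam_sorted))
            for i_tr, i_val in inner:
                warm: tuple[float, np.ndarray] | None = None
                # descend the grid so each fit warm-starts from a more
                # regularized (smaller-coefficient) solution
                for li in range(len(lam_sorted) - 1, -1, -1):
                    m = fit_ridge_logistic(X_tr[i_tr], y_tr[i_tr], lam_sorted[li],
                                           feature_names=list(X.columns), init=warm)
                    warm = (m.intercept, m.coef)
                    s = m.predict_proba(X_tr[i_val])
                    lam_auc[li] += roc_auc_score(y_tr[i_val], s)
            # ties broken toward the larger (more regularized) penalty
            best = max(
                range(len(lam_sorted)),
                key=lambda li: (lam_auc[li], lam_sorted[li]),
            )
            lam_star = lam_sorted[best]
            selected_lams.append(lam_star)
            model = fit_ridge_logistic(X_tr, y_tr, lam_star,
                                       feature_names=list(X.columns))
            te_scores = model.predict_proba(Xv[te_idx])
            pooled_scores[te_idx] = te_scores
            fold_aucs.append(roc_auc_score(y[te_idx], te_scores))
        auc = roc_auc_score(y, pooled_scores)
        thr = _youden_threshold(y, pooled_scores)
        pred = pooled_scores >= thr
        tp = int((pred & (y == 1)).sum())
        fn = int((~pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        fp = int((pred & (y == 0)).sum())
        aucs.append(auc)
        sens.append(tp / (tp + fn))
        specs.append(tn / (tn + fp))

    aucs = np.asarray(aucs)
    sens = np.asarray(sens)
    specs = np.asarray(specs)
    # modal selected penalty; ties toward the larger value
    vals, counts = np.unique(np.asarray(selected_lams), return_counts=True)
    lam_final = float(vals[np.lexsort((vals, counts))[-1]])
    final_model = fit_ridge_logistic(X, y, lam_final, feature_names=list(X.columns))
    importance = normalized_importance(final_model)
    clin_cols = [c for c in final_model.feature_names
                 if c not in set(dose_feature_columns())]
    clin_idx = [final_model.feature_names.index(c) for c in clin_cols]
    clinical_coefs = pd.Series(final_model.coef[clin_idx], index=clin_cols,
                               name="coefficient")

    def sd(a):
        return float(np.std(a, ddof=1)) if len(a) > 1 else 0.0

    return EvalMetrics(
        auc_mean=float(aucs.mean()),
        auc_sd=sd(aucs),
        sensitivity_mean=float(sens.mean()),
        sensitivity_sd=sd(sens),
        specificity_mean=float(specs.mean()),
        specificity_sd=sd(specs),
        n_iterations=n_iterations,
        importance=importance,
        final_model=final_model,
        lambda_final=lam_final,
        auc_per_iteration=aucs,
        auc_sd_folds=sd(np.asarray(fold_aucs)),
        clinical_coefficients=clinical_coefs,
    )
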