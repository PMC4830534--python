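"""Model-comparison statistics: r(g, ĝ), heritability, PRESS, k-fold CV.

Three statistics compare fitted models against the simulator's ground
truth: the Pearson correlation between parametric and estimated genetic
values (total, additive and dominance components), the heritability
coefficient h² = cov(ĝ, y)/var(y), and the predicted residual error sum
of squares PRESS = Σ(θ̂ − θ)² (also applied to variance components).
A 10-fold cross-validation masks whole individuals, refits the model and
correlates predicted with observed phenotypes per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .kinship import RelationshipMatrix
from .mme_reml import ModelFit, ModelSpec, VarianceComponents, fit_gblup
from .simulate import TrueSignal

__all__ = [
    "predictive_correlation",
    "estimated_heritability",
    "press",
    "kfold_cv",
    "CVResult",
    "EvaluationReport",
    "evaluation_report",
]


def predictive_correlation(g_true: np.ndarray, g_hat: np.ndarray) -> float:
    """Pearson correlation between parametric and estimated genetic values."""
    g_true = np.asarray(g_true, dtype=float)
    g_hat = np.asarray(g_hat, dtype=float)
    if g_true.shape != g_hat.shape:
        raise ValueError("length mismatch")
    if g_true.size < 3:
        raise ValueError("need at least 3 values")
    if np.std(g_true) == 0 or np.std(g_hat) == 0:
        raise ValueError("zero variance in one of the inputs")
    return float(stats.pearsonr(g_true, g_hat).statistic)


def estimated_heritability(g_hat: np.ndarray, y: np.ndarray) -> float:
    """h² = cov(ĝ, y) / var(y) with sample (n-1) denominators."""
    g_hat = np.asarray(g_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if g_hat.shape != y.shape:
        raise ValueError("length mismatch")
    var_y = np.var(y, ddof=1)
    if var_y == 0:
        raise ValueError("phenotypic variance is zero")
    cov = np.cov(g_hat, y, ddof=1)[0, 1]
    return float(cov / var_y)


def press(theta_hat: np.ndarray, theta: np.ndarray) -> float:
    """Predicted residual error sum of squares Σ(θ̂ − θ)²."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if theta_hat.shape != theta.shape:
        raise ValueError("length mismatch")
    return float(np.sum((theta_hat - theta) ** 2))


@dataclass
class CVResult:
    """Fold-wise and pooled cross-validation correlations per trait."""

    trait_names: list[str]
    fold_corr: np.ndarray  # k x t, NaN for skipped folds
    mean: np.ndarray  # t, mean over valid folds (pooled value if none valid)
    sd: np.ndarray  # t, SD over valid folds (0 if fewer than 2 valid)
    pooled: np.ndarray  # t, single correlation over all held-out predictions

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": self.trait_names,
                "cv_corr_mean": self.mean,
                "cv_corr_sd": self.sd,
                "cv_corr_pooled": self.pooled,
            }
        )


def kfold_cv(
    phenotypes,
    A: Union[RelationshipMatrix, np.ndarray],
    D: Optional[Union[RelationshipMatrix, np.ndarray]],
    spec: ModelSpec,
    k: int = 10,
    seed: Optional[int] = None,
    tol: float = 1e-5,
    max_iter: int = 200,
    warm_start: bool = True,
    refit_variance: bool = True,
    per_cell: bool = False,
) -> CVResult:
    """k-fold cross-validation of one model variant.

    Individuals are partitioned into k seeded folds.  By default all
    traits of a held-out individual are masked together (whole-individual
    CV, i.e. predicting new hybrids); ``per_cell`` instead masks the
    fold's cells of one trait at a time so the remaining traits can
    support the prediction.  Per fold the model is refit (EM warm-started
    from the full-data variance components) and the masked phenotypes are
    predicted as β̂ + α̂ + δ̂.  With ``refit_variance=False`` the
    variance components estimated once on the full data are held fixed
    and each fold only re-solves the mixed-model equations — much faster
    and adequate when CV ranks models rather than re-estimates variances.
    Folds whose held-out values have zero variance (or fewer than 3 of
    them) are skipped with a warning; a pooled correlation over all
    held-out predictions is always reported.
    """
    from .mme_reml import _extract_Y  # shared input handling

    Y, ids = _extract_Y(phenotypes, spec.traits)
    n, t = Y.shape
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n folds")
    init_vc = None
    if warm_start or not refit_variance:
        full = fit_gblup(Y, A, D=D, spec=spec, tol=tol, max_iter=max_iter)
        init_vc = full.vc
    fold_max_iter = max_iter if refit_variance else 0
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_corr = np.full((k, t), np.nan)
    pred_all = np.full_like(Y, np.nan)
    for f, (_, test_idx) in enumerate(kf.split(np.arange(n))):
        if per_cell:
            trait_sets = [np.array([ti]) for ti in range(t)]
        else:
            trait_sets = [np.arange(t)]
        pred_fold = np.full((n, t), np.nan)
        for traits_masked in trait_sets:
            Y_train = Y.copy()
            Y_train[np.ix_(test_idx, traits_masked)] = np.nan
            fit = fit_gblup(
                Y_train, A, D=D, spec=spec, init_vc=init_vc, tol=tol,
                max_iter=fold_max_iter,
            )
            pred = fit.predict()
            pred_fold[np.ix_(test_idx, traits_masked)] = pred[
                np.ix_(test_idx, traits_masked)
            ]
        pred_all[test_idx] = pred_fold[test_idx]
        for ti in range(t):
            obs = ~np.isnan(Y[test_idx, ti])
            yo = Y[test_idx, ti][obs]
            po = pred_fold[test_idx, ti][obs]
            if yo.size < 3 or np.std(yo) == 0 or np.std(po) == 0:
                warnings.warn(
                    f"fold {f}: trait {spec.traits[ti]} skipped "
                    "(too few held-out values or zero variance)"
                )
                continue
            fold_corr[f, ti] = stats.pearsonr(yo, po).statistic
    pooled = np.full(t, np.nan)
    for ti in range(t):
        obs = ~np.isnan(Y[:, ti]) & ~np.isnan(pred_all[:, ti])
        if obs.sum() >= 3 and np.std(Y[obs, ti]) > 0:
            pooled[ti] = stats.pearsonr(Y[obs, ti], pred_all[obs, ti]).statistic
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(fold_corr, axis=0)
        sd = np.nanstd(fold_corr, axis=0, ddof=1)
    mean = np.where(np.isnan(mean), pooled, mean)
    sd = np.nan_to_num(sd, nan=0.0)
    return CVResult(
        trait_names=list(spec.traits),
        fold_corr=fold_corr,
        mean=mean,
        sd=sd,
        pooled=pooled,
    )


@dataclass
class EvaluationReport:
    """Tidy per-trait statistics of one fitted model against the truth."""

    table: pd.DataFrame  # columns: trait, statistic, component, value
    cv: Optional[CVResult] = None

    def value(self, trait: str, statistic: str, component: str = "total") -> float:
        sub = self.table.query(
            "trait == @trait and statistic == @statistic and component == @component"
        )
        if sub.empty:
            raise KeyError((trait, statistic, component))
        return float(sub["value"].iloc[0])

    def to_json_dict(self) -> dict:
        return {"records": self.table.to_dict(orient="records")}


def evaluation_report(
    fit: ModelFit,
    truth: TrueSignal,
    phenotypes,
    cv: Optional[CVResult] = None,
) -> EvaluationReport:
    """Per-trait r(g, ĝ), h², and PRESS for genetic effects and variances.

    Correlations and PRESS are computed for the total genetic value
    (α̂+δ̂ vs g−μ), the additive component (α̂ vs W_A a*) and — for
    dominance models — the dominance component (δ̂ vs W_D d*); PRESS is
    also applied to the variance-component estimates against the
    empirical truth.
    """
    from .mme_reml import _extract_Y

    Y, _ = _extract_Y(phenotypes, fit.spec.traits)
    trait_pos = {tr: i for i, tr in enumerate(truth.trait_names)}
    rows = []
    for ti, trait in enumerate(fit.spec.traits):
        tj = trait_pos[trait]
        g_true = truth.g[:, tj] - truth.mu[tj]
        add_true = truth.g_additive[:, tj]
        dom_true = truth.g_dominance[:, tj]
        g_hat = fit.g_hat[:, ti]
        rows += [
            dict(trait=trait, statistic="r_gg", component="total",
                 value=predictive_correlation(g_true, g_hat)),
            dict(trait=trait, statistic="r_gg", component="additive",
                 value=predictive_correlation(add_true, fit.alpha_hat[:, ti])),
            dict(trait=trait, statistic="press", component="total",
                 value=press(g_hat, g_true)),
            dict(trait=trait, statistic="press", component="additive",
                 value=press(fit.alpha_hat[:, ti], add_true)),
            dict(trait=trait, statistic="press", component="sigma2_alpha",
                 value=press(np.atleast_1d(fit.vc.V_alpha[ti, ti]),
                             np.atleast_1d(truth.V_alpha_emp[tj, tj]))),
        ]
        obs = ~np.isnan(Y[:, ti])
        rows.append(
            dict(trait=trait, statistic="h2_hat", component="total",
                 value=estimated_heritability(g_hat[obs], Y[obs, ti]))
        )
        if fit.spec.include_dominance:
            rows += [
                dict(trait=trait, statistic="r_gg", component="dominance",
                     value=predictive_correlation(dom_true, fit.delta_hat[:, ti])),
                dict(trait=trait, statistic="press", component="dominance",
                     value=press(fit.delta_hat[:, ti], dom_true)),
                dict(trait=trait, statistic="press", component="sigma2_delta",
                     value=press(np.atleast_1d(fit.vc.V_delta[ti, ti]),
                                 np.atleast_1d(truth.V_delta_emp[tj, tj]))),
            ]
        if cv is not None:
            ci = cv.trait_names.index(trait)
            rows += [
                dict(trait=trait, statistic="cv_corr_mean", component="total",
                     value=cv.mean[ci]),
                dict(trait=trait, statistic="cv_corr_sd", component="total",
                     value=cv.sd[ci]),
            ]
    return EvaluationReport(table=pd.DataFrame(rows), cv=cv)
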