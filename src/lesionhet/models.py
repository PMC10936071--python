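"""Prognostic survival models over the heterogeneity features.

Three feature sets are supported per endpoint (PFS, OS): ``conventional``
(clinical covariates plus primary-lesion measurements), ``heterogeneity``
(the 107 inter-tumor metrics) and ``integrated`` (their union).  Feature
selection and coefficient estimation use L1-penalized (LASSO) Cox
regression with the penalty chosen by stratified k-fold cross-validated
partial likelihood; evaluation uses Harrell's concordance index with a
bootstrap CI, Kaplan-Meier curves with the log-rank test after a
training-median risk split, and IPCW time-dependent ROC AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored, cumulative_dynamic_auc
from sksurv.util import Surv
from statsmodels.duration.hazard_regression import PHReg

from .stats import ALL_METRIC_NAMES
from .types import ASCITES_CHARACTERS, FIGO_STAGES, IMPLANT_REGIONS, LNM_SITES

MODEL_KINDS = ("conventional", "heterogeneity", "integrated")

#: Primary-lesion measurement columns entering the conventional model.
PRIMARY_MEASUREMENT_COLUMNS = (
    "pixel_number", "maj", "min", "hu", "suv_max", "suv_mean", "suv_peak", "tlg",
)


class ModelFitError(RuntimeError):
    """Raised when a Cox fit cannot be completed (no events, separation...)."""


def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the clinical table.

    FIGO stage and invasion pattern are ordinal; surgical status and
    ascites character are one-hot against their reference levels (R0, no
    ascites); nodal and implant-location flags stay binary.
    """
    out = pd.DataFrame(index=clinical.index)
    out["age"] = clinical["age"].astype(float)
    out["ca125"] = clinical["ca125"].astype(float)
    out["figo_stage"] = clinical["figo_stage"].map({s: i for i, s in enumerate(FIGO_STAGES)})
    for status in ("R1", "R2"):
        out[f"sur_status_{status}"] = (clinical["sur_status"] == status).astype(float)
    out["ascites_volume"] = clinical["ascites_volume"].astype(float)
    for char in ASCITES_CHARACTERS[1:]:
        out[f"ascites_{char}"] = (clinical["ascites_character"] == char).astype(float)
    for site in LNM_SITES:
        out[f"lnm_{site}"] = clinical[f"lnm_{site}"].astype(float)
    out["n_implants"] = clinical["n_implants"].astype(float)
    for region in IMPLANT_REGIONS:
        out[f"implant_{region}"] = clinical[f"implant_{region}"].astype(float)
    out["invasion_pattern"] = clinical["invasion_pattern"].astype(float)
    out["solid_ratio"] = clinical["solid_ratio"].astype(float)
    if out.isna().any().any():
        missing = out.columns[out.isna().any()].tolist()
        raise ValueError(f"clinical encoding produced missing values in {missing}")
    return out


@dataclass
class FeatureTable:
    """A named feature matrix plus training-set standardization constants."""

    X: pd.DataFrame
    kind: str
    means: pd.Series | None = None
    sds: pd.Series | None = None
    dropped: list[str] = field(default_factory=list)

    def fit_standardizer(self, train_ids: list[str]) -> "FeatureTable":
        """Learn per-column mean/SD from the training rows only; columns
        with zero training variance are dropped (and logged)."""
        train = self.X.loc[train_ids]
        sds = train.std(ddof=0)
        keep = sds[sds > 0].index
        self.dropped = [c for c in self.X.columns if c not in keep]
        if self.dropped:
            warnings.warn(f"dropping zero-variance columns: {self.dropped}", stacklevel=2)
        self.X = self.X[keep]
        self.means = train[keep].mean()
        self.sds = sds[keep]
        return self

    def transform(self, ids: list[str] | None = None) -> pd.DataFrame:
        if self.means is None or self.sds is None:
            raise RuntimeError("call fit_standardizer(train_ids) first")
        rows = self.X if ids is None else self.X.loc[ids]
        return (rows - self.means) / self.sds


def assemble_feature_table(
    clinical: pd.DataFrame,
    lesion_measurements: pd.DataFrame,
    heterogeneity: pd.DataFrame,
    model_kind: str,
) -> FeatureTable:
    """Build the raw (unstandardized) feature matrix for one model kind."""
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    if model_kind in ("conventional", "integrated"):
        enc = encode_clinical(clinical)
        primary = (
            lesion_measurements[lesion_measurements["region"] == "primary"]
            .set_index("patient_id")[list(PRIMARY_MEASUREMENT_COLUMNS)]
            .add_prefix("primary_")
        )
        conventional = enc.join(primary, how="inner")
        if conventional.isna().any().any():
            raise ValueError("missing primary-lesion measurements for some patients")
    if model_kind == "conventional":
        X = conventional
    elif model_kind == "heterogeneity":
        missing = [c for c in ALL_METRIC_NAMES if c not in heterogeneity.columns]
        if missing:
            raise ValueError(f"heterogeneity table lacks metrics: {missing[:5]}...")
        X = heterogeneity[list(ALL_METRIC_NAMES)].copy()
    else:
        X = conventional.join(heterogeneity, how="inner")
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"feature table has missing values in {bad[:5]}")
    return FeatureTable(X=X, kind=model_kind)


def breslow_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood of given linear predictors."""
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    order = np.argsort(time, kind="stable")
    lp, time, event = lp[order], time[order], event[order]
    suffix = np.logaddexp.accumulate(lp[::-1])[::-1]
    first = np.searchsorted(time, time, side="left")
    return float(np.sum(event * (lp - suffix[first])))


def _breslow_baseline(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Breslow estimate of the baseline cumulative hazard."""
    df = pd.DataFrame({"time": time, "event": event, "exp_lp": np.exp(lp)})
    df = df.sort_values("time")
    risk = df["exp_lp"][::-1].cumsum()[::-1]
    event_times = df.loc[df["event"] == 1, "time"].unique()
    increments = []
    for t in event_times:
        d = df[(df["time"] == t) & (df["event"] == 1)].shape[0]
        denom = df.loc[df["time"] >= t, "exp_lp"].sum()
        increments.append(d / denom)
    return pd.DataFrame({"time": event_times, "cumhaz": np.cumsum(increments)})


@dataclass
class CoxModelFit:
    """A fitted LASSO-Cox model and its risk-score contract."""

    coefficients: pd.Series  # full vector, zeros off the support
    alpha: float  # selected L1 penalty
    cv_alphas: np.ndarray
    cv_scores: np.ndarray  # mean held-out partial log-likelihood per alpha
    baseline_hazard: pd.DataFrame
    train_median_risk: float
    endpoint: str = "pfs"

    @property
    def selected(self) -> list[str]:
        return self.coefficients.index[self.coefficients != 0].tolist()


def fit_lasso_cox(
    X: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    endpoint: str = "pfs",
    n_alphas: int = 50,
    alpha_min_ratio: float = 0.01,
    alphas: np.ndarray | None = None,
) -> CoxModelFit:
    """L1-penalized Cox fit with CV-optimal penalty (lambda_min rule).

    The coordinate-descent path is fit over a log-spaced penalty grid; the
    penalty maximizing the mean held-out Breslow partial log-likelihood
    over event-stratified folds is selected and the model refit on the
    full training table.  ``X`` must already be standardized with the
    training constants.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 2:
        raise ModelFitError("need >= 2 events to fit a Cox model")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    if alphas is None:
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio
        )
    else:
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=np.asarray(alphas, dtype=float))
    path.fit(X.to_numpy(), y)
    alphas = np.asarray(path.alphas_)

    folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros((n_folds, alphas.size))
    valid = np.ones(alphas.size, dtype=bool)
    for f, (tr, te) in enumerate(folds.split(X, event)):
        try:
            fold_model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
            fold_model.fit(X.iloc[tr].to_numpy(), y[tr])
        except Exception as exc:  # noqa: BLE001 - non-convergence on a fold
            warnings.warn(f"fold {f} failed ({exc}); skipping", stacklevel=2)
            scores[f] = np.nan
            continue
        coefs = fold_model.coef_  # (n_features, n_alphas_fit)
        fitted_alphas = np.asarray(fold_model.alphas_)
        for a, alpha in enumerate(alphas):
            j = np.argmin(np.abs(fitted_alphas - alpha))
            if not np.isclose(fitted_alphas[j], alpha, rtol=1e-6):
                valid[a] = False
                continue
            lp = X.iloc[te].to_numpy() @ coefs[:, j]
            scores[f, a] = breslow_partial_loglik(lp, time[te], event[te])
    mean_scores = np.nanmean(scores, axis=0)
    mean_scores[~valid] = -np.inf
    best = int(np.nanargmax(mean_scores))
    coef = pd.Series(path.coef_[:, best], index=X.columns)
    lp_train = X.to_numpy() @ coef.to_numpy()
    return CoxModelFit(
        coefficients=coef,
        alpha=float(alphas[best]),
        cv_alphas=alphas,
        cv_scores=mean_scores,
        baseline_hazard=_breslow_baseline(lp_train, time, event),
        train_median_risk=float(np.median(lp_train)),
        endpoint=endpoint,
    )


def risk_score(fit: CoxModelFit, X: pd.DataFrame) -> pd.Series:
    """Linear predictor sum(beta_j x_j) over the selected features.

    ``X`` must be standardized with the training constants.
    """
    missing = [c for c in fit.selected if c not in X.columns]
    if missing:
        raise KeyError(f"features required by the model are missing: {missing}")
    if not fit.selected:
        return pd.Series(0.0, index=X.index, name="risk_score")
    scores = X[fit.selected].to_numpy() @ fit.coefficients[fit.selected].to_numpy()
    return pd.Series(scores, index=X.index, name="risk_score")


def concordance_index(
    scores, time, event, n_bootstrap: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Harrell's C over usable pairs with a bootstrap-percentile 95% CI.

    Higher scores are expected to precede earlier events; score ties count
    one half.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    c, _, _, _, _ = concordance_index_censored(event, time, scores)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, scores.size, scores.size)
        try:
            cb, *_ = concordance_index_censored(event[idx], time[idx], scores[idx])
        except Exception:  # noqa: BLE001 - resample without comparable pairs
            continue
        boots.append(cb)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = c
    return float(c), (float(lo), float(hi))


def km_logrank(scores, time, event, threshold: float | None = None) -> dict:
    """Two-group Kaplan-Meier curves and log-rank test after a risk split.

    The split threshold defaults to the median of ``scores``; when
    evaluating a test set, pass the training-median risk explicitly.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if threshold is None:
        threshold = float(np.median(scores))
    high = scores >= threshold
    if high.all() or (~high).all():
        raise ValueError("risk split produced an empty group")
    curves = {}
    for name, sel in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel], label=name)
        curves[name] = kmf.survival_function_
    res = logrank_test(time[high], time[~high], event[high], event[~high])
    return {
        "threshold": threshold,
        "curves": curves,
        "statistic": float(res.test_statistic),
        "p_value": float(res.p_value),
    }


def time_dependent_roc(
    scores, time, event, horizons, train_time=None, train_event=None
) -> pd.Series:
    """IPCW cumulative/dynamic AUC at the requested horizons (days).

    The censoring distribution is estimated from the training outcomes
    (defaulting to the evaluated outcomes).  Horizons beyond the follow-up
    range yield NaN with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if train_time is None:
        train_time, train_event = time, event
    y_train = Surv.from_arrays(event=np.asarray(train_event, dtype=bool),
                               time=np.asarray(train_time, dtype=float))
    y_test = Surv.from_arrays(event=event, time=time)
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    tmax = time.max()
    tmin = time.min()
    ok = (horizons > tmin) & (horizons < tmax)
    out = pd.Series(np.nan, index=horizons)
    if not ok.all():
        warnings.warn("some horizons fall outside follow-up; AUC undefined there", stacklevel=2)
    if ok.any():
        aucs, _ = cumulative_dynamic_auc(y_train, y_test, scores, horizons[ok])
        out.iloc[np.flatnonzero(ok)] = aucs
    return out


def cox_hr(
    covariates: pd.DataFrame | pd.Series,
    time,
    event,
) -> pd.DataFrame:
    """Unpenalized Cox fit (Breslow ties): HR with Wald 95% CI and p.

    Pass a single column (e.g. a risk score) for a univariate fit, or the
    risk score joined with clinical covariates for an adjusted fit.
    """
    X = covariates.to_frame() if isinstance(covariates, pd.Series) else covariates
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < X.shape[1]:
        raise ModelFitError("fewer events than parameters")
    try:
        model = PHReg(time, X.to_numpy(), status=event, ties="breslow")
        res = model.fit(disp=False)
    except Exception as exc:  # noqa: BLE001
        raise ModelFitError(f"Cox fit failed: {exc}") from exc
    beta = np.asarray(res.params)
    se = np.asarray(res.bse)
    if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(se)):
        raise ModelFitError("Cox fit did not converge (non-finite estimates)")
    return pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "hr_ci_low": np.exp(beta - 1.959963984540054 * se),
            "hr_ci_high": np.exp(beta + 1.959963984540054 * se),
            "p_value": np.asarray(res.pvalues),
        },
        index=X.columns,
    )


def nomogram_points(fit: CoxModelFit, per_feature_range: float = 4.0) -> pd.DataFrame:
    """Points table standing in for a drawn nomogram.

    Each selected feature's maximal contribution over ``per_feature_range``
    standardized units is scaled so the largest equals 100 points.
    """
    if not fit.selected:
        raise ValueError("model selected no features")
    contrib = fit.coefficients[fit.selected].abs() * per_feature_range
    scale = 100.0 / contrib.max()
    return pd.DataFrame(
        {
            "coefficient": fit.coefficients[fit.selected],
            "points_per_sd": fit.coefficients[fit.selected].abs() * scale,
            "max_points": contrib * scale,
        }
    )
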