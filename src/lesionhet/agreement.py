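"""Immunohistochemistry scoring, rank correlation and reliability screening.

The H-score summarizes staining as %weak*1 + %moderate*2 + %strong*3
(range 0-300).  Model risk scores are correlated with H-scores by
Spearman's rho; heterogeneity metrics are screened for test-retest
reliability with intraclass correlation coefficients (intra-observer:
two-way mixed, consistency, single measurement, ICC(3,1); inter-observer:
two-way random, absolute agreement, single measurement, ICC(2,1)).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps


def h_score(weak_pct: float, moderate_pct: float, strong_pct: float) -> float:
    """H-score = %weak*1 + %moderate*2 + %strong*3, in [0, 300]."""
    vals = (weak_pct, moderate_pct, strong_pct)
    if any(v < 0 for v in vals):
        raise ValueError("staining percentages must be >= 0")
    if sum(vals) > 100 + 1e-9:
        raise ValueError("staining percentages must sum to <= 100")
    return float(weak_pct + 2.0 * moderate_pct + 3.0 * strong_pct)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float, chunk: int = 100_000) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    rx_c = rx - rx.mean()
    sy = (ry - ry.mean()) ** 2
    denom = np.sqrt((rx_c**2).sum() * sy.sum())
    hits = total = 0
    perm_iter = itertools.permutations(ry)
    while True:
        block = np.array(list(itertools.islice(perm_iter, chunk)))
        if block.size == 0:
            break
        rhos = (block - ry.mean()) @ rx_c / denom
        hits += int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        total += block.shape[0]
    return hits / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the t approximation for n > 10 and exact permutation
    enumeration for n <= 10.  Constant inputs have no defined rank
    correlation and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman's rho is undefined for a constant vector")
    rho, p_t = sps.spearmanr(x, y)
    if x.size <= 10:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        return float(rho), _exact_spearman_p(rx, ry, float(rho))
    return float(rho), float(p_t)


def icc(ratings: np.ndarray | pd.DataFrame, form: str = "inter") -> float:
    """Single-measurement ICC of an n_subjects x k_raters table.

    ``intra`` -> two-way mixed, consistency (ICC(3,1));
    ``inter`` -> two-way random, absolute agreement (ICC(2,1)).
    """
    if form not in ("intra", "inter"):
        raise ValueError("form must be 'intra' or 'inter'")
    mat = np.asarray(ratings, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters/sessions")
    if mat.mean(axis=1).var() == 0:
        warnings.warn("zero between-subject variance; ICC undefined", stacklevel=2)
        return float("nan")
    n, k = mat.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": mat.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    # McGraw-Wong labels: ICC(C,1) = two-way consistency (ICC(3,1)),
    # ICC(A,1) = two-way absolute agreement (ICC(2,1))
    key = "ICC(C,1)" if form == "intra" else "ICC(A,1)"
    return float(table.loc[key, "ICC"])


@dataclass
class AgreementReport:
    """Per-metric reliability screen results."""

    per_metric: pd.DataFrame  # index metric, columns icc / passed
    threshold: float
    form: str

    @property
    def fraction_passing(self) -> float:
        return float(self.per_metric["passed"].mean())

    @property
    def min_icc(self) -> float:
        return float(self.per_metric["icc"].min())


def reproducibility_screen(
    metrics_run1: pd.DataFrame,
    metrics_run2: pd.DataFrame,
    threshold: float = 0.75,
    form: str = "inter",
) -> AgreementReport:
    """Per-metric ICC between two extraction runs with a pass threshold.

    Both runs must carry identical metric columns and patient rows;
    metrics whose ICC exceeds the threshold pass the screen.
    """
    if list(metrics_run1.columns) != list(metrics_run2.columns):
        raise ValueError("metric columns differ between runs")
    if list(metrics_run1.index) != list(metrics_run2.index):
        raise ValueError("patient rows differ between runs")
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for col in metrics_run1.columns:
            pair = np.column_stack([metrics_run1[col], metrics_run2[col]])
            value = icc(pair, form=form)
            rows[col] = {"icc": value, "passed": bool(value > threshold)}
    per_metric = pd.DataFrame.from_dict(rows, orient="index")
    return AgreementReport(per_metric=per_metric, threshold=threshold, form=form)


def correlation_table(
    risk_scores: pd.DataFrame, h_scores: pd.Series | pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho and p for every risk-score column x marker pair.

    Rows are restricted to patients carrying the marker's H-score; no
    imputation is performed.
    """
    markers = h_scores.to_frame() if isinstance(h_scores, pd.Series) else h_scores
    rows = []
    for marker in markers.columns:
        hs = markers[marker].dropna()
        for model in risk_scores.columns:
            joined = risk_scores[model].reindex(hs.index).dropna()
            rho, p = spearman(joined.to_numpy(), hs.reindex(joined.index).to_numpy())
            rows.append({"marker": marker, "model": model, "rho": rho, "p_value": p, "n": joined.size})
    return pd.DataFrame(rows)
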