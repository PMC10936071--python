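"""Cross-lesion statistics: the conventional inter-tumor heterogeneity block.

For each of the 8 conventional measurements, 13 statistics are computed over
a patient's lesions (the primary plus its metastatic implants), yielding
8 x 13 = 104 named patient-level heterogeneity metrics such as
``SUVmean_CV`` or ``HU_SM``.

Conventions (declared, since the statistics are named but not defined by a
single universal formula):

* ``Variance``/``Std_dev``/``SM`` use the sample divisor (n - 1).
* ``Skewness`` = m3 / m2^1.5 and ``Kurtosis`` = m4 / m2^2 - 3 (excess) with
  population moments m_k = sum((x - mean)^k) / n, so both are defined from
  n = 2 upward; both are 0 when m2 = 0.
* ``R`` is the quartile deviation (Q3 - Q1) / 2 with linear-interpolation
  quantiles.
* ``Mode`` rounds to 4 significant digits, takes the most frequent value and
  breaks ties toward the smallest value.
* ``CV`` = Std_dev / |mean| (0 if the mean is 0); it is not percentified.
* ``CSS`` = sum((x - mean)^2), ``USS`` = sum(x^2).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .measurements import ConventionalMeasurements

#: Measurement columns in reporting order.
MEASUREMENT_ORDER: tuple[str, ...] = (
    "Pixel_number",
    "Maj",
    "Min",
    "HU",
    "SUVmax",
    "SUVmean",
    "SUVpeak",
    "TLG",
)
_MEASUREMENT_FIELD: dict[str, str] = {
    "Pixel_number": "pixel_number",
    "Maj": "maj",
    "Min": "min",
    "HU": "hu",
    "SUVmax": "suv_max",
    "SUVmean": "suv_mean",
    "SUVpeak": "suv_peak",
    "TLG": "tlg",
}

#: Statistic names in reporting order.
STATISTIC_ORDER: tuple[str, ...] = (
    "Mean",
    "Median",
    "Mode",
    "R",
    "Std_dev",
    "SM",
    "Variance",
    "Range",
    "CV",
    "CSS",
    "USS",
    "Kurtosis",
    "Skewness",
)

#: Names of the 104 conventional heterogeneity metrics, in fixed order.
CONVENTIONAL_METRIC_NAMES: tuple[str, ...] = tuple(
    f"{m}_{s}" for m in MEASUREMENT_ORDER for s in STATISTIC_ORDER
)

#: The three texture-derived metrics appended to the conventional block.
TEXTURE_METRIC_NAMES: tuple[str, ...] = ("cSE", "cluDev", "cluDiss")

#: All 107 heterogeneity metric names.
ALL_METRIC_NAMES: tuple[str, ...] = CONVENTIONAL_METRIC_NAMES + TEXTURE_METRIC_NAMES


@dataclass
class CrossLesionStats:
    """The 13 cross-lesion statistics of one measurement column."""

    mean: float
    median: float
    mode: float
    r: float
    std_dev: float
    sm: float
    variance: float
    range: float
    cv: float
    css: float
    uss: float
    kurtosis: float
    skewness: float

    _BY_NAME = {
        "Mean": "mean",
        "Median": "median",
        "Mode": "mode",
        "R": "r",
        "Std_dev": "std_dev",
        "SM": "sm",
        "Variance": "variance",
        "Range": "range",
        "CV": "cv",
        "CSS": "css",
        "USS": "uss",
        "Kurtosis": "kurtosis",
        "Skewness": "skewness",
    }

    def by_name(self, statistic: str) -> float:
        return float(getattr(self, self._BY_NAME[statistic]))


def round_sig(x: float, digits: int = 4) -> float:
    """Round to a number of significant digits (0 stays 0)."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(round(x, digits - 1 - int(np.floor(np.log10(abs(x))))))


def _mode(values: np.ndarray) -> float:
    rounded = [round_sig(float(v)) for v in values]
    counts = Counter(rounded)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def cross_lesion_stats(values) -> CrossLesionStats:
    """Compute the 13 statistics over one measurement across lesions.

    Requires at least two lesions; inter-tumor heterogeneity is undefined
    for a solitary lesion.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("inter-tumor statistics need >= 2 lesions")
    mean = x.sum() / n
    dev = x - mean
    css = float(np.sum(dev**2))
    variance = css / (n - 1)
    std_dev = float(np.sqrt(variance))
    m2 = css / n
    if m2 == 0.0:
        skewness = 0.0
        kurtosis = 0.0
    else:
        m3 = float(np.sum(dev**3)) / n
        m4 = float(np.sum(dev**4)) / n
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2 - 3.0
    q1, q3 = np.quantile(x, [0.25, 0.75])
    return CrossLesionStats(
        mean=float(mean),
        median=float(np.median(x)),
        mode=_mode(x),
        r=float((q3 - q1) / 2.0),
        std_dev=std_dev,
        sm=std_dev / float(np.sqrt(n)),
        variance=float(variance),
        range=float(x.max() - x.min()),
        cv=0.0 if mean == 0 else std_dev / abs(float(mean)),
        css=css,
        uss=float(np.sum(x**2)),
        kurtosis=float(kurtosis),
        skewness=float(skewness),
    )


def conventional_heterogeneity(
    measurements: list[ConventionalMeasurements],
) -> dict[str, float]:
    """The 104 conventional inter-tumor heterogeneity metrics of a patient.

    Applies :func:`cross_lesion_stats` to each of the 8 measurement columns
    over the patient's lesions, in the fixed documented order.
    """
    if len(measurements) < 2:
        raise ValueError("a patient needs >= 2 lesions for heterogeneity metrics")
    out: dict[str, float] = {}
    for meas_name in MEASUREMENT_ORDER:
        column = [getattr(m, _MEASUREMENT_FIELD[meas_name]) for m in measurements]
        stats = cross_lesion_stats(column)
        for stat_name in STATISTIC_ORDER:
            out[f"{meas_name}_{stat_name}"] = stats.by_name(stat_name)
    return out
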