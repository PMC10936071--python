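"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (explicit loops, sort-based
quantiles, flood fill) and shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np

from lesionhet.types import LesionVOI, VoxelGrid


# ---------------------------------------------------------------- builders

def make_lesion(
    mask: np.ndarray,
    region: str = "primary",
    hu: float | np.ndarray = 40.0,
    suv: float | np.ndarray = 5.0,
    spacing=(1.0, 1.0, 1.0),
    lesion_id: str = "L",
) -> LesionVOI:
    mask = np.asarray(mask).astype(bool)
    ct = np.broadcast_to(np.asarray(hu, dtype=float), mask.shape).copy()
    sv = np.broadcast_to(np.asarray(suv, dtype=float), mask.shape).copy()
    return LesionVOI(
        lesion_id=lesion_id,
        region=region,
        ct=VoxelGrid(ct, spacing),
        suv=VoxelGrid(sv, spacing),
        mask=mask,
    )


def box_mask(shape, box) -> np.ndarray:
    """Zero array of ``shape`` with a solid box of extent ``box`` centred."""
    mask = np.zeros(shape, dtype=bool)
    sl = tuple(
        slice((s - b) // 2, (s - b) // 2 + b) for s, b in zip(shape, box)
    )
    mask[sl] = True
    return mask


# ------------------------------------------------------------- statistics

def naive_cross_stats(values) -> dict[str, float]:
    """The 13 cross-lesion statistics via explicit loops and sorting."""
    x = [float(v) for v in values]
    n = len(x)
    mean = math.fsum(x) / n
    dev = [v - mean for v in x]
    css = math.fsum(d * d for d in dev)
    variance = css / (n - 1)
    std = math.sqrt(variance)
    m2 = css / n
    if m2 == 0:
        skew = kurt = 0.0
    else:
        m3 = math.fsum(d**3 for d in dev) / n
        m4 = math.fsum(d**4 for d in dev) / n
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    s = sorted(x)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(math.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return s[lo] * (1 - frac) + s[hi] * frac

    def sig4(v):
        if v == 0:
            return 0.0
        return round(v, 3 - int(math.floor(math.log10(abs(v)))))

    rounded = [sig4(v) for v in x]
    best_count = max(rounded.count(v) for v in rounded)
    mode = min(v for v in rounded if rounded.count(v) == best_count)
    return {
        "Mean": mean,
        "Median": quantile(0.5),
        "Mode": mode,
        "R": (quantile(0.75) - quantile(0.25)) / 2.0,
        "Std_dev": std,
        "SM": std / math.sqrt(n),
        "Variance": variance,
        "Range": max(x) - min(x),
        "CV": 0.0 if mean == 0 else std / abs(mean),
        "CSS": css,
        "USS": math.fsum(v * v for v in x),
        "Kurtosis": kurt,
        "Skewness": skew,
    }


def naive_spearman_rho(x, y) -> float:
    """Rank correlation via average ranks and a Pearson formula."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def anova_icc(mat: np.ndarray, form: str) -> float:
    """Single-measure ICC from the two-way ANOVA mean squares."""
    mat = np.asarray(mat, dtype=float)
    n, k = mat.shape
    grand = mat.mean()
    row_means = mat.mean(axis=1)
    col_means = mat.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((mat - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "intra":  # ICC(3,1), consistency
        return (msr - mse) / (msr + (k - 1) * mse)
    # ICC(2,1), absolute agreement
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


# --------------------------------------------------------------- survival

def brute_concordance(scores, time, event) -> float:
    """Harrell's C by exhaustive pair enumeration (ties in score = 1/2)."""
    scores = list(scores)
    time = list(time)
    event = list(event)
    n = len(scores)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # usable pair: i has the earlier observed event
            if event[i] == 1 and (time[i] < time[j] or (time[i] == time[j] and event[j] == 0)):
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def manual_km(time, event) -> list[tuple[float, float]]:
    """Product-limit estimate at each distinct event time."""
    pairs = sorted(zip(time, event))
    s = 1.0
    out = []
    distinct = sorted({t for t, e in pairs if e == 1})
    for t in distinct:
        at_risk = sum(1 for tt, _ in pairs if tt >= t)
        d = sum(1 for tt, ee in pairs if tt == t and ee == 1)
        s *= 1.0 - d / at_risk
        out.append((t, s))
    return out


# ----------------------------------------------------------------- texture

def brute_sphere_peak(suv, mask, spacing, radius_mm) -> float:
    """Exhaustive per-voxel sphere-average maximum (mask-restricted)."""
    suv = np.asarray(suv, float)
    mask = np.asarray(mask, bool)
    coords = np.argwhere(mask)
    phys = coords * np.asarray(spacing)
    best = -np.inf
    for c in phys:
        d2 = ((phys - c) ** 2).sum(axis=1)
        sel = d2 <= radius_mm**2
        best = max(best, suv[tuple(coords[sel].T)].mean())
    return float(best)


def brute_zone_count(levels, mask) -> int:
    """Number of 26-connected equal-level zones, by flood fill."""
    mask = np.asarray(mask, bool)
    levels = np.asarray(levels)
    seen = np.zeros_like(mask, dtype=bool)
    shape = mask.shape
    count = 0
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        count += 1
        level = levels[start]
        stack = [start]
        seen[start] = True
        while stack:
            cur = stack.pop()
            for off in offsets:
                nb = tuple(cur[d] + off[d] for d in range(3))
                if any(nb[d] < 0 or nb[d] >= shape[d] for d in range(3)):
                    continue
                if mask[nb] and not seen[nb] and levels[nb] == level:
                    seen[nb] = True
                    stack.append(nb)
    return count


def brute_haralick(p: np.ndarray) -> dict[str, float]:
    g = p.shape[0]
    energy = entropy = contrast = homog = 0.0
    for i in range(g):
        for j in range(g):
            v = p[i, j]
            energy += v * v
            contrast += (i - j) ** 2 * v
            homog += v / (1 + abs(i - j))
            if v > 0:
                entropy -= v * math.log2(v)
    return {"energy": energy, "entropy": entropy, "contrast": contrast, "homogeneity": homog}
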