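"""Distribution statistics over agglomerate diameters.

Number-, volume- and intensity-weighted summaries of Feret diameters
``d``, plus the two-sample comparison test.

* number mean: arithmetic mean of ``d``;
* volume-averaged diameter: the diameter of the sphere with the mean
  per-object volume, ``(mean d³)^{1/3}`` (the π/6 constant cancels);
* intensity-weighted mean: Rayleigh-regime light scattering goes as
  ``d⁶``, so the simulated DLS mean is ``Σ d·d⁶ / Σ d⁶`` — large
  particles dominate, which is exactly the EM-vs-DLS discrepancy the
  weighting exists to demonstrate.

The power-mean/moment-ratio chain guarantees
``number mean ≤ volume average ≤ intensity-weighted mean``
for every sample, with equality iff monodisperse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class SizeDistribution:
    """Summary of a diameter sample under a given weighting."""

    diameters: np.ndarray
    weighting: str  # "number" | "volume" | "intensity"
    n: int
    mean: float
    sem: float
    median: float
    iqr: float

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=np.float64)
        object.__setattr__(self, "diameters", d)


@dataclass(frozen=True)
class ComparisonResult:
    """Welch two-sample unpaired t-test between two diameter samples."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def _as_diameters(diameters) -> np.ndarray:
    d = np.asarray(diameters, dtype=np.float64).ravel()
    if d.size == 0:
        raise ValueError("empty diameter sample")
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("diameters must be finite and strictly positive")
    return d


def _weighted_quantile(d: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(d)
    d, w = d[order], w[order]
    cum = np.cumsum(w)
    cum /= cum[-1]
    return float(np.interp(q, cum, d))


def number_summary(diameters) -> SizeDistribution:
    """Arithmetic (number-weighted) mean, SEM, median and IQR."""
    d = _as_diameters(diameters)
    n = d.size
    sem = float(np.std(d, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    q25, q75 = np.percentile(d, [25, 75])
    return SizeDistribution(d, "number", n, float(np.mean(d)), sem,
                            float(np.median(d)), float(q75 - q25))


def volume_average_diameter(diameters, method: str = "mean_volume") -> float:
    """Diameter corresponding to the mean per-object spherical volume.

    ``method="mean_volume"`` (default): ``(mean d³)^{1/3}``.
    ``method="weighted"``: the volume-weighted mean diameter
    ``Σd⁴/Σd³`` — an alternative convention, not used by default.
    Always ≥ the number mean (power-mean inequality).
    """
    d = _as_diameters(diameters)
    if method == "mean_volume":
        return float(np.cbrt(np.mean(d**3)))
    if method == "weighted":
        return float(np.sum(d**4) / np.sum(d**3))
    raise ValueError(f"unknown volume-average method {method!r}")


def intensity_weighted_summary(diameters) -> SizeDistribution:
    """d⁶ (scattering-intensity) weighted summary, simulating DLS.

    Weighted mean ``Σ d·d⁶ / Σ d⁶``; median and IQR from the weighted
    cumulative distribution. SEM is the weighted sd over √n and is
    indicative only (the weights are not independent observations).
    """
    d = _as_diameters(diameters)
    w = d**6
    w = w / w.sum()
    mean = float(np.sum(w * d))
    var = float(np.sum(w * (d - mean) ** 2))
    sem = float(np.sqrt(var / d.size))
    return SizeDistribution(
        d, "intensity", d.size, mean, sem,
        _weighted_quantile(d, w, 0.5),
        _weighted_quantile(d, w, 0.75) - _weighted_quantile(d, w, 0.25))


def compare_groups(a, b) -> ComparisonResult:
    """Welch unequal-variance two-sample unpaired t-test, two-sided.

    Degrees of freedom by Welch–Satterthwaite. Two identical
    zero-variance samples give t = 0, p = 1 by convention.
    """
    da, db = _as_diameters(a), _as_diameters(b)
    if da.size < 2 or db.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = np.var(da, ddof=1), np.var(db, ddof=1)
    if va == 0 and vb == 0:
        if np.mean(da) == np.mean(db):
            return ComparisonResult(0.0, float(da.size + db.size - 2), 1.0,
                                    float(np.mean(da)), float(np.mean(db)),
                                    da.size, db.size)
        raise ValueError("both groups have zero variance with different means")
    res = sps.ttest_ind(da, db, equal_var=False)
    se2 = va / da.size + vb / db.size
    df = se2**2 / ((va / da.size) ** 2 / (da.size - 1)
                   + (vb / db.size) ** 2 / (db.size - 1))
    return ComparisonResult(float(res.statistic), float(df), float(res.pvalue),
                            float(np.mean(da)), float(np.mean(db)),
                            da.size, db.size)


def histogram(dist: SizeDistribution, bin_width: float):
    """Bin a distribution into half-open bins [lo, hi) of fixed width.

    Returns ``(edges, values)``. Counts (number weighting) or weights
    (volume/intensity) are conserved exactly; a value on a bin edge
    falls in the upper bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    d = dist.diameters
    if dist.weighting == "number":
        w = np.ones_like(d)
    elif dist.weighting == "volume":
        w = d**3
    else:
        w = d**6
    lo = np.floor(d.min() / bin_width) * bin_width
    idx = np.floor((d - lo) / bin_width + 1e-12).astype(int)  # edge -> upper bin
    n_bins = int(idx.max()) + 1
    values = np.zeros(n_bins)
    np.add.at(values, idx, w)
    edges = lo + bin_width * np.arange(n_bins + 1)
    return edges, values


def summarize(diameters) -> dict[str, float]:
    """All headline summaries of one sample in a flat dict."""
    num = number_summary(diameters)
    inten = intensity_weighted_summary(diameters)
    return {
        "n": num.n,
        "mean_nm": num.mean,
        "sem_nm": num.sem,
        "median_nm": num.median,
        "iqr_nm": num.iqr,
        "vol_avg_nm": volume_average_diameter(diameters),
        "intensity_avg_nm": inten.mean,
    }
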