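"""Measurement statistics for projected-particle data.

Implements the statistics conventionally applied to negative-stain EM
particle measurements: geometric-mean diameter of two orthogonal
measurements, long/perpendicular aspect ratio, fixed-step histograms,
polynomial fits to binned curves, per-diameter-bin mean protrusion counts,
binding-fraction summaries, and ordinary least-squares regression with
Pearson r and its two-sided t-test p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .occlusion import BinnedSeries

__all__ = [
    "MeasurementRecord",
    "PolynomialFit",
    "RegressionResult",
    "geometric_mean_diameter",
    "aspect_ratio",
    "build_histogram",
    "fit_polynomial",
    "mean_count_by_diameter",
    "binding_fraction_summary",
    "linear_regression",
]


@dataclass(frozen=True)
class MeasurementRecord:
    """One particle's reduced measurement: diameter (nm, geometric mean of the
    two orthogonal measurements), shape (long/perpendicular aspect ratio, >= 1)
    and the visible protrusion count."""

    diameter: float
    shape: float
    n_visible: int
    group: str | None = None  # optional micrograph / field label

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.shape < 1:
            raise ValueError("aspect ratio must be >= 1")
        if self.n_visible < 0:
            raise ValueError("n_visible must be >= 0")


@dataclass(frozen=True)
class PolynomialFit:
    """Least-squares polynomial fit restricted to its fitted domain."""

    degree: int
    coefficients: np.ndarray  # highest power first (numpy.polyfit order)
    domain: tuple[float, float]
    residual_norm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, dtype=float))
        if len(self.coefficients) != self.degree + 1:
            raise ValueError("coefficient count must equal degree + 1")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        lo, hi = self.domain
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(f"evaluation outside fitted domain [{lo}, {hi}]")
        return np.polyval(self.coefficients, x)


@dataclass(frozen=True)
class RegressionResult:
    """OLS line with Pearson correlation and its two-sided p-value."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs at least 3 points")
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")


def geometric_mean_diameter(d_long, d_perp):
    """Geometric mean sqrt(d_long * d_perp) of two orthogonal diameters (nm)."""
    d_long = np.asarray(d_long, dtype=float)
    d_perp = np.asarray(d_perp, dtype=float)
    if np.any(d_long <= 0) or np.any(d_perp <= 0):
        raise ValueError("diameters must be positive")
    out = np.sqrt(d_long * d_perp)
    return float(out) if out.ndim == 0 else out


def aspect_ratio(d_long, d_perp):
    """Long/perpendicular diameter ratio; inputs are sorted so the result >= 1."""
    d_long = np.asarray(d_long, dtype=float)
    d_perp = np.asarray(d_perp, dtype=float)
    if np.any(d_long <= 0) or np.any(d_perp <= 0):
        raise ValueError("diameters must be positive")
    out = np.maximum(d_long, d_perp) / np.minimum(d_long, d_perp)
    return float(out) if out.ndim == 0 else out


def build_histogram(values, step: float, origin: float = 0.0) -> BinnedSeries:
    """Histogram with half-open bins [origin + k*step, origin + (k+1)*step).

    Bins span the data range only; counts sum to the number of values at or
    above ``origin``.  Empty input returns an empty series.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    values = np.asarray(values, dtype=float)
    values = values[values >= origin]
    if values.size == 0:
        return BinnedSeries(
            bin_centers=np.array([]), values=np.array([]),
            bin_step=step, n_per_bin=np.array([], dtype=int),
        )
    idx = np.floor((values - origin) / step).astype(int)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    centers = origin + (np.arange(n_bins) + 0.5) * step
    return BinnedSeries(
        bin_centers=centers, values=counts.astype(float),
        bin_step=step, n_per_bin=counts,
    )


def fit_polynomial(series: BinnedSeries, degree: int) -> PolynomialFit:
    """Least-squares polynomial fit to the non-empty, unflagged bins of a series.

    Raises if the number of usable points does not exceed the degree
    (the system would be underdetermined).
    """
    ok = np.isfinite(series.values) & ~series.flagged
    x = series.bin_centers[ok]
    y = series.values[ok]
    if len(x) <= degree:
        raise ValueError(f"need more than {degree} points to fit degree {degree}, got {len(x)}")
    coeffs = np.polyfit(x, y, degree)
    resid = y - np.polyval(coeffs, x)
    return PolynomialFit(
        degree=degree,
        coefficients=coeffs,
        domain=(float(x.min()), float(x.max())),
        residual_norm=float(np.linalg.norm(resid)),
    )


def mean_count_by_diameter(records, step: float, origin: float = 0.0) -> BinnedSeries:
    """Per-diameter-bin arithmetic mean of visible protrusion counts.

    Bins are half-open as in :func:`build_histogram`; empty bins inside the
    occupied range carry NaN values (n_per_bin 0).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    diam = np.array([r.diameter for r in records], dtype=float)
    cnt = np.array([r.n_visible for r in records], dtype=float)
    if diam.size == 0:
        return BinnedSeries(
            bin_centers=np.array([]), values=np.array([]),
            bin_step=step, n_per_bin=np.array([], dtype=int),
        )
    idx = np.floor((diam - origin) / step).astype(int)
    if np.any(idx < 0):
        raise ValueError("diameters below the histogram origin")
    n_bins = int(idx.max()) + 1
    n = np.bincount(idx, minlength=n_bins)
    tot = np.bincount(idx, weights=cnt, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(n > 0, tot / np.maximum(n, 1), np.nan)
    centers = origin + (np.arange(n_bins) + 0.5) * step
    return BinnedSeries(bin_centers=centers, values=means, bin_step=step, n_per_bin=n)


def binding_fraction_summary(records):
    """Fractions of particles by visible-count category {0, 1, 2, >2}.

    With ``group`` labels on the records, fractions are computed per group
    and reported as mean ± sd across groups (the convention for
    per-micrograph statistics); otherwise a single pooled fraction per
    category with sd NaN.  Returns a pandas DataFrame indexed by category
    with columns ``fraction`` and ``sd``.
    """
    import pandas as pd

    if len(records) == 0:
        raise ValueError("need at least one record")

    def _fractions(recs):
        n = len(recs)
        c = np.array([r.n_visible for r in recs])
        return np.array([
            np.mean(c == 0),
            np.mean(c == 1),
            np.mean(c == 2),
            np.mean(c > 2),
        ])

    cats = ["0", "1", "2", ">2"]
    groups = {r.group for r in records}
    if len(groups) > 1 or (len(groups) == 1 and next(iter(groups)) is not None):
        per_group = np.array(
            [_fractions([r for r in records if r.group == g]) for g in sorted(groups, key=str)]
        )
        frac = per_group.mean(axis=0)
        sd = per_group.std(axis=0, ddof=1) if per_group.shape[0] > 1 else np.full(4, np.nan)
    else:
        frac = _fractions(records)
        sd = np.full(4, np.nan)
    return pd.DataFrame({"fraction": frac, "sd": sd}, index=pd.Index(cats, name="n_visible"))


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares with Pearson r and two-sided t-test p-value.

    The p-value tests r = 0 with t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees
    of freedom (the standard Pearson-correlation test).  Requires n >= 3 and
    non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression is degenerate")
    res = _sps.linregress(x, y)  # pvalue is exactly the Pearson t-test
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(np.clip(res.rvalue, -1.0, 1.0)),
        p=float(res.pvalue),
        n=n,
    )
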