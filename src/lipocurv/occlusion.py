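"""Projection-visibility model for rod protrusions on spheres.

A rod of length ``l`` attached radially to a sphere of diameter ``D`` is
visible in a 2D projection only if its tip projects outside the sphere's
silhouette disk.  For a tip at radial distance ``D/2 + l`` whose attachment
direction makes angle ``alpha`` with the viewing axis, the projected tip
distance is ``(D/2 + l)·sin(alpha)``, so the rod is hidden whenever

    sin(alpha) <= (D/2 + l_min_vis... ) / (D/2 + l)

Averaging over attachment directions uniform on the sphere gives the
closed-form visibility probability

    P(D, l) = sqrt(1 - (D / (D + 2 l))**2)

which is monotone increasing in ``l`` and decreasing in ``D``.  Dividing an
observed (projected) count histogram by ``P`` evaluated at the bin centers
undoes the orientation-averaged masking in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VisibilityModel",
    "BinnedSeries",
    "visibility_probability",
    "visibility_probability_mc",
    "correct_binned_counts",
]


@dataclass(frozen=True)
class VisibilityModel:
    """Rod-visibility model: protrusion length and optional resolvability cutoff.

    Parameters
    ----------
    l : float
        Protrusion (rod) length in nm.
    min_visible_length : float
        Minimum projected rod length (nm) beyond the silhouette required to
        count the rod as visible.  Default 0: a tip infinitesimally outside
        the silhouette counts.
    """

    l: float
    min_visible_length: float = 0.0

    def __post_init__(self) -> None:
        if self.l < 0:
            raise ValueError(f"protrusion length must be >= 0, got {self.l}")
        if self.min_visible_length < 0:
            raise ValueError("min_visible_length must be >= 0")

    def probability(self, D):
        """Visibility probability at sphere diameter(s) ``D`` (nm)."""
        return visibility_probability(D, self.l, self.min_visible_length)


@dataclass
class BinnedSeries:
    """Uniformly binned 1D series (counts or per-bin means) on a diameter axis.

    ``values`` may contain NaN for empty bins.  ``flagged`` marks bins whose
    values are unreliable (e.g. visibility probability below the correction
    floor); it is empty/False unless set by a producer.
    """

    bin_centers: np.ndarray
    values: np.ndarray
    bin_step: float
    n_per_bin: np.ndarray
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_per_bin = np.asarray(self.n_per_bin, dtype=int)
        if self.flagged is None:
            self.flagged = np.zeros(len(self.bin_centers), dtype=bool)
        else:
            self.flagged = np.asarray(self.flagged, dtype=bool)
        if not (len(self.bin_centers) == len(self.values) == len(self.n_per_bin) == len(self.flagged)):
            raise ValueError("bin_centers, values, n_per_bin, flagged must have equal length")
        if self.bin_step <= 0:
            raise ValueError("bin_step must be positive")
        if len(self.bin_centers) > 1:
            steps = np.diff(self.bin_centers)
            if not np.allclose(steps, self.bin_step, rtol=1e-9, atol=1e-9):
                raise ValueError("bin centers must be uniformly spaced by bin_step")
        if np.any(self.n_per_bin < 0):
            raise ValueError("n_per_bin must be non-negative")

    def __len__(self) -> int:
        return len(self.bin_centers)


def visibility_probability(D, l, min_visible_length: float = 0.0):
    """Probability that a radial rod of length ``l`` on a sphere of diameter
    ``D`` projects outside the sphere silhouette, for a uniformly random
    viewing direction.

    Closed form ``sqrt(1 - (D / (D + 2 l))**2)`` when ``min_visible_length``
    is 0; with a resolvability cutoff ``m`` the tip must project at least
    ``m`` beyond the silhouette, giving
    ``sqrt(1 - ((D + 2 m) / (D + 2 l))**2)`` for ``l > m`` (else 0).

    Accepts scalars or arrays (broadcast).  Raises ``ValueError`` on negative
    inputs or when ``D`` and ``l`` are both zero.
    """
    D = np.asarray(D, dtype=float)
    l = np.asarray(l, dtype=float)
    if np.any(D < 0) or np.any(l < 0):
        raise ValueError("D and l must be non-negative")
    if np.any((D == 0) & (l == 0)):
        raise ValueError("D and l cannot both be zero")
    if min_visible_length < 0:
        raise ValueError("min_visible_length must be >= 0")
    ratio = (D + 2.0 * min_visible_length) / (D + 2.0 * l)
    with np.errstate(invalid="ignore"):
        p = np.sqrt(np.clip(1.0 - ratio**2, 0.0, 1.0))
    p = np.where(l <= min_visible_length, 0.0, p)
    return float(p) if p.ndim == 0 else p


def visibility_probability_mc(
    D: float,
    l: float,
    n: int = 1_000_000,
    seed: int | None = None,
    min_visible_length: float = 0.0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the rod visibility probability.

    Draws ``n`` attachment directions uniform on the sphere with the view
    axis fixed at +z, counts tips whose in-plane projected distance exceeds
    ``D/2 + min_visible_length``, and returns the binomial estimate with its
    standard error ``sqrt(p(1-p)/n)``.

    This estimator is the independent oracle for
    :func:`visibility_probability` and is kept deliberately simple.
    """
    if n < 100:
        raise ValueError(f"need n >= 100 Monte-Carlo samples, got {n}")
    if D < 0 or l < 0:
        raise ValueError("D and l must be non-negative")
    rng = np.random.default_rng(seed)
    # uniform direction <=> cos(alpha) uniform on [-1, 1]
    cos_a = rng.uniform(-1.0, 1.0, size=n)
    sin_a = np.sqrt(1.0 - cos_a**2)
    tip_inplane = (D / 2.0 + l) * sin_a
    visible = tip_inplane > (D / 2.0 + min_visible_length)
    p_hat = float(np.mean(visible))
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n))
    return p_hat, se


def correct_binned_counts(
    series: BinnedSeries,
    model: VisibilityModel,
    p_floor: float = 0.05,
) -> BinnedSeries:
    """Divide per-bin observed values by the visibility probability.

    Each bin value is divided by ``P(bin_center, l)``; bins where ``P`` falls
    below ``p_floor`` are flagged and passed through undivided (an explosive
    correction there would amplify noise without bound).  Empty input yields
    an empty series.
    """
    if len(series) == 0:
        return BinnedSeries(
            bin_centers=np.array([]), values=np.array([]),
            bin_step=series.bin_step, n_per_bin=np.array([], dtype=int),
        )
    if np.any(series.bin_centers <= 0):
        raise ValueError("all bin centers must be positive diameters")
    p = model.probability(series.bin_centers)
    p = np.atleast_1d(np.asarray(p, dtype=float))
    low = p < p_floor
    corrected = np.where(low, series.values, series.values / np.where(low, 1.0, p))
    return BinnedSeries(
        bin_centers=series.bin_centers.copy(),
        values=corrected,
        bin_step=series.bin_step,
        n_per_bin=series.n_per_bin.copy(),
        flagged=low | series.flagged,
    )


def correction_table(
    observed: BinnedSeries,
    corrected: BinnedSeries,
    model: VisibilityModel,
):
    """Assemble the observed/corrected comparison table (one row per bin).

    Returns a pandas DataFrame with columns
    ``bin_center_nm, observed, corrected, P, flagged`` mirroring the
    black (measured) and blue (adjusted) curves of a count-vs-diameter plot.
    """
    import pandas as pd

    return pd.DataFrame(
        {
            "bin_center_nm": observed.bin_centers,
            "observed": observed.values,
            "corrected": corrected.values,
            "P": np.atleast_1d(model.probability(observed.bin_centers)),
            "flagged": corrected.flagged,
        }
    )
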