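"""Canopy height-distribution and mean-reflectance features.

Side-view laser scanning gives a nearly occlusion-free vertical profile of
each tree, so the structural feature set is built entirely from the height
distribution of a specimen's laser returns: 20 point ratios over
normalized-height intervals, the third and fourth standardized moments,
nine height quantiles, and maximum / mean height plus the coefficient of
variation — 34 features in all.  The spectral feature set is the 123
per-channel means over the specimen's fused points.

Conventions (any fixed choice is fine; these are the ones implemented and
tested): one-sided point ratios use strict inequalities, two-sided bands
are half-open ``[lo, hi)``; with continuous heights ties have probability
zero, so the choice only matters for constructed inputs.  Moments are
population (uncorrected) moments and kurtosis is the raw fourth
standardized moment (normal ~ 3).  Quantiles interpolate linearly between
order statistics.  Quantiles, Max, Mean and CV are computed on heights
above the specimen's own base (z - z_min).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from canopyfuse.fusion import FusedPointCloud
from canopyfuse.synthetic_scene import BandSet, default_band_set

__all__ = [
    "STRUCTURAL_FEATURE_NAMES",
    "build_feature_table",
    "height_quantile",
    "moments",
    "normalized_heights",
    "point_ratio",
    "spectral_means",
    "structural_features",
]

# The 34 structural features, in registry order: the 20 point ratios first
# (3 coarse thirds, 8 decile bands, 9 one-sided thresholds), then the two
# moments, the 9 height quantiles, and Max / Mean / CV.
_COARSE = ["PR(hN<0.33)", "PR(0.33<hN<0.67)", "PR(hN>0.67)"]
_BANDS = [(round(lo, 1), round(lo + 0.1, 1)) for lo in np.arange(0.1, 0.9, 0.1)]
_BAND_NAMES = [f"PR({lo}<hN<{hi})" for lo, hi in _BANDS]
_THRESHOLDS = [round(q, 1) for q in np.arange(0.1, 1.0, 0.1)]
_THRESH_NAMES = [f"PR(hN>{q})" for q in _THRESHOLDS]
_QUANTILES = list(range(10, 100, 10))
_QUANT_NAMES = [f"hq{q}" for q in _QUANTILES]

STRUCTURAL_FEATURE_NAMES: tuple[str, ...] = tuple(
    _COARSE
    + _BAND_NAMES
    + _THRESH_NAMES
    + ["skewness", "kurtosis"]
    + _QUANT_NAMES
    + ["Max", "Mean", "CV"]
)
assert len(STRUCTURAL_FEATURE_NAMES) == 34


def normalized_heights(z: np.ndarray) -> np.ndarray:
    """Heights rescaled to [0, 1] by the specimen's own extent.

    ``h_N = (z - z_min) / (z_max - z_min)``.  Raises on fewer than two
    points or a flat specimen (all z equal), for which the normalization is
    undefined.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 2:
        raise ValueError("normalized heights need at least 2 points")
    zmin, zmax = z.min(), z.max()
    if zmax == zmin:
        raise ValueError("degenerate specimen: all heights equal")
    return (z - zmin) / (zmax - zmin)


def point_ratio(
    h_n: np.ndarray,
    interval: tuple[float | None, float | None],
) -> float:
    """Proportion of normalized heights in an interval.

    ``interval`` is ``(lo, hi)`` with ``None`` for an open end: one-sided
    thresholds are strict (``h > lo`` or ``h < hi``), two-sided bands are
    half-open ``[lo, hi)``.
    """
    h_n = np.asarray(h_n, dtype=float)
    lo, hi = interval
    if lo is None and hi is None:
        return 1.0
    if lo is None:
        return float(np.mean(h_n < hi))
    if hi is None:
        return float(np.mean(h_n > lo))
    return float(np.mean((h_n >= lo) & (h_n < hi)))


def height_quantile(heights_above_base: np.ndarray, q: float) -> float:
    """q-th percentile (0 < q < 100) of heights measured from the tree base,
    with linear interpolation between order statistics."""
    if not 0.0 < q < 100.0:
        raise ValueError(f"quantile must be in (0, 100), got {q}")
    h = np.asarray(heights_above_base, dtype=float)
    if h.size < 1:
        raise ValueError("height quantile needs at least 1 point")
    return float(np.percentile(h, q, method="linear"))


def moments(z: np.ndarray) -> tuple[float, float, float, float, float]:
    """(skewness, kurtosis, Max, Mean, CV) of a specimen's height distribution.

    Skewness and kurtosis are the third and fourth standardized moments of
    the raw heights, using population central moments (kurtosis is *not*
    excess: a normal sample gives ~3).  Max, Mean and CV are computed on
    heights above the base: ``Max = z_max - z_min``, ``Mean`` is the mean
    height above base, ``CV`` the population std over the mean.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 2:
        raise ValueError("moments need at least 2 points")
    m = z.mean()
    c = z - m
    m2 = np.mean(c**2)
    if m2 == 0:
        raise ValueError("zero variance: skewness/kurtosis undefined")
    skew = float(np.mean(c**3) / m2**1.5)
    kurt = float(np.mean(c**4) / m2**2)
    above = z - z.min()
    mx = float(above.max())
    mean_above = float(above.mean())
    if mean_above == 0:
        raise ValueError("zero mean height above base: CV undefined")
    cv = float(np.sqrt(np.mean((above - mean_above) ** 2)) / mean_above)
    return skew, kurt, mx, mean_above, cv


def structural_features(z: np.ndarray) -> dict[str, float]:
    """All 34 structural features of one specimen's height values."""
    z = np.asarray(z, dtype=float)
    h_n = normalized_heights(z)
    out: dict[str, float] = {}
    lo_third = point_ratio(h_n, (None, 0.33))
    hi_third = point_ratio(h_n, (0.67, None))
    out["PR(hN<0.33)"] = lo_third
    # middle third as the exact complement, so the partition sums to 1
    out["PR(0.33<hN<0.67)"] = 1.0 - lo_third - hi_third
    out["PR(hN>0.67)"] = hi_third
    for name, (lo, hi) in zip(_BAND_NAMES, _BANDS):
        out[name] = point_ratio(h_n, (lo, hi))
    for name, q in zip(_THRESH_NAMES, _THRESHOLDS):
        out[name] = point_ratio(h_n, (q, None))
    skew, kurt, mx, mean_above, cv = moments(z)
    out["skewness"] = skew
    out["kurtosis"] = kurt
    above = z - z.min()
    for name, q in zip(_QUANT_NAMES, _QUANTILES):
        out[name] = height_quantile(above, q)
    out["Max"] = mx
    out["Mean"] = mean_above
    out["CV"] = cv
    return out


def spectral_means(cloud: FusedPointCloud) -> tuple[np.ndarray, bool]:
    """Per-channel unweighted mean over the points carrying a spectrum.

    Returns ``(vector, missing)``: when no point carries a spectrum the
    vector is all-NaN and ``missing`` is True — absent spectra are flagged,
    never silently zero.
    """
    has = cloud.has_spectrum
    n_ch = cloud.reflectance.shape[1]
    if not has.any():
        return np.full(n_ch, np.nan), True
    return cloud.reflectance[has].mean(axis=0), False


def build_feature_table(
    specimens: Sequence[FusedPointCloud],
    band_set: BandSet | None = None,
) -> pd.DataFrame:
    """One row per specimen: id/species/habit plus 34 + n_channels features.

    Column order is deterministic: the structural registry order, then the
    spectral channels in index order.  Per-specimen feature errors are
    re-raised with the specimen id attached.
    """
    band_set = band_set or default_band_set()
    chan_names = band_set.channel_names()
    rows = []
    for spec in specimens:
        try:
            feats = structural_features(spec.z)
        except ValueError as exc:
            raise ValueError(f"specimen {spec.specimen_id}: {exc}") from exc
        spec_vec, missing = spectral_means(spec)
        row = {"specimen_id": spec.specimen_id, "species": spec.species, "habit": spec.habit}
        row.update(feats)
        row.update(dict(zip(chan_names, spec_vec)))
        rows.append(row)
    columns = (
        ["specimen_id", "species", "habit"]
        + list(STRUCTURAL_FEATURE_NAMES)
        + chan_names
    )
    table = pd.DataFrame(rows, columns=columns)
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
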