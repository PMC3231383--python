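"""Point/pixel fusion: panel normalization, overlap matching, per-tree datasets.

The spectrometer line images and the laser points are matched first along
the driving direction (a time window on the shared clock) and then in the
vertical direction (the point's elevation angle from the frame pose must
fall inside the pixel's angular interval, widened by half the laser
footprint).  Matched pixels are normalized against the white reference
panel and averaged per laser point; the result is the original point cloud
with reflectance spectra mapped onto the subset of points the spectrometer
could see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from canopyfuse.synthetic_scene import (
    BandSet,
    SpectralFrame,
    TreeSpecimen,
    default_band_set,
)

__all__ = [
    "BandSet",
    "FusedPointCloud",
    "FusionParams",
    "build_datasets",
    "fuse",
    "match_points_to_frames",
    "normalize_frame",
    "read_fused_csv",
    "write_fused_csv",
]

logger = logging.getLogger("canopyfuse")

#: Scanner angular resolution (deg); the default footprint used to widen a
#: pixel's vertical interval in the overlap test.  The instrument's beam
#: divergence (0.8 deg x 0.08 deg) is an alternative; both are config.
DEFAULT_FOOTPRINT_DEG = 0.25


@dataclass(frozen=True)
class FusionParams:
    """Tunable knobs of the overlap test."""

    horizontal_window_s: float = 0.25  # half the default frame interval
    footprint_deg: float = DEFAULT_FOOTPRINT_DEG
    sensor_height: float = 2.0


@dataclass
class FusedPointCloud:
    """A specimen's laser points with optional per-point reflectance.

    ``reflectance`` rows are NaN where no pixel was matched; ``n_pixels``
    counts the contributing pixels per point (reflectance present iff
    ``n_pixels >= 1``).
    """

    specimen_id: int
    species: str
    habit: str
    points: np.ndarray  # (n, 4): x, y, z, t
    reflectance: np.ndarray  # (n, n_channels), NaN rows where absent
    n_pixels: np.ndarray  # (n,) int

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("a fused cloud needs at least one point")
        has = self.n_pixels >= 1
        if np.any(np.isnan(self.reflectance[has])):
            raise ValueError("points with n_pixels >= 1 must carry a full spectrum")
        if not np.all(np.isnan(self.reflectance[~has])):
            raise ValueError("points with n_pixels == 0 must carry NaN spectra")
        with np.errstate(invalid="ignore"):
            if np.any(self.reflectance[has] < 0):
                raise ValueError("reflectance values must be >= 0")

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    @property
    def has_spectrum(self) -> np.ndarray:
        return self.n_pixels >= 1

    @property
    def spectral_coverage(self) -> float:
        """Fraction of points carrying a fused spectrum."""
        return float(self.has_spectrum.mean())


def normalize_frame(frame: SpectralFrame) -> tuple[np.ndarray, np.ndarray]:
    """Normalize one frame against its reference-panel pixels.

    Returns ``(pixel_indices, reflectance)`` for the non-reference pixels:
    ``reflectance[i, ch] = dn[pixel_i, ch] / mean_ref_dn[ch]`` where the
    reference spectrum is the channel-wise mean over the 10 panel pixels.
    Dividing by the panel signal converts digital numbers to panel-relative
    reflectance and cancels any illumination factor common to the frame.

    Raises ``ValueError`` naming the first offending (1-based) channel if
    the reference mean is not strictly positive there.
    """
    ref_rows = np.asarray(frame.dn, dtype=float)[list(frame.reference_pixel_indices)]
    ref_mean = ref_rows.mean(axis=0)
    bad = np.flatnonzero(ref_mean <= 0)
    if len(bad):
        raise ValueError(
            f"reference spectrum not positive in channel {int(bad[0]) + 1}"
        )
    target_idx = np.setdiff1d(
        np.arange(frame.dn.shape[0]), np.asarray(frame.reference_pixel_indices)
    )
    reflectance = np.asarray(frame.dn, dtype=float)[target_idx] / ref_mean[None, :]
    return target_idx, reflectance


def _pixel_half_width(frame: SpectralFrame) -> float:
    angles = frame.pixel_angles
    return float(np.median(np.diff(np.sort(angles)))) / 2.0


def match_points_to_frames(
    points: np.ndarray,
    frames: Sequence[SpectralFrame],
    horizontal_window_s: float = 0.25,
    footprint_deg: float = DEFAULT_FOOTPRINT_DEG,
    sensor_height: float = 2.0,
) -> np.ndarray:
    """Candidate (point, frame, pixel) associations from the two overlap tests.

    A pixel is associated with a point iff the point's timestamp is within
    ``horizontal_window_s`` of the frame's, and the point's elevation angle
    seen from the frame pose lies inside the pixel's angular interval
    widened by ``footprint_deg / 2`` on each side.  Reference pixels are
    never matched.  Returns an (m, 3) int array of row indices into
    ``points``, ``frames`` and the frame's pixel axis, sorted
    lexicographically so the result is independent of input order.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 4:
        raise ValueError("points must be an (n, 4) array of x, y, z, t")
    out = []
    for fi, frame in enumerate(frames):
        mask = np.abs(pts[:, 3] - frame.timestamp) <= horizontal_window_s
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        px, py, _ = frame.sensor_pose
        sub = pts[idx]
        gr = np.hypot(sub[:, 0] - px, sub[:, 1] - py)
        elev = np.degrees(np.arctan2(sub[:, 2] - sensor_height, gr))
        half = _pixel_half_width(frame) + footprint_deg / 2.0
        centers = frame.pixel_angles
        ref = set(frame.reference_pixel_indices)
        # uniform pixel grid: a point can only match pixels whose center is
        # within `half`, i.e. at most ceil(half/step) bins away
        step = 2.0 * _pixel_half_width(frame)
        base = np.rint((elev - centers[0]) / step).astype(int)
        reach = int(np.ceil(half / step))
        for off in range(-reach, reach + 1):
            cand = base + off
            ok = (cand >= 0) & (cand < len(centers))
            ok &= np.abs(elev - centers[np.clip(cand, 0, len(centers) - 1)]) <= half
            for pi, ci in zip(idx[ok], cand[ok]):
                if int(ci) not in ref:
                    out.append((int(pi), fi, int(ci)))
    assoc = np.array(sorted(out), dtype=int).reshape(-1, 3)
    return assoc


def fuse(
    specimens: Sequence[TreeSpecimen],
    frames: Sequence[SpectralFrame],
    band_set: BandSet | None = None,
    params: FusionParams | None = None,
) -> list[FusedPointCloud]:
    """Fuse normalized spectrometer pixels onto each specimen's points.

    Every point's reflectance is the unweighted mean of all its associated
    pixels' normalized rows, across frames; points with no association
    carry no spectrum.  Specimens that end up with zero fused spectra are
    retained (structural analyses still apply) with a logged warning.
    """
    band_set = band_set or default_band_set()
    params = params or FusionParams()
    n_ch = len(band_set)

    norm: list[tuple[np.ndarray, np.ndarray] | None] = []
    for frame in frames:
        try:
            target_idx, refl = normalize_frame(frame)
            lut = np.full(frame.dn.shape[0], -1, dtype=int)
            lut[target_idx] = np.arange(len(target_idx))
            norm.append((lut, refl))
        except ValueError:
            norm.append(None)  # dark frame: unusable for normalization

    fused = []
    for spec in specimens:
        n = len(spec.points)
        acc = np.zeros((n, n_ch))
        cnt = np.zeros(n, dtype=int)
        assoc = match_points_to_frames(
            spec.points,
            frames,
            horizontal_window_s=params.horizontal_window_s,
            footprint_deg=params.footprint_deg,
            sensor_height=params.sensor_height,
        )
        for pi, fi, ci in assoc:
            if norm[fi] is None:
                continue
            lut, refl = norm[fi]
            row = lut[ci]
            if row < 0:
                continue
            acc[pi] += refl[row]
            cnt[pi] += 1
        refl_out = np.full((n, n_ch), np.nan)
        has = cnt >= 1
        refl_out[has] = acc[has] / cnt[has, None]
        if not has.any():
            logger.warning(
                "specimen %d (%s): no fused spectra; structural features only",
                spec.specimen_id,
                spec.species,
            )
        fused.append(
            FusedPointCloud(
                specimen_id=spec.specimen_id,
                species=spec.species,
                habit=spec.habit,
                points=spec.points,
                reflectance=refl_out,
                n_pixels=cnt,
            )
        )
    return fused


def build_datasets(
    specimens: Sequence[FusedPointCloud | TreeSpecimen],
    min_count: int = 5,
    unidentified: Sequence[str] = ("unidentified",),
) -> tuple[list, list]:
    """Split specimens into the two classification datasets.

    ``separation_set`` holds every specimen with a habit label (species may
    be unidentified) and feeds the coniferous/deciduous separation task.
    ``species_set`` holds specimens of identified species represented by at
    least ``min_count`` specimens and feeds the species task; rarer species
    would leave their lone members nearly untrainable under leave-one-out.
    """
    separation = [s for s in specimens if s.habit in ("coniferous", "deciduous")]
    counts: dict[str, int] = {}
    for s in separation:
        if not any(u in s.species.lower() for u in unidentified):
            counts[s.species] = counts.get(s.species, 0) + 1
    keep = {sp for sp, c in counts.items() if c >= min_count}
    species_set = [s for s in separation if s.species in keep]
    return separation, species_set


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------


def write_fused_csv(clouds: Sequence[FusedPointCloud], path: str | Path) -> None:
    """`specimen_id,x,y,z,t,n_pixels,ch001..` — empty channel cells when absent."""
    n_ch = clouds[0].reflectance.shape[1] if clouds else 0
    with open(path, "w") as fh:
        chans = ",".join(f"ch{i:03d}" for i in range(1, n_ch + 1))
        fh.write(f"specimen_id,species,habit,x,y,z,t,n_pixels,{chans}\n")
        for c in clouds:
            for i, (x, y, z, t) in enumerate(c.points):
                if c.n_pixels[i] >= 1:
                    cells = ",".join(f"{v:.6f}" for v in c.reflectance[i])
                else:
                    cells = "," * (n_ch - 1)
                fh.write(
                    f"{c.specimen_id},{c.species},{c.habit},"
                    f"{x:.4f},{y:.4f},{z:.4f},{t:.5f},{int(c.n_pixels[i])},{cells}\n"
                )


def read_fused_csv(path: str | Path) -> list[FusedPointCloud]:
    import pandas as pd

    df = pd.read_csv(path)
    chan_cols = [c for c in df.columns if c.startswith("ch")]
    clouds = []
    for sid, grp in df.groupby("specimen_id", sort=True):
        refl = grp[chan_cols].to_numpy(dtype=float)
        cnt = grp["n_pixels"].to_numpy(dtype=int)
        refl[cnt < 1] = np.nan
        clouds.append(
            FusedPointCloud(
                specimen_id=int(sid),
                species=str(grp["species"].iloc[0]),
                habit=str(grp["habit"].iloc[0]),
                points=grp[["x", "y", "z", "t"]].to_numpy(dtype=float),
                reflectance=refl,
                n_pixels=cnt,
            )
        )
    return clouds
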