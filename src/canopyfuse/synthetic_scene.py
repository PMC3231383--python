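"""Synthetic garden scenes for side-view laser + line-spectrometer fusion.

The generator emulates a vehicle-borne survey of an experimental garden:
a four-layer automotive laser scanner builds per-tree point clouds while a
vertically mounted line spectrometer (44.4 deg opening angle, 659 pixels
binned to 123 spectral channels over 397-1,086 nm) records reflectance
frames, with the 10 outermost pixels viewing a white reference panel.

Trees are modelled as uniform-density solids: a cone for conifers (wide
base tapering to the apex) and a trunk cylinder topped by a vertically
offset ellipsoid crown for deciduous species.  These are the simplest
shapes that reproduce the separability of the two habits by canopy
height-distribution features.  Spectra are species-specific 123-channel
reflectance curves degraded by strong multiplicative (lognormal)
illumination noise; directional-lighting variation in side-view surveys
can exceed a factor of two between frames of the same crown.

Two scalar knobs control class structure so null experiments are possible:
``shape_effect`` mixes every species' crown profile with a common neutral
profile, and ``spectral_effect`` shrinks every species' reflectance curve
toward the specimen-weighted grand mean.  At 0 the generated scene carries
no class information of that kind.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Instrument constants
# ---------------------------------------------------------------------------

N_CHANNELS = 123
N_PIXELS = 659
N_REF_PIXELS = 10
FOV_DEG = 44.4
WAVELENGTH_MIN_NM = 397.0
WAVELENGTH_MAX_NM = 1086.0

POINTS_CSV_HEADER = "specimen_id,species,habit,x,y,z,t"


# ---------------------------------------------------------------------------
# Band set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandSet:
    """Mapping from 1-based channel index to band-center wavelength (nm)."""

    centers_nm: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centers_nm, dtype=float)
        if c.ndim != 1:
            raise ValueError("band centers must be a 1-D array")
        if np.any(np.diff(c) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if c[0] < WAVELENGTH_MIN_NM or c[-1] > WAVELENGTH_MAX_NM:
            raise ValueError(
                f"band centers must lie within "
                f"[{WAVELENGTH_MIN_NM}, {WAVELENGTH_MAX_NM}] nm"
            )
        object.__setattr__(self, "centers_nm", c)

    def __len__(self) -> int:
        return len(self.centers_nm)

    def center(self, channel: int) -> float:
        """Wavelength of a 1-based channel index."""
        if not 1 <= channel <= len(self):
            raise IndexError(f"channel {channel} outside 1..{len(self)}")
        return float(self.centers_nm[channel - 1])

    def nearest_channel(self, wavelength_nm: float) -> int:
        """1-based index of the band center closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.centers_nm - wavelength_nm))) + 1

    def channel_names(self) -> list[str]:
        return [f"ch{i:03d}" for i in range(1, len(self) + 1)]


def default_band_set(n_channels: int = N_CHANNELS) -> BandSet:
    """Linearly spaced band centers spanning the spectrometer range.

    The instrument bins 493 CCD rows into 123 channels over 397-1,086 nm;
    with no published center list, linear spacing (~5.65 nm) is used and
    named wavelengths are resolved to the nearest center.
    """
    return BandSet(np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, n_channels))


# ---------------------------------------------------------------------------
# Species templates and crown profiles
# ---------------------------------------------------------------------------

CONIFEROUS = "coniferous"
DECIDUOUS = "deciduous"


def _ellipsoid_cdf(u: np.ndarray | float) -> np.ndarray | float:
    """CDF of the height coordinate of a uniform ellipsoid, u in [-1, 1]."""
    u = np.clip(u, -1.0, 1.0)
    return (2.0 + 3.0 * u - u**3) / 4.0


@dataclass(frozen=True)
class SpeciesTemplate:
    """Generating parameters for one species (or unidentified group).

    Crown geometry is parameterised relative to total tree height ``H``:
    conifers are cones of base radius ``base_radius_frac * H``; deciduous
    trees are a trunk cylinder up to the crown base plus an ellipsoid crown
    centred at normalized height ``crown_center_n`` with vertical semi-axis
    ``crown_halfheight_n`` (both in units of H) and horizontal semi-axis
    ``crown_radius_frac * H``.
    """

    name: str
    habit: str
    count: int
    height_range: tuple[float, float]
    point_density: float = 60.0  # points per m^3
    reflectance_curve: np.ndarray = field(
        default_factory=lambda: np.full(N_CHANNELS, 0.3)
    )
    spectral_sd: float = 0.15  # per-pixel lognormal sigma on target dn
    # conifer geometry
    base_radius_frac: float = 0.30
    # deciduous geometry
    crown_center_n: float = 0.70
    crown_halfheight_n: float = 0.25
    crown_radius_frac: float = 0.30
    trunk_radius_m: float = 0.12

    def __post_init__(self) -> None:
        if self.habit not in (CONIFEROUS, DECIDUOUS):
            raise ValueError(f"unknown habit {self.habit!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        lo, hi = self.height_range
        if lo > hi:
            raise ValueError("height_range min must be <= max")
        curve = np.asarray(self.reflectance_curve, dtype=float)
        if curve.shape != (N_CHANNELS,):
            raise ValueError(f"reflectance_curve must have {N_CHANNELS} values")
        if np.any(curve < 0) or np.any(curve > 1.5):
            # panel-relative reflectance may exceed 1 under specular glare,
            # but not without bound
            raise ValueError("reflectance_curve values must lie in [0, 1.5]")
        if self.habit == DECIDUOUS:
            lo_n = self.crown_center_n - self.crown_halfheight_n
            hi_n = self.crown_center_n + self.crown_halfheight_n
            if not (0.0 <= lo_n and hi_n <= 1.0):
                raise ValueError("deciduous crown ellipsoid must fit within [0, 1]")
        object.__setattr__(self, "reflectance_curve", curve)

    # -- closed-form height-distribution quantities -------------------------

    def fraction_above(self, q: float, shape_effect: float = 1.0) -> float:
        """Expected fraction of points above normalized height ``q``.

        A cone of uniform density has height pdf 3(1-h)^2, so
        P(h > q) = (1-q)^3.  The deciduous profile mixes the trunk cylinder
        (uniform in height up to the crown base) with the ellipsoid crown
        in proportion to their point budgets.  ``shape_effect`` mixes with
        the neutral profile (full-height ellipsoid centred at 0.5).
        """
        q = float(q)
        if self.habit == CONIFEROUS:
            p_species = (1.0 - np.clip(q, 0.0, 1.0)) ** 3
        else:
            c, b = self.crown_center_n, self.crown_halfheight_n
            crown_base = c - b
            f_trunk = self._trunk_point_fraction()
            if crown_base > 0:
                p_trunk = np.clip((crown_base - q) / crown_base, 0.0, 1.0)
            else:
                p_trunk = 0.0
            p_crown = 1.0 - _ellipsoid_cdf((q - c) / b)
            p_species = f_trunk * p_trunk + (1.0 - f_trunk) * p_crown
        p_neutral = 1.0 - _ellipsoid_cdf((q - 0.5) / 0.5)
        s = float(shape_effect)
        return float(s * p_species + (1.0 - s) * p_neutral)

    def _trunk_point_fraction(self, height: float | None = None) -> float:
        """Fraction of a deciduous tree's points that fall on the trunk."""
        v_t, v_c = self._volumes(height if height is not None else 1.0)
        return v_t / (v_t + v_c)

    def _volumes(self, height: float) -> tuple[float, float]:
        """(trunk/base volume, crown volume) in m^3 for a tree of ``height``."""
        if self.habit == CONIFEROUS:
            r = self.base_radius_frac * height
            return 0.0, math.pi * r * r * height / 3.0
        c, b = self.crown_center_n, self.crown_halfheight_n
        a = self.crown_radius_frac * height
        v_crown = 4.0 / 3.0 * math.pi * a * a * (b * height)
        v_trunk = math.pi * self.trunk_radius_m**2 * max(c - b, 0.0) * height
        return v_trunk, v_crown

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reflectance_curve"] = [round(float(v), 6) for v in self.reflectance_curve]
        d["height_range"] = list(self.height_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesTemplate":
        d = dict(d)
        d["height_range"] = tuple(d["height_range"])
        d["reflectance_curve"] = np.asarray(d["reflectance_curve"], dtype=float)
        return cls(**d)


# ---------------------------------------------------------------------------
# Illumination and trajectory models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IlluminationModel:
    """Multiplicative lognormal illumination for the frame simulator.

    ``frame_sd`` scales a factor shared by target *and* reference pixels of
    a frame; it cancels exactly under panel normalization and exists to
    prove that cancellation.  ``directional_sd`` scales a per-(frame, tree)
    factor applied to targets only — the directional-lighting variation
    that survives normalization.  With probability ``shaded_reference_prob``
    a frame's targets are additionally darkened by ``shade_factor`` while
    the panel stays lit, yielding the occasional very dark normalized
    spectrum seen when the panel is sunlit but the crown shaded.
    """

    frame_sd: float = 0.5
    directional_sd: float = 0.35
    shaded_reference_prob: float = 0.03
    shade_factor: float = 0.12
    reference_level: float = 1000.0  # panel digital number under unit illumination

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "IlluminationModel":
        return cls(**d)


@dataclass(frozen=True)
class Trajectory:
    """Straight drive past the garden row at constant speed.

    The vehicle moves along +x at ``speed`` with the sensor at height
    ``sensor_height``; trees stand at y = stand-off distance.  Frames are
    exposed at ``frame_rate`` between ``t_start`` and ``t_end``.  The
    spectrometer's 44.4 deg vertical opening spans elevation angles
    ``elev_min_deg`` .. ``elev_min_deg + 44.4``.
    """

    speed: float = 4.0  # m/s
    frame_rate: float = 2.0  # Hz
    sensor_height: float = 2.0  # m
    elev_min_deg: float = -5.0
    t_start: float = 0.0
    t_end: float = 0.0
    y: float = 0.0

    def frame_times(self) -> np.ndarray:
        if self.t_end <= self.t_start:
            return np.empty(0)
        n = int(math.floor((self.t_end - self.t_start) * self.frame_rate)) + 1
        return self.t_start + np.arange(n) / self.frame_rate

    def pose_at(self, t: float) -> tuple[float, float, float]:
        return (self.speed * t, self.y, 0.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Trajectory":
        return cls(**d)


def pixel_edges_deg(elev_min_deg: float) -> np.ndarray:
    """660 elevation-angle bin edges of the 659 spectrometer pixels."""
    return elev_min_deg + np.linspace(0.0, FOV_DEG, N_PIXELS + 1)


def pixel_centers_deg(elev_min_deg: float) -> np.ndarray:
    edges = pixel_edges_deg(elev_min_deg)
    return 0.5 * (edges[:-1] + edges[1:])


REFERENCE_PIXEL_INDICES = tuple(range(N_PIXELS - N_REF_PIXELS, N_PIXELS))


# ---------------------------------------------------------------------------
# Scene containers
# ---------------------------------------------------------------------------


@dataclass
class TreeSpecimen:
    """A labelled point cloud for one tree — the unit of classification."""

    specimen_id: int
    species: str
    habit: str
    origin: tuple[float, float]
    points: np.ndarray  # (n, 4): x, y, z, t

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 4 or pts.shape[0] < 1:
            raise ValueError("points must be a non-empty (n, 4) array")
        if np.any(pts[:, 2] < 0):
            raise ValueError("all point heights must be >= 0")
        if np.any(np.diff(pts[:, 3]) < 0):
            raise ValueError("timestamps must be non-decreasing")
        self.points = pts

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]


@dataclass
class SpectralFrame:
    """One line-spectrometer exposure."""

    timestamp: float
    sensor_pose: tuple[float, float, float]  # x, y, heading
    pixel_angles: np.ndarray  # (659,) elevation angles, deg
    dn: np.ndarray  # (659, 123) digital numbers
    reference_pixel_indices: tuple[int, ...] = REFERENCE_PIXEL_INDICES

    def __post_init__(self) -> None:
        self.pixel_angles = np.asarray(self.pixel_angles, dtype=float)
        dn = np.asarray(self.dn)
        if self.pixel_angles.shape != (N_PIXELS,):
            raise ValueError(f"expected {N_PIXELS} pixel angles")
        if dn.shape != (N_PIXELS, N_CHANNELS):
            raise ValueError(f"dn must be ({N_PIXELS}, {N_CHANNELS})")
        if np.any(dn < 0):
            raise ValueError("digital numbers must be >= 0")
        ref = dn[list(self.reference_pixel_indices)]
        if float(ref.mean()) <= 0:
            raise ValueError("reference pixels must be illuminated (mean dn > 0)")
        self.dn = dn


@dataclass
class Scene:
    """A generated garden: specimens, frames, and the parameters behind them."""

    specimens: list[TreeSpecimen]
    frames: list[SpectralFrame]
    band_set: BandSet
    seed: int
    config: "GardenConfig"

    def points_table(self) -> "np.ndarray":
        """All points stacked as rows (specimen order, point order preserved)."""
        return np.vstack([s.points for s in self.specimens]) if self.specimens else np.empty((0, 4))

    # -- serialization ------------------------------------------------------

    def save(self, directory: str | Path) -> dict[str, Path]:
        """Write points CSV, frames CSV and a JSON manifest; return paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "points": directory / "points.csv",
            "frames": directory / "frames.csv",
            "manifest": directory / "manifest.json",
        }
        write_points_csv(self.specimens, paths["points"])
        write_frames_csv(self.frames, paths["frames"])
        manifest = {
            "seed": self.seed,
            "config": self.config.to_dict(),
            "n_specimens": len(self.specimens),
            "n_frames": len(self.frames),
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return paths


def write_points_csv(specimens: Sequence[TreeSpecimen], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(POINTS_CSV_HEADER + "\n")
        for s in specimens:
            for x, y, z, t in s.points:
                fh.write(
                    f"{s.specimen_id},{s.species},{s.habit},"
                    f"{x:.4f},{y:.4f},{z:.4f},{t:.5f}\n"
                )


def read_points_csv(path: str | Path) -> list[TreeSpecimen]:
    import pandas as pd

    df = pd.read_csv(path)
    specimens = []
    for sid, grp in df.groupby("specimen_id", sort=True):
        pts = grp[["x", "y", "z", "t"]].to_numpy(dtype=float)
        order = np.argsort(pts[:, 3], kind="stable")
        pts = pts[order]
        specimens.append(
            TreeSpecimen(
                specimen_id=int(sid),
                species=str(grp["species"].iloc[0]),
                habit=str(grp["habit"].iloc[0]),
                origin=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                points=pts,
            )
        )
    return specimens


def write_frames_csv(frames: Sequence[SpectralFrame], path: str | Path) -> None:
    with open(path, "w") as fh:
        chans = ",".join(f"ch{i:03d}" for i in range(1, N_CHANNELS + 1))
        fh.write(f"t,pose_x,pose_y,heading,pixel,angle_deg,ref_flag,{chans}\n")
        for f in frames:
            ref = set(f.reference_pixel_indices)
            px, py, hd = f.sensor_pose
            for p in range(N_PIXELS):
                dn = ",".join(f"{v:.4f}" for v in f.dn[p])
                fh.write(
                    f"{f.timestamp:.5f},{px:.4f},{py:.4f},{hd:.4f},"
                    f"{p},{f.pixel_angles[p]:.5f},{int(p in ref)},{dn}\n"
                )


def read_frames_csv(path: str | Path) -> list[SpectralFrame]:
    import pandas as pd

    df = pd.read_csv(path)
    chan_cols = [c for c in df.columns if c.startswith("ch")]
    frames = []
    for t, grp in df.groupby("t", sort=True):
        grp = grp.sort_values("pixel")
        ref = tuple(int(p) for p in grp.loc[grp["ref_flag"] == 1, "pixel"])
        frames.append(
            SpectralFrame(
                timestamp=float(t),
                sensor_pose=(
                    float(grp["pose_x"].iloc[0]),
                    float(grp["pose_y"].iloc[0]),
                    float(grp["heading"].iloc[0]),
                ),
                pixel_angles=grp["angle_deg"].to_numpy(dtype=float),
                dn=grp[chan_cols].to_numpy(dtype=float),
                reference_pixel_indices=ref or REFERENCE_PIXEL_INDICES,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Garden configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GardenConfig:
    """Every generator parameter, serializable to JSON."""

    templates: tuple[SpeciesTemplate, ...]
    spacing: float = 2.0  # m between neighbouring trees along the row
    stand_off: float = 8.0  # m from the drive line to the tree row
    x_margin: float = 4.0  # m of clear drive before/after the row
    position_jitter: float = 0.3  # m, uniform jitter of tree origins
    shape_effect: float = 1.0
    spectral_effect: float = 1.0
    min_shape_margin: float = 0.3  # required P(h_N>0.5) gap, deciduous - conifer
    trajectory: Trajectory = field(default_factory=Trajectory)
    illumination: IlluminationModel = field(default_factory=IlluminationModel)
    n_channels: int = N_CHANNELS
    horizontal_window_s: float | None = None  # default: half the frame interval

    def band_set(self) -> BandSet:
        return default_band_set(self.n_channels)

    def total_count(self) -> int:
        return sum(t.count for t in self.templates)

    def shape_margin(self) -> float:
        """Analytic P(h_N > 0.5) gap between the habits at this shape effect."""
        dec = [t for t in self.templates if t.habit == DECIDUOUS]
        con = [t for t in self.templates if t.habit == CONIFEROUS]
        if not dec or not con:
            return 0.0
        s = self.shape_effect
        return min(t.fraction_above(0.5, s) for t in dec) - max(
            t.fraction_above(0.5, s) for t in con
        )

    def effective_curves(self) -> dict[str, np.ndarray]:
        """Per-template reflectance after shrinking toward the grand mean."""
        if not self.templates:
            return {}
        counts = np.array([max(t.count, 1) for t in self.templates], dtype=float)
        curves = np.stack([t.reflectance_curve for t in self.templates])
        mean = (curves * counts[:, None]).sum(0) / counts.sum()
        e = self.spectral_effect
        return {
            t.name: np.clip(mean + e * (t.reflectance_curve - mean), 0.0, 1.5)
            for t in self.templates
        }

    def with_effects(
        self, shape_effect: float | None = None, spectral_effect: float | None = None
    ) -> "GardenConfig":
        changes = {}
        if shape_effect is not None:
            changes["shape_effect"] = shape_effect
            changes["min_shape_margin"] = 0.0
        if spectral_effect is not None:
            changes["spectral_effect"] = spectral_effect
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = {
            "templates": [t.to_dict() for t in self.templates],
            "trajectory": self.trajectory.to_dict(),
            "illumination": self.illumination.to_dict(),
        }
        for f in dataclasses.fields(self):
            if f.name not in d:
                d[f.name] = getattr(self, f.name)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GardenConfig":
        d = dict(d)
        d["templates"] = tuple(SpeciesTemplate.from_dict(t) for t in d["templates"])
        d["trajectory"] = Trajectory.from_dict(d["trajectory"])
        d["illumination"] = IlluminationModel.from_dict(d["illumination"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GardenConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Default garden: the 23-species, 168-specimen experimental garden
# ---------------------------------------------------------------------------

# (name, habit, count, height range m); counts follow the surveyed garden's
# specimen table: 161 identified across 23 species plus 7 unidentified
# (5 deciduous, 2 coniferous), 168 in all.
_GARDEN_SPECIES: list[tuple[str, str, int, tuple[float, float]]] = [
    ("Sorbus hybrida", DECIDUOUS, 6, (4.0, 7.0)),
    ("Sorbus intermedia", DECIDUOUS, 8, (4.0, 7.5)),
    ("Sorbus aucuparia", DECIDUOUS, 21, (4.0, 8.0)),
    ("Sorbus aria", DECIDUOUS, 9, (3.5, 6.5)),
    ("Sorbus americana", DECIDUOUS, 23, (4.0, 7.5)),
    ("Quercus robur", DECIDUOUS, 18, (5.0, 10.0)),
    ("Acer platanoides", DECIDUOUS, 4, (5.0, 9.0)),
    ("Malus domestica", DECIDUOUS, 3, (3.0, 5.0)),
    ("Syringa josikea", DECIDUOUS, 1, (2.0, 4.0)),
    ("Alnus glutinosa", DECIDUOUS, 4, (5.0, 9.0)),
    ("Ulmus glabra camperdownii", DECIDUOUS, 5, (3.0, 5.0)),
    ("Salix fragilis", DECIDUOUS, 8, (4.0, 7.0)),
    ("Picea pungens", CONIFEROUS, 5, (4.0, 8.0)),
    ("Picea mariana", CONIFEROUS, 4, (4.0, 8.0)),
    ("Abies concolor", CONIFEROUS, 2, (4.0, 8.0)),
    ("Abies sibirica", CONIFEROUS, 30, (5.0, 11.0)),
    ("Abies balsamea", CONIFEROUS, 2, (4.0, 8.0)),
    ("Juniperus communis", CONIFEROUS, 2, (1.5, 3.5)),
    ("Taxus baccata", CONIFEROUS, 2, (2.0, 4.0)),
    ("Thuja occidentalis", CONIFEROUS, 1, (1.5, 3.0)),
    ("Pseudotsuga menziesii", CONIFEROUS, 1, (5.0, 10.0)),
    ("Betula pendula", DECIDUOUS, 1, (5.0, 10.0)),
    ("Pinus sylvestris", CONIFEROUS, 1, (5.0, 10.0)),
    ("unidentified deciduous", DECIDUOUS, 5, (3.0, 7.0)),
    ("unidentified coniferous", CONIFEROUS, 2, (3.0, 7.0)),
]

UNIDENTIFIED_SPECIES = ("unidentified deciduous", "unidentified coniferous")


def _vegetation_curve(
    wavelengths: np.ndarray,
    nir_level: float,
    red_edge_nm: float,
    green_amp: float,
    wiggle: np.ndarray,
) -> np.ndarray:
    """A smooth leaf-like reflectance curve: green bump, red edge, NIR plateau."""
    sigmoid = 1.0 / (1.0 + np.exp(-(wavelengths - red_edge_nm) / 18.0))
    green = green_amp * np.exp(-(((wavelengths - 550.0) / 35.0) ** 2))
    curve = 0.04 + green + nir_level * sigmoid + wiggle
    return np.clip(curve, 0.01, 1.5)


def _species_curve(index: int, habit: str, wavelengths: np.ndarray) -> np.ndarray:
    """Deterministic species-specific reflectance curve.

    Deciduous canopies are brighter in the near infrared than conifers,
    which drives the IR channels' separation power; species differ further
    in red-edge position, green-peak amplitude and a smooth random ripple.
    """
    rng = np.random.default_rng(90_000 + index)
    base_nir = 0.52 if habit == DECIDUOUS else 0.33
    nir = base_nir + rng.uniform(-0.07, 0.07)
    red_edge = 705.0 + rng.uniform(-18.0, 18.0)
    green = (0.10 if habit == DECIDUOUS else 0.06) + rng.uniform(-0.02, 0.02)
    raw = rng.normal(0.0, 1.0, len(wavelengths))
    kernel = np.exp(-0.5 * (np.arange(-15, 16) / 6.0) ** 2)
    smooth = np.convolve(raw, kernel / kernel.sum(), mode="same")
    return _vegetation_curve(wavelengths, nir, red_edge, green, 0.02 * smooth)


def small_garden_config(
    species: Sequence[str] = (
        "Sorbus aucuparia",
        "Quercus robur",
        "Salix fragilis",
        "Abies sibirica",
        "Picea pungens",
        "Juniperus communis",
    ),
    specimens_per_species: int = 7,
) -> GardenConfig:
    """A reduced garden for simulation studies: a few species, equal counts.

    Templates (crown geometry, reflectance curves, noise) are those of the
    default garden; only the census changes.  Deterministic.
    """
    full = default_garden_config()
    by_name = {t.name: t for t in full.templates}
    unknown = [s for s in species if s not in by_name]
    if unknown:
        raise KeyError(f"unknown species {unknown}")
    templates = tuple(
        dataclasses.replace(by_name[s], count=specimens_per_species) for s in species
    )
    return dataclasses.replace(full, templates=templates)


def default_garden_config() -> GardenConfig:
    """The default synthetic garden: 168 specimens, 23 named species.

    Pure and deterministic: two calls return identical configurations.
    """
    band = default_band_set()
    templates = []
    for i, (name, habit, count, hrange) in enumerate(_GARDEN_SPECIES):
        templates.append(
            SpeciesTemplate(
                name=name,
                habit=habit,
                count=count,
                height_range=hrange,
                reflectance_curve=_species_curve(i, habit, band.centers_nm),
            )
        )
    return GardenConfig(templates=tuple(templates))


# ---------------------------------------------------------------------------
# Tree sampling
# ---------------------------------------------------------------------------

MIN_POINTS_PER_TREE = 20


def _sample_cone(n: int, height: float, base_radius: float, rng) -> np.ndarray:
    """Uniform points in a cone, apex up: radius shrinks linearly with height."""
    h = 1.0 - (1.0 - rng.random(n)) ** (1.0 / 3.0)  # pdf 3(1-h)^2
    r = (1.0 - h) * base_radius * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), h * height])


def _sample_ellipsoid(n: int, a: float, b: float, rng) -> np.ndarray:
    """Uniform points in an axis-aligned ellipsoid (a, a, b), centred at 0."""
    out = np.empty((0, 3))
    while len(out) < n:
        cand = rng.uniform(-1.0, 1.0, (2 * (n - len(out)) + 16, 3))
        keep = (cand**2).sum(1) <= 1.0
        out = np.vstack([out, cand[keep]])
    out = out[:n] * np.array([a, a, b])
    return out


def _sample_neutral(n: int, height: float, radius: float, rng) -> np.ndarray:
    """The neutral (habit-free) profile: full-height ellipsoid centred at 0.5."""
    pts = _sample_ellipsoid(n, radius, 0.5 * height, rng)
    pts[:, 2] += 0.5 * height
    return pts


def sample_tree(
    template: SpeciesTemplate,
    rng: np.random.Generator,
    *,
    specimen_id: int = 1,
    origin: tuple[float, float] = (0.0, 0.0),
    scan_speed: float = 4.0,
    shape_effect: float = 1.0,
) -> TreeSpecimen:
    """Draw one specimen point cloud from a species template.

    Total height is uniform on the template's height range; the point count
    is ``point_density`` times the crown volume (at least 20).  Each point's
    timestamp is the moment the scan line passes its x position
    (``t = x / scan_speed``), matching a constant-speed drive along +x, and
    points are returned in time order.  ``shape_effect`` in [0, 1] draws
    each point from the species profile with that probability and from the
    neutral profile otherwise.
    """
    lo, hi = template.height_range
    height = float(rng.uniform(lo, hi))
    if height <= 0:
        raise ValueError(f"template {template.name!r}: non-positive tree height")
    v_trunk, v_crown = template._volumes(height)
    if v_crown <= 0:
        raise ValueError(f"template {template.name!r}: degenerate (zero-volume) crown")
    n = max(MIN_POINTS_PER_TREE, int(round(template.point_density * (v_trunk + v_crown))))

    n_species = int(rng.binomial(n, np.clip(shape_effect, 0.0, 1.0)))
    n_neutral = n - n_species

    parts = []
    if n_species:
        if template.habit == CONIFEROUS:
            parts.append(
                _sample_cone(n_species, height, template.base_radius_frac * height, rng)
            )
        else:
            f_trunk = template._trunk_point_fraction(height)
            n_trunk = int(rng.binomial(n_species, f_trunk))
            n_cr = n_species - n_trunk
            c, b = template.crown_center_n, template.crown_halfheight_n
            if n_cr:
                crown = _sample_ellipsoid(
                    n_cr, template.crown_radius_frac * height, b * height, rng
                )
                crown[:, 2] += c * height
                parts.append(crown)
            if n_trunk:
                r = template.trunk_radius_m * np.sqrt(rng.random(n_trunk))
                phi = rng.uniform(0.0, 2.0 * np.pi, n_trunk)
                z = rng.uniform(0.0, (c - b) * height, n_trunk)
                parts.append(np.column_stack([r * np.cos(phi), r * np.sin(phi), z]))
    if n_neutral:
        radius = (
            template.base_radius_frac
            if template.habit == CONIFEROUS
            else template.crown_radius_frac
        ) * height
        parts.append(_sample_neutral(n_neutral, height, radius, rng))

    xyz = np.vstack(parts)
    xyz[:, 2] = np.clip(xyz[:, 2], 0.0, None)
    xyz[:, 0] += origin[0]
    xyz[:, 1] += origin[1]
    t = xyz[:, 0] / scan_speed
    order = np.argsort(t, kind="stable")
    pts = np.column_stack([xyz, t])[order]
    return TreeSpecimen(
        specimen_id=specimen_id,
        species=template.name,
        habit=template.habit,
        origin=origin,
        points=pts,
    )


# ---------------------------------------------------------------------------
# Frame simulation
# ---------------------------------------------------------------------------


def simulate_frames(
    specimens: Sequence[TreeSpecimen],
    trajectory: Trajectory,
    band_set: BandSet,
    illumination: IlluminationModel,
    rng: np.random.Generator,
    *,
    reflectance_by_species: dict[str, np.ndarray],
    spectral_sd_by_species: dict[str, float] | None = None,
    horizontal_window_s: float | None = None,
    dilate_px: int = 3,
) -> list[SpectralFrame]:
    """Expose spectrometer frames along the trajectory.

    For every frame, each non-reference pixel that views a tree (a laser
    point within the horizontal time window whose elevation angle falls in
    the pixel's interval) records
    ``dn = reference_level * reflectance * illumination * lognormal noise``;
    the 10 reference pixels record ``reference_level * illumination`` so
    panel normalization cancels the shared factor exactly.  Pixels above
    the 44.4 deg opening never see tall near trees' tops, which truncates
    their spectral coverage.  When two trees compete for a pixel the one
    nearer the sensor wins.
    """
    times = trajectory.frame_times()
    if len(times) == 0:
        raise ValueError("empty trajectory: no frame times (t_end <= t_start?)")
    if horizontal_window_s is None:
        horizontal_window_s = 0.5 / trajectory.frame_rate
    n_ch = len(band_set)
    edges = pixel_edges_deg(trajectory.elev_min_deg)
    centers = pixel_centers_deg(trajectory.elev_min_deg)
    ref_idx = np.array(REFERENCE_PIXEL_INDICES)
    sd_by_species = spectral_sd_by_species or {}

    frames: list[SpectralFrame] = []
    for t_f in times:
        px, py, heading = trajectory.pose_at(t_f)
        g = float(np.exp(illumination.frame_sd * rng.standard_normal()))
        dn = np.zeros((N_PIXELS, n_ch), dtype=np.float32)
        owner_range = np.full(N_PIXELS, np.inf)
        shaded = rng.random() < illumination.shaded_reference_prob
        for spec in specimens:
            pts = spec.points
            mask = np.abs(pts[:, 3] - t_f) <= horizontal_window_s
            d = float(np.exp(illumination.directional_sd * rng.standard_normal()))
            if shaded:
                d *= illumination.shade_factor
            if not mask.any():
                continue
            sub = pts[mask]
            gr = np.hypot(sub[:, 0] - px, sub[:, 1] - py)
            elev = np.degrees(np.arctan2(sub[:, 2] - trajectory.sensor_height, gr))
            pix = np.searchsorted(edges, elev, side="right") - 1
            ok = (pix >= 0) & (pix < N_PIXELS - N_REF_PIXELS)
            pix, gr = pix[ok], gr[ok]
            if len(pix) == 0:
                continue
            # per-pixel nearest range for this tree, dilated: a crown is a
            # continuous surface, so lines of sight between sampled laser
            # points also see it
            tree_range = np.full(N_PIXELS, np.inf)
            np.minimum.at(tree_range, pix, gr)
            if dilate_px > 0:
                stacked = np.full((2 * dilate_px + 1, N_PIXELS), np.inf)
                for k, off in enumerate(range(-dilate_px, dilate_px + 1)):
                    src = np.roll(tree_range, off)
                    if off > 0:
                        src[:off] = np.inf
                    elif off < 0:
                        src[off:] = np.inf
                    stacked[k] = src
                tree_range = stacked.min(axis=0)
                tree_range[N_PIXELS - N_REF_PIXELS :] = np.inf
            win = tree_range < owner_range
            upix = np.flatnonzero(win)
            if len(upix) == 0:
                continue
            owner_range[upix] = tree_range[upix]
            curve = reflectance_by_species[spec.species]
            sd = sd_by_species.get(spec.species, 0.0)
            noise = (
                np.exp(sd * rng.standard_normal((len(upix), n_ch))) if sd > 0 else 1.0
            )
            dn[upix] = (
                illumination.reference_level * g * d * curve[None, :] * noise
            ).astype(np.float32)
        dn[ref_idx] = illumination.reference_level * g
        frames.append(
            SpectralFrame(
                timestamp=float(t_f),
                sensor_pose=(px, py, heading),
                pixel_angles=centers,
                dn=dn,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------


def generate_scene(config: GardenConfig, seed: int) -> Scene:
    """Generate a full garden scene, deterministically in (config, seed).

    Trees of all templates are interleaved (seeded shuffle) along a row at
    the stand-off distance, the trajectory end times are fitted to the row,
    trees are sampled and the spectrometer frames exposed.
    """
    rng = np.random.default_rng(seed)
    band = config.band_set()
    curves = config.effective_curves()

    order: list[SpeciesTemplate] = []
    for t in config.templates:
        order.extend([t] * t.count)
    perm = rng.permutation(len(order))
    order = [order[i] for i in perm]

    specimens = []
    for i, template in enumerate(order):
        x = config.x_margin + i * config.spacing + float(
            rng.uniform(-config.position_jitter, config.position_jitter)
        )
        specimens.append(
            sample_tree(
                template,
                rng,
                specimen_id=i + 1,
                origin=(x, config.stand_off),
                scan_speed=config.trajectory.speed,
                shape_effect=config.shape_effect,
            )
        )

    if specimens:
        all_t = np.concatenate([s.points[:, 3] for s in specimens])
        pad = config.x_margin / config.trajectory.speed
        traj = dataclasses.replace(
            config.trajectory,
            t_start=float(all_t.min() - pad),
            t_end=float(all_t.max() + pad),
        )
        frames = simulate_frames(
            specimens,
            traj,
            band,
            config.illumination,
            rng,
            reflectance_by_species=curves,
            spectral_sd_by_species={t.name: t.spectral_sd for t in config.templates},
            horizontal_window_s=config.horizontal_window_s,
        )
    else:
        frames = []
    return Scene(specimens=specimens, frames=frames, band_set=band, seed=seed, config=config)
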