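"""Voxelized tissue/photoseed phantoms and their material property tables.

The in-vivo geometry is a multi-layered block of breast tissue (a superficial
fat layer over gland) hosting a small array of cylindrical plasmonic
"photoseeds" -- PDMS rods loaded with gold nanoparticles that convert NIR
laser light to heat.  The bench-validation geometry is a single cubic seed
immersed in distilled water.

Conventions
-----------
* Axis-aligned regular grid, uniform spacing per axis, voxel *centers* at
  ``(i + 1/2) * h``; 0-based indices; SI units throughout (m, K, W).
* The laser travels along -z and enters through the top face (z = z_max);
  seed axes are parallel to z.
* A voxel belongs to a seed iff its center lies inside the seed solid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "OpticalProperties",
    "ThermoPhysicalProperties",
    "BloodProperties",
    "Material",
    "PhotoseedSpec",
    "LaserBeam",
    "TissuePhantom",
    "PhantomConfig",
    "WaterModelConfig",
    "build_breast_phantom",
    "build_water_model",
    "cylinder_height",
    "FAT",
    "GLAND",
    "SEED",
    "WATER",
]

# integer voxel labels
FAT, GLAND, SEED, WATER = 0, 1, 2, 3
LABEL_NAMES = {FAT: "fat", GLAND: "gland", SEED: "seed", WATER: "water"}


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption / reduced-scattering pair with the standard
    diffusion-approximation derived quantities.

    Parameters are the absorption coefficient ``mu_a`` and the reduced
    scattering coefficient ``mu_s_prime``, both in 1/m.  The transport
    coefficient, diffusion coefficient and effective attenuation follow the
    usual diffusion-theory definitions::

        mu_tr  = mu_a + mu_s'
        D      = 1 / (3 * mu_tr)        [m]
        mu_eff = sqrt(3 * mu_a * mu_tr) [1/m]
    """

    mu_a: float
    mu_s_prime: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s_prime < 0:
            raise ValueError("optical coefficients must be non-negative")

    @property
    def mu_tr(self) -> float:
        return self.mu_a + self.mu_s_prime

    @property
    def diffusion_coefficient(self) -> float:
        if self.mu_tr <= 0:
            raise ValueError("D undefined for mu_tr = 0")
        return 1.0 / (3.0 * self.mu_tr)

    @property
    def mu_eff(self) -> float:
        return math.sqrt(3.0 * self.mu_a * self.mu_tr)


@dataclass(frozen=True)
class ThermoPhysicalProperties:
    """Bulk thermal properties of one material.

    c        specific heat capacity, J kg^-1 K^-1
    lambda_37  thermal conductivity at the reference temperature, W m^-1 K^-1
    rho      density, kg m^-3
    q_met    metabolic volumetric heat, W m^-3 (0 for non-living material)
    omega_b0 baseline blood-perfusion coefficient, s^-1 (0 for implants/water)
    """

    c: float
    lambda_37: float
    rho: float
    q_met: float = 0.0
    omega_b0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c", "lambda_37", "rho", "q_met", "omega_b0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * c, J m^-3 K^-1."""
        return self.rho * self.c


@dataclass(frozen=True)
class BloodProperties:
    """Arterial blood entering the perfusion sink term."""

    rho_b: float = 1050.0
    c_b: float = 3617.0


@dataclass(frozen=True)
class Material:
    name: str
    optical: OpticalProperties
    thermo: ThermoPhysicalProperties


# ---------------------------------------------------------------------------
# Default property tables (breast fat / gland / blood at 810 nm).
# ---------------------------------------------------------------------------

FAT_MATERIAL = Material(
    "fat",
    OpticalProperties(mu_a=3.0, mu_s_prime=950.0),
    ThermoPhysicalProperties(c=2348.0, lambda_37=0.21, rho=911.0,
                             q_met=400.0, omega_b0=2.0e-4),
)

GLAND_MATERIAL = Material(
    "gland",
    OpticalProperties(mu_a=6.0, mu_s_prime=1100.0),
    ThermoPhysicalProperties(c=2960.0, lambda_37=0.48, rho=1041.0,
                             q_met=700.0, omega_b0=5.0e-4),
)

BLOOD = BloodProperties(rho_b=1050.0, c_b=3617.0)

# Distilled water for the bench model (conduction only, no perfusion).
WATER_MATERIAL = Material(
    "water",
    OpticalProperties(mu_a=0.0, mu_s_prime=0.0),
    ThermoPhysicalProperties(c=4185.0, lambda_37=0.60, rho=998.0),
)

# PDMS bulk values for the nanocomposite seed matrix.  Perfusion and
# metabolic heat are zero inside an implant by construction.
PDMS_THERMO = ThermoPhysicalProperties(c=1460.0, lambda_37=0.16, rho=970.0)


@dataclass(frozen=True)
class PhotoseedSpec:
    """Geometry and absorptivity of one photoseed.

    ``shape`` is ``"cylinder"`` (diameter ``d_s``, length ``length``) or
    ``"cube"`` (side ``side``).  ``mu_a_seed`` is the bulk absorption
    coefficient of the nanocomposite, normally derived from the measured
    NIR absorbance via :func:`photoseed.optics.absorbance_to_mua`.
    """

    shape: str = "cylinder"
    d_s: float = 1.0e-3
    length: float = 1.5e-2
    side: float = 5.0e-3
    mu_a_seed: float = 0.0
    thermo: ThermoPhysicalProperties = PDMS_THERMO

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "cube"):
            raise ValueError(f"unknown seed shape {self.shape!r}")
        if self.shape == "cylinder" and (self.d_s <= 0 or self.length <= 0):
            raise ValueError("cylinder dimensions must be positive")
        if self.shape == "cube" and self.side <= 0:
            raise ValueError("cube side must be positive")
        if self.mu_a_seed < 0:
            raise ValueError("mu_a_seed must be non-negative")
        if self.thermo.omega_b0 != 0.0 or self.thermo.q_met != 0.0:
            raise ValueError("a seed is an implant: omega_b0 = q_met = 0")

    def material(self) -> Material:
        return Material("seed", OpticalProperties(self.mu_a_seed, 0.0), self.thermo)


@dataclass(frozen=True)
class LaserBeam:
    """CW laser: power ``p0`` (W), surface entry point (m) and unit direction."""

    p0: float
    entry_point: tuple[float, float, float]
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)

    def __post_init__(self) -> None:
        if self.p0 < 0:
            raise ValueError("laser power must be non-negative")
        n = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(n))
        if not math.isclose(norm, 1.0, rel_tol=1e-9):
            raise ValueError("beam direction must be a unit vector")

    @property
    def n_hat(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


@dataclass
class TissuePhantom:
    """Labeled voxel grid plus per-label material lookup and probe points.

    ``labels`` has shape ``(nx, ny, nz)``; ``spacing`` is the per-axis voxel
    pitch in metres; the grid origin is the block's minimum corner at (0,0,0).
    ``probes`` maps probe names (e.g. ``"P1"``) to physical coordinates.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    materials: dict[int, Material]
    probes: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    blood: BloodProperties = BLOOD

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if any(h <= 0 for h in self.spacing):
            raise ValueError("spacing must be positive")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.materials)
        if missing:
            raise ValueError(f"no material registered for labels {sorted(missing)}")
        for name, p in self.probes.items():
            if not self.contains_point(p):
                raise ValueError(f"probe {name!r} at {p} lies outside the grid")

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(n * h for n, h in zip(self.shape, self.spacing))  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        hx, hy, hz = self.spacing
        return hx * hy * hz

    def contains_point(self, p) -> bool:
        return all(0.0 <= p[a] <= self.extent[a] for a in range(3))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D arrays of voxel-center coordinates."""
        return tuple(
            (np.arange(n) + 0.5) * h for n, h in zip(self.shape, self.spacing)
        )  # type: ignore[return-value]

    # -- property lookup ----------------------------------------------------

    def _lookup(self, getter) -> np.ndarray:
        table = np.zeros(int(self.labels.max()) + 1)
        for lbl, mat in self.materials.items():
            if lbl < table.size:
                table[lbl] = getter(mat)
        return table[self.labels]

    def mu_a_field(self) -> np.ndarray:
        return self._lookup(lambda m: m.optical.mu_a)

    def mu_eff_field(self) -> np.ndarray:
        return self._lookup(lambda m: m.optical.mu_eff if m.optical.mu_tr > 0 else 0.0)

    def diffusion_field(self) -> np.ndarray:
        return self._lookup(
            lambda m: m.optical.diffusion_coefficient if m.optical.mu_tr > 0 else np.inf
        )

    def rho_c_field(self) -> np.ndarray:
        return self._lookup(lambda m: m.thermo.volumetric_heat_capacity)

    def lambda37_field(self) -> np.ndarray:
        return self._lookup(lambda m: m.thermo.lambda_37)

    def q_met_field(self) -> np.ndarray:
        return self._lookup(lambda m: m.thermo.q_met)

    def omega_b0_field(self) -> np.ndarray:
        return self._lookup(lambda m: m.thermo.omega_b0)

    def seed_mask(self) -> np.ndarray:
        return self.labels == SEED


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomConfig:
    """In-vivo breast block configuration.

    The block is ``block_size`` on each axis with a fat layer of thickness
    ``fat_thickness`` at the top (beam-entry) face and gland below.  Seeds
    form a ``seed_rows x seed_cols`` array of z-parallel cylinders, centred
    laterally on the block, axial midpoint at the block's mid-depth, with
    center-to-center pitch ``seed_spacing``.
    """

    block_size: tuple[float, float, float] = (0.06, 0.06, 0.06)
    spacing: float = 1.0e-3
    fat_thickness: float = 0.01
    seed_rows: int = 2
    seed_cols: int = 2
    seed_spacing: float = 5.0e-3
    seed: PhotoseedSpec = PhotoseedSpec()

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.block_size) or self.spacing <= 0:
            raise ValueError("block dimensions and spacing must be positive")
        if not 0 <= self.fat_thickness <= self.block_size[2]:
            raise ValueError("fat layer must fit inside the block")
        if self.seed_rows < 0 or self.seed_cols < 0:
            raise ValueError("seed array counts must be non-negative")


def _seed_axis_positions(cfg: PhantomConfig) -> list[tuple[float, float]]:
    cx, cy = cfg.block_size[0] / 2.0, cfg.block_size[1] / 2.0
    xs = (np.arange(cfg.seed_rows) - (cfg.seed_rows - 1) / 2.0) * cfg.seed_spacing
    ys = (np.arange(cfg.seed_cols) - (cfg.seed_cols - 1) / 2.0) * cfg.seed_spacing
    return [(cx + dx, cy + dy) for dx in xs for dy in ys]


def build_breast_phantom(cfg: PhantomConfig = PhantomConfig()) -> TissuePhantom:
    """Voxelize the layered breast block with its photoseed array.

    Raises a geometry error if any seed pokes out of the block or out of the
    gland layer, and a resolution error if the grid cannot represent the seed
    diameter at all.
    """
    if cfg.seed_rows * cfg.seed_cols > 0 and cfg.spacing > cfg.seed.d_s:
        raise ValueError(
            f"grid spacing {cfg.spacing} m is coarser than the seed diameter "
            f"{cfg.seed.d_s} m: seeds would vanish from the voxelization"
        )

    n = tuple(int(round(s / cfg.spacing)) for s in cfg.block_size)
    labels = np.full(n, GLAND, dtype=np.uint8)
    h = cfg.spacing
    x, y, z = ((np.arange(m) + 0.5) * h for m in n)

    # fat: superficial layer at the beam-entry (top, z = z_max) face
    z_fat = cfg.block_size[2] - cfg.fat_thickness
    labels[:, :, z >= z_fat] = FAT

    axes = _seed_axis_positions(cfg)
    z_mid = cfg.block_size[2] / 2.0
    z_lo, z_hi = z_mid - cfg.seed.length / 2.0, z_mid + cfg.seed.length / 2.0
    r = cfg.seed.d_s / 2.0
    for ax, ay in axes:
        if not (r <= ax <= cfg.block_size[0] - r and r <= ay <= cfg.block_size[1] - r):
            raise ValueError("seed array exceeds the lateral block bounds")
        if z_lo < 0 or z_hi > z_fat:
            raise ValueError("seeds must lie fully inside the gland layer")
        mask = ((x[:, None] - ax) ** 2 + (y[None, :] - ay) ** 2) <= r**2
        zsel = (z >= z_lo) & (z <= z_hi)
        if not (mask.any() and zsel.any()):
            raise ValueError(
                f"seed at ({ax:.4g}, {ay:.4g}) m captures no voxel centers at "
                f"spacing {h:.4g} m; align the grid or refine it"
            )
        labels[mask[:, :, None] & zsel[None, None, :]] = SEED

    if axes:
        p1 = (float(np.mean([a[0] for a in axes])),
              float(np.mean([a[1] for a in axes])), z_mid)
    else:
        p1 = tuple(s / 2.0 for s in cfg.block_size)

    materials = {FAT: FAT_MATERIAL, GLAND: GLAND_MATERIAL, SEED: cfg.seed.material()}
    return TissuePhantom(labels, (h, h, h), materials, probes={"P1": p1})


@dataclass(frozen=True)
class WaterModelConfig:
    """Bench-validation geometry: one cubic seed in distilled water.

    The tube is modelled as a square-base box of width ``container_width``
    whose height is set so the water volume (box minus seed) equals
    ``water_volume`` (default 0.5 mL).  The cubic seed (default side 0.5 cm,
    volume 0.125 cm^3) sits centred laterally, resting near the bottom; the
    probe records the temperature at the centre of the seed's bottom face.
    """

    water_volume: float = 0.5e-6
    container_width: float = 9.0e-3
    spacing: float = 5.0e-4
    seed: PhotoseedSpec = replace(PhotoseedSpec(), shape="cube", side=5.0e-3)
    include_seed: bool = True

    def __post_init__(self) -> None:
        if self.water_volume <= 0 or self.container_width <= 0 or self.spacing <= 0:
            raise ValueError("water model dimensions must be positive")


def build_water_model(cfg: WaterModelConfig = WaterModelConfig()) -> TissuePhantom:
    """Voxelize the water-calorimetry validation phantom."""
    w = cfg.container_width
    seed_vol = cfg.seed.side**3 if cfg.include_seed else 0.0
    height = (cfg.water_volume + seed_vol) / (w * w)
    if cfg.include_seed and (cfg.seed.side > w or cfg.seed.side > height):
        raise ValueError("seed cube does not fit inside the water container")

    h = cfg.spacing
    n = (int(round(w / h)), int(round(w / h)), int(round(height / h)))
    labels = np.full(n, WATER, dtype=np.uint8)
    materials: dict[int, Material] = {WATER: WATER_MATERIAL}
    probes: dict[str, tuple[float, float, float]] = {}

    if cfg.include_seed:
        x, y, z = ((np.arange(m) + 0.5) * h for m in n)
        side = cfg.seed.side
        cx = cy = w / 2.0
        z0 = h  # rest one voxel above the tube bottom
        inx = np.abs(x - cx) <= side / 2.0
        iny = np.abs(y - cy) <= side / 2.0
        inz = (z >= z0) & (z <= z0 + side)
        labels[inx[:, None, None] & iny[None, :, None] & inz[None, None, :]] = SEED
        materials[SEED] = cfg.seed.material()
        probes["seed_bottom"] = (cx, cy, z0)

    return TissuePhantom(labels, (h, h, h), materials, probes=probes)


def cylinder_height(volume: float, radius: float) -> float:
    """Height of a cylinder of given volume and radius (V = pi r^2 h)."""
    if volume < 0 or radius <= 0:
        raise ValueError("need volume >= 0 and radius > 0")
    return volume / (math.pi * radius**2)
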