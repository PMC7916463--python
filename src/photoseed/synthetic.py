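"""Deterministic synthetic inputs with attached ground truth.

Bench IR-camera heating curves are emulated as a saturating exponential --
a fast initial rise approaching a plateau, which is the phenomenology of a
lumped thermal mass heated at constant power while losing heat to the room
-- plus additive i.i.d. Gaussian measurement noise (default sd 0.1 degC at
1 Hz, appropriate for a consumer-class thermal camera).  Every generator is
deterministic given its seed, and returns a ground-truth record from which
downstream expected values (slopes, efficiencies, damage integrals) can be
computed without re-deriving constants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calorimetry import HeatingCurve
from .phantom import (
    GLAND_MATERIAL,
    PhantomConfig,
    PhotoseedSpec,
    TissuePhantom,
    WaterModelConfig,
    build_breast_phantom,
    build_water_model,
)

__all__ = [
    "CurveGeneratorSpec",
    "CurveGroundTruth",
    "make_heating_curve",
    "make_efficiency_curve",
    "make_constant_T_history",
    "make_toy_phantom",
]


@dataclass(frozen=True)
class CurveGeneratorSpec:
    """Parameters of the synthetic heating-curve family.

    ``shape="saturating"`` gives ``T(t) = baseline + rise*(1 - exp(-t/tau))``;
    ``shape="linear"`` gives the early-time limit ``baseline + (rise/tau)*t``
    (useful when the generating initial rate must equal the fitted slope
    exactly).
    """

    baseline: float = 25.0
    rise: float = 27.46
    tau: float = 180.0
    noise_sd: float = 0.1
    rate_hz: float = 1.0
    duration: float = 300.0
    seed: int = 0
    shape: str = "saturating"

    def __post_init__(self) -> None:
        if self.rise < 0 or self.tau <= 0 or self.noise_sd < 0:
            raise ValueError("need rise >= 0, tau > 0, noise sd >= 0")
        if self.rate_hz <= 0 or self.duration <= 0:
            raise ValueError("sampling rate and duration must be positive")
        if self.shape not in ("saturating", "linear"):
            raise ValueError(f"unknown curve shape {self.shape!r}")


@dataclass(frozen=True)
class CurveGroundTruth:
    """What the generator actually used: enough to predict any statistic."""

    spec: CurveGeneratorSpec
    initial_slope: float          # degC/s: analytic dT/dt at t = 0
    plateau: float                # degC: baseline + rise
    eta: float | None = None      # only for efficiency-targeted curves


def make_heating_curve(
    spec: CurveGeneratorSpec, **curve_metadata
) -> tuple[HeatingCurve, CurveGroundTruth]:
    """Generate one noisy heating curve plus its ground truth.

    Sampling is uniform at ``rate_hz`` from t = 0 to ``duration`` inclusive.
    The same seed reproduces the series bit for bit.
    """
    n = int(round(spec.duration * spec.rate_hz)) + 1
    t = np.arange(n) / spec.rate_hz
    if spec.shape == "saturating":
        clean = spec.baseline + spec.rise * (1.0 - np.exp(-t / spec.tau))
    else:
        clean = spec.baseline + (spec.rise / spec.tau) * t
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else clean
    curve = HeatingCurve(t, noisy, **curve_metadata)
    truth = CurveGroundTruth(
        spec=spec, initial_slope=spec.rise / spec.tau, plateau=spec.baseline + spec.rise
    )
    return curve, truth


def make_efficiency_curve(
    eta: float,
    p0: float,
    a810: float,
    *,
    m_w: float = 0.5,
    c_p: float = 4.185,
    spec: CurveGeneratorSpec = CurveGeneratorSpec(),
    **curve_metadata,
) -> tuple[HeatingCurve, CurveGroundTruth]:
    """Curve whose generating initial rate corresponds to a known efficiency.

    Inverts the lumped energy balance: the initial rate is
    ``eta * P0 * (1 - 10^-A810) / (m_w * c_p)`` and the curve's rise is set
    so the requested shape has exactly that t = 0 slope.
    """
    if not 0 <= eta <= 1:
        raise ValueError("eta must lie in [0, 1]")
    rate = eta * p0 * (1.0 - 10.0 ** (-a810)) / (m_w * c_p)
    spec = replace(spec, rise=rate * spec.tau)
    curve, truth = make_heating_curve(
        spec, p0=p0, a810=a810, m_w=m_w, c_p=c_p, **curve_metadata
    )
    return curve, replace(truth, eta=eta)


def make_constant_T_history(
    T: float, duration: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Constant stepped temperature trace (times s, temperatures K)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(duration / dt))
    times = np.arange(n + 1) * dt
    return times, np.full(n + 1, float(T))


def make_toy_phantom(kind: str) -> tuple[TissuePhantom, dict]:
    """Small phantoms (< 40^3 voxels) with their analytic reference attached.

    ``"slab"``        quasi-1D fat slab, L = 2 cm: with fixed-temperature
                      ends, constant conductivity, no perfusion and uniform
                      volumetric heating Q, the steady peak rise over the end
                      temperature is Q*L^2/(8*lambda).
    ``"single-seed"`` one cylindrical seed centred in a 2 cm gland cube;
                      reference: temperature decays monotonically with
                      radial distance from the seed axis.
    ``"water-model"`` the default bench-validation phantom.
    """
    if kind == "slab":
        L, h = 0.02, 1.0e-3
        n = int(round(L / h))
        labels = np.zeros((n, 1, 1), dtype=np.uint8)
        from dataclasses import replace as _rep

        from .phantom import FAT, FAT_MATERIAL, Material

        # inert conductor with fat's thermal constants: the parabolic
        # closed form assumes no perfusion and no metabolic heat
        inert = Material(
            "slab",
            FAT_MATERIAL.optical,
            _rep(FAT_MATERIAL.thermo, q_met=0.0, omega_b0=0.0),
        )
        ph = TissuePhantom(
            labels, (h, h, h), {FAT: inert},
            probes={"center": (L / 2.0, h / 2.0, h / 2.0)},
        )
        lam = FAT_MATERIAL.thermo.lambda_37
        ref = {
            "length": L,
            "lambda": lam,
            "max_rise": lambda Q, L=L, lam=lam: Q * L**2 / (8.0 * lam),
        }
        return ph, ref

    if kind == "single-seed":
        # odd voxel count: the single seed's axis must land on voxel centers
        cfg = PhantomConfig(
            block_size=(0.021, 0.021, 0.021),
            spacing=1.0e-3,
            fat_thickness=0.0,
            seed_rows=1,
            seed_cols=1,
            seed=PhotoseedSpec(length=0.01, mu_a_seed=1.0e5),
        )
        ph = build_breast_phantom(cfg)
        return ph, {"property": "radial monotone decay", "material": GLAND_MATERIAL}

    if kind == "water-model":
        ph = build_water_model(WaterModelConfig())
        return ph, {"seed_volume": 0.125e-6, "water_volume": 0.5e-6}

    raise ValueError(f"unknown toy phantom kind {kind!r}")
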