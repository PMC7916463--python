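"""Bench-side photothermal calorimetry and viability arithmetic.

A photoseed sits in a known mass of water and is irradiated by a CW NIR
laser while an IR camera logs the water temperature.  Treating the water as
a lumped thermal mass, the photothermal conversion efficiency follows the
Roper-style energy balance

    eta = m_w * c_p * (dT/dt)_initial / (P0 * (1 - 10^(-A810)))

where the denominator is the optical power actually absorbed by a sample of
decadic absorbance ``A810`` and the numerator the rate heat appears in the
water before losses matter.  The initial rate is a least-squares slope over
the first ``window`` seconds (default 30 s) -- robust to camera noise.

The trypan-blue viability expression is implemented exactly as the printed
formula, ``%CV = (1 - viable/total) * 100``; because that orientation
conflicts with the usual reading of a dye-exclusion assay, the complementary
percentage is always reported alongside it rather than silently "fixed".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HeatingCurve",
    "ViabilityCount",
    "ViabilityResult",
    "read_heating_curve",
    "initial_rate",
    "conversion_efficiency",
    "delta_T",
    "cell_viability",
    "relative_viability",
    "summarize_batch",
]


@dataclass
class HeatingCurve:
    """Temperature-time series with the metadata the lumped analysis needs.

    times in s (strictly increasing, starting at 0), temperatures in deg C;
    ``m_w`` is the water mass in grams, ``c_p`` its specific heat in
    J g^-1 degC^-1 (4.185 by default), ``p0`` the laser power in W and
    ``a810`` the sample's decadic absorbance at the laser wavelength.
    """

    times: np.ndarray
    temperatures: np.ndarray
    label: str = ""
    p0: float = 0.0
    a810: float = 0.0
    m_w: float = 0.5
    c_p: float = 4.185
    au_wt_pct: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.times.size < 2 or self.times.size != self.temperatures.size:
            raise ValueError("need >= 2 matched (time, temperature) samples")
        if self.times[0] != 0.0:
            raise ValueError("time axis must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.times[-1])


def read_heating_curve(path: str | Path, **metadata) -> HeatingCurve:
    """Load a two-column CSV (header ``time_s,temp_C``) into a HeatingCurve."""
    df = pd.read_csv(path)
    required = {"time_s", "temp_C"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    return HeatingCurve(df["time_s"].to_numpy(), df["temp_C"].to_numpy(), **metadata)


def initial_rate(curve: HeatingCurve, window: float = 30.0) -> float:
    """Initial heating rate (degC/s): least-squares slope over [0, window]."""
    if window > curve.duration:
        raise ValueError("fit window exceeds the curve duration")
    sel = curve.times <= window
    if np.count_nonzero(sel) < 2:
        raise ValueError("fewer than 2 samples inside the fit window")
    slope, _ = np.polyfit(curve.times[sel], curve.temperatures[sel], 1)
    return float(slope)


def conversion_efficiency(curve: HeatingCurve, rate: float) -> float:
    """Photothermal conversion efficiency eta (dimensionless, 0..1 scale)."""
    if curve.p0 <= 0:
        raise ValueError("laser power must be positive")
    if curve.a810 < 0:
        raise ValueError("absorbance must be non-negative")
    absorbed_fraction = 1.0 - 10.0 ** (-curve.a810)
    if absorbed_fraction == 0.0:
        if rate == 0.0:
            return 0.0
        raise ZeroDivisionError("A810 = 0: no absorbed power to normalize by")
    return curve.m_w * curve.c_p * rate / (curve.p0 * absorbed_fraction)


def delta_T(curve: HeatingCurve, endpoint: float = 300.0) -> float:
    """Temperature rise T(endpoint) - T(0), endpoint default 5 min."""
    if endpoint > curve.duration:
        raise ValueError(
            f"endpoint {endpoint} s beyond the recorded {curve.duration} s"
        )
    t_end = float(np.interp(endpoint, curve.times, curve.temperatures))
    return t_end - float(curve.temperatures[0])


@dataclass(frozen=True)
class ViabilityCount:
    total: int
    viable: int
    label: str = ""
    delta_T_C: float | None = None

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total cell count must be positive")
        if not 0 <= self.viable <= self.total:
            raise ValueError("viable count must lie in [0, total]")


@dataclass(frozen=True)
class ViabilityResult:
    """Both orientations of the viability percentage.

    ``formula_pct`` is the printed expression ``(1 - viable/total)*100``;
    ``viable_pct`` is the complementary ``viable/total*100``.  They always
    sum to 100.
    """

    formula_pct: float
    viable_pct: float


def cell_viability(vc: ViabilityCount) -> ViabilityResult:
    frac = vc.viable / vc.total
    return ViabilityResult(formula_pct=(1.0 - frac) * 100.0, viable_pct=frac * 100.0)


def relative_viability(condition: ViabilityCount, control: ViabilityCount) -> float:
    """Condition viable fraction normalized by the control's."""
    c = cell_viability(control).viable_pct
    if c == 0:
        raise ZeroDivisionError("control has no viable cells")
    return cell_viability(condition).viable_pct / c


def summarize_batch(
    curves: list[HeatingCurve],
    *,
    window: float = 30.0,
    endpoint: float = 300.0,
    control: HeatingCurve | None = None,
) -> pd.DataFrame:
    """Calorimetry summary table: one row per curve.

    Columns mirror a bench results table: sample label, Au loading, laser
    power, initial rate, 5-min temperature rise and conversion efficiency
    (percent).  If ``control`` is given (a no-photoseed curve at the same
    power), its temperature rise is subtracted from each sample's rise
    before any reporting -- off by default.
    """
    rows = []
    ctrl_dT = delta_T(control, endpoint) if control is not None else 0.0
    for c in curves:
        rate = initial_rate(c, window)
        dT = delta_T(c, endpoint) - ctrl_dT
        eta = conversion_efficiency(c, rate)
        rows.append(
            {
                "sample": c.label,
                "au_wt_pct": c.au_wt_pct,
                "P0_W": c.p0,
                "dTdt_C_per_s": rate,
                "deltaT_C": dT,
                "eta_pct": 100.0 * eta,
            }
        )
    return pd.DataFrame(rows)
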