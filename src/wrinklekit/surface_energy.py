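"""Owens-Wendt surface free energy of a solid from probe-liquid contact angles.

The Owens-Wendt model splits surface free energy into dispersive and polar
components, gamma = gamma_d + gamma_p, and combines them geometrically at the
solid-liquid interface. For a probe liquid with components (gamma_L_d,
gamma_L_p) making contact angle theta on the solid,

    gamma_L (1 + cos theta) = 2 sqrt(gamma_S_d gamma_L_d) + 2 sqrt(gamma_S_p gamma_L_p),

which is linear in transformed coordinates

    y = gamma_L (1 + cos theta) / (2 sqrt(gamma_L_d)),   x = sqrt(gamma_L_p / gamma_L_d),

with slope sqrt(gamma_S_p) and intercept sqrt(gamma_S_d). At least two
liquids, one of them polar, identify both components.

The probe-liquid component split is data, not code: the bundled table
(``data/probe_liquids.csv``) carries literature-typical dispersive/polar
splits for water, hexadecane (fully dispersive) and nitromethane, and can be
replaced by any CSV with columns ``name,gamma_total,gamma_d,gamma_p``.
All surface tensions are in mN/m; angles at the interface are in degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ProbeLiquid:
    """Probe liquid with total, dispersive and polar surface tension (mN/m)."""

    name: str
    gamma_total: float
    gamma_d: float
    gamma_p: float

    def __post_init__(self) -> None:
        if self.gamma_d < 0 or self.gamma_p < 0:
            raise ValueError(f"{self.name}: surface tension components must be >= 0")
        if not math.isclose(self.gamma_d + self.gamma_p, self.gamma_total, rel_tol=1e-6, abs_tol=1e-9):
            raise ValueError(
                f"{self.name}: gamma_d + gamma_p = {self.gamma_d + self.gamma_p} "
                f"does not equal gamma_total = {self.gamma_total}"
            )


@dataclass(frozen=True)
class ContactAngleMeasurement:
    liquid: ProbeLiquid
    theta_deg: float

    def __post_init__(self) -> None:
        if not 0 <= self.theta_deg <= 180:
            raise ValueError(f"theta_deg must be in [0, 180], got {self.theta_deg}")


@dataclass(frozen=True)
class SurfaceEnergyResult:
    """Fitted solid surface energy components (mN/m) plus regression diagnostics."""

    gamma_d: float
    gamma_p: float
    slope: float
    intercept: float
    residuals: tuple[float, ...]

    @property
    def gamma_total(self) -> float:
        return self.gamma_d + self.gamma_p


class PredictedAngle(NamedTuple):
    theta_deg: float
    saturated: str | None  # None | "wetting" | "dewetting"


def load_liquids(path: str | Path | None = None) -> dict[str, ProbeLiquid]:
    """Load a probe-liquid table (bundled literature defaults if no path given)."""
    if path is None:
        with resources.files("wrinklekit.data").joinpath("probe_liquids.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    return {
        row["name"]: ProbeLiquid(row["name"], row["gamma_total"], row["gamma_d"], row["gamma_p"])
        for row in df.to_dict("records")
    }


def owens_wendt_fit(
    measurements: Iterable[ContactAngleMeasurement],
    allow_dispersive_only: bool = False,
) -> SurfaceEnergyResult:
    """Least-squares Owens-Wendt regression over contact-angle measurements.

    With ``allow_dispersive_only`` and exclusively apolar liquids the polar
    component is fixed at zero and only the dispersive intercept is fitted;
    otherwise at least one liquid with a polar component is required to
    identify gamma_S_p.

    Negative fitted square roots (slope or intercept) are clamped to zero with
    a warning: they arise from noise when the corresponding component of the
    solid is near zero.
    """
    ms = list(measurements)
    if len(ms) < 1 or (len(ms) < 2 and not allow_dispersive_only):
        raise ValueError("owens_wendt_fit requires at least 2 measurements")
    for m in ms:
        if m.liquid.gamma_d <= 0:
            raise ValueError(f"{m.liquid.name}: gamma_d must be > 0 for the Owens-Wendt transform")
    x = np.array([math.sqrt(m.liquid.gamma_p / m.liquid.gamma_d) for m in ms])
    y = np.array(
        [
            m.liquid.gamma_total * (1.0 + math.cos(math.radians(m.theta_deg)))
            / (2.0 * math.sqrt(m.liquid.gamma_d))
            for m in ms
        ]
    )
    if np.all(x == 0):
        if not allow_dispersive_only:
            raise ValueError(
                "polar component unidentifiable: all probe liquids are purely dispersive"
            )
        slope = 0.0
        intercept = float(y.mean())
    else:
        design = np.column_stack([x, np.ones_like(x)])
        (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = tuple(float(r) for r in y - (slope * x + intercept))
    if slope < 0:
        warnings.warn("fitted sqrt(gamma_S_p) is negative; clamping polar component to 0")
        slope_eff = 0.0
    else:
        slope_eff = slope
    if intercept < 0:
        warnings.warn("fitted sqrt(gamma_S_d) is negative; clamping dispersive component to 0")
        intercept_eff = 0.0
    else:
        intercept_eff = intercept
    return SurfaceEnergyResult(
        gamma_d=intercept_eff**2,
        gamma_p=slope_eff**2,
        slope=float(slope),
        intercept=float(intercept),
        residuals=resid,
    )


def predict_contact_angle(
    gamma_s_d: float, gamma_s_p: float, liquid: ProbeLiquid
) -> PredictedAngle:
    """Forward Owens-Wendt relation: contact angle of ``liquid`` on a known solid.

    cos(theta) outside [-1, 1] is reported as saturated complete wetting
    (theta = 0) or complete dewetting (theta = 180) with a flag.
    """
    if gamma_s_d < 0 or gamma_s_p < 0:
        raise ValueError("solid surface energy components must be >= 0")
    cos_theta = (
        2.0 * math.sqrt(gamma_s_d * liquid.gamma_d) + 2.0 * math.sqrt(gamma_s_p * liquid.gamma_p)
    ) / liquid.gamma_total - 1.0
    if cos_theta > 1.0:
        return PredictedAngle(0.0, "wetting")
    if cos_theta < -1.0:
        return PredictedAngle(180.0, "dewetting")
    return PredictedAngle(math.degrees(math.acos(cos_theta)), None)


def fit_from_table(angles: pd.DataFrame, liquids: dict[str, ProbeLiquid]) -> SurfaceEnergyResult:
    """Fit from a tidy table with columns ``liquid`` and ``theta_deg``."""
    ms = []
    for row in angles.itertuples(index=False):
        name = getattr(row, "liquid")
        if name not in liquids:
            raise KeyError(f"unknown probe liquid {name!r}; add it to the liquid table")
        ms.append(ContactAngleMeasurement(liquids[name], getattr(row, "theta_deg")))
    return owens_wendt_fit(ms)
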