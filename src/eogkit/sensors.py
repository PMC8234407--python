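"""Design and characterization calculators for the flexible strain biosensor.

All quantities are SI.  The cantilever stiffness and load–deflection
relations describe a thin rectangular film (the PDMS/hydrogel laminate)
treated as an elastic cantilever / clamped plate:

    K = E·W·T³ / (6·L³)                 (cantilever elastic constant, N/m)
    P = π⁴·E·T³·c / (6·(1 − ν²)·L⁴)     (pressure at deflection c, Pa)

The π exponent in the plate formula follows plate-deflection theory's π⁴
series term; it is exposed as a module constant so the alternative π/4
reading is a one-line change.  Tensile and electrical characterization:

    E = F·L / (A·ΔL)                    (Young's modulus, Pa)
    ρ = U·S / (I·L)                     (resistivity, Ω·m; σ = 1/ρ)

The last formula is sometimes labelled "conductivity" in sensor data
sheets although it yields resistivity; both are returned, explicitly named.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

#: Exponent of π in the load–deflection pressure formula.
PLATE_PI_EXPONENT = 4


@dataclass
class SensorGeometry:
    """Rectangular-film geometry and elastic constants (SI units)."""

    width: float          # W, m
    thickness: float      # T, m
    length: float         # L, m
    youngs_modulus: float  # E, Pa
    poisson_ratio: float = 0.0  # ν

    def __post_init__(self) -> None:
        for name in ("width", "thickness", "length", "youngs_modulus"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5)")


def cantilever_constant(g: SensorGeometry) -> float:
    """Elastic constant K = E·W·T³/(6·L³) of the film cantilever, N/m."""
    return g.youngs_modulus * g.width * g.thickness ** 3 / (6.0 * g.length ** 3)


def load_deflection_pressure(g: SensorGeometry, deflection: float) -> float:
    """Pressure P = π⁴·E·T³·c / (6·(1 − ν²)·L⁴) at deflection ``c`` metres."""
    if abs(g.poisson_ratio) >= 1:
        raise ValueError("poisson_ratio magnitude must be < 1")
    return (np.pi ** PLATE_PI_EXPONENT * g.youngs_modulus * g.thickness ** 3
            * deflection) / (6.0 * (1.0 - g.poisson_ratio ** 2) * g.length ** 4)


def youngs_modulus(force: float, length: float, area: float,
                   elongation: float) -> float:
    """Tensile modulus E = F·L/(A·ΔL) in Pa from a pull test."""
    for name, v in (("force", force), ("length", length), ("area", area),
                    ("elongation", elongation)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return force * length / (area * elongation)


def resistivity(voltage: float, current: float, cross_section: float,
                length: float) -> Dict[str, float]:
    """Voltammetric resistivity ρ = U·S/(I·L) and conductivity 1/ρ.

    Returns ``{"resistivity_ohm_m": ρ, "conductivity_S_per_m": 1/ρ}``.
    """
    for name, v in (("voltage", voltage), ("current", current),
                    ("cross_section", cross_section), ("length", length)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    rho = voltage * cross_section / (current * length)
    return {"resistivity_ohm_m": rho, "conductivity_S_per_m": 1.0 / rho}
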