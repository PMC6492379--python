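"""Static air-chamber compliance physics.

A sealed chamber partly filled with air realizes an adjustable compliance
C = dV/dp: liquid entering the chamber compresses the trapped gas, which obeys
the isentropic relation p0 * V0**lam = p1 * V1**lam (lam = 1.4 for air; lam = 1
recovers the isothermal/Boyle limit).  Differentiating the gas law gives the
pressure-dependent compliance

    C(p1) = (1/lam) * p0**(1/lam) * V0 * p1**(-(1+lam)/lam)

so a chamber's compliance at an operating pressure is set purely by the
initial air volume -- which is how the bench tunes the cranial and spinal
compartments.  Gas-law arithmetic is done in ABSOLUTE pressure (atmosphere +
gauge); reported craniospinal pressures are gauge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, PhysicalStateError

#: Standard atmosphere in mmHg; gauge pressures are relative to this.
ATM_MMHG = 760.0

#: Isentropic exponent of air.
LAMBDA_AIR = 1.4


@dataclass(frozen=True)
class AirChamber:
    """Sealed gas volume acting as a compliance element.

    ``v0_air`` (ml) and ``p0_abs`` (mmHg absolute) define the reference state;
    ``lam`` is the polytropic exponent (1 = isothermal ... 1.67 = monatomic
    adiabatic; 1.4 = air, adiabatic).
    """

    v0_air: float
    p0_abs: float
    lam: float = LAMBDA_AIR

    def __post_init__(self):
        if self.v0_air <= 0:
            raise InvalidParameterError(f"v0_air must be positive, got {self.v0_air}")
        if self.p0_abs <= 0:
            raise InvalidParameterError(f"p0_abs must be positive, got {self.p0_abs}")
        if not 1.0 <= self.lam <= 1.67:
            raise InvalidParameterError(f"lam must lie in [1.0, 1.67], got {self.lam}")


def chamber_pressure(ch: AirChamber, v_air: float) -> float:
    """Absolute pressure (mmHg) of the chamber at air volume ``v_air`` (ml).

    Evaluated in the log domain for numerical robustness:
    p = p0 * (V0 / V)**lam.
    """
    if v_air <= 0:
        raise PhysicalStateError(f"air volume must be positive, got {v_air}")
    return float(ch.p0_abs * np.exp(ch.lam * (np.log(ch.v0_air) - np.log(v_air))))


def air_volume_at(ch: AirChamber, p_abs: float) -> float:
    """Inverse of :func:`chamber_pressure`: air volume (ml) at ``p_abs`` (mmHg)."""
    if p_abs <= 0:
        raise PhysicalStateError(f"pressure must be positive, got {p_abs}")
    return float(ch.v0_air * np.exp((np.log(ch.p0_abs) - np.log(p_abs)) / ch.lam))


def compliance_at(ch: AirChamber, p1_abs: float) -> float:
    """Chamber compliance dV/dp (ml/mmHg) at absolute pressure ``p1_abs``.

    C = (1/lam) * p0**(1/lam) * V0 * p1**(-(1+lam)/lam); monotonically
    decreasing in pressure (stiffer when compressed).
    """
    if p1_abs <= 0:
        raise PhysicalStateError(f"pressure must be positive, got {p1_abs}")
    lam = ch.lam
    log_c = (
        -np.log(lam)
        + np.log(ch.p0_abs) / lam
        + np.log(ch.v0_air)
        - (1 + lam) / lam * np.log(p1_abs)
    )
    return float(np.exp(log_c))


def size_air_volume(c_target: float, p_op_abs: float, lam: float = LAMBDA_AIR) -> float:
    """Initial air volume (ml) giving compliance ``c_target`` at the operating
    pressure ``p_op_abs`` (mmHg absolute).

    With the reference state placed at the operating point, the closed form is
    V0 = c_target * lam * p_op_abs.
    """
    if c_target <= 0:
        raise InvalidParameterError(f"target compliance must be positive, got {c_target}")
    if p_op_abs <= 0:
        raise InvalidParameterError(f"operating pressure must be positive, got {p_op_abs}")
    return c_target * lam * p_op_abs


@dataclass(frozen=True)
class ComplianceBudget:
    """Total craniospinal compliance and its split across compartments.

    ``shares`` are integer percentages (rounded half-up) computed from the
    values; with rounding they may not sum to exactly 100.
    """

    parts: tuple[float, ...]
    c_total: float
    shares: tuple[int, ...]

    @property
    def c_cranial(self) -> float:
        return self.parts[0]

    @property
    def c_spinal(self) -> float:
        return self.parts[1] if len(self.parts) > 1 else 0.0


def total_compliance(parts: list[float]) -> ComplianceBudget:
    """Sum compartment compliances (ml/mmHg) and compute percentage shares."""
    if not parts:
        raise InvalidParameterError("at least one compliance compartment required")
    if any(p <= 0 for p in parts):
        raise InvalidParameterError("compartment compliances must be positive")
    total = float(sum(parts))
    # round half-up, not banker's rounding, for report parity
    shares = tuple(int(np.floor(100.0 * p / total + 0.5)) for p in parts)
    return ComplianceBudget(parts=tuple(float(p) for p in parts), c_total=total, shares=shares)
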