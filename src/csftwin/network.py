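"""Hydraulic network of the craniospinal bench and its time integration.

Topology (four nodes, caudal-positive flows)::

    pump --> N1 (cranial compliance chamber)
             N1 --Valve1--> N2 --aqueduct--> N3      (parenchyma path)
             N1 --------Valve2-------------> N3      (cranial SAS path)
             N3 --spinal canal (series Poiseuille)--> N4 (spinal chamber)

N1 and N4 carry the only storage (air chambers); N2 is the ventricular
pressure tap (ICP) inside the parenchyma path, N3 the cistern where the
cranial SAS meets the spinal canal.  The state of the system is the pair of
chamber air volumes; all node pressures and branch flows follow algebraically
from the gas law and the resistive network.  A fixed-step classical
Runge-Kutta (RK4) scheme keeps cycle boundaries exact and runs
bit-reproducibly.

Units: flows ml/min, pressures mmHg (gauge at the interface, absolute inside
the gas law), resistances mmHg/(ml/min), time seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import optimize

from .compliance import ATM_MMHG, AirChamber, air_volume_at
from .errors import ConfigError, DriftError, GridMismatchError, InvalidParameterError
from .waveforms import SampledWaveform

#: Conversion: dynamic viscosity mPa*s, lengths mm -> resistance mmHg/(ml/min).
_PA_PER_MMHG = 133.322387415
_NET_VOLUME_TOL = 1e-6  # ml; larger net pump volume per cycle refuses to run


@dataclass(frozen=True)
class ValveResistance:
    """Adjustable valve, lumped as a linear resistance (mmHg per ml/min)."""

    r: float
    label: str = ""

    def __post_init__(self):
        if self.r < 0:
            raise InvalidParameterError(f"resistance must be >= 0, got {self.r}")


@dataclass(frozen=True)
class CanalSegment:
    """Straight spinal-canal segment characterized by its hydraulic diameter."""

    length_mm: float
    hydraulic_diameter_mm: float
    viscosity_mpa_s: float = 1.0  # water at room temperature

    def __post_init__(self):
        if self.length_mm <= 0 or self.hydraulic_diameter_mm <= 0:
            raise InvalidParameterError("segment length and diameter must be positive")
        if self.viscosity_mpa_s <= 0:
            raise InvalidParameterError("viscosity must be positive")


def poiseuille_resistance(seg: CanalSegment) -> float:
    """Laminar (Hagen-Poiseuille) resistance of a segment, mmHg/(ml/min).

    R = 128 * mu * L / (pi * d**4), converted from SI.  Peak Reynolds numbers
    in the canal stay in the laminar range, so no entrance or minor losses.
    """
    mu = seg.viscosity_mpa_s * 1e-3  # Pa*s
    length = seg.length_mm * 1e-3  # m
    d = seg.hydraulic_diameter_mm * 1e-3  # m
    r_si = 128.0 * mu * length / (np.pi * d**4)  # Pa/(m^3/s)
    # 1 ml/min = 1e-6/60 m^3/s
    return float(r_si * (1e-6 / 60.0) / _PA_PER_MMHG)


@dataclass(frozen=True)
class NetworkModel:
    """Assembled hydraulic model (see module docstring for the topology)."""

    cranial_chamber: AirChamber
    spinal_chamber: AirChamber
    r_valve1: ValveResistance
    r_aqueduct: float
    r_valve2: ValveResistance
    canal: tuple[CanalSegment, ...]
    baseline_icp_gauge: float
    atm_mmHg: float = ATM_MMHG

    def __post_init__(self):
        if not self.canal:
            raise ConfigError("spinal canal needs at least one segment")
        if self.r_aqueduct < 0:
            raise InvalidParameterError("aqueduct resistance must be >= 0")
        if self.r_canal <= 0:
            raise ConfigError("total spinal canal resistance must be positive")
        if self.r_parenchyma_path == 0 and self.r_valve2.r == 0:
            raise ConfigError("both cranial paths have zero resistance (unresolvable loop)")

    @property
    def r_parenchyma_path(self) -> float:
        """Series resistance of Valve 1 plus the aqueduct."""
        return self.r_valve1.r + self.r_aqueduct

    @property
    def r_canal(self) -> float:
        return float(sum(poiseuille_resistance(s) for s in self.canal))

    @property
    def baseline_abs(self) -> float:
        return self.atm_mmHg + self.baseline_icp_gauge


def assemble(cfg) -> NetworkModel:
    """Build a :class:`NetworkModel` from a validated :class:`~csftwin.config.Config`.

    Chambers given as compliance targets are sized via
    :func:`~csftwin.compliance.size_air_volume` at the configured baseline
    operating pressure; chambers given as air volumes take the baseline as
    their reference pressure directly.
    """
    from .compliance import size_air_volume  # local import keeps namespaces tidy

    p_op = cfg.atmospheric_mmHg + cfg.baseline_icp_mmHg

    def build_chamber(spec) -> AirChamber:
        if spec.c_target_ml_per_mmHg is not None:
            v0 = size_air_volume(spec.c_target_ml_per_mmHg, p_op, spec.lam)
        else:
            v0 = spec.v0_air_ml
        return AirChamber(v0_air=v0, p0_abs=p_op, lam=spec.lam)

    canal = tuple(
        CanalSegment(
            length_mm=s.length_mm,
            hydraulic_diameter_mm=s.hydraulic_diameter_mm,
            viscosity_mpa_s=s.viscosity_mpa_s,
        )
        for s in cfg.canal.segments
    )
    # the configured parenchyma-path resistance lumps Valve 1 and the aqueduct;
    # split evenly so the ICP tap sits midway along the path
    r_path = cfg.valves.valve1_parenchyma_path
    return NetworkModel(
        cranial_chamber=build_chamber(cfg.chambers.cranial),
        spinal_chamber=build_chamber(cfg.chambers.spinal),
        r_valve1=ValveResistance(r=0.5 * r_path, label="valve1_parenchyma_path"),
        r_aqueduct=0.5 * r_path,
        r_valve2=ValveResistance(r=cfg.valves.valve2_cranial_sas, label="valve2_cranial_sas"),
        canal=canal,
        baseline_icp_gauge=cfg.baseline_icp_mmHg,
        atm_mmHg=cfg.atmospheric_mmHg,
    )


@dataclass(frozen=True)
class OperatingState:
    """Equilibrium state: all flows zero, every node at the baseline pressure."""

    v_air_cranial: float
    v_air_spinal: float
    pressure_gauge: float


def operating_point(net: NetworkModel, pump: Optional[SampledWaveform] = None) -> OperatingState:
    """Equilibrium initialization at the configured baseline ICP.

    Without a pump waveform this is the rest state: all flows zero, every
    node at the baseline pressure.  With a pump waveform, the baseline is
    interpreted as the *running-mean* operating pressure (which is what a
    bench reports): the pump's cumulative displaced volume has a nonzero
    time average over the cycle, so the initial chamber fill is offset by
    that mean stored volume -- distributed across both chambers at a common
    pressure -- to make the cycle-mean pressure of the periodic orbit equal
    the baseline.  The offset is solved exactly by Newton iteration on the
    common pressure.
    """
    p_abs = net.baseline_abs
    chc, chs = net.cranial_chamber, net.spinal_chamber
    v1 = air_volume_at(chc, p_abs)
    v4 = air_volume_at(chs, p_abs)
    if pump is not None:
        # time-mean of the cumulative pump volume over one cycle, ml
        from scipy.integrate import cumulative_trapezoid

        cumvol = cumulative_trapezoid(pump.values / 60.0, pump.times, initial=0.0)
        m_bar = float(cumvol.mean())
        if m_bar != 0.0:
            # extra air volume m_bar at a common pressure p: solve
            # Vc(p) + Vs(p) = v1 + v4 + m_bar
            target = v1 + v4 + m_bar
            p = p_abs
            for _ in range(30):
                vc = air_volume_at(chc, p)
                vs = air_volume_at(chs, p)
                f = vc + vs - target
                # dV/dp = -V/(lam*p)
                dfdp = -(vc / (chc.lam * p) + vs / (chs.lam * p))
                step = f / dfdp
                p -= step
                if abs(step) < 1e-12 * p_abs:
                    break
            v1 = air_volume_at(chc, p)
            v4 = air_volume_at(chs, p)
            p_abs = p
    return OperatingState(
        v_air_cranial=v1,
        v_air_spinal=v4,
        pressure_gauge=p_abs - net.atm_mmHg,
    )


@dataclass(frozen=True)
class SimulationResult:
    """Recorded pressure/flow time series after warm-up discard.

    ``icp`` is the ventricular tap (node N2), ``p_cistern`` node N3,
    ``p_cranial_chamber`` node N1 (all mmHg gauge); ``q_spinal`` the flow in
    the first canal segment (C2-C3 level) in ml/min, caudal positive.
    ``cycle_marks`` index the start of each recorded cycle.
    """

    time: np.ndarray
    icp: np.ndarray
    p_cistern: np.ndarray
    p_cranial_chamber: np.ndarray
    p_spinal_chamber: np.ndarray
    q_spinal: np.ndarray
    cycle_marks: np.ndarray
    period: float

    @property
    def steps_per_cycle(self) -> int:
        return int(self.cycle_marks[1] - self.cycle_marks[0])

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_marks) - 1

    def _cycle_stack(self, series: np.ndarray) -> np.ndarray:
        n, s = self.n_cycles, self.steps_per_cycle
        return series[: n * s].reshape(n, s)

    def cycle_mean_flow(self) -> SampledWaveform:
        """Cycle-averaged spinal flow as a single-cycle waveform."""
        return SampledWaveform(period=self.period, values=self._cycle_stack(self.q_spinal).mean(axis=0))

    def cycle_mean_icp(self) -> SampledWaveform:
        return SampledWaveform(period=self.period, values=self._cycle_stack(self.icp).mean(axis=0))


def _pump_tables(pump: SampledWaveform, steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Pump flow at the integration grid points and midpoints of one cycle."""
    tp = np.append(pump.times, pump.period)
    vp = np.append(pump.values, pump.values[0])
    dt = pump.period / steps
    t_full = (np.arange(steps) * dt) % pump.period
    t_mid = ((np.arange(steps) + 0.5) * dt) % pump.period
    return np.interp(t_full, tp, vp), np.interp(t_mid, tp, vp)


def simulate(
    net: NetworkModel,
    pump: SampledWaveform,
    n_cycles: int = 9,
    warmup_cycles: int = 2,
    dt: Optional[float] = None,
) -> SimulationResult:
    """Integrate the network driven by the pump waveform.

    The pump must carry zero net volume per cycle (otherwise the sealed system
    would drift and the run is refused).  ``warmup_cycles`` full cycles are
    integrated and discarded before recording starts, mirroring the bench
    protocol of two pump rotations before data acquisition.  ``dt`` must
    divide the cycle period exactly; default ``period / 2048``.
    """
    if n_cycles < 1:
        raise InvalidParameterError("n_cycles must be >= 1")
    if warmup_cycles < 0:
        raise InvalidParameterError("warmup_cycles must be >= 0")
    net_vol = pump.cycle_volume()
    if abs(net_vol) > _NET_VOLUME_TOL:
        raise DriftError(
            f"pump waveform carries {net_vol:.3e} ml net volume per cycle; "
            "volume-match it before simulating"
        )
    period = pump.period
    if dt is None:
        dt = period / 2048.0
    steps = int(round(period / dt))
    if steps < 2 or abs(steps * dt - period) > 1e-9 * period:
        raise GridMismatchError(f"dt={dt} does not divide the period {period}")
    dt = period / steps

    # unpack scalars for the tight loop
    chc, chs = net.cranial_chamber, net.spinal_chamber
    p0c, v0c, lamc = chc.p0_abs, chc.v0_air, chc.lam
    p0s, v0s, lams = chs.p0_abs, chs.v0_air, chs.lam
    atm = net.atm_mmHg
    big = 1e12  # conductance stand-in for a zero-resistance branch
    g_par = 1.0 / net.r_parenchyma_path if net.r_parenchyma_path > 0 else big
    g_v2 = 1.0 / net.r_valve2.r if net.r_valve2.r > 0 else big
    ga = g_par + g_v2
    gc = 1.0 / net.r_canal
    w = ga / (ga + gc)

    def rhs(v1: float, v4: float, qp: float) -> tuple[float, float]:
        p1 = p0c * (v0c / v1) ** lamc - atm
        p4 = p0s * (v0s / v4) ** lams - atm
        p3 = w * p1 + (1.0 - w) * p4
        q_out = (p1 - p3) * ga  # = q_spinal by node balance at N3
        return -(qp - q_out) / 60.0, -q_out / 60.0

    q_grid, q_mid = _pump_tables(pump, steps)
    state = operating_point(net, pump)
    v1, v4 = state.v_air_cranial, state.v_air_spinal

    total = (warmup_cycles + n_cycles) * steps
    rec_start = warmup_cycles * steps
    n_rec = n_cycles * steps + 1
    rec_v1 = np.empty(n_rec)
    rec_v4 = np.empty(n_rec)
    j = 0
    if rec_start == 0:
        rec_v1[0], rec_v4[0] = v1, v4
        j = 1
    h = dt
    for k in range(total):
        i = k % steps
        qa, qm, qb = q_grid[i], q_mid[i], q_grid[(i + 1) % steps]
        k1a, k1b = rhs(v1, v4, qa)
        k2a, k2b = rhs(v1 + 0.5 * h * k1a, v4 + 0.5 * h * k1b, qm)
        k3a, k3b = rhs(v1 + 0.5 * h * k2a, v4 + 0.5 * h * k2b, qm)
        k4a, k4b = rhs(v1 + h * k3a, v4 + h * k3b, qb)
        v1 += h / 6.0 * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
        v4 += h / 6.0 * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
        if k + 1 >= rec_start:
            rec_v1[j], rec_v4[j] = v1, v4
            j += 1

    # algebraic post-processing on the recorded states (vectorized)
    p1 = p0c * (v0c / rec_v1) ** lamc - atm
    p4 = p0s * (v0s / rec_v4) ** lams - atm
    p3 = w * p1 + (1.0 - w) * p4
    q_spinal = (p3 - p4) * gc
    q_par = (p1 - p3) * g_par
    icp = p1 - q_par * net.r_valve1.r

    time = np.arange(n_rec) * dt
    cycle_marks = np.arange(n_cycles + 1) * steps
    return SimulationResult(
        time=time,
        icp=icp,
        p_cistern=p3,
        p_cranial_chamber=p1,
        p_spinal_chamber=p4,
        q_spinal=q_spinal,
        cycle_marks=cycle_marks,
        period=period,
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the valve-resistance calibration.

    The spinal flow depends on the two cranial paths only through their
    parallel combination, so the individually reported resistances are one
    representative of a one-parameter family; ``r_parallel`` is the
    identifiable quantity.
    """

    r_parenchyma_path: float
    r_valve2: float
    achieved_caudal_max: float
    achieved_cranial_max: float
    residuals: tuple[float, float]
    converged: bool
    n_evaluations: int
    network: NetworkModel

    @property
    def r_parallel(self) -> float:
        g = 0.0
        if self.r_parenchyma_path > 0:
            g += 1.0 / self.r_parenchyma_path
        if self.r_valve2 > 0:
            g += 1.0 / self.r_valve2
        return 1.0 / g


def _with_resistances(net: NetworkModel, r_path: float, r_v2: float) -> NetworkModel:
    split = 0.5
    if net.r_parenchyma_path > 0:
        split = net.r_valve1.r / net.r_parenchyma_path
    return replace(
        net,
        r_valve1=replace(net.r_valve1, r=split * r_path),
        r_aqueduct=(1.0 - split) * r_path,
        r_valve2=replace(net.r_valve2, r=r_v2),
    )


def calibrate_resistances(
    net: NetworkModel,
    pump: SampledWaveform,
    target_caudal_max: float,
    target_cranial_max: float,
    *,
    bounds: tuple[float, float] = (1e-4, 1.0),
    grid_points: int = 8,
    dt_divisor: int = 512,
    warmup_cycles: int = 2,
    record_cycles: int = 2,
    rel_tol: float = 0.05,
    maxiter: int = 150,
) -> CalibrationResult:
    """Fit the two valve resistances to target spinal-flow extrema.

    Deterministic bounded search: an ``grid_points`` x ``grid_points``
    log-spaced scan of (parenchyma-path, Valve-2) resistance followed by a
    derivative-free Nelder-Mead refinement in log space.  The objective is the
    summed squared relative mismatch of the cycle-mean spinal-flow extrema.
    Failure to reach ``rel_tol`` is reported via ``converged=False`` (with
    residuals), not raised.
    """
    if not (target_caudal_max > 0 > target_cranial_max):
        raise InvalidParameterError("targets must be (positive caudal, negative cranial)")
    dt = pump.period / dt_divisor
    n_evals = 0

    def extrema(log_r: np.ndarray) -> tuple[float, float]:
        nonlocal n_evals
        n_evals += 1
        trial = _with_resistances(net, 10.0 ** log_r[0], 10.0 ** log_r[1])
        res = simulate(trial, pump, n_cycles=record_cycles, warmup_cycles=warmup_cycles, dt=dt)
        q = res.cycle_mean_flow().values
        return float(q.max()), float(q.min())

    def cost(log_r: np.ndarray) -> float:
        mx, mn = extrema(log_r)
        return (
            ((mx - target_caudal_max) / target_caudal_max) ** 2
            + ((mn - target_cranial_max) / target_cranial_max) ** 2
        )

    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    grid = np.linspace(lo, hi, grid_points)
    best_x, best_c = None, np.inf
    for a in grid:
        for b in grid:
            c = cost(np.array([a, b]))
            if c < best_c:
                best_c, best_x = c, np.array([a, b])

    opt = optimize.minimize(
        cost,
        best_x,
        method="Nelder-Mead",
        bounds=[(lo, hi), (lo, hi)],
        options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-10},
    )
    x = opt.x if opt.fun <= best_c else best_x
    r_path, r_v2 = float(10.0 ** x[0]), float(10.0 ** x[1])
    fitted = _with_resistances(net, r_path, r_v2)

    # achieved extrema at full resolution
    res = simulate(fitted, pump, n_cycles=record_cycles, warmup_cycles=warmup_cycles)
    q = res.cycle_mean_flow().values
    mx, mn = float(q.max()), float(q.min())
    residuals = (
        (mx - target_caudal_max) / target_caudal_max,
        (mn - target_cranial_max) / abs(target_cranial_max),
    )
    converged = max(abs(residuals[0]), abs(residuals[1])) <= rel_tol
    return CalibrationResult(
        r_parenchyma_path=r_path,
        r_valve2=r_v2,
        achieved_caudal_max=mx,
        achieved_cranial_max=mn,
        residuals=residuals,
        converged=converged,
        n_evaluations=n_evals,
        network=fitted,
    )
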