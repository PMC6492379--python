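"""Cam-disc synthesis: from a pump flow waveform to a polar cam contour.

The piston pump realizes an arbitrary periodic flow by letting a cam disc,
rotating once per cardiac cycle, push a syringe piston.  The required piston
displacement is the running integral of the flow divided by the piston area;
mapping that displacement onto the cam radius (radial knife-edge follower
model, r(theta) = base_radius + x(theta)) is the displacement (hodograph)
transformation.  A cam contour only closes if the flow carries zero net
volume per cycle.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import FormatError, InvalidParameterError, OpenProfileError
from .waveforms import SampledWaveform

#: Default syringe bore (2 ml syringe class), mm.
DEFAULT_BORE_MM = 9.0

#: Default cam base-circle radius, mm.
DEFAULT_BASE_RADIUS_MM = 20.0

_CLOSURE_TOL_ML = 1e-6


def piston_area_mm2(bore_mm: float = DEFAULT_BORE_MM) -> float:
    """Piston cross-section (mm^2) of a syringe with the given bore."""
    if bore_mm <= 0:
        raise InvalidParameterError("bore must be positive")
    return float(np.pi * (bore_mm / 2.0) ** 2)


@dataclass(frozen=True)
class CamProfile:
    """Polar cam contour: radius vs angle on a uniform [0, 2*pi) grid."""

    angles: np.ndarray
    radii: np.ndarray
    base_radius: float
    piston_area: float  # mm^2

    def __post_init__(self):
        angles = np.asarray(self.angles, float)
        radii = np.asarray(self.radii, float)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "radii", radii)
        if self.base_radius <= 0:
            raise InvalidParameterError("base radius must be positive")
        if angles.shape != radii.shape or angles.ndim != 1:
            raise InvalidParameterError("angles and radii must be matching 1-D arrays")
        if np.any(radii < self.base_radius - 1e-9):
            raise InvalidParameterError("cam radius undercuts the base circle")

    @property
    def lift(self) -> np.ndarray:
        return self.radii - self.base_radius

    @property
    def max_lift(self) -> float:
        return float(self.lift.max())


def displacement_profile(
    pump: SampledWaveform, piston_area: float
) -> tuple[np.ndarray, np.ndarray]:
    """Piston displacement x(theta) in mm over one cam revolution.

    x is the cumulative displaced volume divided by the piston area,
    normalized so min x = 0 (the follower rides the base circle at the
    bottom of the stroke).  Raises :class:`OpenProfileError` when the flow
    carries net volume (the contour would not close).
    """
    if piston_area <= 0:
        raise InvalidParameterError("piston area must be positive")
    net = pump.cycle_volume()
    if abs(net) > _CLOSURE_TOL_ML:
        raise OpenProfileError(
            f"pump waveform has net cycle volume {net:.3e} ml; cam contour would not close"
        )
    # ml/min -> mm^3/s, integrate over the cycle
    vol_mm3 = cumulative_trapezoid(pump.values * (1000.0 / 60.0), pump.times, initial=0.0)
    x = vol_mm3 / piston_area
    x = x - x.min()
    theta = pump.times / pump.period * 2.0 * np.pi
    return theta, x


def cam_profile(
    theta: np.ndarray,
    x: np.ndarray,
    base_radius: float = DEFAULT_BASE_RADIUS_MM,
    piston_area: float = piston_area_mm2(),
) -> CamProfile:
    """Radial knife-edge follower contour r(theta) = base_radius + x(theta)."""
    return CamProfile(
        angles=np.asarray(theta, float),
        radii=base_radius + np.asarray(x, float),
        base_radius=base_radius,
        piston_area=piston_area,
    )


def cam_from_waveform(
    pump: SampledWaveform,
    base_radius: float = DEFAULT_BASE_RADIUS_MM,
    bore_mm: float = DEFAULT_BORE_MM,
) -> CamProfile:
    """Convenience pipeline: flow waveform -> displacement -> cam contour."""
    area = piston_area_mm2(bore_mm)
    theta, x = displacement_profile(pump, area)
    return cam_profile(theta, x, base_radius=base_radius, piston_area=area)


def export_profile(profile: CamProfile, path: str | Path) -> None:
    """Write the contour as CSV: polar and Cartesian columns plus metadata.

    Metadata lines (piston area, base radius, stroke volume implied by the
    maximum lift) are ``#``-prefixed; numeric values use ``repr`` precision so
    a re-import reproduces the radii bitwise.
    """
    path = Path(path)
    sv_ml = profile.max_lift * profile.piston_area / 1000.0
    with path.open("w", newline="") as fh:
        fh.write(f"# piston_area_mm2 = {profile.piston_area!r}\n")
        fh.write(f"# base_radius_mm = {profile.base_radius!r}\n")
        fh.write(f"# stroke_volume_ml = {sv_ml!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["theta_rad", "r_mm", "x_mm", "y_mm"])
        for th, r in zip(profile.angles, profile.radii):
            writer.writerow([repr(float(th)), repr(float(r)),
                             repr(float(r * np.cos(th))), repr(float(r * np.sin(th)))])


def load_profile(path: str | Path) -> CamProfile:
    """Re-import a contour written by :func:`export_profile`."""
    path = Path(path)
    meta: dict[str, float] = {}
    angles: list[float] = []
    radii: list[float] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = float(val)
                continue
            if line.startswith("theta_rad"):
                continue
            fields = line.split(",")
            if len(fields) < 2:
                raise FormatError(f"malformed cam profile row: {line!r}")
            angles.append(float(fields[0]))
            radii.append(float(fields[1]))
    if "base_radius_mm" not in meta or "piston_area_mm2" not in meta:
        raise FormatError("cam profile file lacks metadata header")
    return CamProfile(
        angles=np.asarray(angles),
        radii=np.asarray(radii),
        base_radius=meta["base_radius_mm"],
        piston_area=meta["piston_area_mm2"],
    )
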