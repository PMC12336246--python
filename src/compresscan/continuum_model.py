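"""Interface pressure and soft-tissue deformation from continuum elasticity.

The chain of operations mirrors the analytical route from fabric to tissue:

1. circumferential garment stretch -> interface pressure (elastic
   half-space surface-deflection relation);
2. pressurized-annulus (thick-walled cylinder) stress field for the fabric
   layer, with exact boundary conditions;
3. linear-elastic and Neo-Hookean-parameterized static tissue deformation,
   the latter being an exact reparameterization of the former through the
   (C1, D1) <-> (Es, vs) conversion;
4. forced damped dynamics of the garment mass integrated with classical
   RK4, coupled back into tissue displacement through an effective
   pressure.

Lengths are mm at the public API; conversion to SI happens here only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import IntegrationError, InvalidGeometryError, InvalidTissueError
from .fabric_mechanics import FabricProperties

__all__ = [
    "LimbSectionGeometry",
    "TissueModel",
    "LameSolution",
    "DynamicSystem",
    "DynamicTrace",
    "SectionPrediction",
    "interface_pressure",
    "lame_field",
    "neo_hookean_params",
    "elastic_from_neo_hookean",
    "static_deformation_linear",
    "static_deformation_nh",
    "simulate_dynamic",
    "predict_sections",
    "contact_area_m2",
]

_MM_TO_M = 1e-3
_M_TO_MM = 1e3

#: Default damping of the garment-tissue interface, N*s/m.
DEFAULT_DAMPING = 5.0
#: Default RK4 step, s.
DEFAULT_DT = 1e-4
#: Default vertical-vibration forcing frequency, Hz.
DEFAULT_FORCING_HZ = 60.0


@dataclass(frozen=True)
class LimbSectionGeometry:
    """Geometry of one horizontal body section under a garment.

    All lengths in mm.  ``garment_stretch`` is the radial extension of the
    worn fabric; when ``None`` it is derived from the limb/garment
    circumference mismatch, clamped at zero.
    """

    section_id: int
    limb_radius: float
    garment_circumference: float
    section_height: float
    garment_stretch: Optional[float] = None

    def __post_init__(self):
        if self.limb_radius <= 0:
            raise InvalidGeometryError(
                f"section {self.section_id}: limb_radius must be > 0"
            )
        if self.garment_circumference <= 0:
            raise InvalidGeometryError(
                f"section {self.section_id}: garment_circumference must be > 0"
            )
        if self.garment_stretch is not None and self.garment_stretch < 0:
            raise InvalidGeometryError(
                f"section {self.section_id}: garment_stretch must be >= 0"
            )

    @property
    def stretch(self) -> float:
        """Radial fabric extension ul in mm (explicit value or derived)."""
        if self.garment_stretch is not None:
            return self.garment_stretch
        return max(0.0, self.limb_radius - self.garment_circumference / (2 * np.pi))


@dataclass(frozen=True)
class TissueModel:
    """Soft-tissue constitutive parameters: linear (Es, vs) and the
    consistent Neo-Hookean pair (C1, D1)."""

    Es: float
    vs: float
    C1: float = field(default=0.0)
    D1: float = field(default=0.0)

    def __post_init__(self):
        if self.Es <= 0:
            raise InvalidTissueError(f"Es={self.Es} must be > 0")
        if not (0 <= self.vs < 0.5):
            raise InvalidTissueError(f"vs={self.vs} outside [0, 0.5)")
        if self.C1 == 0.0 and self.D1 == 0.0:
            c1, d1 = neo_hookean_params(self.Es, self.vs)
            object.__setattr__(self, "C1", c1)
            object.__setattr__(self, "D1", d1)
        else:
            c1, d1 = neo_hookean_params(self.Es, self.vs)
            if not (
                np.isclose(c1, self.C1, rtol=1e-6)
                and np.isclose(d1, self.D1, rtol=1e-6)
            ):
                raise InvalidTissueError(
                    f"(C1={self.C1}, D1={self.D1}) inconsistent with "
                    f"(Es={self.Es}, vs={self.vs}); expected ({c1:.6g}, {d1:.6g})"
                )

    @classmethod
    def from_neo_hookean(cls, C1: float, D1: float) -> "TissueModel":
        """Build from (C1, D1), recovering the consistent (Es, vs)."""
        Es, vs = elastic_from_neo_hookean(C1, D1)
        return cls(Es=Es, vs=vs, C1=C1, D1=D1)


@dataclass(frozen=True)
class LameSolution:
    """Stress field of a pressurized annulus a < r < b (mm), loaded by
    internal pressure P (Pa): sigma_rho = A/r^2 + 2C, sigma_phi = -A/r^2 + 2C,
    zero shear."""

    inner_radius: float
    outer_radius: float
    pressure: float
    A: float
    C: float

    def radial_stress(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return self.A / r**2 + 2 * self.C

    def hoop_stress(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return -self.A / r**2 + 2 * self.C

    def shear_stress(self, r) -> np.ndarray:
        return np.zeros_like(np.asarray(r, dtype=float))


@dataclass
class DynamicSystem:
    """Forced, damped garment-mass system m*u'' + k*u' = F(t).

    ``forcing`` maps time (s) to force (N).  ``static_pressure`` is the
    baseline interface pressure (Pa); ``contact_area`` (m^2) converts
    inertial force to pressure.  ``forcing_frequency`` (Hz), when set,
    defines the cycle length for per-cycle summaries.
    """

    mass: float
    damping: float
    forcing: Callable[[float], float]
    static_pressure: float
    contact_area: float
    initial_displacement: float = 0.0
    initial_velocity: float = 0.0
    forcing_frequency: Optional[float] = None

    def __post_init__(self):
        if self.mass <= 0:
            raise InvalidGeometryError("dynamic system: mass must be > 0")
        if self.damping < 0:
            raise InvalidGeometryError("dynamic system: damping must be >= 0")
        if self.contact_area <= 0:
            raise InvalidGeometryError("dynamic system: contact_area must be > 0")


@dataclass(frozen=True)
class DynamicTrace:
    """Time series of tissue displacement under inertial forcing.

    ``tissue_displacement`` is in mm; ``garment_displacement`` (m) and
    ``garment_velocity`` (m/s) expose the integrated oscillator state.
    ``cycle_summary`` holds per-cycle max/min/mean of the tissue
    displacement.
    """

    times: np.ndarray
    tissue_displacement: np.ndarray
    garment_displacement: np.ndarray
    garment_velocity: np.ndarray
    cycle_summary: dict

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise IntegrationError("trace times must be strictly increasing")
        if len(self.times) != len(self.tissue_displacement):
            raise IntegrationError("trace arrays must have equal length")


def contact_area_m2(limb_radius_mm: float, section_height_mm: float) -> float:
    """Lateral contact area 2*pi*R*h of one section, converted to m^2."""
    if limb_radius_mm <= 0 or section_height_mm <= 0:
        raise InvalidGeometryError("contact area needs positive radius and height")
    return 2 * np.pi * (limb_radius_mm * _MM_TO_M) * (section_height_mm * _MM_TO_M)


def interface_pressure(geom: LimbSectionGeometry, fabric: FabricProperties) -> float:
    """Interface pressure P (Pa) from radial garment stretch.

    Inverts the surface-deflection relation
    ``ul = 2 * (1 - vxy^2) * P * R / (pi * Ex)``:
    P grows linearly with stretch and course modulus, and inversely with
    limb radius.
    """
    ul = geom.stretch
    if ul == 0.0:
        return 0.0
    return float(
        np.pi * fabric.Ex * ul / (2.0 * (1.0 - fabric.vxy**2) * geom.limb_radius)
    )


def lame_field(a: float, b: float, P: float) -> LameSolution:
    """Stress field of the fabric annulus under internal pressure P.

    Solves the two boundary conditions sigma_rho(a) = -P, sigma_rho(b) = 0
    for the integration constants A and C.
    """
    if not (b > a > 0):
        raise InvalidGeometryError(f"annulus needs b > a > 0, got a={a}, b={b}")
    if P < 0:
        raise InvalidGeometryError(f"pressure must be >= 0, got {P}")
    denom = b**2 - a**2
    A = -P * a**2 * b**2 / denom
    C = 0.5 * P * a**2 / denom
    return LameSolution(inner_radius=a, outer_radius=b, pressure=P, A=A, C=C)


def neo_hookean_params(Es: float, vs: float) -> tuple[float, float]:
    """(C1, D1) from Young's modulus and Poisson's ratio.

    C1 = Es / (4 (1 + vs)); D1 = 6 (1 - 2 vs) / Es.  At vs = 0.5 the
    material is incompressible and D1 = 0 (warned, not raised).
    """
    if Es <= 0:
        raise InvalidTissueError(f"Es={Es} must be > 0")
    if not (0 <= vs <= 0.5):
        raise InvalidTissueError(f"vs={vs} outside [0, 0.5]")
    if vs == 0.5:
        warnings.warn("vs = 0.5: incompressible limit, D1 = 0", stacklevel=2)
    C1 = Es / (4.0 * (1.0 + vs))
    D1 = 6.0 * (1.0 - 2.0 * vs) / Es
    return C1, D1


def elastic_from_neo_hookean(C1: float, D1: float) -> tuple[float, float]:
    """Inverse conversion: (Es, vs) from (C1, D1).

    Joint solution of C1 = Es/(4(1+vs)) and D1 = 6(1-2vs)/Es:
    vs = (6 - 4 C1 D1) / (12 + 4 C1 D1), Es = 4 C1 (1 + vs).
    """
    if C1 <= 0 or D1 < 0:
        raise InvalidTissueError(f"need C1 > 0 and D1 >= 0, got C1={C1}, D1={D1}")
    cd = C1 * D1
    vs = (6.0 - 4.0 * cd) / (12.0 + 4.0 * cd)
    Es = 4.0 * C1 * (1.0 + vs)
    return Es, vs


def static_deformation_linear(P: float, R: float, tissue: TissueModel) -> float:
    """Static tissue deformation us = (1 - vs) * P * R / Es, in mm."""
    if P < 0:
        raise InvalidGeometryError(f"pressure must be >= 0, got {P}")
    if tissue.Es <= 0:
        raise InvalidTissueError(f"Es={tissue.Es} must be > 0")
    return (1.0 - tissue.vs) * P * R / tissue.Es


def static_deformation_nh(P: float, R: float, tissue: TissueModel) -> float:
    """Neo-Hookean-parameterized static deformation, in mm.

    Defined as the exact (C1, D1) reparameterization of the linear form;
    equals :func:`static_deformation_linear` under the parameter
    conversion by construction.
    """
    if P < 0:
        raise InvalidGeometryError(f"pressure must be >= 0, got {P}")
    if tissue.C1 <= 0 or tissue.D1 < 0:
        raise InvalidTissueError(
            f"need C1 > 0 and D1 >= 0, got C1={tissue.C1}, D1={tissue.D1}"
        )
    Es, vs = elastic_from_neo_hookean(tissue.C1, tissue.D1)
    return (1.0 - vs) * P * R / Es


def _rk4(deriv, y0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Classical 4th-order Runge-Kutta over a fixed grid."""
    out = np.empty((len(times), len(y0)))
    out[0] = y0
    y = np.array(y0, dtype=float)
    for i in range(len(times) - 1):
        t = times[i]
        h = times[i + 1] - t
        k1 = deriv(t, y)
        k2 = deriv(t + 0.5 * h, y + 0.5 * h * k1)
        k3 = deriv(t + 0.5 * h, y + 0.5 * h * k2)
        k4 = deriv(t + h, y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state at t={times[i + 1]:.6g} s")
        out[i + 1] = y
    return out


def simulate_dynamic(
    sys: DynamicSystem,
    R: float,
    tissue: TissueModel,
    t_end: float,
    dt: float = DEFAULT_DT,
) -> DynamicTrace:
    """Integrate the garment oscillator and map it to tissue displacement.

    The oscillator m u'' + k u' = F(t) is advanced with classical RK4 on
    the state (u, u').  At every step the tissue displacement is the
    static response to the effective pressure
    ``max(0, P + F(t)/contact_area)``; the clamp encodes that the garment
    cannot pull the tissue outward.

    Parameters
    ----------
    R : float
        Limb cross-section radius, mm.
    t_end, dt : float
        Integration window and step, s.
    """
    if dt <= 0 or t_end <= dt:
        raise IntegrationError(f"need t_end > dt > 0, got t_end={t_end}, dt={dt}")
    n = int(round(t_end / dt))
    times = np.linspace(0.0, n * dt, n + 1)

    force = np.array([sys.forcing(t) for t in times], dtype=float)
    if not np.all(np.isfinite(force)):
        bad = times[~np.isfinite(force)][0]
        raise IntegrationError(f"non-finite forcing at t={bad:.6g} s")

    m, k = sys.mass, sys.damping

    def deriv(t, y):
        f = sys.forcing(t)
        return np.array([y[1], (f - k * y[1]) / m])

    y0 = np.array([sys.initial_displacement, sys.initial_velocity])
    state = _rk4(deriv, y0, times)

    eff_pressure = np.maximum(0.0, sys.static_pressure + force / sys.contact_area)
    Es, vs = elastic_from_neo_hookean(tissue.C1, tissue.D1)
    u_ds = (1.0 - vs) * eff_pressure * R / Es  # mm, linear in pressure

    summary = _cycle_summary(times, u_ds, sys.forcing_frequency)
    return DynamicTrace(
        times=times,
        tissue_displacement=u_ds,
        garment_displacement=state[:, 0],
        garment_velocity=state[:, 1],
        cycle_summary=summary,
    )


def _cycle_summary(times, values, frequency):
    """Per-cycle max/min/mean (whole trace when no frequency given)."""
    if not frequency or frequency <= 0:
        return {
            "max": [float(np.max(values))],
            "min": [float(np.min(values))],
            "mean": [float(np.mean(values))],
        }
    period = 1.0 / frequency
    n_cycles = int(np.floor(times[-1] / period))
    maxima, minima, means = [], [], []
    for c in range(max(n_cycles, 1)):
        mask = (times >= c * period) & (times < (c + 1) * period)
        if not np.any(mask):
            continue
        chunk = values[mask]
        maxima.append(float(np.max(chunk)))
        minima.append(float(np.min(chunk)))
        means.append(float(np.mean(chunk)))
    return {"max": maxima, "min": minima, "mean": means}


@dataclass(frozen=True)
class SectionPrediction:
    """Predicted static response of one section."""

    section_id: int
    stretch: float  # mm
    pressure: float  # Pa
    deformation: float  # mm


def predict_sections(
    fabric: FabricProperties,
    sections: Sequence[LimbSectionGeometry],
    tissue: TissueModel,
) -> tuple[list[SectionPrediction], float]:
    """Static deformation per section plus the mean over sections."""
    if not sections:
        raise InvalidGeometryError("sections must be non-empty")
    preds = []
    for geom in sections:
        P = interface_pressure(geom, fabric)
        us = static_deformation_nh(P, geom.limb_radius, tissue)
        preds.append(
            SectionPrediction(
                section_id=geom.section_id,
                stretch=geom.stretch,
                pressure=P,
                deformation=us,
            )
        )
    mean = float(np.mean([p.deformation for p in preds]))
    return preds, mean
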