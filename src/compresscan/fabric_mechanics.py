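"""Orthotropic fabric constants from mechanical-test records.

Knit fabrics are treated as orthotropic laminae: distinct Young's moduli
along the course (x) and wale (y) loop directions, an in-plane shear
modulus, and one independent Poisson's ratio.  Moduli are estimated as
fitted slopes of stress--strain records; the compliance matrix maps a
plane-stress vector (sigma_x, sigma_y, tau_xy) to engineering strains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "Direction",
    "StressStrainRecord",
    "FabricProperties",
    "ComplianceMatrix",
    "estimate_modulus",
    "estimate_poisson_ratio",
    "estimate_fabric_properties",
    "build_compliance",
    "strain_from_stress",
    "read_records_csv",
    "load_fabric_table",
    "load_garment_sections",
    "SECTION_HEIGHTS_MM",
]

#: Vertical extent of each garment section, top (hip) to bottom (calf), mm.
SECTION_HEIGHTS_MM = {1: 75.0, 2: 90.0, 3: 95.0, 4: 185.0, 5: 100.0, 6: 195.0}

#: Default garment section mass when none is supplied, kg.
DEFAULT_GARMENT_MASS_KG = 0.2


class Direction(str, Enum):
    """Loading direction of a mechanical test record."""

    COURSE = "x"
    WALE = "y"
    SHEAR = "shear"


@dataclass(frozen=True)
class StressStrainRecord:
    """One uniaxial-tension or pure-shear test record.

    Parameters
    ----------
    direction : Direction
        Loading direction; ``SHEAR`` records hold (tau, gamma) pairs.
    stress : array-like of float
        Normal stress sigma or shear stress tau, Pa.
    strain : array-like of float
        Engineering strain (dimensionless), non-decreasing.
    transverse_strain : array-like of float, optional
        Strain perpendicular to the load, required for Poisson's ratio.
    label : str
        Free-text identifier used in error messages.
    """

    direction: Direction
    stress: np.ndarray
    strain: np.ndarray
    transverse_strain: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self):
        stress = np.asarray(self.stress, dtype=float)
        strain = np.asarray(self.strain, dtype=float)
        object.__setattr__(self, "stress", stress)
        object.__setattr__(self, "strain", strain)
        if self.transverse_strain is not None:
            tr = np.asarray(self.transverse_strain, dtype=float)
            object.__setattr__(self, "transverse_strain", tr)
            if tr.shape != strain.shape:
                raise InvalidInputError(
                    f"record {self.label!r}: transverse_strain length "
                    f"{tr.size} != strain length {strain.size}"
                )
        if stress.ndim != 1 or strain.ndim != 1:
            raise InvalidInputError(f"record {self.label!r}: sequences must be 1-D")
        if stress.size != strain.size:
            raise InvalidInputError(
                f"record {self.label!r}: stress length {stress.size} != "
                f"strain length {strain.size}"
            )
        if stress.size < 2:
            raise InvalidInputError(f"record {self.label!r}: needs >= 2 points")
        if not np.all(np.isfinite(strain)) or not np.all(np.isfinite(stress)):
            raise InvalidInputError(f"record {self.label!r}: non-finite values")
        if np.any(np.diff(strain) < 0):
            raise InvalidInputError(
                f"record {self.label!r}: strain must be non-decreasing"
            )


@dataclass(frozen=True)
class FabricProperties:
    """Orthotropic constants of one legging fabric.

    ``Ex``/``Ey`` are course/wale Young's moduli (Pa), ``Gxy`` the in-plane
    shear modulus (Pa), ``vxy`` the course-load Poisson's ratio, and
    ``mass`` the garment section mass (kg) used by the dynamic model.
    """

    Ex: float
    Ey: float
    Gxy: float
    vxy: float
    mass: float = DEFAULT_GARMENT_MASS_KG
    label: str = ""

    def __post_init__(self):
        if not (self.Ex > 0 and self.Ey > 0 and self.Gxy > 0):
            raise InvalidInputError(
                f"fabric {self.label!r}: moduli must be positive "
                f"(Ex={self.Ex}, Ey={self.Ey}, Gxy={self.Gxy})"
            )
        if not (0 <= self.vxy < 0.5):
            raise InvalidInputError(
                f"fabric {self.label!r}: vxy={self.vxy} outside [0, 0.5)"
            )
        if self.mass < 0:
            raise InvalidInputError(f"fabric {self.label!r}: negative mass")


@dataclass(frozen=True)
class ComplianceMatrix:
    """3x3 plane-stress compliance, 1/Pa, orthotropic sparsity pattern."""

    entries: np.ndarray = field(repr=False)

    def __post_init__(self):
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        if entries.shape != (3, 3):
            raise InvalidInputError("compliance matrix must be 3x3")
        off = [entries[0, 2], entries[1, 2], entries[2, 0], entries[2, 1]]
        if any(v != 0.0 for v in off):
            raise InvalidInputError("orthotropic compliance: normal-shear coupling must be zero")
        if entries[0, 1] != entries[1, 0]:
            raise InvalidInputError("compliance matrix must be symmetric")
        if np.any(np.diag(entries) <= 0):
            raise InvalidInputError("compliance diagonal must be positive")


def _fit_slope(x: np.ndarray, y: np.ndarray, label: str) -> float:
    """OLS slope of y on x, with intercept (robust to load-cell offset)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:
        raise InvalidInputError(f"record {label!r}: zero strain range, slope undefined")
    xm = x - x.mean()
    return float(np.dot(xm, y - y.mean()) / np.dot(xm, xm))


def estimate_modulus(record: StressStrainRecord) -> float:
    """Fitted slope of stress vs strain: Ex, Ey, or (shear) Gxy, in Pa."""
    slope = _fit_slope(record.strain, record.stress, record.label)
    if slope <= 0:
        warnings.warn(
            f"record {record.label!r}: non-positive fitted modulus {slope:.3g} Pa",
            stacklevel=2,
        )
    return slope


def estimate_poisson_ratio(record: StressStrainRecord) -> float:
    """Poisson's ratio v = -(slope of transverse vs axial strain).

    Warns (does not raise) when the estimate leaves [0, 0.5).
    """
    if record.transverse_strain is None:
        raise InvalidInputError(
            f"record {record.label!r}: transverse_strain required for Poisson's ratio"
        )
    if np.ptp(record.strain) == 0:
        raise InvalidInputError(f"record {record.label!r}: zero strain range")
    v = -_fit_slope(record.strain, record.transverse_strain, record.label)
    if not (0 <= v < 0.5):
        warnings.warn(
            f"record {record.label!r}: Poisson ratio {v:.4f} outside [0, 0.5)",
            stacklevel=2,
        )
    return v


def estimate_fabric_properties(
    records: Sequence[StressStrainRecord],
    mass: float = DEFAULT_GARMENT_MASS_KG,
    label: str = "",
) -> FabricProperties:
    """Fit (Ex, Ey, Gxy, vxy) from a battery of test records.

    Expects at least one record per direction; the course-direction record
    must carry transverse strain.  Multiple records per direction are
    averaged.
    """
    moduli: dict[Direction, list[float]] = {d: [] for d in Direction}
    poissons: list[float] = []
    for rec in records:
        moduli[rec.direction].append(estimate_modulus(rec))
        if rec.direction is Direction.COURSE and rec.transverse_strain is not None:
            poissons.append(estimate_poisson_ratio(rec))
    for d in (Direction.COURSE, Direction.WALE, Direction.SHEAR):
        if not moduli[d]:
            raise InvalidInputError(f"no record for direction {d.value!r}")
    if not poissons:
        raise InvalidInputError("no course record with transverse strain; cannot fit vxy")
    return FabricProperties(
        Ex=float(np.mean(moduli[Direction.COURSE])),
        Ey=float(np.mean(moduli[Direction.WALE])),
        Gxy=float(np.mean(moduli[Direction.SHEAR])),
        vxy=float(np.mean(poissons)),
        mass=mass,
        label=label,
    )


def build_compliance(props: FabricProperties) -> ComplianceMatrix:
    """Orthotropic compliance with reciprocity: both off-diagonals -vxy/Ex."""
    s12 = -props.vxy / props.Ex
    entries = np.array(
        [
            [1.0 / props.Ex, s12, 0.0],
            [s12, 1.0 / props.Ey, 0.0],
            [0.0, 0.0, 1.0 / props.Gxy],
        ]
    )
    return ComplianceMatrix(entries=entries)


def strain_from_stress(S: ComplianceMatrix, stress) -> np.ndarray:
    """Strains (eps_x, eps_y, gamma_xy) for a plane-stress vector in Pa."""
    stress = np.asarray(stress, dtype=float)
    if stress.shape != (3,):
        raise InvalidInputError("stress must be a 3-vector (sigma_x, sigma_y, tau_xy)")
    return S.entries @ stress


def read_records_csv(path) -> list[StressStrainRecord]:
    """Read test records from CSV with columns
    ``direction,stress_pa,strain,transverse_strain``.

    ``direction`` is one of ``x``, ``y``, ``shear``; blank transverse
    strains are allowed for wale/shear rows.  Rows are grouped by
    direction, in file order.
    """
    df = pd.read_csv(path)
    required = {"direction", "stress_pa", "strain"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for direction, group in df.groupby("direction", sort=False):
        d = Direction(direction)
        tr = None
        if "transverse_strain" in group and group["transverse_strain"].notna().all():
            tr = group["transverse_strain"].to_numpy(dtype=float)
        records.append(
            StressStrainRecord(
                direction=d,
                stress=group["stress_pa"].to_numpy(dtype=float),
                strain=group["strain"].to_numpy(dtype=float),
                transverse_strain=tr,
                label=f"{Path(path).name}:{d.value}",
            )
        )
    return records


def _data_path(name: str):
    return resources.files("compresscan.data").joinpath(name)


def load_fabric_table() -> pd.DataFrame:
    """Bundled reference table of the five legging fabrics (Pa units)."""
    with resources.as_file(_data_path("fabric_samples.csv")) as p:
        return pd.read_csv(p)


def load_garment_sections() -> pd.DataFrame:
    """Bundled garment circumference/height table, mm, per sample and section."""
    with resources.as_file(_data_path("garment_sections.csv")) as p:
        return pd.read_csv(p)


def fabric_from_table(sample: int, mass: float = DEFAULT_GARMENT_MASS_KG) -> FabricProperties:
    """Construct :class:`FabricProperties` for one bundled sample (1-5)."""
    table = load_fabric_table()
    row = table[table["sample"] == sample]
    if row.empty:
        raise InvalidInputError(f"no bundled fabric sample {sample}")
    r = row.iloc[0]
    return FabricProperties(
        Ex=float(r["Ex_pa"]),
        Ey=float(r["Ey_pa"]),
        Gxy=float(r["Gxy_pa"]),
        vxy=float(r["vxy"]),
        mass=mass,
        label=f"sample-{sample}",
    )
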