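"""Ground-truth fixture generators for the whole measurement pipeline.

Every generator is a pure function of its spec plus a seed, and returns
(or writes next to the data) the exact ground truth needed to score the
downstream measurement.  Contours are Fourier polar curves, which are
star-shaped by construction whenever the base radius exceeds the summed
harmonic amplitudes.

The polar parameterization matches the measurement convention in
:mod:`compresscan.scan_geometry`: angle 0 = anterior (+y), increasing
counter-clockwise, point = center + r(t) * (-sin t, cos t).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .continuum_model import (
    LimbSectionGeometry,
    TissueModel,
    predict_sections,
)
from .errors import InvalidFieldError, InvalidSpecError
from .fabric_mechanics import (
    Direction,
    FabricProperties,
    StressStrainRecord,
    load_fabric_table,
    load_garment_sections,
)
from .scan_geometry import VibrationSequence, centroid, save_stl_ascii, vertex_angles

__all__ = [
    "ContourSpec",
    "DeformationFieldSpec",
    "DeformedContour",
    "make_contour",
    "deform_contour",
    "render_contour",
    "make_limb_mesh",
    "loft_mesh",
    "combine_meshes",
    "make_stress_strain",
    "make_fabric_records",
    "make_vibration",
    "write_fixture_battery",
]

MARKER_YELLOW = (255, 255, 0)


@dataclass(frozen=True)
class ContourSpec:
    """Fourier polar contour r(t) = base_radius + sum a_k cos(k t + phi_k)."""

    base_radius: float  # mm
    fourier_amplitudes: tuple = ()  # (harmonic k, amplitude mm, phase rad)
    center: tuple[float, float] = (0.0, 0.0)
    n_vertices: int = 720
    radial_noise_sd: float = 0.0  # mm, optional jitter
    seed: int = 0

    def __post_init__(self):
        total = sum(abs(a) for _, a, _ in self.fourier_amplitudes)
        if self.base_radius <= total + 3.0 * self.radial_noise_sd:
            raise InvalidSpecError(
                f"base_radius {self.base_radius} must exceed total harmonic "
                f"amplitude {total} (+ noise) to stay star-shaped"
            )
        if self.n_vertices < 8:
            raise InvalidSpecError("n_vertices must be >= 8")


@dataclass(frozen=True)
class DeformationFieldSpec:
    """Radial inward offset field (theta, z) -> mm with |offset| bounded."""

    radial_offset: Callable[[np.ndarray, float], np.ndarray]
    description: str = ""


@dataclass(frozen=True)
class DeformedContour:
    """Deformed vertices plus the per-vertex ground-truth deformation."""

    points: np.ndarray
    angles: np.ndarray
    deformation: np.ndarray  # mm, positive = inward


def _polar_points(center, r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    x = center[0] - r * np.sin(theta)
    y = center[1] + r * np.cos(theta)
    return np.column_stack([x, y])


def contour_radius(spec: ContourSpec, theta: np.ndarray) -> np.ndarray:
    """Closed-form polar radius of a spec (noise-free part)."""
    r = np.full_like(theta, spec.base_radius, dtype=float)
    for k, a, phi in spec.fourier_amplitudes:
        r = r + a * np.cos(k * theta + phi)
    return r


def make_contour(spec: ContourSpec) -> np.ndarray:
    """Sample the polar curve at n_vertices uniform angles; deterministic."""
    theta = np.arange(spec.n_vertices) * (2 * np.pi / spec.n_vertices)
    r = contour_radius(spec, theta)
    if spec.radial_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        r = r + rng.normal(0.0, spec.radial_noise_sd, size=r.shape)
    if np.any(r <= 0):
        raise InvalidSpecError("contour radius went non-positive")
    return _polar_points(spec.center, r, theta)


def deform_contour(
    points: np.ndarray, field: DeformationFieldSpec, z: float = 0.0
) -> DeformedContour:
    """Move each vertex radially toward the vertex centroid by field(theta, z)."""
    pts = np.asarray(points, dtype=float)
    c = centroid(pts)
    theta = vertex_angles(pts, c)
    r = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
    offset = np.asarray(field.radial_offset(theta, z), dtype=float)
    offset = np.broadcast_to(offset, r.shape)
    r_new = r - offset
    if np.any(r_new <= 0):
        raise InvalidFieldError("deformation field produces non-positive radii")
    return DeformedContour(
        points=_polar_points(c, r_new, theta), angles=theta, deformation=offset.copy()
    )


def render_contour(
    points: np.ndarray,
    image_size: int,
    pixel_scale: float,
    marker_color: tuple[int, int, int] = MARKER_YELLOW,
    line_width: int = 2,
) -> Image.Image:
    """Rasterize the contour as a closed 1-2 px polyline on black.

    Image origin convention matches extraction: lower-left, y up.
    """
    pts = np.asarray(points, dtype=float)
    extent = (image_size - 1) * pixel_scale
    if (
        pts[:, 0].min() < 0
        or pts[:, 1].min() < 0
        or pts[:, 0].max() > extent
        or pts[:, 1].max() > extent
    ):
        raise InvalidSpecError(
            "contour exceeds the raster; enlarge image_size or pixel_scale"
        )
    img = Image.new("RGB", (image_size, image_size), (0, 0, 0))
    draw = ImageDraw.Draw(img)
    px = pts[:, 0] / pixel_scale
    py = (image_size - 1) - pts[:, 1] / pixel_scale
    xy = list(zip(px.tolist(), py.tolist()))
    xy.append(xy[0])
    draw.line(xy, fill=marker_color, width=line_width, joint="curve")
    return img


def loft_mesh(
    levels: Sequence[tuple[float, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Watertight loft of stacked (z, ring-points) levels.

    Rings must share their vertex count and be consistently ordered; z
    strictly increasing.  End caps are triangle fans around the ring
    centroid.
    """
    if len(levels) < 2:
        raise InvalidSpecError("loft needs >= 2 z-levels")
    zs = [z for z, _ in levels]
    if np.any(np.diff(zs) <= 0):
        raise InvalidSpecError("z-levels must be strictly increasing")
    n = len(levels[0][1])
    if any(len(ring) != n for _, ring in levels):
        raise InvalidSpecError("all levels must share the vertex count")

    rings = []
    for z, ring2d in levels:
        rings.append(np.column_stack([np.asarray(ring2d, float), np.full(n, float(z))]))
    vertices = np.vstack(rings)

    faces = []
    for lv in range(len(levels) - 1):
        base0 = lv * n
        base1 = (lv + 1) * n
        for i in range(n):
            j = (i + 1) % n
            faces.append([base0 + i, base0 + j, base1 + i])
            faces.append([base0 + j, base1 + j, base1 + i])

    # end caps: fan around ring centroids (bottom faces down, top faces up)
    bottom_c = len(vertices)
    vertices = np.vstack([vertices, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    top_c = bottom_c + 1
    top_base = (len(levels) - 1) * n
    for i in range(n):
        j = (i + 1) % n
        faces.append([bottom_c, j, i])  # reversed winding: bottom cap faces down
        faces.append([top_c, top_base + i, top_base + j])
    return vertices, np.asarray(faces, dtype=int)


def make_limb_mesh(
    levels: Sequence[tuple[float, ContourSpec]],
) -> tuple[np.ndarray, np.ndarray]:
    """Loft of Fourier contour specs; see :func:`loft_mesh`."""
    n = levels[0][1].n_vertices if levels else 0
    if any(spec.n_vertices != n for _, spec in levels):
        raise InvalidSpecError("all levels must share n_vertices")
    return loft_mesh([(z, make_contour(spec)) for z, spec in levels])


def combine_meshes(*meshes) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate (vertices, faces) meshes, e.g. for a two-limb fixture."""
    verts, faces, offset = [], [], 0
    for v, f in meshes:
        verts.append(v)
        faces.append(np.asarray(f) + offset)
        offset += len(v)
    return np.vstack(verts), np.vstack(faces)


def make_stress_strain(
    E: float,
    v: float = 0.0,
    noise_sd: float = 0.0,
    n: int = 50,
    seed: int = 0,
    direction: Direction = Direction.COURSE,
) -> StressStrainRecord:
    """Linear-elastic record: stress = E*strain*(1+noise) over strain [0, 0.5].

    ``noise_sd`` is relative (1% -> 0.01).  Transverse strain
    -v*strain*(1+noise) is attached for non-shear directions.
    """
    rng = np.random.default_rng(seed)
    strain = np.linspace(0.0, 0.5, n)
    stress = E * strain * (1.0 + rng.normal(0.0, noise_sd, n))
    transverse = None
    if direction is not Direction.SHEAR:
        transverse = -v * strain * (1.0 + rng.normal(0.0, noise_sd, n))
    return StressStrainRecord(
        direction=direction,
        stress=stress,
        strain=strain,
        transverse_strain=transverse,
        label=f"synthetic-{direction.value}-E{E:g}",
    )


def make_fabric_records(
    props: FabricProperties, noise_sd: float = 0.0, n: int = 50, seed: int = 0
) -> list[StressStrainRecord]:
    """One record per direction reproducing a fabric's constants."""
    return [
        make_stress_strain(props.Ex, props.vxy, noise_sd, n, seed, Direction.COURSE),
        make_stress_strain(props.Ey, 0.0, noise_sd, n, seed + 1, Direction.WALE),
        make_stress_strain(props.Gxy, 0.0, noise_sd, n, seed + 2, Direction.SHEAR),
    ]


def make_vibration(
    amplitude: float,
    frequency: float,
    frame_rate: float = 120.0,
    n_cycles: float = 5.0,
    phase: float = np.pi / 2,
) -> VibrationSequence:
    """Sinusoidal vertical position, peak-to-peak = 2*amplitude.

    The default phase starts the sinusoid at its crest so that frame rates
    commensurate with the frequency (e.g. 120 fps at 60 Hz, exactly two
    samples per cycle) still sample both extremes.
    """
    if frequency <= 0:
        n = max(int(frame_rate), 2)
        times = np.arange(n) / frame_rate
        pos = np.full(n, amplitude * np.sin(phase))
        return VibrationSequence(times=times, vertical_position=pos, frame_rate=frame_rate)
    n = int(np.ceil(n_cycles * frame_rate / frequency)) + 1
    times = np.arange(n) / frame_rate
    pos = amplitude * np.sin(2 * np.pi * frequency * times + phase)
    return VibrationSequence(times=times, vertical_position=pos, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# full fixture battery

#: Sections 1-2 cut the hip; 3-6 cut both legs.
HIP_SECTIONS = (1, 2)
LEG_SECTIONS = (3, 4, 5, 6)
#: Limb circumference inflation over the garment, keeps stretch positive.
DEFAULT_INFLATION = 1.10


def section_geometries(
    sample: int, inflation: float = DEFAULT_INFLATION
) -> list[LimbSectionGeometry]:
    """Six per-section geometries from the bundled garment table.

    Limb radii are the garment circumferences divided by 2*pi, inflated so
    every section carries positive stretch.
    """
    table = load_garment_sections()
    rows = table[table["sample"] == sample]
    geoms = []
    for _, r in rows.iterrows():
        circ = float(r["circumference_mm"])
        geoms.append(
            LimbSectionGeometry(
                section_id=int(r["section"]),
                limb_radius=inflation * circ / (2 * np.pi),
                garment_circumference=circ,
                section_height=float(r["height_mm"]),
            )
        )
    return geoms


def write_fixture_battery(
    out_dir,
    seed: int = 0,
    tissue: Optional[TissueModel] = None,
    samples: Sequence[int] = (1, 2, 3, 4, 5),
    image_size: int = 512,
    noise_sd: float = 0.01,
    measurement_noise_mm: float = 0.0,
) -> dict:
    """Write a complete self-consistent fixture tree and return the manifest.

    Layout: stress-strain CSVs per fabric sample, marker-contour PNGs per
    (condition, section, side), ground-truth CSVs, one ASCII STL limb
    mesh, a vibration CSV, and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    tissue = tissue or TissueModel(Es=15000.0, vs=0.3)
    fabric_table = load_fabric_table()

    manifest: dict = {
        "seed": seed,
        "tissue": {"Es": tissue.Es, "vs": tissue.vs},
        "stress_strain": {},
        "images": [],
        "ground_truth": {},
        "mesh": None,
        "vibration": None,
    }

    ss_dir = out / "stress_strain"
    ss_dir.mkdir(exist_ok=True)
    for _, row in fabric_table.iterrows():
        sample = int(row["sample"])
        if sample not in samples:
            continue
        props = FabricProperties(
            Ex=row["Ex_pa"], Ey=row["Ey_pa"], Gxy=row["Gxy_pa"], vxy=row["vxy"],
            label=f"sample-{sample}",
        )
        recs = make_fabric_records(props, noise_sd=noise_sd, n=50, seed=seed + sample)
        path = ss_dir / f"sample_{sample}.csv"
        _write_records_csv(recs, path)
        manifest["stress_strain"][str(sample)] = {
            "path": str(path.relative_to(out)),
            "true": {"Ex": float(row["Ex_pa"]), "Ey": float(row["Ey_pa"]),
                     "Gxy": float(row["Gxy_pa"]), "vxy": float(row["vxy"])},
        }

    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    gt_rows = []
    sides_of = lambda s: ("hip",) if s in HIP_SECTIONS else ("left", "right")

    # control contours: one per (section, side), reused across conditions
    geoms = {g.section_id: g for g in section_geometries(samples[0])}
    control_specs = {}
    for sec_id, geom in geoms.items():
        for side in sides_of(sec_id):
            phase = float(rng.uniform(0, 2 * np.pi))
            control_specs[(sec_id, side)] = ContourSpec(
                base_radius=geom.limb_radius,
                fourier_amplitudes=(
                    (2, 0.03 * geom.limb_radius, phase),
                    (3, 0.015 * geom.limb_radius, phase / 2),
                ),
                n_vertices=720,
                seed=seed + sec_id,
            )

    def _render_and_log(points, condition, sec_id, side, truth_mm):
        radius = np.hypot(*(points - points.mean(axis=0)).T).max()
        scale = 2.4 * radius / image_size
        shift = points - points.mean(axis=0) + (image_size - 1) * scale / 2
        img = render_contour(shift, image_size, scale)
        name = f"{condition}_s{sec_id}_{side}.png"
        img.save(img_dir / name)
        manifest["images"].append(
            {
                "path": f"images/{name}",
                "condition": condition,
                "section": sec_id,
                "side": side,
                "pixel_scale": scale,
                "true_mean_deformation_mm": truth_mm,
            }
        )

    for (sec_id, side), spec in control_specs.items():
        _render_and_log(make_contour(spec), "control", sec_id, side, 0.0)

    for sample in samples:
        fabric = FabricProperties(
            Ex=float(fabric_table.loc[fabric_table["sample"] == sample, "Ex_pa"].iloc[0]),
            Ey=float(fabric_table.loc[fabric_table["sample"] == sample, "Ey_pa"].iloc[0]),
            Gxy=float(fabric_table.loc[fabric_table["sample"] == sample, "Gxy_pa"].iloc[0]),
            vxy=float(fabric_table.loc[fabric_table["sample"] == sample, "vxy"].iloc[0]),
            label=f"sample-{sample}",
        )
        preds, _ = predict_sections(fabric, list(geoms.values()), tissue)
        for pred in preds:
            for side in sides_of(pred.section_id):
                jitter = (
                    float(rng.normal(0.0, measurement_noise_mm))
                    if measurement_noise_mm > 0
                    else 0.0
                )
                truth = max(pred.deformation + jitter, 0.0)
                fld = DeformationFieldSpec(
                    radial_offset=lambda th, z, u=truth: np.full_like(th, u),
                    description=f"uniform {truth:.4f} mm",
                )
                base = make_contour(control_specs[(pred.section_id, side)])
                deformed = deform_contour(base, fld)
                _render_and_log(
                    deformed.points, f"legging_{sample}", pred.section_id, side, truth
                )
                gt_rows.append(
                    (f"legging_{sample}", pred.section_id, side, truth, pred.pressure)
                )

    gt_path = out / "ground_truth.csv"
    with open(gt_path, "w") as fh:
        fh.write("condition,section,side,deformation_mm,pressure_pa\n")
        for row in gt_rows:
            fh.write(f"{row[0]},{row[1]},{row[2]},{row[3]:.6f},{row[4]:.6f}\n")
    manifest["ground_truth"] = str(gt_path.relative_to(out))

    # demo mesh: two-level loft of section-4 contours, both legs
    spec4 = control_specs[(4, "left")]
    lvl = [(0.0, spec4), (float(geoms[4].section_height), spec4)]
    leg = make_limb_mesh(lvl)
    other = (leg[0] + np.array([3.0 * spec4.base_radius, 0.0, 0.0]), leg[1])
    verts, faces = combine_meshes(leg, other)
    mesh_path = out / "limb.stl"
    save_stl_ascii(mesh_path, verts, faces, name="synthetic-limb")
    manifest["mesh"] = str(mesh_path.relative_to(out))

    vib = make_vibration(amplitude=4.71, frequency=60.0, frame_rate=120.0, n_cycles=5)
    vib_path = out / "vibration.csv"
    with open(vib_path, "w") as fh:
        fh.write("time_s,vertical_position_mm\n")
        for t, p in zip(vib.times, vib.vertical_position):
            fh.write(f"{t:.8f},{p:.8f}\n")
    manifest["vibration"] = {
        "path": str(vib_path.relative_to(out)),
        "frame_rate": 120.0,
        "amplitude_mm": 4.71,
        "frequency_hz": 60.0,
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _write_records_csv(records: Sequence[StressStrainRecord], path):
    with open(path, "w") as fh:
        fh.write("direction,stress_pa,strain,transverse_strain\n")
        for rec in records:
            tr = rec.transverse_strain
            for i in range(len(rec.strain)):
                tval = f"{tr[i]:.10g}" if tr is not None else ""
                fh.write(
                    f"{rec.direction.value},{rec.stress[i]:.10g},"
                    f"{rec.strain[i]:.10g},{tval}\n"
                )
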