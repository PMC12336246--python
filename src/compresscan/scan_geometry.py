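"""Cross-section measurement: mesh slicing, marker-contour extraction,
centroid-anchored radial profiles, and with/without-garment differencing.

Coordinate conventions
----------------------
Section plane: x = subject's left->right (lateral), y = posterior->anterior.
Angles: 0 = anterior (+y), increasing counter-clockwise viewed from above;
ray direction for angle t is (-sin t, cos t).
Images: origin at the lower-left corner, y up; ``pixel_scale`` converts
pixels to mm.
Quadrants: anterior [-45, 45), lateral [45, 135), posterior [135, 225),
medial [225, 315) degrees.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage import measure

from .errors import (
    EmptyContourError,
    InvalidGeometryError,
    InvalidInputError,
    InvalidPairingError,
    NonStarShapedError,
)

__all__ = [
    "CrossSectionProfile",
    "DeformationProfile",
    "VibrationSequence",
    "marker_yellow",
    "marker_any",
    "extract_contour",
    "centroid",
    "resample_contour",
    "radial_profile",
    "profile_from_points",
    "deformation_profile",
    "load_stl",
    "save_stl_ascii",
    "slice_mesh",
    "label_left_right",
    "select_extreme_frames",
    "write_profile_csv",
    "write_deformation_csv",
]

QUADRANTS_DEG = {
    "anterior": (-45.0, 45.0),
    "lateral": (45.0, 135.0),
    "posterior": (135.0, 225.0),
    "medial": (225.0, 315.0),
}

DEFAULT_RESAMPLE_VERTICES = 720
DEFAULT_N_ANGLES = 360


@dataclass(frozen=True)
class CrossSectionProfile:
    """Ordered contour + vertex centroid + angular radial profile for one
    body section under one wear condition."""

    section_id: int
    side: str  # left | right | hip
    condition: str  # control | legging_1..legging_5
    points: np.ndarray  # (N, 2) mm
    centroid: tuple[float, float]
    angles: np.ndarray  # radians [0, 2*pi), uniform
    radii: np.ndarray  # mm
    pixel_scale: Optional[float] = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        if len(pts) < 8:
            raise InvalidInputError(
                f"section {self.section_id}/{self.side}: contour needs >= 8 points"
            )
        if len(self.angles) != len(self.radii):
            raise InvalidInputError("angles and radii must have equal length")
        if np.any(np.diff(self.angles) <= 0):
            raise InvalidInputError("angles must be strictly increasing")
        if np.any(self.radii <= 0):
            raise InvalidInputError(
                f"section {self.section_id}/{self.side}: non-positive radii"
            )


@dataclass(frozen=True)
class DeformationProfile:
    """Per-angle control-minus-garment radius difference for one section."""

    section_id: int
    side: str
    angles: np.ndarray
    per_angle: np.ndarray  # mm; negative = tissue bulge
    mean: float
    max: float
    quadrants: dict  # quadrant name -> mean mm


@dataclass(frozen=True)
class VibrationSequence:
    """Uniformly sampled vertical-position time series of a vibration run."""

    times: np.ndarray  # s
    vertical_position: np.ndarray  # mm
    frame_rate: float  # Hz

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.vertical_position, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "vertical_position", p)
        if t.size != p.size:
            raise InvalidInputError("times and positions must have equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, 1.0 / self.frame_rate, rtol=1e-6):
                raise InvalidInputError("sampling must be uniform at frame_rate")


# ---------------------------------------------------------------------------
# marker predicates and contour extraction


def marker_yellow(rgb: np.ndarray) -> np.ndarray:
    """Robust yellow: R >= 200 and G >= 200 and B <= 100."""
    return (rgb[..., 0] >= 200) & (rgb[..., 1] >= 200) & (rgb[..., 2] <= 100)


def marker_any(rgb: np.ndarray) -> np.ndarray:
    """Permissive threshold-1 predicate: any channel >= 1 (non-black)."""
    return rgb.max(axis=-1) >= 1


def extract_contour(
    image,
    marker: Callable[[np.ndarray], np.ndarray] = marker_yellow,
    pixel_scale: float = 1.0,
) -> np.ndarray:
    """Ordered boundary (mm, CCW, lower-left origin) of the largest
    connected marker component.

    Ties between equal-area components are broken by topmost-then-leftmost
    centroid and logged as a warning.
    """
    if isinstance(image, Image.Image):
        image = np.asarray(image.convert("RGB"))
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] < 3:
        raise InvalidInputError("image must be an RGB raster (H, W, 3)")
    if image.size == 0:
        raise InvalidInputError("image is empty")

    mask = marker(image)
    if not mask.any():
        raise EmptyContourError("no marker pixels found")

    labels, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    best = np.max(sizes)
    candidates = [i + 1 for i, s in enumerate(sizes) if s == best]
    if len(candidates) > 1:
        # topmost in y-up coordinates = smallest mean row
        cents = ndimage.center_of_mass(mask, labels, candidates)
        order = sorted(range(len(candidates)), key=lambda i: (cents[i][0], cents[i][1]))
        warnings.warn(
            f"{len(candidates)} equal-area marker components; "
            "tie broken by topmost-then-leftmost centroid",
            stacklevel=2,
        )
        candidates = [candidates[order[0]]]
    component = labels == candidates[0]

    filled = ndimage.binary_fill_holes(component)
    contours = measure.find_contours(filled.astype(float), 0.5)
    if not contours:
        raise EmptyContourError("marker component has no traceable boundary")
    rc = max(contours, key=len)
    if np.allclose(rc[0], rc[-1]):
        rc = rc[:-1]
    h = image.shape[0]
    xy = np.column_stack([rc[:, 1], (h - 1) - rc[:, 0]]) * pixel_scale
    if _signed_area(xy) < 0:
        xy = xy[::-1]
    return xy


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


# ---------------------------------------------------------------------------
# centroid and radial profiles


def centroid(points) -> tuple[float, float]:
    """Vertex centroid: arithmetic mean of the contour coordinates.

    Deliberately the plain vertex mean (not the area centroid); contours
    should be resampled to uniform arc length first so vertex density does
    not bias it.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise InvalidInputError("centroid of an empty point list")
    return float(pts[:, 0].mean()), float(pts[:, 1].mean())


def resample_contour(points, n: int = DEFAULT_RESAMPLE_VERTICES) -> np.ndarray:
    """Resample a closed polygon to ``n`` vertices at uniform arc length."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise InvalidInputError("resampling needs >= 3 points")
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise InvalidInputError("degenerate contour with zero perimeter")
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return np.column_stack([x, y])


def _ray_directions(angles: np.ndarray) -> np.ndarray:
    return np.column_stack([-np.sin(angles), np.cos(angles)])


def vertex_angles(points, center) -> np.ndarray:
    """Angle of each vertex in the anterior-zero CCW convention, [0, 2*pi)."""
    pts = np.asarray(points, dtype=float)
    dx = pts[:, 0] - center[0]
    dy = pts[:, 1] - center[1]
    return np.mod(np.arctan2(-dx, dy), 2 * np.pi)


def radial_profile(
    points, center, n_angles: int = DEFAULT_N_ANGLES
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid-to-contour distance on a uniform angular grid.

    Rays are cast from ``center``; crossings interpolate linearly along
    contour edges.  Rays with multiple boundary crossings take the FIRST
    one outward (non-star-shaped contour, warned once).
    """
    pts = np.asarray(points, dtype=float)
    if not Polygon(pts).buffer(0).contains(Point(center)):
        raise NonStarShapedError(f"centroid {center} lies outside the contour")
    angles = np.arange(n_angles) * (2 * np.pi / n_angles)
    dirs = _ray_directions(angles)

    p1 = pts
    p2 = np.roll(pts, -1, axis=0)
    e = p2 - p1  # (N, 2)
    w = p1 - np.asarray(center, dtype=float)  # (N, 2)

    # broadcast: (n_angles, N)
    denom = dirs[:, 0:1] * e[:, 1] - dirs[:, 1:2] * e[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]) / denom
        s = (w[:, 0] * dirs[:, 1:2] - w[:, 1] * dirs[:, 0:1]) / denom
    # small slack on s so rays through a shared vertex still register once
    valid = (np.abs(denom) > 1e-300) & (s >= -1e-9) & (s < 1.0 - 1e-9) & (t > 1e-12)
    t = np.where(valid, t, np.inf)

    t_sorted = np.sort(t, axis=1)
    t1 = t_sorted[:, 0]
    if np.any(~np.isfinite(t1)):
        raise NonStarShapedError(
            f"{int((~np.isfinite(t1)).sum())} rays found no boundary crossing"
        )
    t2 = t_sorted[:, 1] if t_sorted.shape[1] > 1 else np.full_like(t1, np.inf)
    multiple = np.isfinite(t2) & (t2 > t1 * (1.0 + 1e-6))
    if np.any(multiple):
        warnings.warn(
            f"non-star-shaped contour: {int(multiple.sum())} rays cross the "
            "boundary more than once; taking first crossing",
            stacklevel=2,
        )
    radii = t1
    return angles, radii


def profile_from_points(
    points,
    section_id: int,
    side: str,
    condition: str,
    n_angles: int = DEFAULT_N_ANGLES,
    resample_to: int = DEFAULT_RESAMPLE_VERTICES,
    pixel_scale: Optional[float] = None,
) -> CrossSectionProfile:
    """Resample -> centroid -> radial profile, packaged as a profile."""
    pts = resample_contour(points, resample_to)
    c = centroid(pts)
    angles, radii = radial_profile(pts, c, n_angles)
    return CrossSectionProfile(
        section_id=section_id,
        side=side,
        condition=condition,
        points=pts,
        centroid=c,
        angles=angles,
        radii=radii,
        pixel_scale=pixel_scale,
    )


def deformation_profile(
    control: CrossSectionProfile, garment: CrossSectionProfile
) -> DeformationProfile:
    """Per-angle deformation control.radii - garment.radii.

    Each profile is anchored to its OWN centroid, which cancels rigid
    displacement between the two scans.  Negative values (tissue bulge)
    are kept and reported.
    """
    if control.section_id != garment.section_id or control.side != garment.side:
        raise InvalidPairingError(
            f"cannot pair section {control.section_id}/{control.side} with "
            f"{garment.section_id}/{garment.side}"
        )
    if len(control.angles) != len(garment.angles) or not np.allclose(
        control.angles, garment.angles
    ):
        raise InvalidPairingError("profiles are on different angular grids")
    diff = control.radii - garment.radii
    deg = np.degrees(control.angles)
    quadrants = {}
    for name, (lo, hi) in QUADRANTS_DEG.items():
        if lo < 0:
            mask = (deg >= lo % 360) | (deg < hi)
        else:
            mask = (deg >= lo) & (deg < hi)
        quadrants[name] = float(diff[mask].mean()) if mask.any() else float("nan")
    return DeformationProfile(
        section_id=control.section_id,
        side=control.side,
        angles=control.angles,
        per_angle=diff,
        mean=float(diff.mean()),
        max=float(diff.max()),
        quadrants=quadrants,
    )


# ---------------------------------------------------------------------------
# STL I/O and plane slicing


def load_stl(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an STL mesh (ASCII or binary); returns (vertices, faces).

    Units are assumed mm.  Vertices are deduplicated exactly.
    """
    with open(path, "rb") as fh:
        head = fh.read(5)
    if head == b"solid":
        tris = _read_stl_ascii(path)
    else:
        tris = _read_stl_binary(path)
    flat = tris.reshape(-1, 3)
    vertices, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return vertices, faces


def _read_stl_ascii(path) -> np.ndarray:
    coords = []
    with open(path, "r") as fh:
        for line in fh:
            parts = line.split()
            if parts and parts[0] == "vertex":
                coords.append([float(v) for v in parts[1:4]])
    if len(coords) % 3 != 0 or not coords:
        raise InvalidInputError(f"{path}: malformed ASCII STL")
    return np.asarray(coords, dtype=float).reshape(-1, 3, 3)


def _read_stl_binary(path) -> np.ndarray:
    with open(path, "rb") as fh:
        fh.seek(80)
        (n,) = struct.unpack("<I", fh.read(4))
        data = np.frombuffer(fh.read(n * 50), dtype=np.uint8)
    if data.size != n * 50:
        raise InvalidInputError(f"{path}: truncated binary STL")
    rec = data.reshape(n, 50)
    tri = rec[:, 12:48].copy().view("<f4").reshape(n, 3, 3)
    return tri.astype(float)


def save_stl_ascii(path, vertices: np.ndarray, faces: np.ndarray, name: str = "mesh"):
    """Write an ASCII STL (text-only artifact, mm units)."""
    v = np.asarray(vertices, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"solid {name}\n")
        for f in faces:
            a, b, c = v[f[0]], v[f[1]], v[f[2]]
            nvec = np.cross(b - a, c - a)
            norm = np.linalg.norm(nvec)
            nvec = nvec / norm if norm > 0 else nvec
            fh.write(f"  facet normal {nvec[0]:.6e} {nvec[1]:.6e} {nvec[2]:.6e}\n")
            fh.write("    outer loop\n")
            for p in (a, b, c):
                fh.write(f"      vertex {p[0]:.6e} {p[1]:.6e} {p[2]:.6e}\n")
            fh.write("    endloop\n")
            fh.write("  endfacet\n")
        fh.write(f"endsolid {name}\n")


def slice_mesh(vertices: np.ndarray, faces: np.ndarray, z: float) -> list[np.ndarray]:
    """Closed intersection loops of the plane {height = z} with the mesh.

    Returns ordered (x, y) polygons sorted by descending area, each CCW.
    No intersection -> empty list.  Open loops (cracked mesh) are closed
    by joining endpoints, with a warning.
    """
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=int)
    d = v[:, 2] - z
    # nudge on-plane vertices so every crossing triangle has exactly 2 cut edges
    scale = max(np.ptp(v[:, 2]), 1.0)
    d = np.where(d == 0.0, 1e-12 * scale, d)

    df = d[f]  # (F, 3)
    crossing = ~(np.all(df > 0, axis=1) | np.all(df < 0, axis=1))
    if not np.any(crossing):
        return []

    segments = []
    for tri in f[crossing]:
        pts = []
        for i, j in ((0, 1), (1, 2), (2, 0)):
            di, dj = d[tri[i]], d[tri[j]]
            if di * dj < 0:
                w = di / (di - dj)
                p = v[tri[i]] + w * (v[tri[j]] - v[tri[i]])
                pts.append(p[:2])
        if len(pts) == 2:
            segments.append((pts[0], pts[1]))
    if not segments:
        return []

    loops = _chain_segments(segments)
    loops = [lp if _signed_area(lp) >= 0 else lp[::-1] for lp in loops]
    loops.sort(key=lambda lp: abs(_signed_area(lp)), reverse=True)
    return loops


def _chain_segments(segments, tol: float = 1e-9) -> list[np.ndarray]:
    """Stitch unordered 2-D segments into closed loops by endpoint matching."""

    def key(p):
        return (round(p[0] / tol), round(p[1] / tol))

    adjacency: dict[tuple, list[int]] = {}
    for idx, (a, b) in enumerate(segments):
        adjacency.setdefault(key(a), []).append(idx)
        adjacency.setdefault(key(b), []).append(idx)

    used = [False] * len(segments)
    loops = []
    for start in range(len(segments)):
        if used[start]:
            continue
        used[start] = True
        a, b = segments[start]
        chain = [np.asarray(a), np.asarray(b)]
        while True:
            k = key(chain[-1])
            nxt = next((i for i in adjacency.get(k, []) if not used[i]), None)
            if nxt is None:
                break
            used[nxt] = True
            p, q = segments[nxt]
            chain.append(np.asarray(q) if key(p) == k else np.asarray(p))
        closed = key(chain[0]) == key(chain[-1])
        if closed:
            chain = chain[:-1]
        else:
            warnings.warn("open intersection loop; closing by joining endpoints",
                          stacklevel=3)
        if len(chain) >= 3:
            loops.append(np.asarray(chain))
    return loops


def label_left_right(
    loops: Sequence[np.ndarray], flip: bool = False
) -> dict[str, np.ndarray]:
    """Label the two largest loops of a leg-level slice.

    The scanner faces the subject, so the loop whose centroid has the
    smaller lateral (x) coordinate is the subject's RIGHT leg; ``flip``
    reverses the convention.
    """
    if len(loops) < 2:
        raise InvalidGeometryError("left/right labelling needs two loops")
    big = sorted(loops, key=lambda lp: abs(_signed_area(lp)), reverse=True)[:2]
    big.sort(key=lambda lp: centroid(lp)[0])
    right, left = (big[1], big[0]) if flip else (big[0], big[1])
    return {"right": right, "left": left}


# ---------------------------------------------------------------------------
# vibration frames


def select_extreme_frames(seq: VibrationSequence) -> tuple[int, int, float, float]:
    """Indices of the highest/lowest frames, their displacement and interval.

    First occurrence wins on ties.  A constant sequence yields displacement
    0 with a degenerate-cycle warning.
    """
    pos = seq.vertical_position
    if pos.size < 2:
        raise InvalidInputError("need >= 2 frames")
    i_high = int(np.argmax(pos))
    i_low = int(np.argmin(pos))
    displacement = float(pos[i_high] - pos[i_low])
    if displacement == 0.0:
        warnings.warn("degenerate cycle: constant vertical position", stacklevel=2)
    interval = float(abs(seq.times[i_high] - seq.times[i_low]))
    return i_high, i_low, displacement, interval


# ---------------------------------------------------------------------------
# CSV writers


def write_profile_csv(profile: CrossSectionProfile, path):
    """Write ``angle_deg,radius_mm`` rows for one profile."""
    deg = np.degrees(profile.angles)
    with open(path, "w") as fh:
        fh.write("angle_deg,radius_mm\n")
        for a, r in zip(deg, profile.radii):
            fh.write(f"{a:.6f},{r:.6f}\n")


def write_deformation_csv(profiles: Sequence[DeformationProfile], path):
    """Write ``section,side,angle_deg,deformation_mm`` rows."""
    with open(path, "w") as fh:
        fh.write("section,side,angle_deg,deformation_mm\n")
        for dp in profiles:
            deg = np.degrees(dp.angles)
            for a, v in zip(deg, dp.per_angle):
                fh.write(f"{dp.section_id},{dp.side},{a:.6f},{v:.6f}\n")
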