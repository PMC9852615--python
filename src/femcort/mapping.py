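"""The 31-ROI cortical mapping protocol on a segmented CT volume.

Stages, mirroring the clinical measurement procedure:

1. :func:`segment_bone` thresholds the HU grid (bone = HU >= 350).
2. :func:`build_axis_frame` derives the femoral neck axis from the
   subcephalic and neck-bottom landmarks and the shaft axis from a
   least-squares line through per-slice bone centroids below the lesser
   trochanter.
3. :func:`place_sections` positions the eight cutting planes: S1-S3
   perpendicular to the neck axis at the subcephalic, middle and bottom
   sites; S4-S8 perpendicular to the shaft axis at 20 mm above the
   lesser-trochanter upper edge, the upper edge, the vertex, the lower
   edge, and 20 mm below the vertex.
4. :func:`extract_section_contours` resamples each plane on a fine
   in-plane grid and extracts the outer cortical contour and the inner
   (endosteal) contour.
5. :func:`longest_wall_chord` finds, among all chords parallel to an
   anatomical in-plane direction, the longest wall-to-wall chord and the
   cortical crossing segment at each end.
6. :func:`measure_roi` refines each crossing to sub-voxel precision on
   the interpolated HU profile and reports cortical thickness (mm) and
   the mean cortical HU of the crossing interior.

:func:`measure_femur` runs the whole chain and returns the 31
measurements (S4 contributes only anterior / lateral / posterior, since
its medial wall merges with the neck).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import BONE_THRESHOLD_HU, CTVolume
from .roi import NECK_SECTIONS, SHAFT_SECTIONS, SITE_TO_ROI, walls_of

#: in-plane resampling step for section images (mm)
PLANE_STEP_MM = 0.1
#: sampling step along chords for HU profiles (mm)
CHORD_STEP_MM = 0.1


class GeometryError(RuntimeError):
    """A measurement stage could not be completed on this geometry."""


class MeasurementError(RuntimeError):
    """A cortical crossing was too degenerate to measure."""


@dataclass
class BoneMask:
    """Binary bone grid aligned with its source volume.

    ``source`` keeps a reference to the HU volume so downstream plane
    resampling can threshold interpolated HU at sub-voxel precision.
    """

    values: np.ndarray
    voxel_spacing: np.ndarray
    origin: np.ndarray
    threshold: float
    empty: bool = False
    source: CTVolume | None = None

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) / self.voxel_spacing


def segment_bone(volume: CTVolume, threshold: float = BONE_THRESHOLD_HU) -> BoneMask:
    """Threshold segmentation: bone wherever HU >= ``threshold``."""
    values = volume.values >= threshold
    empty = not bool(values.any())
    if empty:
        warnings.warn("bone segmentation produced an empty mask", stacklevel=2)
    return BoneMask(values=values, voxel_spacing=volume.voxel_spacing,
                    origin=volume.origin, threshold=threshold, empty=empty,
                    source=volume)


# ---------------------------------------------------------------------------
# axes and section planes


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length direction vector")
    return v / n


def _project_inplane(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return _unit(v - (v @ normal) * normal)


@dataclass
class AxisFrame:
    """Neck and shaft axes plus the anatomical in-plane direction pairs."""

    neck_point: np.ndarray
    neck_dir: np.ndarray
    shaft_point: np.ndarray
    shaft_dir: np.ndarray
    superior: np.ndarray
    anterior: np.ndarray
    medial: np.ndarray

    def neck_inplane(self) -> tuple[np.ndarray, np.ndarray]:
        """(upper, anterior) directions within neck sections."""
        u1 = _project_inplane(self.superior, self.neck_dir)
        u2 = self.anterior - (self.anterior @ self.neck_dir) * self.neck_dir
        u2 = _unit(u2 - (u2 @ u1) * u1)
        return u1, u2

    def shaft_inplane(self) -> tuple[np.ndarray, np.ndarray]:
        """(medial, anterior) directions within shaft sections."""
        m = _project_inplane(self.medial, self.shaft_dir)
        a = self.anterior - (self.anterior @ self.shaft_dir) * self.shaft_dir
        a = _unit(a - (a @ m) * m)
        return m, a


def build_axis_frame(mask: BoneMask, landmarks: dict[str, np.ndarray]) -> AxisFrame:
    """Construct the measurement frame from a bone mask and landmarks.

    The neck axis passes through the subcephalic and neck-bottom points.
    The shaft axis is fitted through per-slice bone centroids below the
    lesser-trochanter lower edge; slicing runs along the grid axis most
    aligned with the anatomical superior direction.
    """
    if mask.empty:
        raise GeometryError("cannot build axes on an empty bone mask")
    sup = _unit(np.asarray(landmarks["superior"], dtype=float))
    ant = _unit(np.asarray(landmarks["anterior"], dtype=float))
    med = _unit(np.asarray(landmarks["medial"], dtype=float))

    bottom = np.asarray(landmarks["neck_bottom"], dtype=float)
    subceph = np.asarray(landmarks["neck_subcephalic"], dtype=float)
    neck_dir = _unit(subceph - bottom)

    lt_lower = np.asarray(landmarks["lt_lower_edge"], dtype=float)
    cut = float(lt_lower @ sup) - 2.0

    # slice in 2 mm bins along the superior coordinate, trimmed away from
    # the distal end so every bin holds a complete cross-section (partial
    # end-cap slices would drag centroids off the axis)
    idx = np.argwhere(mask.values)
    world = idx * mask.voxel_spacing + mask.origin
    coord = world @ sup
    lo = float(coord.min()) + 5.0
    hi = cut - 2.0
    sel = (coord >= lo) & (coord <= hi)
    if not sel.any():
        raise GeometryError("no shaft voxels below the lesser trochanter")
    world = world[sel]
    coord = coord[sel]
    bins = np.floor((coord - lo) / 2.0).astype(int)
    uniq = np.unique(bins)
    if uniq.size < 3:
        raise GeometryError(
            f"only {uniq.size} shaft slices below the lesser trochanter; need >= 3")
    centroids = np.stack([world[bins == s].mean(axis=0) for s in uniq])
    mean = centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centroids - mean, full_matrices=False)
    shaft_dir = _unit(vt[0])
    if shaft_dir @ sup < 0:
        shaft_dir = -shaft_dir

    return AxisFrame(neck_point=bottom, neck_dir=neck_dir,
                     shaft_point=mean, shaft_dir=shaft_dir,
                     superior=sup, anterior=ant, medial=med)


@dataclass
class SectionPlane:
    """One cutting plane with its anatomical in-plane direction pair."""

    id: str
    origin: np.ndarray
    normal: np.ndarray
    dir1: np.ndarray
    dir2: np.ndarray
    labels: tuple[tuple[str, str], tuple[str, str]]
    # labels[i] = (wall at +dir_i end, wall at -dir_i end)


def place_sections(frame: AxisFrame, landmarks: dict[str, np.ndarray]) -> list[SectionPlane]:
    """Position S1-S8 along the neck and shaft axes."""
    u1, u2 = frame.neck_inplane()
    m, a = frame.shaft_inplane()

    def on_shaft(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        t = (p - frame.shaft_point) @ frame.shaft_dir
        return frame.shaft_point + t * frame.shaft_dir

    s1 = np.asarray(landmarks["neck_subcephalic"], dtype=float)
    s3 = np.asarray(landmarks["neck_bottom"], dtype=float)
    s2 = (s1 + s3) / 2.0
    s5 = on_shaft(landmarks["lt_upper_edge"])
    s6 = on_shaft(landmarks["lt_vertex"])
    s7 = on_shaft(landmarks["lt_lower_edge"])
    s4 = s5 + 20.0 * frame.shaft_dir
    s8 = s6 - 20.0 * frame.shaft_dir

    neck_labels = (("upper", "lower"), ("anterior", "posterior"))
    shaft_labels = (("medial", "lateral"), ("anterior", "posterior"))
    planes = [
        SectionPlane("S1", s1, frame.neck_dir, u1, u2, neck_labels),
        SectionPlane("S2", s2, frame.neck_dir, u1, u2, neck_labels),
        SectionPlane("S3", s3, frame.neck_dir, u1, u2, neck_labels),
        SectionPlane("S4", s4, frame.shaft_dir, m, a, shaft_labels),
        SectionPlane("S5", s5, frame.shaft_dir, m, a, shaft_labels),
        SectionPlane("S6", s6, frame.shaft_dir, m, a, shaft_labels),
        SectionPlane("S7", s7, frame.shaft_dir, m, a, shaft_labels),
        SectionPlane("S8", s8, frame.shaft_dir, m, a, shaft_labels),
    ]
    return planes


# ---------------------------------------------------------------------------
# section resampling and contours


@dataclass
class SectionContours:
    """Resampled in-plane bone images and their boundary polygons.

    Image axes are [q, p]: axis 1 runs along ``plane.dir1``, axis 0 along
    ``plane.dir2``; in-plane mm coordinate of pixel (iq, ip) is
    (p0 + ip*step, q0 + iq*step) in the (dir1, dir2) basis relative to
    the plane origin.
    """

    plane: SectionPlane
    bone: np.ndarray          # largest connected bone component
    filled: np.ndarray        # bone component with interior cavity filled
    holes: np.ndarray         # enclosed non-bone region
    step: float
    p0: float
    q0: float
    outer_polygon: np.ndarray = field(repr=False, default=None)  # (N, 2) mm (p, q)
    inner_polygon: np.ndarray = field(repr=False, default=None)
    hu_image: np.ndarray = field(repr=False, default=None)  # interpolated HU

    def to_mm(self, ip: np.ndarray, iq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.p0 + np.asarray(ip) * self.step, self.q0 + np.asarray(iq) * self.step

    def to_world(self, p: float, q: float) -> np.ndarray:
        return (self.plane.origin + p * self.plane.dir1 + q * self.plane.dir2)


def _polygon_from_image(img: np.ndarray, step: float, p0: float, q0: float):
    from skimage import measure

    contours = measure.find_contours(img.astype(float), 0.5)
    if not contours:
        return None
    best = max(contours, key=len)
    # rows are (iq, ip); convert to (p, q) mm
    poly = np.column_stack([p0 + best[:, 1] * step, q0 + best[:, 0] * step])
    return poly


def _polygons_from_hu(hu: np.ndarray, level: float, filled: np.ndarray,
                      holes: np.ndarray, step: float, p0: float, q0: float):
    """Sub-pixel outer/inner iso-contours of the HU image at ``level``.

    The outer contour is the largest iso-contour enclosing the selected
    component; the inner (endosteal) contour is the largest one whose
    interior is the component's cavity.
    """
    from skimage import measure

    outer = inner = None
    for c in sorted(measure.find_contours(hu, level), key=lambda c: len(c),
                    reverse=True):
        cy, cx = c.mean(axis=0)
        iq = int(np.clip(round(cy), 0, filled.shape[0] - 1))
        ip = int(np.clip(round(cx), 0, filled.shape[1] - 1))
        poly = np.column_stack([p0 + c[:, 1] * step, q0 + c[:, 0] * step])
        if outer is None and filled[iq, ip]:
            # centroid of a ring around the cavity lands in the cavity,
            # so the outer contour is the one whose centroid is solid bone
            # or whose enclosed region is the whole component
            outer = poly
        elif inner is None and holes.any() and holes[iq, ip]:
            inner = poly
        if outer is not None and (inner is not None or not holes.any()):
            break
    if outer is None:
        outer = _polygon_from_image(filled, step, p0, q0)
    if inner is None and holes.any():
        inner = _polygon_from_image(holes, step, p0, q0)
    return outer, inner


def extract_section_contours(mask: BoneMask, plane: SectionPlane,
                             step: float = PLANE_STEP_MM) -> SectionContours:
    """Resample the mask within a section plane and extract contours.

    The plane is sampled on a 0.1 mm grid whose axes follow the plane's
    anatomical direction pair, so wall-to-wall chords coincide with image
    rows/columns.  Bone membership is the thresholded trilinearly
    interpolated HU when the source volume is attached (sub-voxel smooth;
    contours as iso-lines of the HU image), else nearest-neighbour mask
    lookup.
    """
    shape = np.asarray(mask.values.shape)
    corners = np.array([[i, j, k] for i in (0, shape[0] - 1)
                        for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)])
    corners_w = corners * mask.voxel_spacing + mask.origin
    rel = corners_w - plane.origin
    p_rng = rel @ plane.dir1
    q_rng = rel @ plane.dir2
    p0, p1 = float(p_rng.min()), float(p_rng.max())
    q0, q1 = float(q_rng.min()), float(q_rng.max())
    # clamp extents; sections live well inside +/-100 mm of the axes
    p0, p1 = max(p0, -100.0), min(p1, 100.0)
    q0, q1 = max(q0, -100.0), min(q1, 100.0)

    ps = np.arange(p0, p1 + step, step)
    qs = np.arange(q0, q1 + step, step)
    # fractional voxel coordinates: idx_k = A_k + p*b_k + q*c_k
    A = (plane.origin - mask.origin) / mask.voxel_spacing
    b = plane.dir1 / mask.voxel_spacing
    c = plane.dir2 / mask.voxel_spacing
    coords = [A[k] + qs[:, None] * c[k] + ps[None, :] * b[k] for k in range(3)]
    hu = None
    if mask.source is not None:
        # threshold the trilinearly interpolated HU: sub-voxel-smooth
        # contours, so chord extents are not dominated by voxel aliasing
        hu = ndimage.map_coordinates(
            mask.source.values, np.stack([cc.ravel() for cc in coords]),
            order=1, mode="constant", cval=-1000.0).reshape(coords[0].shape)
        img = hu >= mask.threshold
    else:
        nn = [np.rint(cc).astype(np.int64) for cc in coords]
        valid = np.ones(nn[0].shape, dtype=bool)
        for k in range(3):
            valid &= (nn[k] >= 0) & (nn[k] < mask.values.shape[k])
        img = np.zeros(nn[0].shape, dtype=bool)
        if valid.any():
            img[valid] = mask.values[nn[0][valid], nn[1][valid], nn[2][valid]]
    if not img.any():
        raise GeometryError(f"section {plane.id}: plane does not intersect bone")

    lab, n = ndimage.label(img)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    comp = lab == int(np.argmax(sizes))
    filled = ndimage.binary_fill_holes(comp)
    holes = filled & ~comp

    if hu is not None:
        outer, inner = _polygons_from_hu(hu, mask.threshold, filled, holes,
                                         step, p0, q0)
    else:
        outer = _polygon_from_image(filled, step, p0, q0)
        inner = _polygon_from_image(holes, step, p0, q0) if holes.any() else None
    return SectionContours(plane=plane, bone=comp, filled=filled, holes=holes,
                           step=step, p0=p0, q0=q0,
                           outer_polygon=outer, inner_polygon=inner,
                           hu_image=hu)


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as (N, 2) vertices."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


# ---------------------------------------------------------------------------
# chords


@dataclass
class WallChord:
    """The longest wall-to-wall chord along one in-plane direction.

    ``p_min``/``p_max`` are the outer-contour endpoints (mm, along the
    chord direction); ``q`` is the perpendicular offset of the chord.
    ``crossing_min``/``crossing_max`` are the coarse cortical crossing
    lengths at each end (mm); ``has_cavity`` is False when the section has
    no enclosed endosteal cavity on this chord, in which case crossings
    extend to the chord midpoint and downstream measurements are flagged.
    """

    section: str
    direction_index: int      # 0 -> chord parallel to plane.dir1, 1 -> dir2
    labels: tuple[str, str]   # (wall at max end, wall at min end)
    q: float
    p_min: float
    p_max: float
    crossing_min: float
    crossing_max: float
    has_cavity: bool
    contours: SectionContours = field(repr=False, default=None)

    @property
    def length(self) -> float:
        return self.p_max - self.p_min

    def endpoint_world(self, end: str) -> np.ndarray:
        p = self.p_min if end == "min" else self.p_max
        if self.direction_index == 0:
            return self.contours.to_world(p, self.q)
        return self.contours.to_world(self.q, p)


def _subpixel_outer_edge(profile: np.ndarray, i_edge: int, inward: int) -> float:
    """Refine an outer-contour crossing to sub-pixel precision.

    ``i_edge`` is the first/last above-threshold pixel of the row;
    ``inward`` is +1 at the low end, -1 at the high end.  The edge is the
    crossing of the half level between the plateaus just outside and just
    inside, searched within +/-1.2 mm of the coarse edge.
    """
    n = profile.size
    def med(lo: int, hi: int, fallback: float) -> float:
        lo, hi = max(0, lo), min(n, hi)
        if hi <= lo:
            return fallback
        return float(np.median(profile[lo:hi]))

    if inward > 0:
        inside = med(i_edge + 3, i_edge + 15, float(profile[i_edge]))
        outside = med(i_edge - 25, i_edge - 8, float(profile[max(0, i_edge - 1)]))
    else:
        inside = med(i_edge - 14, i_edge - 2, float(profile[i_edge]))
        outside = med(i_edge + 9, i_edge + 26, float(profile[min(n - 1, i_edge + 1)]))
    level = (inside + outside) / 2.0
    lo, hi = max(0, i_edge - 12), min(n - 1, i_edge + 12)
    seg = profile[lo:hi + 1]
    above = seg >= level
    if inward > 0:
        trans = np.flatnonzero(~above[:-1] & above[1:])
    else:
        trans = np.flatnonzero(above[:-1] & ~above[1:])
    if trans.size == 0:
        return float(i_edge)
    j = int(trans[np.argmin(np.abs(trans + lo - i_edge))])
    f0, f1 = seg[j], seg[j + 1]
    if f1 == f0:
        return float(lo + j + 0.5)
    return float(lo + j + (level - f0) / (f1 - f0))


def longest_wall_chord(contours: SectionContours, direction_index: int) -> WallChord:
    """Longest chord parallel to one anatomical in-plane direction.

    Chords are sampled on the resampled plane grid (0.1 mm perpendicular
    spacing); chord length is the outer-contour extent.  Ties are broken
    toward the chord nearest the filled-contour centroid.
    """
    plane = contours.plane
    if direction_index == 0:
        F, B = contours.filled, contours.bone
        H = contours.hu_image
        off0, step = contours.p0, contours.step
        qoff = contours.q0
        labels = plane.labels[0]
    elif direction_index == 1:
        F, B = contours.filled.T, contours.bone.T
        H = None if contours.hu_image is None else contours.hu_image.T
        off0, step = contours.q0, contours.step
        qoff = contours.p0
        labels = plane.labels[1]
    else:
        raise ValueError("direction_index must be 0 or 1")

    any_row = F.any(axis=1)
    if not any_row.any():
        raise GeometryError(f"section {plane.id}: no chords intersect the contour")
    first = F.argmax(axis=1)
    last = F.shape[1] - 1 - F[:, ::-1].argmax(axis=1)
    lengths = np.where(any_row, (last - first) * contours.step, -1.0)

    # Rasterization flattens the extent profile near its maximum into a
    # plateau of rows tied within one pixel; the centre of that plateau is
    # the stable estimate of the true argmax.  Among multiple runs of tied
    # rows, prefer the one nearest the contour centroid.
    best_len = lengths.max()
    cand = np.flatnonzero(lengths >= best_len - contours.step - 1e-12)
    runs: list[np.ndarray] = np.split(cand, np.flatnonzero(np.diff(cand) > 1) + 1)
    iq_pts, _ = np.nonzero(F)
    centroid_q = iq_pts.mean()
    run = min(runs, key=lambda r: abs((r[0] + r[-1]) / 2 - centroid_q))
    row = int(run[len(run) // 2])

    i0, i1 = int(first[row]), int(last[row])
    seg = B[row, i0:i1 + 1]
    has_cavity = not bool(seg.all())
    if has_cavity:
        n_lo = int(np.argmin(seg))                 # first False
        n_hi = int(np.argmin(seg[::-1]))
    else:
        half = (i1 - i0 + 1) // 2
        n_lo = n_hi = half
    e0, e1 = float(i0), float(i1)
    if H is not None:
        e0 = _subpixel_outer_edge(H[row], i0, +1)
        e1 = _subpixel_outer_edge(H[row], i1, -1)
    chord = WallChord(
        section=plane.id,
        direction_index=direction_index,
        labels=labels,
        q=qoff + row * contours.step,
        p_min=off0 + e0 * contours.step,
        p_max=off0 + e1 * contours.step,
        crossing_min=(i0 - e0 + n_lo) * contours.step,
        crossing_max=(e1 - i1 + n_hi) * contours.step,
        has_cavity=has_cavity,
        contours=contours,
    )
    return chord


# ---------------------------------------------------------------------------
# ROI measurement


@dataclass
class ROIMeasurement:
    """One of the 31 cortical measurements: thickness (mm) and mean HU."""

    roi_id: int
    section: str
    wall: str
    cth: float
    hu: float
    endpoint: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cth <= 0:
            raise MeasurementError(
                f"ROI {self.roi_id} ({self.section} {self.wall}): non-positive "
                f"thickness {self.cth}")


def _interp_profile(volume: CTVolume, points: np.ndarray) -> np.ndarray:
    idx = volume.world_to_index(points)
    return ndimage.map_coordinates(volume.values, idx.T, order=1, mode="nearest")


def _refine_crossing(u: np.ndarray, f: np.ndarray, coarse: float
                     ) -> tuple[float, float, tuple[str, ...]]:
    """Sub-voxel cortical crossing from an HU profile.

    ``u`` is the inward distance from the coarse outer endpoint, ``f``
    the interpolated HU profile, ``coarse`` the coarse crossing length.
    Edges are located where the profile crosses the half level between
    the adjacent tissue plateaus; plateau estimates are medians taken
    away from the edges.
    """
    flags: list[str] = []

    def med(lo: float, hi: float, fallback: float) -> float:
        sel = (u >= lo) & (u <= hi)
        if not sel.any():
            return fallback
        return float(np.median(f[sel]))

    cortex = med(0.3 * coarse, 0.7 * coarse, float(f.max()))
    outside = med(u.min(), -0.8, float(f.min()))
    cavity = med(coarse + 0.8, min(coarse + 2.5, u.max()), outside)

    def crossing(level: float, center: float, halfwin: float, rising: bool) -> float:
        lo, hi = center - halfwin, center + halfwin
        sel = np.flatnonzero((u >= lo) & (u <= hi))
        if sel.size < 2:
            return center
        uu, ff = u[sel], f[sel]
        above = ff >= level
        if rising:
            trans = np.flatnonzero(~above[:-1] & above[1:])
        else:
            trans = np.flatnonzero(above[:-1] & ~above[1:])
        if trans.size == 0:
            return center
        # crossing nearest the coarse edge
        mids = (uu[trans] + uu[trans + 1]) / 2
        j = int(trans[np.argmin(np.abs(mids - center))])
        f0, f1 = ff[j], ff[j + 1]
        if f1 == f0:
            return float((uu[j] + uu[j + 1]) / 2)
        t = (level - f0) / (f1 - f0)
        return float(uu[j] + t * (uu[j + 1] - uu[j]))

    halfwin = min(1.2, 0.45 * coarse) if coarse > 0 else 1.2
    u_out = crossing((outside + cortex) / 2.0, 0.0, 1.2, rising=True)
    u_in = crossing((cortex + cavity) / 2.0, coarse, halfwin, rising=False)
    if u_in <= u_out:
        flags.append("degenerate-refinement")
        u_out, u_in = 0.0, coarse
    return u_out, u_in, tuple(flags)


def measure_roi(volume: CTVolume, chord: WallChord, end: str) -> ROIMeasurement:
    """Measure cortical thickness and HU at one end of a wall chord.

    ``end`` is ``"max"`` (wall at the +direction side) or ``"min"``.
    The HU value is the mean of the interpolated profile strictly inside
    the refined crossing, with an inset of min(1 mm, cth/4) at each edge
    to keep partial-volume samples out of the average.
    """
    c = chord.contours
    plane = c.plane
    d = plane.dir1 if chord.direction_index == 0 else plane.dir2
    if end == "max":
        outer_p, sgn, coarse = chord.p_max, -1.0, chord.crossing_max
    elif end == "min":
        outer_p, sgn, coarse = chord.p_min, 1.0, chord.crossing_min
    else:
        raise ValueError("end must be 'min' or 'max'")
    if coarse < CHORD_STEP_MM:
        raise MeasurementError(
            f"{chord.section}: cortical crossing at {end} end shorter than one sample step")

    halfspan = chord.length / 2.0
    u = np.arange(-3.0, min(coarse + 3.0, halfspan) + CHORD_STEP_MM, CHORD_STEP_MM)
    origin_w = c.to_world(outer_p, chord.q) if chord.direction_index == 0 \
        else c.to_world(chord.q, outer_p)
    points = origin_w[None, :] + (sgn * u)[:, None] * d[None, :]
    f = _interp_profile(volume, points)

    u_out, u_in, flags = _refine_crossing(u, f, coarse)
    if not chord.has_cavity:
        u_in = halfspan
        flags = flags + ("no-cavity",)
    cth = u_in - u_out
    inset = min(1.0, 0.25 * cth)
    sel = (u >= u_out + inset) & (u <= u_in - inset)
    if sel.any():
        hu = float(np.mean(f[sel]))
    else:
        hu = float(np.interp((u_out + u_in) / 2.0, u, f))
        flags = flags + ("midpoint-hu",)

    wall = chord.labels[0] if end == "max" else chord.labels[1]
    return ROIMeasurement(
        roi_id=SITE_TO_ROI[(chord.section, wall)],
        section=chord.section,
        wall=wall,
        cth=float(cth),
        hu=hu,
        endpoint=chord.endpoint_world(end),
        flags=flags,
    )


def measure_femur(volume: CTVolume, landmarks: dict[str, np.ndarray],
                  threshold: float = BONE_THRESHOLD_HU) -> list[ROIMeasurement]:
    """Run the full protocol and return all 31 ROI measurements in id order."""
    mask = segment_bone(volume, threshold)
    if mask.empty:
        raise GeometryError("empty bone mask; nothing to measure")
    frame = build_axis_frame(mask, landmarks)
    planes = place_sections(frame, landmarks)

    out: dict[int, ROIMeasurement] = {}
    for plane in planes:
        try:
            contours = extract_section_contours(mask, plane)
        except GeometryError as exc:
            raise GeometryError(f"section {plane.id}: {exc}") from exc
        wanted = set(walls_of(plane.id))
        for direction_index in (0, 1):
            chord = longest_wall_chord(contours, direction_index)
            for end in ("max", "min"):
                wall = chord.labels[0] if end == "max" else chord.labels[1]
                if wall not in wanted:
                    continue
                try:
                    m = measure_roi(volume, chord, end)
                except MeasurementError as exc:
                    raise MeasurementError(
                        f"section {plane.id}, wall {wall}: {exc}") from exc
                out[m.roi_id] = m
    if sorted(out) != list(range(1, 32)):
        missing = sorted(set(range(1, 32)) - set(out))
        raise GeometryError(f"protocol incomplete; missing ROIs {missing}")
    return [out[r] for r in sorted(out)]


def measurements_to_frame(measurements: list[ROIMeasurement], patient_id: str = "phantom"):
    """Measurements as a tidy table matching the CSV interchange schema."""
    import pandas as pd

    return pd.DataFrame(
        [{"patient_id": patient_id, "roi_id": m.roi_id, "section": m.section,
          "wall": m.wall, "cth_mm": m.cth, "hu": m.hu} for m in measurements])
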