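"""Analytic CT phantoms of a simplified proximal femur.

The phantom is a union of three analytic solids expressed in a canonical
anatomical frame (x = medial, y = anterior, z = superior):

* an elliptic-cylinder **shaft** along z carrying a hemiellipsoidal
  lesser-trochanter bump on its medial wall,
* an elliptic-cylinder **neck** tilted medially-superiorly at a fixed
  neck-shaft angle (default 130 degrees),
* a spherical **head** capping the neck.

Each tube has an outer surface given in polar form per cross-section and a
cortical shell whose radial thickness (and cortical HU) is constant per
section band and blended angularly between the four labelled wall
directions with a cosine ease.  Because the blend is flat at the wall
directions, the ground-truth thickness at every chord endpoint the
measurement protocol touches equals the configured per-wall value exactly.

Voxels are filled by supersampled point classification (partial-volume
averaging), optionally followed by Gaussian HU noise.  The default
background is soft tissue (40 HU), not air, so that bone segmentation at
the 350 HU threshold is genuinely exercised.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib

from .roi import (
    ALL_SECTIONS,
    NECK_SECTIONS,
    NECK_WALLS,
    ROI_TABLE,
    SHAFT_SECTIONS,
    SHAFT_WALLS,
)

#: operational bone threshold in HU (cortical bone lies well above it)
BONE_THRESHOLD_HU = 350.0

# wall angle (degrees) within a cross-section, measured from the first
# in-plane anatomical direction toward the second.
_SHAFT_WALL_ANGLE = {"medial": 0.0, "anterior": 90.0, "lateral": 180.0, "posterior": 270.0}
_NECK_WALL_ANGLE = {"upper": 0.0, "anterior": 90.0, "lower": 180.0, "posterior": 270.0}


def _default_wall_thickness() -> dict[tuple[str, str], float]:
    """Per (section, wall) cortical thickness in mm.

    Where the study prints a mean thickness for a site the default equals
    it (S5 medial 6.01, S6 anterior 3.37, S6 posterior 2.67, S7 anterior
    3.91, S8 medial 6.39); the remaining walls carry population-plausible
    values: thick medial calcar, moderate lateral/anterior/posterior
    shaft walls, thinner superior neck cortex.
    """
    t: dict[tuple[str, str], float] = {}
    for sec in NECK_SECTIONS:
        t[(sec, "upper")] = 2.0
        t[(sec, "lower")] = 3.5
        t[(sec, "anterior")] = 2.5
        t[(sec, "posterior")] = 2.5
    shaft_defaults = {
        "S4": {"medial": 4.0, "anterior": 3.0, "lateral": 3.2, "posterior": 3.0},
        "S5": {"medial": 6.01, "anterior": 3.2, "lateral": 3.5, "posterior": 3.0},
        "S6": {"medial": 6.2, "anterior": 3.37, "lateral": 3.8, "posterior": 2.67},
        "S7": {"medial": 6.3, "anterior": 3.91, "lateral": 4.2, "posterior": 3.2},
        "S8": {"medial": 6.39, "anterior": 4.5, "lateral": 4.8, "posterior": 4.0},
    }
    for sec, walls in shaft_defaults.items():
        for w, v in walls.items():
            t[(sec, w)] = v
    return t


def _default_cortical_hu() -> dict[tuple[str, str], float]:
    """Per (section, wall) cortical HU; printed site means where available."""
    hu: dict[tuple[str, str], float] = {}
    for sec in NECK_SECTIONS:
        for w in NECK_WALLS:
            hu[(sec, w)] = 600.0
    shaft_defaults = {
        "S4": {"medial": 500.0, "anterior": 450.0, "lateral": 419.48, "posterior": 460.0},
        "S5": {"medial": 550.0, "anterior": 480.0, "lateral": 470.0, "posterior": 470.0},
        "S6": {"medial": 600.0, "anterior": 520.0, "lateral": 520.0, "posterior": 474.74},
        "S7": {"medial": 700.0, "anterior": 620.0, "lateral": 640.0, "posterior": 570.09},
        "S8": {"medial": 900.0, "anterior": 919.90, "lateral": 880.0, "posterior": 850.0},
    }
    for sec, walls in shaft_defaults.items():
        for w, v in walls.items():
            hu[(sec, w)] = v
    return hu


@dataclass
class PhantomSpec:
    """Full parameterization of the phantom geometry and tissue HU.

    Lengths are mm, HU values Hounsfield units.  The lesser-trochanter
    vertex sits at canonical z = 0; its upper/lower edges at +/-
    ``lt_half_extent``.  ``rotation``, if given, is a 3x3 rotation matrix
    applied to the whole geometry (solids, landmarks and anatomical axes),
    so rotated phantoms exercise the measurement pipeline off-grid.
    """

    voxel_spacing: float | tuple[float, float, float] = 1.0
    head_radius: float = 20.0
    head_shell_thickness: float = 1.5
    head_shell_hu: float = 700.0
    neck_length: float = 50.0            # junction point -> head centre, along neck axis
    neck_semi_axes: tuple[float, float] = (14.0, 12.0)   # (superior-inferior, anterior-posterior)
    neck_shaft_angle_deg: float = 130.0
    neck_section_s: tuple[float, float, float] = (26.0, 21.0, 16.0)  # S1, S2, S3 axial positions
    shaft_semi_axes: tuple[float, float] = (15.0, 14.0)  # (medial-lateral, anterior-posterior)
    shaft_top: float = 55.0
    shaft_bottom: float = -45.0
    lt_half_extent: float = 15.0         # axial half-extent of the lesser-trochanter bump
    lt_height: float = 12.0              # radial height of the bump at its vertex
    lt_angular_halfwidth_deg: float = 60.0
    wall_thickness: dict[tuple[str, str], float] = field(default_factory=_default_wall_thickness)
    cortical_hu: dict[tuple[str, str], float] = field(default_factory=_default_cortical_hu)
    trabecular_hu: float = 150.0
    background_hu: float = 40.0
    hu_noise_sd: float = 0.0
    rng_seed: int = 0
    antialias: int = 3                   # supersampling factor per axis (partial volume)
    rotation: np.ndarray | None = None
    margin: float = 10.0

    # -- derived geometry -------------------------------------------------

    @property
    def spacing(self) -> np.ndarray:
        s = np.asarray(self.voxel_spacing, dtype=float)
        if s.ndim == 0:
            s = np.repeat(s, 3)
        return s

    @property
    def neck_axis_dir(self) -> np.ndarray:
        """Unit neck-axis direction (canonical frame, pointing toward the head)."""
        a = np.deg2rad(180.0 - self.neck_shaft_angle_deg)
        return np.array([np.sin(a), 0.0, np.cos(a)])

    @property
    def neck_base(self) -> np.ndarray:
        """Junction point of the neck axis on the shaft axis (canonical)."""
        return np.array([0.0, 0.0, self.shaft_top])

    @property
    def head_center(self) -> np.ndarray:
        return self.neck_base + self.neck_length * self.neck_axis_dir

    def rotation_matrix(self) -> np.ndarray:
        if self.rotation is None:
            return np.eye(3)
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        return R

    def shaft_section_z(self) -> dict[str, float]:
        h = self.lt_half_extent
        return {"S4": h + 20.0, "S5": h, "S6": 0.0, "S7": -h, "S8": -20.0}

    def validate(self) -> None:
        sp = self.spacing
        if np.any(sp <= 0):
            raise ValueError("voxel_spacing must be strictly positive")
        if self.antialias < 1:
            raise ValueError("antialias must be >= 1")
        if not (self.cortical_hu and self.wall_thickness):
            raise ValueError("wall_thickness and cortical_hu maps must be populated")
        for sec in ALL_SECTIONS:
            walls = NECK_WALLS if sec in NECK_SECTIONS else SHAFT_WALLS
            semi = min(self.neck_semi_axes) if sec in NECK_SECTIONS else min(self.shaft_semi_axes)
            for w in walls:
                key = (sec, w)
                if key not in self.wall_thickness:
                    raise ValueError(f"wall_thickness missing entry for {key}")
                if key not in self.cortical_hu:
                    raise ValueError(f"cortical_hu missing entry for {key}")
                t = self.wall_thickness[key]
                if not 0.0 < t < semi:
                    raise ValueError(
                        f"thickness {t} mm at {key} must be positive and below the "
                        f"outer semi-axis {semi} mm"
                    )
        if not (min(self.cortical_hu.values()) > self.trabecular_hu > self.background_hu):
            raise ValueError("need cortical HU > trabecular HU > background HU")
        if self.head_shell_thickness >= self.head_radius:
            raise ValueError("head shell thickness must be below the head radius")
        if self.shaft_bottom >= self.shaft_top:
            raise ValueError("shaft_bottom must lie below shaft_top")
        s1, s2, s3 = self.neck_section_s
        if not (0 < s3 < s2 < s1 < self.neck_length):
            raise ValueError("neck sections must be ordered bottom < middle < subcephalic "
                             "inside the neck span")


@dataclass
class CTVolume:
    """A 3D HU grid with isotropic or anisotropic spacing.

    ``origin`` is the world position of the centre of voxel (0, 0, 0);
    ``axes`` labels which anatomical direction each grid axis most nearly
    points along (a permutation of medial / anterior / superior for the
    canonical phantom).
    """

    values: np.ndarray
    voxel_spacing: np.ndarray
    origin: np.ndarray
    axes: tuple[str, str, str] = ("medial", "anterior", "superior")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.voxel_spacing = np.asarray(self.voxel_spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("volume grid must be a non-empty 3D array")
        if np.any(self.voxel_spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        if len(set(self.axes)) != 3:
            raise ValueError("axes labels must be three distinct anatomical axes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to fractional voxel indices."""
        return (np.asarray(points, dtype=float) - self.origin) / self.voxel_spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.voxel_spacing + self.origin


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a generated phantom.

    ``landmarks`` holds world-mm points (head centre, neck subcephalic /
    middle / bottom axis points, lesser-trochanter upper edge / vertex /
    lower edge on the shaft axis) plus the three anatomical unit vectors.
    ``roi`` maps roi_id -> (true cortical thickness mm, true cortical HU).
    """

    landmarks: dict[str, np.ndarray]
    roi: dict[int, tuple[float, float]]

    def __post_init__(self) -> None:
        if sorted(self.roi) != list(range(1, 32)):
            raise ValueError("ground truth must cover exactly ROIs 1..31")
        sup = self.landmarks["superior"]
        zs = [float(self.landmarks[k] @ sup) for k in
              ("lt_upper_edge", "lt_vertex", "lt_lower_edge")]
        if not zs[0] > zs[1] > zs[2]:
            raise ValueError("lesser-trochanter landmarks must run upper edge -> "
                             "vertex -> lower edge along the shaft axis")

    def to_frame(self):
        """Ground truth as a tidy table (roi_id, section, wall, true values)."""
        import pandas as pd

        rows = [
            {"roi_id": r, "section": s, "wall": w,
             "true_cth_mm": self.roi[r][0], "true_hu": self.roi[r][1]}
            for r, s, w in ROI_TABLE
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# membership evaluation


def _quadrant_blend(theta_deg: np.ndarray, band_idx: np.ndarray,
                    table: np.ndarray) -> np.ndarray:
    """Blend per-wall values angularly with a cosine ease.

    ``table`` has shape (n_bands, 4) with columns ordered by wall angle
    0, 90, 180, 270 degrees.  The ease is flat (zero slope) at each wall
    direction, so values at the labelled walls are exact.
    """
    t = np.mod(theta_deg, 360.0)
    q = np.floor_divide(t, 90.0).astype(np.intp) % 4
    f = (t - 90.0 * q) / 90.0
    w = 0.5 - 0.5 * np.cos(np.pi * f)
    v0 = table[band_idx, q]
    v1 = table[band_idx, (q + 1) % 4]
    return v0 * (1.0 - w) + v1 * w


def _ellipse_radius(theta_deg: np.ndarray, a: float, b: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return (a * b) / np.sqrt((b * c) ** 2 + (a * s) ** 2)


class _PhantomModel:
    """Vectorized canonical-frame classifier for phantom sample points."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        order = ["medial", "anterior", "lateral", "posterior"]
        self.shaft_secs = list(SHAFT_SECTIONS)            # band order S4..S8
        zs = spec.shaft_section_z()
        z_desc = [zs[s] for s in self.shaft_secs]         # descending z
        # band edges between consecutive section planes (descending z)
        self.shaft_edges = np.array(
            [(z_desc[i] + z_desc[i + 1]) / 2 for i in range(4)])
        self.shaft_t = np.array(
            [[spec.wall_thickness[(s, w)] for w in order] for s in self.shaft_secs])
        self.shaft_hu = np.array(
            [[spec.cortical_hu[(s, w)] for w in order] for s in self.shaft_secs])

        norder = ["upper", "anterior", "lower", "posterior"]
        self.neck_secs = list(NECK_SECTIONS)              # band order S1..S3 (descending s)
        s_desc = list(spec.neck_section_s)
        self.neck_edges = np.array(
            [(s_desc[i] + s_desc[i + 1]) / 2 for i in range(2)])
        self.neck_t = np.array(
            [[spec.wall_thickness[(s, w)] for w in norder] for s in self.neck_secs])
        self.neck_hu = np.array(
            [[spec.cortical_hu[(s, w)] for w in norder] for s in self.neck_secs])

        d = spec.neck_axis_dir
        sup = np.array([0.0, 0.0, 1.0])
        u1 = sup - (sup @ d) * d
        self.neck_u1 = u1 / np.linalg.norm(u1)            # in-plane superior ("upper")
        self.neck_u2 = np.array([0.0, 1.0, 0.0])          # anterior

    def _bump(self, theta_deg: np.ndarray, z: np.ndarray) -> np.ndarray:
        sp = self.spec
        ax = np.clip(1.0 - (z / sp.lt_half_extent) ** 2, 0.0, None)
        tw = np.mod(theta_deg + 180.0, 360.0) - 180.0     # wrap to [-180, 180)
        hw = sp.lt_angular_halfwidth_deg
        ang = np.where(np.abs(tw) < hw,
                       np.cos(np.pi * tw / (2.0 * hw)) ** 2, 0.0)
        return sp.lt_height * ax * ang

    def hu(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """HU of canonical-frame sample points (pure geometry, no noise)."""
        sp = self.spec

        # shaft
        a, b = sp.shaft_semi_axes
        r = np.hypot(x, y)
        theta = np.degrees(np.arctan2(y, x))
        in_ax = (z >= sp.shaft_bottom) & (z <= sp.shaft_top)
        band = np.digitize(-z, -self.shaft_edges)         # descending edges
        r_out = _ellipse_radius(theta, a, b) + self._bump(theta, z)
        t = _quadrant_blend(theta, band, self.shaft_t)
        shaft_in = in_ax & (r <= r_out)
        shaft_trab = shaft_in & (r < r_out - t)
        shaft_cort = shaft_in & ~shaft_trab
        shaft_hu = _quadrant_blend(theta, band, self.shaft_hu)

        # neck
        base = sp.neck_base
        d = sp.neck_axis_dir
        px, py, pz = x - base[0], y - base[1], z - base[2]
        s = px * d[0] + py * d[1] + pz * d[2]
        u = px * self.neck_u1[0] + py * self.neck_u1[1] + pz * self.neck_u1[2]
        v = px * self.neck_u2[0] + py * self.neck_u2[1] + pz * self.neck_u2[2]
        rn = np.hypot(u, v)
        thn = np.degrees(np.arctan2(v, u))
        nband = np.digitize(-s, -self.neck_edges)
        na, nb = sp.neck_semi_axes
        rn_out = _ellipse_radius(thn, na, nb)
        tn = _quadrant_blend(thn, nband, self.neck_t)
        neck_in = (s >= 0) & (s <= sp.neck_length) & (rn <= rn_out)
        neck_trab = neck_in & (rn < rn_out - tn)
        neck_cort = neck_in & ~neck_trab
        neck_hu = _quadrant_blend(thn, nband, self.neck_hu)

        # head
        hc = sp.head_center
        rh = np.sqrt((x - hc[0]) ** 2 + (y - hc[1]) ** 2 + (z - hc[2]) ** 2)
        head_in = rh <= sp.head_radius
        head_trab = rh < sp.head_radius - sp.head_shell_thickness
        head_cort = head_in & ~head_trab

        trab = shaft_trab | neck_trab | head_trab
        out = np.full(x.shape, sp.background_hu)
        out[head_cort] = sp.head_shell_hu
        out[neck_cort] = neck_hu[neck_cort]
        out[shaft_cort] = shaft_hu[shaft_cort]
        out[trab] = sp.trabecular_hu
        return out

    def extreme_points(self) -> np.ndarray:
        """Canonical points bounding the solid (for grid sizing)."""
        sp = self.spec
        a, b = sp.shaft_semi_axes
        h = sp.lt_height
        pts = []
        for zc in (sp.shaft_bottom, sp.shaft_top, 0.0):
            pts += [[a + h, 0, zc], [-a, 0, zc], [0, b + h, zc], [0, -(b + h), zc]]
        hc = sp.head_center
        R = sp.head_radius
        for k in range(3):
            for sgn in (-1, 1):
                p = hc.copy()
                p[k] += sgn * R
                pts.append(p.tolist())
        na = max(sp.neck_semi_axes)
        for s in np.linspace(0, sp.neck_length, 6):
            c = sp.neck_base + s * sp.neck_axis_dir
            for dvec in (self.neck_u1, self.neck_u2):
                pts.append((c + na * dvec).tolist())
                pts.append((c - na * dvec).tolist())
        return np.array(pts)


def _phantom_truth(spec: PhantomSpec, R: np.ndarray) -> PhantomTruth:
    d = spec.neck_axis_dir
    s1, s2, s3 = spec.neck_section_s
    h = spec.lt_half_extent
    canonical = {
        "head_center": spec.head_center,
        "neck_subcephalic": spec.neck_base + s1 * d,
        "neck_middle": spec.neck_base + s2 * d,
        "neck_bottom": spec.neck_base + s3 * d,
        "lt_upper_edge": np.array([0.0, 0.0, h]),
        "lt_vertex": np.array([0.0, 0.0, 0.0]),
        "lt_lower_edge": np.array([0.0, 0.0, -h]),
        "shaft_axis_point": np.array([0.0, 0.0, spec.shaft_bottom]),
        "medial": np.array([1.0, 0.0, 0.0]),
        "anterior": np.array([0.0, 1.0, 0.0]),
        "superior": np.array([0.0, 0.0, 1.0]),
    }
    landmarks = {k: R @ v for k, v in canonical.items()}
    roi = {rid: (spec.wall_thickness[(sec, wall)], spec.cortical_hu[(sec, wall)])
           for rid, sec, wall in ROI_TABLE}
    return PhantomTruth(landmarks=landmarks, roi=roi)


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Voxelize a phantom and return the volume plus its exact ground truth.

    Each voxel HU is the mean over ``antialias**3`` sub-voxel sample
    points (partial-volume averaging); ``hu_noise_sd`` adds i.i.d.
    Gaussian noise seeded by ``rng_seed`` afterwards.
    """
    spec.validate()
    R = spec.rotation_matrix()
    model = _PhantomModel(spec)
    sp = spec.spacing

    world_pts = model.extreme_points() @ R.T
    lo = world_pts.min(axis=0) - spec.margin
    hi = world_pts.max(axis=0) + spec.margin
    shape = np.ceil((hi - lo) / sp).astype(int) + 1
    origin = lo

    vals = np.zeros(tuple(shape), dtype=np.float64)
    k = spec.antialias
    offs = (np.arange(k) + 0.5) / k - 0.5
    Rt = R.T

    def canonical(wx, wy, wz):
        cx = Rt[0, 0] * wx + Rt[0, 1] * wy + Rt[0, 2] * wz
        cy = Rt[1, 0] * wx + Rt[1, 1] * wy + Rt[1, 2] * wz
        cz = Rt[2, 0] * wx + Rt[2, 1] * wy + Rt[2, 2] * wz
        return cx, cy, cz

    # pass 1: voxel-centre classification everywhere
    iy = np.arange(shape[1])
    iz = np.arange(shape[2])
    chunk = max(1, int(4e6 // (shape[1] * shape[2])))
    for x0 in range(0, shape[0], chunk):
        ix = np.arange(x0, min(x0 + chunk, shape[0]))
        wx = origin[0] + ix[:, None, None] * sp[0]
        wy = origin[1] + iy[None, :, None] * sp[1]
        wz = origin[2] + iz[None, None, :] * sp[2]
        vals[x0:x0 + chunk] = model.hu(*canonical(wx, wy, wz))

    # pass 2: partial-volume supersampling, restricted to voxels near a
    # material boundary (the phantom is piecewise constant elsewhere)
    if k > 1:
        from scipy import ndimage

        mx = ndimage.maximum_filter(vals, size=3)
        mn = ndimage.minimum_filter(vals, size=3)
        mixed = ndimage.binary_dilation(mx != mn)
        idx = np.argwhere(mixed)
        if idx.size:
            base = origin + idx * sp
            acc = np.zeros(idx.shape[0])
            for ox in offs:
                for oy in offs:
                    for oz in offs:
                        wx = base[:, 0] + ox * sp[0]
                        wy = base[:, 1] + oy * sp[1]
                        wz = base[:, 2] + oz * sp[2]
                        acc += model.hu(*canonical(wx, wy, wz))
            vals[mixed] = acc / k ** 3

    if spec.hu_noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        vals += rng.normal(0.0, spec.hu_noise_sd, size=vals.shape)

    axes = _grid_axis_labels(R)
    volume = CTVolume(values=vals, voxel_spacing=sp, origin=origin, axes=axes)
    return volume, _phantom_truth(spec, R)


def _grid_axis_labels(R: np.ndarray) -> tuple[str, str, str]:
    """Label each grid axis by the anatomical axis it is most aligned with."""
    names = ["medial", "anterior", "superior"]
    labels = []
    used: set[int] = set()
    for g in range(3):
        comps = np.abs(R[g, :])
        for j in np.argsort(-comps):
            if j not in used:
                used.add(int(j))
                labels.append(names[int(j)])
                break
    return tuple(labels)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# NIfTI I/O


def write_volume(volume: CTVolume, path) -> None:
    """Write a CTVolume as NIfTI-1, preserving HU, spacing and axis labels."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.voxel_spacing)
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.values.astype(np.float64), affine)
    img.header.set_zooms(tuple(volume.voxel_spacing))
    img.header["descrip"] = ("axes=" + ",".join(volume.axes)).encode()
    nib.save(img, str(path))


def read_volume(path) -> CTVolume:
    """Read a NIfTI-1 volume written by :func:`write_volume`."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"cannot parse NIfTI volume at {path}: {exc}") from exc
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if np.any(zooms <= 0):
        raise ValueError(f"malformed volume {path}: non-positive voxel spacing {zooms}")
    affine = img.affine
    origin = affine[:3, 3]
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="replace")
    axes: tuple[str, str, str] = ("medial", "anterior", "superior")
    if descrip.startswith("axes="):
        parts = tuple(descrip[5:].split(","))
        if len(parts) == 3 and len(set(parts)) == 3:
            axes = parts  # type: ignore[assignment]
        else:
            raise ValueError(f"malformed volume {path}: bad axes field {descrip!r}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    return CTVolume(values=data, voxel_spacing=zooms, origin=origin, axes=axes)


def write_truth_csv(truth: PhantomTruth, path) -> None:
    """Write the per-ROI ground truth as CSV."""
    truth.to_frame().to_csv(path, index=False)


def rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues), for rotated phantoms."""
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    t = np.deg2rad(angle_deg)
    K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)
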