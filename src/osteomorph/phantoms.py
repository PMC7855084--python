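"""In silico phantoms of vascular canals and osteocyte lacunae.

Vascular canals are modelled as elliptic cylinders and osteocyte lacunae as
3:1:1 prolate spheroids, placed at the centre of a cubic voxel domain and
rotated by three random elemental rotations.  Shapes are rendered with
supersampled occupancy (partial-volume grey values) and binarised with a
minimum-cross-entropy (Li) threshold, emulating the surface-to-mask plus
auto-threshold route of typical CT segmentation toolchains.

Coordinate conventions
----------------------
Volumes are stored as ``values[z, y, x]``; vectors are ``(x, y, z)``.
Voxel centres sit at integer + 0.5 positions, so a cubic domain of edge
``N`` spans ``[0, N]`` with its geometric centre at ``N / 2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "RotationTriple",
    "CylinderSpec",
    "EllipsoidSpec",
    "GroundTruth",
    "VoxelVolume",
    "sample_rotation",
    "rotation_matrix",
    "ground_truth_angles",
    "fold_axis_angle",
    "voxelise",
    "li_threshold",
    "li_threshold_iterative",
    "extract_slices",
    "generate_cohort",
    "cohort_manifest",
]

#: half body-diagonal of a unit voxel; any point of a voxel lies within this
#: distance of its centre, so centre-distance bounds beyond it are decisive.
_HALF_DIAGONAL = float(np.sqrt(3.0) / 2.0)

_TRANSVERSE_EPS = 1e-9


# ---------------------------------------------------------------------------
# rotations and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RotationTriple:
    """Three elemental rotation angles in degrees, applied about the fixed
    world y-, x- and z-axis, in that order."""

    ry: float
    rx: float
    rz: float

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.ry, self.rx, self.rz)


def sample_rotation(range_max: float, rng: np.random.Generator) -> RotationTriple:
    """Draw three independent angles, each uniform on ``[0, range_max]`` degrees.

    ``range_max = 90`` emulates randomly oriented structures (woven bone),
    ``range_max = 22.5`` near-longitudinally aligned ones (parallel-fibred
    bone).
    """
    if not range_max > 0:
        raise ValueError(f"range_max must be positive, got {range_max}")
    ry, rx, rz = rng.uniform(0.0, range_max, size=3)
    return RotationTriple(float(ry), float(rx), float(rz))


def _ry(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rx(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rz(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_matrix(rot: RotationTriple) -> np.ndarray:
    """Compose the three elemental rotations about fixed world axes,
    y then x then z: ``R = Rz @ Rx @ Ry``."""
    if not all(np.isfinite(rot.as_tuple())):
        raise ValueError("rotation angles must be finite")
    return _rz(rot.rz) @ _rx(rot.rx) @ _ry(rot.ry)


def fold_axis_angle(angle_deg: float, reference_deg: float = 0.0) -> float:
    """Acute angle between two undirected lines given their direction angles,
    folded into [0, 90] degrees."""
    d = abs(angle_deg - reference_deg) % 180.0
    return min(d, 180.0 - d)


@dataclass
class GroundTruth:
    """Set orientation (and, for lacunae, set volume) of a phantom.

    ``omega_true`` is the longitudinal angle: 90 deg for a structure parallel
    to the bone's long (z) axis, 0 deg for a transverse one.  ``theta_true``
    is the radial angle of the transverse projection against the x-axis
    tangent; it is ``None`` for perfectly longitudinal axes, whose transverse
    projection vanishes.
    """

    axis_vector: np.ndarray
    omega_true: float
    theta_true: Optional[float]
    volume_true: Optional[float] = None


def ground_truth_angles(
    rot: RotationTriple,
    initial_axis: Tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> GroundTruth:
    """Rotate ``initial_axis`` and derive the set longitudinal and radial angles."""
    u = np.asarray(initial_axis, dtype=float)
    norm = np.linalg.norm(u)
    if norm < _TRANSVERSE_EPS:
        raise ValueError("initial_axis must be a nonzero vector")
    u = u / norm
    v = rotation_matrix(rot) @ u
    omega = float(np.degrees(np.arcsin(np.clip(abs(v[2]), 0.0, 1.0))))
    planar = float(np.hypot(v[0], v[1]))
    if planar < _TRANSVERSE_EPS:
        theta: Optional[float] = None
    else:
        theta = fold_axis_angle(float(np.degrees(np.arctan2(v[1], v[0]))))
    return GroundTruth(axis_vector=v, omega_true=omega, theta_true=theta)


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CylinderSpec:
    """Elliptic cylinder standing in for a vascular canal.

    The unrotated cylinder lies in the transverse plane, along the y-axis,
    so that the three elemental rotations play distinct roles: the first
    (about y) spins the elliptic cross-section about the canal's own axis,
    the second (about x) sets the longitudinal angle directly (omega = rx),
    and the third (about z) sets the radial angle (theta = 90 - rz).  Both
    set angles are therefore uniform on [0, 90] under uniform rotation
    draws.  The elliptic cross-section has minor diameter
    ``minor_diameter`` and major diameter ``minor_diameter * aspect_ratio``.
    All lengths are in voxel units.
    """

    rotation: RotationTriple
    length: float = 400.0
    minor_diameter: float = 10.0
    aspect_ratio: float = 1.0
    domain_edge: int = 500

    def __post_init__(self):
        if self.aspect_ratio < 1.0:
            raise ValueError("aspect_ratio must be >= 1")
        if self.length <= 0 or self.minor_diameter <= 0:
            raise ValueError("length and minor_diameter must be positive")

    @property
    def semi_minor(self) -> float:
        return self.minor_diameter / 2.0

    @property
    def semi_major(self) -> float:
        return self.semi_minor * self.aspect_ratio

    @property
    def voxel_size(self) -> float:
        return 1.0

    #: unrotated canal direction: in-plane, along y
    initial_axis: Tuple[float, float, float] = (0.0, 1.0, 0.0)

    def ground_truth(self) -> GroundTruth:
        return ground_truth_angles(self.rotation, initial_axis=self.initial_axis)


@dataclass(frozen=True)
class EllipsoidSpec:
    """3:1:1 prolate spheroid standing in for an osteocyte lacuna.

    ``full_axes`` are the physical full axis lengths in micrometres; the
    unrotated major axis lies along z.  The rendered size in voxels is
    ``full_axes / voxel_size``, emulating the same lacuna imaged at different
    nominal voxel sizes.
    """

    rotation: RotationTriple
    voxel_size: float = 0.8
    full_axes: Tuple[float, float, float] = (15.0, 5.0, 5.0)
    domain_edge: int = 50
    alignment_mode: str = "woven"

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.alignment_mode not in ("woven", "parallel_fibred"):
            raise ValueError(f"unknown alignment_mode {self.alignment_mode!r}")

    @property
    def semi_axes_um(self) -> Tuple[float, float, float]:
        a, b, c = self.full_axes
        return (a / 2.0, b / 2.0, c / 2.0)

    @property
    def semi_axes_voxels(self) -> np.ndarray:
        return np.asarray(self.semi_axes_um) / self.voxel_size

    @property
    def nominal_volume(self) -> float:
        """Analytic ellipsoid volume in cubic micrometres (about 196.3)."""
        r1, r2, r3 = self.semi_axes_um
        return float(4.0 / 3.0 * np.pi * r1 * r2 * r3)

    def ground_truth(self) -> GroundTruth:
        # major axis initially along z: parallel-fibred rotations (<= 22.5 deg)
        # keep the lacuna near-longitudinal
        gt = ground_truth_angles(self.rotation, initial_axis=(0.0, 0.0, 1.0))
        gt.volume_true = self.nominal_volume
        return gt


PhantomSpec = Union[CylinderSpec, EllipsoidSpec]


# ---------------------------------------------------------------------------
# voxel volume container
# ---------------------------------------------------------------------------

@dataclass
class VoxelVolume:
    """A 3D image plus voxel metadata.

    ``values`` may be a cropped sub-block of the nominal cubic domain;
    ``offset`` holds the (z, y, x) voxel index of the crop origin within the
    full domain and ``domain_shape`` the full domain shape.  Grey volumes hold
    occupancy fractions in [0, 1]; binary volumes hold booleans.
    """

    values: np.ndarray
    voxel_size: float = 1.0
    offset: Tuple[int, int, int] = (0, 0, 0)
    domain_shape: Optional[Tuple[int, int, int]] = None

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if self.domain_shape is None:
            self.domain_shape = tuple(self.values.shape)

    @property
    def is_binary(self) -> bool:
        return self.values.dtype == bool

    def foreground_count(self) -> int:
        if self.is_binary:
            return int(self.values.sum())
        return int(np.count_nonzero(self.values))

    def foreground_volume(self) -> float:
        """Physical foreground volume (count x voxel_size^3)."""
        return self.foreground_count() * self.voxel_size ** 3

    def full_array(self) -> np.ndarray:
        """Materialise the full (uncropped) domain array."""
        out = np.zeros(self.domain_shape, dtype=self.values.dtype)
        z0, y0, x0 = self.offset
        nz, ny, nx = self.values.shape
        out[z0:z0 + nz, y0:y0 + ny, x0:x0 + nx] = self.values
        return out


# ---------------------------------------------------------------------------
# voxelisation
# ---------------------------------------------------------------------------

def _local_frame(spec: PhantomSpec):
    """Return (R, centre, margins_fn, inside_fn, support) for a phantom.

    ``margins_fn`` maps local (x', y', z') coordinate arrays to a signed
    bound ``d``: ``d <= -m`` guarantees the whole voxel (half-diagonal m)
    is inside the shape, ``d >= m`` guarantees it is outside.  The bound
    relies on the implicit functions being Lipschitz with constant
    1 / (smallest semi-axis) in each term.
    """
    R = rotation_matrix(spec.rotation)
    centre = spec.domain_edge / 2.0

    if isinstance(spec, CylinderSpec):
        # the implicit solid is defined along its local z-axis; align local z
        # with the unrotated canal direction (y) before the world rotation
        R = R @ _rx(-90.0)
        a, b, hl = spec.semi_major, spec.semi_minor, spec.length / 2.0

        def margins(lx, ly, lz):
            rho = np.sqrt((lx / a) ** 2 + (ly / b) ** 2)
            return np.maximum((rho - 1.0) * b, np.abs(lz) - hl)

        def inside(lx, ly, lz):
            return ((lx / a) ** 2 + (ly / b) ** 2 <= 1.0) & (np.abs(lz) <= hl)

        # exact support of the rotated solid along each world axis
        support = np.array([
            hl * abs(R[i, 2]) + np.hypot(R[i, 0] * a, R[i, 1] * b)
            for i in range(3)
        ])
    else:
        semi = spec.semi_axes_voxels  # (major, minor, minor), local z = major
        sx, sy, sz = semi[1], semi[2], semi[0]
        smin = float(min(sx, sy, sz))

        def margins(lx, ly, lz):
            rho = np.sqrt((lx / sx) ** 2 + (ly / sy) ** 2 + (lz / sz) ** 2)
            return (rho - 1.0) * smin

        def inside(lx, ly, lz):
            return (lx / sx) ** 2 + (ly / sy) ** 2 + (lz / sz) ** 2 <= 1.0

        s_local = np.array([sx, sy, sz])
        support = np.sqrt(((R * s_local[None, :]) ** 2).sum(axis=1))

    return R, centre, margins, inside, support


def voxelise(spec: PhantomSpec, supersampling: int = 5) -> VoxelVolume:
    """Render a phantom to a grey occupancy volume.

    Each voxel's value is the fraction of ``supersampling ** 3`` regularly
    spaced sample points falling inside the rotated implicit surface.  Voxels
    provably interior or exterior (by a signed distance bound at the voxel
    centre) skip the supersampling.  Only the axis-aligned bounding box of
    the rotated shape (plus a 2-voxel margin) is evaluated; the result is a
    cropped :class:`VoxelVolume` that remembers its position in the domain.
    """
    if supersampling < 1:
        raise ValueError("supersampling must be >= 1")
    R, centre, margins, inside, support = _local_frame(spec)
    n = spec.domain_edge

    if np.any(support > centre):
        warnings.warn(
            "phantom extends beyond the cubic domain and will be clipped",
            stacklevel=2,
        )

    lo = np.maximum(np.floor(centre - support - 2.0).astype(int), 0)
    hi = np.minimum(np.ceil(centre + support + 2.0).astype(int), n)
    # lo/hi are in (x, y, z) order; array axes are (z, y, x)
    x0, y0, z0 = lo
    x1, y1, z1 = hi
    shape = (z1 - z0, y1 - y0, x1 - x0)
    occ = np.zeros(shape, dtype=np.float32)

    xs = (np.arange(x0, x1) + 0.5) - centre
    ys = (np.arange(y0, y1) + 0.5) - centre
    m = _HALF_DIAGONAL + 1e-6

    boundary_idx = []  # (nz_chunk arrays) of global crop indices
    chunk = max(1, int(4e6 // (shape[1] * shape[2] + 1)))
    for zc in range(0, shape[0], chunk):
        zs = (np.arange(z0 + zc, min(z1, z0 + zc + chunk)) + 0.5) - centre
        xg = xs[None, None, :]
        yg = ys[None, :, None]
        zg = zs[:, None, None]
        # local coords: l_k = sum_i R[i, k] * p_i  (R orthonormal)
        lx = xg * R[0, 0] + yg * R[1, 0] + zg * R[2, 0]
        ly = xg * R[0, 1] + yg * R[1, 1] + zg * R[2, 1]
        lz = xg * R[0, 2] + yg * R[1, 2] + zg * R[2, 2]
        d = margins(lx, ly, lz)
        occ[zc:zc + len(zs)][d <= -m] = 1.0
        bz, by, bx = np.nonzero(np.abs(d) < m)
        boundary_idx.append((bz + zc, by, bx))

    bz = np.concatenate([b[0] for b in boundary_idx])
    by = np.concatenate([b[1] for b in boundary_idx])
    bx = np.concatenate([b[2] for b in boundary_idx])

    if bz.size:
        s = supersampling
        off = (np.arange(s) + 0.5) / s - 0.5
        ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
        offs = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])  # (s^3, 3)
        block = max(1, int(2e6 // (offs.shape[0] + 1)))
        for i in range(0, bz.size, block):
            sl = slice(i, i + block)
            cx = (bx[sl] + x0 + 0.5) - centre
            cy = (by[sl] + y0 + 0.5) - centre
            cz = (bz[sl] + z0 + 0.5) - centre
            pts = np.stack([cx, cy, cz], axis=1)[:, None, :] + offs[None, :, :]
            loc = pts @ R  # row-vector form of R^T p
            frac = inside(loc[..., 0], loc[..., 1], loc[..., 2]).mean(axis=1)
            occ[bz[sl], by[sl], bx[sl]] = frac.astype(np.float32)

    return VoxelVolume(
        values=occ,
        voxel_size=spec.voxel_size,
        offset=(z0, y0, x0),
        domain_shape=(n, n, n),
    )


# ---------------------------------------------------------------------------
# Li (minimum cross-entropy) threshold
# ---------------------------------------------------------------------------

def _cross_entropy_curve(values: np.ndarray, nbins: int, vmin: float, vmax: float):
    hist, edges = np.histogram(values, bins=nbins, range=(vmin, vmax))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist * centers
    cum_n = np.cumsum(hist)
    cum_w = np.cumsum(w)
    total_n, total_w = cum_n[-1], cum_w[-1]

    # candidate cut before bin k (k = 1 .. nbins-1); background = bins < k
    nb = cum_n[:-1].astype(float)
    sb = cum_w[:-1]
    nf = total_n - nb
    sf = total_w - sb
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_b = np.where(nb > 0, sb / np.maximum(nb, 1), 0.0)
        mu_f = np.where(nf > 0, sf / np.maximum(nf, 1), 0.0)
        term_b = np.where((sb > 0) & (mu_b > 0), -sb * np.log(mu_b), 0.0)
        term_f = np.where((sf > 0) & (mu_f > 0), -sf * np.log(mu_f), 0.0)
    return edges, term_b + term_f


def li_threshold(
    grey: Union[VoxelVolume, np.ndarray],
    nbins: int = 256,
    ignore_zero: bool = True,
) -> Tuple[Union[VoxelVolume, np.ndarray], float]:
    """Binarise a grey image at the minimum-cross-entropy (Li) threshold.

    The cross-entropy is minimised exhaustively over the cut points of a
    256-bin histogram of the grey values.  With ``ignore_zero`` (default),
    exactly-zero voxels are excluded from the histogram: synthetic occupancy
    volumes are dominated by empty background at exactly 0, which carries no
    grey-level information (unlike the noisy background of a real CT scan)
    and would otherwise swamp the background statistics.  The histogram then
    spans ``(0, max]``, matching the 8-bit convention of histogram-based
    implementations.  Foreground is ``grey >= threshold``.
    """
    arr = grey.values if isinstance(grey, VoxelVolume) else np.asarray(grey)
    vals = arr[np.isfinite(arr)].ravel()
    if ignore_zero:
        vals = vals[vals > 0]
    if vals.size == 0 or vals.min() == vals.max():
        raise ValueError("image is constant; no threshold exists")

    vmin = 0.0 if ignore_zero else float(vals.min())
    vmax = float(vals.max())
    edges, ce = _cross_entropy_curve(vals, nbins, vmin, vmax)
    k = int(np.argmin(ce)) + 1
    threshold = float(edges[k])

    binary = arr >= threshold
    if isinstance(grey, VoxelVolume):
        return (
            VoxelVolume(
                values=binary,
                voxel_size=grey.voxel_size,
                offset=grey.offset,
                domain_shape=grey.domain_shape,
            ),
            threshold,
        )
    return binary, threshold


def li_threshold_iterative(
    grey: Union[VoxelVolume, np.ndarray],
    ignore_zero: bool = True,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Li's fixed-point iteration for the minimum-cross-entropy threshold.

    ``t <- (mu_b(t) - mu_f(t)) / (ln mu_b(t) - ln mu_f(t))`` on the raw grey
    values.  Serves as an independent check of the exhaustive histogram
    search; the two agree to within a histogram bin width.
    """
    arr = grey.values if isinstance(grey, VoxelVolume) else np.asarray(grey)
    vals = arr[np.isfinite(arr)].ravel().astype(float)
    if ignore_zero:
        vals = vals[vals > 0]
    if vals.size == 0 or vals.min() == vals.max():
        raise ValueError("image is constant; no threshold exists")
    if vals.min() <= 0:
        vals = vals - vals.min() + 1e-12  # log-mean iteration needs positives

    t = float(vals.mean())
    for _ in range(max_iter):
        back = vals[vals < t]
        fore = vals[vals >= t]
        if back.size == 0 or fore.size == 0:
            break
        mu_b, mu_f = back.mean(), fore.mean()
        if mu_b <= 0 or abs(np.log(mu_b) - np.log(mu_f)) < 1e-30:
            break
        t_new = (mu_b - mu_f) / (np.log(mu_b) - np.log(mu_f))
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    return float(t)


# ---------------------------------------------------------------------------
# slice extraction
# ---------------------------------------------------------------------------

def extract_slices(volume: VoxelVolume) -> Tuple[np.ndarray, np.ndarray]:
    """Extract the transverse (xy) and perpendicular (xz) mid-slices.

    The xy slice is taken at z index ``floor(Nz / 2)`` and the xz reslice at
    y index ``floor(Ny / 2)``; for centred phantoms both pass through the
    shape midpoint.  Slices are returned at full domain extent, with the
    cropped data placed at its true position.
    """
    nz, ny, nx = volume.domain_shape
    z0, y0, x0 = volume.offset
    cz, cy, cx = volume.values.shape
    zmid, ymid = nz // 2, ny // 2

    xy = np.zeros((ny, nx), dtype=volume.values.dtype)
    if z0 <= zmid < z0 + cz:
        xy[y0:y0 + cy, x0:x0 + cx] = volume.values[zmid - z0]

    xz = np.zeros((nz, nx), dtype=volume.values.dtype)
    if y0 <= ymid < y0 + cy:
        xz[z0:z0 + cz, x0:x0 + cx] = volume.values[:, ymid - y0, :]

    return xy, xz


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class PhantomRecord:
    """One generated phantom: its specification, ground truth and rendering."""

    index: int
    seed: int
    spec: PhantomSpec
    truth: GroundTruth
    binary: VoxelVolume
    threshold: float
    grey: Optional[VoxelVolume] = None


def generate_cohort(
    kind: str,
    n: int,
    seed: int,
    *,
    aspect_ratio: float = 1.0,
    voxel_size: float = 0.8,
    alignment_mode: str = "woven",
    length: float = 400.0,
    minor_diameter: float = 10.0,
    domain_edge: Optional[int] = None,
    supersampling: int = 5,
    keep_grey: bool = False,
) -> Iterator[PhantomRecord]:
    """Generate a cohort of phantoms with independent random rotations.

    Yields one :class:`PhantomRecord` at a time (volumes are large, so the
    cohort is streamed rather than held in memory).  Each phantom uses its
    own RNG seeded ``seed + index``, making any phantom reproducible from the
    manifest alone.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind not in ("cylinder", "ellipsoid"):
        raise ValueError(f"unknown phantom kind {kind!r}")

    for i in range(n):
        sub_seed = (seed + i) % (2 ** 31)
        rng = np.random.default_rng(sub_seed)
        if kind == "cylinder":
            rot = sample_rotation(90.0, rng)
            spec: PhantomSpec = CylinderSpec(
                rotation=rot,
                length=length,
                minor_diameter=minor_diameter,
                aspect_ratio=aspect_ratio,
                domain_edge=500 if domain_edge is None else domain_edge,
            )
        else:
            range_max = 90.0 if alignment_mode == "woven" else 22.5
            rot = sample_rotation(range_max, rng)
            spec = EllipsoidSpec(
                rotation=rot,
                voxel_size=voxel_size,
                alignment_mode=alignment_mode,
                domain_edge=50 if domain_edge is None else domain_edge,
            )
        truth = spec.ground_truth()
        grey = voxelise(spec, supersampling=supersampling)
        binary, thr = li_threshold(grey)
        yield PhantomRecord(
            index=i,
            seed=sub_seed,
            spec=spec,
            truth=truth,
            binary=binary,
            threshold=thr,
            grey=grey if keep_grey else None,
        )


def cohort_manifest(records, paths=None) -> pd.DataFrame:
    """Build the cohort manifest: per-phantom seed, rotation, ground truth."""
    rows = []
    for k, rec in enumerate(records):
        rot = rec.spec.rotation
        rows.append({
            "index": rec.index,
            "seed": rec.seed,
            "ry": rot.ry,
            "rx": rot.rx,
            "rz": rot.rz,
            "omega_true": rec.truth.omega_true,
            "theta_true": np.nan if rec.truth.theta_true is None else rec.truth.theta_true,
            "volume_true": np.nan if rec.truth.volume_true is None else rec.truth.volume_true,
            "path": "" if paths is None else str(paths[k]),
        })
    return pd.DataFrame(rows)
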