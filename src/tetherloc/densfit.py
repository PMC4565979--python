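"""Density-map operations: rasterization, filtering, rigid-body fitting,
FSC, contouring, mirroring and the handedness test.

A :class:`DensityMap` is a 3-D voxel grid indexed ``grid[ix, iy, iz]`` with an
isotropic voxel edge (Å) and a physical origin (Å, position of voxel
``(0, 0, 0)``'s center).  Maps are read and written in CCP4/MRC mode-2 float
format through gemmi, with voxel size and origin honored bit-exactly on
round-trip.

The exhaustive fitting search rasterizes a Cα probe model onto the map grid
for each orientation of a near-uniform SO(3) grid and scores all translations
at once with FFT cross-correlation.  Filters used inside the search (the
point-spread Gaussian and the optional Laplacian contrast filter, applied to
both map and probe) act by circular convolution so that the spectral score
equals a direct-space correlation exactly; the standalone :func:`laplacian`
operator instead uses zero-flux boundaries, the convention expected of a
stencil filter applied once to a finished map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy import ndimage
from scipy.stats import binomtest

from .structio import RigidTransform, StructureModel

__all__ = [
    "DensityMap",
    "FitResult",
    "FSCCurve",
    "read_ccp4",
    "rasterize_points",
    "lowpass",
    "laplacian",
    "mirror",
    "rotation_grid",
    "exhaustive_fit",
    "match_maps",
    "handedness_test",
    "fsc",
    "resolution_at",
    "contour_by_volume",
    "model_volume",
    "residual_segment",
]

# FWHM = 2·sqrt(2·ln 2)·σ for a Gaussian
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class DensityMap:
    """Voxel grid with isotropic spacing; physical position of voxel (i,j,k)
    is ``origin + voxel * (i, j, k)``."""

    grid: np.ndarray
    voxel: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.voxel <= 0:
            raise ValueError("voxel size must be positive")
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel, self.origin.copy())

    def total_volume(self) -> float:
        return self.grid.size * self.voxel**3

    def voxel_center(self, idx) -> np.ndarray:
        return self.origin + self.voxel * np.asarray(idx, dtype=float)

    # -- CCP4/MRC I/O ---------------------------------------------------
    def write_ccp4(self, path: str | Path) -> None:
        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(np.ascontiguousarray(self.grid, dtype=np.float32))
        n = self.grid.shape
        m.grid.unit_cell = gemmi.UnitCell(
            n[0] * self.voxel, n[1] * self.voxel, n[2] * self.voxel, 90, 90, 90
        )
        m.grid.spacegroup = gemmi.SpaceGroup("P1")
        m.update_ccp4_header()
        for word, val in zip((50, 51, 52), self.origin):
            m.set_header_float(word, float(val))
        m.write_ccp4_map(str(path))


def read_ccp4(path: str | Path) -> DensityMap:
    m = gemmi.read_ccp4_map(str(path))
    grid = np.array(m.grid, copy=True)
    voxel = m.grid.unit_cell.a / m.grid.nu
    origin = np.array([m.header_float(w) for w in (50, 51, 52)])
    return DensityMap(grid.astype(np.float64), float(voxel), origin)


# ---------------------------------------------------------------------------
# rasterization (model → density bridge)
# ---------------------------------------------------------------------------

def rasterize_points(
    points: np.ndarray,
    shape: tuple[int, int, int],
    voxel: float,
    origin: np.ndarray,
    resolution: float,
) -> np.ndarray:
    """Sum of unit-integral isotropic Gaussians (FWHM = ``resolution``)
    centered on ``points``, sampled at voxel centers.

    The grid integral (sum × voxel³) approaches the number of points as the
    grid covers the Gaussians' support.
    """
    if resolution < 2.0 * voxel:
        raise ValueError(
            f"resolution {resolution} Å below Nyquist limit 2·voxel = {2 * voxel} Å"
        )
    sigma = resolution / _FWHM
    amp = (2.0 * math.pi * sigma**2) ** -1.5
    grid = np.zeros(shape, dtype=np.float64)
    reach = int(math.ceil(4.0 * sigma / voxel))
    pts = (np.atleast_2d(points) - origin) / voxel  # fractional voxel coords
    for u in pts:
        lo = np.maximum(np.ceil(u - reach).astype(int), 0)
        hi = np.minimum(np.floor(u + reach).astype(int), np.array(shape) - 1)
        if np.any(lo > hi):
            continue
        ax = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        d2 = (
            (ax[0][:, None, None] - u[0]) ** 2
            + (ax[1][None, :, None] - u[1]) ** 2
            + (ax[2][None, None, :] - u[2]) ** 2
        ) * voxel**2
        grid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += amp * np.exp(
            -d2 / (2.0 * sigma**2)
        )
    return grid


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def lowpass(dmap: DensityMap, resolution: float) -> DensityMap:
    """Gaussian low-pass: attenuation reaches one half at spatial frequency
    1/``resolution``. The mean density (zero-frequency term) is preserved."""
    if resolution < 2.0 * dmap.voxel:
        raise ValueError(
            f"resolution {resolution} Å below Nyquist limit 2·voxel = {2 * dmap.voxel} Å"
        )
    F = np.fft.fftn(dmap.grid)
    f2 = _freq2_grid(dmap.shape, dmap.voxel)
    F *= np.exp(-math.log(2.0) * f2 * resolution**2)
    return DensityMap(np.fft.ifftn(F).real, dmap.voxel, dmap.origin.copy())


def _freq2_grid(shape, voxel) -> np.ndarray:
    fx = np.fft.fftfreq(shape[0], d=voxel)
    fy = np.fft.fftfreq(shape[1], d=voxel)
    fz = np.fft.fftfreq(shape[2], d=voxel)
    return (
        fx[:, None, None] ** 2 + fy[None, :, None] ** 2 + fz[None, None, :] ** 2
    )


def laplacian(dmap: DensityMap) -> DensityMap:
    """Discrete 6-neighbor Laplacian (∇²) with zero-flux boundaries, in Å⁻²."""
    out = ndimage.laplace(dmap.grid, mode="nearest") / dmap.voxel**2
    return DensityMap(out, dmap.voxel, dmap.origin.copy())


def _spectral_laplacian_transfer(shape, voxel) -> np.ndarray:
    """Transfer function of the circular 6-point Laplacian stencil."""
    wx = 2.0 * np.cos(2.0 * np.pi * np.fft.fftfreq(shape[0]))
    wy = 2.0 * np.cos(2.0 * np.pi * np.fft.fftfreq(shape[1]))
    wz = 2.0 * np.cos(2.0 * np.pi * np.fft.fftfreq(shape[2]))
    return (
        wx[:, None, None] + wy[None, :, None] + wz[None, None, :] - 6.0
    ) / voxel**2


def mirror(dmap: DensityMap) -> DensityMap:
    """Flip handedness by reversing the x axis (an involution).  The origin is
    kept, so the mirrored grid occupies the same physical extents."""
    return DensityMap(dmap.grid[::-1, :, :].copy(), dmap.voxel, dmap.origin.copy())


# ---------------------------------------------------------------------------
# orientation sampling
# ---------------------------------------------------------------------------

def rotation_grid(step_deg: float) -> np.ndarray:
    """Near-uniform SO(3) grid: Fibonacci-sphere axis directions crossed with
    uniformly spaced in-plane spins, sized so nearest-neighbor angular spacing
    stays at or below ``step_deg``.  Returns (n, 3, 3) rotation matrices."""
    if step_deg <= 0:
        raise ValueError("angular step must be positive")
    step = math.radians(step_deg)
    n_dir = max(1, int(math.ceil((3.6 / step) ** 2)))
    n_spin = max(1, int(math.ceil(2.0 * math.pi / step)))
    # Fibonacci sphere
    i = np.arange(n_dir) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n_dir
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    spins = 2.0 * math.pi * np.arange(n_spin) / n_spin
    cos_s, sin_s = np.cos(spins), np.sin(spins)
    Rz = np.zeros((n_spin, 3, 3))
    Rz[:, 0, 0] = cos_s
    Rz[:, 0, 1] = -sin_s
    Rz[:, 1, 0] = sin_s
    Rz[:, 1, 1] = cos_s
    Rz[:, 2, 2] = 1.0
    out = np.empty((1 + n_dir * n_spin, 3, 3))
    out[0] = np.eye(3)  # the identity is always on the grid
    zhat = np.array([0.0, 0.0, 1.0])
    for j, d in enumerate(dirs):
        # minimal rotation taking z onto d
        v = np.cross(zhat, d)
        c = float(zhat @ d)
        if np.linalg.norm(v) < 1e-12:
            A = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            A = np.eye(3) + vx + vx @ vx / (1.0 + c)
        out[1 + j * n_spin:1 + (j + 1) * n_spin] = A @ Rz
    return out


def _rotation_angle_deg(Ra: np.ndarray, Rb: np.ndarray) -> float:
    c = np.clip((np.trace(Ra.T @ Rb) - 1.0) / 2.0, -1.0, 1.0)
    return math.degrees(math.acos(c))


# ---------------------------------------------------------------------------
# exhaustive rigid-body fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    transform: RigidTransform  # maps original probe coordinates into map frame
    ccc: float
    rank: int = 0


def _trilinear_deposit(grid: np.ndarray, frac: np.ndarray) -> None:
    """Deposit unit weights at fractional voxel coordinates (cloud-in-cell),
    wrapping periodically (consistent with circular FFT correlation)."""
    shape = np.array(grid.shape)
    base = np.floor(frac).astype(int)
    w = frac - base
    for corner in range(8):
        off = np.array([(corner >> d) & 1 for d in range(3)])
        weight = np.prod(np.where(off == 1, w, 1.0 - w), axis=1)
        idx = (base + off) % shape
        np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), weight)


def placed_ccc(
    dmap: DensityMap,
    points: np.ndarray,
    resolution: float,
    laplacian_filter: bool = False,
) -> float:
    """Correlation coefficient of the map against the density of an already
    placed point set, rasterized exactly (direct Gaussian evaluation).  Used
    to re-score search candidates free of the fast path's interpolation."""
    dens = rasterize_points(points, dmap.shape, dmap.voxel, dmap.origin, resolution)
    f, g = dmap.grid, dens
    if laplacian_filter:
        f = _circular_laplacian(f, dmap.voxel)
        g = _circular_laplacian(g, dmap.voxel)
    f = f - f.mean()
    g = g - g.mean()
    denom = math.sqrt(float((f**2).sum()) * float((g**2).sum()))
    if denom == 0.0:
        return 0.0
    return float((f * g).sum() / denom)


def _fit_spectra(dmap: DensityMap, psf: float, laplacian_filter: bool):
    """Shared preprocessing for spectral scoring: the zero-mean (optionally
    Laplacian-filtered) map spectrum, the probe transfer function and the map
    norm."""
    shape = dmap.shape
    voxel = dmap.voxel
    sigma = psf / _FWHM
    N = dmap.grid.size
    F_map = np.fft.fftn(dmap.grid)
    F_map.flat[0] = 0.0  # subtract mean
    transfer = np.exp(-2.0 * (math.pi * sigma) ** 2 * _freq2_grid(shape, voxel))
    transfer = transfer * (2.0 * math.pi * sigma**2) ** -1.5 * voxel**3
    if laplacian_filter:
        L = _spectral_laplacian_transfer(shape, voxel)
        F_map = F_map * L
        transfer = transfer * L
    map_norm = math.sqrt(float(np.sum(np.abs(F_map) ** 2)) / N)
    return F_map, transfer, map_norm


def _spectral_scores(F_map, transfer, map_norm, shape, voxel, pts, R, u0):
    """ccc over all circular shifts for one probe orientation, plus the
    rasterized (CIC + point-spread) probe delta grid."""
    N = int(np.prod(shape))
    center_pts = pts.mean(axis=0)
    frac = (pts - center_pts) @ R.T / voxel + u0
    delta = np.zeros(shape)
    _trilinear_deposit(delta, frac)
    F_probe = np.fft.fftn(delta) * transfer
    probe_mean = F_probe.flat[0].real / N
    probe_norm2 = float(np.sum(np.abs(F_probe) ** 2)) / N - N * probe_mean**2
    if probe_norm2 <= 0:
        return None, delta
    corr = np.fft.ifftn(F_map * np.conj(F_probe)).real
    return corr / (map_norm * math.sqrt(probe_norm2)), delta


def correlation_scores(
    dmap: DensityMap,
    probe: StructureModel,
    rotation: np.ndarray,
    lowpass_to: float | None = None,
    laplacian_filter: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of the probe against the map for one
    orientation, over every circular voxel shift (the spectral fast path of
    :func:`exhaustive_fit`, exposed for direct-space verification).

    Returns ``(ccc_grid, probe_density)`` where ``probe_density`` is the
    point-spread-filtered probe on the map grid before optional Laplacian
    filtering.
    """
    pts = probe.ca_array()
    voxel = dmap.voxel
    psf = lowpass_to if lowpass_to is not None else 2.5 * voxel
    F_map, transfer, map_norm = _fit_spectra(dmap, psf, laplacian_filter)
    u0 = np.array(dmap.shape, dtype=float) / 2.0
    ccc, delta = _spectral_scores(
        F_map, transfer, map_norm, dmap.shape, voxel, pts, rotation, u0
    )
    # probe density without the Laplacian part of the transfer
    sigma = psf / _FWHM
    psf_only = np.exp(
        -2.0 * (math.pi * sigma) ** 2 * _freq2_grid(dmap.shape, voxel)
    ) * (2.0 * math.pi * sigma**2) ** -1.5 * voxel**3
    dens = np.fft.ifftn(np.fft.fftn(delta) * psf_only).real
    return ccc, dens


def exhaustive_fit(
    dmap: DensityMap,
    probe: StructureModel,
    angular_step: float = 10.0,
    lowpass_to: float | None = None,
    laplacian_filter: bool = False,
    n_results: int = 10,
    refine: bool = True,
    n_refine: int = 3,
) -> list[FitResult]:
    """Six-dimensional exhaustive search of a Cα probe against a map.

    Orientations come from :func:`rotation_grid`; for each one the probe is
    rasterized onto the map grid (point-spread FWHM ``lowpass_to``, default
    2.5·voxel) and every translation is scored at once by FFT cross-
    correlation, normalized so the score is a correlation coefficient in
    [-1, 1] invariant under affine rescaling of either density.  With
    ``laplacian_filter`` both map and probe density are passed through the
    circular Laplacian stencil before correlation (edge-contrast matching).
    Peaks closer than one voxel and one angular step merge; the survivors are
    re-scored by exact rasterization (:func:`placed_ccc`) and returned ranked
    by that ccc.
    """
    pts = probe.ca_array()
    if pts.size == 0:
        raise ValueError("empty probe model")
    grid = dmap.grid
    if float(grid.std()) == 0.0:
        raise ValueError("degenerate map: zero variance")
    shape = grid.shape
    voxel = dmap.voxel
    psf = lowpass_to if lowpass_to is not None else 2.5 * voxel
    if psf < 2.0 * voxel:
        raise ValueError(f"point-spread {psf} Å below Nyquist limit {2 * voxel} Å")
    F_map, transfer, map_norm = _fit_spectra(dmap, psf, laplacian_filter)
    if map_norm == 0.0:
        raise ValueError("degenerate map after filtering: zero variance")

    center_pts = pts.mean(axis=0)
    u0 = np.array(shape, dtype=float) / 2.0  # deposition center (voxels)
    rotations = rotation_grid(angular_step)
    candidates: list[tuple[float, np.ndarray, np.ndarray]] = []  # (ccc, R, t_vox)
    for R in rotations:
        ccc_grid, _ = _spectral_scores(
            F_map, transfer, map_norm, shape, voxel, pts, R, u0
        )
        if ccc_grid is None:
            continue
        t_idx = np.unravel_index(int(np.argmax(ccc_grid)), shape)
        candidates.append((float(ccc_grid[t_idx]), R, np.array(t_idx, dtype=float)))

    candidates.sort(key=lambda c: -c[0])
    results: list[FitResult] = []
    for ccc, R, t_vox in candidates:
        t_signed = np.where(t_vox > np.array(shape) / 2.0, t_vox - np.array(shape), t_vox)
        pos = dmap.origin + voxel * (u0 + t_signed)
        rt = RigidTransform(R, pos - R @ center_pts)
        merged = False
        for kept in results:
            dt = np.linalg.norm(
                (rt.apply(center_pts) - kept.transform.apply(center_pts))
            )
            da = _rotation_angle_deg(R, kept.transform.rotation)
            if dt <= voxel and da <= angular_step:
                merged = True
                break
        if not merged:
            results.append(FitResult(rt, ccc, rank=len(results) + 1))
            if len(results) >= n_results:
                break
    # exact re-scoring of the surviving peaks
    for r in results:
        r.ccc = placed_ccc(dmap, r.transform.apply(pts), psf, laplacian_filter)
    results.sort(key=lambda r: -r.ccc)
    if refine:
        for r in results[:n_refine]:
            r.transform, r.ccc = _refine_fit(
                dmap, pts, r.transform, psf, laplacian_filter
            )
        results.sort(key=lambda r: -r.ccc)
    for i, r in enumerate(results):
        r.rank = i + 1
    return results


def _refine_fit(
    dmap: DensityMap,
    pts: np.ndarray,
    start: RigidTransform,
    resolution: float,
    laplacian_filter: bool,
) -> tuple[RigidTransform, float]:
    """Off-lattice local refinement: Powell search over a rotation-vector
    perturbation and a sub-voxel translation around a grid peak."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    center = pts.mean(axis=0)

    def build(x):
        dR = Rotation.from_rotvec(x[:3]).as_matrix()
        R = dR @ start.rotation
        # perturb the rotation about the placed centroid, then shift
        t = start.apply(center) + x[3:] - R @ center
        return RigidTransform(R, t)

    def cost(x):
        return -placed_ccc(dmap, build(x).apply(pts), resolution, laplacian_filter)

    res = minimize(
        cost,
        np.zeros(6),
        method="Powell",
        options={"xtol": 1e-3, "ftol": 1e-6, "maxfev": 400},
    )
    rt = build(res.x)
    return rt, float(-res.fun)


def direct_space_ccc(
    dmap: DensityMap,
    probe_density: np.ndarray,
    shift_vox: tuple[int, int, int],
    laplacian_filter: bool = False,
) -> float:
    """Reference implementation of the fitting score for one placement:
    circular correlation evaluated entirely in direct space."""
    f = dmap.grid.copy()
    g = probe_density.copy()
    if laplacian_filter:
        f = _circular_laplacian(f, dmap.voxel)
        g = _circular_laplacian(g, dmap.voxel)
    f = f - f.mean()
    g = g - g.mean()
    g = np.roll(g, shift_vox, axis=(0, 1, 2))
    denom = math.sqrt(float((f**2).sum()) * float((g**2).sum()))
    return float((f * g).sum() / denom)


def _circular_laplacian(grid: np.ndarray, voxel: float) -> np.ndarray:
    out = -6.0 * grid
    for axis in range(3):
        out += np.roll(grid, 1, axis=axis) + np.roll(grid, -1, axis=axis)
    return out / voxel**2


# ---------------------------------------------------------------------------
# map-vs-map matching and the handedness test
# ---------------------------------------------------------------------------

def match_maps(
    reference: DensityMap, template: DensityMap, angular_step: float = 30.0
) -> float:
    """Best normalized cross-correlation of ``template`` against ``reference``
    over the rotation grid and all (circular) translations."""
    if reference.shape != template.shape:
        raise ValueError("grids must have identical shapes")
    shape = reference.shape
    # the (possibly noisy) template stays untouched; the clean reference is
    # the side that gets rotated, so interpolation never smooths the
    # template's noise and inflates off-grid correlations
    F_tmpl = np.conj(np.fft.fftn(template.grid))
    F_tmpl.flat[0] = 0.0
    N = reference.grid.size
    tmpl_norm = math.sqrt(float(np.sum(np.abs(F_tmpl) ** 2)) / N)
    if tmpl_norm == 0.0:
        raise ValueError("degenerate template: zero variance")
    center = (np.array(shape, dtype=float) - 1.0) / 2.0
    best = -1.0
    for R in rotation_grid(angular_step):
        Rinv = R.T
        rot = ndimage.affine_transform(
            reference.grid, Rinv, offset=center - Rinv @ center, order=1,
            mode="constant",
        )
        g = rot - rot.mean()
        norm = math.sqrt(float((g**2).sum()))
        if norm == 0.0:
            continue
        corr = np.fft.ifftn(np.fft.fftn(g) * F_tmpl).real
        best = max(best, float(corr.max()) / (tmpl_norm * norm))
    return best


def handedness_test(
    particles: list[DensityMap],
    dmap: DensityMap,
    angular_step: float = 45.0,
) -> dict:
    """Absolute-hand validation: per particle, ΔCCC = best correlation against
    the map minus best correlation against its mirror.  A positive mean ΔCCC
    says the map's hand matches the particles; a two-sided sign test gives the
    significance."""
    if len(particles) < 2:
        raise ValueError("need at least 2 particles")
    mirrored = mirror(dmap)
    deltas = []
    for p in particles:
        cc_true = match_maps(dmap, p, angular_step)
        cc_mirr = match_maps(mirrored, p, angular_step)
        deltas.append(cc_true - cc_mirr)
    deltas = np.array(deltas)
    n_pos = int((deltas > 0).sum())
    n_nonzero = int((deltas != 0).sum())
    p_value = (
        binomtest(n_pos, n_nonzero, 0.5, alternative="two-sided").pvalue
        if n_nonzero
        else 1.0
    )
    return {
        "delta_ccc": deltas,
        "mean_delta_ccc": float(deltas.mean()),
        "fraction_positive": float(n_pos / len(deltas)),
        "p_value": float(p_value),
    }


# ---------------------------------------------------------------------------
# FSC and contouring
# ---------------------------------------------------------------------------

@dataclass
class FSCCurve:
    frequencies: np.ndarray  # 1/Å, strictly increasing shell centers
    values: np.ndarray


def fsc(map_a: DensityMap, map_b: DensityMap) -> FSCCurve:
    """Fourier shell correlation between two maps on identical grids."""
    if map_a.shape != map_b.shape or map_a.voxel != map_b.voxel:
        raise ValueError("grids must match in shape and voxel size")
    A = np.fft.fftn(map_a.grid)
    B = np.fft.fftn(map_b.grid)
    f = np.sqrt(_freq2_grid(map_a.shape, map_a.voxel))
    n_min = min(map_a.shape)
    df = 1.0 / (n_min * map_a.voxel)  # one-voxel-wide shells
    shell = np.floor(f / df).astype(int)
    n_shells = n_min // 2
    freqs, vals = [], []
    for s in range(n_shells):
        m = shell == s
        if not m.any():
            continue
        num = np.sum(A[m] * np.conj(B[m])).real
        den = math.sqrt(float(np.sum(np.abs(A[m]) ** 2)) * float(np.sum(np.abs(B[m]) ** 2)))
        freqs.append((s + 0.5) * df if s > 0 else 0.0)
        vals.append(num / den if den > 0 else 0.0)
    return FSCCurve(np.array(freqs), np.array(vals))


def resolution_at(curve: FSCCurve, threshold: float = 0.5) -> float:
    """Resolution (Å) at the first downward crossing of ``threshold``, with
    linear interpolation between shells; inf if the curve never drops."""
    f, v = curve.frequencies, curve.values
    for i in range(1, len(v)):
        if v[i - 1] >= threshold > v[i]:
            frac = (v[i - 1] - threshold) / (v[i - 1] - v[i])
            fc = f[i - 1] + frac * (f[i] - f[i - 1])
            return float(1.0 / fc) if fc > 0 else float("inf")
    return float("inf")


def contour_by_volume(dmap: DensityMap, target_volume: float) -> float:
    """Threshold whose enclosed volume (#voxels ≥ t × voxel³) is the largest
    value not exceeding ``target_volume`` Å³; monotone in the target."""
    if target_volume <= 0:
        raise ValueError("target volume must be positive")
    if target_volume > dmap.total_volume():
        raise ValueError("target volume exceeds the grid volume")
    n_vox = int(target_volume // dmap.voxel**3)
    flat = np.sort(dmap.grid, axis=None)[::-1]
    if n_vox < 1:
        return float(flat[0]) + abs(float(flat[0])) * 1e-9 + 1e-30
    return float(flat[n_vox - 1])


def model_volume(
    model: StructureModel,
    mean_residue_mass: float = 110.0,
    specific_volume: float = 1.21,
) -> float:
    """Theoretical molecular volume in Å³: residues × mean residue mass (Da)
    × partial specific volume (Å³/Da)."""
    return model.n_residues() * mean_residue_mass * specific_volume


def residual_segment(
    dmap: DensityMap,
    fitted: StructureModel,
    threshold: float,
    resolution: float = 22.0,
    mask_radius: float | None = None,
) -> tuple[DensityMap, dict]:
    """Density above ``threshold`` left unexplained by a fitted model.

    Voxels within ``mask_radius`` (default 1.5 × resolution / 2) of any fitted
    Cα are removed; the largest connected component of what remains is
    returned as a binary mask together with its volume.
    """
    from scipy.spatial import cKDTree

    radius = mask_radius if mask_radius is not None else 1.5 * resolution / 2.0
    above = dmap.grid >= threshold
    if above.any():
        idx = np.argwhere(above)
        coords = dmap.origin + dmap.voxel * idx
        tree = cKDTree(fitted.ca_array())
        d, _ = tree.query(coords, k=1)
        keep = d > radius
        mask = np.zeros(dmap.shape, dtype=bool)
        mask[tuple(idx[keep].T)] = True
    else:
        mask = np.zeros(dmap.shape, dtype=bool)
    labels, n_comp = ndimage.label(mask)
    if n_comp > 0:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        largest = int(np.argmax(sizes)) + 1
        seg = labels == largest
        volume = float(sizes[largest - 1]) * dmap.voxel**3
    else:
        seg = mask
        volume = 0.0
    info = {"n_components": int(n_comp), "largest_volume": volume,
            "total_masked_voxels": int(mask.sum())}
    return DensityMap(seg.astype(np.float64), dmap.voxel, dmap.origin.copy()), info
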