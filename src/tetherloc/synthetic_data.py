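"""Synthetic inputs for every pipeline stage: toy tethered two-domain
complexes, conformer triples related by a hinge rotation, simulated
cross-link sets with a controlled false-positive fraction, and Gaussian
density maps — so the whole analysis runs end-to-end with no downloads.

Toy domains are self-avoiding Cα random walks with the canonical ~3.8 Å
consecutive-Cα spacing and a 4.0 Å excluded-volume radius for non-adjacent
residues.  The two domains are joined notionally by a disordered linker of
``linker_length`` residues (default 8) which is never built explicitly: it
only bounds the anchor-to-anchor distance at (linker_length + 1) × 3.8 Å.

Everything is bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .densfit import DensityMap, rasterize_points
from .structio import Residue, RigidTransform, StructureModel
from .xlink import CrosslinkRecord, CrosslinkSet

__all__ = [
    "ToyComplexSpec",
    "XlinkSimSpec",
    "GenerationError",
    "make_toy_complex",
    "assemble",
    "simulate_crosslinks",
    "make_conformer_triple",
    "simulate_density",
    "simulate_particles",
]

CA_STEP = 3.8  # Å, consecutive Cα spacing
EXCLUSION = 4.0  # Å, excluded volume between non-adjacent residues


class GenerationError(RuntimeError):
    """A synthetic spec could not be satisfied within the retry budget."""


@dataclass
class ToyComplexSpec:
    """Stand-in for a two-domain protein: a fixed core (chain A) and a mobile
    domain (chain B) flexibly tethered by a short disordered linker."""

    n_core_residues: int = 60
    n_mobile_residues: int = 40
    linker_length: int = 8
    seed: int = 0
    true_placement: RigidTransform | None = None  # None → drawn from seed

    def __post_init__(self):
        if self.linker_length < 0:
            raise ValueError("linker_length must be ≥ 0")
        if self.n_core_residues < 4 or self.n_mobile_residues < 4:
            raise ValueError("domains need at least 4 residues")

    @property
    def tether_max(self) -> float:
        return (self.linker_length + 1) * CA_STEP


@dataclass
class XlinkSimSpec:
    """Simulated lysine–lysine cross-link detection.

    ``n_true`` links are drawn from residue pairs whose Cα distance on the
    generating structure is at most ``max_true_distance`` (default 30 Å, the
    span of a short lysine-reactive cross-linker plus side chains); a further
    ⌈fp_fraction·n_true⌉ false positives come from pairs beyond it.  Each link
    gets a per-dataset detection count from ``1 + Poisson(1)`` truncated at 3,
    mimicking the small (0–2 extra) redundancy of real detection tables.
    """

    n_true: int = 20
    max_true_distance: float = 30.0
    fp_fraction: float = 0.0
    datasets: Sequence[str] = ("sim",)
    seed: int = 0
    interchain_only: bool = False
    p_detect: float = 1.0  # per-dataset detection probability; <1 gives 0-counts

    def __post_init__(self):
        if self.n_true < 1:
            raise ValueError("n_true must be ≥ 1")
        if not 0.0 <= self.fp_fraction <= 1.0:
            raise ValueError("fp_fraction must be in [0, 1]")
        if not 0.0 < self.p_detect <= 1.0:
            raise ValueError("p_detect must be in (0, 1]")


COMPACTNESS = 0.5  # centripetal bias of the domain walk; 0 → pure coil


def _self_avoiding_walk(
    n: int,
    rng: np.random.Generator,
    max_restarts: int = 200,
    compactness: float = COMPACTNESS,
) -> np.ndarray:
    """Compact self-avoiding Cα chain: 3.8 Å steps, ≥ 4.0 Å between
    non-adjacent residues, with each step direction biased toward the running
    centroid so the chain collapses to a globule.  The default bias gives
    Rg ≈ 2.2·n^0.38 Å, the empirical scaling of folded protein domains."""
    for _ in range(max_restarts):
        pts = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            placed = False
            prior = np.array(pts)
            centroid = prior.mean(axis=0)
            pull = centroid - pts[-1]
            pull_norm = np.linalg.norm(pull)
            for _ in range(80):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                if pull_norm > 1e-9:
                    v = v + compactness * pull / pull_norm
                    v /= np.linalg.norm(v)
                cand = pts[-1] + CA_STEP * v
                # all but the immediate predecessor must respect exclusion
                if len(pts) < 2 or np.min(
                    np.linalg.norm(prior[:-1] - cand, axis=1)
                ) >= EXCLUSION:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise GenerationError(
        f"self-avoiding walk of {n} residues failed after {max_restarts} restarts "
        f"(step {CA_STEP} Å, exclusion {EXCLUSION} Å)"
    )


def _chain_from_points(chain_id: str, start_seq: int, pts: np.ndarray) -> StructureModel:
    residues = [
        Residue(chain_id, start_seq + i, "ALA", pts[i].copy()) for i in range(len(pts))
    ]
    return StructureModel(f"toy_{chain_id}", {chain_id: residues})


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()


def make_toy_complex(
    spec: ToyComplexSpec,
) -> tuple[StructureModel, StructureModel, RigidTransform]:
    """Build (core, mobile, truth): core chain A numbered from 1, mobile chain
    B numbered after the (unbuilt) linker, and the true rigid placement of the
    mobile domain relative to the core.

    Under the true placement the core C-terminal anchor and the mobile
    N-terminal anchor lie within the tether maximum, and no core–mobile Cα
    pair comes closer than the exclusion radius.  Coordinates are quantized to
    0.001 Å (PDB precision) so file round-trips are exact.
    """
    rng = np.random.default_rng(spec.seed)
    core_pts = np.round(_self_avoiding_walk(spec.n_core_residues, rng), 3)
    mobile_pts = np.round(_self_avoiding_walk(spec.n_mobile_residues, rng), 3)
    core = _chain_from_points("A", 1, core_pts)
    mobile_start = spec.n_core_residues + spec.linker_length + 1
    mobile = _chain_from_points("B", mobile_start, mobile_pts)

    truth = spec.true_placement
    if truth is None:
        # contact-docked truth: tethered domains pack against their partner,
        # so the true placement touches the core surface (4–6 Å closest
        # approach) while keeping the anchors within the tether span
        core_anchor = core_pts[-1]
        mobile_anchor = mobile_pts[0]
        tree = cKDTree(core_pts)
        for attempt in range(20_000):
            R = _random_rotation(rng)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = spec.tether_max * rng.uniform(0.2, 0.95)
            target = core_anchor + radius * direction
            t = target - R @ mobile_anchor
            placed = mobile_pts @ R.T + t
            dmin = tree.query(placed, k=1)[0].min()
            if EXCLUSION <= dmin <= EXCLUSION + 2.0:
                truth = RigidTransform(R, np.round(t, 3))
                break
        else:
            raise GenerationError(
                "no clash-free contact-docked placement found within the tether "
                f"maximum {spec.tether_max:.1f} Å after 20000 attempts"
            )
    return core, mobile, truth


def assemble(
    core: StructureModel, mobile: StructureModel, placement: RigidTransform
) -> StructureModel:
    """Core plus mobile under a placement, merged into one model."""
    return core.merged(mobile.transformed(placement), model_id="assembled")


def simulate_crosslinks(assembled: StructureModel, spec: XlinkSimSpec) -> CrosslinkSet:
    """Draw true links from residue pairs within ``max_true_distance`` on the
    generating structure and false positives from pairs beyond it."""
    rng = np.random.default_rng(spec.seed)
    sites, coords = [], []
    for r in assembled.residues():
        if r.mappable:
            sites.append((r.chain_id, r.seq_id))
            coords.append(r.ca)
    coords = np.array(coords)
    n = len(sites)
    iu = np.triu_indices(n, k=1)
    dists = np.linalg.norm(coords[iu[0]] - coords[iu[1]], axis=1)
    if spec.interchain_only:
        chains = np.array([s[0] for s in sites])
        keep = chains[iu[0]] != chains[iu[1]]
    else:
        keep = np.ones(len(dists), dtype=bool)
    true_pool = np.flatnonzero(keep & (dists <= spec.max_true_distance))
    fp_pool = np.flatnonzero(keep & (dists > spec.max_true_distance))
    n_fp = math.ceil(spec.fp_fraction * spec.n_true)
    if len(true_pool) < spec.n_true:
        raise GenerationError(
            f"only {len(true_pool)} qualifying pairs ≤ {spec.max_true_distance} Å "
            f"(need {spec.n_true})"
        )
    if len(fp_pool) < n_fp:
        raise GenerationError(
            f"only {len(fp_pool)} pairs beyond {spec.max_true_distance} Å (need {n_fp})"
        )
    chosen = list(rng.choice(true_pool, size=spec.n_true, replace=False))
    chosen += list(rng.choice(fp_pool, size=n_fp, replace=False))
    records = []
    datasets = list(spec.datasets)
    for k in chosen:
        a, b = sites[iu[0][k]], sites[iu[1][k]]
        detected = [rng.random() < spec.p_detect for _ in datasets]
        if not any(detected):
            # a simulated link exists because it was detected somewhere
            detected[int(rng.integers(len(datasets)))] = True
        for ds, det in zip(datasets, detected):
            if det:
                count = int(min(1 + rng.poisson(1.0), 3))
                records.append(CrosslinkRecord(a, b, ds, count))
    return CrosslinkSet(records)


# ---------------------------------------------------------------------------
# conformer triple
# ---------------------------------------------------------------------------

def make_conformer_triple(
    base: StructureModel,
    hinge: int,
    angles: tuple[float, float, float],
    labels: tuple[str, str, str] = ("open", "semi-closed", "closed"),
    axis: np.ndarray | None = None,
    clash_min: float = 3.0,
) -> dict[str, StructureModel]:
    """Three conformers of a single-chain model related by rotating the
    second lobe (residues with seq_id ≥ ``hinge``) about an axis through the
    hinge residue's Cα by each angle (degrees).

    Lobe-internal geometry is rigidly preserved; a rotation that drives the
    lobes into a clash raises, naming the offending angle.
    """
    if len(base.chains) != 1:
        raise ValueError("base model must have exactly one chain")
    (chain_id, residues), = base.chains.items()
    lobe1 = [r for r in residues if r.seq_id < hinge]
    lobe2 = [r for r in residues if r.seq_id >= hinge]
    if len(lobe1) < 4 or len(lobe2) < 4:
        raise ValueError("hinge must leave at least 4 residues in each lobe")
    pivot = lobe2[0].ca
    if pivot is None:
        raise ValueError("hinge residue has no Cα")
    c1 = np.array([r.ca for r in lobe1 if r.ca is not None]).mean(axis=0)
    c2 = np.array([r.ca for r in lobe2 if r.ca is not None]).mean(axis=0)
    p1 = np.array([r.ca for r in lobe1 if r.ca is not None])
    p2_base = np.array([r.ca for r in lobe2 if r.ca is not None])
    tree1 = cKDTree(p1)

    def clearance(ax: np.ndarray, theta: float) -> float:
        R = Rotation.from_rotvec(np.radians(theta) * ax).as_matrix()
        moved = (p2_base - pivot) @ R.T + pivot
        # the hinge residue itself stays bonded to lobe 1; exempt it
        return float(tree1.query(moved[1:], k=1)[0].min()) if len(moved) > 1 else np.inf

    if axis is None:
        # base direction: normal of the lobe-centroid plane, signed so a
        # positive angle opens the inter-lobe angle (swings lobe 2 away);
        # scan deterministic tilts of it for one clearing every angle
        v2 = c2 - pivot
        base_axis = np.cross(v2, c1 - pivot)
        if np.linalg.norm(base_axis) < 1e-9:  # collinear lobes: any normal
            ref = np.array([0.0, 0.0, 1.0])
            if abs(v2 @ ref) > 0.9 * np.linalg.norm(v2):
                ref = np.array([1.0, 0.0, 0.0])
            base_axis = np.cross(v2, ref)
        base_axis /= np.linalg.norm(base_axis)
        R5 = Rotation.from_rotvec(np.radians(5.0) * base_axis).as_matrix()
        if np.linalg.norm(R5 @ v2 + pivot - c1) < np.linalg.norm(c2 - c1):
            base_axis = -base_axis
        u = v2 / np.linalg.norm(v2)
        candidates = [
            Rotation.from_rotvec(np.radians(tilt) * u).as_matrix() @ base_axis
            for tilt in (0, 30, -30, 60, -60, 90, -90, 120, -120, 150, -150, 180)
        ]
        axis = next(
            (a for a in candidates
             if all(clearance(a, th) >= clash_min for th in angles if th != 0.0)),
            None,
        )
        if axis is None:
            raise GenerationError(
                f"no hinge axis clears all angles {angles} at {clash_min} Å"
            )
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    out: dict[str, StructureModel] = {}
    for label, theta in zip(labels, angles):
        if theta == 0.0:
            out[label] = base.copy(model_id=label)
            continue
        dmin = clearance(axis, theta)
        if dmin < clash_min:
            raise GenerationError(
                f"lobes clash ({dmin:.2f} Å < {clash_min} Å) at angle {theta}°"
            )
        R = Rotation.from_rotvec(np.radians(theta) * axis).as_matrix()
        model = base.copy(model_id=label)
        for r in model.chains[chain_id]:
            if r.seq_id >= hinge and r.ca is not None:
                r.ca = R @ (r.ca - pivot) + pivot
        out[label] = model
    return out


def make_domain(
    n_residues: int, seed: int, chain_id: str = "M", start_seq: int = 1
) -> StructureModel:
    """Single compact globular Cα domain (self-avoiding biased walk)."""
    rng = np.random.default_rng(seed)
    pts = np.round(_self_avoiding_walk(n_residues, rng), 3)
    return _chain_from_points(chain_id, start_seq, pts)


def make_two_lobe_domain(
    n_lobe1: int, n_lobe2: int, seed: int, chain_id: str = "M", start_seq: int = 1
) -> tuple[StructureModel, int]:
    """Bilobed ATPase-like domain: two compact globules on one chain, joined
    where the chain crosses between them (the hinge).

    Returns the model and the hinge residue's seq_id (first lobe-2 residue).
    The lobes touch (4–6 Å closest approach) but do not interpenetrate, so a
    hinge rotation of lobe 2 that opens the inter-lobe angle is clash-free.
    """
    rng = np.random.default_rng(seed)
    for _ in range(20):  # some walk draws bury the junction; redraw then
        p1 = _self_avoiding_walk(n_lobe1, rng)
        p2_local = _self_avoiding_walk(n_lobe2, rng)
        join = p1[-1]
        for _ in range(4000):
            R = _random_rotation(rng)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            # chain-continuous: lobe-2 start one Cα step from lobe-1 end
            t = join + CA_STEP * direction - R @ p2_local[0]
            p2 = p2_local @ R.T + t
            d = np.linalg.norm(p1[:, None, :] - p2[None, :, :], axis=2)
            d[-1, 0] = np.inf  # the junction step itself is exempt
            if EXCLUSION <= d.min() <= EXCLUSION + 2.0:
                pts = np.round(np.vstack([p1, p2]), 3)
                return (
                    _chain_from_points(chain_id, start_seq, pts),
                    start_seq + n_lobe1,
                )
    raise GenerationError("no touching, clash-free lobe arrangement found")


def make_solenoid(
    n_residues: int = 160,
    arc_radius: float = 28.0,
    arc_span: float = 280.0,
    coil_radius: float = 6.0,
    residues_per_turn: int = 10,
    chain_id: str = "A",
) -> StructureModel:
    """Cα model of a helical coil wound along a circular arc — a C-shaped
    solenoid emulating an α-helical repeat (HEAT-like) horseshoe.

    The default parameters give ~3.8 Å consecutive-Cα spacing.  Unlike a
    quasi-globular blob, this shape stays strongly chiral even in a 20–25 Å
    density map, which is what a handedness test needs to discriminate.
    """
    if n_residues < 8:
        raise ValueError("need at least 8 residues")
    pts = []
    phi_tot = math.radians(arc_span)
    for i in range(n_residues):
        phi = phi_tot * i / (n_residues - 1)
        cen = np.array([arc_radius * math.cos(phi), arc_radius * math.sin(phi), 0.0])
        normal = np.array([math.cos(phi), math.sin(phi), 0.0])
        binormal = np.array([0.0, 0.0, 1.0])
        theta = 2.0 * math.pi * i / residues_per_turn
        pts.append(
            cen + coil_radius * (math.cos(theta) * normal + math.sin(theta) * binormal)
        )
    return _chain_from_points(chain_id, 1, np.round(np.array(pts), 3))


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def simulate_density(
    model: StructureModel, resolution: float, voxel: float, pad: float = 10.0
) -> DensityMap:
    """Map of unit-integral Gaussians (FWHM = ``resolution``) on the model's
    Cα positions; the grid covers the model plus ``pad`` Å on every side, so
    the grid integral approximates the residue count."""
    if resolution < 2.0 * voxel:
        raise ValueError(
            f"resolution {resolution} Å below Nyquist limit 2·voxel = {2 * voxel} Å"
        )
    pts = model.ca_array()
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    shape = tuple(int(math.ceil(e / voxel)) + 1 for e in hi - lo)
    grid = rasterize_points(pts, shape, voxel, lo, resolution)
    return DensityMap(grid, voxel, lo)


def simulate_particles(
    dmap: DensityMap, n: int, snr: float, seed: int, rotate: bool = False
) -> list[DensityMap]:
    """Noisy particle stand-ins for a handedness test: full-frame crops of
    the map with white Gaussian noise added at the requested signal-to-noise
    ratio (variance ratio).  With ``rotate`` each particle is additionally
    turned to a random orientation about the grid center before noise."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    rng = np.random.default_rng(seed)
    center = (np.array(dmap.shape, dtype=float) - 1.0) / 2.0
    sig = float(dmap.grid.std())
    noise_sd = sig / math.sqrt(snr)
    out = []
    for _ in range(n):
        base = dmap.grid
        if rotate:
            R = _random_rotation(rng)
            Rinv = R.T
            base = ndimage.affine_transform(
                base, Rinv, offset=center - Rinv @ center, order=1, mode="constant"
            )
        noisy = base + rng.normal(scale=noise_sd, size=dmap.shape)
        out.append(DensityMap(noisy, dmap.voxel, dmap.origin.copy()))
    return out
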