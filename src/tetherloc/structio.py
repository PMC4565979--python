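"""Structure I/O and rigid-body geometry primitives.

All coordinates are Cartesian, in Ångström, with author (1-based) residue
numbering taken verbatim from the coordinate file.  Geometry throughout the
package is Cα-level: full-atom detail read from a PDB file is carried along
opaquely (so models can be written back out) but only Cα positions enter any
distance, superposition or density calculation.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "RigidTransform",
    "DegenerateSelectionError",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "ca_distance",
    "superpose",
]


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class DegenerateSelectionError(ValueError):
    """Raised when a superposition selection is too small or collinear."""


@dataclass
class Atom:
    name: str
    pos: np.ndarray  # (3,) Å
    occ: float = 1.0
    b: float = 0.0
    element: str = ""


@dataclass
class Residue:
    """One residue; ``ca`` is None when no Cα atom is present (unmappable)."""

    chain_id: str
    seq_id: int
    name: str
    ca: np.ndarray | None = None
    atoms: list[Atom] = field(default_factory=list)

    @property
    def mappable(self) -> bool:
        return self.ca is not None


class StructureModel:
    """Ordered chains of residues with Cα coordinates.

    Chain order and residue order are preserved exactly across read → write →
    read round trips.  Residue ``seq_id`` values are unique and strictly
    increasing within each chain.
    """

    def __init__(self, model_id: str, chains: dict[str, list[Residue]] | None = None):
        self.model_id = model_id
        self.chains: dict[str, list[Residue]] = chains if chains is not None else {}
        self._validate()

    def _validate(self) -> None:
        for cid, residues in self.chains.items():
            seq = [r.seq_id for r in residues]
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError(
                    f"chain {cid!r}: residue seq_ids must be strictly increasing"
                )

    # -- access ---------------------------------------------------------
    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def residue(self, chain_id: str, seq_id: int) -> Residue | None:
        for r in self.chains.get(chain_id, ()):
            if r.seq_id == seq_id:
                return r
        return None

    def ca(self, chain_id: str, seq_id: int) -> np.ndarray | None:
        r = self.residue(chain_id, seq_id)
        return None if r is None else r.ca

    def ca_array(self, mappable_only: bool = True) -> np.ndarray:
        """(n, 3) array of Cα positions in chain/residue order."""
        pts = [r.ca for r in self.residues() if r.ca is not None or not mappable_only]
        if not mappable_only:
            pts = [p if p is not None else np.full(3, np.nan) for p in pts]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    def n_mappable(self) -> int:
        return sum(1 for r in self.residues() if r.mappable)

    def centroid(self) -> np.ndarray:
        return self.ca_array().mean(axis=0)

    def radius_of_gyration(self) -> float:
        pts = self.ca_array()
        return float(np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum(axis=1).mean()))

    # -- manipulation ---------------------------------------------------
    def copy(self, model_id: str | None = None) -> "StructureModel":
        out = StructureModel(model_id or self.model_id)
        out.chains = {
            cid: [
                Residue(
                    r.chain_id,
                    r.seq_id,
                    r.name,
                    None if r.ca is None else r.ca.copy(),
                    [Atom(a.name, a.pos.copy(), a.occ, a.b, a.element) for a in r.atoms],
                )
                for r in residues
            ]
            for cid, residues in self.chains.items()
        }
        return out

    def transformed(self, rt: "RigidTransform", model_id: str | None = None) -> "StructureModel":
        out = self.copy(model_id)
        for r in out.residues():
            if r.ca is not None:
                r.ca = rt.apply(r.ca)
            for a in r.atoms:
                a.pos = rt.apply(a.pos)
        return out

    def merged(self, other: "StructureModel", model_id: str = "merged") -> "StructureModel":
        """Combine two models; chain ids must not collide."""
        overlap = set(self.chains) & set(other.chains)
        if overlap:
            raise ValueError(f"chain id collision: {sorted(overlap)}")
        out = self.copy(model_id)
        out.chains.update(other.copy().chains)
        return out


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t  (det R = +1; reflections forbidden)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1); reflections are forbidden")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def angle_to(self, other: "RigidTransform") -> float:
        """Geodesic rotation angle between the two rotations, degrees."""
        R = self.rotation.T @ other.rotation
        c = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))


# ---------------------------------------------------------------------------
# file I/O (PDB via gemmi; optional mmCIF read)
# ---------------------------------------------------------------------------

def _from_gemmi(st: gemmi.Structure, model_id: str) -> StructureModel:
    if len(st) == 0:
        raise StructureParseError(f"{model_id}: file contains no coordinate model")
    model = st[0]
    out = StructureModel(model_id)
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            # resolve alternate locations: keep highest-occupancy copy per atom name
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    by_name[atom.name] = atom
            atoms = [
                Atom(a.name, np.array([a.pos.x, a.pos.y, a.pos.z]), a.occ, a.b_iso,
                     a.element.name)
                for a in by_name.values()
            ]
            ca = next((a.pos.copy() for a in atoms if a.name == "CA"), None)
            residues.append(Residue(chain.name, res.seqid.num, res.name, ca, atoms))
        if residues:
            out.chains[chain.name] = residues
    out._validate()
    return out


def read_structure(path: str | Path, format: str = "pdb") -> StructureModel:
    """Read a coordinate file into a :class:`StructureModel`.

    Cα atoms are extracted for geometry; all other atoms are retained for
    write-back.  A residue without a Cα atom is flagged unmappable rather than
    raising.  Alternate locations resolve to the highest-occupancy copy.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unsupported format: {format!r}")
    except (RuntimeError, ValueError) as exc:  # gemmi reports offending line text
        raise StructureParseError(f"{path}: {exc}") from exc
    return _from_gemmi(st, model_id=path.stem)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as PDB. Coordinates print at the format's 0.001 Å precision."""
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for cid, residues in model.chains.items():
        gc = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.name
            gr.seqid = gemmi.SeqId(r.seq_id, " ")
            atoms = r.atoms
            if not atoms and r.ca is not None:
                atoms = [Atom("CA", r.ca, 1.0, 0.0, "C")]
            for a in atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occ
                ga.b_iso = a.b
                ga.element = gemmi.Element(a.element or a.name[:1])
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def write_multi_model(models: Sequence[StructureModel], path: str | Path) -> None:
    """Write several placements as a multi-MODEL PDB file."""
    st = gemmi.Structure()
    for i, model in enumerate(models, start=1):
        gm = gemmi.Model(str(i))
        for cid, residues in model.chains.items():
            gc = gemmi.Chain(cid)
            for r in residues:
                gr = gemmi.Residue()
                gr.name = r.name
                gr.seqid = gemmi.SeqId(r.seq_id, " ")
                atoms = r.atoms or ([Atom("CA", r.ca, 1.0, 0.0, "C")] if r.ca is not None else [])
                for a in atoms:
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.pos = gemmi.Position(*a.pos)
                    ga.occ = a.occ
                    ga.b_iso = a.b
                    ga.element = gemmi.Element(a.element or a.name[:1])
                    gr.add_atom(ga)
            gc.add_residue(gr)
            gm.add_chain(gc)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def ca_distance(
    model: StructureModel,
    a: tuple[str, int],
    b: tuple[str, int],
    proxy: dict[tuple[str, int], np.ndarray] | None = None,
) -> float:
    """Euclidean Cα–Cα distance in Å; symmetric in its arguments.

    Residues absent from the model may be substituted from ``proxy``
    coordinates.  An unmappable endpoint yields NaN (a sentinel, never a
    silent zero).
    """

    def locate(key: tuple[str, int]) -> np.ndarray | None:
        p = model.ca(*key)
        if p is None and proxy is not None:
            p = proxy.get(key)
        return p

    pa, pb = locate(a), locate(b)
    if pa is None or pb is None:
        return float("nan")
    return float(np.linalg.norm(np.asarray(pa) - np.asarray(pb)))


def superpose_points(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper superposition (Kabsch) of paired point sets.

    Returns the transform taking ``mobile`` onto ``reference`` and the
    post-fit RMSD.  The rotation determinant is forced to +1: a selection that
    would be better matched by a reflection is still fit with a proper
    rotation.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired (n, 3) arrays required")
    n = P.shape[0]
    if n < 3:
        raise DegenerateSelectionError("need at least 3 paired positions")
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - Pc, Q - Qc
    # collinearity: centered mobile cloud must span a plane
    if np.linalg.matrix_rank(P0, tol=1e-8 * max(1.0, np.abs(P0).max())) < 2:
        raise DegenerateSelectionError("selection is collinear")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    rt = RigidTransform(R, t)
    rmsd = float(np.sqrt(((rt.apply(P) - Q) ** 2).sum(axis=1).mean()))
    return rt, rmsd


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    selection: Iterable[tuple[tuple[str, int], tuple[str, int]]],
) -> tuple[RigidTransform, float]:
    """Superpose ``mobile`` onto ``reference`` over an explicit residue pairing.

    ``selection`` is an iterable of ((mobile_chain, seq_id),
    (reference_chain, seq_id)) pairs; each must resolve to a mappable Cα.
    """
    P, Q = [], []
    for (mc, ms), (rc, rs) in selection:
        pm, pr = mobile.ca(mc, ms), reference.ca(rc, rs)
        if pm is None or pr is None:
            raise DegenerateSelectionError(
                f"unmappable residue in selection: {(mc, ms)} / {(rc, rs)}"
            )
        P.append(pm)
        Q.append(pr)
    return superpose_points(np.array(P), np.array(Q))
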