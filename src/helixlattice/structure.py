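"""Filament model building and structure I/O.

Builds explicit 3D filament models by applying screw operators to per-species
reference monomers according to a subunit labeling, with the filament axis
along +z through the origin.  Models are written to and read from mmCIF
(primary) or legacy PDB via gemmi, one chain per subunit.  Also provides
domain annotation (tail / hinge / head), an N-glycosylation sequon scanner
(N-X-S/T) and simple whole-filament measurements.
"""

from __future__ import annotations

import math
import re
import string
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

from ._geometry import rotation_z
from .errors import (
    AnnotationError,
    ChainIdExhaustionError,
    ConfigurationError,
    InvalidArgumentError,
    StructureParseError,
)
from .register import SubunitLabeling
from .symmetry import HelicalSymmetry, ScrewOperator, screw_operator

__all__ = [
    "DomainAnnotation",
    "MonomerModel",
    "PlacedSubunit",
    "FilamentModel",
    "build_filament",
    "write_structure",
    "read_monomer",
    "read_filament",
    "find_sequons",
    "filament_diameter",
]

# 62 legacy single-character chain identifiers
_PDB_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_AA_ALPHABET = set(THREE_TO_ONE.values())


@dataclass(frozen=True)
class DomainAnnotation:
    """Tail / hinge / head residue ranges (inclusive, mature numbering).

    The archaellin fold splits into an N-terminal α-helical tail, a
    two-residue hinge and a C-terminal globular head; ranges must be ordered
    tail < hinge < head and disjoint.
    """

    tail: Tuple[int, int]
    hinge: Tuple[int, int]
    head: Tuple[int, int]

    def __post_init__(self):
        for name in ("tail", "hinge", "head"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidArgumentError(f"{name} range {lo}-{hi} is empty")
        if not (self.tail[1] < self.hinge[0] and self.hinge[1] < self.head[0]):
            raise InvalidArgumentError(
                "domain ranges must be ordered tail < hinge < head and disjoint"
            )

    def domain_of(self, res_id: int) -> str:
        for name in ("tail", "hinge", "head"):
            lo, hi = getattr(self, name)
            if lo <= res_id <= hi:
                return name
        raise AnnotationError(f"residue {res_id} falls outside all annotated domains")


@dataclass
class MonomerModel:
    """One subunit's atoms in a reduced (pseudo-atomic or full) representation.

    Arrays are parallel, one entry per atom.  Residue ids must be
    non-decreasing; coordinates finite.
    """

    atom_name: list
    element: list
    res_name: list
    res_id: np.ndarray
    xyz: np.ndarray
    species: int = 0
    annotation: Optional[DomainAnnotation] = None

    def __post_init__(self):
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        n = len(self.atom_name)
        if not (len(self.element) == len(self.res_name) == len(self.res_id) == len(self.xyz) == n):
            raise InvalidArgumentError("atom arrays must have equal length")
        if n and np.any(np.diff(self.res_id) < 0):
            raise InvalidArgumentError("residue ids must be non-decreasing along the chain")
        if n and not np.all(np.isfinite(self.xyz)):
            raise InvalidArgumentError("coordinates must be finite")
        if self.annotation is not None:
            for rid in np.unique(self.res_id):
                self.annotation.domain_of(int(rid))  # raises if uncovered

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def centroid(self) -> np.ndarray:
        return self.xyz.mean(axis=0)

    def residue_ids(self) -> np.ndarray:
        return np.unique(self.res_id)

    def domain_mask(self, domain: str) -> np.ndarray:
        if self.annotation is None:
            raise AnnotationError("monomer carries no domain annotation")
        lo, hi = getattr(self.annotation, domain)
        return (self.res_id >= lo) & (self.res_id <= hi)

    def domain_xyz(self, domain: str) -> np.ndarray:
        return self.xyz[self.domain_mask(domain)]

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "MonomerModel":
        return replace(self, xyz=self.xyz @ np.asarray(R, float).T + np.asarray(t, float))

    def sequence(self) -> str:
        """One-letter sequence over the distinct residues (chain order)."""
        seen = {}
        for rid, rn in zip(self.res_id, self.res_name):
            if rid not in seen:
                seen[int(rid)] = THREE_TO_ONE.get(rn, "X")
        return "".join(seen[k] for k in sorted(seen))


@dataclass
class PlacedSubunit:
    """A subunit placed in a filament: reference monomer + rigid transform."""

    index: int
    species: int
    R: np.ndarray
    t: np.ndarray
    atoms: MonomerModel
    operator: Optional[ScrewOperator] = None  # set for straight (screw) placements

    def centroid(self) -> np.ndarray:
        return self.atoms.centroid()

    def station(self) -> np.ndarray:
        """Image of the lattice origin under this subunit's transform."""
        return np.asarray(self.t, float).copy()

    def local_axis(self) -> np.ndarray:
        """Local filament axis direction (image of +z)."""
        return np.asarray(self.R, float) @ np.array([0.0, 0.0, 1.0])


@dataclass
class FilamentModel:
    """A filament: helical symmetry, labeling and placed subunits.

    For straight filaments every subunit's transform is the lattice screw
    operator for its index applied to the species reference monomer.
    """

    sym: HelicalSymmetry
    labeling: Optional[SubunitLabeling]
    subunits: list
    references: Dict[int, MonomerModel] = field(default_factory=dict)
    straight: bool = True

    @property
    def n_subunits(self) -> int:
        return len(self.subunits)

    def species_counts(self) -> Dict[int, int]:
        counts: Dict[int, int] = {}
        for su in self.subunits:
            counts[su.species] = counts.get(su.species, 0) + 1
        return counts

    def all_xyz(self) -> np.ndarray:
        return np.vstack([su.atoms.xyz for su in self.subunits])


def build_filament(
    monomers: Dict[int, MonomerModel],
    sym: HelicalSymmetry,
    lab: Optional[SubunitLabeling],
    n: int,
) -> FilamentModel:
    """Place ``n`` subunits on the lattice of ``sym`` labeled by ``lab``.

    ``monomers`` maps species id -> reference monomer positioned in the
    subunit-0 frame (filament axis = +z through the origin).  With no
    labeling, species 0 is used throughout.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    subunits = []
    for i in range(int(n)):
        sp = lab.species(i) if lab is not None else 0
        if sp not in monomers:
            raise ConfigurationError(f"no reference monomer supplied for species {sp}")
        op = screw_operator(sym, i)
        R, t = op.rotation_matrix(), op.translation()
        subunits.append(
            PlacedSubunit(
                index=i,
                species=sp,
                R=R,
                t=t,
                atoms=monomers[sp].transformed(R, t),
                operator=op,
            )
        )
    return FilamentModel(sym=sym, labeling=lab, subunits=subunits, references=dict(monomers), straight=True)


def _chain_id(i: int, fmt: str, n_total: int) -> str:
    if fmt == "pdb":
        if n_total > len(_PDB_CHAIN_IDS):
            raise ChainIdExhaustionError(
                f"PDB provides only {len(_PDB_CHAIN_IDS)} single-character chain ids; "
                f"{n_total} subunits requested — write mmCIF instead"
            )
        return _PDB_CHAIN_IDS[i]
    return f"S{i:04d}"


def write_structure(model: FilamentModel, path, format: str = "mmcif") -> None:
    """Write a filament with one chain per subunit (mmCIF or legacy PDB).

    PDB output is limited to 62 subunits by the single-character chain-id
    field; larger models must use mmCIF.
    """
    import gemmi

    fmt = format.lower().replace(".", "")
    if fmt not in ("mmcif", "cif", "pdb"):
        raise InvalidArgumentError(f"unsupported format {format!r}; use 'mmcif' or 'pdb'")
    fmt = "pdb" if fmt == "pdb" else "mmcif"

    st = gemmi.Structure()
    st.name = "helixlattice filament"
    md = gemmi.Model("1")
    n_total = model.n_subunits
    for su in model.subunits:
        ch = gemmi.Chain(_chain_id(su.index, fmt, n_total))
        m = su.atoms
        cur_res = None
        cur_rid = None
        for aname, el, rname, rid, pos in zip(m.atom_name, m.element, m.res_name, m.res_id, m.xyz):
            if cur_rid != rid:
                cur_res = gemmi.Residue()
                cur_res.name = rname
                cur_res.seqid = gemmi.SeqId(int(rid), " ")
                ch.add_residue(cur_res)
                cur_rid = rid
            at = gemmi.Atom()
            at.name = aname
            at.element = gemmi.Element(el)
            at.pos = gemmi.Position(*pos)
            at.occ = 1.0
            at.b_iso = 0.0
            cur_res = ch[-1]
            cur_res.add_atom(at)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    path = str(path)
    if fmt == "pdb":
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)


def _chain_to_monomer(chain, species: int, annotation: Optional[DomainAnnotation]) -> MonomerModel:
    atom_name, element, res_name, res_id, xyz = [], [], [], [], []
    for res in chain:
        for at in res:
            atom_name.append(at.name)
            element.append(at.element.name)
            res_name.append(res.name)
            res_id.append(res.seqid.num)
            xyz.append([at.pos.x, at.pos.y, at.pos.z])
    return MonomerModel(
        atom_name=atom_name,
        element=element,
        res_name=res_name,
        res_id=np.array(res_id, int),
        xyz=np.array(xyz, float),
        species=species,
        annotation=annotation,
    )


def read_monomer(
    path,
    species: int = 0,
    annotation: Optional[DomainAnnotation] = None,
    tail: Optional[Tuple[int, int]] = None,
    hinge: Optional[Tuple[int, int]] = None,
) -> MonomerModel:
    """Read a single-chain monomer from mmCIF/PDB.

    Supply either a full :class:`DomainAnnotation`, or just ``tail`` and
    ``hinge`` ranges — the head range is then completed as everything from
    the residue after the hinge to the chain's last residue.
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0 or len(st[0]) == 0:
        raise StructureParseError(f"no chains found in {path}")
    chain = st[0][0]
    mono = _chain_to_monomer(chain, species, None)
    if annotation is None and tail is not None and hinge is not None:
        last = int(mono.res_id.max())
        annotation = DomainAnnotation(tail=tail, hinge=hinge, head=(hinge[1] + 1, last))
    mono.annotation = annotation
    if annotation is not None:
        for rid in mono.residue_ids():
            annotation.domain_of(int(rid))
    return mono


def read_filament(
    path,
    sym: HelicalSymmetry,
    labeling: Optional[SubunitLabeling] = None,
    annotation: Optional[DomainAnnotation] = None,
    tail: Optional[Tuple[int, int]] = None,
    hinge: Optional[Tuple[int, int]] = None,
) -> FilamentModel:
    """Read a multi-chain filament written by :func:`write_structure`.

    Chains are taken in file order as subunits 0..n−1; species come from the
    labeling when given (labels are not recoverable from coordinates alone).
    Transforms are reconstructed as the lattice screw operators, so this is
    intended for straight filaments.  Supplying ``tail`` and ``hinge`` ranges
    instead of a full annotation completes the head range per chain (species
    may differ in C-terminal length).
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"no models found in {path}")
    subunits = []
    for i, chain in enumerate(st[0]):
        sp = labeling.species(i) if labeling is not None else 0
        op = screw_operator(sym, i)
        atoms = _chain_to_monomer(chain, sp, None)
        ann = annotation
        if ann is None and tail is not None and hinge is not None:
            ann = DomainAnnotation(tail=tail, hinge=hinge, head=(hinge[1] + 1, int(atoms.res_id.max())))
        if ann is not None:
            atoms.annotation = ann
            for rid in atoms.residue_ids():
                ann.domain_of(int(rid))
        subunits.append(
            PlacedSubunit(
                index=i,
                species=sp,
                R=op.rotation_matrix(),
                t=op.translation(),
                atoms=atoms,
                operator=op,
            )
        )
    return FilamentModel(sym=sym, labeling=labeling, subunits=subunits, straight=True)


def find_sequons(sequence: str, exclude_proline: bool = False) -> list:
    """1-based positions of N in N-X-S/T glycosylation sequons.

    Overlapping motifs (e.g. both asparagines of ``NNTT``) are all reported.
    With ``exclude_proline`` the central X may not be proline, matching the
    stricter form of the consensus.
    """
    seq = sequence.upper()
    bad = set(seq) - _AA_ALPHABET
    if bad:
        raise StructureParseError(
            f"invalid amino-acid letters {sorted(bad)} in sequence"
        )
    x = "[^P]" if exclude_proline else "."
    pat = re.compile(f"(?=N{x}[ST])")
    return [m.start() + 1 for m in pat.finditer(seq)]


def filament_diameter(model: FilamentModel) -> float:
    """Twice the maximum radial atom distance from the filament axis (+z)."""
    if model.n_subunits == 0:
        raise InvalidArgumentError("model has no subunits")
    xyz = model.all_xyz()
    r = np.hypot(xyz[:, 0], xyz[:, 1])
    return float(2.0 * r.max())
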