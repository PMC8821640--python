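"""Geometric inter-subunit contact analysis.

Counts polar contacts between placed subunits with purely geometric criteria:
hydrogen bonds as donor/acceptor N/O heavy-atom pairs within a distance
cutoff (no angular term), and salt bridges as basic-nitrogen to
carboxyl-oxygen pairs.  Also classifies which neighbour offsets k a reference
subunit touches, and which neighbours' tail center-lines pack against the
reference tail in the filament core.

The counts are distance-threshold tallies, not an interface energetics
calculation: no buried surface area, no dissociation free energies.  Reports
are labelled accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geometry import fit_line_segment, segment_segment_distance
from .errors import AnnotationError, BoundaryError, InvalidArgumentError
from .structure import FilamentModel, PlacedSubunit

__all__ = [
    "ContactCriteria",
    "ContactReport",
    "polar_contacts",
    "neighbor_contact_map",
    "tail_core_contacts",
    "HBOND_DONORS",
    "HBOND_ACCEPTORS",
    "SALT_BASIC",
    "SALT_ACIDIC",
]

GEOMETRIC_DISCLAIMER = (
    "geometric distance-threshold contact counts; not an interface "
    "energetics (PISA-style) calculation"
)

# Donor / acceptor capability by (residue, atom). "*" matches any residue:
# backbone amide N donates (except proline), carbonyl O accepts.
HBOND_DONORS = {
    ("*", "N"), ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("ASN", "ND2"), ("GLN", "NE2"), ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("TRP", "NE1"),
}
HBOND_ACCEPTORS = {
    ("*", "O"), ("*", "OXT"), ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
}
SALT_BASIC = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
SALT_ACIDIC = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


@dataclass(frozen=True)
class ContactCriteria:
    """Distance cutoffs (Å) for the geometric contact definitions."""

    hbond_max: float = 3.5
    saltbridge_max: float = 4.0
    tail_segment_cutoff: float = 8.0

    def __post_init__(self):
        for name in ("hbond_max", "saltbridge_max", "tail_segment_cutoff"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")


def _capability(res: str, atom: str, table) -> bool:
    return (res, atom) in table or ("*", atom) in table and not (res == "PRO" and atom == "N" and table is HBOND_DONORS)


def _polar_flags(sub: PlacedSubunit):
    m = sub.atoms
    n = m.n_atoms
    donor = np.zeros(n, bool)
    acceptor = np.zeros(n, bool)
    basic = np.zeros(n, bool)
    acidic = np.zeros(n, bool)
    for j, (rn, an, el) in enumerate(zip(m.res_name, m.atom_name, m.element)):
        if el not in ("N", "O"):
            continue
        donor[j] = _capability(rn, an, HBOND_DONORS)
        acceptor[j] = _capability(rn, an, HBOND_ACCEPTORS)
        basic[j] = (rn, an) in SALT_BASIC
        acidic[j] = (rn, an) in SALT_ACIDIC
    return donor, acceptor, basic, acidic


def polar_contacts(
    subA: PlacedSubunit,
    subB: PlacedSubunit,
    criteria: ContactCriteria = ContactCriteria(),
) -> Tuple[int, int, pd.DataFrame]:
    """Hydrogen-bond and salt-bridge tally between two placed subunits.

    A hydrogen bond is an N/O pair across the interface within
    ``criteria.hbond_max`` where one atom can donate and the other accept
    (role table keyed by residue chemistry).  A salt bridge is a
    Lys/Arg/His basic nitrogen within ``criteria.saltbridge_max`` of an
    Asp/Glu carboxyl oxygen.  Returns (n_hbond, n_saltbridge, contact table);
    the table lists each contact once with a deterministic ordering and a
    ``direction`` column ('AB' = A donates).
    """
    for sub in (subA, subB):
        if any(not el for el in sub.atoms.element):
            raise AnnotationError("subunit atoms lack element annotations")
    dA, aA, bA, cA = _polar_flags(subA)
    dB, aB, bB, cB = _polar_flags(subB)
    XA, XB = subA.atoms.xyz, subB.atoms.xyz
    polarA = np.where(dA | aA)[0]
    polarB = np.where(dB | aB)[0]
    rows = []
    nh = ns = 0
    if polarA.size and polarB.size:
        tree = cKDTree(XB[polarB])
        rmax = max(criteria.hbond_max, criteria.saltbridge_max)
        for ia in polarA:
            for jj in tree.query_ball_point(XA[ia], rmax):
                ib = polarB[jj]
                d = float(np.linalg.norm(XA[ia] - XB[ib]))
                is_h = d <= criteria.hbond_max and (
                    (dA[ia] and aB[ib]) or (aA[ia] and dB[ib])
                )
                is_s = d <= criteria.saltbridge_max and (
                    (bA[ia] and cB[ib]) or (cA[ia] and bB[ib])
                )
                if not (is_h or is_s):
                    continue
                direction = "AB" if (dA[ia] and aB[ib]) or (bA[ia] and cB[ib]) else "BA"
                if is_h:
                    nh += 1
                if is_s:
                    ns += 1
                mA, mB = subA.atoms, subB.atoms
                rows.append(
                    (
                        int(mA.res_id[ia]), mA.res_name[ia], mA.atom_name[ia],
                        int(mB.res_id[ib]), mB.res_name[ib], mB.atom_name[ib],
                        round(d, 4), "hbond" if is_h else "", "salt" if is_s else "",
                        direction,
                    )
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "res_a", "resname_a", "atom_a", "res_b", "resname_b", "atom_b",
            "dist_A", "hbond", "salt", "direction",
        ],
    )
    if len(table):
        table = table.sort_values(
            ["res_a", "atom_a", "res_b", "atom_b"], kind="mergesort"
        ).reset_index(drop=True)
    return nh, ns, table


def min_interatomic_distance(subA: PlacedSubunit, subB: PlacedSubunit) -> float:
    """Smallest heavy-atom distance between two subunits (KD-tree)."""
    tree = cKDTree(subB.atoms.xyz)
    d, _ = tree.query(subA.atoms.xyz, k=1)
    return float(np.min(d))


@dataclass
class ContactReport:
    """Per-neighbour-offset contact summary for one reference subunit."""

    reference_index: int
    table: pd.DataFrame  # columns: k, species_a, species_b, n_hbond, n_saltbridge, min_dist_A, tail_contact
    disclaimer: str = GEOMETRIC_DISCLAIMER

    def offsets_with_tail_contact(self) -> frozenset:
        t = self.table
        return frozenset(int(k) for k in t.loc[t["tail_contact"], "k"])

    def offsets_in_contact(self, max_dist: float = 4.0) -> frozenset:
        t = self.table
        return frozenset(int(k) for k in t.loc[t["min_dist_A"] <= max_dist, "k"])

    def species_pair(self, k: int) -> Tuple[int, int]:
        row = self.table.loc[self.table["k"] == k]
        if row.empty:
            raise InvalidArgumentError(f"offset {k} not in report")
        return int(row["species_a"].iloc[0]), int(row["species_b"].iloc[0])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {self.disclaimer}\n")
            fh.write(f"# reference subunit: {self.reference_index}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def neighbor_contact_map(
    model: FilamentModel,
    reference: int,
    max_k: int,
    criteria: ContactCriteria = ContactCriteria(),
) -> ContactReport:
    """Contact summary between subunit ``reference`` and each neighbour n±k.

    The reference must be interior: all offsets in [−max_k, +max_k] must
    exist.  For straight filaments the report is independent of which
    interior subunit is chosen (screw symmetry).
    """
    n = model.n_subunits
    if not (0 <= reference < n):
        raise InvalidArgumentError(f"reference {reference} out of range")
    if reference - max_k < 0 or reference + max_k >= n:
        raise BoundaryError(
            f"reference {reference} needs {max_k} neighbours on each side "
            f"(filament has {n} subunits)"
        )
    ref = model.subunits[reference]
    tails_annotated = ref.atoms.annotation is not None
    ref_seg = _tail_segment(ref) if tails_annotated else None
    rows = []
    for k in range(-max_k, max_k + 1):
        if k == 0:
            continue
        nb = model.subunits[reference + k]
        nh, ns, _ = polar_contacts(ref, nb, criteria)
        mind = min_interatomic_distance(ref, nb)
        tail_contact = False
        if tails_annotated and nb.atoms.annotation is not None:
            d = segment_segment_distance(*ref_seg, *_tail_segment(nb))
            tail_contact = d <= criteria.tail_segment_cutoff
        rows.append((k, ref.species, nb.species, nh, ns, round(mind, 4), tail_contact))
    table = pd.DataFrame(
        rows,
        columns=["k", "species_a", "species_b", "n_hbond", "n_saltbridge", "min_dist_A", "tail_contact"],
    )
    return ContactReport(reference_index=reference, table=table)


def _tail_segment(sub: PlacedSubunit):
    xyz = sub.atoms.domain_xyz("tail")
    if len(xyz) < 2:
        raise AnnotationError("tail domain has fewer than 2 atoms")
    return fit_line_segment(xyz)


def tail_core_contacts(
    model: FilamentModel,
    reference: int,
    criteria: ContactCriteria = ContactCriteria(),
    max_k: int = 10,
) -> frozenset:
    """Offsets k whose tail center-line passes near the reference tail.

    Each tail is reduced to its least-squares center-line segment; offset k is
    reported when the minimal segment–segment distance is within
    ``criteria.tail_segment_cutoff``.  This is the packing pattern of the
    hydrophobic tails in the filament core.
    """
    n = model.n_subunits
    if reference - max_k < 0 or reference + max_k >= n:
        raise BoundaryError(
            f"reference {reference} needs {max_k} neighbours on each side "
            f"(filament has {n} subunits)"
        )
    ref = model.subunits[reference]
    if ref.atoms.annotation is None:
        raise AnnotationError("tail annotation required")
    ref_seg = _tail_segment(ref)
    out = set()
    for k in range(-max_k, max_k + 1):
        if k == 0:
            continue
        nb = model.subunits[reference + k]
        if nb.atoms.annotation is None:
            raise AnnotationError("tail annotation required on all neighbours")
        if segment_segment_distance(*ref_seg, *_tail_segment(nb)) <= criteria.tail_segment_cutoff:
            out.add(k)
    return frozenset(out)
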