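"""Synthetic two-species filament fixtures.

Generates everything the analysis stack needs without any downloads: toy
archaellin-like monomers (an α-helical tail of 46 residues, a two-residue
Ser-Gly hinge, a globular pseudo-atomic head, and — for the second species —
an extra outward-facing surface loop carrying an NNTT sequon), a straight
two-species filament on the (5.57 Å, 108°) lattice with three alternating
3-start strands of which one is out of register, and noisy label sequences
for register inference.

The toy monomer emulates the domain architecture and core packing of a real
archaellin at reduced resolution; it is not derived from any deposited
coordinates.  The tail center-line anchors below are calibration constants,
fixed in version control, chosen once so that the tails of a straight
filament built on the default lattice touch (segment–segment distance within
the 8 Å core cutoff) exactly the neighbours at offsets ±1, ±3, ±4 and ±7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .errors import InvalidArgumentError
from .register import RegisterPattern, SubunitLabeling, labeling_from_register
from .structure import DomainAnnotation, FilamentModel, MonomerModel, build_filament
from .symmetry import HelicalSymmetry

__all__ = ["FixtureConfig", "make_toy_monomer", "make_fixture_filament", "make_label_sequence"]

# --- calibrated tail center-line (cylindrical: radius Å, azimuth °) ----------
# start = N-terminal end buried near the axis, end = hinge-proximal end at the
# core boundary; axial extent follows from the 69 Å tail length.
TAIL_START_R = 4.5
TAIL_START_AZ = 0.0
TAIL_END_R = 16.5
TAIL_END_AZ = 75.0

HELIX_CA_RADIUS = 2.3   # Å, CA orbit radius of an ideal α-helix
HELIX_DEG_PER_RES = 100.0

HEAD_CENTER_R = 40.0    # Å, head centroid radius (head reaches ~49 Å)
HEAD_SPHERE_R = 9.0     # Å

_TAIL_CYCLE = ("LEU", "VAL", "ALA", "MET", "PHE")
_HEAD_CYCLE = ("LYS", "GLU", "SER", "VAL", "ARG", "ASP", "THR", "GLY", "ASN", "TYR")
_SIDECHAIN = {"LYS": ("NZ", "N", 2.5), "GLU": ("OE1", "O", 2.2),
              "ARG": ("NH1", "N", 2.3), "ASP": ("OD1", "O", 2.0),
              "ASN": ("ND2", "N", 1.9), "SER": ("OG", "O", 1.4),
              "THR": ("OG1", "O", 1.4), "TYR": ("OH", "O", 2.6)}


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic filament.

    Defaults are the published lattice (rise 5.57 Å, twist 108°), the
    out-of-register two-species pattern on three 3-start strands
    (offsets (0, 0, 1)), and a 46-residue tail at the ideal α-helical rise
    of 1.5 Å per residue.
    """

    rise: float = 5.57
    twist: float = 108.0
    s: int = 3
    q: int = 2
    offsets: Tuple[int, ...] = (0, 0, 1)
    tail_residues: int = 46
    helix_rise_per_residue: float = 1.5
    n_head_residues: int = 40
    species2_extra_loop: bool = True
    seed: int = 7

    @property
    def tail_length(self) -> float:
        return self.tail_residues * self.helix_rise_per_residue

    def symmetry(self) -> HelicalSymmetry:
        return HelicalSymmetry(rise=self.rise, twist_raw=self.twist)

    def register(self) -> RegisterPattern:
        return RegisterPattern(s=self.s, q=self.q, offsets=self.offsets)

    def labeling(self) -> SubunitLabeling:
        return labeling_from_register(self.register())


def _cyl(r: float, az_deg: float, z: float) -> np.ndarray:
    t = math.radians(az_deg)
    return np.array([r * math.cos(t), r * math.sin(t), z])


def _tail_anchors(config: FixtureConfig) -> Tuple[np.ndarray, np.ndarray]:
    start = _cyl(TAIL_START_R, TAIL_START_AZ, 0.0)
    end_xy = _cyl(TAIL_END_R, TAIL_END_AZ, 0.0)
    lateral = np.linalg.norm(end_xy[:2] - start[:2])
    L = config.tail_length
    if lateral >= L:
        raise InvalidArgumentError("tail anchors further apart laterally than the tail length")
    end = end_xy + np.array([0.0, 0.0, math.sqrt(L * L - lateral * lateral)])
    return start, end


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = math.pi * (1 + 5 ** 0.5) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def make_toy_monomer(config: FixtureConfig = FixtureConfig(), species: int = 0) -> MonomerModel:
    """Deterministic toy archaellin monomer in the subunit-0 frame.

    The tail is an ideal α-helix of ``config.tail_residues`` residues wound
    about the calibrated core center-line; the head is a compact pseudo-atom
    cluster at the filament surface; species 1 carries an extra outward loop
    (residues 131–137) with consecutive sequon asparagines.  Identical
    (config, species) inputs give bitwise-identical coordinates.
    """
    rng = np.random.default_rng([config.seed, species])
    S, E = _tail_anchors(config)
    d = (E - S) / np.linalg.norm(E - S)
    # orthonormal frame transverse to the tail axis
    e1 = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.array([1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)

    atom_name, element, res_name, res_id, xyz = [], [], [], [], []

    def add(an, el, rn, rid, pos):
        atom_name.append(an)
        element.append(el)
        res_name.append(rn)
        res_id.append(rid)
        xyz.append(np.asarray(pos, float))

    nt = config.tail_residues
    L = config.tail_length
    for j in range(nt):
        rid = 14 + j
        if rid == 14:
            rn = "ILE"
        elif rid == 13 + nt:
            rn = "ALA"
        else:
            rn = _TAIL_CYCLE[j % len(_TAIL_CYCLE)]
        axis_pt = S + (L * j / (nt - 1)) * d
        ph = math.radians(HELIX_DEG_PER_RES * j)
        ca = axis_pt + HELIX_CA_RADIUS * (math.cos(ph) * e1 + math.sin(ph) * e2)
        phN, phO = ph - math.radians(30), ph + math.radians(30)
        add("N", "N", rn, rid, axis_pt - 0.5 * d + 1.6 * (math.cos(phN) * e1 + math.sin(phN) * e2))
        add("CA", "C", rn, rid, ca)
        add("O", "O", rn, rid, axis_pt + 0.5 * d + 1.7 * (math.cos(phO) * e1 + math.sin(phO) * e2))

    head_center = _cyl(HEAD_CENTER_R, TAIL_END_AZ, E[2])
    # hinge bridges tail end and head
    to_head = head_center - E
    ca60 = E + 0.15 * to_head
    ca61 = E + 0.30 * to_head
    add("N", "N", "SER", 60, ca60 - 0.7 * d)
    add("CA", "C", "SER", 60, ca60)
    add("OG", "O", "SER", 60, ca60 + 1.4 * e1)
    add("O", "O", "SER", 60, ca60 + 0.7 * d)
    add("N", "N", "GLY", 61, ca61 - 0.7 * d)
    add("CA", "C", "GLY", 61, ca61)
    add("O", "O", "GLY", 61, ca61 + 0.7 * d)

    pts = _fibonacci_sphere(config.n_head_residues)
    radii = HEAD_SPHERE_R * (0.45 + 0.55 * rng.random(config.n_head_residues))
    jitter = rng.normal(scale=0.25, size=(config.n_head_residues, 3))
    for j in range(config.n_head_residues):
        rid = 62 + j
        rn = _HEAD_CYCLE[j % len(_HEAD_CYCLE)]
        ca = head_center + radii[j] * pts[j] + jitter[j]
        add("N", "N", rn, rid, ca + np.array([0.0, 0.0, -0.6]))
        add("CA", "C", rn, rid, ca)
        add("O", "O", rn, rid, ca + np.array([0.0, 0.0, 0.6]))
        if rn in _SIDECHAIN:
            an, el, reach = _SIDECHAIN[rn]
            outward = pts[j]
            add(an, el, rn, rid, ca + reach * outward)

    last = 62 + config.n_head_residues - 1
    if species == 1 and config.species2_extra_loop:
        # outward-facing glycosylation loop K131..A137 with the NNTT sequon
        loop = [("LYS", 131), ("GLY", 132), ("ASN", 133), ("ASN", 134),
                ("THR", 135), ("THR", 136), ("ALA", 137)]
        radial = np.array([head_center[0], head_center[1], 0.0])
        radial /= np.linalg.norm(radial)
        up = np.array([0.0, 0.0, 1.0])
        for jj, (rn, rid) in enumerate(loop):
            arc = math.pi * jj / (len(loop) - 1)
            pos = (
                head_center
                + (HEAD_SPHERE_R + 1.5 + 2.5 * math.sin(arc)) * radial
                + 3.0 * math.cos(arc) * up
            )
            add("CA", "C", rn, rid, pos)
            if rn == "ASN":
                add("ND2", "N", rn, rid, pos + 1.9 * radial)
        last = 137

    annotation = DomainAnnotation(tail=(14, 13 + nt), hinge=(60, 61), head=(62, last))
    return MonomerModel(
        atom_name=atom_name,
        element=element,
        res_name=res_name,
        res_id=np.array(res_id, int),
        xyz=np.vstack(xyz),
        species=species,
        annotation=annotation,
    )


def make_fixture_filament(
    preset: str = "mvillosus",
    n: int = 36,
    config: FixtureConfig | None = None,
) -> FilamentModel:
    """Straight two-species fixture filament on the published lattice.

    ``preset='mvillosus'``: rise 5.57 Å, twist 108°, three 3-start strands
    with species alternating along each and one strand out of register —
    label period 6, first six labels (0, 0, 1, 1, 1, 0) — calibrated so the
    tail-core contact set of an interior subunit is {±1, ±3, ±4, ±7}.
    """
    if preset != "mvillosus":
        raise InvalidArgumentError(f"unknown preset {preset!r}")
    if n < 6:
        raise InvalidArgumentError(f"need n >= 6 subunits (one label period), got {n}")
    config = config or FixtureConfig()
    monomers = {sp: make_toy_monomer(config, sp) for sp in range(config.q)}
    return build_filament(monomers, config.symmetry(), config.labeling(), n)


def make_label_sequence(
    rp: RegisterPattern, n: int, error_rate: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Species labels for subunits 0..n−1 with optional per-position corruption.

    Each position is independently replaced by a different random species with
    probability ``error_rate``; deterministic for a given seed.
    """
    if not (0.0 <= error_rate <= 1.0):
        raise InvalidArgumentError(f"error_rate must be in [0, 1], got {error_rate}")
    labels = labeling_from_register(rp).labels(n)
    if error_rate > 0 and rp.q > 1:
        rng = np.random.default_rng(seed)
        flip = rng.random(n) < error_rate
        shift = rng.integers(1, rp.q, size=n)
        labels = np.where(flip, (labels + shift) % rp.q, labels)
    return labels
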