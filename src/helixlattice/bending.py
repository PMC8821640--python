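"""Forward rigid-body model of filament bending.

Bending a filament of rigid subunits is modelled by mapping the straight
filament axis onto a circular arc of radius 1/κ and carrying each subunit
along as a rigid body: the subunit whose lattice station sits at axial
position z moves to arc angle θ = κ·z and its local frame is rotated so the
local +z follows the arc tangent.  Arc length along the neutral axis is
preserved, so subunits on the convex side of the bend spread apart and
subunits on the concave side compress — the geometric signature of a bent
helical polymer.  An optional hinge swing adds a relative rotation of the
head domain about the two-residue hinge, emulating head/tail decoupling.

Motion reports compare two conformations subunit by subunit the way bent
cryo-EM frames are compared to straight ones: centroid displacement vectors,
head displacement after tail superposition, signed tail slide along the local
filament axis and tail rotation about it, plus head-centroid trajectories
across a series of frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from ._geometry import kabsch, rmsd_after_superposition
from .errors import InvalidArgumentError, SelfIntersectionError, TopologyMismatchError
from .structure import DomainAnnotation, FilamentModel, PlacedSubunit

__all__ = ["BendSpec", "MotionReport", "bend_filament", "motion_report", "head_trajectories"]


@dataclass(frozen=True)
class BendSpec:
    """Curvature specification for the forward bend model.

    Parameters
    ----------
    kappa : float
        Curvature in 1/Å (0 = straight).  The bend radius is 1/κ.
    azimuth_deg : float
        Azimuth of the bend plane; the filament bulges toward this direction
        (subunits at this azimuth lie on the convex, stretched side).
    hinge_swing_deg : float
        Optional extra rigid rotation of each head about its hinge midpoint
        (0 = pure arc mapping).
    superhelix_pitch : float or None
        If set, the bend-plane azimuth advances by 360° per this axial
        distance (Å), producing a superhelical rather than planar bend.
    """

    kappa: float
    azimuth_deg: float = 0.0
    hinge_swing_deg: float = 0.0
    superhelix_pitch: Optional[float] = None

    def __post_init__(self):
        if self.kappa < 0 or not math.isfinite(self.kappa):
            raise InvalidArgumentError(f"kappa must be finite and >= 0, got {self.kappa}")
        if self.superhelix_pitch is not None and self.superhelix_pitch <= 0:
            raise InvalidArgumentError("superhelix_pitch must be positive")


def _bend_frame(kappa: float, azimuth_deg: float, z: float):
    """Rigid transform (R, t) carrying the station at (0,0,z) onto the arc."""
    beta = math.radians(azimuth_deg)
    u = np.array([math.cos(beta), math.sin(beta), 0.0])  # convex direction
    theta = kappa * z
    R_arc = 1.0 / kappa
    # circle centre at -R*u; neutral axis keeps arc length == z
    t = -R_arc * (1.0 - math.cos(theta)) * u + np.array([0.0, 0.0, R_arc * math.sin(theta)])
    axis = np.cross(np.array([0.0, 0.0, 1.0]), -u)  # = u x z rotated; tilts +z toward -u
    R = Rotation.from_rotvec(theta * axis).as_matrix()
    return R, t


def bend_filament(model: FilamentModel, spec: BendSpec) -> FilamentModel:
    """Map a straight filament onto a circular arc, subunit by subunit.

    Each subunit is moved rigidly: no internal deformation, κ = 0 returns
    coordinates identical to the input.  Raises
    :class:`SelfIntersectionError` when κ times the filament radius reaches 1
    (the concave side would pass through the arc centre).
    """
    if not model.straight:
        raise InvalidArgumentError("bend_filament expects a straight input model")
    if spec.kappa == 0.0:
        subunits = [
            replace(su, atoms=replace(su.atoms, xyz=su.atoms.xyz.copy())) for su in model.subunits
        ]
        return FilamentModel(
            sym=model.sym, labeling=model.labeling, subunits=subunits,
            references=model.references, straight=True,
        )
    xyz_all = model.all_xyz()
    radius = float(np.hypot(xyz_all[:, 0], xyz_all[:, 1]).max())
    if spec.kappa * radius >= 1.0:
        raise SelfIntersectionError(
            f"kappa*radius = {spec.kappa * radius:.3f} >= 1: bend radius "
            f"{1 / spec.kappa:.1f} Å is inside the filament envelope ({radius:.1f} Å)"
        )
    bent = []
    for su in model.subunits:
        z_i = float(su.t[2])  # lattice station of this subunit
        az = spec.azimuth_deg
        if spec.superhelix_pitch is not None:
            az = az + 360.0 * z_i / spec.superhelix_pitch
        Rb, tb = _bend_frame(spec.kappa, az, z_i)
        new_xyz = (su.atoms.xyz - su.station()) @ Rb.T + tb
        atoms = replace(su.atoms, xyz=new_xyz)
        if spec.hinge_swing_deg and su.atoms.annotation is not None:
            atoms = _swing_head(atoms, Rb, spec.hinge_swing_deg)
        bent.append(
            PlacedSubunit(
                index=su.index, species=su.species,
                R=Rb @ su.R, t=tb, atoms=atoms, operator=None,
            )
        )
    return FilamentModel(
        sym=model.sym, labeling=model.labeling, subunits=bent,
        references=model.references, straight=False,
    )


def _swing_head(atoms, Rb: np.ndarray, swing_deg: float):
    """Rotate the head rigidly about an axis through the hinge midpoint."""
    hinge_xyz = atoms.xyz[atoms.domain_mask("hinge")]
    pivot = hinge_xyz.mean(axis=0)
    axis = Rb @ np.array([0.0, 1.0, 0.0])  # transverse local axis
    Rs = Rotation.from_rotvec(math.radians(swing_deg) * axis).as_matrix()
    mask = atoms.domain_mask("head")
    xyz = atoms.xyz.copy()
    xyz[mask] = (xyz[mask] - pivot) @ Rs.T + pivot
    return replace(atoms, xyz=xyz)


@dataclass
class MotionReport:
    """Per-subunit rigid-body motion summary between two conformations."""

    table: pd.DataFrame
    # columns: index, species, disp_x/y/z, disp_norm, head_disp_after_tail_align,
    #          head_internal_rmsd, tail_slide_A, tail_rotation_deg

    def max_displacement(self) -> float:
        return float(self.table["disp_norm"].max())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _check_topology(frameA: FilamentModel, frameB: FilamentModel) -> None:
    if frameA.n_subunits != frameB.n_subunits:
        raise TopologyMismatchError(
            f"frames have {frameA.n_subunits} vs {frameB.n_subunits} subunits"
        )
    for a, b in zip(frameA.subunits, frameB.subunits):
        if a.atoms.n_atoms != b.atoms.n_atoms or a.species != b.species:
            raise TopologyMismatchError(f"subunit {a.index}: atom/species mismatch")
        if a.atoms.atom_name != b.atoms.atom_name:
            raise TopologyMismatchError(f"subunit {a.index}: atom names differ")


def motion_report(
    frameA: FilamentModel,
    frameB: FilamentModel,
    annotation: Optional[DomainAnnotation] = None,
) -> MotionReport:
    """Rigid-body motion metrics of ``frameB`` relative to ``frameA``.

    Per subunit: total centroid displacement; head-centroid displacement
    after superposing B's tail onto A's tail (isolates head motion relative
    to its own tail); internal head RMSD after optimal head superposition
    (0 for perfectly rigid heads); tail slide — the component of the tail
    centroid displacement along the subunit's local filament axis, in excess
    of its lattice station's displacement — and tail rotation about that
    axis.  Annotation defaults to the one carried by the subunits.
    """
    _check_topology(frameA, frameB)
    rows = []
    zhat = np.array([0.0, 0.0, 1.0])
    for a, b in zip(frameA.subunits, frameB.subunits):
        ann = annotation or a.atoms.annotation
        ca, cb = a.centroid(), b.centroid()
        disp = cb - ca
        head_disp = head_rmsd = tail_slide = tail_rot = np.nan
        if ann is not None:
            atoms_a = replace(a.atoms, annotation=ann)
            atoms_b = replace(b.atoms, annotation=ann)
            tail_a, tail_b = atoms_a.domain_xyz("tail"), atoms_b.domain_xyz("tail")
            head_a, head_b = atoms_a.domain_xyz("head"), atoms_b.domain_xyz("head")
            # head motion relative to the tail frame
            R, t = kabsch(tail_b, tail_a)
            head_b_in_a = head_b @ R.T + t
            head_disp = float(np.linalg.norm(head_b_in_a.mean(axis=0) - head_a.mean(axis=0)))
            head_rmsd = rmsd_after_superposition(head_a, head_b)
            # tail slide: station-relative tail-centroid displacement projected
            # on the local filament axis (convex side +, concave side −)
            axis_b = b.local_axis()
            rel = (tail_b.mean(axis=0) - b.station()) - (tail_a.mean(axis=0) - a.station())
            tail_slide = float(rel @ axis_b)
            # tail rotation about the local axis, from local-frame azimuths
            va = a.R.T @ (tail_a.mean(axis=0) - a.station())
            vb = b.R.T @ (tail_b.mean(axis=0) - b.station())
            tail_rot = math.degrees(
                math.atan2(vb[1], vb[0]) - math.atan2(va[1], va[0])
            )
            tail_rot = float(math.remainder(tail_rot, 360.0))
        rows.append(
            (
                a.index, a.species, disp[0], disp[1], disp[2],
                float(np.linalg.norm(disp)), head_disp, head_rmsd,
                tail_slide, tail_rot,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "index", "species", "disp_x", "disp_y", "disp_z", "disp_norm",
            "head_disp_after_tail_align", "head_internal_rmsd",
            "tail_slide_A", "tail_rotation_deg",
        ],
    )
    return MotionReport(table=table)


def head_trajectories(
    frames: Sequence[FilamentModel],
    selection: Sequence[int],
    annotation: Optional[DomainAnnotation] = None,
) -> Dict[int, dict]:
    """Head-centroid paths of selected subunits across ordered conformations.

    Returns per subunit the (n_frames, 3) centroid path plus its total path
    length and net displacement (Å).  Falls back to whole-subunit centroids
    when no domain annotation is available.
    """
    if len(frames) < 2:
        raise InvalidArgumentError("need at least 2 frames for a trajectory")
    for f in frames[1:]:
        _check_topology(frames[0], f)
    out: Dict[int, dict] = {}
    for idx in selection:
        pts = []
        for f in frames:
            su = f.subunits[idx]
            ann = annotation or su.atoms.annotation
            if ann is not None:
                atoms = replace(su.atoms, annotation=ann)
                pts.append(atoms.domain_xyz("head").mean(axis=0))
            else:
                pts.append(su.centroid())
        path = np.asarray(pts)
        steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
        out[int(idx)] = {
            "path": path,
            "path_length": float(steps.sum()),
            "net_displacement": float(np.linalg.norm(path[-1] - path[0])),
        }
    return out
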