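"""Screw-operator algebra on 1-start helical lattices.

A helical (1-start) lattice is generated by a single screw operation: translate
by the *rise* (Å) along the filament axis and rotate by the *twist* (degrees)
about it.  Subunit ``i`` sits at axial position ``i * rise`` and azimuth
``i * twist``.  Everything in this module is exact arithmetic on that
generator: composing screw operators, reducing the symmetry to every p-th
subunit, enumerating k-start strand families, and laying subunits out on an
unwrapped helical net.

Sign convention: positive twist is a right-handed rotation about +z when
advancing along +z.  Under this convention a k-start family whose principal
per-step rotation is negative is left-handed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError

#: default tolerance for angle comparisons, degrees
ANGLE_TOL = 1e-6
#: default tolerance for length comparisons, Å
LENGTH_TOL = 1e-9

__all__ = [
    "HelicalSymmetry",
    "ScrewOperator",
    "StartFamilyGeometry",
    "NetDiagram",
    "normalize_twist",
    "screw_operator",
    "reduce_symmetry",
    "start_family",
    "axial_repeat",
    "net_diagram",
]


def normalize_twist(angle_degrees: float) -> float:
    """Reduce an angle to its principal value in (−180, 180].

    The raw and principal representations of a twist are congruent mod 360;
    e.g. a six-subunit step of a 108° lattice is 648° raw and −72° principal.
    """
    if not math.isfinite(angle_degrees):
        raise InvalidArgumentError(f"angle must be finite, got {angle_degrees!r}")
    t = math.remainder(float(angle_degrees), 360.0)
    if t <= -180.0:
        t += 360.0
    return t + 0.0  # drop negative zero


@dataclass(frozen=True)
class HelicalSymmetry:
    """Rise/twist pair generating a 1-start helical lattice.

    Parameters
    ----------
    rise : float
        Axial translation per subunit, Å.  Must be positive.
    twist : float
        Rotation per subunit about the axis, degrees.  Stored as given
        (``twist_raw``) and as the principal value in (−180, 180]
        (``twist``).
    """

    rise: float
    twist_raw: float
    twist: float = field(init=False)

    def __post_init__(self):
        if not (math.isfinite(self.rise) and self.rise > 0):
            raise InvalidArgumentError(f"rise must be finite and > 0, got {self.rise!r}")
        object.__setattr__(self, "twist", normalize_twist(self.twist_raw))

    def __repr__(self) -> str:
        return f"HelicalSymmetry(rise={self.rise:g} Å, twist={self.twist:g}°)"


@dataclass(frozen=True)
class ScrewOperator:
    """Rigid screw transform for a subunit offset ``k`` on a helical lattice.

    ``delta_z = k * rise`` and ``delta_phi = k * twist`` (raw, unreduced so
    that composition is exact integer arithmetic on k).
    """

    delta_z: float
    delta_phi: float
    k: int

    @property
    def delta_phi_principal(self) -> float:
        return normalize_twist(self.delta_phi)

    def is_identity(self, angle_tol: float = ANGLE_TOL, length_tol: float = LENGTH_TOL) -> bool:
        return abs(self.delta_z) <= length_tol and abs(self.delta_phi_principal) <= angle_tol

    def rotation_matrix(self) -> np.ndarray:
        t = math.radians(self.delta_phi)
        c, s = math.cos(t), math.sin(t)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def translation(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.delta_z])

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Apply the screw to an (N, 3) coordinate array (Å)."""
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.rotation_matrix().T + self.translation()

    def compose(self, other: "ScrewOperator") -> "ScrewOperator":
        """Composition of two screws about the same axis (commutative)."""
        return ScrewOperator(
            delta_z=self.delta_z + other.delta_z,
            delta_phi=self.delta_phi + other.delta_phi,
            k=self.k + other.k,
        )

    def inverse(self) -> "ScrewOperator":
        return ScrewOperator(delta_z=-self.delta_z, delta_phi=-self.delta_phi, k=-self.k)


@dataclass(frozen=True)
class StartFamilyGeometry:
    """Geometry of the k-start strand family of a 1-start lattice.

    Connecting every k-th subunit partitions the lattice into ``k`` strands;
    one step along a strand advances ``k * rise`` axially and rotates by the
    principal value of ``k * twist``.
    """

    k: int
    step_rise: float
    step_phi: float
    handedness: str  # "left" | "right" | "vertical"
    n_strands: int


def screw_operator(sym: HelicalSymmetry, k: int) -> ScrewOperator:
    """Screw operator carrying subunit n to subunit n + k."""
    k = int(k)
    return ScrewOperator(delta_z=k * sym.rise, delta_phi=k * sym.twist_raw, k=k)


def reduce_symmetry(sym: HelicalSymmetry, period: int) -> HelicalSymmetry:
    """Symmetry of the sub-lattice formed by every ``period``-th subunit.

    The new rise is ``period * rise``; the new twist is ``period * twist``
    stored raw in [0, 360) with its principal value in (−180, 180] alongside.
    E.g. reducing (5.57 Å, 108°) by 6 gives 33.42 Å and 648° ≡ −72°.
    """
    if not isinstance(period, (int, np.integer)) or period < 1:
        raise InvalidArgumentError(f"period must be an integer >= 1, got {period!r}")
    raw = (period * sym.twist_raw) % 360.0
    return HelicalSymmetry(rise=period * sym.rise, twist_raw=raw)


def start_family(sym: HelicalSymmetry, k: int, angle_tol: float = ANGLE_TOL) -> StartFamilyGeometry:
    """Geometry of the k-start family (k >= 1) of ``sym``."""
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise InvalidArgumentError(f"k must be an integer >= 1, got {k!r}")
    step_phi = normalize_twist(k * sym.twist_raw)
    if abs(step_phi) <= angle_tol or abs(abs(step_phi) - 180.0) <= angle_tol:
        hand = "vertical"
    elif step_phi > 0:
        hand = "right"
    else:
        hand = "left"
    return StartFamilyGeometry(
        k=int(k), step_rise=k * sym.rise, step_phi=step_phi, handedness=hand, n_strands=int(k)
    )


def axial_repeat(sym: HelicalSymmetry, max_k: int, tol_degrees: float = ANGLE_TOL) -> Optional[int]:
    """Smallest k <= max_k whose k-step rotation is within ``tol_degrees`` of 0.

    Subunits n, n+k, n+2k, ... then form (near-)vertical axial columns.
    Returns None when no such k exists within the bound.
    """
    if max_k < 1:
        raise InvalidArgumentError(f"max_k must be >= 1, got {max_k!r}")
    if tol_degrees < 0:
        raise InvalidArgumentError(f"tol_degrees must be >= 0, got {tol_degrees!r}")
    for k in range(1, int(max_k) + 1):
        if abs(normalize_twist(k * sym.twist_raw)) <= tol_degrees:
            return k
    return None


@dataclass
class NetDiagram:
    """Unwrapped helical net: one (azimuth, z) point per subunit.

    ``azimuth_deg`` is reported mod 360 in [0, 360); ``z_angstrom`` is the
    axial position ``i * rise``.  Species labels are attached when a labeling
    is supplied.
    """

    index: np.ndarray
    azimuth_deg: np.ndarray
    z_angstrom: np.ndarray
    species: Optional[np.ndarray] = None

    def to_frame(self):
        import pandas as pd

        cols = {
            "index": self.index,
            "azimuth_deg": self.azimuth_deg,
            "z_angstrom": self.z_angstrom,
        }
        if self.species is not None:
            cols["species"] = self.species
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, ax=None, wrap_margin_deg: float = 0.0):
        """Scatter azimuth vs z, colored by species when present."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 6))
        if self.species is None:
            ax.scatter(self.azimuth_deg, self.z_angstrom, s=30)
        else:
            for sp in np.unique(self.species):
                m = self.species == sp
                ax.scatter(self.azimuth_deg[m], self.z_angstrom[m], s=30, label=f"species {sp}")
            ax.legend()
        ax.set_xlabel("azimuth (°)")
        ax.set_ylabel("z (Å)")
        ax.set_xlim(-wrap_margin_deg, 360 + wrap_margin_deg)
        return ax


def net_diagram(sym: HelicalSymmetry, n_subunits: int, labeling=None) -> NetDiagram:
    """Helical net for subunits 0..n−1; subunit 0 sits at the origin."""
    if n_subunits < 1:
        raise InvalidArgumentError(f"n_subunits must be >= 1, got {n_subunits!r}")
    idx = np.arange(int(n_subunits))
    az = np.mod(idx * sym.twist_raw, 360.0)
    z = idx * sym.rise
    species = None
    if labeling is not None:
        species = np.array([labeling.species(int(i)) for i in idx])
    return NetDiagram(index=idx, azimuth_deg=az, z_angstrom=z, species=species)


def read_symmetry_config(path) -> HelicalSymmetry:
    """Read a plain ``key = value`` config with rise_angstrom / twist_degrees."""
    vals = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            vals[key.strip()] = val.strip()
    try:
        return HelicalSymmetry(rise=float(vals["rise_angstrom"]), twist_raw=float(vals["twist_degrees"]))
    except KeyError as exc:
        raise InvalidArgumentError(f"symmetry config missing key {exc}") from exc


def write_symmetry_config(sym: HelicalSymmetry, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"rise_angstrom = {sym.rise!r}\n")
        fh.write(f"twist_degrees = {sym.twist_raw!r}\n")
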