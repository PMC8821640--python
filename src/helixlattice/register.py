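"""Multi-species register patterns on a helical lattice.

A filament built from q chemically distinct subunit species can decorate a
1-start helical lattice in many ways.  The model here assigns species along
the s strands of one k-start family: within each strand the species cycle
(0, 1, ..., q−1, 0, ...), and each strand carries its own phase offset.  The
label of subunit ``i`` (1-start index) is::

    species(i) = (i // s + offsets[i % s]) % q

With all offsets equal, a two-species filament on three strands repeats every
``s * q`` = 6 subunits as plain blocks (0,0,0,1,1,1).  Shifting one strand by
one subunit — the out-of-register arrangement — changes which screw operation
maps the filament onto itself: the label sequence (0,0,1,1,1,0,...) still has
minimal period 6, but single-species traces become "stepped" pseudo-strands
and different neighbour directions see different species-pair combinations.
This module computes minimal label periods, the induced reduced helical
symmetry, out-of-register strands, species pairs along any neighbour offset,
pseudo-strand step motifs, and the inverse problem of recovering a register
pattern from an observed label sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    AmbiguousRegisterError,
    InconsistentLabelingError,
    InvalidArgumentError,
    NoPeriodError,
)
from .symmetry import HelicalSymmetry, reduce_symmetry

__all__ = [
    "RegisterPattern",
    "SubunitLabeling",
    "labeling_from_register",
    "minimal_label_period",
    "reduced_symmetry_for_labeling",
    "out_of_register_strands",
    "species_pairs_along",
    "pseudo_strand_steps",
    "infer_register",
    "canonical_register",
]


@dataclass(frozen=True)
class RegisterPattern:
    """Species assignment rule: s strands, q species, per-strand phase offsets.

    ``offsets[j]`` is the phase (mod q) of strand ``j``; strands are indexed by
    subunit index mod s.
    """

    s: int
    q: int
    offsets: tuple

    def __post_init__(self):
        if self.s < 1:
            raise InvalidArgumentError(f"n_strands s must be >= 1, got {self.s}")
        if self.q < 1:
            raise InvalidArgumentError(f"n_species q must be >= 1, got {self.q}")
        offs = tuple(int(o) for o in self.offsets)
        if len(offs) != self.s:
            raise InvalidArgumentError(
                f"offsets must have length s={self.s}, got {len(offs)}"
            )
        if any(not (0 <= o < self.q) for o in offs):
            raise InvalidArgumentError(f"offsets must lie in [0, q={self.q}), got {offs}")
        object.__setattr__(self, "offsets", offs)


@dataclass(frozen=True)
class SubunitLabeling:
    """Species labels species(i) for subunit indices i >= 0, exactly periodic."""

    pattern: RegisterPattern
    period: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "period", _minimal_period_of_pattern(self.pattern))

    def species(self, i: int) -> int:
        rp = self.pattern
        return (i // rp.s + rp.offsets[i % rp.s]) % rp.q

    def labels(self, n: int) -> np.ndarray:
        """Labels for subunits 0..n−1 as an int array."""
        i = np.arange(int(n))
        rp = self.pattern
        offs = np.asarray(rp.offsets)
        return (i // rp.s + offs[i % rp.s]) % rp.q

    @property
    def n_species(self) -> int:
        return self.pattern.q


def labeling_from_register(rp: RegisterPattern) -> SubunitLabeling:
    """Realize a register pattern as a concrete subunit labeling."""
    return SubunitLabeling(pattern=rp)


def _minimal_period_of_pattern(rp: RegisterPattern) -> int:
    # s*q is always a period (one full cycle on every strand); the minimal
    # period of a periodic sequence divides any period, so scanning divisors
    # of s*q over a 2*s*q window is exhaustive.
    sq = rp.s * rp.q
    offs = np.asarray(rp.offsets)
    i = np.arange(2 * sq)
    lab = (i // rp.s + offs[i % rp.s]) % rp.q
    for p in range(1, sq + 1):
        if sq % p:
            continue
        if np.array_equal(lab[: len(lab) - p], lab[p:]):
            return p
    return sq


def minimal_label_period(lab: SubunitLabeling, max_period: int | None = None) -> int:
    """Smallest p >= 1 with species(i + p) = species(i) for all i.

    The verification window is twice the guaranteed period bound ``s*q`` so a
    finite scan is exact.  ``max_period`` optionally caps the search; if the
    true period exceeds it a :class:`NoPeriodError` is raised.
    """
    rp = lab.pattern
    sq = rp.s * rp.q
    bound = sq if max_period is None else int(max_period)
    if max_period is not None and bound < sq and lab.period > bound:
        raise NoPeriodError(
            f"no label period <= {bound} (minimal period is {lab.period})"
        )
    if lab.period > bound:
        raise NoPeriodError(f"no label period <= {bound}")
    return lab.period


def reduced_symmetry_for_labeling(sym: HelicalSymmetry, lab: SubunitLabeling) -> HelicalSymmetry:
    """Helical symmetry of the species-respecting sub-lattice.

    The smallest screw operation mapping every subunit onto one of the same
    species is the p-step screw, p the minimal label period; e.g. the
    out-of-register two-species pattern on a (5.57 Å, 108°) lattice reduces to
    (33.42 Å, −72°).
    """
    return reduce_symmetry(sym, minimal_label_period(lab))


def out_of_register_strands(rp: RegisterPattern) -> frozenset:
    """Strands whose phase offset deviates from the strict-majority offset."""
    if rp.q < 2:
        raise InvalidArgumentError("out-of-register is undefined for a single species")
    counts: dict[int, int] = {}
    for o in rp.offsets:
        counts[o] = counts.get(o, 0) + 1
    best = max(counts.values())
    modal = [o for o, c in counts.items() if c == best]
    if len(modal) != 1 or best * 2 <= rp.s:
        raise AmbiguousRegisterError(
            f"no strict majority offset among {rp.offsets}; register is ambiguous"
        )
    return frozenset(j for j, o in enumerate(rp.offsets) if o != modal[0])


def species_pairs_along(lab: SubunitLabeling, k: int) -> frozenset:
    """Distinct ordered species pairs (species(i), species(i+k)) over one period."""
    if k == 0:
        raise InvalidArgumentError("k must be nonzero")
    p = lab.period
    return frozenset((lab.species(i), lab.species(i + k)) for i in range(p))


def pseudo_strand_steps(lab: SubunitLabeling, species: int) -> tuple:
    """Cyclic index-gap motif of one species' trace through the lattice.

    Gaps between consecutive subunits of the given species over one label
    period, returned as the lexicographically minimal rotation of the cyclic
    gap sequence.  A uniform trace gives a single gap; a broken ("stepped")
    pseudo-strand gives a mixed motif such as (1, 1, 4).
    """
    p = lab.period
    idx = [i for i in range(p) if lab.species(i) == species]
    if not idx:
        raise InvalidArgumentError(f"species {species} does not occur in the labeling")
    gaps = [idx[j + 1] - idx[j] for j in range(len(idx) - 1)]
    gaps.append(idx[0] + p - idx[-1])
    return _min_rotation(tuple(gaps))


def _min_rotation(seq: tuple) -> tuple:
    rots = [seq[i:] + seq[:i] for i in range(len(seq))]
    return min(rots)


def infer_register(observed: Sequence[int], s: int, q: int) -> RegisterPattern:
    """Recover the register pattern generating an observed label sequence.

    The within-strand species progression is the fixed cycle +1 mod q, so the
    solution is unique only up to a global cyclic shift of species names
    (equivalently, a global phase).  The result is canonicalized by that
    shift: ``offsets[0] = 0``, i.e. the returned pattern reproduces
    ``observed`` after subtracting ``observed[0]`` from every label (mod q).
    An observation not generated by any register pattern raises
    :class:`InconsistentLabelingError` carrying the first mismatching index.
    """
    obs = [int(x) for x in observed]
    if len(obs) < 2 * s * q:
        raise InvalidArgumentError(
            f"need at least 2*s*q = {2 * s * q} labels to infer a register, got {len(obs)}"
        )
    if any(not (0 <= x < q) for x in obs):
        raise InvalidArgumentError(f"labels must lie in [0, q={q})")

    shift = obs[0]
    offsets = tuple((obs[j] - shift) % q for j in range(s))
    rp = RegisterPattern(s=s, q=q, offsets=offsets)
    lab = labeling_from_register(rp)
    for i, x in enumerate(obs):
        if (lab.species(i) + shift) % q != x:
            raise InconsistentLabelingError(
                f"observed labels inconsistent with any (s={s}, q={q}) register "
                f"pattern; first mismatch at index {i}",
                index=i,
            )
    return rp


def canonical_register(rp: RegisterPattern) -> RegisterPattern:
    """Canonical form of a register pattern (species shifted so offsets[0] = 0),
    i.e. the representative :func:`infer_register` returns."""
    lab = labeling_from_register(rp)
    return infer_register(lab.labels(2 * rp.s * rp.q), rp.s, rp.q)


def read_register_config(path) -> RegisterPattern:
    """Read a plain key-value config with s, q and comma-separated offsets."""
    vals = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            vals[key.strip()] = val.strip()
    try:
        offsets = tuple(int(x) for x in vals["offsets"].split(","))
        return RegisterPattern(s=int(vals["s"]), q=int(vals["q"]), offsets=offsets)
    except KeyError as exc:
        raise InvalidArgumentError(f"register config missing key {exc}") from exc


def write_register_config(rp: RegisterPattern, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"s = {rp.s}\nq = {rp.q}\n")
        fh.write("offsets = " + ",".join(str(o) for o in rp.offsets) + "\n")
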