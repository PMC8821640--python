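"""Filament building, structure I/O, domain annotation, sequon scanning."""

import math

import numpy as np
import pytest

import helixlattice as hx
from helixlattice.errors import (
    AnnotationError,
    ChainIdExhaustionError,
    ConfigurationError,
    InvalidArgumentError,
    StructureParseError,
)


def test_build_single_subunit_is_reference(toy_monomers, paper_sym, paper_labeling):
    model = hx.build_filament(toy_monomers, paper_sym, paper_labeling, 1)
    np.testing.assert_array_equal(model.subunits[0].atoms.xyz, toy_monomers[0].xyz)


def test_build_centroid_azimuth_advances_by_twist(toy_monomers, paper_sym, paper_labeling):
    model = hx.build_filament(toy_monomers, paper_sym, paper_labeling, 12)
    # compare subunits of the same species so the reference centroid matches
    ref = toy_monomers[0].centroid()
    az0 = math.degrees(math.atan2(ref[1], ref[0]))
    for su in model.subunits:
        if su.species != 0:
            continue
        c = su.centroid()
        az = math.degrees(math.atan2(c[1], c[0]))
        expected = hx.normalize_twist(az0 + su.index * 108.0)
        assert hx.normalize_twist(az - expected) == pytest.approx(0.0, abs=1e-6)
        assert c[2] == pytest.approx(ref[2] + su.index * 5.57, abs=1e-9)


def test_build_species_counts(toy_monomers, paper_sym, paper_labeling):
    model = hx.build_filament(toy_monomers, paper_sym, paper_labeling, 60)
    assert model.species_counts() == {0: 30, 1: 30}


def test_species_counts_constant_per_period_window(fixture_filament):
    # any window of 6 consecutive subunits holds 3 of each species
    labels = [su.species for su in fixture_filament.subunits]
    for start in range(len(labels) - 6):
        window = labels[start : start + 6]
        assert window.count(0) == 3 and window.count(1) == 3


def test_build_missing_species_monomer(toy_monomers, paper_sym, paper_labeling):
    with pytest.raises(ConfigurationError):
        hx.build_filament({0: toy_monomers[0]}, paper_sym, paper_labeling, 6)
    with pytest.raises(InvalidArgumentError):
        hx.build_filament(toy_monomers, paper_sym, paper_labeling, 0)


def test_superposition_identity(fixture_filament, toy_monomers):
    """Undoing subunit i's screw reproduces the reference monomer exactly."""
    for i in (0, 7, 20, 35):
        su = fixture_filament.subunits[i]
        back = su.operator.inverse().apply(su.atoms.xyz)
        ref = toy_monomers[su.species].xyz
        rmsd = np.sqrt(np.mean(np.sum((back - ref) ** 2, axis=1)))
        assert rmsd < 1e-6


@pytest.mark.parametrize("fmt, tol", [("mmcif", 1e-3), ("pdb", 1e-3)])
def test_write_read_round_trip(tmp_path, fixture_config, fmt, tol):
    model = hx.make_fixture_filament("mvillosus", n=12)
    path = tmp_path / f"fil.{ 'cif' if fmt == 'mmcif' else 'pdb'}"
    hx.write_structure(model, path, format=fmt)
    back = hx.read_filament(path, fixture_config.symmetry(), fixture_config.labeling())
    assert back.n_subunits == model.n_subunits
    for a, b in zip(model.subunits, back.subunits):
        assert a.atoms.n_atoms == b.atoms.n_atoms
        assert a.atoms.atom_name == b.atoms.atom_name
        np.testing.assert_allclose(a.atoms.xyz, b.atoms.xyz, atol=tol)
        assert a.species == b.species


def test_pdb_chain_exhaustion(tmp_path):
    model = hx.make_fixture_filament("mvillosus", n=63)
    with pytest.raises(ChainIdExhaustionError):
        hx.write_structure(model, tmp_path / "big.pdb", format="pdb")
    # 62 subunits still fit
    hx.write_structure(hx.make_fixture_filament(n=62), tmp_path / "ok.pdb", format="pdb")


def test_read_monomer_completes_head_range(tmp_path, toy_monomers, paper_sym):
    mono = toy_monomers[0]
    single = hx.build_filament({0: mono}, paper_sym, None, 1)
    path = tmp_path / "mono.cif"
    hx.write_structure(single, path)
    back = hx.read_monomer(path, species=0, tail=(14, 59), hinge=(60, 61))
    assert back.annotation.tail == (14, 59)
    assert back.annotation.hinge == (60, 61)
    assert back.annotation.head == (62, int(mono.res_id.max()))


def test_read_malformed_file(tmp_path):
    bad = tmp_path / "bad.cif"
    bad.write_text("this is not a structure\n")
    with pytest.raises(StructureParseError):
        hx.read_monomer(bad)


def test_domain_annotation_validation():
    ann = hx.DomainAnnotation(tail=(14, 59), hinge=(60, 61), head=(62, 120))
    assert ann.domain_of(14) == "tail"
    assert ann.domain_of(60) == "hinge"
    assert ann.domain_of(120) == "head"
    with pytest.raises(AnnotationError):
        ann.domain_of(5)
    with pytest.raises(InvalidArgumentError):
        hx.DomainAnnotation(tail=(14, 61), hinge=(60, 61), head=(62, 120))


@pytest.mark.parametrize(
    "seq, exclude_p, expected",
    [
        ("ANNTTA", False, [2, 3]),   # overlapping sequons in the NNTT motif
        ("ANPTA", True, []),
        ("ANPTA", False, [2]),
        ("ACDEF", False, []),
        ("NNS", False, [1]),
        ("NGT", False, [1]),
    ],
)
def test_find_sequons(seq, exclude_p, expected):
    assert hx.find_sequons(seq, exclude_proline=exclude_p) == expected


def test_find_sequons_rejects_bad_letters():
    with pytest.raises(StructureParseError):
        hx.find_sequons("ANXTB")


def test_sequon_in_second_species_loop(toy_monomers):
    """The second species' surface loop carries consecutive sequon asparagines."""
    seq = toy_monomers[1].sequence()
    assert "NNTT" in seq
    pos = seq.index("NNTT") + 1
    hits = hx.find_sequons(seq)
    assert pos in hits and pos + 1 in hits
    assert "NNTT" not in toy_monomers[0].sequence()


def test_filament_diameter(paper_sym):
    # single atom on the axis
    mono = hx.MonomerModel(
        atom_name=["CA"], element=["C"], res_name=["GLY"],
        res_id=np.array([1]), xyz=np.array([[0.0, 0.0, 3.0]]),
    )
    m = hx.build_filament({0: mono}, paper_sym, None, 1)
    assert hx.filament_diameter(m) == pytest.approx(0.0)
    # farthest atom at radius 49 -> diameter 98, invariant under the screw
    mono2 = hx.MonomerModel(
        atom_name=["CA", "CB"], element=["C", "C"], res_name=["GLY", "GLY"],
        res_id=np.array([1, 1]), xyz=np.array([[10.0, 0.0, 0.0], [49.0, 0.0, 5.0]]),
    )
    d1 = hx.filament_diameter(hx.build_filament({0: mono2}, paper_sym, None, 1))
    d20 = hx.filament_diameter(hx.build_filament({0: mono2}, paper_sym, None, 20))
    assert d1 == pytest.approx(98.0)
    assert d20 == pytest.approx(98.0)


def test_monomer_validation():
    with pytest.raises(InvalidArgumentError):
        hx.MonomerModel(
            atom_name=["CA", "CA"], element=["C", "C"], res_name=["GLY", "GLY"],
            res_id=np.array([2, 1]), xyz=np.zeros((2, 3)),
        )
    with pytest.raises(InvalidArgumentError):
        hx.MonomerModel(
            atom_name=["CA"], element=["C"], res_name=["GLY"],
            res_id=np.array([1]), xyz=np.array([[np.nan, 0, 0]]),
        )


def test_kabsch_against_scipy_oracle():
    """Rigid superposition matches scipy's independent Wahba solver."""
    from scipy.spatial.transform import Rotation

    from helixlattice._geometry import kabsch

    rng = np.random.default_rng(3)
    pts = rng.normal(size=(30, 3)) * 10
    R_true = Rotation.from_rotvec([0.3, -0.5, 1.1]).as_matrix()
    t_true = np.array([4.0, -2.0, 7.0])
    moved = pts @ R_true.T + t_true
    R, t = kabsch(pts, moved)
    np.testing.assert_allclose(R, R_true, atol=1e-10)
    np.testing.assert_allclose(t, t_true, atol=1e-9)
    est, rssd = Rotation.align_vectors(moved - moved.mean(0), pts - pts.mean(0))
    np.testing.assert_allclose(R, est.as_matrix(), atol=1e-8)
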