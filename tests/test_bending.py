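"""Forward bend model: arc mapping, rigidity, motion metrics, trajectories."""

import numpy as np
import pytest

import helixlattice as hx
from helixlattice._geometry import rmsd_after_superposition
from helixlattice.errors import (
    InvalidArgumentError,
    SelfIntersectionError,
    TopologyMismatchError,
)


@pytest.fixture(scope="module")
def straight():
    return hx.make_fixture_filament("mvillosus", n=36)


@pytest.fixture(scope="module")
def bent(straight):
    return hx.bend_filament(straight, hx.BendSpec(kappa=1e-3, azimuth_deg=0.0))


def test_zero_curvature_is_identity(straight):
    out = hx.bend_filament(straight, hx.BendSpec(kappa=0.0))
    for a, b in zip(straight.subunits, out.subunits):
        np.testing.assert_array_equal(a.atoms.xyz, b.atoms.xyz)


def test_neutral_axis_isometry(straight):
    """Arc length between consecutive stations equals the straight rise."""
    for kappa in (1e-4, 1e-3, 5e-3):
        out = hx.bend_filament(straight, hx.BendSpec(kappa=kappa))
        R = 1.0 / kappa
        stations = np.array([su.station() for su in out.subunits])
        chord = np.linalg.norm(np.diff(stations, axis=0), axis=1)
        # chord of arc angle kappa*rise on radius R
        expected = 2 * R * np.sin(kappa * 5.57 / 2)
        np.testing.assert_allclose(chord, expected, rtol=1e-9)


def test_station_arc_distance(straight):
    kappa = 2e-3
    out = hx.bend_filament(straight, hx.BendSpec(kappa=kappa))
    R = 1.0 / kappa
    for su in out.subunits:
        z = su.index * 5.57
        theta = kappa * z
        # station sits on the circle of radius R in the bend plane
        s = su.station()
        center = np.array([-R, 0.0, 0.0])
        assert np.linalg.norm(s - center) == pytest.approx(R, rel=1e-9)
        # arc length from origin = |1/kappa| * |theta| = z
        assert R * theta == pytest.approx(z)


def test_convex_concave_spacing_ratio(paper_sym):
    """Spacing ratio across the bend equals (1+rκ)/(1−rκ) for point subunits."""
    kappa, r = 1e-3, 49.0
    point = hx.MonomerModel(
        atom_name=["CA"], element=["C"], res_name=["GLY"],
        res_id=np.array([1]), xyz=np.array([[r, 0.0, 0.0]]),
    )
    model = hx.build_filament({0: point}, paper_sym, None, 36)
    out = hx.bend_filament(model, hx.BendSpec(kappa=kappa, azimuth_deg=0.0))

    def spacing(m, ids):
        pts = [m.subunits[i].centroid() for i in ids]
        return np.mean([np.linalg.norm(b - a) for a, b in zip(pts, pts[1:])])

    conv_ids, conc_ids = [0, 10, 20, 30], [5, 15, 25]  # azimuth 0° vs 180° columns
    ratio = spacing(out, conv_ids) / spacing(out, conc_ids)
    expected = (1 + r * kappa) / (1 - r * kappa)
    assert expected == pytest.approx(1.103, abs=5e-4)
    assert ratio == pytest.approx(expected, rel=1e-9)
    # asymmetry is strict: convex stretched, concave compressed
    assert spacing(out, conv_ids) > spacing(model, conv_ids)
    assert spacing(out, conc_ids) < spacing(model, conc_ids)


def test_self_intersection_guard(straight):
    with pytest.raises(SelfIntersectionError):
        hx.bend_filament(straight, hx.BendSpec(kappa=0.05))


def test_continuity_in_kappa(straight):
    """Max atom displacement vanishes linearly as δκ → 0."""
    base = 1e-3
    ref = hx.bend_filament(straight, hx.BendSpec(kappa=base))
    deltas = [4e-5, 2e-5, 1e-5]
    max_disp = []
    for d in deltas:
        out = hx.bend_filament(straight, hx.BendSpec(kappa=base + d))
        disp = max(
            np.abs(a.atoms.xyz - b.atoms.xyz).max()
            for a, b in zip(ref.subunits, out.subunits)
        )
        max_disp.append(disp)
    assert max_disp[0] > max_disp[1] > max_disp[2]
    # halving δ halves the displacement (linear vanishing)
    assert max_disp[1] / max_disp[0] == pytest.approx(0.5, rel=0.05)
    assert max_disp[2] / max_disp[1] == pytest.approx(0.5, rel=0.05)


def test_per_domain_rigidity(straight):
    """Every domain is carried rigidly: internal RMSD 0 across frames."""
    for spec in (hx.BendSpec(kappa=2e-3), hx.BendSpec(kappa=1e-3, hinge_swing_deg=8.0)):
        out = hx.bend_filament(straight, spec)
        for i in (0, 9, 23):
            a, b = straight.subunits[i].atoms, out.subunits[i].atoms
            for dom in ("tail", "head"):
                assert rmsd_after_superposition(a.domain_xyz(dom), b.domain_xyz(dom)) < 1e-9


def test_motion_report_self_is_zero(straight):
    rep = hx.motion_report(straight, straight)
    t = rep.table
    assert t["disp_norm"].abs().max() == pytest.approx(0.0, abs=1e-12)
    assert t["tail_slide_A"].abs().max() == pytest.approx(0.0, abs=1e-12)
    assert t["tail_rotation_deg"].abs().max() == pytest.approx(0.0, abs=1e-9)
    assert t["head_disp_after_tail_align"].abs().max() < 1e-9


def test_motion_report_head_rigidity_and_hinge(straight, bent):
    rep = hx.motion_report(straight, bent)
    assert rep.table["head_internal_rmsd"].max() < 1e-9
    # pure arc mapping: heads do not move relative to their own tails
    assert rep.table["head_disp_after_tail_align"].max() < 1e-9
    # with hinge swing the heads decouple from the tails
    swung = hx.bend_filament(straight, hx.BendSpec(kappa=1e-3, hinge_swing_deg=10.0))
    rep2 = hx.motion_report(straight, swung)
    assert rep2.table["head_internal_rmsd"].max() < 1e-9
    # displacement magnitude depends on each subunit's azimuth relative to the
    # swing axis, but every head moves visibly off its tail frame
    assert rep2.table["head_disp_after_tail_align"].min() > 0.5
    assert rep2.table["head_disp_after_tail_align"].mean() > 1.5


def test_opposite_axial_columns_slide_oppositely(straight, bent):
    """Tails of opposite n+10 columns slide up/down with opposite signs."""
    rep = hx.motion_report(straight, bent)
    t = rep.table.set_index("index")
    convex = t.loc[[10, 20, 30], "tail_slide_A"]   # azimuth 0 = bend direction
    concave = t.loc[[5, 15, 25], "tail_slide_A"]   # azimuth 180
    assert (convex > 0).all()
    assert (concave < 0).all()


def test_motion_report_topology_mismatch(straight):
    small = hx.make_fixture_filament("mvillosus", n=12)
    with pytest.raises(TopologyMismatchError):
        hx.motion_report(straight, small)


def test_head_trajectories_monotone_ramp(straight):
    frames = [
        hx.bend_filament(straight, hx.BendSpec(kappa=k))
        for k in np.linspace(0.0, 1.5e-3, 5)
    ]
    traj = hx.head_trajectories(frames, [12, 15, 24])
    for rec in traj.values():
        path = rec["path"]
        d0 = np.linalg.norm(path - path[0], axis=1)
        assert np.all(np.diff(d0) > -1e-9)  # monotone displacement from frame 0
        assert rec["path_length"] >= rec["net_displacement"] - 1e-9


def test_head_trajectories_invariances(straight, bent):
    frames = [straight, bent]
    traj = hx.head_trajectories(frames, [15])
    # identical frames give zero-length paths
    same = hx.head_trajectories([straight, straight], [15])
    assert same[15]["path_length"] == pytest.approx(0.0, abs=1e-12)
    # rigid whole-filament translation leaves path shapes congruent
    shift = np.array([7.0, -3.0, 2.0])
    shifted = []
    for f in frames:
        subs = []
        for su in f.subunits:
            atoms = hx.MonomerModel(
                atom_name=su.atoms.atom_name, element=su.atoms.element,
                res_name=su.atoms.res_name, res_id=su.atoms.res_id,
                xyz=su.atoms.xyz + shift, species=su.species,
                annotation=su.atoms.annotation,
            )
            subs.append(
                hx.PlacedSubunit(index=su.index, species=su.species, R=su.R,
                                 t=su.t + shift, atoms=atoms, operator=None)
            )
        shifted.append(hx.FilamentModel(sym=f.sym, labeling=f.labeling,
                                        subunits=subs, straight=False))
    traj_shifted = hx.head_trajectories(shifted, [15])
    assert traj_shifted[15]["path_length"] == pytest.approx(traj[15]["path_length"])
    assert traj_shifted[15]["net_displacement"] == pytest.approx(traj[15]["net_displacement"])
    np.testing.assert_allclose(
        traj_shifted[15]["path"] - shift, traj[15]["path"], atol=1e-9
    )


def test_head_trajectories_requires_two_frames(straight):
    with pytest.raises(InvalidArgumentError):
        hx.head_trajectories([straight], [0])
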