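"""Geometry primitives against independent oracles and constructions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from g4geom.geometry import (
    DegenerateGeometryError,
    backbone_torsions,
    base_plane,
    circular_difference_deg,
    dihedral,
    ensemble_pairwise_rmsd,
    glycosidic_class,
    place_atom,
    pseudorotation,
    pucker_class_from_P,
    residue_geometry_table,
    stacking_twist,
    sugar_pucker,
    superpose_rmsd,
    z_deviation,
    wrap360,
)
from g4geom.structure_io import Atom, Residue
from g4geom.synth import (
    apply_noise,
    build_nucleoside,
    build_torsion_chain,
    nu_from_pucker,
)

from conftest import random_rotation


# ---------------------------------------------------------------------------
# independent oracles

def dihedral_oracle(p1, p2, p3, p4) -> float:
    """atan2 on cross products, written independently of the implementation:
    φ = atan2(|b2|·b1·(b2×b3), (b1×b2)·(b2×b3))."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    y = np.linalg.norm(b2) * np.dot(b1, np.cross(b2, b3))
    x = np.dot(np.cross(b1, b2), np.cross(b2, b3))
    return math.degrees(math.atan2(y, x)) % 360.0


def quaternion_rmsd_oracle(ref, mob) -> float:
    """Quaternion-eigenvalue superposition RMSD (Kearsley matrix)."""
    x = ref - ref.mean(axis=0)
    y = mob - mob.mean(axis=0)
    sm = x.T @ y
    sxx, sxy, sxz = sm[0]
    syx, syy, syz = sm[1]
    szx, szy, szz = sm[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(x ** 2) + np.sum(y ** 2) - 2.0 * lam) / len(x)
    return math.sqrt(max(0.0, msd))


# ---------------------------------------------------------------------------
# dihedral

def test_dihedral_planar_configurations():
    cis = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]
    trans = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)]
    assert dihedral(*map(np.array, cis)) == pytest.approx(0.0, abs=1e-9)
    assert dihedral(*map(np.array, trans)) == pytest.approx(180.0, abs=1e-9)


def test_dihedral_against_cross_product_oracle(rng):
    for _ in range(1000):
        pts = rng.normal(size=(4, 3)) * 3.0
        try:
            ours = dihedral(*pts)
        except DegenerateGeometryError:
            continue
        assert ours == pytest.approx(dihedral_oracle(*pts), abs=1e-6)


def test_dihedral_degenerate_points_raise():
    p = np.zeros(3)
    with pytest.raises(DegenerateGeometryError):
        dihedral(p, p, np.array([1.0, 0, 0]), np.array([1.0, 1, 0]))
    colinear = [np.array([float(i), 0, 0]) for i in range(3)]
    with pytest.raises(DegenerateGeometryError):
        dihedral(*colinear, np.array([3.0, 1.0, 0.0]))


def test_place_atom_round_trips_its_torsion(rng):
    for _ in range(50):
        a, b, c = rng.normal(size=(3, 3)) * 2.0
        if np.linalg.norm(np.cross(b - a, c - b)) < 1e-3:
            continue
        tor = float(rng.uniform(0, 360))
        d = place_atom(a, b, c, 1.5, 109.5, tor)
        assert dihedral(a, b, c, d) == pytest.approx(tor, abs=1e-8)


def test_torsions_invariant_under_rigid_motion(rng):
    pts = rng.normal(size=(4, 3)) * 3.0
    ref = dihedral(*pts)
    for _ in range(20):
        rot = random_rotation(rng)
        t = rng.normal(size=3) * 10.0
        moved = pts @ rot.T + t
        assert dihedral(*moved) == pytest.approx(ref, abs=1e-9)


# ---------------------------------------------------------------------------
# backbone torsions

def test_backbone_torsions_from_torsion_chain():
    values = {"alpha": 60.0, "beta": 60.0, "gamma": 60.0,
              "delta": 60.0, "epsilon": 60.0, "zeta": 60.0}
    model = build_torsion_chain(4, values)
    nts = model.chains["A"]
    ts = backbone_torsions(nts[1], nts[0], nts[2])
    for name, want in values.items():
        assert getattr(ts, name) == pytest.approx(want, abs=1e-3), name


def test_five_prime_terminal_alpha_undefined():
    model = build_torsion_chain(2)
    nts = model.chains["A"]
    ts = backbone_torsions(nts[0], None, nts[1])
    assert ts.alpha is None
    assert "alpha" in ts.reasons
    ts_end = backbone_torsions(nts[-1], nts[-2], None)
    assert ts_end.epsilon is None and ts_end.zeta is None


def test_chi_anti_center():
    res = build_nucleoside("G", chi=240.0)
    ts = backbone_torsions(res)
    assert ts.chi == pytest.approx(240.0, abs=1e-6)
    assert glycosidic_class(ts.chi) == "anti"


@pytest.mark.parametrize("chi,expected", [
    (240.0, "anti"), (171.0, "anti"), (309.0, "anti"),
    (60.0, "syn"), (170.0, "syn"), (310.0, "syn"), (0.0, "syn"),
])
def test_glycosidic_window(chi, expected):
    assert glycosidic_class(chi) == expected


# ---------------------------------------------------------------------------
# pseudorotation

@pytest.mark.parametrize("tau_m", [25.0, 35.0, 45.0])
def test_pseudorotation_inverts_cosine_model_on_grid(tau_m):
    for P in range(0, 360):
        pk = pseudorotation(*nu_from_pucker(float(P), tau_m))
        assert pk.P == pytest.approx(P % 360, abs=1e-9)
        assert pk.tau_m == pytest.approx(tau_m, abs=1e-9)


def test_pseudorotation_classes():
    assert pseudorotation(*nu_from_pucker(162.0, 35.0)).pucker_class == "C2'-endo"
    assert pseudorotation(*nu_from_pucker(18.0, 35.0)).pucker_class == "C3'-endo"
    assert pucker_class_from_P(90.0) == "O4'-endo"
    assert pucker_class_from_P(350.0) == "C2'-exo"


def test_planar_ring_has_undefined_phase():
    pk = pseudorotation(0.0, 0.0, 0.0, 0.0, 0.0)
    assert pk.is_planar
    assert pk.tau_m == 0.0
    assert pk.pucker_class == "planar"


def test_pseudorotation_rejects_out_of_range_torsions():
    with pytest.raises(ValueError):
        pseudorotation(95.0, 0.0, 0.0, 0.0, 0.0)


def test_sugar_pucker_of_embedded_nucleoside():
    res = build_nucleoside("G", P=162.0, tau_m=35.0)
    pk = sugar_pucker(res)
    assert pk.P == pytest.approx(162.0, abs=0.5)
    assert pk.tau_m == pytest.approx(35.0, abs=0.5)
    assert pk.pucker_class == "C2'-endo"


# ---------------------------------------------------------------------------
# z-deviation

def _sugar_only_residue(positions: dict) -> Residue:
    atoms = [Atom(name=n, element=n[0], position=np.array(p))
             for n, p in positions.items()]
    return Residue(chain_id="A", seq_number=1, name="DG", atoms=atoms)


def test_z_deviation_in_plane_is_zero():
    res = _sugar_only_residue({
        "C4'": (0.0, 0.0, 0.0), "O4'": (1.4, 0.0, 0.0),
        "C1'": (2.0, 1.3, 0.0), "C2'": (1.2, 2.2, 0.0),
        "C3'": (0.1, 1.5, 0.4),
    })
    assert z_deviation(res).z_c2 == pytest.approx(0.0, abs=1e-12)


def test_z_deviation_matches_constructed_displacement():
    base = {
        "C4'": np.array([0.0, 0.0, 0.0]),
        "O4'": np.array([1.4, 0.0, 0.0]),
        "C1'": np.array([2.0, 1.3, 0.0]),
        "C3'": np.array([0.1, 1.5, -0.2]),
    }
    n = np.cross(base["C1'"] - base["C4'"], base["O4'"] - base["C4'"])
    n /= np.linalg.norm(n)
    base["C2'"] = np.array([1.2, 2.2, 0.0]) + 0.5 * n
    in_plane_part = np.array([1.2, 2.2, 0.0])
    expected = 0.5 + float(np.dot(n, in_plane_part - base["C4'"]))
    res = _sugar_only_residue(base)
    assert z_deviation(res).z_c2 == pytest.approx(expected, abs=1e-12)


def test_z_deviation_missing_atom_names_it():
    res = _sugar_only_residue({"C4'": (0, 0, 0), "O4'": (1.4, 0, 0),
                               "C1'": (2, 1.3, 0), "C2'": (1.2, 2.2, 0.5)})
    with pytest.raises(KeyError, match="C3'"):
        z_deviation(res)


@pytest.mark.parametrize("P", [float(p) for p in range(6, 360, 24)])
def test_z_deviation_sign_structure_across_the_wheel(P):
    """C2'-endo sugars have z_c2 > 0 and C3'-endo sugars z_c3 > 0; in the
    north/south ranges (where DNA sugars live) C2' and C3' fall on opposite
    sides of the reference plane or one lies in it."""
    res = build_nucleoside("G", P=P)
    zd = z_deviation(res)
    cls = sugar_pucker(res).pucker_class
    if cls == "C2'-endo":
        assert zd.z_c2 > 0
    if cls == "C3'-endo":
        assert zd.z_c3 > 0
    dist_north = min(P, 360 - P)
    dist_south = abs(P - 180)
    if min(dist_north, dist_south) <= 18.0:
        assert zd.z_c2 * zd.z_c3 <= 1e-3


# ---------------------------------------------------------------------------
# base planes

def _guanine_at(rot=np.eye(3), trans=np.zeros(3)) -> Residue:
    from g4geom.synth import GUANINE_TEMPLATE

    coords = dict(GUANINE_TEMPLATE)
    coords["C1'"] = np.array([-2.477, 5.399, 0.0])  # standard frame
    atoms = [Atom(name=n, element=n[0], position=rot @ p + trans)
             for n, p in coords.items()]
    return Residue(chain_id="A", seq_number=1, name="DG", atoms=atoms)


def test_base_plane_of_flat_guanine():
    res = _guanine_at()
    centroid, normal = base_plane(res)
    from g4geom.geometry import ring_atom_names
    for n in ring_atom_names(res):
        assert abs(np.dot(res.pos(n) - centroid, normal)) < 1e-6


def test_base_plane_equivariance(rng):
    res = _guanine_at()
    _, n0 = base_plane(res)
    rot = random_rotation(rng)
    moved = _guanine_at(rot=rot, trans=np.array([3.0, -2.0, 7.0]))
    _, n1 = base_plane(moved)
    assert np.allclose(rot @ n0, n1, atol=1e-9)


def test_base_plane_rms_matches_svd_oracle(rng):
    from g4geom.geometry import plane_rms, ring_atom_names
    res = _guanine_at()
    pts = np.array([res.pos(n) for n in ring_atom_names(res)])
    pts_noisy = pts + rng.normal(0, 0.05, pts.shape)
    # brute-force oracle: smallest singular value of centered coordinates
    centered = pts_noisy - pts_noisy.mean(axis=0)
    rms_oracle = np.linalg.svd(centered)[1][-1] / math.sqrt(len(pts))
    assert plane_rms(pts_noisy) == pytest.approx(rms_oracle, abs=1e-12)
    assert plane_rms(pts_noisy) <= 0.05 * 3


# ---------------------------------------------------------------------------
# stacking twist

def test_stacking_twist_recovers_construction(rng):
    res = _guanine_at(trans=np.array([4.0, 0.0, 0.0]))
    for angle in (-27.0, 30.0, 120.0):
        c, s = math.cos(math.radians(angle)), math.sin(math.radians(angle))
        rotz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        upper = _guanine_at(rot=rotz, trans=rotz @ np.array([4.0, 0.0, 0.0])
                            + np.array([0, 0, 3.3]))
        got = stacking_twist(res, upper, np.array([0, 0, 1.0]))
        assert got == pytest.approx(angle, abs=1e-9)


def test_stacking_twist_same_residue_is_zero():
    res = _guanine_at()
    assert stacking_twist(res, res, np.array([0, 0, 1.0])) == 0.0


def test_stacking_twist_degenerate_axis():
    res = _guanine_at()
    v = res.pos("N9") - res.pos("C1'")
    with pytest.raises(DegenerateGeometryError):
        stacking_twist(res, res, v)


# ---------------------------------------------------------------------------
# superposition

def test_superpose_identical_is_zero(rng):
    pts = rng.normal(size=(10, 3))
    rmsd, rot, trans = superpose_rmsd(pts, pts)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(rot, np.eye(3), atol=1e-9)


def test_superpose_rigid_motion_invariance(rng):
    pts = rng.normal(size=(25, 3)) * 5.0
    rot = random_rotation(rng)
    moved = pts @ rot.T + np.array([1.0, -2.0, 3.0])
    rmsd, _, _ = superpose_rmsd(pts, moved)
    assert rmsd == pytest.approx(0.0, abs=1e-9)


def test_superpose_matches_quaternion_oracle(rng):
    for _ in range(50):
        ref = rng.normal(size=(10, 3)) * 4.0
        mob = ref + rng.normal(0, 0.7, ref.shape)
        ours, _, _ = superpose_rmsd(ref, mob)
        assert ours == pytest.approx(quaternion_rmsd_oracle(ref, mob), abs=1e-8)


def test_superpose_is_symmetric(rng):
    ref = rng.normal(size=(12, 3))
    mob = ref + rng.normal(0, 0.5, ref.shape)
    assert superpose_rmsd(ref, mob)[0] == pytest.approx(
        superpose_rmsd(mob, ref)[0], abs=1e-10)


def test_superpose_no_reflection(rng):
    """Mirror images must NOT superpose to zero: only proper rotations."""
    pts = rng.normal(size=(20, 3)) * 3.0
    mirrored = pts * np.array([-1.0, 1.0, 1.0])
    rmsd, rot, _ = superpose_rmsd(pts, mirrored)
    assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
    assert rmsd > 0.1


def test_superpose_length_mismatch():
    with pytest.raises(ValueError, match="correspondence"):
        superpose_rmsd(np.zeros((5, 3)), np.zeros((4, 3)))


def test_superpose_rmsd_increases_with_noise(rng):
    ref = rng.normal(size=(30, 3)) * 5.0
    meds = []
    for sd in (0.05, 0.2, 0.8):
        vals = [superpose_rmsd(ref, ref + rng.normal(0, sd, ref.shape))[0]
                for _ in range(20)]
        meds.append(np.median(vals))
    assert meds[0] < meds[1] < meds[2]


# ---------------------------------------------------------------------------
# ensemble RMSD

def test_ensemble_identical_models(left_twin):
    mean, sd = ensemble_pairwise_rmsd([left_twin, left_twin, left_twin])
    assert mean == pytest.approx(0.0, abs=1e-12)
    assert sd == pytest.approx(0.0, abs=1e-12)


def test_ensemble_matches_enumeration_oracle(left_twin):
    import itertools
    sigma = 0.1
    models = [apply_noise(left_twin, sigma, seed) for seed in range(6)]
    mean, sd = ensemble_pairwise_rmsd(models)
    coords = []
    for m in models:
        coords.append(np.array([a.position for r in m.residues()
                                for a in r.atoms if not a.is_hydrogen]))
    oracle = [quaternion_rmsd_oracle(coords[i], coords[j])
              for i, j in itertools.combinations(range(6), 2)]
    assert mean == pytest.approx(np.mean(oracle), abs=1e-8)
    assert sd == pytest.approx(np.std(oracle, ddof=1), abs=1e-8)
    # independent noise on both models gives per-atom displacement variance
    # 2σ² per coordinate, i.e. an expected RMSD of σ·√6, slightly reduced by
    # the 6 rigid degrees of freedom the superposition removes
    assert mean == pytest.approx(sigma * math.sqrt(6), rel=0.1)


def test_ensemble_selector_too_small(left_twin):
    with pytest.raises(ValueError, match="3"):
        ensemble_pairwise_rmsd([left_twin, left_twin],
                               lambda res, atom: atom.name == "XX")


# ---------------------------------------------------------------------------
# geometry table

def test_residue_geometry_table_schema(left_twin):
    df = residue_geometry_table(left_twin)
    assert list(df.columns) == [
        "chain", "resnum", "base", "alpha", "beta", "gamma", "delta",
        "epsilon", "zeta", "chi", "P", "tau_m", "pucker_class", "z_c2",
        "z_c3", "glycosidic"]
    assert len(df) == sum(1 for _ in left_twin.nucleotides())
    core_rows = df[df.base == "G"]
    assert (core_rows.glycosidic == "anti").all()
    assert (core_rows.pucker_class == "C2'-endo").all()


# ---------------------------------------------------------------------------
# circular difference properties

@settings(deadline=None, max_examples=200)
@given(st.floats(-720, 720), st.floats(-720, 720))
def test_circular_difference_properties(a, b):
    d = circular_difference_deg(a, b)
    assert 0.0 <= d <= 180.0
    assert d == pytest.approx(circular_difference_deg(b, a), abs=1e-9)
    if d < 1e-9:
        wa, wb = wrap360(a), wrap360(b)
        assert min(abs(wa - wb), 360.0 - abs(wa - wb)) < 1e-6


def test_circular_difference_wraparound_examples():
    assert circular_difference_deg(10.0, 350.0) == pytest.approx(20.0)
    assert circular_difference_deg(100.0, 350.0) == pytest.approx(110.0)
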