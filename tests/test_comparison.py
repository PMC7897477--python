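"""Reference profiles, transition-angle deviations and pucker comparison."""

import json
import math

import numpy as np
import pytest

from g4geom.comparison import (
    build_reference_profile,
    circular_mean_deg,
    circular_sd_deg,
    compare_pucker,
    compare_to_reference,
    extract_transitions,
    render_report,
    report_to_tsv,
    TRANSITION_ANGLES,
)
from g4geom.g4_annotation import annotate
from g4geom.synth import BuildSpec, build_g4


# ---------------------------------------------------------------------------
# circular statistics

def test_circular_mean_of_two_offset_angles():
    """Mean of θ and θ+20° is θ+10°, including across the wrap; checked
    against a brute-force resultant-vector computation."""
    for theta in (5.0, 175.0, 350.0):
        angles = [theta, theta + 20.0]
        got = circular_mean_deg(angles)
        sx = sum(math.sin(math.radians(a)) for a in angles)
        cx = sum(math.cos(math.radians(a)) for a in angles)
        brute = math.degrees(math.atan2(sx, cx)) % 360.0
        assert math.cos(math.radians(got - brute)) == pytest.approx(1.0, abs=1e-12)
        want = (theta + 10.0) % 360.0
        assert math.cos(math.radians(got - want)) == pytest.approx(1.0, abs=1e-12)


def test_circular_sd_matches_resultant_formula(rng):
    angles = rng.normal(90.0, 12.0, size=200)
    got = circular_sd_deg(angles)
    r = math.hypot(np.mean(np.sin(np.radians(angles))),
                   np.mean(np.cos(np.radians(angles))))
    assert got == pytest.approx(math.degrees(math.sqrt(-2 * math.log(r))),
                                abs=1e-9)
    assert got == pytest.approx(12.0, rel=0.15)


# ---------------------------------------------------------------------------
# reference profiles

def test_profile_from_uniform_core_has_zero_spread(left_twin):
    profile = build_reference_profile([left_twin], "left")
    for name in (*TRANSITION_ANGLES, "chi", "P"):
        mean, sd, n = profile.stats[name]
        assert n >= 4 or name in ("chi", "P")
        assert sd == pytest.approx(0.0, abs=0.01), name
    assert profile.stats["P"][0] == pytest.approx(162.0, abs=0.5)
    assert profile.majority_pucker_class == "C2'-endo"


def test_profile_pooling_invariance(left_twin):
    one = build_reference_profile([left_twin], "left")
    two = build_reference_profile([left_twin, left_twin], "left")
    for name, (mean, sd, n) in one.stats.items():
        m2, s2, n2 = two.stats[name]
        assert m2 == pytest.approx(mean, abs=1e-9)
        assert n2 == 2 * n


def test_profile_rejects_bulged_and_wrong_handed_structures(
        left_twin, left_bulged, right_core):
    with pytest.warns(UserWarning, match="bulge"):
        profile = build_reference_profile([left_twin, left_bulged], "left")
    assert profile.source_ids == [left_twin.source_id]
    with pytest.warns(UserWarning, match="handedness"):
        profile = build_reference_profile([left_twin, right_core], "left")
    assert len(profile.source_ids) == 1
    with pytest.raises(ValueError, match="no usable"):
        build_reference_profile([left_bulged], "left")


def test_profile_recovers_von_mises_glycosidic_mean(rng):
    """Profiles built from small sets of structures whose χ is drawn from a
    von Mises distribution recover the distribution mean within
    3·sd/√n_structures in at least 95% of repeats."""
    mu, kappa = 240.0, 30.0  # circular sd ≈ 10.5 deg
    n_struct, n_rep = 3, 25
    hits = 0
    for _ in range(n_rep):
        chis = np.degrees(rng.vonmises(math.radians(mu), kappa, n_struct))
        models = [
            build_g4(BuildSpec(n_tetrads=2, loop_lengths=None,
                               twist_per_step=30.0, chi=float(c % 360)))
            for c in chis
        ]
        profile = build_reference_profile(models, "right")
        mean, sd, _ = profile.stats["chi"]
        bound = 3.0 * max(sd, 1.0) / math.sqrt(n_struct)
        d = abs((mean - mu + 180.0) % 360.0 - 180.0)
        hits += d <= bound
    assert hits >= round(0.95 * n_rep) - 1


# ---------------------------------------------------------------------------
# transitions and deviations

def test_no_bulge_means_no_transitions(left_twin):
    core, elements = annotate(left_twin)
    assert extract_transitions(core, elements, left_twin) == []


def test_transition_records_step_convention(left_bulged):
    core, elements = annotate(left_bulged)
    records = extract_transitions(core, elements, left_bulged)
    assert len(records) == 2
    sides = {r.side for r in records}
    assert sides == {"previous", "next"}
    for rec in records:
        assert rec.core_residue.base_type == "G"
        for name in TRANSITION_ANGLES:
            assert rec.angles[name] is not None


def test_transition_records_skip_convention(left_bulged):
    core, elements = annotate(left_bulged)
    records = extract_transitions(core, elements, left_bulged,
                                  convention="skip")
    assert len(records) == 2
    prev = next(r for r in records if r.side == "previous")
    nxt = next(r for r in records if r.side == "next")
    assert prev.angles == nxt.angles  # both sides measure the core guanines
    with pytest.raises(ValueError):
        extract_transitions(core, elements, left_bulged, convention="bogus")


def test_wraparound_deviation_and_threshold():
    profile_stub = type("P", (), {})()
    profile_stub.stats = {name: (350.0, 0.0, 1) for name in TRANSITION_ANGLES}
    rec = type("R", (), {})()
    rec.bulge_id, rec.side, rec.reasons = "b", "previous", {}
    rec.angles = {"epsilon": 10.0, "zeta": 100.0, "alpha+1": 350.0,
                  "beta+1": None, "gamma+1": 170.0}
    devs = compare_to_reference([rec], profile_stub, threshold=60.0)
    by_name = {d.angle_name: d for d in devs}
    assert by_name["epsilon"].deviation == pytest.approx(20.0)
    assert not by_name["epsilon"].flagged
    assert by_name["zeta"].deviation == pytest.approx(110.0)
    assert by_name["zeta"].flagged
    assert by_name["alpha+1"].deviation == pytest.approx(0.0)
    assert by_name["beta+1"].deviation is None
    assert not by_name["beta+1"].flagged
    assert by_name["gamma+1"].flagged  # 180 deviation


def test_flag_count_monotone_in_threshold(left_twin, left_bulged):
    core, elements = annotate(left_bulged)
    profile = build_reference_profile([left_twin], "left")
    records = extract_transitions(core, elements, left_bulged)
    counts = []
    for threshold in (0.0, 30.0, 60.0, 90.0, 180.0):
        devs = compare_to_reference(records, profile, threshold)
        counts.append(sum(d.flagged for d in devs))
    assert counts == sorted(counts, reverse=True)
    assert counts[-1] == 0  # nothing exceeds 180°


def test_bulge_alters_exactly_alpha_and_beta(left_twin, left_bulged):
    """A bulge whose step torsions are offset 90°/70° in α/β from the
    no-bulge twin flags exactly α+1 and β+1 at the 60° threshold."""
    core, elements = annotate(left_bulged)
    profile = build_reference_profile([left_twin], "left")
    records = extract_transitions(core, elements, left_bulged)
    devs = compare_to_reference(records, profile, threshold=60.0)
    flagged = {d.angle_name for d in devs if d.flagged}
    assert flagged == {"alpha+1", "beta+1"}
    by = {(d.side, d.angle_name): d.deviation for d in devs}
    for side in ("previous", "next"):
        assert by[(side, "alpha+1")] == pytest.approx(90.0, abs=0.5)
        assert by[(side, "beta+1")] == pytest.approx(70.0, abs=0.5)
        for quiet in ("epsilon", "zeta", "gamma+1"):
            assert by[(side, quiet)] == pytest.approx(0.0, abs=0.5)


# ---------------------------------------------------------------------------
# pucker comparison

def test_uniform_sugars_are_never_altered(left_twin, left_bulged):
    core, elements = annotate(left_bulged)
    profile = build_reference_profile([left_twin], "left")
    comps = compare_pucker(core, elements, profile)
    assert len(comps) == 2  # previous + next residue of the single bulge
    for c in comps:
        assert c.pucker_class == "C2'-endo"
        assert c.altered is False
        assert c.P == pytest.approx(162.0, abs=0.5)
        assert c.z_c2 > 0


# ---------------------------------------------------------------------------
# reporting

def test_report_counts_and_round_trip(left_twin, left_two_bulged, tmp_path):
    core, elements = annotate(left_two_bulged)
    profile = build_reference_profile([left_twin], "left")
    records = extract_transitions(core, elements, left_two_bulged)
    devs = compare_to_reference(records, profile)
    puckers = compare_pucker(core, elements, profile)
    assert len(records) == 4          # 2 sides per bulge
    assert len(devs) == 20            # 5 angles per record
    report = render_report(devs, puckers, core, profile,
                           provenance={"source": "synthetic"})
    path = tmp_path / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh)
    assert json.loads(path.read_text()) == json.loads(json.dumps(report))
    tsv = report_to_tsv(report)
    assert len(tsv.strip().splitlines()) == 21  # header + rows


def test_empty_report_is_valid(left_twin):
    core, _ = annotate(left_twin)
    report = render_report([], [], core)
    assert report["deviations"] == [] and report["puckers"] == []
    assert report_to_tsv(report).startswith("bulge\t")
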