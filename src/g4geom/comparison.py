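"""Bulge-induced backbone and sugar-pucker alterations vs. reference G4s.

The analysis mirrors how bulged quadruplexes are compared against standard
(non-bulged) parallel structures of the same handedness: a reference
profile of the five transition torsions (ε, ζ of a step's 5' residue and
α, β, γ of its 3' residue — written ε, ζ, α+1, β+1, γ+1), the glycosidic
angle χ and the pseudorotation phase P is pooled over all intra-block core
steps of the reference set; each bulge then contributes a 'previous
residue' record (the step from the core guanine 5' of the bulge into the
bulge) and a 'next residue' record (the step out of the bulge into the core
guanine 3' of it), and every angle is compared to the reference by circular
difference, flagged when it deviates by more than a threshold (60° by
default).

All angular statistics are circular (resultant-vector mean; circular sd
√(−2 ln R̄)) because the interesting deviations sit near the 0°/360° wrap.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structure_io import Residue, StructureModel
from .geometry import (
    backbone_torsions,
    circular_difference_deg,
    sugar_pucker,
    wrap360,
    z_deviation,
)
from .g4_annotation import G4Core, StructuralElement, annotate

__all__ = [
    "TRANSITION_ANGLES",
    "DEVIATION_THRESHOLD",
    "ReferenceProfile",
    "TransitionRecord",
    "DeviationRecord",
    "PuckerComparison",
    "circular_mean_deg",
    "circular_sd_deg",
    "build_reference_profile",
    "extract_transitions",
    "compare_to_reference",
    "compare_pucker",
    "render_report",
]

TRANSITION_ANGLES = ("epsilon", "zeta", "alpha+1", "beta+1", "gamma+1")
DEVIATION_THRESHOLD = 60.0  # degrees


def circular_mean_deg(angles: Sequence[float]) -> float:
    """Resultant-vector circular mean, degrees in [0, 360)."""
    a = np.radians(np.asarray(angles, dtype=float))
    return wrap360(math.degrees(math.atan2(np.sin(a).mean(), np.cos(a).mean())))


def circular_sd_deg(angles: Sequence[float]) -> float:
    """Circular standard deviation √(−2 ln R̄), degrees."""
    a = np.radians(np.asarray(angles, dtype=float))
    r = math.hypot(float(np.sin(a).mean()), float(np.cos(a).mean()))
    r = min(1.0, r)
    if r < 1e-12:
        return float("inf")
    return math.degrees(math.sqrt(-2.0 * math.log(r)))


@dataclass
class ReferenceProfile:
    """Circular mean/sd per angle pooled from non-bulged reference cores."""

    handedness: str
    stats: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    source_ids: list[str] = field(default_factory=list)
    majority_pucker_class: str = ""

    def mean(self, angle: str) -> float:
        return self.stats[angle][0]


@dataclass
class TransitionRecord:
    """Five transition torsions of one bulge-adjacent step."""

    bulge_id: str
    side: str  # previous | next
    core_residue: Residue
    angles: dict[str, float | None]
    reasons: dict[str, str] = field(default_factory=dict)


@dataclass
class DeviationRecord:
    """One (record, angle) comparison against the reference profile."""

    bulge_id: str
    side: str
    angle_name: str
    observed: float | None
    reference: float
    deviation: float | None
    flagged: bool
    reason: str = ""


@dataclass
class PuckerComparison:
    """Pucker state of one bulge-adjacent core residue vs. the reference."""

    core_residue: Residue
    side: str
    bulge_id: str
    P: float | None
    pucker_class: str
    z_c2: float | None
    z_c3: float | None
    altered: bool | None


# ---------------------------------------------------------------------------
# reference profile

def _sequence_neighbors(model: StructureModel) -> dict[tuple[str, int], tuple[Residue | None, Residue | None]]:
    out = {}
    for chain_id, residues in model.chains.items():
        nts = [r for r in residues if r.is_nucleotide]
        for i, r in enumerate(nts):
            out[(chain_id, r.seq_number)] = (
                nts[i - 1] if i > 0 else None,
                nts[i + 1] if i + 1 < len(nts) else None,
            )
    return out


def _step_angles(res5: Residue, res3: Residue, model: StructureModel
                 ) -> tuple[dict[str, float | None], dict[str, str]]:
    """ε, ζ of the step's 5' residue; α, β, γ of its 3' residue."""
    nbrs = _sequence_neighbors(model)
    p5, n5 = nbrs[(res5.chain_id, res5.seq_number)]
    p3, n3 = nbrs[(res3.chain_id, res3.seq_number)]
    t5 = backbone_torsions(res5, p5, n5)
    t3 = backbone_torsions(res3, p3, n3)
    angles = {
        "epsilon": t5.epsilon,
        "zeta": t5.zeta,
        "alpha+1": t3.alpha,
        "beta+1": t3.beta,
        "gamma+1": t3.gamma,
    }
    reasons = {}
    for key, src, name in (("epsilon", t5, "epsilon"), ("zeta", t5, "zeta"),
                           ("alpha+1", t3, "alpha"), ("beta+1", t3, "beta"),
                           ("gamma+1", t3, "gamma")):
        if angles[key] is None:
            reasons[key] = src.reasons.get(name, "undefined")
    return angles, reasons


def _core_steps(core: G4Core, model: StructureModel
                ) -> list[tuple[Residue, Residue]]:
    """Sequence-adjacent consecutive column guanine pairs (intra-block)."""
    nbrs = _sequence_neighbors(model)
    steps = []
    for col in core.columns:
        for a, b in zip(col.guanines, col.guanines[1:]):
            r5, r3 = (a, b) if a.seq_number < b.seq_number else (b, a)
            _, nxt = nbrs[(r5.chain_id, r5.seq_number)]
            if nxt is not None and nxt.seq_number == r3.seq_number \
                    and nxt.chain_id == r3.chain_id:
                steps.append((r5, r3))
    return steps


def build_reference_profile(models: Sequence[StructureModel], handedness: str,
                            pool: str = "steps") -> ReferenceProfile:
    """Pool transition-angle, χ and P statistics over non-bulged cores.

    Structures that contain bulges, fail to annotate, or have the wrong
    handedness are rejected from the reference set with an explicit warning.
    ``pool='steps'`` weights every step of every structure equally;
    ``pool='structures'`` averages per structure first.
    """
    if handedness not in ("left", "right"):
        raise ValueError("handedness must be 'left' or 'right'")
    per_struct: list[dict[str, list[float]]] = []
    sources = []
    for model in models:
        core, elements = annotate(model)
        sid = model.source_id or f"model-{model.model_index}"
        if core is None:
            warnings.warn(f"reference {sid}: no G4 core found; rejected")
            continue
        if core.handedness != handedness:
            warnings.warn(
                f"reference {sid}: handedness {core.handedness!r} does not "
                f"match requested {handedness!r}; rejected")
            continue
        if any(e.kind == "bulge" for e in elements):
            warnings.warn(
                f"reference {sid}: contains bulges and cannot serve as a "
                "non-bulged reference; rejected")
            continue
        vals: dict[str, list[float]] = {k: [] for k in
                                        (*TRANSITION_ANGLES, "chi", "P")}
        for r5, r3 in _core_steps(core, model):
            angles, _ = _step_angles(r5, r3, model)
            for k, v in angles.items():
                if v is not None:
                    vals[k].append(v)
        nbrs = _sequence_neighbors(model)
        for g in core.guanines():
            p, n = nbrs[(g.chain_id, g.seq_number)]
            chi = backbone_torsions(g, p, n).chi
            if chi is not None:
                vals["chi"].append(chi)
            try:
                pk = sugar_pucker(g)
                if pk.P is not None:
                    vals["P"].append(pk.P)
            except (KeyError, ValueError):
                pass
        per_struct.append(vals)
        sources.append(sid)
    if not per_struct:
        raise ValueError("no usable reference structures remain")

    profile = ReferenceProfile(handedness=handedness, source_ids=sources)
    for key in (*TRANSITION_ANGLES, "chi", "P"):
        if pool == "structures":
            means = [circular_mean_deg(v[key]) for v in per_struct if v[key]]
            pooled = means
        else:
            pooled = [x for v in per_struct for x in v[key]]
        if pooled:
            profile.stats[key] = (
                circular_mean_deg(pooled), circular_sd_deg(pooled), len(pooled))
    if "P" in profile.stats:
        from .geometry import pucker_class_from_P
        classes = [pucker_class_from_P(x)
                   for v in per_struct for x in v["P"]]
        profile.majority_pucker_class = max(set(classes), key=classes.count)
    return profile


# ---------------------------------------------------------------------------
# transitions around bulges

def extract_transitions(core: G4Core, elements: Sequence[StructuralElement],
                        model: StructureModel, convention: str = "step"
                        ) -> list[TransitionRecord]:
    """Two transition records per bulge.

    ``convention='step'`` (default): the 'previous' record measures the step
    from the 5'-side core guanine into the bulge's first residue, the 'next'
    record the step from the bulge's last residue into the 3'-side core
    guanine.  ``convention='skip'`` measures both records on the core
    guanines themselves, treating the bulge as absent (ε, ζ of the previous
    guanine with α, β, γ of the next guanine); the two sides then coincide.
    """
    if convention not in ("step", "skip"):
        raise ValueError("convention must be 'step' or 'skip'")
    records = []
    for e in elements:
        if e.kind != "bulge" or not e.residues:
            continue
        bulge_id = ",".join(r.label for r in e.residues)
        if convention == "step":
            sides = [
                ("previous", e.previous_core, e.previous_core, e.residues[0]),
                ("next", e.next_core, e.residues[-1], e.next_core),
            ]
        else:
            sides = [
                ("previous", e.previous_core, e.previous_core, e.next_core),
                ("next", e.next_core, e.previous_core, e.next_core),
            ]
        for side, core_res, r5, r3 in sides:
            angles, reasons = _step_angles(r5, r3, model)
            records.append(TransitionRecord(
                bulge_id=bulge_id, side=side, core_residue=core_res,
                angles=angles, reasons=reasons))
    return records


def compare_to_reference(records: Sequence[TransitionRecord],
                         profile: ReferenceProfile,
                         threshold: float = DEVIATION_THRESHOLD
                         ) -> list[DeviationRecord]:
    """One deviation row per (record, transition angle).

    The deviation is the absolute circular difference (degrees, [0, 180]);
    rows with undefined observed angles carry deviation None, flagged False
    and the recorded reason.
    """
    out = []
    for rec in records:
        for name in TRANSITION_ANGLES:
            ref_mean = profile.stats[name][0]
            obs = rec.angles.get(name)
            if obs is None:
                out.append(DeviationRecord(
                    rec.bulge_id, rec.side, name, None, ref_mean, None,
                    False, reason=rec.reasons.get(name, "undefined")))
                continue
            dev = circular_difference_deg(obs, ref_mean)
            out.append(DeviationRecord(
                rec.bulge_id, rec.side, name, obs, ref_mean, dev,
                bool(dev > threshold)))
    return out


def compare_pucker(core: G4Core, elements: Sequence[StructuralElement],
                   profile: ReferenceProfile) -> list[PuckerComparison]:
    """Pucker state of every bulge-adjacent core residue vs. the reference
    majority class."""
    out = []
    for e in elements:
        if e.kind != "bulge" or not e.residues:
            continue
        bulge_id = ",".join(r.label for r in e.residues)
        for side, res in (("previous", e.previous_core), ("next", e.next_core)):
            if res is None:
                continue
            try:
                pk = sugar_pucker(res)
                P, cls = pk.P, pk.pucker_class
            except (KeyError, ValueError) as exc:
                out.append(PuckerComparison(res, side, bulge_id, None,
                                            f"error: {exc}", None, None, None))
                continue
            try:
                zd = z_deviation(res)
                z2, z3 = zd.z_c2, zd.z_c3
            except (KeyError, ValueError):
                z2 = z3 = None
            altered: bool | None
            if cls == "planar" or not profile.majority_pucker_class:
                altered = None
            else:
                altered = cls != profile.majority_pucker_class
            out.append(PuckerComparison(res, side, bulge_id, P, cls, z2, z3,
                                        altered))
    return out


# ---------------------------------------------------------------------------
# reporting

def render_report(deviations: Sequence[DeviationRecord],
                  puckers: Sequence[PuckerComparison],
                  core: G4Core | None,
                  profile: ReferenceProfile | None = None,
                  threshold: float = DEVIATION_THRESHOLD,
                  provenance: dict | None = None) -> dict:
    """Machine-readable report of one structure's bulge analysis."""
    report = {
        "schema_version": 1,
        "handedness": core.handedness if core else "none",
        "threshold_deg": threshold,
        "profile": {
            "handedness": profile.handedness,
            "source_ids": profile.source_ids,
            "majority_pucker_class": profile.majority_pucker_class,
            "stats": {k: {"mean_deg": round(m, 3), "sd_deg": round(s, 3), "n": n}
                      for k, (m, s, n) in profile.stats.items()},
        } if profile else None,
        "deviations": [
            {
                "bulge": d.bulge_id,
                "side": d.side,
                "angle": d.angle_name,
                "observed_deg": None if d.observed is None else round(d.observed, 3),
                "reference_deg": round(d.reference, 3),
                "deviation_deg": None if d.deviation is None else round(d.deviation, 3),
                "flagged": d.flagged,
                **({"reason": d.reason} if d.reason else {}),
            }
            for d in deviations
        ],
        "puckers": [
            {
                "residue": p.core_residue.label,
                "side": p.side,
                "bulge": p.bulge_id,
                "P_deg": None if p.P is None else round(p.P, 3),
                "pucker_class": p.pucker_class,
                "z_c2_A": None if p.z_c2 is None else round(p.z_c2, 4),
                "z_c3_A": None if p.z_c3 is None else round(p.z_c3, 4),
                "altered": p.altered,
            }
            for p in puckers
        ],
        "provenance": provenance or {},
    }
    return report


def report_to_tsv(report: dict) -> str:
    """Flat TSV twin of the deviation rows of a report."""
    lines = ["bulge\tside\tangle\tobserved_deg\treference_deg\tdeviation_deg\tflagged"]
    for d in report["deviations"]:
        lines.append("\t".join(str(d[k]) for k in
                     ("bulge", "side", "angle", "observed_deg",
                      "reference_deg", "deviation_deg", "flagged")))
    return "\n".join(lines) + "\n"


def write_report(report: dict, json_path, tsv_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write(report_to_tsv(report))
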