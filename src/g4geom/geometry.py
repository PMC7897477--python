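"""Primitive geometric computations for nucleic-acid structures.

Torsion angles (backbone α–ζ and glycosidic χ), furanose pseudorotation
(Altona–Sundaralingam phase angle P and amplitude τm), the z-deviation
pucker descriptor, least-squares base planes, inter-tetrad stacking twist,
and rigid-body superposition.

Conventions
-----------
* Torsions are reported in degrees on [0, 360), matching how glycosidic
  restraints (anti ≈ 240°) and pucker windows (C2'-endo: 135–180°) are
  quoted in the structural literature.  Signed quantities — stacking twist
  and z-deviation — keep their natural signed ranges.
* χ is O4'–C1'–N9–C4 for purines and O4'–C1'–N1–C2 for pyrimidines.
* The z-deviation plane normal is n = unit((O4'−C4') × (C1'−C4')) and
  z(X) = n · (X − C4'), calibrated so an ideal C2'-endo sugar gives
  z_C2' > 0.
* Stacking twist is positive for a right-handed (counter-clockwise viewed
  down the 5'→3' axis) progression and negative for a left-handed one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .structure_io import Residue, StructureModel

__all__ = [
    "DegenerateGeometryError",
    "TorsionSet",
    "SugarPucker",
    "ZDeviation",
    "dihedral",
    "wrap360",
    "wrap_signed",
    "circular_difference_deg",
    "place_atom",
    "backbone_torsions",
    "glycosidic_class",
    "sugar_torsions",
    "pseudorotation",
    "sugar_pucker",
    "z_deviation",
    "base_plane",
    "ring_atom_names",
    "stacking_twist",
    "superpose_rmsd",
    "ensemble_pairwise_rmsd",
    "residue_geometry_table",
    "PUCKER_CLASSES",
]


class DegenerateGeometryError(ValueError):
    """Raised when an angle is undefined for the given points."""


def wrap360(angle_deg: float) -> float:
    """Map an angle to [0, 360)."""
    a = float(angle_deg) % 360.0
    return 0.0 if a >= 360.0 else a  # guard against -1e-16 % 360 == 360.0


def wrap_signed(angle_deg: float) -> float:
    """Map an angle to (-180, 180]."""
    a = float(angle_deg) % 360.0
    return a - 360.0 if a > 180.0 else a


def circular_difference_deg(a: float, b: float) -> float:
    """Absolute circular difference in [0, 180]."""
    d = abs(wrap360(a) - wrap360(b)) % 360.0
    return min(d, 360.0 - d)


_EPS = 1e-10


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, IUPAC sign, mapped to [0, 360).

    Raises :class:`DegenerateGeometryError` for coincident consecutive
    points or colinear consecutive triples.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for i, b in enumerate((b1, b2, b3)):
        if np.linalg.norm(b) < _EPS:
            raise DegenerateGeometryError(
                f"coincident points {i + 1} and {i + 2} in dihedral"
            )
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError("colinear points: dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(b1, n2) * np.linalg.norm(b2))
    return wrap360(math.degrees(math.atan2(y, x)))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given chain A-B-C, |C-D|, angle B-C-D and torsion A-B-C-D.

    The natural-extension (NeRF) construction: the returned point satisfies
    ``dihedral(a, b, c, d) == torsion_deg`` exactly (up to roundoff).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm_n = np.linalg.norm(n)
    if norm_n < _EPS:
        raise DegenerateGeometryError("colinear reference atoms in place_atom")
    n /= norm_n
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(phi),
            bond * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# Backbone and glycosidic torsions

@dataclass
class TorsionSet:
    """Backbone torsions α–ζ and glycosidic χ of one residue, degrees [0,360).

    Angles that cannot be computed (chain termini, missing atoms) are None,
    with the reason recorded in :attr:`reasons`.
    """

    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    delta: float | None = None
    epsilon: float | None = None
    zeta: float | None = None
    chi: float | None = None
    reasons: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {
            k: getattr(self, k)
            for k in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")
        }


def _torsion_or_none(
    ts: TorsionSet, name: str, atoms: Sequence[tuple[Residue | None, str]]
) -> None:
    positions = []
    for res, atom_name in atoms:
        if res is None:
            ts.reasons[name] = "missing neighbor residue (chain terminus)"
            return
        a = res.atom(atom_name)
        if a is None:
            ts.reasons[name] = f"missing atom {atom_name} in {res.label}"
            return
        positions.append(a.position)
    try:
        setattr(ts, name, dihedral(*positions))
    except DegenerateGeometryError as exc:
        ts.reasons[name] = str(exc)


def backbone_torsions(
    residue: Residue, prev: Residue | None = None, next: Residue | None = None
) -> TorsionSet:
    """Backbone α, β, γ, δ, ε, ζ and glycosidic χ of a nucleotide.

    Standard definitions: α: O3'(i-1)–P–O5'–C5'; β: P–O5'–C5'–C4';
    γ: O5'–C5'–C4'–C3'; δ: C5'–C4'–C3'–O3'; ε: C4'–C3'–O3'–P(i+1);
    ζ: C3'–O3'–P(i+1)–O5'(i+1).  Missing atoms or neighbors yield None for
    the affected angles with a recorded reason, never an exception.
    """
    r = residue
    ts = TorsionSet()
    _torsion_or_none(ts, "alpha", [(prev, "O3'"), (r, "P"), (r, "O5'"), (r, "C5'")])
    _torsion_or_none(ts, "beta", [(r, "P"), (r, "O5'"), (r, "C5'"), (r, "C4'")])
    _torsion_or_none(ts, "gamma", [(r, "O5'"), (r, "C5'"), (r, "C4'"), (r, "C3'")])
    _torsion_or_none(ts, "delta", [(r, "C5'"), (r, "C4'"), (r, "C3'"), (r, "O3'")])
    _torsion_or_none(ts, "epsilon", [(r, "C4'"), (r, "C3'"), (r, "O3'"), (next, "P")])
    _torsion_or_none(ts, "zeta", [(r, "C3'"), (r, "O3'"), (next, "P"), (next, "O5'")])
    if r.base_type in ("A", "G"):
        chi_atoms = [(r, "O4'"), (r, "C1'"), (r, "N9"), (r, "C4")]
    else:
        chi_atoms = [(r, "O4'"), (r, "C1'"), (r, "N1"), (r, "C2")]
    _torsion_or_none(ts, "chi", chi_atoms)
    return ts


# anti window: the structural anti restraint 240 ± 70° widened symmetrically
# into a closed decision rule; everything outside is called syn.
ANTI_WINDOW = (170.0, 310.0)


def glycosidic_class(chi_deg: float) -> str:
    """'anti' iff χ lies in the anti window (170°, 310°), else 'syn'."""
    chi = wrap360(chi_deg)
    return "anti" if ANTI_WINDOW[0] < chi < ANTI_WINDOW[1] else "syn"


# ---------------------------------------------------------------------------
# Sugar pucker: pseudorotation and z-deviation

PUCKER_CLASSES = (
    "C3'-endo", "C4'-exo", "O4'-endo", "C1'-exo", "C2'-endo",
    "C3'-exo", "C4'-endo", "O4'-exo", "C1'-endo", "C2'-exo",
)

_SIN36_PLUS_SIN72 = math.sin(math.radians(36.0)) + math.sin(math.radians(72.0))


@dataclass
class SugarPucker:
    """Furanose pucker: endocyclic torsions, phase P, amplitude τm, class."""

    nu0: float
    nu1: float
    nu2: float
    nu3: float
    nu4: float
    P: float | None
    tau_m: float
    pucker_class: str

    @property
    def is_planar(self) -> bool:
        return self.P is None


def pucker_class_from_P(P_deg: float) -> str:
    """Name of the 36°-wide pseudorotation sector containing P.

    Sectors are centered at 18° + k·36°, so C3'-endo covers [0°, 36°) and
    C2'-endo covers [144°, 180°).
    """
    return PUCKER_CLASSES[int(wrap360(P_deg) // 36.0) % 10]


def pseudorotation(nu0: float, nu1: float, nu2: float, nu3: float, nu4: float) -> SugarPucker:
    """Pseudorotation phase P and amplitude τm from endocyclic torsions.

    Inverts the cosine model ν_j = τm·cos(P + 144°·(j−2)) exactly:
    P = atan2((ν4+ν1) − (ν3+ν0), 2·ν2·(sin36° + sin72°)), with
    τm = hypot of the two resultant components.  A planar ring (all ν ≈ 0)
    yields τm = 0, P undefined and class 'planar'.
    """
    nus = [wrap_signed(v) for v in (nu0, nu1, nu2, nu3, nu4)]
    for v in nus:
        if not -90.0 < v < 90.0:
            raise ValueError(f"endocyclic torsion {v:.1f}° outside (-90°, 90°)")
    n0, n1, n2, n3, n4 = nus
    y = (n4 + n1) - (n3 + n0)
    x = 2.0 * n2 * _SIN36_PLUS_SIN72
    tau_m = math.hypot(y / (2.0 * _SIN36_PLUS_SIN72), n2)
    if tau_m < 1e-9:
        return SugarPucker(n0, n1, n2, n3, n4, None, 0.0, "planar")
    P = wrap360(math.degrees(math.atan2(y, x)))
    return SugarPucker(n0, n1, n2, n3, n4, P, tau_m, pucker_class_from_P(P))


_RING_TORSION_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),  # nu0
    ("O4'", "C1'", "C2'", "C3'"),  # nu1
    ("C1'", "C2'", "C3'", "C4'"),  # nu2
    ("C2'", "C3'", "C4'", "O4'"),  # nu3
    ("C3'", "C4'", "O4'", "C1'"),  # nu4
)

SUGAR_RING_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")


def sugar_torsions(residue: Residue) -> tuple[float, float, float, float, float]:
    """Endocyclic torsions ν0–ν4 of the deoxyribose ring, signed degrees."""
    missing = [n for n in SUGAR_RING_ATOMS if residue.atom(n) is None]
    if missing:
        raise KeyError(f"residue {residue.label}: missing sugar atoms {missing}")
    return tuple(
        wrap_signed(dihedral(*(residue.pos(n) for n in quad)))
        for quad in _RING_TORSION_ATOMS
    )


def sugar_pucker(residue: Residue) -> SugarPucker:
    """Pseudorotation analysis of one residue's sugar ring."""
    return pseudorotation(*sugar_torsions(residue))


@dataclass
class ZDeviation:
    """Signed distances of C2' and C3' from the C4'–O4'–C1' plane, Å."""

    z_c2: float
    z_c3: float


def z_deviation(residue: Residue) -> ZDeviation:
    """z-deviation pucker descriptor.

    The plane through C4', O4', C1' has normal
    n = unit((C1' − C4') × (O4' − C4')); the deviation of atom X is
    n · (X − C4').  The cross-product order is calibrated on D-deoxyribose
    so an ideal C2'-endo sugar has z_C2' > 0 and an ideal C3'-endo sugar
    has z_C3' > 0 (the endo side, toward C5' and the base, is positive).
    """
    for name in ("C4'", "O4'", "C1'", "C2'", "C3'"):
        if residue.atom(name) is None:
            raise KeyError(f"residue {residue.label}: missing sugar atom {name}")
    c4 = residue.pos("C4'")
    n = np.cross(residue.pos("C1'") - c4, residue.pos("O4'") - c4)
    norm = np.linalg.norm(n)
    if norm < _EPS:
        raise DegenerateGeometryError(
            f"residue {residue.label}: C4'/O4'/C1' are colinear"
        )
    n /= norm
    return ZDeviation(
        z_c2=float(np.dot(n, residue.pos("C2'") - c4)),
        z_c3=float(np.dot(n, residue.pos("C3'") - c4)),
    )


# ---------------------------------------------------------------------------
# Base planes and stacking twist

PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


def ring_atom_names(residue: Residue) -> tuple[str, ...]:
    return PURINE_RING if residue.base_type in ("A", "G") else PYRIMIDINE_RING


def base_plane(residue: Residue) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through the base ring atoms.

    Returns (centroid, unit normal).  The normal is oriented to agree with
    the polygon normal implied by the ring atom order, so it is consistent
    for every base of a given type and flips under reflection.
    """
    names = [n for n in ring_atom_names(residue) if residue.atom(n) is not None]
    if len(names) < 3:
        raise ValueError(
            f"residue {residue.label}: need ≥3 ring atoms for a base plane, "
            f"found {len(names)}"
        )
    pts = np.array([residue.pos(n) for n in names])
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    # orient by the ring-order polygon normal
    poly = np.zeros(3)
    for i in range(len(centered)):
        poly += np.cross(centered[i], centered[(i + 1) % len(centered)])
    if np.dot(normal, poly) < 0:
        normal = -normal
    return centroid, normal / np.linalg.norm(normal)


def plane_rms(points: np.ndarray) -> float:
    """RMS distance of points from their least-squares plane."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, s, _ = np.linalg.svd(centered, full_matrices=False)
    return float(s[-1] / math.sqrt(len(pts)))


def _glycosidic_vector(residue: Residue) -> np.ndarray:
    n_name = "N9" if residue.base_type in ("A", "G") else "N1"
    c1 = residue.atom("C1'")
    n = residue.atom(n_name)
    if c1 is None or n is None:
        raise KeyError(f"residue {residue.label}: need C1' and {n_name} for twist")
    return n.position - c1.position


def stacking_twist(lower: Residue, upper: Residue, axis) -> float:
    """Signed base rotation between two stacked residues, degrees (−180, 180].

    The C1'→N(glycosidic) vectors of the two residues are projected onto the
    plane perpendicular to ``axis`` (which should point 5'→3' along the
    stack); the returned angle rotates the lower projection onto the upper
    one, positive for a right-handed (counter-clockwise looking down the
    axis) progression.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < _EPS:
        raise ValueError("stacking axis must be nonzero")
    axis = axis / norm
    u = _glycosidic_vector(lower)
    v = _glycosidic_vector(upper)
    u = u - np.dot(u, axis) * axis
    v = v - np.dot(v, axis) * axis
    if np.linalg.norm(u) < 1e-6 or np.linalg.norm(v) < 1e-6:
        raise DegenerateGeometryError(
            "glycosidic vector parallel to the stacking axis; twist undefined"
        )
    ang = math.degrees(
        math.atan2(float(np.dot(axis, np.cross(u, v))), float(np.dot(u, v)))
    )
    return wrap_signed(ang)


# ---------------------------------------------------------------------------
# Superposition

def superpose_rmsd(
    reference, mobile
) -> tuple[float, np.ndarray, np.ndarray]:
    """Optimal rigid-body superposition (Kabsch, proper rotations only).

    ``reference`` and ``mobile`` are equal-length, correspondence-ordered
    (n, 3) coordinate arrays.  Returns (rmsd, rotation, translation) such
    that ``mobile @ rotation.T + translation`` best fits ``reference``.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape:
        raise ValueError(
            f"correspondence error: {ref.shape[0]} reference vs "
            f"{mob.shape[0]} mobile atoms"
        )
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise ValueError("need ≥3 correspondence-ordered 3D points")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    h = (mob - mob_c).T @ (ref - ref_c)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = ref_c - rot @ mob_c
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rmsd, rot, trans


AtomSelector = Callable[[Residue, "object"], bool]


def _selected_coords(model: StructureModel, selector: AtomSelector) -> tuple[list, np.ndarray]:
    keys = []
    coords = []
    for res in model.residues():
        for atom in res.atoms:
            if selector(res, atom):
                keys.append((res.chain_id, res.seq_number, atom.name))
                coords.append(atom.position)
    return keys, np.array(coords)


def ensemble_pairwise_rmsd(
    models: Sequence[StructureModel], atom_selector: AtomSelector | None = None
) -> tuple[float, float]:
    """Mean ± sd of superposition RMSD over all unordered model pairs.

    Atom correspondence is by (chain, seq_number, atom name); the selector
    is a predicate (residue, atom) → bool, defaulting to all heavy atoms.
    """
    if len(models) < 2:
        raise ValueError("need ≥2 models for ensemble RMSD")
    if atom_selector is None:
        atom_selector = lambda res, atom: not atom.is_hydrogen  # noqa: E731
    per_model = [_selected_coords(m, atom_selector) for m in models]
    ref_keys = per_model[0][0]
    if len(ref_keys) < 3:
        raise ValueError("atom selector yields fewer than 3 atoms")
    for i, (keys, _) in enumerate(per_model[1:], start=2):
        if keys != ref_keys:
            raise ValueError(
                f"model {i} atom selection does not match model 1 "
                f"({len(keys)} vs {len(ref_keys)} atoms)"
            )
    rmsds = [
        superpose_rmsd(per_model[i][1], per_model[j][1])[0]
        for i, j in itertools.combinations(range(len(per_model)), 2)
    ]
    arr = np.array(rmsds)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


# ---------------------------------------------------------------------------
# Per-residue geometry table

GEOMETRY_COLUMNS = [
    "chain", "resnum", "base",
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi",
    "P", "tau_m", "pucker_class", "z_c2", "z_c3", "glycosidic",
]


def residue_geometry_table(model: StructureModel):
    """Per-residue geometry as a pandas DataFrame with a fixed column order."""
    import pandas as pd

    rows = []
    for chain_id, residues in model.chains.items():
        nts = [r for r in residues if r.is_nucleotide]
        for i, res in enumerate(nts):
            prev = nts[i - 1] if i > 0 else None
            nxt = nts[i + 1] if i + 1 < len(nts) else None
            ts = backbone_torsions(res, prev, nxt)
            row = {"chain": chain_id, "resnum": res.seq_number, "base": res.base_type}
            row.update(ts.as_dict())
            try:
                pk = sugar_pucker(res)
                row["P"], row["tau_m"] = pk.P, pk.tau_m
                row["pucker_class"] = pk.pucker_class
            except (KeyError, ValueError):
                row["P"] = row["tau_m"] = None
                row["pucker_class"] = None
            try:
                zd = z_deviation(res)
                row["z_c2"], row["z_c3"] = zd.z_c2, zd.z_c3
            except (KeyError, DegenerateGeometryError):
                row["z_c2"] = row["z_c3"] = None
            row["glycosidic"] = (
                glycosidic_class(ts.chi) if ts.chi is not None else None
            )
            rows.append(row)
    return pd.DataFrame(rows, columns=GEOMETRY_COLUMNS)
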