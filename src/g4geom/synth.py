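"""Idealized G-quadruplex coordinate generator.

Builds fully parameterized synthetic G4 models so that every stage of the
annotation and comparison pipeline can be exercised with known ground
truth: planar C4-symmetric G-tetrads with exact cyclic Hoogsteen hydrogen-
bond geometry (N2→N7 and N1→O6 at 2.9 Å), stacked layers with a controlled
signed twist and rise, deoxyribose sugars embedded in 3D from a chosen
pseudorotation phase/amplitude, glycosidic angles set explicitly, thymine
bulges projecting radially out of the core, propeller loops, block–block
(5'-5' polarity-inverted) interfaces with a linker, and optional Gaussian
coordinate noise.

The generator is geometric, not thermodynamic: bond lengths are ideal and
backbone linkers between rigidly placed residues are solved numerically.
Core, loop and linker steps use a deterministic relaxed closure (ideal
bonds, near-ideal angles; the inter-residue torsions ε, ζ, α, β, γ emerge,
identically on congruent steps).  Around a bulge, the thymine pose and both
flanking linkers are solved jointly so the step torsions equal the
no-bulge baseline plus the requested per-angle offsets exactly.  Base
geometry comes from fixed internal templates of idealized planar
guanine/thymine rings (standard reference-frame coordinates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .structure_io import Atom, Residue, StructureModel
from .geometry import dihedral, place_atom, wrap_signed, wrap360

__all__ = [
    "BuildSpec",
    "BuildError",
    "build_tetrad",
    "build_g4",
    "build_nucleoside",
    "mirror",
    "apply_noise",
    "build_torsion_chain",
    "ground_truth",
    "GUANINE_TEMPLATE",
    "THYMINE_TEMPLATE",
]


class BuildError(RuntimeError):
    """A requested geometry cannot be realized (e.g. unreachable closure)."""


# ---------------------------------------------------------------------------
# Base templates: idealized planar bases in the standard reference frame
# (x-y plane, glycosidic nitrogen toward the viewer's lower left).

GUANINE_TEMPLATE: dict[str, np.ndarray] = {
    name: np.array(xyz)
    for name, xyz in {
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, 0.000),
        "N3": (-2.342, 2.364, 0.000),
        "C4": (-1.265, 3.177, 0.000),
    }.items()
}

THYMINE_TEMPLATE: dict[str, np.ndarray] = {
    name: np.array(xyz)
    for name, xyz in {
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.000),
        "C6": (-0.024, 5.057, 0.000),
    }.items()
}

# Ideal covalent geometry used throughout the builder (Å / degrees).
BOND = {
    ("C1'", "N"): 1.470,
    ("C1'", "O4'"): 1.413,
    ("C1'", "C2'"): 1.528,
    ("C2'", "C3'"): 1.525,
    ("C3'", "C4'"): 1.528,
    ("C4'", "O4'"): 1.414,
    ("C3'", "O3'"): 1.423,
    ("C4'", "C5'"): 1.510,
    ("C5'", "O5'"): 1.440,
    ("O5'", "P"): 1.593,
    ("P", "O3'"): 1.607,
}

# Chirality of the D-deoxyribose stereocenters, expressed as the signed
# torsional offsets of exocyclic substituents from endocyclic torsions.
# Calibrated once against an independently embedded 2'-deoxyguanosine.
_C2_CHIRALITY_SIGN = -1.0    # sign of det(O4'-C1', N(gly)-C1', C2'-C1')
_C5_TORSION_OFFSET = -118.0  # torsion(C2'-C3'-C4'-C5') - nu3, degrees
_O3_TORSION_OFFSET = 118.0   # torsion(C1'-C2'-C3'-O3') - nu2, degrees

# γ given to the 5'-terminal residue, whose O5' has no incoming phosphate.
TERMINAL_GAMMA = 54.0


@dataclass(frozen=True)
class BuildSpec:
    """Complete recipe for one synthetic G4 model.

    Parameters
    ----------
    n_tetrads : total stacked tetrad layers.
    blocks : tetrads per block, e.g. ``(2, 2)`` for two polarity-inverted
        blocks joined by a linker; ``None`` means one block.
    twist_per_step : signed base rotation per intra-block step, degrees;
        ≈ −27° reproduces a left-handed core, ≈ +30° a right-handed one.
    rise_per_step : layer separation, Å.
    bulges : ``(column, step)`` single-thymine insertions; ``step`` is the
        global intra-block step index (between layers step and step+1).
    loop_lengths : thymines per column-to-column propeller connection
        (3 connections per block); ``None`` builds four separate strands
        (tetramolecular, no loops).
    linker_length : thymines joining two blocks.  The default (3) spans the
        outside of the flipped block, whose strand threads from its far
        face toward the interface (rigid residue units close the backbone
        in one direction only).
    bulge_torsion_offsets : per-angle offsets (degrees) added to the
        no-bulge baseline torsions on the two steps flanking every bulge;
        keys from {'epsilon','zeta','alpha','beta','gamma'}.  Default:
        α −90°, β −70° — 90°/70° circular deviations on the transition
        angles α+1 and β+1.
    sugar_P, sugar_tau_m : pseudorotation phase/amplitude of every sugar.
    chi : glycosidic torsion of every residue; None resolves to a
        handedness-dependent anti default (240° right-handed, 280°
        left-handed — both inside the anti restraint windows; the higher
        left-handed value is what lets the backbone close between stacked
        layers of a left-handed core).
    overhang_3p : extra 3'-thymines stacked over the top outer tetrad
        (capping-style overhang).
    noise_sd : isotropic Gaussian coordinate noise, Å, applied last.
    seed : RNG seed for the noise.
    """

    n_tetrads: int = 2
    blocks: tuple[int, ...] | None = None
    twist_per_step: float = -27.0
    rise_per_step: float = 3.3
    bulges: tuple[tuple[int, int], ...] = ()
    loop_lengths: tuple[int, ...] | None = (1, 1, 1)
    linker_length: int = 3
    bulge_torsion_offsets: tuple[tuple[str, float], ...] = ()
    sugar_P: float = 162.0
    sugar_tau_m: float = 35.0
    chi: float | None = None
    interface_gap: float = 3.5
    overhang_3p: int = 0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_tetrads < 1:
            raise ValueError("n_tetrads must be ≥ 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        blocks = self.blocks or (self.n_tetrads,)
        if sum(blocks) != self.n_tetrads:
            raise ValueError("blocks must partition n_tetrads")
        valid_steps = set(self._bulge_steps())
        for col, step in self.bulges:
            if col not in range(4) or step not in valid_steps:
                raise ValueError(
                    f"bulge position (column {col}, step {step}) does not "
                    f"reference a valid step {sorted(valid_steps)} (bulges "
                    "live in the even, unflipped blocks)"
                )

    def _blocks(self) -> tuple[int, ...]:
        return self.blocks or (self.n_tetrads,)

    def _intra_block_steps(self) -> list[int]:
        steps, base = [], 0
        for nb in self._blocks():
            steps.extend(range(base, base + nb - 1))
            base += nb
        return steps

    def _bulge_steps(self) -> list[int]:
        """Intra-block steps that can host a bulge (even blocks only; odd
        blocks are polarity-flipped and thread 3'→5' in layer order)."""
        steps, base = [], 0
        for bi, nb in enumerate(self._blocks()):
            if bi % 2 == 0:
                steps.extend(range(base, base + nb - 1))
            base += nb
        return steps

    @property
    def handedness(self) -> str:
        return "left" if self.twist_per_step < 0 else "right"

    @property
    def resolved_chi(self) -> float:
        if self.chi is not None:
            return self.chi
        return 280.0 if self.handedness == "left" else 240.0


# ---------------------------------------------------------------------------
# small rigid-motion helpers

def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_FLIP_X = np.diag([1.0, -1.0, -1.0])  # 180° rotation about x (proper)


def _transform(atoms: dict[str, np.ndarray], rot: np.ndarray, trans: np.ndarray
               ) -> dict[str, np.ndarray]:
    return {k: rot @ v + trans for k, v in atoms.items()}


# ---------------------------------------------------------------------------
# tetrad placement: solve the in-plane pose so the cyclic Hoogsteen pairs hit
# their restraint-target heavy-atom distances N2→N7 = N1→O6 = 2.9 Å.

HOOGSTEEN_NN = 2.90  # N2→N7 target, Å
HOOGSTEEN_NO = 2.90  # N1→O6 target, Å


@lru_cache(maxsize=1)
def _tetrad_pose() -> tuple[float, float, float]:
    """(x, y, phi): in-plane pose of the guanine template such that four
    copies related by successive 90° rotations close the Hoogsteen cycle."""

    def residuals(v, prior_r=5.0, with_prior=True):
        x, y, phi = v
        a = _transform(GUANINE_TEMPLATE, _rot_z(phi), np.array([x, y, 0.0]))
        b = _transform(a, _rot_z(90.0), np.zeros(3))
        r = [
            np.linalg.norm(a["N2"] - b["N7"]) - HOOGSTEEN_NN,
            np.linalg.norm(a["N1"] - b["O6"]) - HOOGSTEEN_NO,
        ]
        if with_prior:
            r.append(0.02 * (math.hypot(x, y) - prior_r))
        return r

    best = None
    for prior_r in (3.0, 4.0, 5.0, 6.0):
        for phi0 in range(0, 360, 30):
            sol = least_squares(residuals, [prior_r, 0.0, float(phi0)],
                                kwargs={"prior_r": prior_r},
                                xtol=1e-14, ftol=1e-14)
            sol = least_squares(residuals, sol.x,
                                kwargs={"with_prior": False},
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
            hard = residuals(sol.x, with_prior=False)
            if abs(hard[0]) + abs(hard[1]) > 1e-8:
                continue
            # the exact solutions are discrete; keep the physical one:
            # glycosidic nitrogens outside the base centroids (sugars point
            # outward) and no steric overlap between neighbouring bases
            placed = _transform(GUANINE_TEMPLATE, _rot_z(sol.x[2]),
                                np.array([sol.x[0], sol.x[1], 0.0]))
            ring = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
            cen = np.mean([placed[n] for n in ring], axis=0)
            cen_r = math.hypot(cen[0], cen[1])
            n9_r = math.hypot(placed["N9"][0], placed["N9"][1])
            if n9_r <= cen_r:
                continue
            neighbor = _transform(placed, _rot_z(90.0), np.zeros(3))
            min_dist = min(np.linalg.norm(p - q)
                           for p in placed.values()
                           for q in neighbor.values())
            if min_dist < 2.5:
                continue
            score = abs(cen_r - 5.0)
            if best is None or score < best[0]:
                best = (score, tuple(float(q) for q in sol.x))
    if best is None:
        raise BuildError("tetrad Hoogsteen placement did not converge")
    return best[1]


# ---------------------------------------------------------------------------
# sugar ring embedding from (P, tau_m)

def nu_from_pucker(P: float, tau_m: float) -> tuple[float, ...]:
    """Endocyclic torsions from the cosine model ν_j = τm·cos(P + 144°(j−2))."""
    return tuple(
        tau_m * math.cos(math.radians(P + 144.0 * (j - 2))) for j in range(5)
    )


_RING_BONDS = (
    BOND[("C1'", "O4'")],   # O4'-C1'
    BOND[("C1'", "C2'")],   # C1'-C2'
    BOND[("C2'", "C3'")],   # C2'-C3'
    BOND[("C3'", "C4'")],   # C3'-C4'
    BOND[("C4'", "O4'")],   # C4'-O4'
)


@lru_cache(maxsize=256)
def _ring_coords(P_key: float, tau_key: float) -> tuple[tuple[float, ...], ...]:
    """Cartesian furanose ring (O4', C1', C2', C3', C4') in a local frame,
    solved so the endocyclic torsions meet the cosine-model targets in least
    squares with exact ideal bond lengths (closure to 1e-4 Å; torsions to a
    few hundredths of a degree, the intrinsic slack of the cosine model)."""
    nus = nu_from_pucker(P_key, tau_key)
    r_penta = _RING_BONDS[0] / (2.0 * math.sin(math.pi / 5.0))

    # gauge-fixed frame: O4' at the origin, C1' on +x, C2' in the xy-plane
    o4 = np.zeros(3)
    c1 = np.array([_RING_BONDS[0], 0.0, 0.0])

    def unpack(v):
        c2 = np.array([v[0], v[1], 0.0])
        return o4, c1, c2, v[2:5], v[5:8]

    def residuals(v):
        _, _, c2, c3, c4 = unpack(v)
        ring = [o4, c1, c2, c3, c4]
        r = [
            600.0 * (np.linalg.norm(ring[(i + 1) % 5] - ring[i]) - _RING_BONDS[i])
            for i in range(1, 5)
        ]
        quads = ((c4, o4, c1, c2), (o4, c1, c2, c3), (c1, c2, c3, c4),
                 (c2, c3, c4, o4), (c3, c4, o4, c1))
        r += [2.0 * _torsion_residual_deg(_safe_dihedral(*q), nus[i])
              for i, q in enumerate(quads)]
        # weak prior keeping internal angles near a regular ring
        for i in range(5):
            a, b, c = ring[(i - 1) % 5], ring[i], ring[(i + 1) % 5]
            r.append(0.01 * (_angle_deg(a, b, c) - 104.0))
        return r

    # primary seed: an open chain built by NeRF from the target torsions
    # themselves (guarantees the correct chirality branch); fallbacks sweep
    # cosine out-of-plane phases
    seeds = []
    th0 = 104.0
    c2_seed = c1 + _RING_BONDS[1] * np.array(
        [-math.cos(math.radians(th0)), math.sin(math.radians(th0)), 0.0])
    c3_seed = place_atom(o4, c1, c2_seed, _RING_BONDS[2], th0, nus[1])
    c4_seed = place_atom(c1, c2_seed, c3_seed, _RING_BONDS[3], th0, nus[2])
    seeds.append(np.concatenate([c2_seed[:2], c3_seed, c4_seed]))
    for phase in range(0, 360, 36):
        pent = [
            np.array([r_penta * math.cos(2 * math.pi * j / 5) + r_penta,
                      r_penta * math.sin(2 * math.pi * j / 5),
                      0.35 * math.cos(math.radians(phase + 144.0 * j))])
            for j in range(5)
        ]
        seeds.append(np.concatenate([pent[2][:2], pent[3], pent[4]]))

    best = None
    for x0 in seeds:
        sol = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12,
                            gtol=1e-12, max_nfev=500)
        res = residuals(sol.x)
        bond_err = max(abs(x) / 600.0 for x in res[:4])
        tors_err = max(abs(x) / 2.0 for x in res[4:9])
        score = bond_err + tors_err
        if best is None or score < best[0]:
            best = (score, bond_err, tors_err, sol.x)
        if bond_err < 1e-5 and tors_err < 0.05:
            break
    _, bond_err, tors_err, x = best
    # a closed fixed-bond 5-ring has only 4 torsional degrees of freedom, so
    # the five cosine-model targets are met in least squares: bonds exact,
    # with up to ~0.6° absorbed by the torsions depending on the phase
    if bond_err > 1e-4 or tors_err > 1.0:
        raise BuildError(
            f"sugar ring closure failed for P={P_key}, tau_m={tau_key} "
            f"(bond error {bond_err:.2e} Å, torsion error {tors_err:.2e}°)"
        )
    ring = unpack(x)
    return tuple(tuple(float(q) for q in p) for p in ring)


def _solve_c2_direction(c1, n_gly, o4, theta1: float, bond: float) -> np.ndarray:
    """Position of C2' bonded to C1' with the ring angle O4'-C1'-C2' = θ1,
    a tetrahedral angle to the glycosidic nitrogen, and D-sugar chirality."""
    u = o4 - c1
    u /= np.linalg.norm(u)
    w = n_gly - c1
    w /= np.linalg.norm(w)
    cos_t1 = math.cos(math.radians(theta1))
    cos_t2 = math.cos(math.radians(113.7))  # O? N9-C1'-C2'
    # solve d = a*u + b*w + c*(u×w) with d·u = cos θ1, d·w = cos θ2, |d| = 1
    uw = float(np.dot(u, w))
    m = np.array([[1.0, uw], [uw, 1.0]])
    ab = np.linalg.solve(m, [cos_t1, cos_t2])
    cross = np.cross(u, w)
    cross_norm2 = float(np.dot(cross, cross))
    planar = ab[0] * u + ab[1] * w
    c2sq = (1.0 - float(np.dot(planar, planar))) / cross_norm2
    if c2sq < 0:
        raise BuildError("C2' placement infeasible for requested sugar geometry")
    c = _C2_CHIRALITY_SIGN * math.sqrt(c2sq)
    d = planar + c * cross
    return c1 + bond * d


def _build_sugar(base: dict[str, np.ndarray], base_type: str,
                 P: float, tau_m: float, chi: float) -> dict[str, np.ndarray]:
    """Attach a deoxyribose (C1', O4', C2', C3', C4', O3') to a placed base.

    The ring is solved once in a local frame from (P, τm), then rigidly
    attached: C1' continues the glycosidic bond, O4' is rotated to the
    requested χ, C2' takes the D-sugar branch of the C1' stereocenter, and
    the remaining ring atoms follow by exact three-point superposition.
    """
    ring = [np.array(p) for p in _ring_coords(round(P, 6), round(tau_m, 6))]
    l_o4, l_c1, l_c2, l_c3, l_c4 = ring
    theta1 = _angle_deg(l_o4, l_c1, l_c2)
    if base_type in ("A", "G"):
        n_gly, c_chi, a1, a2 = "N9", "C4", "N7", "C8"
        angle_cn = 127.0
    else:
        n_gly, c_chi, a1, a2 = "N1", "C2", "C5", "C6"
        angle_cn = 120.7
    c1 = place_atom(base[a1], base[a2], base[n_gly],
                    BOND[("C1'", "N")], angle_cn, 180.0)
    o4 = place_atom(base[c_chi], base[n_gly], c1,
                    float(np.linalg.norm(l_o4 - l_c1)), 108.2, chi)
    c2 = _solve_c2_direction(c1, base[n_gly], o4, theta1,
                             float(np.linalg.norm(l_c2 - l_c1)))
    # exact congruent three-point fit: local (C1', O4', C2') → world
    from .geometry import superpose_rmsd
    _, rot, trans = superpose_rmsd(np.array([c1, o4, c2]),
                                   np.array([l_c1, l_o4, l_c2]))
    c3 = rot @ l_c3 + trans
    c4 = rot @ l_c4 + trans
    nu2 = dihedral(c1, c2, c3, c4)
    o3 = place_atom(c1, c2, c3, BOND[("C3'", "O3'")], 110.6,
                    nu2 + _O3_TORSION_OFFSET)
    out = dict(base)
    out.update({"C1'": c1, "O4'": o4, "C2'": c2, "C3'": c3, "C4'": c4, "O3'": o3})
    return out


def _place_c5_terminal(atoms: dict[str, np.ndarray], gamma: float) -> None:
    """Rigidly place C5' and O5' on a residue with no incoming backbone."""
    nu3 = dihedral(atoms["C2'"], atoms["C3'"], atoms["C4'"], atoms["O4'"])
    c5 = place_atom(atoms["C2'"], atoms["C3'"], atoms["C4'"],
                    BOND[("C4'", "C5'")], 114.7, nu3 + _C5_TORSION_OFFSET)
    atoms["C5'"] = c5
    atoms["O5'"] = place_atom(atoms["C3'"], atoms["C4'"], c5,
                              BOND[("C5'", "O5'")], 110.2, gamma)


# ---------------------------------------------------------------------------
# backbone step solver

_STEP_BONDS = (
    BOND[("P", "O3'")], BOND[("O5'", "P")], BOND[("C5'", "O5'")],
    BOND[("C4'", "C5'")],
)
_STEP_ANGLE_PRIORS = (119.7, 104.0, 120.9, 110.2, 114.7)


def _dist(a, b) -> float:
    dx = a[0] - b[0]
    dy = a[1] - b[1]
    dz = a[2] - b[2]
    return math.sqrt(dx * dx + dy * dy + dz * dz)


def _angle_deg(a, b, c) -> float:
    ux, uy, uz = a[0] - b[0], a[1] - b[1], a[2] - b[2]
    vx, vy, vz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nv = math.sqrt(vx * vx + vy * vy + vz * vz)
    cosv = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def _safe_dihedral(p1, p2, p3, p4) -> float:
    """Scalar-math torsion identical to :func:`g4geom.geometry.dihedral`;
    degenerate inputs return 0 instead of raising (solver hot path)."""
    b1x, b1y, b1z = p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2]
    b2x, b2y, b2z = p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2]
    b3x, b3y, b3z = p4[0] - p3[0], p4[1] - p3[1], p4[2] - p3[2]
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    x = n1x * n2x + n1y * n2y + n1z * n2z
    y = (b1x * n2x + b1y * n2y + b1z * n2z) * math.sqrt(
        b2x * b2x + b2y * b2y + b2z * b2z)
    if x == 0.0 and y == 0.0:
        return 0.0
    return math.degrees(math.atan2(y, x)) % 360.0


def _torsion_residual_deg(observed: float, target: float) -> float:
    """Smooth wrap-free angular residual: 2·sin(Δ/2) scaled to degrees.

    Equals Δ for small differences, is differentiable across the 0/360 wrap
    (unlike a wrapped difference), and vanishes iff the angles agree mod 360.
    """
    d = math.radians(observed - target)
    return math.degrees(2.0 * math.sin(d / 2.0))


def _step_torsions(c4p, c3p, o3p, p, o5, c5, c4n, c3n) -> dict[str, float]:
    """The five inter-residue torsions of one backbone step, degrees."""
    return {
        "epsilon": _safe_dihedral(c4p, c3p, o3p, p),
        "zeta": _safe_dihedral(c3p, o3p, p, o5),
        "alpha": _safe_dihedral(o3p, p, o5, c5),
        "beta": _safe_dihedral(p, o5, c5, c4n),
        "gamma": _safe_dihedral(o5, c5, c4n, c3n),
    }


def _step_bond_residuals(o3p, p, o5, c5, c4n, weight: float) -> list[float]:
    return [
        weight * (_dist(o3p, p) - _STEP_BONDS[0]),
        weight * (_dist(p, o5) - _STEP_BONDS[1]),
        weight * (_dist(o5, c5) - _STEP_BONDS[2]),
        weight * (_dist(c5, c4n) - _STEP_BONDS[3]),
    ]


def _step_angle_residuals(c3p, o3p, p, o5, c5, c4n, c3n, weight: float) -> list[float]:
    angles = (
        _angle_deg(c3p, o3p, p), _angle_deg(o3p, p, o5),
        _angle_deg(p, o5, c5), _angle_deg(o5, c5, c4n),
        _angle_deg(c5, c4n, c3n),
    )
    return [weight * (a - pr) for a, pr in zip(angles, _STEP_ANGLE_PRIORS)]


def _solve_step(c4p, c3p, o3p, c4n, c3n, label: str
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relaxed closure of one backbone step between two rigidly placed
    residues: P, O5', C5' of the 3' residue are solved for exact ideal bond
    lengths and near-ideal bond angles; the step torsions emerge.

    The solver is deterministic and equivariant under rigid motions of the
    endpoints, so congruent steps receive congruent (identical-torsion)
    backbones.
    """
    span = np.linalg.norm(c4n - o3p)
    if span > 6.3:
        raise BuildError(
            f"step {label}: O3'→C4' span {span:.2f} Å exceeds the reach of "
            "the three linking backbone atoms"
        )

    def residuals(v, angle_weight=0.2):
        p, o5, c5 = v[0:3], v[3:6], v[6:9]
        return (_step_bond_residuals(o3p, p, o5, c5, c4n, 60.0)
                + _step_angle_residuals(c3p, o3p, p, o5, c5, c4n, c3n,
                                        angle_weight))

    axis = c4n - o3p
    # deterministic, step-frame-local offset directions (equivariant)
    perp1 = np.cross(axis, c3n - c3p)
    if np.linalg.norm(perp1) < 1e-6:
        perp1 = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp1) < 1e-6:
        perp1 = np.cross(axis, [1.0, 0.0, 0.0])
    perp1 /= np.linalg.norm(perp1)
    perp2 = np.cross(axis / np.linalg.norm(axis), perp1)
    best = None
    starts = [perp1, -perp1, perp2, -perp2,
              (perp1 + perp2) / math.sqrt(2), (perp1 - perp2) / math.sqrt(2)]
    for k, direction in enumerate(starts):
        off = direction * 1.0
        x0 = np.concatenate([
            o3p + 0.25 * axis + off,
            o3p + 0.50 * axis + off,
            o3p + 0.75 * axis + off,
        ])
        sol = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12,
                            gtol=1e-12, max_nfev=400)
        # refine: drop the angle-prior weight so the bond lengths close
        # exactly from the angle-balanced starting point
        sol = least_squares(residuals, sol.x, kwargs={"angle_weight": 0.002},
                            xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=400)
        res = residuals(sol.x)
        bond_err = max(abs(x) / 60.0 for x in res[:4])
        angle_cost = sum(x * x for x in res[4:])
        score = (bond_err > 1e-6, angle_cost)
        if best is None or score < best[0]:
            best = (score, bond_err, sol.x)
        # starts are ordered deterministically in the step-local frame, so
        # taking the first converged solution stays equivariant
        if bond_err < 1e-6:
            break
    _, bond_err, x = best
    if bond_err > 1e-4:
        raise BuildError(
            f"step {label}: backbone closure did not converge "
            f"(bond error {bond_err:.2e} Å)"
        )
    return x[0:3], x[3:6], x[6:9]


def _rotvec_matrix(v: np.ndarray) -> np.ndarray:
    """Rotation matrix from a rotation vector (axis × angle, radians)."""
    theta = float(np.linalg.norm(v))
    if theta < 1e-12:
        return np.eye(3)
    k = v / theta
    kx = np.array([[0.0, -k[2], k[1]], [k[2], 0.0, -k[0]], [-k[1], k[0], 0.0]])
    return np.eye(3) + math.sin(theta) * kx + (1.0 - math.cos(theta)) * (kx @ kx)


def _solve_bulge(prev_atoms: dict[str, np.ndarray],
                 next_atoms: dict[str, np.ndarray],
                 unit: dict[str, np.ndarray],
                 targets_in: dict[str, float],
                 targets_out: dict[str, float],
                 centroid_prior: np.ndarray,
                 base_type: str,
                 label: str):
    """Jointly solve a bulge residue's rigid pose and both flanking backbone
    linkers so the inter-residue torsions of the steps into and out of the
    bulge hit their targets exactly with ideal bond lengths.

    The bulge pose contributes six free parameters, making the torsion
    targets reachable (a fixed pose would over-constrain the closure).  The
    solve is a homotopy: the torsion targets are ramped from the values the
    starting configuration already satisfies to the requested ones, each
    increment warm-started from the last, which tracks the solution
    manifold reliably even for 90° target moves.  A weak prior keeps the
    bulge base centroid near ``centroid_prior`` (radially outside the
    core).
    """
    names = list(unit.keys())
    local_centroid = _base_centroid(unit, base_type)
    # only C4', C3', O3' and the base centroid enter the residuals; the
    # centroid is the rotation center, so it depends on the shift alone
    _key_local = {n: unit[n] - local_centroid for n in ("C4'", "C3'", "O3'")}
    keys = ("epsilon", "zeta", "alpha", "beta", "gamma")

    def placed_key(v):
        rot = _rotvec_matrix(v[0:3])
        off = local_centroid + v[3:6]
        return {n: rot @ p + off for n, p in _key_local.items()}

    def placed(v):
        rot = _rotvec_matrix(v[0:3])
        return {n: rot @ (unit[n] - local_centroid) + local_centroid + v[3:6]
                for n in names}

    def step_state(v):
        t = placed_key(v[0:6])
        p1, o51, c51 = v[6:9], v[9:12], v[12:15]
        p2, o52, c52 = v[15:18], v[18:21], v[21:24]
        tors_in = _step_torsions(prev_atoms["C4'"], prev_atoms["C3'"],
                                 prev_atoms["O3'"], p1, o51, c51,
                                 t["C4'"], t["C3'"])
        tors_out = _step_torsions(t["C4'"], t["C3'"], t["O3'"], p2, o52, c52,
                                  next_atoms["C4'"], next_atoms["C3'"])
        return t, (p1, o51, c51), (p2, o52, c52), tors_in, tors_out

    def residuals(v, tgt_in, tgt_out):
        t, (p1, o51, c51), (p2, o52, c52), tors_in, tors_out = step_state(v)
        r = _step_bond_residuals(prev_atoms["O3'"], p1, o51, c51, t["C4'"], 60.0)
        r += [2.0 * _torsion_residual_deg(tors_in[k], tgt_in[k]) for k in keys]
        r += _step_bond_residuals(t["O3'"], p2, o52, c52, next_atoms["C4'"], 60.0)
        r += [2.0 * _torsion_residual_deg(tors_out[k], tgt_out[k]) for k in keys]
        cen = local_centroid + v[3:6]
        r += [0.05 * q for q in (cen - centroid_prior)]
        r += _step_angle_residuals(prev_atoms["C3'"], prev_atoms["O3'"],
                                   p1, o51, c51, t["C4'"], t["C3'"], 0.002)
        r += _step_angle_residuals(t["C3'"], t["O3'"], p2, o52, c52,
                                   next_atoms["C4'"], next_atoms["C3'"], 0.002)
        return r

    def errors(v, tgt_in, tgt_out):
        res = residuals(v, tgt_in, tgt_out)
        bond_err = max(abs(q) / 60.0 for q in res[0:4] + res[9:13])
        tors_err = max(abs(q) / 2.0 for q in res[4:9] + res[13:18])
        return bond_err, tors_err

    def interp(start, target, lam):
        return {k: wrap360(start[k] + lam * wrap_signed(target[k] - start[k]))
                for k in keys}

    def run_homotopy(pose0):
        """Ramp the targets from the start configuration's torsions; returns
        the solved vector or None when the path folds."""
        t0 = placed(pose0)
        try:
            l_in = np.concatenate(_solve_step(
                prev_atoms["C4'"], prev_atoms["C3'"], prev_atoms["O3'"],
                t0["C4'"], t0["C3'"], label=f"{label} init-in"))
            l_out = np.concatenate(_solve_step(
                t0["C4'"], t0["C3'"], t0["O3'"],
                next_atoms["C4'"], next_atoms["C3'"], label=f"{label} init-out"))
        except BuildError:
            return None
        x = np.concatenate([pose0, l_in, l_out])
        _, _, _, start_in, start_out = step_state(x)
        lam, step = 0.0, 0.25
        n_fail = 0
        while lam < 1.0 - 1e-9:
            nxt = min(1.0, lam + step)
            tgt_in = interp(start_in, targets_in, nxt)
            tgt_out = interp(start_out, targets_out, nxt)
            sol = least_squares(residuals, x, args=(tgt_in, tgt_out),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=800)
            bond_err, tors_err = errors(sol.x, tgt_in, tgt_out)
            # interior waypoints only guide the path: loose acceptance there
            if bond_err < 1e-3 and tors_err < 1.0:
                x, lam = sol.x, nxt
                step = min(0.25, step * 2.0)
                continue
            step /= 2.0
            n_fail += 1
            if n_fail > 5:
                return None
        # polish the endpoint to the strict tolerances
        sol = least_squares(residuals, x, args=(targets_in, targets_out),
                            xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=2000)
        bond_err, tors_err = errors(sol.x, targets_in, targets_out)
        if bond_err > 1e-4 or tors_err > 0.01:
            return None
        return sol.x

    # the identity start usually works; alternative spins of the heuristic
    # pose give the homotopy different paths around folds
    radial = centroid_prior - np.array([0.0, 0.0, centroid_prior[2]])
    rn = np.linalg.norm(radial)
    radial = radial / rn if rn > 1e-9 else np.array([1.0, 0.0, 0.0])
    pose_starts = [np.zeros(6)]
    for spin in (0.8, -0.8, 1.6, -1.6):
        pose_starts.append(np.concatenate([spin * np.array([0.0, 0.0, 1.0]),
                                           np.zeros(3)]))
        pose_starts.append(np.concatenate([spin * radial, np.zeros(3)]))
    x = None
    for pose0 in pose_starts:
        x = run_homotopy(pose0)
        if x is not None:
            break
    if x is None:
        raise BuildError(
            f"bulge {label}: homotopy to the torsion targets stalled from "
            "every starting pose")
    bond_err, tors_err = errors(x, targets_in, targets_out)
    if bond_err > 1e-4 or tors_err > 0.01:
        raise BuildError(
            f"bulge {label}: joint pose/backbone solve did not converge "
            f"(bond error {bond_err:.2e} Å, torsion error {tors_err:.2e}°)")
    t = placed(x[0:6])
    return t, (x[6:9], x[9:12], x[12:15]), (x[15:18], x[18:21], x[21:24])


# ---------------------------------------------------------------------------
# residue unit placement

_BASE_TEMPLATES = {"G": GUANINE_TEMPLATE, "T": THYMINE_TEMPLATE}
_RES_NAMES = {"G": "DG", "T": "DT"}


def _residue_unit(base_type: str, spec: BuildSpec) -> dict[str, np.ndarray]:
    """Base + sugar + O3' in the base's standard reference frame."""
    base = dict(_BASE_TEMPLATES[base_type])
    return _build_sugar(base, base_type, spec.sugar_P, spec.sugar_tau_m,
                        spec.resolved_chi)


def _base_centroid(atoms: dict[str, np.ndarray], base_type: str) -> np.ndarray:
    names = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4") \
        if base_type == "G" else ("N1", "C2", "N3", "C4", "C5", "C6")
    return np.mean([atoms[n] for n in names], axis=0)


def _orient_unit_between(unit: dict[str, np.ndarray], base_type: str,
                         attach_from: np.ndarray, attach_to: np.ndarray,
                         outward: np.ndarray, c4_target: np.ndarray
                         ) -> dict[str, np.ndarray]:
    """Pose a free (bulge/loop/linker) residue: its C4' lands on
    ``c4_target``, its O3' leans toward ``attach_to``, and its base points
    along ``outward``."""
    # build an orthonormal world frame
    ez = attach_to - attach_from
    ez = ez / max(np.linalg.norm(ez), 1e-9)
    er = outward - np.dot(outward, ez) * ez
    er = er / max(np.linalg.norm(er), 1e-9)
    et = np.cross(ez, er)
    # local frame of the unit: f1 = C4'→base direction, f2 = C4'→O3'
    cb = _base_centroid(unit, base_type)
    f1 = cb - unit["C4'"]
    f1 /= np.linalg.norm(f1)
    f2v = unit["O3'"] - unit["C4'"]
    f2 = f2v - np.dot(f2v, f1) * f1
    f2 /= np.linalg.norm(f2)
    f3 = np.cross(f1, f2)
    local = np.column_stack([f1, f2, f3])
    world = np.column_stack([er, ez, et])
    rot = world @ local.T
    # proper rotation guaranteed: both frames are right-handed
    trans = c4_target - rot @ unit["C4'"]
    return _transform(unit, rot, trans)


# ---------------------------------------------------------------------------
# top-level builders

def _make_residue(chain: str, seq: int, base_type: str,
                  atoms: dict[str, np.ndarray]) -> Residue:
    order = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
             "C2'", "C1'"]
    order += list((_BASE_TEMPLATES[base_type]).keys())
    alist = [
        Atom(name=n, element=n[0], position=atoms[n])
        for n in order if n in atoms
    ]
    return Residue(chain_id=chain, seq_number=seq, name=_RES_NAMES[base_type],
                   atoms=alist)


def build_nucleoside(base_type: str = "G", P: float = 162.0,
                     tau_m: float = 35.0, chi: float = 240.0) -> Residue:
    """One free nucleoside with its sugar embedded from (P, τm) and the
    glycosidic torsion set to χ — handy for sugar-level geometry checks."""
    unit = _build_sugar(dict(_BASE_TEMPLATES[base_type]), base_type,
                        P, tau_m, chi)
    _place_c5_terminal(unit, TERMINAL_GAMMA)
    return _make_residue("A", 1, base_type, unit)


def build_tetrad(spec: BuildSpec | None = None) -> StructureModel:
    """One planar C4-symmetric G-tetrad (four single-residue chains)."""
    spec = spec or BuildSpec(n_tetrads=1, loop_lengths=None)
    x, y, phi = _tetrad_pose()
    unit = _residue_unit("G", spec)
    chains: dict[str, list[Residue]] = {}
    for k, cid in enumerate("ABCD"):
        rot = _rot_z(90.0 * k)
        atoms = _transform(
            _transform(unit, _rot_z(phi), np.array([x, y, 0.0])),
            rot, np.zeros(3))
        res = _make_residue(cid, 1, "G", atoms)
        chains[cid] = [res]
    model = StructureModel(model_index=1, chains=chains, source_id="synthetic-tetrad")
    return _noised(model, spec)


def _layer_pose(spec: BuildSpec, column: int, layer: int) -> tuple[np.ndarray, np.ndarray]:
    """(rotation, translation) world pose for the guanine of (column, layer).

    ``layer`` counts in strand (5'→3') order; z ascends and accumulates
    previous blocks' heights plus the interface gap.  Blocks alternate
    base-plane polarity (every odd block is flipped 180° about x, a proper
    rotation, so chirality is preserved while base normals invert across
    the 5'-5' interface).
    """
    z, block, local = 0.0, 0, layer
    for nb in spec._blocks():
        if local < nb:
            z += local * spec.rise_per_step
            break
        z += (nb - 1) * spec.rise_per_step + spec.interface_gap
        local -= nb
        block += 1
    flipped = (block % 2) == 1
    inplane = _rot_z(local * spec.twist_per_step + 90.0 * column)
    rot = inplane @ (_FLIP_X if flipped else np.eye(3))
    return rot, np.array([0.0, 0.0, z])


def _core_guanine_atoms(spec: BuildSpec) -> dict[tuple[int, int], dict[str, np.ndarray]]:
    x, y, phi = _tetrad_pose()
    unit = _transform(_residue_unit("G", spec), _rot_z(phi), np.array([x, y, 0.0]))
    out = {}
    for layer in range(spec.n_tetrads):
        for col in range(4):
            rot, trans = _layer_pose(spec, col, layer)
            out[(col, layer)] = _transform(unit, rot, trans)
    return out


def build_g4(spec: BuildSpec) -> StructureModel:
    """Build a full synthetic G4 model from a :class:`BuildSpec`.

    The strand threads column 0 → 3 within each block (5'→3' ascending in
    z), with propeller loops between columns, bulge thymines inserted inside
    their column runs, and a linker thymine between blocks.  Backbone
    linking atoms (P, O5', C5') are solved per step by relaxed
    ideal-geometry closure; congruent core steps therefore carry identical
    emergent torsions.  Around each bulge, the thymine pose and both
    flanking linkers are solved jointly so the five step torsions equal the
    no-bulge baseline plus ``bulge_torsion_offsets`` exactly.
    """
    core = _core_guanine_atoms(spec)
    blocks = spec._blocks()
    # default alteration: the transition angles α+1 and β+1 move by 90° and
    # 70° in circular deviation; the offset signs are a geometric free
    # choice (deviations are unsigned) picked for backbone solvability
    bulge_offsets = dict(spec.bulge_torsion_offsets) or \
        {"alpha": -90.0, "beta": -70.0}

    # --- thread the sequence into entries {type, atoms, kind, role, ...}
    Entry = dict
    strands: list[list[Entry]] = []
    layer_base = 0
    bulge_set = {(c, s) for c, s in spec.bulges}
    unimolecular = spec.loop_lengths is not None

    def column_run(col: int, layers: Sequence[int]) -> list[Entry]:
        run: list[Entry] = []
        for idx, lay in enumerate(layers):
            run.append(Entry(type="G", atoms=core[(col, lay)], kind="core",
                             role=f"core c{col} l{lay}"))
            if idx + 1 < len(layers) and (col, lay) in bulge_set:
                g5, g3 = core[(col, lay)], core[(col, lay + 1)]
                mid = 0.5 * (g5["O3'"] + g3["C4'"])
                outward = np.array([mid[0], mid[1], 0.0])
                outward /= max(np.linalg.norm(outward), 1e-9)
                # base projects radially outward past the backbone radius
                r_backbone = math.hypot(g5["O3'"][0], g5["O3'"][1])
                r_prior = max(6.0, r_backbone + 1.5)
                centroid_prior = np.array([0.0, 0.0, mid[2]]) + r_prior * outward
                unit = _residue_unit("T", spec)
                # start the sugar 4 Å outward of the anchor midpoint so both
                # flanking linkers begin with comfortable, solvable spans
                u = g3["C4'"] - g5["O3'"]
                u /= max(np.linalg.norm(u), 1e-9)
                w = outward - np.dot(outward, u) * u
                w /= max(np.linalg.norm(w), 1e-9)
                placed = _orient_unit_between(
                    unit, "T", g5["O3'"], g3["C4'"], outward, mid + 4.0 * w)
                run.append(Entry(type="T", atoms=placed, kind="bulge",
                                 centroid_prior=centroid_prior,
                                 role=f"bulge c{col} s{lay}"))
        return run

    def free_connector(n_res: int, frm: np.ndarray, to: np.ndarray,
                       role: str) -> list[Entry]:
        """Thymines bridging two anchor points (loops, linkers).

        Each residue's C4' is placed along the anchor line no further from
        the previous attachment point than the backbone linker can reach
        (about 5.5 Å per step plus the residue's own C4'→O3' extent).
        """
        entries = []
        d = to - frm
        dist = float(np.linalg.norm(d))
        for k in range(n_res):
            f = min((k + 1) * dist / (n_res + 1), 5.5 + k * 7.9) / dist
            pt = frm + f * d
            radial = np.array([pt[0], pt[1], 0.0])
            nr = np.linalg.norm(radial)
            outward = radial / nr if nr > 1e-6 else np.array([1.0, 0.0, 0.0])
            unit = _residue_unit("T", spec)
            # C4' sits on the anchor line; base pushed outward
            placed = _orient_unit_between(unit, "T", frm, to, outward, pt)
            entries.append(Entry(type="T", atoms=placed, kind="connector",
                                 role=role))
        return entries

    # propeller loops wind with the helical sense: the strand visits the
    # columns in the azimuthal direction that keeps single-residue loops
    # within backbone reach; polarity-flipped (odd) blocks thread downward
    # and therefore wind the other way
    order_normal = [0, 1, 2, 3] if spec.twist_per_step >= 0 else [0, 3, 2, 1]
    order_flipped = [0, 3, 2, 1] if spec.twist_per_step >= 0 else [0, 1, 2, 3]

    if unimolecular:
        seq: list[Entry] = []
        loop_lengths = list(spec.loop_lengths)
        for b, nb in enumerate(blocks):
            layers = list(range(layer_base, layer_base + nb))
            visit_order = order_flipped if b % 2 == 1 else order_normal
            if b % 2 == 1:
                # flipped blocks thread top layer first: their units close
                # the backbone in the descending direction
                layers = layers[::-1]
            if b > 0:
                # linker between blocks (previous entry exists)
                frm = seq[-1]["atoms"]["O3'"]
                to = core[(visit_order[0], layers[0])]["C4'"]
                seq += free_connector(spec.linker_length, frm, to, "linker")
            for ci, col in enumerate(visit_order):
                if ci > 0:
                    ll = loop_lengths[(ci - 1) % len(loop_lengths)]
                    frm = seq[-1]["atoms"]["O3'"]
                    to = core[(col, layers[0])]["C4'"]
                    if ll > 0:
                        seq += free_connector(ll, frm, to,
                                              f"loop b{b} #{ci}")
                seq += column_run(col, layers)
            layer_base += nb
        # 3' overhang thymines stacked over the top tetrad, sugar spun
        # toward the preceding residue so the backbone stays closable
        if spec.overhang_3p:
            top_z = max(e["atoms"]["C1'"][2] for e in seq)
            for k in range(spec.overhang_3p):
                unit = _residue_unit("T", spec)
                cen = _base_centroid(unit, "T")
                prev_o3 = seq[-1]["atoms"]["O3'"]
                exit_dir = np.array([prev_o3[0], prev_o3[1], 0.0])
                exit_dir /= max(np.linalg.norm(exit_dir), 1e-9)
                center = 1.5 * exit_dir + np.array(
                    [0.0, 0.0, top_z + 3.3 * (k + 1)])
                a_t = math.atan2(*(unit["C4'"] - cen)[1::-1])
                a_w = math.atan2(*(prev_o3 - center)[1::-1])
                rot = _rot_z(math.degrees(a_w - a_t))
                placed = _transform(unit, rot, center - rot @ cen)
                seq.append(Entry(type="T", atoms=placed, kind="connector",
                                 role="overhang"))
        strands.append(seq)
    else:
        for col in range(4):
            strands.append(column_run(col, list(range(spec.n_tetrads))))

    # --- backbone pass per strand: relaxed closure everywhere except around
    # bulges, where the bulge pose and both flanking linkers are solved
    # jointly so the step torsions equal the no-bulge baseline plus the
    # requested offsets
    chains: dict[str, list[Residue]] = {}
    chain_ids = ["A"] if unimolecular else ["A", "B", "C", "D"]
    seq_counter = 1
    for cid, entries in zip(chain_ids, strands):
        residues = []
        for i, e in enumerate(entries):
            atoms = e["atoms"]
            if i == 0:
                _place_c5_terminal(atoms, TERMINAL_GAMMA)
            elif "presolved" in e:
                atoms["P"], atoms["O5'"], atoms["C5'"] = e["presolved"]
            elif e["kind"] == "bulge":
                prev = entries[i - 1]["atoms"]
                nxt = entries[i + 1]["atoms"]
                # baseline: the relaxed direct closure this step would have
                # in the no-bulge twin
                p, o5, c5 = _solve_step(prev["C4'"], prev["C3'"], prev["O3'"],
                                        nxt["C4'"], nxt["C3'"],
                                        label=f"{e['role']} baseline")
                baseline = _step_torsions(prev["C4'"], prev["C3'"], prev["O3'"],
                                          p, o5, c5, nxt["C4'"], nxt["C3'"])
                targets = {k: wrap360(baseline[k] + bulge_offsets.get(k, 0.0))
                           for k in baseline}
                t_atoms, link_in, link_out = _solve_bulge(
                    prev, nxt, atoms, targets, targets,
                    e["centroid_prior"], "T", e["role"])
                e["atoms"] = atoms = t_atoms
                atoms["P"], atoms["O5'"], atoms["C5'"] = link_in
                entries[i + 1]["presolved"] = link_out
            else:
                prev = entries[i - 1]["atoms"]
                p, o5, c5 = _solve_step(
                    prev["C4'"], prev["C3'"], prev["O3'"],
                    atoms["C4'"], atoms["C3'"], label=f"{e['role']} (#{i})")
                atoms["P"], atoms["O5'"], atoms["C5'"] = p, o5, c5
            residues.append(_make_residue(cid, seq_counter, e["type"], atoms))
            seq_counter += 1
        chains[cid] = residues
        if not unimolecular:
            seq_counter = 1
    model = StructureModel(model_index=1, chains=chains,
                           source_id="synthetic-g4")
    return _noised(model, spec)


def _noised(model: StructureModel, spec: BuildSpec) -> StructureModel:
    if spec.noise_sd == 0:
        return model
    return apply_noise(model, spec.noise_sd, spec.seed)


def apply_noise(model: StructureModel, sd: float, seed: int) -> StructureModel:
    """Isotropic Gaussian coordinate noise (fresh model; input untouched)."""
    rng = np.random.default_rng(seed)
    chains = {}
    for cid, residues in model.chains.items():
        out = []
        for r in residues:
            atoms = [
                Atom(name=a.name, element=a.element,
                     position=a.position + rng.normal(0.0, sd, 3),
                     occupancy=a.occupancy, is_hydrogen=a.is_hydrogen)
                for a in r.atoms
            ]
            out.append(Residue(chain_id=cid, seq_number=r.seq_number,
                               name=r.name, atoms=atoms,
                               is_nucleotide=r.is_nucleotide))
        chains[cid] = out
    return StructureModel(model_index=model.model_index, chains=chains,
                          source_id=model.source_id + "+noise")


def mirror(model: StructureModel) -> StructureModel:
    """Reflect all coordinates through the y-z plane.

    Chirality-dependent quantities negate: handedness flips and the
    pseudorotation phase maps P → 360° − P.
    """
    chains = {}
    for cid, residues in model.chains.items():
        out = []
        for r in residues:
            atoms = [
                Atom(name=a.name, element=a.element,
                     position=a.position * np.array([-1.0, 1.0, 1.0]),
                     occupancy=a.occupancy, is_hydrogen=a.is_hydrogen)
                for a in r.atoms
            ]
            out.append(Residue(chain_id=cid, seq_number=r.seq_number,
                               name=r.name, atoms=atoms,
                               is_nucleotide=r.is_nucleotide))
        chains[cid] = out
    return StructureModel(model_index=model.model_index, chains=chains,
                          source_id=model.source_id + "+mirror")


# ---------------------------------------------------------------------------
# pure-torsion backbone chain (for torsion round-trip fixtures)

def build_torsion_chain(n_residues: int,
                        torsions: dict[str, float] | None = None
                        ) -> StructureModel:
    """A backbone-only chain built atom-by-atom from explicit torsions.

    Every residue carries P, O5', C5', C4', C3', O3'; all six backbone
    torsions take the requested values (degrees), so measuring them back is
    an exact round-trip.  No bases or sugars are attached.
    """
    t = {"alpha": 60.0, "beta": 60.0, "gamma": 60.0,
         "delta": 60.0, "epsilon": 60.0, "zeta": 60.0}
    if torsions:
        t.update(torsions)
    bonds = {"P-O5'": 1.593, "O5'-C5'": 1.440, "C5'-C4'": 1.510,
             "C4'-C3'": 1.528, "C3'-O3'": 1.423, "O3'-P": 1.607}
    angles = {"P": 119.7, "O5'": 104.0, "C5'": 120.9, "C4'": 110.2,
              "C3'": 115.5, "O3'": 110.5}
    pos: list[tuple[str, np.ndarray]] = [
        ("P", np.zeros(3)),
        ("O5'", np.array([bonds["P-O5'"], 0.0, 0.0])),
    ]
    c5 = place_atom(np.array([0.0, -1.0, 0.0]), pos[0][1], pos[1][1],
                    bonds["O5'-C5'"], angles["C5'"], 60.0)
    pos.append(("C5'", c5))
    chain_spec = [
        ("C4'", "C5'-C4'", angles["C4'"], "beta"),
        ("C3'", "C4'-C3'", angles["C3'"], "gamma"),
        ("O3'", "C3'-O3'", angles["O3'"], "delta"),
        ("P", "O3'-P", angles["P"], "epsilon"),
        ("O5'", "P-O5'", angles["O5'"], "zeta"),
        ("C5'", "O5'-C5'", angles["C5'"], "alpha"),
    ]
    step_i = 0
    while len(pos) < 6 * n_residues:
        name, bond_key, ang, tor_key = chain_spec[step_i % 6]
        a, b, c = (p for _, p in pos[-3:])
        newp = place_atom(a, b, c, bonds[bond_key], ang, t[tor_key])
        pos.append((name, newp))
        step_i += 1
    residues = []
    for i in range(n_residues):
        atoms = [Atom(name=n, element=n[0], position=p)
                 for n, p in pos[6 * i: 6 * (i + 1)]]
        residues.append(Residue(chain_id="A", seq_number=i + 1, name="BKB",
                                atoms=atoms, is_nucleotide=True))
    return StructureModel(model_index=1, chains={"A": residues},
                          source_id="torsion-chain")


def ground_truth(spec: BuildSpec) -> dict:
    """JSON-serializable ground-truth sidecar for a build."""
    return {
        "n_tetrads": spec.n_tetrads,
        "blocks": list(spec._blocks()),
        "twist_per_step_deg": spec.twist_per_step,
        "rise_per_step_A": spec.rise_per_step,
        "handedness": spec.handedness,
        "n_bulges": len(spec.bulges),
        "bulges": [list(b) for b in spec.bulges],
        "loop_lengths": list(spec.loop_lengths) if spec.loop_lengths else None,
        "sugar_P_deg": spec.sugar_P,
        "sugar_tau_m_deg": spec.sugar_tau_m,
        "chi_deg": spec.resolved_chi,
        "noise_sd_A": spec.noise_sd,
        "seed": spec.seed,
    }
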