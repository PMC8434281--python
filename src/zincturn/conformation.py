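"""Torsion angles, rotamers, hydrogen bonds, turn typing and metal-site geometry.

All angles are reported in degrees on (-180, 180] with the IUPAC sign
convention.  Angle arithmetic on sets of torsions is always circular;
nothing in this module averages angles naively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from zincturn.structure_io import Residue, Structure

__all__ = [
    "TorsionProfile",
    "SiteGeometry",
    "dihedral",
    "bond_angle",
    "torsion_profile",
    "rotamer_class",
    "hbond_i_i4",
    "classify_alpha_turn",
    "site_geometry",
    "lambda_delta",
    "karplus_phi_solutions",
    "IDEAL_TET_ANGLE",
    "ALPHA_RS_TEMPLATE",
]

IDEAL_TET_ANGLE = 109.4712206344907  # arccos(-1/3)

#: Backbone torsion template of the Ialpha(RS) alpha-turn: the circular means
#: (phi_{i+1}, psi_{i+1}, phi_{i+2}, psi_{i+2}, phi_{i+3}, psi_{i+3}) of the
#: dominant cluster of Zn-bound C-X1-X2-H-X3 turns.
ALPHA_RS_TEMPLATE = (-59.0, -37.0, -65.0, -47.0, -79.0, -21.0)


def _wrap(angle: float) -> float:
    """Map an angle in degrees onto (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, on (-180, 180].

    Positive for a clockwise rotation of p4 relative to p1 when viewed
    from p2 toward p3 (IUPAC convention).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < 1e-9:
        raise ValueError("undefined torsion: p2 and p3 coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("undefined torsion: collinear points")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    return _wrap(-np.degrees(np.arctan2(y, x)))


def bond_angle(p1, p2, p3) -> float:
    """Angle at p2 (degrees in [0, 180])."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    c = float(v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class TorsionProfile:
    """Backbone phi/psi of the three central turn residues plus chi1 of the
    coordinating Cys (position i) and His (position i+3)."""

    phi1: float
    psi1: float
    phi2: float
    psi2: float
    phi3: float
    psi3: float
    chi1_cys: float
    chi1_his: float

    @property
    def backbone(self) -> tuple[float, ...]:
        return (self.phi1, self.psi1, self.phi2, self.psi2, self.phi3, self.psi3)

    def as_dict(self) -> dict[str, float]:
        return {
            "phi1": self.phi1, "psi1": self.psi1,
            "phi2": self.phi2, "psi2": self.psi2,
            "phi3": self.phi3, "psi3": self.psi3,
            "chi1_cys": self.chi1_cys, "chi1_his": self.chi1_his,
        }


def _pos(res: Residue, name: str) -> np.ndarray:
    try:
        return res.atom(name).position
    except KeyError as exc:
        raise ValueError(f"missing atom {name} in {res.label}") from exc


def torsion_profile(motif, s: Structure) -> TorsionProfile:
    """Compute the eight torsions of a mined C-X1-X2-H-X3 motif.

    chi1(Cys) is N-CA-CB-SG; chi1(His) is N-CA-CB-CG; phi/psi follow the
    standard backbone definitions over residues i+1 .. i+3.
    """
    residues = motif.window_residues(s)
    phis, psis = [], []
    for k in (1, 2, 3):
        prev_r, r, next_r = residues[k - 1], residues[k], residues[k + 1]
        phis.append(dihedral(_pos(prev_r, "C"), _pos(r, "N"), _pos(r, "CA"), _pos(r, "C")))
        psis.append(dihedral(_pos(r, "N"), _pos(r, "CA"), _pos(r, "C"), _pos(next_r, "N")))
    cys, his = residues[0], residues[3]
    chi1_cys = dihedral(_pos(cys, "N"), _pos(cys, "CA"), _pos(cys, "CB"), _pos(cys, "SG"))
    chi1_his = dihedral(_pos(his, "N"), _pos(his, "CA"), _pos(his, "CB"), _pos(his, "CG"))
    return TorsionProfile(
        phi1=phis[0], psi1=psis[0], phi2=phis[1], psi2=psis[1],
        phi3=phis[2], psi3=psis[2], chi1_cys=chi1_cys, chi1_his=chi1_his,
    )


def rotamer_class(chi1: float) -> str:
    """Classify a chi1 torsion as ``g+``, ``g-`` or ``trans``.

    Bins: g+ on [0, 120), g- on (-120, 0), trans elsewhere on (-180, 180].
    """
    chi1 = _wrap(chi1)
    if 0.0 <= chi1 < 120.0:
        return "g+"
    if -120.0 < chi1 < 0.0:
        return "g-"
    return "trans"


def hbond_i_i4(motif, s: Structure, max_on: float = 3.5) -> bool:
    """Is the turn closed by an i -> i+4 backbone hydrogen bond?

    Criterion: d(O_i...N_{i+4}) <= 3.5 A and angle(C_i=O_i...N_{i+4}) >= 90
    degrees; when residue i+4 is not proline the amide hydrogen is built
    geometrically and angle(N-H...O) >= 120 degrees is also required.
    """
    residues = motif.window_residues(s)
    r_i, r_i3, r_i4 = residues[0], residues[3], residues[4]
    o_i = _pos(r_i, "O")
    c_i = _pos(r_i, "C")
    n_i4 = _pos(r_i4, "N")
    if np.linalg.norm(o_i - n_i4) > max_on:
        return False
    if bond_angle(c_i, o_i, n_i4) < 90.0:
        return False
    if r_i4.name == "PRO":
        return True
    try:
        h = amide_hydrogen(r_i4, prev_residue=r_i3)
    except ValueError:
        return True  # cannot build H; fall back to distance/C=O gate
    return bond_angle(n_i4, h, o_i) >= 120.0


def amide_hydrogen(res: Residue, prev_residue: Residue) -> np.ndarray:
    """Backbone amide H: on N, in the peptide plane, N-H = 1.01 A, anti to
    the carbonyl O of the preceding residue."""
    n = _pos(res, "N")
    ca = _pos(res, "CA")
    c_prev = _pos(prev_residue, "C")
    o_prev = _pos(prev_residue, "O")
    # in-plane direction opposing both substituents of N
    d1 = (ca - n) / np.linalg.norm(ca - n)
    d2 = (c_prev - n) / np.linalg.norm(c_prev - n)
    h_dir = -(d1 + d2)
    norm = np.linalg.norm(h_dir)
    if norm < 1e-6:
        raise ValueError("degenerate amide geometry")
    h = n + 1.01 * h_dir / norm
    # anti to O of the previous residue by construction of trans peptides
    return h


def classify_alpha_turn(
    t: TorsionProfile,
    template: tuple[float, ...] = ALPHA_RS_TEMPLATE,
    tolerance: float = 40.0,
) -> str:
    """Label a torsion profile ``IaRS`` when every backbone torsion lies
    within ``tolerance`` degrees (circularly) of the alpha-turn template,
    else ``other``."""
    for value, ref in zip(t.backbone, template):
        delta = abs(_wrap(value - ref))
        if delta > tolerance:
            return "other"
    return "IaRS"


@dataclass
class SiteGeometry:
    """First-shell geometry of a 4-coordinate metal site."""

    bond_lengths: list[float]
    angles: list[float]
    tetrahedricity: float
    chirality: str = "undefined"


def site_geometry(zinc_position, ligand_positions) -> SiteGeometry:
    """Bond lengths, the six inter-ligand angles, and the tetrahedricity
    score (mean |angle - 109.47|) of a 4-ligand metal site."""
    zn = np.asarray(zinc_position, float)
    lig = [np.asarray(p, float) for p in ligand_positions]
    if len(lig) != 4:
        raise ValueError(f"site_geometry requires exactly 4 ligand atoms, got {len(lig)}")
    bonds = [float(np.linalg.norm(p - zn)) for p in lig]
    angles = []
    for i in range(4):
        for j in range(i + 1, 4):
            angles.append(bond_angle(lig[i], zn, lig[j]))
    tet = float(np.mean([abs(a - IDEAL_TET_ANGLE) for a in angles]))
    return SiteGeometry(bond_lengths=bonds, angles=angles, tetrahedricity=tet)


def tetrahedricity(zinc_position, ligand_positions) -> float:
    """Mean absolute deviation of the six inter-ligand angles from 109.47 deg."""
    return site_geometry(zinc_position, ligand_positions).tetrahedricity


#: Sign -> label calibration for lambda_delta.  Fixed once so that the four
#: pseudo-symmetric Cys3His dimers of the survey (2v0c_A, 4ijd_A, 4ijd_B,
#: 2au3_A) evaluate to Lambda; see docs/methods.md.
LAMBDA_SIGN = +1.0


def lambda_delta(pair_a, pair_b) -> str:
    """Chirality (Lambda/Delta) of a metal centre from two skew ligand-pair axes.

    ``pair_a`` and ``pair_b`` are (S, N) coordinate pairs, one per motif copy.
    With u1 = unit(S1->N1), u2 = unit(S2->N2) and d the unit vector between
    the pair midpoints, the sign of d . (u1 x u2) gives the handedness.
    """
    (s1, n1), (s2, n2) = pair_a, pair_b
    s1, n1, s2, n2 = (np.asarray(p, float) for p in (s1, n1, s2, n2))
    u1 = (n1 - s1) / np.linalg.norm(n1 - s1)
    u2 = (n2 - s2) / np.linalg.norm(n2 - s2)
    cross = np.cross(u1, u2)
    if np.linalg.norm(cross) < 1e-8:
        return "undefined"
    mid1 = (s1 + n1) / 2.0
    mid2 = (s2 + n2) / 2.0
    d = mid2 - mid1
    norm = np.linalg.norm(d)
    if norm < 1e-8:
        return "undefined"
    s = float(d / norm @ cross)
    if abs(s) < 1e-10:
        return "undefined"
    return "Lambda" if s * LAMBDA_SIGN > 0 else "Delta"


def karplus_phi_solutions(
    j_obs: float,
    coeffs: tuple[float, float, float] = (6.4, -1.4, 1.9),
    theta_offset: float = -60.0,
    tol: float = 0.05,
) -> list[float]:
    """All phi in (-180, 180] with A cos^2(theta) + B cos(theta) + C = J,
    theta = phi + offset, found by dense grid + bisection refinement.

    Returns an empty list when ``j_obs`` exceeds the curve's maximum.
    """
    a, b, c = coeffs
    if a <= 0:
        raise ValueError("Karplus coefficient A must be positive")

    def f(phi):
        th = np.radians(phi + theta_offset)
        return a * np.cos(th) ** 2 + b * np.cos(th) + c - j_obs

    grid = np.arange(-180.0, 180.0001, 0.05)
    vals = f(grid)
    roots: list[float] = []
    from scipy.optimize import brentq, minimize_scalar

    for k in range(len(grid) - 1):
        v0, v1 = vals[k], vals[k + 1]
        if v0 == 0.0:
            roots.append(float(grid[k]))
        elif v0 * v1 < 0:
            roots.append(float(brentq(f, grid[k], grid[k + 1], xtol=1e-10)))
    if f(180.0) == 0.0:
        roots.append(180.0)
    # tangent roots (J at a curve extremum): refine local minima of |f|
    absvals = np.abs(vals)
    for k in range(1, len(grid) - 1):
        if absvals[k] <= tol and absvals[k] <= absvals[k - 1] and absvals[k] <= absvals[k + 1]:
            res = minimize_scalar(lambda p: abs(f(p)),
                                  bracket=(grid[k - 1], grid[k], grid[k + 1]))
            if abs(f(res.x)) <= tol:
                roots.append(float(res.x))
    # dedupe near-identical roots, wrap onto (-180, 180]
    out: list[float] = []
    for r in sorted(_wrap(r) for r in roots):
        if not out or abs(r - out[-1]) > 1e-3:
            out.append(r)
    return [r for r in out if abs(f(r)) <= tol]
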