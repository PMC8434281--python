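"""Pseudo-symmetric dimer detection and C2-symmetric dimer reconstruction.

Two zinc-binding turn segments sharing one metal are *pseudo-symmetric*
when their corresponding coordinating residues adopt the same chi1 rotamer
classes.  From a single observed motif, a C2 homodimer is generated by
rotating the whole chain 180 degrees about an axis through the zinc chosen
to make the resulting 4-ligand set {S, N, R(S), R(N)} as tetrahedral as
possible.  From an observed pseudo-symmetric pair, the best-fit transform
between the two segments is projected onto the nearest exact two-fold
rotation.

Hydrogens needed for dipolar-contact reports (His H-epsilon-1 and backbone
amide H) are placed geometrically with standard bond lengths, since crystal
structures carry no hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from zincturn.clustering import kabsch_superpose
from zincturn.conformation import (
    amide_hydrogen,
    dihedral,
    lambda_delta,
    rotamer_class,
    site_geometry,
    tetrahedricity,
)
from zincturn.structure_io import Atom, Residue, Structure

__all__ = [
    "SymmetricPair",
    "DimerModel",
    "find_pseudosymmetric_pairs",
    "idealize_c2",
    "build_c2_dimer_from_motif",
    "place_his_epsilon_hydrogen",
    "dimer_to_structure",
]

CLASH_CUTOFF = 2.4  # heavy-atom inter-chain clash threshold (A)


def _chi1(res: Residue) -> float:
    tip = {"CYS": "SG", "HIS": "CG", "SER": "OG", "THR": "OG1"}.get(res.name, "CG")
    return dihedral(res.atom("N").position, res.atom("CA").position,
                    res.atom("CB").position, res.atom(tip).position)


@dataclass
class SymmetricPair:
    """Two 5-residue Zn-binding segments on one zinc with matching rotamers."""

    structure_id: str
    zinc_position: np.ndarray
    segment_a: list[Residue]
    segment_b: list[Residue]
    rotamer_match: dict[int, bool] = field(default_factory=dict)


@dataclass
class DimerModel:
    """A C2 dimer: chain A residues, their rotated copy, and the shared zinc."""

    chain_a: list[Residue]
    chain_b: list[Residue]
    zinc_position: np.ndarray
    c2_axis: np.ndarray  # unit vector; axis passes through the zinc
    rotation: np.ndarray  # the 3x3 two-fold rotation (about the axis)
    source: str  # observed_pair | idealized_from_motif
    chirality: str = "undefined"
    clash: bool = False
    report: dict[str, float] = field(default_factory=dict)


def _binding_atoms(segment: list[Residue]) -> list[tuple[int, str]]:
    """(position, atom) of the coordinating residues at slots 0 and 3."""
    out = []
    for k in (0, 3):
        res = segment[k]
        if res.name == "CYS":
            out.append((k, "SG"))
        elif res.name == "HIS":
            out.append((k, "ND1" if res.has_atom("ND1") else "NE2"))
        else:
            raise ValueError(f"segment slot {k} is {res.name}, expected CYS or HIS")
    return out


def find_pseudosymmetric_pairs(structure: Structure, sites, segments) -> list[SymmetricPair]:
    """Pair up 5-residue Zn-binding segments that share a zinc and whose
    coordinating residues (slots 0 and 3) have matching chi1 rotamer classes.

    ``segments`` is a list of residue 5-windows (C-X-X-[C/H]-X) annotated by
    the caller; motif windows from mining qualify directly.
    """
    pairs = []
    for si, site in enumerate(sites):
        on_site = []
        for seg in segments:
            try:
                atoms = _binding_atoms(seg)
            except ValueError:
                continue
            dists = [
                np.linalg.norm(seg[k].atom(a).position - site.zinc_position)
                for k, a in atoms
            ]
            if all(d <= 3.0 for d in dists):
                on_site.append(seg)
        for i in range(len(on_site)):
            for j in range(i + 1, len(on_site)):
                a, b = on_site[i], on_site[j]
                match = {}
                for k in (0, 3):
                    ra = rotamer_class(_chi1(a[k]))
                    rb = rotamer_class(_chi1(b[k]))
                    match[k] = ra == rb
                if all(match.values()):
                    pairs.append(SymmetricPair(
                        structure_id=structure.id,
                        zinc_position=site.zinc_position,
                        segment_a=a, segment_b=b, rotamer_match=match,
                    ))
    return pairs


def _segment_fit_coordinates(segment: list[Residue]) -> np.ndarray:
    """Superposition atom set: N, CA, C, CB of all five residues plus the
    coordinating side-chain atoms of slots 0 and 3."""
    coords = []
    for res in segment:
        for name in ("N", "CA", "C"):
            coords.append(res.atom(name).position)
        if res.has_atom("CB"):
            coords.append(res.atom("CB").position)
    for k, a in _binding_atoms(segment):
        coords.append(segment[k].atom(a).position)
    return np.array(coords)


def _axis_angle_from_rotation(rot: np.ndarray) -> tuple[np.ndarray, float]:
    from scipy.spatial.transform import Rotation

    r = Rotation.from_matrix(rot)
    vec = r.as_rotvec()
    angle = np.linalg.norm(vec)
    axis = vec / angle if angle > 1e-12 else np.array([0.0, 0.0, 1.0])
    return axis, np.degrees(angle)


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (normalized) axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    kx, ky, kz = axis
    k = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _copy_residues(residues: list[Residue], rot: np.ndarray, center: np.ndarray,
                   chain_id: str) -> list[Residue]:
    out = []
    for res in residues:
        atoms = [
            Atom(a.name, a.element, rot @ (a.position - center) + center, a.occupancy)
            for a in res.atoms
        ]
        out.append(Residue(name=res.name, chain_id=chain_id,
                           seq_number=res.seq_number,
                           insertion_code=res.insertion_code, atoms=atoms))
    return out


def place_his_epsilon_hydrogen(his: Residue) -> np.ndarray:
    """H-epsilon-1 on CE1: in the ring plane, along the external bisector of
    Nd1-Ce1-Ne2, C-H = 1.08 A."""
    for name in ("ND1", "CE1", "NE2"):
        if not his.has_atom(name):
            raise ValueError(f"His {his.label} lacks ring atom {name}")
    nd1 = his.atom("ND1").position
    ce1 = his.atom("CE1").position
    ne2 = his.atom("NE2").position
    d1 = (nd1 - ce1) / np.linalg.norm(nd1 - ce1)
    d2 = (ne2 - ce1) / np.linalg.norm(ne2 - ce1)
    h_dir = -(d1 + d2)
    h_dir /= np.linalg.norm(h_dir)
    return ce1 + 1.08 * h_dir


def _his_slot(segment: list[Residue]) -> Residue | None:
    res = segment[3]
    return res if res.name == "HIS" else None


def _distance_report(chain_a: list[Residue], chain_b: list[Residue],
                     zinc: np.ndarray) -> dict[str, float]:
    """Named distances for the NOE comparison: inter-chain His He1 -> amide H
    of the partner His, the intra-residue He1/HN distance, and ligand-zinc
    bond lengths."""
    rep: dict[str, float] = {}
    his_a, his_b = _his_slot(chain_a), _his_slot(chain_b)
    if his_a is not None and his_b is not None:
        he1_a = place_his_epsilon_hydrogen(his_a)
        he1_b = place_his_epsilon_hydrogen(his_b)
        hn_a = amide_hydrogen(his_a, prev_residue=chain_a[2])
        hn_b = amide_hydrogen(his_b, prev_residue=chain_b[2])
        rep["his_he1_a_to_hn_b"] = float(np.linalg.norm(he1_a - hn_b))
        rep["his_he1_b_to_hn_a"] = float(np.linalg.norm(he1_b - hn_a))
        rep["intra_he1_hn"] = float(np.linalg.norm(he1_a - hn_a))
    for tag, seg in (("a", chain_a), ("b", chain_b)):
        for k, name in _binding_atoms(seg):
            rep[f"zn_{seg[k].name.lower()}{seg[k].seq_number}_{name.lower()}_{tag}"] = float(
                np.linalg.norm(seg[k].atom(name).position - zinc)
            )
    return rep


def _chirality_of(chain_a, chain_b, zinc) -> str:
    (ka, aa), (kb, ab) = _binding_atoms(chain_a)
    pair_a = (chain_a[ka].atom(aa).position, chain_a[kb].atom(ab).position)
    (ka2, aa2), (kb2, ab2) = _binding_atoms(chain_b)
    pair_b = (chain_b[ka2].atom(aa2).position, chain_b[kb2].atom(ab2).position)
    return lambda_delta(pair_a, pair_b)


def _clash_check(chain_a, chain_b) -> bool:
    pa = np.array([a.position for r in chain_a for a in r.atoms])
    pb = np.array([a.position for r in chain_b for a in r.atoms])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return bool((d < CLASH_CUTOFF).any())


def idealize_c2(pair: SymmetricPair, max_rmsd: float = 2.5) -> DimerModel:
    """Idealize an observed pseudo-symmetric pair into an exact C2 dimer.

    The best-fit rigid transform mapping segment B onto segment A is
    computed on backbone + CB + coordinating atoms; its rotation is
    projected to the nearest exact 180-degree rotation (same axis), the
    axis is translated through the zinc, and chain B is replaced by the
    rotated copy of chain A.
    """
    xa = _segment_fit_coordinates(pair.segment_a)
    xb = _segment_fit_coordinates(pair.segment_b)
    if xa.shape != xb.shape:
        raise ValueError("segments are not superposable (atom sets differ)")
    rot, _, rmsd = kabsch_superpose(xa, xb)  # maps B onto A
    if rmsd > max_rmsd:
        raise ValueError(
            f"pair is not pseudo-symmetric: superposition RMSD {rmsd:.2f} A"
        )
    axis, _ = _axis_angle_from_rotation(rot)
    r180 = _rotation_about_axis(axis, 180.0)
    zinc = pair.zinc_position
    chain_b = _copy_residues(pair.segment_a, r180, zinc, chain_id="B")
    chain_a = [  # relabel originals as chain A without moving them
        Residue(name=r.name, chain_id="A", seq_number=r.seq_number,
                insertion_code=r.insertion_code, atoms=r.atoms)
        for r in pair.segment_a
    ]
    model = DimerModel(
        chain_a=chain_a, chain_b=chain_b, zinc_position=zinc,
        c2_axis=axis, rotation=r180, source="observed_pair",
    )
    model.chirality = _chirality_of(chain_a, chain_b, zinc)
    model.clash = _clash_check(chain_a, chain_b)
    model.report = _distance_report(chain_a, chain_b, zinc)
    return model


def _min_interchain_distance(chain_a, chain_b) -> float:
    pa = np.array([a.position for r in chain_a for a in r.atoms])
    pb = np.array([a.position for r in chain_b for a in r.atoms])
    return float(np.min(np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)))


def enumerate_c2_axes(motif, s: Structure, max_tetrahedricity: float = 30.0):
    """Distinct two-fold axes through the zinc whose symmetric completion
    {S, N, R(S), R(N)} is near-tetrahedral.

    A near-tetrahedral ligand pair admits several such axes (typically four,
    two per handedness); all are returned with their tetrahedricity scores.
    """
    chain_a = motif.window_residues(s)
    zinc = motif.site.zinc_position
    sg = chain_a[0].atom("SG").position
    nn = chain_a[3].atom(motif.his_binding_atom).position

    def score(x):
        theta, phi = x
        axis = np.array([
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
            np.cos(theta),
        ])
        r = _rotation_about_axis(axis, 180.0)
        lig = [sg, nn, r @ (sg - zinc) + zinc, r @ (nn - zinc) + zinc]
        return tetrahedricity(zinc, lig)

    axes: list[tuple[np.ndarray, float]] = []
    for th0 in np.arange(0.15, np.pi, 0.35):
        for ph0 in np.arange(0.0, np.pi, 0.35):  # an axis is a line: half sphere
            res = minimize(score, x0=[th0, ph0], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 1500})
            if res.fun > max_tetrahedricity:
                continue
            ax = np.array([
                np.sin(res.x[0]) * np.cos(res.x[1]),
                np.sin(res.x[0]) * np.sin(res.x[1]),
                np.cos(res.x[0]),
            ])
            if any(min(np.linalg.norm(ax - a), np.linalg.norm(ax + a)) < 0.05
                   for a, _ in axes):
                continue
            axes.append((ax, float(res.fun)))
    return axes


def build_c2_dimer_from_motif(
    motif,
    s: Structure,
    prefer_chirality: str | None = None,
    max_tetrahedricity: float = 30.0,
) -> DimerModel:
    """Generate a C2 homodimer from one motif by a two-fold rotation about an
    axis through the zinc that makes {S, N, R(S), R(N)} near-tetrahedral.

    The tetrahedral completion is degenerate (several axes, both
    handednesses); the axis is selected by (1) the requested chirality when
    ``prefer_chirality`` is "Lambda" or "Delta" -- natural CysxHisy dimers
    are universally Lambda -- then (2) the least inter-chain crowding, then
    (3) the lowest tetrahedricity.  Chain A atoms are never moved; ligand-
    zinc distances are preserved exactly in the copy.
    """
    axes = enumerate_c2_axes(motif, s, max_tetrahedricity)
    if not axes:
        raise ValueError("no two-fold axis yields a near-tetrahedral site")
    chain_a_src = motif.window_residues(s)
    zinc = motif.site.zinc_position
    candidates = []
    for ax, tet in axes:
        rot = _rotation_about_axis(ax, 180.0)
        chain_b = _copy_residues(chain_a_src, rot, zinc, chain_id="B")
        chain_a = [
            Residue(name=r.name, chain_id="A", seq_number=r.seq_number,
                    insertion_code=r.insertion_code, atoms=r.atoms)
            for r in chain_a_src
        ]
        chir = _chirality_of(chain_a, chain_b, zinc)
        dmin = _min_interchain_distance(chain_a, chain_b)
        candidates.append((ax, tet, rot, chain_a, chain_b, chir, dmin))
    pool = candidates
    if prefer_chirality is not None:
        matching = [c for c in candidates if c[5] == prefer_chirality]
        if matching:
            pool = matching
    ax, tet, rot, chain_a, chain_b, chir, dmin = max(
        pool, key=lambda c: (round(c[6], 3), -c[1])
    )
    model = DimerModel(
        chain_a=chain_a, chain_b=chain_b, zinc_position=zinc,
        c2_axis=ax, rotation=rot, source="idealized_from_motif",
    )
    model.chirality = chir
    model.clash = dmin < CLASH_CUTOFF
    model.report = _distance_report(chain_a, chain_b, zinc)
    model.report["tetrahedricity"] = tet
    model.report["min_interchain_distance"] = dmin
    sg = chain_a[0].atom("SG").position
    nn = chain_a[3].atom(motif.his_binding_atom).position
    lig = [sg, nn, rot @ (sg - zinc) + zinc, rot @ (nn - zinc) + zinc]
    geom = site_geometry(zinc, lig)
    model.report["site_angles_mean"] = float(np.mean(geom.angles))
    return model


def dimer_to_structure(model: DimerModel, structure_id: str = "dimer") -> Structure:
    """Pack a dimer model into a two-chain Structure with a HETATM zinc."""
    st = Structure(id=structure_id)
    st.chains["A"] = model.chain_a
    st.chains["B"] = model.chain_b
    st.chains["Z"] = [Residue(name="ZN", chain_id="Z", seq_number=1,
                              atoms=[Atom("ZN", "ZN", model.zinc_position)])]
    return st
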