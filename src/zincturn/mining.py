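"""Detection of Zn-coordinated C-X1-X2-H-X3 motifs and the alpha-turn filters.

A motif is a five-residue window with Cys at the first and His at the fourth
position, consecutive in author numbering on one chain, in which the Cys
S-gamma and one His ring nitrogen coordinate the same zinc ion.  Motifs are
kept when the Calpha(i)-Calpha(i+4) distance is at most 7 A (the alpha-turn
criterion) and can be deduplicated to one representative per distinct
five-residue sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from zincturn.structure_io import Residue, Structure

log = logging.getLogger(__name__)

__all__ = [
    "ZincSite",
    "ZincMotif",
    "find_zinc_sites",
    "find_cxxhx_motifs",
    "alpha_turn_filter",
    "deduplicate_sequences",
    "mine_structure",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "AIB": "U",
}

#: default heavy-atom Zn coordination cutoff (A); generously covers the
#: observed S-Zn (2.34 +/- 0.07 A) and N-Zn (2.1 +/- 0.1 A) bond lengths.
DEFAULT_COORDINATION_CUTOFF = 3.0


def _ligand_kind(res: Residue, atom_name: str) -> str:
    if res.name == "CYS" and atom_name == "SG":
        return "cys_sg"
    if res.name == "HIS" and atom_name in ("ND1", "NE2"):
        return "his_n"
    if res.name in ("ASP", "GLU") and atom_name in ("OD1", "OD2", "OE1", "OE2"):
        return "carboxylate_o"
    if res.name in ("HOH", "WAT") and atom_name == "O":
        return "water_o"
    if atom_name == "O":
        return "backbone_o"
    return "other"


@dataclass
class ZincSite:
    """One zinc ion with its inventory of coordinating atoms."""

    structure_id: str
    chain_id: str
    seq_number: int
    zinc_position: np.ndarray
    #: (residue, atom name, distance A, ligand kind), sorted by distance
    ligands: list[tuple[Residue, str, float, str]] = field(default_factory=list)

    def ligand_atoms(self, kind: str | None = None):
        return [l for l in self.ligands if kind is None or l[3] == kind]


@dataclass
class ZincMotif:
    """A C-X1-X2-H-X3 window whose Cys and His coordinate one zinc."""

    structure_id: str
    chain_id: str
    start: int  # author seq number of the Cys (position i)
    sequence: str  # 5 one-letter codes, C at 0 and H at 3
    site: ZincSite
    ca_distance_i_i4: float
    his_binding_atom: str  # ND1 or NE2
    s_zn_distance: float
    n_zn_distance: float
    hbond_i_i4: bool | None = None
    ambiguous_tautomer: bool = False

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.structure_id, self.chain_id, self.start)

    def window_residues(self, s: Structure) -> list[Residue]:
        """The five residues i..i+4 from their parent structure."""
        chain = s.chains[self.chain_id]
        by_num = {r.seq_number: r for r in chain if not r.insertion_code}
        try:
            return [by_num[self.start + k] for k in range(5)]
        except KeyError as exc:
            raise ValueError(
                f"residue window {self.start}..{self.start + 4} incomplete "
                f"in {self.structure_id} chain {self.chain_id}"
            ) from exc


def find_zinc_sites(
    s: Structure, cutoff: float = DEFAULT_COORDINATION_CUTOFF
) -> list[ZincSite]:
    """Inventory every Zn ion in ``s`` with its ligands within ``cutoff`` A.

    Sites without any ligand inside the cutoff are dropped.
    """
    if not 1.5 < cutoff < 3.5:
        raise ValueError("coordination cutoff must lie in (1.5, 3.5) A")
    zincs = []
    for res in s.residues():
        if res.name == "ZN" or any(a.element.upper() == "ZN" for a in res.atoms):
            for a in res.atoms:
                if a.element.upper() == "ZN" or a.name == "ZN":
                    zincs.append((res, a))
    sites = []
    for zres, zatom in zincs:
        site = ZincSite(
            structure_id=s.id,
            chain_id=zres.chain_id,
            seq_number=zres.seq_number,
            zinc_position=zatom.position,
        )
        for res in s.residues():
            if res is zres:
                continue
            for a in res.atoms:
                if a.element.upper() in ("C", "H", "ZN"):
                    continue  # carbon/metal contacts are not dative ligands
                d = float(np.linalg.norm(a.position - zatom.position))
                if d <= cutoff:
                    site.ligands.append((res, a.name, d, _ligand_kind(res, a.name)))
        site.ligands.sort(key=lambda l: l[2])
        if site.ligands:
            sites.append(site)
    return sites


def find_cxxhx_motifs(
    s: Structure,
    sites: list[ZincSite] | None = None,
    cutoff: float = DEFAULT_COORDINATION_CUTOFF,
    chains: list[str] | None = None,
) -> list[ZincMotif]:
    """Emit every C-X1-X2-H-X3 window whose Cys S-gamma and His ring N bind
    the same zinc.

    Residues must be consecutive in author numbering on one chain with no
    insertion codes inside the window.  The His binding atom is the ring
    nitrogen closer to the zinc; near-ties (< 0.1 A) are flagged ambiguous.
    """
    if sites is None:
        sites = find_zinc_sites(s, cutoff)
    motifs: list[ZincMotif] = []
    for chain_id, residues in s.chains.items():
        if chains is not None and chain_id not in chains:
            continue
        clean = [r for r in residues if not r.insertion_code]
        by_num = {r.seq_number: r for r in clean}
        skipped_insertion = {r.seq_number for r in residues if r.insertion_code}
        for res in clean:
            if res.name != "CYS":
                continue
            i = res.seq_number
            window = [by_num.get(i + k) for k in range(5)]
            if any(w is None for w in window):
                continue
            if any((i + k) in skipped_insertion for k in range(5)):
                log.warning(
                    "skipping window at %s %s%d: insertion codes inside window",
                    s.id, chain_id, i,
                )
                continue
            if window[3].name != "HIS":
                continue
            cys, his = window[0], window[3]
            if not cys.has_atom("SG"):
                continue
            sg = cys.atom("SG").position
            for site in sites:
                d_s = float(np.linalg.norm(sg - site.zinc_position))
                if d_s > cutoff:
                    continue
                dn = {}
                for nname in ("ND1", "NE2"):
                    if his.has_atom(nname):
                        dn[nname] = float(
                            np.linalg.norm(his.atom(nname).position - site.zinc_position)
                        )
                bound = {k: v for k, v in dn.items() if v <= cutoff}
                if not bound:
                    continue
                his_atom = min(bound, key=bound.get)
                ambiguous = len(dn) == 2 and abs(dn["ND1"] - dn["NE2"]) < 0.1
                try:
                    ca_i = window[0].atom("CA").position
                    ca_i4 = window[4].atom("CA").position
                except KeyError:
                    log.warning("missing CA in window at %s %s%d", s.id, chain_id, i)
                    continue
                seq = "".join(THREE_TO_ONE.get(w.name, "X") for w in window)
                motifs.append(
                    ZincMotif(
                        structure_id=s.id,
                        chain_id=chain_id,
                        start=i,
                        sequence=seq,
                        site=site,
                        ca_distance_i_i4=float(np.linalg.norm(ca_i - ca_i4)),
                        his_binding_atom=his_atom,
                        s_zn_distance=d_s,
                        n_zn_distance=bound[his_atom],
                        ambiguous_tautomer=ambiguous,
                    )
                )
                break  # one zinc per motif: nearest-qualifying site wins
    return motifs


def alpha_turn_filter(m: ZincMotif, max_ca: float = 7.0) -> bool:
    """True iff the Calpha(i)-Calpha(i+4) distance is <= ``max_ca`` A
    (boundary inclusive)."""
    if m.ca_distance_i_i4 <= 0:
        raise ValueError(f"invalid Calpha distance for motif {m.key}")
    return m.ca_distance_i_i4 <= max_ca


def deduplicate_sequences(motifs: list[ZincMotif]) -> list[ZincMotif]:
    """One representative per distinct five-residue sequence.

    The representative is the motif with the lexicographically smallest
    (structure_id, chain_id, start) key.
    """
    best: dict[str, ZincMotif] = {}
    for m in motifs:
        cur = best.get(m.sequence)
        if cur is None or m.key < cur.key:
            best[m.sequence] = m
    return sorted(best.values(), key=lambda m: m.key)


def mine_structure(
    s: Structure,
    cutoff: float = DEFAULT_COORDINATION_CUTOFF,
    max_ca: float = 7.0,
    chains: list[str] | None = None,
) -> list[ZincMotif]:
    """find_zinc_sites + find_cxxhx_motifs + alpha-turn filter in one call."""
    sites = find_zinc_sites(s, cutoff)
    motifs = find_cxxhx_motifs(s, sites, cutoff=cutoff, chains=chains)
    return [m for m in motifs if alpha_turn_filter(m, max_ca)]
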