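"""Reference summary statistics of the Zn-bound C-X1-X2-H-X3 alpha-turn survey.

These tables summarize a published retrostructural survey of the Protein
Data Bank (X-ray entries at 2.4 A resolution or better, 50% sequence
identity culling, snapshot of September 2020): 129 Zn-coordinated
C-X1-X2-H-X3 alpha-turn motifs, 44 of them with unique sequences, grouped
into four conformational clusters plus three outliers.  They serve as
generator inputs and as ground truth for bookkeeping checks; they are not
recomputable without the original PDB snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CLUSTER_TORSIONS",
    "CLUSTER_SIZES",
    "TOTAL_MOTIFS",
    "UNIQUE_SEQUENCES",
    "OCCURRENCES",
    "DIMER_ENTRIES",
    "METP3_SEQUENCE",
    "BINDING",
    "SG_ZN_DISTANCE",
    "ND1_ZN_DISTANCE",
    "INTRA_HE1_HN_DISTANCE",
]


@dataclass(frozen=True)
class ClusterRow:
    """Circular-mean torsions of one cluster (sizes in the survey's set)."""

    size: int
    backbone: tuple[float, ...]  # phi1, psi1, phi2, psi2, phi3, psi3
    chi1_cys: float
    chi1_his: float
    kind: str  # cluster | outlier


#: four clusters + three outliers, ordered as in the survey
CLUSTER_TORSIONS: dict[int, ClusterRow] = {
    1: ClusterRow(86, (-59, -37, -65, -47, -79, -21), 72, -75, "cluster"),
    2: ClusterRow(16, (-63, -26, -91, -34, -116, 10), 177, -61, "cluster"),
    3: ClusterRow(13, (-63, -31, -79, -41, -116, -6), 67, -53, "cluster"),
    4: ClusterRow(11, (-62, -40, -83, -33, -119, 78), -178, -51, "cluster"),
    5: ClusterRow(1, (-86, -3, -110, -24, -135, 158), -175, 93, "outlier"),
    6: ClusterRow(1, (-58, -48, -59, -54, -63, -45), -177, -81, "outlier"),
    7: ClusterRow(1, (-121, -37, -57, -30, -115, 18), 178, -50, "outlier"),
}

CLUSTER_SIZES = tuple(row.size for row in CLUSTER_TORSIONS.values())
TOTAL_MOTIFS = 129
UNIQUE_SEQUENCES = 44

#: occurrences of each standard residue at X1/X2/X3 over the 44 unique
#: sequences of the survey's non-redundant set
OCCURRENCES: dict[str, tuple[int, int, int]] = {
    "A": (3, 3, 1), "C": (0, 0, 0), "D": (1, 1, 0), "E": (6, 6, 8),
    "F": (0, 1, 1), "G": (0, 0, 7), "H": (1, 4, 3), "I": (1, 3, 0),
    "K": (5, 2, 4), "L": (2, 0, 2), "M": (0, 0, 0), "N": (2, 3, 2),
    "P": (8, 3, 3), "Q": (4, 0, 0), "R": (6, 3, 1), "S": (0, 3, 2),
    "T": (3, 3, 3), "V": (1, 4, 3), "W": (1, 1, 0), "Y": (0, 4, 4),
}


@dataclass(frozen=True)
class DimerEntry:
    """One observed pseudo-symmetric Cys3His dimer: the C-X1-X2-H-X3 motif
    segment with its printed chi1 values and parent cluster."""

    entry: str
    cluster: int
    sequence: str  # the CXXHX segment
    start: int  # author numbering of the Cys
    chi1_cys: float
    chi1_his: float
    partner_sequence: str  # the companion CXXCX segment
    partner_chi1: tuple[float, float]


DIMER_ENTRIES: list[DimerEntry] = [
    DimerEntry("2v0c_A", 4, "CWRHE", 176, 174, -59, "CPKCQ", (177, -65)),
    DimerEntry("4ijd_A", 2, "CAAHG", 216, 174, -62, "CEMCQ", (179, -61)),
    DimerEntry("4ijd_B", 2, "CAAHG", 216, -176, -56, "CEMCQ", (177, -57)),
    DimerEntry("2au3_A", 5, "CPFHP", 35, -175, 93, "CFGCG", (-172, 67)),
]

def unique_sequence_fixture() -> list[str]:
    """44 distinct C-X1-X2-H-X3 sequences whose per-position residue counts
    match :data:`OCCURRENCES` exactly.

    The survey's actual sequence list is not reproduced here; this fixture
    realizes the same occurrence table (each column is a permutation of the
    counted residues), which is all the occurrence/propensity stage sees.
    """
    def column(idx: int) -> list[str]:
        return [aa for aa, counts in sorted(OCCURRENCES.items())
                for _ in range(counts[idx])]

    import random

    x1, x2, x3 = column(0), column(1), column(2)
    n = len(x1)
    rng = random.Random(44)
    for _ in range(10000):
        seqs = [f"C{a}{b}H{c}" for a, b, c in zip(x1, x2, x3)]
        if len(set(seqs)) == n:
            return seqs
        rng.shuffle(x2)
        rng.shuffle(x3)
    raise RuntimeError("could not arrange distinct sequences")


#: the undecapeptide whose homodimer houses the Cys2His2 site
METP3_SEQUENCE = "Ac-CTGHSGN{Aib}SEI-NH2"
METP3_AVERAGE_MASS = 1130.4  # amu, calculated value reported for the peptide


@dataclass(frozen=True)
class BindingConstants:
    """Experimental binding parameters (molar units; K_D on the
    K_D = Mf^(1/n) Pf / C^(1/n) scale with n = 2)."""

    k_d_co: float = 85e-6
    k_d_zn: float = 5.6e-6
    k_d_cd: float = 5.0e-6
    n: int = 2
    p_total_direct: float = 8.0e-4
    p_total_competition: float = 1.0e-3
    co_excess_equivalents: float = 3.5
    ph_midpoint: float = 7.1

    @property
    def k_ex_zn(self) -> float:
        return (self.k_d_co / self.k_d_zn) ** 2

    @property
    def k_ex_cd(self) -> float:
        return (self.k_d_co / self.k_d_cd) ** 2


BINDING = BindingConstants()

SG_ZN_DISTANCE = 2.34  # A, survey mean (+/- 0.07)
ND1_ZN_DISTANCE = 2.1  # A, survey mean (+/- 0.1)
INTRA_HE1_HN_DISTANCE = 6.0  # A, intra-residue His He1/HN in both dimers
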