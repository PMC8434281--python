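"""Molecular masses of peptides with noncanonical residues and terminal caps.

Masses are assembled from per-residue elemental formulas (residue = amino
acid minus water) plus one water, an optional N-terminal acetyl cap and an
optional C-terminal amide.  Atomic weights follow the IUPAC 2021 standard
table (average) and the dominant-isotope masses (monoisotopic).

Sequence strings use one-letter codes with noncanonical residues in braces,
e.g. ``"Ac-CTGHSGN{Aib}SEI-NH2"``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = ["PeptideSequence", "average_mass", "monoisotopic_mass", "parse_sequence"]

AVERAGE_WEIGHTS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}
MONO_WEIGHTS = {
    "C": 12.0, "H": 1.00782503207, "N": 14.0030740048,
    "O": 15.9949146196, "S": 31.97207100,
}

#: residue (= amino acid - H2O) elemental formulas
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
    # 2-aminoisobutyric acid (Aib)
    "AIB": {"C": 4, "H": 7, "N": 1, "O": 1},
}


@dataclass
class PeptideSequence:
    residues: list[str]
    n_cap: str = "free"  # free | acetyl
    c_cap: str = "free_acid"  # free_acid | amide

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty peptide sequence")
        for code in self.residues:
            if code.upper() not in RESIDUE_FORMULAS:
                raise ValueError(f"unknown residue code {code!r}")
        if self.n_cap not in ("free", "acetyl") or self.c_cap not in ("free_acid", "amide"):
            raise ValueError("unknown terminal cap")

    def formula(self) -> Counter:
        counts: Counter = Counter()
        for code in self.residues:
            counts.update(RESIDUE_FORMULAS[code.upper()])
        counts.update({"H": 2, "O": 1})  # one water closes the chain
        if self.n_cap == "acetyl":
            counts.update({"C": 2, "H": 2, "O": 1})
        if self.c_cap == "amide":
            counts.update({"N": 1, "H": 1})
            counts["O"] -= 1
        return counts


def parse_sequence(text: str) -> PeptideSequence:
    """Parse ``"Ac-CTGHSGN{Aib}SEI-NH2"`` style sequence strings."""
    s = text.strip()
    n_cap, c_cap = "free", "free_acid"
    if s.lower().startswith("ac-"):
        n_cap = "acetyl"
        s = s[3:]
    for suffix in ("-NH2", "-nh2", "-CONH2"):
        if s.endswith(suffix):
            c_cap = "amide"
            s = s[: -len(suffix)]
            break
    if s.endswith("-OH"):
        s = s[:-3]
    residues: list[str] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "{":
            j = s.index("}", i)
            residues.append(s[i + 1 : j].upper())
            i = j + 1
        elif ch.isalpha():
            residues.append(ch.upper())
            i += 1
        else:
            raise ValueError(f"cannot parse sequence at {s[i:]!r}")
    return PeptideSequence(residues=residues, n_cap=n_cap, c_cap=c_cap)


def _mass(p: PeptideSequence | str, weights: dict[str, float]) -> float:
    if isinstance(p, str):
        p = parse_sequence(p)
    return sum(weights[el] * n for el, n in p.formula().items())


def average_mass(p: PeptideSequence | str) -> float:
    """Average molecular mass in amu."""
    return _mass(p, AVERAGE_WEIGHTS)


def monoisotopic_mass(p: PeptideSequence | str) -> float:
    """Monoisotopic molecular mass in amu."""
    return _mass(p, MONO_WEIGHTS)
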