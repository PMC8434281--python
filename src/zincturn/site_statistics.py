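"""Occurrence and propensity tables for the X1, X2, X3 motif positions.

Propensity(r, pos) = observed frequency of residue r at the position divided
by its background frequency in a reference amino-acid composition.  The
bundled default background is the UniProtKB/Swiss-Prot average composition;
any other composition can be supplied, and the background source label is
carried in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "STANDARD_AA",
    "BackgroundComposition",
    "SWISSPROT_BACKGROUND",
    "OccurrenceTable",
    "occurrence_table",
    "propensity_table",
]

STANDARD_AA = list("ACDEFGHIKLMNPQRSTVWY")
POSITIONS = ("X1", "X2", "X3")


@dataclass
class BackgroundComposition:
    frequencies: dict[str, float]
    source: str

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-6:
            self.frequencies = {k: v / total for k, v in self.frequencies.items()}
        if any(v <= 0 for v in self.frequencies.values()):
            raise ValueError("background frequencies must all be positive")

    def __call__(self, residue: str) -> float:
        try:
            return self.frequencies[residue]
        except KeyError as exc:
            raise ValueError(f"background lacks residue {residue!r}") from exc


#: UniProtKB/Swiss-Prot average amino-acid composition (percent, 2021 era).
SWISSPROT_BACKGROUND = BackgroundComposition(
    frequencies={
        "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0138,
        "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
        "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
        "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0685,
    },
    source="uniprotkb-swissprot-average",
)


@dataclass
class OccurrenceTable:
    """Counts of each standard residue at positions X1, X2, X3."""

    counts: pd.DataFrame  # index: residues, columns: X1 X2 X3
    total_sequences: int
    other: dict[str, int] = field(default_factory=dict)

    def count(self, residue: str, position: str) -> int:
        return int(self.counts.at[residue, position])


def occurrence_table(unique_motifs) -> OccurrenceTable:
    """Count residues at X1, X2, X3 over a deduplicated motif set.

    ``unique_motifs`` may be ZincMotif objects or bare 5-letter sequences.
    Nonstandard residues are tallied under ``other`` per position.
    """
    counts = pd.DataFrame(0, index=STANDARD_AA, columns=list(POSITIONS))
    other: dict[str, int] = {p: 0 for p in POSITIONS}
    n = 0
    for m in unique_motifs:
        seq = m if isinstance(m, str) else m.sequence
        if len(seq) != 5:
            raise ValueError(f"motif sequence {seq!r} is not 5 residues")
        n += 1
        for pos, idx in zip(POSITIONS, (1, 2, 4)):
            aa = seq[idx]
            if aa in counts.index:
                counts.at[aa, pos] += 1
            else:
                other[pos] += 1
    return OccurrenceTable(counts=counts, total_sequences=n, other=other)


def propensity_table(
    occ: OccurrenceTable, bg: BackgroundComposition = SWISSPROT_BACKGROUND
) -> pd.DataFrame:
    """Propensities (count/total)/background per residue and position.

    Zero counts yield propensity 0.  The frame carries the background source
    in ``df.attrs['background']``.
    """
    if occ.total_sequences <= 0:
        raise ValueError("occurrence table is empty")
    out = occ.counts.astype(float).copy()
    for aa in out.index:
        f_bg = bg(aa)
        out.loc[aa] = (occ.counts.loc[aa] / occ.total_sequences) / f_bg
    out.attrs["background"] = bg.source
    out.attrs["total_sequences"] = occ.total_sequences
    return out
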