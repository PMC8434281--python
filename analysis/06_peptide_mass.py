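#!/usr/bin/env python
"""Molecular mass of the undecapeptide.

Computes the average and monoisotopic masses of the acetylated, C-amidated
undecapeptide Ac-CTGHSGN{Aib}SEI-NH2 (Aib = 2-aminoisobutyric acid) from
per-residue elemental formulas.
"""

import sys

from zincturn import refdata
from zincturn.peptide_chem import average_mass, monoisotopic_mass, parse_sequence


def main() -> int:
    seq = refdata.METP3_SEQUENCE
    p = parse_sequence(seq)
    formula = dict(sorted(p.formula().items()))
    avg = average_mass(p)
    mono = monoisotopic_mass(p)
    print(f"sequence:      {seq} ({len(p.residues)} residues)")
    print(f"formula:       {''.join(f'{el}{n}' for el, n in formula.items())}")
    print(f"average:       {avg:.1f} amu  (reported calculated: "
          f"{refdata.METP3_AVERAGE_MASS})")
    print(f"monoisotopic:  {mono:.3f} amu")
    return 0


if __name__ == "__main__":
    sys.exit(main())
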