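#!/usr/bin/env python
"""Occurrence and propensity tables of the non-redundant motif set.

Counts residues at the X1/X2/X3 positions over the 44 unique C-X1-X2-H-X3
sequences (realized from the survey's occurrence table) and converts them
to propensities against the Swiss-Prot average composition.  Prints the
hallmark preferences: Pro enriched at X1, Gly forbidden at X1/X2 but common
at X3.
"""

import sys
from pathlib import Path

import pandas as pd

from zincturn import refdata
from zincturn.site_statistics import occurrence_table, propensity_table

RESULTS = Path("results")


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    seqs = refdata.unique_sequence_fixture()
    occ = occurrence_table(seqs)
    prop = propensity_table(occ)

    merged = pd.DataFrame({
        **{f"occ_{p}": occ.counts[p] for p in ("X1", "X2", "X3")},
        **{f"prop_{p}": prop[p].round(2) for p in ("X1", "X2", "X3")},
    })
    merged.index.name = "residue"
    out = RESULTS / "propensities.tsv"
    merged.to_csv(out, sep="\t")

    print(f"{occ.total_sequences} unique sequences; column sums "
          f"{[int(occ.counts[p].sum()) for p in ('X1', 'X2', 'X3')]}")
    print(f"Pro at X1: {occ.count('P', 'X1')} occurrences, "
          f"propensity {prop.at['P', 'X1']:.2f} (highest at X1)")
    print(f"Gly: X1 {occ.count('G', 'X1')}, X2 {occ.count('G', 'X2')}, "
          f"X3 {occ.count('G', 'X3')} occurrences "
          f"(absent before the turn corner, favored at the C-cap)")
    print(f"background: {prop.attrs['background']}")
    print(f"table -> {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
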