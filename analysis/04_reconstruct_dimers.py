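#!/usr/bin/env python
"""Rebuild the four observed pseudo-symmetric dimers and their C2 models.

Each survey entry's C-X1-X2-H-X3 motif is rebuilt from its published
backbone torsions and chi1 values (the His ring orientation is resolved
from the published intra-residue He1/HN ~6 A distance plus zinc closure),
then completed into an idealized C2 homodimer about the axis that makes
the Cys2His2 site most tetrahedral.  Reports the chirality and the
inter-chain His He1 -> amide H distance that discriminates the dimer
topologies (only the 2au3-based dimer brings the two protons close enough
for an NOE contact).
"""

import json
import sys
from pathlib import Path

from zincturn import refdata
from zincturn.dimer import dimer_to_structure
from zincturn.reconstruct import reconstruct_dimer_entry
from zincturn.structure_io import write_structure

RESULTS = Path("results")
MODELS = Path("scratch/dimers")


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    MODELS.mkdir(parents=True, exist_ok=True)
    report = {}
    for entry in refdata.DIMER_ENTRIES:
        st, motif, model = reconstruct_dimer_entry(entry)
        pdb = MODELS / f"{entry.entry}_dimer.pdb"
        write_structure(dimer_to_structure(model, structure_id=entry.entry), pdb)
        r = model.report
        report[entry.entry] = {
            "cluster": entry.cluster,
            "sequence": entry.sequence,
            "chirality": model.chirality,
            "he1_to_partner_hn_A": round(r["his_he1_a_to_hn_b"], 2),
            "intra_he1_hn_A": round(r["intra_he1_hn"], 2),
            "tetrahedricity_deg": round(r["tetrahedricity"], 2),
            "min_interchain_distance_A": round(r["min_interchain_distance"], 2),
            "clash_flag": model.clash,
            "model_pdb": str(pdb),
        }
        print(f"{entry.entry} ({entry.sequence}, cluster {entry.cluster}): "
              f"{model.chirality}, He1->HN' {r['his_he1_a_to_hn_b']:.2f} A, "
              f"intra He1/HN {r['intra_he1_hn']:.2f} A")
    d1 = report["2au3_A"]["he1_to_partner_hn_A"]
    d2 = report["4ijd_A"]["he1_to_partner_hn_A"]
    print(f"\nonly the 2au3-based dimer supports the inter-chain NOE "
          f"({d1} A vs {d2} A in the 4ijd-based dimer)")
    out = RESULTS / "dimers.json"
    out.write_text(json.dumps(report, indent=2))
    print(f"report -> {out}; models -> {MODELS}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
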