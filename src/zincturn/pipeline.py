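"""End-to-end orchestration: mine -> torsions -> cluster -> stats -> report.

One :func:`run_pipeline` call takes a directory (or explicit list) of
structure files and writes, into the output directory:

* ``motifs.tsv``     one row per mined motif (all motifs, pre-dedup)
* ``torsions.tsv``   torsion profile, rotamers and turn type per motif
* ``clusters.json``  GROMOS clustering with per-cluster circular statistics
* ``propensities.tsv`` occurrence/propensity table over unique sequences
* ``summary.json``   counts at every stage and the partition identity

Everything is deterministic given the configuration; filters log their
input/output counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from zincturn import clustering as cl
from zincturn import site_statistics as stats
from zincturn.conformation import classify_alpha_turn, hbond_i_i4, rotamer_class, torsion_profile
from zincturn.mining import deduplicate_sequences, mine_structure
from zincturn.structure_io import read_structure, resolution_filter

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Cutoffs and inputs of one pipeline run."""

    inputs: list[str] = field(default_factory=list)  # files or directories
    coordination_cutoff: float = 3.0  # A
    max_ca_distance: float = 7.0  # A (alpha-turn gate)
    cluster_cutoff: float = 0.4  # A (RMSD)
    max_resolution: float | None = None  # A; None disables the filter
    subset: str = "default18"
    background: str = "swissprot"
    chains: list[str] | None = None
    out_dir: str = "results/pipeline"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coordination_cutoff", "max_ca_distance", "cluster_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(dataclasses.asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        import yaml

        return cls(**yaml.safe_load(text))


def _collect_files(inputs: list[str]) -> list[Path]:
    files: list[Path] = []
    for item in inputs:
        p = Path(item)
        if p.is_dir():
            files.extend(sorted(p.glob("*.pdb")) + sorted(p.glob("*.cif")))
        elif p.exists():
            files.append(p)
        else:
            raise FileNotFoundError(p)
    return files


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the summary dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = _collect_files(config.inputs)
    log.info("pipeline: %d input files", len(files))

    structures = [read_structure(f) for f in files]
    n_read = len(structures)
    if config.max_resolution is not None:
        structures = resolution_filter(structures, config.max_resolution)
        log.info("resolution filter: %d -> %d", n_read, len(structures))

    motifs, parents = [], []
    for s in structures:
        found = mine_structure(s, cutoff=config.coordination_cutoff,
                               max_ca=config.max_ca_distance, chains=config.chains)
        motifs.extend(found)
        parents.extend([s] * len(found))
    log.info("mining: %d motifs", len(motifs))

    rows = []
    profiles = []
    for m, s in zip(motifs, parents):
        t = torsion_profile(m, s)
        profiles.append(t)
        rows.append({
            "structure_id": m.structure_id, "chain": m.chain_id, "start": m.start,
            "sequence": m.sequence, "his_atom": m.his_binding_atom,
            "s_zn": round(m.s_zn_distance, 3), "n_zn": round(m.n_zn_distance, 3),
            "ca_i_i4": round(m.ca_distance_i_i4, 3),
            "hbond": hbond_i_i4(m, s),
            **{k: round(v, 2) for k, v in t.as_dict().items()},
            "rotamer_cys": rotamer_class(t.chi1_cys),
            "rotamer_his": rotamer_class(t.chi1_his),
            "turn_type": classify_alpha_turn(t),
        })
    motif_df = pd.DataFrame(rows)
    motif_cols = ["structure_id", "chain", "start", "sequence", "his_atom",
                  "s_zn", "n_zn", "ca_i_i4", "hbond"]
    if len(motif_df):
        motif_df[motif_cols].to_csv(out / "motifs.tsv", sep="\t", index=False)
        motif_df.to_csv(out / "torsions.tsv", sep="\t", index=False)
    else:
        pd.DataFrame(columns=motif_cols).to_csv(out / "motifs.tsv", sep="\t", index=False)
        motif_df.to_csv(out / "torsions.tsv", sep="\t", index=False)

    # clustering on the fixed atom subset
    clusters_doc: dict = {"cutoff": config.cluster_cutoff,
                          "subset": cl.DEFAULT_SUBSET.name,
                          "subset_note": "backbone N/CA/C of the 5 residues + "
                                         "Cys SG + His ND1 + Zn (18 atoms)"}
    if motifs:
        coords = [cl.motif_subset_coordinates(m, s)
                  for m, s in zip(motifs, parents)]
        matrix = cl.pairwise_rmsd(coords)
        clustering = cl.gromos_cluster(matrix, cutoff=config.cluster_cutoff)
        summary_rows = cl.cluster_summary(clustering, profiles)
        clusters_doc.update({
            "clusters": [
                {"centroid": c, "members": mm} for c, mm in clustering.clusters
            ],
            "outliers": clustering.outliers,
            "sizes": clustering.sizes,
            "summary": [
                {k: (round(v, 2) if isinstance(v, float) else v)
                 for k, v in row.items()}
                for row in summary_rows
            ],
        })
    else:
        clustering = None
        clusters_doc.update({"clusters": [], "outliers": [], "sizes": [], "summary": []})
    (out / "clusters.json").write_text(json.dumps(clusters_doc, indent=2))

    unique = deduplicate_sequences(motifs)
    occ = stats.occurrence_table(unique)
    prop_df = None
    if occ.total_sequences > 0:
        prop_df = stats.propensity_table(occ)
        merged = pd.DataFrame({
            **{f"occ_{p}": occ.counts[p] for p in ("X1", "X2", "X3")},
            **{f"prop_{p}": prop_df[p].round(3) for p in ("X1", "X2", "X3")},
        })
        merged.index.name = "residue"
        merged.to_csv(out / "propensities.tsv", sep="\t")

    n_clustered = (sum(clustering.sizes) + len(clustering.outliers)) if clustering else 0
    summary = {
        "inputs": len(files),
        "structures_after_resolution_filter": len(structures),
        "motifs": len(motifs),
        "unique_sequences": len(unique),
        "cluster_sizes": clustering.sizes if clustering else [],
        "outliers": len(clustering.outliers) if clustering else 0,
        "partition_identity": n_clustered == len(motifs),
        "mean_s_zn": (round(float(np.mean([m.s_zn_distance for m in motifs])), 3)
                      if motifs else None),
        "mean_n_zn": (round(float(np.mean([m.n_zn_distance for m in motifs])), 3)
                      if motifs else None),
        "background": stats.SWISSPROT_BACKGROUND.source,
        "config": dataclasses.asdict(config),
    }
    if not summary["partition_identity"]:
        raise RuntimeError("count conservation violated between mining and clustering")
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
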