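"""Metabolome workflow: QC filter, PQN, differential metabolites, origin
partition, and pathway enrichment.

Features must be detected in at least half the QC injections with a QC
RSD of at most 30%; intensities are then probabilistic-quotient
normalized (reference = QC median profile) and log transformed.
Differential metabolites are Wilcoxon P < 0.05 with a geometric HOS/LOS
fold change; metabolites are partitioned into host / microbiota /
cometabolism / others and each category's pathways are tested for
enrichment of the differential set by a hypergeometric tail.
"""

import json
from pathlib import Path

import pandas as pd

from gutosi.differential import wilcoxon_fold_change
from gutosi.metabolome import (MetaboliteTable, OriginAnnotation,
                               classify_origins, pathway_enrichment,
                               pqn_normalize, qc_filter)
from gutosi.tables import read_table, write_table

STUDY = Path("results/study")
REDOX = Path("results/redox")
OUT = Path("results/metabolome")


def main() -> None:
    raw = read_table(STUDY / "metabolome.tsv")
    qc_samples = [s for s in raw.index if str(s).startswith("QC")]
    table = MetaboliteTable(raw, qc_samples=qc_samples)
    annotation = OriginAnnotation.from_frame(
        pd.read_csv(STUDY / "annotation.tsv", sep="\t", index_col=0))
    groups = read_table(REDOX / "groups.tsv").iloc[:, 0]
    with open(STUDY / "truth.json") as fh:
        truth = json.load(fh)

    qc_res = qc_filter(table)
    print(f"QC filter: {qc_res.table.intensities.shape[1]} of {raw.shape[1]} "
          f"features kept ({len(qc_res.removed_presence)} below QC presence, "
          f"{len(qc_res.removed_rsd)} above 30% RSD)")

    pqn = pqn_normalize(qc_res.table)
    bio = pqn.table.biological
    print(f"PQN dilution quotients: {pqn.quotients.min():.2f}.."
          f"{pqn.quotients.max():.2f}; log offset {pqn.log_offset:.3g}")

    met_groups = groups.reindex(bio.index).dropna()
    met_groups = met_groups[met_groups != "unassigned"]
    diff = wilcoxon_fold_change(bio.loc[met_groups.index], met_groups,
                                log_scale=True)
    write_table(pqn.table.intensities, OUT / "normalized.tsv")
    write_table(diff.rename_axis("feature"), OUT / "differential_metabolites.tsv")

    sig = diff[diff["significant"]]
    planted = {f for f, _ in truth["differential_metabolites"]}
    print(f"\n{len(sig)} differential metabolites (Wilcoxon P < 0.05); "
          f"planted recovered: {len(planted & set(sig.index))} of {len(planted)}")

    counts, _ = classify_origins(list(bio.columns), annotation)
    write_table(counts.to_frame().rename_axis("origin"), OUT / "origin_counts.tsv")
    print("origin partition:", counts.to_dict())

    enrich = pathway_enrichment(list(sig.index), list(bio.columns), annotation)
    write_table(enrich.set_index(["pathway", "origin"]), OUT / "enrichment.tsv")
    hits = enrich[enrich["significant"]]
    print(f"\nenriched pathways (hypergeometric P < 0.05):")
    cols = ["pathway", "origin", "k", "K", "n", "N", "pvalue"]
    print(hits[cols].to_string(index=False) if len(hits) else "  none")


if __name__ == "__main__":
    main()
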