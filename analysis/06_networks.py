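"""Per-group co-occurrence networks, their comparison, and the
taxon-OSI correlation panel.

Builds a Spearman network within each group (edges: BH-adjusted p < 0.05
and |rho| > 0.70), compares the two structures by shared signed edges,
harmonic closeness and eigenvector centrality, and correlates the
significant differential genera with plasma OSI.
"""

from pathlib import Path

import pandas as pd

from gutosi.abundance import prevalence_filter
from gutosi.networks import (compare_networks, cooccurrence_network,
                             feature_phenotype_correlations)
from gutosi.tables import read_table, write_json, write_table

STUDY = Path("results/study")
REDOX = Path("results/redox")
DIFF = Path("results/differential")
OUT = Path("results/networks")


def main() -> None:
    abundance = read_table(STUDY / "abundance.tsv")
    phenotypes = read_table(STUDY / "phenotypes.tsv")
    groups = read_table(REDOX / "groups.tsv").iloc[:, 0]
    taxon_meta = read_table(STUDY / "taxon_meta.tsv")

    filt = prevalence_filter(abundance)
    nets = {}
    for label in ("LOS", "HOS"):
        members = groups.index[groups == label]
        nets[label] = cooccurrence_network(
            filt.table.loc[members], group=label, node_meta=taxon_meta,
        )
        write_table(nets[label].edges.rename_axis("edge"),
                    OUT / f"network_{label}.tsv")
        print(f"{label}: {len(nets[label].edges)} significant edges "
              f"(|rho| > 0.70, BH p < 0.05) over "
              f"{nets[label].graph.number_of_nodes()} genera")

    cmp = compare_networks(nets["LOS"], nets["HOS"])
    write_table(cmp.closeness.rename_axis("taxon"), OUT / "closeness.tsv")
    write_json({"shared_edges": len(cmp.shared_edges),
                "unique_LOS": cmp.unique_a, "unique_HOS": cmp.unique_b},
               OUT / "comparison.json")
    print(f"comparison: {len(cmp.shared_edges)} shared edges "
          f"(same pair, same sign), {cmp.unique_a} unique to LOS, "
          f"{cmp.unique_b} unique to HOS")

    diff = pd.read_csv(DIFF / "differential_taxa.tsv", sep="\t", index_col=0)
    sig_taxa = diff.index[diff["significant"]]
    selected = groups.index[groups != "unassigned"]
    panel = feature_phenotype_correlations(
        filt.table.loc[selected, sig_taxa], phenotypes.loc[selected, "OSI"])
    write_table(panel.rename_axis("taxon"), OUT / "osi_correlations.tsv")
    print("\nSpearman correlation of significant genera with plasma OSI:")
    print(panel.sort_values("rho").round(4).to_string())


if __name__ == "__main__":
    main()
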