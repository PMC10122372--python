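"""Differential genera between the HOS and LOS groups (LEfSe-style).

Kruskal-Wallis screen (exact p-values at 9 + 9) plus a bootstrapped LDA
effect size on the per-million scale; a genus is significant at P < 0.05
with an LDA score > 2.  Reports how many of the generator's planted
differential taxa were recovered.
"""

import json
from pathlib import Path

from gutosi.abundance import prevalence_filter
from gutosi.differential import lefse
from gutosi.tables import read_table, write_table

STUDY = Path("results/study")
REDOX = Path("results/redox")
OUT = Path("results/differential")
SEED = 1


def main() -> None:
    abundance = read_table(STUDY / "abundance.tsv")
    groups = read_table(REDOX / "groups.tsv").iloc[:, 0]
    with open(STUDY / "truth.json") as fh:
        truth = json.load(fh)

    filt = prevalence_filter(abundance)
    selected = groups.index[groups != "unassigned"]
    res = lefse(filt.table.loc[selected], groups.loc[selected], seed=SEED)
    write_table(res.table.rename_axis("taxon"), OUT / "differential_taxa.tsv")

    sig = res.table[res.table["significant"]].sort_values("lda_score",
                                                          ascending=False)
    planted = {t for t, _ in truth["differential_taxa"]}
    print(f"{len(sig)} significant genera of {len(res.table)} tested "
          f"(P < 0.05 and LDA score > 2)")
    print(sig[["pvalue", "lda_score", "higher_in"]].round(4).to_string())
    print(f"\nplanted differential taxa recovered: "
          f"{len(planted & set(sig.index))} of {len(planted)} "
          f"({sorted(planted & set(sig.index))})")


if __name__ == "__main__":
    main()
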