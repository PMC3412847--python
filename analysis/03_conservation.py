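"""Cross-species intron position/phase conservation over the fixture.

Aligns each family's proteins, projects intron sites into alignment
coordinates, and writes the site table, pairwise sharing matrix and
combinatorial subset grouping to results/conservation/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from introntrace.conservation import (
    OrthologFamily, align_family, build_site_table, sharing_report,
    site_table_to_tsv,
)
from introntrace.gene_models import load_gene_models


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=Path("results/fixture"))
    ap.add_argument("--out", type=Path, default=Path("results/conservation"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fam_df = pd.read_csv(args.bundle / "families.tsv", sep="\t")
    models = {}
    for sp in sorted(fam_df["species_id"].unique()):
        loaded, _ = load_gene_models(
            str(args.bundle / f"{sp}.gff3"), str(args.bundle / f"{sp}.fasta"),
            species_id=sp)
        models[sp] = {g.gene_id: g for g in loaded}

    tables = []
    for fam_id, grp in fam_df.groupby("family_id"):
        members = {r.species_id: models[r.species_id][r.gene_id]
                   for r in grp.itertuples()}
        fam = OrthologFamily.from_members(str(fam_id), members)
        if len(fam.proteins) < 2:
            continue
        tables.append(build_site_table(fam, align_family(fam)))

    rep = sharing_report(tables)
    site_table_to_tsv(tables).to_csv(args.out / "site_table.tsv", sep="\t",
                                     index=False)
    rep.pairwise.round(1).to_csv(args.out / "pairwise_sharing.tsv", sep="\t")
    rep.subset_table().to_csv(args.out / "subset_counts.tsv", sep="\t",
                              index=False)
    (args.out / "sharing.json").write_text(json.dumps({
        "n_sites": rep.n_sites,
        "unique_ratio_pct": {k: round(v, 1) for k, v in rep.unique_ratio.items()},
    }, indent=2))
    print(f"{len(tables)} families -> {rep.n_sites} distinct intron sites")
    print("unique-intron ratios (%):",
          {k: round(v, 1) for k, v in rep.unique_ratio.items()})
    print("pairwise sharing (% of row species' introns present in column):")
    print(rep.pairwise.round(1).to_string())


if __name__ == "__main__":
    main()
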