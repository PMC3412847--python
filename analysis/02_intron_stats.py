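"""Intron structural statistics per species over the fixture bundle.

Reloads each species' GFF3+FASTA through the gene-model parser (so the
strand-normalization path is exercised), extracts every intron, and writes
length/phase/GC/splice-class summaries to results/stats/.
"""

import argparse
import json
from pathlib import Path

from introntrace.gene_models import (
    extract_introns, introns_to_fasta, load_gene_models, summarize_intron_stats,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=Path("results/fixture"))
    ap.add_argument("--out", type=Path, default=Path("results/stats"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for gff in sorted(args.bundle.glob("*.gff3")):
        sp = gff.stem
        models, problems = load_gene_models(
            str(gff), str(args.bundle / f"{sp}.fasta"), species_id=sp)
        introns = [r for g in models for r in extract_introns(g)]
        stats = summarize_intron_stats(introns, models, species_id=sp)
        (args.out / f"{sp}.stats.json").write_text(stats.to_json())
        (args.out / f"{sp}.introns.fasta").write_text(introns_to_fasta(introns))
        p0, p1, p2 = stats.phase_fractions or (float("nan"),) * 3
        print(f"{sp}: {stats.n_genes} genes, {stats.n_introns} introns "
              f"(mean {stats.mean_length:.1f} nt, median {stats.median_length:.0f} nt); "
              f"phases {100*p0:.0f}/{100*p1:.0f}/{100*p2:.0f}; "
              f"GC introns {100*stats.mean_gc_introns:.1f}% vs CDS "
              f"{100*stats.mean_gc_cds:.1f}%; {len(problems)} problem genes")


if __name__ == "__main__":
    main()
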