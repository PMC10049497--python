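"""Generate the synthetic study inputs used by the downstream analyses.

Writes, under results/data/: 40 per-contrast DE summary tables with a
planted concordant core (150 up + 120 down genes, concordant in 60% of
contrasts, two gain-of-function contrasts sign-inverted at generation),
their metadata, a gene annotation with a planted positional cluster on
chr8, a 20-vs-20 negative binomial count matrix with ~300 planted mostly
sub-two-fold effects, and the ground-truth tables for all of them.
"""

from pathlib import Path

import pandas as pd

from mecp2core import io, simulate

SEED = 20240901
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    defaults = simulate.default_parameters()

    params = {k: v for k, v in defaults["multi_contrast"].items() if k != "n_inverted"}
    tables, meta, truth = simulate.generate_multi_contrast(seed=SEED, **params)
    contrast_dir = OUT / "contrasts"
    contrast_dir.mkdir(exist_ok=True)
    for t in tables:
        io.write_contrast_table(t, contrast_dir / f"{t.contrast_id}.tsv")
    io.write_metadata(meta, OUT / "metadata.tsv")
    pd.DataFrame(
        {
            "gene": sorted(truth.core_up) + sorted(truth.core_down),
            "direction": ["up"] * len(truth.core_up) + ["down"] * len(truth.core_down),
        }
    ).to_csv(OUT / "core_truth.tsv", sep="\t", index=False)
    print(f"{len(tables)} contrast tables ({len(tables[0].genes)} genes each); "
          f"planted core: {len(truth.core_up)} up + {len(truth.core_down)} down; "
          f"inverted contrasts: {sorted(truth.inverted_contrasts)}")

    ann = simulate.generate_annotation(params["n_genes"], seed=SEED + 1)
    up_on_chr8 = sorted(truth.core_up)[:100]
    ann = simulate.plant_positional_cluster(
        ann, set(up_on_chr8), "chr8", 4_000_000, 50_000_000, seed=SEED + 2
    )
    io.write_annotation(ann, OUT / "annotation.tsv")
    print(f"annotation: {len(ann)} genes, {len(up_on_chr8)} core-up genes "
          f"clustered on chr8:4000000-50000000")

    cm, ctruth = simulate.generate_counts(seed=SEED + 3, **defaults["counts"])
    io.write_count_matrix(cm, OUT / "counts.tsv", OUT / "groups.tsv")
    pd.DataFrame(
        {"gene": sorted(ctruth.de_genes),
         "planted_lfc": [ctruth.planted_lfc[g] for g in sorted(ctruth.de_genes)]}
    ).to_csv(OUT / "counts_truth.tsv", sep="\t", index=False)
    print(f"count matrix: {len(cm.genes)} genes x {len(cm.samples)} samples, "
          f"{len(ctruth.de_genes)} planted DE genes")


if __name__ == "__main__":
    main()
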