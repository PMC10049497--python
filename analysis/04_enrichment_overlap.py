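"""Enrichment of the core in held-out contrasts and directional overlap.

Ranks each of three illustrative contrasts (a concordant loss-of-function
contrast, a gain-of-function contrast before and after score inversion)
by -log10(FDR) * log2FC and tests the up and down cores with the
permutation-null weighted-KS statistic; then runs direction-stratified
Fisher/hypergeometric overlap of a concordant contrast's DEGs against
the core. Outputs under results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from mecp2core import core, enrichment as en, io

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20240904


def main() -> None:
    out = BASE / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    meta = io.read_metadata(BASE / "data" / "metadata.tsv")
    core_df = pd.read_csv(BASE / "core" / "core.tsv", sep="\t")
    idx = core_df.set_index("gene")
    res = core.CoreResult(core_genes=set(core_df["gene"]), support=idx["support"],
                          mean_lfc=idx["mean_lfc"], direction=idx["direction"])
    gene_sets = {"core_up": res.core_up, "core_down": res.core_down}

    lof = next(m.contrast_id for m in meta if m.model_class == "loss_of_function")
    gof = next(m.contrast_id for m in meta if m.model_class == "gain_of_function")
    rows = []
    for cid, invert in [(lof, False), (gof, False), (gof, True)]:
        t = io.read_contrast_table(BASE / "data" / "contrasts" / f"{cid}.tsv", cid)
        ranked = en.rank_genes(t)
        if invert:
            ranked = en.invert_scores(ranked)
        for r in en.permutation_enrichment(ranked, gene_sets, n_perm=1000, seed=SEED):
            rows.append({"contrast": cid, "score_inverted": invert,
                         "gene_set": r.gene_set_name, "es": round(r.es, 4),
                         "nes": round(r.nes, 3), "pvalue": r.pvalue, "fdr": r.fdr})
    enr = pd.DataFrame(rows)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    print("pre-ranked enrichment against the up/down cores:")
    print(enr.to_string(index=False))

    t = io.read_contrast_table(BASE / "data" / "contrasts" / f"{lof}.tsv", lof)
    universe = set(t.genes)
    strata = en.directional_overlap(t, res, alpha=0.01, universe=universe)
    orows = []
    for name, ov in strata.items():
        orows.append({"stratum": name, "overlap": ov.n_overlap,
                      "odds_ratio": round(ov.odds_ratio, 2),
                      "p_fisher": ov.p_fisher, "p_hypergeom": ov.p_hypergeom})
    odf = pd.DataFrame(orows)
    odf.to_csv(out / "overlap.tsv", sep="\t", index=False)
    print(f"\ndirectional overlap of {lof} DEGs with the core "
          f"(universe {len(universe)} genes):")
    print(odf.to_string(index=False))


if __name__ == "__main__":
    main()
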