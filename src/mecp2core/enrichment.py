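"""Pre-ranked gene-set enrichment and overlap significance testing.

Enrichment follows the weighted Kolmogorov–Smirnov running-sum statistic
of pre-ranked GSEA: genes are ranked by ``-log10(FDR) * log2FC``, the
running sum gains ``|score|^w / sum_hits |score|^w`` at set members and
loses ``1/(N - n_hits)`` elsewhere, and the enrichment score (ES) is the
signed maximum deviation from zero. Significance comes from a
gene-permutation null with sign-stratified normalization (NES) and a
GSEA-style FDR. Overlap between gene sets is tested with Fisher's exact
test and the upper-tail hypergeometric probability, optionally stratified
by direction of change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mecp2core.io import ContrastTable
from mecp2core.core import CoreResult


@dataclass
class RankedList:
    """Genes with ranking scores, sorted descending (ties by gene id)."""

    data: pd.DataFrame  # columns gene, score

    def __post_init__(self) -> None:
        if list(self.data.columns[:2]) != ["gene", "score"]:
            self.data = self.data.rename(
                columns=dict(zip(self.data.columns[:2], ["gene", "score"]))
            )
        if self.data["gene"].duplicated().any():
            raise ValueError("duplicate gene in ranked list")
        self.data = self.data.sort_values(
            ["score", "gene"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> list[str]:
        return self.data["gene"].tolist()

    @property
    def scores(self) -> np.ndarray:
        return self.data["score"].to_numpy(dtype=float)


@dataclass
class EnrichmentResult:
    gene_set_name: str
    es: float
    nes: float
    pvalue: float
    fdr: float
    n_hits: int


@dataclass
class OverlapResult:
    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    odds_ratio: float
    p_fisher: float
    p_hypergeom: float


def rank_genes(table: ContrastTable, pseudocount: float = 1e-300) -> RankedList:
    """Rank genes by ``-log10(max(fdr, pseudocount)) * log2fc``.

    The FDR clamp keeps scores finite when an adjusted p-value underflows
    to zero, as happens in real DE output.
    """
    fdr = np.maximum(table.data["fdr"].to_numpy(dtype=float), pseudocount)
    score = -np.log10(fdr) * table.data["log2fc"].to_numpy(dtype=float)
    return RankedList(data=pd.DataFrame({"gene": table.data["gene"], "score": score}))


def invert_scores(ranked: RankedList) -> RankedList:
    """Negate all ranking scores and re-sort.

    Harmonizes a gain-of-function contrast with loss-of-function ones at
    the ranking stage, so downstream ES/NES inherit the inversion.
    """
    df = ranked.data.copy()
    df["score"] = -df["score"]
    return RankedList(data=df)


def _es_from_positions(
    abs_scores_w: np.ndarray, positions: np.ndarray, n: int
) -> np.ndarray:
    """ES for one or many hit-position sets, evaluated only at hit corners.

    ``positions`` is (B, k) of sorted 0-based ranks. Between hits the
    running sum decays linearly, so its extrema sit immediately before or
    after a hit; ES is the candidate of maximum absolute value.
    """
    positions = np.atleast_2d(positions)
    B, k = positions.shape
    w = abs_scores_w[positions]  # (B, k)
    nr = w.sum(axis=1, keepdims=True)
    zero_nr = nr[:, 0] == 0
    if zero_nr.any():  # all hit scores zero: fall back to unweighted steps
        w = np.where(zero_nr[:, None], 1.0, w)
        nr = np.where(zero_nr[:, None], float(k), nr)
    cum_w = np.cumsum(w, axis=1) / nr
    miss_step = 1.0 / (n - k)
    hit_no = np.arange(1, k + 1)
    after = cum_w - (positions + 1 - hit_no) * miss_step
    before = np.concatenate([np.zeros((B, 1)), cum_w[:, :-1]], axis=1) - (
        positions - (hit_no - 1)
    ) * miss_step
    candidates = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(candidates), axis=1)
    return candidates[np.arange(B), idx]


def enrichment_score(
    ranked: RankedList, gene_set: set[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and the full running sum.

    Returns ``(es, running_sum)`` where the running sum has one value per
    ranked gene and ends at zero (to numerical precision).
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    genes = ranked.genes
    hit = np.fromiter((g in gene_set for g in genes), dtype=bool, count=len(genes))
    k = int(hit.sum())
    if k == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if k == len(genes):
        raise ValueError("gene set covers the whole ranked list (no misses)")
    w = np.abs(ranked.scores) ** weight
    nr = w[hit].sum()
    hit_steps = w / nr if nr > 0 else np.full_like(w, 1.0 / k)
    steps = np.where(hit, hit_steps, -1.0 / (len(genes) - k))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def permutation_enrichment(
    ranked: RankedList,
    gene_sets: dict[str, set[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Gene-permutation significance for many gene sets on one ranking.

    For each set, ``n_perm`` random same-size gene-label sets give the
    null ES distribution. The p-value and NES are sign-stratified
    (compared only against nulls of the observed sign); FDR is the
    GSEA-style ratio of null to observed tail fractions of normalized
    scores, clipped to [0, 1]. Null draws are shared between sets of the
    same size, so results are deterministic given the seed but invariant
    to the order of ``gene_sets``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(ranked)
    w_abs = np.abs(ranked.scores) ** weight
    gene_index = {g: i for i, g in enumerate(ranked.genes)}

    sizes: dict[int, np.ndarray] = {}
    observed: list[tuple[str, float, int]] = []
    for name in sorted(gene_sets):
        members = gene_sets[name]
        pos = np.array(sorted(gene_index[g] for g in members if g in gene_index))
        if pos.size == 0:
            raise ValueError(f"gene set {name!r} does not intersect the ranked list")
        if pos.size >= n:
            raise ValueError(f"gene set {name!r} covers the whole ranked list")
        es = float(_es_from_positions(w_abs, pos[None, :], n)[0])
        observed.append((name, es, int(pos.size)))
        sizes.setdefault(int(pos.size), np.empty(0))

    rng = np.random.default_rng(seed)
    null_es: dict[int, np.ndarray] = {}
    for k in sorted(sizes):
        draws = np.empty((n_perm, k), dtype=int)
        for b in range(n_perm):
            draws[b] = np.sort(rng.choice(n, size=k, replace=False))
        null_es[k] = _es_from_positions(w_abs, draws, n)

    # sign-stratified normalization of observed and null scores
    results: list[EnrichmentResult] = []
    norm_obs: list[float] = []
    norm_null_pool: list[np.ndarray] = []
    for name, es, k in observed:
        nulls = null_es[k]
        same = nulls >= 0 if es >= 0 else nulls < 0
        n_same = int(same.sum())
        if n_same == 0:
            p, nes = 1.0, 0.0
        else:
            p = (1 + int(np.sum(np.abs(nulls[same]) >= abs(es)))) / (1 + n_same)
            mean_same = float(np.mean(np.abs(nulls[same])))
            nes = es / mean_same if mean_same > 0 else 0.0
        pos_mean = float(np.mean(nulls[nulls >= 0])) if (nulls >= 0).any() else 1.0
        neg_mean = float(np.mean(np.abs(nulls[nulls < 0]))) if (nulls < 0).any() else 1.0
        scaled = np.where(
            nulls >= 0,
            nulls / (pos_mean if pos_mean > 0 else 1.0),
            nulls / (neg_mean if neg_mean > 0 else 1.0),
        )
        norm_null_pool.append(scaled)
        norm_obs.append(nes)
        results.append(EnrichmentResult(name, es, nes, p, 0.0, k))

    pool = np.concatenate(norm_null_pool)
    obs = np.asarray(norm_obs)
    for res in results:
        nes = res.nes
        if nes >= 0:
            null_tail = np.mean(pool[pool >= 0] >= nes) if (pool >= 0).any() else 0.0
            obs_tail = np.mean(obs[obs >= 0] >= nes) if (obs >= 0).any() else 1.0
        else:
            null_tail = np.mean(pool[pool < 0] <= nes) if (pool < 0).any() else 0.0
            obs_tail = np.mean(obs[obs < 0] <= nes) if (obs < 0).any() else 1.0
        res.fdr = float(np.clip(null_tail / obs_tail if obs_tail > 0 else 1.0, 0.0, 1.0))
    return results


def overlap_test(set_a: set[str], set_b: set[str], universe: set[str]) -> OverlapResult:
    """Fisher / hypergeometric significance of the overlap of two sets.

    The 2x2 table partitions the universe by membership in each set. The
    hypergeometric p is the upper tail P(X >= overlap); the odds ratio is
    the sample cross-product ratio, with a 0.5 Haldane correction applied
    only when a zero cell makes the ratio undefined.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a) - a
    c = len(set_b) - a
    d = len(universe) - a - b - c
    _, p_fisher = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    p_hyper = float(stats.hypergeom.sf(a - 1, len(universe), len(set_a), len(set_b)))
    if b * c == 0:  # zero cell in the denominator: Haldane correction
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    return OverlapResult(
        n_universe=len(universe),
        n_set_a=len(set_a),
        n_set_b=len(set_b),
        n_overlap=a,
        odds_ratio=float(odds),
        p_fisher=float(min(p_fisher, 1.0)),
        p_hypergeom=min(p_hyper, 1.0),
    )


def directional_overlap(
    table: ContrastTable,
    core: CoreResult,
    alpha: float,
    universe: set[str],
) -> dict[str, OverlapResult]:
    """Overlap of a contrast's DEGs with a consensus core, by direction.

    ``both`` ignores direction; ``up_only`` intersects the contrast's
    upregulated DEGs with the core-up genes, ``down_only`` analogously.
    """
    df = table.data
    sig = df["fdr"].to_numpy() <= alpha
    degs = set(df.loc[sig, "gene"]) & universe
    degs_up = set(df.loc[sig & (df["log2fc"].to_numpy() > 0), "gene"]) & universe
    degs_down = set(df.loc[sig & (df["log2fc"].to_numpy() < 0), "gene"]) & universe
    return {
        "both": overlap_test(degs, core.core_genes & universe, universe),
        "up_only": overlap_test(degs_up, core.core_up & universe, universe),
        "down_only": overlap_test(degs_down, core.core_down & universe, universe),
    }
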