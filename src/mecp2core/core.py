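"""Consensus common-core identification across many DE contrasts.

The procedure: per-gene log2 fold changes with FDR above a significance
threshold (default 0.01) are set to zero, contrasts left with no
significant gene are removed, gain-of-function contrasts are
direction-inverted so all fold changes share the loss-of-function
orientation, and genes significant in at least k contrasts (default 4,
~10% of the full contrast set) form the core. The core is split into
consistently up- and downregulated halves by the mean of the significant
fold changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mecp2core.io import ContrastMetadata, ContrastTable

logger = logging.getLogger(__name__)


@dataclass
class ConsensusConfig:
    """Thresholds for core identification.

    Exactly one of ``min_contrasts`` (absolute support) and
    ``min_fraction`` (fraction of the contrasts under analysis) is set.
    A fraction is converted with round-half-down and floored at 1, so the
    canonical 10%-of-43 operating point yields k = 4.
    """

    alpha: float = 0.01
    min_contrasts: int | None = 4
    min_fraction: float | None = None
    invert_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if (self.min_contrasts is None) == (self.min_fraction is None):
            raise ValueError("set exactly one of min_contrasts / min_fraction")
        if self.min_contrasts is not None and self.min_contrasts < 1:
            raise ValueError("min_contrasts must be >= 1")
        if self.min_fraction is not None and not (0.0 < self.min_fraction <= 1.0):
            raise ValueError("min_fraction must be in (0, 1]")
        self.invert_ids = frozenset(self.invert_ids)

    def support_threshold(self, n_contrasts: int) -> int:
        """Resolve the support threshold k for ``n_contrasts`` contrasts."""
        if self.min_contrasts is not None:
            return self.min_contrasts
        # round-half-down: 4.3 -> 4, 4.5 -> 4, 4.51 -> 5; never below 1
        return max(1, math.ceil(self.min_fraction * n_contrasts - 0.5))


@dataclass
class FCMatrix:
    """Genes x contrasts significance-masked log2 fold changes.

    Entry (g, c) is the log2 fold change when gene g passed the FDR
    threshold in contrast c, and exactly 0 otherwise.
    """

    genes: list[str]
    contrasts: list[str]
    masked_lfc: np.ndarray

    def __post_init__(self) -> None:
        self.masked_lfc = np.asarray(self.masked_lfc, dtype=float)
        if self.masked_lfc.shape != (len(self.genes), len(self.contrasts)):
            raise ValueError("masked_lfc shape does not match gene/contrast lists")
        if not np.isfinite(self.masked_lfc).all():
            raise ValueError("masked_lfc must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.masked_lfc, index=self.genes, columns=self.contrasts)


@dataclass
class CoreResult:
    """Consensus core membership with per-gene support and direction."""

    core_genes: set[str]
    support: pd.Series  # all genes, count of significant contrasts
    mean_lfc: pd.Series  # core genes, mean over significant entries
    direction: pd.Series  # core genes, "up" or "down"

    @property
    def core_up(self) -> set[str]:
        return set(self.direction.index[self.direction == "up"])

    @property
    def core_down(self) -> set[str]:
        return set(self.direction.index[self.direction == "down"])

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.core_genes)
        return pd.DataFrame(
            {
                "gene": genes,
                "support": self.support.loc[genes].to_numpy(),
                "mean_lfc": self.mean_lfc.loc[genes].to_numpy(),
                "direction": self.direction.loc[genes].to_numpy(),
            }
        )


def build_fc_matrix(tables: list[ContrastTable], cfg: ConsensusConfig) -> FCMatrix:
    """Assemble the masked fold-change matrix over the gene union.

    A gene absent from a contrast's table is treated as not significant
    there (entry 0), keeping support counts well defined on the union
    universe.
    """
    if not tables:
        raise ValueError("at least one contrast table required")
    genes: list[str] = []
    seen: set[str] = set()
    for t in tables:
        for g in t.genes:
            if g not in seen:
                seen.add(g)
                genes.append(g)
    gene_index = {g: i for i, g in enumerate(genes)}
    mat = np.zeros((len(genes), len(tables)))
    for j, t in enumerate(tables):
        df = t.data
        sig = df["fdr"].to_numpy() <= cfg.alpha
        rows = df.loc[sig]
        idx = rows["gene"].map(gene_index).to_numpy(dtype=int)
        mat[idx, j] = rows["log2fc"].to_numpy()
    return FCMatrix(genes=genes, contrasts=[t.contrast_id for t in tables], masked_lfc=mat)


def drop_empty_contrasts(m: FCMatrix) -> FCMatrix:
    """Remove contrasts in which no gene passed the significance mask."""
    keep = np.flatnonzero((m.masked_lfc != 0).any(axis=0))
    if keep.size == 0:
        raise ValueError("no contrast has any significant gene")
    if keep.size == len(m.contrasts):
        return m
    dropped = [c for i, c in enumerate(m.contrasts) if i not in set(keep)]
    logger.info("dropping %d all-nonsignificant contrast(s): %s", len(dropped), dropped)
    return FCMatrix(
        genes=m.genes,
        contrasts=[m.contrasts[i] for i in keep],
        masked_lfc=m.masked_lfc[:, keep],
    )


def invert_gain_of_function(m: FCMatrix, invert_ids: set[str] | frozenset[str]) -> FCMatrix:
    """Negate the fold changes of gain-of-function contrasts.

    Overexpression models perturb transcription in the direction opposite
    to loss-of-function models; sign-flipping them makes directions
    comparable before aggregation.
    """
    invert_ids = set(invert_ids)
    unknown = invert_ids - set(m.contrasts)
    if unknown:
        raise ValueError(f"invert_ids not among contrasts: {sorted(unknown)}")
    if not invert_ids:
        return m
    mat = m.masked_lfc.copy()
    for j, c in enumerate(m.contrasts):
        if c in invert_ids:
            mat[:, j] = -mat[:, j]
    return FCMatrix(genes=m.genes, contrasts=list(m.contrasts), masked_lfc=mat)


def identify_core(m: FCMatrix, cfg: ConsensusConfig) -> CoreResult:
    """Select genes significant in at least k contrasts and split by direction.

    Mean fold change is taken over the significant (non-zero) entries only;
    a mean of exactly zero is labelled "up" (deterministic tie-break on a
    measure-zero event, logged).
    """
    k = cfg.support_threshold(len(m.contrasts))
    nonzero = m.masked_lfc != 0
    support = pd.Series(nonzero.sum(axis=1), index=m.genes, name="support")
    in_core = support >= k
    core_genes = set(support.index[in_core])
    core_idx = np.flatnonzero(in_core.to_numpy())
    sums = m.masked_lfc[core_idx].sum(axis=1)
    counts = nonzero[core_idx].sum(axis=1)
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    gene_order = [m.genes[i] for i in core_idx]
    mean_lfc = pd.Series(means, index=gene_order, name="mean_lfc")
    n_zero = int((means == 0).sum())
    if n_zero:
        logger.warning("%d core gene(s) with mean fold change exactly 0 labelled 'up'", n_zero)
    direction = pd.Series(
        np.where(means > 0, "up", np.where(means < 0, "down", "up")),
        index=gene_order,
        name="direction",
    )
    return CoreResult(core_genes=core_genes, support=support, mean_lfc=mean_lfc, direction=direction)


def run_core_pipeline(
    tables: list[ContrastTable], cfg: ConsensusConfig
) -> tuple[FCMatrix, CoreResult]:
    """Full pipeline: mask, drop empty contrasts, invert, identify."""
    m = build_fc_matrix(tables, cfg)
    m = drop_empty_contrasts(m)
    m = invert_gain_of_function(m, cfg.invert_ids & set(m.contrasts))
    return m, identify_core(m, cfg)


def concordance_profile(m: FCMatrix) -> pd.Series:
    """Per-gene fraction of significant appearances that are upregulated.

    Values of 0 or 1 indicate full directional consistency; genes with no
    significant appearance are NaN (flagged undefined).
    """
    nonzero = m.masked_lfc != 0
    n_sig = nonzero.sum(axis=1).astype(float)
    n_up = (m.masked_lfc > 0).sum(axis=1).astype(float)
    frac = np.divide(n_up, n_sig, out=np.full_like(n_sig, np.nan), where=n_sig > 0)
    return pd.Series(frac, index=m.genes, name="concordance")


def grid_core_counts(
    tables: list[ContrastTable],
    alphas: list[float],
    ks: list[int],
    invert_ids: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Core sizes over an FDR-threshold x support-threshold grid.

    Returns one row per (alpha, k) with columns alpha, k, n_core, n_up,
    n_down; n_core is non-increasing in k at fixed alpha.
    """
    rows = []
    for alpha in alphas:
        cfg = ConsensusConfig(alpha=alpha, min_contrasts=1, invert_ids=frozenset(invert_ids))
        m = build_fc_matrix(tables, cfg)
        m = drop_empty_contrasts(m)
        m = invert_gain_of_function(m, set(invert_ids) & set(m.contrasts))
        for k in ks:
            res = identify_core(m, ConsensusConfig(alpha=alpha, min_contrasts=k, invert_ids=frozenset(invert_ids)))
            rows.append(
                {
                    "alpha": alpha,
                    "k": k,
                    "n_core": len(res.core_genes),
                    "n_up": len(res.core_up),
                    "n_down": len(res.core_down),
                }
            )
    return pd.DataFrame(rows)


def subgroup_core(
    tables: list[ContrastTable],
    metadata: list[ContrastMetadata],
    feature: str,
    value: str,
    cfg: ConsensusConfig,
) -> CoreResult:
    """Core identification restricted to contrasts matching a metadata value.

    The support threshold is re-resolved against the size of the selected
    subset when the config specifies a fraction.
    """
    by_id = {m.contrast_id: m for m in metadata}
    selected = []
    for t in tables:
        meta = by_id.get(t.contrast_id)
        if meta is None:
            raise ValueError(f"no metadata for contrast {t.contrast_id!r}")
        if str(getattr(meta, feature)) == value:
            selected.append(t)
    if not selected:
        raise ValueError(f"no contrast with {feature}={value!r}")
    _, res = run_core_pipeline(selected, cfg)
    return res
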