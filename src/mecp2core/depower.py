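"""Two-group differential expression and replicate down-sampling power.

The DE caller is a deliberately desk-scale negative binomial Wald test:
median-of-ratios size factors, a loose expression filter, per-gene moment
dispersion estimates shrunk toward a 1/mean + constant trend, a Wald
z-statistic on the log2 ratio of group means, and Benjamini–Hochberg
adjustment over the tested genes. The down-sampling experiment repeatedly
draws smaller balanced designs from a large two-group count matrix,
re-runs the caller, and records DEG counts at fold-change cutoffs plus
the Rand index of each drawing's DEG partition against the full-data
partition — quantifying how replicate number limits detection when most
true effects are below two-fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import rand_score
from statsmodels.stats.multitest import multipletests

from mecp2core.io import ContrastTable, CountMatrix

logger = logging.getLogger(__name__)

_MIN_DISPERSION = 1e-8
# prior weight (in pseudo-samples) pulling gene-wise dispersions to the trend
_DISPERSION_PRIOR_N = 20.0
_LFC_PSEUDOCOUNT = 0.5


@dataclass
class DEResult:
    """ContrastTable plus per-gene fit diagnostics and the filter mask."""

    table: ContrastTable
    base_mean: pd.Series
    dispersion: pd.Series
    filter_mask: pd.Series  # over all genes of the input matrix

    @property
    def data(self) -> pd.DataFrame:
        return self.table.data

    def deg_genes(self, fdr_threshold: float, fc_ratio: float = 1.0) -> set[str]:
        """DEGs at an FDR threshold and a fold-change ratio cutoff.

        ``fc_ratio`` is on the linear scale (1.2 = "20% changed"); the
        comparison is |log2fc| >= log2(fc_ratio), so 1.0 means any FC.
        """
        df = self.data
        keep = (df["fdr"].to_numpy() <= fdr_threshold) & (
            np.abs(df["log2fc"].to_numpy()) >= np.log2(fc_ratio)
        )
        return set(df.loc[keep, "gene"])


@dataclass
class PowerConfig:
    """Design of the down-sampling experiment."""

    sample_sizes: list[int] = field(default_factory=lambda: [10, 9, 8, 7, 6, 5, 4, 3])
    n_reps: int = 100
    fdr_threshold: float = 0.01
    fc_cutoffs: list[float] = field(default_factory=lambda: [1.0, 1.1, 1.2])
    seed: int = 0

    def __post_init__(self) -> None:
        self.sample_sizes = sorted({int(n) for n in self.sample_sizes}, reverse=True)
        if min(self.sample_sizes) < 2:
            raise ValueError("sample sizes must be >= 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if any(c < 1.0 for c in self.fc_cutoffs):
            raise ValueError("fold-change cutoffs are linear ratios >= 1")


def expression_filter(
    cm: CountMatrix, min_count: int = 10, min_fraction: float = 0.5
) -> np.ndarray:
    """Loose expression filter: count >= min_count in >= min_fraction of samples."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    need = int(np.ceil(min_fraction * len(cm.samples)))
    return (cm.counts >= min_count).sum(axis=1) >= need


def size_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios library-size factors, rescaled to geometric mean 1.

    Uses genes with non-zero counts in every sample; when none exist,
    falls back to per-gene geometric means over positive counts only
    (logged).
    """
    counts = cm.counts.astype(float)
    if counts.shape[1] == 1:
        return np.ones(1)
    all_pos = (counts > 0).all(axis=1)
    if all_pos.any():
        sub = counts[all_pos]
        log_gm = np.mean(np.log(sub), axis=1, keepdims=True)
        ratios = np.log(sub) - log_gm
        sf = np.exp(np.median(ratios, axis=0))
    else:
        logger.info("no gene positive in all samples; using positive-count fallback")
        any_pos = (counts > 0).any(axis=1)
        if not any_pos.any():
            raise ValueError("no usable genes for size-factor estimation")
        sub = counts[any_pos]
        with np.errstate(divide="ignore"):
            logc = np.where(sub > 0, np.log(sub), np.nan)
        log_gm = np.nanmean(logc, axis=1, keepdims=True)
        ratios = logc - log_gm
        sf = np.exp(np.nanmedian(ratios, axis=0))
        if np.isnan(sf).any():
            raise ValueError("size factor undefined for some samples")
    return sf / np.exp(np.mean(np.log(sf)))


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fit_dispersion_trend(means: np.ndarray, disps: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu to gene-wise moment estimates.

    One round of least squares on genes with informative estimates,
    followed by a refit excluding >10x outliers; coefficients floored at
    zero so the trend stays a valid dispersion.
    """
    ok = (disps > _MIN_DISPERSION * 10) & (means > 0)
    if ok.sum() < 10:
        level = float(np.median(disps[disps > 0])) if (disps > 0).any() else 0.01
        return np.full_like(means, max(level, _MIN_DISPERSION))
    x = np.column_stack([np.ones(ok.sum()), 1.0 / means[ok]])
    y = disps[ok]
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    for _round in range(1):
        fit = x @ coef
        keep = (y < 10 * np.maximum(fit, _MIN_DISPERSION)) & (
            y > 0.1 * np.maximum(fit, _MIN_DISPERSION)
        )
        if keep.sum() >= 10:
            coef, *_ = np.linalg.lstsq(x[keep], y[keep], rcond=None)
    coef = np.maximum(coef, 0.0)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.maximum(means, 1e-12)
    return np.maximum(trend, _MIN_DISPERSION)


def nb_wald_test(
    cm: CountMatrix,
    min_count: int = 10,
    min_fraction: float = 0.5,
    contrast_id: str = "contrast",
) -> DEResult:
    """Two-group NB Wald test on filter-passing genes.

    Per gene: counts are normalized by size factors; dispersion is the
    pooled within-group moment estimate (var - mean)/mean^2 floored at
    1e-8 and shrunk toward the fitted trend by a prior-weighted average
    in log space; log2 fold change is the pseudocounted ratio of group
    means; the Wald z uses the NB variance of each group mean. BH
    adjustment runs over tested genes only.
    """
    case = cm.columns("case")
    ctrl = cm.columns("control")
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("both groups need >= 2 samples")
    if cm.counts[:, case].sum() == 0 or cm.counts[:, ctrl].sum() == 0:
        raise ValueError("a group has an all-zero library")
    mask = expression_filter(cm, min_count, min_fraction)
    if not mask.any():
        raise ValueError("no gene passes the expression filter")
    sf = size_factors(cm)
    q = cm.counts.astype(float) / sf  # normalized counts
    qf = q[mask]
    q1, q2 = qf[:, case], qf[:, ctrl]
    n1, n2 = len(case), len(ctrl)
    m1, m2 = q1.mean(axis=1), q2.mean(axis=1)
    base_mean = qf.mean(axis=1)

    # pooled within-group moment dispersion
    v1 = q1.var(axis=1, ddof=1)
    v2 = q2.var(axis=1, ddof=1)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    # shot-noise term of normalized counts is mu * mean(1/sf)
    shot = grand * np.mean(1.0 / sf)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_gene = (pooled_var - shot) / np.maximum(grand, 1e-12) ** 2
    disp_gene = np.maximum(np.nan_to_num(disp_gene), _MIN_DISPERSION)
    trend = _fit_dispersion_trend(grand, disp_gene)
    n_obs = n1 + n2 - 2
    w = n_obs / (n_obs + _DISPERSION_PRIOR_N)
    disp = np.exp(w * np.log(disp_gene) + (1 - w) * np.log(trend))

    lfc = np.log2((m1 + _LFC_PSEUDOCOUNT) / (m2 + _LFC_PSEUDOCOUNT))
    inv_sf_case = np.mean(1.0 / sf[case])
    inv_sf_ctrl = np.mean(1.0 / sf[ctrl])
    var_m1 = (m1 * inv_sf_case + disp * m1**2) / n1
    var_m2 = (m2 * inv_sf_ctrl + disp * m2**2) / n2
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_m1 / (m1 + _LFC_PSEUDOCOUNT) ** 2 + var_m2 / (m2 + _LFC_PSEUDOCOUNT) ** 2
    ) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, 0.0, 1.0)
    dead = (m1 == 0) & (m2 == 0)
    pvals[dead] = 1.0
    fdr = bh_adjust(pvals)

    genes = [g for g, keep in zip(cm.genes, mask) if keep]
    table = ContrastTable(
        contrast_id=contrast_id,
        data=pd.DataFrame(
            {"gene": genes, "log2fc": lfc, "pvalue": pvals, "fdr": fdr}
        ),
    )
    return DEResult(
        table=table,
        base_mean=pd.Series(base_mean, index=genes, name="base_mean"),
        dispersion=pd.Series(disp, index=genes, name="dispersion"),
        filter_mask=pd.Series(mask, index=cm.genes, name="filter_mask"),
    )


def rand_index(a: np.ndarray | list, b: np.ndarray | list) -> float:
    """Rand index between two binary partitions of the same genes.

    The fraction of gene pairs co-clustered in both vectors or separated
    in both; symmetric and invariant to complementing labels.
    """
    a = np.asarray(a).astype(int)
    b = np.asarray(b).astype(int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if len(a) < 2:
        raise ValueError("need at least two elements")
    return float(rand_score(a, b))


def _deg_indicator(de: DEResult, all_genes: list[str], fdr_threshold: float) -> np.ndarray:
    degs = de.deg_genes(fdr_threshold)
    return np.fromiter((g in degs for g in all_genes), dtype=bool, count=len(all_genes))


def downsampling_experiment(cm: CountMatrix, cfg: PowerConfig) -> pd.DataFrame:
    """Replicate down-sampling power analysis.

    For each n in ``cfg.sample_sizes`` and each of ``cfg.n_reps``
    repetitions, n samples per group are drawn without replacement
    (independent RNG substream per (n, rep), so adding reps never
    perturbs earlier drawings), size factors are recomputed within the
    drawing, the NB Wald test is re-run, and DEG counts at each
    fold-change cutoff plus the Rand index against the full-data DEG
    partition are recorded. Returns one row per (n, rep).
    """
    case = cm.columns("case")
    ctrl = cm.columns("control")
    n_max = max(cfg.sample_sizes)
    if n_max > min(len(case), len(ctrl)):
        raise ValueError("requested sample size exceeds a group size")
    full = nb_wald_test(cm)
    full_ind = _deg_indicator(full, cm.genes, cfg.fdr_threshold)
    rows = []
    for n in cfg.sample_sizes:
        for rep in range(cfg.n_reps):
            rng = np.random.default_rng([cfg.seed, n, rep])
            pick = np.concatenate(
                [
                    rng.choice(case, size=n, replace=False),
                    rng.choice(ctrl, size=n, replace=False),
                ]
            )
            de = nb_wald_test(cm.subset_samples(pick))
            row: dict[str, float] = {"n_per_group": n, "rep": rep}
            for cut in cfg.fc_cutoffs:
                row[f"n_deg_fc_{cut:g}"] = len(de.deg_genes(cfg.fdr_threshold, cut))
            ind = _deg_indicator(de, cm.genes, cfg.fdr_threshold)
            row["rand_index"] = rand_index(ind, full_ind)
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_power_curve(curve: pd.DataFrame) -> pd.DataFrame:
    """Box-plot statistics (min, Q1, median, Q3, max) per sample size."""
    value_cols = [c for c in curve.columns if c.startswith("n_deg_") or c == "rand_index"]
    out = []
    for n, grp in curve.groupby("n_per_group"):
        for col in value_cols:
            v = grp[col].to_numpy(dtype=float)
            out.append(
                {
                    "n_per_group": n,
                    "metric": col,
                    "min": v.min(),
                    "q1": np.percentile(v, 25),
                    "median": np.median(v),
                    "q3": np.percentile(v, 75),
                    "max": v.max(),
                    "mean": v.mean(),
                }
            )
    return pd.DataFrame(out)


def fc_survival_curve(
    de: DEResult, fdr_threshold: float, grid: np.ndarray | list[float]
) -> pd.DataFrame:
    """Percent of DEGs surviving |log2FC| cutoffs, and the 50% crossing.

    Returns a frame with columns ``cutoff`` and ``pct_remaining``; the
    first grid cutoff at which fewer than half the DEGs remain is exposed
    via the ``attrs['half_loss_cutoff']`` entry (NaN when never crossed).
    """
    df = de.data
    degs = df.loc[df["fdr"].to_numpy() <= fdr_threshold, "log2fc"].abs().to_numpy()
    if degs.size == 0:
        raise ValueError("no DEG at the requested threshold")
    grid = np.asarray(list(grid), dtype=float)
    pct = np.array([100.0 * np.mean(degs >= c) for c in grid])
    out = pd.DataFrame({"cutoff": grid, "pct_remaining": pct})
    below = np.flatnonzero(pct < 50.0)
    out.attrs["half_loss_cutoff"] = float(grid[below[0]]) if below.size else float("nan")
    return out
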