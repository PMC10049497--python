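"""Synthetic inputs with full ground truth for recovery testing.

Three generators emulate the statistical structure of a many-contrast
MeCP2-style meta-analysis: (1) per-contrast DE summary tables with a
planted concordant core, per-contrast noise, and a few direction-inverted
gain-of-function contrasts; (2) gene annotation with biotype categories
and TSS positions, optionally with a planted positional cluster; (3)
two-group negative binomial count matrices with planted, mostly
sub-two-fold effects (the low signal-to-noise regime the power analysis
probes). All generators are pure functions of their arguments, including
the seed.

A background gene's spurious significance events are drawn at
``background_sig_rate`` per contrast but truncated so that no background
gene is significant in 5% or more of the contrasts: without the
truncation a background gene would occasionally satisfy the core
definition outright, and "recovery of the planted truth" would no longer
be a well-posed benchmark (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mecp2core.io import (
    CATEGORIES,
    AnnotationTable,
    ContrastMetadata,
    ContrastTable,
    CountMatrix,
)

_DEFAULTS_PATH = Path(__file__).with_name("defaults.yaml")


def default_parameters() -> dict:
    """The versioned default generator parameters shipped with the package."""
    with open(_DEFAULTS_PATH) as fh:
        return yaml.safe_load(fh)


@dataclass
class MultiContrastTruth:
    core_up: set[str]
    core_down: set[str]
    concordant_contrasts: set[str]
    inverted_contrasts: set[str]
    planted_lfc: dict[str, float]


@dataclass
class CountTruth:
    de_genes: set[str]
    planted_lfc: dict[str, float]
    dispersion: dict[str, float]
    size_factor: dict[str, float]


def generate_annotation(
    n_genes: int,
    n_chroms: int = 19,
    biotype_fractions: dict[str, float] | None = None,
    seed: int = 0,
) -> AnnotationTable:
    """Random annotation: categories multinomial, chromosomes uniform,
    TSS uniform on [1, 2e8].

    Default category fractions roughly match a GENCODE-style genome
    (~41% protein-coding).
    """
    if biotype_fractions is None:
        biotype_fractions = {
            "protein_coding": 0.41,
            "lncRNA": 0.20,
            "ncRNA": 0.05,
            "pseudogene": 0.22,
            "small_rna": 0.06,
            "ig_tr": 0.01,
            "tec": 0.03,
            "other": 0.02,
        }
    unknown = set(biotype_fractions) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    probs = np.array([biotype_fractions.get(c, 0.0) for c in CATEGORIES])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("biotype fractions must sum to 1")
    rng = np.random.default_rng(seed)
    cats = rng.choice(len(CATEGORIES), size=n_genes, p=probs)
    width = len(str(max(n_genes, 1)))
    genes = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    df = pd.DataFrame(
        {
            "gene": genes,
            "biotype": [CATEGORIES[c] for c in cats],
            "category": [CATEGORIES[c] for c in cats],
            "chromosome": [f"chr{c}" for c in rng.integers(1, n_chroms + 1, size=n_genes)],
            "tss": rng.integers(1, 200_000_001, size=n_genes),
        }
    )
    return AnnotationTable(data=df)


def plant_positional_cluster(
    ann: AnnotationTable,
    genes: set[str],
    chromosome: str,
    start: int,
    end: int,
    seed: int = 0,
) -> AnnotationTable:
    """Relocate genes to one chromosome with TSS uniform in [start, end]."""
    if start >= end:
        raise ValueError("start must be < end")
    missing = genes - set(ann.data["gene"])
    if missing:
        raise ValueError(f"genes not in annotation: {sorted(missing)[:5]}")
    if not genes:
        return AnnotationTable(data=ann.data.copy())
    rng = np.random.default_rng(seed)
    df = ann.data.copy()
    # draw in sorted-gene order so the result depends only on the set
    targets = sorted(genes)
    tss = rng.integers(start, end + 1, size=len(targets))
    loc = df.set_index("gene")
    loc.loc[targets, "chromosome"] = chromosome
    loc.loc[targets, "tss"] = tss
    return AnnotationTable(data=loc.reset_index())


def _draw_fdr(rng: np.random.Generator, size: int, significant: bool, alpha: float) -> np.ndarray:
    if significant:
        return rng.uniform(1e-6, alpha, size=size)
    return rng.uniform(alpha, 1.0, size=size)


def generate_multi_contrast(
    n_genes: int = 5000,
    n_contrasts: int = 40,
    n_core_up: int = 150,
    n_core_down: int = 120,
    concordance: float = 0.6,
    mean_core_lfc: float = 0.6,
    noise_sd: float = 0.2,
    background_sig_rate: float = 0.03,
    inverted_ids: tuple[str, ...] | None = None,
    alpha: float = 0.01,
    max_background_frac: float = 0.05,
    seed: int = 0,
) -> tuple[list[ContrastTable], list[ContrastMetadata], MultiContrastTruth]:
    """Multi-contrast DE tables with a planted concordant core.

    Core genes carry a signed ~N(mean_core_lfc, noise_sd) fold change and
    are significant (FDR drawn below ``alpha``) in a Bernoulli
    (``concordance``) subset of contrasts. Background genes are
    spuriously significant at ``background_sig_rate`` per contrast,
    sign-symmetric, with per-gene significant-contrast counts truncated
    below ``max_background_frac`` of the contrasts. Contrasts listed in
    ``inverted_ids`` (default: the last two, emulating gain-of-function
    models) have every true signal sign-flipped at generation.
    """
    if n_core_up + n_core_down > n_genes:
        raise ValueError("more core genes than genes")
    if not (0.0 < concordance <= 1.0):
        raise ValueError("concordance must be in (0, 1]")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = np.array([f"G{i:0{width}d}" for i in range(1, n_genes + 1)])
    contrast_ids = [f"C{j:02d}" for j in range(1, n_contrasts + 1)]
    if inverted_ids is None:
        inverted_ids = tuple(contrast_ids[-2:]) if n_contrasts >= 2 else ()
    unknown = set(inverted_ids) - set(contrast_ids)
    if unknown:
        raise ValueError(f"inverted ids not among contrasts: {sorted(unknown)}")

    core_up = set(genes[:n_core_up])
    core_down = set(genes[n_core_up : n_core_up + n_core_down])
    n_core = n_core_up + n_core_down
    sign = np.concatenate([np.ones(n_core_up), -np.ones(n_core_down)])
    planted = dict(zip(genes[:n_core], sign * mean_core_lfc))

    # per-core-gene significance indicators, Bernoulli(concordance)
    core_sig = rng.random((n_core, n_contrasts)) < concordance
    # background significance: Bernoulli(rate) truncated below the cap
    n_bg = n_genes - n_core
    cap = int(np.ceil(max_background_frac * n_contrasts)) - 1
    cap = max(cap, 1)
    bg_support = rng.binomial(n_contrasts, background_sig_rate, size=n_bg)
    bg_support = np.minimum(bg_support, cap)
    bg_sig = np.zeros((n_bg, n_contrasts), dtype=bool)
    for i, s in enumerate(bg_support):
        if s:
            bg_sig[i, rng.choice(n_contrasts, size=s, replace=False)] = True

    tables: list[ContrastTable] = []
    meta: list[ContrastMetadata] = []
    tissues = ["cortex", "forebrain", "hippocampus", "cerebellum"]
    fractions = ["whole_cell", "nucleus", "chromatin"]
    sexes = ["male", "female", "mixed"]
    for j, cid in enumerate(contrast_ids):
        flip = -1.0 if cid in inverted_ids else 1.0
        lfc = np.empty(n_genes)
        fdr = np.empty(n_genes)
        # core genes
        mags = rng.normal(mean_core_lfc, noise_sd, size=n_core)
        lfc[:n_core] = flip * sign * mags
        sig_mask = core_sig[:, j]
        fdr[:n_core] = np.where(
            sig_mask,
            _draw_fdr(rng, n_core, True, alpha),
            _draw_fdr(rng, n_core, False, alpha),
        )
        lfc[:n_core] = np.where(
            sig_mask, lfc[:n_core], rng.normal(0.0, noise_sd, size=n_core)
        )
        # background genes: sign-symmetric
        bg_signs = rng.choice([-1.0, 1.0], size=n_bg)
        bg_mags = rng.normal(mean_core_lfc, noise_sd, size=n_bg)
        bmask = bg_sig[:, j]
        lfc[n_core:] = np.where(
            bmask, flip * bg_signs * bg_mags, rng.normal(0.0, noise_sd, size=n_bg)
        )
        fdr[n_core:] = np.where(
            bmask,
            _draw_fdr(rng, n_bg, True, alpha),
            _draw_fdr(rng, n_bg, False, alpha),
        )
        pval = fdr * rng.uniform(0.1, 1.0, size=n_genes)
        tables.append(
            ContrastTable(
                contrast_id=cid,
                data=pd.DataFrame(
                    {"gene": genes, "log2fc": lfc, "pvalue": pval, "fdr": fdr}
                ),
            )
        )
        meta.append(
            ContrastMetadata(
                contrast_id=cid,
                study_id=f"S{1 + j // 2}",
                tissue=tissues[j % len(tissues)],
                cell_fraction=fractions[j % len(fractions)],
                sex=sexes[j % len(sexes)],
                species="mouse",
                model_class="gain_of_function" if cid in inverted_ids else "loss_of_function",
                n_case=int(rng.integers(3, 6)),
                n_control=int(rng.integers(3, 6)),
            )
        )
    truth = MultiContrastTruth(
        core_up=core_up,
        core_down=core_down,
        concordant_contrasts=set(contrast_ids) - set(inverted_ids),
        inverted_contrasts=set(inverted_ids),
        planted_lfc=planted,
    )
    return tables, meta, truth


def generate_counts(
    n_genes: int = 2000,
    n_per_group: int = 20,
    de_fraction: float = 0.15,
    lfc_distribution: str = "exponential",
    lfc_mean: float = 0.5,
    lfc_sd: float = 0.2,
    dispersion_mean: float = 0.02,
    dispersion_asymptote: float = 0.005,
    size_factor_sd: float = 0.1,
    base_mean_log_mu: float = np.log(100.0),
    base_mean_log_sd: float = 1.7,
    seed: int = 0,
) -> tuple[CountMatrix, CountTruth]:
    """Two-group NB count matrix with planted, mostly sub-two-fold DE.

    Baseline means are log-normal; per-gene dispersions follow the usual
    declining trend ``a0 + a1/mu`` (value ``dispersion_mean`` at the
    median baseline, asymptote ``dispersion_asymptote`` for high-count
    genes) with multiplicative inverse-gamma gene-to-gene noise; library
    size factors are log-normal with log-sd ``size_factor_sd``. Planted
    effects are sign-symmetric with |log2FC| magnitudes drawn from
    ``lfc_distribution``: "exponential" (mean ``lfc_mean``; many subtle
    effects, most below two-fold — the low signal-to-noise regime) or
    "halfnormal" (|N(lfc_mean, lfc_sd)|).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]
    n_samples = 2 * n_per_group
    samples = [f"case_{i}" for i in range(1, n_per_group + 1)] + [
        f"control_{i}" for i in range(1, n_per_group + 1)
    ]
    group = ["case"] * n_per_group + ["control"] * n_per_group

    base = rng.lognormal(base_mean_log_mu, base_mean_log_sd, size=n_genes)
    median_base = np.exp(base_mean_log_mu)
    a1 = max(dispersion_mean - dispersion_asymptote, 0.0) * median_base
    trend = dispersion_asymptote + a1 / base
    shape = 4.0
    disp = trend * (shape - 1) / rng.gamma(shape, 1.0, size=n_genes)
    sf = rng.lognormal(0.0, size_factor_sd, size=n_samples) if size_factor_sd > 0 else np.ones(n_samples)

    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    lfc = np.zeros(n_genes)
    if n_de:
        if lfc_distribution == "exponential":
            mags = rng.exponential(lfc_mean, size=n_de)
        elif lfc_distribution == "halfnormal":
            mags = np.abs(rng.normal(lfc_mean, lfc_sd, size=n_de))
        else:
            raise ValueError(f"unknown lfc_distribution {lfc_distribution!r}")
        lfc[de_idx] = rng.choice([-1.0, 1.0], size=n_de) * mags

    is_case = np.array([g == "case" for g in group])
    mu = base[:, None] * sf[None, :] * np.power(2.0, lfc[:, None] * is_case[None, :])
    r = 1.0 / disp[:, None]  # NB size parameter
    p = r / (r + mu)
    counts = rng.negative_binomial(np.broadcast_to(r, mu.shape), p)

    truth = CountTruth(
        de_genes={genes[i] for i in de_idx},
        planted_lfc={genes[i]: float(lfc[i]) for i in de_idx},
        dispersion=dict(zip(genes, disp)),
        size_factor=dict(zip(samples, sf)),
    )
    return (
        CountMatrix(genes=genes, samples=samples, counts=counts, group=group),
        truth,
    )
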