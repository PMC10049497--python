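"""Tabular input/output for the meta-analysis.

All artifacts travel as tab-delimited UTF-8 text with a header row ("." or
empty for missing). Five table kinds are supported: per-contrast
differential-expression summaries, contrast metadata, gene annotation,
ortholog maps, and two-group count matrices (TSV or MatrixMarket).
Gene identifiers are opaque strings; GENCODE-style version suffixes
(``ENSMUSG...​.N``) are stripped by default so tables from different
annotation releases join cleanly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: the eight broad annotation super-categories used for composition analysis
CATEGORIES = (
    "protein_coding",
    "lncRNA",
    "ncRNA",
    "pseudogene",
    "small_rna",
    "ig_tr",
    "tec",
    "other",
)

CELL_FRACTIONS = ("chromatin", "nucleus", "whole_cell", "other")
SEXES = ("male", "female", "mixed", "unknown")
MODEL_CLASSES = ("loss_of_function", "gain_of_function")

_VERSION_RE = re.compile(r"\.\d+$")


class FormatError(ValueError):
    """Raised when a table violates its declared format or invariants."""


def strip_gene_version(gene: str) -> str:
    """Drop a trailing ``.N`` version suffix from a gene identifier."""
    return _VERSION_RE.sub("", gene)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ContrastTable:
    """Per-gene log2 fold change / p-value / BH-FDR summary of one contrast.

    ``data`` has columns ``gene`` (unique strings), ``log2fc`` (finite,
    case over control), ``pvalue`` and ``fdr`` (both in [0, 1]).
    """

    contrast_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "log2fc", "pvalue", "fdr"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"contrast table missing column(s): {missing}")
        self.data = self.data[required].reset_index(drop=True)
        genes = self.data["gene"]
        if genes.isna().any():
            raise FormatError("contrast table has missing gene ids")
        dup = genes[genes.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate gene id(s): {sorted(set(dup))[:5]}")
        for col in ("log2fc", "pvalue", "fdr"):
            vals = self.data[col].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise FormatError(f"non-finite value in column {col!r}")
        for col in ("pvalue", "fdr"):
            vals = self.data[col].to_numpy(dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                raise FormatError(f"column {col!r} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> list[str]:
        return self.data["gene"].tolist()


@dataclass
class ContrastMetadata:
    """Study-level annotation of one contrast (Sankey-plot axes)."""

    contrast_id: str
    study_id: str
    tissue: str
    cell_fraction: str
    sex: str
    species: str
    model_class: str
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        cf = str(self.cell_fraction).strip().lower().replace(" ", "_")
        if cf not in CELL_FRACTIONS:
            logger.warning(
                "contrast %s: unknown cell_fraction %r mapped to 'other'",
                self.contrast_id,
                self.cell_fraction,
            )
            cf = "other"
        self.cell_fraction = cf
        sex = str(self.sex).strip().lower()
        if sex not in SEXES:
            sex = "unknown"
        self.sex = sex
        mc = str(self.model_class).strip().lower().replace(" ", "_")
        if mc not in MODEL_CLASSES:
            raise FormatError(
                f"contrast {self.contrast_id}: invalid model_class {self.model_class!r}"
            )
        self.model_class = mc
        self.n_case = int(self.n_case)
        self.n_control = int(self.n_control)
        if self.n_case < 1 or self.n_control < 1:
            raise FormatError(f"contrast {self.contrast_id}: non-positive group size")


@dataclass
class AnnotationTable:
    """Gene annotation: biotype, broad category, chromosome and TSS.

    ``data`` columns: ``gene`` (unique), ``biotype``, ``category`` (one of
    :data:`CATEGORIES`), ``chromosome``, ``tss`` (1-based, >= 1).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "biotype", "category", "chromosome", "tss"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"annotation missing column(s): {missing}")
        self.data = self.data[required].reset_index(drop=True)
        if self.data["gene"].duplicated().any():
            raise FormatError("duplicate gene id in annotation")
        bad = set(self.data["category"]) - set(CATEGORIES)
        if bad:
            raise FormatError(f"unknown annotation categories: {sorted(bad)}")
        tss = self.data["tss"].to_numpy(dtype=np.int64)
        if (tss < 1).any():
            raise FormatError("tss must be >= 1 (1-based coordinates)")
        self.data["tss"] = tss

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class OrthologMap:
    """Cross-species gene mapping with a match score per pair."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["source_gene", "target_gene", "score"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"ortholog map missing column(s): {missing}")
        self.data = self.data[required].reset_index(drop=True)
        if self.data["score"].isna().any():
            raise FormatError("ortholog map has missing scores")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CountMatrix:
    """Genes x samples integer count matrix with a two-group design."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray
    group: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise FormatError("counts must be integral")
            self.counts = as_int
        if (self.counts < 0).any():
            raise FormatError("counts must be non-negative")
        if len(self.group) != len(self.samples):
            raise FormatError("one group label per sample required")
        bad = set(self.group) - {"case", "control"}
        if bad:
            raise FormatError(f"invalid group label(s): {sorted(bad)}")
        for g in ("case", "control"):
            if g not in self.group:
                raise FormatError(f"group {g!r} is empty")

    def columns(self, group: str) -> np.ndarray:
        """Indices of the samples belonging to ``group``."""
        return np.flatnonzero(np.asarray(self.group) == group)

    def subset_samples(self, idx: np.ndarray | list[int]) -> "CountMatrix":
        idx = np.asarray(idx, dtype=int)
        return CountMatrix(
            genes=list(self.genes),
            samples=[self.samples[i] for i in idx],
            counts=self.counts[:, idx],
            group=[self.group[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {"gene": "gene", "log2fc": "log2fc", "pvalue": "pvalue", "fdr": "fdr"}


def load_column_config(path: str | Path) -> dict[str, str]:
    """Read a YAML mapping of canonical to file-specific column names."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return {**_DEFAULT_COLUMNS, **{k: str(v) for k, v in cfg.items()}}


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["."], keep_default_na=True)


def read_contrast_table(
    path: str | Path,
    contrast_id: str,
    columns: dict[str, str] | None = None,
    strip_versions: bool = True,
) -> ContrastTable:
    """Read one contrast's DE summary TSV into a validated table.

    ``columns`` maps the canonical names gene/log2fc/pvalue/fdr to the
    names used in the file.
    """
    colmap = {**_DEFAULT_COLUMNS, **(columns or {})}
    raw = _read_tsv(path)
    for canonical, actual in colmap.items():
        if actual not in raw.columns:
            raise FormatError(f"{path}: missing column {actual!r} (for {canonical})")
    df = raw.rename(columns={v: k for k, v in colmap.items()})
    for col in ("log2fc", "pvalue", "fdr"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            line = int(bad.index[bad.isna() & df[col].notna()][0]) + 2  # header + 1-based
            raise FormatError(f"{path}: non-numeric {col!r} at line {line}") from exc
    df["gene"] = df["gene"].astype(str)
    if strip_versions:
        df["gene"] = df["gene"].map(strip_gene_version)
    return ContrastTable(contrast_id=contrast_id, data=df)


def write_contrast_table(table: ContrastTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_metadata(path: str | Path) -> list[ContrastMetadata]:
    """Read contrast metadata; enums are normalized case-insensitively."""
    df = _read_tsv(path)
    required = [
        "contrast_id",
        "study_id",
        "tissue",
        "cell_fraction",
        "sex",
        "species",
        "model_class",
        "n_case",
        "n_control",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing column(s): {missing}")
    if df["contrast_id"].duplicated().any():
        dup = df["contrast_id"][df["contrast_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate contrast_id {dup!r}")
    if df["model_class"].isna().any():
        raise FormatError(f"{path}: model_class missing for some contrasts")
    return [ContrastMetadata(**{k: row[k] for k in required}) for _, row in df.iterrows()]


def write_metadata(meta: list[ContrastMetadata], path: str | Path) -> None:
    pd.DataFrame([vars(m) for m in meta]).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path, strip_versions: bool = True) -> AnnotationTable:
    df = _read_tsv(path)
    df["gene"] = df["gene"].astype(str)
    if strip_versions:
        df["gene"] = df["gene"].map(strip_gene_version)
    return AnnotationTable(data=df)


def write_annotation(ann: AnnotationTable, path: str | Path) -> None:
    ann.data.to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    df = _read_tsv(path)
    df["source_gene"] = df["source_gene"].astype(str)
    df["target_gene"] = df["target_gene"].astype(str)
    return OrthologMap(data=df)


def read_count_matrix(path: str | Path, groups: dict[str, str] | str | Path) -> CountMatrix:
    """Read a genes x samples TSV (first column gene ids) plus group labels.

    ``groups`` is either a sample -> {case, control} mapping or a path to a
    two-column TSV (sample, group).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if isinstance(groups, (str, Path)):
        gdf = pd.read_csv(groups, sep="\t")
        groups = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)))
    samples = [str(s) for s in df.columns]
    missing = [s for s in samples if s not in groups]
    if missing:
        raise FormatError(f"no group label for sample(s): {missing}")
    return CountMatrix(
        genes=[str(g) for g in df.index],
        samples=samples,
        counts=df.to_numpy(),
        group=[groups[s] for s in samples],
    )


def read_count_matrix_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
    groups: dict[str, str],
) -> CountMatrix:
    """Read a MatrixMarket count matrix with sidecar gene/sample lists."""
    from scipy.io import mmread

    mat = mmread(mtx_path)
    if hasattr(mat, "toarray"):
        mat = mat.toarray()
    mat = np.asarray(mat)
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    return CountMatrix(genes=genes, samples=samples, counts=mat, group=[groups[s] for s in samples])


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, groups_path: str | Path) -> None:
    pd.DataFrame(cm.counts, index=cm.genes, columns=cm.samples).to_csv(
        counts_path, sep="\t", index_label="gene"
    )
    pd.DataFrame({"sample": cm.samples, "group": cm.group}).to_csv(
        groups_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# ortholog joining
# ---------------------------------------------------------------------------


def best_match_reduce(omap: OrthologMap) -> OrthologMap:
    """Keep, per source gene, only the highest-scoring target.

    Score ties are broken by lexicographically smallest target gene so the
    reduction is deterministic; the operation is idempotent.
    """
    df = omap.data
    if df.empty:
        return OrthologMap(data=df.copy())
    df = df.sort_values(
        ["source_gene", "score", "target_gene"], ascending=[True, False, True]
    )
    best = df.drop_duplicates("source_gene", keep="first").reset_index(drop=True)
    return OrthologMap(data=best)


def translate_contrast(table: ContrastTable, omap: OrthologMap) -> ContrastTable:
    """Move a contrast table into ortholog target gene space.

    Unmapped genes are dropped. When two source genes collapse onto one
    target, the more significant row (smaller FDR, then smaller gene id)
    is kept — the mapping is applied after best-match reduction, so each
    source has a single target.
    """
    reduced = best_match_reduce(omap).data
    mapping = dict(zip(reduced["source_gene"], reduced["target_gene"]))
    df = table.data.copy()
    df["_source"] = df["gene"]
    df["gene"] = df["gene"].map(mapping)
    df = df.dropna(subset=["gene"])
    df = df.sort_values(["gene", "fdr", "_source"], kind="mergesort")
    df = df.drop_duplicates("gene", keep="first").drop(columns="_source")
    return ContrastTable(contrast_id=table.contrast_id, data=df.reset_index(drop=True))
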