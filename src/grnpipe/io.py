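"""Reading, validation and normalization of NanoString-style count tables.

The central container is :class:`ExpressionMatrix`, a genes x samples table of
non-negative expression values together with the sample design (condition,
timepoint in hours, replicate) and a scale tag (``raw_counts``, ``normalized``
or ``log2``).  All downstream stages — differential expression, hierarchical
clustering, network inference — consume this container.

Normalization follows standard nCounter practice: two successive per-sample
geometric-mean scalings, first against positive-control probes, then against
housekeeping genes.  Each step multiplies every value in a sample by

    factor_s = geomean(grand) / geomean(sample)

so that the reference probes end up with equal geometric means across samples.
Both steps are pure rescalings and either can be switched off via
:class:`NormalizationConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SampleDesign",
    "ProbeAnnotation",
    "ExpressionMatrix",
    "NormalizationConfig",
    "read_counts",
    "read_design",
    "read_annotation",
    "normalize",
    "floor_low_expression",
    "log_transform",
    "invert_log_transform",
]

DESIGN_COLUMNS = ("sample_id", "condition", "timepoint_hrs", "replicate")
ANNOTATION_COLUMNS = ("gene", "is_tf", "category", "is_housekeeping", "is_positive_control")


@dataclass(frozen=True)
class SampleDesign:
    """Design metadata for one sample."""

    sample_id: str
    condition: str
    timepoint: float
    replicate: int
    batch: str | None = None

    def __post_init__(self) -> None:
        if self.timepoint <= 0:
            raise ValueError(f"timepoint must be positive, got {self.timepoint}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate}")


@dataclass(frozen=True)
class ProbeAnnotation:
    """Per-gene probe annotation."""

    gene: str
    is_tf: bool = False
    category: str | None = None
    is_housekeeping: bool = False
    is_positive_control: bool = False


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with aligned design metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample_id.
    design
        List of :class:`SampleDesign`, one per column, in column order.
    scale
        One of ``raw_counts``, ``normalized``, ``log2``.
    absent_genes
        Genes whose whole row was floored to zero (treated as absent and
        excluded from regulator/target sets downstream).
    """

    values: pd.DataFrame
    design: list[SampleDesign]
    scale: str = "raw_counts"
    absent_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.scale not in ("raw_counts", "normalized", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if len(self.design) != self.values.shape[1]:
            raise ValueError(
                f"design has {len(self.design)} samples but matrix has "
                f"{self.values.shape[1]} columns"
            )
        ids = [d.sample_id for d in self.design]
        if ids != list(self.values.columns):
            raise ValueError("design sample order does not match matrix columns")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in design")
        if self.values.index.has_duplicates:
            dups = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValueError(f"duplicate gene symbols: {dups}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.scale != "log2" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values on a linear scale")

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def present_genes(self) -> list[str]:
        """Genes not flagged absent."""
        return [g for g in self.genes if g not in self.absent_genes]

    def design_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [d.sample_id for d in self.design],
                "condition": [d.condition for d in self.design],
                "timepoint_hrs": [d.timepoint for d in self.design],
                "replicate": [d.replicate for d in self.design],
            }
        )

    def samples_where(self, condition: str | None = None, timepoint: float | None = None) -> list[str]:
        """Sample ids matching the given condition and/or timepoint."""
        out = []
        for d in self.design:
            if condition is not None and d.condition != condition:
                continue
            if timepoint is not None and d.timepoint != timepoint:
                continue
            out.append(d.sample_id)
        return out

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.design:
            seen.setdefault(d.condition, None)
        return list(seen)

    @property
    def timepoints(self) -> list[float]:
        return sorted({d.timepoint for d in self.design})


@dataclass(frozen=True)
class NormalizationConfig:
    positive_control_genes: tuple[str, ...] = ()
    housekeeping_genes: tuple[str, ...] = ()
    low_expression_floor: float = 0.00004
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.low_expression_floor < 0:
            raise ValueError("low_expression_floor must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


# -- file readers ----------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def read_design(path) -> list[SampleDesign]:
    """Read a sample-design table (columns sample_id, condition, timepoint_hrs, replicate)."""
    df = _read_table(path)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design file {path} missing columns {missing}")
    designs = [
        SampleDesign(
            sample_id=str(r.sample_id),
            condition=str(r.condition),
            timepoint=float(r.timepoint_hrs),
            replicate=int(r.replicate),
            batch=str(r.batch) if "batch" in df.columns and not pd.isna(r.batch) else None,
        )
        for r in df.itertuples()
    ]
    ids = [d.sample_id for d in designs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in design file")
    return designs


def read_annotation(path) -> list[ProbeAnnotation]:
    """Read a probe-annotation table (columns gene, is_tf, category, is_housekeeping, is_positive_control)."""
    df = _read_table(path)
    if "gene" not in df.columns:
        raise ValueError(f"annotation file {path} has no 'gene' column")

    def _bool(v) -> bool:
        if isinstance(v, str):
            return v.strip().lower() in ("true", "1", "yes")
        return bool(v) and not pd.isna(v)

    return [
        ProbeAnnotation(
            gene=str(r["gene"]),
            is_tf=_bool(r.get("is_tf", False)),
            category=None if pd.isna(r.get("category", np.nan)) else str(r["category"]),
            is_housekeeping=_bool(r.get("is_housekeeping", False)),
            is_positive_control=_bool(r.get("is_positive_control", False)),
        )
        for _, r in df.iterrows()
    ]


def read_counts(path, design) -> ExpressionMatrix:
    """Read a counts table against its sample design.

    The table must have a ``gene`` column (first column also accepted under any
    name) and exactly one numeric column per design sample.  Row order is
    preserved.
    """
    if not isinstance(design, list):
        design = read_design(design)
    df = _read_table(path)
    gene_col = "gene" if "gene" in df.columns else df.columns[0]
    genes = df[gene_col].astype(str)
    dup = sorted(genes[genes.duplicated()].unique())
    if dup:
        raise ValueError(f"duplicate gene symbols in {path}: {dup}")
    table = df.drop(columns=[gene_col])
    table.index = genes

    design_ids = [d.sample_id for d in design]
    extra = [c for c in table.columns if c not in design_ids]
    missing = [s for s in design_ids if s not in table.columns]
    if extra:
        raise ValueError(f"samples in table but not in design: {extra}")
    if missing:
        raise ValueError(f"samples in design but not in table: {missing}")
    table = table[design_ids]

    arr = table.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(arr.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-numeric cell at gene {table.index[i]!r}, sample {table.columns[j]!r}"
        )
    neg = np.argwhere(arr.to_numpy() < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative count at gene {arr.index[i]!r}, sample {arr.columns[j]!r}"
        )
    return ExpressionMatrix(values=arr.astype(float), design=list(design), scale="raw_counts")


def write_counts(m: ExpressionMatrix, path) -> None:
    out = m.values.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False)


# -- transforms ------------------------------------------------------------------


def _geometric_scale_factors(m: ExpressionMatrix, ref_genes: tuple[str, ...]) -> np.ndarray:
    missing = [g for g in ref_genes if g not in m.values.index]
    if missing:
        raise ValueError(f"reference genes absent from matrix: {missing}")
    sub = m.values.loc[list(ref_genes)].to_numpy()
    if (sub <= 0).any():
        bad = [g for g, row in zip(ref_genes, sub) if (row <= 0).any()]
        raise ValueError(
            f"reference genes with zero/negative values (geometric mean undefined): {bad}"
        )
    log_means = np.log(sub).mean(axis=0)  # per sample
    grand = log_means.mean()
    return np.exp(grand - log_means)


def normalize(m: ExpressionMatrix, cfg: NormalizationConfig) -> ExpressionMatrix:
    """Two-step geometric-mean scaling: positive controls, then housekeeping genes.

    Each step computes per-sample factors (grand geometric mean of the
    reference probes over the sample's geometric mean) and multiplies the
    sample's column by the product of its factors.  Skips a step whose gene
    list is empty, but errors if both are empty.
    """
    if m.scale == "log2":
        raise ValueError("cannot normalize a log2-scale matrix")
    if not cfg.positive_control_genes and not cfg.housekeeping_genes:
        raise ValueError("no positive-control or housekeeping genes configured")
    factors = np.ones(m.shape[1])
    if cfg.positive_control_genes:
        factors *= _geometric_scale_factors(m, tuple(cfg.positive_control_genes))
    if cfg.housekeeping_genes:
        scaled = ExpressionMatrix(m.values * factors, m.design, m.scale, m.absent_genes)
        factors *= _geometric_scale_factors(scaled, tuple(cfg.housekeeping_genes))
    return ExpressionMatrix(
        values=m.values * factors,
        design=list(m.design),
        scale="normalized",
        absent_genes=m.absent_genes,
    )


def floor_low_expression(m: ExpressionMatrix, floor: float) -> ExpressionMatrix:
    """Set values strictly below ``floor`` to 0; flag all-zero rows as absent.

    Genes flagged absent are excluded from regulator and target sets by the
    inference stage.  The comparison is strict: a value exactly equal to the
    floor is kept.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    if m.scale == "log2":
        raise ValueError("flooring applies to linear-scale values only")
    vals = m.values.where(m.values >= floor, 0.0)
    absent = frozenset(vals.index[(vals == 0).all(axis=1)]) | m.absent_genes
    return ExpressionMatrix(values=vals, design=list(m.design), scale=m.scale, absent_genes=absent)


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); monotone and invertible given the pseudocount."""
    if m.scale == "log2":
        raise ValueError("matrix is already log2-scale")
    if pseudocount <= 0 and (m.values.to_numpy() == 0).any():
        raise ValueError("pseudocount must be > 0 when zeros are present")
    vals = np.log2(m.values + pseudocount)
    return ExpressionMatrix(values=vals, design=list(m.design), scale="log2", absent_genes=m.absent_genes)


def invert_log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Inverse of :func:`log_transform`: 2**value - pseudocount."""
    if m.scale != "log2":
        raise ValueError("matrix is not log2-scale")
    vals = np.exp2(m.values) - pseudocount
    vals = vals.clip(lower=0.0)  # guard tiny negative round-off
    return ExpressionMatrix(values=vals, design=list(m.design), scale="normalized", absent_genes=m.absent_genes)
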