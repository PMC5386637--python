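"""Expression-matrix handling: RPKM computation, the mean-RPKM expression
filter, low/medium/high categorization, annotation merging and the
two-group Mann-Whitney comparison.

Matrices are plain pandas DataFrames, feature rows x sample columns,
non-negative and on the RPKM scale unless stated otherwise.  On disk they
are tab-delimited UTF-8: first column the feature id, header row the sample
ids, no quoting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError

__all__ = [
    "FeatureAnnotation",
    "validate_matrix",
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
    "read_gtf_annotations",
    "read_bed_annotations",
    "compute_rpkm",
    "filter_expressed",
    "categorize_expression",
    "merge_annotations",
    "mean_center_log2",
    "two_group_test",
]

# RPKM category boundaries: low < 0.01 <= medium < 1 <= high
LOW_MEDIUM_CUT = 0.01
MEDIUM_HIGH_CUT = 1.0
#: default mean-RPKM threshold defining "expressed" features (strict >)
EXPRESSED_MEAN_RPKM = 0.01


@dataclass(frozen=True)
class FeatureAnnotation:
    """Genomic interval of a feature; coordinates 1-based inclusive."""

    feature_id: str
    chromosome: str
    start: int
    end: int
    strand: str  # "+", "-" or "."
    source: str  # "gencode" or "predicted"

    def __post_init__(self):
        if self.start > self.end or self.start < 1:
            raise ValidationError(f"{self.feature_id}: bad interval [{self.start}, {self.end}]")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"{self.feature_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValidationError("duplicate feature or sample identifiers")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("expression values must be numeric")
    if np.any(values < 0) or np.any(~np.isfinite(values)):
        raise ValidationError("expression values must be finite and non-negative")
    return matrix


def read_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    return validate_matrix(matrix)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    validate_matrix(matrix)
    matrix.to_csv(path, sep="\t", index_label="feature_id")


def read_clinical(path) -> pd.DataFrame:
    """Read a per-sample clinical/survival table (sample_id, time_days,
    event, and any covariate columns)."""
    table = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "time_days" not in table.columns or "event" not in table.columns:
        raise ValidationError("clinical table needs time_days and event columns")
    if (table["time_days"] <= 0).any():
        raise ValidationError("time_days must be positive")
    if not table["event"].isin((0, 1)).all():
        raise ValidationError("event must be 0 or 1")
    return table


def write_clinical(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_gtf_annotations(path, source: str) -> list[FeatureAnnotation]:
    """Read transcript-level annotations from a GTF file (attribute key
    ``gene_id``), converting to 1-based inclusive coordinates."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    if "Feature" in df:
        for level in ("transcript", "gene"):
            if (df["Feature"] == level).any():
                df = df[df["Feature"] == level]
                break
    out = []
    for row in df.itertuples():
        out.append(
            FeatureAnnotation(
                feature_id=str(row.gene_id),
                chromosome=str(row.Chromosome),
                start=int(row.Start) + 1,  # pyranges is 0-based half-open
                end=int(row.End),
                strand=str(getattr(row, "Strand", ".")),
                source=source,
            )
        )
    return out


def read_bed_annotations(path, source: str) -> list[FeatureAnnotation]:
    """Read BED6 annotations (0-based half-open on disk)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return [
        FeatureAnnotation(
            feature_id=str(r.name), chromosome=str(r.chrom),
            start=int(r.start) + 1, end=int(r.end),
            strand=str(r.strand), source=source,
        )
        for r in df.itertuples(index=False)
    ]


def compute_rpkm(counts: pd.DataFrame, feature_lengths, library_sizes) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``value = count / (length_kb * mapped_reads_millions)``; zeros in
    ``counts`` stay zero.
    """
    validate_matrix(counts)
    lengths = pd.Series(feature_lengths).reindex(counts.index)
    libs = pd.Series(library_sizes).reindex(counts.columns)
    if lengths.isna().any() or libs.isna().any():
        raise ValidationError("feature_lengths/library_sizes must cover all features/samples")
    if (lengths <= 0).any():
        raise ValidationError("feature lengths must be positive")
    if (libs <= 0).any():
        raise ValidationError("library sizes must be positive")
    denom = np.outer(lengths.to_numpy() / 1e3, libs.to_numpy() / 1e6)
    return pd.DataFrame(counts.to_numpy() / denom, index=counts.index, columns=counts.columns)


def filter_expressed(matrix: pd.DataFrame, mean_threshold: float = EXPRESSED_MEAN_RPKM) -> pd.DataFrame:
    """Keep features whose arithmetic mean across samples is strictly above
    ``mean_threshold`` (default mean RPKM > 0.01); row order preserved."""
    validate_matrix(matrix)
    return matrix.loc[matrix.mean(axis=1) > mean_threshold]


def categorize_expression(value):
    """Categorize RPKM values: low < 0.01, 0.01 <= medium < 1, high >= 1."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("RPKM values must be non-negative")
    cats = np.where(arr < LOW_MEDIUM_CUT, "low", np.where(arr < MEDIUM_HIGH_CUT, "medium", "high"))
    return cats.item() if np.isscalar(value) or arr.ndim == 0 else cats


def merge_annotations(
    gencode: list[FeatureAnnotation], predicted: list[FeatureAnnotation]
) -> list[FeatureAnnotation]:
    """Union of both annotation sources, GENCODE taking precedence: any
    predicted feature whose interval overlaps (>= 1 bp, same strand, same
    chromosome) a GENCODE feature is dropped."""
    for records, label in ((gencode, "gencode"), (predicted, "predicted")):
        ids = [r.feature_id for r in records]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate feature ids in {label} annotations")

    by_key: dict = {}
    for g in gencode:
        by_key.setdefault((g.chromosome, g.strand), []).append((g.start, g.end))
    for key in by_key:
        by_key[key].sort()

    kept = list(gencode)
    for p in predicted:
        intervals = by_key.get((p.chromosome, p.strand), [])
        i = np.searchsorted([s for s, _ in intervals], p.end, side="right")
        if any(e >= p.start for _, e in intervals[:i]):
            continue
        kept.append(p)
    return kept


def mean_center_log2(matrix: pd.DataFrame, pseudocount: float = 0.01) -> pd.DataFrame:
    """log2(value + pseudocount), then subtract each feature's row mean."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    validate_matrix(matrix)
    logged = np.log2(matrix.to_numpy() + pseudocount)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=matrix.index, columns=matrix.columns)


def two_group_test(values_a, values_b) -> float:
    """Two-sided Mann-Whitney U p-value (midranks for ties)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
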