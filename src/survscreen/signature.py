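"""Knockdown-signature analysis: fold-change gene selection, overlap
statistics across siRNAs and cell lines, shared-signature extraction,
tumor-correlation filtering, clustering of tumor samples on the signature,
and cluster-outcome association.

The workflow mirrors the functional arm of the screen: genes responding
(>= 1.25-fold, either direction) to knockdown in every cell line and siRNA
form the shared signature; that signature is then taken back to the tumor
cohort, where hierarchical clustering (average linkage, Pearson correlation
distance on mean-centered log2 RPKM) should separate patients into groups
that differ in survival and in marker expression if the signature is
biologically real.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from ._errors import DegenerateError, ValidationError
from .expression import mean_center_log2
from .survival import LogRankResult, logrank_test

__all__ = [
    "GeneSet",
    "OverlapResult",
    "ClusterAssignment",
    "fold_changes",
    "select_by_fold_change",
    "overlap_test",
    "shared_signature",
    "correlate_with_feature",
    "cluster_samples",
    "cluster_outcome_association",
    "FOLD_CHANGE_CUTOFF",
    "CORRELATION_CUTOFF",
]

FOLD_CHANGE_CUTOFF = 1.25
CORRELATION_CUTOFF = 0.15


@dataclass(frozen=True)
class GeneSet:
    label: str
    members: frozenset
    universe_size: int

    def __post_init__(self):
        if len(self.members) > self.universe_size:
            raise ValidationError("gene set larger than its universe")

    def __len__(self):
        return len(self.members)


@dataclass(frozen=True)
class OverlapResult:
    overlap: int
    size_a: int
    size_b: int
    universe_size: int
    p_value: float  # upper-tail hypergeometric


@dataclass(frozen=True)
class ClusterAssignment:
    sample_ids: tuple
    labels: np.ndarray          # cluster 1 or 2 per sample
    linkage_matrix: np.ndarray = field(repr=False)


def fold_changes(kd: pd.Series, ctrl: pd.Series, pseudocount: float = 0.01) -> pd.Series:
    """Per-gene expression ratio ``(kd + pc) / (ctrl + pc)``."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    if not kd.index.equals(ctrl.index):
        raise ValidationError("knockdown and control gene lists differ")
    return (kd + pseudocount) / (ctrl + pseudocount)


def select_by_fold_change(
    ratios: pd.Series, cutoff: float = FOLD_CHANGE_CUTOFF, universe_size: int | None = None,
) -> tuple[GeneSet, GeneSet]:
    """Split genes into (up, down) sets: up if ratio >= cutoff, down if
    ratio <= 1/cutoff (both boundaries inclusive)."""
    if cutoff <= 1:
        raise ValidationError("fold-change cutoff must exceed 1")
    universe = universe_size if universe_size is not None else ratios.size
    up = frozenset(ratios.index[ratios >= cutoff])
    down = frozenset(ratios.index[ratios <= 1.0 / cutoff])
    return (
        GeneSet("up", up, universe),
        GeneSet("down", down, universe),
    )


def overlap_test(set_a: GeneSet, set_b: GeneSet, universe_size: int | None = None) -> OverlapResult:
    """Upper-tail hypergeometric probability of an overlap at least as large
    as observed, drawing |B| genes from a universe containing |A| marked."""
    m = universe_size if universe_size is not None else max(set_a.universe_size, set_b.universe_size)
    k = len(set_a.members & set_b.members)
    if len(set_a) > m or len(set_b) > m:
        raise ValidationError("set sizes exceed the universe")
    p = float(stats.hypergeom.sf(k - 1, m, len(set_a), len(set_b)))
    return OverlapResult(overlap=k, size_a=len(set_a), size_b=len(set_b), universe_size=m, p_value=p)


def shared_signature(sets: dict) -> GeneSet:
    """Genes affected in the same direction in every condition.

    ``sets`` maps ``(cell_line, sirna, direction)`` — direction "up" or
    "down" — to a :class:`GeneSet`.  Per direction, the intersection across
    all (line, siRNA) pairs is taken; the result is the union of the two
    directional intersections, with genes assigned opposite directions by
    different conditions excluded (membership in both intersections is
    impossible unless inputs conflict, and such genes are dropped).
    """
    if not sets:
        return GeneSet("shared", frozenset(), 0)
    universe = max(s.universe_size for s in sets.values())
    by_direction: dict[str, list] = {"up": [], "down": []}
    for (line, sirna, direction), gs in sets.items():
        if direction not in by_direction:
            raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
        by_direction[direction].append(gs.members)
    inter = {}
    for direction, members in by_direction.items():
        inter[direction] = frozenset.intersection(*members) if members else frozenset()
    conflicted = inter["up"] & inter["down"]
    shared = (inter["up"] | inter["down"]) - conflicted
    return GeneSet("shared", shared, universe)


def correlate_with_feature(
    tumor_matrix: pd.DataFrame, feature_id: str, r_threshold: float = CORRELATION_CUTOFF,
) -> GeneSet:
    """Genes whose expression across tumors has Pearson r >= ``r_threshold``
    with the named feature (the feature itself excluded)."""
    if feature_id not in tumor_matrix.index:
        raise ValidationError(f"feature {feature_id!r} not in matrix")
    target = tumor_matrix.loc[feature_id].to_numpy(dtype=float)
    if np.std(target) == 0:
        raise DegenerateError(f"feature {feature_id!r} has zero variance")
    others = tumor_matrix.drop(index=feature_id)
    x = others.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    tc = target - target.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (tc ** 2).sum())
    with np.errstate(invalid="ignore"):
        r = np.where(denom > 0, (xc @ tc) / denom, np.nan)
    members = frozenset(others.index[np.nan_to_num(r, nan=-np.inf) >= r_threshold])
    return GeneSet(f"corr>={r_threshold}", members, tumor_matrix.shape[0])


def cluster_samples(matrix: pd.DataFrame, k: int = 2, pseudocount: float = 0.01) -> ClusterAssignment:
    """Cluster tumor samples on a signature: average-linkage agglomeration
    of 1 - Pearson correlation between sample profiles of mean-centered
    log2 RPKM, cut into ``k`` clusters."""
    if matrix.shape[1] < k:
        raise ValidationError(f"need at least {k} samples")
    if matrix.shape[0] < 2:
        raise ValidationError("need at least 2 genes to correlate profiles")
    centered = mean_center_log2(matrix, pseudocount=pseudocount)
    profiles = centered.to_numpy().T  # samples x genes
    if np.any(profiles.std(axis=1) == 0):
        raise ValidationError("constant sample profile; correlation undefined")
    z = linkage(profiles, method="average", metric="correlation")
    labels = fcluster(z, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        raise DegenerateError(f"dendrogram cut produced fewer than {k} clusters")
    return ClusterAssignment(sample_ids=tuple(matrix.columns), labels=labels, linkage_matrix=z)


def cluster_outcome_association(
    assignment: ClusterAssignment, clinical: pd.DataFrame, marker_high,
) -> tuple[LogRankResult, float]:
    """Associate the two sample clusters with outcome and with the marker:
    log-rank test between the clusters' survival and a two-sided Fisher
    exact test on the 2x2 cluster x marker-high table."""
    ids = list(assignment.sample_ids)
    missing = set(ids) - set(clinical.index)
    if missing:
        raise ValidationError(f"samples without survival records: {sorted(missing)[:5]}")
    clin = clinical.loc[ids]
    labels = assignment.labels
    in1 = labels == 1
    if not in1.any() or in1.all():
        raise ValidationError("a cluster has no survival records")
    time = clin["time_days"].to_numpy(dtype=float)
    event = clin["event"].to_numpy(dtype=int)
    lr = logrank_test(time[in1], event[in1], time[~in1], event[~in1])
    marker_high = np.asarray(marker_high, dtype=bool)
    table = [
        [int((in1 & marker_high).sum()), int((in1 & ~marker_high).sum())],
        [int((~in1 & marker_high).sum()), int((~in1 & ~marker_high).sum())],
    ]
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return lr, fisher_p
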