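"""Hierarchical clustering of expression time courses.

Profiles are grouped by temporal shape: per-gene z-scoring followed by
agglomerative clustering on correlation distance (1 − Pearson r between
profiles) with average linkage, tree cut to k clusters (default 12).  All
steps are deterministic — identical inputs give identical assignments — and
cutting the same tree at k and k+1 gives nested partitions.  Metric, linkage
and standardization are configurable since shape-based defaults are a
modeling choice, not a given.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError
from .expression import CorrelationReport, ExpressionMatrix

DEFAULT_K = 12


def _standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # flat profiles stay flat (all-zero) rather than NaN
    return (values - mu) / sd


def _correlation_distance(values: np.ndarray) -> np.ndarray:
    """Condensed 1 − Pearson distance that tolerates flat profiles.

    Two flat profiles are at distance 0 (same shape); a flat and a varying
    profile at distance 1 (correlation treated as 0).
    """
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms == 0
    safe = np.where(flat, 1.0, norms)
    unit = centered / safe[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = 1.0 - corr
    dist[np.ix_(flat, ~flat)] = 1.0
    dist[np.ix_(~flat, flat)] = 1.0
    dist[np.ix_(flat, flat)] = 0.0
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


@dataclass
class ClusterAssignment:
    """A partition of genes into 1..k clusters plus the merge history.

    Cluster labels are arbitrary; they are relabeled by decreasing size
    (ties by smallest member gene id) for stable reporting.
    """

    labels: dict[str, int]
    k: int
    linkage_record: np.ndarray
    genes: list[str]

    def members(self, cluster: int) -> list[str]:
        return [g for g, c in self.labels.items() if c == cluster]

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.labels.values():
            out[c] = out.get(c, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "cluster": [self.labels[g] for g in self.genes]}
        )


def hierarchical_clusters(
    expr: ExpressionMatrix,
    k: int = DEFAULT_K,
    metric: str = "correlation",
    linkage: str = "average",
    standardize: bool = True,
) -> ClusterAssignment:
    """Agglomerative clustering of expression profiles, tree cut to k.

    Raises ConfigError for k < 1 or k > number of genes.  Every returned
    cluster is non-empty and the assignment is a partition.
    """
    genes = expr.genes
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if k > len(genes):
        raise ConfigError(f"k={k} exceeds the number of genes ({len(genes)})")
    values = expr.values.to_numpy(dtype=float)
    if standardize:
        values = _standardize(values)
    if metric == "correlation":
        dist = _correlation_distance(values)
    else:
        dist = pdist(values, metric=metric)
    Z = hierarchy.linkage(dist, method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = _relabel_by_size(genes, raw)
    return ClusterAssignment(labels=labels, k=int(raw.max()), linkage_record=Z,
                             genes=list(genes))


def _relabel_by_size(genes, raw) -> dict[str, int]:
    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(g)
    order = sorted(clusters, key=lambda c: (-len(clusters[c]), min(clusters[c])))
    rank = {c: i + 1 for i, c in enumerate(order)}
    return {g: rank[int(c)] for g, c in zip(genes, raw)}


def cluster_profiles(
    expr: ExpressionMatrix, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Arithmetic mean raw expression profile per cluster.

    Returns a cluster × time DataFrame with an ``n_genes`` member-count
    column prepended.  The size-weighted mean of the cluster means equals
    the global mean profile.
    """
    missing = set(assignment.genes) - set(expr.genes)
    if missing:
        raise ConfigError(f"assignment covers genes absent from matrix: {sorted(missing)}")
    rows = {}
    for c in sorted(set(assignment.labels.values())):
        members = assignment.members(c)
        rows[c] = expr.values.loc[members].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "cluster"
    out.insert(0, "n_genes", [len(assignment.members(c)) for c in out.index])
    return out


def genome_track(
    assignment: ClusterAssignment,
    report: CorrelationReport | None,
    gene_order: list[str],
) -> pd.DataFrame:
    """The data behind a genome-order track: position, cluster, r, class.

    ``gene_order`` supplies chromosomal ordering (e.g. by SCO number).
    Clustered genes missing from the order are appended at the end with a
    warning, so the track always covers the assignment.
    """
    in_order = [g for g in gene_order if g in assignment.labels]
    missing = [g for g in assignment.genes if g not in set(gene_order)]
    if missing:
        warnings.warn(
            f"{len(missing)} clustered genes missing from gene_order; appended at end",
            stacklevel=2,
        )
    ordered = in_order + sorted(missing)
    by_gene = {}
    if report is not None:
        for p in report.profiles:
            by_gene[p.gene] = p
    rows = []
    for pos, g in enumerate(ordered, start=1):
        p = by_gene.get(g)
        rows.append(
            {
                "gene": g,
                "position": pos,
                "cluster": assignment.labels[g],
                "r": (np.nan if p is None or p.r is None else p.r),
                "class": ("" if p is None or p.cls is None else p.cls),
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "position", "cluster", "r", "class"])
    if report is None:
        df = df[["gene", "position", "cluster"]]
    return df
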