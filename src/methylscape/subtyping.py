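"""Gene- and enhancer-aggregated profiles, PCA, hierarchical clustering and
two-subclass calling.

Feature matrices throughout are features x samples DataFrames (genes or
region ids as rows), matching the orientation of beta matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

from .types import (
    BetaMatrix,
    Manifest,
    RegionSet,
    SampleSheet,
    probes_in_regions,
)

LESION_GROUPS = ("AK", "cSCC")


def aggregate_gene_beta(
    beta: BetaMatrix,
    manifest: Manifest,
    gene_symbols: Iterable[str],
    gene_region: str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Average beta per gene over the probes linked to it.

    A probe linked to several genes contributes to each; missing values are
    skipped.  Returns the gene x sample matrix and the list of requested
    genes with no resolvable probes (excluded from the matrix).
    """
    gene_symbols = sorted(set(gene_symbols))
    if not gene_symbols:
        raise ValueError("empty gene set")
    gmap = manifest.gene_probe_map(genes=gene_symbols, gene_region=gene_region)
    rows = {}
    missing = []
    for gene in gene_symbols:
        probes = [p for p in gmap.get(gene, []) if p in beta.probe_ids]
        if not probes:
            missing.append(gene)
            continue
        rows[gene] = beta.df.loc[probes].mean(axis=0, skipna=True)
    if not rows:
        raise ValueError("no requested gene has probes in the beta matrix")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out, missing


def aggregate_region_beta(
    beta: BetaMatrix, manifest: Manifest, regions: RegionSet
) -> tuple[pd.DataFrame, list[str]]:
    """Average beta per region over its member probes.

    Regions without member probes in the matrix are dropped and reported.
    """
    membership = probes_in_regions(manifest, regions)
    rows = {}
    empty = []
    for region_id, probes in membership.items():
        probes = [p for p in probes if p in beta.probe_ids]
        if not probes:
            empty.append(region_id)
            continue
        rows[region_id] = beta.df.loc[probes].mean(axis=0, skipna=True)
    if not rows:
        raise ValueError(f"no region of {regions.name!r} covers any probe")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "region_id"
    return out, empty


def harmonize_platforms(
    features_a: pd.DataFrame, features_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Join two per-cohort feature matrices on shared feature names.

    Each cohort is expected to have aggregated over its own probe basis
    already.  Features present in only one cohort are dropped and reported.
    Returns the joint features x samples matrix, a sample -> origin label
    Series, and the dropped-feature report.
    """
    overlap = features_a.columns.intersection(features_b.columns)
    if len(overlap):
        raise ValueError(f"cohorts share sample ids: {list(overlap[:3])}")
    shared = features_a.index.intersection(features_b.index)
    dropped = {
        "a": features_a.index.difference(shared).tolist(),
        "b": features_b.index.difference(shared).tolist(),
    }
    if len(shared) == 0:
        raise ValueError("cohorts share no features")
    joint = pd.concat([features_a.loc[shared], features_b.loc[shared]], axis=1)
    origin = pd.Series(
        ["a"] * features_a.shape[1] + ["b"] * features_b.shape[1],
        index=joint.columns,
        name="origin",
    )
    return joint, origin, dropped


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # components x features
    explained_variance_ratio: np.ndarray


def pca_embed(
    features: pd.DataFrame, n_components: int = 2, *, scale: bool = False
) -> PCAResult:
    """PCA of samples over centered (optionally scaled) features.

    Deterministic: each component's sign is fixed so that its
    largest-magnitude loading is positive.
    """
    if features.shape[1] < 2 or features.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    X = features.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    if not np.any(X):
        raise ValueError("constant feature matrix: no variance to decompose")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(S))
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    coords = U[:, :k] * S[:k]
    total = float((S**2).sum())
    ratio = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=features.columns, columns=comp_names),
        loadings=pd.DataFrame(Vt[:k], index=comp_names, columns=features.index),
        explained_variance_ratio=ratio,
    )


@dataclass
class DendrogramResult:
    linkage: np.ndarray
    labels: list[str]
    distance: str
    method: str
    clusters: pd.Series | None = None

    def to_newick(self) -> str:
        """Serialize the tree with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


def cluster_dendrogram(
    features: pd.DataFrame,
    distance: str = "euclidean",
    method: str = "average",
    k: int | None = None,
) -> DendrogramResult:
    """Agglomerative clustering of samples (columns) with optional flat cut.

    ``distance`` is ``euclidean`` or ``correlation``; ``method`` is
    ``average``, ``complete`` or ``ward`` (ward requires euclidean).
    SciPy's deterministic lowest-index tie-breaking applies.
    """
    if distance not in ("euclidean", "correlation"):
        raise ValueError("distance must be 'euclidean' or 'correlation'")
    if method not in ("average", "complete", "ward"):
        raise ValueError("method must be 'average', 'complete' or 'ward'")
    if method == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    n = features.shape[1]
    if n < 2:
        raise ValueError("clustering needs at least 2 samples")
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    X = features.to_numpy(dtype=float).T
    D = pdist(X, metric=distance)
    Z = hierarchy.linkage(D, method=method)
    clusters = None
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        clusters = pd.Series(flat, index=features.columns, name="cluster")
    return DendrogramResult(
        linkage=Z,
        labels=list(features.columns),
        distance=distance,
        method=method,
        clusters=clusters,
    )


@dataclass
class SubtypeResult:
    calls: pd.DataFrame  # sample_id index; method, subclass, cluster_id, distance_to_healthy
    method: str
    no_structure: bool = False
    silhouette: float = np.nan
    anchor: str = ""
    dendrogram: DendrogramResult | None = None
    notes: list[str] = field(default_factory=list)


def _centroid(features: pd.DataFrame, samples: Sequence[str]) -> np.ndarray:
    return features[list(samples)].mean(axis=1).to_numpy()


def call_subclasses(
    features: pd.DataFrame,
    samplesheet: SampleSheet,
    references: pd.DataFrame | None = None,
    *,
    method: str,
    k: int = 2,
    distance: str = "euclidean",
    linkage_method: str = "average",
    silhouette_floor: float = 0.15,
    fallback_features: Sequence[str] | None = None,
) -> SubtypeResult:
    """Cluster AK/cSCC samples at k = 2 and label the two subclasses.

    Labeling rule: the cluster whose centroid is nearer the
    healthy/keratinocyte anchor is ``keratinocyte_like``, the other
    ``EpSC_like``.  The anchor is the healthy-sample centroid when healthy
    samples are present in ``features``, else a keratinocyte-flavored
    reference column; without any anchor the fallback labels by mean
    methylation over ``fallback_features`` (higher -> EpSC_like).

    If the k = 2 split has silhouette below ``silhouette_floor`` (or
    degenerates to one cluster), a "no subclass structure" result is
    returned instead of a forced call.
    """
    if k != 2:
        raise ValueError("subclass calling is defined for k = 2")
    groups = samplesheet.df.loc[
        samplesheet.sample_ids.intersection(features.columns), "group"
    ]
    lesion = groups.index[groups.isin(LESION_GROUPS)].tolist()
    if len(lesion) < k:
        raise ValueError("need at least k AK/cSCC samples to cluster")
    lesion = [s for s in features.columns if s in set(lesion)]  # column order
    sub = features[lesion]
    dg = cluster_dendrogram(sub, distance=distance, method=linkage_method, k=2)
    labels = dg.clusters.to_numpy()
    X = sub.to_numpy(dtype=float).T
    if len(np.unique(labels)) < 2:
        return SubtypeResult(
            calls=pd.DataFrame(
                columns=["method", "subclass", "cluster_id", "distance_to_healthy"]
            ),
            method=method,
            no_structure=True,
            silhouette=np.nan,
            dendrogram=dg,
            notes=["k=2 cut produced a single cluster"],
        )
    sil = float(silhouette_score(X, labels, metric="euclidean"))
    if sil < silhouette_floor:
        return SubtypeResult(
            calls=pd.DataFrame(
                columns=["method", "subclass", "cluster_id", "distance_to_healthy"]
            ),
            method=method,
            no_structure=True,
            silhouette=sil,
            dendrogram=dg,
            notes=[f"silhouette {sil:.3f} below floor {silhouette_floor}"],
        )

    healthy = [
        s
        for s in features.columns
        if s in samplesheet.sample_ids and samplesheet.df.loc[s, "group"] == "healthy"
    ]
    kc_anchor = None
    anchor_name = ""
    if healthy:
        kc_anchor = _centroid(features, healthy)
        anchor_name = "healthy_centroid"
    elif references is not None:
        for col in references.columns:
            if "keratinocyte" in str(col).lower() or "diffkc" in str(col).lower():
                kc_anchor = references[col].reindex(features.index).to_numpy()
                anchor_name = f"reference:{col}"
                break

    centroids = {c: sub.iloc[:, labels == c].mean(axis=1).to_numpy() for c in (1, 2)}
    if kc_anchor is not None and np.isfinite(kc_anchor).all():
        d = {c: float(np.linalg.norm(centroids[c] - kc_anchor)) for c in (1, 2)}
        kc_cluster = min(d, key=d.get)
    else:
        if fallback_features is None:
            raise ValueError(
                "no healthy/keratinocyte anchor available and no fallback features"
            )
        anchor_name = "fallback:gained_region_mean"
        rows = [f for f in fallback_features if f in sub.index]
        if not rows:
            raise ValueError("fallback features absent from the feature matrix")
        means = {c: float(sub.loc[rows].iloc[:, labels == c].mean().mean()) for c in (1, 2)}
        kc_cluster = min(means, key=means.get)  # higher gained methylation -> EpSC

    subclass = np.where(labels == kc_cluster, "keratinocyte_like", "EpSC_like")
    if kc_anchor is not None and np.isfinite(kc_anchor).all():
        dist_healthy = np.linalg.norm(X - kc_anchor[None, :], axis=1)
    else:
        dist_healthy = np.full(len(lesion), np.nan)
    calls = pd.DataFrame(
        {
            "method": method,
            "subclass": subclass,
            "cluster_id": labels,
            "distance_to_healthy": dist_healthy,
        },
        index=pd.Index(lesion, name="sample_id"),
    )
    return SubtypeResult(
        calls=calls,
        method=method,
        no_structure=False,
        silhouette=sil,
        anchor=anchor_name,
        dendrogram=dg,
    )


def delta_vs_healthy(
    features: pd.DataFrame, samplesheet: SampleSheet
) -> pd.DataFrame:
    """Subtract the healthy-group mean of each feature from every sample.

    By construction the output rows average to zero over the healthy samples.
    """
    healthy = [
        s
        for s in features.columns
        if s in samplesheet.sample_ids and samplesheet.df.loc[s, "group"] == "healthy"
    ]
    if not healthy:
        raise ValueError("no healthy samples in the feature matrix")
    baseline = features[healthy].mean(axis=1)
    return features.sub(baseline, axis=0)


def select_hypermethylated_genes(
    delta: pd.DataFrame,
    region_genes: Mapping[str, Sequence[str]],
    calls: pd.DataFrame,
    threshold: float = 0.2,
) -> list[str]:
    """Genes in regions hypermethylated in the EpSC-like subclass.

    A region qualifies when its mean normalized delta-beta across EpSC-like
    samples is strictly greater than ``threshold``; linked genes are
    deduplicated and sorted.  An empty EpSC-like subclass yields an empty
    list with a warning.
    """
    epsc = calls.index[calls["subclass"] == "EpSC_like"]
    epsc = [s for s in epsc if s in delta.columns]
    if not epsc:
        warnings.warn("no EpSC-like samples: returning an empty gene list")
        return []
    means = delta[epsc].mean(axis=1)
    selected = means.index[means > threshold]
    genes: set[str] = set()
    for region_id in selected:
        genes.update(region_genes.get(region_id, ()))
    return sorted(genes)
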