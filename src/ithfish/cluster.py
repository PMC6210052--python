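"""Hierarchical clustering of per-sample composition vectors.

Tumors are grouped by the fractions of their cell classes: agglomerative
clustering (Ward linkage on Euclidean distances by default) of the
composition matrix, with the tree cut at a fixed number of groups k.  The
published analyses report three groups per category system (phenotype P1-P3,
genotype G1-G3, combined PG1-PG3); k = 3 is therefore the default, but k is
an analyst choice, not discovered from the data.  Raw fractions are
clustered by default; an optional centred-log-ratio transform is available
for a compositional-geometry variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from ithfish.diversity import SampleComposition

__all__ = ["ClusterAssignment", "cluster_compositions", "characterize_clusters", "clr_transform"]


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster labels for one composition system plus the merge history.

    ``labels`` maps sample key (patient_id, timepoint) -> contiguous integer
    cluster id starting at 1; ``linkage_matrix`` is the scipy linkage record,
    sufficient to redraw the dendrogram.
    """

    system: str
    labels: pd.Series
    linkage_matrix: np.ndarray
    method: str
    metric: str
    k: int

    def __post_init__(self):
        lab = np.sort(self.labels.unique())
        if not np.array_equal(lab, np.arange(1, len(lab) + 1)):
            raise ValueError(f"cluster ids must be contiguous from 1, got {lab}")


def clr_transform(fractions: np.ndarray, pseudo: float = 1e-6) -> np.ndarray:
    """Centred log-ratio transform of composition rows (pseudo-count for zeros)."""
    x = np.asarray(fractions, dtype=float) + pseudo
    x = x / x.sum(axis=1, keepdims=True)
    logx = np.log(x)
    return logx - logx.mean(axis=1, keepdims=True)


def _composition_matrix(comps: list[SampleComposition]) -> tuple[pd.DataFrame, str]:
    systems = {c.system for c in comps}
    if len(systems) != 1:
        raise ValueError(f"compositions mix systems: {sorted(systems)}")
    system = systems.pop()
    index = pd.MultiIndex.from_tuples(
        [(c.patient_id, c.timepoint) for c in comps], names=["patient_id", "timepoint"]
    )
    mat = pd.DataFrame([c.fractions for c in comps], index=index, columns=list(comps[0].categories))
    return mat, system


def cluster_compositions(
    comps: list[SampleComposition],
    k: int = 3,
    method: str = "ward",
    metric: str = "euclidean",
    use_clr: bool = False,
) -> ClusterAssignment:
    """Agglomeratively cluster sample compositions and cut the tree at k groups.

    Deterministic given the inputs: scipy's linkage breaks distance ties by
    observation order, and cluster ids are relabeled contiguously (1..k) in
    order of first appearance in the input.
    """
    if len(comps) == 0:
        raise ValueError("no compositions to cluster")
    mat, system = _composition_matrix(comps)
    n = len(mat)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}] for {n} samples")
    X = clr_transform(mat.to_numpy()) if use_clr else mat.to_numpy()
    Z = linkage(pdist(X, metric=metric), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel contiguously in order of first appearance
    order: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        order.setdefault(r, len(order) + 1)
        labels[i] = order[r]
    return ClusterAssignment(
        system=system,
        labels=pd.Series(labels, index=mat.index, name="cluster"),
        linkage_matrix=Z,
        method=method,
        metric=metric,
        k=int(labels.max()),
    )


def characterize_clusters(
    assignment: ClusterAssignment,
    comps: list[SampleComposition],
    si: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-cluster summary: dominant category, mean fractions, mean SI, size.

    ``si`` (optional) is a Series of per-sample Shannon indices keyed like
    ``assignment.labels``; keys must intersect the assignment.
    """
    from ithfish.diversity import shannon_index

    mat, _ = _composition_matrix(comps)
    common = mat.index.intersection(assignment.labels.index)
    if len(common) == 0:
        raise ValueError("no samples shared between assignment and compositions")
    mat = mat.loc[common]
    labels = assignment.labels.loc[common]
    if si is None:
        si = pd.Series([shannon_index(mat.loc[i].to_numpy()) for i in mat.index], index=mat.index)
    else:
        si = si.loc[si.index.intersection(common)]
    rows = []
    for cid, idx in labels.groupby(labels).groups.items():
        sub = mat.loc[idx]
        mean_frac = sub.mean(axis=0)
        rows.append(
            {
                "cluster": cid,
                "n": len(sub),
                "dominant_category": mean_frac.idxmax(),
                "mean_si": float(si.loc[si.index.intersection(idx)].mean()),
                **{f"mean_frac_{c}": float(v) for c, v in mean_frac.items()},
            }
        )
    return pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
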