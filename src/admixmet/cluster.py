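"""Metabolic clustering: modulated modularity + biology refinement.

Screened metabolites are grouped in two passes. First, modulated
modularity clustering (MMC) of the pairwise Pearson correlation matrix:
|r| is pushed through a sigmoid with an adaptive midpoint (the median
off-diagonal |r|) and a sharpness s swept over a grid; for each s the
weighted-graph modularity Q is maximized and the best (s, partition) over
the grid is returned. Unsigned |r| is used so strongly anti-correlated
metabolites co-cluster — their opposing signs are absorbed by the cluster
PC1 loadings downstream. Second, a biology pass: pathway-classified
metabolites are grouped by their (merge-mapped) sub-pathway, while
unknown or unclassified metabolites inherit the label of their MMC
community if it contains pathway-classified members — otherwise they are
excluded as non-clustering, the operational reading of "did not cluster
well with any of the known classified metabolites".

For n <= ``exact_max`` (default 8) the modularity optimum is found by
exhaustive enumeration of all set partitions; above that, greedy
agglomeration (lowest-id tie-breaks) followed by single-move refinement.
Both paths are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ClusterSet",
    "MMCResult",
    "correlation_matrix",
    "mmc_cluster",
    "biology_refine",
    "default_merge_map",
    "modularity",
]

REASON_UNKNOWN = "unknown-nonclustering"
REASON_UNCLASSIFIED = "unclassified-nonclustering"
REASON_ORPHAN = "small-orphan"


@dataclass
class ClusterSet:
    """Disjoint named clusters plus the excluded metabolites."""

    clusters: dict[str, list[str]]
    excluded: dict[str, str]                 # id -> reason
    provenance: str = "merged"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.clusters.items():
            if not members:
                raise ValueError(f"empty cluster {label!r}")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"clusters overlap on {sorted(overlap)}")
            seen |= set(members)
        dup = seen & set(self.excluded)
        if dup:
            raise ValueError(f"metabolites both clustered and excluded: {sorted(dup)}")

    @property
    def members(self) -> list[str]:
        return [m for ms in self.clusters.values() for m in ms]

    def to_dict(self) -> dict:
        return {
            "clusters": {k: list(v) for k, v in self.clusters.items()},
            "excluded": dict(self.excluded),
            "provenance": self.provenance,
        }


@dataclass
class MMCResult:
    partition: list[list[str]]
    sharpness: float
    modularity: float
    tau: float
    per_sharpness: dict[float, float] = field(default_factory=dict)


def correlation_matrix(imputed: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of the (complete) imputed log matrix."""
    x = imputed.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    if np.isnan(x).any():
        raise ValueError("correlation_matrix expects the imputed layer (no missing)")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = imputed.columns[sd == 0].tolist()
        raise ValueError(f"zero-variance metabolites: {bad}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=imputed.columns, columns=imputed.columns)


def modularity(w: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity of a partition (zero-diagonal weights)."""
    m2 = w.sum()
    if m2 <= 0:
        return 0.0
    k = w.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += w[np.ix_(idx, idx)].sum() / m2 - (k[idx].sum() / m2) ** 2
    return float(q)


def _partitions_rgs(n: int):
    """All set partitions of range(n) as restricted-growth strings."""
    a = [0] * n
    b = [0] * n  # b[i] = max(a[:i+1])
    while True:
        yield a.copy()
        # advance
        i = n - 1
        while i > 0 and a[i] == b[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        b[i] = max(b[i - 1], a[i])
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = b[i]


def _exact_partition(w: np.ndarray) -> tuple[np.ndarray, float]:
    n = w.shape[0]
    best_q = -np.inf
    best = np.zeros(n, dtype=int)
    for rgs in _partitions_rgs(n):
        labels = np.asarray(rgs)
        q = modularity(w, labels)
        if q > best_q + 1e-15:
            best_q = q
            best = labels
    return best, best_q


def _greedy_partition(w: np.ndarray) -> tuple[np.ndarray, float]:
    """CNM-style agglomeration with deterministic lowest-pair tie-breaking,
    then single-move refinement."""
    n = w.shape[0]
    m2 = w.sum()
    k = w.sum(axis=1)
    # community bookkeeping: e[a, b] = total weight between communities a, b
    e = w.copy()
    deg = k.copy()
    alive = np.ones(n, dtype=bool)
    members: list[list[int]] = [[i] for i in range(n)]
    while alive.sum() > 1:
        idx = np.flatnonzero(alive)
        ea = e[np.ix_(idx, idx)]
        da = deg[idx]
        dq = 2.0 * ea / m2 - 2.0 * np.outer(da, da) / m2 ** 2
        np.fill_diagonal(dq, -np.inf)
        best = np.unravel_index(np.argmax(dq), dq.shape)  # argmax is first-max: lowest ids
        if dq[best] <= 1e-12:
            break
        a, b = sorted((idx[best[0]], idx[best[1]]))
        # merge b into a
        e[a, :] += e[b, :]
        e[:, a] += e[:, b]
        e[a, a] = e[a, a]  # self weight accumulated via the two adds
        deg[a] += deg[b]
        members[a].extend(members[b])
        alive[b] = False
        e[b, :] = 0.0
        e[:, b] = 0.0
        deg[b] = 0.0
    labels = np.empty(n, dtype=int)
    for c, i in enumerate(np.flatnonzero(alive)):
        for node in members[i]:
            labels[node] = c
    labels = _refine_moves(w, labels)
    return labels, modularity(w, labels)


def _refine_moves(w: np.ndarray, labels: np.ndarray, max_passes: int = 20) -> np.ndarray:
    """Move single nodes to the community with the best modularity gain."""
    n = w.shape[0]
    m2 = w.sum()
    if m2 <= 0:
        return labels
    k = w.sum(axis=1)
    labels = labels.copy()
    for _ in range(max_passes):
        changed = False
        comms = np.unique(labels)
        # community degrees and node-to-community weights
        for v in range(n):
            kc = {c: k[labels == c].sum() for c in comms}
            wvc = {c: w[v, labels == c].sum() for c in comms}
            cur = labels[v]
            base = wvc[cur] / m2 * 2 - 2 * k[v] * (kc[cur] - k[v]) / m2 ** 2
            best_c, best_gain = cur, 0.0
            for c in comms:
                if c == cur:
                    continue
                gain = (wvc[c] / m2 * 2 - 2 * k[v] * kc[c] / m2 ** 2) - base
                if gain > best_gain + 1e-12 or (
                    abs(gain - best_gain) <= 1e-12 and best_c != cur and c < best_c
                ):
                    best_c, best_gain = c, gain
            if best_c != cur:
                labels[v] = best_c
                changed = True
        if not changed:
            break
    # relabel compactly in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def mmc_cluster(
    r: pd.DataFrame,
    sharpness_grid: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0),
    exact_max: int = 8,
) -> MMCResult:
    """Modulated modularity clustering of a correlation matrix.

    Edge weights w_ij = sigmoid(s * (|r_ij| - tau)) with tau the median
    off-diagonal |r|; the returned partition maximizes weighted modularity
    over the sharpness grid (ties broken toward smaller s). Deterministic.
    """
    ids = [str(c) for c in r.columns]
    n = len(ids)
    if n < 2:
        raise ValueError("need >= 2 metabolites to cluster")
    absr = np.abs(r.to_numpy(dtype=float)).copy()
    np.fill_diagonal(absr, 0.0)
    off = absr[~np.eye(n, dtype=bool)]
    tau = float(np.median(off))
    if np.allclose(off, off[0]):
        warnings.warn("degenerate all-equal correlation weights; returning one cluster",
                      stacklevel=2)
        return MMCResult(partition=[ids], sharpness=sharpness_grid[0],
                         modularity=0.0, tau=tau)

    best: tuple[float, np.ndarray, float] | None = None  # (q, labels, s)
    per_s: dict[float, float] = {}
    for s in sharpness_grid:
        w = 1.0 / (1.0 + np.exp(-s * (absr - tau)))
        np.fill_diagonal(w, 0.0)
        if n <= exact_max:
            labels, q = _exact_partition(w)
        else:
            labels, q = _greedy_partition(w)
        per_s[float(s)] = q
        if best is None or q > best[0] + 1e-12:
            best = (q, labels, float(s))
    assert best is not None
    q, labels, s = best
    partition = [
        [ids[i] for i in np.flatnonzero(labels == c)] for c in np.unique(labels)
    ]
    partition.sort(key=lambda ms: ms[0])
    return MMCResult(partition=partition, sharpness=s, modularity=q, tau=tau,
                     per_sharpness=per_s)


def default_merge_map() -> dict[str, str]:
    """The curated sub-pathway -> cluster-label map shipped with the package."""
    with resources.files("admixmet").joinpath("data/merge_map.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["sub_pathway"], df["cluster_label"]))


def biology_refine(
    partition: list[list[str]],
    annotations: pd.DataFrame,
    merge_map: dict[str, str] | None = None,
    min_size: int = 2,
    corr: pd.DataFrame | None = None,
    min_inherit_r: float = 0.3,
) -> ClusterSet:
    """Assign final cluster labels from pathway annotations.

    Known pathway-classified metabolites get the merge-mapped label of
    their sub-pathway (unmapped sub-pathways label themselves). Unknown or
    known-but-unclassified metabolites inherit the majority biology label
    of the pathway-classified members of their MMC community (lexicographic
    tie-break) provided they cluster *well* with them: when ``corr`` is
    supplied, the metabolite's mean |r| with those classified co-members
    must reach ``min_inherit_r`` (a moderate-correlation floor — community
    co-membership alone is too weak a notion of clustering well, since a
    modularity partition assigns every node somewhere). Failing either
    condition they are excluded as non-clustering. Clusters smaller than
    ``min_size`` dissolve, their members excluded as small orphans.
    Idempotent.
    """
    if merge_map is None:
        merge_map = default_merge_map()
    all_ids = [m for ms in partition for m in ms]
    missing = [m for m in all_ids if m not in annotations.index]
    if missing:
        raise ValueError(f"metabolites without annotation: {missing[:10]}")

    known = annotations["known"].astype(bool)
    subp = annotations["sub_pathway"].fillna("").astype(str)

    def is_classified(m: str) -> bool:
        return bool(known.loc[m]) and subp.loc[m] != ""

    def bio_label(m: str) -> str:
        sp = subp.loc[m]
        return merge_map.get(sp, sp)

    assigned: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for community in partition:
        classified_ids = [m for m in community if is_classified(m)]
        classified = sorted(bio_label(m) for m in classified_ids)
        for m in community:
            if is_classified(m):
                assigned[m] = bio_label(m)
                continue
            target: str | None = None
            if classified:
                if corr is None:
                    # majority label of classified co-members, lexicographic tie-break
                    counts = pd.Series(classified).value_counts()
                    target = counts[counts == counts.max()].index.min()
                else:
                    # best-correlated biology label whose members it clusters
                    # well with (mean |r| floor); ties toward the smaller label
                    best_r = -np.inf
                    for label in sorted(set(classified)):
                        ids = [c for c in classified_ids if bio_label(c) == label]
                        mean_r = float(corr.loc[m, ids].abs().mean())
                        if mean_r > best_r + 1e-12:
                            best_r, target = mean_r, label
                    if best_r < min_inherit_r:
                        target = None
            if target is not None:
                assigned[m] = target
            else:
                reason = REASON_UNCLASSIFIED if known.loc[m] else REASON_UNKNOWN
                excluded[m] = reason

    clusters: dict[str, list[str]] = {}
    for m in sorted(assigned):
        clusters.setdefault(assigned[m], []).append(m)
    for label in sorted(clusters):
        if len(clusters[label]) < min_size:
            for m in clusters.pop(label):
                excluded[m] = REASON_ORPHAN
    return ClusterSet(clusters=clusters, excluded=excluded, provenance="merged")
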