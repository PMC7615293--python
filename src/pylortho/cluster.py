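"""Similarity-space UPGMA clustering with an identity merge-threshold cut.

Synthetase (and tRNA) sequences are grouped by unweighted average-linkage
agglomerative clustering performed directly on percent-identity matrices: at
each step the two clusters with the highest average pairwise identity (over
all cross-cluster leaf pairs) are merged, and the identity at which each
merge happens is recorded.  Cutting the resulting merge tree so that only
merges with average identity strictly greater than a threshold are applied
yields the cluster partition used to pick candidate orthogonal systems
(55% for synthetase catalytic domains, 75% for tRNAs).

This is equivalent to classical UPGMA on the distance ``100 - identity``;
working in identity space keeps merge heights directly comparable to the
thresholds.  Ties between candidate merges are broken deterministically by
the lexicographically least leaf id of each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import InvalidMatrixError
from .seqid import IdentityMatrix

@dataclass(frozen=True)
class MergeTree:
    """Record of an agglomerative clustering run.

    Leaves are numbered ``0 .. n-1`` in the order of ``leaves``; internal
    nodes are numbered ``n .. 2n-2`` in merge order.  ``merges[k]`` is
    ``(left, right, merge_identity)`` for internal node ``n + k``; merge
    identities are non-increasing (average linkage produces no inversions).
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of leaves at a stated identity threshold."""

    threshold_identity: float
    labels: Mapping[str, int]
    k: int

    def members(self, cluster: int) -> list[str]:
        return [i for i, c in self.labels.items() if c == cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.labels), "cluster": list(self.labels.values())}
        )


def upgma_tree(m: IdentityMatrix) -> MergeTree:
    """Average-linkage agglomerative clustering of an identity matrix.

    Greedy merging of the most similar cluster pair, with the unweighted
    average updated by the Lance–Williams rule (exactly the mean identity
    over all cross-cluster leaf pairs).  Deterministic: ties on merge
    identity are broken by the least leaf id of each candidate pair.
    """
    n = len(m.ids)
    if n < 2:
        raise InvalidMatrixError("clustering needs >= 2 sequences")
    sim = m.values.astype(float).copy()

    active: dict[int, dict] = {
        i: {"node": i, "size": 1, "min_id": m.ids[i]} for i in range(n)
    }
    merges: list[tuple[int, int, float]] = []
    next_node = n
    keys = list(active)

    while len(keys) > 1:
        best = None  # (neg_sim, tie_key, ki, kj)
        for a_pos in range(len(keys)):
            for b_pos in range(a_pos + 1, len(keys)):
                ki, kj = keys[a_pos], keys[b_pos]
                s = sim[ki, kj]
                ids = sorted((active[ki]["min_id"], active[kj]["min_id"]))
                cand = (-s, ids[0], ids[1], ki, kj)
                if best is None or cand < best:
                    best = cand
        _, _, _, ki, kj = best
        s = sim[ki, kj]
        ci, cj = active[ki], active[kj]
        left, right = ci["node"], cj["node"]
        if active[kj]["min_id"] < active[ki]["min_id"]:
            left, right = right, left
        merges.append((left, right, float(s)))

        # Lance-Williams unweighted average update onto slot ki.
        ni, nj = ci["size"], cj["size"]
        for other in keys:
            if other in (ki, kj):
                continue
            new = (ni * sim[ki, other] + nj * sim[kj, other]) / (ni + nj)
            sim[ki, other] = sim[other, ki] = new
        active[ki] = {
            "node": next_node,
            "size": ni + nj,
            "min_id": min(ci["min_id"], cj["min_id"]),
        }
        del active[kj]
        keys.remove(kj)
        next_node += 1

    heights = [h for _, _, h in merges]
    if any(heights[k] < heights[k + 1] - 1e-9 for k in range(len(heights) - 1)):
        raise InvalidMatrixError("merge inversion detected; matrix invalid")
    return MergeTree(leaves=m.ids, merges=tuple(merges))


def clusters_at_identity(tree: MergeTree, threshold: float) -> ClusterAssignment:
    """Cut the merge tree, applying merges with identity strictly > threshold.

    Two clusters end up merged iff their average identity at merge time
    exceeded the threshold; this mirrors the "merged if, and only if,
    greater than" rule.  Cluster indices are contiguous from 0 in leaf
    order.
    """
    n = tree.n_leaves
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (left, right, h) in enumerate(tree.merges):
        # strict cut, except that exact duplicates (identity 100) never
        # split at any threshold
        if h > threshold or h == 100.0:
            node = n + k
            parent[find(left)] = node
            parent[find(right)] = node

    roots: dict[int, int] = {}
    labels: dict[str, int] = {}
    for i, leaf in enumerate(tree.leaves):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        labels[leaf] = roots[r]
    return ClusterAssignment(
        threshold_identity=float(threshold), labels=labels, k=len(roots)
    )


def to_newick(tree: MergeTree, escape: str = "underscore") -> str:
    """Serialise the merge tree as an ultrametric Newick string.

    Node heights are ``(100 - merge_identity) / 2`` so that the leaf-to-leaf
    path length between two sequences equals ``100 - identity`` at their
    join.  ``escape`` controls leaf names containing whitespace:
    ``"underscore"`` replaces runs of whitespace, ``"quote"`` wraps the name
    in single quotes.
    """
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (left, right, h) in enumerate(tree.merges):
        node = n + k
        children[node] = (left, right)
        height[node] = (100.0 - h) / 2.0

    def name(i: int) -> str:
        raw = tree.leaves[i]
        if any(c.isspace() for c in raw) or any(c in raw for c in "():;,"):
            if escape == "quote":
                return "'" + raw.replace("'", "''") + "'"
            return "_".join(raw.split()).replace("(", "_").replace(")", "_")
        return raw

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - height[node]
        if node < n:
            return f"{name(node)}:{bl:.10g}"
        a, b = children[node]
        inner = ",".join(render(c, height[node]) for c in (a, b))
        return f"({inner}):{bl:.10g}"

    root = n + len(tree.merges) - 1 if tree.merges else 0
    a, b = children[root]
    inner = ",".join(render(c, height[root]) for c in (a, b))
    return f"({inner});"


def write_newick(tree: MergeTree, path: str | Path, **kw) -> None:
    Path(path).write_text(to_newick(tree, **kw) + "\n")


def cluster_representatives(
    assignment: ClusterAssignment,
    identity: IdentityMatrix,
    eligibility: Optional[Mapping[str, bool] | Callable[[str], bool]] = None,
) -> dict[int, Optional[str]]:
    """Pick one deterministic representative per cluster.

    Among eligible members (all members when ``eligibility`` is omitted) the
    representative maximises its average identity to the other members of
    its own cluster (a medoid in identity space); ties break to the
    lexicographically least id.  Clusters with no eligible member map to
    ``None`` — mirroring sequence clusters for which no cognate tRNA gene
    exists.
    """
    if eligibility is None:
        is_ok = lambda _i: True
    elif callable(eligibility):
        is_ok = eligibility
    else:
        is_ok = lambda i: bool(eligibility.get(i, False))

    out: dict[int, Optional[str]] = {}
    for c in range(assignment.k):
        members = assignment.members(c)
        candidates = [i for i in members if is_ok(i)]
        if not candidates:
            out[c] = None
            continue

        def mean_ident(i: str) -> float:
            others = [j for j in members if j != i]
            if not others:
                return 100.0
            return float(np.mean([identity.value(i, j) for j in others]))

        out[c] = min(candidates, key=lambda i: (-mean_ident(i), i))
    return out


def write_cluster_table(
    assignment: ClusterAssignment,
    path: str | Path,
    representatives: Optional[Mapping[int, Optional[str]]] = None,
) -> None:
    """TSV of id, cluster index and representative flag."""
    df = assignment.to_frame()
    if representatives is not None:
        reps = {v for v in representatives.values() if v is not None}
        df["representative"] = df["id"].isin(reps).astype(int)
    df.to_csv(path, sep="\t", index=False)
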