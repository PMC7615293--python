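"""Independent brute-force oracles used to cross-check the package.

These deliberately re-derive everything from first principles (exhaustive
enumeration, naive re-averaging) and share no code with the implementations
they check.
"""

import itertools
import math

import numpy as np


def brute_force_upgma_heights(sim: np.ndarray) -> list[float]:
    """Merge heights of average-linkage clustering, recomputed naively.

    At every step the average similarity between each pair of clusters is
    recomputed as the mean over all cross-cluster leaf pairs of the
    *original* matrix (no incremental update).  Returns heights in merge
    order.
    """
    n = sim.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights: list[float] = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                vals = [sim[i, j] for i in clusters[a] for j in clusters[b]]
                s = float(np.mean(vals))
                # tie-break irrelevant for height comparison but keep it
                # deterministic: smallest leaf index first
                key = (-s, min(clusters[a]), min(clusters[b]))
                if best is None or key < best[0]:
                    best = (key, a, b, s)
        _, a, b, s = best
        heights.append(s)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


def brute_force_orthogonal_sets(
    values: np.ndarray,
    trnas: list[str],
    synths: list[str],
    order: int,
    min_cognate: float = 40.0,
    max_cross: float = 20.0,
    min_oc: float = 2.5,
) -> dict[frozenset, float]:
    """Exhaustive enumeration of passing N-sets.

    Returns ``{frozenset of (synthetase, trna) pairs: oc}``.  Tuples that
    touch an unmeasured cell are excluded.
    """
    T, S = values.shape
    results: dict[frozenset, float] = {}
    for cols in itertools.combinations(range(S), order):
        for rows in itertools.combinations(range(T), order):
            sub = values[np.ix_(rows, cols)]
            if np.isnan(sub).any():
                continue
            for perm in itertools.permutations(range(order)):
                diag = sub[list(perm), list(range(order))]
                if not (diag > min_cognate).all():
                    continue
                mask = np.ones((order, order), dtype=bool)
                mask[list(perm), list(range(order))] = False
                off = sub[mask]
                if not (off < max_cross).all():
                    continue
                max_off = float(off.max())
                oc = math.inf if max_off == 0 else float(diag.min()) / max_off
                if not oc > min_oc:
                    continue
                pairs = frozenset(
                    (synths[cols[j]], trnas[rows[perm[j]]]) for j in range(order)
                )
                results[pairs] = oc
    return results


def random_activity_values(
    rng: np.random.Generator,
    n_trnas: int,
    n_synths: int,
    p_high: float = 0.25,
    p_missing: float = 0.0,
) -> np.ndarray:
    """Mixture matrix: mostly low cross-reactivity, some strong cells."""
    high = rng.random((n_trnas, n_synths)) < p_high
    vals = np.where(
        high,
        rng.uniform(40.0, 100.0, (n_trnas, n_synths)),
        rng.uniform(0.0, 30.0, (n_trnas, n_synths)),
    )
    if p_missing > 0:
        vals[rng.random((n_trnas, n_synths)) < p_missing] = np.nan
    return vals
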