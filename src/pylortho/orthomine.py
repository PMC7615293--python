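"""Combinatorial mining of mutually orthogonal synthetase/tRNA sets.

A candidate set of N pairs ``(synthetase_k, tRNA_k)`` defines an N x N
submatrix of the activity matrix: the diagonal holds the cognate (intra-pair)
activities and the off-diagonal the cross-reactivities.  The set is mutually
orthogonal when

  (i)   every cognate activity is strictly greater than ``min_cognate``
        (default 40% of the wtGFP control),
  (ii)  every cross-reactivity is strictly less than ``max_cross``
        (default 20%), and
  (iii) the orthogonality coefficient — the lowest cognate activity divided
        by the highest cross-reactivity — is strictly greater than
        ``min_oc`` (screens at 2.5, stricter analyses at 5.0).

Any measured combination whose activity clears ``min_cognate`` may serve as
a cognate pair, including heterologous synthetase/tRNA combinations from
different organisms.  Enumeration uses candidate pre-filtering and
branch-and-bound pruning but is output-equivalent to exhaustive search over
all assignments with distinct synthetases and distinct tRNAs.

Key property exploited for pruning: the criteria are hereditary.  Removing
a pair from a passing set cannot lower the minimum cognate activity nor
raise the maximum cross-reactivity, so every sub-tuple of a passing set
passes with an orthogonality coefficient at least as high.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .activity import ActivityMatrix, EntityMetadata
from .errors import (
    IncompleteDataError,
    MetadataError,
    ParameterError,
    SetOrderError,
)

Pair = tuple[str, str]  # (synthetase_id, trna_id)


@dataclass(frozen=True)
class OrthogonalityCriteria:
    """Thresholds defining a mutually orthogonal set (all strict)."""

    min_cognate: float = 40.0
    max_cross: float = 20.0
    min_oc: float = 2.5

    def __post_init__(self):
        if not (self.min_cognate > self.max_cross > 0):
            raise ParameterError(
                "criteria require min_cognate > max_cross > 0, got "
                f"{self.min_cognate} / {self.max_cross}"
            )
        if not self.min_oc > 1:
            raise ParameterError(f"min_oc must be > 1, got {self.min_oc}")


@dataclass(frozen=True)
class OrthogonalSet:
    """An N-tuple of pairs with its orthogonality coefficient.

    ``oc`` is ``math.inf`` when every cross-reactivity is exactly zero.
    Pairs are stored sorted by (synthetase id, tRNA id); two sets are equal
    iff their pair sets coincide.
    """

    pairs: tuple[Pair, ...]
    oc: float
    min_cognate_observed: float
    max_cross_observed: float

    @property
    def order(self) -> int:
        return len(self.pairs)

    @property
    def synthetase_ids(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.pairs)

    @property
    def trna_ids(self) -> frozenset[str]:
        return frozenset(t for _, t in self.pairs)


@dataclass(frozen=True)
class Family:
    """Orthogonal sets sharing the same unordered synthetase set."""

    synthetase_set: frozenset[str]
    members: tuple[OrthogonalSet, ...]

    @property
    def best(self) -> OrthogonalSet:
        return self.members[0]


@dataclass(frozen=True)
class CheckResult:
    """Outcome of an orthogonality check with diagnostics."""

    passed: bool
    oc: float
    min_cognate_observed: float
    max_cross_observed: float
    failed_criterion: Optional[str] = None  # 'cognate' | 'cross' | 'oc'
    offending_cell: Optional[tuple[str, str]] = None  # (trna, synthetase)

    def __bool__(self) -> bool:
        return self.passed


def _submatrix(
    m: ActivityMatrix, pairs: Sequence[Pair], treat_missing_as_zero: bool
) -> np.ndarray:
    """N x N array: rows follow the pairs' tRNAs, columns their synthetases."""
    n = len(pairs)
    if n < 2:
        raise SetOrderError(f"a set needs >= 2 pairs, got {n}")
    synths = [s for s, _ in pairs]
    trnas = [t for _, t in pairs]
    if len(set(synths)) != n or len(set(trnas)) != n:
        raise SetOrderError("pairs must use distinct synthetases and distinct tRNAs")
    sub = m.table.loc[trnas, synths].to_numpy(dtype=float)
    if np.isnan(sub).any():
        if treat_missing_as_zero:
            sub = np.nan_to_num(sub, nan=0.0)
        else:
            i, j = map(int, np.argwhere(np.isnan(sub))[0])
            raise IncompleteDataError(
                f"unmeasured combination: tRNA {trnas[i]!r} x synthetase {synths[j]!r}"
            )
    return sub


def orthogonality_coefficient(
    m: ActivityMatrix,
    pairs: Sequence[Pair],
    treat_missing_as_zero: bool = False,
) -> float:
    """Lowest cognate activity over highest cross-reactivity for a set.

    Returns ``math.inf`` when all cross entries are exactly zero.
    """
    sub = _submatrix(m, pairs, treat_missing_as_zero)
    n = sub.shape[0]
    diag = np.diag(sub)
    off = sub[~np.eye(n, dtype=bool)]
    max_off = float(off.max())
    if max_off == 0.0:
        return math.inf
    return float(diag.min() / max_off)


def is_orthogonal(
    m: ActivityMatrix,
    pairs: Sequence[Pair],
    criteria: OrthogonalityCriteria = OrthogonalityCriteria(),
    treat_missing_as_zero: bool = False,
) -> CheckResult:
    """Check criteria (i)-(iii) with diagnostics naming the first violation."""
    sub = _submatrix(m, pairs, treat_missing_as_zero)
    n = sub.shape[0]
    trnas = [t for _, t in pairs]
    synths = [s for s, _ in pairs]
    diag = np.diag(sub)
    off_mask = ~np.eye(n, dtype=bool)
    min_cog = float(diag.min())
    max_cross = float(sub[off_mask].max())
    oc = math.inf if max_cross == 0 else min_cog / max_cross

    for k in range(n):
        if not sub[k, k] > criteria.min_cognate:
            return CheckResult(
                False, oc, min_cog, max_cross, "cognate", (trnas[k], synths[k])
            )
    for i in range(n):
        for j in range(n):
            if i != j and not sub[i, j] < criteria.max_cross:
                return CheckResult(
                    False, oc, min_cog, max_cross, "cross", (trnas[i], synths[j])
                )
    if not oc > criteria.min_oc:
        return CheckResult(False, oc, min_cog, max_cross, "oc", None)
    return CheckResult(True, oc, min_cog, max_cross)


def _sort_key(s: OrthogonalSet):
    # +inf oc first; among infinities, higher observed cognate floor first;
    # then lexicographic pair ids for a stable order.
    return (
        0 if math.isinf(s.oc) else 1,
        -s.min_cognate_observed if math.isinf(s.oc) else -s.oc,
        s.pairs,
    )


def enumerate_orthogonal_sets(
    m: ActivityMatrix,
    order: int,
    criteria: OrthogonalityCriteria = OrthogonalityCriteria(),
    allow_heterologous: bool = True,
    cognate_map: Optional[Mapping[str, str]] = None,
    treat_missing_as_zero: bool = False,
) -> list[OrthogonalSet]:
    """All mutually orthogonal N-sets of pairs, sorted by descending oc.

    Candidate cognate pairs are every measured combination with activity
    strictly above ``min_cognate``; with ``allow_heterologous=False`` they
    are restricted to the supplied ``cognate_map`` (tRNA id -> synthetase
    id).  Tuples touching an unmeasured cross-reactivity are excluded
    unless ``treat_missing_as_zero`` is set.  The backtracking search
    prunes on criteria (ii) and on the oc upper bound, and is
    output-equivalent to exhaustive enumeration.
    """
    if order < 2:
        raise SetOrderError(f"order must be >= 2, got {order}")
    table = m.table
    if treat_missing_as_zero:
        table = table.fillna(0.0)
    vals = table.to_numpy(dtype=float)
    trnas = list(table.index)
    synths = list(table.columns)

    candidates: list[tuple[str, str, int, int, float]] = []
    for ti, t in enumerate(trnas):
        for si, s in enumerate(synths):
            x = float(vals[ti, si])
            if math.isnan(x) or not x > criteria.min_cognate:
                continue
            if not allow_heterologous:
                if cognate_map is None:
                    raise MetadataError(
                        "allow_heterologous=False requires a cognate_map"
                    )
                if cognate_map.get(t) != s:
                    continue
            candidates.append((s, t, si, ti, x))
    candidates.sort()  # lexicographic by (synthetase id, trna id)

    results: list[OrthogonalSet] = []
    chosen: list[tuple[str, str, int, int, float]] = []

    def compatible(cand, other) -> Optional[float]:
        """Max of the two new cross entries, or None if the pair is barred."""
        _, _, si, ti, _ = cand
        _, _, sj, tj, _ = other
        a = float(vals[ti, sj])
        b = float(vals[tj, si])
        if math.isnan(a) or math.isnan(b):
            return None
        if a >= criteria.max_cross or b >= criteria.max_cross:
            return None
        return max(a, b)

    def extend(start: int, min_cog: float, max_cross: float):
        if len(chosen) == order:
            oc = math.inf if max_cross == 0 else min_cog / max_cross
            if oc > criteria.min_oc:
                pairs = tuple(sorted((s, t) for s, t, *_ in chosen))
                results.append(
                    OrthogonalSet(pairs, oc, min_cog, max_cross)
                )
            return
        for k in range(start, len(candidates)):
            cand = candidates[k]
            s, t, si, ti, x = cand
            if any(s == cs or t == ct for cs, ct, *_ in chosen):
                continue
            worst = max_cross
            ok = True
            for other in chosen:
                mx = compatible(cand, other)
                if mx is None:
                    ok = False
                    break
                worst = max(worst, mx)
            if not ok:
                continue
            new_min = min(min_cog, x)
            # oc can only fall as the set grows: prune on its upper bound.
            if worst > 0 and new_min / worst <= criteria.min_oc:
                continue
            chosen.append(cand)
            extend(k + 1, new_min, worst)
            chosen.pop()

    extend(0, math.inf, 0.0)
    results.sort(key=_sort_key)
    return results


def group_into_families(sets: Iterable[OrthogonalSet]) -> list[Family]:
    """Partition sets by their unordered synthetase set.

    Families are sorted by their best member's oc (descending); members
    within a family likewise.
    """
    sets = list(sets)
    if not sets:
        return []
    orders = {s.order for s in sets}
    if len(orders) != 1:
        raise SetOrderError(f"mixed set orders: {sorted(orders)}")
    groups: dict[frozenset[str], list[OrthogonalSet]] = {}
    for s in sets:
        groups.setdefault(s.synthetase_ids, []).append(s)
    families = [
        Family(k, tuple(sorted(v, key=_sort_key))) for k, v in groups.items()
    ]
    families.sort(key=lambda f: _sort_key(f.best))
    return families


@dataclass(frozen=True)
class InterClassRelation:
    """Orthogonality status of one unordered pair of synthetase classes."""

    class_a: str
    class_b: str
    status: str  # mutually-orthogonal | one-sided | two-sided | no-candidates
    witnesses: tuple[tuple[Pair, Pair], ...] = ()


def classify_interclass(
    m: ActivityMatrix,
    metadata: Mapping[str, EntityMetadata],
    criteria: OrthogonalityCriteria = OrthogonalityCriteria(),
) -> list[InterClassRelation]:
    """Classify every pair of synthetase classes by attainable orthogonality.

    For classes R1 and R2, the relation is ``mutually-orthogonal`` when
    some doublet combining an R1 pair with an R2 pair passes all criteria.
    Otherwise each candidate doublet is inspected: when both of its cross
    entries are individually disqualifying (at or above ``max_cross``, or
    forcing the oc at or below ``min_oc``) for *every* candidate, the
    relation shows ``two-sided`` cross-reactivity; if some candidate fails
    through a single cross entry only, it is ``one-sided``.  Witnesses
    record the best supporting doublet.
    """
    for sid in m.synthetase_ids:
        if sid not in metadata:
            raise MetadataError(f"synthetase {sid!r} has no metadata entry")
    classes = sorted({metadata[s].class_label for s in m.synthetase_ids})
    by_class: dict[str, list[str]] = {c: [] for c in classes}
    for s in m.synthetase_ids:
        by_class[metadata[s].class_label].append(s)

    vals = m.table
    # viable cognate pairs per synthetase
    cognates: dict[str, list[tuple[str, float]]] = {}
    for s in m.synthetase_ids:
        col = vals[s]
        cognates[s] = [
            (t, float(col[t]))
            for t in m.trna_ids
            if not math.isnan(col[t]) and col[t] > criteria.min_cognate
        ]

    def cross_violates(cross: float, min_cog: float) -> bool:
        if cross >= criteria.max_cross:
            return True
        return cross > 0 and min_cog / cross <= criteria.min_oc

    relations: list[InterClassRelation] = []
    for ai in range(len(classes)):
        for bi in range(ai + 1, len(classes)):
            ra, rb = classes[ai], classes[bi]
            best_pass: Optional[tuple[float, tuple[Pair, Pair]]] = None
            any_candidate = False
            any_single = False
            for s1 in by_class[ra]:
                for s2 in by_class[rb]:
                    if s1 == s2:
                        continue
                    for t1, c1 in cognates[s1]:
                        for t2, c2 in cognates[s2]:
                            if t1 == t2:
                                continue
                            a = vals.at[t1, s2]
                            b = vals.at[t2, s1]
                            if math.isnan(a) or math.isnan(b):
                                continue
                            any_candidate = True
                            pairs = ((s1, t1), (s2, t2))
                            check = is_orthogonal(m, pairs, criteria)
                            if check.passed:
                                if best_pass is None or check.oc > best_pass[0]:
                                    best_pass = (check.oc, pairs)
                                continue
                            min_cog = min(c1, c2)
                            nviol = sum(
                                cross_violates(float(x), min_cog) for x in (a, b)
                            )
                            if nviol <= 1:
                                any_single = True
            if best_pass is not None:
                status = "mutually-orthogonal"
                witnesses = (best_pass[1],)
            elif not any_candidate:
                status, witnesses = "no-candidates", ()
            elif any_single:
                status, witnesses = "one-sided", ()
            else:
                status, witnesses = "two-sided", ()
            relations.append(InterClassRelation(ra, rb, status, witnesses))
    return relations


def count_summary(
    m: ActivityMatrix,
    criteria: OrthogonalityCriteria = OrthogonalityCriteria(),
    orders: Sequence[int] = (2, 3, 4, 5),
    **enumerate_kw,
) -> dict[int, dict]:
    """Per-order set counts, family counts and maximum oc."""
    out: dict[int, dict] = {}
    for n in orders:
        sets = enumerate_orthogonal_sets(m, n, criteria, **enumerate_kw)
        fams = group_into_families(sets)
        out[n] = {
            "count": len(sets),
            "family_count": len(fams),
            "max_oc": (max((s.oc for s in sets), default=None)),
        }
    return out


def write_sets_tsv(
    sets: Sequence[OrthogonalSet],
    path: str | Path,
    families: Optional[Sequence[Family]] = None,
) -> None:
    """Per-set TSV: order, ids, oc, observed extremes and family index."""
    fam_of: dict[frozenset[str], int] = {}
    if families is not None:
        for k, f in enumerate(families):
            fam_of[f.synthetase_set] = k
    rows = []
    for s in sets:
        rows.append(
            {
                "order": s.order,
                "synthetase_ids": ";".join(sorted(s.synthetase_ids)),
                "trna_ids": ";".join(sorted(s.trna_ids)),
                "pairs": ";".join(f"{a}|{b}" for a, b in s.pairs),
                "oc": "inf" if math.isinf(s.oc) else round(s.oc, 4),
                "min_cognate": round(s.min_cognate_observed, 4),
                "max_cross": round(s.max_cross_observed, 4),
                "family": fam_of.get(s.synthetase_ids, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary_json(summary: Mapping[int, Mapping], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({str(k): dict(v) for k, v in summary.items()}, indent=1)
    )
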