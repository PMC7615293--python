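"""Identity-vs-activity calibration of orthogonality thresholds.

The empirical observation motivating the whole pipeline: when two
synthetases share more than ~55% sequence identity (or two tRNAs more than
~75%), one enzyme is usually active with the other's cognate tRNA.  This
module assembles, from an activity matrix and identity matrices, the scatter
of (identity, activity) points behind that observation, and computes the
fraction of high-identity combinations that are cross-active — as a single
threshold or scanned over a grid.

The activity level that counts as "active" is deliberately a parameter:
published summary fractions rarely state it, so the honest output is the
fraction as a function of the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd

from .activity import ActivityMatrix
from .errors import EmptyStratumError, MetadataError
from .seqid import IdentityMatrix

Axis = Literal["synthetase", "trna"]


def _ident(matrix: IdentityMatrix, a: str, b: str) -> float:
    try:
        return matrix.value(a, b)
    except ValueError:
        raise MetadataError(
            f"identity matrix lacks an entry for {a!r} / {b!r}"
        ) from None


@dataclass(frozen=True)
class IdentityActivityPoint:
    """One measured combination with the identity of the relevant entities.

    For ``axis='synthetase'`` the identity is between the synthetase of the
    combination and the cognate synthetase of the combination's tRNA; for
    ``axis='trna'`` between the tRNA and the cognate tRNA of the
    synthetase.
    """

    entity_pair: tuple[str, str]
    identity: float
    activity: float


@dataclass(frozen=True)
class FractionResult:
    fraction: float
    n_active: int
    n_above: int


@dataclass(frozen=True)
class ThresholdCurve:
    """fraction_active_above evaluated over a grid of identity thresholds.

    ``fractions[k]`` is ``None`` where no point lies above ``thresholds[k]``
    (an empty stratum is undefined, not zero).
    """

    thresholds: tuple[float, ...]
    fractions: tuple[Optional[float], ...]
    n_above: tuple[int, ...]
    activity_cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "identity_threshold": self.thresholds,
                "fraction_active": [
                    float("nan") if f is None else f for f in self.fractions
                ],
                "n_above": self.n_above,
            }
        )


def build_identity_activity_points(
    m: ActivityMatrix,
    synth_identity: Optional[IdentityMatrix],
    trna_identity: Optional[IdentityMatrix],
    cognate_map: Mapping[str, str],
    axis: Axis = "synthetase",
) -> list[IdentityActivityPoint]:
    """One point per measured activity cell.

    ``cognate_map`` maps each tRNA id to its cognate synthetase id (the
    same-organism partner by default; heterologous cognates simply appear
    as the mapped partner).  It must be invertible for ``axis='trna'``.
    """
    points: list[IdentityActivityPoint] = []
    if axis == "synthetase":
        ident = synth_identity
        if ident is None:
            raise MetadataError("synthetase identity matrix required for this axis")
        for t in m.trna_ids:
            cognate = cognate_map.get(t)
            if cognate is None:
                raise MetadataError(f"tRNA {t!r} has no cognate synthetase mapping")
            for s in m.synthetase_ids:
                x = m.value(t, s)
                if math.isnan(x):
                    continue
                points.append(
                    IdentityActivityPoint((cognate, s), _ident(ident, cognate, s), x)
                )
    elif axis == "trna":
        ident = trna_identity
        if ident is None:
            raise MetadataError("tRNA identity matrix required for this axis")
        inverse: dict[str, str] = {}
        for t, s in cognate_map.items():
            if s in inverse:
                raise MetadataError(
                    f"cognate map is not invertible: synthetase {s!r} maps "
                    f"to both {inverse[s]!r} and {t!r}"
                )
            inverse[s] = t
        for t in m.trna_ids:
            for s in m.synthetase_ids:
                x = m.value(t, s)
                if math.isnan(x):
                    continue
                cognate = inverse.get(s)
                if cognate is None:
                    raise MetadataError(f"synthetase {s!r} has no cognate tRNA")
                points.append(
                    IdentityActivityPoint((cognate, t), _ident(ident, cognate, t), x)
                )
    else:  # pragma: no cover
        raise ValueError(f"unknown axis {axis!r}")
    return points


def fraction_active_above(
    points: Sequence[IdentityActivityPoint],
    identity_threshold: float,
    activity_cutoff: float,
) -> FractionResult:
    """Fraction of points with identity strictly above the threshold whose
    activity is at least ``activity_cutoff``."""
    above = [p for p in points if p.identity > identity_threshold]
    if not above:
        raise EmptyStratumError(
            f"no points with identity > {identity_threshold}"
        )
    active = sum(p.activity >= activity_cutoff for p in above)
    return FractionResult(active / len(above), active, len(above))


def scan_thresholds(
    points: Sequence[IdentityActivityPoint],
    activity_cutoff: float,
    grid: Sequence[float],
) -> ThresholdCurve:
    """Evaluate :func:`fraction_active_above` across a threshold grid."""
    if len(grid) == 0:
        raise EmptyStratumError("threshold grid is empty")
    fractions: list[Optional[float]] = []
    counts: list[int] = []
    for t in grid:
        try:
            res = fraction_active_above(points, t, activity_cutoff)
            fractions.append(res.fraction)
            counts.append(res.n_above)
        except EmptyStratumError:
            fractions.append(None)
            counts.append(0)
    return ThresholdCurve(
        thresholds=tuple(float(t) for t in grid),
        fractions=tuple(fractions),
        n_above=tuple(counts),
        activity_cutoff=float(activity_cutoff),
    )


def write_points_tsv(
    points: Sequence[IdentityActivityPoint], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "entity_a": [p.entity_pair[0] for p in points],
            "entity_b": [p.entity_pair[1] for p in points],
            "identity": [round(p.identity, 4) for p in points],
            "activity": [round(p.activity, 4) for p in points],
        }
    ).to_csv(path, sep="\t", index=False)
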