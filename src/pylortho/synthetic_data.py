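"""Synthetic alignments and activity matrices with planted ground truth.

Every pipeline stage can be exercised without any sequence database or
plate-reader data: this module generates

* aligned sequence families with a planted class structure whose
  within-class identities sit above, and between-class identities below,
  configurable bands (emulating the synthetase/tRNA family structure that
  identity-threshold clustering is meant to recover);
* activity matrices in which combinations of high-identity entities are
  active with high probability (~0.9, the empirically observed rate) while
  low-identity combinations behave unpredictably; and
* a fixture with exactly one planted mutually orthogonal quintuplet plus
  decoys that each violate exactly one orthogonality criterion.

All generators draw from a single :class:`numpy.random.Generator` seeded
explicitly, so identical seeds give byte-identical outputs, and each
generator validates its own declared truth before returning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .activity import ActivityMatrix, activity_matrix
from .errors import FeasibilityError, ParameterError
from .orthomine import (
    OrthogonalityCriteria,
    OrthogonalSet,
    is_orthogonal,
    orthogonality_coefficient,
)
from .seqid import AlignedSequenceSet, IdentityMatrix, aligned_set, identity_matrix

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDE_ALPHABET = "ACGU"

_MAX_TRIES = 60


@dataclass(frozen=True)
class SyntheticTruth:
    """Declared ground truth emitted alongside every synthetic dataset."""

    class_of: dict[str, str]
    planted_sets: tuple[OrthogonalSet, ...]
    generator_params: dict

    def write_json(self, path: str | Path) -> None:
        payload = {
            "class_of": self.class_of,
            "planted_sets": [
                {
                    "pairs": list(map(list, s.pairs)),
                    "oc": ("inf" if math.isinf(s.oc) else s.oc),
                }
                for s in self.planted_sets
            ],
            "generator_params": self.generator_params,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _alphabet_chars(alphabet: str) -> str:
    if alphabet == "protein":
        return PROTEIN_ALPHABET
    if alphabet == "nucleotide":
        return NUCLEOTIDE_ALPHABET
    raise ParameterError(f"unknown alphabet {alphabet!r}")


def _mutate(seq: np.ndarray, rate: float, chars: str, rng: np.random.Generator):
    """Replace each position, with probability ``rate``, by a different char."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    idx = np.nonzero(hit)[0]
    pool = np.array(list(chars), dtype="U1")
    for i in idx:
        choices = pool[pool != out[i]]
        out[i] = rng.choice(choices)
    return out


def simulate_sequence_classes(
    n_classes: int,
    sizes: Sequence[int],
    intra_identity_min: float = 70.0,
    inter_identity_max: float = 40.0,
    length: int = 120,
    alphabet: str = "protein",
    seed: int = 0,
) -> tuple[AlignedSequenceSet, SyntheticTruth]:
    """Sequence families with planted classes and controlled identity bands.

    Each class descends from its own independently drawn ancestor string,
    placing between-class identity near the random-composition baseline of
    the alphabet; members mutate from their ancestor at a per-site rate
    targeting the middle of the within-class band.  The draw is
    rejection-resampled
    until every realised within-class identity is at least
    ``intra_identity_min`` and every between-class identity at most
    ``inter_identity_max``; an infeasible band raises
    :class:`FeasibilityError` rather than silently relaxing.
    """
    if n_classes < 1 or len(sizes) != n_classes:
        raise ParameterError("sizes must list one member count per class")
    if not intra_identity_min > inter_identity_max:
        raise ParameterError(
            "need intra_identity_min > inter_identity_max, got "
            f"{intra_identity_min} <= {inter_identity_max}"
        )
    chars = _alphabet_chars(alphabet)
    baseline = 100.0 / len(chars)
    if n_classes > 1 and inter_identity_max <= baseline + 5:
        raise FeasibilityError(
            f"inter_identity_max={inter_identity_max} is at or below the "
            f"random-match baseline (~{baseline:.0f}%) for a "
            f"{len(chars)}-letter alphabet"
        )

    rng = np.random.default_rng(seed)
    # Two members mutated from a shared ancestor at per-site rate r match
    # with probability (1-r)^2 + r^2/(k-1): both untouched, or both mutated
    # to the same of the k-1 alternatives.  Solve for r targeting the middle
    # of the within-class band.
    k = len(chars)
    intra_target = (intra_identity_min / 100.0 + 1.0) / 2.0
    lo, hi = 0.0, (k - 1) / k
    for _ in range(60):
        mid = (lo + hi) / 2
        ident = (1 - mid) ** 2 + mid**2 / (k - 1)
        if ident > intra_target:
            lo = mid
        else:
            hi = mid
    member_rate = (lo + hi) / 2

    for _ in range(_MAX_TRIES):
        ids: list[str] = []
        seqs: list[str] = []
        class_of: dict[str, str] = {}
        for c in range(n_classes):
            # independent ancestors put between-class identity near the
            # random-composition baseline, well under inter_identity_max
            ancestor = rng.choice(list(chars), size=length)
            for k in range(sizes[c]):
                sid = f"C{c + 1}_{k + 1:02d}"
                member = _mutate(ancestor, member_rate, chars, rng)
                ids.append(sid)
                seqs.append("".join(member))
                class_of[sid] = f"C{c + 1}"
        aln = aligned_set(zip(ids, seqs), alphabet)  # type: ignore[arg-type]
        ident = identity_matrix(aln)
        ok = True
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                v = ident.values[i, j]
                same = class_of[ids[i]] == class_of[ids[j]]
                if same and v < intra_identity_min:
                    ok = False
                elif not same and v > inter_identity_max:
                    ok = False
            if not ok:
                break
        if ok:
            truth = SyntheticTruth(
                class_of=class_of,
                planted_sets=(),
                generator_params={
                    "seed": seed,
                    "n_classes": n_classes,
                    "sizes": list(sizes),
                    "intra_identity_min": intra_identity_min,
                    "inter_identity_max": inter_identity_max,
                    "length": length,
                    "alphabet": alphabet,
                },
            )
            return aln, truth
    raise FeasibilityError(
        f"could not realise identity bands ({intra_identity_min}, "
        f"{inter_identity_max}) in {_MAX_TRIES} draws; bands too tight for "
        f"length {length}"
    )


def simulate_activity_matrix(
    identity: IdentityMatrix,
    identity_threshold: float,
    p_active_high: float = 0.9,
    p_active_low: float = 0.3,
    active_range: tuple[float, float] = (40.0, 100.0),
    inactive_range: tuple[float, float] = (0.0, 20.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    class_of: Optional[Mapping[str, str]] = None,
) -> tuple[ActivityMatrix, SyntheticTruth]:
    """Activity matrix whose structure follows the identity threshold rule.

    Each identity-matrix entity ``e`` contributes one synthetase ``e_RS``
    (column) and one tRNA ``e_tRNA`` (row).  A combination whose entity
    identity is strictly above ``identity_threshold`` (cognates included,
    at identity 100) is drawn active with probability ``p_active_high``
    (uniform on ``active_range``), otherwise inactive (uniform on
    ``inactive_range``); below-threshold combinations are active with the
    lower probability ``p_active_low``.  Gaussian noise of s.d.
    ``noise_sd`` is added and the result clamped at zero.
    """
    if not (0.0 < p_active_high <= 1.0) or not (0.0 <= p_active_low <= 1.0):
        raise ParameterError("activation probabilities must lie in (0, 1]")
    if not active_range[0] > inactive_range[1]:
        raise ParameterError(
            f"active range {active_range} must lie strictly above the "
            f"inactive range {inactive_range}"
        )
    rng = np.random.default_rng(seed)
    ids = identity.ids
    n = len(ids)
    vals = np.zeros((n, n))
    for i in range(n):  # tRNA of entity i
        for j in range(n):  # synthetase of entity j
            above = identity.values[i, j] > identity_threshold
            p = p_active_high if above else p_active_low
            if rng.random() < p:
                vals[i, j] = rng.uniform(*active_range)
            else:
                vals[i, j] = rng.uniform(*inactive_range)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, vals.shape)
    vals = np.clip(vals, 0.0, None)

    m = activity_matrix(
        vals,
        trna_ids=[f"{e}_tRNA" for e in ids],
        synthetase_ids=[f"{e}_RS" for e in ids],
    )
    truth = SyntheticTruth(
        class_of=dict(class_of) if class_of else {},
        planted_sets=(),
        generator_params={
            "seed": seed,
            "identity_threshold": identity_threshold,
            "p_active_high": p_active_high,
            "p_active_low": p_active_low,
            "active_range": list(active_range),
            "inactive_range": list(inactive_range),
            "noise_sd": noise_sd,
        },
    )
    if noise_sd == 0.0:
        lo = min(inactive_range[0], active_range[0])
        hi = max(inactive_range[1], active_range[1])
        assert float(vals.min()) >= lo and float(vals.max()) <= hi
    return m, truth


def planted_quintuplet_fixture(
    seed: int = 0,
    criteria: OrthogonalityCriteria = OrthogonalityCriteria(),
) -> tuple[ActivityMatrix, SyntheticTruth]:
    """Activity matrix with exactly one mutually orthogonal quintuplet.

    Five planted pairs have cognate activities in [50, 95] and mutual
    cross-reactivities in [0, 10].  Three decoy pairs are near-misses, each
    violating exactly one criterion when substituted into the planted set:

    * ``s6/t6`` — cognate activity 35, failing the cognate-activity floor;
    * ``s7/t7`` — cross-reactivity 25 against every planted synthetase,
      failing the cross-reactivity ceiling;
    * ``s8/t8`` — cross-reactivity 18 against every planted synthetase
      with cognate activity 42, passing (i) and (ii) but dragging the
      orthogonality coefficient to 42/18 < 2.5.

    The decoy cross levels apply to *all* planted synthetases, so no
    five-tuple other than the planted one can pass.  Self-validated on
    every call.
    """
    rng = np.random.default_rng(seed)
    n_planted = 5
    synths = [f"s{k + 1}" for k in range(8)]
    trnas = [f"t{k + 1}" for k in range(8)]
    vals = rng.uniform(0.0, 10.0, size=(8, 8))

    for k in range(n_planted):
        vals[k, k] = rng.uniform(50.0, 95.0)
    # decoy cognates
    vals[5, 5] = 35.0  # fails (i)
    vals[6, 6] = 80.0
    vals[7, 7] = 42.0
    for k in range(n_planted):
        vals[6, k] = 25.0  # t7 cross vs planted synthetases: fails (ii)
        vals[7, k] = 18.0  # t8 cross: passes (ii) but caps oc below 2.5
    # planted tRNAs stay clean against decoy synthetases (already < 10)

    m = activity_matrix(vals, trna_ids=trnas, synthetase_ids=synths)
    pairs = tuple((synths[k], trnas[k]) for k in range(n_planted))
    oc = orthogonality_coefficient(m, pairs)
    planted = OrthogonalSet(
        pairs=tuple(sorted(pairs)),
        oc=oc,
        min_cognate_observed=float(min(vals[k, k] for k in range(n_planted))),
        max_cross_observed=float(
            max(
                vals[i, j]
                for i in range(n_planted)
                for j in range(n_planted)
                if i != j
            )
        ),
    )
    truth = SyntheticTruth(
        class_of={},
        planted_sets=(planted,),
        generator_params={"seed": seed, "n_synthetases": 8, "n_trnas": 8},
    )
    check = is_orthogonal(m, pairs, criteria)
    if not check.passed:  # pragma: no cover - construction guarantees this
        raise RuntimeError(f"planted quintuplet failed self-validation: {check}")
    return m, truth
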