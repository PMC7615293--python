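"""tRNA x synthetase reporter-activity matrices.

Interactions between candidate synthetases and tRNAs are measured with an
amber-suppression GFP reporter and expressed as a matrix ``x[i][j]``: the
activity of synthetase ``j`` with tRNA ``i`` as a percentage of a wild-type
GFP control (a reporter without the stop codon).  This module loads such
tables from delimited text, normalises raw fluorescence readings, and
filters to entities that show meaningful activity with at least one
partner.

Missing measurements are kept explicit (``NaN``): absence of a measurement
is never evidence of orthogonality, and downstream consumers must either
reject incomplete tuples or opt into an explicit missing-as-zero policy.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdError,
    EmptyInputError,
    InvalidControlError,
    MetadataError,
    TableParseError,
)

GROUPS = {"+N", "dN", "sN", "archaeal-sN", "engineered"}
CLASS_LABELS = {"N", "A", "B", "C", "S", "SdB", "SdC", "engineered-variant"}

# Accept the Greek-letter spellings used in the literature.
_LABEL_ALIASES = {
    "ΔN": "dN",  # ΔN
    "S^ΔB": "SdB",
    "S^ΔC": "SdC",
}

_MISSING_TOKENS = {"", "na", "nan", "n/a", "none", "null", "."}


@dataclass(frozen=True)
class ActivityMatrix:
    """Interaction matrix: rows are tRNAs, columns are synthetases.

    ``table`` holds percent-of-wtGFP activities, ``NaN`` marking missing
    measurements.
    """

    table: pd.DataFrame

    def __post_init__(self):
        idx, cols = self.table.index, self.table.columns
        if idx.duplicated().any():
            raise DuplicateIdError(f"duplicate tRNA ids: {list(idx[idx.duplicated()])}")
        if cols.duplicated().any():
            raise DuplicateIdError(
                f"duplicate synthetase ids: {list(cols[cols.duplicated()])}"
            )
        object.__setattr__(self, "table", self.table.astype(float))

    @property
    def trna_ids(self) -> tuple[str, ...]:
        return tuple(str(i) for i in self.table.index)

    @property
    def synthetase_ids(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.table.columns)

    def value(self, trna: str, synthetase: str) -> float:
        """Activity of ``synthetase`` with ``trna``; NaN when unmeasured."""
        return float(self.table.at[trna, synthetase])

    def is_measured(self, trna: str, synthetase: str) -> bool:
        return not math.isnan(self.value(trna, synthetase))

    @property
    def n_missing(self) -> int:
        return int(self.table.isna().sum().sum())

    def subset(
        self, trnas: Sequence[str] | None = None, synthetases: Sequence[str] | None = None
    ) -> "ActivityMatrix":
        t = self.table
        if trnas is not None:
            t = t.loc[list(trnas)]
        if synthetases is not None:
            t = t[list(synthetases)]
        return ActivityMatrix(t.copy())

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.4g", na_rep="NA")


def activity_matrix(
    values: Mapping[str, Mapping[str, float]] | np.ndarray,
    trna_ids: Sequence[str] | None = None,
    synthetase_ids: Sequence[str] | None = None,
) -> ActivityMatrix:
    """Convenience constructor from a nested mapping or a 2-D array.

    Nested mappings are keyed ``values[trna][synthetase]``; arrays are
    ``(n_trnas, n_synthetases)`` and require both id sequences.
    """
    if isinstance(values, np.ndarray):
        df = pd.DataFrame(values, index=list(trna_ids), columns=list(synthetase_ids))
    else:
        df = pd.DataFrame.from_dict(values, orient="index")
        if trna_ids is not None:
            df = df.reindex(index=list(trna_ids))
        if synthetase_ids is not None:
            df = df.reindex(columns=list(synthetase_ids))
    return ActivityMatrix(df)


def _sniff_delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_activity_table(
    path: str | Path, delimiter: str | None = None
) -> ActivityMatrix:
    """Load a delimited activity table.

    The header row carries synthetase ids and the first column tRNA ids;
    cells are numeric or empty/``NA`` (missing).  Ragged rows and
    non-numeric cells raise :class:`TableParseError` with the offending
    row/column named.
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter=delim)]
    rows = [r for r in rows if any(c.strip() for c in r)]
    if len(rows) < 2:
        raise EmptyInputError(f"activity table {path} has no data rows")
    header = [c.strip() for c in rows[0]]
    synth_ids = header[1:]
    if len(set(synth_ids)) != len(synth_ids):
        raise DuplicateIdError("duplicate synthetase ids in header")
    width = len(header)
    trna_ids: list[str] = []
    data: list[list[float]] = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise TableParseError(
                f"{path}: row {r} has {len(row)} fields, expected {width}"
            )
        trna = row[0].strip()
        if trna in trna_ids:
            raise DuplicateIdError(f"duplicate tRNA id {trna!r}")
        trna_ids.append(trna)
        parsed: list[float] = []
        for c, cell in enumerate(row[1:], start=2):
            cell = cell.strip()
            if cell.lower() in _MISSING_TOKENS:
                parsed.append(math.nan)
                continue
            try:
                parsed.append(float(cell))
            except ValueError:
                raise TableParseError(
                    f"{path}: non-numeric cell {cell!r} at row {r} "
                    f"(tRNA {trna!r}), column {c} "
                    f"(synthetase {synth_ids[c - 2]!r})"
                )
        data.append(parsed)
    return ActivityMatrix(
        pd.DataFrame(data, index=trna_ids, columns=synth_ids)
    )


def normalize_activity(
    raw: pd.DataFrame,
    wt_control: float,
    background: Mapping[str, float] | pd.Series | float | None = None,
) -> ActivityMatrix:
    """Convert raw reporter readings (e.g. GFP/OD600) to percent of control.

    ``x = 100 * (raw - background) / wt_control``, with the per-tRNA
    background (reporter plus tRNA, no synthetase) defaulting to zero and
    negative results clamped to zero.  Missing raw readings stay missing.
    """
    if not (wt_control > 0):
        raise InvalidControlError(f"wt_control must be > 0, got {wt_control}")
    raw = raw.astype(float)
    if background is None:
        shifted = raw
    elif isinstance(background, (int, float)):
        shifted = raw - float(background)
    else:
        bg = pd.Series(background, dtype=float).reindex(raw.index).fillna(0.0)
        shifted = raw.sub(bg, axis=0)
    x = (100.0 * shifted / wt_control).clip(lower=0.0)
    return ActivityMatrix(x)


@dataclass(frozen=True)
class FilterResult:
    matrix: ActivityMatrix
    kept_trnas: tuple[str, ...]
    kept_synthetases: tuple[str, ...]
    dropped_trnas: tuple[str, ...]
    dropped_synthetases: tuple[str, ...]


def filter_active_entities(m: ActivityMatrix, min_best: float) -> FilterResult:
    """Keep entities whose best measured partner activity reaches ``min_best``.

    Mirrors the activity screen in which tRNAs/synthetases qualify by
    producing at least a stated fraction of the wtGFP control with at least
    one partner.  The comparison is non-strict ("at least").  Idempotent.
    """
    t = m.table
    best_t = t.max(axis=1, skipna=True)
    best_s = t.max(axis=0, skipna=True)
    keep_t = [i for i in t.index if best_t[i] >= min_best]
    keep_s = [j for j in t.columns if best_s[j] >= min_best]
    return FilterResult(
        matrix=ActivityMatrix(t.loc[keep_t, keep_s].copy()),
        kept_trnas=tuple(keep_t),
        kept_synthetases=tuple(keep_s),
        dropped_trnas=tuple(i for i in t.index if i not in keep_t),
        dropped_synthetases=tuple(j for j in t.columns if j not in keep_s),
    )


@dataclass(frozen=True)
class EntityMetadata:
    """Group/class annotation for one synthetase or tRNA."""

    id: str
    kind: Literal["synthetase", "trna"]
    group: str
    class_label: str
    organism: str = ""

    def __post_init__(self):
        object.__setattr__(self, "group", _LABEL_ALIASES.get(self.group, self.group))
        object.__setattr__(
            self, "class_label", _LABEL_ALIASES.get(self.class_label, self.class_label)
        )
        if self.kind not in ("synthetase", "trna"):
            raise MetadataError(f"{self.id}: unknown kind {self.kind!r}")
        if self.group not in GROUPS:
            raise MetadataError(
                f"{self.id}: group {self.group!r} not in {sorted(GROUPS)}"
            )
        if self.class_label not in CLASS_LABELS:
            raise MetadataError(
                f"{self.id}: class {self.class_label!r} not in {sorted(CLASS_LABELS)}"
            )


def read_metadata_table(path: str | Path) -> dict[str, EntityMetadata]:
    """TSV with columns id, kind, group, class_label[, organism]."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "kind", "group", "class_label"}
    if not required <= set(df.columns):
        raise MetadataError(
            f"metadata table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out: dict[str, EntityMetadata] = {}
    for _, row in df.iterrows():
        meta = EntityMetadata(
            id=row["id"],
            kind=row["kind"],
            group=row["group"],
            class_label=row["class_label"],
            organism=row.get("organism", ""),
        )
        if meta.id in out:
            raise DuplicateIdError(f"duplicate metadata id {meta.id!r}")
        out[meta.id] = meta
    return out


def validation_report(m: ActivityMatrix) -> dict:
    """Machine-readable summary of an activity matrix for pipeline manifests."""
    t = m.table
    return {
        "n_trnas": len(m.trna_ids),
        "n_synthetases": len(m.synthetase_ids),
        "n_missing": m.n_missing,
        "min": None if t.isna().all().all() else float(np.nanmin(t.to_numpy())),
        "max": None if t.isna().all().all() else float(np.nanmax(t.to_numpy())),
        "negative_values": int((t < 0).sum().sum()),
    }


def write_validation_report(m: ActivityMatrix, path: str | Path) -> None:
    Path(path).write_text(json.dumps(validation_report(m), indent=1))
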