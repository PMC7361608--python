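"""Reading, validating, scoring and filtering longitudinal Likert survey tables.

A survey wave is a participants x items table of integer Likert responses.
This module provides the bookkeeping every longitudinal attitude study needs
before any network can be built: schema-checked CSV ingestion, attention-check
exclusions, matching participants across waves into a balanced panel,
scale scoring with Cronbach's alpha, and plain descriptives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LikertScale",
    "ItemSpec",
    "ResponseMatrix",
    "ExclusionReport",
    "ScaleScore",
    "DescriptiveStats",
    "read_wave",
    "write_wave",
    "apply_attention_exclusions",
    "match_waves",
    "score_scale",
    "cronbach_alpha",
    "describe",
]

#: item blocks recognised by the pipeline
BLOCKS = ("attitude", "compliance", "clarity", "attention", "demographic")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A cell value violates its item's Likert scale."""


@dataclass(frozen=True)
class LikertScale:
    """Closed integer response scale, e.g. 1-4 ("not at all" .. "a lot")."""

    min: int
    max: int

    def __post_init__(self) -> None:
        if self.max <= self.min:
            raise ValueError(f"scale max ({self.max}) must exceed min ({self.min})")

    @property
    def midpoint(self) -> Fraction:
        return Fraction(self.min + self.max, 2)

    @property
    def has_attainable_midpoint(self) -> bool:
        """True iff the midpoint is itself a response value (odd-length scales)."""
        return (self.max - self.min) % 2 == 0

    def contains(self, value: float) -> bool:
        return self.min <= value <= self.max


@dataclass(frozen=True)
class ItemSpec:
    """One survey item: identifier, human label, response scale and block tag."""

    item_id: str
    scale: LikertScale
    block: str = "attitude"
    label: str = ""

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}; expected one of {BLOCKS}")


@dataclass
class ResponseMatrix:
    """Participants x items Likert responses for a single wave.

    Values are stored as a float DataFrame (NaN = missing) indexed by
    participant id, one column per item_id, in item order.
    """

    wave_id: str
    items: list[ItemSpec]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        item_ids = [it.item_id for it in self.items]
        if len(set(item_ids)) != len(item_ids):
            raise ValueError("duplicate item_id in item specs")
        if list(self.data.columns) != item_ids:
            raise ValueError("data columns do not match item specs")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate participant ids: {dup}")
        self.data = self.data.astype(float)
        self._validate_ranges()

    def _validate_ranges(self) -> None:
        for spec in self.items:
            col = self.data[spec.item_id]
            bad = col.notna() & ((col < spec.scale.min) | (col > spec.scale.max))
            if bad.any():
                pid = self.data.index[bad][0]
                raise ValidationError(
                    f"wave {self.wave_id!r}: value {col[bad].iloc[0]:g} for item "
                    f"{spec.item_id!r} (participant {pid!r}) outside scale "
                    f"[{spec.scale.min}, {spec.scale.max}]"
                )

    @property
    def participant_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def n_participants(self) -> int:
        return len(self.data)

    def item(self, item_id: str) -> ItemSpec:
        for spec in self.items:
            if spec.item_id == item_id:
                return spec
        raise KeyError(item_id)

    def select_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        specs = [self.item(i) for i in item_ids]
        return ResponseMatrix(self.wave_id, specs, self.data[list(item_ids)].copy())

    def select_participants(self, ids: Sequence[str]) -> "ResponseMatrix":
        return ResponseMatrix(self.wave_id, list(self.items), self.data.loc[list(ids)].copy())


@dataclass
class ExclusionReport:
    """Bookkeeping for participants removed at one wave."""

    wave_id: str
    failed_attention: list[str] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)
    n_before: int = 0
    n_after: int = 0

    def __post_init__(self) -> None:
        if set(self.failed_attention) & set(self.unmatched):
            raise ValueError("failed_attention and unmatched must be disjoint")
        expected = self.n_before - len(self.failed_attention) - len(self.unmatched)
        if self.n_after != expected:
            raise ValueError(
                f"inconsistent report: n_after={self.n_after}, expected {expected}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [("failed_attention", pid) for pid in self.failed_attention]
        rows += [("unmatched", pid) for pid in self.unmatched]
        return pd.DataFrame(rows, columns=["reason", "participant_id"]).assign(
            wave_id=self.wave_id
        )


@dataclass
class ScaleScore:
    """Per-participant mean of a multi-item scale plus Cronbach's alpha."""

    scale_name: str
    per_participant_mean: "pd.Series[float]"
    alpha: float
    n_items: int
    n_complete_cases: int


@dataclass(frozen=True)
class DescriptiveStats:
    mean: float
    sd: float
    n: int


def read_wave(path: str | Path, item_specs: Sequence[ItemSpec], wave_id: str,
              id_column: str = "participant_id") -> ResponseMatrix:
    """Read one wave from a UTF-8 CSV with a header row.

    Blank cells and the sentinels ``NA``/``nan`` become missing values.
    Raises :class:`SchemaError` for absent columns and
    :class:`ValidationError` for out-of-range values.
    """
    df = pd.read_csv(path, dtype={id_column: str}, na_values=["NA", "nan"])
    if id_column not in df.columns:
        raise SchemaError(f"missing participant-id column {id_column!r} in {path}")
    missing = [s.item_id for s in item_specs if s.item_id not in df.columns]
    if missing:
        raise SchemaError(f"missing item column(s) {missing} in {path}")
    df = df.set_index(id_column)
    return ResponseMatrix(wave_id, list(item_specs), df[[s.item_id for s in item_specs]])


def write_wave(matrix: ResponseMatrix, path: str | Path,
               id_column: str = "participant_id") -> None:
    """Write a wave back to CSV; integer-valued cells are written without decimals."""
    # integral floats become nullable Int64 so cells round-trip as "3", not "3.0"
    out = matrix.data.convert_dtypes()
    out.index.name = id_column
    out.to_csv(path)


def apply_attention_exclusions(matrix: ResponseMatrix, attention_item: str,
                               expected: int) -> tuple[ResponseMatrix, ExclusionReport]:
    """Drop participants whose attention-check response differs from ``expected``.

    The attention column itself is removed from the returned matrix.
    """
    if attention_item not in matrix.item_ids:
        raise KeyError(f"attention item {attention_item!r} not in wave {matrix.wave_id!r}")
    col = matrix.data[attention_item]
    keep = col == expected  # NaN compares False: a missing check is a failure
    failed = [str(p) for p in matrix.data.index[~keep]]
    if not keep.any():
        logger.warning("wave %s: every participant failed the attention check", matrix.wave_id)
    remaining = [s for s in matrix.items if s.item_id != attention_item]
    out = ResponseMatrix(
        matrix.wave_id, remaining,
        matrix.data.loc[keep, [s.item_id for s in remaining]].copy(),
    )
    report = ExclusionReport(
        wave_id=matrix.wave_id, failed_attention=failed,
        n_before=matrix.n_participants, n_after=out.n_participants,
    )
    return out, report


def match_waves(waves: Sequence[ResponseMatrix]) -> tuple[list[ResponseMatrix], list[ExclusionReport]]:
    """Reduce each wave to the participants present at every wave.

    Returned matrices share a common row order (order of appearance at the
    first wave). Raises ``ValueError`` when no participant appears in all
    waves, since then no longitudinal panel exists.
    """
    if len(waves) < 2:
        raise ValueError("need at least two waves to match")
    common: set[str] = set(waves[0].participant_ids)
    for w in waves[1:]:
        common &= set(w.participant_ids)
    if not common:
        raise ValueError("no participant appears in every wave; empty panel")
    order = [p for p in waves[0].participant_ids if p in common]
    matched, reports = [], []
    for w in waves:
        dropped = [p for p in w.participant_ids if p not in common]
        matched.append(w.select_participants(order))
        reports.append(ExclusionReport(
            wave_id=w.wave_id, unmatched=dropped,
            n_before=w.n_participants, n_after=len(order),
        ))
    return matched, reports


def cronbach_alpha(scores: pd.DataFrame) -> tuple[float, int]:
    """Cronbach's alpha over complete cases of an items-as-columns frame.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total score),
    with sample (n-1) variances. Returns (alpha, n_complete_cases).
    """
    if scores.shape[1] < 2:
        raise ValueError("alpha requires at least 2 items")
    complete = scores.dropna()
    if len(complete) < 2:
        raise ValueError("alpha requires at least 2 complete cases")
    k = scores.shape[1]
    item_vars = complete.var(axis=0, ddof=1)
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var)), len(complete)


def score_scale(matrix: ResponseMatrix, item_ids: Sequence[str], scale_name: str) -> ScaleScore:
    """Score a multi-item scale: available-item mean per participant plus alpha.

    All items must share one Likert scale. The mean uses whatever items a
    participant answered; alpha uses complete cases only.
    """
    specs = [matrix.item(i) for i in item_ids]
    scales = {(s.scale.min, s.scale.max) for s in specs}
    if len(scales) != 1:
        raise ValueError(f"items {list(item_ids)} do not share a single Likert scale")
    sub = matrix.data[list(item_ids)]
    alpha, n_complete = cronbach_alpha(sub)
    return ScaleScore(
        scale_name=scale_name,
        per_participant_mean=sub.mean(axis=1, skipna=True),
        alpha=alpha,
        n_items=len(item_ids),
        n_complete_cases=n_complete,
    )


def describe(values: Iterable[float]) -> DescriptiveStats:
    """Mean and sample (n-1) standard deviation, as reported in M(SD) form."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("describe requires at least one value")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return DescriptiveStats(mean=float(np.mean(arr)), sd=sd, n=int(arr.size))


def save_item_specs(items: Sequence[ItemSpec], path: str | Path) -> None:
    """Persist item specifications as YAML (id, label, block, scale range)."""
    import yaml

    payload = [
        {"item_id": s.item_id, "label": s.label, "block": s.block,
         "min": s.scale.min, "max": s.scale.max}
        for s in items
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def load_item_specs(path: str | Path) -> list[ItemSpec]:
    """Load item specifications from YAML written by :func:`save_item_specs`."""
    import yaml

    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return [
        ItemSpec(d["item_id"], LikertScale(int(d["min"]), int(d["max"])),
                 d.get("block", "attitude"), d.get("label", ""))
        for d in payload
    ]


def scores_to_csv(scores: Mapping[str, ScaleScore], path: str | Path) -> None:
    """Write scored scales as a tidy CSV (participant_id, scale, mean)."""
    frames = []
    for name, sc in scores.items():
        frames.append(pd.DataFrame({
            "participant_id": sc.per_participant_mean.index,
            "scale": name,
            "mean": sc.per_participant_mean.values,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
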