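"""Benchmark statistics for density-functional reduction energies.

Given per-complex predictions from a set of density functionals and
reference values (CCSD(T)/CBS composites), this module computes signed
errors, the summary statistics used throughout the field — mean signed
error (MSE), mean unsigned error (MUE) and maximum absolute error (MaxE,
with the complex where it occurs) — classifies functionals into accuracy
groups based on a volt-scale threshold, and ranks them.

Accuracy groups: group I has MUE below 0.1 V per electron transferred
(2.3061 kcal/mol for a one-electron couple), group II between 0.1 and
0.2 V, group III above. Thresholds are applied unrounded by default; a
strict display mode uses the conventionally printed 2.31/4.62 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import COMPLEX_GROUPS, complex_sort_key
from .units import EV_TO_KCAL, Quantity, Unit, UnitError


@dataclass(frozen=True)
class ErrorRecord:
    """Signed deviation of one functional on one complex (DFT - reference)."""

    functional: str
    complex_id: str
    signed_error: float  # kcal/mol


@dataclass(frozen=True)
class GroupThresholds:
    """MUE boundaries (kcal/mol) of accuracy groups I/II/III."""

    group1_max: float
    group2_max: float
    electrons: int = 1

    def __post_init__(self) -> None:
        if not self.group1_max < self.group2_max:
            raise ValueError("group1_max must be below group2_max")

    @classmethod
    def from_volts(cls, group1_volts: float = 0.1, group2_volts: float = 0.2,
                   electrons: int = 1, rounded: bool = False) -> "GroupThresholds":
        """Thresholds from per-electron potentials (0.1 / 0.2 V defaults).

        ``rounded=True`` reproduces the conventional 2-dp printed values
        (2.31 / 4.62 kcal/mol) instead of the unrounded conversions.
        """
        t1 = volts_to_kcal(Quantity(group1_volts, Unit.VOLT), electrons).value
        t2 = volts_to_kcal(Quantity(group2_volts, Unit.VOLT), electrons).value
        if rounded:
            t1, t2 = round(t1, 2), round(t2, 2)
        return cls(group1_max=t1, group2_max=t2, electrons=electrons)


@dataclass(frozen=True)
class BenchmarkSummary:
    """Per-functional benchmark statistics."""

    functional: str
    mse: float
    mue: float
    maxe: float          # magnitude of the largest error
    maxe_complex: str
    group: str           # "I" | "II" | "III"
    family: str = ""     # LDA / GGA / h-GGA / hm-GGA / ...
    hf_exchange_pct: str = ""  # verbatim text; some functionals print "a/b"
    rank: int = 0


def volts_to_kcal(potential: Quantity, electrons: int = 1) -> Quantity:
    """Energy (kcal/mol) of transferring ``electrons`` across ``potential``."""
    if potential.unit is not Unit.VOLT:
        raise UnitError(f"expected a potential in volt, got {potential.unit}")
    if electrons < 1:
        raise ValueError(f"electron count must be >= 1, got {electrons}")
    return Quantity(potential.value * electrons * EV_TO_KCAL, Unit.KCAL_PER_MOL)


#: Unrounded one-electron 0.1 / 0.2 V boundaries (2.3061 / 4.6121 kcal/mol).
DEFAULT_THRESHOLDS = GroupThresholds.from_volts()


def signed_errors(predictions: Mapping[str, Mapping[str, float]],
                  references: Mapping[str, float]) -> list[ErrorRecord]:
    """Per-(functional, complex) deviations, prediction minus reference.

    ``predictions`` maps functional -> {complex_id -> delta_e_kcal};
    ``references`` maps complex_id -> delta_e_kcal. Every predicted complex
    must have a reference.
    """
    out: list[ErrorRecord] = []
    for functional in predictions:
        preds = predictions[functional]
        for complex_id in sorted(preds, key=complex_sort_key):
            if complex_id not in references:
                raise KeyError(
                    f"no reference value for complex {complex_id!r} "
                    f"(functional {functional!r})"
                )
            out.append(ErrorRecord(
                functional=functional,
                complex_id=complex_id,
                signed_error=preds[complex_id] - references[complex_id],
            ))
    return out


def _values(errors: Sequence[ErrorRecord] | Sequence[float]) -> list[float]:
    if not errors:
        raise ValueError("at least one error record is required")
    if isinstance(errors[0], ErrorRecord):
        return [e.signed_error for e in errors]  # type: ignore[union-attr]
    return [float(e) for e in errors]  # type: ignore[arg-type]


def mse(errors: Sequence[ErrorRecord] | Sequence[float]) -> float:
    """Mean signed error."""
    vals = _values(errors)
    return sum(vals) / len(vals)


def mue(errors: Sequence[ErrorRecord] | Sequence[float]) -> float:
    """Mean unsigned (absolute) error."""
    vals = _values(errors)
    return sum(abs(v) for v in vals) / len(vals)


def maxe(errors: Sequence[ErrorRecord]) -> tuple[float, str]:
    """Largest absolute error and the complex where it occurs.

    Ties break toward the earlier complex in canonical order.
    """
    vals = _values(errors)
    if not isinstance(errors[0], ErrorRecord):
        raise TypeError("maxe needs ErrorRecords to report the argmax complex")
    # tie-break: max |error|, then canonical complex order
    best_abs = max(abs(v) for v in vals)
    candidates = [e for e in errors if abs(e.signed_error) == best_abs]
    best = min(candidates, key=lambda e: complex_sort_key(e.complex_id))
    return best_abs, best.complex_id


def classify_group(mue_value: float,
                   thresholds: GroupThresholds = DEFAULT_THRESHOLDS) -> str:
    """Accuracy group for an MUE: I / II / III (boundaries inclusive downward)."""
    if mue_value < 0:
        raise ValueError(f"MUE cannot be negative, got {mue_value}")
    if mue_value <= thresholds.group1_max:
        return "I"
    if mue_value <= thresholds.group2_max:
        return "II"
    return "III"


def summarize_functional(functional: str, errors: Sequence[ErrorRecord],
                         thresholds: GroupThresholds = DEFAULT_THRESHOLDS,
                         family: str = "", hf_exchange_pct: str = "",
                         ) -> BenchmarkSummary:
    own = [e for e in errors if e.functional == functional]
    if not own:
        raise ValueError(f"no error records for functional {functional!r}")
    m, mx = maxe(own)
    u = mue(own)
    return BenchmarkSummary(
        functional=functional,
        mse=mse(own),
        mue=u,
        maxe=m,
        maxe_complex=mx,
        group=classify_group(u, thresholds),
        family=family,
        hf_exchange_pct=hf_exchange_pct,
    )


def summarize(errors: Sequence[ErrorRecord],
              thresholds: GroupThresholds = DEFAULT_THRESHOLDS,
              metadata: Mapping[str, Mapping[str, str]] | None = None,
              ) -> list[BenchmarkSummary]:
    """One :class:`BenchmarkSummary` per functional present in ``errors``.

    ``metadata`` optionally maps functional -> {"family": ..., "hf_exchange_pct": ...}.
    """
    metadata = metadata or {}
    functionals = sorted({e.functional for e in errors})
    out = []
    for f in functionals:
        meta = metadata.get(f, {})
        out.append(summarize_functional(
            f, errors, thresholds,
            family=meta.get("family", ""),
            hf_exchange_pct=meta.get("hf_exchange_pct", ""),
        ))
    return rank_functionals(out)


def rank_functionals(summaries: Iterable[BenchmarkSummary]) -> list[BenchmarkSummary]:
    """Ascending by MUE; ties by smaller MaxE, then functional name.

    Returns new summaries with the ``rank`` field assigned 1..n.
    """
    ordered = sorted(summaries, key=lambda s: (s.mue, s.maxe, s.functional))
    if not ordered:
        raise ValueError("no summaries to rank")
    return [replace(s, rank=i + 1) for i, s in enumerate(ordered)]


def report_table(summaries: Sequence[BenchmarkSummary],
                 errors: Sequence[ErrorRecord] | None = None,
                 grouping: str = "overall", top: int | None = None,
                 ) -> pd.DataFrame:
    """Ranking table for one complex grouping ("A", "B", "C" or "overall").

    For a named group the per-complex signed errors appear as columns (the
    four complexes of that group); the overall table reports the MaxE
    complex instead. Statistics are rounded to 2 dp (round-half-even).
    """
    if grouping not in {"overall", *COMPLEX_GROUPS}:
        raise ValueError(f"unknown grouping {grouping!r}; "
                         f"expected one of {['overall', *COMPLEX_GROUPS]}")
    if not summaries:
        raise ValueError(f"no summaries supplied for grouping {grouping!r}")
    ordered = rank_functionals(summaries)
    if top is not None:
        ordered = ordered[:top]
    rows = []
    for s in ordered:
        row: dict[str, object] = {
            "rank": s.rank,
            "functional": s.functional,
            "type": s.family,
            "hf_exchange_pct": s.hf_exchange_pct,
            "MUE": round(s.mue, 2),
            "MaxE": round(s.maxe, 2),
            "group": s.group,
        }
        if grouping == "overall":
            row["MaxE_complex"] = s.maxe_complex
        else:
            if errors is None:
                raise ValueError("per-group tables need the error records")
            own = {e.complex_id: e.signed_error for e in errors
                   if e.functional == s.functional}
            for cid in COMPLEX_GROUPS[grouping]:
                row[cid] = round(own[cid], 2) if cid in own else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def format_report(table: pd.DataFrame) -> str:
    """Deterministic fixed-width text rendering of a ranking table."""
    return table.to_string(index=False)
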