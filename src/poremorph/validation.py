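"""Method-comparison arithmetic for validating automated pore analysis.

Two kinds of comparison are supported:

* *Matched-pore* comparison: the same pore is measured by a reference
  method (manual freehand tracing) and by the automated pipeline;
  per-pore agreement is the unsigned percent deviation
  ``|reference − test| / |reference| × 100``.

* *Group* comparison: several analysts each measure the pores of the
  same image with both methods.  Each analyst contributes a mean and a
  sample standard deviation per parameter; the group is then described
  by the mean of those averages, the standard deviation of the
  averages (between-analyst variability), and the mean of the standard
  deviations (within-analyst spread).  Methods are compared cell by
  cell with the signed percent difference
  ``(test − reference)/reference × 100``.

Sample (n−1) standard deviations are used throughout, matching
spreadsheet STDEV conventions.  Display rounding is half-even to one
decimal; full precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, PoremorphError

__all__ = [
    "MethodGroupSummary",
    "ComparisonTable",
    "percent_deviation",
    "signed_percent_difference",
    "summarize_group",
    "compare_methods",
    "round_display",
]


class UndefinedDeviationError(PoremorphError):
    """Percent deviation/difference against a zero reference."""


def percent_deviation(reference_value: float, test_value: float) -> float:
    """Unsigned percent deviation of ``test_value`` from ``reference_value``.

    ``|reference − test| / |reference| × 100``; undefined for a zero
    reference.
    """
    if reference_value == 0:
        raise UndefinedDeviationError("percent deviation is undefined for a zero reference")
    return abs(reference_value - test_value) / abs(reference_value) * 100.0


def signed_percent_difference(reference_value: float, test_value: float) -> float:
    """Signed percent difference ``(test − reference)/reference × 100``."""
    if reference_value == 0:
        raise UndefinedDeviationError("percent difference is undefined for a zero reference")
    return (test_value - reference_value) / reference_value * 100.0


def round_display(value: float, decimals: int = 1) -> float:
    """Half-even rounding for display; raw values stay full-precision."""
    return float(np.round(value, decimals))


@dataclass(frozen=True)
class MethodGroupSummary:
    """Per-analyst means/stds for one parameter, plus group aggregates.

    ``std_of_averages`` is None (flagged undefined) with a single
    analyst; an analyst with a single measurement contributes a std of
    0 and sets ``degenerate_users``.
    """

    per_user_means: tuple[float, ...]
    per_user_stds: tuple[float, ...]
    mean_of_averages: float
    std_of_averages: float | None
    mean_of_stds: float
    degenerate_users: bool = False


def summarize_group(per_user_measurements: list[list[float]]) -> MethodGroupSummary:
    """Aggregate one parameter's measurements across analysts.

    Each inner list holds one analyst's raw per-pore measurements.
    """
    if not per_user_measurements:
        raise ContractError("need at least one analyst")
    if any(len(u) == 0 for u in per_user_measurements):
        raise ContractError("every analyst needs at least one measurement")
    means = []
    stds = []
    degenerate = False
    for user in per_user_measurements:
        arr = np.asarray(user, dtype=float)
        means.append(float(arr.mean()))
        if len(arr) < 2:
            stds.append(0.0)
            degenerate = True
        else:
            stds.append(float(arr.std(ddof=1)))
    means_a = np.array(means)
    return MethodGroupSummary(
        per_user_means=tuple(means),
        per_user_stds=tuple(stds),
        mean_of_averages=float(means_a.mean()),
        std_of_averages=float(means_a.std(ddof=1)) if len(means) >= 2 else None,
        mean_of_stds=float(np.mean(stds)),
        degenerate_users=degenerate,
    )


_COLUMNS = ("mean_of_averages", "std_of_averages", "mean_of_stds")


@dataclass(frozen=True)
class ComparisonTable:
    """Three summary columns per method per parameter, plus signed % differences.

    ``rows`` maps parameter name -> {"A": MethodGroupSummary,
    "B": MethodGroupSummary, "pct_difference": {column: float | None}},
    with B compared relative to A.  A None cell means the difference is
    undefined (zero or missing reference).
    """

    rows: dict[str, dict[str, object]]

    def to_csv(self) -> str:
        """Serialize as CSV (comma-delimited, LF line endings)."""
        lines = ["parameter,method," + ",".join(_COLUMNS)]
        for param, row in self.rows.items():
            for key in ("A", "B"):
                s: MethodGroupSummary = row[key]
                cells = [
                    repr(s.mean_of_averages),
                    "" if s.std_of_averages is None else repr(s.std_of_averages),
                    repr(s.mean_of_stds),
                ]
                lines.append(f"{param},{key}," + ",".join(cells))
            pct = row["pct_difference"]
            cells = ["" if pct[c] is None else repr(pct[c]) for c in _COLUMNS]
            lines.append(f"{param},pct_difference," + ",".join(cells))
        return "\n".join(lines) + "\n"


def compare_methods(
    group_a: dict[str, MethodGroupSummary],
    group_b: dict[str, MethodGroupSummary],
) -> ComparisonTable:
    """Compare two methods parameter by parameter (B relative to A).

    ``group_a`` and ``group_b`` map parameter names (e.g. "area",
    "perimeter", "orientation", "time") to their group summaries; the
    parameter sets must match.
    """
    if set(group_a) != set(group_b):
        raise ContractError(
            f"parameter sets differ: {sorted(group_a)} vs {sorted(group_b)}"
        )
    rows: dict[str, dict[str, object]] = {}
    for param in group_a:
        a, b = group_a[param], group_b[param]
        pct: dict[str, float | None] = {}
        for col in _COLUMNS:
            ref = getattr(a, col)
            test = getattr(b, col)
            if ref in (None, 0) or test is None:
                pct[col] = None
            else:
                pct[col] = signed_percent_difference(ref, test)
        rows[param] = {"A": a, "B": b, "pct_difference": pct}
    return ComparisonTable(rows=rows)
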