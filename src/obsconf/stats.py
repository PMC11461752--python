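"""Validation statistics: does confidence track expert-verified accuracy?

The three variables of interest — confidence band, expert accuracy label,
and the platform quality grade — are all ordinal with heavy ties, so
association is measured with Kendall's tau-b, the tie-corrected variant:

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2))

with C/D the concordant/discordant pair counts over all n(n-1)/2 unordered
pairs, n0 = n(n-1)/2, and n1, n2 the tie corrections sum(t*(t-1)/2) over
tied groups in each variable. Two-sided p-values use the large-sample normal
approximation z = 3(C - D) / sqrt(n(n-1)(2n+5)/2). Strength labels follow
the conventional banding for correlation magnitude (|tau| < 0.10 negligible,
< 0.40 weak, < 0.70 moderate, < 0.90 strong, else very strong).

By default, unscorable observations participate in correlations as the
lowest confidence rank; set ``include_unscorable=False`` on the coding to
drop them pairwise instead.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .observations import AccuracyLabel, DataError, QualityGrade
from .rubric import Band, ScoredSet


class ZeroVarianceError(DataError):
    """Tau is undefined when one variable is constant."""


class Strength(str, enum.Enum):
    NEGLIGIBLE = "negligible"
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"
    VERY_STRONG = "very_strong"


_STRENGTH_EDGES = (
    (0.10, Strength.NEGLIGIBLE),
    (0.40, Strength.WEAK),
    (0.70, Strength.MODERATE),
    (0.90, Strength.STRONG),
)


def interpret_strength(tau: float) -> Strength:
    """Band |tau| into a conventional strength label (sign ignored)."""
    mag = abs(tau)
    if mag > 1:
        raise ValueError(f"|tau| must be <= 1, got {tau}")
    for edge, label in _STRENGTH_EDGES:
        if mag < edge:
            return label
    return Strength.VERY_STRONG


@dataclass(frozen=True)
class TauResult:
    tau: float
    n: int
    concordant: int
    discordant: int
    ties_x: int  # n1: sum t(t-1)/2 over tied groups in x
    ties_y: int  # n2: likewise for y
    p_value: float
    strength: Strength
    n_dropped: int = 0

    def to_csv_row(self) -> list:
        return [self.tau, self.n, self.concordant, self.discordant, self.p_value,
                self.strength.value]


def kendall_tau_b(x: Sequence, y: Sequence) -> TauResult:
    """Tie-corrected Kendall rank correlation between two ordinal sequences.

    Inputs must already be rank-comparable (integers or anything with a
    total order). Pair counting goes through the contingency table of the
    two codings, which is exact and fast for heavily tied ordinal data.
    """
    x_arr, y_arr = np.asarray(x), np.asarray(y)
    if x_arr.shape != y_arr.shape or x_arr.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = x_arr.size
    if n < 2:
        raise ValueError("need at least two observations")

    _, xi = np.unique(x_arr, return_inverse=True)
    _, yi = np.unique(y_arr, return_inverse=True)
    table = np.zeros((xi.max() + 1, yi.max() + 1), dtype=np.int64)
    np.add.at(table, (xi, yi), 1)

    n0 = n * (n - 1) // 2
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    n1 = int((row_tot * (row_tot - 1) // 2).sum())
    n2 = int((col_tot * (col_tot - 1) // 2).sum())
    if n1 == n0:
        raise ZeroVarianceError("tau undefined: first variable is constant")
    if n2 == n0:
        raise ZeroVarianceError("tau undefined: second variable is constant")

    # For each cell, pairs concordant with it sit strictly below-right;
    # discordant pairs sit strictly below-left. Each pair counted once.
    concordant = discordant = 0
    r, c = table.shape
    for i in range(r - 1):
        below = table[i + 1:, :]
        for j in range(c):
            nij = int(table[i, j])
            if nij == 0:
                continue
            concordant += nij * int(below[:, j + 1:].sum())
            discordant += nij * int(below[:, :j].sum())

    s = concordant - discordant
    tau = s / np.sqrt(float(n0 - n1) * float(n0 - n2))
    result = TauResult(
        tau=float(tau),
        n=n,
        concordant=concordant,
        discordant=discordant,
        ties_x=n1,
        ties_y=n2,
        p_value=_normal_p(s, n),
        strength=interpret_strength(float(tau)),
    )
    return result


def _normal_p(s: int, n: int) -> float:
    z = 3.0 * s / np.sqrt(n * (n - 1) * (2 * n + 5) / 2.0)
    return float(2.0 * norm.sf(abs(z)))


def tau_p_value(result: TauResult) -> float:
    """Two-sided p for S = C - D under the null, by normal approximation."""
    if result.n < 2:
        raise ValueError("need at least two observations")
    return _normal_p(result.concordant - result.discordant, result.n)


@dataclass(frozen=True)
class OrdinalCoding:
    """Rank orders for the three ordinal variables, worst to best."""

    confidence_order: tuple[str, ...] = ("unscorable", "low", "medium", "high")
    accuracy_order: tuple[str, ...] = ("incorrect", "uncertain", "correct")
    grade_order: tuple[str, ...] = ("casual", "needs_id", "research_grade")
    include_unscorable: bool = True

    def __post_init__(self) -> None:
        for order in (self.confidence_order, self.accuracy_order, self.grade_order):
            if len(set(order)) != len(order):
                raise ValueError(f"duplicate level in ordinal coding: {order}")

    def order_for(self, variable: str) -> tuple[str, ...]:
        try:
            return {
                "confidence": self.confidence_order,
                "accuracy": self.accuracy_order,
                "quality_grade": self.grade_order,
            }[variable]
        except KeyError:
            raise ValueError(
                f"unknown variable {variable!r}; expected confidence, accuracy "
                "or quality_grade"
            ) from None


def _variable_values(scored: ScoredSet, variable: str) -> list[str | None]:
    if variable == "confidence":
        return [res.band.value for _, res in scored]
    if variable == "accuracy":
        return [rec.accuracy_label.value if rec.accuracy_label else None for rec, _ in scored]
    if variable == "quality_grade":
        return [rec.quality_grade.value for rec, _ in scored]
    raise ValueError(f"unknown variable {variable!r}")


def correlate(
    scored: ScoredSet,
    var_x: str,
    var_y: str,
    coding: OrdinalCoding = OrdinalCoding(),
) -> TauResult:
    """Encode two record variables to ranks per the coding, then tau-b.

    Records excluded by the coding (unscorable confidence when
    ``include_unscorable`` is off, or a missing accuracy label) are dropped
    pairwise; the dropped count is reported on the result.
    """
    xs_raw = _variable_values(scored, var_x)
    ys_raw = _variable_values(scored, var_y)
    rank_x = {lvl: i for i, lvl in enumerate(coding.order_for(var_x))}
    rank_y = {lvl: i for i, lvl in enumerate(coding.order_for(var_y))}
    if not coding.include_unscorable:
        rank_x.pop(Band.UNSCORABLE.value, None)
        rank_y.pop(Band.UNSCORABLE.value, None)

    xs, ys, dropped = [], [], 0
    for xv, yv in zip(xs_raw, ys_raw):
        if xv is None or yv is None or xv not in rank_x or yv not in rank_y:
            dropped += 1
            continue
        xs.append(rank_x[xv])
        ys.append(rank_y[yv])
    if len(xs) < 2:
        raise DataError("fewer than two records remain after coding exclusions")
    return dataclasses.replace(kendall_tau_b(xs, ys), n_dropped=dropped)


@dataclass(frozen=True)
class ContingencyTable:
    row_variable: str
    col_variable: str
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # shape (rows, cols), non-negative ints

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> dict[str, int]:
        return dict(zip(self.row_labels, (int(v) for v in self.counts.sum(axis=1))))

    def col_totals(self) -> dict[str, int]:
        return dict(zip(self.col_labels, (int(v) for v in self.counts.sum(axis=0))))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow([f"{self.row_variable}\\{self.col_variable}", *self.col_labels])
            for label, row in zip(self.row_labels, self.counts):
                writer.writerow([label, *(int(v) for v in row)])


def crosstab(
    scored: ScoredSet,
    row: str,
    col: str,
    coding: OrdinalCoding = OrdinalCoding(),
) -> ContingencyTable:
    """Cross-tabulate two record variables with ordinal-ordered margins."""
    if len(scored) == 0:
        raise DataError("empty_input")
    row_order = coding.order_for(row)
    col_order = coding.order_for(col)
    counts = np.zeros((len(row_order), len(col_order)), dtype=np.int64)
    row_idx = {lvl: i for i, lvl in enumerate(row_order)}
    col_idx = {lvl: i for i, lvl in enumerate(col_order)}
    for rv, cv in zip(_variable_values(scored, row), _variable_values(scored, col)):
        if rv is None or cv is None:
            raise DataError(f"record missing a value for {row!r} or {col!r}")
        counts[row_idx[rv], col_idx[cv]] += 1
    return ContingencyTable(row, col, tuple(row_order), tuple(col_order), counts)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (so 23.65 -> 23.7, not banker's 23.6)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SummaryReport:
    """Counts and percentages by band, accuracy class and quality grade.

    Percentages are of the full set, rounded half-up to one decimal at
    formatting time only; ``retained_fraction`` is the percentage of
    observations at medium-or-high confidence — the recommended retention
    rule for downstream analyses.
    """

    total: int
    band_counts: Mapping[str, int]
    accuracy_counts: Mapping[str, int]
    grade_counts: Mapping[str, int]
    n_unlabeled: int = 0

    def _pct(self, count: int) -> float:
        return round_half_up(count / self.total * 100.0, 1)

    def band_percentages(self) -> dict[str, float]:
        return {k: self._pct(v) for k, v in self.band_counts.items()}

    def accuracy_percentages(self) -> dict[str, float]:
        return {k: self._pct(v) for k, v in self.accuracy_counts.items()}

    def grade_percentages(self) -> dict[str, float]:
        return {k: self._pct(v) for k, v in self.grade_counts.items()}

    @property
    def retained_fraction(self) -> float:
        kept = self.band_counts.get("medium", 0) + self.band_counts.get("high", 0)
        return round_half_up(kept / self.total * 100.0, 1)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["grouping", "level", "count", "percent"])
            for grouping, counts, pcts in (
                ("confidence", self.band_counts, self.band_percentages()),
                ("accuracy", self.accuracy_counts, self.accuracy_percentages()),
                ("quality_grade", self.grade_counts, self.grade_percentages()),
            ):
                for level, count in counts.items():
                    writer.writerow([grouping, level, count, pcts[level]])
            writer.writerow(["retention", "medium_or_high", "", self.retained_fraction])

    def format_text(self) -> str:
        lines = [f"observations: {self.total}"]
        for title, counts, pcts in (
            ("confidence band", self.band_counts, self.band_percentages()),
            ("accuracy", self.accuracy_counts, self.accuracy_percentages()),
            ("quality grade", self.grade_counts, self.grade_percentages()),
        ):
            lines.append(f"{title}:")
            for level, count in counts.items():
                lines.append(f"  {level:<16} {count:>6}  ({pcts[level]}%)")
        lines.append(f"retained at medium-or-high confidence: {self.retained_fraction}%")
        return "\n".join(lines)


def summarize_proportions(
    scored: ScoredSet, coding: OrdinalCoding = OrdinalCoding()
) -> SummaryReport:
    """Marginal counts and percentages of a scored set."""
    if len(scored) == 0:
        raise DataError("empty_input")
    band_counts = {lvl: 0 for lvl in coding.confidence_order}
    acc_counts = {lvl: 0 for lvl in coding.accuracy_order}
    grade_counts = {lvl: 0 for lvl in coding.grade_order}
    unlabeled = 0
    for rec, res in scored:
        band_counts[res.band.value] += 1
        grade_counts[rec.quality_grade.value] += 1
        if rec.accuracy_label is None:
            unlabeled += 1
        else:
            acc_counts[rec.accuracy_label.value] += 1
    return SummaryReport(
        total=len(scored),
        band_counts=band_counts,
        accuracy_counts=acc_counts,
        grade_counts=grade_counts,
        n_unlabeled=unlabeled,
    )
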