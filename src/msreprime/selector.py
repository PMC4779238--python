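"""Post-design primer selection: ranked quality-matrix filtering and the
MSRE-specific validation filter.

A quality matrix is a ranked list of comparison rules over summary-table
columns (ranks 1–10, 1 strictest). Semantics are cumulative by default: a
pair's quality level is the smallest rank r such that it satisfies *all*
rules of rank <= r, so level 1 is the strictest ladder step. An
``independent`` mode (each rank judged on its own rules only) is available
behind a flag. Without any rules, pairs are ranked purely by design
penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .annotator import AnnotatedPair
from .report import SUMMARY_COLUMNS, summary_row

__all__ = [
    "QualityRule",
    "RuleCheck",
    "PairSelection",
    "SelectionResult",
    "parse_quality_matrix",
    "assign_quality_levels",
    "msre_validation_filter",
]

_OPERATORS = (">", "<", ">=", "<=", "-")


class QualityMatrixError(ValueError):
    """Malformed quality-matrix file."""


@dataclass(frozen=True)
class QualityRule:
    """One ranked filter rule over a summary-output column."""

    column: str
    operator: str
    value: float | tuple[float, float]
    rank: int

    def __post_init__(self) -> None:
        if self.operator not in _OPERATORS:
            raise QualityMatrixError(
                f"bad operator {self.operator!r}; expected one of {_OPERATORS}"
            )
        if not 1 <= self.rank <= 10:
            raise QualityMatrixError(f"rank {self.rank} outside 1-10")
        if self.operator == "-":
            if not (isinstance(self.value, tuple) and len(self.value) == 2):
                raise QualityMatrixError("range rule '-' needs two values lo,hi")
            lo, hi = self.value
            if lo > hi:
                raise QualityMatrixError(f"range rule lo {lo} > hi {hi}")
        elif isinstance(self.value, tuple):
            raise QualityMatrixError(
                f"operator {self.operator!r} takes a single value"
            )

    def satisfied_by(self, row: Mapping) -> bool:
        cell = row[self.column]
        if cell == "":
            return False
        x = float(cell)
        if self.operator == ">":
            return x > self.value
        if self.operator == "<":
            return x < self.value
        if self.operator == ">=":
            return x >= self.value
        if self.operator == "<=":
            return x <= self.value
        lo, hi = self.value  # "-": inclusive on both ends
        return lo <= x <= hi


@dataclass
class RuleCheck:
    rule: QualityRule
    passed: bool


@dataclass
class PairSelection:
    """Audit record for one pair: its level (or None) and every rule check."""

    pair: AnnotatedPair
    quality_level: Optional[int]
    checks: list[RuleCheck] = field(default_factory=list)

    @property
    def violated(self) -> list[QualityRule]:
        return [c.rule for c in self.checks if not c.passed]


@dataclass
class SelectionResult:
    """Per-target selection outcome with a full audit trail."""

    records: list[PairSelection]
    selected: list[PairSelection]
    best_level: Optional[int]


def parse_quality_matrix(
    path: str | Path,
    output_schema: Sequence[str] = SUMMARY_COLUMNS,
) -> list[QualityRule]:
    """Parse a quality-matrix TSV: ``column  operator  value[,value]  rank``.

    '#' comment lines are allowed; rule order is preserved within ranks.
    Unknown columns, out-of-range ranks, and bad operators are hard errors.
    """
    rules: list[QualityRule] = []
    schema = set(output_schema)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise QualityMatrixError(
                    f"{path}:{lineno}: expected 4 tab-delimited fields"
                )
            column, operator, value_s, rank_s = (p.strip() for p in parts)
            if column not in schema:
                raise QualityMatrixError(
                    f"{path}:{lineno}: unknown column {column!r}; valid columns: "
                    + ", ".join(sorted(schema))
                )
            try:
                rank = int(rank_s)
            except ValueError as exc:
                raise QualityMatrixError(
                    f"{path}:{lineno}: non-integer rank {rank_s!r}"
                ) from exc
            try:
                if operator == "-":
                    lo_s, _, hi_s = value_s.partition(",")
                    value: float | tuple[float, float] = (float(lo_s), float(hi_s))
                else:
                    value = float(value_s)
            except ValueError as exc:
                raise QualityMatrixError(
                    f"{path}:{lineno}: unparseable value {value_s!r}"
                ) from exc
            rules.append(QualityRule(column, operator, value, rank))
    return rules


def assign_quality_levels(
    annotated_pairs: Sequence[AnnotatedPair],
    rules: Sequence[QualityRule],
    *,
    assembly: str = "hg19",
    cumulative: bool = True,
) -> SelectionResult:
    """Assign hierarchical quality levels and select the best pairs.

    With cumulative semantics a pair's level is the smallest rank r such
    that it satisfies all rules of rank <= r; with ``cumulative=False`` the
    smallest rank whose own rules it fully satisfies. Pairs failing every
    ladder step get no level. The pairs achieving the best (lowest) level
    present are selected, ordered by pair penalty; with an empty rule set
    all pairs are selected in pure penalty order.
    """
    records: list[PairSelection] = []
    if not rules:
        for apair in annotated_pairs:
            records.append(PairSelection(apair, None))
        ordered = sorted(records, key=lambda r: r.pair.pair.pair_penalty)
        return SelectionResult(records=records, selected=ordered, best_level=None)

    ranks = sorted({r.rank for r in rules})
    by_rank = {k: [r for r in rules if r.rank == k] for k in ranks}
    for apair in annotated_pairs:
        row = summary_row(apair, assembly=assembly)
        checks = [RuleCheck(rule, rule.satisfied_by(row)) for rule in rules]
        passed = {c.rule for c in checks if c.passed}
        level: Optional[int] = None
        for k in ranks:
            if cumulative:
                required = [r for r in rules if r.rank <= k]
            else:
                required = by_rank[k]
            if all(r in passed for r in required):
                level = k
                break
        records.append(PairSelection(apair, level, checks))

    levels = [r.quality_level for r in records if r.quality_level is not None]
    best = min(levels) if levels else None
    selected = sorted(
        (r for r in records if r.quality_level == best and best is not None),
        key=lambda r: r.pair.pair.pair_penalty,
    )
    return SelectionResult(records=records, selected=selected, best_level=best)


def msre_validation_filter(
    apair: AnnotatedPair,
    proximity_bp: int = 50,
    *,
    whole_target: bool = False,
) -> tuple[bool, list[str]]:
    """MSRE assay acceptability: the four wet-lab design criteria.

    Pass requires (1) at least one restriction cut site in the amplicon,
    (2) no SNP under either primer, (3) no common repeat within the assay
    (amplicon), and (4) the original target inside or within ±``proximity_bp``
    of the amplified sequence — judged by the target midpoint by default, or
    by whole-target containment with ``whole_target=True``.

    Returns (passed, violated-criterion names).
    """
    reasons: list[str] = []
    if apair.cut_summary.n_amplicon < 1:
        reasons.append("no_cutsite_in_amplicon")
    if apair.n_snps_fwd > 0 or apair.n_snps_rev > 0:
        reasons.append("snp_in_primer")
    if apair.n_repeats > 0:
        reasons.append("repeat_in_assay")
    a_start, a_end = apair.genomic.amplicon
    target = apair.design_range.target
    if whole_target:
        near = (target.start >= a_start - proximity_bp
                and target.end <= a_end + proximity_bp)
    else:
        mid = target.midpoint
        near = a_start - proximity_bp <= mid < a_end + proximity_bp
    if not near:
        reasons.append("target_outside_assay")
    return (not reasons, reasons)
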