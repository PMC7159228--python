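"""Rule-based positive/negative drug cohorts for hepatotoxicity modeling.

Positives are drugs with a strong disproportionality signal for the target
event class: at least ``min_reports`` primary-suspect reports (default 13),
RRR strictly greater than 1 and Fisher p strictly below 0.05.  Negatives are
drugs with no target-event report at all that have been on the market long
enough (default 10 years) for absence of reports to be informative rather
than an artifact of recency.  The two rules are mutually exclusive by
construction (>= 13 reports vs. exactly 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .faers_io import DrugEventMatrix
from .signal_stats import SignalRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RuleParams:
    min_reports: int = 13
    rrr_threshold: float = 1.0
    p_threshold: float = 0.05
    min_market_years: int = 10


@dataclass(frozen=True)
class CohortLabels:
    positives: frozenset[str]
    negatives: frozenset[str]
    rule_params: RuleParams

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"drugs labeled both positive and negative: {sorted(overlap)}")


def label_positives(
    signals: Iterable[SignalRecord],
    min_reports: int = 13,
    rrr_gt: float = 1.0,
    p_lt: float = 0.05,
) -> set[str]:
    """Drugs passing the positive rule.

    Inclusive on the report floor (>= min_reports), strict on RRR (> rrr_gt)
    and on the p-value (< p_lt).
    """
    return {
        s.drug
        for s in signals
        if s.report_count >= min_reports and s.rrr > rrr_gt and s.p_value < p_lt
    }


def label_negatives(
    matrix: DrugEventMatrix,
    event_class: str,
    market_years: Mapping[str, float],
    min_years: int = 10,
) -> set[str]:
    """Drugs passing the negative rule.

    A drug qualifies iff its target-event count is exactly zero and it has
    been marketed for at least ``min_years``.  Drugs absent from the
    market-years table cannot be assessed and are excluded with a log line.
    """
    negatives: set[str] = set()
    n_unknown = 0
    for drug in matrix.drugs:
        if matrix.get(drug, event_class) != 0:
            continue
        years = market_years.get(drug)
        if years is None:
            n_unknown += 1
            continue
        if years >= min_years:
            negatives.add(drug)
    if n_unknown:
        logger.info("%d report-free drug(s) lack market-years data; excluded", n_unknown)
    return negatives


def build_cohorts(
    signals: Iterable[SignalRecord],
    matrix: DrugEventMatrix,
    event_class: str,
    market_years: Mapping[str, float],
    params: RuleParams = RuleParams(),
) -> CohortLabels:
    """Apply both labeling rules and return the disjoint cohorts."""
    pos = label_positives(
        signals, params.min_reports, params.rrr_threshold, params.p_threshold
    )
    neg = label_negatives(matrix, event_class, market_years, params.min_market_years)
    return CohortLabels(frozenset(pos), frozenset(neg), params)
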