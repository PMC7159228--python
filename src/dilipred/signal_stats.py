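"""Disproportionality statistics for drug-event association.

For each drug against a target event class, a 2x2 contingency table is built
with margins from the consolidated report matrix::

                      event of interest   all other events   total
    drug of interest          a                  b            a+b
    all other drugs           c                  d            c+d
    total                    a+c                b+d            N

The Relative Reporting Ratio RRR = a*N / ((a+c)*(a+b)) compares the observed
pair count to its expectation under row-column independence (RRR = 1 when the
drug reports events at the background rate).  Significance is assessed by the
Fisher exact test with margins fixed; one-sided ("greater", enrichment) by
default since downstream labeling requires RRR > 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from scipy import stats

from .faers_io import DrugEventMatrix

logger = logging.getLogger(__name__)


class DegenerateTableError(ValueError):
    """A disproportionality statistic is undefined for this table."""


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # drug of interest, event of interest
    b: int  # drug of interest, other events
    c: int  # other drugs, event of interest
    d: int  # other drugs, other events

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} negative")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalRecord:
    drug: str
    event_class: str
    report_count: int
    rrr: float
    p_value: float
    q_value: float | None = None  # BH-adjusted, when requested


def contingency_table(matrix: DrugEventMatrix, drug: str, event_class: str) -> ContingencyTable:
    """Build the 2x2 table for one drug against one event class."""
    if drug not in matrix.drug_marginals:
        raise KeyError(f"drug {drug!r} not in matrix")
    a = matrix.get(drug, event_class)
    b = matrix.drug_marginals[drug] - a
    c = matrix.event_marginals.get(event_class, 0) - a
    d = matrix.grand_total - a - b - c
    return ContingencyTable(a, b, c, d)


def rrr(table: ContingencyTable) -> float:
    """Relative Reporting Ratio a*N / ((a+c)*(a+b)).

    Raises :class:`DegenerateTableError` when a margin is zero (0/0 is not
    silently reported as 0).
    """
    row = table.a + table.b
    col = table.a + table.c
    if row == 0 or col == 0:
        raise DegenerateTableError("RRR undefined: zero drug or event margin")
    return table.a * table.total / (col * row)


def fisher_pvalue(table: ContingencyTable, sidedness: str = "greater") -> float:
    """Fisher exact test p-value with margins fixed.

    ``sidedness`` is ``"greater"`` (enrichment of the pair, default) or
    ``"two_sided"``.
    """
    alt = {"greater": "greater", "two_sided": "two-sided"}.get(sidedness)
    if alt is None:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return float(
        stats.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative=alt).pvalue
    )


def detect_signals(
    matrix: DrugEventMatrix,
    event_class: str,
    sidedness: str = "greater",
    adjust: bool = False,
) -> list[SignalRecord]:
    """Score every drug with at least one target-event report.

    Emits one :class:`SignalRecord` per drug whose count for ``event_class``
    is >= 1; drugs with zero target-event reports are not emitted (they are
    candidates for negative labeling directly from the matrix).  With
    ``adjust=True`` a Benjamini-Hochberg q-value is attached (off by
    default; the labeling rule uses raw p-values).
    """
    if event_class not in matrix.event_marginals:
        raise KeyError(f"event class {event_class!r} not in matrix")
    records: list[SignalRecord] = []
    for drug in matrix.drugs:
        count = matrix.get(drug, event_class)
        if count == 0:
            continue
        table = contingency_table(matrix, drug, event_class)
        records.append(
            SignalRecord(
                drug=drug,
                event_class=event_class,
                report_count=count,
                rrr=rrr(table),
                p_value=fisher_pvalue(table, sidedness),
            )
        )
    if adjust:
        records = _attach_bh(records)
    return records


def _attach_bh(records: list[SignalRecord]) -> list[SignalRecord]:
    from dataclasses import replace

    import numpy as np

    p = np.array([r.p_value for r in records])
    order = np.argsort(p)
    m = len(p)
    q = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        i = m - rank_from_end  # 1-based rank of this p-value
        running = min(running, p[idx] * m / i)
        q[idx] = running
    return [replace(r, q_value=float(qi)) for r, qi in zip(records, q)]
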