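"""Synthetic report streams and descriptor tables with known ground truth.

Two generators make every pipeline stage testable without external data:

* :func:`generate_reports` emulates a spontaneous-reporting stream.  Each
  report draws a drug from a weight vector and one event from that drug's
  event distribution; planted drug-event pairs have their event probability
  multiplied by a relative-risk factor and renormalized, so their
  disproportionality is controlled and the exact expected cell counts are
  returned alongside the records.

* :func:`generate_descriptors` emulates a compounds x descriptors table with
  planted class structure: features are equicorrelated within blocks
  (mimicking redundant descriptor panels), a chosen subset of informative
  features is mean-shifted between the positive and negative class by a
  standardized effect size, and values can be masked missing at random.

Both are fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorMatrix
from .faers_io import ReportRecord, Role


@dataclass(frozen=True)
class ReportSimConfig:
    """Configuration of the report-stream generator.

    Defaults are sized for signal-detection power studies: 20k reports over
    50 drugs and 30 events with one strongly disproportionate planted pair
    (relative risk 8).
    """

    n_drugs: int = 50
    n_events: int = 30
    n_reports: int = 20_000
    drug_weights: tuple[float, ...] | None = None  # uniform when None
    event_weights: tuple[float, ...] | None = None  # background; uniform when None
    planted_pairs: tuple[tuple[int, int, float], ...] = ((0, 0, 8.0),)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_events, self.n_reports) < 1:
            raise ValueError("n_drugs, n_events and n_reports must be positive")
        for d, e, m in self.planted_pairs:
            if not (0 <= d < self.n_drugs and 0 <= e < self.n_events):
                raise ValueError(f"planted pair ({d},{e}) out of range")
            if m < 1:
                raise ValueError("relative-risk multipliers must be >= 1")
        for w, n in ((self.drug_weights, self.n_drugs), (self.event_weights, self.n_events)):
            if w is not None:
                if len(w) != n or min(w) <= 0:
                    raise ValueError("weights must be positive and match the count")


@dataclass(frozen=True)
class ReportTruth:
    """Bookkeeping for planted pairs: exact expectations and realized counts."""

    expected_counts: dict[tuple[str, str], float]
    realized_counts: dict[tuple[str, str], int]
    relative_risk: dict[tuple[str, str], float]


def drug_name(i: int) -> str:
    return f"D{i:03d}"


def event_name(j: int) -> str:
    return f"E{j:03d}"


def generate_reports(config: ReportSimConfig) -> tuple[list[ReportRecord], ReportTruth]:
    """Draw a report stream and the planted-pair truth record.

    Every record is a primary-suspect line with one event, so the resulting
    drug-event matrix has grand total ``n_reports``.
    """
    rng = np.random.default_rng(config.seed)
    dw = np.asarray(config.drug_weights or np.ones(config.n_drugs), dtype=float)
    dw = dw / dw.sum()
    base = np.asarray(config.event_weights or np.ones(config.n_events), dtype=float)
    base = base / base.sum()

    # per-drug event distributions with planted pairs up-weighted
    boosts: dict[int, dict[int, float]] = {}
    for d, e, m in config.planted_pairs:
        boosts.setdefault(d, {})[e] = m
    event_probs = np.tile(base, (config.n_drugs, 1))
    for d, em in boosts.items():
        for e, m in em.items():
            event_probs[d, e] *= m
        event_probs[d] /= event_probs[d].sum()

    per_drug = rng.multinomial(config.n_reports, dw)
    records: list[ReportRecord] = []
    realized: dict[tuple[str, str], int] = {}
    rid = 0
    for d in range(config.n_drugs):
        if per_drug[d] == 0:
            continue
        per_event = rng.multinomial(per_drug[d], event_probs[d])
        for e in np.nonzero(per_event)[0]:
            key = (drug_name(d), event_name(int(e)))
            realized[key] = realized.get(key, 0) + int(per_event[e])
            for _ in range(int(per_event[e])):
                records.append(
                    ReportRecord(
                        report_id=f"R{rid:07d}",
                        drug_name_raw=key[0],
                        role=Role.PRIMARY_SUSPECT,
                        event_pt=key[1],
                        date="2010Q1",
                    )
                )
                rid += 1

    expected = {}
    rr = {}
    for d, e, m in config.planted_pairs:
        key = (drug_name(d), event_name(e))
        expected[key] = config.n_reports * dw[d] * event_probs[d, e]
        rr[key] = m
    truth = ReportTruth(
        expected_counts=expected,
        realized_counts={k: realized.get(k, 0) for k in expected},
        relative_risk=rr,
    )
    return records, truth


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DescriptorSimConfig:
    """Configuration of the descriptor-table generator.

    Defaults mirror the study conditions of the modeling pipeline: 155
    positive and 164 negative compounds with an 818-descriptor panel whose
    features are redundant in correlated blocks, and 15 informative
    descriptors separated by a standardized mean shift of 1.
    """

    n_pos: int = 155
    n_neg: int = 164
    n_features: int = 818
    n_informative: int = 15
    effect_size: float = 1.0  # standardized mean shift per informative feature
    rho: float = 0.3  # within-block equicorrelation
    block_size: int = 10
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def feature_name(j: int) -> str:
    return f"F{j:04d}"


def informative_indices(config: DescriptorSimConfig) -> list[int]:
    """Spread informative features across distinct correlation blocks.

    Each informative descriptor then drags a block of correlated but
    class-uninformative companions, mimicking redundant real panels.  When
    there are more informative features than blocks the assignment wraps.
    """
    n_blocks = -(-config.n_features // config.block_size)
    idx = []
    for i in range(config.n_informative):
        block = i % n_blocks
        offset = i // n_blocks
        j = block * config.block_size + offset
        idx.append(j if j < config.n_features else i)
    return sorted(set(idx))[: config.n_informative]


def generate_descriptors(
    config: DescriptorSimConfig,
) -> tuple[DescriptorMatrix, pd.Series, list[str]]:
    """Draw a labeled descriptor table; returns (matrix, labels, informative).

    Feature j in block b is ``sqrt(rho) * g_b + sqrt(1-rho) * e_j`` (unit
    marginal variance); informative features additionally get a mean shift
    of ``effect_size`` in the positive class.  Labels are 1 (positive) / 0
    (negative).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_neg
    p = config.n_features
    blocks = np.arange(p) // config.block_size
    g = rng.standard_normal((n, blocks.max() + 1))
    eps = rng.standard_normal((n, p))
    X = np.sqrt(config.rho) * g[:, blocks] + np.sqrt(1.0 - config.rho) * eps

    labels = np.concatenate([np.ones(config.n_pos, int), np.zeros(config.n_neg, int)])
    informative = informative_indices(config)
    if informative:
        X[np.ix_(labels == 1, informative)] += config.effect_size

    if config.missing_rate > 0:
        mask = rng.random((n, p)) < config.missing_rate
        X = np.where(mask, np.nan, X)

    ids = [f"POS{i:03d}" for i in range(config.n_pos)] + [
        f"NEG{i:03d}" for i in range(config.n_neg)
    ]
    names = [feature_name(j) for j in range(p)]
    matrix = DescriptorMatrix(pd.DataFrame(X, index=ids, columns=names))
    y = pd.Series(labels, index=ids, name="label")
    return matrix, y, [feature_name(j) for j in informative]
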