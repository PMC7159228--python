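"""Reading, normalization and aggregation of spontaneous adverse-event reports.

A spontaneous reporting system (FAERS-like) report names one primary-suspect
drug and one or more adverse events coded as MedDRA Preferred Terms (PT).
This module turns delimited report files into a drug-event count matrix:
records are filtered to primary-suspect entries, drug names are canonicalized
against a user-supplied synonym table (exact match after case-folding and
whitespace trimming only), PTs are optionally rolled up to System Organ Class
(SOC), and every unique drug-event pair is consolidated by summing its report
counts.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ("report_id", "drug_name_raw", "role", "event_pt", "date")

#: role codes accepted for the primary-suspect flag in the dollar dialect
_PRIMARY_CODES = {"PS", "PRIMARY_SUSPECT"}


class Role(str, Enum):
    PRIMARY_SUSPECT = "primary_suspect"
    OTHER = "other"


class EventLevel(str, Enum):
    PT = "PT"
    SOC = "SOC"


@dataclass(frozen=True)
class ReportRecord:
    """One drug-event line from a spontaneous report.

    ``date`` is a calendar quarter string such as ``"2004Q1"``; it is carried
    through unparsed.  ``canonical_drug`` is filled by
    :func:`normalize_drug_names`, ``event_soc`` by :func:`map_pt_to_soc`.
    """

    report_id: str
    drug_name_raw: str
    role: Role
    event_pt: str
    date: str
    event_soc: str | None = None
    canonical_drug: str | None = None

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if not self.event_pt:
            raise ValueError("event_pt must be non-empty")
        if not isinstance(self.role, Role):
            raise ValueError(f"role must be a Role, got {self.role!r}")


def _fold(name: str) -> str:
    return name.strip().casefold()


@dataclass(frozen=True)
class SynonymTable:
    """Exact-match mapping from raw drug names to canonical drug ids.

    Raw names are keyed after case-folding and whitespace trimming; no fuzzy
    matching is ever attempted, mirroring the exact-match policy used when
    aligning free-text FAERS drug names to a reference vocabulary.
    """

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        folded: dict[str, str] = {}
        for raw, canon in self.entries.items():
            key = _fold(raw)
            if key in folded and folded[key] != canon:
                raise ValueError(f"raw name {raw!r} duplicated after folding")
            if not canon:
                raise ValueError(f"canonical id for {raw!r} is empty")
            folded[key] = canon
        object.__setattr__(self, "entries", folded)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SynonymTable":
        """Read a two-column CSV ``raw_name,canonical_id`` (with header)."""
        entries: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries[row["raw_name"]] = row["canonical_id"]
        return cls(entries)

    def lookup(self, raw_name: str) -> str | None:
        return self.entries.get(_fold(raw_name))


@dataclass(frozen=True)
class PTSOCMap:
    """Many-to-one mapping from MedDRA Preferred Term to System Organ Class."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for pt, soc in self.entries.items():
            if not soc:
                raise ValueError(f"PT {pt!r} maps to empty SOC")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PTSOCMap":
        """Read a two-column CSV ``pt,soc`` (with header)."""
        entries: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                pt, soc = row["pt"], row["soc"]
                if pt in entries and entries[pt] != soc:
                    raise ValueError(f"PT {pt!r} maps to more than one SOC")
                entries[pt] = soc
        return cls(entries)


def read_reports(path: str | Path, dialect: str = "simple_csv") -> list[ReportRecord]:
    """Parse a delimited report file into :class:`ReportRecord` objects.

    Two dialects are supported:

    ``simple_csv``
        comma-separated, header row with the five columns
        ``report_id,drug_name_raw,role,event_pt,date``; role values are
        ``primary_suspect`` or ``other``.
    ``faers_dollar``
        ``$``-separated in the style of FAERS quarterly ASCII extracts, same
        header; role codes ``PS`` (primary suspect) vs. anything else.

    Malformed rows (missing report id or event term, unknown role) are
    counted and reported through logging, never silently dropped.
    """
    if dialect == "simple_csv":
        sep = ","
    elif dialect == "faers_dollar":
        sep = "$"
    else:
        raise ValueError(f"unknown report dialect {dialect!r}")

    records: list[ReportRecord] = []
    n_bad = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        missing = set(REPORT_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row, dialect))
            except ValueError as exc:
                n_bad += 1
                logger.warning("%s line %d rejected: %s", path, lineno, exc)
    if n_bad:
        logger.info("%s: %d malformed row(s) rejected", path, n_bad)
    return records


def _parse_row(row: Mapping[str, str], dialect: str) -> ReportRecord:
    raw_role = (row.get("role") or "").strip()
    if dialect == "faers_dollar":
        role = Role.PRIMARY_SUSPECT if raw_role.upper() in _PRIMARY_CODES else Role.OTHER
    else:
        try:
            role = Role(raw_role)
        except ValueError:
            raise ValueError(f"unknown role {raw_role!r}")
    return ReportRecord(
        report_id=(row.get("report_id") or "").strip(),
        drug_name_raw=(row.get("drug_name_raw") or "").strip(),
        role=role,
        event_pt=(row.get("event_pt") or "").strip(),
        date=(row.get("date") or "").strip(),
    )


def filter_primary_suspect(records: Iterable[ReportRecord]) -> list[ReportRecord]:
    """Keep only entries whose drug is flagged as the primary suspect.

    Every event in a report is attributed to that report's primary-suspect
    drug; entries for concomitant drugs are discarded.  Order is preserved
    and the operation is idempotent.
    """
    return [r for r in records if r.role is Role.PRIMARY_SUSPECT]


def normalize_drug_names(
    records: Iterable[ReportRecord], synonyms: SynonymTable
) -> tuple[list[ReportRecord], list[ReportRecord]]:
    """Attach canonical drug ids; split off records with no exact match.

    Matching is exact after case-folding/trimming only — a raw name carrying
    dose or purchase text does not match.  Returns ``(matched, unmatched)``;
    unmatched records must never feed downstream aggregation.
    """
    matched: list[ReportRecord] = []
    unmatched: list[ReportRecord] = []
    for rec in records:
        canon = synonyms.lookup(rec.drug_name_raw)
        if canon is None:
            unmatched.append(rec)
        else:
            matched.append(replace(rec, canonical_drug=canon))
    if unmatched:
        logger.info("%d record(s) with no exact drug-name match", len(unmatched))
    return matched, unmatched


def map_pt_to_soc(
    records: Iterable[ReportRecord], ptsoc: PTSOCMap
) -> tuple[list[ReportRecord], list[ReportRecord]]:
    """Populate the System Organ Class for each record's Preferred Term.

    Returns ``(mapped, unmapped)``.  Unmapped records keep their PT-level
    information but are excluded from any SOC-level rollup.
    """
    mapped: list[ReportRecord] = []
    unmapped: list[ReportRecord] = []
    for rec in records:
        soc = ptsoc.entries.get(rec.event_pt)
        if soc is None:
            unmapped.append(rec)
        else:
            mapped.append(replace(rec, event_soc=soc))
    if unmapped:
        logger.info("%d record(s) with unmapped PT excluded from SOC rollup", len(unmapped))
    return mapped, unmapped


@dataclass
class DrugEventMatrix:
    """Consolidated report counts for every unique drug-event pair.

    ``counts`` maps ``(drug_id, event_key)`` to the total number of report
    lines for that pair; marginals and the grand total are derived and kept
    consistent by construction.
    """

    counts: dict[tuple[str, str], int]
    event_level: EventLevel = EventLevel.PT
    drug_marginals: dict[str, int] = field(init=False)
    event_marginals: dict[str, int] = field(init=False)
    grand_total: int = field(init=False)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative count in drug-event matrix")
        dm: Counter[str] = Counter()
        em: Counter[str] = Counter()
        for (d, e), n in self.counts.items():
            dm[d] += n
            em[e] += n
        self.drug_marginals = dict(dm)
        self.event_marginals = dict(em)
        self.grand_total = sum(self.counts.values())

    @property
    def drugs(self) -> list[str]:
        return sorted(self.drug_marginals)

    @property
    def events(self) -> list[str]:
        return sorted(self.event_marginals)

    def get(self, drug: str, event: str) -> int:
        return self.counts.get((drug, event), 0)

    def write_csv(self, path: str | Path) -> None:
        """Serialize as ``drug,event,count`` triplets, sorted, with header."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["drug", "event", "count"])
            writer.writerow(["#event_level", self.event_level.value, ""])
            for (d, e), n in sorted(self.counts.items()):
                writer.writerow([d, e, n])

    @classmethod
    def read_csv(cls, path: str | Path) -> "DrugEventMatrix":
        counts: dict[tuple[str, str], int] = {}
        level = EventLevel.PT
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader)  # header
            for row in reader:
                if row[0] == "#event_level":
                    level = EventLevel(row[1])
                    continue
                counts[(row[0], row[1])] = int(row[2])
        return cls(counts, event_level=level)


def build_drug_event_matrix(
    records: Sequence[ReportRecord], event_level: EventLevel | str = EventLevel.PT
) -> DrugEventMatrix:
    """Consolidate records into a :class:`DrugEventMatrix`.

    Each record contributes one count to its (drug, event) cell, so a report
    listing k events for its primary-suspect drug contributes k pairs.  The
    drug key is the canonical id when present (records should be normalized
    first), the event key is the PT or the SOC depending on ``event_level``.
    """
    event_level = EventLevel(event_level)
    counts: Counter[tuple[str, str]] = Counter()
    n_skipped = 0
    for rec in records:
        drug = rec.canonical_drug or rec.drug_name_raw
        if event_level is EventLevel.SOC:
            if rec.event_soc is None:
                n_skipped += 1
                continue
            event = rec.event_soc
        else:
            event = rec.event_pt
        counts[(drug, event)] += 1
    if n_skipped:
        logger.warning("%d record(s) without SOC skipped in SOC-level matrix", n_skipped)
    return DrugEventMatrix(dict(counts), event_level=event_level)
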