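"""Spontaneous-report tables: reading, deduplication, indexing, 2x2 counts.

A spontaneous reporting system (SRS) such as FAERS is, for the purposes of
disproportionality analysis, a bag of reports, each carrying a set of drug
identifiers and a set of adverse-drug-event (ADE) identifiers.  All counting
here is report-level: a report contributes at most 1 to any count no matter
how many times a drug or event is coded on it.

The 2x2 contingency counts for a drug i / ADE j pair follow the standard
notation: c_ij (reports with both), c_i+ (reports with the drug), c_+j
(reports with the ADE) and c_++ (all reports).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"

#: tokens accepted in reference-set label columns, mapped to canonical labels
_LABEL_TOKENS = {
    "positive": POSITIVE, "pos": POSITIVE, "1": POSITIVE, "true": POSITIVE,
    "negative": NEGATIVE, "neg": NEGATIVE, "0": NEGATIVE, "false": NEGATIVE,
}


class FormatError(ValueError):
    """Raised when an input file does not match the expected table layout."""


class DataError(ValueError):
    """Raised when inputs are structurally valid but unusable (e.g. empty)."""


@dataclass(frozen=True)
class Report:
    """One spontaneous report: an ID, a receipt date and two identifier sets."""

    report_id: str
    receipt_date: _dt.date
    drugs: frozenset
    ades: frozenset

    def __post_init__(self):
        if not self.drugs:
            raise DataError(f"report {self.report_id!r}: empty drug set")
        if not self.ades:
            raise DataError(f"report {self.report_id!r}: empty ADE set")


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts for one drug-ADE pair: c_ij, c_i+, c_+j, c_++."""

    c_ij: int
    c_i_plus: int
    c_plus_j: int
    c_plus_plus: int

    def __post_init__(self):
        c = (self.c_ij, self.c_i_plus, self.c_plus_j, self.c_plus_plus)
        if any(int(x) != x or x < 0 for x in c):
            raise DataError(f"counts must be non-negative integers: {c}")
        if self.c_ij > min(self.c_i_plus, self.c_plus_j):
            raise DataError(f"c_ij exceeds a margin: {c}")
        if max(self.c_i_plus, self.c_plus_j) > self.c_plus_plus:
            raise DataError(f"margin exceeds total: {c}")
        if self.c_i_plus + self.c_plus_j - self.c_ij > self.c_plus_plus:
            raise DataError(f"inclusion-exclusion violated: {c}")

    @property
    def expected(self) -> float:
        """Expected pair count under drug-ADE independence, c_i+ * c_+j / c_++."""
        return self.c_i_plus * self.c_plus_j / self.c_plus_plus

    def cells(self) -> tuple:
        """The four 2x2 cells (a, b, c, d) = (both, drug only, ADE only, neither)."""
        a = self.c_ij
        b = self.c_i_plus - self.c_ij
        c = self.c_plus_j - self.c_ij
        d = self.c_plus_plus - self.c_i_plus - self.c_plus_j + self.c_ij
        return a, b, c, d


class ReportDatabase:
    """An ordered collection of reports with drug/ADE inverted indexes.

    Indexes map each identifier to the set of *positions* of reports that
    mention it; positions (not report_ids) are used because a raw database
    may legitimately contain several versions of the same report until
    :func:`deduplicate_reports` is applied.
    """

    def __init__(self, reports: Sequence[Report]):
        self.reports = list(reports)
        self.drug_index: dict = {}
        self.ade_index: dict = {}
        for pos, rep in enumerate(self.reports):
            for d in rep.drugs:
                self.drug_index.setdefault(d, set()).add(pos)
            for a in rep.ades:
                self.ade_index.setdefault(a, set()).add(pos)

    @property
    def n_reports(self) -> int:
        """Total report count c_++."""
        return len(self.reports)

    @property
    def drugs(self):
        return self.drug_index.keys()

    @property
    def ades(self):
        return self.ade_index.keys()

    def __len__(self) -> int:
        return len(self.reports)

    def __repr__(self) -> str:
        return (f"ReportDatabase({len(self.reports)} reports, "
                f"{len(self.drug_index)} drugs, {len(self.ade_index)} ADEs)")


def read_reports(
    path,
    delimiter: str = "\t",
    cell_separator: str = "|",
    columns: Mapping[str, str] | None = None,
) -> ReportDatabase:
    """Read a delimited report table into a :class:`ReportDatabase`.

    The canonical dialect is tab-separated with columns ``report_id``,
    ``receipt_date`` (ISO-8601), ``drugs`` and ``ades``, the latter two
    holding ``cell_separator``-joined identifier lists.  ``columns`` may remap
    canonical names to the file's actual headers.  Rows with an empty drug or
    ADE cell, or an unparseable date, are dropped with a logged count; the
    reader performs no deduplication.
    """
    cols = {"report_id": "report_id", "receipt_date": "receipt_date",
            "drugs": "drugs", "ades": "ades"}
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for canonical, name in cols.items():
        if name not in df.columns:
            raise FormatError(f"missing required column {name!r} ({canonical})")
    reports, n_dropped = [], 0
    for row in df.itertuples(index=False):
        rid = getattr(row, cols["report_id"])
        date_s = getattr(row, cols["receipt_date"])
        drugs = frozenset(t for t in getattr(row, cols["drugs"]).split(cell_separator) if t)
        ades = frozenset(t for t in getattr(row, cols["ades"]).split(cell_separator) if t)
        try:
            date = _dt.date.fromisoformat(date_s.strip())
        except ValueError:
            n_dropped += 1
            continue
        if not drugs or not ades:
            n_dropped += 1
            continue
        reports.append(Report(str(rid), date, drugs, ades))
    if n_dropped:
        logger.warning("read_reports: dropped %d malformed row(s) from %s",
                       n_dropped, path)
    return ReportDatabase(reports)


def write_reports(db: ReportDatabase, path, delimiter: str = "\t",
                  cell_separator: str = "|") -> None:
    """Write the canonical report-table dialect (round-trips with read_reports)."""
    rows = [
        {
            "report_id": r.report_id,
            "receipt_date": r.receipt_date.isoformat(),
            "drugs": cell_separator.join(sorted(r.drugs)),
            "ades": cell_separator.join(sorted(r.ades)),
        }
        for r in db.reports
    ]
    pd.DataFrame(rows, columns=["report_id", "receipt_date", "drugs", "ades"]) \
        .to_csv(path, sep=delimiter, index=False)


def deduplicate_reports(db: ReportDatabase) -> ReportDatabase:
    """Keep, for each report_id, only the version with the latest receipt date.

    Spontaneous reports are amended over time under a constant primary ID;
    only the latest version reflects the curated record.  Ties on the date
    are broken by keeping the row that occurs last in file order.  Idempotent.
    """
    best: dict = {}
    for pos, rep in enumerate(db.reports):
        cur = best.get(rep.report_id)
        if cur is None or (rep.receipt_date, pos) >= (cur[0].receipt_date, cur[1]):
            best[rep.report_id] = (rep, pos)
    kept = [rep for rep, _ in sorted(best.values(), key=lambda t: t[1])]
    return ReportDatabase(kept)


def build_contingency(db: ReportDatabase, drug, ade) -> ContingencyTable:
    """Report-level 2x2 counts for one (drug, ADE) pair.

    Identifiers absent from the database yield zero counts rather than an
    error, so candidate pairs can be scored uniformly.
    """
    d_set = db.drug_index.get(drug, set())
    a_set = db.ade_index.get(ade, set())
    return ContingencyTable(
        c_ij=len(d_set & a_set),
        c_i_plus=len(d_set),
        c_plus_j=len(a_set),
        c_plus_plus=db.n_reports,
    )


def build_all_contingencies(
    db: ReportDatabase, pairs: Iterable | None = None
) -> dict:
    """Contingency tables for many pairs, sharing margin computations.

    When ``pairs`` is omitted, every co-occurring pair (c_ij >= 1) in the
    database is returned — the set over which an empirical-Bayes prior is
    normally fitted.
    """
    if db.n_reports == 0:
        raise DataError("empty database")
    n = db.n_reports
    if pairs is None:
        counts: dict = {}
        for rep in db.reports:
            for d in rep.drugs:
                for a in rep.ades:
                    counts[(d, a)] = counts.get((d, a), 0) + 1
        # sorted for a deterministic iteration order downstream (fits that
        # sum likelihood terms must not depend on set-iteration order)
        return {
            (d, a): ContingencyTable(counts[(d, a)], len(db.drug_index[d]),
                                     len(db.ade_index[a]), n)
            for (d, a) in sorted(counts)
        }
    return {(d, a): build_contingency(db, d, a) for d, a in pairs}


@dataclass
class ReferenceSet:
    """Labeled (drug, ADE, label) pairs used as evaluation ground truth."""

    pairs: list = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for d, a, lab in self.pairs:
            if lab not in (POSITIVE, NEGATIVE):
                raise FormatError(f"unknown label {lab!r} for pair ({d}, {a})")
            if (d, a) in seen:
                raise FormatError(f"duplicate reference pair ({d}, {a})")
            seen.add((d, a))

    @property
    def positives(self) -> list:
        return [(d, a) for d, a, lab in self.pairs if lab == POSITIVE]

    @property
    def negatives(self) -> list:
        return [(d, a) for d, a, lab in self.pairs if lab == NEGATIVE]

    def labels(self) -> dict:
        return {(d, a): lab == POSITIVE for d, a, lab in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


def read_reference_set(path, delimiter: str = "\t") -> ReferenceSet:
    """Read a delimited drug/ade/label table into a :class:`ReferenceSet`."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in ("drug", "ade", "label"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if len(df) == 0:
        raise DataError("empty reference set")
    pairs = []
    for row in df.itertuples(index=False):
        token = str(row.label).strip().lower()
        if token not in _LABEL_TOKENS:
            raise FormatError(f"unknown label token {row.label!r}")
        pairs.append((str(row.drug), str(row.ade), _LABEL_TOKENS[token]))
    return ReferenceSet(pairs)


def write_reference_set(ref: ReferenceSet, path, delimiter: str = "\t") -> None:
    pd.DataFrame(ref.pairs, columns=["drug", "ade", "label"]) \
        .to_csv(path, sep=delimiter, index=False)
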