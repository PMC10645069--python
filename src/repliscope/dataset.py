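"""Coded-dataset schema: study pairs, reported statistics, validation, CSV I/O.

One row of the coded dataset describes an original/replication pair: the
subjective replication score, demographic and design predictors, and the
reported key statistic for both studies.  The canonical column names are
defined here; files with other headers can be read through a column-mapping
config (``mapping`` argument of :func:`read_coded_dataset`).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

from .errors import SchemaError

SUBFIELDS = ("cognitive", "social", "other_psych", "non_psych")
CLOSENESS_LEVELS = ("exact", "very_close", "close", "far")
SCORE_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
TEST_TYPES = (
    "means_between",
    "means_within",
    "t_between",
    "t_within",
    "f_test",
    "proportions",
    "beta_se",
    "none",
)

#: statistic fields that must be present (non-None) for each test type
REQUIRED_STAT_FIELDS: dict[str, tuple[str, ...]] = {
    "means_between": ("m1", "s1", "n1", "m2", "s2", "n2"),
    # means_within carries the mean and SD of the paired difference scores
    "means_within": ("m1", "s1", "n1"),
    "t_between": ("statistic", "n1", "n2"),
    "t_within": ("statistic", "n1"),
    "f_test": ("statistic", "df1", "df2", "n1"),
    "proportions": ("success1", "total1", "success2", "total2"),
    "beta_se": ("beta", "se"),
    "none": (),
}


@dataclass
class StatisticsReport:
    """The key statistic reported by one study, in one of several shapes."""

    test_type: str = "none"
    statistic: float | None = None  # t or F value
    df1: float | None = None
    df2: float | None = None
    m1: float | None = None
    s1: float | None = None
    n1: int | None = None
    m2: float | None = None
    s2: float | None = None
    n2: int | None = None
    success1: int | None = None
    total1: int | None = None
    success2: int | None = None
    total2: int | None = None
    beta: float | None = None
    se: float | None = None

    def issues(self, label: str = "stats") -> list[str]:
        out: list[str] = []
        if self.test_type not in TEST_TYPES:
            out.append(
                f"{label}: unknown test_type {self.test_type!r}; "
                f"expected one of {TEST_TYPES}"
            )
            return out
        for name in REQUIRED_STAT_FIELDS[self.test_type]:
            if getattr(self, name) is None:
                out.append(
                    f"{label}: test_type {self.test_type!r} requires field {name!r}"
                )
        for name in ("s1", "s2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                out.append(f"{label}: {name} must be > 0 (got {v})")
        if self.se is not None and self.se <= 0:
            out.append(f"{label}: se must be > 0 (got {self.se})")
        for name in ("success1", "success2", "total1", "total2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                out.append(f"{label}: {name} must be non-negative (got {v})")
        if self.test_type == "proportions" and not out:
            if self.success1 > self.total1 or self.success2 > self.total2:
                out.append(f"{label}: successes exceed totals")
        return out


@dataclass
class StudyPair:
    """One original/replication record."""

    pair_id: str
    class_year: int
    subfield: str
    open_data: bool
    open_materials: bool
    original_online: bool
    replication_online: bool
    stanford_affiliation: bool
    within_participants: bool
    single_vignette: bool
    n_trials: int
    publication_year: int
    n_original: int
    n_replication: int
    closeness: str
    subjective_score: float
    same_direction: bool
    sensitivity_include: bool
    original_stats: StatisticsReport = field(default_factory=StatisticsReport)
    replication_stats: StatisticsReport = field(default_factory=StatisticsReport)


def validate_record(pair: StudyPair) -> list[str]:
    """Return a list of invariant violations; empty iff the record is valid.

    Issues are returned rather than raised so that a whole file can be
    checked and reported in one pass.
    """
    issues: list[str] = []
    if pair.subfield not in SUBFIELDS:
        issues.append(
            f"subfield {pair.subfield!r} not in {SUBFIELDS}"
        )
    if pair.closeness not in CLOSENESS_LEVELS:
        issues.append(
            f"closeness {pair.closeness!r} not in {CLOSENESS_LEVELS}"
        )
    if not any(math.isclose(pair.subjective_score, g) for g in SCORE_GRID):
        issues.append(
            f"subjective_score {pair.subjective_score} not on the "
            f"five-level grid {SCORE_GRID}"
        )
    for name in ("n_trials", "n_original", "n_replication"):
        v = getattr(pair, name)
        if v is None or v < 1:
            issues.append(f"{name} must be >= 1 (got {v})")
    issues.extend(pair.original_stats.issues("original_stats"))
    issues.extend(pair.replication_stats.issues("replication_stats"))
    return issues


# ---------------------------------------------------------------------------
# CSV serialization

_BOOL_COLS = (
    "open_data",
    "open_materials",
    "original_online",
    "replication_online",
    "stanford_affiliation",
    "within_participants",
    "single_vignette",
    "same_direction",
    "sensitivity_include",
)
_INT_COLS = ("class_year", "n_trials", "publication_year", "n_original", "n_replication")
_STAT_FIELDS = [f.name for f in dc_fields(StatisticsReport)]
_STAT_INT_FIELDS = ("n1", "n2", "success1", "total1", "success2", "total2")

CANONICAL_COLUMNS: tuple[str, ...] = tuple(
    [
        "pair_id",
        "class_year",
        "subfield",
        *_BOOL_COLS[:7],
        "n_trials",
        "publication_year",
        "n_original",
        "n_replication",
        "closeness",
        "subjective_score",
        "same_direction",
        "sensitivity_include",
    ]
    + [f"orig_{f}" for f in _STAT_FIELDS]
    + [f"rep_{f}" for f in _STAT_FIELDS]
)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_bool(text: str, col: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValueError(f"column {col}: cannot parse boolean from {text!r}")


def _parse_stats(row: dict[str, str], prefix: str) -> StatisticsReport:
    kwargs = {}
    for name in _STAT_FIELDS:
        raw = row.get(f"{prefix}_{name}", "").strip()
        if raw == "":
            kwargs[name] = "none" if name == "test_type" else None
        elif name == "test_type":
            kwargs[name] = raw
        elif name in _STAT_INT_FIELDS:
            kwargs[name] = int(float(raw))
        else:
            kwargs[name] = float(raw)
    return StatisticsReport(**kwargs)


def _fmt_stat(name: str, value) -> str:
    if value is None or name == "test_type":
        return _fmt(value)
    if name in _STAT_INT_FIELDS:
        return str(int(value))
    return repr(float(value))  # canonical float text, so round-trips are byte-stable


def pair_to_row(pair: StudyPair) -> dict[str, str]:
    row: dict[str, str] = {}
    for col in CANONICAL_COLUMNS:
        if col.startswith("orig_"):
            row[col] = _fmt_stat(col[5:], getattr(pair.original_stats, col[5:]))
        elif col.startswith("rep_"):
            row[col] = _fmt_stat(col[4:], getattr(pair.replication_stats, col[4:]))
        else:
            row[col] = _fmt(getattr(pair, col))
    return row


def row_to_pair(row: dict[str, str]) -> StudyPair:
    kwargs: dict = {"pair_id": row["pair_id"].strip()}
    for col in _BOOL_COLS:
        kwargs[col] = _parse_bool(row[col], col)
    for col in _INT_COLS:
        kwargs[col] = int(float(row[col]))
    kwargs["subfield"] = row["subfield"].strip()
    kwargs["closeness"] = row["closeness"].strip()
    kwargs["subjective_score"] = float(row["subjective_score"])
    kwargs["original_stats"] = _parse_stats(row, "orig")
    kwargs["replication_stats"] = _parse_stats(row, "rep")
    return StudyPair(**kwargs)


@dataclass
class ReadResult:
    """Outcome of reading a coded dataset: valid pairs plus per-row issues."""

    pairs: list[StudyPair]
    issues: list[tuple[int, str]]  # (1-based data row number, description)


def read_coded_dataset(
    path: str | Path,
    mapping: dict[str, str] | None = None,
) -> ReadResult:
    """Read a coded-dataset CSV into validated :class:`StudyPair` records.

    Parameters
    ----------
    path:
        CSV file with a header row.
    mapping:
        Optional ``{file_column: canonical_column}`` renaming applied to the
        header before schema checking, for files using other conventions.

    Rows that fail parsing or validation are reported in
    :attr:`ReadResult.issues` with their row number — never silently dropped.

    Raises
    ------
    SchemaError
        If a required canonical column is absent after mapping.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if mapping:
            header = [mapping.get(h, h) for h in header]
        missing = [c for c in CANONICAL_COLUMNS if c not in header]
        if missing:
            raise SchemaError(
                f"{path}: missing required columns {missing[:8]}"
                + (" ..." if len(missing) > 8 else "")
            )
        pairs: list[StudyPair] = []
        issues: list[tuple[int, str]] = []
        for i, raw in enumerate(reader, start=1):
            if mapping:
                raw = {mapping.get(k, k): v for k, v in raw.items()}
            try:
                pair = row_to_pair(raw)
            except (ValueError, KeyError) as exc:
                issues.append((i, f"unparseable row: {exc}"))
                continue
            record_issues = validate_record(pair)
            if record_issues:
                issues.extend((i, msg) for msg in record_issues)
            else:
                pairs.append(pair)
    return ReadResult(pairs=pairs, issues=issues)


def write_coded_dataset(pairs: Iterable[StudyPair], path: str | Path) -> None:
    """Write pairs as a canonical-dialect CSV (RFC 4180, UTF-8, header row)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(CANONICAL_COLUMNS))
        writer.writeheader()
        for pair in pairs:
            writer.writerow(pair_to_row(pair))


def sensitivity_subset(pairs: Sequence[StudyPair]) -> list[StudyPair]:
    """Pairs flagged for the sensitivity analysis (matching test
    specification, primary-importance result, no major replication issues).

    Raises
    ------
    ValueError
        If no pair is flagged for inclusion.
    """
    subset = [p for p in pairs if p.sensitivity_include]
    if not subset:
        raise ValueError("sensitivity subset is empty: no pair has sensitivity_include")
    return subset
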