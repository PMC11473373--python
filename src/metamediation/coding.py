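"""Study coding tables for three-variable correlation meta-analysis.

A coding table has one row per independent sample, carrying the sample size
and the three Pearson correlations among physical activity (X), resilience
(M), and a mental-health indicator (Y).  Indicators are stratified by
polarity: ``positive`` for adaptive constructs (subjective well-being, life
satisfaction) and ``negative`` for deficit constructs (depression, anxiety,
negative affect).  Rows drawn from the same underlying subjects are linked
through ``shares_sample_with`` so subjects are not double-counted.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Polarity",
    "StudyRecord",
    "CodingTable",
    "CodingTableError",
    "read_coding_table",
    "write_coding_table",
    "subset_by_polarity",
    "load_reference_table",
]

#: Canonical CSV column order.
COLUMNS = (
    "study_id",
    "n",
    "indicator_name",
    "polarity",
    "r_pa_re",
    "r_pa_mh",
    "r_re_mh",
    "population",
    "shares_sample_with",
)

#: Columns that must be present in every coding-table CSV.
REQUIRED_COLUMNS = COLUMNS[:7]


class CodingTableError(ValueError):
    """Raised when a coding table violates its contract."""


class Polarity(str, enum.Enum):
    """Direction of the coded mental-health construct."""

    POSITIVE = "positive"
    NEGATIVE = "negative"

    @classmethod
    def coerce(cls, value: "Polarity | str") -> "Polarity":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise CodingTableError(
                f"invalid polarity {value!r}; expected 'positive' or 'negative'"
            ) from None


@dataclass(frozen=True)
class StudyRecord:
    """One independent sample's coded correlations and metadata.

    ``n`` must be at least 4 so the Fisher-z sampling variance 1/(n-3) is
    finite and positive; correlations must lie strictly inside (-1, 1).
    The sign of the correlations is never forced to match the polarity:
    data may contradict expectations and should be allowed to.
    """

    study_id: str
    n: int
    indicator_name: str
    polarity: Polarity
    r_pa_re: float
    r_pa_mh: float
    r_re_mh: float
    population: str = ""
    shares_sample_with: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "polarity", Polarity.coerce(self.polarity))

    def validate(self) -> None:
        if not self.study_id:
            raise CodingTableError("study_id must be non-empty")
        if int(self.n) != self.n or self.n < 4:
            raise CodingTableError(
                f"{self.study_id}: n must be an integer >= 4, got {self.n!r}"
            )
        for name in ("r_pa_re", "r_pa_mh", "r_re_mh"):
            r = getattr(self, name)
            if not -1.0 < float(r) < 1.0:
                raise CodingTableError(
                    f"{self.study_id}: {name}={r!r} outside the open interval (-1, 1)"
                )

    def correlation(self, which: str) -> float:
        """Return one of the three coded correlations by key.

        ``which`` is one of ``pa_re``, ``pa_mh``, ``re_mh``.
        """
        try:
            return float(getattr(self, f"r_{which}"))
        except AttributeError:
            raise KeyError(
                f"unknown correlation {which!r}; expected pa_re, pa_mh or re_mh"
            ) from None


@dataclass
class CodingTable:
    """An ordered collection of :class:`StudyRecord` with provenance text."""

    records: list[StudyRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def k(self) -> int:
        """Number of independent samples (rows)."""
        return len(self.records)

    @property
    def study_ids(self) -> list[str]:
        return [rec.study_id for rec in self.records]

    @property
    def unique_subjects(self) -> int:
        """Total subjects, counting each shared-sample group once.

        Rows linked through ``shares_sample_with`` (transitively) form a
        group contributing the sample size of its first row.  Links to
        studies absent from this table (e.g. after subsetting) are inert.
        """
        parent: dict[str, str] = {rec.study_id: rec.study_id for rec in self.records}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for rec in self.records:
            other = rec.shares_sample_with
            if other and other in parent:
                parent[find(rec.study_id)] = find(other)

        seen: set[str] = set()
        total = 0
        for rec in self.records:
            root = find(rec.study_id)
            if root not in seen:
                seen.add(root)
                total += rec.n
        return total

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            rec.validate()
            if rec.study_id in seen:
                raise CodingTableError(f"duplicate study_id {rec.study_id!r}")
            seen.add(rec.study_id)

    def exclude(self, study_ids: Iterable[str]) -> "CodingTable":
        """Return a copy without the named studies (order preserved)."""
        drop = set(study_ids)
        unknown = drop - set(self.study_ids)
        if unknown:
            raise CodingTableError(f"cannot exclude unknown study_id(s): {sorted(unknown)}")
        kept = [rec for rec in self.records if rec.study_id not in drop]
        return CodingTable(records=kept, provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "study_id": rec.study_id,
                    "n": rec.n,
                    "indicator_name": rec.indicator_name,
                    "polarity": rec.polarity.value,
                    "r_pa_re": rec.r_pa_re,
                    "r_pa_mh": rec.r_pa_mh,
                    "r_re_mh": rec.r_re_mh,
                    "population": rec.population,
                    "shares_sample_with": rec.shares_sample_with or "",
                }
            )
        return pd.DataFrame(rows, columns=list(COLUMNS))


def _parse_row(row: pd.Series, index: int) -> StudyRecord:
    try:
        n = int(str(row["n"]).replace(",", ""))
    except ValueError:
        raise CodingTableError(f"row {index}: non-numeric n {row['n']!r}") from None
    rs = {}
    for col in ("r_pa_re", "r_pa_mh", "r_re_mh"):
        try:
            rs[col] = float(row[col])
        except ValueError:
            raise CodingTableError(
                f"row {index}: non-numeric {col} {row[col]!r}"
            ) from None
    shares = str(row.get("shares_sample_with", "") or "").strip()
    return StudyRecord(
        study_id=str(row["study_id"]).strip(),
        n=n,
        indicator_name=str(row["indicator_name"]).strip(),
        polarity=Polarity.coerce(row["polarity"]),
        r_pa_re=rs["r_pa_re"],
        r_pa_mh=rs["r_pa_mh"],
        r_re_mh=rs["r_re_mh"],
        population=str(row.get("population", "") or "").strip(),
        shares_sample_with=shares or None,
    )


def read_coding_table(path, strict: bool = True) -> CodingTable:
    """Read a coding-table CSV.

    Parameters
    ----------
    path
        CSV file with the canonical header (comma-separated, UTF-8,
        decimal point).  ``population`` and ``shares_sample_with`` may be
        omitted.
    strict
        If true (default) any invalid row aborts with
        :class:`CodingTableError`; otherwise offending rows are dropped
        with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CodingTableError(f"{path.name}: missing required column(s) {missing}")

    records: list[StudyRecord] = []
    for index, row in df.iterrows():
        try:
            rec = _parse_row(row, int(index))
            rec.validate()
        except CodingTableError as exc:
            if strict:
                raise
            logger.warning("dropping invalid row %d: %s", index, exc)
            continue
        records.append(rec)

    if not records:
        logger.warning("%s: no valid data rows", path.name)

    table = CodingTable(records=records, provenance=str(path))
    seen: set[str] = set()
    deduped: list[StudyRecord] = []
    for rec in table.records:
        if rec.study_id in seen:
            msg = f"duplicate study_id {rec.study_id!r}"
            if strict:
                raise CodingTableError(msg)
            logger.warning("dropping row with %s", msg)
            continue
        seen.add(rec.study_id)
        deduped.append(rec)
    table.records = deduped
    return table


def write_coding_table(table: CodingTable, path) -> None:
    """Write a coding table to CSV in the canonical column order."""
    table.to_frame().to_csv(path, index=False)


def subset_by_polarity(table: CodingTable, polarity: Polarity | str) -> CodingTable:
    """Rows whose indicator has the given polarity, original order kept."""
    pol = Polarity.coerce(polarity)
    kept = [rec for rec in table.records if rec.polarity is pol]
    return CodingTable(records=kept, provenance=table.provenance)


def load_reference_table() -> CodingTable:
    """Load the packaged reference coding table.

    Sixteen independent samples from fifteen published studies (17,043
    unique subjects) relating physical activity, resilience, and mental
    health; two rows share one middle-school sample and are linked through
    ``shares_sample_with``.  Correlations are stored exactly as published,
    including their mixed decimal precision.
    """
    source = resources.files("metamediation.data") / "reference_coding_table.csv"
    with resources.as_file(source) as path:
        table = read_coding_table(path, strict=True)
    table.provenance = "packaged reference coding table (16 samples, 15 studies)"
    return table
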