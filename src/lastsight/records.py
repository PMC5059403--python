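"""Sighting-record data model, TSV input/output and record filtering.

A *sighting record* is one directly dated fossil occurrence of the taxon:
an uncalibrated radiocarbon determination (``c14_age ± c14_err``) together
with the calendar-scale summaries obtained by calibration (``cal_mean ±
cal_sd``, median and central 95% interval).  All calendar ages are in
calibrated years before present (cal BP, present = AD 1950), so larger
values are older.  The packaged reference table ships the 23 published
cave-bear dates younger than 26,000 radiocarbon years BP, including the
duplicate determinations of the Stajnia Cave specimen (Poz-61719 and
GdA-3894) and the curated conservative-exclusion flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import RecordParseError, RecordValidationError, UsageError

__all__ = [
    "SightingRecord",
    "RecordSet",
    "read_records",
    "write_records",
    "apply_range_filter",
    "select_variant",
    "load_reference_records",
    "COLUMNS",
    "VARIANTS",
    "DEFAULT_RANGE_CUTOFF",
]

COLUMNS = (
    "site",
    "country",
    "specimen",
    "lab_code",
    "c14_age",
    "c14_err",
    "cal_mean",
    "cal_sd",
    "cal_median",
    "cal_lo95",
    "cal_hi95",
    "haplotype",
    "conservative_excluded",
    "source",
)

_FLOAT_COLUMNS = ("c14_age", "c14_err", "cal_mean", "cal_sd", "cal_median", "cal_lo95", "cal_hi95")

VARIANTS = ("include_poz", "include_gda", "conservative")

#: Older-side cutoff in cal BP implementing the "47,500 ± 3000 BP after
#: calibration" acceptance window; dates older than this are discarded.
DEFAULT_RANGE_CUTOFF = 50_500.0

# Lab codes of the two determinations of the same Stajnia specimen; only one
# may enter a given calculation.
_STAJNIA_POZ = "Poz-61719"
_STAJNIA_GDA = "GdA-3894"


@dataclass(frozen=True)
class SightingRecord:
    """One dated fossil occurrence.

    ``cal_mean``/``cal_sd`` are the calibrated posterior mean and standard
    deviation consumed by the extinction estimators; ``cal_lo95`` is the
    older interval bound and ``cal_hi95`` the younger one.
    """

    lab_code: str
    site: str = ""
    country: str = ""
    specimen: str = ""
    c14_age: float | None = None
    c14_err: float | None = None
    cal_mean: float | None = None
    cal_sd: float | None = None
    cal_median: float | None = None
    cal_lo95: float | None = None
    cal_hi95: float | None = None
    haplotype: str | None = None
    conservative_excluded: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if not self.lab_code:
            raise RecordValidationError("record without a lab_code")
        if (self.c14_age is None) != (self.c14_err is None):
            raise RecordValidationError(
                f"{self.lab_code}: c14_age and c14_err must be present together"
            )
        if self.c14_err is not None and self.c14_err <= 0:
            raise RecordValidationError(f"{self.lab_code}: c14_err must be > 0")
        if self.cal_sd is not None and self.cal_sd <= 0:
            raise RecordValidationError(f"{self.lab_code}: cal_sd must be > 0")
        if (
            self.cal_lo95 is not None
            and self.cal_hi95 is not None
            and self.cal_lo95 < self.cal_hi95
        ):
            raise RecordValidationError(
                f"{self.lab_code}: cal_lo95 (older bound) must be >= cal_hi95"
            )


class RecordSet:
    """Ordered collection of :class:`SightingRecord` with a filter log.

    Records are kept sorted ascending by ``cal_mean`` (youngest first) when
    calibrated means are available; ties are broken by ``lab_code`` so the
    ordering is deterministic.
    """

    def __init__(
        self,
        records: Iterable[SightingRecord],
        variant_label: str = "custom",
        provenance: Iterable[str] | None = None,
    ) -> None:
        records = list(records)
        codes = [r.lab_code for r in records]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise RecordValidationError(f"duplicate lab_code(s): {sorted(dupes)}")
        if all(r.cal_mean is not None for r in records):
            records.sort(key=lambda r: (r.cal_mean, r.lab_code))
        self.records: list[SightingRecord] = records
        self.variant_label = variant_label
        self.provenance: list[str] = list(provenance or [])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SightingRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SightingRecord:
        return self.records[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RecordSet) and self.records == other.records

    def lab_codes(self) -> list[str]:
        return [r.lab_code for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Return the records as a DataFrame with the canonical columns."""
        return pd.DataFrame(
            [{c: getattr(r, c) for c in COLUMNS} for r in self.records],
            columns=list(COLUMNS),
        )

    def _derive(self, records: Iterable[SightingRecord], note: str, label: str | None = None) -> "RecordSet":
        return RecordSet(
            records,
            variant_label=label if label is not None else self.variant_label,
            provenance=self.provenance + [note],
        )


def _parse_cell(raw: str, row: int, col: str) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise RecordParseError(f"row {row}, column {col!r}: not a number: {raw!r}") from exc


def _parse_flag(raw: str, row: int) -> bool:
    v = raw.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise RecordParseError(f"row {row}, column 'conservative_excluded': not a boolean: {raw!r}")


def read_records(path, dialect: Mapping[str, str] | None = None) -> RecordSet:
    """Read a tab-separated record table.

    ``dialect`` optionally maps file column names to the canonical names of
    :data:`COLUMNS`.  Empty cells are recorded as absent (``None``), never
    as zero.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect:
        df = df.rename(columns=dict(dialect))
    missing = {"lab_code"} - set(df.columns)
    if missing:
        raise RecordParseError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        row = row._asdict()
        kwargs: dict = {"lab_code": str(row.get("lab_code", "")).strip()}
        for col in ("site", "country", "specimen", "source"):
            kwargs[col] = str(row.get(col, "") or "").strip()
        hap = str(row.get("haplotype", "") or "").strip()
        kwargs["haplotype"] = hap or None
        for col in _FLOAT_COLUMNS:
            kwargs[col] = _parse_cell(str(row.get(col, "") or ""), idx, col)
        kwargs["conservative_excluded"] = _parse_flag(str(row.get("conservative_excluded", "") or ""), idx)
        records.append(SightingRecord(**kwargs))
    return RecordSet(records, provenance=[f"READ {getattr(path, 'name', path)} n={len(records)}"])


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v) if v != int(v) else str(int(v))
    return str(v)


def write_records(rs: RecordSet, path) -> None:
    """Write a :class:`RecordSet` back to canonical TSV (lossless round trip)."""
    lines = ["\t".join(COLUMNS)]
    for r in rs:
        lines.append("\t".join(_fmt(getattr(r, c)) for c in COLUMNS))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_reference_records() -> RecordSet:
    """Load the packaged 23-date cave-bear reference table."""
    with resources.as_file(
        resources.files("lastsight.data").joinpath("cave_bear_dates.tsv")
    ) as p:
        return read_records(p)


def apply_range_filter(rs: RecordSet, cutoff_older: float = DEFAULT_RANGE_CUTOFF) -> RecordSet:
    """Drop records calibrated older than ``cutoff_older`` cal BP.

    Only an older-side cutoff is applied: the record-selection window keeps
    every younger date (the youngest records are the object of study).
    """
    for r in rs:
        if r.cal_mean is None:
            raise RecordValidationError(f"{r.lab_code}: range filter requires cal_mean")
    kept = [r for r in rs if r.cal_mean <= cutoff_older]
    dropped = len(rs) - len(kept)
    return rs._derive(kept, f"FILTER range_older kept={len(kept)} dropped={dropped}")


def select_variant(rs: RecordSet, variant: str) -> RecordSet:
    """Build one of the three analysis variants.

    ``include_poz``/``include_gda`` retain only one of the two duplicate
    Stajnia determinations; ``conservative`` drops every record flagged
    ``conservative_excluded`` (dates younger than the first youngest date
    with vetted collagen chemistry, which also removes both Stajnia dates).
    """
    if variant == "include_poz":
        kept = [r for r in rs if r.lab_code != _STAJNIA_GDA]
    elif variant == "include_gda":
        kept = [r for r in rs if r.lab_code != _STAJNIA_POZ]
    elif variant == "conservative":
        kept = [r for r in rs if not r.conservative_excluded]
    else:
        raise UsageError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    dropped = len(rs) - len(kept)
    return rs._derive(
        kept, f"FILTER variant:{variant} kept={len(kept)} dropped={dropped}", label=variant
    )


def _replace(record: SightingRecord, **changes) -> SightingRecord:
    return replace(record, **changes)
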