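"""Reading and writing fragment-analysis peak tables.

Genotyping software (GeneMapper and kin) exports called peaks as tabular
text: one row per peak with a sample identifier, the fragment size in base
pairs and the peak height.  This module parses such tab-delimited exports,
converts fragment sizes to integer CAG repeat counts against an explicit
run calibration, and assembles per-sample :class:`~cagscore.instability.RepeatTrace`
objects.

Sizing calibration is always an explicit input: every run includes control
DNA of known repeat length, and fragment size maps linearly onto repeat
count at 3 bp per repeat unit anchored on that control.  Nothing is
inferred from the data.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .instability import RepeatTrace

logger = logging.getLogger(__name__)

#: canonical column names; a column_map may rename them per export dialect
CANONICAL_COLUMNS = ("sample", "tissue", "size_bp", "height")

VALID_TISSUES = ("tail", "striatum", "liver", "other")


class PeakTableError(ValueError):
    """Malformed peak table (bad value, duplicate peak); carries line numbers."""


class ConfigError(ValueError):
    """Missing or inconsistent configuration (e.g. absent column)."""


@dataclass(frozen=True)
class PeakTableRow:
    sample_id: str
    tissue: str
    size_bp: float
    height: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "size_bp", float(self.size_bp))
        object.__setattr__(self, "height", float(self.height))
        if self.size_bp <= 0:
            raise PeakTableError(f"size_bp must be > 0, got {self.size_bp}")
        if self.height < 0:
            raise PeakTableError(f"height must be >= 0, got {self.height}")


@dataclass(frozen=True)
class SizeCalibration:
    """Linear bp -> repeat-count mapping anchored on a control of known size.

    ``anchor_size_bp`` is the called fragment size of a control DNA whose
    repeat length ``anchor_cag`` is known; ``bp_per_repeat`` is the slope
    (3 bp for a trinucleotide repeat).
    """

    anchor_cag: int
    anchor_size_bp: float
    bp_per_repeat: float = 3.0

    def __post_init__(self) -> None:
        if self.anchor_cag <= 0:
            raise ConfigError(f"anchor_cag must be positive, got {self.anchor_cag}")
        if self.bp_per_repeat <= 0:
            raise ConfigError(
                f"bp_per_repeat must be positive, got {self.bp_per_repeat}"
            )


def cag_from_size(size_bp: float, cal: SizeCalibration) -> int:
    """Convert a fragment size to an integer repeat count.

    Linear in size with slope 1/bp_per_repeat, rounded to the nearest
    integer with ties rounding up (toward the longer repeat).
    """
    delta = (size_bp - cal.anchor_size_bp) / cal.bp_per_repeat
    cag = cal.anchor_cag + math.floor(delta + 0.5)
    if cag < 1:
        raise PeakTableError(
            f"size {size_bp} bp maps to non-positive repeat count {cag}"
        )
    return int(cag)


def _resolve_columns(
    header: Sequence[str], column_map: Optional[Mapping[str, str]]
) -> dict[str, int]:
    column_map = dict(column_map or {})
    index: dict[str, int] = {}
    for canon in CANONICAL_COLUMNS:
        name = column_map.get(canon, canon)
        if name not in header:
            raise ConfigError(
                f"peak table is missing column {name!r} (for field {canon!r}); "
                f"header has {list(header)}"
            )
        index[canon] = header.index(name)
    return index


def read_peak_table(
    path: str | Path, column_map: Optional[Mapping[str, str]] = None
) -> list[PeakTableRow]:
    """Parse a tab-delimited peak table into rows, in file order.

    ``column_map`` maps the canonical field names (``sample``, ``tissue``,
    ``size_bp``, ``height``) to the column names actually present, so
    different export dialects parse without code changes.  Malformed rows
    raise :class:`PeakTableError` naming the offending line.
    """
    path = Path(path)
    rows: list[PeakTableRow] = []
    seen: set[tuple[str, str, float]] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise PeakTableError(f"{path}: empty file, expected a header row")
        idx = _resolve_columns(header, column_map)
        for lineno, rec in enumerate(reader, start=2):
            if not rec or all(not f.strip() for f in rec):
                continue
            try:
                sample = rec[idx["sample"]].strip()
                tissue = rec[idx["tissue"]].strip().lower()
                size_bp = float(rec[idx["size_bp"]])
                height = float(rec[idx["height"]])
            except (IndexError, ValueError) as exc:
                raise PeakTableError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if tissue not in VALID_TISSUES:
                logger.warning(
                    "%s:%d: unknown tissue %r, treating as 'other'",
                    path, lineno, tissue,
                )
                tissue = "other"
            try:
                row = PeakTableRow(sample, tissue, size_bp, height)
            except PeakTableError as exc:
                raise PeakTableError(f"{path}:{lineno}: {exc}") from exc
            key = (sample, tissue, size_bp)
            if key in seen:
                raise PeakTableError(
                    f"{path}:{lineno}: duplicate peak {key} within file"
                )
            seen.add(key)
            rows.append(row)
    return rows


def write_peak_table(
    rows: Iterable[PeakTableRow], path: str | Path
) -> None:
    """Write rows in the same tab-delimited dialect read_peak_table parses."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for r in rows:
            writer.writerow(
                [r.sample_id, r.tissue, repr(float(r.size_bp)), repr(float(r.height))]
            )


def build_trace(
    rows: Sequence[PeakTableRow],
    cal: SizeCalibration,
    constitutive_cag: Optional[int] = None,
) -> RepeatTrace:
    """Assemble one RepeatTrace from the rows of a single sample x tissue.

    Fragment sizes are converted to integer repeat counts; rows rounding to
    the same repeat count have their heights summed (total height is
    conserved).  All rows must share one sample id and tissue.
    """
    if not rows:
        raise PeakTableError("cannot build a trace from zero rows")
    ids = {r.sample_id for r in rows}
    tissues = {r.tissue for r in rows}
    if len(ids) > 1 or len(tissues) > 1:
        raise PeakTableError(
            f"rows mix samples/tissues: samples={sorted(ids)}, tissues={sorted(tissues)}"
        )
    peaks: dict[int, float] = {}
    for r in rows:
        cag = cag_from_size(r.size_bp, cal)
        if cag in peaks:
            logger.debug(
                "sample %s/%s: merging %.2f bp into CAG %d (height %+.1f)",
                r.sample_id, r.tissue, r.size_bp, cag, r.height,
            )
        peaks[cag] = peaks.get(cag, 0.0) + r.height
    return RepeatTrace(
        peaks=peaks,
        sample_id=rows[0].sample_id,
        tissue=rows[0].tissue,
        constitutive_cag=constitutive_cag,
    )


def group_rows(
    rows: Iterable[PeakTableRow],
) -> dict[tuple[str, str], list[PeakTableRow]]:
    """Split a parsed table into per-(sample, tissue) row lists, file order."""
    grouped: dict[tuple[str, str], list[PeakTableRow]] = {}
    for r in rows:
        grouped.setdefault((r.sample_id, r.tissue), []).append(r)
    return grouped
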