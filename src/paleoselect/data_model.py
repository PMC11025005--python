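"""Core data structures and delimited-text I/O for fossil occurrence data.

This module defines the stratigraphic frame (:class:`StageSequence`), the
row-level record types (:class:`OccurrenceRecord`, :class:`SizeRecord`), the
per-genus aggregation (:class:`GenusSummary`), and the readers/writers for
the CSV/TSV formats the rest of the pipeline consumes.

Conventions
-----------
* Stage sequences are ordered oldest to youngest; the focal extinction
  boundary sits between ``boundary_index`` and ``boundary_index + 1``.
* A genus's boundary fate is classified from its sampled stratigraphic
  range: extinct if its last appearance is at or before the boundary stage,
  survivor if it is also sampled after the boundary, and undefined (excluded
  from extinction tallies) if it first appears after the boundary.
* Readers are permissive by default: malformed rows are rejected with a
  recorded reason and line number rather than aborting the run.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: Default column names for occurrence tables (PBDB-style exports can be
#: adapted by overriding this mapping).
DEFAULT_OCCURRENCE_COLUMNS: dict[str, str] = {
    "genus": "genus",
    "clade": "clade",
    "interval": "stage",
    "locality": "locality",
    "paleolat": "paleolat",
    "paleolng": "paleolng",
}

DEFAULT_SIZE_COLUMNS: dict[str, str] = {
    "species": "species",
    "genus": "genus",
    "clade": "clade",
    "interval": "stage",
    "max_length": "max_length_mm",
}


class DataError(ValueError):
    """A hard data/configuration error that should abort the run."""


@dataclass(frozen=True)
class StageSequence:
    """An ordered sequence of stratigraphic intervals with a focal boundary.

    Parameters
    ----------
    names
        Interval identifiers, ordered oldest to youngest. Must be unique
        and at least two.
    boundary_index
        Index ``b`` such that the extinction boundary lies between
        ``names[b]`` and ``names[b + 1]``. ``names[b]`` is the boundary
        (pre-extinction cohort) stage.
    """

    names: tuple[str, ...]
    boundary_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) < 2:
            raise DataError("a stage sequence needs at least 2 intervals")
        if len(set(self.names)) != len(self.names):
            raise DataError(f"duplicate stage names in {self.names}")
        if not 0 <= self.boundary_index < len(self.names) - 1:
            raise DataError(
                f"boundary_index {self.boundary_index} must satisfy "
                f"0 <= b < {len(self.names) - 1}"
            )

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise DataError(f"interval {name!r} not in stage sequence") from None

    @property
    def boundary_stage(self) -> str:
        """The last pre-extinction stage (e.g. the Changhsingian)."""
        return self.names[self.boundary_index]

    @property
    def supports_rate_estimators(self) -> bool:
        """Three-timer / gap-filler estimation needs at least 4 intervals."""
        return len(self.names) >= 4


#: The minimal two-stage frame around the Permian-Triassic boundary.
PT_MINIMAL_STAGES = StageSequence(("Changhsingian", "Induan"), 0)

#: A six-stage frame straddling the Permian-Triassic boundary, long enough
#: for the sampling-standardized rate estimators.
PT_SIX_STAGES = StageSequence(
    ("Capitanian", "Wuchiapingian", "Changhsingian", "Induan", "Olenekian", "Anisian"),
    boundary_index=2,
)


@dataclass(frozen=True)
class OccurrenceRecord:
    """One fossil occurrence of a genus in an interval at a locality."""

    genus: str
    clade: str
    interval: str
    locality: str | None = None
    paleolat: float | None = None
    paleolng: float | None = None

    def validate(self, stages: StageSequence) -> None:
        if not self.genus:
            raise DataError("empty genus")
        if not self.clade:
            raise DataError("empty clade")
        if self.interval not in stages:
            raise DataError(f"interval {self.interval!r} not in stage sequence")
        if (self.paleolat is None) != (self.paleolng is None):
            raise DataError("paleolat/paleolng must be given together")
        if self.paleolat is not None:
            if not -90.0 <= self.paleolat <= 90.0:
                raise DataError(f"paleolat {self.paleolat} out of [-90, 90]")
            if not -180.0 <= self.paleolng <= 180.0:  # type: ignore[operator]
                raise DataError(f"paleolng {self.paleolng} out of [-180, 180]")


@dataclass(frozen=True)
class SizeRecord:
    """Maximum body length (mm) for one species in one interval."""

    species: str
    genus: str
    clade: str
    interval: str
    max_length: float

    def validate(self, stages: StageSequence) -> None:
        if not self.species or not self.genus or not self.clade:
            raise DataError("species, genus and clade must be non-empty")
        if self.interval not in stages:
            raise DataError(f"interval {self.interval!r} not in stage sequence")
        if not (self.max_length > 0 and math.isfinite(self.max_length)):
            raise DataError(f"max_length must be a positive real, got {self.max_length}")


@dataclass
class GenusSummary:
    """Per-genus aggregation over its occurrence records.

    ``extinct_at_boundary`` is ``True``/``False`` for genera in the boundary
    cohort and ``None`` for genera excluded from the extinction tally
    (post-boundary originators, or — under the default cohort rule — genera
    not sampled in the boundary stage itself).
    """

    genus: str
    clade: str
    intervals_present: frozenset[str]
    n_occurrences: int
    extinct_at_boundary: bool | None
    geo_range: float | None = None
    traits: "object | None" = None  # TraitAssignment, attached by assign_traits

    def interval_indices(self, stages: StageSequence) -> tuple[int, ...]:
        return tuple(sorted(stages.index(n) for n in self.intervals_present))


@dataclass(frozen=True)
class RowReject:
    """A rejected input row with its 1-based line number and reason."""

    line: int
    reason: str


@dataclass
class ReadResult:
    """Validated records plus an audit trail of rejected rows."""

    records: list
    rejects: list[RowReject] = field(default_factory=list)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def _open_table(path: str | Path, required: Sequence[str], column_map: Mapping[str, str]):
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    delim = _sniff_delimiter(path)
    fh = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(fh, delimiter=delim)
    header = reader.fieldnames or []
    missing = [column_map[k] for k in required if column_map[k] not in header]
    if missing:
        fh.close()
        raise DataError(f"{path}: missing required column(s) {missing}; header = {header}")
    return fh, reader


def _opt_float(raw: str | None) -> float | None:
    if raw is None or raw.strip() == "":
        return None
    return float(raw)


def read_occurrences(
    path: str | Path,
    stages: StageSequence,
    column_map: Mapping[str, str] | None = None,
    strict: bool = False,
) -> ReadResult:
    """Read an occurrence table (CSV or TSV, auto-detected; header required).

    Parameters
    ----------
    path
        Delimited-text file with one row per occurrence.
    stages
        Stage sequence; rows whose interval is not a member are rejected
        (or, in strict mode, abort the read).
    column_map
        Logical-field -> column-name mapping; defaults to
        :data:`DEFAULT_OCCURRENCE_COLUMNS`. ``locality``/``paleolat``/
        ``paleolng`` columns are optional.
    strict
        If True, any malformed row raises :class:`DataError`; otherwise the
        row is skipped and recorded in :attr:`ReadResult.rejects`.

    Returns
    -------
    ReadResult
        Records in file order, plus the reject report.
    """
    cmap = dict(DEFAULT_OCCURRENCE_COLUMNS)
    if column_map:
        cmap.update(column_map)
    fh, reader = _open_table(path, ("genus", "clade", "interval"), cmap)
    records: list[OccurrenceRecord] = []
    rejects: list[RowReject] = []
    with fh:
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = OccurrenceRecord(
                    genus=(row.get(cmap["genus"]) or "").strip(),
                    clade=(row.get(cmap["clade"]) or "").strip(),
                    interval=(row.get(cmap["interval"]) or "").strip(),
                    locality=(row.get(cmap["locality"]) or "").strip() or None,
                    paleolat=_opt_float(row.get(cmap["paleolat"])),
                    paleolng=_opt_float(row.get(cmap["paleolng"])),
                )
                rec.validate(stages)
            except (DataError, ValueError) as exc:
                if strict:
                    raise DataError(f"{path} line {lineno}: {exc}") from exc
                logger.warning("%s line %d rejected: %s", path, lineno, exc)
                rejects.append(RowReject(lineno, str(exc)))
                continue
            records.append(rec)
    return ReadResult(records, rejects)


def read_sizes(
    path: str | Path,
    stages: StageSequence,
    column_map: Mapping[str, str] | None = None,
    strict: bool = False,
) -> ReadResult:
    """Read a body-size table (species, genus, clade, stage, max length mm)."""
    cmap = dict(DEFAULT_SIZE_COLUMNS)
    if column_map:
        cmap.update(column_map)
    fh, reader = _open_table(path, ("species", "genus", "clade", "interval", "max_length"), cmap)
    records: list[SizeRecord] = []
    rejects: list[RowReject] = []
    with fh:
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = SizeRecord(
                    species=(row.get(cmap["species"]) or "").strip(),
                    genus=(row.get(cmap["genus"]) or "").strip(),
                    clade=(row.get(cmap["clade"]) or "").strip(),
                    interval=(row.get(cmap["interval"]) or "").strip(),
                    max_length=float(row.get(cmap["max_length"]) or "nan"),
                )
                rec.validate(stages)
            except (DataError, ValueError) as exc:
                if strict:
                    raise DataError(f"{path} line {lineno}: {exc}") from exc
                logger.warning("%s line %d rejected: %s", path, lineno, exc)
                rejects.append(RowReject(lineno, str(exc)))
                continue
            records.append(rec)
    return ReadResult(records, rejects)


def write_occurrences(records: Iterable[OccurrenceRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["genus", "clade", "stage", "locality", "paleolat", "paleolng"])
        for r in records:
            w.writerow(
                [
                    r.genus,
                    r.clade,
                    r.interval,
                    r.locality or "",
                    "" if r.paleolat is None else repr(r.paleolat),
                    "" if r.paleolng is None else repr(r.paleolng),
                ]
            )


def write_sizes(records: Iterable[SizeRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "genus", "clade", "stage", "max_length_mm"])
        for r in records:
            w.writerow([r.species, r.genus, r.clade, r.interval, repr(r.max_length)])


def build_genus_summaries(
    occurrences: Sequence[OccurrenceRecord],
    stages: StageSequence,
    cohort: str = "boundary_interval",
) -> list[GenusSummary]:
    """Aggregate occurrences into per-genus summaries with boundary fates.

    Parameters
    ----------
    occurrences
        Validated occurrence records.
    stages
        The stratigraphic frame.
    cohort
        Which genera enter the extinction denominator:

        ``"boundary_interval"`` (default)
            genera sampled in the boundary stage itself;
        ``"range_through"``
            genera whose sampled range (first to last appearance) includes
            the boundary stage, i.e. the default cohort plus survivors not
            sampled in the boundary stage.

    Returns
    -------
    list of GenusSummary
        One per distinct genus, sorted by genus name. Genera outside the
        chosen cohort (including post-boundary originators) carry
        ``extinct_at_boundary = None``.

    Raises
    ------
    DataError
        If the occurrence list is empty, a genus maps to more than one
        clade, or ``cohort`` is unknown.
    """
    if not occurrences:
        raise DataError("no occurrences given")
    if cohort not in ("boundary_interval", "range_through"):
        raise DataError(f"unknown cohort rule {cohort!r}")

    by_genus: dict[str, list[OccurrenceRecord]] = {}
    for rec in occurrences:
        by_genus.setdefault(rec.genus, []).append(rec)

    conflicts = {
        g: sorted({r.clade for r in recs})
        for g, recs in by_genus.items()
        if len({r.clade for r in recs}) > 1
    }
    if conflicts:
        raise DataError(f"genera assigned to multiple clades: {conflicts}")

    b = stages.boundary_index
    out: list[GenusSummary] = []
    for genus in sorted(by_genus):
        recs = by_genus[genus]
        present = frozenset(r.interval for r in recs)
        idx = sorted(stages.index(n) for n in present)
        first, last = idx[0], idx[-1]
        if first > b:
            status: bool | None = None  # post-boundary originator
        elif cohort == "boundary_interval":
            status = (last <= b) if b in idx else None
        else:  # range_through: sampled range must span the boundary stage
            status = (last <= b) if (first <= b <= last) else None
        out.append(
            GenusSummary(
                genus=genus,
                clade=recs[0].clade,
                intervals_present=present,
                n_occurrences=len(recs),
                extinct_at_boundary=status,
            )
        )
    return out


def _haversine_km(lat1: float, lng1: float, lat2: float, lng2: float) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lng2 - lng1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def compute_geographic_range(
    records: Sequence[OccurrenceRecord], method: str = "n_localities"
) -> float:
    """Geographic range of one genus from its occurrence records.

    ``"n_localities"`` counts distinct locality identifiers (records without
    a locality are binned by their coordinates, or pooled into a single
    anonymous locality). ``"max_gcd"`` is the maximum great-circle distance
    in km (spherical Earth, R = 6371 km) over all pairs of records with
    paleocoordinates; a single point gives 0.
    """
    if not records:
        raise DataError("no records for geographic range")
    if method == "n_localities":
        keys = {
            r.locality if r.locality is not None else (r.paleolat, r.paleolng)
            for r in records
        }
        return float(len(keys))
    if method == "max_gcd":
        pts = [(r.paleolat, r.paleolng) for r in records if r.paleolat is not None]
        if not pts:
            raise DataError("max_gcd requested but no records have paleocoordinates")
        best = 0.0
        uniq = sorted(set(pts))  # type: ignore[type-var]
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                best = max(best, _haversine_km(*uniq[i], *uniq[j]))  # type: ignore[misc]
        return best
    raise DataError(f"unknown geographic-range method {method!r}")


def attach_geographic_ranges(
    summaries: Sequence[GenusSummary],
    occurrences: Sequence[OccurrenceRecord],
    method: str = "n_localities",
) -> list[GenusSummary]:
    """Return copies of ``summaries`` with ``geo_range`` filled in."""
    by_genus: dict[str, list[OccurrenceRecord]] = {}
    for rec in occurrences:
        by_genus.setdefault(rec.genus, []).append(rec)
    return [
        replace(s, geo_range=compute_geographic_range(by_genus[s.genus], method))
        for s in summaries
    ]
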