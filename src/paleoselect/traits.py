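"""Clade-level physiological trait assignments.

Marine clades are binned by the respiratory protein they use to move O2
from seawater into their tissues: simple diffusion (no carrier pigment),
hemerythrin, hemocyanin, or hemoglobin. The four groups are ranked by
O2-carrying capacity — hemerythrin's pigment concentration and Hill
coefficient are far below those of hemocyanin and hemoglobin, and the
diffusion group has no carrier at all — so the default capacity covariate
is the ordinal rank 0..3. Quantitative capacities (e.g. pigment
concentrations) can be supplied instead, provided they respect the same
ordering.

The packaged default table also codes circulatory system (cephalopods,
conodonts and fish closed; other shelled invertebrates open; diffusion
taxa none), skeletal mineralogy, motility, and a binary physiological
buffering flag, all at clade level. Extinct members of a clade are assumed
to share the protein type of its modern members (phylogenetic bracketing).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .data_model import DataError, GenusSummary

logger = logging.getLogger(__name__)

PROTEIN_GROUPS = ("diffusion", "hemerythrin", "hemocyanin", "hemoglobin")
CIRCULATORY = ("none", "open", "closed")
MINERALOGY = ("carbonate", "siliceous", "phosphatic", "unmineralized", "other")

#: Common plural / variant spellings accepted by lookups.
_ALIASES = {
    "foraminifer": "foraminifera",
    "foram": "foraminifera",
    "radiolaria": "radiolarian",
    "bryozoa": "bryozoan",
    "bivalve-p": "bivalve_protobranch",
    "bivalve-non-p": "bivalve_non_protobranch",
    "bivalve-non_p": "bivalve_non_protobranch",
}


_CANONICAL = frozenset(
    {
        "foraminifera", "radiolarian", "sponge", "coral", "brachiopod",
        "bryozoan", "ostracod", "gastropod", "cephalopod",
        "bivalve_protobranch", "bivalve_non_protobranch", "echinoderm",
        "conodont", "fish",
    }
)


def normalize_clade(name: str) -> str:
    key = name.strip().lower().replace(" ", "_")
    if key in _CANONICAL:
        return key
    if key in _ALIASES:
        return _ALIASES[key]
    if key.endswith("s"):
        stem = key[:-1]
        if stem in _CANONICAL:
            return stem
        if stem in _ALIASES:
            return _ALIASES[stem]
    return key


@dataclass(frozen=True)
class TraitAssignment:
    """Clade-level physiological covariates."""

    clade: str
    protein_group: str
    o2_capacity: float
    circulatory: str
    mineralogy: str
    motility: str
    buffered: str

    def __post_init__(self) -> None:
        if self.protein_group not in PROTEIN_GROUPS:
            raise DataError(f"unknown protein group {self.protein_group!r}")
        if self.circulatory not in CIRCULATORY:
            raise DataError(f"unknown circulatory system {self.circulatory!r}")
        if self.mineralogy not in MINERALOGY:
            raise DataError(f"unknown mineralogy {self.mineralogy!r}")
        if self.motility not in ("motile", "non_motile"):
            raise DataError(f"motility must be motile/non_motile, got {self.motility!r}")
        if self.buffered not in ("buffered", "unbuffered"):
            raise DataError(f"buffered must be buffered/unbuffered, got {self.buffered!r}")
        if self.protein_group == "diffusion" and self.circulatory != "none":
            raise DataError(
                f"{self.clade}: diffusion taxa have no circulatory system "
                f"(got {self.circulatory!r})"
            )

    @property
    def is_motile(self) -> bool:
        return self.motility == "motile"

    @property
    def is_buffered(self) -> bool:
        return self.buffered == "buffered"

    @property
    def is_carbonate(self) -> bool:
        return self.mineralogy == "carbonate"


def _parse_rows(rows: Iterable[dict]) -> list[TraitAssignment]:
    table = [
        TraitAssignment(
            clade=normalize_clade(row["clade"]),
            protein_group=row["protein_group"].strip(),
            o2_capacity=float(row["o2_capacity"]),
            circulatory=row["circulatory"].strip(),
            mineralogy=row["mineralogy"].strip(),
            motility=row["motility"].strip(),
            buffered=row["buffered"].strip(),
        )
        for row in rows
    ]
    seen: set[str] = set()
    for t in table:
        if t.clade in seen:
            raise DataError(f"duplicate clade {t.clade!r} in trait table")
        seen.add(t.clade)
    return table


def default_trait_table() -> list[TraitAssignment]:
    """The packaged clade -> trait mapping (14 Permian-Triassic marine clades)."""
    src = resources.files("paleoselect.data").joinpath("default_traits.csv")
    with src.open("r", encoding="utf-8") as fh:
        return _parse_rows(csv.DictReader(fh))


def read_trait_table(path: str | Path) -> list[TraitAssignment]:
    """Read a user trait table (CSV, same columns as the packaged default)."""
    with open(path, newline="", encoding="utf-8") as fh:
        return _parse_rows(csv.DictReader(fh))


def lookup(table: Sequence[TraitAssignment], clade: str) -> TraitAssignment:
    key = normalize_clade(clade)
    for t in table:
        if t.clade == key:
            return t
    raise DataError(f"clade {clade!r} not in trait table")


def capacity_values(
    mode: str = "ordinal", custom: Mapping[str, float] | None = None
) -> dict[str, float]:
    """O2-carrying capacity per protein group.

    ``"ordinal"`` returns ranks 0..3 in the order diffusion < hemerythrin <
    hemocyanin < hemoglobin. ``"custom"`` accepts user-supplied quantitative
    values covering all four groups; values must be strictly increasing in
    that same order, which is the one property the group ranking guarantees.
    """
    if mode == "ordinal":
        return {g: float(i) for i, g in enumerate(PROTEIN_GROUPS)}
    if mode != "custom":
        raise DataError(f"capacity mode must be 'ordinal' or 'custom', got {mode!r}")
    if custom is None:
        raise DataError("custom capacity mode needs a mapping")
    missing = [g for g in PROTEIN_GROUPS if g not in custom]
    if missing:
        raise DataError(f"custom capacities missing groups: {missing}")
    vals = [float(custom[g]) for g in PROTEIN_GROUPS]
    if not all(a < b for a, b in zip(vals, vals[1:])):
        raise DataError(
            "custom capacities must be strictly increasing over "
            f"{PROTEIN_GROUPS}, got {vals}"
        )
    return {g: float(custom[g]) for g in PROTEIN_GROUPS}


def apply_capacities(
    table: Sequence[TraitAssignment], capacities: Mapping[str, float]
) -> list[TraitAssignment]:
    """Return a trait table with o2_capacity replaced per protein group."""
    return [replace(t, o2_capacity=capacities[t.protein_group]) for t in table]


def assign_traits(
    summaries: Sequence[GenusSummary],
    table: Sequence[TraitAssignment] | None = None,
    strict: bool = True,
) -> tuple[list[GenusSummary], list[GenusSummary]]:
    """Attach clade traits to genus summaries.

    Returns ``(annotated, dropped)``. In strict mode an unmapped clade is a
    hard error; in permissive mode its genera are dropped and logged.
    Assignment is a pure function of the clade name, so genus order cannot
    change any annotation.
    """
    if table is None:
        table = default_trait_table()
    by_clade = {t.clade: t for t in table}
    annotated: list[GenusSummary] = []
    dropped: list[GenusSummary] = []
    for s in summaries:
        t = by_clade.get(normalize_clade(s.clade))
        if t is None:
            if strict:
                raise DataError(f"clade {s.clade!r} (genus {s.genus}) not in trait table")
            dropped.append(s)
            continue
        annotated.append(replace(s, traits=t))
    if dropped:
        logger.warning(
            "dropped %d genera from %d unmapped clades",
            len(dropped),
            len({s.clade for s in dropped}),
        )
    return annotated, dropped
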