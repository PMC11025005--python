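import numpy as np
import pytest

from paleoselect.data_model import GenusSummary, OccurrenceRecord, StageSequence
from paleoselect.traits import default_trait_table, lookup


@pytest.fixture(scope="session")
def five_stages() -> StageSequence:
    return StageSequence(("s1", "s2", "s3", "s4", "s5"), boundary_index=2)


@pytest.fixture(scope="session")
def pt_stages() -> StageSequence:
    return StageSequence(("Changhsingian", "Induan"), boundary_index=0)


@pytest.fixture(scope="session")
def trait_table():
    return default_trait_table()


def presence_to_summaries(presence: np.ndarray, stages: StageSequence) -> list[GenusSummary]:
    """Turn a boolean taxa-by-intervals matrix into genus summaries."""
    out = []
    for g, row in enumerate(presence):
        idx = np.flatnonzero(row)
        if idx.size == 0:
            continue
        out.append(
            GenusSummary(
                genus=f"g{g:03d}",
                clade="toyclade",
                intervals_present=frozenset(stages.names[i] for i in idx),
                n_occurrences=int(idx.size),
                extinct_at_boundary=None,
            )
        )
    return out


def make_annotated(statuses: dict[str, list[bool | None]], table=None) -> list[GenusSummary]:
    """Build annotated summaries: clade -> list of boundary statuses."""
    table = table or default_trait_table()
    out = []
    for clade, flags in statuses.items():
        t = lookup(table, clade)
        for i, st in enumerate(flags):
            out.append(
                GenusSummary(
                    genus=f"{clade}_{i}",
                    clade=clade,
                    intervals_present=frozenset({"Changhsingian"}),
                    n_occurrences=1,
                    extinct_at_boundary=st,
                    geo_range=1.0,
                    traits=t,
                )
            )
    return out


def occurrence(genus, clade, interval, locality=None, lat=None, lng=None):
    return OccurrenceRecord(genus, clade, interval, locality, lat, lng)
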