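import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleoselect.data_model import (
    DataError,
    OccurrenceRecord,
    StageSequence,
    build_genus_summaries,
    compute_geographic_range,
    read_occurrences,
    read_sizes,
    write_occurrences,
)
from conftest import occurrence
from oracles import max_gcd_oracle


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


class TestStageSequence:
    def test_validation(self):
        with pytest.raises(DataError):
            StageSequence(("a",), 0)
        with pytest.raises(DataError):
            StageSequence(("a", "a"), 0)
        with pytest.raises(DataError):
            StageSequence(("a", "b"), 1)  # boundary must be < len-1
        seq = StageSequence(("a", "b", "c", "d"), 1)
        assert seq.boundary_stage == "b"
        assert seq.supports_rate_estimators
        assert not StageSequence(("a", "b"), 0).supports_rate_estimators


class TestReaders:
    def test_well_formed_file(self, tmp_path, pt_stages):
        p = write_lines(
            tmp_path / "occ.csv",
            [
                "genus,clade,stage,locality,paleolat,paleolng",
                "Ga,brachiopod,Changhsingian,L1,10,20",
                "Gb,brachiopod,Induan,L2,,",
                "Gc,gastropod,Changhsingian,,,",
            ],
        )
        res = read_occurrences(p, pt_stages)
        assert len(res.records) == 3 and not res.rejects
        assert res.records[0].paleolat == 10.0
        assert [r.genus for r in res] == ["Ga", "Gb", "Gc"]  # file order

    def test_tsv_autodetect(self, tmp_path, pt_stages):
        p = write_lines(
            tmp_path / "occ.tsv",
            ["genus\tclade\tstage", "Ga\tbrachiopod\tChanghsingian"],
        )
        assert len(read_occurrences(p, pt_stages)) == 1

    def test_rejects_report_line_numbers(self, tmp_path, pt_stages):
        rows = ["genus,clade,stage"]
        rows += [f"G{i},coral,Changhsingian" for i in range(8)]
        rows.insert(4, "Gbad,coral,Olenekian")  # line 5: unknown interval
        rows.insert(7, ",coral,Induan")  # line 8: empty genus
        p = write_lines(tmp_path / "occ.csv", rows)
        res = read_occurrences(p, pt_stages)
        assert len(res.records) == 8
        assert [r.line for r in res.rejects] == [5, 8]

    def test_strict_mode_raises(self, tmp_path, pt_stages):
        p = write_lines(
            tmp_path / "occ.csv",
            ["genus,clade,stage", "Ga,coral,Olenekian"],
        )
        with pytest.raises(DataError, match="Olenekian"):
            read_occurrences(p, pt_stages, strict=True)

    def test_missing_column_is_config_error(self, tmp_path, pt_stages):
        p = write_lines(tmp_path / "occ.csv", ["genus,stage", "Ga,Changhsingian"])
        with pytest.raises(DataError, match="clade"):
            read_occurrences(p, pt_stages)

    def test_column_map_override(self, tmp_path, pt_stages):
        p = write_lines(
            tmp_path / "pbdb.csv",
            ["accepted_name,phylum,early_interval", "Ga,brachiopod,Changhsingian"],
        )
        res = read_occurrences(
            p, pt_stages,
            column_map={"genus": "accepted_name", "clade": "phylum",
                        "interval": "early_interval"},
        )
        assert res.records[0].genus == "Ga"

    def test_read_sizes_validation(self, tmp_path, pt_stages):
        p = write_lines(
            tmp_path / "sz.csv",
            [
                "species,genus,clade,stage,max_length_mm",
                "Sa,Ga,brachiopod,Changhsingian,12.5",
                "Sb,Gb,brachiopod,Changhsingian,0",
                "Sc,Gc,gastropod,Induan,3.1",
                "Sd,Gd,gastropod,Induan,notanumber",
            ],
        )
        res = read_sizes(p, pt_stages)
        assert [r.max_length for r in res.records] == [12.5, 3.1]
        assert [r.line for r in res.rejects] == [3, 5]
        by_clade = {}
        for r in res.records:
            by_clade.setdefault(r.clade, 0)
            by_clade[r.clade] += 1
        assert by_clade == {"brachiopod": 1, "gastropod": 1}

    def test_roundtrip_identity(self, tmp_path, pt_stages):
        recs = [
            occurrence("Ga", "coral", "Changhsingian", "L1", 12.25, -33.5),
            occurrence("Gb", "coral", "Induan"),
            occurrence("Gc", "fish", "Induan", "L2"),
        ]
        path = tmp_path / "out.csv"
        write_occurrences(recs, path)
        back = read_occurrences(path, pt_stages)
        assert back.records == recs and not back.rejects


class TestGenusSummaries:
    def three_genus_toy(self):
        return [
            occurrence("A", "coral", "Changhsingian"),
            occurrence("B", "coral", "Changhsingian"),
            occurrence("B", "coral", "Induan"),
            occurrence("C", "coral", "Induan"),
        ]

    def test_boundary_fates(self, pt_stages):
        summ = {s.genus: s for s in build_genus_summaries(self.three_genus_toy(), pt_stages)}
        assert summ["A"].extinct_at_boundary is True
        assert summ["B"].extinct_at_boundary is False
        assert summ["C"].extinct_at_boundary is None
        cohort = [s for s in summ.values() if s.extinct_at_boundary is not None]
        assert len(cohort) == 2  # post-boundary originator excluded

    def test_multi_clade_genus_is_hard_error(self, pt_stages):
        recs = self.three_genus_toy() + [occurrence("A", "sponge", "Changhsingian")]
        with pytest.raises(DataError, match="A"):
            build_genus_summaries(recs, pt_stages)

    def test_range_through_includes_unsampled_survivor(self, five_stages):
        # present s2 and s4 only: spans the boundary stage s3 without being
        # sampled in it -> excluded by the default cohort, a survivor under
        # range-through
        recs = [occurrence("G", "coral", "s2"), occurrence("G", "coral", "s4")]
        default = build_genus_summaries(recs, five_stages)[0]
        through = build_genus_summaries(recs, five_stages, cohort="range_through")[0]
        assert default.extinct_at_boundary is None
        assert through.extinct_at_boundary is False

    @settings(max_examples=80, deadline=None)
    @given(
        st.lists(
            st.sets(st.integers(min_value=0, max_value=3), min_size=1),
            min_size=1,
            max_size=12,
        ),
        st.sampled_from(["boundary_interval", "range_through"]),
    )
    def test_cohort_partition(self, presences, cohort):
        """extinct + survivors + undefined always partition the genus list."""
        stages = StageSequence(("s1", "s2", "s3", "s4"), 1)
        recs = [
            occurrence(f"g{i}", "coral", stages.names[j])
            for i, pres in enumerate(presences)
            for j in pres
        ]
        summ = build_genus_summaries(recs, stages, cohort=cohort)
        assert len(summ) == len(presences)
        n_ext = sum(s.extinct_at_boundary is True for s in summ)
        n_surv = sum(s.extinct_at_boundary is False for s in summ)
        n_undef = sum(s.extinct_at_boundary is None for s in summ)
        assert n_ext + n_surv + n_undef == len(summ)


class TestGeographicRange:
    def test_single_locality(self):
        assert compute_geographic_range([occurrence("G", "c", "s", "L1")]) == 1.0

    def test_antipodal_points(self):
        recs = [
            occurrence("G", "c", "s", lat=0.0, lng=0.0),
            occurrence("G", "c", "s", lat=0.0, lng=180.0),
        ]
        assert compute_geographic_range(recs, "max_gcd") == pytest.approx(
            math.pi * 6371.0, abs=0.1
        )

    def test_matches_all_pairs_oracle(self):
        pts = [(10.0, 20.0), (-35.0, 140.0), (60.0, -90.0), (0.0, 0.0)]
        recs = [occurrence("G", "c", "s", lat=a, lng=b) for a, b in pts]
        got = compute_geographic_range(recs, "max_gcd")
        assert got == pytest.approx(max_gcd_oracle(pts), rel=1e-9)

    def test_permutation_and_duplicate_invariance(self):
        pts = [(10.0, 20.0), (-35.0, 140.0), (60.0, -90.0)]
        recs = [occurrence("G", "c", "s", lat=a, lng=b) for a, b in pts]
        base = compute_geographic_range(recs, "max_gcd")
        assert compute_geographic_range(recs[::-1], "max_gcd") == base
        assert compute_geographic_range(recs + [recs[0]], "max_gcd") == base

    def test_no_coordinates_error(self):
        with pytest.raises(DataError):
            compute_geographic_range([occurrence("G", "c", "s", "L1")], "max_gcd")


def test_coordinate_bounds_rejected(pt_stages):
    rec = OccurrenceRecord("G", "c", "Induan", None, 95.0, 0.0)
    with pytest.raises(DataError):
        rec.validate(pt_stages)
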