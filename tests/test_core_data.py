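"""Flow-record truth labeling, reach-length arithmetic, and metric computation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdamaw.core_data import (
    FlowRecord,
    IndicatorRecord,
    MetricMeta,
    MetricTable,
    Reach,
    StreamflowClass,
    TaxonObservation,
    Visit,
    classify_flow_record,
    compute_metrics,
    reach_length,
)


def _record(n_days: int, n_flowing: int) -> FlowRecord:
    dates = tuple(dt.date(2020, 1, 1) + dt.timedelta(days=i) for i in range(n_days))
    flowing = tuple(i < n_flowing for i in range(n_days))
    return FlowRecord(dates, flowing)


class TestClassifyFlowRecord:
    @pytest.mark.parametrize(
        "n_days, n_flowing, expected",
        [
            (365, 365, StreamflowClass.PERENNIAL),  # zero-flow fraction 0
            (365, 10, StreamflowClass.EPHEMERAL),  # 2.7% flowing days
            (365, 348, StreamflowClass.PERENNIAL),  # 17 zero days = 4.66% < 5%
            (100, 95, StreamflowClass.INTERMITTENT),  # exactly 5.0% zero-flow
            (100, 5, StreamflowClass.INTERMITTENT),  # exactly 5.0% flowing
            (100, 50, StreamflowClass.INTERMITTENT),
        ],
    )
    def test_five_percent_rule(self, n_days, n_flowing, expected):
        assert classify_flow_record(_record(n_days, n_flowing)) is expected

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_flow_record(FlowRecord((), ()))

    @given(n_flowing=st.integers(0, 365))
    @settings(max_examples=100, deadline=None)
    def test_partitions_all_records(self, n_flowing):
        # exactly one class; fewer-than-5% on both sides simultaneously is
        # impossible because the fractions sum to one
        cls = classify_flow_record(_record(365, n_flowing))
        f = n_flowing / 365
        if f < 0.05:
            assert cls is StreamflowClass.EPHEMERAL
        elif 1 - f < 0.05:
            assert cls is StreamflowClass.PERENNIAL
        else:
            assert cls is StreamflowClass.INTERMITTENT

    def test_dates_must_increase(self):
        d = dt.date(2020, 1, 1)
        with pytest.raises(ValueError, match="increasing"):
            FlowRecord((d, d), (True, True))


class TestReachLength:
    @pytest.mark.parametrize(
        "widths, expected",
        [((2, 2, 2), 80.0), ((10, 10, 10), 200.0), ((0.5, 0.5, 0.5), 40.0), ((1.5,), 60.0)],
    )
    def test_forty_times_mean_clamped(self, widths, expected):
        assert reach_length(widths) == pytest.approx(expected)

    def test_rejects_non_positive_width(self):
        with pytest.raises(ValueError, match="positive"):
            reach_length([2.0, 0.0])

    @given(st.lists(st.floats(0.01, 50), min_size=1, max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_always_in_bounds(self, widths):
        assert 40.0 <= reach_length(widths) <= 200.0


def _full_indicators(**overrides) -> IndicatorRecord:
    base = dict(
        hydrophyte_species_count=2,
        invertebrates=[],
        surface_flow_pct=10.0,
        algal_cover_livedead="2_10",
    )
    base.update(overrides)
    return IndicatorRecord(**base)


class TestComputeMetrics:
    def test_hand_counted_invertebrate_metrics(self):
        taxa = [
            TaxonObservation("Baetidae", 5, frozenset({"EPT", "mayfly"})),
            TaxonObservation("Chironomidae", 10, frozenset({"GOLD"})),
            TaxonObservation("Physidae", 2, frozenset({"noninsect", "GOLD"})),
        ]
        visit = Visit("R1", 1, indicators=_full_indicators(invertebrates=taxa))
        table = compute_metrics([visit])
        row = table.data.loc[("R1", 1)]
        assert row["TotalAbundance"] == 17
        assert row["Richness"] == 3
        assert row["EPT_taxa"] == 1
        assert row["EPT_relabd"] == pytest.approx(5 / 17)
        assert row["Noninsect_reltaxa"] == pytest.approx(1 / 3)
        assert row["mayfly_abundance"] == 5
        assert row["GOLD_relabd"] == pytest.approx(12 / 17)

    def test_empty_sample_convention(self):
        visit = Visit("R1", 1, indicators=_full_indicators(invertebrates=[]))
        row = compute_metrics([visit]).data.loc[("R1", 1)]
        assert row["TotalAbundance"] == 0
        assert row["Richness"] == 0
        # 0/0 relative metrics are defined as 0
        for m in ("EPT_relabd", "EPT_reltaxa", "Noninsect_relabund", "GOLDOCH_reltaxa"):
            assert row[m] == 0.0

    def test_morphotaxon_tally_capped_at_ten(self):
        taxa = [TaxonObservation("Baetidae", 25, frozenset({"EPT"}))]
        row = compute_metrics(
            [Visit("R1", 1, indicators=_full_indicators(invertebrates=taxa))]
        ).data.loc[("R1", 1)]
        assert row["TotalAbundance"] == 10
        assert row["EPT_abundance"] == 10

    def test_incomplete_visit_excluded_with_reason(self):
        good = Visit("R1", 1, indicators=_full_indicators())
        bad = Visit("R2", 1, indicators=_full_indicators(hydrophyte_species_count=None))
        table = compute_metrics([good, bad])
        assert ("R2", 1) not in table.data.index
        assert any(key == ("R2", 1) for key, _ in table.exclusions)

    def test_extra_geospatial_columns_passed_through(self):
        visit = Visit("R1", 1, indicators=_full_indicators())
        extra = pd.DataFrame(
            {"ppt_annual": [412.0]},
            index=pd.MultiIndex.from_tuples([("R1", 1)]),
        )
        table = compute_metrics([visit], extra_columns=extra)
        assert table.data.loc[("R1", 1), "ppt_annual"] == 412.0
        assert table.metadata["ppt_annual"].metric_type == "geospatial"

    @given(
        counts=st.lists(st.integers(0, 30), min_size=0, max_size=6),
        ept_flags=st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_relative_metrics_are_fractions(self, counts, ept_flags):
        taxa = [
            TaxonObservation(
                f"T{i}",
                c,
                frozenset({"EPT"}) if ept_flags.draw(st.booleans()) else frozenset(),
            )
            for i, c in enumerate(counts)
        ]
        row = compute_metrics(
            [Visit("R1", 1, indicators=_full_indicators(invertebrates=taxa))]
        ).data.loc[("R1", 1)]
        assert 0.0 <= row["EPT_relabd"] <= 1.0
        assert 0.0 <= row["EPT_reltaxa"] <= 1.0
        if row["TotalAbundance"] > 0:
            assert row["EPT_relabd"] == pytest.approx(
                row["EPT_abundance"] / row["TotalAbundance"]
            )

    def test_flow_state_derived_from_surface_flow(self):
        dry = Visit("R1", 1, indicators=_full_indicators(surface_flow_pct=0.0))
        wet = Visit("R2", 1, indicators=_full_indicators(surface_flow_pct=5.0))
        assert dry.flow_state == "dry"
        assert wet.flow_state == "flowing"


class TestDomainTypes:
    def test_class_ordering_by_duration(self):
        assert StreamflowClass.EPHEMERAL < StreamflowClass.INTERMITTENT
        assert StreamflowClass.INTERMITTENT < StreamflowClass.PERENNIAL

    def test_reach_validates_subregion(self):
        with pytest.raises(ValueError, match="subregion"):
            Reach("R1", "OR", StreamflowClass.PERENNIAL)

    def test_metric_table_rejects_duplicate_keys(self):
        idx = pd.MultiIndex.from_tuples([("R1", 1), ("R1", 1)])
        data = pd.DataFrame({"x": [1.0, 2.0]}, index=idx)
        with pytest.raises(ValueError, match="duplicate"):
            MetricTable(data, {"x": MetricMeta("biological")})

    def test_direct_water_only_on_hydrological(self):
        with pytest.raises(ValueError, match="direct_water"):
            MetricMeta("biological", direct_water=True)

    def test_select_metrics_filters_types(self):
        idx = pd.MultiIndex.from_tuples([("R1", 1)])
        data = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}, index=idx)
        meta = {
            "a": MetricMeta("biological"),
            "b": MetricMeta("geospatial"),
            "c": MetricMeta("hydrological", direct_water=True),
        }
        t = MetricTable(data, meta)
        assert t.select_metrics(include_geospatial=False).metric_names == ["a", "c"]
        assert t.select_metrics(include_direct_water=False).metric_names == ["a", "b"]

    def test_percent_validation(self):
        rec = _full_indicators(surface_flow_pct=120.0)
        assert any("surface_flow_pct" in p for p in rec.validate())
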