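"""Food-web pooling, terrestrial screening and table IO."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mudflatmix import datasets
from mudflatmix.errors import FormatError, ValidationError
from mudflatmix.foodweb import (
    IsotopeSample,
    SourceSummary,
    pool_endpoints,
    read_food_web,
    read_samples,
    screen_terrestrial,
    write_food_web,
    write_samples,
)


class TestPoolEndpoints:
    def test_sediment_endpoint_matches_study(self, sediment_rows):
        """Three sediment surveys pool to the biofilm endpoint
        -19.7 +/- 1.7 (d13C), 6.4 +/- 1.5 (d15N), n = 96."""
        pooled = pool_endpoints(sediment_rows)
        assert pooled.n_total == 96
        assert round(pooled.mean_d13C, 1) == -19.7
        assert round(pooled.mean_d15N, 1) == 6.4
        assert round(pooled.sd_d13C, 1) == 1.7
        assert round(pooled.sd_d15N, 1) == 1.5

    def test_single_summary_identity(self):
        s = SourceSummary("MPB", "survey_b", 36, -16.6, 1.9, 5.8, 0.7, 8.1)
        pooled = pool_endpoints([s])
        assert (pooled.n_total, pooled.mean_d13C, pooled.sd_d13C) == (36, -16.6, 1.9)
        assert (pooled.mean_d15N, pooled.sd_d15N, pooled.cn_ratio) == (5.8, 0.7, 8.1)

    def test_pooled_sd_equals_brute_force_concatenation(self):
        """Pooled sd must equal the sd of concatenated raw groups built to
        have exactly the stated group means and sds."""
        rng = np.random.default_rng(42)
        groups = []
        specs = [(9, -19.5, 1.0), (32, -19.2, 2.6), (55, -20.1, 0.9)]
        for n, mean, sd in specs:
            x = rng.normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)  # exact moments 0/1
            groups.append(mean + sd * x)
        concatenated = np.concatenate(groups)
        summaries = [
            SourceSummary("s", f"g{i}", n, float(g.mean()), float(g.std(ddof=1)), None, None)
            for i, ((n, _, _), g) in enumerate(zip(specs, groups))
        ]
        pooled = pool_endpoints(summaries)
        assert math.isclose(pooled.mean_d13C, concatenated.mean(), abs_tol=1e-9)
        assert math.isclose(pooled.sd_d13C, concatenated.std(ddof=1), abs_tol=1e-9)

    def test_groups_without_sd_contribute_only_their_mean(self):
        """n <= 2 rows without a printed sd still shift the pooled mean and
        its between-group dispersion, but add no within-group variance."""
        rows = [
            SourceSummary("polychaetes", "a", 2, -11.2, None, 11.5, None, 5.1),
            SourceSummary("polychaetes", "b", 18, -15.0, 1.5, 12.1, 1.1, 5.1),
        ]
        pooled = pool_endpoints(rows)
        assert pooled.n_total == 20
        expected_mean = (2 * -11.2 + 18 * -15.0) / 20
        assert math.isclose(pooled.mean_d13C, expected_mean)
        ss = 17 * 1.5**2 + 2 * (-11.2 - expected_mean) ** 2 + 18 * (-15.0 - expected_mean) ** 2
        assert math.isclose(pooled.sd_d13C, math.sqrt(ss / 19))

    def test_order_invariance_and_n_conservation(self, sediment_rows):
        a = pool_endpoints(sediment_rows)
        b = pool_endpoints(sediment_rows[::-1])
        assert a == b
        assert a.n_total == sum(s.n for s in sediment_rows)

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 50),
                st.floats(-30, -10),
                st.floats(0.1, 3.0),
            ),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_pooled_mean_bounded_by_group_means(self, rows):
        summaries = [
            SourceSummary("s", f"g{i}", n, m, sd, None, None)
            for i, (n, m, sd) in enumerate(rows)
        ]
        pooled = pool_endpoints(summaries)
        means = [s.mean_d13C for s in summaries]
        assert min(means) - 1e-12 <= pooled.mean_d13C <= max(means) + 1e-12

    def test_validation_errors(self, sediment_rows):
        with pytest.raises(ValidationError):
            pool_endpoints([])
        mixed = sediment_rows + [SourceSummary("MPB", "x", 36, -16.6, 1.9, 5.8, 0.7)]
        with pytest.raises(ValidationError):
            pool_endpoints(mixed)


class TestScreenTerrestrial:
    def test_depleted_liver_flagged_marine_retained(self, liver_samples):
        result = screen_terrestrial(liver_samples, threshold_d13C=-19.0)
        flagged = {s.d13C for s in result.flagged_terrestrial}
        assert flagged == {-21.4, -23.1}
        assert all(s.d13C > -19.0 for s in result.retained)

    def test_threshold_is_strict_inequality(self):
        s = IsotopeSample("x", "wesa", "liver", -19.0, 13.0)
        result = screen_terrestrial([s], threshold_d13C=-19.0)
        assert result.retained == (s,)
        assert result.flagged_terrestrial == ()

    @given(st.lists(st.floats(-30, -5), max_size=30), st.floats(-25, -10))
    @settings(max_examples=100, deadline=None)
    def test_exact_partition(self, values, threshold):
        samples = [
            IsotopeSample(f"s{i}", "sp", "liver", v, None) for i, v in enumerate(values)
        ]
        result = screen_terrestrial(samples, threshold)
        assert len(result.retained) + len(result.flagged_terrestrial) == len(samples)
        assert set(result.retained) | set(result.flagged_terrestrial) == set(samples)
        assert not set(result.retained) & set(result.flagged_terrestrial)


class TestTableIO:
    def test_round_trip_identity(self, tmp_path, sediment_rows):
        path = tmp_path / "foodweb.csv"
        write_food_web(sediment_rows, path)
        assert read_food_web(path) == sediment_rows

    def test_samples_round_trip(self, tmp_path, liver_samples):
        path = tmp_path / "samples.csv"
        write_samples(liver_samples, path)
        assert read_samples(path) == liver_samples

    def test_missing_isotope_cell_reports_row(self, tmp_path):
        path = tmp_path / "samples.csv"
        path.write_text(
            "sample_id,species,tissue,date,site,d13C,d15N\n"
            "a,wesa,liver,2016-04-20,roberts,-16.0,13.0\n"
            "b,wesa,liver,2016-04-20,roberts,,13.1\n"
        )
        with pytest.raises(FormatError, match="row 3"):
            read_samples(path)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "foodweb.csv"
        path.write_text("source,study,n\nMPB,x,36\n")
        with pytest.raises(FormatError, match="missing required columns"):
            read_food_web(path)

    def test_packaged_study_table_loads(self):
        rows = datasets.load_foodweb()
        assert len(rows) == 12
        assert sum(1 for r in rows if r.source_name == "surface_sediment") == 3
        assert sum(1 for r in rows if r.source_name == "polychaetes") == 4
        mpb = [r for r in rows if r.source_name == "MPB"]
        assert mpb[0].n == 36 and mpb[0].cn_ratio == 8.1
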