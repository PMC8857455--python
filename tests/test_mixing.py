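"""Concentration-dependent Bayesian mixing model: likelihood, MCMC, geometry."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from mudflatmix import datasets
from mudflatmix.errors import DomainError, ValidationError
from mudflatmix.mixing import (
    DietProportions,
    MixingChains,
    MixingModelSpec,
    SourceSpec,
    TrophicDiscrimination,
    concentrations_equal_n,
    concentrations_from_cn,
    expected_signature,
    in_mixing_polygon,
    log_likelihood,
    sample_posterior,
    summarize_posterior,
)

TDF0 = TrophicDiscrimination("liver", 0.0, 0.0, 0.0, 0.0)


def _sources(concs=None, means_c=(-19.9, -11.7, -15.1), means_n=(5.8, 8.4, 11.9)):
    concs = concs or [(0.4, 0.05)] * 3
    return tuple(
        SourceSpec(f"s{i}", means_c[i], 1.0, means_n[i], 1.0, cc, cn)
        for i, (cc, cn) in enumerate(concs)
    )


class TestConcentrations:
    def test_equal_carbon_convention(self):
        conc_c, conc_n = concentrations_from_cn(8.1, 0.40)
        assert conc_c == 0.40
        assert conc_n == pytest.approx(0.0494, abs=1e-4)

    def test_unit_ratio(self):
        assert concentrations_from_cn(1.0, 0.40) == (0.40, 0.40)

    def test_equal_nitrogen_convention(self):
        conc_c, conc_n = concentrations_equal_n(8.1, 0.05)
        assert conc_n == 0.05
        assert conc_c == pytest.approx(0.405)

    def test_invalid_inputs_rejected(self):
        for bad in (0.0, -1.0):
            with pytest.raises(ValidationError):
                concentrations_from_cn(bad)
            with pytest.raises(ValidationError):
                concentrations_equal_n(bad)

    def test_equal_cn_reduces_to_concentration_free(self):
        """Sources sharing one C:N get identical weights, so the expected
        signature equals the plain proportion-weighted mixture."""
        sources = _sources([(0.3, 0.06)] * 3)
        p = (0.2, 0.5, 0.3)
        simple = sum(pi * s.mean_d13C for pi, s in zip(p, sources))
        assert expected_signature(p, sources, TDF0, "C") == pytest.approx(simple)


class TestExpectedSignature:
    def test_single_source_identity(self):
        tdf = datasets.TDF_LIVER
        sources = _sources()
        out = expected_signature((1.0, 0.0, 0.0), sources, tdf, "C")
        assert out == pytest.approx(sources[0].mean_d13C + tdf.d13C_mean)

    def test_against_weighted_mean_oracle(self):
        rng = np.random.default_rng(3)
        tdf = TrophicDiscrimination("liver", 1.1, 0.3, 4.0, 0.3)
        for _ in range(1000):
            concs = [(rng.uniform(0.1, 0.6), rng.uniform(0.02, 0.2)) for _ in range(3)]
            sources = _sources(concs)
            p = rng.dirichlet([1, 1, 1])
            for isotope, attr_mean, conc_idx, delta in (
                ("C", "mean_d13C", 0, tdf.d13C_mean),
                ("N", "mean_d15N", 1, tdf.d15N_mean),
            ):
                num = den = 0.0
                for pi, s, c in zip(p, sources, concs):
                    num += pi * c[conc_idx] * (getattr(s, attr_mean) + delta)
                    den += pi * c[conc_idx]
                assert expected_signature(p, sources, tdf, isotope) == pytest.approx(
                    num / den, abs=1e-12
                )


class TestLogLikelihood:
    def _spec(self, consumers, sources=None, error="process"):
        return MixingModelSpec(
            sources=sources or _sources(),
            tdf=datasets.TDF_LIVER,
            consumers=tuple(consumers),
            error_structure=error,
        )

    def test_matches_normal_density_oracle(self):
        """Against an independently coded normal-density computation on
        random configurations."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            concs = [(rng.uniform(0.1, 0.6), rng.uniform(0.02, 0.2)) for _ in range(3)]
            sources = _sources(concs)
            consumers = [tuple(rng.uniform([-20, 8], [-12, 16])) for _ in range(4)]
            p = rng.dirichlet([1, 1, 1])
            eps = rng.uniform(0.1, 1.0)
            spec = self._spec(consumers, sources, error="process_residual")
            tdf = spec.tdf
            oracle = 0.0
            for iso, col in (("C", 0), ("N", 1)):
                if iso == "C":
                    mus = np.array([s.mean_d13C for s in sources]) + tdf.d13C_mean
                    sds = np.array([s.sd_d13C for s in sources])
                    conc = np.array([c[0] for c in concs])
                    tdf_sd = tdf.d13C_sd
                else:
                    mus = np.array([s.mean_d15N for s in sources]) + tdf.d15N_mean
                    sds = np.array([s.sd_d15N for s in sources])
                    conc = np.array([c[1] for c in concs])
                    tdf_sd = tdf.d15N_sd
                w = p * conc / np.sum(p * conc)
                mu = float(np.sum(w * mus))
                var = float(np.sum(w**2 * (sds**2 + tdf_sd**2))) + eps**2
                for obs in consumers:
                    oracle += stats.norm.logpdf(obs[col], mu, np.sqrt(var))
            assert log_likelihood(spec, p, eps) == pytest.approx(oracle, rel=1e-10)

    def test_duplicating_consumers_doubles_loglik(self):
        consumers = [(-16.0, 13.5), (-15.5, 13.0)]
        spec = self._spec(consumers)
        spec2 = self._spec(consumers * 2)
        p = (0.4, 0.2, 0.4)
        assert log_likelihood(spec2, p) == pytest.approx(2 * log_likelihood(spec, p))

    def test_maximized_at_expected_signature(self):
        """With near-zero dispersion everywhere, the likelihood peaks when
        the consumer sits exactly at the expected signature."""
        sources = tuple(
            SourceSpec(f"s{i}", mc, 1e-3, mn, 1e-3, 0.4, 0.05)
            for i, (mc, mn) in enumerate([(-19.9, 5.8), (-11.7, 8.4), (-15.1, 11.9)])
        )
        p0 = (0.3, 0.3, 0.4)
        mu_c = expected_signature(p0, sources, TDF0, "C")
        mu_n = expected_signature(p0, sources, TDF0, "N")
        spec = MixingModelSpec(
            sources=sources, tdf=TDF0,
            consumers=((mu_c, mu_n), (mu_c, mu_n)), error_structure="process",
        )
        best = log_likelihood(spec, p0)
        for perturbed in [(0.31, 0.29, 0.4), (0.3, 0.32, 0.38), (0.25, 0.35, 0.4)]:
            assert log_likelihood(spec, perturbed) < best

    def test_non_finite_inputs_rejected(self):
        spec = self._spec([(-16.0, 13.5), (-15.5, 13.0)])
        with pytest.raises(DomainError):
            log_likelihood(spec, (np.nan, 0.5, 0.5))


class TestSamplePosterior:
    def test_symmetric_sources_share_the_posterior(self):
        """Two sources placed symmetrically about the consumers (third source
        pushed far away) must receive statistically identical contributions."""
        sources = (
            SourceSpec("left", -18.0, 1.0, 10.0, 1.0, 0.4, 0.05),
            SourceSpec("right", -14.0, 1.0, 10.0, 1.0, 0.4, 0.05),
            SourceSpec("far", -16.0, 1.0, 24.0, 1.0, 0.4, 0.05),
        )
        spec = MixingModelSpec(
            sources=sources, tdf=TDF0,
            consumers=((-16.0, 10.0), (-16.0, 10.0)), error_structure="process",
        )
        chains = sample_posterior(spec, n_chains=3, n_iter=30_000, n_burn=5_000, seed=5)
        summary = summarize_posterior(chains)
        assert summary.median_pct[0] == pytest.approx(summary.median_pct[1], abs=3.0)

    def test_recovers_known_diet_proportions(self):
        """n = 100 low-noise consumers generated at p = (0.5, 0.2, 0.3) are
        recovered within +/- 0.05 in every proportion."""
        sources = tuple(datasets.endpoint_set("MPB-protein"))
        tdf = datasets.TDF_LIVER
        p_true = (0.5, 0.2, 0.3)
        mu_c = expected_signature(p_true, sources, tdf, "C")
        mu_n = expected_signature(p_true, sources, tdf, "N")
        rng = np.random.default_rng(17)
        consumers = tuple(
            (mu_c + rng.normal(0, 0.15), mu_n + rng.normal(0, 0.15)) for _ in range(100)
        )
        low_sd = tuple(
            dataclasses.replace(s, sd_d13C=0.2, sd_d15N=0.2) for s in sources
        )
        spec = MixingModelSpec(
            sources=low_sd,
            tdf=dataclasses.replace(tdf, d13C_sd=0.0, d15N_sd=0.0),
            consumers=consumers,
            error_structure="process_residual",
        )
        chains = sample_posterior(spec, n_chains=3, n_iter=30_000, n_burn=5_000, seed=17)
        summary = summarize_posterior(chains)
        for median, truth in zip(summary.median_pct, p_true):
            assert median / 100.0 == pytest.approx(truth, abs=0.05)

    def test_reproducible_given_seed(self):
        spec = MixingModelSpec(
            sources=tuple(datasets.endpoint_set("BIOF")),
            tdf=datasets.TDF_LIVER,
            consumers=((-16.0, 13.5), (-15.5, 13.2), (-16.2, 13.8)),
        )
        a = sample_posterior(spec, n_chains=2, n_iter=3_000, n_burn=1_000, seed=9)
        b = sample_posterior(spec, n_chains=2, n_iter=3_000, n_burn=1_000, seed=9)
        assert np.array_equal(a.p, b.p)
        assert np.array_equal(a.residual_scale, b.residual_scale)

    def test_every_draw_is_a_simplex_point(self):
        spec = MixingModelSpec(
            sources=tuple(datasets.endpoint_set("BIOF")),
            tdf=datasets.TDF_LIVER,
            consumers=((-16.0, 13.5), (-15.5, 13.2)),
        )
        chains = sample_posterior(spec, n_chains=2, n_iter=4_000, n_burn=1_000, seed=1)
        assert np.all(chains.p >= 0)
        assert np.allclose(chains.p.sum(axis=2), 1.0, atol=1e-9)
        assert np.all(chains.residual_scale > 0)

    def test_prior_only_recovers_dirichlet_mean(self):
        """With the likelihood disabled, posterior means must match the
        Dirichlet prior mean (both for the flat and an asymmetric prior)."""
        consumers = ((-16.0, 13.5), (-15.5, 13.2))
        for alpha, expected in [((1, 1, 1), (1 / 3,) * 3), ((2, 1, 1), (0.5, 0.25, 0.25))]:
            spec = MixingModelSpec(
                sources=tuple(datasets.endpoint_set("BIOF")),
                tdf=datasets.TDF_LIVER,
                consumers=consumers,
                prior_alpha=alpha,
            )
            chains = sample_posterior(
                spec, n_chains=2, n_iter=40_000, n_burn=5_000, seed=3, prior_only=True
            )
            means = chains.p.reshape(-1, 3).mean(axis=0)
            assert np.allclose(means, expected, atol=0.02)

    def test_equal_concentrations_match_concentration_free_model(self):
        """With equal source concentrations the concentration weighting
        cancels, so medians agree with an all-equal-concentration refit on
        the same seed within Monte-Carlo error."""
        means = dict(means_c=(-19.0, -12.0, -15.0), means_n=(6.0, 9.0, 12.0))
        spec_a = MixingModelSpec(
            sources=_sources([(0.4, 0.05)] * 3, **means),
            tdf=datasets.TDF_LIVER,
            consumers=((-15.5, 13.0), (-16.0, 13.5), (-15.0, 12.5)),
        )
        spec_b = MixingModelSpec(
            sources=_sources([(0.1, 0.1)] * 3, **means),
            tdf=datasets.TDF_LIVER,
            consumers=spec_a.consumers,
        )
        sa = summarize_posterior(sample_posterior(spec_a, 2, 20_000, 4_000, seed=21))
        sb = summarize_posterior(sample_posterior(spec_b, 2, 20_000, 4_000, seed=21))
        for ma, mb in zip(sa.median_pct, sb.median_pct):
            assert ma == pytest.approx(mb, abs=2.0)

    def test_invalid_iteration_counts_rejected(self):
        spec = MixingModelSpec(
            sources=tuple(datasets.endpoint_set("BIOF")),
            tdf=datasets.TDF_LIVER,
            consumers=((-16.0, 13.5), (-15.5, 13.2)),
        )
        with pytest.raises(ValidationError):
            sample_posterior(spec, n_iter=100, n_burn=100, seed=0)


class TestSummarizePosterior:
    def _chains(self, p):
        return MixingChains(
            p=p, residual_scale=np.ones(p.shape[:2]), acceptance_rate=0.3,
            rhat={"a": 1.0, "b": 1.0, "c": 1.0}, ess={"a": 1.0, "b": 1.0, "c": 1.0},
            source_names=("a", "b", "c"), seed=0,
        )

    def test_constant_chain(self):
        p = np.tile(np.array([0.2, 0.3, 0.5]), (2, 100, 1))
        summary = summarize_posterior(self._chains(p))
        assert summary.median_pct == (20.0, 30.0, 50.0)
        assert summary.ci_low_pct == summary.ci_high_pct == (20.0, 30.0, 50.0)

    def test_quantiles_match_sort_oracle(self):
        rng = np.random.default_rng(8)
        draws = rng.dirichlet([2, 3, 4], size=10_000)
        summary = summarize_posterior(self._chains(draws[None, :, :]))
        for i in range(3):
            col = np.sort(draws[:, i])
            assert summary.median_pct[i] == pytest.approx(100 * np.median(col))
            assert summary.ci_low_pct[i] == pytest.approx(100 * np.quantile(col, 0.025))
            assert summary.ci_high_pct[i] == pytest.approx(100 * np.quantile(col, 0.975))

    def test_invariant_to_chain_concatenation_order(self):
        rng = np.random.default_rng(4)
        p = rng.dirichlet([1, 1, 1], size=(3, 500))
        a = summarize_posterior(self._chains(p))
        b = summarize_posterior(self._chains(p[::-1]))
        assert a.median_pct == b.median_pct

    def test_empty_chains_rejected(self):
        with pytest.raises(ValidationError):
            summarize_posterior(self._chains(np.empty((1, 0, 3))))


class TestMixingPolygon:
    SOURCES = (
        SourceSpec("a", -19.9, 1.9, 5.8, 0.7, 0.4, 0.05),
        SourceSpec("b", -11.7, 1.0, 8.4, 1.1, 0.4, 0.08),
        SourceSpec("c", -15.1, 1.9, 11.9, 1.2, 0.4, 0.08),
    )

    def test_centroid_inside(self):
        tdf = datasets.TDF_LIVER
        cx = np.mean([s.mean_d13C for s in self.SOURCES]) + tdf.d13C_mean
        cn = np.mean([s.mean_d15N for s in self.SOURCES]) + tdf.d15N_mean
        check = in_mixing_polygon((cx, cn), self.SOURCES, tdf)
        assert check.inside and not check.degenerate
        assert all(d > 0 for d in check.signed_edge_distances)

    def test_far_point_outside(self):
        check = in_mixing_polygon((0.0, 0.0), self.SOURCES, datasets.TDF_LIVER)
        assert not check.inside
        assert min(check.signed_edge_distances) < 0

    def test_vertex_on_boundary_is_inside(self):
        s = self.SOURCES[0]
        check = in_mixing_polygon((s.mean_d13C, s.mean_d15N), self.SOURCES, TDF0)
        assert check.inside

    def test_collinear_sources_flagged_degenerate(self):
        collinear = tuple(
            SourceSpec(f"s{i}", -20.0 + i, 1.0, 5.0 + i, 1.0, 0.4, 0.05) for i in range(3)
        )
        check = in_mixing_polygon((-18.0, 6.0), collinear, TDF0)
        assert check.degenerate and not check.inside
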