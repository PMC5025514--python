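"""Intensity normalisation, mixture fitting, pattern taxonomy and calling."""

import numpy as np
import pytest

from polyarray import (
    ClusterParams,
    Pattern,
    SimConfig,
    call_genotypes,
    classify_pattern,
    derive_diploid_cluster_file,
    fit_and_classify,
    fit_cluster_model,
    fit_panel,
    normalize,
    read_cluster_file,
    rescue_shifted,
    simulate_intensities,
    write_cluster_file,
)
from polyarray.clusters import ClusterModel, Component

P = ClusterParams(seed=0)


class TestNormalize:
    def test_axis_and_symmetry_cases(self):
        theta, r = normalize([3.0, 5.0, 0.0, 2.0], [3.0, 0.0, 5.0, 0.0])
        assert theta[0] == pytest.approx(0.5)   # X == Y
        assert theta[1] == pytest.approx(0.0)   # pure A signal
        assert theta[2] == pytest.approx(1.0)   # pure B signal
        assert r[0] == pytest.approx(6.0)

    def test_closed_form_value(self):
        theta, _ = normalize(3.0, 1.0)
        assert float(theta) == pytest.approx((2 / np.pi) * np.arctan(1 / 3), abs=1e-12)

    def test_no_signal_sentinel(self):
        theta, r = normalize([0.0], [0.0])
        assert np.isnan(theta[0]) and r[0] == 0.0

    def test_scale_invariance_of_theta(self, rng):
        x = rng.uniform(0.1, 5, 50)
        y = rng.uniform(0.1, 5, 50)
        t1, r1 = normalize(x, y)
        t2, r2 = normalize(7 * x, 7 * y)
        np.testing.assert_allclose(t1, t2, atol=1e-12)
        np.testing.assert_allclose(r2, 7 * r1, rtol=1e-12)

    def test_negative_channel_rejected(self):
        with pytest.raises(ValueError):
            normalize([-1.0], [1.0])


def _cloud(rng, means, n_per, sd=0.03):
    thetas = np.concatenate([rng.normal(m, sd, n_per) for m in means])
    thetas = 1 - np.abs(1 - np.abs(thetas))
    rs = rng.normal(1.0, 0.1, len(thetas)).clip(0.3)
    return thetas, rs


class TestMixtureFit:
    def test_recovers_three_separated_clouds(self, rng):
        thetas, rs = _cloud(rng, [0.05, 0.50, 0.95], 70)
        m = fit_cluster_model(thetas, rs, P)
        assert m.k == 3
        got = sorted(c.mean_theta for c in m.components)
        for g, want in zip(got, [0.05, 0.50, 0.95]):
            assert g == pytest.approx(want, abs=0.02)

    def test_single_cloud_gives_one_component(self, rng):
        thetas, rs = _cloud(rng, [0.4], 120)
        assert fit_cluster_model(thetas, rs, P).k == 1

    def test_five_planted_clouds(self, rng):
        thetas, rs = _cloud(rng, [0.05, 0.27, 0.5, 0.73, 0.95], 50)
        assert fit_cluster_model(thetas, rs, P).k == 5

    def test_all_no_signal_fails_immediately(self):
        m = fit_cluster_model(np.full(20, np.nan), np.zeros(20), P)
        assert m.pattern is Pattern.FAILED_LOW_INTENSITY

    def test_deterministic_given_seed(self, rng):
        thetas, rs = _cloud(rng, [0.1, 0.6], 60)
        m1 = fit_cluster_model(thetas, rs, P)
        m2 = fit_cluster_model(thetas, rs, P)
        assert [c.mean_theta for c in m1.components] == [c.mean_theta for c in m2.components]


def _model(means, weights=None, labels=None, n=100):
    k = len(means)
    weights = weights or [1 / k] * k
    comps = [
        Component(mean_theta=m, sd_theta=0.03, mean_r=1.0, sd_r=0.1, weight=w,
                  label=(labels[i] if labels else "none"))
        for i, (m, w) in enumerate(zip(means, weights))
    ]
    m = ClusterModel(snp_id="s", components=comps, sample_ids=[f"x{i}" for i in range(n)])
    m._signal_mask = np.ones(n, dtype=bool)
    m.responsibilities = np.zeros((n, k))
    return m


class TestTaxonomy:
    def test_extreme_separation_is_genome_specific(self):
        assert classify_pattern(_model([0.05, 0.5, 0.95]), P) is Pattern.GENOME_SPECIFIC

    def test_sub_threshold_separation_is_not_genome_specific(self):
        got = classify_pattern(_model([0.3, 0.5, 0.7]), P)
        assert got is not Pattern.GENOME_SPECIFIC

    def test_inflated_middle_weight_is_unresolvable(self):
        m = _model([0.1, 0.5, 0.9], weights=[0.15, 0.7, 0.15])
        assert classify_pattern(m, P) is Pattern.MULTI_CLUSTER_UNRESOLVABLE

    def test_five_components_unresolvable(self):
        m = _model([0.05, 0.27, 0.5, 0.73, 0.95])
        assert classify_pattern(m, P) is Pattern.MULTI_CLUSTER_UNRESOLVABLE

    def test_half_space_compression_is_shifted(self):
        assert classify_pattern(_model([0.04, 0.16, 0.33]), P) is Pattern.SHIFTED

    def test_single_cloud_is_monomorphic(self):
        assert classify_pattern(_model([0.1]), P) is Pattern.MONOMORPHIC

    def test_no_signal_majority_is_failed(self):
        m = _model([0.1], n=100)
        m._signal_mask = np.zeros(100, dtype=bool)
        m._signal_mask[:40] = True
        assert classify_pattern(m, P) is Pattern.FAILED_LOW_INTENSITY

    def test_signal_vs_silence_split_is_presence_absence(self):
        m = _model([0.05], n=100)
        m._signal_mask = np.ones(100, dtype=bool)
        m._signal_mask[70:] = False
        assert classify_pattern(m, P) is Pattern.PRESENCE_ABSENCE


class TestRescue:
    def test_relabels_in_theta_order(self):
        m = _model([0.16, 0.04, 0.33])
        m.pattern = Pattern.SHIFTED
        out = rescue_shifted(m)
        assert out.pattern is Pattern.SHIFTED_RESCUED and out.scorable
        by_theta = sorted(out.components, key=lambda c: c.mean_theta)
        assert [c.label for c in by_theta] == ["AA", "AB", "BB"]

    def test_two_cluster_dh_panel_gets_no_ab(self):
        m = _model([0.05, 0.3])
        m.pattern = Pattern.SHIFTED
        out = rescue_shifted(m)
        assert sorted(c.label for c in out.components) == ["AA", "BB"]

    def test_responsibilities_untouched(self, rng):
        cfg = SimConfig(seed=5, n_snps=6, n_samples=150, noise_sd=0.02,
                        class_mixture={"SHIFTED": 1.0})
        panel, _ = simulate_intensities(cfg)
        for sid in panel.snp_ids():
            d = panel.per_snp(sid)
            m = fit_cluster_model(d["theta"].to_numpy(), d["R"].to_numpy(), P, snp_id=sid)
            m.pattern = classify_pattern(m, P)
            if m.pattern is not Pattern.SHIFTED:
                continue
            before = m.responsibilities.copy()
            out = rescue_shifted(m)
            np.testing.assert_array_equal(before, out.responsibilities)

    def test_rescue_refuses_four_clusters(self):
        m = _model([0.04, 0.16, 0.31, 0.45])
        m.pattern = Pattern.SHIFTED
        assert rescue_shifted(m).pattern is Pattern.SHIFTED

    def test_rescued_truth_genotypes_recovered_fully(self):
        """Noiseless shifted fixture: rescue + calling reproduce the planted
        AAAA/AAAB/AABB genotypes for every sample."""
        cfg = SimConfig(seed=5, n_snps=12, n_samples=200, noise_sd=0.01,
                        class_mixture={"SHIFTED": 1.0})
        panel, truth = simulate_intensities(cfg)
        models = fit_panel(panel, P)
        for sid, m in models.items():
            assert m.pattern is Pattern.SHIFTED_RESCUED
            for c in call_genotypes(m):
                assert c.call == truth.genotype_truth[sid][c.sample_id]


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(8)
    thetas, rs = _cloud(rng, [0.05, 0.5, 0.95], 70)
    m = fit_and_classify(thetas, rs, P)
    return m, thetas, rs


class TestCalling:
    def test_sample_at_component_mean_has_high_confidence(self, fitted):
        m, *_ = fitted
        mean0 = sorted(c.mean_theta for c in m.components)[0]
        (c,) = call_genotypes(m, np.array([mean0]), np.array([1.0]), P)
        assert c.call == "AA" and c.confidence > 0.99

    def test_responsibility_midpoint_is_no_call(self, fitted):
        """A sample with equal responsibility for AA and AB sits below any
        positive confidence margin."""
        m, *_ = fitted
        comps = sorted(m.components, key=lambda c: c.mean_theta)
        # equal-responsibility point between the two left clouds
        lo, hi = comps[0], comps[1]
        grid = np.linspace(lo.mean_theta, hi.mean_theta, 2001)
        calls = call_genotypes(m, grid, np.ones_like(grid), P)
        margins = np.array([c.confidence for c in calls])
        assert margins.min() < 0.05  # crosses the no-call band at the boundary
        assert any(c.call == "NO_CALL" for c in calls)

    def test_unscorable_snp_is_all_no_call(self):
        m = _model([0.05, 0.27, 0.5, 0.73, 0.95])
        m.pattern = Pattern.MULTI_CLUSTER_UNRESOLVABLE
        m.scorable = False
        calls = call_genotypes(m, np.array([0.5]), np.array([1.0]), P)
        assert calls[0].call == "NO_CALL"

    def test_call_rate_monotone_in_no_call_threshold(self, fitted):
        m, thetas, rs = fitted
        rates = []
        for thr in (0.3, 0.1, 0.05, 0.01, 0.0):
            params = ClusterParams(no_call_threshold=thr, seed=0)
            calls = call_genotypes(m, thetas, rs, params)
            rates.append(sum(c.call != "NO_CALL" for c in calls))
        assert rates == sorted(rates)

    def test_simulated_panel_concordance(self):
        """>= 99 % agreement with planted genotypes on well-separated clouds
        at realistic noise."""
        cfg = SimConfig(seed=3, n_snps=25, n_samples=200, noise_sd=0.04,
                        class_mixture={"GENOME_SPECIFIC": 1.0})
        panel, truth = simulate_intensities(cfg)
        models = fit_panel(panel, P)
        ok = tot = 0
        for sid, m in models.items():
            for c in call_genotypes(m):
                if c.call == "NO_CALL":
                    continue
                tot += 1
                ok += c.call == truth.genotype_truth[sid][c.sample_id]
        assert tot > 0 and ok / tot >= 0.99


class TestClusterFiles:
    def test_round_trip(self, tmp_path):
        cfg = SimConfig(seed=21, n_snps=15, n_samples=80, noise_sd=0.03)
        panel, _ = simulate_intensities(cfg)
        models = fit_panel(panel, P)
        path = tmp_path / "cluster.json"
        write_cluster_file(models, path)
        back = read_cluster_file(path)
        assert set(back) == set(models)
        for sid in models:
            a, b = models[sid], back[sid]
            assert a.pattern == b.pattern and a.scorable == b.scorable
            assert [c.__dict__ for c in a.components] == [c.__dict__ for c in b.components]

    def test_diploid_derivation_counts_match_truth(self):
        """Genome-specific assays targeting the other subgenome fail in the
        diploid; scorable/polymorphic counts equal the simulator's books."""
        n = 120
        species = ["NAPUS"] * 60 + ["OLERACEA"] * 60
        cfg = SimConfig(seed=31, n_snps=40, n_samples=n, noise_sd=0.03,
                        class_mixture={"GENOME_SPECIFIC": 0.7, "MONOMORPHIC": 0.3})
        panel, truth = simulate_intensities(cfg, species=species)
        tetra = fit_panel(panel, P)
        models, counts = derive_diploid_cluster_file(tetra, panel, "OLERACEA", P)
        want_failed = sum(
            1 for sid, cls in truth.pattern_truth.items()
            if cls == "GENOME_SPECIFIC" and truth.target_subgenome[sid] == "A"
        )
        assert counts["failed"] == want_failed
        assert counts["scorable"] == len(models) - want_failed

    def test_missing_species_tags_rejected(self):
        cfg = SimConfig(seed=1, n_snps=2, n_samples=30, noise_sd=0.03)
        panel, _ = simulate_intensities(cfg)
        panel.species = {}
        with pytest.raises(ValueError, match="species"):
            derive_diploid_cluster_file({}, panel, "RAPA", P)
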