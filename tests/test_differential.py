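import numpy as np
import pytest

from chalm.differential import (
    UNIFORM_PRIOR,
    BetaBinomPrior,
    DiffResult,
    RegionDiffInput,
    adjust_and_call,
    diff_region,
    export_metilene,
    fit_prior,
    read_metilene,
)


class TestFitPrior:
    def test_recovers_symmetric_concentrated_prior(self):
        rng = np.random.default_rng(0)
        p = rng.beta(5, 5, 2000)
        m = rng.binomial(60, p)
        prior = fit_prior([(int(a), 60 - int(a)) for a in m])
        assert prior.mean == pytest.approx(0.5, abs=0.03)
        # Beta(5,5) truth: both shapes recovered within 25%
        assert prior.alpha == pytest.approx(5.0, rel=0.25)
        assert prior.beta == pytest.approx(5.0, rel=0.25)

    def test_recovers_skewed_prior_mean(self):
        rng = np.random.default_rng(1)
        p = rng.beta(2, 8, 2000)
        m = rng.binomial(50, p)
        prior = fit_prior([(int(a), 50 - int(a)) for a in m])
        assert prior.mean == pytest.approx(0.2, abs=0.03)

    def test_degenerate_counts_fall_back_to_flat(self):
        prior = fit_prior([(0, 10)] * 50)
        assert (prior.alpha, prior.beta) == (1.0, 1.0)

    def test_pure_binomial_data_falls_back(self):
        # no overdispersion: variance at the binomial floor
        rng = np.random.default_rng(2)
        m = rng.binomial(40, 0.5, 2000)
        prior = fit_prior([(int(a), 40 - int(a)) for a in m])
        # moment estimate of rho is ~0 (often <=0) -> flat fallback or huge concentration
        assert prior.alpha + prior.beta >= 100 or (prior.alpha, prior.beta) == (1.0, 1.0)

    def test_too_few_regions_is_error(self):
        with pytest.raises(ValueError, match="explicit"):
            fit_prior([(3, 4)] * 9)

    def test_positivity_validation(self):
        with pytest.raises(ValueError):
            BetaBinomPrior(0.0, 1.0)
        with pytest.raises(ValueError):
            BetaBinomPrior(1.0, float("nan"))


class TestDiffRegion:
    def test_identical_counts_symmetric(self):
        r = diff_region(RegionDiffInput("x", (10, 10), (10, 10)))
        assert r.delta == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_identical_counts_any_shared_prior(self):
        prior = BetaBinomPrior(3.0, 1.5)
        r = diff_region(RegionDiffInput("x", (5, 15), (5, 15)), prior, prior)
        assert r.p_value == pytest.approx(1.0)

    def test_extreme_separation(self):
        r = diff_region(RegionDiffInput("x", (0, 20), (20, 0)))
        assert r.p_value < 0.001
        assert r.delta > 0.8

    def test_zero_reads_is_error(self):
        with pytest.raises(ValueError, match="> 0 reads"):
            diff_region(RegionDiffInput("x", (0, 0), (5, 5)))

    def test_monotone_in_ratio_separation(self):
        # fixed totals; p-value non-increasing as the ratio gap widens
        pvals = [
            diff_region(RegionDiffInput("x", (10, 30), (10 + k, 30 - k))).p_value
            for k in range(0, 21, 4)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(pvals, pvals[1:]))

    def test_grid_convergence(self):
        inp = RegionDiffInput("x", (12, 28), (22, 18))
        p512 = diff_region(inp, grid_size=512).p_value
        p1024 = diff_region(inp, grid_size=1024).p_value
        assert abs(p512 - p1024) < 1e-3

    def test_agrees_with_monte_carlo_posterior_sampling(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 20:
            nm1, nu1, nm2, nu2 = (int(v) for v in rng.integers(0, 40, 4))
            if nm1 + nu1 == 0 or nm2 + nu2 == 0:
                continue
            prior = BetaBinomPrior(
                float(rng.uniform(0.5, 3)), float(rng.uniform(0.5, 3))
            )
            r = diff_region(
                RegionDiffInput("x", (nm1, nu1), (nm2, nu2)), prior, prior
            )
            d = rng.beta(prior.alpha + nm2, prior.beta + nu2, 10**6) - rng.beta(
                prior.alpha + nm1, prior.beta + nu1, 10**6
            )
            p_mc = min(2 * min((d <= 0).mean(), (d >= 0).mean()), 1.0)
            assert r.p_value == pytest.approx(p_mc, abs=0.01)
            checked += 1


class TestAdjustAndCall:
    def test_bh_hand_computation(self):
        results = [
            DiffResult(f"r{i}", 0.1, 0.5, 0.4, p)
            for i, p in enumerate([0.01, 0.02, 0.03, 0.04])
        ]
        out = adjust_and_call(results)
        # BH with m=4: q_i = min_{j>=i} p_j * 4 / j = 0.04 for all
        assert [r.q_value for r in out] == pytest.approx([0.04] * 4)
        assert all(r.significant for r in out)

    def test_all_null_pvalues(self):
        results = [DiffResult(f"r{i}", 0.2, 0.7, 0.5, 1.0) for i in range(5)]
        assert not any(r.significant for r in adjust_and_call(results))

    def test_delta_gate(self):
        results = [DiffResult("r0", 0.2, 0.29, 0.09, 0.001)]
        (out,) = adjust_and_call(results)
        assert out.q_value < 0.05 and not out.significant

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        results = [
            DiffResult(f"r{i}", 0.1, 0.5, 0.4, float(p))
            for i, p in enumerate(rng.uniform(0.001, 1.0, 40))
        ]
        fwd = {r.region_id: r.q_value for r in adjust_and_call(results)}
        rev = {r.region_id: r.q_value for r in adjust_and_call(results[::-1])}
        assert fwd == pytest.approx(rev)

    def test_matches_reference_bh(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(0.001, 1.0, 100)
        results = [
            DiffResult(f"r{i}", 0.1, 0.5, 0.4, float(v)) for i, v in enumerate(p)
        ]
        q_ref = multipletests(p, method="fdr_bh")[1]
        q_ours = [r.q_value for r in adjust_and_call(results)]
        assert q_ours == pytest.approx(q_ref.tolist())

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            adjust_and_call([DiffResult("r", 0.1, 0.2, 0.1, 0.0)])


class TestCalibrationAndPower:
    def test_null_calibration(self):
        # shared p_i per region, independent read draws per condition
        rng = np.random.default_rng(7)
        n, depth = 1000, 30
        p = rng.beta(2, 8, n)
        m1, m2 = rng.binomial(depth, p), rng.binomial(depth, p)
        c1 = [(int(a), depth - int(a)) for a in m1]
        c2 = [(int(a), depth - int(a)) for a in m2]
        pr1, pr2 = fit_prior(c1), fit_prior(c2)
        pv = np.array(
            [
                diff_region(RegionDiffInput(f"r{i}", c1[i], c2[i]), pr1, pr2).p_value
                for i in range(n)
            ]
        )
        assert 0.02 <= (pv < 0.05).mean() <= 0.08

    def test_power_at_large_effect(self):
        rng = np.random.default_rng(8)
        depth = 50
        m1 = rng.binomial(depth, 0.2, 300)
        m2 = rng.binomial(depth, 0.6, 300)
        prior = BetaBinomPrior(2.0, 8.0)
        out = adjust_and_call(
            [
                diff_region(
                    RegionDiffInput(
                        f"r{i}", (int(a), depth - int(a)), (int(b), depth - int(b))
                    ),
                    prior,
                    prior,
                )
                for i, (a, b) in enumerate(zip(m1, m2))
            ]
        )
        assert np.mean([r.significant for r in out]) >= 0.8


class TestMetileneExport:
    def test_shape_and_missing(self, tmp_path):
        path = tmp_path / "metilene.tsv"
        export_metilene(
            path, "chr1", [{100: 0.2, 200: 0.8}], [{100: 0.4, 300: 0.1}]
        )
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["chrom", "pos", "g1_1", "g2_1"]
        assert len(lines) == 4  # header + 3 positions
        assert lines[2].split("\t") == ["chr1", "200", "0.8", "."]
        assert lines[3].split("\t") == ["chr1", "300", ".", "0.1"]

    def test_roundtrip(self, tmp_path):
        path = tmp_path / "metilene.tsv"
        g1 = [{100: 0.25, 200: 0.75}, {100: 0.5}]
        g2 = [{200: 1.0, 300: 0.0}]
        export_metilene(path, "chrX", g1, g2)
        chrom, reps, names = read_metilene(path)
        assert chrom == "chrX"
        assert names == ["g1_1", "g1_2", "g2_1"]
        assert reps == [*g1, *g2]

    def test_unsorted_input_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\tg1_1\tg2_1\nchr1\t200\t0.5\t0.5\nchr1\t100\t0.5\t0.5\n")
        with pytest.raises(ValueError, match="sorted"):
            read_metilene(path)
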