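import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from epikit.methylome import (
    Dmr,
    DmrCallParams,
    aggregate_profile,
    call_dmrs,
    dmr_pipeline,
    empirical_null_curve,
    estimate_dispersion,
    filter_dmrs,
    methylome_summary,
    prepare_tests,
    smooth_methylation,
    stability_fraction,
    wald_test,
    wald_test_cpg,
)
from epikit.io_formats import GenomicInterval

from conftest import make_meth_frame


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

class TestSmoothing:
    def test_constant_signal(self):
        pos = np.arange(0, 1000, 50)
        meth = np.full(len(pos), 8)
        total = np.full(len(pos), 10)
        mu = smooth_methylation(pos, meth, total)
        np.testing.assert_allclose(mu, 0.8)

    def test_isolated_cpg(self):
        mu = smooth_methylation(np.array([5000]), np.array([3]), np.array([4]))
        assert mu[0] == pytest.approx(0.75)

    def test_three_cpg_window(self):
        pos = np.array([100, 200, 300])
        mu = smooth_methylation(pos, np.array([8, 1, 6]),
                                np.array([10, 10, 10]), window_bp=500)
        assert mu[1] == pytest.approx(15 / 30)

    def test_zero_coverage_uses_neighbors(self):
        pos = np.array([100, 150])
        mu = smooth_methylation(pos, np.array([0, 9]), np.array([0, 10]))
        assert mu[0] == pytest.approx(0.9)

    def test_all_zero_coverage_flagged_missing(self):
        mu = smooth_methylation(np.array([100]), np.array([0]), np.array([0]))
        assert np.isnan(mu[0])

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            smooth_methylation(np.array([200, 100]), np.array([1, 1]),
                               np.array([2, 2]))


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

class TestDispersion:
    def test_zero_variance_floor(self):
        meth = np.tile([[5], [5]], (100, 1)).reshape(100, 2) * 0 + 5
        total = np.full((100, 2), 10)
        phi = estimate_dispersion([meth, meth], [total, total])
        assert np.all(phi >= 1e-4)

    def test_recovers_simulated_phi(self):
        rng = np.random.default_rng(0)
        n, reps, cov, true_phi, mu = 5000, 4, 30, 0.1, 0.6
        conc = 1 / true_phi - 1
        total = rng.poisson(cov, (n, reps)) + 1
        meth = rng.binomial(total, rng.beta(mu * conc, (1 - mu) * conc,
                                            (n, reps)))
        phi = estimate_dispersion([meth[:, :2], meth[:, 2:]],
                                  [total[:, :2], total[:, 2:]])
        assert 0.07 <= np.median(phi) <= 0.13

    def test_single_sample_global_fallback(self):
        rng = np.random.default_rng(1)
        n = 500
        total = rng.poisson(30, (n, 1)) + 1
        meth = rng.binomial(total, 0.7)
        mu = np.full(n, 0.7)
        phi = estimate_dispersion([meth, total * 0 + meth], [total, total],
                                  mu_smoothed=mu)
        assert len(np.unique(phi)) == 1  # one global value for all CpGs

    def test_clipped_range(self):
        rng = np.random.default_rng(2)
        total = rng.poisson(20, (200, 2)) + 1
        meth = rng.binomial(total, 0.5)
        phi = estimate_dispersion([meth, meth], [total, total])
        assert np.all((phi >= 1e-4) & (phi <= 0.5))


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

class TestWald:
    def test_equal_proportions(self):
        t = wald_test_cpg(5, 10, 10, 20, 0.05)
        assert t.wald == 0 and t.p == pytest.approx(1.0)

    def test_hand_evaluated(self):
        t = wald_test_cpg(18, 20, 2, 20, 0.0)
        assert t.wald == pytest.approx(0.8 / np.sqrt(0.009), rel=1e-6)
        assert t.wald == pytest.approx(8.43, abs=0.01)
        assert t.p < 1e-15

    def test_degenerate_zero(self):
        t = wald_test_cpg(0, 20, 0, 20, 0.05)
        assert t.wald == 0 and t.p == pytest.approx(1.0)

    def test_zero_coverage_skipped(self):
        t = wald_test_cpg(0, 0, 5, 10, 0.05)
        assert np.isnan(t.p)

    def test_antisymmetry(self):
        a = wald_test_cpg(15, 20, 5, 20, 0.1)
        b = wald_test_cpg(5, 20, 15, 20, 0.1)
        assert a.wald == pytest.approx(-b.wald)
        assert a.p == pytest.approx(b.p)

    def test_null_uniformity_ks(self):
        rng = np.random.default_rng(1)
        n, cov, phi = 10_000, 30, 0.1
        mu = rng.uniform(0.2, 0.8, n)
        conc = 1 / phi - 1
        t1 = rng.poisson(cov, n) + 1
        t2 = rng.poisson(cov, n) + 1
        m1 = rng.binomial(t1, rng.beta(mu * conc, (1 - mu) * conc))
        m2 = rng.binomial(t2, rng.beta(mu * conc, (1 - mu) * conc))
        _, p = wald_test(m1 / t1, t1, m2 / t2, t2, np.full(n, phi))
        ks = stats.kstest(p[~np.isnan(p)], "uniform").statistic
        assert ks < 0.05


# ---------------------------------------------------------------------------
# region assembly + brute-force oracle
# ---------------------------------------------------------------------------

def oracle_call_dmrs(tests: pd.DataFrame, params: DmrCallParams) -> list[tuple]:
    """Independent enumeration of all maximal qualifying CpG runs.

    A window [i..j] with significant endpoints is *chained* iff every
    adjacent genomic gap is <= max_gap, every internal insignificant
    stretch is <= max_insig_run, and all significant CpGs share one sign.
    Candidates are maximal chained windows; then the length / CpG count /
    significant-fraction filters and same-direction merging apply.
    """
    out = []
    for c in pd.unique(tests["chrom"]):
        sub = tests[tests["chrom"] == c].reset_index(drop=True)
        pos = sub["pos"].to_numpy()
        diff = (sub["mu1"] - sub["mu2"]).to_numpy()
        sig = ((sub["p"] < params.p_threshold) & sub["p"].notna()
               & (np.abs(diff) > params.delta) & (diff != 0)).to_numpy()
        sign = np.sign(diff).astype(int)
        n = len(sub)

        def chained(i, j):
            if not (sig[i] and sig[j]):
                return False
            signs = {int(s) for k, s in enumerate(sign[i:j + 1], start=i)
                     if sig[k]}
            if len(signs) > 1:
                return False
            run = 0
            for k in range(i, j + 1):
                if k > i and pos[k] - pos[k - 1] > params.max_gap:
                    return False
                run = 0 if sig[k] else run + 1
                if run > params.max_insig_run:
                    return False
            return True

        windows = []
        for i in range(n):
            for j in range(i, n):
                if not chained(i, j):
                    continue
                left = any(chained(k, j) for k in range(i) if sig[k])
                right = any(chained(i, k) for k in range(j + 1, n) if sig[k])
                if not left and not right:
                    windows.append((i, j))
        survivors = []
        for i, j in sorted(set(windows)):
            span = pos[j] + 2 - pos[i]
            frac = sig[i:j + 1].mean()
            if span >= params.minlen and (j - i + 1) >= params.min_cg \
                    and frac >= params.pct_sig:
                survivors.append([i, j, int(sign[i])])
        merged = []
        for s in survivors:
            if merged and s[2] == merged[-1][2] \
                    and pos[s[0]] - (pos[merged[-1][1]] + 2) <= params.dis_merge:
                merged[-1][1] = s[1]
            else:
                merged.append(s)
        for i, j, _ in merged:
            out.append((str(c), int(pos[i]), int(pos[j]) + 2, j - i + 1))
    return sorted(out)


def _tests_frame(pos, p, diff, t=40):
    n = len(pos)
    return pd.DataFrame({
        "chrom": "chr1", "pos": pos,
        "mu1": 0.5 + np.asarray(diff) / 2, "mu2": 0.5 - np.asarray(diff) / 2,
        "t1": t, "t2": t, "phi": 0.01,
        "wald": np.sign(diff) * 5.0, "p": p,
    })


class TestCallDmrs:
    params = DmrCallParams()

    def test_six_sig_cpgs_one_dmr(self):
        pos = np.arange(100, 100 + 6 * 50, 50)  # span 250 bp
        t = _tests_frame(pos, [1e-8] * 6, [0.4] * 6)
        dmrs = call_dmrs(t, self.params)
        assert len(dmrs) == 1 and dmrs[0].n_cpgs == 6

    def test_four_sig_cpgs_rejected(self):
        pos = np.array([100, 200, 300, 400])
        t = _tests_frame(pos, [1e-8] * 4, [0.4] * 4)
        assert call_dmrs(t, self.params) == []

    def test_dis_merge_boundary(self):
        # two qualifying 6-CpG regions separated by a 3-CpG insignificant
        # stretch (which breaks the run) packed inside the gap
        for gap, expected in ((40, 1), (60, 2)):
            pos1 = np.arange(100, 100 + 300, 50)          # ends at 350
            region_end = pos1[-1] + 2                     # 352
            pos2_start = region_end + gap
            insig = np.linspace(region_end + 4, pos2_start - 6, 3).astype(int)
            pos2 = np.arange(pos2_start, pos2_start + 300, 50)
            pos = np.concatenate([pos1, insig, pos2])
            p = [1e-8] * 6 + [0.5] * 3 + [1e-8] * 6
            t = _tests_frame(pos, p, [0.4] * 15)
            dmrs = call_dmrs(t, self.params)
            assert len(dmrs) == expected, f"gap={gap}"

    def test_empty_input(self):
        assert call_dmrs(_tests_frame(np.array([], dtype=int), [], []),
                         self.params) == []

    def test_output_sorted_nonoverlapping(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(20_000, 300, replace=False))
        p = rng.uniform(0, 1, 300) ** 6
        diff = rng.choice([-0.4, 0.4], 300)
        dmrs = call_dmrs(_tests_frame(pos, p, diff), self.params)
        for a, b in zip(dmrs, dmrs[1:]):
            assert a.interval.end <= b.interval.start

    def test_oracle_equivalence_random_fixtures(self):
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 50))
            pos = np.sort(rng.choice(5000, n, replace=False))
            p = np.where(rng.random(n) < 0.5, 1e-8, 0.5)
            diff = rng.choice([-0.4, 0.4], n)
            t = _tests_frame(pos, p, diff)
            got = sorted(
                (d.interval.chrom, d.interval.start, d.interval.end, d.n_cpgs)
                for d in call_dmrs(t, self.params)
            )
            assert got == oracle_call_dmrs(t, self.params), f"seed={seed}"

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_oracle_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        pos = np.sort(rng.choice(3000, n, replace=False))
        p = np.where(rng.random(n) < 0.6, 1e-8, 0.5)
        diff = rng.choice([-0.4, 0.3, 0.4], n)
        t = _tests_frame(pos, p, diff)
        got = sorted(
            (d.interval.chrom, d.interval.start, d.interval.end, d.n_cpgs)
            for d in call_dmrs(t, self.params)
        )
        assert got == oracle_call_dmrs(t, self.params)

    def test_monotone_in_threshold_on_simulated_data(self):
        # relaxing the threshold does not reduce the DMR count on
        # realistic signal fixtures (merging pathologies aside)
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(100_000, 2000, replace=False))
        p = rng.uniform(0, 1, 2000) ** 8
        diff = np.where(rng.random(2000) < 0.8, 0.4, -0.4)
        t = _tests_frame(pos, p, diff)
        counts = []
        for thr in (1e-8, 1e-6, 1e-4, 1e-2):
            params = DmrCallParams(p_threshold=thr)
            counts.append(len(call_dmrs(t, params)))
        assert counts == sorted(counts)


class TestFilterDmrs:
    def test_small_effect_removed(self):
        d = Dmr(GenomicInterval("chr1", 0, 300), 6, 0.20, "a", 30.0)
        t = _tests_frame(np.arange(0, 300, 50), [1e-8] * 6, [0.2] * 6)
        assert filter_dmrs([d], t, DmrCallParams()) == []

    def test_low_coverage_removed(self):
        d = Dmr(GenomicInterval("chr1", 0, 300), 6, 0.4, "a", 30.0)
        t = _tests_frame(np.arange(0, 300, 50), [1e-8] * 6, [0.4] * 6)
        t.loc[t.index[:2], "t2"] = 3  # only 4 CpGs covered >= 5x in group 2
        assert filter_dmrs([d], t, DmrCallParams()) == []

    def test_good_dmr_kept(self):
        d = Dmr(GenomicInterval("chr1", 0, 300), 6, 0.4, "a", 30.0)
        t = _tests_frame(np.arange(0, 300, 50), [1e-8] * 6, [0.4] * 6)
        assert len(filter_dmrs([d], t, DmrCallParams())) == 1


# ---------------------------------------------------------------------------
# pipeline-level recovery and the empirical null
# ---------------------------------------------------------------------------

def _two_group_fixture(seed, n_dmrs=40, effect=0.4, coverage=20, phi=0.05,
                       n_bg=3000, reps=2):
    """Planted-DMR two-group fixture on one chromosome."""
    rng = np.random.default_rng(seed)
    dmr_regions = []
    pos_list = []
    mu_bg = []
    spacing = 4000
    for k in range(n_dmrs):
        start = 2000 + k * spacing
        dmr_regions.append(GenomicInterval("chr1", start, start + 500))
        pos_list.append(np.arange(start + 30, start + 500, 60))
    planted = np.concatenate(pos_list)
    genome_len = 2000 + n_dmrs * spacing + 50_000
    bg = np.sort(rng.choice(genome_len, n_bg, replace=False))
    bg = bg[~np.isin(bg, planted)]
    pos = np.sort(np.concatenate([planted, bg]))
    in_dmr = np.zeros(len(pos), dtype=bool)
    for r in dmr_regions:
        in_dmr |= (pos >= r.start) & (pos < r.end)
    mu1 = np.where(in_dmr, 0.85 - effect, 0.8)
    mu2 = np.full(len(pos), 0.8)
    mu2[in_dmr] = 0.85
    g1 = [make_meth_frame(rng, pos, mu1, coverage, phi) for _ in range(reps)]
    g2 = [make_meth_frame(rng, pos, mu2, coverage, phi) for _ in range(reps)]
    return g1, g2, dmr_regions


class TestDmrRecovery:
    def test_planted_recovery(self):
        g1, g2, regions = _two_group_fixture(seed=0)
        dmrs = dmr_pipeline(g1, g2)
        called = [d.interval for d in dmrs]
        rec = sum(any(r.overlaps(c) for c in called) for r in regions)
        prec = sum(any(c.overlaps(r) for r in regions) for c in called)
        assert rec / len(regions) >= 0.9
        assert prec / max(len(called), 1) >= 0.9
        # planted DMRs are hypomethylated in group 1
        assert all(d.hypo_in == "group1" for d in dmrs)


class TestEmpiricalNull:
    def test_null_vs_signal(self):
        g1, g2, _ = _two_group_fixture(seed=1, n_dmrs=30)
        thresholds = [1e-3, 1e-5]
        curve = empirical_null_curve(
            {"rep_pair": ([g1[0]], [g1[1]])},
            {"signal": (g1, g2)},
            thresholds,
        )
        for thr in thresholds:
            null = curve[(curve["kind"] == "replicate_null")
                         & (curve["p_threshold"] == thr)]["n_dmrs"].iloc[0]
            sig = curve[(curve["comparison"] == "signal")
                        & (curve["p_threshold"] == thr)]["n_dmrs"].iloc[0]
            assert sig >= 10 * max(null, 1)

    def test_empty_input(self):
        curve = empirical_null_curve({}, {}, [1e-5])
        assert len(curve) == 0 or curve["n_dmrs"].sum() == 0


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

class TestSummary:
    def test_fully_methylated(self):
        df = pd.DataFrame({"chrom": "chr1", "pos": [1, 2], "meth": [10, 8],
                           "total": [10, 8]})
        s = methylome_summary(df)
        assert s["global_mcg"] == 1.0 and s["frac_high"] == 1.0

    def test_two_cpgs_hand(self):
        df = pd.DataFrame({"chrom": "chr1", "pos": [1, 2], "meth": [8, 1],
                           "total": [10, 10]})
        s = methylome_summary(df)
        assert s["global_mcg"] == pytest.approx(0.45)
        assert s["frac_high"] == 0.5 and s["frac_low"] == 0.5

    def test_bins_partition(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"chrom": "chr1", "pos": np.arange(500),
                           "total": rng.poisson(20, 500) + 5})
        df["meth"] = rng.binomial(df["total"], rng.uniform(0, 1, 500))
        s = methylome_summary(df)
        assert s["frac_low"] + s["frac_medium"] + s["frac_high"] == \
            pytest.approx(1.0)


class TestStability:
    def test_identical(self):
        df = pd.DataFrame({"chrom": "chr1", "pos": [100, 150, 200],
                           "meth": [8, 8, 8], "total": [10, 10, 10]})
        r = stability_fraction([GenomicInterval("chr1", 50, 250)], df, df)
        assert r["fraction_stable"] == 1.0

    def test_planted_change(self):
        regions = [GenomicInterval("chr1", i * 1000, i * 1000 + 500)
                   for i in range(10)]
        pos = np.concatenate([np.arange(r.start + 50, r.end, 100)
                              for r in regions])
        t0 = pd.DataFrame({"chrom": "chr1", "pos": pos,
                           "meth": 16, "total": 20})
        t4 = t0.copy()
        mask = (t4["pos"] >= regions[0].start) & (t4["pos"] < regions[0].end)
        t4.loc[mask, "meth"] = 8  # delta 0.4 in region 0
        r = stability_fraction(regions, t0, t4)
        assert r["fraction_stable"] == pytest.approx(0.9)

    def test_missing_excluded(self):
        df = pd.DataFrame({"chrom": "chr1", "pos": [100], "meth": [8],
                           "total": [10]})
        empty = pd.DataFrame({"chrom": [], "pos": [], "meth": [], "total": []})
        r = stability_fraction([GenomicInterval("chr1", 50, 150)], df, empty)
        assert r["n_missing"] == 1 and r["n_evaluated"] == 0


class TestAggregateProfile:
    def test_constant_signal(self):
        sig = pd.DataFrame({"chrom": "chr1", "pos": np.arange(0, 20_000, 20),
                            "value": 0.8})
        ivs = [GenomicInterval("chr1", 9_000, 9_400)]
        mat, means = aggregate_profile(ivs, sig, flank=5000, n_bins=100)
        np.testing.assert_allclose(mat[0][~np.isnan(mat[0])], 0.8)

    def test_step_signal(self):
        pos = np.arange(0, 40_000, 10)
        inside = (pos >= 19_000) & (pos < 21_000)
        sig = pd.DataFrame({"chrom": "chr1", "pos": pos,
                            "value": np.where(inside, 0.0, 1.0)})
        ivs = [GenomicInterval("chr1", 19_000, 21_000)]
        mat, means = aggregate_profile(ivs, sig, flank=5000, n_bins=100)
        assert means[50] == pytest.approx(0.0)
        assert means[0] == pytest.approx(1.0)
        assert means[-1] == pytest.approx(1.0)

    def test_row_count(self):
        sig = pd.DataFrame({"chrom": "chr1", "pos": [100], "value": [1.0]})
        ivs = [GenomicInterval("chr1", 0, 200),
               GenomicInterval("chr1", 300, 500)]
        mat, _ = aggregate_profile(ivs, sig)
        assert mat.shape[0] == 2
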