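import math
from decimal import Decimal, getcontext

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epikit.io_formats import GenomicInterval, Pwm
from epikit.regulatory_network import (
    build_grn,
    compare_target_response,
    fit_footprint_model,
    motif_enrichment,
    scan_pwm,
    score_grna,
    select_upstream_tfs,
)


def sharp_pwm(consensus, name="m", p=0.85):
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = p
    return Pwm(name, mat)


RC = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(RC)[::-1]


class TestScanPwm:
    def test_planted_consensus_found(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 5000))
        cons = "ACGTACGTAA"
        seq = seq[:2000] + cons + seq[2000 + len(cons):]
        pwm = sharp_pwm(cons)
        hits = scan_pwm({"chr1": seq}, pwm)
        assert any(h.interval.start == 2000 and h.strand == "+" for h in hits)
        best = min(hits, key=lambda h: h.p)
        assert best.interval.start == 2000

    def test_reverse_complement_hit(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 3000))
        cons = "ACCGTTAGGC"
        seq = seq[:1000] + revcomp(cons) + seq[1000 + len(cons):]
        hits = scan_pwm({"chr1": seq}, sharp_pwm(cons))
        assert any(h.interval.start == 1000 and h.strand == "-" for h in hits)

    def test_strand_score_symmetry(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 500))
        pwm = sharp_pwm("ACGTAC" + "GTAC")
        fwd = scan_pwm({"s": seq}, pwm, p_threshold=1.1)
        rev = scan_pwm({"s": revcomp(seq)}, pwm, p_threshold=1.1)
        f = {(h.interval.start, h.strand): h.score for h in fwd}
        n = len(seq) - len(pwm) + 1
        r = {(n - 1 - h.interval.start,
              "+" if h.strand == "-" else "-"): h.score
             for h in rev}
        shared = set(f) & set(r)
        assert len(shared) == len(f) == len(r)
        for k in shared:
            assert f[k] == pytest.approx(r[k], abs=1e-9)

    def test_short_sequence_no_hits(self):
        assert scan_pwm({"s": "ACG"}, sharp_pwm("ACGTACGTAA")) == []

    def test_dp_matches_exhaustive_enumeration(self):
        # 4-long PWM: enumerate all 256 tetramers under a uniform
        # background and compare the DP tail with the exact mass
        rng = np.random.default_rng(3)
        mat = rng.dirichlet(np.ones(4) * 2, size=4)
        pwm = Pwm("t", mat)
        bg = np.full(4, 0.25)
        bin_bits = 0.01
        lods = np.log2(pwm.matrix / bg)
        q = np.round(lods / bin_bits).astype(int)

        def quantized_score(word):
            return sum(q[i, b] for i, b in enumerate(word))

        words = [(a, b, c, d) for a in range(4) for b in range(4)
                 for c in range(4) for d in range(4)]
        qscores = np.array([quantized_score(w) for w in words])

        # scan every tetramer and compare its reported p with the
        # enumeration tail at its own quantized score
        from epikit.regulatory_network import _score_pvalue_table

        _, sf, min_total = _score_pvalue_table(pwm, bg, bin_bits)
        for w, qs in zip(words[:64], qscores[:64]):
            p_dp = sf[qs - min_total]
            p_enum = (qscores >= qs).mean()
            assert p_dp == pytest.approx(p_enum, abs=1e-12)


class TestEnrichment:
    def test_exact_binomial_tail(self):
        n, k, q = 100, 50, 0.1
        hits = {"m": [GenomicInterval(f"t{i}", 10, 20) for i in range(k)]}
        targets = [GenomicInterval(f"t{i}", 0, 100) for i in range(n)]
        bg = [GenomicInterval(f"b{i}", 0, 100) for i in range(1000)]
        hits["m"] += [GenomicInterval(f"b{i}", 10, 20) for i in range(100)]
        res = motif_enrichment(hits, targets, bg)
        p = res.loc[res["pwm"] == "m", "p"].iloc[0]
        getcontext().prec = 60
        exact = sum(
            Decimal(math.comb(n, j)) * Decimal(1) / Decimal(10) ** j
            * (Decimal(9) / Decimal(10)) ** (n - j)
            for j in range(k, n + 1)
        )
        assert abs(p - float(exact)) / float(exact) < 1e-12

    def test_null_rate_not_significant(self):
        rng = np.random.default_rng(4)
        targets = [GenomicInterval(f"t{i}", 0, 100) for i in range(100)]
        bg = [GenomicInterval(f"b{i}", 0, 100) for i in range(100)]
        hits = {"m": [GenomicInterval(f"t{i}", 0, 10)
                      for i in range(100) if rng.random() < 0.3]
                + [GenomicInterval(f"b{i}", 0, 10)
                   for i in range(100) if rng.random() < 0.3]}
        res = motif_enrichment(hits, targets, bg)
        assert res["p"].iloc[0] > 0.05

    def test_planted_motif_ranks_first(self, small_config):
        from epikit import synthetic_data as sd
        from epikit.regulatory_network import scan_pwm as scan

        layout = sd.build_layout(small_config)
        seqs, _, pwms, _, truth = sd.simulate_genome(small_config, layout)
        control = sharp_pwm("ATATGCGCATAT"[:10], name="control")
        gained = {d["peak"] for d in truth.dars if d["direction"] == "gained"}
        targets = [layout.peaks[i] for i in sorted(gained)]
        bg = [p for i, p in enumerate(layout.peaks) if i not in gained]
        hits = {p.name: scan(seqs, p) for p in list(pwms) + [control]}
        res = motif_enrichment(hits, targets, bg)
        assert res.iloc[0]["pwm"] != "control"
        assert res.iloc[0]["p"] < res[res["pwm"] == "control"]["p"].iloc[0]


def _footprint_fixture(seed, n=500, depth=100, depletion=0.7):
    rng = np.random.default_rng(seed)
    w = 200
    prof = np.full(w, 1.0)
    prof[:50] *= 1.5
    prof[-50:] *= 1.5
    prof[95:105] = (1 - depletion) * 1.5
    prof /= prof.sum()
    labels = np.zeros(n, dtype=bool)
    labels[: n // 2] = True
    X = np.zeros((n, w))
    for i in range(n):
        p = prof if labels[i] else np.full(w, 1 / w)
        X[i] = rng.multinomial(rng.poisson(depth), p)
    scores = rng.normal(labels * 2.0, 1.0)
    return X, scores, labels


class TestFootprint:
    def test_classification_and_precision(self):
        X, scores, labels = _footprint_fixture(seed=0)
        fit = fit_footprint_model(X, scores, seed=0)
        assert (((fit.posterior > 0.5) == labels).mean()) >= 0.9
        called = fit.posterior > 0.95
        assert called.any()
        assert labels[called].mean() >= 0.95

    def test_identical_windows_equal_posteriors(self):
        X = np.tile(np.full(200, 0.5), (30, 1))
        fit = fit_footprint_model(X, np.zeros(30), seed=0)
        assert np.allclose(fit.posterior, fit.posterior[0], atol=1e-6)

    def test_loglik_monotone(self):
        for seed in range(3):
            X, scores, _ = _footprint_fixture(seed=seed, n=200)
            fit = fit_footprint_model(X, scores, seed=0)
            diffs = np.diff(fit.loglik_trace)
            assert np.all(diffs >= -1e-6)

    def test_refuses_below_20_sites(self):
        X, scores, _ = _footprint_fixture(seed=1, n=10)
        with pytest.warns(UserWarning):
            fit = fit_footprint_model(X, scores, seed=0)
        assert np.allclose(fit.posterior, 0.5)
        assert not fit.converged

    def test_seed_determinism(self):
        X, scores, _ = _footprint_fixture(seed=2, n=100)
        f1 = fit_footprint_model(X, scores, seed=3)
        f2 = fit_footprint_model(X, scores, seed=3)
        np.testing.assert_array_equal(f1.posterior, f2.posterior)

    def test_conservation_nan_imputed(self):
        X, scores, _ = _footprint_fixture(seed=4, n=60)
        cons = np.full(60, np.nan)
        cons[:30] = 0.5
        fit = fit_footprint_model(X, scores, conservation=cons, seed=0)
        assert np.all(np.isfinite(fit.posterior))


class TestSelectTfs:
    def _expr(self, rows):
        cols = [f"t{t}_r{r}" for t in (0, 1, 2, 4) for r in (1, 2)]
        design = pd.DataFrame({
            "sample": cols,
            "timepoint": [t for t in (0, 1, 2, 4) for _ in (1, 2)],
        })
        return pd.DataFrame(rows, columns=cols), design

    def test_selection_logic(self):
        expr, design = self._expr({
            "gflat": [100] * 8,
            "gup": [100, 100, 300, 300, 300, 300, 300, 300],
        }.values())
        expr.index = ["gflat", "gup"]
        enrich = pd.DataFrame({
            "pwm": ["Mflat", "Mup", "Mnone"],
            "p": [1e-8, 1e-8, 0.5],
            "fdr": [1e-7, 1e-7, 0.5],
        })
        mapping = {"Mflat": "gflat", "Mup": "gup", "Mnone": "gup"}
        out = select_upstream_tfs(enrich, expr, design, mapping)
        assert out == ["Mup"]


def _tss(chrom, pos, gid):
    return (chrom, pos, gid)


class TestBuildGrn:
    def test_edge_fires(self):
        site = GenomicInterval("chr1", 1000, 1010)
        dar = GenomicInterval("chr1", 800, 1200)
        edges = build_grn(["TF0"], [("TF0", site)], [dar],
                         [_tss("chr1", 5000, "gA")], {"gA"}, {"TF0": "gTF"})
        assert len(edges) == 1
        assert edges[0].target == "gA" and edges[0].edge_type == "tf_target"

    def test_not_upregulated_no_edge(self):
        site = GenomicInterval("chr1", 1000, 1010)
        dar = GenomicInterval("chr1", 800, 1200)
        edges = build_grn(["TF0"], [("TF0", site)], [dar],
                         [_tss("chr1", 5000, "gA")], set(), {"TF0": "gTF"})
        assert edges == []

    def test_outside_dar_no_edge(self):
        site = GenomicInterval("chr1", 5000, 5010)
        dar = GenomicInterval("chr1", 800, 1200)
        edges = build_grn(["TF0"], [("TF0", site)], [dar],
                         [_tss("chr1", 5000, "gA")], {"gA"}, {"TF0": "gTF"})
        assert edges == []

    def test_auto_and_tf_tf_edges(self):
        site0 = GenomicInterval("chr1", 1000, 1010)
        site1 = GenomicInterval("chr1", 21_000, 21_010)
        dars = [GenomicInterval("chr1", 900, 1100),
                GenomicInterval("chr1", 20_900, 21_100)]
        tss = [_tss("chr1", 2000, "g0"), _tss("chr1", 22_000, "g1")]
        mapping = {"TF0": "g0", "TF1": "g1"}
        edges = build_grn(["TF0", "TF1"],
                         [("TF0", site0), ("TF0", site1)],
                         dars, tss, {"g0", "g1"}, mapping)
        types = {(e.tf, e.target): e.edge_type for e in edges}
        assert types[("TF0", "g0")] == "auto"
        assert types[("TF0", "g1")] == "tf_tf"

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        sites = [("TF0", GenomicInterval("chr1", int(p), int(p) + 10))
                 for p in rng.integers(0, 100_000, 30)]
        dars = [GenomicInterval("chr1", i * 2000, i * 2000 + 500)
                for i in range(50)]
        tss = [_tss("chr1", i * 2000 + 1500, f"g{i}") for i in range(50)]
        up = {f"g{i}" for i in range(0, 50, 2)}
        a = build_grn(["TF0"], sites, dars, tss, up, {"TF0": "gx"})
        b = build_grn(["TF0"], sites[::-1], dars[::-1], tss[::-1], up,
                      {"TF0": "gx"})
        assert [(e.tf, e.target) for e in a] == [(e.tf, e.target) for e in b]


class TestCompareResponse:
    def test_identical_fold_changes(self):
        fc = {f"g{i}": float(i) for i in range(10)}
        out = compare_target_response(fc, fc, set(fc), set())
        assert out["targets"]["p"] == 1.0

    def test_attenuated_targets(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(200)]
        wt = {g: float(rng.normal(2, 0.5)) for g in genes}
        mut = {g: (wt[g] * 0.5 if i < 100 else wt[g] + rng.normal(0, 0.05))
               for i, g in enumerate(genes)}
        out = compare_target_response(mut, wt, set(genes[:100]),
                                      set(genes[100:]))
        assert out["targets"]["p"] < 0.001
        assert out["nontargets"]["p"] > 0.05

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(50)]
        a = {g: float(rng.normal(1, 1)) for g in genes}
        b = {g: float(rng.normal(1.5, 1)) for g in genes}
        p1 = compare_target_response(a, b, set(genes), set())["targets"]["p"]
        p2 = compare_target_response(b, a, set(genes), set())["targets"]["p"]
        assert p1 == pytest.approx(p2)


class TestScoreGrna:
    def test_all_g(self):
        assert score_grna("G" * 20, 1.0, 0.0) == 72.0

    def test_all_at_ending_t(self):
        assert score_grna("A" * 19 + "T", 0.0, 1.0) == -30.0

    def test_hand_mixed(self):
        seq = "G" * 10 + "T" * 9 + "A"  # GC 0.5, ends in A
        assert score_grna(seq, 0.5, 0.5) == 17.0

    def test_monotone_gc(self):
        scores = [score_grna("G" * k + "T" * (20 - k), 0.5, 0.5)
                  for k in range(1, 19)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_monotone_relpos(self):
        s = [score_grna("G" * 20, 0.5, r) for r in (0.0, 0.3, 0.7, 1.0)]
        assert all(b < a for a, b in zip(s, s[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            score_grna("ACGT", 0.5, 0.5)
        with pytest.raises(ValueError):
            score_grna("N" * 20, 0.5, 0.5)
        with pytest.raises(ValueError):
            score_grna("A" * 20, 1.5, 0.5)
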