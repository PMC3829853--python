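import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crcnet.stats import (crosstab_association, km_logrank,
                          select_development_genes, signature_score,
                          stage_correlation)


def expand_counts(counts: pd.DataFrame):
    """Turn a printed contingency table into per-sample label maps."""
    a, b = {}, {}
    i = 0
    for row in counts.index:
        for col in counts.columns:
            for _ in range(int(counts.at[row, col])):
                a[f"s{i}"] = row
                b[f"s{i}"] = col
                i += 1
    return pd.Series(a), pd.Series(b)


class TestCrosstab:
    def test_row_percentage_hand_cell(self):
        # 40 of a 68-sample row -> 59% row percentage
        counts = pd.DataFrame([[40, 10, 18], [5, 14, 13], [13, 13, 25]],
                              index=["S1", "S2", "S3"],
                              columns=["MSI/CIMP", "Invasive", "CIN"])
        a, b = expand_counts(counts)
        out = crosstab_association(a, b)
        cell = out[(out["row"] == "S1") & (out["col"] == "MSI/CIMP")].iloc[0]
        assert round(cell["row_pct"]) == 59
        assert cell["count"] == 40

    def test_independent_labels_fold_near_one(self):
        rng = np.random.default_rng(0)
        folds = []
        for rep in range(200):
            idx = [f"s{i}" for i in range(120)]
            a = pd.Series(rng.integers(0, 3, size=120), index=idx)
            b = pd.Series(rng.integers(0, 2, size=120), index=idx)
            out = crosstab_association(a, b)
            folds.append(out["fold"].mean())
        assert np.mean(folds) == pytest.approx(1.0, abs=0.05)

    def test_hypergeometric_p_matches_enumeration(self):
        # diagonal 2x2 table (10, 0; 0, 10)
        counts = pd.DataFrame([[10, 0], [0, 10]], index=["r1", "r2"],
                              columns=["c1", "c2"])
        a, b = expand_counts(counts)
        out = crosstab_association(a, b)
        cell = out[(out["row"] == "r1") & (out["col"] == "c1")].iloc[0]
        # exact tail: P(X >= 10), X ~ Hypergeom(N=20, K=10, n=10)
        from math import comb
        expected = comb(10, 10) * comb(10, 0) / comb(20, 10)
        assert cell["p"] == pytest.approx(expected, rel=1e-10)

    def test_small_table_p_matches_enumeration_everywhere(self):
        from math import comb
        counts = pd.DataFrame([[3, 2], [1, 4]], index=["r1", "r2"],
                              columns=["c1", "c2"])
        a, b = expand_counts(counts)
        out = crosstab_association(a, b)
        for _, cell in out.iterrows():
            N = 10
            K = int(cell["col_total"])
            n = int(cell["row_total"])
            k = int(cell["count"])
            tail = sum(comb(K, x) * comb(N - K, n - x) / comb(N, n)
                       for x in range(k, min(K, n) + 1))
            assert cell["p"] == pytest.approx(tail, rel=1e-10)

    def test_no_shared_samples_errors(self):
        with pytest.raises(ValueError):
            crosstab_association(pd.Series({"a": 1}), pd.Series({"b": 1}))


class TestDevelopmentGenes:
    def _timecourse(self, rows, genes):
        return pd.DataFrame(rows, index=genes,
                            columns=[f"t{j}" for j in range(len(rows[0]))])

    def test_monotone_gene_passes(self):
        tc = self._timecourse([[1, 2, 3, 4, 5, 6, 7],
                               [5, 5, 5, 5, 5, 5, 5]], ["inc", "const"])
        genes = select_development_genes(tc)
        assert genes == ["inc"]

    def test_top_n_by_mad_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        n = 150
        scale = rng.exponential(1.0, size=n) + 0.1
        rows = np.outer(scale, np.arange(7.0))
        tc = self._timecourse(rows, [f"g{i:03d}" for i in range(n)])
        top = select_development_genes(tc, top_n=100)
        mad = tc.sub(tc.median(axis=1), axis=0).abs().median(axis=1)
        expected = list(mad.sort_values(ascending=False, kind="stable")
                        .index[:100])
        assert top == expected

    def test_no_passing_gene_errors(self):
        rng = np.random.default_rng(2)
        tc = self._timecourse(rng.normal(size=(5, 8)),
                              [f"g{i}" for i in range(5)])
        with pytest.raises(ValueError):
            select_development_genes(tc, rho_threshold=0.999)


class TestStageCorrelation:
    def test_matching_and_negated_profiles(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        profile = rng.normal(size=30)
        tc = pd.DataFrame({"early": profile, "late": rng.normal(size=30)},
                          index=genes)
        centroids = pd.DataFrame({"sub1": profile, "sub2": -profile},
                                 index=genes)
        out = stage_correlation(centroids, tc, genes)
        r1 = out[(out["subtype"] == "sub1")
                 & (out["timepoint"] == "early")].iloc[0]
        r2 = out[(out["subtype"] == "sub2")
                 & (out["timepoint"] == "early")].iloc[0]
        assert r1["r"] == pytest.approx(1.0)
        assert r2["r"] == pytest.approx(-1.0)
        assert r1["ci_low"] <= r1["r"] <= r1["ci_high"]

    def test_noisy_subtype_tracks_its_stage(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(200)]
        early = rng.normal(size=200)
        late = rng.normal(size=200)
        tc = pd.DataFrame({"early": early, "mid": (early + late) / 2,
                           "late": late}, index=genes)
        centroids = pd.DataFrame(
            {"sub": early + rng.normal(0, 0.5, size=200)}, index=genes)
        out = stage_correlation(centroids, tc, genes)
        best = out.loc[out["r"].idxmax()]
        assert best["timepoint"] == "early"

    def test_too_few_genes_errors(self):
        tc = pd.DataFrame({"t0": [1.0, 2.0]}, index=["a", "b"])
        cent = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            stage_correlation(cent, tc, ["a", "b"])


class TestSignatureScore:
    def test_single_gene_set(self, expr_factory):
        expr = expr_factory([[1.0, -2.0, 3.0]])
        score = signature_score(expr, ["g0"])
        assert np.allclose(score, [1.0, -2.0, 3.0])

    def test_centered_data_scores_near_zero(self, expr_factory):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(50, 30))
        values -= values.mean(axis=1, keepdims=True)
        expr = expr_factory(values)
        score = signature_score(expr, [f"g{i}" for i in range(0, 50, 3)])
        assert score.mean() == pytest.approx(0.0, abs=0.1)

    def test_planted_shift_recovered(self, expr_factory):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 0.2, size=(40, 60))
        # EMT-like +1 shift for samples 0..19 on genes 0..9
        values[:10, :20] += 1.0
        expr = expr_factory(values)
        score = signature_score(expr, [f"g{i}" for i in range(10)])
        assert score.iloc[:20].mean() == pytest.approx(1.0, abs=0.1)
        assert score.iloc[20:].mean() == pytest.approx(0.0, abs=0.1)

    def test_absent_set_errors(self, expr_factory):
        expr = expr_factory([[1.0, 2.0]])
        with pytest.raises(ValueError):
            signature_score(expr, ["nope"])


class TestKMLogrank:
    def _table(self, times, events, groups):
        return pd.DataFrame({"sample": [f"s{i}" for i in range(len(times))],
                             "time": times, "event": events,
                             "group": groups})

    def test_identical_groups_null(self):
        surv = self._table([5, 10, 15, 5, 10, 15], [1, 1, 0, 1, 1, 0],
                           ["a"] * 3 + ["b"] * 3)
        res = km_logrank(surv)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_statistic_matches_hand_tabulation(self):
        # fixed 8-sample, 2-group table
        times = [6, 6, 6, 7, 10, 12, 13, 15]
        events = [1, 1, 0, 1, 1, 0, 1, 1]
        groups = ["a", "a", "a", "a", "b", "b", "b", "b"]
        surv = self._table(times, events, groups)
        res = km_logrank(surv)

        # brute-force observed-minus-expected over event times (group a)
        df = surv.sort_values("time")
        obs_a = exp_a = var_a = 0.0
        for t in sorted(df.loc[df.event == 1, "time"].unique()):
            at_risk = df[df.time >= t]
            n = len(at_risk)
            n_a = (at_risk.group == "a").sum()
            d = ((df.time == t) & (df.event == 1)).sum()
            d_a = ((df.time == t) & (df.event == 1)
                   & (df.group == "a")).sum()
            obs_a += d_a
            exp_a += d * n_a / n
            if n > 1:
                var_a += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected_chi2 = (obs_a - exp_a) ** 2 / var_a
        assert res.statistic == pytest.approx(expected_chi2, rel=1e-6)
        assert res.df == 1

    def test_km_curve_shape(self):
        surv = self._table([2, 4, 6, 3, 5, 7], [1, 1, 1, 1, 0, 1],
                           ["a"] * 3 + ["b"] * 3)
        res = km_logrank(surv)
        for curve in res.curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)    # before first event
            assert (np.diff(s) <= 1e-12).all()   # non-increasing

    def test_single_group_errors(self):
        surv = self._table([1, 2], [1, 1], ["a", "a"])
        with pytest.raises(ValueError):
            km_logrank(surv)
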