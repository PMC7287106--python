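import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isomirseq.diffexp import (
    CONCORDANCE_CATEGORIES,
    DispersionEstimate,
    bh_adjust,
    classify_concordance,
    cpm_filter,
    differential_expression,
    equalize_library_sizes,
    estimate_dispersion,
    exact_test,
    group_log2fc,
    log2fc_from_means,
    select_strong,
)
from isomirseq.simulate import simulate_nb_matrix


def oracle_exact_p(total, a_obs, n_a, n_b, phi, tol=1e-8):
    """Independent two-sided conditional p via scipy's closed-form laws.

    phi = 0: Binomial(total, n_a/(n_a+n_b)). phi > 0: the split of a sum of
    iid NB counts given the total is beta-binomial with a = n_a/phi,
    b = n_b/phi (two-category Dirichlet-multinomial).
    """
    k = np.arange(total + 1)
    if phi == 0:
        pmf = stats.binom.pmf(k, total, n_a / (n_a + n_b))
    else:
        pmf = stats.betabinom.pmf(k, total, n_a / phi, n_b / phi)
    return min(1.0, pmf[pmf <= pmf[a_obs] * (1 + tol)].sum())


class TestLog2FC:
    @pytest.mark.parametrize(
        "mean_a,mean_b,expected",
        [(5.76, 163.17, 4.82), (4.33, 39.28, 3.18), (218299.38, 36740.32, -2.57),
         (1286.41, 70.65, -4.19)],
    )
    def test_reported_mean_pairs(self, mean_a, mean_b, expected):
        assert round(float(log2fc_from_means(mean_a, mean_b)), 2) == expected

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(1, 1e5, 50), rng.uniform(1, 1e5, 50)
        assert np.allclose(log2fc_from_means(a, b), -log2fc_from_means(b, a))

    def test_zero_mean_flagged_not_dropped(self):
        counts = pd.DataFrame(
            {"a1": [0, 50], "a2": [0, 50], "b1": [10, 40], "b2": [10, 40]},
            index=["f", "g"],
        )
        groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        out = group_log2fc(counts, groups, "A", "B")
        assert not out.loc["f", "finite"] and np.isposinf(out.loc["f", "log2fc"])
        assert out.loc["g", "finite"]

    def test_pseudocount_makes_finite(self):
        lfc = log2fc_from_means([0.0], [100.0], pseudocount=1.0)
        assert np.isfinite(lfc[0])

    def test_empty_group_rejected(self):
        counts = pd.DataFrame({"a1": [1]}, index=["f"])
        with pytest.raises(ValueError, match="empty group"):
            group_log2fc(counts, pd.Series({"a1": "A"}), "A", "B")


class TestEqualization:
    def test_equal_libraries_are_identity(self):
        counts = pd.DataFrame({"s1": [10, 20, 70], "s2": [30, 30, 40]})
        out, common = equalize_library_sizes(counts)
        assert np.array_equal(out.values, counts.values.astype(float))
        assert common == pytest.approx(100.0)

    def test_column_totals_move_toward_common(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.poisson([200, 400, 800], size=(60, 3)),
                              columns=["s1", "s2", "s3"])
        out, common = equalize_library_sizes(counts, dispersion=0.1)
        new_lib = out.sum(axis=0)
        assert np.all(np.abs(new_lib - common) < np.abs(counts.sum(axis=0) - common))

    def test_nonnegative_and_deterministic(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson([100, 900], size=(40, 2)))
        o1, _ = equalize_library_sizes(counts, dispersion=0.2)
        o2, _ = equalize_library_sizes(counts, dispersion=0.2)
        assert (o1.values >= 0).all() and o1.equals(o2)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0], "s2": [5]})
        with pytest.raises(ValueError, match="zero library"):
            equalize_library_sizes(counts)


class TestDispersion:
    @staticmethod
    def groups_for(counts, n_a):
        labels = ["A"] * n_a + ["B"] * (counts.shape[1] - n_a)
        return pd.Series(labels, index=counts.columns)

    def test_poisson_data_drives_phi_to_floor(self):
        rng = np.random.default_rng(10)
        counts = pd.DataFrame(rng.poisson(200, size=(300, 8)))
        est = estimate_dispersion(counts, self.groups_for(counts, 4), "A", "B")
        assert est.common_phi < 5e-3

    def test_recovers_injected_dispersion(self):
        counts, groups = simulate_nb_matrix(800, 5, 5, dispersion=0.4, seed=3)
        est = estimate_dispersion(counts, groups, "A", "B")
        assert 0.25 < est.common_phi < 0.60

    def test_large_prior_collapses_tagwise_to_common(self):
        counts, groups = simulate_nb_matrix(100, 4, 4, dispersion=0.2, seed=6)
        est = estimate_dispersion(counts, groups, "A", "B", prior_df=1e9)
        assert np.abs(est.tagwise_phi - est.common_phi).max() < 1e-6

    def test_small_prior_lets_tagwise_spread(self):
        counts, groups = simulate_nb_matrix(100, 4, 4, dispersion=0.2, seed=6)
        tight = estimate_dispersion(counts, groups, "A", "B", prior_df=1e9)
        loose = estimate_dispersion(counts, groups, "A", "B", prior_df=1.0)
        assert loose.tagwise_phi.std() > tight.tagwise_phi.std()

    def test_all_zero_matrix_warns_zero(self):
        counts = pd.DataFrame(0, index=["f"], columns=["a", "b"])
        est = estimate_dispersion(counts, pd.Series({"a": "A", "b": "B"}), "A", "B")
        assert est.common_phi == 0.0


class TestExactTest:
    def test_matches_binomial_oracle_poisson_limit(self):
        n_a, n_b = 2, 7
        worst = 0.0
        from isomirseq.diffexp import _exact_p

        for total in range(1, 120):
            for a_obs in range(total + 1):
                p = _exact_p(total, a_obs, n_a, n_b, 0.0)
                q = oracle_exact_p(total, a_obs, n_a, n_b, 0.0)
                worst = max(worst, abs(p - q))
        assert worst < 1e-10

    @pytest.mark.parametrize("phi", [0.05, 0.2, 1.0])
    def test_matches_betabinomial_oracle(self, phi):
        from isomirseq.diffexp import _exact_p

        n_a, n_b = 3, 5
        worst = 0.0
        for total in range(1, 80):
            for a_obs in range(0, total + 1, 3):
                p = _exact_p(total, a_obs, n_a, n_b, phi)
                q = oracle_exact_p(total, a_obs, n_a, n_b, phi)
                worst = max(worst, abs(p - q))
        assert worst < 1e-10

    def test_duplicated_balanced_columns_give_p_one(self):
        col = np.array([40, 7, 130, 0, 55])
        counts = pd.DataFrame({"a1": col, "a2": col, "b1": col, "b2": col})
        groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        p = exact_test(counts, groups, 0.1, "A", "B")
        assert np.allclose(p.values, 1.0)

    def test_label_swap_invariance_balanced(self):
        counts, groups = simulate_nb_matrix(50, 4, 4, dispersion=0.2, seed=8)
        p1 = exact_test(counts, groups, 0.2, "A", "B")
        p2 = exact_test(counts, groups, 0.2, "B", "A")
        assert np.allclose(p1.values, p2.values)

    def test_extreme_split_is_small(self):
        from isomirseq.diffexp import _exact_p

        assert _exact_p(200, 0, 5, 5, 0.0) < 1e-20
        assert _exact_p(0, 0, 5, 5, 0.2) == 1.0

    def test_type_one_error_calibration(self):
        counts, groups = simulate_nb_matrix(3000, 5, 5, dispersion=0.2, seed=42)
        est = estimate_dispersion(counts, groups, "A", "B")
        p = exact_test(counts, groups, est, "A", "B")
        rate = float((p < 0.05).mean())
        assert 0.02 < rate < 0.08
        assert (bh_adjust(p.values) < 0.1).mean() <= 0.01


class TestEdgeROracle:
    def test_agrees_with_edger_doubletail(self, tmp_path):
        """Cross-check against edgeR's exact test on a balanced design.

        With equal group sizes the smallp and doubletail two-sided conventions
        coincide by symmetry, and small totals keep edgeR on its exact path.
        """
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the cross-check oracle")
        rng = np.random.default_rng(17)
        counts = pd.DataFrame(
            rng.negative_binomial(1 / 0.15, (1 / 0.15) / (1 / 0.15 + 25), size=(40, 10)),
            columns=[f"s{i}" for i in range(10)],
        )
        counts.to_csv(tmp_path / "counts.tsv", sep="\t")
        script = textwrap.dedent(
            """\
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim("counts.tsv", row.names = 1))
            grp <- factor(rep(c("A", "B"), each = 5))
            d <- DGEList(counts = x, group = grp)
            d$samples$norm.factors <- rep(1, ncol(x))
            et <- exactTest(d, dispersion = 0.15, rejection.region = "doubletail")
            write.table(data.frame(feature = rownames(et$table), p = et$table$PValue),
                        "edger_p.tsv", sep = "\\t", row.names = FALSE, quote = FALSE)
            """
        )
        (tmp_path / "run.R").write_text(script)
        subprocess.run(
            ["Rscript", "run.R"], cwd=tmp_path, check=True,
            capture_output=True, timeout=300,
        )
        edger = pd.read_csv(tmp_path / "edger_p.tsv", sep="\t").set_index("feature")["p"]
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=counts.columns)
        ours = exact_test(counts, groups, 0.15, "A", "B")
        diff = np.abs(ours.values - edger.reindex(ours.index).values)
        assert diff.max() < 1e-8


class TestBH:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        assert bh_adjust([]).size == 0


class TestSelection:
    def make_results(self):
        return pd.DataFrame(
            {
                "mean_cpm_a": [5.0, 100.0, 9.9, 50.0, 400.0],
                "mean_cpm_b": [80.0, 420.0, 9.9, 4.0, 100.0],
                "log2fc": [4.0, 2.0748, 0.0, -3.64, -2.0],
                "fdr_bh": [0.04, 0.5, 0.9, 0.2, 0.04],
            },
            index=["up_big", "up_mid", "flat_low", "down_big", "down_exact"],
        )

    def test_strict_lfc_boundary(self):
        out = select_strong(self.make_results(), lfc_threshold=2.0)
        assert "down_exact" not in out.index  # |log2fc| == 2.0 exactly
        assert list(out.index) == ["up_big", "up_mid", "down_big"]
        assert list(out["direction"]) == ["up", "up", "down"]

    def test_group_size_weighted_cpm_floor(self):
        res = pd.DataFrame(
            {
                "mean_cpm_a": [9.0, 2.0],
                "mean_cpm_b": [10.2, 200.0],
                "log2fc": [3.0, 6.64],
                "fdr_bh": [0.01, 0.01],
            },
            index=["borderline", "clear"],
        )
        # (2*9.0 + 7*10.2)/9 = 9.93 < 10 -> borderline excluded
        out = select_strong(res, group_sizes=(2, 7))
        assert list(out.index) == ["clear"]
        out2 = select_strong(res)
        assert "borderline" in out2.index

    def test_significance_flag(self):
        out = select_strong(self.make_results(), fdr_threshold=0.1)
        assert bool(out.loc["up_big", "significant"])
        assert not bool(out.loc["up_mid", "significant"])

    def test_cpm_filter_threshold_inclusive(self):
        # "edge" sits at exactly 10 CPM: the floor is inclusive
        counts = pd.DataFrame(
            {"s1": [1, 10, 999989], "s2": [1, 10, 999989]},
            index=["lo", "edge", "hi"],
        )
        assert cpm_filter(counts, min_mean_cpm=10.0) == ["edge", "hi"]
        assert cpm_filter(counts, min_mean_cpm=10.0001) == ["hi"]


class TestConcordance:
    def test_all_four_categories(self):
        disc = pd.DataFrame({"log2fc": [3.0, 2.5, -4.0, 2.2]},
                            index=["conf", "nodiff", "opp", "notexpr"])
        val = pd.DataFrame({"log2fc": [1.5, 0.2, 1.1, 5.0]},
                           index=["conf", "nodiff", "opp", "notexpr"])
        out = classify_concordance(disc, val, {"conf", "nodiff", "opp"})
        assert out.loc["conf", "category"] == "confirmed"
        assert out.loc["nodiff", "category"] == "no_difference"
        assert out.loc["opp", "category"] == "opposite"
        assert out.loc["notexpr", "category"] == "not_expressed"
        assert np.isnan(out.loc["notexpr", "validation_log2fc"])
        assert set(out["category"]) <= set(CONCORDANCE_CATEGORIES)

    def test_lfc_min_boundary(self):
        disc = pd.DataFrame({"log2fc": [2.0]}, index=["f"])
        val = pd.DataFrame({"log2fc": [0.5]}, index=["f"])
        out = classify_concordance(disc, val, {"f"}, lfc_min=0.5)
        assert out.loc["f", "category"] == "confirmed"  # strict < for no_difference

    def test_duplicate_ids_rejected(self):
        disc = pd.DataFrame({"log2fc": [1.0, 2.0]}, index=["f", "f"])
        val = pd.DataFrame({"log2fc": [1.0]}, index=["f"])
        with pytest.raises(ValueError, match="duplicate"):
            classify_concordance(disc, val, {"f"})


class TestIntegration:
    def test_injected_effects_recovered_end_to_end(self):
        rng = np.random.default_rng(21)
        n, n_de = 200, 20
        mu = rng.uniform(50, 500, size=n)
        lfc = np.zeros(n)
        lfc[:n_de] = np.where(np.arange(n_de) % 2 == 0, 3.0, -3.0)
        phi = 0.15
        r = 1 / phi
        cols = {}
        for j in range(5):
            cols[f"a{j}"] = rng.negative_binomial(r, r / (r + mu))
        for j in range(5):
            mu_b = mu * 2.0 ** lfc
            cols[f"b{j}"] = rng.negative_binomial(r, r / (r + mu_b))
        counts = pd.DataFrame(cols, index=[f"f{i}" for i in range(n)])
        groups = pd.Series({c: ("A" if c.startswith("a") else "B") for c in counts.columns})
        res = differential_expression(counts, groups, "A", "B")
        strong = select_strong(res)
        true_de = {f"f{i}" for i in range(n_de)}
        hit = true_de & set(strong[strong["significant"]].index)
        assert len(hit) >= 0.9 * n_de
        false = set(strong[strong["significant"]].index) - true_de
        assert len(false) <= 0.01 * (n - n_de) + 1
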