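"""Differential-expression tests: the three statistics and the combined screen."""

import shutil
import subprocess
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ibstriage as ib
from ibstriage.de import InsufficientDataError, estimate_variance_prior, top_n_filter


class TestStudentT:
    def test_identical_groups_null(self):
        assert ib.student_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_textbook_pooled_variance_case(self):
        # pooled-variance t with df=4 on (1,2,3) vs (4,5,6)
        # t = -3/sqrt(2/3) = -3.6742, df = 4 -> two-tailed p = 0.021312
        assert ib.student_t_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.021312, abs=5e-6)

    def test_zero_variance_conventions(self):
        assert ib.student_t_test([2.0, 2.0], [2.0, 2.0]) == 1.0
        assert ib.student_t_test([2.0, 2.0], [3.0, 3.0]) == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            ib.student_t_test([1.0], [2.0, 3.0])


def _enumerate_mw_p(x, y):
    """Exact two-tailed Mann-Whitney p by enumerating all rank assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    stat_obs = min(u_obs, len(x) * len(y) - u_obs)
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        stat = min(u, len(x) * len(y) - u)
        total += 1
        if stat <= stat_obs:
            count += 1
    return count / total


class TestMannWhitney:
    def test_extreme_separation_exact(self):
        # U=0 on 2-vs-2: both one-sided extremes of C(4,2)=6 assignments
        assert ib.mannwhitney_u_test([1, 2], [3, 4]) == pytest.approx(2 / 6)

    def test_identical_multisets_near_one(self):
        assert ib.mannwhitney_u_test([1, 2, 3], [1, 2, 3]) > 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            ib.mannwhitney_u_test([], [1.0])

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_exact_path_equals_enumeration(self, data):
        """For tie-free inputs with min group <= 8, p equals full enumeration."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        nx = data.draw(st.integers(2, 6))
        ny = data.draw(st.integers(2, 6))
        pooled = rng.permutation(np.arange(nx + ny, dtype=float))
        x, y = pooled[:nx], pooled[nx:]
        assert ib.mannwhitney_u_test(x, y) == pytest.approx(_enumerate_mw_p(x, y), abs=1e-12)

    def test_exact_and_asymptotic_agree_at_boundary(self):
        """Shifted normals at the n=8 exact boundary: both paths within 0.01."""
        rng = np.random.default_rng(42)
        x = rng.normal(0.0, 1.0, 8)
        y = rng.normal(1.0, 1.0, 8)
        from scipy.stats import mannwhitneyu

        p_exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        p_asym = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert ib.mannwhitney_u_test(x, y) == pytest.approx(p_exact, abs=1e-12)
        assert abs(p_exact - p_asym) < 0.01


class TestModeratedT:
    def test_zero_prior_df_reproduces_student_t(self, de_matrix, case_mask):
        vals = de_matrix.values[:100]
        p_mod = ib.moderated_t_test(vals, case_mask, prior_df=0.0)
        p_stu = np.array(
            [ib.student_t_test(vals[i, case_mask], vals[i, ~case_mask]) for i in range(100)]
        )
        assert np.abs(p_mod - p_stu).max() < 1e-10

    def test_infinite_prior_df_pools_to_common_variance(self, de_matrix, case_mask):
        """d0 -> inf: statistic becomes z-like with the shared prior variance."""
        vals = de_matrix.values[:100]
        s0 = 0.25
        p = ib.moderated_t_test(vals, case_mask, prior_df=np.inf, prior_var=s0)
        n1, n2 = case_mask.sum(), (~case_mask).sum()
        diff = vals[:, case_mask].mean(1) - vals[:, ~case_mask].mean(1)
        from scipy.stats import norm

        z = diff / (np.sqrt(s0) * np.sqrt(1 / n1 + 1 / n2))
        np.testing.assert_allclose(p, 2 * norm.sf(np.abs(z)), atol=1e-12)

    def test_type_i_error_calibrated_on_null_genes(self, null_matrix):
        """2000 null genes: fraction significant at alpha 0.05 lies in [0.04, 0.06]."""
        cohort, matrix = null_matrix
        p = ib.moderated_t_test(matrix, (cohort["classification"] == "case").to_numpy())
        frac = float((p <= 0.05).mean())
        assert 0.04 <= frac <= 0.06

    def test_single_gene_falls_back_to_ordinary_t(self, de_matrix, case_mask):
        vals = de_matrix.values[:1]
        with pytest.warns(UserWarning, match="single-gene"):
            p = ib.moderated_t_test(vals, case_mask)
        p_stu = ib.student_t_test(vals[0, case_mask], vals[0, ~case_mask])
        assert p[0] == pytest.approx(p_stu, abs=1e-12)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: Bioconductor limma's eBayes on the same matrix."""
        cfg = ib.SimulationConfig(seed=11, n_genes=300, n_de_genes=30, n_cases=5, n_controls=6)
        cohort = ib.simulate_cohort(cfg)
        m = ib.simulate_microarray(cfg, cohort)
        is_case = (cohort["classification"] == "case").to_numpy()
        df = m.to_frame()
        df.to_csv(tmp_path / "m.tsv", sep="\t")
        groups = ",".join("case" if c else "control" for c in is_case)
        script = f"""
suppressMessages(library(limma))
x <- as.matrix(read.delim("{tmp_path}/m.tsv", row.names=1, check.names=FALSE))
g <- factor(strsplit("{groups}", ",")[[1]], levels=c("control", "case"))
fit <- eBayes(lmFit(x, model.matrix(~g)))
write.csv(data.frame(p=fit$p.value[,2]), "{tmp_path}/out.csv", row.names=FALSE)
"""
        (tmp_path / "limma.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "limma.R")], check=True, capture_output=True)
        import pandas as pd

        p_limma = pd.read_csv(tmp_path / "out.csv")["p"].to_numpy()
        p_mine = ib.moderated_t_test(m, is_case)
        assert np.abs(p_mine - p_limma).max() < 1e-8


class TestVariancePrior:
    def test_recovers_known_prior_from_simulated_variances(self):
        """Variances drawn as s0^2 * F(dg, d0): moments estimator lands near (d0, s0^2)."""
        rng = np.random.default_rng(0)
        d0, s0_sq, dg = 8.0, 0.3, 10
        s2 = s0_sq * (rng.chisquare(dg, 20000) / dg) / (rng.chisquare(d0, 20000) / d0)
        d0_hat, s0_hat = estimate_variance_prior(s2, dg)
        assert d0_hat == pytest.approx(d0, rel=0.15)
        assert s0_hat == pytest.approx(s0_sq, rel=0.05)


class TestScreen:
    def test_p_values_bounded_and_folds_positive(self, de_matrix, default_cohort):
        res = ib.run_de_screen(de_matrix, default_cohort)
        for col in ("p_student", "p_mw", "p_moderated"):
            assert res[col].between(0, 1).all()
        assert (res["fold_change"] > 0).all()

    def test_label_swap_inverts_fold_and_preserves_p(self, default_cohort):
        cfg = ib.SimulationConfig(seed=21, n_genes=80, n_de_genes=20)
        m = ib.simulate_microarray(cfg, default_cohort)
        res = ib.run_de_screen(m, default_cohort)
        flipped = default_cohort.copy()
        flipped["classification"] = flipped["classification"].map(
            {"case": "control", "control": "case"}
        )
        flipped["subtype"] = np.where(flipped["classification"] == "control", "none", "IBS-D")
        res_f = ib.run_de_screen(m, flipped)
        a = res.set_index("gene")
        b = res_f.set_index("gene").loc[a.index]
        np.testing.assert_allclose(a["fold_change"], 1.0 / b["fold_change"], rtol=1e-10)
        for col in ("p_student", "p_mw", "p_moderated"):
            np.testing.assert_allclose(a[col], b[col], atol=1e-10)

    def test_noise_free_repressed_gene_called(self):
        cfg = ib.SimulationConfig(seed=5, n_genes=40, n_de_genes=5,
                                  array_noise_sd=1e-6, log2_effect_range=(1.0, 1.0))
        cohort = ib.simulate_cohort(cfg)
        m = ib.simulate_microarray(cfg, cohort)
        res = ib.run_de_screen(m, cohort).set_index("gene")
        for gene, effect in m.planted_truth.items():
            assert bool(res.loc[gene, "significant"])
            assert (res.loc[gene, "fold_change"] < 1) == (effect < 0)

    def test_null_false_positive_rate_near_alpha(self, null_matrix):
        cohort, matrix = null_matrix
        res = ib.run_de_screen(matrix, cohort, rule="moderated_only")
        fpr = res["significant"].mean()
        assert 0.03 <= fpr <= 0.07

    def test_missing_sample_listed_in_error(self, de_matrix, default_cohort):
        bad = default_cohort.copy()
        bad.loc[0, "sample_id"] = "GHOST-001"
        with pytest.raises(KeyError, match="GHOST-001"):
            ib.run_de_screen(de_matrix, bad)

    def test_top_n_filter_ranks_by_moderated_p(self, de_matrix, default_cohort):
        res = ib.run_de_screen(de_matrix, default_cohort)
        short = top_n_filter(res, 50)
        assert len(short) == 50
        assert short["significant"].all()
        assert short["p_moderated"].max() <= res.loc[res["significant"], "p_moderated"].nlargest(1).iloc[0]
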