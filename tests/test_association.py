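import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import oracles
from braincci import (
    ExpressionMatrix,
    MarkerSetCollection,
    SampleMetadata,
    bh_fdr,
    gene_de_test,
    marker_enrichment,
    mgp_group_test,
    mgp_severity_test,
)
from braincci.mgp import MGPMatrix


def _mgp_from(values, pairs=None, samples=None, gene_to_type=None):
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    if pairs is None:
        # synthetic antisymmetric universe: rows come in mirrored halves
        assert n % 2 == 0
        genes = [f"g{i}" for i in range(n)]
        pairs = [(f"a{i}", f"b{i}") for i in range(n // 2)]
        pairs += [(b, a) for a, b in pairs]
        values = np.vstack([values[: n // 2], -values[: n // 2]])
        gene_to_type = {g: "t" for p in pairs for g in p}
    samples = samples or [f"s{i}" for i in range(s)]
    return MGPMatrix(pairs=pairs, sample_ids=samples, values=values,
                     gene_to_type=gene_to_type)


def _meta(n_ctrl, n_case, **extra):
    ids = [f"s{i}" for i in range(n_ctrl + n_case)]
    return SampleMetadata(pd.DataFrame({
        "group": ["control"] * n_ctrl + ["case"] * n_case, **extra,
    }, index=pd.Index(ids, name="sample_id")))


class TestGroupTest:
    def test_welch_matches_textbook_oracle(self):
        """4-vs-4 toy with a planted mean shift of ~2, sd ~0.5."""
        ctrl = [0.1, -0.4, 0.5, 0.2]
        case = [2.0, 1.6, 2.5, 2.2]
        mgp = _mgp_from(np.array([ctrl + case, ctrl + case]))
        stats = mgp_group_test(mgp, _meta(4, 4), method="t_test")
        t_exp, _ = oracles.welch_t(case, ctrl)
        assert stats["statistic"].iloc[0] == pytest.approx(t_exp, abs=1e-8)

    def test_identical_groups_give_zero_statistics(self):
        block = np.random.default_rng(0).normal(0, 1, (4, 5))
        mgp = _mgp_from(np.hstack([block, block]))
        stats = mgp_group_test(mgp, _meta(5, 5))
        assert (stats["statistic"] == 0).all()
        assert (stats["p"] == 1).all()

    def test_label_swap_negates_statistics(self):
        rng = np.random.default_rng(1)
        mgp = _mgp_from(rng.normal(0, 1, (6, 10)))
        a = mgp_group_test(mgp, _meta(5, 5))
        swapped = _meta(5, 5).table.copy()
        swapped["group"] = swapped["group"].map({"case": "control",
                                                 "control": "case"})
        b = mgp_group_test(mgp, SampleMetadata(swapped))
        assert np.allclose(a["statistic"], -b["statistic"])
        assert np.allclose(a["p"], b["p"])

    def test_statistic_antisymmetry_across_reciprocal_rows(self):
        rng = np.random.default_rng(2)
        mgp = _mgp_from(rng.normal(0, 1, (8, 12)))
        for method in ("t_test", "linear_model"):
            stats = mgp_group_test(mgp, _meta(6, 6), method=method)
            n = len(stats) // 2
            fwd = stats["statistic"].to_numpy()[:n]
            rev = stats["statistic"].to_numpy()[n:]
            assert np.array_equal(fwd, -rev)

    def test_small_group_rejected(self):
        mgp = _mgp_from(np.random.default_rng(0).normal(0, 1, (2, 4)))
        with pytest.raises(ValueError, match=">=2 samples"):
            mgp_group_test(mgp, _meta(1, 3))

    def test_zero_variance_row_warns_with_p_one(self):
        vals = np.zeros((2, 8))
        mgp = _mgp_from(vals)
        with pytest.warns(UserWarning, match="zero-variance"):
            stats = mgp_group_test(mgp, _meta(4, 4))
        assert (stats["p"] == 1).all()

    def test_linear_model_without_moderation_is_pooled_t(self):
        rng = np.random.default_rng(3)
        mgp = _mgp_from(rng.normal(0, 1, (10, 14)))
        pooled = mgp_group_test(mgp, _meta(7, 7), method="t_test", equal_var=True)
        lm = mgp_group_test(mgp, _meta(7, 7), method="linear_model",
                            moderated=False)
        assert np.abs(pooled["p"] - lm["p"]).max() < 1e-8
        assert np.abs(pooled["statistic"] - lm["statistic"]).max() < 1e-8

    def test_covariate_adjustment_removes_confounded_effect(self):
        # group difference entirely explained by a measured covariate
        rng = np.random.default_rng(4)
        age = np.r_[rng.uniform(60, 70, 10), rng.uniform(80, 90, 10)]
        row = 0.1 * age + rng.normal(0, 0.2, 20)
        mgp = _mgp_from(np.vstack([row, row]))
        meta = _meta(10, 10, age=age)
        raw = mgp_group_test(mgp, meta, method="linear_model", moderated=False)
        adj = mgp_group_test(mgp, meta, method="linear_model",
                             covariates=["age"], moderated=False)
        assert raw["p"].iloc[0] < 0.01
        assert adj["p"].iloc[0] > 0.05

    def test_moderated_t_matches_limma(self, tmp_path):
        """Dual route: empirical-Bayes moderated t vs Bioconductor limma."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the limma oracle")
        rng = np.random.default_rng(11)
        sd = np.exp(rng.normal(0, 0.6, 30))
        vals = rng.normal(0, 1, (30, 12)) * sd[:, None]
        vals[:5] += np.r_[np.zeros(6), np.ones(6)][None, :]
        mgp = _mgp_from(vals)
        stats = mgp_group_test(mgp, _meta(6, 6), method="linear_model")
        ypath = tmp_path / "y.tsv"
        # the same mirrored matrix the MGP stats were computed on
        pd.DataFrame(np.vstack([vals[:15], -vals[:15]])).to_csv(ypath, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            Y <- as.matrix(read.delim("{ypath}", row.names=1))
            design <- cbind(1, c(rep(0,6), rep(1,6)))
            fit <- eBayes(lmFit(Y, design))
            write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2]),
                        "{tmp_path}/out.tsv", quote=FALSE)
        """)
        (tmp_path / "lim.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "lim.R")], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep=" ")
        assert np.abs(stats["statistic"].to_numpy() - ref["t"].to_numpy()).max() < 1e-10
        assert np.abs(stats["p"].to_numpy() - ref["p"].to_numpy()).max() < 1e-10

    def test_null_p_values_approximately_uniform(self):
        """Fraction of p<0.05 under the global null sits in the 99% binomial
        band (independent rows, 200 per seed, 20 seeds, n=50 per group)."""
        hits = total = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            mgp = _mgp_from(rng.normal(0, 1, (200, 100)))
            stats = mgp_group_test(mgp, _meta(50, 50))
            p = stats["p"].to_numpy()[:100]  # one orientation per pair
            hits += (p < 0.05).sum()
            total += p.size
        lo, hi = oracles.binomial_99_band(0.05, total)
        assert lo < hits / total < hi


class TestSeverityTest:
    def _sev_meta(self, sev):
        ids = [f"s{i}" for i in range(len(sev))]
        return SampleMetadata(pd.DataFrame({"severity": sev},
                                           index=pd.Index(ids, name="sample_id")))

    def test_perfect_monotone_gives_unit_rho(self):
        sev = np.arange(12, dtype=float)
        mgp = _mgp_from(np.vstack([sev * 2 + 1, -sev]))
        stats = mgp_severity_test(mgp, self._sev_meta(sev))
        assert stats["statistic"].iloc[0] == pytest.approx(1.0)
        assert stats["statistic"].iloc[1] == pytest.approx(-1.0)

    def test_tied_severities_match_bruteforce_oracle(self):
        sev = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        row = [0.3, 1.2, 0.8, 2.0, 1.9, 2.6]
        mgp = _mgp_from(np.vstack([row, row]))
        stats = mgp_severity_test(mgp, self._sev_meta(sev))
        rho_exp = oracles.spearman_rho(row, sev)
        p_exp = oracles.spearman_exact_p(row, sev)
        assert stats["statistic"].iloc[0] == pytest.approx(rho_exp, abs=1e-10)
        assert stats["p"].iloc[0] == pytest.approx(p_exp, abs=1e-10)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        sev = rng.uniform(0, 6, 40)
        row = sev + rng.normal(0, 2, 40)
        mgp = _mgp_from(np.vstack([row, row]))
        stats = mgp_severity_test(mgp, self._sev_meta(sev))
        from scipy.stats import spearmanr

        rho_ref, p_ref = spearmanr(row, sev)
        assert stats["statistic"].iloc[0] == pytest.approx(rho_ref, abs=1e-12)
        assert stats["p"].iloc[0] == pytest.approx(p_ref, rel=1e-6)

    def test_constant_severity_rejected(self):
        mgp = _mgp_from(np.random.default_rng(0).normal(0, 1, (2, 6)))
        with pytest.raises(ValueError, match="constant"):
            mgp_severity_test(mgp, self._sev_meta([2.0] * 6))

    def test_constant_row_gets_zero_rho(self):
        mgp = _mgp_from(np.zeros((2, 6)))
        with pytest.warns(UserWarning, match="constant rows"):
            stats = mgp_severity_test(mgp, self._sev_meta([1., 2., 3., 4., 5., 6.]))
        assert (stats["statistic"] == 0).all()
        assert (stats["p"] == 1).all()


class TestBH:
    def test_single_p_is_its_own_q(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_stepup_toy(self):
        # p*(m/rank): 0.04, 0.04, 0.04, 0.04 after cumulative min
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_ones(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_fdr([0.1, np.nan])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_matches_bruteforce_definition(self, p):
        assert np.allclose(bh_fdr(p), oracles.bh_stepup(p), atol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 500)
        assert np.allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1])


class TestGeneDE:
    def _expr_meta(self, case_shift, n=20, seed=0, genes=30):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(4, 0.3, (genes, 2 * n))
        base[0, n:] *= case_shift
        df = pd.DataFrame(base, index=[f"G{i}" for i in range(genes)],
                          columns=[f"s{i}" for i in range(2 * n)])
        return ExpressionMatrix(df, "linear"), _meta(n, n)

    def test_identical_groups_yield_nothing(self):
        rng = np.random.default_rng(1)
        half = rng.lognormal(4, 0.3, (20, 10))
        df = pd.DataFrame(np.hstack([half, half]),
                          index=[f"G{i}" for i in range(20)],
                          columns=[f"s{i}" for i in range(20)])
        de = gene_de_test(ExpressionMatrix(df, "linear"), _meta(10, 10))
        assert (de["status"] == "ns").all()

    def test_planted_twofold_gene_called_up(self):
        expr, meta = self._expr_meta(case_shift=2.0, n=40)
        de = gene_de_test(expr, meta)
        assert de.loc["G0", "status"] == "up"
        assert de.loc["G0", "log2_fc"] > np.log2(1.5)

    def test_infinite_fc_threshold_blocks_everything(self):
        expr, meta = self._expr_meta(case_shift=8.0, n=40)
        de = gene_de_test(expr, meta, fc_min=np.inf)
        assert (de["status"] == "ns").all()


class TestMarkerEnrichment:
    def test_full_set_recovery_is_minimal_tail(self):
        markers = MarkerSetCollection({"a": [f"a{i}" for i in range(5)],
                                       "b": [f"b{i}" for i in range(15)]})
        de = pd.DataFrame({
            "status": ["up"] * 5 + ["ns"] * 15,
        }, index=markers.all_genes)
        enr = marker_enrichment(de, markers, "up")
        p_exp = oracles.hypergeom_upper_tail(5, 20, 5, 5)
        assert enr.loc["a", "p"] == pytest.approx(p_exp, abs=1e-12)
        assert enr.loc["a", "hits"] == 5
        # minimal achievable tail for this margin layout
        assert p_exp == pytest.approx(1 / 15504)

    def test_zero_overlap(self):
        markers = MarkerSetCollection({"a": ["a1", "a2", "a3"]})
        de = pd.DataFrame({"status": ["up", "ns", "ns", "ns", "ns", "ns"]},
                          index=["x1", "a1", "a2", "a3", "x2", "x3"])
        enr = marker_enrichment(de, markers, "up")
        assert enr.loc["a", "fold"] == 0
        assert enr.loc["a", "p"] >= 0.5

    def test_empty_de_list(self):
        markers = MarkerSetCollection({"a": ["a1", "a2"]})
        de = pd.DataFrame({"status": ["ns", "ns", "ns"]},
                          index=["a1", "a2", "x"])
        enr = marker_enrichment(de, markers, "up")
        assert np.isnan(enr.loc["a", "fold"])
        assert enr.loc["a", "p"] == 1.0

    def test_random_de_lists_have_unit_mean_fold(self):
        """Monte-Carlo: uniformly random DE lists give mean fold ~ 1."""
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(100)]
        markers = MarkerSetCollection({"a": genes[:20]})
        folds = []
        for _ in range(1000):
            de_mask = np.zeros(100, dtype=bool)
            de_mask[rng.choice(100, 10, replace=False)] = True
            de = pd.DataFrame({"status": np.where(de_mask, "up", "ns")},
                              index=genes)
            folds.append(marker_enrichment(de, markers, "up").loc["a", "fold"])
        folds = np.array(folds)
        se = folds.std(ddof=1) / np.sqrt(len(folds))
        assert abs(folds.mean() - 1.0) < 3 * se
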