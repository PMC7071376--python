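"""Expression screen: log-CPM, moderated t, set partition, amelioration."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dendroplast import (CountSimParams, ModeratedTDE, amelioration_distance,
                         amelioration_rank, de_vs_control, estimate_prior,
                         load_mediator_panel, logcpm, mediator_panel_report,
                         moderated_t_de, simulate_counts, venn_partition)
from dendroplast.screen import NONCONTROL_GROUPS


def _toy_counts(rng, n_genes=40, n_per=3, scale=200.0):
    groups = ["H2O_VEH", "EtOH_VEH", "EtOH_CNO", "H2O_CNO"]
    cols, labels = [], []
    gene_scale = rng.uniform(0.3, 3.0, size=n_genes)
    for g in groups:
        for j in range(n_per):
            cols.append(rng.poisson(scale * gene_scale))
            labels.append(g)
    counts = pd.DataFrame(
        np.column_stack(cols),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"{g}_s{j}" for g, j in
                 zip(labels, range(len(labels)))])
    meta = pd.DataFrame({"sample": counts.columns, "group": labels})
    return counts, meta


class TestLogCPM:
    def test_zero_count_value(self):
        counts = pd.DataFrame({"s1": [0, 10 ** 6 - 0]},
                              index=["g1", "g2"]).astype(int)
        counts.loc["g2", "s1"] = 10 ** 6
        out = logcpm(counts, min_mean_cpm=None)
        expected = np.log2(0.5 / (10 ** 6 + 1) * 1e6)
        assert out.loc["g1", "s1"] == pytest.approx(expected)
        assert expected == pytest.approx(-1.0, abs=1e-5)

    def test_scale_invariance_in_large_count_limit(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(5000, size=(50, 4)))
        a = logcpm(counts, min_mean_cpm=None)
        b = logcpm(2 * counts, min_mean_cpm=None)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=2e-3)

    def test_low_abundance_gene_filtered(self):
        lib = 10 ** 6
        counts = pd.DataFrame(
            {"s1": [int(0.9 * 1), lib], "s2": [1, lib]}, index=["lo", "hi"])
        # make mean CPM of 'lo' equal 0.9 against ~1e6 libraries
        counts.loc["lo"] = [1, 1]
        counts.loc["lo", "s1"] = 0  # mean CPM = 0.5 -> filtered
        out = logcpm(counts, min_mean_cpm=1.0)
        assert "lo" not in out.index and "hi" in out.index

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            logcpm(pd.DataFrame({"s": [-1]}))


class TestModeratedT:
    def test_zero_prior_df_is_ordinary_t(self):
        rng = np.random.default_rng(1)
        counts, meta = _toy_counts(rng)
        expr = logcpm(counts, min_mean_cpm=None)
        tab = moderated_t_de(expr, meta, ("EtOH_VEH", "H2O_VEH"),
                             prior_df=0)
        ev = meta.loc[meta.group == "EtOH_VEH", "sample"]
        ct = meta.loc[meta.group == "H2O_VEH", "sample"]
        for gene in expr.index[:10]:
            x, y = expr.loc[gene, ev], expr.loc[gene, ct]
            # pooled residual variance uses all four groups, so rebuild it
            groups = meta.set_index("sample").loc[expr.columns, "group"]
            resid = expr.loc[gene] - groups.map(
                expr.loc[gene].groupby(groups).mean())
            s2 = (resid ** 2).sum() / (len(resid) - 4)
            t_exp = (x.mean() - y.mean()) / np.sqrt(s2 * (2 / 3))
            assert tab.loc[gene, "t"] == pytest.approx(t_exp, rel=1e-9)
            p_exp = 2 * stats.t.sf(abs(t_exp), len(resid) - 4)
            assert tab.loc[gene, "p"] == pytest.approx(p_exp, rel=1e-9)

    def test_two_group_zero_prior_matches_scipy_ttest(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 25))
        y = np.array(["a"] * 3 + ["b"] * 3)
        model = ModeratedTDE(prior_df=0).fit(X, y)
        tab = model.contrast("a", "b")
        ref = stats.ttest_ind(X[:3], X[3:], equal_var=True)
        assert np.allclose(tab["t"], ref.statistic)
        assert np.allclose(tab["p"], ref.pvalue)

    def test_infinite_prior_pools_all_variances(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 30)) * rng.uniform(0.5, 2.0, size=30)
        y = np.array(["a"] * 4 + ["b"] * 4)
        model = ModeratedTDE(prior_df=np.inf).fit(X, y)
        assert np.allclose(model.var_post_, model.prior_var_)

    def test_posterior_variance_between_extremes(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 60)) * rng.uniform(0.2, 3.0, size=60)
        y = np.repeat(["a", "b", "c"], 4)
        model = ModeratedTDE().fit(X, y)
        lo = np.minimum(model.s2_, model.prior_var_)
        hi = np.maximum(model.s2_, model.prior_var_)
        assert np.all(model.var_post_ >= lo - 1e-12)
        assert np.all(model.var_post_ <= hi + 1e-12)

    def test_prior_estimate_satisfies_moment_equations(self):
        rng = np.random.default_rng(5)
        df = 8.0
        s2 = 0.7 * rng.chisquare(df, size=3000) / df * \
            np.exp(rng.normal(0, 0.7, size=3000))
        d0, s02 = estimate_prior(s2, df)
        from scipy.special import polygamma, digamma
        e = np.log(s2) - digamma(df / 2) + np.log(df / 2)
        evar = np.var(e, ddof=1) - polygamma(1, df / 2)
        assert polygamma(1, d0 / 2) == pytest.approx(float(evar), rel=1e-6)

    def test_fallback_prior_warns(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 1.0], [3.0, 1.0]])
        # zero residual variance everywhere -> estimation fails
        y = np.array(["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="falling back"):
            ModeratedTDE(fallback_prior_df=5.0).fit(X, y)

    def test_matches_r_limma_on_fixture(self, tmp_path):
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript is required for the limma cross-check"
        rng = np.random.default_rng(7)
        n_genes, n_per = 60, 3
        counts, meta = _toy_counts(rng, n_genes=n_genes, n_per=n_per)
        # heterogeneous gene variances so the prior df is finite
        expr = logcpm(counts, min_mean_cpm=None)
        expr = expr * rng.uniform(0.5, 2.0, size=(n_genes, 1))
        tab = moderated_t_de(expr, meta, ("EtOH_VEH", "H2O_VEH"))

        expr.to_csv(tmp_path / "expr.csv")
        meta.to_csv(tmp_path / "meta.csv", index=False)
        script = tmp_path / "limma.R"
        script.write_text("""
suppressMessages(library(limma))
args <- commandArgs(trailingOnly=TRUE)
x <- as.matrix(read.csv(args[1], row.names=1, check.names=FALSE))
meta <- read.csv(args[2])
grp <- factor(meta$group[match(colnames(x), meta$sample)])
design <- model.matrix(~0 + grp)
colnames(design) <- levels(grp)
fit <- lmFit(x, design)
ct <- makeContrasts(EtOH_VEH - H2O_VEH, levels=design)
fit2 <- eBayes(contrasts.fit(fit, ct))
out <- data.frame(gene=rownames(x), t=fit2$t[,1], p=fit2$p.value[,1],
                  lfc=fit2$coefficients[,1])
out$d0 <- fit2$df.prior
write.csv(out, args[3], row.names=FALSE)
""")
        out_csv = tmp_path / "limma_out.csv"
        subprocess.run([rscript, str(script), str(tmp_path / "expr.csv"),
                        str(tmp_path / "meta.csv"), str(out_csv)],
                       check=True, capture_output=True)
        ref = pd.read_csv(out_csv).set_index("gene")
        assert tab.attrs["prior_df"] == pytest.approx(
            float(ref["d0"].iloc[0]), rel=1e-4)
        assert np.allclose(tab["lfc"], ref["lfc"], atol=1e-8)
        assert np.allclose(tab["t"], ref["t"], rtol=1e-5)
        assert np.allclose(tab["p"], ref["p"], rtol=1e-4, atol=1e-12)


class TestVenn:
    def test_worked_example(self):
        part = venn_partition({
            "A": {"g1", "g2"}, "B": {"g2", "g3"}, "C": {"g3", "g4"}})
        d = dict(zip(part["region"], part["genes"]))
        assert d["A_only"] == ["g1"]
        assert d["B_only"] == []
        assert d["C_only"] == ["g4"]
        assert d["A&B"] == ["g2"]
        assert d["B&C"] == ["g3"]
        assert d["A&C"] == [] and d["all"] == []
        assert part["count"].sum() == 4

    def test_identical_sets_all_triple(self):
        part = venn_partition({"A": {"x", "y"}, "B": {"x", "y"},
                               "C": {"x", "y"}})
        d = dict(zip(part["region"], part["count"]))
        assert d["all"] == 2 and part["count"].sum() == 2

    def test_disjoint_sets(self):
        part = venn_partition({"A": {"a"}, "B": {"b"}, "C": {"c"}})
        d = dict(zip(part["region"], part["count"]))
        assert d["A_only"] == d["B_only"] == d["C_only"] == 1

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.sets(st.integers(0, 30)) for _ in range(3)]))
    def test_partition_is_disjoint_and_exhaustive(self, sets):
        a, b, c = sets
        part = venn_partition({"A": a, "B": b, "C": c})
        members = [g for gs in part["genes"] for g in gs]
        assert len(members) == len(set(members))
        assert set(members) == a | b | c
        assert part["count"].sum() == len(a | b | c)


class TestAmelioration:
    def _lfc(self, rows):
        return pd.DataFrame(rows, columns=list(NONCONTROL_GROUPS))

    def test_identical_vectors_zero(self):
        lfc = self._lfc([[1.0, 1.0, 0.2]])
        assert amelioration_distance(lfc).iloc[0] == 0.0

    def test_unit_case(self):
        lfc = self._lfc([[1.0, 0.0, 0.0]])
        assert amelioration_distance(lfc).iloc[0] == 1.0

    def test_metric_properties(self):
        rng = np.random.default_rng(11)
        x, y, z = rng.normal(size=(3, 50))
        zeros = np.zeros(50)
        dxy = np.abs(x - y)
        dyx = np.abs(y - x)
        assert np.allclose(dxy, dyx)  # symmetry
        dxz, dzy = np.abs(x - z), np.abs(z - y)
        assert np.all(dxy <= dxz + dzy + 1e-12)  # triangle inequality
        lfc = self._lfc(np.column_stack([x, y, zeros]))
        assert np.allclose(amelioration_distance(lfc), dxy)

    def test_all_pairs_mode(self):
        lfc = self._lfc([[1.0, 0.0, 0.0]])
        d = amelioration_distance(lfc, mode="all_pairs")
        assert d.iloc[0] == pytest.approx(np.sqrt(2.0))

    def test_ranking_ties_broken_by_gene_id(self):
        tabs = {}
        for g in NONCONTROL_GROUPS:
            tabs[g] = pd.DataFrame(
                {"lfc": [1.0, 1.0, 3.0]}, index=["gB", "gA", "gC"])
        tabs["EtOH_CNO"] = pd.DataFrame(
            {"lfc": [0.0, 0.0, 3.0]}, index=["gB", "gA", "gC"])
        rank = amelioration_rank(tabs)
        assert list(rank.index) == ["gA", "gB", "gC"]
        assert list(rank["rank"]) == [1, 2, 3]

    def test_recovers_planted_amelioration(self):
        params = CountSimParams(n_genes=3000, samples_per_group=8,
                                n_binge_genes=200, n_cno_genes=100,
                                amelioration_fraction=0.5, seed=6)
        counts, meta, truth = simulate_counts(params)
        expr = logcpm(counts)
        tabs = de_vs_control(expr, meta)
        rank = amelioration_rank(tabs)
        truth = truth.set_index("gene")
        keep = rank.index.intersection(truth.index)
        d = rank.loc[keep, "distance"]
        amel = d[truth.loc[keep, "class"] == "binge_ameliorated"]
        pers = d[truth.loc[keep, "class"] == "binge_only"]
        auroc = stats.mannwhitneyu(amel, pers).statistic / \
            (len(amel) * len(pers))
        assert auroc > 0.75  # unconditional over all planted genes


class TestPanelReport:
    def test_packaged_panel_contents(self):
        panel = load_mediator_panel()
        assert panel[0] == "Ntrk2" and "Dlg4" in panel and len(panel) == 11

    def test_missing_gene_flagged_not_dropped(self):
        de = pd.DataFrame({"lfc": [1.0], "p": [0.001]}, index=["Ntrk2"])
        rep = mediator_panel_report(de, de, ["Ntrk2", "Ghost"])
        assert len(rep) == 2
        assert bool(rep.loc[rep.gene == "Ghost", "missing"].iloc[0])
        assert rep.loc[rep.gene == "Ntrk2", "stars_veh"].iloc[0] == "**"

    def test_planted_effect_starred_only_in_veh_contrast(self):
        rng = np.random.default_rng(8)
        n_per, n_genes = 6, 40
        groups = np.repeat(["H2O_VEH", "EtOH_VEH", "H2O_CNO", "EtOH_CNO"],
                           n_per)
        X = rng.normal(5.0, 0.3, size=(4 * n_per, n_genes))
        X[(groups == "EtOH_VEH"), 0] += 4.0  # huge VEH-only effect on gene 0
        expr = pd.DataFrame(
            X.T, index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(4 * n_per)])
        meta = pd.DataFrame({"sample": expr.columns, "group": groups})
        de_veh = moderated_t_de(expr, meta, ("EtOH_VEH", "H2O_VEH"))
        de_cno = moderated_t_de(expr, meta, ("EtOH_CNO", "H2O_CNO"))
        rep = mediator_panel_report(de_veh, de_cno, ["g0"])
        assert rep["stars_veh"].iloc[0] in ("*", "**")
        assert rep["stars_veh"].iloc[0] == "**"
        assert rep["stars_cno"].iloc[0] == ""
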