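"""Differential expression: filtering, normalization, moderated t, BH, flags."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from stressomics.diffexpr import (
    EBayesHyperparams,
    batch_center,
    bh_adjust,
    cpm_filter,
    de_flag,
    estimate_hyperparams,
    filter_proteins,
    fit_moderated_t,
    log_cpm,
)
from stressomics.errors import InsufficientDataError, InvalidInputError, InvalidMatrixError
from stressomics.synthetic import SignalSpec, make_sample_meta, simulate_counts
from stressomics.types import OmicsMatrix


def counts_matrix(arr, groups=None, batches=None, modality="mrna"):
    arr = np.asarray(arr)
    samples = [f"s{i}" for i in range(arr.shape[1])]
    meta = pd.DataFrame(
        {
            "strain": "B6",
            "tissue": "bnst",
            "group": groups or ["control"] * arr.shape[1],
            "batch": batches or ["b0"] * arr.shape[1],
        },
        index=samples,
    )
    values = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=samples)
    return OmicsMatrix(values, meta, modality)


class TestCpmFilter:
    def test_all_zero_feature_removed(self):
        mat = counts_matrix([[0, 0, 0], [5, 5, 5]])
        kept = cpm_filter(mat, min_cpm=1, min_samples=1)
        assert list(kept.features) == ["g1"]

    def test_boundary_cpm_inclusive(self):
        # count 1 at library size 1e6 is exactly CPM 1 and must survive
        arr = np.ones((1, 3), dtype=int)
        filler = np.full((1, 3), 10**6 - 1)
        mat = counts_matrix(np.vstack([arr, filler]))
        kept = cpm_filter(mat, min_cpm=1.0, min_samples=3)
        assert "g0" in kept.features

    def test_matches_brute_force_on_toy_matrix(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 50, size=(5, 4))
        mat = counts_matrix(arr)
        lib = arr.sum(axis=0)
        keep_oracle = [
            sum(1e6 * arr[i, j] / lib[j] >= 2.0 for j in range(4)) >= 2 for i in range(5)
        ]
        kept = cpm_filter(mat, min_cpm=2.0, min_samples=2)
        assert list(kept.features) == [f"g{i}" for i in range(5) if keep_oracle[i]]

    def test_zero_library_rejected(self):
        with pytest.raises(InvalidMatrixError):
            cpm_filter(counts_matrix([[0, 5], [0, 5]]))


class TestLogCpm:
    def test_pseudocount_anchor(self):
        mat = counts_matrix([[0], [10**6 - 1]])
        out = log_cpm(mat)
        assert out.values.iloc[0, 0] == pytest.approx(np.log2(0.5), abs=1e-9)

    def test_doubling_counts_and_library_is_invariant(self):
        # exact up to the +0.5/+1 pseudo-counts, so checked at counts where
        # the offset is negligible
        arr = np.array([[100, 200], [300, 400], [50, 80]])
        a = log_cpm(counts_matrix(arr)).values.to_numpy()
        b = log_cpm(counts_matrix(2 * arr)).values.to_numpy()
        assert np.allclose(a, b, atol=0.01)

    def test_hand_arithmetic(self):
        arr = np.array([[3, 7], [9, 1]])
        out = log_cpm(counts_matrix(arr)).values.to_numpy()
        lib = arr.sum(axis=0)
        expected = np.log2((arr + 0.5) / (lib + 1.0) * 1e6)
        assert np.allclose(out, expected)

    def test_filter_then_log_commutes_with_sample_reordering(self):
        rng = np.random.default_rng(3)
        arr = rng.integers(0, 100, size=(20, 6))
        mat = counts_matrix(arr)
        out = log_cpm(cpm_filter(mat, 1, 3))
        perm = ["s4", "s1", "s5", "s0", "s2", "s3"]
        mat_perm = OmicsMatrix(mat.values[perm], mat.meta.loc[perm], "mrna")
        out_perm = log_cpm(cpm_filter(mat_perm, 1, 3))
        pd.testing.assert_frame_equal(out.values[perm], out_perm.values)


class TestBatchCenter:
    def test_single_batch_identity(self):
        mat = log_cpm(counts_matrix([[10, 20, 30], [5, 5, 5]]))
        pd.testing.assert_frame_equal(batch_center(mat).values, mat.values)

    def test_constant_shift_removed_exactly(self):
        base = np.array([[1.0, 2.0, 1.0, 2.0]])
        shifted = base + np.array([[0.0, 0.0, 3.0, 3.0]])
        mat = counts_matrix(shifted, batches=["b0", "b0", "b1", "b1"], modality="protein")
        adjusted = batch_center(mat).values.to_numpy()
        assert np.allclose(adjusted[0], [1.0, 2.0, 1.0, 2.0] + shifted.mean() - base.mean())
        # grand mean preserved
        assert adjusted.mean() == pytest.approx(shifted.mean())
        # within-batch differences intact, between-batch offset gone
        assert adjusted[0, 2] - adjusted[0, 0] == pytest.approx(0.0)

    def test_planted_batch_effect_suppressed(self):
        from scipy import stats

        meta = make_sample_meta(["B6"], 6, groups=("control",), n_batches=2)
        sig = SignalSpec(dispersion=0.05, batch_effect=1.0, seed=5)
        mat = log_cpm(simulate_counts(200, meta, sig))
        adjusted = batch_center(mat)
        batches = meta["batch"]
        f_stats = []
        for _, row in adjusted.values.iterrows():
            a = row[batches == "b0"]
            b = row[batches == "b1"]
            f_stats.append(stats.f_oneway(a, b).statistic)
        # with the shift removed, between/within variance ratio is ~ F(1, n-2)
        assert np.nanmean(f_stats) < 2.0


class TestModeratedT:
    def test_identical_group_means_give_null_stats(self):
        arr = np.array([[1.0, 2.0, 1.0, 2.0], [5.0, 6.0, 5.0, 6.0]])
        mat = counts_matrix(arr, groups=["control", "control", "susceptible", "susceptible"],
                            modality="protein")
        de, _ = fit_moderated_t(mat, "susceptible-vs-control")
        assert np.allclose(de["logFC"], 0)
        assert np.allclose(de["t"], 0)
        assert np.allclose(de["P"], 1)

    def test_equal_residual_variances_reduce_to_ordinary_t(self):
        # every feature has the same within-group scatter: shrinkage has no
        # pairwise information to borrow and the moderated t must equal the
        # ordinary two-sample (pooled) t feature-wise
        rng = np.random.default_rng(1)
        base = np.array([0.0, 1.0, -1.0, 0.0])  # identical spread per feature
        rows, means = [], rng.normal(0, 2, 10)
        for m in means:
            rows.append(np.concatenate([base + 0, base + m]))
        mat = counts_matrix(np.array(rows), groups=["control"] * 4 + ["susceptible"] * 4,
                            modality="protein")
        de, hp = fit_moderated_t(mat, "susceptible-vs-control")
        assert np.isinf(hp.d0)
        s_sq = np.var(base, ddof=0) * 8 / 6  # pooled residual variance, 6 df
        t_ord = de["logFC"] / np.sqrt(s_sq * (1 / 4 + 1 / 4))
        assert np.allclose(de["t"], t_ord)

    def test_pinned_infinite_d0_uses_prior_variance(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(0, 1, size=(20, 8))
        mat = counts_matrix(arr, groups=["control"] * 4 + ["susceptible"] * 4,
                            modality="protein")
        hp = EBayesHyperparams(np.inf, 2.0)
        de, _ = fit_moderated_t(mat, "susceptible-vs-control", hyperparams=hp)
        diff = arr[:, 4:].mean(axis=1) - arr[:, :4].mean(axis=1)
        assert np.allclose(de["t"], diff / np.sqrt(2.0 * (1 / 4 + 1 / 4)))

    def test_sign_of_t_matches_sign_of_logfc(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(0, 1, size=(50, 12))
        mat = counts_matrix(arr, groups=["control"] * 6 + ["susceptible"] * 6,
                            modality="protein")
        de, _ = fit_moderated_t(mat, "susceptible-vs-control")
        nz = de["logFC"] != 0
        assert (np.sign(de.loc[nz, "t"]) == np.sign(de.loc[nz, "logFC"])).all()
        assert ((de["Padj"] >= de["P"] - 1e-12).all())

    def test_insufficient_replication_rejected(self):
        arr = np.zeros((3, 3))
        mat = counts_matrix(arr, groups=["control", "control", "susceptible"],
                            modality="protein")
        with pytest.raises(InsufficientDataError):
            fit_moderated_t(mat, "susceptible-vs-control")

    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Independent cross-check against the reference R implementation."""
        rng = np.random.default_rng(7)
        arr = rng.normal(5, 1, size=(60, 8)) + rng.normal(
            0, rng.uniform(0.2, 1.5, 60)[:, None], (60, 8)
        )
        arr[:5, 4:] += 2.0
        mat = counts_matrix(arr, groups=["control"] * 4 + ["susceptible"] * 4,
                            modality="protein")
        de, hp = fit_moderated_t(mat, "susceptible-vs-control")

        mfile, rfile, out = tmp_path / "m.tsv", tmp_path / "fit.R", tmp_path / "out.tsv"
        mat.values.to_csv(mfile, sep="\t")
        rfile.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{mfile}", row.names=1, check.names=FALSE))
            grp <- factor(c(rep("control",4), rep("susceptible",4)), levels=c("control","susceptible"))
            design <- model.matrix(~0+grp)
            colnames(design) <- levels(grp)
            fit <- lmFit(m, design)
            fit <- contrasts.fit(fit, makeContrasts(susceptible-control, levels=design))
            fit <- eBayes(fit)
            out <- data.frame(feature_id=rownames(m), logFC=fit$coefficients[,1],
                              t=fit$t[,1], P=fit$p.value[,1],
                              d0=fit$df.prior, s0_sq=fit$s2.prior)
            write.table(out, "{out}", sep="\t", quote=FALSE, row.names=FALSE)
        """))
        subprocess.run(["Rscript", str(rfile)], check=True, capture_output=True)
        ref = pd.read_csv(out, sep="\t")
        merged = de.merge(ref, on="feature_id", suffixes=("", "_limma"))
        assert np.allclose(merged["logFC"], merged["logFC_limma"], atol=1e-8)
        assert hp.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-3)
        assert hp.s0_sq == pytest.approx(ref["s0_sq"].iloc[0], rel=1e-3)
        assert np.allclose(merged["t"], merged["t_limma"], rtol=1e-4)
        assert np.allclose(merged["P"], merged["P_limma"], rtol=1e-3, atol=1e-12)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_evaluated_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @staticmethod
    def brute_force(p):
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        q = [None] * m
        for rank, i in enumerate(order, start=1):
            q[i] = min(
                min((m / r) * p[j] for r, j in enumerate(order, start=1) if r >= rank), 1.0
            )
        return q

    @given(
        st.lists(st.floats(0, 1, allow_nan=False, allow_infinity=False), min_size=1, max_size=50)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_definitional_brute_force(self, pvals):
        mine = bh_adjust(pvals)
        assert np.allclose(mine, self.brute_force(pvals), atol=1e-12)
        # contract: element-wise >= input, <= 1, rank order preserved
        assert (mine >= np.asarray(pvals) - 1e-12).all() and (mine <= 1).all()
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(mine[order]) >= -1e-12).all()

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, 200)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref, atol=1e-12)


class TestDeFlag:
    def test_boundary_semantics(self, toy_de):
        flagged = de_flag(toy_de)
        ids = set(flagged["feature_id"])
        assert "g3" not in ids  # P exactly 0.05: strict inequality
        assert "g5" in ids  # |FC| exactly 1.2 with P = 0.01: inclusive bound
        assert "g2" not in ids  # significant but tiny fold change

    def test_matches_per_row_rule(self, toy_de):
        flagged = de_flag(toy_de)
        oracle = {
            r.feature_id
            for r in toy_de.itertuples()
            if r.P < 0.05 and abs(r.logFC) >= np.log2(1.2)
        }
        assert set(flagged["feature_id"]) == oracle
        assert (flagged["direction"] == np.sign(flagged["logFC"])).all()


class TestFilterProteins:
    @staticmethod
    def rep_table(rows):
        return pd.DataFrame(
            rows, columns=["protein_id", "sample_id", "replicate", "n_unique_peptides", "hl_ratio"]
        )

    def test_single_peptide_protein_removed(self):
        t = self.rep_table([("p1", "s1", r, 1, 1.0) for r in (1, 2, 3)])
        assert filter_proteins(t).empty

    def test_consistent_protein_retained(self):
        t = self.rep_table([("p1", "s1", r, 3, 2.0) for r in (1, 2, 3)])
        out = filter_proteins(t)
        assert len(out) == 1
        assert out["log2_ratio"].iloc[0] == pytest.approx(1.0)
        assert out["cv"].iloc[0] == 0.0

    def test_high_cv_protein_removed(self):
        # replicate ratios constructed with 50% coefficient of variation
        ratios = np.array([1.0, 1.0, 2.2])  # CV ~ 0.495
        assert np.std(ratios, ddof=1) / ratios.mean() > 0.3
        t = self.rep_table(
            [("p1", "s1", r + 1, 3, x) for r, x in enumerate(ratios)]
        )
        assert filter_proteins(t).empty

    def test_mixed_table_matches_rule_evaluation(self):
        rng = np.random.default_rng(13)
        rows = []
        for pi in range(8):
            peps = rng.integers(1, 4, 3)
            ratios = np.exp(rng.normal(0, rng.uniform(0.05, 0.5), 3))
            for r in range(3):
                rows.append((f"p{pi}", "s1", r + 1, peps[r], ratios[r]))
        t = self.rep_table(rows)
        out = filter_proteins(t)
        expected = set()
        for pi in range(8):
            grp = t[t["protein_id"] == f"p{pi}"]
            ok_pep = (grp["n_unique_peptides"] >= 2).sum() >= 2
            cv = grp["hl_ratio"].std(ddof=1) / grp["hl_ratio"].mean()
            if ok_pep and cv < 0.3:
                expected.add(f"p{pi}")
        assert set(out["protein_id"]) == expected

    def test_malformed_table_rejected(self):
        with pytest.raises(InvalidInputError):
            filter_proteins(pd.DataFrame({"protein_id": ["p1"]}))


class TestPower:
    def test_planted_features_mostly_flagged(self):
        meta = make_sample_meta(["B6"], 10, groups=("control", "susceptible"))
        planted = [f"g{i:05d}" for i in range(10)]
        sig = SignalSpec(
            planted_sets={"S": planted},
            effect_sizes={"S": 1.0},
            strain_signs={"B6": +1},
            dispersion=0.1,
            seed=12,
        )
        mat = simulate_counts(200, meta, sig)
        de, _ = fit_moderated_t(log_cpm(cpm_filter(mat, 1, 6)), "susceptible-vs-control")
        flagged = de_flag(de)
        assert len(flagged.loc[flagged["feature_id"].isin(planted)]) >= 8
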