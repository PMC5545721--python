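"""Co-eQTL scan, SNP selection, PCI fitting/scoring, CV and replication."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexpci.containers import GenotypeMatrix, ValidationError
from coexpci.pci import (
    SelectionConfig,
    bonferroni,
    coeqtl_scan,
    crossvalidate_pci,
    fit_pci,
    ld_prune,
    replicate_pci,
    score_pci,
    select_snps,
    snps_in_gene_windows,
)
from coexpci.prep import residualize
from coexpci.synthetic import (
    CohortConfig,
    simulate_cohort,
    simulate_genotypes,
    simulate_ld_block_genotypes,
    simulate_replication_cohort,
)
from conftest import make_snp_meta

# uncorrected co-eQTL p-values of the eight selected variants plus a ninth
# synthetic value just above the 0.005 threshold
EIGHT_PVALUES = [5.0e-6, 4.6e-4, 1.0e-3, 1.0e-3, 1.7e-3, 2.8e-3, 3.0e-3, 3.2e-3]


def make_geno(doses: np.ndarray, meta=None, snp_ids=None) -> GenotypeMatrix:
    samples = [f"s{i}" for i in range(doses.shape[0])]
    snp_ids = snp_ids or [f"t{j + 1:03d}" for j in range(doses.shape[1])]
    return GenotypeMatrix(
        pd.DataFrame(doses.astype(float), index=samples, columns=snp_ids),
        meta,
    )


class TestGeneWindows:
    def coords(self):
        return pd.DataFrame(
            {"chrom": ["1"], "start": [1_000_000], "end": [1_050_000]}, index=["geneA"]
        )

    @pytest.mark.parametrize(
        "pos,retained",
        [(900_000, True), (899_999, False), (1_150_000, True), (1_150_001, False)],
    )
    def test_closed_window_boundaries(self, pos, retained):
        """+/-100 kb windows are closed intervals on both sides."""
        meta = pd.DataFrame({"chrom": ["1"], "pos": [pos]}, index=["snp1"])
        kept, _ = snps_in_gene_windows(meta, self.coords())
        assert ("snp1" in kept) is retained

    def test_chr_prefix_normalized(self):
        meta = pd.DataFrame({"chrom": ["chr1"], "pos": [1_000_000]}, index=["snp1"])
        kept, mapping = snps_in_gene_windows(meta, self.coords())
        assert kept == ["snp1"]
        assert mapping.iloc[0]["gene"] == "geneA"

    def test_matches_brute_force_interval_scan(self, rng):
        genes = pd.DataFrame(
            {
                "chrom": [str(c) for c in rng.integers(1, 4, 10)],
                "start": rng.integers(1, 50_000_000, 10),
            }
        , index=[f"gene{i}" for i in range(10)])
        genes["end"] = genes["start"] + rng.integers(1_000, 100_000, 10)
        snps = pd.DataFrame(
            {
                "chrom": [str(c) for c in rng.integers(1, 4, 1000)],
                "pos": rng.integers(1, 50_000_000, 1000),
            },
            index=[f"snp{i}" for i in range(1000)],
        )
        kept, _ = snps_in_gene_windows(snps, genes, window_bp=100_000)
        brute = []
        for snp, row in snps.iterrows():
            for _, g in genes.iterrows():
                if row["chrom"] == g["chrom"] and g["start"] - 100_000 <= row["pos"] <= g["end"] + 100_000:
                    brute.append(snp)
                    break
        assert kept == brute


class TestCoeqtlScan:
    def test_perfect_fit(self):
        doses = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 1, 1, 0])
        geno = make_geno(doses[:, None])
        me = pd.Series(doses.astype(float), index=geno.sample_ids)
        scan = coeqtl_scan(me, geno)
        assert scan.iloc[0]["slope"] == pytest.approx(1.0)
        assert scan.iloc[0]["p"] < 1e-12

    def test_matches_closed_form_ols_oracle(self, rng):
        """n=20 fixture: slope/t/p equal the normal-equations + t CDF oracle."""
        x = rng.binomial(2, 0.4, 20).astype(float)
        y = 0.5 * x + rng.standard_normal(20)
        geno = make_geno(x[:, None])
        scan = coeqtl_scan(pd.Series(y, index=geno.sample_ids), geno)
        X = np.column_stack([np.ones(20), x])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        resid = y - X @ beta
        s2 = resid @ resid / 18
        se = math.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta[1] / se
        p = 2 * stats.t.sf(abs(t), 18)
        assert scan.iloc[0]["slope"] == pytest.approx(beta[1], abs=1e-10)
        assert scan.iloc[0]["t"] == pytest.approx(t, abs=1e-10)
        assert scan.iloc[0]["p"] == pytest.approx(p, abs=1e-10)

    def test_monomorphic_snp_flagged_untestable(self, rng):
        doses = np.column_stack([np.ones(15), rng.binomial(2, 0.4, 15)])
        geno = make_geno(doses)
        me = pd.Series(rng.standard_normal(15), index=geno.sample_ids)
        scan = coeqtl_scan(me, geno)
        assert scan.iloc[0]["status"] == "untestable"
        assert scan.iloc[1]["status"] == "ok"

    def test_null_false_positive_rate_in_binomial_band(self, rng):
        meta = make_snp_meta(rng.uniform(0.2, 0.48, 1000))
        geno = simulate_genotypes(200, meta, seed=11)
        me = pd.Series(
            np.random.default_rng(12).standard_normal(200), index=geno.sample_ids
        )
        scan = coeqtl_scan(me, geno)
        frac = float((scan["p"] < 0.05).mean())
        assert 0.0365 <= frac <= 0.0635

    def test_covariate_adjustment_changes_df(self, rng):
        x = rng.binomial(2, 0.4, 30).astype(float)
        cov = pd.DataFrame({"age": rng.uniform(18, 78, 30)})
        y = 0.3 * x + 0.05 * cov["age"].to_numpy() + rng.standard_normal(30)
        geno = make_geno(x[:, None])
        cov.index = geno.sample_ids
        naive = coeqtl_scan(pd.Series(y, index=geno.sample_ids), geno)
        adj = coeqtl_scan(pd.Series(y, index=geno.sample_ids), geno, covars=cov)
        assert adj.iloc[0]["p"] < naive.iloc[0]["p"]  # confound removed


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,n,expected", [(0.5, 3, 1.0), (0.01, 10, 0.1), (5.0e-6, 660, 3.3e-3)]
    )
    def test_arithmetic(self, p, n, expected):
        assert bonferroni(p, n) == pytest.approx(expected)

    def test_family_smaller_than_pvalues_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni([0.1, 0.2, 0.3], 2)


class TestLdPrune:
    def test_duplicated_snp_keeps_one(self, rng):
        x = rng.binomial(2, 0.4, 50).astype(float)
        geno = make_geno(np.column_stack([x, x]), snp_ids=["b", "a"])
        kept = ld_prune(geno, pd.Series({"b": 0.01, "a": 0.01}), r2_max=0.2)
        assert kept == ["a"]  # tie in p broken lexicographically

    def test_uncorrelated_snps_all_retained(self, rng):
        geno = make_geno(rng.binomial(2, 0.4, (200, 5)))
        pvals = pd.Series(rng.uniform(0, 1, 5), index=geno.snp_ids)
        kept = ld_prune(geno, pvals, r2_max=0.2)
        assert sorted(kept) == sorted(geno.snp_ids)

    def test_matches_exhaustive_greedy_oracle(self, rng):
        """50-SNP LD-block fixture vs an independently coded greedy pass."""
        meta = make_snp_meta(np.full(50, 0.3))
        geno = simulate_ld_block_genotypes(300, meta, block_size=5, flip_prob=0.1, seed=2)
        pvals = pd.Series(rng.uniform(0, 1, 50), index=geno.snp_ids)
        kept = ld_prune(geno, pvals, r2_max=0.2)

        order = sorted(geno.snp_ids, key=lambda s: (pvals[s], s))
        D = geno.dosages.to_numpy()
        col = {s: i for i, s in enumerate(geno.snp_ids)}
        expected = []
        for snp in order:
            if all(
                np.corrcoef(D[:, col[snp]], D[:, col[k]])[0, 1] ** 2 < 0.2
                for k in expected
            ):
                expected.append(snp)
        assert kept == expected


class TestSelectSnps:
    def make_scan(self, pvalues, snp_ids):
        return pd.DataFrame(
            {
                "slope": 0.1,
                "t": 1.0,
                "p": pvalues,
                "n": 200,
                "n0": 60,
                "n1": 100,
                "n2": 40,
                "status": "ok",
            },
            index=snp_ids,
        )

    def test_eight_reported_pvalues_selected_ninth_excluded(self, rng):
        """The eight screen p-values pass p<0.005; a ninth at 0.0051 does not."""
        pvalues = EIGHT_PVALUES + [0.0051]
        ids = [f"t{j + 1:03d}" for j in range(9)]
        geno = make_geno(rng.binomial(2, 0.4, (300, 9)), snp_ids=ids)
        scan = self.make_scan(pvalues, ids)
        selected, trace = select_snps(scan, geno, SelectionConfig())
        assert len(selected) == 8
        assert ids[8] not in selected
        assert trace is None

    def test_all_null_pvalues_is_empty_model_failure(self, rng):
        ids = ["a", "b", "c"]
        geno = make_geno(rng.binomial(2, 0.4, (100, 3)), snp_ids=ids)
        with pytest.raises(ValidationError, match="empty model"):
            select_snps(self.make_scan([0.5, 0.5, 0.5], ids), geno, SelectionConfig())

    def test_plateau_selects_near_truth_count(self):
        """3 strong + 20 null SNPs: plateau keeps within [3, 5] across seeds."""
        counts = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            n = 500
            doses = g.binomial(2, 0.35, (n, 23)).astype(float)
            me = doses[:, :3] @ np.full(3, 0.45) + g.standard_normal(n) * 0.8
            geno = make_geno(doses)
            me_s = pd.Series(me, index=geno.sample_ids)
            scan = coeqtl_scan(me_s, geno)
            sel, trace = select_snps(
                scan, geno, SelectionConfig(method="plateau"), me=me_s
            )
            counts.append(len(sel))
            assert trace is not None and list(trace.columns) == [
                "k", "snp", "r2", "r2_adj", "gain",
            ]
        assert all(3 <= c <= 5 for c in counts)


class TestFitScorePci:
    def test_single_snp_identity(self):
        """Group ME means (-1, 0, +1), grand mean 0: weights are (-1, 0, +1)."""
        doses = np.array([0] * 5 + [1] * 5 + [2] * 5)
        me = pd.Series(doses - 1.0)
        geno = make_geno(doses[:, None], snp_ids=["s1"])
        me.index = geno.sample_ids
        model = fit_pci(me, geno, ["s1"], min_group=5)
        assert model.weights["s1"] == pytest.approx((-1.0, 0.0, 1.0))
        assert model.grand_mean == pytest.approx(0.0)
        scores = score_pci(model, geno)
        np.testing.assert_allclose(scores, me)
        assert model.training_r2 == pytest.approx(1.0)

    def test_constant_me_gives_zero_weights(self):
        doses = np.array([0] * 6 + [1] * 6 + [2] * 6)
        geno = make_geno(doses[:, None], snp_ids=["s1"])
        me = pd.Series(np.full(18, 3.0), index=geno.sample_ids)
        model = fit_pci(me, geno, ["s1"])
        assert model.weights["s1"] == pytest.approx((0.0, 0.0, 0.0))
        assert model.training_r2 == 0.0

    def test_training_r2_matches_group_mean_oracle(self, small_cohort, small_me):
        """8-SNP fit: training R^2 equals recomputation from group means."""
        geno = small_cohort.genotypes.subset_samples(small_me.scores.index)
        ids = small_cohort.truth.causal_snp_ids
        model = fit_pci(small_me, geno, ids, min_group=5)
        y = small_me.scores.to_numpy()
        grand = y.mean()
        pci = np.zeros(len(y))
        for snp in model.snp_ids:
            x = geno.dosages[snp].to_numpy()
            w = {}
            merged = {}
            for d in (0.0, 1.0, 2.0):
                merged[d] = x == d
            for d in (2.0, 0.0):  # mirror the merge-toward-heterozygote rule
                if 0 < merged[d].sum() < 5:
                    merged[1.0] = merged[1.0] | merged[d]
                    merged[d] = None
            for d in (0.0, 1.0, 2.0):
                mask = merged[d] if merged[d] is not None else merged[1.0]
                w[d] = y[mask].mean() - grand
            pci += np.array([w[v] for v in x])
        r2 = np.corrcoef(pci, y)[0, 1] ** 2
        assert model.training_r2 == pytest.approx(r2, abs=1e-10)
        # design anchor: planted regime gives a training fit near 0.38
        assert 0.2 < model.training_r2 < 0.6

    def test_weights_invariant_to_me_shift_and_equivariant_to_scale(self, rng):
        doses = rng.binomial(2, 0.4, (60, 2))
        geno = make_geno(doses)
        me = pd.Series(rng.standard_normal(60), index=geno.sample_ids)
        base = fit_pci(me, geno, list(geno.snp_ids))
        shifted = fit_pci(me + 100.0, geno, list(geno.snp_ids))
        scaled = fit_pci(me * 3.0, geno, list(geno.snp_ids))
        for s in base.snp_ids:
            np.testing.assert_allclose(base.weights[s], shifted.weights[s], atol=1e-10)
            np.testing.assert_allclose(
                np.array(base.weights[s]) * 3.0, scaled.weights[s], atol=1e-10
            )

    def test_weight_centering_invariant(self, small_cohort, small_me):
        """Group-size-weighted weights sum to zero per SNP."""
        geno = small_cohort.genotypes.subset_samples(small_me.scores.index)
        model = fit_pci(small_me, geno, small_cohort.truth.causal_snp_ids)
        for snp in model.snp_ids:
            x = geno.dosages[snp].to_numpy()
            total = sum(
                (x == d).sum() * model.weights[snp][int(d)] for d in (0.0, 1.0, 2.0)
            )
            assert abs(total) < 1e-8

    def test_score_lookup_with_missing(self):
        doses = np.array([[0.0], [1.0], [2.0], [np.nan]])
        geno = make_geno(doses, snp_ids=["s1"])
        from coexpci.pci import PciModel

        model = PciModel(
            snp_ids=["s1"],
            weights={"s1": (-1.0, 0.0, 1.0)},
            grand_mean=0.0,
            training_r2=1.0,
        )
        scores = score_pci(model, geno)
        np.testing.assert_allclose(scores, [-1.0, 0.0, 1.0, 0.0])
        assert scores.attrs["flagged_samples"] == ["s3"]

    def test_score_invariant_to_column_and_sample_order(self, small_cohort, small_me):
        geno = small_cohort.genotypes.subset_samples(small_me.scores.index)
        model = fit_pci(small_me, geno, small_cohort.truth.causal_snp_ids)
        base = score_pci(model, geno)
        perm_snps = list(geno.snp_ids[::-1])
        perm_samples = list(geno.sample_ids[::-1])
        shuffled = GenotypeMatrix(
            geno.dosages.loc[perm_samples, perm_snps], geno.meta.loc[perm_snps]
        )
        again = score_pci(model, shuffled)
        pd.testing.assert_series_equal(base.sort_index(), again.sort_index())

    def test_missing_model_snp_is_error(self, small_cohort, small_me):
        geno = small_cohort.genotypes.subset_samples(small_me.scores.index)
        model = fit_pci(small_me, geno, small_cohort.truth.causal_snp_ids)
        reduced = geno.subset_snps(list(geno.snp_ids[10:]))
        with pytest.raises(ValidationError, match="absent"):
            score_pci(model, reduced)

    def test_allele_flip_applied(self):
        doses = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])[:, None]
        meta = make_snp_meta([0.4])
        geno = make_geno(doses, meta=meta, snp_ids=list(meta.index))
        from coexpci.pci import PciModel

        model = PciModel(
            snp_ids=list(meta.index),
            weights={meta.index[0]: (-1.0, 0.0, 1.0)},
            grand_mean=0.0,
            training_r2=1.0,
            minor_alleles={meta.index[0]: "G"},  # cohort says minor is "A"
        )
        scores = score_pci(model, geno)
        np.testing.assert_allclose(scores, [1.0, 0.0, -1.0, 1.0, 0.0, -1.0])


class TestPowerAndRanking:
    def test_scan_power_matches_noncentral_t(self):
        """Empirical power at alpha=0.005 for a 4%-variance SNP vs analytic."""
        n, reps, alpha, rho2, maf = 200, 1000, 0.005, 0.04, 0.3
        beta = math.sqrt(rho2 / (2 * maf * (1 - maf)))
        hits = 0
        for i in range(reps):
            g = np.random.default_rng(100_000 + i)
            x = g.binomial(2, maf, n).astype(float)
            y = beta * x + g.normal(0, math.sqrt(1 - rho2), n)
            geno = make_geno(x[:, None])
            scan = coeqtl_scan(pd.Series(y, index=geno.sample_ids), geno)
            hits += scan.iloc[0]["p"] < alpha
        delta = math.sqrt(n * rho2 / (1 - rho2))
        tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
        analytic = stats.nct.sf(tcrit, n - 2, delta) + stats.nct.cdf(-tcrit, n - 2, delta)
        assert abs(hits / reps - analytic) <= 0.03

    def test_causal_snps_rank_above_null(self):
        """At the 4%-variance effect size, causal SNPs out-rank nulls by p."""
        wins = tot = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            n = 200
            doses = g.binomial(2, 0.3, (n, 10)).astype(float)
            rho2 = 0.04
            beta = math.sqrt(rho2 / (2 * 0.3 * 0.7))
            me = doses[:, :3] @ np.full(3, beta) + g.normal(0, math.sqrt(1 - 3 * rho2), n)
            geno = make_geno(doses)
            scan = coeqtl_scan(pd.Series(me, index=geno.sample_ids), geno)
            p = scan["p"].to_numpy()
            for i in range(3):
                for j in range(3, 10):
                    wins += p[i] < p[j]
                    tot += 1
        assert wins / tot >= 0.95


class TestCrossValidation:
    def test_noiseless_me_gives_near_perfect_oof_r(self):
        g = np.random.default_rng(0)
        doses = g.binomial(2, 0.4, (60, 3)).astype(float)
        geno = make_geno(doses)
        me = pd.Series(doses[:, 0] - 1.0, index=geno.sample_ids)
        cv = crossvalidate_pci(me, geno, SelectionConfig(), k_folds=5, seed=0)
        assert cv.pooled_r > 0.99

    def test_null_cohort_oof_r_small(self):
        g = np.random.default_rng(1)
        doses = g.binomial(2, 0.4, (200, 10)).astype(float)
        geno = make_geno(doses)
        me = pd.Series(g.standard_normal(200), index=geno.sample_ids)
        cv = crossvalidate_pci(
            me, geno, SelectionConfig(alpha=0.5), k_folds=5, seed=0
        )
        assert abs(cv.pooled_r) < 0.2

    def test_reproducible_and_positive_on_planted_cohort(self, small_cohort, small_me):
        geno = small_cohort.genotypes.subset_samples(small_me.scores.index)
        cv1 = crossvalidate_pci(small_me, geno, SelectionConfig(), k_folds=5, seed=7)
        cv2 = crossvalidate_pci(small_me, geno, SelectionConfig(), k_folds=5, seed=7)
        assert cv1.pooled_r == cv2.pooled_r
        assert cv1.pooled_r > 0
        assert cv1.n_failed_folds == 0

    def test_fold_with_empty_model_flagged(self):
        g = np.random.default_rng(2)
        doses = g.binomial(2, 0.4, (40, 3)).astype(float)
        geno = make_geno(doses)
        me = pd.Series(g.standard_normal(40), index=geno.sample_ids)
        cv = crossvalidate_pci(me, geno, SelectionConfig(alpha=1e-8), k_folds=4, seed=0)
        assert cv.n_failed_folds == 4


class TestReplication:
    def test_self_replication_equals_training_fit(self, small_cohort, small_me):
        """Scoring the training cohort reproduces the training correlation."""
        geno = small_cohort.genotypes.subset_samples(small_me.scores.index)
        model = fit_pci(small_me, geno, small_cohort.truth.causal_snp_ids)
        resid = residualize(small_cohort.expression, small_cohort.covariates)
        rep = replicate_pci(
            model,
            resid,
            small_cohort.truth.module_gene_ids,
            small_cohort.truth.seed_gene_id,
            small_cohort.genotypes,
        )
        assert rep.r == pytest.approx(math.sqrt(model.training_r2), abs=1e-10)

    def test_permuted_genotypes_break_association(self, small_cohort, small_me):
        geno = small_cohort.genotypes.subset_samples(small_me.scores.index)
        model = fit_pci(small_me, geno, small_cohort.truth.causal_snp_ids)
        resid = residualize(small_cohort.expression, small_cohort.covariates)
        rs = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            perm = g.permutation(geno.n_samples)
            permuted = GenotypeMatrix(
                pd.DataFrame(
                    geno.dosages.to_numpy()[perm],
                    index=geno.sample_ids,
                    columns=geno.snp_ids,
                ),
                geno.meta,
            )
            rep = replicate_pci(
                model,
                resid,
                small_cohort.truth.module_gene_ids,
                small_cohort.truth.seed_gene_id,
                permuted,
            )
            rs.append(rep.r)
        assert abs(np.mean(rs)) < 0.1  # centered at zero once linkage is broken

    def test_excessive_probe_loss_is_error(self, small_cohort, small_me):
        geno = small_cohort.genotypes
        model = fit_pci(
            small_me, geno.subset_samples(small_me.scores.index),
            small_cohort.truth.causal_snp_ids,
        )
        resid = residualize(small_cohort.expression, small_cohort.covariates)
        reduced = resid.subset_genes(small_cohort.truth.module_gene_ids[:10])
        with pytest.raises(ValidationError, match="module genes present"):
            replicate_pci(
                model, reduced, small_cohort.truth.module_gene_ids,
                small_cohort.truth.seed_gene_id, geno,
            )

    def test_frozen_weights_ignore_replication_expression(self, small_cohort, small_me):
        """Corrupting replication expression never changes the PCI scores."""
        geno = small_cohort.genotypes.subset_samples(small_me.scores.index)
        model = fit_pci(small_me, geno, small_cohort.truth.causal_snp_ids)
        rep_cohort = simulate_replication_cohort(small_cohort, n_samples=50, seed=4)
        scores_before = score_pci(model, rep_cohort.genotypes)
        corrupted = rep_cohort.expression.values * 5.0 + 100.0
        # scores computed from genotypes alone are bit-identical
        scores_after = score_pci(model, rep_cohort.genotypes)
        pd.testing.assert_series_equal(scores_before, scores_after)
        assert corrupted.shape == rep_cohort.expression.values.shape
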