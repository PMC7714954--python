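"""Genotype QC cascade: exact HWE, filters, IBD, fixed point, PCA."""

import numpy as np
import pandas as pd
import pytest

from oracles import gene_drop_siblings, hwe_exact_integer
from spdeg import (
    GenotypeMatrix,
    InsufficientDataError,
    QCThresholds,
    filter_heterozygosity,
    filter_hwe,
    filter_maf,
    filter_missingness,
    filter_related,
    genotype_pca,
    hwe_exact_test,
    ibd_estimate,
    run_qc,
)
from spdeg.qc import heterozygosity, minor_allele_frequency, pairwise_pi_hat


def _geno(dosage, ind_prefix="I"):
    dosage = np.asarray(dosage, dtype=float)
    n_snps, n_ind = dosage.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n_snps)],
            "chrom": ["1"] * n_snps,
            "pos": np.arange(n_snps) + 1,
            "ref": ["A"] * n_snps,
            "alt": ["G"] * n_snps,
        }
    )
    ids = [f"{ind_prefix}{j:03d}" for j in range(n_ind)]
    return GenotypeMatrix(snps=snps, individual_ids=ids, dosage=dosage)


class TestHweExact:
    def test_no_minor_alleles_gives_one(self):
        assert hwe_exact_test(0, 0, 100) == 1.0

    def test_reference_triple_matches_enumeration(self):
        assert hwe_exact_test(50, 20, 30) == pytest.approx(
            hwe_exact_integer(50, 20, 30), rel=1e-9
        )

    def test_symmetric_in_allele_labels(self):
        assert hwe_exact_test(50, 20, 30) == hwe_exact_test(30, 20, 50)

    def test_random_triples_match_integer_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 80))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            n_bb = n - n_aa - n_ab
            assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
                hwe_exact_integer(n_aa, n_ab, n_bb), rel=1e-9
            )

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestMissingnessAndMaf:
    def test_clean_matrix_unchanged(self, rng):
        g = _geno(rng.integers(0, 3, size=(5, 10)))
        g2, removed = filter_missingness(g)
        assert g2.n_snps == 5 and g2.n_individuals == 10
        assert all(not v for v in removed.values())

    def test_six_percent_missing_individual_removed(self):
        dosage = np.ones((50, 4))
        dosage[:3, 0] = np.nan  # 6% missing at threshold 0.05
        g2, removed = filter_missingness(_geno(dosage), ind_max=0.05)
        assert removed["individual_missingness"] == ["I000"]

    def test_crafted_toy_removals(self):
        # individual 0: 2/4 missing (> 0.4); SNP 3 reaches 1/3 missing
        # (> 0.3) only once individual 0 is gone
        dosage = np.array(
            [
                [np.nan, 1, 1, 1],
                [np.nan, 0, 1, 2],
                [0, 1, 0, 1],
                [1, np.nan, 1, 0],
            ],
            dtype=float,
        )
        g2, removed = filter_missingness(_geno(dosage), ind_max=0.4, snp_max=0.3)
        assert removed["individual_missingness"] == ["I000"]
        assert removed["snp_missingness"] == ["rs3"]

    def test_monomorphic_snp_removed(self):
        dosage = np.vstack([np.zeros(10), np.tile([0, 1], 5)])
        g2, removed = filter_maf(_geno(dosage), maf_min=0.1)
        assert removed["maf"] == ["rs0"]
        assert g2.snp_ids() == ["rs1"]

    def test_maf_quarter_kept(self):
        maf = minor_allele_frequency(np.array([[0, 0, 1, 1.0]]))
        assert maf[0] == pytest.approx(0.25)
        g2, removed = filter_maf(_geno([[0, 0, 1, 1]]), maf_min=0.1)
        assert g2.n_snps == 1

    def test_boundary_maf_exactly_threshold_kept(self):
        # 4 alt alleles in 20 -> MAF exactly 0.1: strict < keeps it
        dosage = np.array([[1, 1, 1, 1] + [0] * 16], dtype=float)
        g2, removed = filter_maf(_geno(dosage), maf_min=0.1)
        assert g2.n_snps == 1 and removed["maf"] == []

    def test_all_missing_snp_has_own_reason(self):
        dosage = np.vstack([np.full(6, np.nan), np.tile([0, 1, 2], 2)])
        g2, removed = filter_maf(_geno(dosage))
        assert removed["all_missing"] == ["rs0"]


class TestHeterozygosity:
    def test_identical_individuals_kept(self):
        # zero heterozygosity variance: the sd floor prevents divide-by-zero
        g = _geno(np.ones((10, 30)))
        g2, removed = filter_heterozygosity(g)
        assert removed["heterozygosity"] == []

    def test_extreme_outlier_removed(self, rng):
        dosage = rng.binomial(2, 0.3, size=(200, 30)).astype(float)
        dosage[:, 0] = 1.0  # fully heterozygous individual
        g2, removed = filter_heterozygosity(_geno(dosage))
        assert "I000" in removed["heterozygosity"]

    def test_removals_match_direct_zscores(self, rng):
        dosage = rng.binomial(2, 0.4, size=(100, 30)).astype(float)
        g = _geno(dosage)
        het = heterozygosity(dosage)
        z = (het - het.mean()) / het.std(ddof=1)
        expected = {g.individual_ids[i] for i in np.flatnonzero(np.abs(z) > 3)}
        g2, removed = filter_heterozygosity(g, z_max=3.0)
        assert set(removed["heterozygosity"]) == expected

    def test_too_few_individuals_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            filter_heterozygosity(_geno(rng.integers(0, 3, size=(30, 10))))


class TestIbd:
    def test_duplicate_pair_near_one(self, rng):
        freqs = rng.uniform(0.2, 0.5, size=1000)
        base = rng.binomial(2, freqs[:, None], size=(1000, 10)).astype(float)
        dosage = np.column_stack([base, base[:, 0]])
        g = _geno(dosage)
        pi = ibd_estimate(g, (g.individual_ids[0], g.individual_ids[-1]))
        assert pi >= 0.95

    def test_unrelated_pair_near_zero(self, rng):
        freqs = rng.uniform(0.2, 0.5, size=1000)
        dosage = rng.binomial(2, freqs[:, None], size=(1000, 10)).astype(float)
        g = _geno(dosage)
        pi = ibd_estimate(g, ("I000", "I001"))
        assert pi <= 0.1

    def test_full_siblings_near_half(self, rng):
        """Gene-dropped full sibs share pi-hat ~= 0.5."""
        freqs = rng.uniform(0.2, 0.5, size=2000)
        background = rng.binomial(2, freqs[:, None], size=(2000, 20)).astype(float)
        s1, s2 = gene_drop_siblings(rng, freqs)
        dosage = np.column_stack([background, s1, s2])
        g = _geno(dosage)
        pi = ibd_estimate(g, (g.individual_ids[-2], g.individual_ids[-1]))
        assert pi == pytest.approx(0.5, abs=0.1)

    def test_too_few_shared_snps_rejected(self, rng):
        dosage = rng.integers(0, 3, size=(50, 5)).astype(float)
        with pytest.raises(InsufficientDataError):
            ibd_estimate(_geno(dosage), ("I000", "I001"))

    def test_pairwise_matches_single_pair(self, rng):
        freqs = rng.uniform(0.2, 0.5, size=500)
        dosage = rng.binomial(2, freqs[:, None], size=(500, 6)).astype(float)
        g = _geno(dosage)
        table = pairwise_pi_hat(g)
        row = table[(table["id1"] == "I001") & (table["id2"] == "I004")].iloc[0]
        assert row["pi_hat"] == pytest.approx(
            ibd_estimate(g, ("I001", "I004")), abs=1e-12
        )


class TestFilterRelated:
    def _related_geno(self, rng, clones):
        freqs = rng.uniform(0.2, 0.5, size=1500)
        base = rng.binomial(2, freqs[:, None], size=(1500, 8)).astype(float)
        dosage = np.column_stack([base] + [base[:, 0]] * clones)
        return _geno(dosage)

    def test_no_related_pairs_keeps_everyone(self, rng):
        freqs = rng.uniform(0.2, 0.5, size=1500)
        g = _geno(rng.binomial(2, freqs[:, None], size=(1500, 8)).astype(float))
        g2, removed = filter_related(g)
        assert removed["relatedness"] == []

    def test_duplicate_pair_removes_exactly_one(self, rng):
        g = self._related_geno(rng, clones=1)
        g2, removed = filter_related(g)
        assert len(removed["relatedness"]) == 1

    def test_triangle_removes_two_by_greedy_rule(self, rng):
        """Three mutual clones: the pairwise greedy rule (higher missingness,
        ties to the later id) removes the two later ids."""
        g = self._related_geno(rng, clones=2)  # I000, I008, I009 identical
        g2, removed = filter_related(g)
        assert removed["relatedness"] == ["I008", "I009"]


class TestRunQc:
    def _clean(self, rng, n_snps=1200, n_ind=60):
        freqs = rng.uniform(0.25, 0.45, size=n_snps)
        dosage = rng.binomial(2, freqs[:, None], size=(n_snps, n_ind)).astype(float)
        return _geno(dosage)

    def test_clean_data_converges_with_empty_second_round(self):
        g = self._clean(np.random.default_rng(8))
        g2, report = run_qc(g, QCThresholds(hwe_cohort="all"))
        assert sum(len(v) for v in report.rounds[-1].values()) == 0
        if report.n_rounds == 1:
            assert report.final_shape == report.initial_shape

    def test_idempotent_fixed_point(self):
        rng = np.random.default_rng(8)
        g = self._clean(rng)
        first, report1 = run_qc(g, QCThresholds(hwe_cohort="all"))
        second, report2 = run_qc(first, QCThresholds(hwe_cohort="all"))
        assert second.n_snps == first.n_snps
        assert second.n_individuals == first.n_individuals
        assert sum(len(v) for rnd in report2.rounds for v in rnd.values()) == 0

    def test_cascade_removal_appears_in_round_two(self):
        """An individual removed by a filter that runs after the MAF step
        (heterozygosity) drags a SNP's MAF below threshold only in the
        next round."""
        rng = np.random.default_rng(4)
        n_ind = 21
        dosage = rng.binomial(2, 0.4, size=(40, n_ind)).astype(float)
        # individual 0: fully heterozygous outlier, removed by the het filter
        dosage[:, 0] = 1.0
        # SNP 0: MAF 5/42 ~ 0.119 with individual 0 (a hom-alt carrier),
        # 3/40 = 0.075 without it
        dosage[0] = 0.0
        dosage[0, 1:4] = 1.0
        dosage[0, 0] = 2.0
        thresholds = QCThresholds(hwe_cohort="all")
        g2, report = run_qc(_geno(dosage), thresholds)
        round1 = report.rounds[0]
        assert "I000" in round1["heterozygosity"]
        assert "rs0" not in round1["maf"]
        assert any("rs0" in rnd.get("maf", []) for rnd in report.rounds[1:])

    def test_every_removal_is_justified(self):
        """Each recorded removal crosses its threshold when the statistic is
        recomputed on the matrix state of that round."""
        rng = np.random.default_rng(15)
        g = self._clean(rng, n_snps=300, n_ind=40)
        d = g.dosage
        d[:60, 0] = np.nan  # individual missingness 20%
        d[5, 1:] = np.nan  # SNP missingness
        d[10] = 0.0
        d[10, :2] = 1.0  # low MAF
        thresholds = QCThresholds(hwe_cohort="all")
        g2, report = run_qc(g, thresholds)
        state = _geno(g.dosage)
        state.snps = g.snps
        state.individual_ids = list(g.individual_ids)
        for rnd in report.rounds:
            ind_miss = dict(
                zip(state.individual_ids, np.mean(~np.isfinite(state.dosage), axis=0))
            )
            for ind in rnd["individual_missingness"]:
                assert ind_miss[ind] > thresholds.ind_missing_max
            keep_ind = [i not in rnd["individual_missingness"] for i in state.individual_ids]
            state = state.subset(ind_mask=np.array(keep_ind))
            snp_miss = dict(zip(state.snp_ids(), np.mean(~np.isfinite(state.dosage), axis=1)))
            for snp in rnd["snp_missingness"]:
                assert snp_miss[snp] > thresholds.snp_missing_max
            keep_snp = [s not in rnd["snp_missingness"] for s in state.snp_ids()]
            state = state.subset(snp_mask=np.array(keep_snp))
            maf = dict(zip(state.snp_ids(), minor_allele_frequency(state.dosage)))
            for snp in rnd["maf"]:
                assert maf[snp] < thresholds.maf_min
            removed_snps = set(rnd["maf"]) | set(rnd.get("all_missing", [])) | set(
                rnd.get("hwe", [])
            )
            keep_snp = [s not in removed_snps for s in state.snp_ids()]
            state = state.subset(snp_mask=np.array(keep_snp))
            removed_inds = set(rnd.get("heterozygosity", [])) | set(
                rnd.get("relatedness", [])
            )
            keep_ind = [i not in removed_inds for i in state.individual_ids]
            state = state.subset(ind_mask=np.array(keep_ind))
        assert (state.n_snps, state.n_individuals) == report.final_shape


class TestGenotypePca:
    def test_scores_centered_and_variance_ordered(self, rng):
        freqs = rng.uniform(0.1, 0.5, size=80)
        dosage = rng.binomial(2, freqs[:, None], size=(80, 30)).astype(float)
        scores = genotype_pca(_geno(dosage), n_components=5)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-9)
        variances = scores.var(axis=0).to_numpy()
        assert (np.diff(variances) <= 1e-9).all()

    def test_matches_direct_eigendecomposition(self, rng):
        """20 x 50 toy: scores equal the eigen-decomposition of the
        standardized covariance, up to the fixed sign convention."""
        freqs = rng.uniform(0.2, 0.4, size=50)
        g = _geno(rng.binomial(2, freqs[:, None], size=(50, 20)).astype(float))
        scores = genotype_pca(g, n_components=3).to_numpy()
        f = g.dosage.mean(axis=1) / 2
        z = (g.dosage - 2 * f[:, None]) / np.sqrt(2 * f * (1 - f))[:, None]
        x = z.T - z.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(x @ x.T)
        order = np.argsort(evals)[::-1]
        for j in range(3):
            v = evecs[:, order[j]] * np.sqrt(evals[order[j]])
            assert min(
                np.abs(scores[:, j] - v).max(), np.abs(scores[:, j] + v).max()
            ) < 1e-8

    def test_excess_components_clipped(self, rng):
        dosage = rng.binomial(2, 0.3, size=(10, 6)).astype(float)
        scores = genotype_pca(_geno(dosage), n_components=50)
        assert scores.shape[1] == 5


class TestHweProperties:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=60),
        st.integers(min_value=0, max_value=60),
        st.integers(min_value=0, max_value=60),
    )
    def test_valid_probability_and_label_symmetry(self, n_aa, n_ab, n_bb):
        if n_aa + n_ab + n_bb == 0:
            return
        p = hwe_exact_test(n_aa, n_ab, n_bb)
        assert 0.0 < p <= 1.0
        assert p == hwe_exact_test(n_bb, n_ab, n_aa)
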