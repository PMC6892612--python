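import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diallel.assoc import (
    ADDITIVE,
    OVERDOMINANT,
    EncodedGenotypes,
    LMMScanner,
    association_scan,
    compute_kinship,
    effect_size,
    encode_genotypes,
    lmm_scan,
    maf_enrichment,
    permutation_threshold,
    variance_explained,
)
from diallel.design import (
    HOM_ALT,
    HOM_REF,
    enumerate_half_diallel,
    synthesize_hybrid_genotypes,
)
from diallel.pheno import PhenotypeTable, inverse_normal_transform
from diallel.simdata import simulate_founders

from conftest import make_panel


def _toy_encoded(matrix, chroms=None, dosage=None):
    matrix = np.asarray(matrix)
    n, m = matrix.shape
    chroms = chroms or [f"chr{1 + j % 2:02d}" for j in range(m)]
    order = np.argsort(chroms, kind="stable")
    matrix = matrix[:, order]
    chroms = [chroms[k] for k in order]
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": range(100, 100 + 100 * m, 100), "ref": "A", "alt": "C"}
    )
    dosage = matrix if dosage is None else np.asarray(dosage)[:, order]
    freq = dosage.mean(axis=0) / 2
    return EncodedGenotypes(
        encoding=ADDITIVE,
        matrix=matrix,
        dosage=dosage,
        sites=sites,
        hybrid_ids=[f"h{i}" for i in range(n)],
        maf_panel=np.minimum(freq, 1 - freq),
    )


def _identity_kinships(encoded):
    n = encoded.matrix.shape[0]
    return {c: np.eye(n) for c in pd.unique(encoded.chroms)}


class TestEncoding:
    def _panel(self):
        genotypes = [
            [HOM_REF, HOM_REF, HOM_ALT],
            [HOM_REF, HOM_ALT, HOM_ALT],
            [HOM_REF, HOM_ALT, HOM_REF],
        ]
        founders = make_panel(genotypes)
        crosses = enumerate_half_diallel(founders.parent_ids, include_diagonal=True)
        return synthesize_hybrid_genotypes(founders, crosses)

    def test_monomorphic_site_codes_all_zero(self):
        panel = self._panel()
        add = encode_genotypes(panel, ADDITIVE)
        over = encode_genotypes(panel, OVERDOMINANT)
        assert (add.matrix[:, 0] == 0).all() and (over.matrix[:, 0] == 0).all()

    def test_het_and_hom_minor_codes(self):
        panel = self._panel()
        add = encode_genotypes(panel, ADDITIVE)
        over = encode_genotypes(panel, OVERDOMINANT)
        # site 1: P01 is the only hom-ref founder -> ref is minor there
        row_het = panel.crosses.index[panel.crosses["hybrid_id"] == "P01xP02"][0]
        row_hom_minor = panel.crosses.index[panel.crosses["hybrid_id"] == "P01xP01"][0]
        assert add.matrix[row_het, 1] == 1 and over.matrix[row_het, 1] == 1
        assert add.matrix[row_hom_minor, 1] == 2 and over.matrix[row_hom_minor, 1] == 0

    def test_three_of_34_carriers_boost_panel_maf_to_nine_percent(self):
        genotypes = np.zeros((34, 2), dtype=np.int8)
        genotypes[:3, 0] = HOM_ALT   # 3 homozygous carriers
        genotypes[10:, 1] = HOM_ALT  # filler polymorphic site
        founders = make_panel(genotypes, chroms=["chr01", "chr02"], positions=[100, 100])
        crosses = enumerate_half_diallel(founders.parent_ids, include_diagonal=True)
        panel = synthesize_hybrid_genotypes(founders, crosses)
        enc = encode_genotypes(panel, ADDITIVE)
        assert panel.n_hybrids == 595
        minor_copies = int(enc.dosage[:, 0].sum())
        assert minor_copies == 105
        assert enc.maf_panel[0] == pytest.approx(105 / 1190)
        assert round(enc.maf_panel[0] * 100) == 9


class TestKinship:
    def test_identical_hybrids_share_diagonal_value(self):
        mat = np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0], [1, 0, 1]])
        enc = _toy_encoded(mat, chroms=["chr01", "chr01", "chr01"])
        k = compute_kinship(enc)
        assert k[0, 1] == pytest.approx(k[0, 0])
        assert k[0, 1] == pytest.approx(k[1, 1])

    def test_toy_matrix_matches_hand_calculation(self):
        mat = np.array([[0, 0], [1, 2], [2, 0]])
        enc = _toy_encoded(mat, chroms=["chr01", "chr01"])
        z = (mat - mat.mean(axis=0)) / mat.std(axis=0)
        expected = z @ z.T / 2
        expected *= 3 / np.trace(expected)
        np.testing.assert_allclose(compute_kinship(enc), expected, atol=1e-12)

    def test_mean_diagonal_is_one(self, rng):
        mat = rng.integers(0, 3, size=(12, 30))
        enc = _toy_encoded(mat)
        for exclude in (None, "chr01"):
            k = compute_kinship(enc, exclude_chromosome=exclude)
            assert np.diag(k).mean() == pytest.approx(1.0)
            np.testing.assert_allclose(k, k.T, atol=1e-12)

    def test_no_usable_sites_raises(self):
        enc = _toy_encoded(np.zeros((4, 2), dtype=int), chroms=["chr01", "chr01"])
        with pytest.raises(ValueError, match="polymorphic"):
            compute_kinship(enc)


class TestLmmScan:
    def test_identity_kinship_reduces_to_ols(self, rng):
        """With K = I the mixed model collapses to ordinary least squares."""
        for _ in range(20):
            n = 30
            mat = rng.integers(0, 3, size=(n, 8))
            enc = _toy_encoded(mat)
            y = rng.normal(size=n)
            scanner = LMMScanner(enc, kinships=_identity_kinships(enc))
            beta, p = scanner.scan(y)
            for j in range(enc.n_sites):
                g = enc.matrix[:, j].astype(float)
                if g.std() == 0:
                    assert p[j] == 1.0
                    continue
                res = stats.linregress(g, y)
                assert beta[j] == pytest.approx(res.slope, abs=1e-8)
                assert p[j] == pytest.approx(res.pvalue, abs=1e-8)

    def test_printed_toy_example(self):
        y = np.array([0.0, 1.0, 1.0, 2.0, 2.0, 3.0])
        g = np.array([0, 0, 1, 1, 2, 2])
        filler = np.array([0, 1, 0, 1, 0, 1])
        enc = _toy_encoded(np.column_stack([g, filler]), chroms=["chr01", "chr02"])
        df = lmm_scan(y, enc, kinships=_identity_kinships(enc))
        row = df.iloc[0]
        assert row["beta"] == pytest.approx(1.0, abs=1e-10)
        assert row["p"] == pytest.approx(0.0309, abs=1e-3)

    def test_monomorphic_site_flagged(self):
        mat = np.column_stack([np.zeros(8, dtype=int), np.arange(8) % 3])
        enc = _toy_encoded(mat, chroms=["chr01", "chr02"])
        df = lmm_scan(np.random.default_rng(0).normal(size=8), enc,
                      kinships=_identity_kinships(enc))
        mono = df.loc[df["monomorphic"]]
        assert len(mono) == 1
        assert mono["p"].iloc[0] == 1.0 and mono["beta"].iloc[0] == 0.0

    def test_nonfinite_phenotype_raises(self):
        enc = _toy_encoded(np.arange(12).reshape(6, 2) % 3)
        scanner = LMMScanner(enc, kinships=_identity_kinships(enc))
        with pytest.raises(ValueError, match="non-finite"):
            scanner.scan(np.array([0.0, 1.0, np.nan, 0.0, 1.0, 2.0]))

    def test_causal_site_attains_minimum_p(self, rng):
        """A planted causal site of one phenotypic sd is the top hit in
        nearly every simulated trait on the 595-hybrid panel."""
        founders = simulate_founders(34, 120, n_chromosomes=4, seed=21)
        crosses = enumerate_half_diallel(founders.parent_ids, include_diagonal=True)
        panel = synthesize_hybrid_genotypes(founders, crosses)
        enc = encode_genotypes(panel, ADDITIVE)
        scanner = LMMScanner(enc)
        common = np.flatnonzero(enc.maf_panel > 0.15)
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            causal = common[s % len(common)]
            g = enc.matrix[:, causal].astype(float)
            y = (g - g.mean()) / g.std() + rng.normal(size=len(g))
            y = inverse_normal_transform(y)
            _, p = scanner.scan(y)
            if p.argmin() == causal:
                hits += 1
        assert hits >= int(0.9 * n_seeds)

    def test_null_pvalues_are_uniform(self):
        """P-values under fully null traits pass a KS uniformity check.

        Sites within one scan are correlated through the shared founders, so
        near-independent site-tests are collected as one site per chromosome
        across many independent null traits.
        """
        founders = simulate_founders(34, 100, n_chromosomes=4, seed=31)
        crosses = enumerate_half_diallel(founders.parent_ids, include_diagonal=True)
        panel = synthesize_hybrid_genotypes(founders, crosses)
        enc = encode_genotypes(panel, ADDITIVE)
        scanner = LMMScanner(enc)
        picks = [np.flatnonzero(enc.chroms == c)[0] for c in np.unique(enc.chroms)]
        perm_rng = np.random.default_rng(777)
        pooled = []
        for _ in range(2500):
            p = scanner.scan(perm_rng.normal(size=panel.n_hybrids))[1]
            pooled.extend(p[picks])
        pooled = np.asarray(pooled)
        assert len(pooled) == 10_000
        assert stats.kstest(pooled, "uniform").pvalue > 0.001


class TestPermutationThreshold:
    def test_threshold_is_the_kth_smallest_minimum(self, rng):
        mat = rng.integers(0, 3, size=(20, 10))
        enc = _toy_encoded(mat)
        scanner = LMMScanner(enc, kinships=_identity_kinships(enc))
        y = rng.normal(size=20)
        threshold = permutation_threshold(
            y, enc, n_perm=40, alpha=0.1, seed=5, scanner=scanner
        )
        perm_rng = np.random.default_rng(5)
        minima = sorted(scanner.min_p(perm_rng.permutation(y)) for _ in range(40))
        assert threshold == pytest.approx(minima[3])  # ceil(0.1*40) = 4th smallest

    def test_pooled_method_uses_all_pvalues(self, rng):
        mat = rng.integers(0, 3, size=(20, 10))
        enc = _toy_encoded(mat)
        scanner = LMMScanner(enc, kinships=_identity_kinships(enc))
        y = rng.normal(size=20)
        pooled = permutation_threshold(
            y, enc, n_perm=40, alpha=0.1, seed=5, method="pooled", scanner=scanner
        )
        minp = permutation_threshold(
            y, enc, n_perm=40, alpha=0.1, seed=5, method="minp", scanner=scanner
        )
        assert pooled <= minp

    def test_constant_phenotype_gives_threshold_one(self):
        mat = np.arange(40).reshape(20, 2) % 3
        enc = _toy_encoded(mat)
        scanner = LMMScanner(enc, kinships=_identity_kinships(enc))
        threshold = permutation_threshold(
            np.zeros(20), enc, n_perm=20, alpha=0.25, seed=1, scanner=scanner
        )
        assert threshold == 1.0

    def test_invalid_parameters_raise(self, rng):
        enc = _toy_encoded(rng.integers(0, 3, size=(10, 4)))
        with pytest.raises(ValueError, match="at least 1"):
            permutation_threshold(rng.normal(size=10), enc, n_perm=100, alpha=0.001)
        with pytest.raises(ValueError, match="at least 20"):
            permutation_threshold(rng.normal(size=10), enc, n_perm=5, alpha=0.5)


class TestEffectSize:
    def test_equal_sds_give_unit_d(self, rng):
        het = rng.normal(1.2, 0.2, 200_000)
        hom = rng.normal(1.0, 0.2, 200_000)
        y = np.concatenate([het, hom])
        dosage = np.concatenate([np.ones(200_000, int), np.zeros(200_000, int)])
        assert effect_size(y, dosage, ADDITIVE) == pytest.approx(1.0, abs=0.02)

    def test_formula_arithmetic(self):
        # means 2.0 vs 1.5, sds 0.3 and 0.4 -> pooled 0.35355, d = 1.4142
        rng = np.random.default_rng(3)
        g1 = rng.normal(size=500)
        g1 = (g1 - g1.mean()) / g1.std(ddof=1) * 0.3 + 2.0
        g2 = rng.normal(size=500)
        g2 = (g2 - g2.mean()) / g2.std(ddof=1) * 0.4 + 1.5
        y = np.concatenate([g1, g2])
        dosage = np.concatenate([np.ones(500, int), np.zeros(500, int)])
        assert effect_size(y, dosage, ADDITIVE) == pytest.approx(0.5 / 0.35355, abs=1e-4)

    def test_overdominant_contrast_centered_heterozygote_gives_zero(self):
        y = np.array([1.0, 1.0, 0.5, 1.5, 0.4, 1.6])
        dosage = np.array([1, 1, 0, 0, 2, 2])
        assert effect_size(y, dosage, OVERDOMINANT) == pytest.approx(0.0)

    def test_small_group_gives_nan(self):
        y = np.array([1.0, 2.0, 3.0])
        dosage = np.array([1, 0, 0])
        assert np.isnan(effect_size(y, dosage, ADDITIVE))


class TestVarianceExplained:
    def test_proportional_phenotype_explains_everything(self):
        g = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        assert variance_explained(2.0 * g + 1.0, g) == pytest.approx(1.0)

    def test_r_squared_identity(self, rng):
        g = rng.integers(0, 3, 300).astype(float)
        y = 0.45 * (g - g.mean()) / g.std() + rng.normal(size=300)
        r = np.corrcoef(g, y)[0, 1]
        assert variance_explained(y, g) == pytest.approx(r * r)

    def test_null_mean_is_small(self, rng):
        g = rng.integers(0, 3, 595).astype(float)
        values = [variance_explained(rng.normal(size=595), g) for _ in range(100)]
        assert np.mean(values) < 0.02

    def test_flat_site_returns_zero(self):
        assert variance_explained(np.arange(5, dtype=float), np.ones(5)) == 0.0


class TestMafEnrichment:
    def _results(self, n_sig=100, n_low=16, n_rare=3):
        n = n_sig + 50
        maf_source = np.full(n, 0.3)
        maf_source[:n_low] = 0.03
        maf_source[:n_rare] = 0.005
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "significant": [True] * n_sig + [False] * 50,
                "maf_source": maf_source,
                "maf_panel": np.clip(maf_source + 0.05, 0, 0.5),
                "variance_explained": rng.uniform(0.05, 0.3, n),
                "cohens_d": rng.normal(0, 0.3, n),
            }
        )

    def test_low_frequency_proportion_counting(self):
        out = maf_enrichment(self._results())
        assert out["n_significant"] == 100
        assert out["n_low_frequency"] == 16 and out["prop_low_frequency"] == 0.16
        assert out["n_rare"] == 3
        assert np.isfinite(out["mannwhitney_p_abs_d"])

    def test_all_common_leaves_classes_empty(self):
        results = self._results(n_low=0, n_rare=0)
        out = maf_enrichment(results)
        assert out["n_low_frequency"] == 0 and out["n_rare"] == 0

    def test_no_significant_sites_warns(self):
        results = self._results()
        results["significant"] = False
        with pytest.warns(UserWarning, match="no significant"):
            out = maf_enrichment(results)
        assert out["n_significant"] == 0


class TestAssociationScan:
    def test_end_to_end_scan_columns_and_flags(self):
        founders = simulate_founders(12, 80, n_chromosomes=4, seed=17)
        crosses = enumerate_half_diallel(founders.parent_ids, include_diagonal=True)
        panel = synthesize_hybrid_genotypes(founders, crosses)
        rng = np.random.default_rng(17)
        summary = pd.DataFrame(
            {
                "individual_id": panel.hybrid_ids,
                "condition": "c",
                "median": rng.normal(1.0, 0.2, panel.n_hybrids),
                "sd": 0.05,
                "n": 6,
            }
        )
        result = association_scan(
            panel, PhenotypeTable(summary=summary), "c", n_perm=20, alpha=0.1, seed=3
        )
        assert set(result["encoding"]) == {ADDITIVE, OVERDOMINANT}
        assert ((result["p"] > 0) & (result["p"] <= 1)).all()
        assert result["variance_explained"].between(0, 1).all()
        assert (result["significant"] == (result["p"] <= result["threshold_p"])).all()
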