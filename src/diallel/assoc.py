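"""Mixed-model association on a diallel hybrid panel.

Two genotype encodings are scanned: *additive* (minor-allele dosage 0/1/2,
testing a linear allele-dose effect) and *overdominant* (heterozygote
indicator 0/1, testing heterozygote-specific effects that a dosage model
misses).  Each site is tested in the single-random-effect linear mixed
model

    y = μ + g·β + u + ε,     u ~ N(0, σ²_g K),  ε ~ N(0, σ²_e I)

with K a genome-wide kinship matrix computed leaving out the chromosome of
the tested site (LOCO) to avoid proximal contamination.  The variance
ratio is profiled once per (trait, chromosome) on the null model via the
eigendecomposition of that chromosome's LOCO kinship; each site then gets a
generalized-least-squares slope and a two-sided t-test on n−2 degrees of
freedom.  Family-wise significance thresholds come from phenotype
permutations: the threshold is a low order statistic of the per-permutation
genome-wide minimum p-values.

Per-site summaries reported alongside the scan: variance explained (squared
genotype–phenotype correlation on the transformed scale) and Cohen's d
(heterozygotes vs major-allele homozygotes under the additive encoding,
heterozygotes vs all homozygotes under the overdominant one).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DiallelPanel
from .pheno import PhenotypeTable, inverse_normal_transform

ADDITIVE = "additive"
OVERDOMINANT = "overdominant"
ENCODINGS = (ADDITIVE, OVERDOMINANT)


@dataclass
class EncodedGenotypes:
    """Numeric genotype codes for association testing.

    ``matrix`` is hybrids × sites: minor-allele dosage {0,1,2} for the
    additive encoding, heterozygosity indicator {0,1} for the overdominant
    one.  ``dosage`` always keeps the minor-allele dosage (the two
    encodings share it for kinship and effect-size grouping).
    """

    encoding: str
    matrix: np.ndarray
    dosage: np.ndarray
    sites: pd.DataFrame
    hybrid_ids: list[str]
    maf_panel: np.ndarray
    maf_source: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def chroms(self) -> np.ndarray:
        return self.sites["chrom"].to_numpy()


def encode_genotypes(panel: DiallelPanel, encoding: str) -> EncodedGenotypes:
    """Encode synthesized hybrid genotypes for one association model.

    The minor allele is defined within the hybrid panel (ties broken
    toward the alt allele).  Panel MAF is counted over the hybrids' 2n
    allele copies; a source-population MAF annotation is carried through
    unchanged when the site table provides one.
    """
    if encoding not in ENCODINGS:
        raise ValueError(f"encoding must be one of {ENCODINGS}")
    if panel.hybrid_genotypes is None:
        raise ValueError("panel has no hybrid genotypes; run synthesize_hybrid_genotypes")
    alt_dosage = panel.hybrid_genotypes.astype(np.int16)
    if np.any(alt_dosage < 0):
        raise ValueError("missing hybrid calls present; they should not survive synthesis")
    alt_freq = alt_dosage.mean(axis=0) / 2.0
    minor_is_alt = alt_freq <= 0.5
    dosage = np.where(minor_is_alt, alt_dosage, 2 - alt_dosage).astype(np.int8)
    matrix = (alt_dosage == 1).astype(np.int8) if encoding == OVERDOMINANT else dosage
    maf_source = None
    if panel.sites is not None and "maf_source" in panel.sites.columns:
        maf_source = panel.sites["maf_source"].to_numpy(dtype=float)
    return EncodedGenotypes(
        encoding=encoding,
        matrix=matrix,
        dosage=dosage,
        sites=panel.sites.copy(),
        hybrid_ids=panel.hybrid_ids,
        maf_panel=np.minimum(alt_freq, 1.0 - alt_freq),
        maf_source=maf_source,
    )


def compute_kinship(encoded: EncodedGenotypes, exclude_chromosome: str | None = None) -> np.ndarray:
    """Realized kinship K = ZZᵀ/m from standardized dosage columns.

    Columns are centered and scaled to unit variance (zero-variance sites
    skipped); ``exclude_chromosome`` implements the leave-one-chromosome-out
    matrix.  K is rescaled so its mean diagonal equals 1.
    """
    use = np.ones(encoded.n_sites, dtype=bool)
    if exclude_chromosome is not None:
        use &= encoded.chroms != exclude_chromosome
    g = encoded.dosage[:, use].astype(float)
    sd = g.std(axis=0)
    poly = sd > 0
    if not poly.any():
        raise ValueError("no usable (polymorphic) sites for kinship")
    z = (g[:, poly] - g[:, poly].mean(axis=0)) / sd[poly]
    k = z @ z.T / poly.sum()
    k *= len(k) / np.trace(k)
    return k


class LMMScanner:
    """Reusable LOCO mixed-model scanner for one genotype panel.

    Eigendecompositions of each chromosome's LOCO kinship and the rotated
    genotype columns are precomputed once, so scanning a new phenotype
    vector (an observed trait or a permutation) costs only per-chromosome
    vector rotations, a vectorized grid profile of the variance ratio
    h = σ²_g/(σ²_g+σ²_e), and closed-form GLS per site.
    """

    def __init__(
        self,
        encoded: EncodedGenotypes,
        kinship_from: EncodedGenotypes | None = None,
        kinships: dict | None = None,
        h_grid: int = 65,
    ):
        """``kinships`` optionally supplies a precomputed LOCO kinship per
        chromosome (mapping chrom → matrix), bypassing computation from
        ``kinship_from`` (default: the encoded genotypes themselves)."""
        self.encoded = encoded
        kin_src = kinship_from if kinship_from is not None else encoded
        self.n = encoded.matrix.shape[0]
        self.h_values = np.linspace(0.0, 0.99, h_grid)
        self.site_variable = encoded.matrix.std(axis=0) > 0
        chroms = encoded.chroms
        self._chrom_blocks = []
        for chrom in pd.unique(chroms):
            sites = np.flatnonzero(chroms == chrom)
            if (chroms != chrom).sum() == 0:
                raise ValueError(
                    f"cannot build LOCO kinship: all sites lie on {chrom!r}"
                )
            if kinships is not None:
                k = kinships[chrom]
            else:
                k = compute_kinship(kin_src, exclude_chromosome=chrom)
            evals, evecs = np.linalg.eigh(k)
            evals = np.clip(evals, 0.0, None)
            gt = evecs.T @ encoded.matrix[:, sites].astype(float)
            self._chrom_blocks.append(
                {
                    "chrom": chrom,
                    "sites": sites,
                    "S": evals,
                    "U": evecs,
                    "xt0": evecs.T @ np.ones(self.n),
                    "Gt": gt,
                    "Gt2": gt * gt,
                }
            )

    def _fit_h(self, block, yt: np.ndarray) -> float:
        """ML profile of the variance ratio on the null (intercept) model."""
        S, xt0 = block["S"], block["xt0"]
        h = self.h_values[:, None]
        v = h * S[None, :] + (1.0 - h)          # grid × n
        w = 1.0 / v
        b0 = (w * xt0 * yt).sum(axis=1) / (w * xt0 * xt0).sum(axis=1)
        resid = yt[None, :] - b0[:, None] * xt0[None, :]
        sigma2 = (w * resid * resid).sum(axis=1) / self.n
        with np.errstate(divide="ignore"):  # constant phenotype: sigma2 = 0
            loglik = -0.5 * (self.n * np.log(sigma2) + np.log(v).sum(axis=1))
        return float(self.h_values[int(np.argmax(loglik))])

    def scan(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (beta, p) for one phenotype vector.

        Monomorphic sites get beta 0 and p 1.  Non-finite phenotypes raise.
        """
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError(f"phenotype length {y.shape} != {self.n} hybrids")
        if not np.all(np.isfinite(y)):
            raise ValueError("phenotype contains non-finite values")
        beta = np.zeros(self.encoded.n_sites)
        pval = np.ones(self.encoded.n_sites)
        dof = self.n - 2
        for block in self._chrom_blocks:
            yt = block["U"].T @ y
            h = self._fit_h(block, yt)
            v = h * block["S"] + (1.0 - h)
            w = 1.0 / v
            xt0 = block["xt0"]
            a00 = float(np.sum(w * xt0 * xt0))
            b0 = float(np.sum(w * xt0 * yt))
            wxt0 = w * xt0
            wyt = w * yt
            a01 = wxt0 @ block["Gt"]
            a11 = w @ block["Gt2"]
            b1 = wyt @ block["Gt"]
            syy = float(np.sum(w * yt * yt))
            det = a00 * a11 - a01 * a01
            ok = self.site_variable[block["sites"]] & (det > 1e-12 * max(a00, 1.0))
            det_safe = np.where(ok, det, 1.0)
            b_site = (a00 * b1 - a01 * b0) / det_safe
            b_int = (a11 * b0 - a01 * b1) / det_safe
            wsse = np.maximum(syy - b_int * b0 - b_site * b1, 0.0)
            sigma2 = wsse / dof
            var_b = sigma2 * a00 / det_safe
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(var_b > 0, b_site / np.sqrt(np.where(var_b > 0, var_b, 1.0)), 0.0)
            p = 2.0 * stats.t.sf(np.abs(t), dof)
            sites = block["sites"]
            beta[sites] = np.where(ok, b_site, 0.0)
            pval[sites] = np.where(ok, np.clip(p, np.finfo(float).tiny, 1.0), 1.0)
        return beta, pval

    def min_p(self, y: np.ndarray) -> float:
        return float(self.scan(y)[1].min())


def lmm_scan(
    y: np.ndarray,
    encoded: EncodedGenotypes,
    kinship_from: EncodedGenotypes | None = None,
    kinships: dict | None = None,
) -> pd.DataFrame:
    """LOCO mixed-model scan of one (inverse-normal) phenotype.

    Returns one row per site with ``chrom``, ``pos``, ``beta``, ``p`` and a
    ``monomorphic`` flag.  Kinship is computed from ``kinship_from`` (the
    additive encoding, by convention), from ``encoded`` itself, or taken
    from a precomputed per-chromosome mapping ``kinships``.
    """
    scanner = LMMScanner(encoded, kinship_from=kinship_from, kinships=kinships)
    beta, p = scanner.scan(y)
    return pd.DataFrame(
        {
            "chrom": encoded.sites["chrom"],
            "pos": encoded.sites["pos"],
            "beta": beta,
            "p": p,
            "monomorphic": ~scanner.site_variable,
        }
    )


def permutation_threshold(
    y: np.ndarray,
    encoded: EncodedGenotypes,
    kinship_from: EncodedGenotypes | None = None,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "minp",
    scanner: LMMScanner | None = None,
) -> float:
    """Permutation family-wise significance threshold for one trait.

    Phenotype values are shuffled across individuals ``n_perm`` times and
    the full scan re-run each time.  ``method="minp"`` (default) keeps each
    permutation's genome-wide minimum p-value and returns the
    ⌈alpha·n_perm⌉-th smallest of those minima (the 5th of 100 at
    alpha=0.05), so observed p-values at or below the threshold carry an
    ~alpha family-wise error rate.  ``method="pooled"`` instead returns the
    ⌈alpha·n_perm⌉-th smallest of *all* permuted p-values pooled.
    """
    if alpha * n_perm < 1:
        raise ValueError("alpha * n_perm must be at least 1")
    k = math.ceil(alpha * n_perm)
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    if method not in ("minp", "pooled"):
        raise ValueError("method must be 'minp' or 'pooled'")
    if scanner is None:
        scanner = LMMScanner(encoded, kinship_from=kinship_from)
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    stats_: list = []
    for _ in range(n_perm):
        yp = rng.permutation(y)
        _, p = scanner.scan(yp)
        if method == "minp":
            stats_.append(p.min())
        else:
            stats_.append(p)
    if method == "minp":
        return float(np.sort(np.asarray(stats_))[k - 1])
    pooled = np.sort(np.concatenate(stats_))
    return float(pooled[k - 1])


def effect_size(y: np.ndarray, dosage: np.ndarray, encoding: str) -> float:
    """Cohen's d for one site.

    Under the additive encoding the heterozygotes are contrasted with the
    major-allele homozygotes (the larger homozygote class, hence the better
    powered contrast); under the overdominant encoding with all homozygotes
    pooled.  Pooled sd = sqrt((sd₁² + sd₂²)/2).  Either group smaller than
    2 yields NaN.
    """
    if encoding not in ENCODINGS:
        raise ValueError(f"encoding must be one of {ENCODINGS}")
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage)
    het = dosage == 1
    other = (dosage == 0) if encoding == ADDITIVE else (dosage != 1)
    g1, g2 = y[het], y[other]
    if len(g1) < 2 or len(g2) < 2:
        return float("nan")
    sd_pooled = math.sqrt((g1.std(ddof=1) ** 2 + g2.std(ddof=1) ** 2) / 2.0)
    if sd_pooled == 0:
        return float("nan")
    return float((g1.mean() - g2.mean()) / sd_pooled)


def variance_explained(y: np.ndarray, g: np.ndarray) -> float:
    """Squared genotype–phenotype Pearson correlation (0 for a flat site)."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if g.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(g, y)[0, 1]
    return float(r * r)


def association_scan(
    panel: DiallelPanel,
    phenotypes: PhenotypeTable,
    condition: str,
    encodings=ENCODINGS,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Full association analysis of one condition under one or both encodings.

    Phenotype medians are aligned to the panel's hybrids, inverse-normal
    transformed, scanned per encoding with the additive-dosage LOCO kinship,
    and thresholded by ``n_perm`` phenotype permutations (per encoding).
    Returns one row per site × encoding with effect, p-value, variance
    explained, Cohen's d, panel and source MAF, and the significance flag.
    """
    summ = phenotypes.condition(condition).set_index("individual_id")
    missing = [h for h in panel.hybrid_ids if h not in summ.index]
    if missing:
        raise ValueError(f"missing phenotypes for {len(missing)} hybrids")
    raw = summ.loc[panel.hybrid_ids, "median"].to_numpy(dtype=float)
    y = inverse_normal_transform(raw)
    additive = encode_genotypes(panel, ADDITIVE)
    frames = []
    for encoding in encodings:
        enc = additive if encoding == ADDITIVE else encode_genotypes(panel, encoding)
        scanner = LMMScanner(enc, kinship_from=additive)
        beta, p = scanner.scan(y)
        threshold = permutation_threshold(
            y, enc, n_perm=n_perm, alpha=alpha, seed=seed, scanner=scanner
        )
        ve = np.array([variance_explained(y, enc.matrix[:, j]) for j in range(enc.n_sites)])
        d = np.array([effect_size(y, enc.dosage[:, j], encoding) for j in range(enc.n_sites)])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": enc.sites["chrom"],
                    "pos": enc.sites["pos"],
                    "condition": condition,
                    "encoding": encoding,
                    "beta": beta,
                    "p": p,
                    "variance_explained": ve,
                    "cohens_d": d,
                    "maf_panel": enc.maf_panel,
                    "maf_source": enc.maf_source if enc.maf_source is not None else np.nan,
                    "threshold_p": threshold,
                    "significant": p <= threshold,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def maf_enrichment(
    results: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
) -> dict:
    """Source-population MAF composition of the significant associations.

    Classifies significant sites by source MAF (low-frequency below the
    ``low`` threshold, rare below ``rare``, common otherwise), and compares
    variance explained and |Cohen's d| between the low-frequency and common
    classes with a two-sided Mann–Whitney rank-sum test.  Also returns the
    panel-vs-source MAF table for plotting the frequency boost.
    """
    thresholds = thresholds or {"low": 0.05, "rare": 0.01}
    if "maf_source" not in results.columns:
        raise ValueError("results lack source-population MAF annotation")
    sig = results.loc[results["significant"] & results["maf_source"].notna()]
    scatter = results[["maf_source", "maf_panel", "significant"]].copy()
    if sig.empty:
        warnings.warn("no significant sites; enrichment summary is empty")
        return {"n_significant": 0, "scatter": scatter, "note": "no significant sites"}
    low = sig["maf_source"] < thresholds["low"]
    rare = sig["maf_source"] < thresholds["rare"]
    out = {
        "n_significant": int(len(sig)),
        "n_low_frequency": int(low.sum()),
        "n_rare": int(rare.sum()),
        "prop_low_frequency": float(low.mean()),
        "prop_rare": float(rare.mean()),
        "max_panel_maf_of_source_low": (
            float(sig.loc[low, "maf_panel"].max()) if low.any() else float("nan")
        ),
        "scatter": scatter,
    }
    common = ~low
    for col, name in (("variance_explained", "variance_explained"), ("cohens_d", "abs_d")):
        a = sig.loc[low, col].abs().dropna()
        b = sig.loc[common, col].abs().dropna()
        out[f"median_{name}_low"] = float(a.median()) if len(a) else float("nan")
        out[f"median_{name}_common"] = float(b.median()) if len(b) else float("nan")
        if len(a) >= 2 and len(b) >= 2:
            out[f"mannwhitney_p_{name}"] = float(
                stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            )
        else:
            out[f"mannwhitney_p_{name}"] = float("nan")
    return out
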