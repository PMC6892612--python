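"""Combining abilities and heritability from half-diallel phenotypes.

The phenotype of the hybrid between parents i and j is modeled as

    z_ij = μ + g_i + g_j + s_ij + e

where g_i is parent i's general combining ability (GCA, its average
additive contribution across all its hybrids), s_ij the cross-specific
combining ability (SCA, the non-additive residual), and e measurement
error.  Estimation uses the heterozygous half diallel only (homozygous
self-crosses are excluded):

    μ    = mean of the C(N,2) hybrid phenotypes
    ĝ_i  = (N−1)/(N−2) · (z̄_i· − μ),   z̄_i· the mean over parent i's hybrids
    ŝ_ij = z_ij − ĝ_i − ĝ_j − μ

Variance components follow: σ²A = Var(ĝ_i + ĝ_j) over crosses, σ²SCA =
Var(ŝ_ij), and σ²e the sampling variance of a cross phenotype estimated as
the mean over crosses of (replicate variance / n).  Narrow-sense
heritability is h² = σ²A / (σ²A + σ²SCA + σ²e) and broad-sense
H² = (σ²A + σ²SCA) / (σ²A + σ²SCA + σ²e).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DiallelPanel
from .pheno import PhenotypeTable


@dataclass
class CombiningAbilityResult:
    """Combining-ability decomposition for one condition."""

    condition: str
    mu: float
    gca: pd.Series              # ĝ_i per parent
    sca: pd.Series              # ŝ_ij per unordered cross (parent1, parent2)
    e_g: pd.Series | None = None     # GCA error term per parent
    e_s: pd.Series | None = None     # SCA error term per cross
    sigma2_e: float | None = None    # error variance of a cross phenotype
    var_additive: float | None = None   # σ²A = Var(ĝ_i + ĝ_j) over crosses
    var_sca: float | None = None        # Var(ŝ_ij)
    h2: float | None = None
    H2: float | None = None

    @property
    def n_parents(self) -> int:
        return len(self.gca)


def _cross_phenotypes(
    phenotypes: PhenotypeTable, panel: DiallelPanel, condition: str
) -> pd.DataFrame:
    """Per unordered heterozygous cross: phenotype and replicate variance.

    In a full-matrix panel, reciprocal hybrids are replicate constructions
    of the same unordered cross; their medians are averaged and their
    replicate variances pooled (mean).
    """
    het = panel.heterozygous_crosses()
    summ = phenotypes.condition(condition).set_index("individual_id")
    missing = [h for h in het["hybrid_id"] if h not in summ.index]
    if missing:
        raise ValueError(
            f"missing phenotypes for {len(missing)} crosses in condition "
            f"{condition!r}: {missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    rows = het.assign(
        value=summ.loc[het["hybrid_id"], "median"].to_numpy(),
        rep_var=(
            summ.loc[het["hybrid_id"], "sd"].to_numpy() ** 2
            if "sd" in summ.columns
            else np.nan
        ),
        n_rep=(
            summ.loc[het["hybrid_id"], "n"].to_numpy()
            if "n" in summ.columns
            else 1
        ),
    )
    key = rows.apply(
        lambda r: tuple(sorted((r["parent1"], r["parent2"]))), axis=1
    )
    rows = rows.assign(p1=[k[0] for k in key], p2=[k[1] for k in key])
    agg = (
        rows.groupby(["p1", "p2"], sort=True)
        .agg(value=("value", "mean"), rep_var=("rep_var", "mean"), n_rep=("n_rep", "mean"))
        .reset_index()
    )
    return agg


def estimate_combining_abilities(
    phenotypes: PhenotypeTable, panel: DiallelPanel, condition: str
) -> CombiningAbilityResult:
    """Estimate μ, per-parent GCA and per-cross SCA for one condition.

    Requires a phenotype for every heterozygous cross (no imputation) and
    at least 4 parents; the (N−1)/(N−2) factor is undefined below that.
    """
    parents = panel.parent_ids or sorted(
        set(panel.crosses["parent1"]) | set(panel.crosses["parent2"])
    )
    n = len(parents)
    if n < 4:
        raise ValueError(f"combining-ability estimation needs N >= 4 parents, got {n}")
    crosses = _cross_phenotypes(phenotypes, panel, condition)
    if len(crosses) != n * (n - 1) // 2:
        raise ValueError(
            f"expected {n*(n-1)//2} unordered heterozygous crosses, got {len(crosses)}"
        )
    z = crosses["value"].to_numpy()
    mu = float(z.mean())
    gca = {}
    for p in parents:
        mask = (crosses["p1"] == p) | (crosses["p2"] == p)
        zbar = crosses.loc[mask, "value"].mean()
        gca[p] = (n - 1) / (n - 2) * (zbar - mu)
    gca = pd.Series(gca, name="gca")
    sca = z - gca[crosses["p1"]].to_numpy() - gca[crosses["p2"]].to_numpy() - mu
    sca = pd.Series(
        sca,
        index=pd.MultiIndex.from_frame(crosses[["p1", "p2"]]).rename(["parent1", "parent2"]),
        name="sca",
    )
    return CombiningAbilityResult(condition=condition, mu=mu, gca=gca, sca=sca)


def estimate_error_variances(
    result: CombiningAbilityResult,
    phenotypes: PhenotypeTable,
    panel: DiallelPanel,
) -> CombiningAbilityResult:
    """Attach GCA/SCA error terms and the phenotype error variance σ²e.

    With σ²(z_ij) the replicate variance of cross ij and n its replicate
    count:  e_gi = (N−1)·σ̄²_i / (n·N·(N−2)) where σ̄²_i averages replicate
    variance over parent i's crosses; e_sij = (N−3)·σ²(z_ij) / (n·(N−1));
    σ²e = mean over crosses of σ²(z_ij)/n, the sampling variance of a cross
    phenotype.  Single-replicate data give σ²e = 0 with a warning.
    """
    crosses = _cross_phenotypes(phenotypes, panel, result.condition)
    n_parents = result.n_parents
    n_rep = crosses["n_rep"].to_numpy(dtype=float)
    rep_var = crosses["rep_var"].to_numpy(dtype=float)
    if np.all(n_rep <= 1) or np.all(~np.isfinite(rep_var)):
        warnings.warn("replicate variances unavailable; sigma2_e set to 0")
        rep_var = np.zeros_like(rep_var)
        n_rep = np.ones_like(n_rep)
    e_g = {}
    for p in result.gca.index:
        mask = (crosses["p1"] == p) | (crosses["p2"] == p)
        sig2_bar = rep_var[mask.to_numpy()].mean()
        nbar = n_rep[mask.to_numpy()].mean()
        e_g[p] = (n_parents - 1) * sig2_bar / (nbar * n_parents * (n_parents - 2))
    result.e_g = pd.Series(e_g, name="e_g")
    e_s = (n_parents - 3) * rep_var / (n_rep * (n_parents - 1))
    result.e_s = pd.Series(
        e_s,
        index=pd.MultiIndex.from_frame(crosses[["p1", "p2"]]).rename(["parent1", "parent2"]),
        name="e_s",
    )
    result.sigma2_e = float(np.mean(rep_var / n_rep))
    return result


def estimate_heritabilities(result: CombiningAbilityResult) -> CombiningAbilityResult:
    """Fill σ²A, σ²SCA, h² and H² on a result with combining abilities.

    σ²A is the variance (n−1 denominator) over crosses of ĝ_i + ĝ_j, σ²SCA
    the variance of ŝ_ij, and σ²P their sum plus σ²e.  Both heritabilities
    are clipped to [0, 1]; zero total variance yields NaN with a warning.
    """
    if result.sigma2_e is None:
        result.sigma2_e = 0.0
    p1 = result.sca.index.get_level_values("parent1")
    p2 = result.sca.index.get_level_values("parent2")
    g_sum = result.gca[p1].to_numpy() + result.gca[p2].to_numpy()
    var_a = float(np.var(g_sum, ddof=1))
    var_s = float(np.var(result.sca.to_numpy(), ddof=1))
    total = var_a + var_s + result.sigma2_e
    result.var_additive = var_a
    result.var_sca = var_s
    if total <= 0:
        warnings.warn("zero phenotypic variance; heritabilities undefined")
        result.h2 = float("nan")
        result.H2 = float("nan")
        return result
    result.h2 = float(np.clip(var_a / total, 0.0, 1.0))
    result.H2 = float(np.clip((var_a + var_s) / total, 0.0, 1.0))
    return result


def expected_phenotypes(
    result: CombiningAbilityResult,
    phenotypes: PhenotypeTable,
    panel: DiallelPanel,
) -> tuple[pd.DataFrame, float]:
    """Model-expected phenotype per hybrid and its correlation with data.

    Heterozygous crosses reconstruct exactly (μ + ĝ_i + ĝ_j + ŝ_ij equals
    the observed value by construction); homozygous diagonal hybrids, which
    were excluded from estimation, are predicted as μ + 2ĝ_i, so any
    inbreeding effect lowers the overall Pearson correlation below 1.
    """
    summ = phenotypes.condition(result.condition).set_index("individual_id")
    rows = []
    for _, cr in panel.crosses.iterrows():
        hid = cr["hybrid_id"]
        if hid not in summ.index:
            continue
        observed = float(summ.loc[hid, "median"])
        if cr["is_homozygous"]:
            expected = result.mu + 2 * result.gca[cr["parent1"]]
        else:
            key = tuple(sorted((cr["parent1"], cr["parent2"])))
            expected = result.mu + result.gca[key[0]] + result.gca[key[1]] + result.sca[key]
        rows.append((hid, cr["is_homozygous"], expected, observed))
    table = pd.DataFrame(rows, columns=["hybrid_id", "is_homozygous", "expected", "observed"])
    if len(table) < 2 or table["observed"].nunique() < 2:
        return table, float("nan")
    r = stats.pearsonr(table["expected"], table["observed"]).statistic
    return table, float(r)


def analyze_condition(
    phenotypes: PhenotypeTable, panel: DiallelPanel, condition: str
) -> CombiningAbilityResult:
    """Full combining-ability + heritability analysis for one condition."""
    result = estimate_combining_abilities(phenotypes, panel, condition)
    result = estimate_error_variances(result, phenotypes, panel)
    return estimate_heritabilities(result)


def analyze_diallel(
    phenotypes: PhenotypeTable, panel: DiallelPanel, conditions=None
) -> dict[str, CombiningAbilityResult]:
    """Run :func:`analyze_condition` across conditions."""
    conditions = conditions or phenotypes.conditions()
    return {c: analyze_condition(phenotypes, panel, c) for c in conditions}


def heritability_summary(results: dict[str, CombiningAbilityResult]) -> pd.DataFrame:
    """One row per condition: μ, variance components, h², H²."""
    rows = [
        {
            "condition": c,
            "mu": r.mu,
            "var_additive": r.var_additive,
            "var_sca": r.var_sca,
            "sigma2_e": r.sigma2_e,
            "h2": r.h2,
            "H2": r.H2,
        }
        for c, r in results.items()
    ]
    return pd.DataFrame(rows)


def heritability_calibration(summary: pd.DataFrame) -> dict[str, float]:
    """Cross-condition calibration statistics of the heritability table:
    means and ranges of h² and H², mean non-additive share H²−h², and the
    Pearson correlation between H² and h² across conditions."""
    h2 = summary["h2"].to_numpy(dtype=float)
    H2 = summary["H2"].to_numpy(dtype=float)
    ok = np.isfinite(h2) & np.isfinite(H2)
    h2, H2 = h2[ok], H2[ok]
    out = {
        "n_conditions": int(ok.sum()),
        "mean_h2": float(h2.mean()),
        "mean_H2": float(H2.mean()),
        "mean_nonadditive": float((H2 - h2).mean()),
        "min_h2": float(h2.min()),
        "max_h2": float(h2.max()),
        "min_H2": float(H2.min()),
        "max_H2": float(H2.max()),
    }
    if len(h2) >= 3 and np.std(h2) > 0 and np.std(H2) > 0:
        out["pearson_r_H2_h2"] = float(stats.pearsonr(H2, h2).statistic)
    else:
        out["pearson_r_H2_h2"] = float("nan")
    return out
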