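"""Synthetic founder genotypes and diallel phenotypes with known architecture.

The generator emulates the study system downstream modules are built for: a
panel of homozygous diploid yeast founders drawn from a large natural
population whose site-frequency spectrum is heavily skewed toward rare
alleles (≈93% of polymorphic sites below 5% minor-allele frequency), crossed
in a diallel and phenotyped as colony growth ratios with a handful of
replicates per hybrid and many per parent.  Every quantity the analysis
modules estimate — combining abilities, heritabilities, inheritance modes,
per-site effects — has a ground truth here, so the whole pipeline is
testable without external data.

Genotypic values use the classical single-locus parameterization: the
homozygote for the major allele scores ``+a``, the minor homozygote ``-a``,
and the heterozygote ``d``.  ``d = 0`` is additivity, ``|d| = |a|`` complete
dominance, and ``|d| > |a|`` over/underdominance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    HOM_ALT,
    HOM_REF,
    DiallelPanel,
    FounderPanel,
    enumerate_half_diallel,
)

_BASES = np.array(list("ACGT"))


@dataclass
class MafSpectrum:
    """Binned minor-allele-frequency spectrum used to draw site frequencies.

    ``bin_edges`` are strictly increasing breakpoints in [0, 0.5];
    ``bin_weights`` (one per bin) sum to 1.
    """

    bin_edges: np.ndarray
    bin_weights: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.bin_weights = np.asarray(self.bin_weights, dtype=float)
        if len(self.bin_edges) != len(self.bin_weights) + 1:
            raise ValueError("need len(bin_edges) == len(bin_weights) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.bin_edges[0] < 0 or self.bin_edges[-1] > 0.5:
            raise ValueError("bin edges must lie in [0, 0.5]")
        if np.any(self.bin_weights < 0) or not np.isclose(self.bin_weights.sum(), 1.0):
            raise ValueError("bin weights must be non-negative and sum to 1")

    @classmethod
    def rare_skewed(cls, low_fraction: float = 0.927) -> "MafSpectrum":
        """Spectrum mimicking a large natural isolate collection where
        ``low_fraction`` of sites have MAF < 0.05, the rest tapering off."""
        rest = 1.0 - low_fraction
        w = np.array([0.41, 0.21, 0.16, 0.12, 0.10])
        return cls(
            bin_edges=np.array([0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5]),
            bin_weights=np.concatenate([[low_fraction], rest * w]),
        )


@dataclass
class TraitModel:
    """Ground-truth genetic architecture for one trait.

    ``additive_effects[k]`` is the half-difference ``a`` between the two
    homozygotes at causal site ``causal_site_ids[k]``; ``dominance_effects``
    holds the heterozygote deviation ``d``.  ``true_gca``/``true_sca`` are
    the combining abilities implied by exhaustive evaluation of noiseless
    genotypic values over the founder panel's half diallel.
    """

    causal_site_ids: np.ndarray
    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    env_sd: float
    true_gca: pd.Series = field(default=None)  # type: ignore[assignment]
    true_sca: pd.Series = field(default=None)  # type: ignore[assignment]
    minor_is_alt: np.ndarray = field(default=None)  # type: ignore[assignment]

    def genotypic_values(self, dosages: np.ndarray) -> np.ndarray:
        """Genotypic values for individuals given alt-allele dosages at the
        causal sites (columns aligned with ``causal_site_ids``)."""
        dosages = np.asarray(dosages)
        a = self.additive_effects
        d = self.dominance_effects
        # score per genotype: hom-major +a, het d, hom-minor -a
        minor_dosage = np.where(self.minor_is_alt, dosages, 2 - dosages)
        values = np.where(
            minor_dosage == 1, d, np.where(minor_dosage == 0, a, -a)
        )
        return values.sum(axis=-1)


def _achievable_counts(n_founders: int) -> np.ndarray:
    return np.arange(1, max(1, n_founders // 2) + 1)


def simulate_founders(
    n_founders: int,
    n_sites: int,
    spectrum: MafSpectrum | None = None,
    n_chromosomes: int = 16,
    seed: int = 0,
    chrom_length: int = 1_000_000,
) -> FounderPanel:
    """Draw a panel of homozygous founders with a target MAF spectrum.

    Each site's minor-allele carrier count is drawn so that the realized
    founder-sample MAF (carriers / n_founders, since founders are
    homozygous) falls in a spectrum bin sampled by weight; bins containing
    no achievable count are excluded with weights renormalized.  Every site
    keeps at least one carrier.  Sites are placed uniformly on
    ``n_chromosomes`` chromosomes (16 by default, the yeast karyotype, so
    leave-one-chromosome-out kinship has material to work with).

    The drawn (continuous) bin frequency is recorded per site as
    ``maf_source``, playing the role of the variant's frequency in the
    large source population the founders were sampled from; the realized
    founder MAF is typically boosted above it for rare variants.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_sites < 1:
        raise ValueError("need at least 1 site")
    spectrum = spectrum or MafSpectrum.rare_skewed()
    rng = np.random.default_rng(seed)

    ks = _achievable_counts(n_founders)
    freqs = ks / n_founders
    lo, hi = spectrum.bin_edges[:-1], spectrum.bin_edges[1:]
    achievable: list[np.ndarray] = []
    for b in range(len(spectrum.bin_weights)):
        inside = (freqs >= lo[b]) & (
            (freqs <= hi[b]) if b == len(spectrum.bin_weights) - 1 else (freqs < hi[b])
        )
        achievable.append(ks[inside])
    usable = np.array([len(a) > 0 for a in achievable])
    positive = spectrum.bin_weights > 0
    if not (usable & positive).any():
        if hi[positive].max() <= 1.0 / (2 * n_founders):
            raise ValueError(
                "spectrum unattainable: all weight lies below MAF "
                f"1/(2*n_founders) = {1/(2*n_founders):.4g}"
            )
        fallback = True
    else:
        fallback = False

    if fallback:
        # no bin contains an achievable count: draw a frequency and clamp
        # to the nearest achievable carrier count (at least one carrier)
        bins = rng.choice(len(spectrum.bin_weights), size=n_sites, p=spectrum.bin_weights)
        target = rng.uniform(lo[bins], hi[bins])
        counts = np.clip(np.rint(target * n_founders), 1, ks[-1]).astype(int)
    else:
        w = np.where(usable, spectrum.bin_weights, 0.0)
        w = w / w.sum()
        bins = rng.choice(len(w), size=n_sites, p=w)
        counts = np.array([rng.choice(achievable[b]) for b in bins])
    target_maf = rng.uniform(lo[bins], np.minimum(hi[bins], 0.5))

    genotypes = np.full((n_founders, n_sites), HOM_REF, dtype=np.int8)
    for j in range(n_sites):
        carriers = rng.choice(n_founders, size=counts[j], replace=False)
        genotypes[carriers, j] = HOM_ALT

    # site coordinates: uniform chromosome, unique positions within it
    chrom_idx = rng.integers(0, n_chromosomes, size=n_sites)
    pos = np.empty(n_sites, dtype=np.int64)
    for c in range(n_chromosomes):
        members = np.flatnonzero(chrom_idx == c)
        pos[members] = np.sort(
            rng.choice(np.arange(1, chrom_length + 1), size=len(members), replace=False)
        )
    order = np.lexsort((pos, chrom_idx))
    ref = rng.choice(_BASES, size=n_sites)
    alt_shift = rng.integers(1, 4, size=n_sites)
    alt = _BASES[(np.searchsorted(_BASES, ref) + alt_shift) % 4]
    sites = pd.DataFrame(
        {
            "chrom": [f"chr{chrom_idx[j] + 1:02d}" for j in order],
            "pos": pos[order],
            "ref": ref[order],
            "alt": alt[order],
            "maf_source": target_maf[order],
        }
    )
    parent_ids = [f"P{i+1:02d}" for i in range(n_founders)]
    return FounderPanel(parent_ids, sites, genotypes[:, order])


def simulate_trait_model(
    panel: FounderPanel,
    n_causal: int,
    additive_sd: float = 0.1,
    dominance_fraction: float = 0.0,
    overdominant_fraction: float = 0.0,
    env_sd: float = 0.05,
    seed: int = 0,
) -> TraitModel:
    """Draw a trait architecture over a founder panel.

    ``dominance_fraction`` of the causal sites get complete dominance
    (``d = ±a``) and ``overdominant_fraction`` get ``|d| > |a|`` (a factor
    1.5–3 beyond the additive effect); the remainder are purely additive.
    The implied per-parent GCA and per-cross SCA are computed by evaluating
    noiseless genotypic values over every heterozygous half-diallel cross
    and applying the combining-ability decomposition.
    """
    if not (0 <= dominance_fraction <= 1 and 0 <= overdominant_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if dominance_fraction + overdominant_fraction > 1:
        raise ValueError("dominance and overdominant fractions exceed 1")
    if additive_sd < 0 or env_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_causal > panel.n_sites:
        raise ValueError("n_causal exceeds number of sites")
    rng = np.random.default_rng(seed)
    causal = np.sort(rng.choice(panel.n_sites, size=n_causal, replace=False))
    a = rng.normal(0.0, additive_sd, size=n_causal)
    d = np.zeros(n_causal)
    n_dom = int(round(dominance_fraction * n_causal))
    n_over = int(round(overdominant_fraction * n_causal))
    n_over = min(n_over, n_causal - n_dom)
    special = rng.permutation(n_causal)
    dom_idx, over_idx = special[:n_dom], special[n_dom:n_dom + n_over]
    d[dom_idx] = np.abs(a[dom_idx]) * rng.choice([-1.0, 1.0], size=n_dom)
    d[over_idx] = (
        np.maximum(np.abs(a[over_idx]), additive_sd * 0.5)
        * rng.uniform(1.5, 3.0, size=n_over)
        * rng.choice([-1.0, 1.0], size=n_over)
    )
    model = TraitModel(
        causal_site_ids=causal,
        additive_effects=a,
        dominance_effects=d,
        env_sd=float(env_sd),
        minor_is_alt=panel.minor_allele_is_alt()[causal],
    )
    model.true_gca, model.true_sca = _true_combining_abilities(panel, model)
    return model


def _true_combining_abilities(panel: FounderPanel, model: TraitModel):
    """Exhaustive noiseless combining abilities over the half diallel."""
    n = panel.n_parents
    founder_dosage = panel.genotypes[:, model.causal_site_ids].astype(np.int16)
    if n < 4:
        zero_g = pd.Series(0.0, index=panel.parent_ids)
        return zero_g, pd.Series(dtype=float)
    crosses = enumerate_half_diallel(panel.parent_ids, include_diagonal=False)
    idx = {p: i for i, p in enumerate(panel.parent_ids)}
    i1 = crosses.crosses["parent1"].map(idx).to_numpy()
    i2 = crosses.crosses["parent2"].map(idx).to_numpy()
    dosage = (founder_dosage[i1] + founder_dosage[i2]) // 2
    z = model.genotypic_values(dosage)
    mu = z.mean()
    zbar = np.zeros(n)
    for i in range(n):
        mask = (i1 == i) | (i2 == i)
        zbar[i] = z[mask].mean()
    gca = (n - 1) / (n - 2) * (zbar - mu)
    sca = z - gca[i1] - gca[i2] - mu
    gca_s = pd.Series(gca, index=panel.parent_ids)
    sca_idx = pd.MultiIndex.from_arrays(
        [crosses.crosses["parent1"], crosses.crosses["parent2"]], names=["parent1", "parent2"]
    )
    return gca_s, pd.Series(sca, index=sca_idx)


def simulate_colony_data(
    panel: FounderPanel,
    crosses: DiallelPanel,
    models,
    n_replicates_hybrid: int = 6,
    n_replicates_parent: int = 54,
    baseline: float = 1.0,
    noise: str = "gaussian",
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate-level growth-ratio table for hybrids and parents.

    ``models`` is a single :class:`TraitModel` (condition named ``"cond1"``)
    or a mapping ``{condition: TraitModel}``.  Each hybrid receives
    ``n_replicates_hybrid`` values per condition and each parent (as a
    homozygous diploid) ``n_replicates_parent``; a replicate is the
    individual's genotypic value plus ``baseline`` plus environmental noise
    with sd ``env_sd`` (Gaussian by default; ``noise="student_t"`` gives a
    heavier-tailed alternative with matched scale, df=3, for exercising the
    median's robustness).

    Returns a long table with columns ``individual_id``, ``condition``,
    ``replicate``, ``value``.
    """
    if not isinstance(models, dict):
        models = {"cond1": models}
    if noise not in ("gaussian", "student_t"):
        raise ValueError("noise must be 'gaussian' or 'student_t'")
    unknown = set(crosses.crosses["parent1"]) | set(crosses.crosses["parent2"])
    unknown -= set(panel.parent_ids)
    if unknown:
        raise ValueError(f"crosses reference unknown parents: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    idx = {p: i for i, p in enumerate(panel.parent_ids)}
    i1 = crosses.crosses["parent1"].map(idx).to_numpy()
    i2 = crosses.crosses["parent2"].map(idx).to_numpy()

    frames = []
    for condition, model in models.items():
        if model.env_sd < 0:
            raise ValueError("env_sd must be non-negative")
        founder_dosage = panel.genotypes[:, model.causal_site_ids].astype(np.int16)
        hyb_dosage = (founder_dosage[i1] + founder_dosage[i2]) // 2
        hyb_values = baseline + model.genotypic_values(hyb_dosage)
        par_values = baseline + model.genotypic_values(founder_dosage)

        def _noise(shape):
            if model.env_sd == 0:
                return np.zeros(shape)
            if noise == "gaussian":
                return rng.normal(0.0, model.env_sd, size=shape)
            # t(3) scaled to sd env_sd
            return rng.standard_t(3, size=shape) * (model.env_sd / np.sqrt(3.0))

        hv = hyb_values[:, None] + _noise((len(hyb_values), n_replicates_hybrid))
        pv = par_values[:, None] + _noise((len(par_values), n_replicates_parent))
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": np.repeat(
                        crosses.crosses["hybrid_id"].to_numpy(), n_replicates_hybrid
                    ),
                    "condition": condition,
                    "replicate": np.tile(
                        np.arange(1, n_replicates_hybrid + 1), len(hyb_values)
                    ),
                    "value": hv.ravel(),
                }
            )
        )
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": np.repeat(panel.parent_ids, n_replicates_parent),
                    "condition": condition,
                    "replicate": np.tile(
                        np.arange(1, n_replicates_parent + 1), panel.n_parents
                    ),
                    "value": pv.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
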