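"""Diallel cross enumeration, in-silico hybrid genotypes, and site filters.

A diallel panel is built from a set of homozygous diploid founders: every
pairwise cross (optionally including selfs, optionally including reciprocal
orderings) yields an F1 hybrid whose genotype is fully determined by its
parents' homozygous calls.  Because the parents are homozygous, a hybrid is
heterozygous at a site exactly when its parents carry different alleles
there.  This module owns the genotype containers, the cross enumerators,
and the two site filters applied before association analysis: the
biallelic/no-missing/no-het filter and the long-range perfect-LD block
pruner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Founder genotype codes (per site, per parent).
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

FULL_MATRIX = "full_matrix"
HALF_MATRIX = "half_matrix"
HALF_MATRIX_WITH_DIAGONAL = "half_matrix_with_diagonal"

_SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class FounderPanel:
    """Homozygous founder genotypes at biallelic sites.

    Parameters
    ----------
    parent_ids
        Unique founder labels, one per row of ``genotypes``.
    sites
        One row per site with columns ``chrom``, ``pos`` (1-based), ``ref``,
        ``alt`` and optionally ``maf_source`` (minor-allele frequency of the
        site in a larger source population, used only as annotation).
    genotypes
        ``(n_parents, n_sites)`` int8 array of {HOM_REF, HET, HOM_ALT,
        MISSING}.  Founders are intended to be homozygous; heterozygous or
        missing calls are tolerated here and removed by :func:`filter_sites`.
    """

    parent_ids: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.parent_ids = list(self.parent_ids)
        if len(set(self.parent_ids)) != len(self.parent_ids):
            raise ValueError("duplicate parent ids")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.parent_ids), len(self.sites)):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{len(self.parent_ids)} parents x {len(self.sites)} sites"
            )
        for col in _SITE_COLUMNS:
            if col not in self.sites.columns:
                raise ValueError(f"sites table lacks column {col!r}")
        self.sites = self.sites.reset_index(drop=True)
        for _, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_parents(self) -> int:
        return len(self.parent_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_sites(self, mask: np.ndarray) -> "FounderPanel":
        mask = np.asarray(mask)
        return FounderPanel(
            self.parent_ids,
            self.sites.loc[mask].reset_index(drop=True),
            self.genotypes[:, mask],
        )

    def minor_allele_is_alt(self) -> np.ndarray:
        """Per site, whether the alt allele is the minor one in the founder
        sample (ties broken toward alt)."""
        alt_count = (self.genotypes == HOM_ALT).sum(axis=0) * 2 + (self.genotypes == HET).sum(axis=0)
        called = 2 * (self.genotypes != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            alt_freq = np.where(called > 0, alt_count / np.maximum(called, 1), 0.0)
        return alt_freq <= 0.5

    def founder_maf(self) -> np.ndarray:
        """Minor-allele frequency per site over the founder sample."""
        alt_count = (self.genotypes == HOM_ALT).sum(axis=0) * 2 + (self.genotypes == HET).sum(axis=0)
        called = 2 * (self.genotypes != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(called > 0, alt_count / np.maximum(called, 1), np.nan)
        return np.minimum(freq, 1.0 - freq)


def hybrid_id(parent1: str, parent2: str) -> str:
    return f"{parent1}x{parent2}"


def cross_key(parent1: str, parent2: str) -> tuple[str, str]:
    """Canonical unordered key for a cross (sorted parent pair)."""
    return (parent1, parent2) if parent1 <= parent2 else (parent2, parent1)


@dataclass
class DiallelPanel:
    """A set of crosses between founders, with optional hybrid genotypes.

    ``crosses`` has one row per hybrid with columns ``hybrid_id``,
    ``parent1``, ``parent2`` and ``is_homozygous`` (a diagonal self-cross).
    ``hybrid_genotypes`` — filled by :func:`synthesize_hybrid_genotypes` —
    is an ``(n_hybrids, n_sites)`` int8 array of alt-allele dosages
    {0, 1, 2}, aligned with ``sites``.
    """

    scheme: str
    crosses: pd.DataFrame
    sites: pd.DataFrame | None = None
    hybrid_genotypes: np.ndarray | None = None
    parent_ids: list[str] = field(default_factory=list)

    @property
    def n_hybrids(self) -> int:
        return len(self.crosses)

    @property
    def hybrid_ids(self) -> list[str]:
        return self.crosses["hybrid_id"].tolist()

    def heterozygous_crosses(self) -> pd.DataFrame:
        return self.crosses.loc[~self.crosses["is_homozygous"]]

    def homozygous_crosses(self) -> pd.DataFrame:
        return self.crosses.loc[self.crosses["is_homozygous"]]


def _check_parents(parent_ids) -> list[str]:
    parent_ids = list(parent_ids)
    if len(parent_ids) == 0:
        raise ValueError("need at least one parent")
    if len(set(parent_ids)) != len(parent_ids):
        raise ValueError("duplicate parent ids")
    return parent_ids


def enumerate_full_diallel(parent_ids) -> DiallelPanel:
    """All N² ordered (MATa x MATalpha) crosses, selfs flagged homozygous.

    With 55 founders this yields 3025 hybrids: 2970 heterozygous ordered
    pairs (reciprocals counted separately, as distinct constructed hybrids)
    plus 55 homozygous diagonal hybrids.
    """
    parent_ids = _check_parents(parent_ids)
    rows = [
        (hybrid_id(a, b), a, b, a == b)
        for a, b in itertools.product(parent_ids, repeat=2)
    ]
    crosses = pd.DataFrame(rows, columns=["hybrid_id", "parent1", "parent2", "is_homozygous"])
    return DiallelPanel(scheme=FULL_MATRIX, crosses=crosses, parent_ids=parent_ids)


def enumerate_half_diallel(parent_ids, include_diagonal: bool = False) -> DiallelPanel:
    """C(N,2) unordered crosses, plus the N selfs when ``include_diagonal``.

    34 founders with the diagonal give the 595-hybrid association panel.
    """
    parent_ids = _check_parents(parent_ids)
    if len(parent_ids) < 2:
        raise ValueError("half diallel needs at least two parents")
    rows = [
        (hybrid_id(a, b), a, b, False)
        for a, b in itertools.combinations(parent_ids, 2)
    ]
    if include_diagonal:
        rows += [(hybrid_id(a, a), a, a, True) for a in parent_ids]
    scheme = HALF_MATRIX_WITH_DIAGONAL if include_diagonal else HALF_MATRIX
    crosses = pd.DataFrame(rows, columns=["hybrid_id", "parent1", "parent2", "is_homozygous"])
    return DiallelPanel(scheme=scheme, crosses=crosses, parent_ids=parent_ids)


def synthesize_hybrid_genotypes(panel: FounderPanel, crosses: DiallelPanel) -> DiallelPanel:
    """Combine parental homozygous calls into F1 hybrid genotypes.

    The hybrid call is homozygous when both parents carry the same allele
    and heterozygous when they differ; the returned matrix stores
    alt-allele dosage (0, 1, 2).  Sites with missing or heterozygous
    founder calls must be removed first with :func:`filter_sites`.
    """
    unknown = set(crosses.crosses["parent1"]) | set(crosses.crosses["parent2"])
    unknown -= set(panel.parent_ids)
    if unknown:
        raise ValueError(f"crosses reference unknown parents: {sorted(unknown)}")
    bad = (panel.genotypes == MISSING) | (panel.genotypes == HET)
    if bad.any():
        raise ValueError(
            "founder panel contains missing or heterozygous calls; "
            "run filter_sites before synthesizing hybrids"
        )
    idx = {p: i for i, p in enumerate(panel.parent_ids)}
    i1 = crosses.crosses["parent1"].map(idx).to_numpy()
    i2 = crosses.crosses["parent2"].map(idx).to_numpy()
    # homozygous codes are 0/2 alt dosages; the hybrid dosage is their mean
    dosage = (panel.genotypes[i1].astype(np.int16) + panel.genotypes[i2]) // 2
    return DiallelPanel(
        scheme=crosses.scheme,
        crosses=crosses.crosses.copy(),
        sites=panel.sites.copy(),
        hybrid_genotypes=dosage.astype(np.int8),
        parent_ids=list(panel.parent_ids),
    )


def filter_sites(panel: FounderPanel) -> tuple[FounderPanel, dict[str, int]]:
    """Drop sites unusable for hybrid synthesis and association.

    A site is removed if it has any missing call, any heterozygous founder
    call, or is monomorphic across the panel.  Each removed site is counted
    under a single reason, checked in that priority order.
    """
    g = panel.genotypes
    has_missing = (g == MISSING).any(axis=0)
    has_het = (g == HET).any(axis=0) & ~has_missing
    clean = ~((g == MISSING) | (g == HET)).any(axis=0)
    mono = clean & ((g == HOM_REF).all(axis=0) | (g == HOM_ALT).all(axis=0))
    keep = clean & ~mono
    report = {
        "missing": int(has_missing.sum()),
        "heterozygous": int(has_het.sum()),
        "monomorphic": int(mono.sum()),
        "retained": int(keep.sum()),
    }
    return panel.subset_sites(keep), report


def prune_long_range_ld(
    panel: FounderPanel,
    max_block_gap: int = 25_000,
    max_shared_blocks: int = 2,
) -> tuple[FounderPanel, dict]:
    """Remove long-range perfect-LD artifacts from a small founder panel.

    With few founders, many distant sites carry the identical genotype
    pattern across all parents by chance, which inflates long-range LD.
    Sites are grouped into perfect-LD classes (identical founder genotype
    columns, either orientation collapsed is NOT applied — exact pattern
    only); within a class, consecutive sites on one chromosome at most
    ``max_block_gap`` bp apart form a haplotype block.  A class spanning
    more than ``max_shared_blocks`` blocks keeps only its first
    ``max_shared_blocks`` blocks in genomic order.
    """
    sites = panel.sites
    order_ok = True
    chrom_codes, _ = pd.factorize(sites["chrom"], sort=False)
    prev = None
    for c, p in zip(chrom_codes, sites["pos"].to_numpy()):
        if prev is not None and c == prev[0] and p <= prev[1]:
            order_ok = False
            break
        prev = (c, p)
    if not order_ok:
        raise ValueError("sites must be sorted by (chrom, pos)")

    n_sites = panel.n_sites
    keep = np.ones(n_sites, dtype=bool)
    patterns: dict[bytes, list[int]] = {}
    for j in range(n_sites):
        patterns.setdefault(panel.genotypes[:, j].tobytes(), []).append(j)

    removed_per_class: list[dict] = []
    chroms = sites["chrom"].to_numpy()
    positions = sites["pos"].to_numpy()
    for pattern, members in patterns.items():
        if len(members) < 2:
            continue
        # members are already in genomic order (sites are sorted)
        blocks: list[list[int]] = [[members[0]]]
        for j_prev, j in zip(members, members[1:]):
            same_chrom = chroms[j_prev] == chroms[j]
            close = same_chrom and (positions[j] - positions[j_prev]) <= max_block_gap
            if close:
                blocks[-1].append(j)
            else:
                blocks.append([j])
        if len(blocks) > max_shared_blocks:
            dropped = [j for block in blocks[max_shared_blocks:] for j in block]
            keep[dropped] = False
            removed_per_class.append(
                {"n_blocks": len(blocks), "n_sites_removed": len(dropped)}
            )
    report = {
        "n_classes_pruned": len(removed_per_class),
        "n_sites_removed": int((~keep).sum()),
        "retained": int(keep.sum()),
        "classes": removed_per_class,
    }
    return panel.subset_sites(keep), report
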