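import itertools

import numpy as np
import pandas as pd
import pytest

from diallel.design import FounderPanel


def make_panel(genotypes, chroms=None, positions=None, parent_ids=None, maf_source=None):
    """Build a FounderPanel from a small genotype matrix (parents x sites)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_parents, n_sites = genotypes.shape
    parent_ids = parent_ids or [f"P{i+1:02d}" for i in range(n_parents)]
    chroms = chroms if chroms is not None else ["chr01"] * n_sites
    positions = positions if positions is not None else list(range(100, 100 + 100 * n_sites, 100))
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": ["A"] * n_sites,
            "alt": ["C"] * n_sites,
        }
    )
    if maf_source is not None:
        sites["maf_source"] = maf_source
    return FounderPanel(parent_ids, sites, genotypes)


def random_homozygous_panel(rng, n_parents=8, n_sites=40, n_chroms=4):
    """Random clean (homozygous, polymorphic-ish) founder panel."""
    g = rng.choice([0, 2], size=(n_parents, n_sites), p=[0.7, 0.3]).astype(np.int8)
    # force at least one carrier and one non-carrier per site
    for j in range(n_sites):
        if (g[:, j] == 2).all():
            g[rng.integers(n_parents), j] = 0
        if (g[:, j] == 0).all():
            g[rng.integers(n_parents), j] = 2
    chroms = [f"chr{1 + j % n_chroms:02d}" for j in range(n_sites)]
    pos = list(itertools.chain.from_iterable([[100 + 100 * (j // n_chroms)] for j in range(n_sites)]))
    order = np.lexsort((pos, chroms))
    return make_panel(g[:, order], chroms=[chroms[k] for k in order],
                      positions=[pos[k] for k in order])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_diallel_phenotypes():
    """The 4-parent additive worked example: z_AB..z_CD = 10,12,14,16,18,20."""
    from diallel.pheno import PhenotypeTable

    rows = [("AxB", 10.0), ("AxC", 12.0), ("AxD", 14.0), ("BxC", 16.0),
            ("BxD", 18.0), ("CxD", 20.0)]
    summary = pd.DataFrame(
        {
            "individual_id": [r[0] for r in rows],
            "condition": "c",
            "median": [r[1] for r in rows],
            "sd": 0.0,
            "n": 6,
        }
    )
    return PhenotypeTable(summary=summary)
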