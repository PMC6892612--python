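"""Replicate-level growth measurements → per-individual phenotypes.

Phenotypes are normalized growth ratios (colony size on a condition over
colony size on rich control medium), summarized per individual × condition
by the replicate median — robust to pinning defects and contamination —
together with the replicate standard deviation and count, then optionally
mapped to standard-normal quantiles for mixed-model association.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PhenotypeTable:
    """Per individual × condition phenotype summaries.

    ``summary`` has columns ``individual_id``, ``condition``, ``median``,
    ``sd`` (replicate sd, n−1 denominator), ``n``; ``replicates`` optionally
    keeps the long replicate table it was derived from.
    """

    summary: pd.DataFrame
    replicates: pd.DataFrame | None = None

    def condition(self, condition: str) -> pd.DataFrame:
        return self.summary.loc[self.summary["condition"] == condition]

    def conditions(self) -> list[str]:
        return sorted(self.summary["condition"].unique())

    def value(self, individual_id: str, condition: str) -> float:
        rows = self.summary.loc[
            (self.summary["individual_id"] == individual_id)
            & (self.summary["condition"] == condition),
            "median",
        ]
        if rows.empty:
            raise KeyError((individual_id, condition))
        return float(rows.iloc[0])

    def to_tsv(self, path) -> None:
        self.summary.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        return cls(summary=pd.read_csv(path, sep="\t"))


def compute_growth_ratios(condition_sizes, control_sizes) -> np.ndarray:
    """Per-replicate growth ratio: condition colony size / control size.

    Non-positive or missing control sizes yield a missing ratio (NaN) and
    are logged rather than raising.
    """
    cond = np.asarray(condition_sizes, dtype=float)
    ctrl = np.asarray(control_sizes, dtype=float)
    if cond.shape != ctrl.shape:
        raise ValueError("condition and control size arrays must align")
    bad = ~np.isfinite(ctrl) | (ctrl <= 0)
    if bad.any():
        logger.warning("%d replicates have missing/zero control size; ratios set missing", bad.sum())
    out = np.full(cond.shape, np.nan)
    np.divide(cond, ctrl, out=out, where=~bad)
    return out


def aggregate_replicates(replicates: pd.DataFrame) -> PhenotypeTable:
    """Summarize a long replicate table into per-individual phenotypes.

    ``replicates`` needs columns ``individual_id``, ``condition``,
    ``value``.  The phenotype is the median over non-missing replicates; the
    replicate sd uses the n−1 denominator (0 for a single replicate).
    Groups whose replicates are all missing are dropped with a log message.
    """
    required = {"individual_id", "condition", "value"}
    if not required.issubset(replicates.columns):
        raise ValueError(f"replicate table needs columns {sorted(required)}")
    grouped = replicates.groupby(["individual_id", "condition"], sort=False)["value"]
    summary = grouped.agg(
        median="median",
        sd=lambda v: float(np.std(v.dropna(), ddof=1)) if v.notna().sum() > 1 else 0.0,
        n=lambda v: int(v.notna().sum()),
    ).reset_index()
    empty = summary["n"] == 0
    if empty.any():
        logger.warning("%d individual×condition groups have no usable replicates", empty.sum())
        summary = summary.loc[~empty].reset_index(drop=True)
    return PhenotypeTable(summary=summary, replicates=replicates)


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform of one condition's phenotypes.

    The value with (average, for ties) rank r of n maps to the standard
    normal quantile at (r − 0.5)/n; missing values stay missing.  Mixed
    models downstream assume normally distributed phenotypes, which raw
    growth ratios rarely are.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    mask = np.isfinite(values)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    obs = values[mask]
    if np.all(obs == obs[0]):
        warnings.warn("all phenotype values identical; transform maps to 0")
        out[mask] = 0.0
        return out
    ranks = stats.rankdata(obs, method="average")
    out[mask] = stats.norm.ppf((ranks - 0.5) / n)
    return out
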