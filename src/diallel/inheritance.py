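"""Inheritance-mode classification from parental and hybrid phenotypes.

A hybrid's phenotype is compared with its two homozygous parents' values
(P1 the less fit, P2 the fitter parent) and the mid-parent value
MPV = (P1 + P2)/2, the expectation under pure additivity.  Replicate
standard deviations define tolerance bands around P1, MPV and P2; the
hybrid's position among those bands yields one of seven modes:

    underdominance < dominance toward P1 < partial dominance toward P1
    < additivity < partial dominance toward P2 < dominance toward P2
    < overdominance

The full seven-way partition is only attempted when the parents themselves
separate (P1 + σP1 < P2 − σP2); otherwise only over- and underdominance —
the hybrid escaping the parental range outright — can be called, everything
in between being unclassifiable.  Note the mode describes how the hybrid's
phenotype sits relative to its parents, not locus-level dominance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DiallelPanel
from .pheno import PhenotypeTable

UNDERDOMINANCE = "underdominance"
DOMINANCE_P1 = "dominance_P1"
PARTIAL_DOMINANCE_P1 = "partial_dominance_P1"
ADDITIVITY = "additivity"
PARTIAL_DOMINANCE_P2 = "partial_dominance_P2"
DOMINANCE_P2 = "dominance_P2"
OVERDOMINANCE = "overdominance"
UNCLASSIFIED = "unclassified"

#: Band order from worst-parent side to best-parent side.
MODE_ORDER = (
    UNDERDOMINANCE,
    DOMINANCE_P1,
    PARTIAL_DOMINANCE_P1,
    ADDITIVITY,
    PARTIAL_DOMINANCE_P2,
    DOMINANCE_P2,
    OVERDOMINANCE,
)


@dataclass
class InheritanceCall:
    cross: tuple[str, str]
    condition: str
    mode: str
    separable: bool
    mpv: float
    hybrid_value: float
    p1: float
    p2: float


def classify_cross(
    P1: float,
    P2: float,
    sigmaP1: float,
    sigmaP2: float,
    Hyb: float,
    sigmaHyb: float,
    cross: tuple[str, str] = ("P1", "P2"),
    condition: str = "",
) -> InheritanceCall:
    """Classify one hybrid/condition combination into an inheritance mode.

    P1 is the least-fit parent by convention; arguments are relabeled
    (with their sds and the cross labels) if given the other way around.
    Band edges are cut points on the phenotype axis — upper bound exclusive,
    so the classification is the index of the first cut point exceeding
    ``Hyb`` — which guarantees exactly one mode per input and monotonicity
    of the call in ``Hyb``.
    """
    if sigmaP1 < 0 or sigmaP2 < 0 or sigmaHyb < 0:
        raise ValueError("standard deviations must be non-negative")
    # canonical order: P1 least fit; on exact phenotype ties, order by sd so
    # the call does not depend on which parent was listed first
    if P1 > P2 or (P1 == P2 and sigmaP1 > sigmaP2):
        P1, P2 = P2, P1
        sigmaP1, sigmaP2 = sigmaP2, sigmaP1
        cross = (cross[1], cross[0])
    mpv = (P1 + P2) / 2.0
    w1 = sigmaP1 + sigmaHyb
    wm = (sigmaP1 + sigmaP2) / 2.0 + sigmaHyb
    w2 = sigmaP2 + sigmaHyb
    separable = (P1 + sigmaP1) < (P2 - sigmaP2)
    if separable:
        cuts = (P1 - w1, P1 + w1, mpv - wm, mpv + wm, P2 - w2, P2 + w2)
        mode = MODE_ORDER[-1]
        for k, cut in enumerate(cuts):
            if Hyb < cut:
                mode = MODE_ORDER[k]
                break
    else:
        if Hyb < P1 - w1:
            mode = UNDERDOMINANCE
        elif Hyb >= P2 + w2:
            mode = OVERDOMINANCE
        else:
            mode = UNCLASSIFIED
    return InheritanceCall(
        cross=cross,
        condition=condition,
        mode=mode,
        separable=separable,
        mpv=mpv,
        hybrid_value=Hyb,
        p1=P1,
        p2=P2,
    )


def classify_panel(
    phenotypes: PhenotypeTable, panel: DiallelPanel, condition: str
) -> list[InheritanceCall]:
    """Classify every heterozygous cross of a panel for one condition.

    Parental phenotypes are the parents' own (homozygous diploid) rows in
    the phenotype table; crosses whose parents or hybrid lack a phenotype
    are skipped.
    """
    summ = phenotypes.condition(condition).set_index("individual_id")
    calls = []
    for _, cr in panel.heterozygous_crosses().iterrows():
        ids = (cr["parent1"], cr["parent2"], cr["hybrid_id"])
        if any(i not in summ.index for i in ids):
            continue
        pa, pb, hyb = (summ.loc[i] for i in ids)
        calls.append(
            classify_cross(
                float(pa["median"]),
                float(pb["median"]),
                float(pa.get("sd", 0.0)),
                float(pb.get("sd", 0.0)),
                float(hyb["median"]),
                float(hyb.get("sd", 0.0)),
                cross=(cr["parent1"], cr["parent2"]),
                condition=condition,
            )
        )
    return calls


def calls_to_frame(calls: list[InheritanceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parent1": [c.cross[0] for c in calls],
            "parent2": [c.cross[1] for c in calls],
            "condition": [c.condition for c in calls],
            "mode": [c.mode for c in calls],
            "separable": [c.separable for c in calls],
            "mpv": [c.mpv for c in calls],
            "hybrid_value": [c.hybrid_value for c in calls],
        }
    )


def summarize_condition(calls: list[InheritanceCall]) -> dict:
    """Per-condition summary of inheritance-mode calls.

    Mode fractions are computed among separable calls; over- and
    underdominance fractions additionally over *all* calls (they are the
    only modes callable without parental separation).  The predominant mode
    is the modal class among separable calls; ties report every tied mode.
    """
    if not calls:
        raise ValueError("need at least one call")
    n_total = len(calls)
    separable = [c for c in calls if c.separable]
    frac_separable = len(separable) / n_total
    mode_fractions = {m: 0.0 for m in MODE_ORDER}
    predominant: list[str] = []
    if separable:
        counts = pd.Series([c.mode for c in separable]).value_counts()
        for m, k in counts.items():
            mode_fractions[m] = k / len(separable)
        best = counts.max()
        predominant = sorted(counts.index[counts == best])
    over_all = sum(c.mode == OVERDOMINANCE for c in calls) / n_total
    under_all = sum(c.mode == UNDERDOMINANCE for c in calls) / n_total
    return {
        "n_calls": n_total,
        "fraction_separable": frac_separable,
        "mode_fractions": mode_fractions,
        "predominant_modes": predominant,
        "overdominance_fraction_all": over_all,
        "underdominance_fraction_all": under_all,
    }
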