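"""Chaperone-dependence classification and interactor enrichment.

Proteins are classified from mPDP significance calls gathered over a time
course of chaperone (HSP90) inhibition.  Significant downregulation of
the *mature* pool at any time point marks the protein as constitutively
chaperone-dependent, irrespective of the nascent pool; downregulation of
the nascent pool only marks dependence during synthesis.  Upregulation is
carried as metadata (stabilized proteins exist) but is not a class.
Enrichment of an annotated interactor list among a class is evaluated
with Fisher's exact test against all other identified proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CLASSES = ("constitutive", "synthesis", "not_regulated", "not_identified")


@dataclass
class EnrichmentResult:
    table: np.ndarray          # 2x2 contingency counts
    odds_ratio: float
    p_value: float
    flags: list


def classify_dependence(calls: pd.DataFrame) -> pd.DataFrame:
    """Classify each protein from its significance calls across time points.

    ``calls`` is long-format with columns ``protein_group``, ``condition``
    (the treatment time point), ``pool`` ('mature'/'nascent'),
    ``significant`` and ``direction``.  Classification keys on
    *downregulation*: 'constitutive' when the mature pool is significantly
    down at any time point (this dominates), 'synthesis' when only the
    nascent pool is, else 'not_regulated'.  Proteins quantified in a
    single pool are classified from that pool alone and flagged partial.
    Returns one row per protein with the class, supporting time points and
    an ``any_up`` metadata flag.
    """
    rows = []
    for protein, grp in calls.groupby("protein_group", sort=True):
        down = grp["significant"] & (grp["direction"] == "down")
        mature_down = grp.loc[down & (grp["pool"] == "mature"), "condition"]
        nascent_down = grp.loc[down & (grp["pool"] == "nascent"), "condition"]
        pools_seen = set(grp["pool"])
        if len(mature_down) > 0:
            cls, support = "constitutive", sorted(mature_down.unique())
        elif len(nascent_down) > 0:
            cls, support = "synthesis", sorted(nascent_down.unique())
        else:
            cls, support = "not_regulated", []
        rows.append(
            {
                "protein_group": protein,
                "dependence_class": cls,
                "supporting_conditions": support,
                "any_up": bool(
                    (grp["significant"] & (grp["direction"] == "up")).any()
                ),
                "partial": len(pools_seen) < 2,
            }
        )
    return pd.DataFrame(rows)


def fisher_enrichment(
    class_members, annotation_list, background
) -> EnrichmentResult:
    """Fisher's exact test for enrichment of annotated proteins in a class.

    ``background`` is the full set of identified proteins; members and
    annotations are intersected with it to form a disjoint 2x2 partition
    (in class / not, annotated / not).  Returns the two-sided exact
    hypergeometric p-value and the sample odds ratio.
    """
    background = set(background)
    members = set(class_members) & background
    annotated = set(annotation_list) & background
    if not annotated:
        raise ValueError("annotation list is disjoint from the background")
    a = len(members & annotated)
    b = len(members - annotated)
    c = len(annotated - members)
    d = len(background) - a - b - c
    table = np.array([[a, b], [c, d]])
    flags = []
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        flags.append("empty_margin")
        return EnrichmentResult(table, float("nan"), 1.0, flags)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(table, float(odds), float(p), flags)
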