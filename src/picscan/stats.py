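"""Rank and exact-count statistics used across the pipeline.

The Mann-Whitney U test compares contact-interface fold changes between WBC
groups (interacting clusters vs passive overlaps) and marker levels between
event groups; Fisher's exact test quantifies phenotype-cluster enrichment of
in-contact events.  Both report the quantities the downstream stages need:
U, a z value, a two-sided p, and the effect size r = |z| / sqrt(N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

#: largest n1*n2 for which the exact U distribution is used (ties force the
#: normal approximation regardless)
EXACT_LIMIT = 200


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-sample rank comparison.

    ``u`` is the U statistic of the first group; ``r`` is the rank effect
    size |z|/sqrt(n1+n2); ``rank_biserial`` (= 2U/(n1 n2) - 1) is emitted
    alongside for comparison since the literature is split on which "r" a
    Mann-Whitney effect size means.
    """

    n1: int
    n2: int
    u: float
    z: float
    p: float
    r: float
    rank_biserial: float


def mann_whitney(group_a, group_b) -> GroupComparison:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The exact null distribution is used when ``n1*n2 <= EXACT_LIMIT`` and
    the pooled sample has no ties; otherwise a normal approximation with
    tie correction is used, with a 0.5 continuity correction applied to the
    p value.  The reported z (which feeds r = |z|/sqrt(N)) is the
    uncorrected standardized U so that it reduces to the closed form
    (U - n1 n2 / 2) / sqrt(n1 n2 (N+1) / 12) in the tie-free case.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    has_ties = bool((counts > 1).any())

    if var <= 0:  # all observations identical
        z = 0.0
        p = 1.0
    else:
        sd = math.sqrt(var)
        z = (u1 - mu) / sd
        if not has_ties and n1 * n2 <= EXACT_LIMIT:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                       method="exact").pvalue)
        else:
            cc = 0.5 if u1 != mu else 0.0
            z_p = (abs(u1 - mu) - cc) / sd
            p = min(1.0, 2.0 * sps.norm.sf(max(z_p, 0.0)))
    r = abs(z) / math.sqrt(n)
    rank_biserial = 2.0 * u1 / (n1 * n2) - 1.0
    return GroupComparison(n1=n1, n2=n2, u=u1, z=z, p=max(p, 0.0), r=r,
                           rank_biserial=rank_biserial)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (sample odds ratio ad/bc, with inf when bc = 0 and ad > 0, and
    the conditional hypergeometric two-sided p obtained by summing tables
    at least as improbable as the observed one).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValidationError("table entries must be non-negative integers")
    t = t.astype(np.int64)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    p = float(sps.fisher_exact(t, alternative="two-sided")[1])
    return odds, min(p, 1.0)
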