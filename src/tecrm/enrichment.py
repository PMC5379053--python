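"""Subfamily-level enrichment of multi-TF binding-site clusters.

For each TE subfamily j and each number of bound TFs i, the over-representation
of i-TF clusters in subfamily j relative to all annotated TEs is quantified as
a base-2 log odds ratio over the 2x2 table

    a = k            TEs of subfamily j bound by i TFs
    b = N_j - k      TEs of subfamily j not bound by i TFs
    c = K_i - k      other TEs bound by i TFs
    d = N - N_j - K_i + k

so LOR = log2(ad / bc); LOR >= 6 corresponds to at least 64-fold enrichment.
Significance is the hypergeometric upper tail of drawing >= k i-TF-bound TEs
in N_j draws from a population of N with K_i successes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "log_odds_ratio",
    "hypergeom_upper",
    "enrichment_scan",
    "fraction_percent",
    "lor_to_fold",
]


def _cells(k: int, n_j: int, k_i: int, n: int) -> tuple[float, float, float, float]:
    a, b, c, d = k, n_j - k, k_i - k, n - n_j - k_i + k
    if min(a, b, c, d) < 0:
        raise ValueError(
            f"invalid 2x2 table from (k={k}, N_j={n_j}, K_i={k_i}, N={n})"
        )
    return float(a), float(b), float(c), float(d)


def log_odds_ratio(k: int, n_j: int, k_i: int, n: int) -> float:
    """Base-2 log odds ratio of i-TF binding in subfamily j vs all other TEs.

    When any cell of the 2x2 table is zero, 0.5 is added to every cell
    (Haldane-Anscombe correction) to keep the LOR finite.
    """
    a, b, c, d = _cells(k, n_j, k_i, n)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(np.log2((a * d) / (b * c)))


def lor_to_fold(lor: float) -> float:
    """Fold-enrichment scale of a base-2 log odds ratio (LOR 6 -> 64-fold)."""
    return float(2.0**lor)


def hypergeom_upper(k: int, n_j: int, k_i: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(population n, successes k_i, draws n_j)."""
    _cells(k, n_j, k_i, n)  # validate
    if k <= 0:
        return 1.0
    # survival function is computed stably in log space internally
    return float(stats.hypergeom.sf(k - 1, n, k_i, n_j))


def fraction_percent(k: int, n: int) -> int:
    """A count fraction as a rounded whole percent (e.g. 1331/6366 -> 21)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return int(round(100.0 * k / n))


def enrichment_scan(
    n_tfs_per_te: Sequence[int],
    subfamilies: Sequence[str],
    min_elements: int = 10,
    lor_threshold: float = 4.5,
    p_threshold: float = 1e-3,
    max_i: int = 5,
) -> pd.DataFrame:
    """Per-(subfamily, i) enrichment table with the reporting filters applied.

    Parameters
    ----------
    n_tfs_per_te : number of distinct TFs bound per TE (from
        :func:`tecrm.intervals.assign_clusters_to_tes`).
    subfamilies : subfamily name per TE, parallel to ``n_tfs_per_te``.
    min_elements : a (subfamily, i) row needs k >= min_elements bound copies
        to be eligible for flagging (the >= 10-element reporting filter).
    lor_threshold, p_threshold : a row is flagged enriched when
        lor >= lor_threshold and pvalue < p_threshold.

    Returns the full unfiltered table; columns ``eligible`` and ``flagged``
    carry the filters. ``i_label`` bins i exactly at 1..max_i plus a ">=2"
    aggregate. A BH-FDR column is included as supplementary output only.
    """
    n_tfs = np.asarray(n_tfs_per_te, dtype=int)
    fams = np.asarray(subfamilies, dtype=object)
    if n_tfs.shape != fams.shape:
        raise ValueError("n_tfs_per_te and subfamilies must be parallel")
    n = len(n_tfs)
    if n == 0:
        import warnings

        warnings.warn("empty TE annotation: returning empty enrichment table")
        return pd.DataFrame(
            columns=["subfamily", "i_label", "k", "N_j", "K_i", "N", "lor",
                     "pvalue", "bh_fdr", "eligible", "flagged"]
        )

    bins: list[tuple[str, np.ndarray]] = [
        (str(i), n_tfs == i) for i in range(1, max_i + 1)
    ]
    bins.append((">=2", n_tfs >= 2))

    rows = []
    for subfam in sorted(set(fams)):
        in_fam = fams == subfam
        n_j = int(in_fam.sum())
        for label, bound in bins:
            k_i = int(bound.sum())
            k = int((in_fam & bound).sum())
            rows.append(
                {
                    "subfamily": subfam,
                    "i_label": label,
                    "k": k,
                    "N_j": n_j,
                    "K_i": k_i,
                    "N": n,
                    "lor": log_odds_ratio(k, n_j, k_i, n),
                    "pvalue": hypergeom_upper(k, n_j, k_i, n),
                }
            )
    table = pd.DataFrame(rows)
    table["bh_fdr"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    table["eligible"] = table["k"] >= min_elements
    table["flagged"] = (
        table["eligible"]
        & (table["lor"] >= lor_threshold)
        & (table["pvalue"] < p_threshold)
    )
    return table
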