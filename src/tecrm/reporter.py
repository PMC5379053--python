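"""Reporter-assay quantification: luciferase, CRE-seq (MPRA) and qPCR ddCt.

Regulatory potential is the reporter fold change relative to the basal /
empty-vector construct. Fold change > 2 classifies a construct as an
enhancer, > 10 as a strong enhancer. Mutant constructs are further
normalized to their matched wild type, with a Welch t-test across replicate
level expression values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegulatoryPotential",
    "classify_potential",
    "luciferase_fold_change",
    "cre_expression",
    "mutant_effect",
    "ddct",
]

ENHANCER_FOLD = 2.0
STRONG_ENHANCER_FOLD = 10.0


@dataclass
class RegulatoryPotential:
    """Per-construct reporter activity relative to the basal construct."""

    construct: str
    fold_change: float
    sd: float
    enhancer_class: str
    replicate_values: np.ndarray  # replicate-level expression, basal-normalized


def classify_potential(fold_change: float) -> str:
    if fold_change > STRONG_ENHANCER_FOLD:
        return "strong enhancer"
    if fold_change > ENHANCER_FOLD:
        return "enhancer"
    return "inactive"


def _luc_construct_values(df: pd.DataFrame) -> pd.Series:
    """Per-experiment construct value: mean F/R over technical replicates."""
    ratios = df.assign(ratio=df["firefly"] / df["renilla"])
    return ratios.groupby("experiment")["ratio"].mean()


def luciferase_fold_change(
    records: pd.DataFrame, empty_records: pd.DataFrame
) -> list[RegulatoryPotential]:
    """Luciferase fold change per construct, normalized to the empty vector.

    ``records`` columns: construct, firefly, renilla, experiment, technical.
    Per replicate the firefly/renilla ratio is taken; technical replicates are
    averaged within an experiment, experiments averaged for the construct
    value; fold change divides by the empty vector treated the same way.
    Records with renilla <= 0 are dropped with a warning.
    """

    def clean(df: pd.DataFrame) -> pd.DataFrame:
        bad = df["renilla"] <= 0
        if bad.any():
            warnings.warn(f"dropping {int(bad.sum())} records with renilla <= 0")
            df = df[~bad]
        if df.empty:
            raise ValueError("no usable records (all renilla <= 0)")
        return df

    records = clean(records)
    empty_records = clean(empty_records)
    empty_value = _luc_construct_values(empty_records).mean()
    out = []
    for construct, df in records.groupby("construct"):
        per_exp = _luc_construct_values(df) / empty_value
        fc = float(per_exp.mean())
        out.append(
            RegulatoryPotential(
                construct=str(construct),
                fold_change=fc,
                sd=float(per_exp.std(ddof=1)) if len(per_exp) > 1 else 0.0,
                enhancer_class=classify_potential(fc),
                replicate_values=per_exp.to_numpy(),
            )
        )
    return out


def cre_expression(
    counts: pd.DataFrame,
    basal_ids: list[str],
    min_dna: int = 10,
    pseudocount: float = 0.5,
) -> list[RegulatoryPotential]:
    """CRE-seq expression per construct from barcode cDNA/DNA count ratios.

    ``counts`` columns: construct, barcode, replicate, dna, cdna. Per-barcode
    expression = (cdna + pseudocount) / (dna + pseudocount); barcodes with
    dna < min_dna are excluded. Construct expression averages retained
    barcode ratios across replicates; fold change normalizes by the mean
    basal-construct expression. Constructs with every barcode excluded are
    reported as missing (NaN fold change).
    """
    if not basal_ids:
        raise ValueError("need at least one basal construct id")
    counts = counts.copy()
    counts["ratio"] = (counts["cdna"] + pseudocount) / (counts["dna"] + pseudocount)
    kept = counts[counts["dna"] >= min_dna]
    basal = kept[kept["construct"].isin(basal_ids)]
    if basal.empty:
        raise ValueError("no basal barcodes survive the DNA-count filter")
    basal_value = basal["ratio"].mean()
    out = []
    for construct, df in counts.groupby("construct"):
        if str(construct) in set(map(str, basal_ids)):
            continue
        retained = df[df["dna"] >= min_dna]
        if retained.empty:
            warnings.warn(f"construct {construct}: all barcodes excluded")
            out.append(
                RegulatoryPotential(
                    construct=str(construct),
                    fold_change=float("nan"),
                    sd=float("nan"),
                    enhancer_class="missing",
                    replicate_values=np.array([]),
                )
            )
            continue
        per_rep = retained.groupby("replicate")["ratio"].mean() / basal_value
        fc = float(retained["ratio"].mean() / basal_value)
        out.append(
            RegulatoryPotential(
                construct=str(construct),
                fold_change=fc,
                sd=float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0,
                enhancer_class=classify_potential(fc),
                replicate_values=per_rep.to_numpy(),
            )
        )
    return out


def mutant_effect(
    mutant: RegulatoryPotential, wildtype: RegulatoryPotential
) -> tuple[float, float]:
    """Mutant-over-wild-type expression ratio with a Welch t-test p-value.

    The ratio divides fold changes; the test compares replicate-level
    basal-normalized expression values of the two constructs.
    """
    if mutant.replicate_values.size == 0 or wildtype.replicate_values.size == 0:
        raise ValueError("both constructs need replicate-level values")
    ratio = mutant.fold_change / wildtype.fold_change
    if np.allclose(mutant.replicate_values, wildtype.replicate_values):
        return float(ratio), 1.0
    t = stats.ttest_ind(
        mutant.replicate_values, wildtype.replicate_values, equal_var=False
    )
    return float(ratio), float(t.pvalue)


def ddct(
    ct_target_wt: np.ndarray,
    ct_ref_wt: np.ndarray,
    ct_target_mut: np.ndarray,
    ct_ref_mut: np.ndarray,
) -> dict:
    """Relative expression of mutant vs wild type by the ddCt method.

    dCt = Ct_target - Ct_ref within condition; ddCt = dCt_mut - dCt_wt;
    relative expression = 2**(-ddCt). Replicates are aggregated by the mean
    with an s.d., and a Welch t-test compares per-replicate dCt values.
    """
    ct_target_wt = np.atleast_1d(np.asarray(ct_target_wt, dtype=float))
    ct_ref_wt = np.atleast_1d(np.asarray(ct_ref_wt, dtype=float))
    ct_target_mut = np.atleast_1d(np.asarray(ct_target_mut, dtype=float))
    ct_ref_mut = np.atleast_1d(np.asarray(ct_ref_mut, dtype=float))
    for arr in (ct_target_wt, ct_ref_wt, ct_target_mut, ct_ref_mut):
        if np.any(arr <= 0):
            raise ValueError("Ct values must be positive")
    dct_wt = ct_target_wt - ct_ref_wt
    dct_mut = ct_target_mut - ct_ref_mut
    ddct_value = float(dct_mut.mean() - dct_wt.mean())
    rel_per_rep = 2.0 ** (-(dct_mut - dct_wt.mean()))
    if dct_wt.size > 1 and dct_mut.size > 1 and not np.allclose(dct_wt, dct_mut):
        pvalue = float(stats.ttest_ind(dct_mut, dct_wt, equal_var=False).pvalue)
    else:
        pvalue = 1.0 if np.allclose(dct_wt.mean(), dct_mut.mean()) else float("nan")
    return {
        "relative_expression": float(2.0 ** (-ddct_value)),
        "sd": float(rel_per_rep.std(ddof=1)) if rel_per_rep.size > 1 else 0.0,
        "ddct": ddct_value,
        "pvalue": pvalue,
    }
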