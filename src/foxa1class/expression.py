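"""Expression and numeric-by-class comparisons plus signature scoring.

Per-class numeric contrasts (FOXA1 TPM, VAF, signature scores, ...) are
summarised by median/IQR and tested against the WT arm with a two-sided
Mann-Whitney rank-sum test, BH-adjusted across classes.  Gene-set
signatures (AR, NEPC, IFN-gamma, T-cell inflammation, ...) are scored per
sample as the mean across the set of per-gene z-scores of log2(TPM+1),
with z computed across samples; gene lists are configuration, not code.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_ARM_SIZE = 3


def compare_numeric_by_class(
    values: pd.Series,
    classes: pd.Series,
    *,
    reference: str = "WT",
    min_arm_size: int = MIN_ARM_SIZE,
) -> pd.DataFrame:
    """Per-class summary and Mann-Whitney test versus the reference arm.

    Returns one row per class with n, median, IQR bounds, the two-sided
    rank-sum p against the reference and its BH q (adjusted across the
    non-reference classes).  Arms smaller than ``min_arm_size`` (either
    side) are flagged untestable with missing p/q.  NaN values are
    dropped per arm.
    """
    df = pd.DataFrame({"value": values, "class": classes}).dropna(subset=["value"])
    ref_vals = df.loc[df["class"] == reference, "value"].to_numpy()
    rows = []
    order = [reference] + sorted(c for c in df["class"].unique() if c != reference)
    for cls in order:
        v = df.loc[df["class"] == cls, "value"].to_numpy()
        q1, med, q3 = (
            np.percentile(v, [25, 50, 75]) if len(v) else (np.nan, np.nan, np.nan)
        )
        row = {
            "class": cls,
            "n": len(v),
            "median": med,
            "q1": q1,
            "q3": q3,
            "p": np.nan,
            "testable": False,
        }
        if cls != reference:
            if len(v) >= min_arm_size and len(ref_vals) >= min_arm_size:
                row["p"] = float(
                    stats.mannwhitneyu(v, ref_vals, alternative="two-sided").pvalue
                )
                row["testable"] = True
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    mask = out["testable"] & out["p"].notna()
    if mask.any():
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


def score_signature(
    tpm: pd.DataFrame,
    gene_set: Sequence[str],
    *,
    signature_name: str = "signature",
) -> pd.Series:
    """Mean-z signature score per sample.

    ``tpm`` is samples x genes in TPM (non-negative).  Each signature gene
    is log2(TPM+1)-transformed and z-scored across samples; the score is
    the mean of those z-scores over the genes present.  Genes absent from
    the matrix are dropped with a warning; no overlap at all is an error.
    Constant genes (zero variance) contribute a z of 0.
    """
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM matrix contains negative entries")
    present = [g for g in gene_set if g in tpm.columns]
    missing = [g for g in gene_set if g not in tpm.columns]
    if missing:
        logger.warning(
            "signature %s: %d/%d genes absent from matrix: %s",
            signature_name, len(missing), len(gene_set), ", ".join(missing[:5]),
        )
    if not present:
        raise ValueError(f"signature {signature_name!r} has no genes in the matrix")
    logx = np.log2(tpm[present].to_numpy(dtype=float) + 1.0)
    mu = logx.mean(axis=0)
    sd = logx.std(axis=0, ddof=0)
    z = np.where(sd > 0, (logx - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(z.mean(axis=1), index=tpm.index, name=signature_name)


def score_signatures(
    tpm: pd.DataFrame, signatures: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Score several signatures; returns samples x signatures."""
    return pd.DataFrame(
        {name: score_signature(tpm, genes, signature_name=name)
         for name, genes in signatures.items()}
    )
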