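"""Expression normalization, sex-specificity calling, and strain variability.

Sex-specificity calls follow a fold-change + FDR rule: a gene is called
male- or female-specific when the male/female expression ratio exceeds a
platform-dependent threshold (2 for RNA-seq, 1.5 for microarray) at
Benjamini-Hochberg FDR < 0.05.  The differential test is a Welch t-test on
log2(FPKM + 0.5); the fold-change is the ratio of pseudocounted sex means.
Inter- and intra-strain variability are coefficients of variation with the
sample (n-1) standard deviation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri
from statsmodels.stats.multitest import multipletests

__all__ = [
    "rankz_transform",
    "call_sex_specificity",
    "strain_sex_specificity",
    "inter_strain_variability",
    "intra_strain_variability",
    "batch_center",
    "PLATFORM_THRESHOLDS",
]

PLATFORM_THRESHOLDS = {"rnaseq": 2.0, "microarray": 1.5}

_PSEUDOCOUNT = 0.5


def rankz_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal (rankZ) transform: Phi^-1(rank / (n + 1)).

    Ties receive average ranks.  An all-identical vector maps to all zeros
    with a warning, since ranks carry no information there.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("rankZ requires at least 2 values")
    if np.all(values == values[0]):
        warnings.warn("rankZ input is constant; returning zeros", stacklevel=2)
        return np.zeros(n)
    ranks = stats.rankdata(values, method="average")
    return ndtri(ranks / (n + 1))


def _fold_change(mean_m: np.ndarray, mean_f: np.ndarray) -> np.ndarray:
    return (mean_m + _PSEUDOCOUNT) / (mean_f + _PSEUDOCOUNT)


def call_sex_specificity(
    expr: pd.DataFrame, meta: pd.DataFrame, platform: str = "rnaseq"
) -> pd.DataFrame:
    """Call each gene male-specific, female-specific, or sex-independent.

    Parameters
    ----------
    expr
        Genes x samples matrix of nonnegative expression values (FPKM or
        normalized intensities).
    meta
        Sample metadata with ``sample_id`` and ``sex`` in {M, F}.
    platform
        "rnaseq" (|fold-change| > 2) or "microarray" (|fold-change| > 1.5),
        both at FDR < 0.05.

    Returns
    -------
    DataFrame indexed by gene with columns log2_fc, fc_magnitude, p, q,
    sex_class, and the strength flags fc_gt_1_5, fc_gt_2, fc_gt_4, fc_lt_1_2.
    """
    if platform not in PLATFORM_THRESHOLDS:
        raise ValueError(f"platform must be one of {sorted(PLATFORM_THRESHOLDS)}")
    meta = meta.set_index("sample_id").loc[expr.columns]
    males = expr.loc[:, (meta["sex"] == "M").to_numpy()]
    females = expr.loc[:, (meta["sex"] == "F").to_numpy()]
    if males.shape[1] < 2 or females.shape[1] < 2:
        raise ValueError("need at least 2 samples per sex")

    log_m = np.log2(males.to_numpy() + _PSEUDOCOUNT)
    log_f = np.log2(females.to_numpy() + _PSEUDOCOUNT)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(log_m, log_f, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]

    fc = _fold_change(males.mean(axis=1).to_numpy(), females.mean(axis=1).to_numpy())
    fc_mag = np.maximum(fc, 1.0 / fc)
    threshold = PLATFORM_THRESHOLDS[platform]
    significant = (fc_mag > threshold) & (q < 0.05)
    sex_class = np.where(
        significant, np.where(fc > 1.0, "male-specific", "female-specific"), "sex-independent"
    )
    return pd.DataFrame(
        {
            "log2_fc": np.log2(fc),
            "fc_magnitude": fc_mag,
            "p": p,
            "q": q,
            "sex_class": sex_class,
            "fc_gt_1_5": fc_mag > 1.5,
            "fc_gt_2": fc_mag > 2.0,
            "fc_gt_4": fc_mag > 4.0,
            "fc_lt_1_2": fc_mag < 1.2,
        },
        index=expr.index,
    )


def strain_sex_specificity(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-founder-strain sex-specificity calls (microarray threshold).

    ``meta`` must carry a ``strain`` column; each strain's replicates are
    tested separately.  Returns one row per (gene, strain).
    """
    if "strain" not in meta.columns:
        raise ValueError("metadata must include a strain column")
    frames = []
    for strain, sub in meta.groupby("strain", sort=False):
        calls = call_sex_specificity(expr[sub["sample_id"]], sub, platform="microarray")
        calls = calls.reset_index(names="gene_id")
        calls.insert(1, "strain", strain)
        frames.append(calls)
    return pd.concat(frames, ignore_index=True)


def inter_strain_variability(strain_means: np.ndarray) -> float:
    """CV across the 8 founder strain means: sd(means, ddof=1) / mean(means).

    Returns NaN (flagged undefined) when the mean of means is 0.
    """
    strain_means = np.asarray(strain_means, dtype=float)
    if strain_means.size != 8:
        raise ValueError("expected 8 founder strain means")
    center = strain_means.mean()
    if center == 0:
        return float("nan")
    return float(np.std(strain_means, ddof=1) / center)


def intra_strain_variability(values: np.ndarray) -> float:
    """CV across replicate livers within one strain: sd(ddof=1) / mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 replicates")
    center = values.mean()
    if center == 0:
        return float("nan")
    return float(np.std(values, ddof=1) / center)


def batch_center(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Remove additive batch shifts on the log2(FPKM + 1) scale.

    Per gene, each batch's mean is subtracted and the grand mean restored, so
    a constant between-batch shift is removed exactly while the overall level
    is preserved.  Singleton batches collapse to the grand mean (warning).
    """
    meta = meta.set_index("sample_id").loc[expr.columns]
    if "batch" not in meta.columns:
        raise ValueError("metadata must include a batch column")
    log_expr = np.log2(expr.to_numpy(dtype=float) + 1.0)
    grand = log_expr.mean(axis=1, keepdims=True)
    out = np.empty_like(log_expr)
    batches = meta["batch"].to_numpy()
    for batch in pd.unique(batches):
        cols = np.flatnonzero(batches == batch)
        if len(cols) == 1:
            warnings.warn(f"batch {batch} has a single sample; centered to grand mean", stacklevel=2)
        batch_mean = log_expr[:, cols].mean(axis=1, keepdims=True)
        out[:, cols] = log_expr[:, cols] - batch_mean + grand
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)
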