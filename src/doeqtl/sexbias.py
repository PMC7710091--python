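"""Sex-dependent eQTL categorization and gain/loss-of-sex-specificity inference.

An eQTL for a sex-specific gene is compared between the male-only and
female-only scans at its own peak marker.  Three binary criteria — the gene's
sex class (male- vs female-specific), the stronger-association sex (sign of
LOD_male - LOD_female), and the sign of the regulating strain's coefficient
in the stronger sex — define eight categories.  Categories 1-4 predict a
decrease of sex specificity in the regulating strain (e.g. a male-specific
gene that is down-regulated where the association is strongest in males);
categories 5-8 predict an increase.  Per-strain sex-specificity calls from
founder-strain expression then decide whether the predicted decrease amounts
to an outright loss (the regulating strain loses the sex-specific call while
at least one other strain retains it) and whether a predicted increase
amounts to an outright gain (the regulating strain holds a sex-specific
call).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import FOUNDER_CODES, FOUNDER_LABELS

__all__ = [
    "delta_lod",
    "assign_category",
    "CATEGORY_TABLE",
    "assess_gain_loss",
    "matched_sex_decile_enrichment",
    "categorize_eqtls",
]

# (gene sex class, stronger sex, coefficient sign) -> category 1..8
CATEGORY_TABLE: dict[tuple[str, str, str], int] = {
    ("male-specific", "M", "-"): 1,
    ("female-specific", "M", "+"): 2,
    ("male-specific", "F", "+"): 3,
    ("female-specific", "F", "-"): 4,
    ("male-specific", "M", "+"): 5,
    ("female-specific", "M", "-"): 6,
    ("male-specific", "F", "-"): 7,
    ("female-specific", "F", "+"): 8,
}

DECREASE_CATEGORIES = frozenset({1, 2, 3, 4})
INCREASE_CATEGORIES = frozenset({5, 6, 7, 8})


def delta_lod(male_scan: pd.DataFrame, female_scan: pd.DataFrame, marker_id: str) -> float:
    """Signed LOD difference (male minus female) at the eQTL's peak marker."""
    m = male_scan.loc[male_scan["marker_id"] == marker_id, "lod"]
    f = female_scan.loc[female_scan["marker_id"] == marker_id, "lod"]
    if m.empty or f.empty:
        raise KeyError(f"marker {marker_id} missing from a sex-stratified scan")
    return float(m.iloc[0]) - float(f.iloc[0])


def assign_category(gene_sex_class: str, stronger_sex: str, coef_sign: str) -> int:
    """Map (gene sex class, stronger sex, coefficient sign) to category 1-8.

    Only sex-specific genes can be categorized; the coefficient sign is that
    of the regulating strain's coefficient in the stronger sex.
    """
    if gene_sex_class not in ("male-specific", "female-specific"):
        raise ValueError(f"only sex-specific genes are categorized, got {gene_sex_class!r}")
    if stronger_sex not in ("M", "F"):
        raise ValueError("stronger_sex must be 'M' or 'F'")
    if coef_sign not in ("+", "-"):
        raise ValueError("coef_sign must be '+' or '-'")
    return CATEGORY_TABLE[(gene_sex_class, stronger_sex, coef_sign)]


def assess_gain_loss(
    category: int,
    regulating_strain: str,
    gene_sex_class: str,
    strain_calls: pd.Series | dict[str, str],
) -> str:
    """Decide outright loss/gain of sex specificity from per-strain calls.

    ``strain_calls`` maps each of the eight founder strains to its
    sex-specificity call for the gene.  Decrease categories (1-4) resolve to
    ``lost_in_regulating_strain`` when the regulating strain's call is
    sex-independent while at least one other strain retains the gene's
    sex-specific call, else ``decreased_retained``.  Increase categories
    (5-8) resolve to ``gained_in_regulating_strain`` when the regulating
    strain is sex-specific, else ``increased_not_gained``.
    """
    calls = dict(strain_calls)
    missing = [s for s in FOUNDER_LABELS if s not in calls]
    if missing:
        raise KeyError(f"missing sex-specificity calls for strains: {missing}")
    own = calls[regulating_strain]
    if category in DECREASE_CATEGORIES:
        others_retain = any(
            calls[s] == gene_sex_class for s in FOUNDER_LABELS if s != regulating_strain
        )
        if own == "sex-independent" and others_retain:
            return "lost_in_regulating_strain"
        return "decreased_retained"
    if category in INCREASE_CATEGORIES:
        if own == gene_sex_class:
            return "gained_in_regulating_strain"
        return "increased_not_gained"
    raise ValueError(f"category must be 1..8, got {category}")


def matched_sex_decile_enrichment(
    records: pd.DataFrame, decile: float = 0.10
) -> tuple[float, float, pd.DataFrame]:
    """Enrichment of matched-sex genes in the top |delta LOD| decile.

    ``records`` needs columns ``delta_lod`` and ``gene_sex_class`` (only
    male-/female-specific rows are used).  An eQTL is *matched* when the
    gene's sex class agrees with the stronger sex (sign of delta LOD).  The
    2x2 table (top decile vs remainder) x (matched vs opposite) yields the
    odds-ratio fold enrichment and a two-sided Fisher exact p.  With an empty
    opposite cell the fold is infinite and the Haldane-corrected (+0.5)
    estimate is returned through the table.
    """
    sub = records[records["gene_sex_class"].isin(["male-specific", "female-specific"])].copy()
    sub = sub[sub["delta_lod"] != 0]
    if len(sub) < 20:
        raise ValueError("need at least 20 sex-informative eQTLs")
    stronger = np.where(sub["delta_lod"].to_numpy() > 0, "M", "F")
    gene_sex = np.where(sub["gene_sex_class"].to_numpy() == "male-specific", "M", "F")
    matched = stronger == gene_sex
    abs_delta = sub["delta_lod"].abs().to_numpy()
    # rank-based decile: the round(decile * n) largest |delta LOD| values
    # (a quantile threshold would mis-size the stratum under ties)
    n_top = max(1, int(round(decile * len(sub))))
    order = np.argsort(-abs_delta, kind="stable")
    top = np.zeros(len(sub), dtype=bool)
    top[order[:n_top]] = True

    a = int(np.sum(top & matched))
    b = int(np.sum(top & ~matched))
    c = int(np.sum(~top & matched))
    d = int(np.sum(~top & ~matched))
    table = pd.DataFrame(
        {"matched": [a, c], "opposite": [b, d]}, index=["top_decile", "remainder"]
    )
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    table.attrs["haldane_fold"] = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    if b == 0 or c == 0:
        fold = float("inf")
    else:
        fold = (a / b) / (c / d)
    return float(fold), float(p), table


def categorize_eqtls(
    eqtls: pd.DataFrame,
    male_records: pd.DataFrame,
    female_records: pd.DataFrame,
    male_scans: dict[str, pd.DataFrame],
    female_scans: dict[str, pd.DataFrame],
    gene_classes: pd.Series,
    strain_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the sex-bias table for eQTLs of sex-specific genes.

    ``eqtls`` lists (gene, marker) eQTLs significant in at least one
    single-sex dataset; ``male_scans`` / ``female_scans`` map gene id to the
    full LOD profile of that sex's scan; ``gene_classes`` maps gene id to its
    sex class.  ``strain_calls`` (optional) is the long table from
    ``expression.strain_sex_specificity`` used for gain/loss calls.
    """
    calls_by_gene: dict[str, dict[str, str]] = {}
    if strain_calls is not None:
        for gene, sub in strain_calls.groupby("gene_id"):
            calls_by_gene[gene] = dict(zip(sub["strain"], sub["sex_class"]))

    rows = []
    for _, rec in eqtls.iterrows():
        gene = rec["gene_id"]
        if gene not in male_scans or gene not in female_scans:
            continue
        gene_class = gene_classes.get(gene, "sex-independent")
        dlod = delta_lod(male_scans[gene], female_scans[gene], rec["marker_id"])
        row = {
            "gene_id": gene,
            "marker_id": rec["marker_id"],
            "chrom": rec["chrom"],
            "lod_m": float(male_scans[gene].loc[male_scans[gene]["marker_id"] == rec["marker_id"], "lod"].iloc[0]),
            "lod_f": float(female_scans[gene].loc[female_scans[gene]["marker_id"] == rec["marker_id"], "lod"].iloc[0]),
            "delta_lod": dlod,
            "gene_sex_class": gene_class,
            "regulating_strain": rec["regulating_strain"],
        }
        if dlod == 0 or gene_class == "sex-independent":
            row.update({"category": pd.NA, "coef_sign": pd.NA, "gain_loss": "n/a"})
            rows.append(row)
            continue
        stronger = "M" if dlod > 0 else "F"
        # coefficient sign of the regulating strain in the stronger sex's scan
        source = male_records if stronger == "M" else female_records
        match = source[(source["gene_id"] == gene) & (source["marker_id"] == rec["marker_id"])]
        if match.empty:
            row.update({"category": pd.NA, "coef_sign": pd.NA, "gain_loss": "n/a"})
            rows.append(row)
            continue
        strain_ix = FOUNDER_LABELS.index(rec["regulating_strain"])
        coef = float(match.iloc[0][f"coef_{FOUNDER_CODES[strain_ix]}"])
        sign = "+" if coef > 0 else "-"
        category = assign_category(gene_class, stronger, sign)
        if gene in calls_by_gene:
            gain_loss = assess_gain_loss(category, rec["regulating_strain"], gene_class, calls_by_gene[gene])
        else:
            gain_loss = "n/a"
        row.update({"category": category, "coef_sign": sign, "gain_loss": gain_loss})
        rows.append(row)
    return pd.DataFrame(rows)
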