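"""Strain-specific variants at sex-biased regulatory elements within eQTL regions.

A variant is *strain-specific* when its alternate allele is carried by
exactly one of the eight founder strains.  For each eQTL (with a regulating
strain and a credible interval < 3 Mb wide), the elements of a given factor
(DHS, STAT5, BCL6, ...) inside the interval are restricted to those that
contain at least one variant private to the regulating strain; the fractions
of those elements that are male-biased, female-biased, or sex-independent
form the eQTL's fraction profile.  Profiles are compared across eQTL sets
(for male-specific, female-specific, and sex-independent genes) with the
two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import FOUNDER_CODES, FOUNDER_LABELS

__all__ = [
    "extract_strain_specific",
    "read_founder_variants",
    "select_enrichment_eqtls",
    "element_fraction_profile",
    "profile_eqtl_sets",
    "compare_profiles_wilcoxon",
]

logger = logging.getLogger(__name__)

SEX_CLASSES = ("male-biased", "female-biased", "sex-independent")
MAX_CI_WIDTH = 3_000_000  # eQTL regions wider than 3 Mb are not profiled


def read_founder_variants(path: str) -> pd.DataFrame:
    """Read a minimal founder VCF into a table with 8 allele-call columns A..H.

    Genotype columns are interpreted per strain: any alt-carrying call counts
    as alt (1); missing calls count as ref (0), which is conservative for the
    exactly-one-founder ownership rule.
    """
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(path)
    if len(vcf.samples) != 8:
        raise ValueError(f"expected 8 founder genotype columns, got {len(vcf.samples)}")
    for rec in vcf:
        alts = rec.ALT or ["."]
        calls = []
        for g in rec.genotypes:  # [allele1, allele2, phased]
            a = [x for x in g[:2] if x is not None and x >= 0]
            calls.append(1 if any(x > 0 for x in a) else 0)
        row = {"chrom": str(rec.CHROM), "pos": int(rec.POS), "ref": rec.REF, "alt": alts[0]}
        row.update(dict(zip(FOUNDER_CODES, calls)))
        rows.append(row)
    return pd.DataFrame(rows)


def extract_strain_specific(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep variants whose alt allele occurs in exactly one founder strain.

    ``variants`` has columns chrom, pos, ref, alt and one 0/1 allele column
    per founder code A..H.  Malformed rows (non-binary calls) are skipped and
    counted in the log.
    """
    missing = [c for c in FOUNDER_CODES if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing founder columns: {missing}")
    calls = variants[list(FOUNDER_CODES)].to_numpy()
    valid = np.isin(calls, (0, 1)).all(axis=1)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("extract_strain_specific: skipped %d malformed rows", n_bad)
    calls = calls[valid]
    kept = variants.loc[valid].reset_index(drop=True)
    private = calls.sum(axis=1) == 1
    out = kept.loc[private, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    owner_ix = calls[private].argmax(axis=1)
    out["owner"] = [FOUNDER_LABELS[i] for i in owner_ix]
    return out


def select_enrichment_eqtls(records: pd.DataFrame, gene_calls: pd.DataFrame) -> pd.DataFrame:
    """Label eQTLs for the enrichment analysis by their gene's sex bias.

    Keeps eQTLs whose credible interval is < 3 Mb wide; each is labeled
    male-specific (|fold-change| > 4, male-biased), female-specific
    (|fold-change| > 4, female-biased), or sex-independent
    (|fold-change| < 1.2).  eQTLs for genes in the 1.2-4 fold gap are
    dropped.  ``gene_calls`` is the per-gene table from
    ``expression.call_sex_specificity``.
    """
    width = records["ci_end"] - records["ci_start"]
    keep = records[width < MAX_CI_WIDTH].copy()
    labels = []
    for gene in keep["gene_id"]:
        if gene not in gene_calls.index:
            labels.append(None)
            continue
        call = gene_calls.loc[gene]
        if call["fc_magnitude"] > 4.0:
            labels.append("male-specific" if call["log2_fc"] > 0 else "female-specific")
        elif call["fc_magnitude"] < 1.2:
            labels.append("sex-independent")
        else:
            labels.append(None)
    keep["eqtl_set"] = labels
    return keep[keep["eqtl_set"].notna()].reset_index(drop=True)


def element_fraction_profile(
    eqtl: pd.Series | dict,
    elements: pd.DataFrame,
    variants: pd.DataFrame,
    factor: str,
) -> dict[str, float] | None:
    """Sex-class fractions of variant-bearing elements inside one eQTL region.

    Among elements of ``factor`` within the eQTL's credible interval, only
    those containing >= 1 variant owned by the eQTL's regulating strain enter
    the denominator; elements without such a variant are excluded.  Returns
    the three class fractions (summing to 1) plus the denominator, or None
    when no element qualifies (an NA profile, excluded downstream).

    ``variants`` is the strain-specific table from
    ``extract_strain_specific``; a variant belongs to an element when its
    (leftmost) position lies inside the element interval.
    """
    chrom = str(eqtl["chrom"])
    lo, hi = float(eqtl["ci_start"]), float(eqtl["ci_end"])
    strain = eqtl["regulating_strain"]
    sub = elements[
        (elements["chrom"].astype(str) == chrom)
        & (elements["factor"] == factor)
        & (elements["end"] >= lo)
        & (elements["start"] <= hi)
    ]
    if sub.empty:
        return None
    own = variants[(variants["owner"] == strain) & (variants["chrom"].astype(str) == chrom)]
    own_pos = own["pos"].to_numpy()
    counts = {c: 0 for c in SEX_CLASSES}
    denom = 0
    for _, el in sub.iterrows():
        if np.any((own_pos >= el["start"]) & (own_pos <= el["end"])):
            counts[el["sex_class"]] += 1
            denom += 1
    if denom == 0:
        return None
    profile = {f"frac_{c}": counts[c] / denom for c in SEX_CLASSES}
    profile["n_elements"] = denom
    return profile


def profile_eqtl_sets(
    labeled_eqtls: pd.DataFrame,
    elements: pd.DataFrame,
    variants: pd.DataFrame,
    factors: tuple[str, ...] = ("DHS", "STAT5", "BCL6"),
) -> pd.DataFrame:
    """Fraction profiles for every (eQTL, factor); NA profiles are dropped."""
    rows = []
    for _, eqtl in labeled_eqtls.iterrows():
        for factor in factors:
            profile = element_fraction_profile(eqtl, elements, variants, factor)
            if profile is None:
                continue
            rows.append(
                {
                    "gene_id": eqtl["gene_id"],
                    "marker_id": eqtl["marker_id"],
                    "eqtl_set": eqtl["eqtl_set"],
                    "cis_trans": eqtl.get("cis_trans", "NA"),
                    "factor": factor,
                    **profile,
                }
            )
    return pd.DataFrame(rows)


def compare_profiles_wilcoxon(
    profiles: pd.DataFrame, factor: str, sex_class: str
) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests of one class fraction across eQTL sets.

    Exact null distribution when the combined sample size is <= 20; normal
    approximation with continuity correction otherwise.  Degenerate
    comparisons (all values equal) give p = 1 with a warning.
    """
    col = f"frac_{sex_class}"
    sub = profiles[profiles["factor"] == factor]
    groups = {name: g[col].to_numpy() for name, g in sub.groupby("eqtl_set")}
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x, y = groups[a], groups[b]
            if len(x) < 3 or len(y) < 3:
                raise ValueError(f"need >= 3 non-NA profiles per set ({a} vs {b})")
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                warnings.warn(f"degenerate samples for {a} vs {b}; p = 1", stacklevel=2)
                p = 1.0
            else:
                method = "exact" if len(x) + len(y) <= 20 else "asymptotic"
                p = float(
                    stats.mannwhitneyu(
                        x, y, alternative="two-sided", method=method, use_continuity=True
                    ).pvalue
                )
            rows.append({"set_a": a, "set_b": b, "factor": factor, "sex_class": sex_class, "p": p})
    return pd.DataFrame(rows)
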