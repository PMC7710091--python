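"""End-to-end orchestration: simulate -> scan -> sex bias -> enrichment -> clusters.

Each stage is a plain function over in-memory tables so the command-line
interface stays thin.  A single master seed fans out to per-stage child
seeds by stable hashing, so adding a stage never perturbs the random streams
of earlier stages, and a rerun with the same configuration and seed produces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import child_seed
from . import coreg, expression, regvar, scan, sexbias, simulate
from .genotype import (
    collapse_to_dosage,
    read_diplotype_probs,
    read_marker_map,
)

__all__ = [
    "Bundle",
    "bundle_from_config",
    "load_bundle",
    "validate_inputs",
    "stage_sexbias",
    "stage_enrich",
    "stage_cluster",
    "run_full",
]

logger = logging.getLogger(__name__)


@dataclass
class Bundle:
    """All pipeline inputs, in memory."""

    probs: np.ndarray
    mmap: pd.DataFrame
    samples: list[str]
    meta: pd.DataFrame
    expr: pd.DataFrame
    gene_annot: pd.DataFrame
    founder_expr: pd.DataFrame | None = None
    founder_meta: pd.DataFrame | None = None
    variants: pd.DataFrame | None = None
    elements: pd.DataFrame | None = None
    tads: pd.DataFrame | None = None
    truth: pd.DataFrame | None = None

    @property
    def dosages(self) -> np.ndarray:
        if not hasattr(self, "_dosages"):
            self._dosages = collapse_to_dosage(self.probs)
        return self._dosages


def bundle_from_config(config: simulate.SimulationConfig) -> Bundle:
    """Generate a full synthetic bundle in memory."""
    probs, mmap, _ = simulate.simulate_genotypes(config)
    meta = simulate.make_metadata(config)
    dosages = collapse_to_dosage(probs)
    expr, annot, truth = simulate.simulate_expression(config, dosages, mmap, meta)
    founder_expr, founder_meta = simulate.simulate_founder_expression(config)
    variants, elements, tads = simulate.simulate_annotations(config, mmap)
    return Bundle(
        probs=probs,
        mmap=mmap,
        samples=list(meta["sample_id"]),
        meta=meta,
        expr=expr,
        gene_annot=annot,
        founder_expr=founder_expr,
        founder_meta=founder_meta,
        variants=variants,
        elements=elements,
        tads=tads,
        truth=truth,
    )


def load_bundle(indir: str | Path) -> Bundle:
    """Load a bundle from the standard input files of a directory."""
    indir = Path(indir)
    mmap = read_marker_map(indir / "marker_map.tsv")
    probs, samples = read_diplotype_probs(indir / "genotype_probs.tsv", mmap)
    meta = pd.read_csv(indir / "metadata.tsv", sep="\t")
    expr = pd.read_csv(indir / "expression.tsv", sep="\t", index_col=0)
    annot = pd.read_csv(indir / "gene_annotations.tsv", sep="\t", dtype={"chrom": str})

    def _opt(name, loader):
        path = indir / name
        return loader(path) if path.exists() else None

    founder_expr = _opt("founder_expression.tsv", lambda p: pd.read_csv(p, sep="\t", index_col=0))
    founder_meta = _opt("founder_metadata.tsv", lambda p: pd.read_csv(p, sep="\t"))
    variants = _opt("founder_variants.vcf", regvar.read_founder_variants)
    elements = _opt("elements.bed", simulate.read_elements_bed)
    tads = _opt("tads.bed", simulate.read_tads_bed)
    truth_path = indir / "truth.json"
    truth = pd.DataFrame(json.loads(truth_path.read_text())) if truth_path.exists() else None
    return Bundle(
        probs, mmap, samples, meta, expr, annot, founder_expr, founder_meta, variants, elements, tads, truth
    )


def validate_inputs(bundle: Bundle) -> dict:
    """Machine-readable consistency report; failures never raise here."""
    failures: list[str] = []
    geno_samples = set(bundle.samples)
    for s in bundle.expr.columns:
        if s not in geno_samples:
            failures.append(f"sample {s} present in expression but not genotype")
    meta_samples = set(bundle.meta["sample_id"])
    for s in bundle.expr.columns:
        if s not in meta_samples:
            failures.append(f"sample {s} present in expression but not metadata")
    sums = bundle.probs.sum(axis=-1)
    bad = np.argwhere(np.abs(sums - 1.0) > 1e-4)
    for s_ix, m_ix in bad[:20]:
        failures.append(
            f"diplotype probabilities for sample {bundle.samples[s_ix]} at marker "
            f"{bundle.mmap['marker_id'].iloc[m_ix]} sum to {sums[s_ix, m_ix]:.4g}"
        )
    for chrom, sub in bundle.mmap.groupby("chrom", sort=False):
        if np.any(np.diff(sub["pos_bp"].to_numpy()) <= 0):
            failures.append(f"marker map not sorted on chromosome {chrom}")
    for name, table in (("elements", bundle.elements), ("tads", bundle.tads)):
        if table is not None and np.any(table["start"].to_numpy() > table["end"].to_numpy()):
            failures.append(f"{name} contain intervals with start > end")
    return {"n_failures": len(failures), "failures": failures}


def combined_records(per_dataset: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """One eQTL per (gene, chromosome): the significant record with the
    highest LOD across datasets."""
    frames = [df[df["significant"]] for df in per_dataset.values() if not df.empty]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame()
    stacked = pd.concat(frames, ignore_index=True)
    stacked = stacked.sort_values("lod", ascending=False, kind="stable")
    return stacked.drop_duplicates(subset=["gene_id", "chrom"], keep="first").reset_index(drop=True)


def _lod_profiles(bundle: Bundle, dataset: str, genes: list[str]) -> dict[str, pd.DataFrame]:
    """Per-gene LOD profiles for one dataset (no permutations)."""
    X = scan.design_matrix(bundle.meta, dataset)
    keep = [s for s in X.index if s in set(bundle.expr.columns)]
    X = X.loc[keep]
    row_of = {s: i for i, s in enumerate(bundle.samples)}
    D = bundle.dosages[[row_of[s] for s in keep]]
    scanner = scan.FounderScanner(D, X.to_numpy())
    profiles = {}
    for gene in genes:
        y_raw = bundle.expr.loc[gene, keep].to_numpy(dtype=float)
        if np.all(y_raw == y_raw[0]):
            continue
        profile = bundle.mmap[["marker_id", "chrom", "pos_bp"]].copy()
        profile["lod"] = scanner.lod_profile(expression.rankz_transform(y_raw))
        profiles[gene] = profile
    return profiles


def gene_sex_calls(bundle: Bundle) -> pd.DataFrame:
    return expression.call_sex_specificity(bundle.expr, bundle.meta, platform="rnaseq")


def stage_sexbias(
    bundle: Bundle,
    male_records: pd.DataFrame,
    female_records: pd.DataFrame,
    combined: pd.DataFrame,
    gene_calls: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Categorize sex-dependent eQTLs and run the matched-sex decile enrichment.

    Returns (sex-bias table, enrichment summary).  The table covers eQTLs of
    sex-specific genes that are significant in at least one single-sex scan;
    the decile enrichment uses all combined eQTLs with a nonzero LOD
    difference between the sexes.
    """
    if gene_calls is None:
        gene_calls = gene_sex_calls(bundle)
    strain_calls = None
    if bundle.founder_expr is not None and bundle.founder_meta is not None:
        strain_calls = expression.strain_sex_specificity(bundle.founder_expr, bundle.founder_meta)

    sexbias_table = pd.DataFrame()
    sig_frames = [df[df["significant"]] for df in (male_records, female_records) if not df.empty]
    sig_frames = [f for f in sig_frames if not f.empty]
    if sig_frames:
        single_sex = pd.concat(sig_frames, ignore_index=True)
        single_sex = single_sex.sort_values("lod", ascending=False, kind="stable")
        single_sex = single_sex.drop_duplicates(subset=["gene_id", "chrom"], keep="first")
        sex_specific = gene_calls[gene_calls["sex_class"] != "sex-independent"].index
        eligible = single_sex[single_sex["gene_id"].isin(sex_specific)]
        genes = sorted(set(eligible["gene_id"]))
        sexbias_table = sexbias.categorize_eqtls(
            eligible,
            male_records,
            female_records,
            _lod_profiles(bundle, "male", genes),
            _lod_profiles(bundle, "female", genes),
            gene_calls["sex_class"],
            strain_calls,
        )

    enrichment_summary: dict = {}
    if not combined.empty:
        genes_all = sorted(set(combined["gene_id"]))
        male_profiles = _lod_profiles(bundle, "male", genes_all)
        female_profiles = _lod_profiles(bundle, "female", genes_all)
        delta_rows = []
        for _, rec in combined.iterrows():
            g = rec["gene_id"]
            if g not in male_profiles or g not in female_profiles:
                continue
            delta_rows.append(
                {
                    "gene_id": g,
                    "delta_lod": sexbias.delta_lod(
                        male_profiles[g], female_profiles[g], rec["marker_id"]
                    ),
                    "gene_sex_class": gene_calls["sex_class"].get(g, "sex-independent"),
                }
            )
        try:
            fold, p, table = sexbias.matched_sex_decile_enrichment(pd.DataFrame(delta_rows))
            enrichment_summary = {
                "fold": fold,
                "haldane_fold": table.attrs["haldane_fold"],
                "fisher_p": p,
                "table": table.to_dict(),
            }
        except ValueError as exc:
            logger.info("matched-sex decile enrichment skipped: %s", exc)
            enrichment_summary = {"skipped": str(exc)}
    return sexbias_table, enrichment_summary


def stage_enrich(
    bundle: Bundle, combined: pd.DataFrame, gene_calls: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strain-specific-variant fraction profiles and Wilcoxon comparisons."""
    if bundle.variants is None or bundle.elements is None or combined.empty:
        return pd.DataFrame(), pd.DataFrame()
    if gene_calls is None:
        gene_calls = gene_sex_calls(bundle)
    private = regvar.extract_strain_specific(bundle.variants)
    labeled = regvar.select_enrichment_eqtls(combined, gene_calls)
    profiles = regvar.profile_eqtl_sets(labeled, bundle.elements, private)
    wilcoxon = pd.DataFrame()
    if not profiles.empty:
        frames = []
        for factor in profiles["factor"].unique():
            for sex_class in regvar.SEX_CLASSES:
                try:
                    frames.append(regvar.compare_profiles_wilcoxon(profiles, factor, sex_class))
                except ValueError:
                    pass
        if frames:
            wilcoxon = pd.concat(frames, ignore_index=True)
    return profiles, wilcoxon


def stage_cluster(
    bundle: Bundle, all_records: pd.DataFrame, gene_calls: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Five-marker regions, same-strain overlap clusters, and sex enrichment."""
    if all_records.empty:
        return pd.DataFrame(), pd.DataFrame()
    if gene_calls is None:
        gene_calls = gene_sex_calls(bundle)
    sig = all_records[all_records["significant"]]
    expressed = coreg.expression_filter(bundle.expr)
    sig = sig[sig["gene_id"].isin(expressed)]
    if sig.empty:
        return pd.DataFrame(), pd.DataFrame()
    annot = bundle.gene_annot.set_index("gene_id")
    rows = []
    for _, rec in sig.iterrows():
        chrom, start, end = coreg.build_region(rec["marker_id"], bundle.mmap)
        rows.append(
            {
                "eqtl_id": f"{rec['gene_id']}@{rec['marker_id']}",
                "gene_id": rec["gene_id"],
                "chrom": chrom,
                "start": start,
                "end": end,
                "regulating_strain": rec["regulating_strain"],
                "coef_sign": "+" if rec["direction"] == "up" else "-",
                "gene_chrom": str(annot.loc[rec["gene_id"], "chrom"])
                if rec["gene_id"] in annot.index
                else "NA",
            }
        )
    clusters = coreg.cluster_regions(pd.DataFrame(rows))
    sex_specific_set = set(gene_calls[gene_calls["sex_class"] != "sex-independent"].index)
    enrich = coreg.cluster_sex_enrichment(clusters, sex_specific_set, universe_size=len(expressed))
    return clusters, enrich


def run_full(
    config: simulate.SimulationConfig,
    outdir: str | Path,
    datasets: tuple[str, ...] = ("all", "male", "female"),
    n_perm: int = 200,
    write_inputs: bool = True,
) -> dict:
    """Run the whole analysis on a synthetic bundle and write all outputs.

    Returns the run manifest (also written to ``manifest.json``).
    """
    if not datasets:
        raise ValueError("datasets must be nonempty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    if write_inputs:
        simulate.write_bundle(config, outdir / "inputs")
    bundle = bundle_from_config(config)
    report = validate_inputs(bundle)
    if report["n_failures"]:
        raise RuntimeError(f"input validation failed: {report['failures'][:3]}")

    counts: dict[str, int] = {}
    per_dataset: dict[str, pd.DataFrame] = {}
    for dataset in datasets:
        records = scan.scan_dataset(
            bundle.expr,
            bundle.dosages,
            bundle.samples,
            bundle.mmap,
            bundle.meta,
            dataset=dataset,
            n_perm=n_perm,
            seed=child_seed(seed, f"scan:{dataset}"),
            gene_annot=bundle.gene_annot,
            tads=bundle.tads,
        )
        per_dataset[dataset] = records
        records.to_csv(outdir / f"eqtls_{dataset}.tsv", sep="\t", index=False)
        counts[f"eqtls_{dataset}"] = int(records["significant"].sum()) if not records.empty else 0
        logger.info("stage scan[%s]: %d significant eQTLs", dataset, counts[f"eqtls_{dataset}"])

    combined = combined_records(per_dataset)
    combined.to_csv(outdir / "eqtls_combined.tsv", sep="\t", index=False)
    counts["eqtls_combined"] = len(combined)

    gene_calls = gene_sex_calls(bundle)
    if bundle.founder_expr is not None and bundle.founder_meta is not None:
        expression.strain_sex_specificity(bundle.founder_expr, bundle.founder_meta).to_csv(
            outdir / "strain_sex_calls.tsv", sep="\t", index=False
        )

    sexbias_table = pd.DataFrame()
    enrichment_summary: dict = {"skipped": "needs both male and female scans"}
    if {"male", "female"} <= set(per_dataset):
        sexbias_table, enrichment_summary = stage_sexbias(
            bundle, per_dataset["male"], per_dataset["female"], combined, gene_calls
        )
    else:
        logger.info("sex-bias stage skipped: needs both male and female scans")
    sexbias_table.to_csv(outdir / "sexbias.tsv", sep="\t", index=False)
    counts["sexbias_eqtls"] = len(sexbias_table)

    profiles, wilcoxon = stage_enrich(bundle, combined, gene_calls)
    profiles.to_csv(outdir / "element_profiles.tsv", sep="\t", index=False)
    wilcoxon.to_csv(outdir / "element_profile_tests.tsv", sep="\t", index=False)
    counts["element_profiles"] = len(profiles)

    clusters, cluster_enrich = stage_cluster(bundle, per_dataset.get("all", pd.DataFrame()), gene_calls)
    clusters.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    cluster_enrich.to_csv(outdir / "cluster_sex_enrichment.tsv", sep="\t", index=False)
    counts["clusters"] = int(clusters["cluster_id"].nunique()) if not clusters.empty else 0

    config_json = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    manifest = {
        "package": "doeqtl",
        "version": __version__,
        "seed": seed,
        "n_perm": n_perm,
        "datasets": list(datasets),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "counts": counts,
        "enrichment": enrichment_summary,
        "validation": report,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
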