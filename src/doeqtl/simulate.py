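"""Synthetic Diversity Outbred data with planted ground truth.

Generates every input the analysis pipeline consumes — founder diplotype
probabilities on a marker map, FPKM expression with sample metadata,
founder-strain replicate expression, a founder variant table, sex-classed
regulatory elements, and TAD intervals — from a single seeded configuration,
so the whole pipeline is testable without any external download.

The genetic model is a stationary founder-mosaic Markov process: each sample
carries two haplotypes per chromosome; each haplotype starts from a uniformly
chosen founder and switches to a new uniformly chosen founder with
probability 1 - exp(-rate * d / 1e8) between markers separated by d bp, where
``recombination_rate`` is the expected number of breakpoints per 100 Mb.
This is deliberately simpler than DO breeding (no pedigree/funnel): the
downstream inference never uses pedigree information, only the marginal
mosaic structure.

Expression follows y = sex_effect + sum_f beta_f(sex) * dosage_f + diet +
batch + N(0, noise_sd) on a log scale, exponentiated to an FPKM-like scale so
the rank-based inverse normal transform downstream is exercised on skewed
data.  Genotype uncertainty puts ``genotype_confidence`` mass on the true
diplotype state and spreads the remainder uniformly over the other 35 states.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import child_seed
from .genotype import (
    FOUNDER_CODES,
    FOUNDER_LABELS,
    N_FOUNDERS,
    N_STATES,
    collapse_to_dosage,
    diplotype_state_index,
    validate_marker_map,
    write_diplotype_probs,
    write_dosages,
    write_marker_map,
)

__all__ = [
    "CausalEffect",
    "PlantedElements",
    "SimulationConfig",
    "make_metadata",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_founder_expression",
    "simulate_annotations",
    "write_bundle",
]


@dataclass(frozen=True)
class CausalEffect:
    """One planted eQTL: additive founder effects at a marker, in noise-SD units.

    ``sex_multiplier`` scales the whole effect vector per sex (male, female),
    so (1, 0) plants a male-only association.  ``sex_effect`` is a baseline
    male-minus-female shift on the log scale present in every strain,
    independent of genotype; it is what makes the gene sex-specific before the
    eQTL modifies it.  ``cis`` controls whether the gene's TSS is placed at the
    causal marker or on a different chromosome.
    """

    gene_id: str
    marker_id: str
    effects: tuple[float, ...]
    sex_multiplier: tuple[float, float] = (1.0, 1.0)
    sex_effect: float = 0.0
    cis: bool = True

    def __post_init__(self) -> None:
        if len(self.effects) != N_FOUNDERS:
            raise ValueError("effects must have 8 entries, one per founder")


@dataclass(frozen=True)
class PlantedElements:
    """Plant n elements of one sex class inside an interval, each containing
    one variant private to ``strain`` (founder code A..H)."""

    chrom: str
    start: int
    end: int
    strain: str
    sex_class: str
    factor: str = "DHS"
    n: int = 5


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic DO cohort.

    Defaults approximate the structure of a large DO liver study at desk
    scale: equal numbers of male and female animals, two diets, two batches,
    evenly spaced markers on equal-length autosomes, and a mosaic breakpoint
    rate giving founder blocks of a few tens of Mb.
    """

    seed: int
    n_per_sex: int = 100
    chromosomes: tuple[tuple[str, int, int], ...] = (
        ("1", 100_000_000, 60),
        ("2", 100_000_000, 60),
        ("3", 100_000_000, 60),
    )
    recombination_rate: float = 5.0  # expected breakpoints per 100 Mb per haplotype
    causal_effects: tuple[CausalEffect, ...] = ()
    n_null_genes: int = 0
    diet_effect: float = 0.3
    batch_effects: tuple[float, ...] = (0.0, 0.4)
    noise_sd: float = 1.0
    genotype_confidence: float = 0.97
    expression_scale: float = 10.0
    founder_reps_per_sex: int = 6
    # annotation layer
    n_variants: int = 2000
    private_fraction: float = 0.7
    n_elements: int = 300
    element_width: int = 1000
    element_class_probs: tuple[float, float, float] = (0.1, 0.1, 0.8)  # male, female, independent
    element_factors: tuple[str, ...] = ("DHS", "STAT5", "BCL6")
    tad_width: int = 2_000_000
    planted_elements: tuple[PlantedElements, ...] = ()

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, length, n_markers in self.chromosomes:
            if n_markers < 5:
                raise ValueError(f"chromosome {name} needs at least 5 markers, got {n_markers}")
        if not 0.0 <= self.genotype_confidence <= 1.0:
            raise ValueError("genotype_confidence must be in [0, 1]")


def _sample_ids(config: SimulationConfig) -> list[str]:
    n = 2 * config.n_per_sex
    return [f"DO{i + 1:04d}" for i in range(n)]


def make_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic balanced metadata: first half male, alternating diet,
    batch, and generation within each sex."""
    samples = _sample_ids(config)
    n = config.n_per_sex
    rows = []
    n_batches = len(config.batch_effects)
    for i, sid in enumerate(samples):
        sex = "M" if i < n else "F"
        j = i % n
        rows.append(
            {
                "sample_id": sid,
                "sex": sex,
                "diet": "chow" if j % 2 == 0 else "high-fat",
                "generation": f"G{j % 2}",
                "batch": f"B{j % n_batches}",
            }
        )
    return pd.DataFrame(rows)


def build_marker_map(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for name, length, n_markers in config.chromosomes:
        if n_markers <= 0:
            raise ValueError(f"chromosome {name} has zero markers")
        pos = np.round(np.linspace(length / n_markers, length, n_markers)).astype(np.int64)
        for k, p in enumerate(pos):
            rows.append({"marker_id": f"chr{name}_m{k + 1:04d}", "chrom": name, "pos_bp": int(p), "measured": True})
    return validate_marker_map(pd.DataFrame(rows))


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Simulate founder mosaics and emit noisy diplotype probabilities.

    Returns
    -------
    probs : (n_samples, n_markers, 36) diplotype probability tensor
    mmap : marker map DataFrame
    mosaics : (n_samples, n_markers, 2) true founder index per haplotype
    """
    rng = np.random.default_rng(child_seed(config.seed, "genotypes"))
    mmap = build_marker_map(config)
    samples = _sample_ids(config)
    n_s = len(samples)
    n_m = len(mmap)

    mosaics = np.zeros((n_s, n_m, 2), dtype=np.int8)
    pos = mmap["pos_bp"].to_numpy(dtype=float)
    chroms = mmap["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        state = rng.integers(0, N_FOUNDERS, size=(n_s, 2))
        mosaics[:, idx[0], :] = state
        for prev, cur in zip(idx[:-1], idx[1:]):
            d = pos[cur] - pos[prev]
            p_switch = 1.0 - np.exp(-config.recombination_rate * d / 1e8)
            switch = rng.random(size=(n_s, 2)) < p_switch
            # a switch moves to a uniformly chosen *different* founder
            jump = rng.integers(1, N_FOUNDERS, size=(n_s, 2))
            state = np.where(switch, (state + jump) % N_FOUNDERS, state)
            mosaics[:, cur, :] = state

    state_idx = np.empty((n_s, n_m), dtype=np.int64)
    lut = np.zeros((N_FOUNDERS, N_FOUNDERS), dtype=np.int64)
    for a in range(N_FOUNDERS):
        for b in range(N_FOUNDERS):
            lut[a, b] = diplotype_state_index(a, b)
    state_idx = lut[mosaics[:, :, 0], mosaics[:, :, 1]]

    c = config.genotype_confidence
    probs = np.full((n_s, n_m, N_STATES), (1.0 - c) / (N_STATES - 1))
    s_ix, m_ix = np.meshgrid(np.arange(n_s), np.arange(n_m), indexing="ij")
    probs[s_ix, m_ix, state_idx] = c
    return probs, mmap, mosaics


def simulate_expression(
    config: SimulationConfig,
    dosages: np.ndarray,
    mmap: pd.DataFrame,
    meta: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate FPKM expression for planted and null genes.

    Returns (expression genes x samples, gene annotations, truth table).
    The truth table holds, per planted gene, the causal marker, the effect
    vector, the expected regulating strain (argmax |effect|), and the expected
    sex-bias direction.
    """
    if dosages.shape[0] != len(meta):
        raise ValueError("dosages and metadata must cover the same samples")
    rng = np.random.default_rng(child_seed(config.seed, "expression"))
    marker_index = {m: i for i, m in enumerate(mmap["marker_id"])}
    sex_sign = np.where(meta["sex"].to_numpy() == "M", 0.5, -0.5)
    diet_term = config.diet_effect * (meta["diet"].to_numpy() == "high-fat")
    batch_levels = {b: config.batch_effects[i % len(config.batch_effects)] for i, b in enumerate(sorted(meta["batch"].unique()))}
    batch_term = meta["batch"].map(batch_levels).to_numpy()
    is_male = meta["sex"].to_numpy() == "M"

    n_samples = len(meta)
    gene_rows: dict[str, np.ndarray] = {}
    annot_rows = []
    truth_rows = []
    chrom_names = [c[0] for c in config.chromosomes]
    chrom_len = {c[0]: c[1] for c in config.chromosomes}

    for eff in config.causal_effects:
        if eff.marker_id not in marker_index:
            raise ValueError(f"causal marker {eff.marker_id} absent from marker map")
        mi = marker_index[eff.marker_id]
        beta = np.asarray(eff.effects, dtype=float)
        per_sex = np.where(is_male, eff.sex_multiplier[0], eff.sex_multiplier[1])
        z = (
            eff.sex_effect * sex_sign
            + per_sex * (dosages[:, mi, :] @ beta)
            + diet_term
            + batch_term
            + rng.normal(0.0, config.noise_sd, size=n_samples)
        )
        gene_rows[eff.gene_id] = config.expression_scale * np.exp(z)
        m_chrom = mmap["chrom"].iloc[mi]
        m_pos = int(mmap["pos_bp"].iloc[mi])
        if eff.cis:
            tss_chrom, tss = m_chrom, m_pos
        else:
            others = [c for c in chrom_names if c != m_chrom] or [m_chrom]
            tss_chrom = others[int(rng.integers(len(others)))]
            tss = int(rng.integers(1, chrom_len[tss_chrom]))
        annot_rows.append(
            {"gene_id": eff.gene_id, "chrom": tss_chrom, "tss": tss, "biotype": "protein_coding"}
        )
        strain_ix = int(np.argmax(np.abs(beta)))
        if eff.sex_multiplier[0] > eff.sex_multiplier[1]:
            bias = "male"
        elif eff.sex_multiplier[1] > eff.sex_multiplier[0]:
            bias = "female"
        else:
            bias = "none"
        truth_rows.append(
            {
                "gene_id": eff.gene_id,
                "marker_id": eff.marker_id,
                "chrom": m_chrom,
                "pos_bp": m_pos,
                "effects": list(beta),
                "regulating_strain": FOUNDER_LABELS[strain_ix],
                "sex_bias": bias,
            }
        )

    for k in range(config.n_null_genes):
        gid = f"null{k + 1:04d}"
        z = (
            diet_term
            + batch_term
            + rng.normal(0.0, config.noise_sd, size=n_samples)
        )
        gene_rows[gid] = config.expression_scale * np.exp(z)
        chrom = chrom_names[k % len(chrom_names)]
        annot_rows.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "tss": int(rng.integers(1, chrom_len[chrom])),
                "biotype": "protein_coding",
            }
        )

    expr = pd.DataFrame(gene_rows, index=meta["sample_id"]).T
    annot = pd.DataFrame(annot_rows, columns=["gene_id", "chrom", "tss", "biotype"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "marker_id", "chrom", "pos_bp", "effects", "regulating_strain", "sex_bias"],
    )
    if truth["gene_id"].duplicated().any():
        raise ValueError("every causal gene must appear once in the truth table")
    return expr, annot, truth


def simulate_founder_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate expression for the eight inbred founder strains.

    Each founder strain is homozygous for its own haplotype everywhere, so a
    planted effect vector contributes 2 * beta_s in strain s (times the sex
    multiplier), on top of the genotype-independent baseline sex effect.
    """
    rng = np.random.default_rng(child_seed(config.seed, "founder_expression"))
    reps = config.founder_reps_per_sex
    rows = []
    for strain in FOUNDER_LABELS:
        for sex in ("M", "F"):
            for r in range(reps):
                rows.append(
                    {
                        "sample_id": f"{strain}_{sex}{r + 1}",
                        "strain": strain,
                        "sex": sex,
                        "diet": "chow",
                        "generation": "G0",
                        "batch": "B0",
                    }
                )
    meta = pd.DataFrame(rows)
    sex_sign = np.where(meta["sex"] == "M", 0.5, -0.5)
    is_male = meta["sex"].to_numpy() == "M"
    strain_ix = meta["strain"].map({s: i for i, s in enumerate(FOUNDER_LABELS)}).to_numpy()

    gene_rows = {}
    for eff in config.causal_effects:
        beta = np.asarray(eff.effects, dtype=float)
        per_sex = np.where(is_male, eff.sex_multiplier[0], eff.sex_multiplier[1])
        z = (
            eff.sex_effect * sex_sign
            + per_sex * 2.0 * beta[strain_ix]
            + rng.normal(0.0, config.noise_sd, size=len(meta))
        )
        gene_rows[eff.gene_id] = config.expression_scale * np.exp(z)
    for k in range(config.n_null_genes):
        gid = f"null{k + 1:04d}"
        z = rng.normal(0.0, config.noise_sd, size=len(meta))
        gene_rows[gid] = config.expression_scale * np.exp(z)
    expr = pd.DataFrame(gene_rows, index=meta["sample_id"]).T
    return expr, meta


def simulate_annotations(
    config: SimulationConfig, mmap: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Founder variant table, sex-classed regulatory elements, and TAD tiling.

    Variants are placed uniformly; a ``private_fraction`` of them carry the
    alt allele in exactly one founder (strain-specific), the rest in two or
    more founders.  Elements get a factor label and a sex class; TADs tile
    each chromosome without overlap.  Planted-element blocks add elements of a
    chosen class inside a target interval, each containing one variant private
    to a chosen strain, to create a recoverable enrichment signal.
    """
    validate_marker_map(mmap)
    rng = np.random.default_rng(child_seed(config.seed, "annotations"))
    chrom_len = {name: length for name, length, _ in config.chromosomes}
    names = list(chrom_len)
    lengths = np.array([chrom_len[c] for c in names], dtype=float)
    chrom_p = lengths / lengths.sum()

    # --- variants ---------------------------------------------------------
    var_rows = []
    for v in range(config.n_variants):
        chrom = names[int(rng.choice(len(names), p=chrom_p))]
        pos = int(rng.integers(1, chrom_len[chrom] + 1))
        carriers = np.zeros(N_FOUNDERS, dtype=int)
        if rng.random() < config.private_fraction:
            carriers[int(rng.integers(N_FOUNDERS))] = 1
        else:
            k = int(rng.integers(2, N_FOUNDERS + 1))
            carriers[rng.choice(N_FOUNDERS, size=k, replace=False)] = 1
        row = {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"}
        row.update({code: int(c) for code, c in zip(FOUNDER_CODES, carriers)})
        var_rows.append(row)

    # --- elements ---------------------------------------------------------
    classes = ("male-biased", "female-biased", "sex-independent")
    elem_rows = []
    for e in range(config.n_elements):
        chrom = names[int(rng.choice(len(names), p=chrom_p))]
        start = int(rng.integers(1, chrom_len[chrom] - config.element_width))
        elem_rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + config.element_width - 1,
                "factor": config.element_factors[int(rng.integers(len(config.element_factors)))],
                "sex_class": classes[int(rng.choice(3, p=np.asarray(config.element_class_probs)))],
            }
        )

    # --- planted co-location ---------------------------------------------
    for plant in config.planted_elements:
        strain_col = plant.strain if plant.strain in FOUNDER_CODES else FOUNDER_CODES[FOUNDER_LABELS.index(plant.strain)]
        width = config.element_width
        for k in range(plant.n):
            lo = plant.start + int((plant.end - plant.start - width) * (k + 0.5) / plant.n)
            elem_rows.append(
                {
                    "chrom": plant.chrom,
                    "start": lo,
                    "end": lo + width - 1,
                    "factor": plant.factor,
                    "sex_class": plant.sex_class,
                }
            )
            carriers = {code: 0 for code in FOUNDER_CODES}
            carriers[strain_col] = 1
            row = {"chrom": plant.chrom, "pos": lo + width // 2, "ref": "A", "alt": "G"}
            row.update(carriers)
            var_rows.append(row)

    variants = pd.DataFrame(var_rows).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    elements = pd.DataFrame(elem_rows).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    # --- TADs: disjoint tiling of each chromosome -------------------------
    tad_rows = []
    for chrom in names:
        start = 1
        while start <= chrom_len[chrom]:
            end = min(start + config.tad_width - 1, chrom_len[chrom])
            tad_rows.append({"chrom": chrom, "start": start, "end": end})
            start = end + 1
    tads = pd.DataFrame(tad_rows)
    return variants, elements, tads


# ---------------------------------------------------------------------------
# Bundle writer: all pipeline input files plus the truth table.
# ---------------------------------------------------------------------------

def _write_vcf(variants: pd.DataFrame, path: Path) -> None:
    strain_headers = [label.replace(" ", "_") for label in FOUNDER_LABELS]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = variants["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(strain_headers) + "\n")
        for i, row in variants.iterrows():
            gts = ["1/1" if row[code] else "0/0" for code in FOUNDER_CODES]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\tv{i + 1}\t{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_elements_bed(elements: pd.DataFrame, path: str | Path) -> None:
    out = elements.copy()
    out["bed_start"] = out["start"] - 1  # 1-based inclusive -> 0-based half-open
    out[["chrom", "bed_start", "end", "factor", "sex_class"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_elements_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "bed_start", "end", "factor", "sex_class"],
        dtype={"chrom": str},
    )
    bed["start"] = bed["bed_start"] + 1
    return bed[["chrom", "start", "end", "factor", "sex_class"]]


def write_tads_bed(tads: pd.DataFrame, path: str | Path) -> None:
    out = tads.copy()
    out["bed_start"] = out["start"] - 1
    out[["chrom", "bed_start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def read_tads_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "bed_start", "end"], dtype={"chrom": str})
    bed["start"] = bed["bed_start"] + 1
    return bed[["chrom", "start", "end"]]


def write_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Generate the full synthetic input bundle and write it to ``outdir``.

    Returns a manifest mapping logical names to file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    probs, mmap, _ = simulate_genotypes(config)
    meta = make_metadata(config)
    dosages = collapse_to_dosage(probs)
    expr, annot, truth = simulate_expression(config, dosages, mmap, meta)
    founder_expr, founder_meta = simulate_founder_expression(config)
    variants, elements, tads = simulate_annotations(config, mmap)

    samples = list(meta["sample_id"])
    paths = {
        "marker_map": outdir / "marker_map.tsv",
        "genotype_probs": outdir / "genotype_probs.tsv",
        "dosages": outdir / "dosages.tsv",
        "expression": outdir / "expression.tsv",
        "gene_annotations": outdir / "gene_annotations.tsv",
        "metadata": outdir / "metadata.tsv",
        "founder_expression": outdir / "founder_expression.tsv",
        "founder_metadata": outdir / "founder_metadata.tsv",
        "variants": outdir / "founder_variants.vcf",
        "elements": outdir / "elements.bed",
        "tads": outdir / "tads.bed",
        "truth": outdir / "truth.json",
    }
    write_marker_map(mmap, paths["marker_map"])
    write_diplotype_probs(probs, samples, mmap, paths["genotype_probs"])
    write_dosages(dosages, samples, mmap, paths["dosages"])
    expr.to_csv(paths["expression"], sep="\t", float_format="%.6g")
    annot.to_csv(paths["gene_annotations"], sep="\t", index=False)
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    founder_expr.to_csv(paths["founder_expression"], sep="\t", float_format="%.6g")
    founder_meta.to_csv(paths["founder_metadata"], sep="\t", index=False)
    _write_vcf(variants, paths["variants"])
    write_elements_bed(elements, paths["elements"])
    write_tads_bed(tads, paths["tads"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(orient="records"), fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
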