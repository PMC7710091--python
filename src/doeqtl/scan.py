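"""Founder-haplotype genome scans: additive model, permutations, peaks, intervals.

The association model regresses a gene's rankZ-transformed expression on the
eight founder dosages at each marker, with additive covariates (sex, diet,
sex x diet, generation, batch).  The LOD score is -log10 of the F-test
p-value comparing the full model to the covariates-only null, with degrees of
freedom taken from matrix ranks.  Because the eight dosages sum to 2 at every
marker (collinear with the intercept), the fit uses minimum-norm least
squares and the reported founder coefficients are centered to sum to zero,
which reproduces founder-effect plots without singling out a reference
strain.

Genome-wide significance is by permutation of the expression vector; peaks
are selected per chromosome; Benjamini-Hochberg FDR is applied across all
candidate peaks of a dataset; a 95% credible interval is taken as the central
mass of the LOD^10 curve on the peak chromosome; eQTLs are cis when that
interval overlaps the TAD containing the gene's TSS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from ._util import child_seed
from .expression import rankz_transform
from .genotype import FOUNDER_CODES, FOUNDER_LABELS, N_FOUNDERS

__all__ = [
    "LOD_CAP",
    "MarkerFit",
    "design_matrix",
    "fit_marker",
    "FounderScanner",
    "scan_gene",
    "permutation_maxima",
    "permutation_pvalue",
    "select_peaks",
    "fdr_across_genes",
    "bayes_credible_interval",
    "assign_regulating_strain",
    "classify_cis_trans",
    "scan_dataset",
]

logger = logging.getLogger(__name__)

LOD_CAP = 300.0
_RSS_EPS = 1e-12

DATASETS = ("all", "male", "female")


def design_matrix(meta: pd.DataFrame, dataset: str = "all") -> pd.DataFrame:
    """Covariate matrix for a dataset, indexed by sample id.

    The all-samples design is intercept + sex + diet + sex x diet +
    generation + batch indicators; single-sex datasets drop the sex and
    sex x diet columns.  Constant and aliased columns are dropped (logged) so
    the returned matrix has full column rank.
    """
    if dataset not in DATASETS:
        raise ValueError(f"dataset must be one of {DATASETS}")
    sub = meta
    if dataset == "male":
        sub = meta[meta["sex"] == "M"]
    elif dataset == "female":
        sub = meta[meta["sex"] == "F"]
    sub = sub.reset_index(drop=True)

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sub))}
    diet = (sub["diet"] == "high-fat").to_numpy(dtype=float)
    if dataset == "all":
        sex = (sub["sex"] == "M").to_numpy(dtype=float)
        cols["sex"] = sex
        cols["diet"] = diet
        cols["sex:diet"] = sex * diet
    else:
        cols["diet"] = diet
    for covar in ("generation", "batch"):
        if covar in sub.columns:
            dummies = pd.get_dummies(sub[covar], prefix=covar, drop_first=True, dtype=float)
            for name in dummies.columns:
                cols[name] = dummies[name].to_numpy()

    X = pd.DataFrame(cols, index=sub["sample_id"])
    # drop constant columns (other than the intercept)
    for name in list(X.columns):
        if name != "intercept" and X[name].nunique() <= 1:
            logger.info("design_matrix: dropping constant covariate %r", name)
            X = X.drop(columns=name)
    # drop aliased columns until full column rank, preferring to keep earlier columns
    while np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        arr = X.to_numpy()
        for j in range(X.shape[1] - 1, 0, -1):
            reduced = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(arr):
                logger.info("design_matrix: dropping aliased covariate %r", X.columns[j])
                X = X.drop(columns=X.columns[j])
                break
        else:  # pragma: no cover - intercept alone is always full rank
            break
    return X


def _orth(a: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (empty matrix for zero input)."""
    if a.size == 0:
        return np.zeros((a.shape[0], 0))
    return linalg.orth(a)


def _lod_from_rss(
    rss_null: np.ndarray, rss_full: np.ndarray, df1: np.ndarray, df2: np.ndarray
) -> np.ndarray:
    """Vectorized F-test LOD with rank-based degrees of freedom, capped."""
    rss_null = np.asarray(rss_null, dtype=float)
    rss_full = np.asarray(rss_full, dtype=float)
    df1 = np.broadcast_to(np.asarray(df1, dtype=float), rss_full.shape)
    df2 = np.broadcast_to(np.asarray(df2, dtype=float), rss_full.shape)
    scale = np.maximum(rss_null, _RSS_EPS)
    perfect = rss_full <= _RSS_EPS * scale
    safe_rss = np.where(perfect, scale, rss_full)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_null - rss_full) / df1) / (safe_rss / df2)
        p = stats.f.sf(F, df1, df2)
    lod = np.where(p > 0, -np.log10(np.maximum(p, 1e-320)), LOD_CAP)
    lod = np.where(perfect | (lod > LOD_CAP), LOD_CAP, lod)
    return np.maximum(lod, 0.0)


@dataclass(frozen=True)
class MarkerFit:
    """Single-marker fit: LOD, zero-sum founder coefficients, residual sums."""

    lod: float
    coefficients: np.ndarray  # 8 centered founder coefficients
    rss_full: float
    rss_null: float
    df1: int
    df2: int


def fit_marker(y: np.ndarray, dosages: np.ndarray, covariates: np.ndarray) -> MarkerFit:
    """Least-squares fit of y on [covariates | 8 founder dosages].

    Uses the minimum-norm solution (the dosage columns are collinear with the
    intercept); the founder coefficients are reported centered to sum zero.
    LOD is the F-test of the full model against the covariates-only null with
    rank-based degrees of freedom, capped at 300.
    """
    y = np.asarray(y, dtype=float).ravel()
    D = np.asarray(dosages, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n = y.size
    if D.shape != (n, N_FOUNDERS):
        raise ValueError(f"dosages must be (n, 8); got {D.shape}")
    if C.shape[0] != n:
        raise ValueError("covariates and y must have matching rows")

    X = np.hstack([C, D])
    rank_null = np.linalg.matrix_rank(C) if C.size else 0
    rank_full = np.linalg.matrix_rank(X)
    df1 = rank_full - rank_null
    df2 = n - rank_full
    if np.var(y) == 0:
        warnings.warn("phenotype has zero variance; LOD set to 0", stacklevel=2)
        coef = np.zeros(N_FOUNDERS)
        return MarkerFit(0.0, coef, 0.0, 0.0, df1, max(df2, 0))
    if df1 <= 0:
        raise ValueError("dosage columns add no rank beyond the covariates")
    if df2 <= 0:
        raise ValueError(f"not enough samples (n={n}) for model rank {rank_full}")

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss_full = float(resid @ resid)
    if C.size:
        beta0, _, _, _ = np.linalg.lstsq(C, y, rcond=None)
        resid0 = y - C @ beta0
        rss_null = float(resid0 @ resid0)
    else:
        rss_null = float(y @ y)
    lod = float(_lod_from_rss(np.array(rss_null), np.array(rss_full), df1, df2))
    founder_coef = beta[-N_FOUNDERS:]
    centered = founder_coef - founder_coef.mean()
    return MarkerFit(lod, centered, rss_full, rss_null, df1, df2)


class FounderScanner:
    """Precomputed genome-scan engine for one (dosages, covariates) pair.

    Residualizes dosages against the covariates once, then evaluates the LOD
    profile for any number of phenotype vectors with a few matrix products
    (Frisch-Waugh projection); residual sums, and hence LODs, are identical to
    the direct per-marker fit.
    """

    def __init__(self, dosages: np.ndarray, covariates: np.ndarray):
        D = np.asarray(dosages, dtype=float)  # (n, M, 8)
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        n, n_markers, _ = D.shape
        self.n = n
        self.n_markers = n_markers
        self.Qc = _orth(C)
        self.rank_null = self.Qc.shape[1]

        flat = D.reshape(n, n_markers * N_FOUNDERS)
        flat_res = flat - self.Qc @ (self.Qc.T @ flat)
        D_res = flat_res.reshape(n, n_markers, N_FOUNDERS)

        self.Q = np.zeros((n_markers, n, N_FOUNDERS))
        self.df1 = np.zeros(n_markers)
        for m in range(n_markers):
            Qm = _orth(D_res[:, m, :])
            r = Qm.shape[1]
            if r == 0:
                raise ValueError(f"dosages at marker index {m} are fully aliased with covariates")
            self.Q[m, :, :r] = Qm
            self.df1[m] = r
        self.df2 = n - self.rank_null - self.df1
        if np.any(self.df2 <= 0):
            raise ValueError("not enough samples for the model rank")

    def _residualize(self, Y: np.ndarray) -> np.ndarray:
        return Y - self.Qc @ (self.Qc.T @ Y)

    def lod_matrix(self, Y: np.ndarray) -> np.ndarray:
        """LOD for each (marker, phenotype): Y is (n, P); result (M, P)."""
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        y_res = self._residualize(Y)
        rss_null = (y_res**2).sum(axis=0)  # (P,)
        proj = np.einsum("mnr,np->mrp", self.Q, y_res)
        rss_full = np.maximum(rss_null[None, :] - (proj**2).sum(axis=1), 0.0)
        return _lod_from_rss(
            np.broadcast_to(rss_null, rss_full.shape),
            rss_full,
            self.df1[:, None],
            self.df2[:, None],
        )

    def lod_profile(self, y: np.ndarray) -> np.ndarray:
        return self.lod_matrix(np.asarray(y, dtype=float)[:, None])[:, 0]


def scan_gene(
    y: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray,
    mmap: pd.DataFrame,
    scanner: FounderScanner | None = None,
) -> pd.DataFrame:
    """Full genome scan for one phenotype: per-marker LOD and founder coefficients.

    Returns a DataFrame aligned to the marker map with columns lod and
    coef_A..coef_H (centered to zero sum).
    """
    D = np.asarray(dosages, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if scanner is None:
        scanner = FounderScanner(D, C)
    lods = scanner.lod_profile(y)
    coefs = np.zeros((len(mmap), N_FOUNDERS))
    for m in range(len(mmap)):
        coefs[m] = fit_marker(y, D[:, m, :], C).coefficients
    out = mmap[["marker_id", "chrom", "pos_bp"]].copy()
    out["lod"] = lods
    for i, code in enumerate(FOUNDER_CODES):
        out[f"coef_{code}"] = coefs[:, i]
    return out


def permutation_maxima(
    y: np.ndarray,
    scanner: FounderScanner,
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """Genome-wide max LOD for ``n_perm`` permutations of the phenotype."""
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)  # (n, P)
    return scanner.lod_matrix(perms).max(axis=0)


def permutation_pvalue(
    y: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
    scanner: FounderScanner | None = None,
) -> float:
    """Genome-wide permutation p for the observed max LOD.

    p = (1 + #{permutation max >= observed max}) / (n_perm + 1), so p is never
    zero and lies on the grid {1/(n_perm+1), ..., 1}.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if scanner is None:
        scanner = FounderScanner(np.asarray(dosages, dtype=float), covariates)
    observed = scanner.lod_profile(y).max()
    maxima = permutation_maxima(y, scanner, n_perm, seed)
    return float((1 + np.sum(maxima >= observed)) / (n_perm + 1))


def _grid_pvalue(lod: float, maxima: np.ndarray) -> float:
    return float((1 + np.sum(maxima >= lod)) / (len(maxima) + 1))


def select_peaks(scan: pd.DataFrame, perm_maxima: np.ndarray) -> pd.DataFrame:
    """Candidate eQTLs for one gene: the global best marker, plus the best
    marker of every other chromosome whose genome-wide permutation p < 0.05.

    At most one candidate per chromosome.  The global best is always
    forwarded (with its p) even when not significant, so the across-genes FDR
    sees every gene once.
    """
    best_ix = int(scan["lod"].to_numpy().argmax())
    best_chrom = scan["chrom"].iloc[best_ix]
    rows = []
    for chrom, sub in scan.groupby("chrom", sort=False):
        ix = sub["lod"].to_numpy().argmax()
        row = sub.iloc[ix]
        p = _grid_pvalue(float(row["lod"]), perm_maxima)
        if chrom == best_chrom:
            rows.append({**row[["marker_id", "chrom", "pos_bp", "lod"]].to_dict(), "perm_p": p, "is_global_best": True})
        elif p < 0.05:
            rows.append({**row[["marker_id", "chrom", "pos_bp", "lod"]].to_dict(), "perm_p": p, "is_global_best": False})
    out = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp", "lod", "perm_p", "is_global_best"])
    return out.sort_values("lod", ascending=False).reset_index(drop=True)


def fdr_across_genes(perm_p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values across all candidate peaks of a dataset."""
    perm_p = np.asarray(perm_p, dtype=float)
    if perm_p.size == 0:
        raise ValueError("need at least one candidate")
    return multipletests(perm_p, method="fdr_bh")[1]


def bayes_credible_interval(
    positions: np.ndarray, lod: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Credible interval from the LOD^10 curve on one chromosome.

    The LOD profile is raised to the 10th power and converted to a density
    over base pairs by assigning each marker's weight to the bin between the
    midpoints to its neighbors (so a single-marker spike stays confined to
    its own bin and the interval degenerates to that marker, while a flat
    curve yields the exact central quantiles of the chromosome span).  The
    central ``level`` mass is returned as (start, end); the interval always
    contains a peak (max-LOD) marker.
    """
    positions = np.asarray(positions, dtype=float)
    lod = np.asarray(lod, dtype=float)
    if positions.size < 3:
        raise ValueError("need at least 3 markers on the chromosome")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    # rescale before the 10th power so extreme LODs cannot overflow
    top = lod.max()
    if top <= 0:
        warnings.warn("all-zero LOD curve; credible interval is the whole chromosome", stacklevel=2)
        return float(positions[0]), float(positions[-1])
    w = (lod / top) ** 10
    mid = (positions[:-1] + positions[1:]) / 2.0
    edges = np.concatenate([[positions[0]], mid, [positions[-1]]])
    mass = w * np.diff(edges)
    cum = np.concatenate([[0.0], np.cumsum(mass)])
    q = cum / cum[-1]
    lo = (1.0 - level) / 2.0
    hi = 1.0 - lo
    start = float(np.interp(lo, q, edges))
    end = float(np.interp(hi, q, edges))
    peaks = positions[lod == top]
    if not np.any((peaks >= start) & (peaks <= end)):
        nearest = peaks[np.argmin(np.minimum(np.abs(peaks - start), np.abs(peaks - end)))]
        start, end = min(start, nearest), max(end, nearest)
    return start, end


def assign_regulating_strain(coefficients: np.ndarray) -> tuple[str, str]:
    """Founder with the largest |centered coefficient| and its direction.

    Ties break to the lower-index founder with a warning; an all-zero vector
    is an error.
    """
    coefs = np.asarray(coefficients, dtype=float)
    if coefs.shape != (N_FOUNDERS,):
        raise ValueError("expected 8 founder coefficients")
    if not np.all(np.isfinite(coefs)):
        raise ValueError("coefficients must be finite")
    if np.all(coefs == 0):
        raise ValueError("all-zero coefficient vector has no regulating strain")
    mags = np.abs(coefs)
    winner = int(mags.argmax())
    if np.sum(mags == mags[winner]) > 1:
        warnings.warn("tied |coefficients|; choosing the lower-index founder", stacklevel=2)
    direction = "up" if coefs[winner] > 0 else "down"
    return FOUNDER_LABELS[winner], direction


def classify_cis_trans(
    ci_chrom: str,
    ci: tuple[float, float],
    gene_chrom: str,
    tss: int,
    tads: pd.DataFrame,
) -> str:
    """cis iff the credible interval overlaps (>= 1 bp) the TAD holding the TSS.

    A TSS falling in no TAD adopts the nearest TAD on its chromosome; a gene
    whose chromosome has no TADs, or whose interval is on another chromosome,
    is trans.
    """
    if str(ci_chrom) != str(gene_chrom):
        return "trans"
    sub = tads[tads["chrom"].astype(str) == str(gene_chrom)]
    if sub.empty:
        return "trans"
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    inside = (starts <= tss) & (tss <= ends)
    if inside.any():
        ix = int(np.argmax(inside))
    else:
        dist = np.where(tss < starts, starts - tss, np.where(tss > ends, tss - ends, 0))
        ix = int(dist.argmin())
    tad = (float(starts[ix]), float(ends[ix]))
    return "cis" if (ci[0] <= tad[1] and tad[0] <= ci[1]) else "trans"


def scan_dataset(
    expr: pd.DataFrame,
    dosages: np.ndarray,
    samples: list[str],
    mmap: pd.DataFrame,
    meta: pd.DataFrame,
    dataset: str = "all",
    n_perm: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
    gene_annot: pd.DataFrame | None = None,
    tads: pd.DataFrame | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Map eQTLs for every gene in one dataset (all / male / female livers).

    Per gene: rankZ-transform FPKM over the dataset's samples, scan all
    markers, permute for genome-wide significance, select per-chromosome
    peaks; then apply BH FDR across all candidates of the dataset and attach
    credible intervals, regulating strains, and cis/trans calls.

    Returns one row per candidate eQTL (the ``significant`` column marks
    q < 0.05).
    """
    X = design_matrix(meta, dataset)
    keep_samples = [s for s in X.index if s in set(expr.columns)]
    X = X.loc[keep_samples]
    row_of = {s: i for i, s in enumerate(samples)}
    rows = [row_of[s] for s in keep_samples]
    D = np.asarray(dosages, dtype=float)[rows]
    C = X.to_numpy()
    scanner = FounderScanner(D, C)

    gene_list = list(genes) if genes is not None else list(expr.index)
    records = []
    for gene in gene_list:
        y_raw = expr.loc[gene, keep_samples].to_numpy(dtype=float)
        if np.all(y_raw == y_raw[0]):
            logger.info("scan_dataset[%s]: gene %s has constant expression; skipped", dataset, gene)
            continue
        y = rankz_transform(y_raw)
        profile = mmap[["marker_id", "chrom", "pos_bp"]].copy()
        profile["lod"] = scanner.lod_profile(y)
        maxima = permutation_maxima(
            y, scanner, n_perm, child_seed(seed, f"perm:{dataset}:{gene}")
        )
        peaks = select_peaks(profile, maxima)
        for _, peak in peaks.iterrows():
            m_ix = int(mmap.index[mmap["marker_id"] == peak["marker_id"]][0])
            fit = fit_marker(y, D[:, m_ix, :], C)
            strain, direction = assign_regulating_strain(fit.coefficients)
            chrom_mask = (mmap["chrom"] == peak["chrom"]).to_numpy()
            ci = bayes_credible_interval(
                mmap.loc[chrom_mask, "pos_bp"].to_numpy(),
                profile.loc[chrom_mask, "lod"].to_numpy(),
                level=ci_level,
            )
            rec = {
                "gene_id": gene,
                "dataset": dataset,
                "marker_id": peak["marker_id"],
                "chrom": peak["chrom"],
                "pos_bp": int(peak["pos_bp"]),
                "lod": float(peak["lod"]),
                "perm_p": float(peak["perm_p"]),
                "regulating_strain": strain,
                "direction": direction,
                "ci_start": ci[0],
                "ci_end": ci[1],
            }
            for i, code in enumerate(FOUNDER_CODES):
                rec[f"coef_{code}"] = float(fit.coefficients[i])
            records.append(rec)

    result = pd.DataFrame(records)
    if result.empty:
        return result
    result["fdr_q"] = fdr_across_genes(result["perm_p"].to_numpy())
    result["significant"] = result["fdr_q"] < 0.05

    if gene_annot is not None and tads is not None:
        annot = gene_annot.set_index("gene_id")
        calls = []
        for _, rec in result.iterrows():
            if rec["gene_id"] not in annot.index:
                calls.append("NA")
                continue
            g = annot.loc[rec["gene_id"]]
            calls.append(
                classify_cis_trans(
                    rec["chrom"], (rec["ci_start"], rec["ci_end"]), g["chrom"], int(g["tss"]), tads
                )
            )
        result["cis_trans"] = calls
    else:
        result["cis_trans"] = "NA"
    logger.info(
        "scan_dataset[%s]: %d genes in, %d candidate eQTLs, %d significant",
        dataset,
        len(gene_list),
        len(result),
        int(result["significant"].sum()),
    )
    return result
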