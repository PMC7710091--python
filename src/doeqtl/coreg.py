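"""Co-regulated gene clusters from overlapping five-marker eQTL regions.

Each eQTL region is centered at its peak marker and bounded by the second
marker on either side (five markers in total, truncated at chromosome ends).
Regions with the same regulating strain on the same chromosome that overlap
by at least one bp join the same cluster (connected components of the
overlap graph, so a chain A-B-C clusters even when A and C do not touch).
Clusters are summarized by the intersection of member regions (flagged when
a chain makes it empty) and by the merged union of member credible
intervals, split into coefficient-sign subclusters, and tested for
enrichment of sex-specific genes against the expressed-gene universe with a
hypergeometric tail + BH correction.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import intervals_overlap, merge_intervals

__all__ = [
    "build_region",
    "cluster_regions",
    "summarize_cluster",
    "split_subclusters",
    "cluster_sex_enrichment",
    "expression_filter",
]


def build_region(peak_marker_id: str, mmap: pd.DataFrame) -> tuple[str, int, int]:
    """Five-marker region around a peak: (chrom, start_bp, end_bp).

    Spans from the marker two positions left of the peak to two positions
    right, by map order, truncated at chromosome ends.
    """
    hits = mmap.index[mmap["marker_id"] == peak_marker_id]
    if len(hits) == 0:
        raise KeyError(f"peak marker {peak_marker_id} absent from the map")
    ix = int(hits[0])
    chrom = mmap.at[ix, "chrom"]
    chrom_ix = mmap.index[mmap["chrom"] == chrom]
    lo_bound, hi_bound = int(chrom_ix.min()), int(chrom_ix.max())
    lo = max(ix - 2, lo_bound)
    hi = min(ix + 2, hi_bound)
    return str(chrom), int(mmap.at[lo, "pos_bp"]), int(mmap.at[hi, "pos_bp"])


def expression_filter(expr: pd.DataFrame, min_fraction: float = 0.25) -> pd.Index:
    """Genes expressed (FPKM > 0) in at least ``min_fraction`` of samples."""
    frac = (expr.to_numpy() > 0).mean(axis=1)
    return expr.index[frac >= min_fraction]


def cluster_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Assign each eQTL region to a co-regulated cluster.

    ``regions`` has one row per eQTL with columns eqtl_id, gene_id, chrom,
    start, end, regulating_strain.  Edges connect same-strain,
    same-chromosome regions overlapping >= 1 bp; clusters are the connected
    components (singletons included).  Returns the input with a cluster_id
    column; cluster ids are deterministic in input order.
    """
    g = nx.Graph()
    g.add_nodes_from(regions.index)
    by_key: dict[tuple[str, str], list[int]] = {}
    for ix, row in regions.iterrows():
        by_key.setdefault((row["regulating_strain"], str(row["chrom"])), []).append(ix)
    for members in by_key.values():
        for i, a in enumerate(members):
            ra = (regions.at[a, "start"], regions.at[a, "end"])
            for b in members[i + 1 :]:
                rb = (regions.at[b, "start"], regions.at[b, "end"])
                if intervals_overlap(ra, rb):
                    g.add_edge(a, b)
    out = regions.copy()
    cluster_of: dict[int, int] = {}
    next_id = 1
    for ix in regions.index:  # deterministic order
        if ix in cluster_of:
            continue
        for member in nx.node_connected_component(g, ix):
            cluster_of[member] = next_id
        next_id += 1
    out["cluster_id"] = [f"cluster{cluster_of[ix]}" for ix in regions.index]
    return out


def summarize_cluster(
    members: pd.DataFrame, credible_intervals: pd.DataFrame | None = None
) -> dict:
    """Intersection of member five-marker regions and union of credible intervals.

    The intersection may be empty for overlap chains whose ends do not
    mutually overlap; it is then flagged.  ``credible_intervals`` (optional)
    has columns eqtl_id, start, end for the members.
    """
    if members.empty:
        raise ValueError("cluster has no members")
    start = int(members["start"].max())
    end = int(members["end"].min())
    summary = {
        "chrom": str(members["chrom"].iloc[0]),
        "n_members": len(members),
        "intersection": (start, end) if start <= end else None,
        "intersection_empty": start > end,
        "multi_chromosome": False,
        "union_ci": None,
    }
    if "gene_chrom" in members.columns:
        summary["multi_chromosome"] = members["gene_chrom"].astype(str).nunique() > 1
    if credible_intervals is not None:
        wanted = credible_intervals[credible_intervals["eqtl_id"].isin(members["eqtl_id"])]
        summary["union_ci"] = merge_intervals(
            [(int(r["start"]), int(r["end"])) for _, r in wanted.iterrows()]
        )
    return summary


def split_subclusters(
    members: pd.DataFrame, centered_expr: pd.DataFrame | None = None
) -> dict:
    """Partition cluster members by the sign of the regulating-strain coefficient.

    When batch-centered log expression is supplied, within- and
    cross-subcluster pairwise Pearson correlation matrices are computed over
    the member genes.
    """
    if "coef_sign" not in members.columns:
        raise ValueError("members need a coef_sign column (+/-)")
    pos = members[members["coef_sign"] == "+"]
    neg = members[members["coef_sign"] == "-"]
    result: dict = {
        "positive": list(pos["gene_id"]),
        "negative": list(neg["gene_id"]),
    }
    if centered_expr is not None:
        genes = [g for g in members["gene_id"] if g in centered_expr.index]
        if len(genes) >= 2:
            corr = np.corrcoef(centered_expr.loc[genes].to_numpy())
            corr_df = pd.DataFrame(corr, index=genes, columns=genes)
            result["correlation"] = corr_df

            def _mean_offdiag(rows: list[str], cols: list[str], same: bool) -> float:
                sub = corr_df.loc[[g for g in rows if g in genes], [g for g in cols if g in genes]]
                if sub.size == 0:
                    return float("nan")
                vals = sub.to_numpy()
                if same:
                    iu = np.triu_indices_from(vals, k=1)
                    return float(vals[iu].mean()) if iu[0].size else float("nan")
                return float(vals.mean())

            result["within_corr"] = np.nanmean(
                [
                    _mean_offdiag(list(pos["gene_id"]), list(pos["gene_id"]), True),
                    _mean_offdiag(list(neg["gene_id"]), list(neg["gene_id"]), True),
                ]
            )
            result["cross_corr"] = _mean_offdiag(list(pos["gene_id"]), list(neg["gene_id"]), False)
    return result


def cluster_sex_enrichment(
    clusters: pd.DataFrame,
    sex_specific_genes: set[str],
    universe_size: int,
) -> pd.DataFrame:
    """Hypergeometric enrichment of sex-specific genes per cluster, BH-corrected.

    For a cluster of n genes containing k sex-specific ones, p is the upper
    hypergeometric tail P(X >= k) drawing n from a universe of
    ``universe_size`` genes of which ``len(sex_specific_genes)`` are
    sex-specific.  Singleton clusters are excluded.
    """
    n_specific = len(sex_specific_genes)
    rows = []
    for cluster_id, members in clusters.groupby("cluster_id", sort=False):
        n = members["gene_id"].nunique()
        if n < 2:
            continue
        if universe_size < n:
            raise ValueError("universe smaller than cluster")
        k = sum(1 for g in set(members["gene_id"]) if g in sex_specific_genes)
        p = float(stats.hypergeom.sf(k - 1, universe_size, n_specific, n))
        rows.append({"cluster_id": cluster_id, "n_genes": n, "n_sex_specific": k, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
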