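"""Five-marker regions, overlap clustering, summaries, and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from doeqtl import coreg
from doeqtl.coreg import (
    build_region,
    cluster_regions,
    cluster_sex_enrichment,
    expression_filter,
    split_subclusters,
    summarize_cluster,
)

from conftest import toy_marker_map


def union_find_oracle(regions: pd.DataFrame) -> list[set]:
    """Brute-force connected components via union-find over pairwise overlaps."""
    parent = list(range(len(regions)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    rows = regions.reset_index(drop=True)
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows.iloc[i], rows.iloc[j]
            if (
                a["regulating_strain"] == b["regulating_strain"]
                and a["chrom"] == b["chrom"]
                and a["start"] <= b["end"]
                and b["start"] <= a["end"]
            ):
                union(i, j)
    groups: dict[int, set] = {}
    for i in range(len(rows)):
        groups.setdefault(find(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=min)


def _regions(rows):
    return pd.DataFrame(
        rows, columns=["eqtl_id", "gene_id", "chrom", "start", "end", "regulating_strain"]
    )


class TestBuildRegion:
    def _map(self):
        return toy_marker_map({"1": [i * 1000 for i in range(1, 12)]})

    def test_interior_peak_spans_five_markers(self):
        mmap = self._map()
        chrom, start, end = build_region("m5", mmap)  # 6th marker of 11
        inside = mmap[(mmap["pos_bp"] >= start) & (mmap["pos_bp"] <= end)]
        assert len(inside) == 5
        assert start == 4000 and end == 8000

    def test_peak_at_chromosome_start_truncates_to_three(self):
        mmap = self._map()
        chrom, start, end = build_region("m0", mmap)
        inside = mmap[(mmap["pos_bp"] >= start) & (mmap["pos_bp"] <= end)]
        assert len(inside) == 3
        assert start == 1000

    def test_denser_map_gives_narrower_region(self):
        sparse = toy_marker_map({"1": [i * 10_000 for i in range(1, 12)]})
        dense = toy_marker_map({"1": [i * 1000 for i in range(1, 12)]})
        _, s1, e1 = build_region("m5", sparse)
        _, s2, e2 = build_region("m5", dense)
        assert (e2 - s2) < (e1 - s1)

    def test_missing_peak_is_an_error(self):
        with pytest.raises(KeyError, match="absent"):
            build_region("nope", self._map())


class TestClustering:
    def test_same_strain_overlap_joins_one_cluster(self):
        out = cluster_regions(
            _regions(
                [
                    ["e1", "g1", "1", 1000, 5000, "CAST/EiJ"],
                    ["e2", "g2", "1", 4000, 8000, "CAST/EiJ"],
                ]
            )
        )
        assert out["cluster_id"].nunique() == 1

    def test_different_strains_stay_apart_despite_overlap(self):
        out = cluster_regions(
            _regions(
                [
                    ["e1", "g1", "1", 1000, 5000, "CAST/EiJ"],
                    ["e2", "g2", "1", 4000, 8000, "PWK/PhJ"],
                ]
            )
        )
        assert out["cluster_id"].nunique() == 2

    def test_chain_is_transitive(self):
        out = cluster_regions(
            _regions(
                [
                    ["e1", "g1", "1", 1000, 5000, "CAST/EiJ"],
                    ["e2", "g2", "1", 4000, 8000, "CAST/EiJ"],
                    ["e3", "g3", "1", 7000, 10_000, "CAST/EiJ"],
                ]
            )
        )
        assert out["cluster_id"].nunique() == 1

    def test_matches_union_find_oracle_on_random_inputs(self, rng):
        strains = ["CAST/EiJ", "PWK/PhJ", "A/J"]
        for trial in range(20):
            n = 50
            starts = rng.integers(0, 200_000, size=n)
            rows = [
                [
                    f"e{i}",
                    f"g{i}",
                    str(rng.integers(1, 3)),
                    int(starts[i]),
                    int(starts[i] + rng.integers(1000, 30_000)),
                    strains[rng.integers(len(strains))],
                ]
                for i in range(n)
            ]
            regions = _regions(rows)
            out = cluster_regions(regions)
            ours = sorted(
                (frozenset(np.flatnonzero((out["cluster_id"] == c).to_numpy()))
                 for c in out["cluster_id"].unique()),
                key=min,
            )
            assert ours == union_find_oracle(regions)

    def test_partition_is_input_order_invariant(self, rng):
        rows = [
            ["e1", "g1", "1", 1000, 5000, "CAST/EiJ"],
            ["e2", "g2", "1", 4000, 8000, "CAST/EiJ"],
            ["e3", "g3", "2", 1000, 2000, "CAST/EiJ"],
            ["e4", "g4", "1", 9000, 9500, "PWK/PhJ"],
        ]
        a = cluster_regions(_regions(rows))
        b = cluster_regions(_regions(rows[::-1]))
        part_a = {frozenset(g["eqtl_id"]) for _, g in a.groupby("cluster_id")}
        part_b = {frozenset(g["eqtl_id"]) for _, g in b.groupby("cluster_id")}
        assert part_a == part_b


class TestSummaries:
    def test_pairwise_overlap_intersection(self):
        members = _regions(
            [
                ["e1", "g1", "1", 1000, 5000, "CAST/EiJ"],
                ["e2", "g2", "1", 4000, 8000, "CAST/EiJ"],
            ]
        )
        s = summarize_cluster(members)
        assert s["intersection"] == (4000, 5000)
        assert not s["intersection_empty"]

    def test_chain_with_empty_intersection_is_flagged(self):
        members = _regions(
            [
                ["e1", "g1", "1", 1000, 5000, "CAST/EiJ"],
                ["e2", "g2", "1", 4000, 8000, "CAST/EiJ"],
                ["e3", "g3", "1", 7000, 10_000, "CAST/EiJ"],
            ]
        )
        s = summarize_cluster(members)
        assert s["intersection_empty"]
        assert s["intersection"] is None

    def test_singleton_summaries_equal_member_region(self):
        members = _regions([["e1", "g1", "1", 1000, 5000, "CAST/EiJ"]])
        ci = pd.DataFrame({"eqtl_id": ["e1"], "start": [500], "end": [6000]})
        s = summarize_cluster(members, ci)
        assert s["intersection"] == (1000, 5000)
        assert s["union_ci"] == [(500, 6000)]

    def test_union_of_credible_intervals_merges_overlaps(self):
        members = _regions(
            [
                ["e1", "g1", "1", 1000, 5000, "CAST/EiJ"],
                ["e2", "g2", "1", 4000, 8000, "CAST/EiJ"],
            ]
        )
        ci = pd.DataFrame(
            {"eqtl_id": ["e1", "e2"], "start": [500, 4500], "end": [5000, 9000]}
        )
        assert summarize_cluster(members, ci)["union_ci"] == [(500, 9000)]

    def test_multi_chromosome_flag_follows_gene_chromosomes(self):
        members = _regions(
            [
                ["e1", "g1", "1", 1000, 5000, "CAST/EiJ"],
                ["e2", "g2", "1", 4000, 8000, "CAST/EiJ"],
            ]
        )
        members["gene_chrom"] = ["1", "7"]
        assert summarize_cluster(members)["multi_chromosome"]


class TestSubclusters:
    def test_all_positive_signs_one_subcluster(self):
        members = _regions([["e1", "g1", "1", 1, 2, "CAST/EiJ"], ["e2", "g2", "1", 1, 2, "CAST/EiJ"]])
        members["coef_sign"] = ["+", "+"]
        out = split_subclusters(members)
        assert out["positive"] == ["g1", "g2"] and out["negative"] == []

    def test_eleven_ten_split(self):
        rows = [[f"e{i}", f"g{i}", "2", 1, 2, "PWK/PhJ"] for i in range(21)]
        members = _regions(rows)
        members["coef_sign"] = ["+"] * 11 + ["-"] * 10
        out = split_subclusters(members)
        assert len(out["positive"]) == 11 and len(out["negative"]) == 10

    def test_opposite_sign_cluster_separates_in_correlation(self, rng):
        # one latent driver, half the genes loaded positively, half negatively
        hits = 0
        for trial in range(10):
            n = 120
            latent = rng.normal(size=n)
            genes, names, signs = [], [], []
            for i in range(6):
                sign = 1.0 if i < 3 else -1.0
                genes.append(sign * latent + 0.8 * rng.normal(size=n))
                names.append(f"g{i}")
                signs.append("+" if sign > 0 else "-")
            expr = pd.DataFrame(genes, index=names, columns=[f"s{i}" for i in range(n)])
            members = _regions([[f"e{i}", f"g{i}", "1", 1, 2, "CAST/EiJ"] for i in range(6)])
            members["coef_sign"] = signs
            out = split_subclusters(members, centered_expr=expr)
            hits += out["within_corr"] > out["cross_corr"]
        assert hits >= 9


class TestEnrichment:
    def _clusters(self, sizes):
        rows = []
        g = 0
        for ci, size in enumerate(sizes):
            for _ in range(size):
                rows.append({"cluster_id": f"c{ci}", "gene_id": f"g{g}"})
                g += 1
        return pd.DataFrame(rows)

    def test_all_sex_specific_cluster_matches_direct_hypergeometric(self):
        clusters = self._clusters([5])
        specific = {f"g{i}" for i in range(5)}
        # universe of 1000 genes, 100 sex-specific
        out = cluster_sex_enrichment(clusters, specific | {f"x{i}" for i in range(95)}, 1000)
        expected = stats.hypergeom.sf(4, 1000, 100, 5)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert out["p"].iloc[0] < 1e-4

    def test_no_sex_specific_genes_gives_p_one(self):
        out = cluster_sex_enrichment(self._clusters([4]), {"other"}, 100)
        assert out["p"].iloc[0] == 1.0

    def test_cluster_at_universe_rate_is_unremarkable(self):
        clusters = self._clusters([10])
        specific = {f"g{i}" for i in range(1)} | {f"x{i}" for i in range(99)}
        out = cluster_sex_enrichment(clusters, specific, 1000)  # 10% universe rate
        assert out["p"].iloc[0] > 0.5

    def test_singletons_are_excluded(self):
        out = cluster_sex_enrichment(self._clusters([1, 3]), {"g0"}, 100)
        assert list(out["cluster_id"]) == ["c1"]

    def test_universe_smaller_than_cluster_is_an_error(self):
        with pytest.raises(ValueError, match="universe"):
            cluster_sex_enrichment(self._clusters([5]), set(), 3)


def test_expression_filter_quarter_rule():
    expr = pd.DataFrame(
        {
            "s1": [1.0, 0.0, 0.0, 0.0],
            "s2": [1.0, 1.0, 0.0, 0.0],
            "s3": [1.0, 0.0, 0.0, 1.0],
            "s4": [1.0, 0.0, 0.0, 1.0],
        },
        index=["always", "quarter", "never", "half"],
    )
    kept = expression_filter(expr, 0.25)
    assert list(kept) == ["always", "quarter", "half"]
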