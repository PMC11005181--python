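import numpy as np
import pandas as pd
import pytest

from chromlink import linking as lk
from chromlink import regions as rg
from chromlink.expression import classify_genes


def genes_df(rows):
    """rows: gene_id -> (chrom, tss[, strand[, ge]])"""
    recs = []
    for gid, vals in rows.items():
        chrom, tss = vals[0], vals[1]
        strand = vals[2] if len(vals) > 2 else "+"
        ge = vals[3] if len(vals) > 3 else 1.0
        recs.append(
            {"gene_id": gid, "chrom": chrom, "strand": strand, "tss": tss, "ge": ge}
        )
    return pd.DataFrame(recs)


def regions_df(centres, chrom="chr1", width=100):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [c - width // 2 for c in centres],
            "end": [c + width // 2 for c in centres],
        }
    )


def tads_df(rows):
    return pd.DataFrame(rows, columns=["tad_id", "chrom", "start", "end"])


class TestAccessibilityIndexProfile:
    def test_single_gene_single_region(self):
        genes = genes_df({"g": ("chr1", 100_000)})
        regions = regions_df([103_000])  # bin [0, 5000) downstream
        prof = lk.accessibility_index_profile(regions, genes, genes, 20_000, 5_000)
        hit = prof[(prof["bin_left"] == 0)]
        assert hit["index"].iloc[0] == pytest.approx(1.0)
        assert prof["index"].sum() == pytest.approx(1.0)

    def test_adding_empty_focal_gene_halves_profile(self):
        genes = genes_df({"g": ("chr1", 100_000)})
        regions = regions_df([103_000])
        both = genes_df({"g": ("chr1", 100_000), "g2": ("chr2", 100_000)})
        prof1 = lk.accessibility_index_profile(regions, genes, both, 20_000, 5_000)
        prof2 = lk.accessibility_index_profile(regions, both, both, 20_000, 5_000)
        assert prof2["index"].sum() == pytest.approx(prof1["index"].sum() / 2)

    def test_strand_orientation_flips_bins(self):
        plus = genes_df({"g": ("chr1", 100_000, "+")})
        minus = genes_df({"g": ("chr1", 100_000, "-")})
        regions = regions_df([103_000])
        p_plus = lk.accessibility_index_profile(regions, plus, plus, 20_000, 5_000)
        p_minus = lk.accessibility_index_profile(regions, minus, minus, 20_000, 5_000)
        assert p_plus.loc[p_plus["bin_left"] == 0, "index"].iloc[0] == 1.0
        assert p_minus.loc[p_minus["bin_left"] == -5_000, "index"].iloc[0] == 1.0

    def test_matches_brute_force_tally(self, small_dataset):
        ds = small_dataset
        classes = classify_genes(ds["expression"])
        ann = ds["annotation"].merge(ds["expression"], on="gene_id")
        focal = ann[ann["gene_id"].isin(
            classes.loc[classes["class_label"] == "DEG_ect", "gene_id"]
        )]
        expressed = ann[ann[["GE_ect", "GE_end", "GE_mes"]].max(axis=1) > 0]
        regions = ds["acc_windows"][["chrom", "start", "end"]]
        V, binw = 50_000, 5_000
        prof = lk.accessibility_index_profile(regions, focal, expressed, V, binw)

        edges = np.arange(-V, V + 1, binw)
        acc = np.zeros(len(edges) - 1)
        used = 0
        centres = regions.assign(c=(regions["start"] + regions["end"]) // 2)
        for g in focal.itertuples():
            ng = (
                (expressed["chrom"] == g.chrom)
                & (expressed["tss"] >= g.tss - V)
                & (expressed["tss"] <= g.tss + V)
            ).sum()
            if ng == 0:
                continue
            used += 1
            sub = centres[centres["chrom"] == g.chrom]
            rel = (sub["c"] - g.tss) if g.strand == "+" else (g.tss - sub["c"])
            counts, _ = np.histogram(rel, bins=edges)
            acc += counts / ng
        oracle = acc / used
        assert np.allclose(prof["index"].to_numpy(), oracle)

    def test_bin_wider_than_vicinity_rejected(self):
        genes = genes_df({"g": ("chr1", 0)})
        with pytest.raises(ValueError):
            lk.accessibility_index_profile(regions_df([0]), genes, genes, 1_000, 5_000)


class TestCac:
    def test_perfectly_proportional_groups(self):
        # three isolated genes with 1, 2, 3 regions and GE 3, 6, 9
        genes = genes_df(
            {
                "a": ("chr1", 1_000_000, "+", 3.0),
                "b": ("chr1", 3_000_000, "+", 6.0),
                "c": ("chr1", 5_000_000, "+", 9.0),
            }
        )
        centres = [1_000_100] + [3_000_100, 3_001_000] + [5_000_100, 5_001_000, 5_002_000]
        res = lk.cac(genes, regions_df(centres), 10_000)
        assert res.defined and res.r == pytest.approx(1.0)

    def test_constant_frequency_is_degenerate(self):
        genes = genes_df(
            {f"g{i}": ("chr1", 1_000_000 * (i + 1), "+", float(i)) for i in range(5)}
        )
        centres = [1_000_000 * (i + 1) + 100 for i in range(5)]
        res = lk.cac(genes, regions_df(centres), 10_000)
        assert not res.defined

    def test_gene_order_and_ge_scaling_invariance(self):
        rng = np.random.default_rng(4)
        genes, regions = _benchmark(seed=4)
        base = lk.cac(genes, regions, 100_000)
        shuffled = genes.sample(frac=1, random_state=1).reset_index(drop=True)
        assert lk.cac(shuffled, regions, 100_000).r == pytest.approx(base.r)
        scaled = genes.assign(ge=genes["ge"] * 7.5)
        assert lk.cac(scaled, regions, 100_000).r == pytest.approx(base.r)


def _benchmark(seed=0, **kw):
    from chromlink.simulate import simulate_cac_benchmark

    return simulate_cac_benchmark(seed=seed, **kw)


GRID = [20_000, 40_000, 80_000, 120_000, 160_000, 200_000, 300_000, 400_000]


class TestZoneScan:
    def test_single_grid_value_is_returned(self):
        genes, regions = _benchmark(seed=2)
        scan = lk.zone_scan(genes, regions, [100_000])
        assert scan["zstar"] == 100_000

    def test_unrelated_regions_give_weak_correlation(self, rng):
        genes, _ = _benchmark(seed=5)
        random_regions = regions_df(sorted(rng.integers(0, 50_000_000, size=5000)))
        scan = lk.zone_scan(genes, random_regions, GRID)
        assert scan["max_r"] < 0.5

    def test_planted_zone_recovered_across_seeds(self):
        hits = 0
        for seed in range(10):
            genes, regions = _benchmark(seed=seed)
            scan = lk.zone_scan(genes, regions, GRID)
            if 100_000 / 1.5 <= scan["zstar"] <= 1.5 * 100_000:
                hits += 1
        assert hits >= 8

    def test_peak_association_is_zone_scan_on_peaks(self):
        genes, regions = _benchmark(seed=1)
        scan_r = lk.zone_scan(genes, regions, GRID)
        scan_p = lk.peak_association(genes, regions, GRID)
        assert [c.r for c in scan_p["curve"]] == [c.r for c in scan_r["curve"]]

    def test_empty_peak_set_rejected(self):
        genes, _ = _benchmark(seed=1)
        with pytest.raises(ValueError):
            lk.peak_association(genes, regions_df([]), GRID)


class TestLinkRegions:
    def test_link_within_zone_and_tad(self):
        genes = genes_df({"g": ("chr1", 100_000)})
        tads = tads_df([("t0", "chr1", 0, 200_000)])
        links = lk.link_regions(genes, regions_df([150_000]), tads, 80_000)
        assert len(links) == 1
        assert links.loc[0, "distance"] == 50_000
        assert links.loc[0, "tad_id"] == "t0"

    def test_tad_boundary_breaks_link(self):
        genes = genes_df({"g": ("chr1", 100_000)})
        tads = tads_df([("t0", "chr1", 0, 120_000), ("t1", "chr1", 120_000, 300_000)])
        links = lk.link_regions(genes, regions_df([150_000]), tads, 80_000)
        assert len(links) == 0

    def test_distance_beyond_zone_excluded(self):
        genes = genes_df({"g": ("chr1", 100_000)})
        tads = tads_df([("t0", "chr1", 0, 300_000)])
        links = lk.link_regions(genes, regions_df([185_000]), tads, 80_000)
        assert len(links) == 0

    def test_minus_strand_distance_sign(self):
        genes = genes_df({"g": ("chr1", 100_000, "-")})
        tads = tads_df([("t0", "chr1", 0, 200_000)])
        links = lk.link_regions(genes, regions_df([150_000]), tads, 80_000)
        assert links.loc[0, "distance"] == -50_000

    def test_missing_tads_rejected(self):
        genes = genes_df({"g": ("chr1", 100_000)})
        with pytest.raises(ValueError, match="TAD"):
            lk.link_regions(genes, regions_df([150_000]), tads_df([]), 80_000)

    def test_catalogue_equals_brute_force_oracle(self, small_dataset):
        ds = small_dataset
        passed, _ = rg.qc_filter(ds["acc_windows"])
        called = rg.call_accessibility_regions(passed)
        dars = called[called["region_class"] == "DAR"].reset_index(drop=True)
        genes = ds["annotation"]
        zstar = 80_000
        links = lk.link_regions(genes, dars, ds["tads"], zstar)

        def tad_of(chrom, pos):
            hit = ds["tads"][
                (ds["tads"]["chrom"] == chrom)
                & (ds["tads"]["start"] <= pos)
                & (pos < ds["tads"]["end"])
            ]
            return hit["tad_id"].iloc[0] if len(hit) else None

        expected = set()
        for g in genes.itertuples():
            tg = tad_of(g.chrom, g.tss)
            if tg is None:
                continue
            for r in dars.itertuples():
                centre = (r.start + r.end) // 2
                if r.chrom != g.chrom or abs(centre - g.tss) > zstar:
                    continue
                if tad_of(r.chrom, centre) == tg:
                    expected.add((g.gene_id, r.chrom, r.start, r.end))
        got = set(zip(links["gene_id"], links["chrom"], links["start"], links["end"]))
        assert got == expected

    def test_planted_links_stay_mostly_proximal(self, dataset):
        ds = dataset
        classes = classify_genes(ds["expression"])
        ann = ds["annotation"].merge(ds["expression"], on="gene_id")
        focal = ann[ann["gene_id"].isin(
            classes.loc[classes["class_label"].str.startswith("DEG"), "gene_id"]
        )]
        passed, _ = rg.qc_filter(ds["acc_windows"])
        called = rg.call_accessibility_regions(passed)
        dars = called[called["region_class"] == "DAR"]
        links = lk.link_regions(focal, dars, ds["tads"], 120_000)
        summary = lk.link_summary(links)
        assert summary["n_links"] > 0
        assert summary["fraction_beyond_100kb"] < 0.5
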