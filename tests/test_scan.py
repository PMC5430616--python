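import gzip

import numpy as np
import pytest

from admixscan import (
    SnpRecord,
    hotelling_two_sample,
    scan_lsbl,
    scan_pairwise,
    top_regions,
    treemix_counts,
    write_treemix,
)
from admixscan.scan import regions_to_bed

# Published per-SNP values for the Amerindian-branch scan: the ten most
# differentiated loci with their component A1 frequencies (Eur, Amr, Afr)
# and the branch Fst computed from them.
AMR_BRANCH_TOP10 = [
    # chrom, id, pos, a1, a2, f_eur, f_amr, f_afr, fst
    ("16", "rs6498115", 10965511, "T", "C", 0.000, 0.908, 0.000, 0.908),
    ("2", "rs1834619", 17901485, "A", "G", 0.041, 0.942, 0.000, 0.899),
    ("16", "rs77979769", 11343560, "A", "G", 0.073, 0.949, 0.035, 0.883),
    ("2", "rs2288697", 23860168, "A", "G", 0.029, 0.906, 0.018, 0.877),
    ("16", "rs35346036", 10951098, "G", "A", 0.065, 0.957, 0.088, 0.872),
    ("16", "rs2021760", 11343992, "G", "A", 0.076, 0.947, 0.065, 0.869),
    ("16", "rs45601437", 10989754, "A", "G", 0.006, 0.912, 0.050, 0.862),
    ("16", "rs2866065", 75822042, "A", "G", 0.075, 0.929, 0.000, 0.849),
    ("16", "rs8054781", 11384776, "C", "T", 0.026, 0.932, 0.092, 0.846),
    ("15", "rs16964480", 37284909, "G", "T", 0.000, 0.837, 0.000, 0.837),
]

# The ten loci most differentiated between the Amerindian component and the
# closest Asian reference population (Bengali), with the two frequencies
# entering the pairwise statistic.
AMR_VS_BEB_TOP10 = [
    # chrom, id, pos, f_amr, f_beb, fst
    ("3", "rs7631391", 64514393, 0.950, 0.058, 0.885),
    ("5", "rs77594147", 169155975, 0.878, 0.017, 0.857),
    ("5", "rs73318286", 169162708, 0.879, 0.029, 0.843),
    ("15", "rs28649017", 85438991, 0.150, 0.983, 0.827),
    ("14", "rs7151991", 32635572, 0.950, 0.116, 0.821),
    ("16", "rs45601437", 10989754, 0.912, 0.081, 0.816),
    ("16", "rs6498115", 10965511, 0.908, 0.081, 0.811),
    ("20", "rs6088519", 33132191, 0.966, 0.163, 0.791),
    ("2", "rs4666032", 28254769, 0.827, 0.029, 0.788),
    ("22", "rs117487308", 41195082, 0.786, 0.000, 0.786),
]


def _branch_inputs():
    snps = [
        SnpRecord(rid, chrom, pos, a1, a2)
        for chrom, rid, pos, a1, a2, *_ in AMR_BRANCH_TOP10
    ]
    P = np.array([
        [r[5] for r in AMR_BRANCH_TOP10],
        [r[6] for r in AMR_BRANCH_TOP10],
        [r[7] for r in AMR_BRANCH_TOP10],
    ])
    return P, snps


class TestScanLsbl:
    def test_reproduces_published_branch_values(self):
        P, snps = _branch_inputs()
        table = scan_lsbl(P, snps, focal=1).table.set_index("id")
        for chrom, rid, pos, a1, a2, fe, fm, fa, fst in AMR_BRANCH_TOP10:
            assert round(table.at[rid, "stat"], 3) == pytest.approx(fst)

    def test_published_rows_rank_in_printed_order(self):
        P, snps = _branch_inputs()
        table = scan_lsbl(P, snps, focal=1).table.sort_values("rank")
        assert list(table["id"]) == [r[1] for r in AMR_BRANCH_TOP10]

    def test_identical_components_give_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 30)
        P = np.tile(p, (3, 1))
        snps = [SnpRecord(f"rs{j}", "1", j + 1, "A", "G") for j in range(30)]
        table = scan_lsbl(P, snps, focal=1)
        np.testing.assert_allclose(table.table["stat"], 0.0, atol=1e-12)
        assert table.summary["mean"] == pytest.approx(0.0, abs=1e-12)

    def test_summary_statistics_match_numpy(self):
        P, snps = _branch_inputs()
        result = scan_lsbl(P, snps, focal=1)
        stats = result.table["stat"].to_numpy()
        assert result.summary["median"] == pytest.approx(np.median(stats))
        assert result.summary["p75"] == pytest.approx(np.percentile(stats, 75))


class TestScanPairwise:
    def test_reproduces_published_pairwise_values(self):
        snps = [
            SnpRecord(rid, chrom, pos, "A", "G")
            for chrom, rid, pos, *_ in AMR_VS_BEB_TOP10
        ]
        f_amr = np.array([r[3] for r in AMR_VS_BEB_TOP10])
        f_beb = np.array([r[4] for r in AMR_VS_BEB_TOP10])
        table = scan_pairwise(f_amr, f_beb, snps, comp_name="beb").table.set_index("id")
        # the two loci whose printed frequencies reproduce the statistic to
        # the printed precision; the rest carry +-0.002 rounding slack from
        # the 3-decimal frequency columns
        assert round(table.at["rs117487308", "stat"], 3) == pytest.approx(0.786)
        assert round(table.at["rs4666032", "stat"], 3) == pytest.approx(0.788)
        for chrom, rid, pos, fm, fb, fst in AMR_VS_BEB_TOP10:
            assert table.at[rid, "stat"] == pytest.approx(fst, abs=2e-3)

    def test_reproduces_panasian_panel_value(self):
        # Amerindian component vs the Italian reference panel at the top
        # second-scan locus
        snps = [SnpRecord("rs77594147", "5", 169155975, "G", "A")]
        table = scan_pairwise(np.array([0.878]), np.array([0.042]), snps, comp_name="tsi")
        assert round(table.table["stat"].iloc[0], 3) == pytest.approx(0.826)

    def test_identical_vectors_all_zero(self):
        p = np.linspace(0.1, 0.9, 9)
        snps = [SnpRecord(f"rs{j}", "1", j + 1, "A", "G") for j in range(9)]
        table = scan_pairwise(p, p.copy(), snps)
        np.testing.assert_allclose(table.table["stat"], 0.0)

    def test_sample_mode_requires_counts_and_allows_negative(self):
        snps = [SnpRecord("rs1", "1", 1, "A", "G")]
        with pytest.raises(ValueError, match="counts"):
            scan_pairwise(np.array([0.5]), np.array([0.5]), snps, mode="sample")
        table = scan_pairwise(
            np.array([0.5]), np.array([0.5]), snps, mode="sample",
            n_focal=np.array([100]), n_comp=np.array([100]),
        )
        assert table.table["stat"].iloc[0] < 0


class TestTopRegions:
    def test_branch_top10_groups_into_five_regions(self):
        P, snps = _branch_inputs()
        table = scan_lsbl(P, snps, focal=1)
        regions = top_regions(table, k=10, merge_bp=1_000_000)
        assert len(regions) == 5

    def test_pairwise_top10_groups_into_eight_regions(self):
        snps = [
            SnpRecord(rid, chrom, pos, "A", "G")
            for chrom, rid, pos, *_ in AMR_VS_BEB_TOP10
        ]
        f_amr = np.array([r[3] for r in AMR_VS_BEB_TOP10])
        f_beb = np.array([r[4] for r in AMR_VS_BEB_TOP10])
        table = scan_pairwise(f_amr, f_beb, snps, comp_name="beb")
        regions = top_regions(table, k=10, merge_bp=1_000_000)
        assert len(regions) == 8

    def test_k1_single_region_single_snp(self):
        P, snps = _branch_inputs()
        table = scan_lsbl(P, snps, focal=1)
        regions = top_regions(table, k=1)
        assert len(regions) == 1 and len(regions[0].snp_ids) == 1
        assert regions[0].snp_ids[0] == "rs6498115"

    def test_bed_export_is_zero_based_half_open(self):
        P, snps = _branch_inputs()
        regions = top_regions(scan_lsbl(P, snps, focal=1), k=1)
        bed = regions_to_bed(regions)
        assert bed.loc[0, "start"] == regions[0].start_bp - 1
        assert bed.loc[0, "end"] == regions[0].end_bp


class TestHotelling:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(1)
        Q = rng.dirichlet(np.ones(3), size=40)
        res = hotelling_two_sample(Q, Q.copy())
        assert res.t2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_power_for_shifted_ancestry_mean(self):
        # a 0.10 shift in mean focal ancestry at n=100/group, sd 0.1, should
        # be detected at the 0.05/15 multiple-testing level essentially always
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(20):
            a = np.clip(rng.normal([0.25, 0.55], 0.1, size=(100, 2)), 0.01, 0.98)
            b = np.clip(rng.normal([0.15, 0.65], 0.1, size=(100, 2)), 0.01, 0.98)
            Qa = np.column_stack([a, 1 - a.sum(axis=1)])
            Qb = np.column_stack([b, 1 - b.sum(axis=1)])
            res = hotelling_two_sample(Qa, Qb)
            hits += res.p_value < 0.05 / 15
        assert hits >= 19

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(3)
        pooled = rng.dirichlet(np.array(3 * [5.0]), size=120)
        pvals = []
        for _ in range(200):
            perm = rng.permutation(120)
            res = hotelling_two_sample(pooled[perm[:60]], pooled[perm[60:]])
            pvals.append(res.p_value)
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_matches_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        Qa = rng.dirichlet(np.ones(3), size=30)
        Qb = rng.dirichlet(np.array([2.0, 1.0, 1.0]), size=25)
        res = hotelling_two_sample(Qa, Qb)
        ref = pg.multivariate_ttest(Qa[:, :2], Qb[:, :2])
        assert res.t2 == pytest.approx(float(ref["T2"].iloc[0]), rel=1e-6)
        assert res.p_value == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            hotelling_two_sample(np.ones((2, 3)) / 3, np.ones((5, 3)) / 3)


class TestTreemixCounts:
    def test_reconstructed_haploid_total(self):
        a1, a2 = treemix_counts(0.2, np.array([0.5]), 1538)
        assert (a1[0], a2[0]) == (308, 307)

    def test_fixed_frequencies(self):
        a1, a2 = treemix_counts(0.2, np.array([0.0, 1.0]), 1538)
        assert (a1[0], a2[0]) == (0, 615)
        assert (a1[1], a2[1]) == (615, 0)

    def test_literal_formula_caps_counts_at_two(self):
        a1, a2 = treemix_counts(0.2, np.linspace(0, 1, 11), 1538, literal=True)
        assert a1.max() <= 2 and a2.max() <= 2

    def test_qbar_validated(self):
        with pytest.raises(ValueError, match="q_bar"):
            treemix_counts(0.0, np.array([0.5]), 100)

    def test_gzipped_export_roundtrip(self, tmp_path):
        counts = {
            "popA": (np.array([3, 0]), np.array([7, 10])),
            "popB": (np.array([5, 5]), np.array([5, 5])),
        }
        path = tmp_path / "counts.treemix.gz"
        write_treemix(path, counts)
        with gzip.open(path, "rt") as fh:
            lines = fh.read().splitlines()
        assert lines[0] == "popA popB"
        assert lines[1] == "3,7 5,5"
        assert lines[2] == "0,10 5,5"
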