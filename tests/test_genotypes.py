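import numpy as np
import pytest

from admixscan import (
    GenotypeMatrix,
    QcThresholds,
    SnpRecord,
    allele_freq,
    filter_snps,
    intersect_snps,
    ld_prune,
    ld_r2,
    read_genotypes,
    write_genotypes,
)


def _gm(dosage, snps=None, samples=None):
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    snps = snps or [SnpRecord(f"rs{j}", "1", 100 * (j + 1), "A", "G") for j in range(m)]
    samples = samples or [f"s{i}" for i in range(n)]
    return GenotypeMatrix(samples, snps, dosage)


class TestDataModel:
    def test_rejects_invalid_dosage(self):
        with pytest.raises(ValueError, match="0, 1 or 2"):
            _gm([[0, 3.0]])

    def test_rejects_duplicate_snp_ids(self):
        snps = [SnpRecord("rs1", "1", 1, "A", "G"), SnpRecord("rs1", "1", 2, "A", "G")]
        with pytest.raises(ValueError, match="unique"):
            GenotypeMatrix(["s"], snps, np.zeros((1, 2)))

    def test_rejects_identical_alleles(self):
        with pytest.raises(ValueError, match="differ"):
            SnpRecord("rs1", "1", 1, "A", "A")


class TestRoundTrips:
    @pytest.mark.parametrize("fmt,fname", [
        ("tsv", "geno.tsv"),
        ("plink-bed", "geno.bed"),
        ("vcf", "geno.vcf"),
    ])
    def test_write_read_identity(self, tmp_path, tiny_gm, fmt, fname):
        path = tmp_path / fname
        write_genotypes(tiny_gm, path, fmt)
        back = read_genotypes(path, fmt)
        assert back.samples == tiny_gm.samples
        assert back.snp_ids == tiny_gm.snp_ids
        np.testing.assert_array_equal(back.dosage, tiny_gm.dosage)
        assert [s.allele_a1 for s in back.snps] == [s.allele_a1 for s in tiny_gm.snps]

    def test_plink_roundtrip_larger(self, tmp_path, small_study):
        gm = small_study.cohort.subset_samples(small_study.cohort.samples[:37])
        write_genotypes(gm, tmp_path / "c.bed", "plink-bed")
        back = read_genotypes(tmp_path / "c", "plink-bed")
        np.testing.assert_array_equal(back.dosage, gm.dosage)

    def test_tsv_fixture_values(self, tmp_path):
        (tmp_path / "g.tsv").write_text(
            "sample_id\trsA\trsB\ns1\t0\t2\ns2\t1\tNA\ns3\t2\t0\n"
        )
        (tmp_path / "g.map.tsv").write_text(
            "id\tchrom\tpos\ta1\ta2\nrsA\t1\t100\tA\tG\nrsB\t2\t200\tC\tT\n"
        )
        gm = read_genotypes(tmp_path / "g.tsv", "tsv")
        assert gm.samples == ["s1", "s2", "s3"]
        np.testing.assert_array_equal(
            gm.dosage, np.array([[0, 2], [1, np.nan], [2, 0]], dtype=float)
        )

    def test_vcf_triallelic_record_skipped(self, tmp_path):
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "##contig=<ID=1>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2",
        ]
        for j in range(5):
            alt = "G,T" if j == 2 else "G"
            lines.append(f"1\t{100 + j}\trs{j}\tA\t{alt}\t.\t.\t.\tGT\t0/0\t0/1")
        (tmp_path / "m.vcf").write_text("\n".join(lines) + "\n")
        with pytest.warns(UserWarning, match="multi-allelic"):
            gm = read_genotypes(tmp_path / "m.vcf", "vcf")
        assert gm.n_snps == 4
        assert "rs2" not in gm.snp_ids

    def test_malformed_tsv_raises(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("sample_id\trsA\ns1\t7\n")
        (tmp_path / "bad.map.tsv").write_text("id\tchrom\tpos\ta1\ta2\nrsA\t1\t1\tA\tG\n")
        with pytest.raises(ValueError, match="row"):
            read_genotypes(tmp_path / "bad.tsv", "tsv")


class TestAlleleFreq:
    @pytest.mark.parametrize("dosages,freq,n", [
        ([0.0, 1.0, 2.0], 0.5, 6),
        ([0.0, 0.0, 0.0], 0.0, 6),
        ([2.0, 2.0, np.nan], 1.0, 4),
    ])
    def test_known_values(self, dosages, freq, n):
        gm = _gm(np.array(dosages).reshape(-1, 1))
        f, cnt = allele_freq(gm)
        assert f[0] == pytest.approx(freq)
        assert cnt[0] == n

    def test_all_missing_flagged(self):
        gm = _gm([[np.nan], [np.nan]])
        f, cnt = allele_freq(gm)
        assert np.isnan(f[0]) and cnt[0] == 0

    def test_empty_subset_rejected(self, tiny_gm):
        with pytest.raises(ValueError):
            allele_freq(tiny_gm, [])

    def test_complement_of_a2_counting(self, small_study):
        gm = small_study.cohort
        f, _ = allele_freq(gm)
        flipped = GenotypeMatrix(
            list(gm.samples),
            [SnpRecord(s.id, s.chromosome, s.position_bp, s.allele_a2, s.allele_a1)
             for s in gm.snps],
            2.0 - gm.dosage,
        )
        f2, _ = allele_freq(flipped)
        np.testing.assert_allclose(f, 1.0 - f2)
        assert ((f >= 0) & (f <= 1)).all()


class TestFilterSnps:
    @pytest.fixture
    def qc_fixture(self):
        # 10 samples x 6 SNPs; call rates [1,.9,1,1,1,1], MAF [.10,.10,0,0,.25,.30]
        cols = [
            [2, 0, 0, 0, 0, 0, 0, 0, 0, 0],               # maf .10, cr 1.0 -> pass
            [2, 0, 0, 0, 0, 0, 0, 0, 0, np.nan],          # cr .9 -> fail
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],               # monomorphic -> fail
            [2, 2, 2, 2, 2, 2, 2, 2, 2, 2],               # monomorphic -> fail
            [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],               # maf .25 -> pass
            [2, 2, 2, 0, 0, 0, 0, 0, 0, 0],               # maf .30 -> pass
        ]
        return _gm(np.array(cols, float).T)

    def test_expected_survivors(self, qc_fixture):
        out, report = filter_snps(qc_fixture, QcThresholds())
        assert out.snp_ids == ["rs0", "rs4", "rs5"]
        assert (report.n_retained, report.n_dropped) == (3, 3)

    def test_idempotent(self, qc_fixture):
        once, _ = filter_snps(qc_fixture)
        twice, rep = filter_snps(once)
        assert twice.snp_ids == once.snp_ids and rep.n_dropped == 0

    def test_zero_thresholds_identity(self, qc_fixture):
        out, _ = filter_snps(qc_fixture, QcThresholds(0.0, 0.0))
        assert out.snp_ids == qc_fixture.snp_ids

    def test_monomorphic_dropped_at_default_maf(self):
        gm = _gm(np.zeros((4, 1)))
        out, _ = filter_snps(gm)
        assert out.n_snps == 0


class TestLd:
    def test_identical_vectors_r2_one(self):
        gm = _gm(np.array([[0, 0], [1, 1], [2, 2], [0, 0]], float))
        assert ld_r2(gm, "rs0", "rs1") == pytest.approx(1.0)

    def test_perfect_anticorrelation_r2_one(self):
        gm = _gm(np.array([[0, 2], [1, 1], [2, 0], [0, 2]], float))
        assert ld_r2(gm, "rs0", "rs1") == pytest.approx(1.0)

    def test_orthogonal_vectors_r2_zero(self):
        gm = _gm(np.array([[0, 0], [2, 0], [0, 2], [2, 2]], float))
        assert ld_r2(gm, "rs0", "rs1") == pytest.approx(0.0)

    def test_zero_variance_undefined(self):
        gm = _gm(np.array([[1, 0], [1, 1], [1, 2]], float))
        assert np.isnan(ld_r2(gm, "rs0", "rs1"))


class TestLdPrune:
    def test_duplicate_snps_one_retained(self):
        gm = _gm(np.array([[0, 0], [1, 1], [2, 2], [1, 1]], float))
        assert len(ld_prune(gm)) == 1

    def test_chain_of_identical_snps_one_retained(self):
        col = np.array([0, 1, 2, 1, 0, 2], float)
        gm = _gm(np.tile(col[:, None], 5))
        assert len(ld_prune(gm)) == 1

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(0)
        gm = _gm(rng.binomial(2, 0.5, size=(400, 30)).astype(float))
        kept = ld_prune(gm, r2_max=0.3)
        assert len(kept) == 30

    def test_no_retained_pair_exceeds_threshold(self, small_study):
        gm = small_study.cohort.subset_snps(small_study.cohort.snp_ids[:60])
        kept = ld_prune(gm, r2_max=0.2, window_snps=20, step_snps=5)
        sub = gm.subset_snps(kept)
        by_chrom: dict[str, list[int]] = {}
        for j, s in enumerate(sub.snps):
            by_chrom.setdefault(s.chromosome, []).append(j)
        for idxs in by_chrom.values():
            for start in range(0, len(idxs), 5):
                window = idxs[start : start + 20]
                for x in range(len(window)):
                    for y in range(x + 1, len(window)):
                        r2 = ld_r2(sub, sub.snps[window[x]].id, sub.snps[window[y]].id)
                        assert np.isnan(r2) or r2 <= 0.2

    def test_unsorted_positions_rejected(self):
        snps = [SnpRecord("a", "1", 500, "A", "G"), SnpRecord("b", "1", 100, "A", "G")]
        gm = GenotypeMatrix(["s1", "s2"], snps, np.zeros((2, 2)))
        with pytest.raises(ValueError, match="sorted"):
            ld_prune(gm)


class TestIntersect:
    def test_identical_maps_identity(self, tiny_gm):
        a, b = intersect_snps(tiny_gm, tiny_gm)
        assert a.snp_ids == tiny_gm.snp_ids
        np.testing.assert_array_equal(b.dosage, tiny_gm.dosage)

    def test_swapped_alleles_flip_dosage(self):
        a = _gm(np.array([[0.0], [2.0]]), snps=[SnpRecord("rs1", "1", 10, "A", "G")])
        b = _gm(np.array([[0.0], [2.0]]), snps=[SnpRecord("rs1", "1", 10, "G", "A")])
        out_a, out_b = intersect_snps(a, b)
        assert out_a.n_snps == 1
        np.testing.assert_array_equal(out_b.dosage, np.array([[2.0], [0.0]]))
        assert out_b.snps[0].allele_a1 == "A"

    def test_strand_ambiguous_dropped(self):
        a = _gm(np.zeros((2, 1)), snps=[SnpRecord("rs1", "1", 10, "A", "T")])
        b = _gm(np.zeros((2, 1)), snps=[SnpRecord("rs1", "1", 10, "A", "T")])
        out_a, _ = intersect_snps(a, b)
        assert out_a.n_snps == 0

    def test_irreconcilable_alleles_warn_and_drop(self):
        a = _gm(np.zeros((2, 1)), snps=[SnpRecord("rs1", "1", 10, "A", "G")])
        b = _gm(np.zeros((2, 1)), snps=[SnpRecord("rs1", "1", 10, "A", "C")])
        with pytest.warns(UserWarning, match="irreconcilable"):
            out_a, _ = intersect_snps(a, b)
        assert out_a.n_snps == 0
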