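import numpy as np
import pytest

from chalm.reads import (
    MethRead,
    ReadFormatError,
    build_matrix,
    merge_mates,
    parse_reads_sam,
    parse_reads_tsv,
    pileup,
    read_bedgraph,
    write_bedgraph,
    write_reads_tsv,
)
from chalm.regions import GenomicInterval

from conftest import mk_read


class TestMethRead:
    def test_counts(self):
        r = mk_read("r", "MUNMU")
        assert (r.n_meth, r.n_unmeth) == (2, 2)

    def test_positions_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            MethRead("r", "chr1", 100, 200, "+", ((150, "M"), (120, "U")))

    def test_calls_must_lie_in_fragment(self):
        with pytest.raises(ValueError, match="outside"):
            MethRead("r", "chr1", 100, 200, "+", ((250, "M"),))


class TestTsvIO:
    def test_parse_row(self, tmp_path):
        p = tmp_path / "reads.tsv"
        p.write_text("r1\tchr1\t100\t200\t+\t105:M,150:U\n")
        (r,) = parse_reads_tsv(p)
        assert (r.n_meth, r.n_unmeth) == (1, 1)
        assert r.calls == ((105, "M"), (150, "U"))

    def test_empty_calls_read_retained(self, tmp_path):
        p = tmp_path / "reads.tsv"
        p.write_text("r1\tchr1\t100\t200\t+\t.\n")
        (r,) = parse_reads_tsv(p)
        assert r.calls == ()

    def test_unsorted_positions_rejected(self, tmp_path):
        p = tmp_path / "reads.tsv"
        p.write_text("r1\tchr1\t100\t200\t+\t150:M,105:U\n")
        with pytest.raises(ReadFormatError, match="increasing"):
            list(parse_reads_tsv(p))

    def test_roundtrip(self, tmp_path):
        reads = [mk_read("a", "MUMUM"), mk_read("b", "NNUUM")]
        p = tmp_path / "reads.tsv"
        write_reads_tsv(reads, p)
        assert list(parse_reads_tsv(p)) == reads


class TestSamRoute:
    def _write_sam(self, path, records):
        lines = ["@HD\tVN:1.6\tSO:unsorted", "@SQ\tSN:chr1\tLN:10000"]
        lines += records
        path.write_text("\n".join(lines) + "\n")

    def test_xm_tag_parsed(self, tmp_path):
        p = tmp_path / "in.sam"
        # 10M read at pos 101 (1-based); XM has Z at offset 2, z at offset 6
        self._write_sam(
            p, ["r1\t0\tchr1\t101\t42\t10M\t*\t0\t0\tAACGAACGAA\tIIIIIIIIII\tXM:Z:..Z...z...\tXG:Z:CT"]
        )
        (r,) = parse_reads_sam(p)
        assert r.calls == ((102, "M"), (106, "U"))

    def test_missing_xm_is_error(self, tmp_path):
        p = tmp_path / "in.sam"
        self._write_sam(p, ["r1\t0\tchr1\t101\t42\t4M\t*\t0\t0\tAACG\tIIII"])
        with pytest.raises(ReadFormatError, match="XM"):
            list(parse_reads_sam(p))

    def test_g_strand_collapsed_and_reference_filter(self, tmp_path):
        p = tmp_path / "in.sam"
        self._write_sam(
            p, ["r1\t16\tchr1\t101\t42\t4M\t*\t0\t0\tAGAA\tIIII\tXM:Z:.Z..\tXG:Z:GA"]
        )
        (r,) = parse_reads_sam(p, cpg_reference={"chr1": [100]})
        assert r.calls == ((100, "M"),)  # G at 101 collapsed onto CpG unit 100
        with pytest.warns(UserWarning, match="not in reference"):
            (r2,) = parse_reads_sam(p, cpg_reference={"chr1": [500]})
        assert r2.calls == ((100, "NA"),)


class TestMergeMates:
    def test_merge_spans_and_calls(self):
        m1 = MethRead("p", "chr1", 100, 200, "+", ((105, "M"),))
        m2 = MethRead("p", "chr1", 180, 280, "-", ((250, "M"),))
        (f,) = merge_mates([m1, m2])
        assert (f.frag_start, f.frag_end) == (100, 280)
        assert f.calls == ((105, "M"), (250, "M"))

    def test_overlap_disagreement_becomes_na(self):
        m1 = MethRead("p", "chr1", 100, 200, "+", ((190, "M"),))
        m2 = MethRead("p", "chr1", 180, 280, "-", ((190, "U"), (250, "M")))
        (f,) = merge_mates([m1, m2])
        assert dict(f.calls)[190] == "NA"

    def test_singleton_passthrough_and_triplet_error(self):
        r = mk_read("solo", "MU")
        assert merge_mates([r]) == [r]
        with pytest.raises(ReadFormatError, match="3 alignments"):
            merge_mates([mk_read("x", "M"), mk_read("x", "U"), mk_read("x", "M")])

    def test_merge_never_gains_calls(self):
        m1 = MethRead("p", "chr1", 100, 200, "+", ((105, "M"), (190, "M")))
        m2 = MethRead("p", "chr1", 180, 280, "-", ((190, "U"),))
        (f,) = merge_mates([m1, m2])
        assert len(f.calls) <= len(m1.calls) + len(m2.calls)
        assert f.n_meth + f.n_unmeth <= m1.n_meth + m1.n_unmeth + m2.n_meth + m2.n_unmeth


class TestPileup:
    def test_counts_and_depth_filter(self, population_a, promoter):
        counts = pileup(population_a, promoter, min_depth=4)
        assert len(counts) == 5
        assert all((c.c_meth, c.c_unmeth) == (2, 8) for c in counts)
        # only 3 reads covering a CpG -> dropped at min_depth=4
        thin = [mk_read(f"t{i}", "M") for i in range(3)]
        assert pileup(thin, min_depth=4) == []
        assert len(pileup(thin, min_depth=0)) == 1

    def test_na_calls_excluded(self):
        reads = [mk_read("a", "N"), mk_read("b", "M"), mk_read("c", "U")]
        (c,) = pileup(reads, min_depth=0)
        assert (c.c_meth, c.c_unmeth) == (1, 1)

    def test_matches_matrix_column_sums(self, promoter):
        rng = np.random.default_rng(0)
        reads = [
            mk_read(f"r{i}", "".join(rng.choice(list("MUN"), 5)))
            for i in range(30)
        ]
        reads = [r for r in reads if any(s != "NA" for _, s in r.calls)]
        m = build_matrix(reads, promoter)
        counts = {c.cpg_pos: c for c in pileup(reads, promoter, min_depth=0)}
        for j, pos in enumerate(m.cpg_positions):
            col = m.data[:, j]
            assert counts[pos].c_meth == int(np.nansum(col == 1.0))
            assert counts[pos].c_unmeth == int(np.nansum(col == 0.0))


class TestBuildMatrix:
    def test_coverage_pattern(self, promoter):
        r1 = MethRead("a", "chr1", 1000, 1060, "+", ((1010, "M"), (1030, "U")))
        r2 = mk_read("b", "UUUUU")
        m = build_matrix([r1, r2], promoter)
        assert m.cpg_positions.tolist() == [1010, 1030, 1050, 1070, 1090]
        assert m.data[0].tolist()[:2] == [1.0, 0.0]
        assert np.isnan(m.data[0, 2:]).all()
        assert not np.isnan(m.data[1]).any()

    def test_no_overlap_is_error(self, promoter):
        far = MethRead("x", "chr1", 5000, 5100, "+", ((5050, "M"),))
        with pytest.raises(ReadFormatError):
            build_matrix([far], promoter)


def test_bedgraph_roundtrip(tmp_path, population_a, promoter):
    counts = pileup(population_a, promoter)
    p = tmp_path / "ratios.bedgraph"
    write_bedgraph(counts, "chr1", p)
    assert read_bedgraph(p)["chr1"] == counts
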