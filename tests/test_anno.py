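"""GTF parsing, interval algebra, and site-to-region assignment."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from apaviz import PACDataset, annotate_sites, load_annotation
from apaviz.anno import merge_intervals, subtract_intervals
from conftest import make_pac, random_annotation, random_sites
from _oracles import brute_force_annotate


GTF_LINE = "{chrom}\tsrc\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"


def write_gtf(path, records):
    path.write_text("".join(
        GTF_LINE.format(chrom=c, ftype=f, start=s, end=e, strand=st, attrs=a)
        for c, f, s, e, st, a in records))
    return path


class TestLoadAnnotation:
    def test_intron_from_exon_gap(self, tmp_path):
        g = 'gene_id "g1";'
        t = 'gene_id "g1"; transcript_id "t1";'
        gtf = write_gtf(tmp_path / "a.gtf", [
            ("chr1", "gene", 1, 300, "+", g),
            ("chr1", "transcript", 1, 300, "+", t),
            ("chr1", "exon", 1, 100, "+", t),
            ("chr1", "exon", 201, 300, "+", t),
        ])
        anno = load_annotation(gtf)
        assert anno.features["g1"]["intron"] == [(101, 200)]

    def test_transcript_union_removes_intron(self, tmp_path):
        g = 'gene_id "g1";'
        t1 = 'gene_id "g1"; transcript_id "t1";'
        t2 = 'gene_id "g1"; transcript_id "t2";'
        gtf = write_gtf(tmp_path / "a.gtf", [
            ("chr1", "gene", 1, 150, "+", g),
            ("chr1", "transcript", 1, 100, "+", t1),
            ("chr1", "exon", 1, 100, "+", t1),
            ("chr1", "transcript", 51, 150, "+", t2),
            ("chr1", "exon", 51, 150, "+", t2),
        ])
        anno = load_annotation(gtf)
        assert anno.features["g1"]["exon"] == [(1, 150)]
        assert anno.features["g1"]["intron"] == []

    @pytest.mark.parametrize("strand,expected", [("+", [(251, 300)]), ("-", [(1, 100), (201, 210)])])
    def test_utr3_derived_from_cds(self, tmp_path, strand, expected):
        # oracle: per-transcript exonic bases strictly 3' of the CDS stop
        g = 'gene_id "g1";'
        t = 'gene_id "g1"; transcript_id "t1";'
        cds = (211, 250) if strand == "+" else (211, 250)
        gtf = write_gtf(tmp_path / "a.gtf", [
            ("chr1", "gene", 1, 300, strand, g),
            ("chr1", "transcript", 1, 300, strand, t),
            ("chr1", "exon", 1, 100, strand, t),
            ("chr1", "exon", 201, 300, strand, t),
            ("chr1", "CDS", cds[0], cds[1], strand, t),
        ])
        anno = load_annotation(gtf)
        assert anno.features["g1"]["UTR3"] == expected

    def test_gff3_dialect_accepted(self, tmp_path):
        gtf = write_gtf(tmp_path / "a.gff3", [
            ("chr1", "gene", 1, 300, "+", "ID=g1"),
            ("chr1", "mRNA", 1, 300, "+", "ID=t1;Parent=g1"),
            ("chr1", "exon", 1, 300, "+", "ID=e1;Parent=t1"),
        ])
        anno = load_annotation(gtf)
        assert anno.features["g1"]["exon"] == [(1, 300)]

    def test_exonless_gene_kept_with_warning(self, tmp_path):
        gtf = write_gtf(tmp_path / "a.gtf", [("chr1", "gene", 1, 300, "+", 'gene_id "g1";')])
        with pytest.warns(UserWarning, match="no exon"):
            anno = load_annotation(gtf)
        assert "g1" in anno.genes.index


class TestIntervalAlgebra:
    @pytest.mark.parametrize("ivs,expected", [
        ([(5, 10), (1, 3)], [(1, 3), (5, 10)]),
        ([(1, 5), (4, 8)], [(1, 8)]),
        ([(1, 5), (6, 8)], [(1, 8)]),  # adjacency merges
        ([], []),
    ])
    def test_merge(self, ivs, expected):
        assert merge_intervals(ivs) == expected

    @pytest.mark.parametrize("ivs,holes,expected", [
        ([(1, 10)], [(4, 6)], [(1, 3), (7, 10)]),
        ([(1, 10)], [(1, 10)], []),
        ([(1, 10)], [], [(1, 10)]),
        ([(1, 10)], [(8, 20)], [(1, 7)]),
    ])
    def test_subtract(self, ivs, holes, expected):
        assert subtract_intervals(ivs, holes) == expected


class TestAnnotateSites:
    def test_utr3_containment(self, plus_gene_annotation):
        pac = make_pac([[1, 0]], [("s1", "chr1", "+", 950)], ["A", "B"])
        out = annotate_sites(pac, plus_gene_annotation)
        assert out.site_meta.loc["s1", "gene_id"] == "gA"
        assert out.site_meta.loc["s1", "region"] == "UTR3"

    def test_extended_utr3_window(self, plus_gene_annotation):
        pac = make_pac([[1, 0]], [("s1", "chr1", "+", 1200)], ["A", "B"])
        out = annotate_sites(pac, plus_gene_annotation, ext3utr=1000)
        assert out.site_meta.loc["s1", "region"] == "ext_UTR3"
        # and beyond the window: intergenic
        far = make_pac([[1, 0]], [("s1", "chr1", "+", 2100)], ["A", "B"])
        out2 = annotate_sites(far, plus_gene_annotation, ext3utr=1000)
        assert out2.site_meta.loc["s1", "region"] == "intergenic"

    def test_strand_mismatch_is_intergenic(self, plus_gene_annotation):
        pac = make_pac([[1, 0]], [("s1", "chr1", "-", 950)], ["A", "B"])
        out = annotate_sites(pac, plus_gene_annotation)
        assert out.site_meta.loc["s1", "region"] == "intergenic"
        assert pd.isna(out.site_meta.loc["s1", "gene_id"])

    def test_unknown_chromosome_warns(self, plus_gene_annotation):
        pac = make_pac([[1, 0]], [("s1", "chrZ", "+", 950)], ["A", "B"])
        with pytest.warns(UserWarning, match="absent"):
            out = annotate_sites(pac, plus_gene_annotation)
        assert out.site_meta.loc["s1", "region"] == "intergenic"

    def test_idempotent(self, plus_gene_annotation):
        pac = make_pac([[1, 0]], [("s1", "chr1", "+", 950)], ["A", "B"])
        once = annotate_sites(pac, plus_gene_annotation)
        twice = annotate_sites(once, plus_gene_annotation)
        assert twice.site_meta.equals(once.site_meta)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        anno = random_annotation(rng, n_genes=10)
        sites = random_sites(rng, n_sites=100)
        pac = PACDataset(counts=sp.csr_matrix((100, 1), dtype=np.int64),
                         site_meta=sites,
                         obs_meta=pd.DataFrame({"group": ["A"]},
                                               index=pd.Index(["c0"], name="obs_id")))
        out = annotate_sites(pac, anno, ext3utr=500)
        genes = {gid: (g["chrom"], g["strand"], int(g["start"]), int(g["end"]))
                 for gid, g in anno.genes.iterrows()}
        for sid, s in sites.iterrows():
            exp_gene, exp_region = brute_force_annotate(
                (s["chrom"], s["strand"], int(s["coord"])), genes, anno.features, 500)
            assert out.site_meta.loc[sid, "region"] == exp_region, sid
            got_gene = out.site_meta.loc[sid, "gene_id"]
            assert (pd.isna(got_gene) and exp_gene is None) or got_gene == exp_gene, sid

    def test_every_site_gets_exactly_one_region(self):
        rng = np.random.default_rng(99)
        anno = random_annotation(rng, n_genes=8)
        sites = random_sites(rng, n_sites=60)
        pac = PACDataset(counts=sp.csr_matrix((60, 1), dtype=np.int64),
                         site_meta=sites,
                         obs_meta=pd.DataFrame({"group": ["A"]},
                                               index=pd.Index(["c0"], name="obs_id")))
        out = annotate_sites(pac, anno)
        regions = out.site_meta["region"]
        assert regions.notna().all()
        assert set(regions) <= {"UTR3", "ext_UTR3", "exon", "intron", "intergenic"}
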