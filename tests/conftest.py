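import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from apaviz import PACDataset, GenomeAnnotation


def make_pac(counts, site_rows, groups):
    """Build a PACDataset from a dense array, site tuples and group labels.

    ``site_rows``: list of (site_id, chrom, strand, coord[, gene_id, region]).
    """
    cols = ["site_id", "chrom", "strand", "coord", "gene_id", "region"][: len(site_rows[0])]
    site_meta = pd.DataFrame(site_rows, columns=cols).set_index("site_id")
    obs_meta = pd.DataFrame(
        {"group": list(groups)},
        index=pd.Index([f"c{i}" for i in range(len(groups))], name="obs_id"),
    )
    return PACDataset(counts=sp.csr_matrix(np.asarray(counts)),
                      site_meta=site_meta, obs_meta=obs_meta)


@pytest.fixture
def tiny_pac():
    """3 sites x 4 cells, two groups, one 2-site + strand gene."""
    counts = [[8, 2, 1, 0],
              [2, 8, 4, 9],
              [5, 5, 0, 1]]
    sites = [("s1", "chr1", "+", 900),
             ("s2", "chr1", "+", 990),
             ("s3", "chr2", "-", 500)]
    return make_pac(counts, sites, ["X", "X", "Y", "Y"])


def make_annotation(gene_rows, features):
    """gene_rows: list of (gene_id, chrom, strand, start, end)."""
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand",
                                             "start", "end"]).set_index("gene_id")
    return GenomeAnnotation(genes=genes, features=features)


@pytest.fixture
def plus_gene_annotation():
    """One + strand gene spanning 1..1000 with UTR3 at 901..1000."""
    return make_annotation(
        [("gA", "chr1", "+", 1, 1000)],
        {"gA": {"UTR3": [(901, 1000)], "exon": [(1, 1000)], "intron": []}},
    )


def random_annotation(rng, n_genes=10, n_chroms=2, chrom_len=100_000):
    """Random non-pathological gene models for oracle cross-checks."""
    rows, feats = [], {}
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(1, chrom_len - 5000))
        length = int(rng.integers(600, 4000))
        end = start + length
        n_exons = int(rng.integers(1, 4))
        bounds = np.sort(rng.choice(np.arange(start + 1, end), size=2 * (n_exons - 1),
                                    replace=False)) if n_exons > 1 else np.array([])
        exon_edges = [start] + list(bounds) + [end]
        exons = [(int(exon_edges[2 * k]), int(exon_edges[2 * k + 1]))
                 for k in range(n_exons)]
        introns = [(exons[k][1] + 1, exons[k + 1][0] - 1) for k in range(n_exons - 1)
                   if exons[k][1] + 1 <= exons[k + 1][0] - 1]
        # 3'UTR: terminal slice of the 3'-most exon
        if strand == "+":
            ls, le = exons[-1]
            u = (max(ls, le - int(rng.integers(50, 400))), le)
        else:
            fs, fe = exons[0]
            u = (fs, min(fe, fs + int(rng.integers(50, 400))))
        rows.append((f"g{i}", chrom, strand, start, end))
        feats[f"g{i}"] = {"UTR3": [u], "exon": exons, "intron": introns}
    return make_annotation(rows, feats)


def random_sites(rng, n_sites=100, n_chroms=2, chrom_len=100_000):
    return pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in rng.integers(1, n_chroms + 1, n_sites)],
            "strand": np.where(rng.random(n_sites) < 0.5, "+", "-"),
            "coord": rng.integers(1, chrom_len, n_sites),
        },
        index=pd.Index([f"s{i}" for i in range(n_sites)], name="site_id"),
    )
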