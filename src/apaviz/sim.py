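"""Synthetic poly(A)-site data with planted APA structure.

The generator emulates a multi-stage single-cell 3'-end dataset: each gene
carries a proximal and a distal poly(A) site in its 3'UTR; per cell, the
gene's total read count is negative-binomial (variance = mu + mu^2 /
dispersion, the standard single-cell overdispersion model) and the distal
count is binomial given the gene's true RUD in that cell's group.  For a
configurable fraction of genes the true RUD shifts monotonically across
the group order (downward by default, i.e. progressive 3'UTR shortening).
A matching toy GTF and per-group toy alignments (reads stacking up to each
site's 3' end) make every reader in the package exercisable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import scipy.sparse as sp

from ._errors import ParameterError
from .core import PACDataset

GENE_SPAN = 2000
GENE_SPACING = 10_000
GENES_PER_CHROM = 100
UTR_LEN = 300


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic dataset."""

    n_genes: int = 200
    groups: tuple[str, ...] = ("A", "B", "C")
    n_cells_per_group: int = 100
    frac_shifted: float = 0.3
    delta_rud: float = 0.4
    base_rud: float = 0.8
    depth_mean: float = 10.0
    dispersion: float = 2.0
    read_len: int = 50
    seed: int = 42
    shift_direction: int = -1  # -1: RUD decreases along group order (3'UTR shortening)

    def validate(self) -> None:
        if self.n_genes < 0 or self.n_cells_per_group < 1 or len(self.groups) < 1:
            raise ParameterError("n_genes >= 0, n_cells_per_group >= 1 and at least "
                                 "one group are required")
        if not (0 <= self.frac_shifted <= 1):
            raise ParameterError("frac_shifted must be in [0, 1]")
        if not (0 <= self.base_rud <= 1) or not (0 <= self.delta_rud <= 1):
            raise ParameterError("base_rud and delta_rud must be in [0, 1]")
        if self.depth_mean <= 0 or self.dispersion <= 0 or self.read_len < 1:
            raise ParameterError("depth_mean, dispersion and read_len must be positive")
        if self.shift_direction not in (-1, 1):
            raise ParameterError("shift_direction must be -1 or +1")


def preset(name: str, seed: int = 42) -> SimConfig:
    """Named study designs.

    ``strong``: 3 groups x 100 cells, 200 genes, 30% shifted by a 0.4 RUD
    decrease across the group order -- a desk-scale analogue of a 3-stage
    differentiation series with progressive 3'UTR shortening.
    ``null``: 2 groups x 50 cells, no shifted genes.
    """
    if name == "strong":
        return SimConfig(seed=seed)
    if name == "null":
        return SimConfig(n_genes=200, groups=("A", "B"), n_cells_per_group=50,
                         frac_shifted=0.0, delta_rud=0.0, seed=seed)
    raise ParameterError(f"unknown preset '{name}' (expected 'strong' or 'null')")


# ---------------------------------------------------------------------------
# gene layout on the toy genome
# ---------------------------------------------------------------------------

def _gene_layout(i: int) -> dict:
    """Deterministic coordinates of gene i on the toy genome."""
    chrom = f"chr{i // GENES_PER_CHROM + 1}"
    start = 1 + (i % GENES_PER_CHROM) * GENE_SPACING
    end = start + GENE_SPAN - 1
    strand = "+" if i % 2 == 0 else "-"
    if strand == "+":
        exons = [(start, start + 799), (start + 1200, end)]
        utr3 = (end - UTR_LEN + 1, end)
        proximal, distal = end - 249, end - 49
    else:
        exons = [(start, start + 799), (start + 1200, end)]
        utr3 = (start, start + UTR_LEN - 1)
        proximal, distal = start + 249, start + 49  # distal is 3'-most: lower coord
    return dict(gene_id=f"g{i:04d}", chrom=chrom, start=start, end=end,
                strand=strand, exons=exons, utr3=utr3,
                proximal=proximal, distal=distal)


def chrom_sizes(cfg: SimConfig) -> dict[str, int]:
    n_chrom = max(1, (max(cfg.n_genes, 1) - 1) // GENES_PER_CHROM + 1)
    return {f"chr{c + 1}": GENES_PER_CHROM * GENE_SPACING + GENE_SPACING
            for c in range(n_chrom)}


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def true_rud_table(cfg: SimConfig) -> pd.DataFrame:
    """Per-gene truth: shifted flag and true RUD per group.

    The first ``round(frac_shifted * n_genes)`` genes are shifted; their
    RUD moves linearly from ``base_rud`` by ``shift_direction * delta_rud``
    over the group order, clamped to [0, 1].
    """
    cfg.validate()
    n_shift = int(round(cfg.frac_shifted * cfg.n_genes)) if cfg.delta_rud > 0 else 0
    n_groups = len(cfg.groups)
    rows = []
    for i in range(cfg.n_genes):
        shifted = i < n_shift
        ruds = []
        for k in range(n_groups):
            frac = k / (n_groups - 1) if n_groups > 1 else 0.0
            r = cfg.base_rud + (cfg.shift_direction * cfg.delta_rud * frac
                                if shifted else 0.0)
            ruds.append(min(1.0, max(0.0, r)))
        rows.append([f"g{i:04d}", shifted] + ruds)
    cols = ["gene_id", "shifted"] + [f"rud_{g}" for g in cfg.groups]
    return pd.DataFrame(rows, columns=cols).set_index("gene_id")


def simulate_pac(cfg: SimConfig) -> tuple[PACDataset, pd.DataFrame]:
    """Simulate a sites x cells PACDataset plus its truth table."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = true_rud_table(cfg)
    n_cells = cfg.n_cells_per_group * len(cfg.groups)
    obs_ids = [f"cell{j:04d}" for j in range(n_cells)]
    group_of = np.repeat(np.arange(len(cfg.groups)), cfg.n_cells_per_group)

    site_rows = []
    count_rows = []
    p_nb = cfg.dispersion / (cfg.dispersion + cfg.depth_mean)
    for i in range(cfg.n_genes):
        lay = _gene_layout(i)
        gid = lay["gene_id"]
        totals = rng.negative_binomial(cfg.dispersion, p_nb, size=n_cells)
        rud_per_cell = truth.loc[gid, [f"rud_{g}" for g in cfg.groups]].to_numpy(
            dtype=float)[group_of]
        distal = rng.binomial(totals, rud_per_cell)
        proximal = totals - distal
        site_rows.append((f"{gid}.p", lay["chrom"], lay["strand"], lay["proximal"]))
        count_rows.append(proximal)
        site_rows.append((f"{gid}.d", lay["chrom"], lay["strand"], lay["distal"]))
        count_rows.append(distal)

    site_meta = pd.DataFrame(site_rows, columns=["site_id", "chrom", "strand", "coord"]
                             ).set_index("site_id")
    obs_meta = pd.DataFrame(
        {"group": [cfg.groups[k] for k in group_of]},
        index=pd.Index(obs_ids, name="obs_id"),
    )
    counts = sp.csr_matrix(np.vstack(count_rows) if count_rows
                           else np.zeros((0, n_cells), dtype=np.int64))
    return PACDataset(counts=counts, site_meta=site_meta, obs_meta=obs_meta), truth


# ---------------------------------------------------------------------------
# toy annotation / alignments
# ---------------------------------------------------------------------------

def simulate_gtf(cfg: SimConfig, path: str | Path) -> Path:
    """Write a GTF whose gene/3'UTR intervals contain the simulated sites."""
    cfg.validate()
    path = Path(path)
    lines = []
    for i in range(cfg.n_genes):
        lay = _gene_layout(i)
        gid, tid = lay["gene_id"], lay["gene_id"] + ".t1"
        def rec(ftype, s, e, attrs):
            return (f"{lay['chrom']}\tapaviz_sim\t{ftype}\t{s}\t{e}\t.\t"
                    f"{lay['strand']}\t.\t{attrs}")
        gattr = f'gene_id "{gid}";'
        tattr = f'gene_id "{gid}"; transcript_id "{tid}";'
        lines.append(rec("gene", lay["start"], lay["end"], gattr))
        lines.append(rec("transcript", lay["start"], lay["end"], tattr))
        for s, e in lay["exons"]:
            lines.append(rec("exon", s, e, tattr))
        lines.append(rec("three_prime_utr", lay["utr3"][0], lay["utr3"][1], tattr))
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def simulate_alignments(cfg: SimConfig, pac: PACDataset, out_dir: str | Path
                        ) -> dict[str, Path]:
    """Per group, a sorted+indexed BAM with reads stacking to each site.

    For every site and group, as many ``read_len``-long fully-matching
    reads as the group's aggregated count, each read's 3' end placed at
    the site coordinate (strand-aware).
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sizes = chrom_sizes(cfg)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": ln} for c, ln in sizes.items()]}
    ref_id = {c: i for i, c in enumerate(sizes)}
    paths: dict[str, Path] = {}
    for grp in pac.groups():
        mask = (pac.obs_meta["group"].astype(str) == grp).to_numpy()
        agg = np.asarray(pac.counts[:, mask].sum(axis=1)).ravel()
        reads = []
        for (sid, s), c in zip(pac.site_meta.iterrows(), agg):
            if s["chrom"] not in ref_id or c == 0:
                continue
            coord = int(s["coord"])
            if s["strand"] == "+":
                start0 = max(0, coord - cfg.read_len)  # 0-based; 3' end at coord
                reverse = False
            else:
                start0 = coord - 1
                reverse = True
            for k in range(int(c)):
                reads.append((ref_id[s["chrom"]], start0, reverse, f"{sid}.r{k}"))
        reads.sort(key=lambda r: (r[0], r[1], r[3]))
        bam = out / f"{grp}.bam"
        with pysam.AlignmentFile(str(bam), "wb", header=header) as af:
            for rid, start0, reverse, name in reads:
                a = pysam.AlignedSegment()
                a.query_name = name
                a.reference_id = rid
                a.reference_start = start0
                a.is_reverse = reverse
                a.mapping_quality = 60
                a.cigarstring = f"{cfg.read_len}M"
                a.query_sequence = "A" * cfg.read_len
                af.write(a)
        pysam.index(str(bam))
        paths[grp] = bam
    return paths
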