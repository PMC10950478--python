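"""Gene-model parsing and poly(A)-site region assignment.

:func:`load_annotation` reduces a GTF/GFF3 file to one merged gene model
per gene: the union of exons over transcripts, introns as the within-gene
gaps between merged exons, and 3'UTRs either taken from explicit
``three_prime_utr`` records or derived per transcript as the exonic
sequence strictly 3' of the CDS stop, then unioned.

:func:`annotate_sites` assigns each cleavage site a gene and a region
label with priority ``UTR3 > ext_UTR3 > exon > intron > intergenic``.
``ext_UTR3`` is a fixed-length window immediately downstream (strand-aware)
of a gene's 3' end, excluding any base covered by another same-strand gene;
it captures distal sites beyond the annotated transcript end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._errors import ApavizError
from .core import PACDataset

logger = logging.getLogger(__name__)

REGION_PRIORITY = {"UTR3": 0, "ext_UTR3": 1, "exon": 2, "intron": 3}
REGIONS = ("UTR3", "ext_UTR3", "exon", "intron", "intergenic")

Interval = tuple[int, int]  # 1-based inclusive


def merge_intervals(ivs: list[Interval]) -> list[Interval]:
    """Union of 1-based inclusive intervals; adjacent intervals merge."""
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(ivs: list[Interval], holes: list[Interval]) -> list[Interval]:
    """Set difference of merged interval lists (both 1-based inclusive)."""
    out: list[Interval] = []
    for s, e in merge_intervals(ivs):
        cur = s
        for hs, he in sorted(holes):
            if he < cur or hs > e:
                continue
            if hs > cur:
                out.append((cur, hs - 1))
            cur = max(cur, he + 1)
            if cur > e:
                break
        if cur <= e:
            out.append((cur, e))
    return out


@dataclass
class GenomeAnnotation:
    """Merged per-gene models parsed from GTF/GFF3.

    ``genes`` is indexed by gene_id with columns chrom/strand/start/end
    (1-based inclusive); ``features`` maps gene_id to interval lists for
    ``UTR3``, ``exon`` and ``intron``.
    """

    genes: pd.DataFrame
    features: dict[str, dict[str, list[Interval]]] = field(default_factory=dict)

    def gene_3prime_end(self, gene_id: str) -> int:
        g = self.genes.loc[gene_id]
        return int(g["end"]) if g["strand"] == "+" else int(g["start"])


class AnnotationParseError(ApavizError):
    pass


def _utr3_from_cds(exons: list[Interval], cds: list[Interval], strand: str) -> list[Interval]:
    """Exonic bases strictly 3' of the CDS stop for one transcript."""
    if not cds or not exons:
        return []
    if strand == "+":
        stop = max(e for _, e in cds)
        return [(max(s, stop + 1), e) for s, e in exons if e > stop]
    stop = min(s for s, _ in cds)
    return [(s, min(e, stop - 1)) for s, e in exons if s < stop]


def load_annotation(gtf_path: str | Path) -> GenomeAnnotation:
    """Parse a GTF/GFF3 file into merged per-gene feature models.

    Tolerates both attribute dialects (``gene_id "x";`` and ``gene_id=x``).
    Genes without exon records are kept with their span only, with a
    warning.
    """
    # skip gffutils' gene/transcript inference when explicit records exist
    has_gene = has_tx = False
    with open(gtf_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            ftype = line.split("\t", 3)[2] if line.count("\t") >= 3 else ""
            has_gene |= ftype == "gene"
            has_tx |= ftype in ("transcript", "mRNA")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            db = gffutils.create_db(
                str(gtf_path), ":memory:",
                merge_strategy="create_unique", keep_order=True,
                disable_infer_genes=has_gene, disable_infer_transcripts=has_tx,
            )
    except Exception as exc:  # gffutils raises assorted types on bad lines
        raise AnnotationParseError(f"failed to parse {gtf_path}: {exc}") from exc

    utr_types = [t for t in ("three_prime_utr", "three_prime_UTR", "3UTR")
                 if t in set(db.featuretypes())]

    rows = []
    features: dict[str, dict[str, list[Interval]]] = {}
    for gene in db.features_of_type("gene"):
        gid = gene.id
        rows.append((gid, gene.seqid, gene.strand, gene.start, gene.end))
        exon_ivs: list[Interval] = []
        utr_ivs: list[Interval] = []
        for t in utr_types:
            utr_ivs += [(f.start, f.end) for f in db.children(gene, featuretype=t)]
        # per-transcript CDS-derived 3'UTR when no explicit records exist
        for tx in db.children(gene, level=1):
            if tx.featuretype not in ("transcript", "mRNA"):
                continue
            tx_exons = [(f.start, f.end) for f in db.children(tx, featuretype="exon")]
            exon_ivs += tx_exons
            if not utr_ivs:
                tx_cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
                utr_ivs += _utr3_from_cds(merge_intervals(tx_exons), tx_cds, gene.strand)
        # exons may hang directly off the gene (single-level files)
        exon_ivs += [(f.start, f.end) for f in db.children(gene, featuretype="exon", level=1)]

        exons = merge_intervals(exon_ivs)
        if not exons:
            warnings.warn(f"gene {gid} has no exon records; kept with span only")
        introns = [(exons[i][1] + 1, exons[i + 1][0] - 1) for i in range(len(exons) - 1)]
        features[gid] = {
            "UTR3": merge_intervals(utr_ivs),
            "exon": exons,
            "intron": introns,
        }
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    genes = genes.set_index("gene_id").sort_values(["chrom", "start"])
    return GenomeAnnotation(genes=genes, features=features)


# ---------------------------------------------------------------------------
# site annotation
# ---------------------------------------------------------------------------

def _ext_window(gene: pd.Series, ext3utr: int) -> list[Interval]:
    if ext3utr <= 0:
        return []
    if gene["strand"] == "+":
        return [(int(gene["end"]) + 1, int(gene["end"]) + ext3utr)]
    lo = max(1, int(gene["start"]) - ext3utr)
    hi = int(gene["start"]) - 1
    return [(lo, hi)] if lo <= hi else []


def _build_trees(anno: GenomeAnnotation, ext3utr: int) -> dict[tuple[str, str], IntervalTree]:
    """One interval tree per (chrom, strand); payload (priority, gene_id, 3' end)."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    spans_by_cs: dict[tuple[str, str], list[Interval]] = {}
    for gid, g in anno.genes.iterrows():
        spans_by_cs.setdefault((g["chrom"], g["strand"]), []).append(
            (int(g["start"]), int(g["end"])))
    for gid, g in anno.genes.iterrows():
        key = (g["chrom"], g["strand"])
        tree = trees.setdefault(key, IntervalTree())
        feats = anno.features.get(gid, {})
        end3 = anno.gene_3prime_end(gid)
        span = (int(g["start"]), int(g["end"]))
        region_ivs = {
            "UTR3": feats.get("UTR3", []),
            "exon": feats.get("exon", []) or [span],  # exonless gene: span only
            "intron": feats.get("intron", []),
        }
        other_spans = [s for s in spans_by_cs[key] if s != span]
        region_ivs["ext_UTR3"] = subtract_intervals(_ext_window(g, ext3utr), other_spans)
        for region, ivs in region_ivs.items():
            for s, e in ivs:
                if s <= e:  # skip degenerate (empty) intervals
                    tree[s:e + 1] = (REGION_PRIORITY[region], gid, end3)
    return trees


def annotate_sites(pac: PACDataset, anno: GenomeAnnotation, ext3utr: int = 1000) -> PACDataset:
    """Assign gene_id and region to every site of ``pac``.

    Region priority is ``UTR3 > ext_UTR3 > exon > intron``; sites matching
    no same-strand gene are ``intergenic`` with missing gene_id.  When two
    genes compete at equal priority the site goes to the gene whose 3' end
    is nearer, ties broken by lexicographically smaller gene_id.
    Idempotent: re-annotating with the same inputs changes nothing.
    """
    trees = _build_trees(anno, ext3utr)
    known_chroms = set(anno.genes["chrom"])
    gene_ids: list[object] = []
    regions: list[str] = []
    n_missing_chrom = 0
    inv_priority = {v: k for k, v in REGION_PRIORITY.items()}
    for sid, s in pac.site_meta.iterrows():
        chrom, strand, coord = s["chrom"], s["strand"], int(s["coord"])
        if chrom not in known_chroms:
            n_missing_chrom += 1
        tree = trees.get((chrom, strand))
        hits = tree[coord] if tree is not None else set()
        if not hits:
            gene_ids.append(pd.NA)
            regions.append("intergenic")
            continue
        prio, gid, end3 = min(
            (iv.data for iv in hits),
            key=lambda d: (d[0], abs(coord - d[2]), d[1]),
        )
        gene_ids.append(gid)
        regions.append(inv_priority[prio])
    if n_missing_chrom:
        warnings.warn(
            f"{n_missing_chrom} site(s) on chromosomes absent from the annotation; "
            "annotated as intergenic"
        )
    site_meta = pac.site_meta.copy()
    site_meta["gene_id"] = pd.array(gene_ids, dtype="string")
    site_meta["region"] = regions
    return PACDataset(counts=pac.counts, site_meta=site_meta, obs_meta=pac.obs_meta)
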