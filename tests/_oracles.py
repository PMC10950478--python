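"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (nested loops, per-base dicts,
exhaustive enumeration) and shares no code with the package internals.
"""

from itertools import combinations
from math import comb

import numpy as np
import pysam

REGION_ORDER = ["UTR3", "ext_UTR3", "exon", "intron"]


def brute_force_annotate(site, genes, features, ext3utr):
    """All-pairs region assignment for one site.

    ``site`` = (chrom, strand, coord); ``genes`` = dict gene_id ->
    (chrom, strand, start, end); ``features`` = dict gene_id ->
    {"UTR3": [...], "exon": [...], "intron": [...]}.
    Returns (gene_id or None, region).
    """
    chrom, strand, coord = site
    candidates = []
    for gid, (gc, gs, start, end) in genes.items():
        if gc != chrom or gs != strand:
            continue
        feats = features.get(gid, {})

        def contains(ivs):
            return any(s <= coord <= e for s, e in ivs)

        region = None
        if contains(feats.get("UTR3", [])):
            region = "UTR3"
        else:
            # ext window: downstream of the 3' end, excluding other genes
            if gs == "+":
                in_window = end < coord <= end + ext3utr
                end3 = end
            else:
                in_window = start - ext3utr <= coord < start
                end3 = start
            if in_window:
                covered = any(
                    oc == chrom and os == strand and s0 <= coord <= e0
                    for og, (oc, os, s0, e0) in genes.items() if og != gid
                )
                if not covered:
                    region = "ext_UTR3"
            if region is None and contains(feats.get("exon", []) or [(start, end)]):
                region = "exon"
            elif region is None and contains(feats.get("intron", [])):
                region = "intron"
        if region is not None:
            end3 = end if gs == "+" else start
            candidates.append((REGION_ORDER.index(region), abs(coord - end3), gid, region))
    if not candidates:
        return None, "intergenic"
    _, _, gid, region = min(candidates)
    return gid, region


def brute_force_coverage(bam_path, chrom, start, end, gene_strand=None):
    """Per-base depth via a per-read, per-base dictionary walk."""
    cover = {}
    with pysam.AlignmentFile(str(bam_path)) as af:
        if chrom not in af.references:
            return np.zeros(end - start + 1, dtype=int)
        for read in af.fetch(chrom, start - 1, end):
            if read.is_unmapped:
                continue
            if gene_strand is not None:
                if ("-" if read.is_reverse else "+") != gene_strand:
                    continue
            pos = read.reference_start + 1  # 1-based
            for op, ln in read.cigartuples or ():
                if op in (0, 2, 7, 8):
                    for p in range(pos, pos + ln):
                        cover[p] = cover.get(p, 0) + 1
                    pos += ln
                elif op == 3:
                    pos += ln
    return np.array([cover.get(p, 0) for p in range(start, end + 1)], dtype=int)


def enumerate_ranksum_pvalue(x, y):
    """Exhaustive two-sided rank-sum p-value (tie-free samples).

    Enumerates all C(m+n, m) placements of group x among the pooled ranks
    and computes p = 2 * min(P(U <= u_obs), P(U >= u_obs)), capped at 1.
    """
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    m, n = len(x), len(y)
    u_obs = sum(rank[v] for v in x) - m * (m + 1) // 2
    n_le = n_ge = 0
    for combo in combinations(range(1, m + n + 1), m):
        u = sum(combo) - m * (m + 1) // 2
        n_le += u <= u_obs
        n_ge += u >= u_obs
    total = comb(m + n, m)
    return min(1.0, 2.0 * min(n_le / total, n_ge / total))


def direct_rud(site_counts, site_coords, strand):
    """RUD by direct per-site tally: distal count over total count.

    ``site_counts``: list of per-site counts for one gene in one cell;
    ``site_coords``: matching coordinates.  Returns (distal, total).
    """
    order = np.argsort(site_coords)
    distal_idx = order[-1] if strand == "+" else order[0]
    total = float(np.sum(site_counts))
    return float(site_counts[distal_idx]), total
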