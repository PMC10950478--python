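"""APA usage indices.

RUD (Relative Usage of Distal poly(A) site) for a gene in one observation
is the fraction of the gene's usable-site reads assigned to the distal
site::

    RUD = count(distal) / count(all usable sites)

Usable sites are those annotated ``UTR3`` or ``ext_UTR3``; the distal site
is the usable site farthest 3' in strand-aware order (highest coordinate
on ``+``, lowest on ``-``).  Genes need at least two usable sites.  For
genes with more than two sites the denominator is the sum over all usable
sites, which keeps RUD in [0, 1] and reduces to the two-site definition.
A value is missing (NaN) when the denominator is below ``min_counts``;
low RUD indicates 3'UTR shortening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ParameterError
from .core import PACDataset

USABLE_REGIONS = ("UTR3", "ext_UTR3")


@dataclass
class RUDMatrix:
    """Gene x observation RUD values with NaN where under-covered.

    ``site_partition`` records, per gene, the (proximal site ids, distal
    site id) split the index was computed from.
    """

    values: pd.DataFrame  # genes x observations, float with NaN
    site_partition: dict[str, tuple[tuple[str, ...], str]] = field(default_factory=dict)
    min_counts: int = 5

    @property
    def gene_index(self) -> pd.Index:
        return self.values.index

    @property
    def obs_index(self) -> pd.Index:
        return self.values.columns

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")
        return path


def compute_rud(pac: PACDataset, min_counts: int = 5) -> RUDMatrix:
    """Per-gene, per-observation RUD from an annotated PACDataset."""
    if min_counts < 1:
        raise ParameterError("min_counts must be a positive integer")
    if "gene_id" not in pac.site_meta.columns or "region" not in pac.site_meta.columns:
        raise ParameterError("PACDataset is not annotated (missing gene_id/region); "
                             "run annotate_sites first")
    sm = pac.site_meta
    usable = sm["region"].isin(USABLE_REGIONS) & sm["gene_id"].notna()
    counts = pac.counts.tocsr()

    rows: list[np.ndarray] = []
    genes: list[str] = []
    partition: dict[str, tuple[tuple[str, ...], str]] = {}
    for gid, sub in sm[usable].groupby("gene_id", sort=True):
        if len(sub) < 2:
            continue
        # strand-aware 3' order: distal has the highest coord on +, lowest on -
        strand = sub["strand"].iloc[0]
        distal_id = sub["coord"].idxmax() if strand == "+" else sub["coord"].idxmin()
        proximal_ids = tuple(i for i in sub.index if i != distal_id)
        idx = pac.site_meta.index.get_indexer(sub.index)
        total = np.asarray(counts[idx].sum(axis=0)).ravel().astype(float)
        distal = np.asarray(
            counts[pac.site_meta.index.get_loc(distal_id)].todense()
        ).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rud = np.where(total >= min_counts, distal / total, np.nan)
        rows.append(rud)
        genes.append(str(gid))
        partition[str(gid)] = (proximal_ids, str(distal_id))

    if not genes:
        warnings.warn("no gene with >= 2 usable (UTR3/ext_UTR3) sites; RUD matrix is empty")
        values = pd.DataFrame(np.zeros((0, pac.n_obs)), columns=pac.obs_ids)
    else:
        values = pd.DataFrame(np.vstack(rows), index=pd.Index(genes, name="gene_id"),
                              columns=pac.obs_ids)
    return RUDMatrix(values=values, site_partition=partition, min_counts=min_counts)


def mean_rud_per_obs(rud: RUDMatrix) -> pd.Series:
    """Per observation, the mean over non-missing gene RUD values.

    NaN where an observation has no non-missing gene.
    """
    return rud.values.mean(axis=0, skipna=True).rename("mean_rud")


def read_rud_tsv(path: str | Path) -> RUDMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    values.index.name = "gene_id"
    return RUDMatrix(values=values)
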