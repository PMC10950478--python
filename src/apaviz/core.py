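"""Unified poly(A)-site dataset container and its I/O.

A :class:`PACDataset` couples a sites x observations count matrix with a
site metadata table (genomic position of each cleavage site) and an
observation metadata table (cell/sample group labels).  Observations are
cells for single-cell data and samples for bulk data.  All downstream
operations -- annotation, usage indices, marker detection, figures --
consume this one container.

Coordinates are 1-based and strand-aware; a poly(A) site is a single base,
the cleavage position reported by an upstream site caller.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._errors import IdAlignmentError, SchemaError, UnknownIdError, ValidationError

SITE_META_REQUIRED = ("chrom", "strand", "coord")
OBS_META_REQUIRED = ("group",)

_COUNTS_SPARSE = "counts.mtx"
_COUNTS_DENSE = "counts.tsv"
_SITES_TSV = "sites.tsv"
_OBS_TSV = "obs.tsv"


@dataclass
class PACDataset:
    """Poly(A)-site counts plus site and observation metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, sites x observations.  Stored sparse
        (CSR) internally; any array or sparse matrix is accepted.
    site_meta
        DataFrame indexed by unique ``site_id`` with columns ``chrom``
        (str), ``strand`` (``+``/``-``), ``coord`` (1-based int), and --
        after annotation -- ``gene_id`` and ``region``.
    obs_meta
        DataFrame indexed by unique ``obs_id`` with a ``group`` column.
    """

    counts: sp.csr_matrix
    site_meta: pd.DataFrame
    obs_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.site_meta = self.site_meta.copy()
        self.obs_meta = self.obs_meta.copy()
        self.site_meta.index = self.site_meta.index.astype(str)
        self.obs_meta.index = self.obs_meta.index.astype(str)
        self.site_meta.index.name = "site_id"
        self.obs_meta.index.name = "obs_id"
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        for col in SITE_META_REQUIRED:
            if col not in self.site_meta.columns:
                raise SchemaError(f"site metadata is missing required column '{col}'")
        for col in OBS_META_REQUIRED:
            if col not in self.obs_meta.columns:
                raise SchemaError(f"observation metadata is missing required column '{col}'")
        if self.counts.shape != (len(self.site_meta), len(self.obs_meta)):
            raise IdAlignmentError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.site_meta)} sites x {len(self.obs_meta)} observations"
            )
        if not self.site_meta.index.is_unique:
            dup = self.site_meta.index[self.site_meta.index.duplicated()][:5].tolist()
            raise ValidationError(f"duplicate site ids: {dup}")
        if not self.obs_meta.index.is_unique:
            dup = self.obs_meta.index[self.obs_meta.index.duplicated()][:5].tolist()
            raise ValidationError(f"duplicate observation ids: {dup}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts contain negative values")
        if len(self.site_meta):
            coords = pd.to_numeric(self.site_meta["coord"], errors="raise")
            if (coords < 1).any():
                raise ValidationError("site coords must be >= 1 (1-based)")
            self.site_meta["coord"] = coords.astype(np.int64)
            bad_strand = ~self.site_meta["strand"].isin(["+", "-"])
            if bad_strand.any():
                raise ValidationError(
                    f"invalid strand values: {sorted(self.site_meta.loc[bad_strand, 'strand'].unique())}"
                )
        if self.obs_meta["group"].isna().any():
            missing = self.obs_meta.index[self.obs_meta["group"].isna()][:5].tolist()
            raise ValidationError(f"observations with missing group label: {missing}")

    # -- convenience ----------------------------------------------------
    @property
    def site_ids(self) -> pd.Index:
        return self.site_meta.index

    @property
    def obs_ids(self) -> pd.Index:
        return self.obs_meta.index

    @property
    def n_sites(self) -> int:
        return len(self.site_meta)

    @property
    def n_obs(self) -> int:
        return len(self.obs_meta)

    def counts_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def groups(self) -> list[str]:
        """Group labels in first-appearance order of obs_meta."""
        return list(pd.unique(self.obs_meta["group"].astype(str)))

    def equals(self, other: "PACDataset") -> bool:
        return (
            (self.counts != other.counts).nnz == 0
            and self.site_meta.equals(other.site_meta)
            and self.obs_meta.equals(other.obs_meta)
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_meta(path: str | Path, key: str, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={key: str}, keep_default_na=True)
    if key not in df.columns:
        raise SchemaError(f"metadata file {path} is missing required column '{key}'")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"metadata file {path} is missing required column '{col}'")
    return df.set_index(key)


def _looks_sparse(path: str | Path) -> bool:
    if str(path).endswith(".mtx"):
        return True
    with open(path, "rb") as fh:
        return fh.read(14) == b"%%MatrixMarket"


def read_pac(counts_path: str | Path, site_meta_path: str | Path,
             obs_meta_path: str | Path) -> PACDataset:
    """Read a PACDataset from disk.

    ``counts_path`` may be a MatrixMarket coordinate file (sites in the row
    order of the sites TSV, observations in the row order of the obs TSV)
    or a dense TSV with site ids as row labels and obs ids as column
    headers.  Rows/columns are reordered to match the metadata key order.
    """
    site_meta = _read_meta(site_meta_path, "site_id", SITE_META_REQUIRED)
    obs_meta = _read_meta(obs_meta_path, "obs_id", OBS_META_REQUIRED)

    if _looks_sparse(counts_path):
        counts = sp.csr_matrix(scipy.io.mmread(counts_path))
        if counts.shape != (len(site_meta), len(obs_meta)):
            raise IdAlignmentError(
                f"matrix shape {counts.shape} does not match metadata "
                f"({len(site_meta)} sites x {len(obs_meta)} observations)"
            )
    else:
        dense = pd.read_csv(counts_path, sep="\t", index_col=0)
        dense.index = dense.index.astype(str)
        dense.columns = dense.columns.astype(str)
        _check_ids(dense.index, site_meta.index, "site")
        _check_ids(dense.columns, obs_meta.index, "observation")
        dense = dense.loc[site_meta.index, obs_meta.index]
        if (dense.to_numpy() < 0).any():
            raise ValidationError("counts contain negative values")
        counts = sp.csr_matrix(dense.to_numpy())
    return PACDataset(counts=counts, site_meta=site_meta, obs_meta=obs_meta)


def _check_ids(found: pd.Index, expected: pd.Index, what: str) -> None:
    extra = found.difference(expected)
    missing = expected.difference(found)
    if len(extra) or len(missing):
        offending = (list(extra[:5]) + list(missing[:5]))[:5]
        raise IdAlignmentError(
            f"{what} ids of counts do not match metadata; first offenders: {offending}"
        )


def write_pac(pac: PACDataset, out_dir: str | Path, layout: str = "sparse") -> Path:
    """Write a PACDataset to ``out_dir`` (MTX+TSV sidecars or dense TSV).

    Guarantees an exact round trip: ``read_pac`` on the written files
    reproduces counts and metadata.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.access(out, os.W_OK):
        raise OSError(f"output directory not writable: {out}")
    pac.site_meta.to_csv(out / _SITES_TSV, sep="\t")
    pac.obs_meta.to_csv(out / _OBS_TSV, sep="\t")
    if layout == "sparse":
        mat = sp.coo_matrix(pac.counts)
        scipy.io.mmwrite(str(out / _COUNTS_SPARSE), mat, field="integer")
    elif layout == "dense":
        df = pd.DataFrame(pac.counts_dense(), index=pac.site_ids, columns=pac.obs_ids)
        df.index.name = "site_id"
        df.to_csv(out / _COUNTS_DENSE, sep="\t")
    else:
        raise ValueError(f"unknown layout '{layout}' (expected 'sparse' or 'dense')")
    return out


def read_pac_dir(in_dir: str | Path) -> PACDataset:
    """Read a directory produced by :func:`write_pac`."""
    d = Path(in_dir)
    counts = d / _COUNTS_SPARSE
    if not counts.exists():
        counts = d / _COUNTS_DENSE
    if not counts.exists():
        raise FileNotFoundError(f"no counts.mtx or counts.tsv under {d}")
    return read_pac(counts, d / _SITES_TSV, d / _OBS_TSV)


# ---------------------------------------------------------------------------
# subsetting / aggregation
# ---------------------------------------------------------------------------

def subset_pac(pac: PACDataset, site_ids: Sequence[str] | None = None,
               obs_ids: Sequence[str] | None = None) -> PACDataset:
    """Submatrix plus matching metadata; output order follows request order."""
    if site_ids is None:
        site_ids = list(pac.site_ids)
    if obs_ids is None:
        obs_ids = list(pac.obs_ids)
    for sid in site_ids:
        if sid not in pac.site_meta.index:
            raise UnknownIdError(f"unknown site id '{sid}'")
    for oid in obs_ids:
        if oid not in pac.obs_meta.index:
            raise UnknownIdError(f"unknown observation id '{oid}'")
    ri = pac.site_meta.index.get_indexer(site_ids)
    ci = pac.obs_meta.index.get_indexer(obs_ids)
    return PACDataset(
        counts=pac.counts[ri][:, ci],
        site_meta=pac.site_meta.iloc[ri],
        obs_meta=pac.obs_meta.iloc[ci],
    )


def aggregate_by_group(pac: PACDataset) -> PACDataset:
    """Pseudo-bulk: one output observation per group, counts summed.

    Groups appear in first-appearance order of ``obs_meta``; the group id
    doubles as the output observation id and group label.
    """
    groups = pac.groups()
    cols = []
    for g in groups:
        mask = (pac.obs_meta["group"].astype(str) == g).to_numpy()
        cols.append(np.asarray(pac.counts[:, mask].sum(axis=1)).ravel())
    agg = sp.csr_matrix(np.column_stack(cols) if cols else
                        np.zeros((pac.n_sites, 0), dtype=np.int64))
    obs_meta = pd.DataFrame({"group": groups}, index=pd.Index(groups, name="obs_id"))
    return PACDataset(counts=agg, site_meta=pac.site_meta, obs_meta=obs_meta)
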