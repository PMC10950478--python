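"""2D embeddings of observations from APA profiles.

Observations are embedded with UMAP either from poly(A)-site expression
(counts normalized per cell to 10k, log1p, reduced to 50 principal
components before the neighbor graph -- standard single-cell practice) or
from RUD usage values (missing entries median-imputed per gene for the
embedding only; the RUDMatrix itself is never modified).  A scalar or
categorical per-observation overlay (e.g. mean RUD, group label) can be
attached for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
import umap

from ._errors import ParameterError, UnknownIdError
from .core import PACDataset
from .metrics import RUDMatrix

SOURCES = ("site_expression", "rud_usage")


@dataclass
class Embedding2D:
    """Observation x 2 coordinates with the parameters that produced them."""

    coords: pd.DataFrame  # index obs_id, columns ["x", "y"]
    source: str
    params: dict
    overlay: pd.Series | None = None

    @property
    def obs_index(self) -> pd.Index:
        return self.coords.index

    def write_tsv(self, path) -> None:
        out = self.coords.copy()
        if self.overlay is not None:
            out["overlay"] = self.overlay
        out.index.name = "obs_id"
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def _site_expression_features(pac: PACDataset) -> tuple[np.ndarray, pd.Index]:
    x = pac.counts_dense().T.astype(float)  # obs x sites
    libsize = x.sum(axis=1, keepdims=True)
    libsize[libsize == 0] = 1.0
    return np.log1p(x / libsize * 1e4), pac.obs_ids


def _rud_features(rud: RUDMatrix) -> tuple[np.ndarray, pd.Index]:
    vals = rud.values.to_numpy(dtype=float).T.copy()  # obs x genes
    med = np.nanmedian(rud.values.to_numpy(dtype=float), axis=1)
    med = np.where(np.isnan(med), 0.5, med)  # all-missing gene: neutral usage
    nan_r, nan_c = np.where(np.isnan(vals))
    vals[nan_r, nan_c] = med[nan_c]
    return vals, rud.obs_index


def compute_embedding(data: PACDataset | RUDMatrix, source: str = "site_expression",
                      n_neighbors: int = 15, min_dist: float = 0.1,
                      seed: int = 42, n_pcs: int = 50) -> Embedding2D:
    """UMAP coordinates of observations from site counts or RUD usage.

    Deterministic for a fixed seed on one platform.  Exactly duplicated
    observations are collapsed before the fit and receive identical
    coordinates.
    """
    if source not in SOURCES:
        raise ParameterError(f"unknown source '{source}'; expected one of {SOURCES}")
    if isinstance(data, PACDataset):
        if source == "rud_usage":
            raise ParameterError("source 'rud_usage' needs a RUDMatrix input")
        feats, obs_index = _site_expression_features(data)
    else:
        if source == "site_expression":
            raise ParameterError("source 'site_expression' needs a PACDataset input")
        feats, obs_index = _rud_features(data)

    n_obs = feats.shape[0]
    if n_obs < n_neighbors + 1:
        raise ParameterError(
            f"n_neighbors={n_neighbors} requires at least {n_neighbors + 1} "
            f"observations, got {n_obs}"
        )

    uniq, inverse = np.unique(feats, axis=0, return_inverse=True)
    k = min(n_pcs, uniq.shape[0] - 1, uniq.shape[1])
    reduced = PCA(n_components=k, random_state=seed).fit_transform(uniq) if k >= 2 else uniq
    reducer = umap.UMAP(n_neighbors=min(n_neighbors, uniq.shape[0] - 1),
                        min_dist=min_dist, n_components=2, random_state=seed)
    emb_uniq = reducer.fit_transform(reduced)
    coords = pd.DataFrame(np.asarray(emb_uniq, dtype=float)[inverse],
                          index=obs_index, columns=["x", "y"])
    if not np.isfinite(coords.to_numpy()).all():
        raise RuntimeError("embedding produced non-finite coordinates")
    params = dict(n_neighbors=n_neighbors, min_dist=min_dist, seed=seed, n_pcs=n_pcs)
    return Embedding2D(coords=coords, source=source, params=params)


def attach_overlay(emb: Embedding2D, values: pd.Series) -> Embedding2D:
    """Return a copy of ``emb`` with a per-observation overlay attached.

    ``values`` must be keyed by obs_id and cover the embedded observations
    (missing values allowed as NaN, rendered neutrally downstream).
    """
    values = values.copy()
    values.index = values.index.astype(str)
    unknown = values.index.difference(emb.obs_index)
    if len(unknown):
        raise UnknownIdError(f"overlay keyed by unknown obs ids: {list(unknown[:5])}")
    missing = emb.obs_index.difference(values.index)
    if len(missing):
        raise UnknownIdError(f"overlay missing obs ids: {list(missing[:5])}")
    return replace(emb, overlay=values.reindex(emb.obs_index))
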