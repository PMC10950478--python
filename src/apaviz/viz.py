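"""Figure rendering: browser-style tracks, per-gene charts, embeddings, markers.

Every figure is first assembled as an inspectable specification object
(track list, mark coordinates, axis limits, panel counts); rendering then
rasterizes that spec with matplotlib.  Tests assert on the spec, not on
pixels.  All plotting functions are pure with respect to their inputs.
Output format (PNG/PDF) follows the file extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import pysam

from ._errors import ParameterError, UnknownIdError
from .anno import GenomeAnnotation
from .core import PACDataset, aggregate_by_group
from .metrics import RUDMatrix

logger = logging.getLogger(__name__)

STAT_CHARTS = ("violin", "box", "dot", "bubble", "heatmap")
MARKER_CHARTS = ("violin", "dot", "heatmap")


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    """Per-base read depth over a 1-based inclusive region."""

    chrom: str
    start: int
    end: int
    depth: np.ndarray  # length end - start + 1
    group: str | None = None
    strand_mode: str = "both"

    def __post_init__(self) -> None:
        expect = max(0, self.end - self.start + 1)
        if len(self.depth) != expect:
            raise ValueError(f"depth length {len(self.depth)} != region length {expect}")


def compute_coverage(alignments: str | Path, chrom: str, start: int, end: int,
                     strand_mode: str = "both", gene_strand: str | None = None,
                     group: str | None = None) -> CoverageProfile:
    """Per-base depth of aligned (match/deletion) bases over [start, end].

    ``strand_mode='same_as_gene'`` keeps only reads whose orientation
    matches ``gene_strand``.  The alignment file must be indexed.
    """
    if strand_mode not in ("both", "same_as_gene"):
        raise ParameterError("strand_mode must be 'both' or 'same_as_gene'")
    if strand_mode == "same_as_gene" and gene_strand not in ("+", "-"):
        raise ParameterError("strand_mode='same_as_gene' needs gene_strand '+' or '-'")
    length = max(0, end - start + 1)
    depth = np.zeros(length, dtype=np.int64)
    if length == 0:
        return CoverageProfile(chrom, start, end, depth, group, strand_mode)
    with pysam.AlignmentFile(str(alignments)) as af:
        if not af.has_index():
            raise OSError(f"alignment file {alignments} has no index")
        if chrom not in af.references:
            return CoverageProfile(chrom, start, end, depth, group, strand_mode)
        for read in af.fetch(chrom, start - 1, end):
            if read.is_unmapped:
                continue
            if strand_mode == "same_as_gene":
                read_strand = "-" if read.is_reverse else "+"
                if read_strand != gene_strand:
                    continue
            pos = read.reference_start  # 0-based
            for op, ln in read.cigartuples or ():
                if op in (0, 2, 7, 8):  # M, D, =, X consume reference and cover it
                    lo = max(pos, start - 1)
                    hi = min(pos + ln, end)
                    if lo < hi:
                        depth[lo - (start - 1): hi - (start - 1)] += 1
                    pos += ln
                elif op == 3:  # N skips reference without coverage
                    pos += ln
    return CoverageProfile(chrom, start, end, depth, group, strand_mode)


# ---------------------------------------------------------------------------
# track figure
# ---------------------------------------------------------------------------

@dataclass
class Track:
    kind: str  # gene_model | pA_sites | coverage | single_cell_counts
    label: str
    payload: dict


@dataclass
class TrackFigure:
    """Composed multi-track plot spec sharing one genomic x-axis."""

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str
    tracks: list[Track] = field(default_factory=list)
    rendered_output: Path | None = None

    @property
    def xlim(self) -> tuple[int, int]:
        return (self.start, self.end)


def _gene_model_track(anno: GenomeAnnotation, gene_id: str) -> Track:
    feats = anno.features.get(gene_id, {})
    return Track(kind="gene_model", label="gene", payload={
        "exons": list(feats.get("exon", [])),
        "introns": list(feats.get("intron", [])),
        "utr3": list(feats.get("UTR3", [])),
        "strand": anno.genes.loc[gene_id, "strand"],
    })


def build_track_figure(pac: PACDataset, anno: GenomeAnnotation, gene: str,
                       alignments_by_group: dict[str, str | Path] | None = None,
                       cells_track: bool = True, ext3utr: int = 1000,
                       strand_mode: str = "both") -> TrackFigure:
    """Assemble the track spec for one gene (no rasterization).

    Region is the gene span plus an ``ext3utr`` margin on the 3' side.
    Tracks, top to bottom: merged gene model; pA marks (height = aggregated
    expression per site); one coverage track per group when alignments are
    given; a sites x cells count heatmap ordered by group then by total
    gene count descending.
    """
    if gene not in anno.genes.index:
        raise UnknownIdError(f"unknown gene id '{gene}'")
    g = anno.genes.loc[gene]
    chrom, strand = g["chrom"], g["strand"]
    start, end = int(g["start"]), int(g["end"])
    if strand == "+":
        end += ext3utr
    else:
        start = max(1, start - ext3utr)
    fig = TrackFigure(chrom=chrom, start=start, end=end, gene_id=gene, strand=strand)
    fig.tracks.append(_gene_model_track(anno, gene))

    in_region = (
        (pac.site_meta["chrom"] == chrom)
        & (pac.site_meta["strand"] == strand)
        & (pac.site_meta["coord"] >= start)
        & (pac.site_meta["coord"] <= end)
    )
    region_sites = pac.site_meta.index[in_region]
    if len(region_sites) == 0:
        logger.info("gene %s has no poly(A) site in the plotted region", gene)
    pseudo = aggregate_by_group(pac)
    site_expr = pd.DataFrame(
        pseudo.counts_dense(), index=pseudo.site_ids, columns=pseudo.obs_ids
    ).loc[region_sites]
    fig.tracks.append(Track(kind="pA_sites", label="pA", payload={
        "coords": pac.site_meta.loc[region_sites, "coord"].tolist(),
        "heights": site_expr.sum(axis=1).tolist(),
        "site_ids": list(region_sites),
    }))

    if alignments_by_group:
        for grp, path in alignments_by_group.items():
            prof = compute_coverage(path, chrom, start, end, strand_mode=strand_mode,
                                    gene_strand=strand, group=grp)
            fig.tracks.append(Track(kind="coverage", label=f"coverage:{grp}",
                                    payload={"profile": prof}))

    if cells_track:
        order = pac.obs_meta.copy()
        order["_total"] = np.asarray(
            pac.counts[pac.site_meta.index.get_indexer(region_sites)].sum(axis=0)
        ).ravel() if len(region_sites) else 0
        order["_grp_rank"] = order["group"].astype(str).map(
            {g: i for i, g in enumerate(pac.groups())})
        cell_order = order.sort_values(["_grp_rank", "_total"],
                                       ascending=[True, False]).index
        mat = pd.DataFrame(pac.counts_dense(), index=pac.site_ids,
                           columns=pac.obs_ids).loc[region_sites, cell_order]
        fig.tracks.append(Track(kind="single_cell_counts", label="cells", payload={
            "matrix": mat,
            "cell_groups": pac.obs_meta.loc[cell_order, "group"].astype(str).tolist(),
            "coords": pac.site_meta.loc[region_sites, "coord"].tolist(),
        }))
    return fig


def render_track_figure(fig: TrackFigure, out: str | Path) -> TrackFigure:
    """Rasterize a TrackFigure to ``out``; all panels share x-limits."""
    n = len(fig.tracks)
    heights = [0.6 if t.kind == "gene_model" else
               (1.6 if t.kind == "single_cell_counts" else 1.0) for t in fig.tracks]
    f, axes = plt.subplots(n, 1, figsize=(9, 1.1 * sum(heights) + 0.8),
                           sharex=True, gridspec_kw={"height_ratios": heights})
    axes = np.atleast_1d(axes)
    for ax, tr in zip(axes, fig.tracks):
        ax.set_xlim(fig.start, fig.end)
        ax.set_ylabel(tr.label, rotation=0, ha="right", va="center", fontsize=8)
        if tr.kind == "gene_model":
            for s, e in tr.payload["introns"]:
                ax.plot([s, e], [0.5, 0.5], color="0.4", lw=1)
            for s, e in tr.payload["exons"]:
                ax.add_patch(plt.Rectangle((s, 0.25), e - s + 1, 0.5, color="0.25"))
            for s, e in tr.payload["utr3"]:
                ax.add_patch(plt.Rectangle((s, 0.32), e - s + 1, 0.36, color="tab:orange"))
            arrow = ">" if tr.payload["strand"] == "+" else "<"
            ax.text(fig.end if tr.payload["strand"] == "+" else fig.start, 0.5,
                    arrow, ha="center", va="center", fontsize=10)
            ax.set_ylim(0, 1)
            ax.set_yticks([])
        elif tr.kind == "pA_sites":
            coords, hts = tr.payload["coords"], tr.payload["heights"]
            if coords:
                ax.vlines(coords, 0, hts, color="tab:red", lw=2)
                ax.plot(coords, hts, "v", color="tab:red", ms=5)
            ax.set_ylim(0, max(hts, default=1) * 1.2 or 1)
        elif tr.kind == "coverage":
            prof: CoverageProfile = tr.payload["profile"]
            xs = np.arange(prof.start, prof.end + 1)
            ax.fill_between(xs, prof.depth, step="mid", color="tab:blue", alpha=0.7)
            ax.set_ylim(bottom=0)
        elif tr.kind == "single_cell_counts":
            mat: pd.DataFrame = tr.payload["matrix"]
            coords = tr.payload["coords"]
            if len(mat) and mat.shape[1]:
                # one thin horizontal lane per cell; dots at site coords sized by count
                vals = mat.to_numpy(dtype=float)
                ax.imshow(np.log1p(vals.T), aspect="auto", cmap="viridis",
                          extent=(fig.start, fig.end, mat.shape[1], 0),
                          interpolation="nearest")
            ax.set_yticks([])
        ax.spines[["top", "right"]].set_visible(False)
    axes[-1].set_xlabel(f"{fig.chrom}:{fig.start}-{fig.end} ({fig.strand})")
    f.suptitle(fig.gene_id, fontsize=10)
    f.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(f)
    fig.rendered_output = Path(out)
    return fig


def viz_tracks(pac: PACDataset, anno: GenomeAnnotation, gene: str, out: str | Path,
               alignments_by_group: dict[str, str | Path] | None = None,
               cells_track: bool = True, ext3utr: int = 1000,
               strand_mode: str = "both") -> TrackFigure:
    """Build and render the browser-style track figure for one gene."""
    fig = build_track_figure(pac, anno, gene, alignments_by_group=alignments_by_group,
                             cells_track=cells_track, ext3utr=ext3utr,
                             strand_mode=strand_mode)
    return render_track_figure(fig, out)


# ---------------------------------------------------------------------------
# per-gene statistics charts
# ---------------------------------------------------------------------------

@dataclass
class ChartSpec:
    """What a rendered chart contains, for inspection in tests."""

    chart: str
    level: str
    gene: str
    groups: list[str]
    panels: int  # violins/boxes/dot rows etc.
    data: pd.DataFrame
    path: Path | None = None


def _gene_site_expression(pac: PACDataset, gene: str) -> pd.DataFrame:
    if "gene_id" not in pac.site_meta.columns:
        raise ParameterError("PACDataset is not annotated; run annotate_sites first")
    sites = pac.site_meta.index[pac.site_meta["gene_id"] == gene]
    if len(sites) == 0:
        raise UnknownIdError(f"gene '{gene}' has no annotated site")
    mat = pd.DataFrame(pac.counts_dense(), index=pac.site_ids, columns=pac.obs_ids)
    long = mat.loc[sites].T.stack().rename("value").reset_index()
    long.columns = ["obs_id", "site_id", "value"]
    long["group"] = long["obs_id"].map(pac.obs_meta["group"].astype(str))
    return long


def viz_stats(data: PACDataset | RUDMatrix, gene: str, out: str | Path,
              chart: str = "violin", level: str = "site_expression",
              groups: pd.Series | None = None) -> ChartSpec:
    """One chart for one gene, grouped by cell group.

    ``level='site_expression'`` (PACDataset input) shows per-site count
    distributions per group; ``level='rud'`` (RUDMatrix input plus a
    ``groups`` series) shows per-cell RUD per group.
    """
    if chart not in STAT_CHARTS:
        raise ParameterError(f"unknown chart '{chart}'; expected one of {STAT_CHARTS}")
    if level == "site_expression":
        if not isinstance(data, PACDataset):
            raise ParameterError("level='site_expression' needs a PACDataset")
        long = _gene_site_expression(data, gene)
        facet = "site_id"
    elif level == "rud":
        if not isinstance(data, RUDMatrix):
            raise ParameterError("level='rud' needs a RUDMatrix")
        if gene not in data.gene_index:
            raise UnknownIdError(f"gene '{gene}' not in RUD matrix")
        if groups is None:
            raise ParameterError("level='rud' needs per-observation group labels")
        long = data.values.loc[gene].rename("value").reset_index()
        long.columns = ["obs_id", "value"]
        long["group"] = long["obs_id"].map(groups.astype(str))
        long = long.dropna(subset=["value"])
        facet = None
    else:
        raise ParameterError("level must be 'site_expression' or 'rud'")

    grp_order = list(pd.unique(long["group"]))
    facets = list(pd.unique(long[facet])) if facet else [gene]
    spec = ChartSpec(chart=chart, level=level, gene=gene, groups=grp_order,
                     panels=len(facets) * len(grp_order), data=long)

    f, ax = plt.subplots(figsize=(1.2 * max(spec.panels, 3) + 1.5, 3.2))
    positions, labels = [], []
    series = []
    for i, fc in enumerate(facets):
        sub = long if facet is None else long[long[facet] == fc]
        for j, grp in enumerate(grp_order):
            v = sub.loc[sub["group"] == grp, "value"].to_numpy(dtype=float)
            positions.append(i * (len(grp_order) + 1) + j)
            labels.append(f"{fc}\n{grp}" if facet else grp)
            series.append(v)
    if chart in ("violin",):
        present = [(p, v) for p, v in zip(positions, series) if len(v)]
        if present:
            ax.violinplot([v for _, v in present], positions=[p for p, _ in present],
                          showmedians=True, widths=0.8)
    elif chart == "box":
        ax.boxplot([v if len(v) else [np.nan] for v in series], positions=positions,
                   widths=0.6)
    elif chart in ("dot", "bubble"):
        means = [v.mean() if len(v) else np.nan for v in series]
        fracs = [np.mean(v > 0) if len(v) else 0 for v in series]
        if chart == "dot":
            ax.scatter(positions, means, s=80, c=fracs, cmap="viridis")
        else:  # bubble: swapped encodings (size = mean, color = fraction expressed)
            sizes = 20 + 180 * np.nan_to_num(np.asarray(means) /
                                             (np.nanmax(means) or 1))
            ax.scatter(positions, fracs, s=sizes, c=means, cmap="viridis")
    elif chart == "heatmap":
        if level == "site_expression":
            piv = long.pivot_table(index="site_id", columns="obs_id", values="value",
                                   sort=False)
        else:
            piv = long.pivot_table(index="group", columns="obs_id", values="value",
                                   sort=False)
        ax.imshow(np.log1p(piv.to_numpy(dtype=float)) if level == "site_expression"
                  else piv.to_numpy(dtype=float), aspect="auto", cmap="viridis")
        ax.set_yticks(range(len(piv.index)), piv.index)
        positions, labels = [], []
    if labels:
        ax.set_xticks(positions, labels, fontsize=7)
    ax.set_title(f"{gene} ({level})", fontsize=10)
    ax.set_ylabel("RUD" if level == "rud" else "count")
    f.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(f)
    spec.path = Path(out)
    return spec


# ---------------------------------------------------------------------------
# embedding plot
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingPlotSpec:
    color_by: str
    n_points: int
    legend_entries: list[str]
    colorbar_limits: tuple[float, float] | None
    path: Path | None = None


def viz_embedding(emb, out: str | Path, color_by: str = "group",
                  groups: pd.Series | None = None,
                  neutral_color: str = "0.8") -> EmbeddingPlotSpec:
    """Scatter of 2D coordinates, colored by group or by scalar overlay.

    Continuous overlays get a gradient with a colorbar spanning the overlay
    range; missing overlay values render in a neutral grey.
    """
    coords = emb.coords
    f, ax = plt.subplots(figsize=(4.5, 4))
    legend_entries: list[str] = []
    cb_lim: tuple[float, float] | None = None
    if color_by == "group":
        if groups is None:
            if emb.overlay is not None and not pd.api.types.is_numeric_dtype(emb.overlay):
                groups = emb.overlay
            else:
                raise ParameterError("color_by='group' needs group labels")
        groups = groups.astype(str).reindex(coords.index)
        for grp in pd.unique(groups):
            m = (groups == grp).to_numpy()
            ax.scatter(coords["x"][m], coords["y"][m], s=8, label=str(grp))
            legend_entries.append(str(grp))
        ax.legend(fontsize=7, markerscale=2)
    elif color_by == "overlay":
        if emb.overlay is None:
            raise ParameterError("color_by='overlay' but no overlay attached")
        vals = pd.to_numeric(emb.overlay.reindex(coords.index), errors="coerce")
        miss = vals.isna().to_numpy()
        vmin, vmax = float(np.nanmin(vals)), float(np.nanmax(vals))
        if 0 <= vmin and vmax <= 1:  # usage-scale overlay: full unit colorbar
            vmin, vmax = 0.0, 1.0
        cb_lim = (vmin, vmax)
        if miss.any():
            ax.scatter(coords["x"][miss], coords["y"][miss], s=8, color=neutral_color)
        sc = ax.scatter(coords["x"][~miss], coords["y"][~miss], s=8,
                        c=vals[~miss], cmap="viridis", vmin=vmin, vmax=vmax)
        f.colorbar(sc, ax=ax, shrink=0.8)
    else:
        raise ParameterError("color_by must be 'group' or 'overlay'")
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    f.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(f)
    return EmbeddingPlotSpec(color_by=color_by, n_points=len(coords),
                             legend_entries=legend_entries, colorbar_limits=cb_lim,
                             path=Path(out))


# ---------------------------------------------------------------------------
# marker panels
# ---------------------------------------------------------------------------

@dataclass
class MarkerPlotSpec:
    chart: str
    genes: list[str]
    groups: list[str]
    panels: int
    values: pd.DataFrame  # gene x group mean RUD used for dot/heatmap
    frac: pd.DataFrame | None = None  # gene x group fraction of covered cells
    path: Path | None = None


def viz_apa_markers(rud: RUDMatrix, markers, out: str | Path, genes=None,
                    top: int = 6, chart: str = "violin",
                    groups: pd.Series | None = None) -> MarkerPlotSpec:
    """Multi-gene marker panel: violins, dot plot, or mean-RUD heatmap.

    ``genes`` may be an explicit list; by default the ``top`` most
    significant markers are shown.  Dot size encodes the fraction of cells
    with non-missing RUD, color the group mean RUD.
    """
    if chart not in MARKER_CHARTS:
        raise ParameterError(f"unknown chart '{chart}'; expected one of {MARKER_CHARTS}")
    if groups is None:
        raise ParameterError("per-observation group labels are required")
    table = markers.table if hasattr(markers, "table") else markers
    if genes is None:
        genes = table.sort_values("q_value")["gene_id"].head(top).tolist()
    for g in genes:
        if g not in rud.gene_index:
            raise UnknownIdError(f"gene '{g}' not in RUD matrix")
        if g not in set(table["gene_id"]):
            raise UnknownIdError(f"gene '{g}' not in marker table")

    groups = groups.astype(str)
    grp_order = list(pd.unique(groups.reindex(rud.obs_index).dropna()))
    mean_rud = pd.DataFrame(index=pd.Index(genes, name="gene_id"),
                            columns=grp_order, dtype=float)
    frac = mean_rud.copy()
    for g in genes:
        row = rud.values.loc[g]
        for grp in grp_order:
            obs = groups.index[groups == grp].intersection(rud.obs_index)
            v = row[obs]
            mean_rud.loc[g, grp] = v.mean(skipna=True)
            frac.loc[g, grp] = v.notna().mean() if len(v) else 0.0

    spec = MarkerPlotSpec(chart=chart, genes=list(genes), groups=grp_order,
                          panels=len(genes) * len(grp_order), values=mean_rud,
                          frac=frac)
    if chart == "violin":
        f, axes = plt.subplots(1, max(len(genes), 1),
                               figsize=(1.5 * max(len(genes), 1) + 1, 3),
                               sharey=True)
        axes = np.atleast_1d(axes)
        for ax, g in zip(axes, genes):
            row = rud.values.loc[g]
            data, pos = [], []
            for j, grp in enumerate(grp_order):
                obs = groups.index[groups == grp].intersection(rud.obs_index)
                v = row[obs].dropna().to_numpy(dtype=float)
                if len(v):
                    data.append(v)
                    pos.append(j)
            if data:
                ax.violinplot(data, positions=pos, showmedians=True, widths=0.8)
            ax.set_title(g, fontsize=8)
            ax.set_xticks(range(len(grp_order)), grp_order, fontsize=7)
            ax.set_ylim(-0.05, 1.05)
        axes[0].set_ylabel("RUD")
    else:
        f, ax = plt.subplots(figsize=(1.0 * len(grp_order) + 2.5,
                                      0.5 * len(genes) + 1.5))
        if chart == "dot":
            for i, g in enumerate(genes):
                sizes = 20 + 280 * frac.loc[g].to_numpy(dtype=float)
                ax.scatter(range(len(grp_order)), [i] * len(grp_order), s=sizes,
                           c=mean_rud.loc[g].to_numpy(dtype=float),
                           cmap="viridis", vmin=0, vmax=1)
            ax.set_yticks(range(len(genes)), genes, fontsize=7)
            ax.set_xticks(range(len(grp_order)), grp_order, fontsize=7)
            ax.invert_yaxis()
        else:  # heatmap of gene x group mean RUD
            im = ax.imshow(mean_rud.to_numpy(dtype=float), aspect="auto",
                           cmap="viridis", vmin=0, vmax=1)
            ax.set_yticks(range(len(genes)), genes, fontsize=7)
            ax.set_xticks(range(len(grp_order)), grp_order, fontsize=7)
            f.colorbar(im, ax=ax, shrink=0.8)
    f.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(f)
    spec.path = Path(out)
    return spec
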