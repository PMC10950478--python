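"""Coverage computation and figure-spec assembly for all chart families."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pysam
import pytest

from apaviz import (ParameterError, UnknownIdError, annotate_sites, compute_coverage,
                    compute_embedding, compute_rud, get_apa_markers, load_annotation,
                    mean_rud_per_obs, attach_overlay, preset, simulate_alignments,
                    simulate_gtf, simulate_pac, viz_apa_markers, viz_embedding,
                    viz_stats, viz_tracks)
from apaviz.viz import build_track_figure
from _oracles import brute_force_coverage


def write_bam(path, reads, chrom_len=10_000):
    """reads: list of (start0, cigar, reverse)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr1", "LN": chrom_len}]}
    reads = sorted(reads, key=lambda r: r[0])
    with pysam.AlignmentFile(str(path), "wb", header=header) as af:
        for i, (start0, cigar, reverse) in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            a.reference_id = 0
            a.reference_start = start0
            a.is_reverse = reverse
            a.mapping_quality = 60
            a.cigarstring = cigar
            ln = sum(n for n, op in _cigar_items(cigar) if op in "MIS=X")
            a.query_sequence = "A" * ln
            af.write(a)
    pysam.index(str(path))
    return path


def _cigar_items(cigar):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


class TestComputeCoverage:
    def test_single_read_depth_one(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", [(99, "50M", False)])
        prof = compute_coverage(bam, "chr1", 1, 300)
        assert prof.depth.sum() == 50
        assert (prof.depth[99:149] == 1).all() and prof.depth[98] == 0

    def test_two_identical_reads_add(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", [(99, "50M", False)] * 2)
        prof = compute_coverage(bam, "chr1", 1, 300)
        assert prof.depth.max() == 2 and prof.depth.sum() == 100

    def test_deletion_covers_skip_does_not(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", [(9, "10M5D10M", False),
                                             (9, "10M5N10M", False)])
        prof = compute_coverage(bam, "chr1", 1, 60)
        assert (prof.depth[9:19] == 2).all()
        assert (prof.depth[19:24] == 1).all()  # D covers, N does not
        assert (prof.depth[24:34] == 2).all()

    def test_strand_filter(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", [(9, "20M", False), (9, "20M", True)])
        both = compute_coverage(bam, "chr1", 1, 60)
        fwd = compute_coverage(bam, "chr1", 1, 60, strand_mode="same_as_gene",
                               gene_strand="+")
        assert both.depth.max() == 2 and fwd.depth.max() == 1

    def test_empty_region(self, tmp_path):
        bam = write_bam(tmp_path / "a.bam", [(9, "20M", False)])
        prof = compute_coverage(bam, "chr1", 100, 99)
        assert len(prof.depth) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        reads = []
        for _ in range(200):
            start0 = int(rng.integers(0, 2000))
            parts = []
            for op in ["M", rng.choice(["M", "D", "N", "M"]), "M"]:
                parts.append(f"{int(rng.integers(5, 60))}{op}")
            reads.append((start0, "".join(parts), bool(rng.random() < 0.5)))
        bam = write_bam(tmp_path / f"r{seed}.bam", reads)
        lo, hi = int(rng.integers(1, 500)), int(rng.integers(1500, 2500))
        prof = compute_coverage(bam, "chr1", lo, hi)
        assert np.array_equal(prof.depth, brute_force_coverage(bam, "chr1", lo, hi))


@pytest.fixture(scope="module")
def sim_bundle(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("viz")
    cfg = replace(preset("strong", seed=3), n_genes=6, n_cells_per_group=10)
    pac, truth = simulate_pac(cfg)
    anno = load_annotation(simulate_gtf(cfg, tmp / "toy.gtf"))
    annotated = annotate_sites(pac, anno)
    bams = simulate_alignments(cfg, pac, tmp / "aln")
    rud = compute_rud(annotated, min_counts=3)
    return tmp, cfg, annotated, anno, bams, rud


class TestVizTracks:
    def test_pa_marks_at_planted_coordinates(self, sim_bundle):
        tmp, cfg, pac, anno, bams, rud = sim_bundle
        fig = build_track_figure(pac, anno, "g0000")
        pa = next(t for t in fig.tracks if t.kind == "pA_sites")
        expected = sorted(pac.site_meta.loc[["g0000.p", "g0000.d"], "coord"])
        assert sorted(pa.payload["coords"]) == expected

    def test_optional_tracks(self, sim_bundle):
        tmp, cfg, pac, anno, bams, rud = sim_bundle
        bare = build_track_figure(pac, anno, "g0001", cells_track=True)
        assert [t.kind for t in bare.tracks] == ["gene_model", "pA_sites",
                                                 "single_cell_counts"]
        full = build_track_figure(pac, anno, "g0001", alignments_by_group=bams)
        assert sum(t.kind == "coverage" for t in full.tracks) == len(cfg.groups)
        labels = [t.label for t in full.tracks if t.kind == "coverage"]
        assert labels == [f"coverage:{g}" for g in cfg.groups]  # fixed group order

    def test_region_covers_gene_plus_3prime_margin(self, sim_bundle):
        tmp, cfg, pac, anno, bams, rud = sim_bundle
        fig = build_track_figure(pac, anno, "g0000", ext3utr=500)
        g = anno.genes.loc["g0000"]
        assert fig.start == g["start"] and fig.end == g["end"] + 500

    def test_renders_file_and_keeps_inputs_unchanged(self, sim_bundle, tmp_path):
        tmp, cfg, pac, anno, bams, rud = sim_bundle
        before = pac.site_meta.copy()
        fig = viz_tracks(pac, anno, "g0002", tmp_path / "t.png",
                         alignments_by_group=bams)
        assert fig.rendered_output.exists() and fig.rendered_output.stat().st_size > 0
        assert pac.site_meta.equals(before)

    def test_unknown_gene(self, sim_bundle, tmp_path):
        tmp, cfg, pac, anno, bams, rud = sim_bundle
        with pytest.raises(UnknownIdError, match="nope"):
            viz_tracks(pac, anno, "nope", tmp_path / "t.png")


class TestVizStats:
    def test_box_panels_site_by_group(self, sim_bundle, tmp_path):
        tmp, cfg, pac, anno, bams, rud = sim_bundle
        spec = viz_stats(pac, "g0000", tmp_path / "s.png", chart="box")
        assert spec.panels == 2 * len(cfg.groups)  # 2 sites x groups
        assert spec.path.exists()

    def test_rud_violin_mass_in_unit_interval(self, sim_bundle, tmp_path):
        tmp, cfg, pac, anno, bams, rud = sim_bundle
        spec = viz_stats(rud, "g0000", tmp_path / "v.png", chart="violin",
                         level="rud", groups=pac.obs_meta["group"])
        assert spec.panels == len(cfg.groups)
        assert spec.data["value"].between(0, 1).all()

    def test_heatmap_grid_shape(self, sim_bundle, tmp_path):
        tmp, cfg, pac, anno, bams, rud = sim_bundle
        spec = viz_stats(pac, "g0000", tmp_path / "h.png", chart="heatmap")
        grid = spec.data.pivot_table(index="site_id", columns="obs_id", values="value")
        assert grid.shape == (2, pac.n_obs)

    def test_unknown_chart_lists_valid(self, sim_bundle, tmp_path):
        tmp, cfg, pac, anno, bams, rud = sim_bundle
        with pytest.raises(ParameterError, match="violin"):
            viz_stats(pac, "g0000", tmp_path / "x.png", chart="sunburst")


@pytest.fixture(scope="module")
def emb(sim_bundle):
    tmp, cfg, pac, anno, bams, rud = sim_bundle
    return compute_embedding(pac, "site_expression", n_neighbors=8, seed=2)


class TestVizEmbedding:
    def test_group_legend_entries(self, sim_bundle, emb, tmp_path):
        tmp, cfg, pac, anno, bams, rud = sim_bundle
        spec = viz_embedding(emb, tmp_path / "e.png", color_by="group",
                             groups=pac.obs_meta["group"])
        assert spec.legend_entries == list(cfg.groups)

    def test_overlay_colorbar_unit_limits(self, sim_bundle, emb, tmp_path):
        tmp, cfg, pac, anno, bams, rud = sim_bundle
        emb2 = attach_overlay(emb, mean_rud_per_obs(rud))
        spec = viz_embedding(emb2, tmp_path / "e2.png", color_by="overlay")
        assert spec.colorbar_limits == (0.0, 1.0)

    def test_overlay_required(self, emb, tmp_path):
        with pytest.raises(ParameterError, match="overlay"):
            viz_embedding(emb, tmp_path / "e3.png", color_by="overlay")


class TestVizApaMarkers:
    def test_violin_panel_cardinality(self, sim_bundle, tmp_path):
        tmp, cfg, pac, anno, bams, rud = sim_bundle
        mt = get_apa_markers(rud, pac.obs_meta["group"], cfg.groups[0],
                             cfg.groups[-1], min_cells=3)
        spec = viz_apa_markers(rud, mt, tmp_path / "m.png", top=2, chart="violin",
                               groups=pac.obs_meta["group"])
        assert spec.panels == 2 * len(cfg.groups)

    def test_dot_fractions_and_heatmap_range(self, sim_bundle, tmp_path):
        tmp, cfg, pac, anno, bams, rud = sim_bundle
        mt = get_apa_markers(rud, pac.obs_meta["group"], cfg.groups[0],
                             cfg.groups[-1], min_cells=3)
        spec = viz_apa_markers(rud, mt, tmp_path / "d.png", top=3, chart="dot",
                               groups=pac.obs_meta["group"])
        fr = spec.frac.to_numpy(dtype=float)
        assert ((fr > 0) & (fr <= 1)).all()
        vals = spec.values.to_numpy(dtype=float)
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1

    def test_absent_gene_named(self, sim_bundle, tmp_path):
        tmp, cfg, pac, anno, bams, rud = sim_bundle
        mt = get_apa_markers(rud, pac.obs_meta["group"], cfg.groups[0],
                             cfg.groups[-1], min_cells=3)
        with pytest.raises(UnknownIdError, match="ghost"):
            viz_apa_markers(rud, mt, tmp_path / "x.png", genes=["ghost"],
                            chart="heatmap", groups=pac.obs_meta["group"])
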