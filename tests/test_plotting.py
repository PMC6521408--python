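"""Rendering tests: every panel draws headlessly, writes a non-empty file,
and never mutates its input container."""

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import pytest

from decoytools import geometry as g, plotting, seqstats as ss, synth
from decoytools.components import DesignTable


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    plt.close("all")


@pytest.fixture
def freq_matrix(small_cfg):
    table = synth.make_population(small_cfg)
    table.add_reference_sequence("A", table.get_sequence("A", 0))
    return ss.sequence_frequencies(table, "A")


def _saved_nonempty(fig, tmp_path, name="panel.png"):
    path = tmp_path / name
    plotting.save_panel(fig, path, dpi=72)
    assert path.stat().st_size > 0
    return path


class TestRamachandran:
    def test_helix_cluster_and_axes(self, helix_structure, tmp_path):
        triples = g.backbone_dihedrals(helix_structure, "A")
        seq = helix_structure.sequence("A")
        classes = [g.rama_class(seq[i], seq[i + 1] if i + 1 < len(seq)
                                else None) for i in range(len(seq))]
        fig, ax = plt.subplots()
        plotting.plot_ramachandran(triples, classes, "GENERAL", ax=ax)
        assert ax.get_xlim() == (-180.0, 180.0)
        assert ax.get_ylim() == (-180.0, 180.0)
        pts = ax.collections[0].get_offsets()
        # helical segments built at (-60, -45) must appear in the scatter
        assert ((np.abs(pts[:, 0] + 60) < 1) & (np.abs(pts[:, 1] + 45) < 1)).any()
        _saved_nonempty(fig, tmp_path)

    def test_empty_flavour_annotated(self):
        fig, ax = plt.subplots()
        plotting.plot_ramachandran([], [], "PRO", ax=ax)
        assert any("no PRO" in t.get_text() for t in ax.texts)

    def test_unknown_flavour_errors(self):
        with pytest.raises(ValueError):
            plotting.plot_ramachandran([], [], "WEIRD")


class TestFragmentQualityPlot:
    def test_requires_quality(self, small_cfg, helix_structure):
        fs = synth.make_fragments(small_cfg, helix_structure, noise_sd=0.0)
        with pytest.raises(ValueError, match="fragment_quality"):
            plotting.plot_fragment_quality(fs)

    def test_renders_with_region(self, small_cfg, helix_structure, tmp_path):
        fs = synth.make_fragments(small_cfg, helix_structure, noise_sd=15.0)
        fq = g.fragment_quality(fs, helix_structure, "A")
        before = fq.quality.copy()
        fig, ax = plt.subplots()
        plotting.plot_fragment_quality(fq, region="21-40", ax=ax)
        _saved_nonempty(fig, tmp_path)
        pd.testing.assert_frame_equal(fq.quality, before)


class TestLogo:
    def test_renders_and_preserves_input(self, freq_matrix, tmp_path):
        before = freq_matrix.df.copy()
        fig, ax = plt.subplots(figsize=(12, 3))
        plotting.plot_logo(freq_matrix, key_residues="30-50", ax=ax)
        _saved_nonempty(fig, tmp_path)
        pd.testing.assert_frame_equal(freq_matrix.df, before)

    def test_one_hot_full_height(self):
        t = DesignTable({"description": ["d"], "sequence_A": ["W"]})
        fm = ss.sequence_frequencies(t, "A")
        fig, ax = plt.subplots()
        plotting.plot_logo(fm, ax=ax)
        assert len(ax.patches) == 1
        assert ax.patches[0].get_path().get_extents().height \
            == pytest.approx(np.log2(20), rel=1e-6)

    def test_empty_selection_errors(self, freq_matrix):
        with pytest.raises((ValueError, IndexError)):
            plotting.plot_logo(freq_matrix, key_residues="500-510")


class TestHeatmap:
    def test_clean_unused_drops_rare_letters(self):
        t = DesignTable({"description": list("abcdefghij"),
                         "sequence_A": ["AA"] * 9 + ["AC"]})
        fm = ss.sequence_frequencies(t, "A")
        fig, ax = plt.subplots()
        plotting.plot_frequency_heatmap(fm, clean_unused=0.2, ax=ax,
                                        cbar=False)
        labels = [t.get_text() for t in ax.get_yticklabels()]
        assert "A" in labels and "C" not in labels

    def test_reference_outlined(self, freq_matrix, tmp_path):
        fig, ax = plt.subplots()
        plotting.plot_frequency_heatmap(freq_matrix, key_residues="30-40",
                                        ax=ax, cbar=False)
        assert len(ax.patches) > 0  # green reference frames
        _saved_nonempty(fig, tmp_path)


class TestDistributions:
    def test_one_panel_per_term(self, small_cfg, tmp_path):
        table = synth.make_population(small_cfg)
        table["hbond"] = table["score"] * 0.1
        axes = plotting.plot_distributions(table, ["score", "rms", "hbond"])
        assert len(axes) == 3
        _saved_nonempty(axes[0].figure, tmp_path)

    def test_grouped_by_experiment(self, small_cfg):
        from decoytools.components import merge_experiments
        labels = ["no_target", "static", "pack", "packmin"]
        tables = [synth.make_population(
            synth.FixtureConfig(seed=s, n_decoys=30)) for s in range(4)]
        merged = merge_experiments(tables, labels=labels)
        axes = plotting.plot_distributions(merged, ["score"],
                                           group_by="experiment",
                                           order=labels)
        ax = axes[0]
        assert [t.get_text() for t in ax.get_xticklabels()] == labels

    def test_reference_overlay_and_immutability(self, small_cfg):
        gen2 = synth.make_population(small_cfg)
        gen1 = synth.make_population(synth.FixtureConfig(seed=9,
                                                         n_decoys=100))
        before = pd.DataFrame(gen2).copy()
        plotting.plot_distributions(gen2, ["score", "rms"], refdata=gen1)
        pd.testing.assert_frame_equal(pd.DataFrame(gen2), before)

    def test_non_numeric_term_errors(self, small_cfg):
        table = synth.make_population(small_cfg)
        with pytest.raises(TypeError):
            plotting.plot_distributions(table, ["description"])


class TestContext:
    def test_query_marks_and_baseline(self, small_cfg, tmp_path):
        ref = synth.make_reference_table(small_cfg)
        query = synth.make_population(small_cfg).head(5)
        axes = plotting.plot_in_context(query, ref, ["score"],
                                        baselines={"score": -150.0})
        assert any(line.get_linestyle() == "--" for line in axes[0].lines)
        _saved_nonempty(axes[0].figure, tmp_path)

    def test_missing_term_errors(self, small_cfg):
        ref = synth.make_reference_table(small_cfg)
        with pytest.raises(KeyError):
            plotting.plot_in_context(pd.DataFrame(), ref, ["nope"])

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            plotting.plot_in_context(pd.DataFrame(), pd.DataFrame(),
                                     ["score"])


class TestScoreTrack:
    def test_highlight_span_covers_selection(self, tmp_path):
        from decoytools.components import ReferenceSequence
        from decoytools.seqstats import per_residue_matrix_score
        ref = ReferenceSequence("B", "ACDEFGHIKLMNPQRSTVWY" * 4, shift=1)
        row = pd.Series({"description": "q",
                         "sequence_B": ref.sequence})
        track = per_residue_matrix_score(row, "B", ref)
        fig, ax = plt.subplots()
        plotting.plot_score_track(track, selections=[("43-64", "red")],
                                  ax=ax)
        spans = [p for p in ax.patches]
        assert spans
        # spans data x in [42.5, 64.5]: the inclusive 43-64 residue range
        assert spans[0].get_x() == pytest.approx(42.5)
        assert spans[0].get_x() + spans[0].get_width() == pytest.approx(64.5)
        _saved_nonempty(fig, tmp_path)

    def test_nan_breaks_line(self):
        from decoytools.seqstats import PositionScoreTrack
        track = PositionScoreTrack(positions=np.arange(1, 6),
                                   scores=np.array([1, 2, np.nan, 4, 5.0]),
                                   matrix="BLOSUM62", query_id="q",
                                   reference_id="B")
        fig, ax = plt.subplots()
        plotting.plot_score_track(track, ax=ax)
        ydata = ax.lines[0].get_ydata()
        assert np.isnan(ydata[2])


class TestTraces:
    def test_cd_renders_requested_sample(self, small_cfg, tmp_path):
        cd, spr = synth.make_traces(small_cfg)
        fig, ax = plt.subplots()
        plotting.plot_cd(cd, ax=ax, sample=7)
        assert len(ax.lines) == 7
        _saved_nonempty(fig, tmp_path)

    def test_spr_fitted_share_fitcolor(self, small_cfg, tmp_path):
        _, spr = synth.make_traces(small_cfg)
        fig, ax = plt.subplots()
        plotting.plot_spr(spr, ax=ax, fitcolor="black")
        dashed = [ln for ln in ax.lines if ln.get_linestyle() == "--"]
        assert dashed and all(ln.get_color() == "black" for ln in dashed)
        assert len(dashed) == small_cfg.n_concentrations
        _saved_nonempty(fig, tmp_path)

    def test_empty_trace_errors(self):
        from decoytools.io import CDTrace
        with pytest.raises((ValueError, KeyError)):
            plotting.plot_cd(CDTrace(pd.DataFrame(
                columns=["wavelength", "ellipticity", "temperature"])))
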