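"""Symmetrical-occlusion mechanics: grids, traces, scores, sweeps."""

import copy

import numpy as np
import pytest

import geneso as gs
from geneso.occlusion import trace_to_frame


def zero_gene_input_weights(model, gene_index):
    """Silence one gene's input path (single-timestep layout assumed)."""
    model = copy.deepcopy(model)
    p = model.network_.layers[0].params
    for name in ("W_xi", "W_xf", "W_xc", "W_xo"):
        w = getattr(p, name).copy()
        w[:, gene_index] = 0.0
        setattr(p, name, w)
    return model


class TestPseudoSamples:
    def test_default_step_enumeration(self):
        ref = np.array([10.0, 20.0, 1.0])
        pset = gs.generate_pseudo_samples(ref, 0)
        # step = 10/10 = 1; gain climbs to 2 x sample max = 40
        np.testing.assert_allclose(pset.gain_values, np.arange(11.0, 41.0))
        np.testing.assert_allclose(pset.loss_values,
                                   np.concatenate([np.arange(9.0, 0.0, -1.0),
                                                   [0.0]]))
        assert len(pset.gain_values) == 30 and len(pset.loss_values) == 10

    def test_fine_step_dialect_endpoints(self):
        ref = np.array([10.0, 20.0])
        cfg = gs.OcclusionConfig(step_fraction=0.01)
        pset = gs.generate_pseudo_samples(ref, 0, cfg)
        assert pset.gain_values[0] == pytest.approx(10.1)
        assert pset.gain_values[-1] == pytest.approx(40.0)
        assert len(pset.gain_values) == 300

    def test_zero_expression_fallback(self):
        ref = np.array([0.0, 20.0])
        pset = gs.generate_pseudo_samples(ref, 0)
        assert pset.loss_values.size == 0
        np.testing.assert_allclose(pset.gain_values,
                                   np.arange(2.0, 42.0, 2.0))

    def test_grid_ordering_invariants(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            ref = rng.random(6) * 10
            pset = gs.generate_pseudo_samples(ref, int(rng.integers(6)))
            assert (np.diff(pset.gain_values) > 0).all()
            assert (pset.gain_values > pset.original).all()
            assert (np.diff(pset.loss_values) < 0).all()
            if pset.loss_values.size:
                assert pset.loss_values[-1] == 0.0
                assert (pset.loss_values < pset.original).all()

    def test_all_zero_reference_rejected(self):
        with pytest.raises(gs.DegenerateSampleError):
            gs.generate_pseudo_samples(np.zeros(4), 1)

    def test_imaginary_flagging_against_observed_range(self):
        ref = np.array([10.0, 20.0])
        pset = gs.generate_pseudo_samples(ref, 0, observed_range=(2.0, 15.0))
        assert pset.gain_real.sum() == 5          # 11..15 inside the range
        assert not pset.gain_real[5:].any()
        assert not pset.loss_real[-2:].any()      # 1 and 0 below observed min


class TestTraces:
    def test_trace_counts_and_distributions(self, small_model, small_dataset):
        nm, _ = small_dataset
        ref = nm.values[:, 0]
        pset = gs.generate_pseudo_samples(ref, 3)
        trace = gs.trace_gene(small_model, ref, nm.gene_ids[3])
        assert len(trace) == len(pset.gain_values) + len(pset.loss_values) + 1
        np.testing.assert_allclose(trace.scores.sum(axis=1), 1.0, atol=1e-6)

    def test_insensitive_gene_has_constant_trace(self, small_model,
                                                 small_dataset):
        nm, _ = small_dataset
        silenced = zero_gene_input_weights(small_model, 4)
        trace = gs.trace_gene(silenced, nm.values[:, 0], nm.gene_ids[4])
        np.testing.assert_array_equal(trace.scores,
                                      np.tile(trace.scores[:1],
                                              (len(trace), 1)))

    def test_gain_plus_loss_traces_merge_into_both(self, small_model,
                                                   small_dataset):
        nm, _ = small_dataset
        ref = nm.values[:, 2]
        gene = nm.gene_ids[7]
        both = gs.trace_gene(small_model, ref, gene,
                             gs.OcclusionConfig(direction="both"))
        gain = gs.trace_gene(small_model, ref, gene,
                             gs.OcclusionConfig(direction="gain"))
        loss = gs.trace_gene(small_model, ref, gene,
                             gs.OcclusionConfig(direction="loss"))
        merged_vals = np.concatenate([loss.occlusion_values[:-1],
                                      gain.occlusion_values])
        np.testing.assert_array_equal(both.occlusion_values, merged_vals)
        merged_scores = np.vstack([loss.scores[:-1], gain.scores])
        np.testing.assert_array_equal(both.scores, merged_scores)

    def test_long_format_export(self, small_model, small_dataset):
        nm, _ = small_dataset
        trace = gs.trace_gene(small_model, nm.values[:, 0], nm.gene_ids[0],
                              reference_id=nm.sample_ids[0])
        df = trace_to_frame(trace)
        assert list(df.columns) == ["gene", "reference_sample",
                                    "occlusion_value", "class", "score"]
        assert len(df) == len(trace) * len(trace.class_labels)


class TestScores:
    def test_silenced_gene_scores_exactly_zero(self, small_model,
                                               small_dataset):
        nm, _ = small_dataset
        silenced = zero_gene_input_weights(small_model, 9)
        for cls in nm.class_labels:
            assert gs.occlusion_score(silenced, nm, nm.gene_ids[9],
                                      cls) == 0.0

    def test_mean_occlusion_arithmetic(self):
        assert gs.mean_occlusion_score({"a": 0.2, "b": 0.0},
                                       ["a", "b"]) == pytest.approx(0.1)
        assert gs.mean_occlusion_score({"a": 0.0, "b": 0.0},
                                       ["a", "b"]) == 0.0
        with pytest.raises(gs.DataError):
            gs.mean_occlusion_score({"a": 0.5}, ["a", "b"])

    def test_unknown_reference_samples_rejected(self, small_model,
                                                small_dataset):
        nm, _ = small_dataset
        with pytest.raises(gs.DataError):
            gs.occlusion_score(small_model, nm, nm.gene_ids[0],
                               nm.class_labels[0],
                               reference_ids=["nope"])

    def test_score_table_shape_and_mean_column(self, small_model,
                                               small_dataset):
        nm, _ = small_dataset
        cfg = gs.OcclusionConfig(reference_cap=2, max_steps=40)
        genes = nm.gene_ids[:10]
        table = gs.score_all_genes(small_model, nm, cfg, genes=genes)
        assert table.scores.shape == (10, 3)
        np.testing.assert_allclose(table.mean_scores,
                                   table.scores.mean(axis=1), atol=1e-12)
        assert ((table.scores >= 0) & (table.scores <= 1)).all()

    def test_score_table_is_deterministic(self, small_model, small_dataset):
        nm, _ = small_dataset
        cfg = gs.OcclusionConfig(reference_cap=2, max_steps=40, seed=5)
        genes = nm.gene_ids[:6]
        t1 = gs.score_all_genes(small_model, nm, cfg, genes=genes)
        t2 = gs.score_all_genes(small_model, nm, cfg, genes=genes)
        np.testing.assert_array_equal(t1.scores, t2.scores)

    def test_halving_step_never_decreases_scores(self, small_model,
                                                 small_dataset):
        nm, _ = small_dataset
        coarse = gs.OcclusionConfig(step_fraction=0.2, reference_cap=2)
        fine = gs.OcclusionConfig(step_fraction=0.1, reference_cap=2)
        genes = nm.gene_ids[:5]
        tc = gs.score_all_genes(small_model, nm, coarse, genes=genes)
        tf = gs.score_all_genes(small_model, nm, fine, genes=genes)
        assert (tf.scores - tc.scores >= -1e-12).all()


class TestSweeps:
    def test_zero_length_sweep_keeps_original_only(self, small_model,
                                                   small_dataset):
        nm, _ = small_dataset
        # bound at 1 x sample max: the sample-max gene itself cannot gain
        cfg = gs.OcclusionConfig(max_multiplier=1.0)
        gi = int(np.argmax(nm.values[:, 0]))
        sw = gs.expression_sweep(small_model, nm, nm.gene_ids[gi], "gain",
                                 cfg, sample_ids=[nm.sample_ids[0]])
        assert sw["n_steps"] == 1

    def test_sweep_tracks_all_samples(self, small_model, small_dataset):
        nm, _ = small_dataset
        cfg = gs.OcclusionConfig(max_steps=20)
        sw = gs.expression_sweep(small_model, nm, nm.gene_ids[1], "loss",
                                 cfg, sample_ids=nm.sample_ids[:5],
                                 target_class=nm.class_labels[0])
        assert sw["labels"].shape[0] == 5
        assert len(sw["target_fraction"]) == sw["n_steps"]
        assert ((sw["target_fraction"] >= 0)
                & (sw["target_fraction"] <= 1)).all()
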