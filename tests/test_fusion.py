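"""Feature fusion and the assembled model: shapes, modes, invariances."""

import numpy as np
import pytest

import molfuse as mf
from molfuse.exceptions import AlignmentError, ModeError
from molfuse.fusion import (ArchConfig, FusionModel, Mode, collate,
                            fuse_features, make_ablation, prepare_molecule)
from molfuse.molgraph import DEFAULT_SCHEMA


@pytest.fixture(scope="module")
def cco(tok_spec):
    return prepare_molecule("CCO", tok_spec=tok_spec)


def build(task, mode="fused", seed=0, tiny_arch=None, **kwargs):
    arch = tiny_arch or ArchConfig(gnn_type="gatv2", hidden=16,
                                   n_gnn_layers=2, d_lang=8, n_lang_layers=1,
                                   dropout=0.1)
    spec = mf.default_tokenizer_spec()
    return FusionModel(task=task, d_node=DEFAULT_SCHEMA.d_node, mode=mode,
                       arch=arch, vocab_size=len(spec.vocabulary),
                       d_edge=DEFAULT_SCHEMA.d_edge, seed=seed, **kwargs)


class TestFuseFeatures:
    def test_zero_embeddings_pad_node_features(self, cco):
        emb = np.zeros((len(cco.tokens), 8))
        fused = fuse_features(cco.graph, emb, cco.amap)
        assert fused.shape == (3, DEFAULT_SCHEMA.d_node + 8)
        np.testing.assert_array_equal(
            fused.data[:, :DEFAULT_SCHEMA.d_node], cco.graph.node_features)
        np.testing.assert_array_equal(
            fused.data[:, DEFAULT_SCHEMA.d_node:], 0.0)

    def test_output_shape_is_nodes_by_dnode_plus_dlang(self, cco):
        emb = np.random.default_rng(0).standard_normal((len(cco.tokens), 8))
        assert fuse_features(cco.graph, emb, cco.amap).shape \
            == (3, DEFAULT_SCHEMA.d_node + 8)

    def test_unmapped_rows_are_never_read(self, tok_spec):
        rec = prepare_molecule("C=O", tok_spec=tok_spec)
        rng = np.random.default_rng(1)
        emb = rng.standard_normal((len(rec.tokens), 4))
        out1 = fuse_features(rec.graph, emb, rec.amap).data
        shuffled = emb.copy()
        mapped = {p for p, _ in rec.amap.pairs}
        unmapped = [i for i in range(len(rec.tokens)) if i not in mapped]
        shuffled[unmapped] = rng.standard_normal((len(unmapped), 4))
        out2 = fuse_features(rec.graph, shuffled, rec.amap).data
        np.testing.assert_array_equal(out1, out2)

    def test_coverage_mismatch_raises(self, cco, tok_spec):
        other = prepare_molecule("C=O", tok_spec=tok_spec)
        emb = np.zeros((len(cco.tokens), 8))
        with pytest.raises(AlignmentError):
            fuse_features(other.graph, emb, cco.amap)


class TestForward:
    def test_batch_order_preserved(self, regression_task, tok_spec,
                                   prepared_records):
        model = build(regression_task).eval()
        batch = collate(prepared_records[:5], tok_spec.pad_id)
        first = model(batch).data
        batch_twice = collate(prepared_records[:5] * 2, tok_spec.pad_id)
        doubled = model(batch_twice).data
        np.testing.assert_allclose(first, doubled[:5], atol=1e-5)
        np.testing.assert_allclose(first, doubled[5:], atol=1e-5)

    def test_classification_outputs_probabilities(self, classification_task,
                                                  tok_spec,
                                                  prepared_records):
        model = build(classification_task).eval()
        batch = collate(prepared_records[:8], tok_spec.pad_id)
        out = model(batch).data
        assert np.all((out > 0) & (out < 1))

    def test_graph_only_invariant_to_smiles_spelling(self, regression_task,
                                                     tok_spec):
        """Two spellings of ethanol parse to the same graph, so GRAPH_ONLY
        predictions must coincide."""
        model = build(regression_task, mode="graph").eval()
        for a, b in [("OCC", "CCO"), ("C(C)O", "CC(O)")]:
            ra = prepare_molecule(a, tok_spec=tok_spec)
            rb = prepare_molecule(b, tok_spec=tok_spec)
            pa = model(collate([ra], tok_spec.pad_id, mode=Mode.GRAPH_ONLY))
            pb = model(collate([rb], tok_spec.pad_id, mode=Mode.GRAPH_ONLY))
            np.testing.assert_allclose(pa.data, pb.data)

    def test_mean_pool_invariant_to_graph_duplication(self, regression_task,
                                                      tok_spec):
        """A disconnected duplicate of every node halves nothing under mean
        pooling: the GRAPH_ONLY prediction for X and X.X coincide."""
        model = build(regression_task, mode="graph").eval()
        single = prepare_molecule("CCO", tok_spec=tok_spec)
        doubled = prepare_molecule("CCO.CCO", tok_spec=tok_spec)
        p1 = model(collate([single], tok_spec.pad_id, mode=Mode.GRAPH_ONLY))
        p2 = model(collate([doubled], tok_spec.pad_id, mode=Mode.GRAPH_ONLY))
        np.testing.assert_allclose(p1.data, p2.data, atol=1e-6)

    def test_mode_mismatch_raises(self, regression_task, tok_spec,
                                  prepared_records):
        model = build(regression_task, mode="graph")
        batch = collate(prepared_records[:2], tok_spec.pad_id,
                        mode=Mode.FUSED)
        with pytest.raises(ModeError):
            model(batch)

    def test_finite_gradients_end_to_end(self, regression_task, tok_spec,
                                         prepared_records):
        model = build(regression_task)
        batch = collate(prepared_records[:6], tok_spec.pad_id)
        pred = model(batch)
        loss = ((pred - 1.0) ** 2).mean()
        loss.backward()
        grads = [p.grad for p in model.parameters()]
        assert all(g is not None and np.isfinite(g).all() for g in grads)

    def test_zero_encoder_matches_graph_only_with_tied_weights(
            self, regression_task, tok_spec, prepared_records):
        """Zero-padding equivalence: if the encoder emits zeros and the
        fused projection's language columns are zero, FUSED == GRAPH_ONLY
        under tied remaining weights."""
        fused = build(regression_task, mode="fused", seed=3).eval()
        graph = build(regression_task, mode="graph", seed=3).eval()
        d_node = DEFAULT_SCHEMA.d_node
        # tie: graph model weights = fused weights restricted to node slots
        fused_sd = fused.state_dict()
        graph_sd = graph.state_dict()
        for name, val in graph_sd.items():
            src = fused_sd[name]
            if name == "proj.W":
                graph_sd[name] = src[:d_node]
            else:
                graph_sd[name] = src
        graph.load_state_dict(graph_sd)
        # zero out the encoder output
        fused.encoder.embed = lambda ids, mask: mf.fusion.Tensor(
            np.zeros((*np.asarray(ids).shape, fused.arch.d_lang),
                     dtype=np.float32))
        recs = prepared_records[:4]
        pf = fused(collate(recs, tok_spec.pad_id, mode=Mode.FUSED)).data
        pg = graph(collate(recs, tok_spec.pad_id, mode=Mode.GRAPH_ONLY)).data
        np.testing.assert_allclose(pf, pg, atol=1e-6)


class TestAblation:
    def test_graph_ablation_drops_encoder(self, regression_task):
        model = build(regression_task)
        ablated = make_ablation(model, Mode.GRAPH_ONLY)
        assert ablated.encoder is None
        assert ablated.num_parameters() < model.num_parameters()

    def test_language_ablation_drops_gnn(self, regression_task):
        model = build(regression_task)
        ablated = make_ablation(model, "language")
        assert ablated.gnn_layers == []
        assert ablated.num_parameters() < model.num_parameters()

    def test_fused_to_fused_rejected(self, regression_task):
        with pytest.raises(ModeError):
            make_ablation(build(regression_task), Mode.FUSED)

    def test_ablation_shares_task_and_arch(self, regression_task):
        model = build(regression_task)
        ablated = make_ablation(model, Mode.GRAPH_ONLY)
        assert ablated.task is model.task
        assert ablated.arch == model.arch
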