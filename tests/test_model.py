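import numpy as np
import pytest

from dualbind.embeddings import MockEmbeddingProvider
from dualbind.metrics import mse_loss
from dualbind.model import (
    AffinityModel,
    IncompatibleProviderError,
    ModelConfig,
    SequenceTooLongError,
    train_val_test_split,
)
from dualbind.sequences import AffinityRecord, ProteinSequence
from dualbind.synthetic import SyntheticSpec, generate

SMALL = dict(
    embed_dim=16, compress_hidden=(), refine_hidden=(), l_ag_max=32, l_ab_max=32,
    gspe_m=8, gspe_q=4, gspe_n_sets=3, head_hidden=(8,), max_epochs=30, patience=30,
)


@pytest.fixture(scope="module")
def tiny_records():
    spec = SyntheticSpec(
        n_pairs=16, ab_length_range=(18, 22), ag_length_range=(24, 30),
        paratope_span=(4, 9), epitope_span=(6, 12), seed=21,
    )
    return generate(spec)[0]


@pytest.fixture(scope="module")
def provider16():
    return MockEmbeddingProvider(dim=16)


def make_model(variant="full", seed=0, **overrides):
    cfg = ModelConfig(variant=variant, seed=seed, **{**SMALL, **overrides})
    return AffinityModel(cfg, MockEmbeddingProvider(dim=16))


class TestConfig:
    def test_invalid_variant(self):
        with pytest.raises(ValueError, match="variant"):
            ModelConfig(variant="bogus")

    def test_head_width_by_variant(self):
        assert ModelConfig(variant="full", gspe_n_sets=5).head_in_width == 7
        assert ModelConfig(variant="no_r2r", gspe_n_sets=5).head_in_width == 5
        assert ModelConfig(variant="no_gspe").head_in_width == 2

    def test_provider_dim_mismatch(self):
        with pytest.raises(IncompatibleProviderError):
            AffinityModel(ModelConfig(embed_dim=8), MockEmbeddingProvider(dim=16))


class TestForward:
    def test_deterministic(self, tiny_records):
        m = make_model()
        r = tiny_records[0]
        assert m.forward(r) == m.forward(r)

    def test_two_models_same_seed_agree(self, tiny_records):
        a, b = make_model(seed=3), make_model(seed=3)
        assert a.forward(tiny_records[0]) == b.forward(tiny_records[0])

    def test_no_r2r_is_permutation_invariant(self, tiny_records):
        """Without the interaction branch, predictions depend on residue
        multisets only (sorted projections), so any reordering is inert."""
        m = make_model(variant="no_r2r")
        r = tiny_records[0]
        rng = np.random.default_rng(0)
        ab_perm = "".join(rng.permutation(list(r.antibody.residues)))
        ag_perm = "".join(rng.permutation(list(r.antigen.residues)))
        shuffled = AffinityRecord(
            antibody=ProteinSequence(id="p", residues=ab_perm, chain_role="antibody"),
            antigen=ProteinSequence(id="q", residues=ag_perm, chain_role="antigen"),
            pkd=r.pkd,
        )
        # permuting residues changes the mock embeddings (context windows), so
        # compare on the signature pathway directly: identical multisets of
        # embedding rows -> identical prediction
        base = m.prepare_batch([r])
        perm = rng.permutation(len(r.antibody))
        assert m.forward(r) == m.forward(r)
        sig_before = m._signature(r.antibody)
        x = m._embedding(r.antibody)
        from dualbind.gspe import compute_signatures

        sig_perm = np.stack([
            s.flat for s in compute_signatures(x[perm], m.bases, m.config.gspe_q)
        ])
        np.testing.assert_array_equal(sig_before, sig_perm)

    def test_no_gspe_zero_embeddings_give_head_zero_response(self, tiny_records):
        class ZeroProvider(MockEmbeddingProvider):
            def embed_residues(self, residues):
                return np.zeros((len(residues), self.dim))

        cfg = ModelConfig(variant="no_gspe", seed=0, **SMALL)
        m = AffinityModel(cfg, ZeroProvider(dim=16))
        r = tiny_records[0]
        pred = m.forward(r)
        # at init: phases 0, biases 0 -> compress(0)=0, h_aa=0, features=0
        head_at_zero = m.label_mean + m.head.forward(np.zeros((1, 2)))[0, 0]
        assert pred == pytest.approx(head_at_zero, abs=1e-12)

    def test_sequence_too_long_raises(self, provider16):
        cfg = ModelConfig(variant="full", seed=0, **{**SMALL, "l_ag_max": 10})
        m = AffinityModel(cfg, provider16)
        ab = ProteinSequence(id="a", residues="ACDEFGHIKL", chain_role="antibody")
        ag = ProteinSequence(id="g", residues="ACDEFGHIKLMNP", chain_role="antigen")
        with pytest.raises(SequenceTooLongError, match="refusing to truncate"):
            m.prepare_batch([AffinityRecord(antibody=ab, antigen=ag, pkd=7.0)])

    def test_batched_forward_matches_single_pair_pipeline(self, tiny_records):
        """The vectorized batch path reproduces the per-pair module chain."""
        from dualbind.gspe import pair_feature, compute_signatures
        from dualbind.interaction import compress, concat_refine, outer_interaction
        from dualbind.nn import softplus

        m = make_model()
        records = tiny_records[:4]
        batch = m.prepare_batch(records)
        preds, cache = m.forward_batch(batch)
        for i, r in enumerate(records):
            x_ab, x_ag = m._embedding(r.antibody), m._embedding(r.antigen)
            v_ab = compress(x_ab, m.compress_ab)
            v_ag = compress(x_ag, m.compress_ag)
            m_inter = outer_interaction(v_ab, v_ag)
            h_aa = concat_refine(m_inter, v_ab, m.refine_stack, l_ag_max=m.config.l_ag_max)
            sig_a = compute_signatures(x_ab, m.bases, m.config.gspe_q)
            sig_g = compute_signatures(x_ag, m.bases, m.config.gspe_q)
            pf = pair_feature(sig_a, sig_g, np.asarray(softplus(m.rho)))
            z = np.concatenate([[h_aa.mean(), h_aa.max()], pf.h_pair])
            z_std = (z - m.feature_loc) / m.feature_scale
            expected = m.label_mean + m.head.forward(z_std[None, :])[0, 0]
            assert preds[i] == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestTraining:
    def test_single_example_memorization(self, tiny_records):
        m = make_model(variant="no_gspe", max_epochs=300, patience=300, lr=3e-2)
        res = m.train(tiny_records[:1])
        assert res.log[-1]["train_loss"] < 1e-4

    def test_seeded_training_reproducible(self, tiny_records):
        results = []
        for _ in range(2):
            m = make_model(seed=5, max_epochs=5, patience=5)
            res = m.train(tiny_records[:12], tiny_records[12:])
            results.append(res)
        assert results[0].log == results[1].log

    def test_nan_labels_abort_with_diagnostic(self, tiny_records):
        import warnings

        m = make_model(max_epochs=2)
        bad = list(tiny_records[:8])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # pkd far outside the typical range
            bad[3] = AffinityRecord(
                antibody=bad[3].antibody, antigen=bad[3].antigen, pkd=1e300,
            )  # drives the loss non-finite
        from dualbind.model import TrainingDivergedError

        with pytest.raises(TrainingDivergedError, match="epoch"):
            m.train(bad)


class TestCheckpoint:
    def test_save_load_round_trip_predictions(self, tmp_path, tiny_records):
        m = make_model(seed=2, max_epochs=3, patience=3)
        m.train(tiny_records[:12], tiny_records[12:])
        preds = m.predict(tiny_records)
        path = tmp_path / "ckpt.npz"
        m.save(path)
        loaded, opt = AffinityModel.load(path)
        np.testing.assert_array_equal(loaded.predict(tiny_records), preds)
        assert opt is not None and opt.t > 0

    def test_load_rejects_dim_mismatch(self, tmp_path, tiny_records):
        m = make_model(seed=2, max_epochs=1, patience=1)
        m.train(tiny_records[:8])
        path = tmp_path / "ckpt.npz"
        m.save(path)
        with pytest.raises(IncompatibleProviderError, match="dim"):
            AffinityModel.load(path, MockEmbeddingProvider(dim=8))

    def test_resume_continues_close_to_saved_loss(self, tmp_path, tiny_records):
        m = make_model(seed=4, max_epochs=10, patience=10)
        res = m.train(tiny_records[:12], tiny_records[12:])
        path = tmp_path / "ckpt.npz"
        m.save(path)
        loaded, opt = AffinityModel.load(path)
        batch = loaded.prepare_batch(tiny_records[12:])
        preds, _ = loaded.forward_batch(batch)
        resumed_mae = float(np.mean(np.abs(preds - batch["y"])))
        assert resumed_mae == pytest.approx(res.best_val_mae, abs=1e-6)


class TestSplit:
    def test_fractions_and_partition(self, tiny_records):
        tr, va, te = train_val_test_split(tiny_records, (0.5, 0.25, 0.25), seed=0)
        assert len(tr) + len(va) + len(te) == len(tiny_records)
        assert len(tr) == 8

    def test_group_split_keeps_antibody_together(self):
        ab = ProteinSequence(id="a", residues="ACDEFGHIKL", chain_role="antibody")
        ags = [
            ProteinSequence(id=f"g{i}", residues="KLMNPQRSTV", chain_role="antigen")
            for i in range(6)
        ]
        records = [AffinityRecord(antibody=ab, antigen=g, pkd=7.0) for g in ags]
        tr, va, te = train_val_test_split(records, (0.4, 0.3, 0.3), seed=1,
                                          group_by_antibody=True)
        non_empty = [p for p in (tr, va, te) if p]
        assert len(non_empty) == 1  # single antibody group cannot straddle splits

    def test_bad_fractions(self, tiny_records):
        with pytest.raises(ValueError, match="sum to 1"):
            train_val_test_split(tiny_records, (0.5, 0.2, 0.2))
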