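"""Network construction, loss, splitting, training behaviour, prediction."""

import time

import numpy as np
import pytest

import domainseg as ds
from domainseg.cropping import CropSpec, extract_crop
from domainseg.network import (
    Network,
    TrainResult,
    softmax2,
    validation_loss,
)


class TestBuildNetwork:
    def test_full_preset_layer_introspection(self):
        net = ds.build_network(ds.NetworkConfig())
        assert net.conv_layer_count == 48
        assert net.dropout_layer_count == 15

    def test_inconsistent_schedule_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ds.NetworkConfig(n_conv_layers=10, filter_schedule=[(3, 8, 1)])

    def test_increasing_dilation_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            ds.NetworkConfig(
                n_conv_layers=6, n_dropout_layers=1, filter_schedule=[(3, 8, 1), (3, 8, 4)]
            )

    def test_tiny_forward_smoke(self):
        net = ds.build_network(ds.NetworkConfig.tiny(0))
        x = np.random.default_rng(0).random((24, 500, 500), dtype=np.float32)
        t0 = time.monotonic()
        logits = net.forward_logits(x)
        elapsed = time.monotonic() - t0
        p = softmax2(logits)
        assert elapsed < 10.0
        assert p.min() >= 0 and p.max() <= 1
        assert np.allclose(p.sum(axis=0), 1.0, atol=1e-5)


class TestTargetMatrix:
    def test_single_domain_all_ones(self):
        truth = ds.DomainSet([set(range(1, 101))])
        spec = CropSpec(((1, 101),), (0,))
        tgt, mask = ds.target_matrix(truth, spec)
        assert tgt[mask].all()
        assert not tgt[~mask].any()

    def test_two_domains_block_diagonal(self):
        truth = ds.DomainSet([set(range(1, 101)), set(range(101, 201))])
        spec = CropSpec(((1, 201),), (0,))
        tgt, _ = ds.target_matrix(truth, spec)
        assert tgt[0, 50] == 1 and tgt[150, 199] == 1
        assert tgt[0, 150] == 0

    def test_discontinuous_domain_membership(self):
        truth = ds.DomainSet(
            [set(range(1, 51)) | set(range(151, 201)), set(range(51, 151))]
        )
        spec = CropSpec(((1, 201),), (0,))
        tgt, _ = ds.target_matrix(truth, spec)
        assert tgt[9, 159] == 1  # residues 10 and 160 share the wrapped domain
        assert tgt[9, 60] == 0

    def test_unassigned_residues_zero_against_everything(self):
        truth = ds.DomainSet([set(range(1, 51))], unassigned=set(range(51, 61)))
        spec = CropSpec(((1, 61),), (0,))
        tgt, _ = ds.target_matrix(truth, spec)
        assert tgt[55, 55] == 0
        assert tgt[55, 10] == 0


class TestMaskedBce:
    def test_perfect_prediction_near_zero(self):
        t = (np.random.default_rng(0).random((20, 20)) > 0.5).astype(float)
        assert ds.masked_bce_loss(t, t, np.ones_like(t, dtype=bool)) <= 1e-6

    def test_uniform_half_is_ln2(self):
        t = (np.random.default_rng(1).random((20, 20)) > 0.5).astype(float)
        p = np.full_like(t, 0.5)
        assert ds.masked_bce_loss(p, t, np.ones_like(t, dtype=bool)) == pytest.approx(
            np.log(2), abs=1e-9
        )

    def test_matches_scalar_loop(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.01, 0.99, size=(10, 10))
        t = (rng.random((10, 10)) > 0.5).astype(float)
        mask = rng.random((10, 10)) > 0.3
        total, n = 0.0, 0
        for i in range(10):
            for j in range(10):
                if mask[i, j]:
                    pi = min(max(p[i, j], 1e-7), 1 - 1e-7)
                    total += -(t[i, j] * np.log(pi) + (1 - t[i, j]) * np.log(1 - pi))
                    n += 1
        assert ds.masked_bce_loss(p, t, mask) == pytest.approx(total / n, rel=1e-12)


class _Ex:
    def __init__(self, cid):
        self.cluster_id = cid


class TestSplitByCluster:
    def test_five_percent_of_hundred_clusters(self):
        examples = [_Ex(f"c{i}") for i in range(100) for _ in range(2)]
        train, val = ds.split_by_cluster(examples, 0.05, seed=3)
        val_clusters = {e.cluster_id for e in val}
        assert len(val_clusters) == 5
        assert len(train) + len(val) == len(examples)

    def test_deterministic_and_disjoint(self):
        examples = [_Ex(f"c{i}") for i in range(30)]
        a = ds.split_by_cluster(examples, 0.1, seed=7)
        b = ds.split_by_cluster(examples, 0.1, seed=7)
        assert [e.cluster_id for e in a[1]] == [e.cluster_id for e in b[1]]
        assert {e.cluster_id for e in a[0]} & {e.cluster_id for e in a[1]} == set()

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="cluster"):
            ds.split_by_cluster([_Ex("only"), _Ex("only")], 0.05, seed=0)


def _mini_records(n=3, seed=0):
    from domainseg.pipeline import build_channels

    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        spec = ds.SyntheticSpec(
            n_domains=2, domain_sizes=(60, 60), seed=int(rng.integers(2**31))
        )
        model, pae, truth, ss = ds.make_protein(spec)
        records.append(
            ds.ProteinRecord(build_channels(model, pae), truth, f"c{i}")
        )
    return records


class TestTraining:
    def test_zero_epochs_leaves_parameters_untouched(self):
        records = _mini_records(2)
        cfg = ds.NetworkConfig.tiny(0)
        reference = ds.build_network(cfg)
        result = ds.train(records, cfg, ds.TrainConfig(epochs=0, seed=1, validation_cluster_fraction=0.4))
        assert result.epoch_log == []
        for a, b in zip(result.network.param_arrays(), reference.param_arrays()):
            assert np.array_equal(a, b)

    def test_seeded_runs_reproduce_loss_logs(self):
        records = _mini_records(3)
        cfg = ds.TrainConfig(epochs=2, seed=5, batch_size=1, validation_cluster_fraction=0.34)
        log1 = ds.train(records, ds.NetworkConfig.tiny(0), cfg).epoch_log
        log2 = ds.train(records, ds.NetworkConfig.tiny(0), cfg).epoch_log
        assert log1 == log2

    def test_synthetic_suite_training_converges(self, trained_tiny):
        result, records, _ = trained_tiny
        final = result.epoch_log[-1]["train_loss"]
        assert final < 0.3  # far below the 0.5-probability baseline ln 2
        losses = [e["train_loss"] for e in result.epoch_log]
        assert min(losses) < losses[0]

    def test_padded_pixels_cannot_influence_the_loss(self):
        records = _mini_records(1)
        rec = records[0]
        net = ds.build_network(ds.NetworkConfig.tiny(0))
        spec = CropSpec(((1, rec.L + 1),), (40,))
        batch = extract_crop(rec.channels, spec)
        tgt, mask = ds.target_matrix(rec.truth, spec)
        pred = net.forward_proba(batch.channels, batch.valid_mask)
        base = ds.masked_bce_loss(pred, tgt, mask)
        perturbed = batch.channels.copy()
        perturbed[:, ~batch.valid_mask] = 77.0  # garbage on padding only
        pred2 = net.forward_proba(perturbed, batch.valid_mask)
        assert ds.masked_bce_loss(pred2, tgt, mask) == base


class TestPredict:
    def test_symmetry_and_range(self, trained_tiny, suite30):
        result, _, _ = trained_tiny
        p = suite30[0]
        pm = ds.predict_protein(p.channels, result.network)
        assert np.allclose(pm.values, pm.values.T)
        assert pm.values.min() >= 0 and pm.values.max() <= 1

    def test_single_domain_probability_is_high(self, trained_tiny):
        from domainseg.pipeline import build_channels

        result, _, _ = trained_tiny
        spec = ds.SyntheticSpec(n_domains=1, domain_sizes=(120,), seed=77)
        model, pae, truth, ss = ds.make_protein(spec)
        pm = ds.predict_protein(build_channels(model, pae), result.network)
        off_diag = pm.values[~np.eye(model.L, dtype=bool)]
        assert np.median(off_diag) > 0.5

    def test_identity_stub_plumbing(self):
        # a stub "network" that thresholds the distance channel end-to-end
        class Stub:
            def forward_proba(self, channels, valid_mask=None):
                return (channels[0] < 0.2).astype(float)

        rng = np.random.default_rng(0)
        L = 600
        d = rng.random((L, L))
        d = (d + d.T) / 2
        channels = np.repeat(d[None], 24, axis=0).astype(np.float32)
        pm = ds.predict_protein(channels, Stub())
        assert np.array_equal(pm.values, (d < 0.2).astype(float))


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        net = ds.build_network(ds.NetworkConfig.tiny(3))
        result = TrainResult(net, [{"epoch": 1, "train_loss": 0.5}])
        ds.save_checkpoint(result, tmp_path / "m.npz")
        again = ds.load_checkpoint(tmp_path / "m.npz")
        assert again.epoch_log == result.epoch_log
        assert again.network.conv_layer_count == net.conv_layer_count
        for a, b in zip(again.network.param_arrays(), net.param_arrays()):
            assert np.array_equal(a, b)
        x = np.random.default_rng(1).random((24, 500, 500), dtype=np.float32)
        assert np.allclose(again.network.forward_proba(x), net.forward_proba(x))
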