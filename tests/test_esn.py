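"""Reservoir transform: initialization contract, readout, transfer learning."""

import numpy as np
import pytest

from ahar.esn import (AugmentationPlan, apply_transfer, augment_class,
                      init_reservoir, learn_readout, learn_transfer,
                      load_transform, run_reservoir, save_transform)
from ahar.features import FeatureSequence
from ahar.proximity import TransferPairing

SMALL_GRID = {"reservoir_size": (0, 50), "spectral_radius": (0.9,),
              "input_scaling": (0.5,), "ridge": (1e-4,)}


def make_seqs(rng, n, frames, dims, label, offset=0.0, scale=1.0,
              prefix="clip"):
    return [FeatureSequence(offset + scale * rng.standard_normal((frames,
                                                                  dims)),
                            "mfcc", clip_id=f"{prefix}_{i}", label=label)
            for i in range(n)]


class TestInitReservoir:
    @pytest.mark.parametrize("sr", [0.8, 0.9, 0.95, 0.99])
    def test_spectral_radius_contract(self, sr):
        rt = init_reservoir(4, 80, spectral_radius=sr, seed=0)
        measured = np.max(np.abs(np.linalg.eigvals(rt.w_res)))
        assert abs(measured - sr) < 1e-6

    def test_input_weights_within_scaling(self):
        rt = init_reservoir(3, 40, input_scaling=0.7, seed=1)
        assert np.abs(rt.w_in).max() <= 0.7

    def test_seed_reproducibility(self):
        a = init_reservoir(3, 30, seed=5)
        b = init_reservoir(3, 30, seed=5)
        assert (a.w_res == b.w_res).all() and (a.w_in == b.w_in).all()

    def test_degenerate_direct_readout(self):
        rt = init_reservoir(4, 0, seed=0)
        assert rt.w_res.shape == (0, 0)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            init_reservoir(0, 10)
        with pytest.raises(ValueError):
            init_reservoir(4, -1)


class TestRunReservoir:
    def test_zero_input_zero_states(self):
        rt = init_reservoir(3, 20, seed=0)
        assert not run_reservoir(rt, np.zeros((15, 3))).any()

    def test_states_strictly_bounded(self, rng):
        rt = init_reservoir(4, 30, seed=2)
        states = run_reservoir(rt, 5.0 * rng.standard_normal((50, 4)))
        assert np.abs(states).max() < 1.0

    def test_impulse_response_decays(self):
        rt = init_reservoir(2, 30, spectral_radius=0.8, input_scaling=0.1,
                            seed=3)
        u = np.zeros((400, 2))
        u[0] = 0.1
        norms = np.linalg.norm(run_reservoir(rt, u), axis=1)
        assert norms[-1] < 1e-6

    def test_echo_state_property(self, rng):
        # two different initial states driven by the same input converge
        rt = init_reservoir(3, 40, spectral_radius=0.9, seed=4)
        u = rng.standard_normal((500, 3))
        xa = np.zeros(40)
        xb = rng.standard_normal(40) * 0.5
        for t in range(500):
            drive = rt.w_in @ u[t]
            xa = np.tanh(drive + rt.w_res @ xa)
            xb = np.tanh(drive + rt.w_res @ xb)
        assert np.linalg.norm(xa - xb) < 1e-6

    def test_dimension_mismatch_rejected(self, rng):
        rt = init_reservoir(3, 10, seed=0)
        with pytest.raises(ValueError, match="dim"):
            run_reservoir(rt, rng.standard_normal((5, 4)))

    def test_identity_states_for_zero_reservoir(self, rng):
        rt = init_reservoir(4, 0, seed=0)
        u = rng.standard_normal((8, 4))
        assert (run_reservoir(rt, u) == u).all()


class TestLearnReadout:
    def test_planted_solution_recovery(self, rng):
        x = rng.standard_normal((60, 8))
        w_true = rng.standard_normal((8, 3))
        w = learn_readout(x, x @ w_true, ridge=0.0)
        np.testing.assert_allclose(w, w_true, atol=1e-8)

    def test_matches_brute_force_normal_equations(self, rng):
        for _ in range(5):
            x = rng.standard_normal((20, 5))
            d = rng.standard_normal((20, 2))
            eps = 1e-3
            w = learn_readout(x, d, ridge=eps)
            brute = np.linalg.inv(x.T @ x + eps * np.eye(5)) @ (x.T @ d)
            np.testing.assert_allclose(w, brute, atol=1e-10)

    def test_defining_identity_holds(self, rng):
        x = rng.standard_normal((40, 6))
        d = rng.standard_normal((40, 2))
        eps = 0.5
        w = learn_readout(x, d, ridge=eps)
        np.testing.assert_allclose((x.T @ x + eps * np.eye(6)) @ w, x.T @ d,
                                   atol=1e-10)

    def test_norm_shrinks_with_regularization(self, rng):
        x = rng.standard_normal((50, 5))
        d = rng.standard_normal((50, 3))
        norms = [np.linalg.norm(learn_readout(x, d, ridge=e))
                 for e in (1e-6, 1.0, 1e6)]
        assert norms[0] > norms[1] > norms[2]

    def test_rank_deficient_without_ridge_rejected(self, rng):
        x = np.tile(rng.standard_normal((30, 1)), (1, 4))  # rank 1
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            learn_readout(x, rng.standard_normal((30, 2)), ridge=0.0)


class TestLearnTransfer:
    def test_self_transfer_beats_untrained_readout(self, rng):
        donor = make_seqs(rng, 10, 60, 4, "d", offset=1.0)
        rt = learn_transfer(donor[:8], donor[:8], grid=SMALL_GRID, seed=0)
        held_out = donor[8:]
        trained_err = np.mean([
            np.mean((apply_transfer(rt, s).values
                     - s.values[rt.washout:]) ** 2) for s in held_out])
        rng2 = np.random.default_rng(1)
        from dataclasses import replace
        rt_rand = replace(rt, w_out=rng2.standard_normal(rt.w_out.shape))
        random_err = np.mean([
            np.mean((apply_transfer(rt_rand, s).values
                     - s.values[rt_rand.washout:]) ** 2) for s in held_out])
        assert random_err / trained_err >= 10.0

    def test_known_affine_map_recovered(self, rng):
        # aligned supervision: targets are an exact affine image of inputs
        a = np.array([[0.5, 0.2, 0.0], [0.0, -1.0, 0.3], [0.1, 0.0, 0.8]])
        b = np.array([0.5, -0.2, 1.0])
        donor = make_seqs(rng, 1, 400, 3, "d")
        limited = [FeatureSequence(s.values @ a.T + b, "mfcc",
                                   clip_id=f"l{i}", label="l")
                   for i, s in enumerate(donor)]
        rt = learn_transfer(donor, limited,
                            grid={"reservoir_size": (0,),
                                  "spectral_radius": (0.9,),
                                  "input_scaling": (0.5,),
                                  "ridge": (1e-8,)},
                            seed=0, pairing_strategy="index")
        out = apply_transfer(rt, donor[0])
        target = donor[0].values[rt.washout:] @ a.T + b
        rel = np.linalg.norm(out.values - target) / np.linalg.norm(target)
        assert rel < 0.05

    def test_output_dims_match_input_dims(self, rng):
        donor = make_seqs(rng, 4, 40, 5, "d")
        limited = make_seqs(rng, 3, 40, 5, "l", offset=2.0)
        rt = learn_transfer(donor, limited, grid=SMALL_GRID, seed=0)
        assert apply_transfer(rt, donor[0]).n_dims == 5

    def test_empty_side_rejected(self, rng):
        donor = make_seqs(rng, 2, 30, 3, "d")
        with pytest.raises(ValueError, match="non-empty"):
            learn_transfer(donor, [])

    def test_untrained_transform_rejected(self, rng):
        rt = init_reservoir(3, 10, seed=0)
        with pytest.raises(ValueError, match="readout"):
            apply_transfer(rt, make_seqs(rng, 1, 30, 3, "d")[0])

    def test_zero_input_yields_constant_bias_output(self, rng):
        donor = make_seqs(rng, 4, 40, 3, "d", offset=1.0)
        limited = make_seqs(rng, 3, 40, 3, "l", offset=2.0)
        rt = learn_transfer(donor, limited, grid=SMALL_GRID, seed=0)
        zeros = FeatureSequence(np.zeros((30, 3)), "mfcc", clip_id="z")
        out = apply_transfer(rt, zeros)
        np.testing.assert_allclose(
            out.values, np.broadcast_to(out.values[0], out.values.shape),
            atol=1e-12)
        np.testing.assert_allclose(out.values[0], rt.w_out[-1], atol=1e-12)


class TestAugmentation:
    def _setup(self, rng):
        donor = make_seqs(rng, 40, 30, 3, "donor", prefix="d")
        limited = make_seqs(rng, 4, 30, 3, "limited", offset=1.0, prefix="l")
        rt = learn_transfer(donor, limited, grid=SMALL_GRID, seed=0)
        pairing = TransferPairing("limited", "donor", 1.0)
        return donor + limited, rt, pairing

    def test_zero_target_leaves_corpus_unchanged(self, rng):
        corpus, rt, pairing = self._setup(rng)
        plan = AugmentationPlan(pairing, target_count=0)
        assert augment_class(corpus, plan, rt) == corpus

    def test_count_bookkeeping(self, rng):
        corpus, rt, pairing = self._setup(rng)
        plan = AugmentationPlan(pairing, target_count=20)
        out = augment_class(corpus, plan, rt, rng=np.random.default_rng(0))
        new = [fs for fs in out if fs.meta.get("synthetic")]
        assert len(out) == len(corpus) + 20
        assert len(new) == 20
        assert all(fs.label == "limited" for fs in new)
        assert all(fs.meta["source_clip"].startswith("d_") for fs in new)

    def test_donor_resampling_when_scarce(self, rng):
        donor = make_seqs(rng, 3, 30, 3, "donor", prefix="d")
        limited = make_seqs(rng, 2, 30, 3, "limited", offset=1.0, prefix="l")
        rt = learn_transfer(donor, limited, grid=SMALL_GRID, seed=0)
        plan = AugmentationPlan(TransferPairing("limited", "donor", 1.0),
                                target_count=7)
        out = augment_class(donor + limited, plan, rt,
                            rng=np.random.default_rng(0))
        assert sum(fs.meta.get("synthetic", False) for fs in out) == 7

    def test_negative_plan_rejected(self):
        with pytest.raises(ValueError):
            AugmentationPlan(TransferPairing("a", "b", 0.0), target_count=-1)


class TestSerialization:
    def test_bit_exact_round_trip(self, rng, tmp_path):
        donor = make_seqs(rng, 4, 40, 3, "d")
        limited = make_seqs(rng, 3, 40, 3, "l", offset=1.0)
        rt = learn_transfer(donor, limited, grid=SMALL_GRID, seed=0)
        path = tmp_path / "frn.npz"
        save_transform(path, rt)
        back = load_transform(path)
        assert (back.w_in == rt.w_in).all()
        assert (back.w_res == rt.w_res).all()
        assert (back.w_out == rt.w_out).all()
        assert back.reservoir_size == rt.reservoir_size
        a = apply_transfer(rt, donor[0]).values
        b = apply_transfer(back, donor[0]).values
        assert (a == b).all()
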