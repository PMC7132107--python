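"""Kabsch superposition, symmetric RMSD, and state classification."""

import itertools

import numpy as np
import pytest

from helixswitch.errors import ParameterError
from helixswitch.state_builder import BundleModel
from helixswitch.state_classify import (classify_state, kabsch_superpose,
                                        state_fractions, symmetric_rmsd)


def rigid(rng):
    """Random proper rotation + translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(scale=20, size=3)
    return R, t


def brute_force_cyclic_rmsd(model, reference):
    """Independent oracle: plain SVD Kabsch over explicit cyclic orders."""
    def kabsch_rmsd(P, Q):
        P0 = P - P.mean(axis=0)
        Q0 = Q - Q.mean(axis=0)
        H = P0.T @ Q0
        U, S, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        D = np.diag([1.0, 1.0, d])
        R = Vt.T @ D @ U.T
        return float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))

    ids = list(model.chain_ids)
    ref = np.concatenate([reference.chains[c] for c in reference.chain_ids])
    best = np.inf
    for shift in range(3):
        order = [ids[(k + shift) % 3] for k in range(3)]
        cand = np.concatenate([model.chains[c] for c in order])
        best = min(best, kabsch_rmsd(cand, ref))
    return best


def noised(model, rng, scale):
    return BundleModel(chains={c: v + rng.normal(scale=scale, size=v.shape)
                               for c, v in model.chains.items()},
                       segments=list(model.segments), sequence=dict(model.sequence))


def relabeled(model, mapping):
    ids = list(model.chains)
    return BundleModel(chains={new: model.chains[old]
                               for new, old in zip(ids, mapping)},
                       segments=list(model.segments), sequence=dict(model.sequence))


class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        P = rng.normal(size=(20, 3)) * 10
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd < 1e-12
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)

    def test_recovers_constructed_rotation(self, rng):
        P = rng.normal(size=(30, 3)) * 10
        R0, t0 = rigid(rng)
        Q = P @ R0.T + t0
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd < 1e-9
        assert np.allclose(R, R0, atol=1e-8)
        assert np.allclose(P @ R.T + t, Q, atol=1e-8)

    def test_reflection_not_used(self, rng):
        P = rng.normal(size=(25, 3)) * 10
        Q = P * np.array([1.0, 1.0, -1.0])  # mirror image
        R, _, rmsd = kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_rmsd_is_minimal_over_rigid_motions(self, rng):
        # perturbing the optimal transform can only increase the residual
        P = rng.normal(size=(20, 3)) * 8
        Q = rng.normal(size=(20, 3)) * 8
        R, t, rmsd = kabsch_superpose(P, Q)
        from scipy.spatial.transform import Rotation
        for _ in range(10):
            wiggle = Rotation.from_rotvec(rng.normal(scale=0.05, size=3)).as_matrix()
            worse = float(np.sqrt(np.mean(np.sum(
                (P @ (wiggle @ R).T + t - Q) ** 2, axis=1))))
            assert worse >= rmsd - 1e-9

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ParameterError):
            kabsch_superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))

    def test_degenerate_input_rejected(self):
        P = np.zeros((5, 3))
        with pytest.raises(ParameterError):
            kabsch_superpose(P, P)


class TestSymmetricRmsd:
    def test_cyclic_relabeling_absorbed(self, short_model):
        rotated = relabeled(short_model, ("B", "C", "A"))
        rmsd, mapping = symmetric_rmsd(rotated, short_model)
        assert rmsd < 1e-9

    def test_matches_brute_force_oracle(self, short_model, long_model, rng):
        cases = [noised(short_model, rng, 1.0), noised(long_model, rng, 2.0),
                 relabeled(noised(short_model, rng, 0.7), ("C", "A", "B"))]
        for model in cases:
            for ref in (short_model, long_model):
                ours, _ = symmetric_rmsd(model, ref)
                oracle = brute_force_cyclic_rmsd(model, ref)
                assert ours == pytest.approx(oracle, abs=1e-9)

    def test_at_most_identity_mapping_rmsd(self, short_model, rng):
        model = noised(short_model, rng, 1.5)
        sym, _ = symmetric_rmsd(model, short_model)
        plain, _, identity_rmsd = None, None, None
        from helixswitch.state_classify import kabsch_superpose
        P = np.concatenate([model.chains[c] for c in model.chain_ids])
        Q = np.concatenate([short_model.chains[c] for c in short_model.chain_ids])
        _, _, identity_rmsd = kabsch_superpose(P, Q)
        assert sym <= identity_rmsd + 1e-12

    def test_noise_scaling(self, short_model, rng):
        # isotropic per-coordinate sigma=1 noise gives RMSD near sqrt(3)
        vals = [symmetric_rmsd(noised(short_model, rng, 1.0), short_model)[0]
                for _ in range(5)]
        assert np.mean(vals) == pytest.approx(np.sqrt(3.0), rel=0.1)

    def test_pseudo_metric_properties(self, short_model, rng):
        a = noised(short_model, rng, 0.8)
        b = noised(short_model, rng, 0.8)
        c = noised(short_model, rng, 0.8)
        d_ab, _ = symmetric_rmsd(a, b)
        d_ba, _ = symmetric_rmsd(b, a)
        assert d_ab == pytest.approx(d_ba, abs=1e-9)
        d_ac, _ = symmetric_rmsd(a, c)
        d_bc, _ = symmetric_rmsd(b, c)
        assert d_ac <= d_ab + d_bc + 1e-9

    def test_two_chain_model_rejected(self, short_model):
        broken = BundleModel(chains={k: short_model.chains[k] for k in "AB"},
                             segments=short_model.segments,
                             sequence={k: short_model.sequence[k] for k in "AB"})
        with pytest.raises(ParameterError):
            symmetric_rmsd(broken, short_model)


class TestClassify:
    def test_self_classification(self, short_model, long_model):
        res = classify_state(short_model, short_model, long_model)
        assert res.label == "short"
        assert res.rmsd_short == pytest.approx(0.0, abs=1e-9)

    def test_noised_long_classifies_long(self, short_model, long_model, rng):
        decoy = noised(long_model, rng, 0.5)
        res = classify_state(decoy, short_model, long_model, threshold=3.0)
        assert res.label == "long"

    def test_unrelated_structure_is_other(self, spec, short_model, long_model):
        from helixswitch.geometry import generate_helix, ideal_helix_params, apply_c3
        n = spec.n_res
        chain = generate_helix(ideal_helix_params(n))
        stretched = BundleModel(
            chains=dict(zip("ABC", apply_c3(chain + np.array([30.0, 0, 0])))),
            segments=["flipping"] * n, sequence={c: "A" * n for c in "ABC"})
        res = classify_state(stretched, short_model, long_model)
        assert res.label == "other"
        assert min(res.rmsd_short, res.rmsd_long) > 3.0

    def test_invariant_to_rigid_motion(self, short_model, long_model, rng):
        decoy = noised(short_model, rng, 0.5)
        R, t = rigid(rng)
        moved = decoy.transformed(rotation=R, translation=t)
        a = classify_state(decoy, short_model, long_model)
        b = classify_state(moved, short_model, long_model)
        assert a.label == b.label
        assert a.rmsd_short == pytest.approx(b.rmsd_short, abs=1e-6)


class TestStateFractions:
    def test_pure_short_set(self, short_model, long_model):
        fs, fl, fo = state_fractions([short_model] * 10, short_model, long_model)
        assert (fs, fl, fo) == (1.0, 0.0, 0.0)

    def test_mixture_recovered(self, short_model, long_model, rng):
        decoys = [noised(short_model, rng, 0.5) for _ in range(5)]
        decoys += [noised(long_model, rng, 0.5) for _ in range(5)]
        fs, fl, fo = state_fractions(decoys, short_model, long_model, threshold=3.0)
        assert (fs, fl, fo) == (0.5, 0.5, 0.0)

    def test_zero_threshold_all_other(self, short_model, long_model, rng):
        decoys = [noised(short_model, rng, 0.5) for _ in range(4)]
        fs, fl, fo = state_fractions(decoys, short_model, long_model, threshold=0.0)
        assert (fs, fl, fo) == (0.0, 0.0, 1.0)

    def test_fractions_sum_to_one(self, short_model, long_model, rng):
        decoys = [noised(short_model, rng, s) for s in (0.2, 1.0, 5.0, 20.0)]
        fs, fl, fo = state_fractions(decoys, short_model, long_model)
        assert fs + fl + fo == pytest.approx(1.0)

    def test_empty_list_rejected(self, short_model, long_model):
        with pytest.raises(ParameterError):
            state_fractions([], short_model, long_model)
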