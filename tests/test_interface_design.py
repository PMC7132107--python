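"""Interface-layer enumeration, assignment, burial analysis, and scoring."""

import numpy as np
import pytest

from helixswitch.errors import ParameterError
from helixswitch.geometry import apply_c3
from helixswitch.interface_design import (LayerConfig, apply_config,
                                          assign_layers, burial_delta,
                                          enumerate_configs,
                                          polar_triad_check, residue_sasa,
                                          score_state_preference)
from helixswitch.state_builder import BundleModel


@pytest.fixture(scope="module")
def assignment(short_model):
    return assign_layers(short_model)


@pytest.fixture(scope="module")
def deltas(short_model, long_model, assignment):
    return burial_delta(short_model, long_model, assignment)


class TestEnumerate:
    def test_exactly_eight_sorted_unique(self):
        configs = enumerate_configs()
        codes = [c.code for c in configs]
        assert len(codes) == 8
        assert codes == sorted(codes)
        assert len(set(codes)) == 8
        for name in ("XXA", "XAX", "XAA", "AAA", "AXA"):
            assert name in codes

    @pytest.mark.parametrize("k,expected", [(1, 2), (2, 4), (4, 16)])
    def test_generalized_enumeration_size(self, k, expected):
        assert len(enumerate_configs(k)) == expected

    def test_name_parsing_round_trip(self):
        for c in enumerate_configs():
            assert LayerConfig.parse(str(c)) == c

    def test_invalid_codes_rejected(self):
        with pytest.raises(ParameterError):
            LayerConfig("XA")
        with pytest.raises(ParameterError):
            LayerConfig("XYZ")


class TestAssignLayers:
    def test_three_nonempty_disjoint_layers(self, assignment):
        for side in (assignment.inner, assignment.flipping):
            assert len(side) == 3
            assert all(len(layer) > 0 for layer in side)
            union = set().union(*side)
            assert len(union) == sum(len(layer) for layer in side)

    def test_layers_ordered_hinge_proximal_first(self, short_model, assignment):
        # hinge sits at the top of the short state; layer 0 must be highest
        chain = short_model.chains["A"]
        mean_z = [np.mean([chain[r - 1, 2] for r in layer])
                  for layer in assignment.inner]
        assert mean_z[0] > mean_z[1] > mean_z[2]

    def test_deterministic(self, short_model, assignment):
        again = assign_layers(short_model)
        assert again.inner == assignment.inner
        assert again.flipping == assignment.flipping

    def test_long_state_has_no_interface_contacts(self, long_model):
        # the assignment is defined on the short state and reused for the long
        with pytest.raises(ParameterError):
            assign_layers(long_model)


class TestApplyConfig:
    def test_all_polar_config(self, short_model, assignment):
        designed = apply_config(short_model, assignment, "AAA")
        seq = designed.sequence["A"]
        for layer in assignment.inner:
            assert all(seq[r - 1] == "N" for r in layer)

    def test_mixed_config_layer_pattern(self, short_model, assignment):
        designed = apply_config(short_model, assignment, "XAX")
        seq = designed.sequence["A"]
        assert all(seq[r - 1] == "N" for r in assignment.inner[1])
        for k in (0, 2):
            assert all(seq[r - 1] in "LIV" for r in assignment.inner[k])

    def test_idempotent_and_pure(self, short_model, assignment):
        once = apply_config(short_model, assignment, "XAA")
        twice = apply_config(once, assignment, "XAA")
        assert once.sequence == twice.sequence
        # original untouched
        assert "N" not in short_model.sequence["A"]

    def test_non_layer_residues_untouched(self, short_model, assignment):
        designed = apply_config(short_model, assignment, "AAA")
        layered = set().union(*assignment.inner, *assignment.flipping)
        for res in range(1, short_model.n_res + 1):
            if res not in layered:
                assert designed.sequence["A"][res - 1] == short_model.sequence["A"][res - 1]

    def test_length_mismatch_rejected(self, short_model, assignment):
        with pytest.raises(ParameterError):
            apply_config(short_model, assignment, "XAXA")


class TestBurial:
    def test_identical_models_zero_delta(self, short_model, assignment):
        d = burial_delta(short_model, short_model, assignment)
        assert np.allclose(d["inner"], 0.0)
        assert np.allclose(d["flipping"], 0.0)

    def test_inner_layers_more_exposed_in_long_state(self, deltas):
        assert np.all(deltas["inner"] > 0)

    def test_additive_over_disjoint_residue_sets(self, short_model, long_model, assignment):
        from helixswitch.interface_design import LayerAssignment
        merged = LayerAssignment(
            inner=[frozenset().union(*assignment.inner), frozenset(), frozenset()],
            flipping=[frozenset().union(*assignment.flipping), frozenset(), frozenset()])
        # fill empties with singletons to satisfy lookups trivially skipped
        d_full = burial_delta(short_model, long_model, assignment)
        d_merged = burial_delta(short_model, long_model, merged)
        # biotite returns float32 SASA values, hence the looser tolerance
        assert d_merged["inner"][0] == pytest.approx(d_full["inner"].sum(), rel=1e-5)

    def test_sasa_matches_analytic_sphere(self):
        # one isolated CA pseudo-residue per chain, far apart
        model = BundleModel(
            chains={"A": np.array([[50.0, 0.0, 0.0]]),
                    "B": np.array([[-50.0, 0.0, 0.0]]),
                    "C": np.array([[0.0, 50.0, 0.0]])},
            segments=["flipping"], sequence={c: "A" for c in "ABC"})
        sasa = residue_sasa(model)
        analytic = 4 * np.pi * (3.0 + 1.4) ** 2
        for cid in "ABC":
            assert sasa[cid][0] == pytest.approx(analytic, rel=0.02)

    def test_fully_buried_sphere_zero_sasa(self):
        # center point caged by a dense shell of neighbours
        shell = []
        for theta in np.linspace(0, np.pi, 8):
            for phi in np.linspace(0, 2 * np.pi, 12, endpoint=False):
                shell.append([3.0 * np.sin(theta) * np.cos(phi),
                              3.0 * np.sin(theta) * np.sin(phi),
                              3.0 * np.cos(theta)])
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        n = len(coords)
        model = BundleModel(chains={"A": coords}, segments=["flipping"] * n,
                            sequence={"A": "A" * n})
        assert residue_sasa(model)["A"][0] == pytest.approx(0.0, abs=1e-9)


class TestPreferenceScore:
    def test_observed_states_reproduced(self, deltas):
        for code in ("XXA", "XAX", "XAA"):
            assert score_state_preference(code, deltas["inner"]) < 0
        assert score_state_preference("AAA", deltas["inner"]) > 0

    def test_monotone_in_network_count(self, deltas):
        by_count = {k: [] for k in range(4)}
        for cfg in enumerate_configs():
            by_count[cfg.n_networks].append(
                score_state_preference(cfg, deltas["inner"]))
        assert min(by_count[3]) > max(by_count[2])
        assert min(by_count[2]) > max(by_count[1])
        assert min(by_count[1]) > max(by_count[0])

    def test_xxx_most_short_favoring(self, deltas):
        scores = {cfg.code: score_state_preference(cfg, deltas["inner"])
                  for cfg in enumerate_configs()}
        assert min(scores, key=scores.get) == "XXX"

    def test_zero_weights_zero_score(self):
        zeros = ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
        for cfg in enumerate_configs():
            assert score_state_preference(cfg, weights=zeros) == 0.0


class TestPolarTriad:
    def triad_model(self, pairwise):
        radius = pairwise / np.sqrt(3)
        images = apply_c3(np.array([[radius, 0.0, 5.0]]))
        return BundleModel(chains={c: img for c, img in zip("ABC", images)},
                           segments=["flipping"], sequence={c: "N" for c in "ABC"})

    def test_triad_at_network_distance(self):
        ok, report = polar_triad_check(self.triad_model(3.0), [1], proxy_offset=0.0)
        assert ok
        assert report[1]["qualifies"]
        assert report[1]["distances"][0] == pytest.approx(3.0, abs=1e-9)

    def test_triad_too_far_apart(self):
        ok, report = polar_triad_check(self.triad_model(8.0), [1], proxy_offset=0.0)
        assert not ok

    def test_empty_residue_set(self, short_model):
        ok, report = polar_triad_check(short_model, [])
        assert not ok
        assert report == {}
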