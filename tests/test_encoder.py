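"""Trial encoding: RF kernel map, spatial/time HVs, polarization, fusion."""

import numpy as np
import pandas as pd
import pytest

from spikehd.hdc import HDConfig, cosine_similarity
from spikehd.encoder import (
    EncoderState,
    build_spatial_hvs,
    encode_receptive_field,
    encode_trial,
    encode_trials,
    make_projection_basis,
    make_time_hvs,
)
from spikehd.resolution import BinnedTensor

CFG = HDConfig(D=4000, seed=7)


def state(**kw):
    return EncoderState(CFG, **kw)


class TestReceptiveFieldEncoding:
    def test_zero_fingerprint_encodes_to_zero(self):
        basis = make_projection_basis(CFG)
        assert np.allclose(encode_receptive_field(np.zeros(81), basis), 0.0)

    def test_identical_fingerprints_identical_encodings(self):
        basis = make_projection_basis(CFG)
        F = np.random.default_rng(0).random(81)
        e1 = encode_receptive_field(F, basis)
        e2 = encode_receptive_field(F.copy(), basis)
        assert np.array_equal(e1, e2)
        assert cosine_similarity(e1, e2) == pytest.approx(1.0)
        assert np.all(np.abs(e1) <= 1.0)

    def test_similarity_decays_with_feature_distance(self):
        # kernel-trick map: growing perturbation -> monotonically falling
        # similarity (averaged over 20 bases)
        eps_grid = [0.0, 0.2, 0.5, 1.0, 2.0]
        mean_sims = []
        for eps in eps_grid:
            sims = []
            for seed in range(20):
                cfg = HDConfig(D=2000, seed=seed)
                basis = make_projection_basis(cfg)
                rng = np.random.default_rng(100 + seed)
                F = rng.random(81)
                e = rng.standard_normal(81)
                e /= np.linalg.norm(e)
                sims.append(cosine_similarity(
                    encode_receptive_field(F, basis),
                    encode_receptive_field(F + eps * e, basis)))
            mean_sims.append(np.mean(sims))
        assert all(a > b for a, b in zip(mean_sims, mean_sims[1:]))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            encode_receptive_field(np.zeros(80), make_projection_basis(CFG))


class TestSpatialHVs:
    def test_neuron_level_rf_and_area_binding(self):
        st = state()
        units = pd.DataFrame({"unit_id": [0, 1, 2], "area": ["VISp", "VISp", "CA1"]})
        F = np.random.default_rng(1).random(81)
        rf = np.stack([F, F, F])
        bt = BinnedTensor(np.zeros((3, 1, 1), dtype=int), [0, 1, 2], 250, "neuron")
        S = build_spatial_hvs(st, bt, units=units, rf_matrix=rf)
        assert np.array_equal(S[0], S[1])  # same area, same fingerprint
        assert not np.array_equal(S[0], S[2])  # area HV differs

    def test_area_level_uses_area_hvs(self):
        st = state()
        bt = BinnedTensor(np.zeros((3, 1, 1), dtype=int), ["VISp", "VISam", "CA1"], 250, "area")
        S = build_spatial_hvs(st, bt)
        for i, a in enumerate(["VISp", "VISam", "CA1"]):
            assert np.array_equal(S[i], st.area_hv(a))
        assert len({tuple(r) for r in S}) == 3

    def test_population_level_binds_shared_ei_hv(self):
        st = state()
        bt = BinnedTensor(np.zeros((4, 1, 1), dtype=int),
                          ["VISp/E", "VISp/I", "CA1/E", "CA1/I"], 250, "population")
        S = build_spatial_hvs(st, bt)
        assert np.array_equal(S[0], st.ei_hv("E") * st.area_hv("VISp"))
        assert np.array_equal(S[3], st.ei_hv("I") * st.area_hv("CA1"))

    def test_whole_brain_has_no_spatial_hv(self):
        bt = BinnedTensor(np.zeros((1, 1, 1), dtype=int), ["brain"], 250, "whole_brain")
        assert build_spatial_hvs(state(), bt) is None

    def test_neuron_level_requires_rf(self):
        bt = BinnedTensor(np.zeros((1, 1, 1), dtype=int), [0], 250, "neuron")
        with pytest.raises(ValueError, match="rf_matrix"):
            build_spatial_hvs(state(), bt)


class TestTimeHVs:
    def test_endpoint_and_midpoint(self):
        st = state()
        T = make_time_hvs(2, st, "k")
        t0, t1 = st.time_endpoints("k")
        assert np.array_equal(T[0], t0)
        assert np.allclose(T[1], 0.5 * t0 + 0.5 * t1)

    def test_polarization_antisymmetric(self):
        st = state()
        assert np.array_equal(st.h_minus, -st.h_plus)

    def test_similarity_decays_with_temporal_distance(self):
        st = state()
        T = make_time_hvs(250, st, "trial9")
        sims = [cosine_similarity(T[0], T[t]) for t in range(0, 250, 25)]
        assert all(a >= b - 1e-12 for a, b in zip(sims, sims[1:]))

    def test_independent_vs_shared_endpoints(self):
        st_ind = state(time_mode="independent_per_trial")
        a0, _ = st_ind.time_endpoints("t1")
        b0, _ = st_ind.time_endpoints("t2")
        assert not np.array_equal(a0, b0)
        st_sh = state(time_mode="shared")
        c0, _ = st_sh.time_endpoints("t1")
        d0, _ = st_sh.time_endpoints("t2")
        assert np.array_equal(c0, d0)

    def test_m_zero_rejected(self):
        with pytest.raises(ValueError):
            make_time_hvs(0, state())


class TestTrialEncoding:
    def test_single_unit_single_bin_polarization(self):
        st = state()
        S = np.random.default_rng(2).choice((-1.0, 1.0), (1, CFG.D))
        T = make_time_hvs(1, st, "k")
        v_silent = encode_trial(np.array([[0]]), S, st, T)
        v_three = encode_trial(np.array([[3]]), S, st, T)
        assert np.allclose(v_silent, (S[0] * st.h_minus) * T[0])
        assert np.allclose(v_three, 3 * (S[0] * st.h_plus) * T[0])

    def test_fast_path_matches_reference(self):
        st = state()
        rng = np.random.default_rng(3)
        counts = rng.poisson(0.8, (5, 10, 4)).astype(np.int32)
        bt = BinnedTensor(counts, ["VISp", "VISam", "CA1", "TH", "ZI"], 25, "area")
        S = build_spatial_hvs(st, bt)
        keys = [f"k{j}" for j in range(4)]
        fast = encode_trials(bt, S, st, keys)
        for j, key in enumerate(keys):
            ref = encode_trial(counts[:, :, j], S, st, make_time_hvs(10, st, key))
            assert np.allclose(fast[j], ref)

    def test_fast_path_matches_reference_whole_brain(self):
        st = state()
        counts = np.random.default_rng(4).poisson(3.0, (1, 5, 3)).astype(np.int32)
        bt = BinnedTensor(counts, ["brain"], 50, "whole_brain")
        fast = encode_trials(bt, None, st, ["a", "b", "c"])
        for j, key in enumerate(["a", "b", "c"]):
            ref = encode_trial(counts[:, :, j], None, st, make_time_hvs(5, st, key))
            assert np.allclose(fast[j], ref)

    def test_linearity_in_counts_away_from_zero_boundary(self):
        st = state()
        counts = np.random.default_rng(5).integers(1, 5, (4, 6)).astype(np.int32)
        S = np.random.default_rng(6).choice((-1.0, 1.0), (4, CFG.D))
        T = make_time_hvs(6, st, "k")
        v1 = encode_trial(counts, S, st, T)
        v2 = encode_trial(2 * counts, S, st, T)
        assert np.allclose(v2, 2 * v1)

    def test_flipping_presence_flips_contribution_sign(self):
        st = state()
        S = np.random.default_rng(7).choice((-1.0, 1.0), (1, CFG.D))
        T = make_time_hvs(1, st, "k")
        v_on = encode_trial(np.array([[1]]), S, st, T)
        v_off = encode_trial(np.array([[0]]), S, st, T)
        assert np.allclose(v_on, -v_off)

    def test_identical_counts_shared_vs_independent_time_hvs(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(1.0, (5, 2, 2)).astype(np.int32)
        counts[:, :, 1] = counts[:, :, 0]  # two identical trials
        bt = BinnedTensor(counts, list("abcde"), 125, "area")
        cfg = HDConfig(D=10_000, seed=0)
        st_sh = EncoderState(cfg, time_mode="shared")
        S = np.random.default_rng(9).choice((-1.0, 1.0), (5, cfg.D))
        v_sh = encode_trials(bt, S, st_sh, ["x", "y"])
        assert cosine_similarity(v_sh[0], v_sh[1]) == pytest.approx(1.0)
        # independent endpoints: similarity strictly below the shared-mode 1.
        # It stays well above 0 because the binary {0,1} endpoints are not
        # zero-mean, so a fraction of the bundle overlap always transfers.
        sims = []
        for seed in range(50):
            st_ind = EncoderState(HDConfig(D=10_000, seed=seed))
            v = encode_trials(bt, S, st_ind, ["x", "y"])
            sims.append(abs(cosine_similarity(v[0], v[1])))
        assert max(sims) < 0.9

    def test_shared_mode_raises_within_class_similarity(self):
        # shared time HVs transfer per-bin similarity across trials, so
        # same-class trials look more alike than under independent HVs
        rng = np.random.default_rng(10)
        base = rng.poisson(2.0, (5, 2))
        counts = np.stack([base + rng.poisson(1, (5, 2)) for _ in range(6)], axis=2)
        bt = BinnedTensor(counts.astype(np.int32), list("abcde"), 125, "area")
        S = np.random.default_rng(11).choice((-1.0, 1.0), (5, CFG.D))
        keys = [f"t{j}" for j in range(6)]

        def mean_abs_pairwise(st):
            V = encode_trials(bt, S, st, keys)
            sims = [abs(cosine_similarity(V[i], V[j]))
                    for i in range(6) for j in range(i + 1, 6)]
            return np.mean(sims)

        assert mean_abs_pairwise(state(time_mode="shared")) > mean_abs_pairwise(state())
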