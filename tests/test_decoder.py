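"""SpD decoder components: elbow filter, OLS refit, coefficient estimation,
adaptive regularization and field-of-view decoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dartfish as df
from dartfish.codebook import barcode_to_onehot
from dartfish.decoder import (AlphaLookup, DecoderConfig, _elbow_ols_batch,
                              build_alpha_lookup, decode_fov,
                              estimate_channel_coefficients)
from dartfish.simulate import simulate_fov


@pytest.fixture(scope="module")
def X131():
    bcs = df.enumerate_barcodes(6, 3, multicolor_only=True)[:131]
    return np.stack([barcode_to_onehot(b) for b in bcs], axis=1)


class TestMaxUndetectedWeight:
    @pytest.mark.parametrize("n,k,alpha,expected", [
        (6, 3, 0.05, 0.3),
        (6, 3, 0.0, 0.0),
        (7, 3, 0.05, 0.35),
    ])
    def test_closed_form(self, n, k, alpha, expected):
        assert df.max_undetected_weight(n, k, alpha) == pytest.approx(expected)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            df.max_undetected_weight(6, 0, 0.05)


class TestElbowFilter:
    def test_all_zero_input_rejected_pixel(self):
        assert df.elbow_filter(np.zeros(10)) == ()

    def test_clear_top1(self):
        w = np.zeros(10)
        w[[2, 5, 8]] = [0.5, 0.20, 0.05]
        assert df.elbow_filter(w) == (2,)

    def test_top2_when_second_strong_but_third_weak(self):
        w = np.zeros(10)
        w[[2, 5, 8]] = [0.5, 0.30, 0.10]
        assert df.elbow_filter(w) == (2, 5)

    def test_ambiguous_pixel_rejected(self):
        w = np.zeros(10)
        w[[2, 5, 8]] = [0.5, 0.30, 0.20]
        assert df.elbow_filter(w) == ()

    def test_tie_broken_toward_smaller_index(self):
        w = np.zeros(6)
        w[[1, 4]] = [0.4, 0.4]
        top = df.elbow_filter(w)
        assert top in ((1, 4), ())  # second == top -> not top1-only
        assert top == (1, 4)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            df.elbow_filter(np.array([-0.1, 0.2]))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=3, max_size=20))
    def test_support_never_exceeds_two(self, ws):
        sup = df.elbow_filter(np.array(ws))
        assert len(sup) <= 2
        if len(sup) == 1:
            w = np.array(ws)
            top = np.sort(w)[::-1]
            assert top[1] < 0.5 * top[0]


class TestOLSRefit:
    def test_single_support_exact(self, X131):
        y = 0.4 * X131[:, 7]
        w = df.ols_refit(y, X131, (7,))
        assert w[7] == pytest.approx(0.4, abs=1e-12)
        assert np.count_nonzero(w) == 1

    def test_orthogonal_pair_exact(self, X131):
        # find two barcodes with disjoint on-positions
        found = None
        for i in range(X131.shape[1]):
            for j in range(i + 1, X131.shape[1]):
                if X131[:, i] @ X131[:, j] == 0:
                    found = (i, j)
                    break
            if found:
                break
        i, j = found
        y = 0.3 * X131[:, i] + 0.2 * X131[:, j]
        w = df.ols_refit(y, X131, (i, j))
        assert w[i] == pytest.approx(0.3, abs=1e-12)
        assert w[j] == pytest.approx(0.2, abs=1e-12)

    def test_noisy_pair_matches_normal_equations(self, X131, rng):
        i, j = 3, 90
        y = np.clip(0.5 * X131[:, i] + 0.35 * X131[:, j]
                    + rng.normal(0, 0.05, 18), 0, None)
        w = df.ols_refit(y, X131, (i, j))
        A = X131[:, [i, j]]
        ref = np.linalg.solve(A.T @ A, A.T @ y)
        assert w[i] == pytest.approx(ref[0], abs=1e-10)
        assert w[j] == pytest.approx(ref[1], abs=1e-10)

    def test_negative_refit_drops_to_single_support(self, X131):
        i, j = 3, 90
        y = 0.5 * X131[:, i]  # j contributes nothing
        # force a tiny anti-correlated component
        y = np.clip(y - 0.01 * X131[:, j], 0, None)
        w = df.ols_refit(y, X131, (i, j))
        assert w[j] == 0
        assert w[i] > 0

    def test_bad_support_size_rejected(self, X131):
        with pytest.raises(ValueError):
            df.ols_refit(np.zeros(18), X131, (1, 2, 3))

    def test_batch_path_agrees_with_scalar_path(self, X131, rng):
        cfg = DecoderConfig()
        P = 200
        Y = np.zeros((18, P))
        for _ in range(2):
            idx = rng.integers(0, 131, P)
            Y += X131[:, idx] * rng.uniform(0, 0.7, P)
        Y = np.clip(Y, 0, 1)
        W, _ = df.solver.nonneg_elastic_net(X131, Y, 0.05, 0.0005, tol=1e-9)
        sup, wref = _elbow_ols_batch(W, X131, Y, cfg)
        for p in range(P):
            expected = df.elbow_filter(W[:, p])
            got = tuple(int(s) for s in sup[:, p] if s >= 0)
            if not expected:
                assert got == ()
                continue
            w_scalar = df.ols_refit(Y[:, p], X131, expected)
            got_set = dict(zip(got, wref[: len(got), p]))
            nz = {i: w_scalar[i] for i in np.nonzero(w_scalar)[0]}
            assert set(got_set) == set(nz)
            for i in nz:
                assert got_set[i] == pytest.approx(nz[i], abs=1e-9)


class TestAlphaLookup:
    def test_single_alpha_grid(self, tiny_sim):
        cfg = DecoderConfig(alpha_grid=(0.05,), lookup_sample_size=200)
        lk = build_alpha_lookup(tiny_sim["stack"], tiny_sim["codebook"],
                                np.ones(18), cfg)
        assert np.all(lk.alphas == 0.05)

    def test_query_clamped_to_grid(self):
        lk = AlphaLookup(norms=np.array([0.0, 1.0, 2.0]),
                         alphas=np.array([0.01, 0.05, 0.1]))
        assert lk.alpha_for(-5.0) == 0.01
        assert lk.alpha_for(99.0) == 0.1
        assert lk.alpha_for(1.1) == 0.05
        np.testing.assert_array_equal(lk.alpha_for([0.4, 1.6]),
                                      [0.01, 0.1])

    def test_narrow_kernel_reproduces_exhaustive_argmax(self, X131, rng):
        """With all training pixels at one norm and a tiny bandwidth, the
        lookup at that norm must equal a direct exhaustive evaluation."""
        from dartfish.io import FOVStack
        # build pixels scaled to unit norm from barcode mixtures
        P = 60
        Y = np.zeros((18, P))
        idx = rng.integers(0, 131, P)
        Y += X131[:, idx] * rng.uniform(0.3, 0.7, P)
        Y /= np.linalg.norm(Y, axis=0)
        book = df.assign_genes(
            df.enumerate_barcodes(6, 3, multicolor_only=True)[:131],
            [f"g{i}" for i in range(121)], 10, rng_seed=0)
        stack = FOVStack(data=Y.reshape(18, P, 1), n=6)
        cfg = DecoderConfig(kernel_bandwidth=1e-4,
                            norm_grid=tuple(np.linspace(0.9, 1.1, 3)),
                            lookup_sample_size=P)
        lk = build_alpha_lookup(stack, book, np.ones(18), cfg)
        # exhaustive oracle at u = 1.0: all kernel weights equal
        scores = []
        for alpha in cfg.alpha_grid:
            W, _ = df.solver.nonneg_elastic_net(book.X, Y, alpha,
                                                alpha * cfg.alpha_ratio,
                                                tol=1e-8)
            l1 = 0.0
            for p in range(P):
                supp = df.elbow_filter(W[:, p])
                if supp:
                    l1 += df.ols_refit(Y[:, p], book.X, supp).sum()
            scores.append(l1)
        best = max(range(len(scores)),
                   key=lambda a: (scores[a], cfg.alpha_grid[a]))
        assert lk.alpha_for(1.0) == pytest.approx(cfg.alpha_grid[best])

    def test_empty_training_sample_rejected(self, tiny_codebook):
        from dartfish.io import FOVStack
        stack = FOVStack(data=np.zeros((18, 8, 8)), n=6)
        with pytest.raises(ValueError):
            build_alpha_lookup(stack, tiny_codebook, np.ones(18),
                               DecoderConfig())


class TestChannelCoefficients:
    def test_identity_coefficients_recovered(self, tiny_codebook):
        stack, _, coeffs = simulate_fov(tiny_codebook, 600, shape=(192, 192),
                                        coeff_range=(1.0, 1.0), rng_seed=11)
        c = estimate_channel_coefficients(stack, tiny_codebook,
                                          DecoderConfig(rng_seed=0))
        assert np.all(np.abs(c - 1.0) < 0.03)

    def test_known_coefficients_recovered(self, tiny_sim):
        c = estimate_channel_coefficients(tiny_sim["stack"],
                                          tiny_sim["codebook"],
                                          DecoderConfig(rng_seed=0))
        rel = np.abs(c - tiny_sim["coeffs"]) / tiny_sim["coeffs"]
        assert np.median(rel) < 0.05

    def test_background_stack_rejected(self, tiny_codebook):
        from dartfish.io import FOVStack
        stack = FOVStack(data=np.zeros((18, 16, 16)), n=6)
        with pytest.raises(ValueError):
            estimate_channel_coefficients(stack, tiny_codebook)


class TestDecodeFOV:
    def test_zero_stack_decodes_to_nothing(self, tiny_codebook):
        from dartfish.io import FOVStack
        stack = FOVStack(data=np.zeros((18, 32, 32)), n=6)
        lk = AlphaLookup(norms=np.array([0.0, 1.0]),
                         alphas=np.array([0.05, 0.05]))
        maps = decode_fov(stack, tiny_codebook, np.ones(18), lk)
        assert maps.n_entries == 0
        assert maps.metadata["n_foreground"] == 0

    def test_single_rolony_recovered_in_its_own_map(self, tiny_codebook):
        stack, truth, _ = simulate_fov(
            tiny_codebook, 1, shape=(64, 64), coeff_range=(1.0, 1.0),
            intensity_range=(0.5, 0.5), rng_seed=4)
        lk = AlphaLookup(norms=np.array([0.0]), alphas=np.array([0.05]))
        maps = decode_fov(stack, tiny_codebook, np.ones(18), lk)
        b = truth[0].barcode_index
        img = maps.dense(b)
        assert img.max() > 0
        # peak weight near the true peak intensity of 0.5
        assert abs(img.max() - 0.5) < 0.05
        # all other maps empty (a faint secondary support may appear only
        # at the rolony's own barcode)
        others = [int(x) for x in maps.barcodes_present() if int(x) != b]
        for o in others:
            assert maps.dense(o).max() < 0.5 * img.max()

    def test_gain_normalization_invariance(self, tiny_codebook):
        stack, _, _ = simulate_fov(tiny_codebook, 50, shape=(96, 96),
                                   coeff_range=(1.0, 1.0), rng_seed=6,
                                   clip=False)
        from dartfish.io import FOVStack
        doubled = FOVStack(data=stack.data * 2.0, n=stack.n)
        lk = AlphaLookup(norms=np.array([0.0]), alphas=np.array([0.05]))
        m1 = decode_fov(stack, tiny_codebook, np.ones(18), lk)
        m2 = decode_fov(doubled, tiny_codebook, 2.0 * np.ones(18), lk)
        assert np.array_equal(m1.pixel_idx, m2.pixel_idx)
        assert np.array_equal(m1.barcode_idx, m2.barcode_idx)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-9)

    def test_dimension_mismatch_rejected(self, tiny_codebook):
        from dartfish.io import FOVStack
        stack = FOVStack(data=np.zeros((21, 8, 8)), n=7)
        lk = AlphaLookup(norms=np.array([0.0]), alphas=np.array([0.05]))
        with pytest.raises(ValueError):
            decode_fov(stack, tiny_codebook, np.ones(21), lk)

    def test_weight_maps_are_nonnegative_with_at_most_two_barcodes(
            self, tiny_decode):
        maps = tiny_decode["results"].maps
        assert np.all(maps.weights >= 0)
        # per pixel, at most two barcode entries
        _, counts = np.unique(maps.pixel_idx, return_counts=True)
        assert counts.max() <= 2
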