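"""Estimator backends against exhaustive-enumeration and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import digamma

from phasete import EmbeddingSpec, EstimatorParams, PhaseEnsemble, dte, \
    te_bin, te_kalpha, te_ksg, te_sym
from phasete.estimators import prepare_te, renyi_entropy
from phasete.exceptions import InsufficientSamplesError, MemoryGuardError

BAND = (15.0, 35.0)


def _pe(arr, fs=100.0):
    return PhaseEnsemble(np.asarray(arr, dtype=float), BAND, fs)


def _plugin_entropy(samples):
    """Exhaustive plug-in Shannon entropy of hashable tuples (oracle)."""
    counts = {}
    for s in samples:
        counts[s] = counts.get(s, 0) + 1
    n = len(samples)
    return -sum(c / n * math.log(c / n) for c in counts.values())


class TestBinningOracle:
    def test_copy_process_equals_ln2_exactly(self):
        # Y_t = X_{t-1} with a balanced two-symbol de Bruijn stream; the four
        # cyclic rotations jointly make every pair count exactly equal, so the
        # plug-in sums evaluate to ln 2 in closed form.
        a, b = -np.pi / 2, np.pi / 2
        k = 6
        xs, ys = [], []
        cycle = [a, a, b, b]
        for r in range(4):
            rot = cycle[r:] + cycle[:r]
            seq = np.array(rot * k + [rot[0]])
            ys.append(seq[:-1])
            xs.append(seq[1:])
        x, y = _pe(np.array(xs)), _pe(np.array(ys))
        params = EstimatorParams(method="bin", n_bins=2)
        val = te_bin(x, y, u=1, params=params).value
        assert val == pytest.approx(math.log(2.0), abs=1e-12)

    def test_matches_exhaustive_enumeration(self, rng):
        # independent oracle: enumerate the four plug-in entropy terms
        x = rng.uniform(-np.pi, np.pi, (3, 40))
        y = rng.uniform(-np.pi, np.pi, (3, 40))
        params = EstimatorParams(method="bin", n_bins=4)
        u = 2
        val = te_bin(_pe(x), _pe(y), u=u, params=params).value
        h = 2 * np.pi / 4
        cx = np.minimum(((x + np.pi) / h).astype(int), 3)
        cy = np.minimum(((y + np.pi) / h).astype(int), 3)
        t0 = max(1, u)
        trip, xy_p, yn_yp, yp = [], [], [], []
        for r in range(3):
            for t in range(t0, 40):
                trip.append((cy[r, t], cy[r, t - 1], cx[r, t - u]))
                xy_p.append((cy[r, t - 1], cx[r, t - u]))
                yn_yp.append((cy[r, t], cy[r, t - 1]))
                yp.append((cy[r, t - 1],))
        expected = (_plugin_entropy(xy_p) - _plugin_entropy(trip)
                    + _plugin_entropy(yn_yp) - _plugin_entropy(yp))
        assert val == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_under_null(self, uniform_phase_pair):
        x, y = uniform_phase_pair
        vals = [te_bin(x.subset(range(i, i + 10)), y.subset(range(i, i + 10)),
                       u=1).value for i in range(0, 20, 10)]
        assert all(v >= -1e-12 for v in vals)


class TestSymbolicOracle:
    def test_monotone_series_yields_zero(self):
        x = _pe(np.linspace(-3, 3, 16)[None, :].repeat(2, axis=0))
        y = _pe(np.linspace(-2.8, 2.9, 16)[None, :].repeat(2, axis=0))
        params = EstimatorParams(
            method="sym", emb_source=EmbeddingSpec(3, 1),
            emb_target=EmbeddingSpec(3, 1))
        assert te_sym(x, y, u=1, params=params).value == pytest.approx(0.0,
                                                                       abs=1e-14)

    def test_matches_exhaustive_symbol_counting(self, rng):
        # independent oracle: stable-argsort patterns counted by hand
        x = rng.uniform(-np.pi, np.pi, (2, 12))
        y = rng.uniform(-np.pi, np.pi, (2, 12))
        d, tau, u = 2, 1, 1
        params = EstimatorParams(method="sym", emb_source=EmbeddingSpec(d, tau),
                                 emb_target=EmbeddingSpec(d, tau))
        val = te_sym(_pe(x), _pe(y), u=u, params=params).value

        def sym_row(row):
            out = {}
            for t in range((d - 1) * tau, len(row)):
                win = tuple(row[t - j * tau] for j in range(d))
                out[t] = tuple(np.argsort(win, kind="stable"))
            return out

        hist = (d - 1) * tau
        t0 = hist + max(1, u)
        trip, xp_yp, yn_yp, yp = [], [], [], []
        for r in range(2):
            sx, sy = sym_row(x[r]), sym_row(y[r])
            for t in range(t0, 12):
                trip.append((sy[t], sy[t - 1], sx[t - u]))
                xp_yp.append((sy[t - 1], sx[t - u]))
                yn_yp.append((sy[t], sy[t - 1]))
                yp.append((sy[t - 1],))
        expected = (_plugin_entropy(xp_yp) - _plugin_entropy(trip)
                    + _plugin_entropy(yn_yp) - _plugin_entropy(yp))
        assert val == pytest.approx(expected, abs=1e-12)

    def test_exact_monotone_transform_invariance(self, rng):
        x = rng.uniform(-1.5, 1.5, (3, 60))
        y = rng.uniform(-1.5, 1.5, (3, 60))
        params = EstimatorParams(method="sym", emb_source=EmbeddingSpec(3, 2),
                                 emb_target=EmbeddingSpec(3, 2))
        v1 = te_sym(_pe(x), _pe(y), u=2, params=params).value
        v2 = te_sym(_pe(np.tanh(x)), _pe(np.tanh(y)), u=2, params=params).value
        assert v1 == pytest.approx(v2, abs=1e-14)


class TestKSGOracle:
    def test_matches_bruteforce_neighbor_counts(self, rng):
        # O(N^2) oracle: circular max-norm distances, k-th NN radius, strict
        # strip counts, digamma average
        x = rng.uniform(-np.pi, np.pi, (2, 25))
        y = rng.uniform(-np.pi, np.pi, (2, 25))
        u, k = 1, 2
        emb = EmbeddingSpec(1, 1)
        params = EstimatorParams(method="ksg", k=k, emb_source=emb,
                                 emb_target=emb, max_samples=None)
        val = te_ksg(_pe(x), _pe(y), u=u, params=params).value

        t0 = max(1, u)
        yn = y[:, t0:].ravel()
        yp = y[:, t0 - 1:-1].ravel()
        xp = x[:, t0 - u:x.shape[1] - u].ravel()

        def cd(a):
            d = np.abs(a[:, None] - a[None, :]) % (2 * np.pi)
            return np.minimum(d, 2 * np.pi - d)

        d_joint = np.maximum(np.maximum(cd(yn), cd(yp)), cd(xp))
        n = d_joint.shape[0]
        eps = np.sort(d_joint + np.diag(np.full(n, np.inf)), axis=1)[:, k - 1]
        n_yp = ((cd(yp) < eps[:, None]).sum(axis=1) - 1)
        n_ynyp = ((np.maximum(cd(yn), cd(yp)) < eps[:, None]).sum(axis=1) - 1)
        n_ypxp = ((np.maximum(cd(yp), cd(xp)) < eps[:, None]).sum(axis=1) - 1)
        expected = digamma(k) + np.mean(
            digamma(n_yp + 1) - digamma(n_ynyp + 1) - digamma(n_ypxp + 1))
        assert val == pytest.approx(expected, abs=1e-10)

    def test_near_zero_under_independence(self, uniform_phase_pair):
        x, y = uniform_phase_pair
        emb = EmbeddingSpec(1, 1)
        params = EstimatorParams(method="ksg", emb_source=emb, emb_target=emb,
                                 max_samples=None)
        vals = [te_ksg(x.subset(range(i, i + 6)), y.subset(range(i, i + 6)),
                       u=1, params=params).value for i in range(0, 30, 6)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 0.01

    def test_too_few_points_rejected(self):
        x = _pe(np.zeros((1, 3)))
        with pytest.raises(InsufficientSamplesError):
            te_ksg(x, x, u=1, params=EstimatorParams(
                method="ksg", k=4, emb_source=EmbeddingSpec(1, 1),
                emb_target=EmbeddingSpec(1, 1)))


class TestRenyiEntropy:
    def test_rank_one_gram_is_zero(self):
        assert renyi_entropy(np.ones((20, 20)), 3.0) == pytest.approx(0.0,
                                                                      abs=1e-12)

    def test_identity_gram_is_log_n(self):
        n = 37
        assert renyi_entropy(np.eye(n), 3.0) == pytest.approx(np.log(n),
                                                              rel=1e-12)

    def test_eigen_equals_trace_power(self, rng):
        a = rng.standard_normal((50, 8))
        gram = np.exp(-((a[:, None, :] - a[None, :, :]) ** 2).sum(-1) / 4.0)
        h_eig = renyi_entropy(gram, 3.0, method="eig")
        h_tr = renyi_entropy(gram, 3.0, method="trace")
        assert h_eig == pytest.approx(h_tr, abs=1e-8)

    def test_kalpha_zero_for_constant_phases(self):
        x = _pe(np.full((3, 30), 0.4))
        y = _pe(np.full((3, 30), -1.2))
        params = EstimatorParams(method="kalpha", emb_source=EmbeddingSpec(1, 1),
                                 emb_target=EmbeddingSpec(1, 1))
        assert te_kalpha(x, y, u=1, params=params).value == pytest.approx(
            0.0, abs=1e-9)

    def test_entropy_terms_bounded(self, uniform_phase_pair):
        x, y = uniform_phase_pair
        emb = EmbeddingSpec(1, 1)
        params = EstimatorParams(method="kalpha", emb_source=emb,
                                 emb_target=emb, max_samples=150)
        prep = prepare_te("kalpha", x.subset(range(5)), y.subset(range(5)),
                          params, u_max=2)
        n = prep.n_used
        assert 0.0 <= prep.H_yp <= np.log(n) + 1e-9
        assert 0.0 <= prep.H_ynyp <= np.log(n) + 1e-9

    def test_memory_guard(self, uniform_phase_pair):
        x, y = uniform_phase_pair
        params = EstimatorParams(method="kalpha", emb_source=EmbeddingSpec(1, 1),
                                 emb_target=EmbeddingSpec(1, 1),
                                 max_samples=None, guard_n=100)
        with pytest.raises(MemoryGuardError):
            te_kalpha(x, y, u=1, params=params)


class TestSharedProperties:
    def test_dte_antisymmetry(self, coupled_phases):
        x, y = coupled_phases
        xs, ys = x.subset(range(20)), y.subset(range(20))
        fwd = dte("bin", xs, ys, u_xy=2, u_yx=3)
        rev = dte("bin", ys, xs, u_xy=3, u_yx=2)
        assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_dte_positive_under_forward_coupling(self, coupled_phases):
        x, y = coupled_phases
        signs = []
        for i in range(0, 60, 20):
            s = dte("bin", x.subset(range(i, i + 20)),
                    y.subset(range(i, i + 20)), u_xy=2, u_yx=2)
            signs.append(s > 0)
        assert all(signs)

    @pytest.mark.parametrize("method", ["bin", "sym", "ksg", "kalpha"])
    def test_joint_trial_relabeling_invariance(self, method,
                                               uniform_phase_pair, rng):
        x, y = uniform_phase_pair
        n_tr = 4 if method == "kalpha" else 12  # keep Gram matrices exact
        xs, ys = x.subset(range(n_tr)), y.subset(range(n_tr))
        perm = rng.permutation(n_tr)
        emb = EmbeddingSpec(1, 1)
        params = EstimatorParams(method=method, symbol_order=2,
                                 emb_source=EmbeddingSpec(2, 1),
                                 emb_target=EmbeddingSpec(2, 1),
                                 max_samples=None)
        fn = {"bin": te_bin, "sym": te_sym, "ksg": te_ksg,
              "kalpha": te_kalpha}[method]
        v1 = fn(xs, ys, u=1, params=params).value
        v2 = fn(xs.subset(perm), ys.subset(perm), u=1, params=params).value
        assert v1 == pytest.approx(v2, abs=1e-9)

    def test_bin_rotation_near_invariance(self, uniform_phase_pair):
        from phasete.signal_core import wrap_phase

        x, y = uniform_phase_pair
        xs, ys = x.subset(range(10)), y.subset(range(10))
        params = EstimatorParams(method="bin", n_bins=8)
        v1 = te_bin(xs, ys, u=1, params=params).value
        rot = 2 * np.pi / 8  # a whole bin width: codes rotate with the data
        xr = PhaseEnsemble(wrap_phase(xs.phase + rot), xs.band, xs.fs)
        yr = PhaseEnsemble(wrap_phase(ys.phase + rot), ys.band, ys.fs)
        v2 = te_bin(xr, yr, u=1, params=params).value
        assert v1 == pytest.approx(v2, abs=1e-10)

    def test_n_samples_used_accounting(self, uniform_phase_pair):
        x, y = uniform_phase_pair
        xs, ys = x.subset(range(7)), y.subset(range(7))
        res = te_bin(xs, ys, u=3)
        assert res.n_samples_used == 7 * (200 - 3)
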