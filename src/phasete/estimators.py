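"""Ensemble phase transfer entropy: four estimator backends and dTE.

Transfer entropy from a source phase series to a target phase series
quantifies how much the source's past (at interaction lag ``u``) improves
prediction of the target's next phase beyond the target's own past:

    TE(X -> Y) = H(Y_past, X_past) - H(Y_now, Y_past, X_past)
               + H(Y_now, Y_past) - H(Y_past)          [nats]

Embedded points are pooled over all repetition trials before any counting,
neighbor or kernel step (the ensemble method); embedding windows never
straddle trial boundaries.  The lag ``u`` applies to the source embedding
only; the target past is anchored one sample back.

Backends
--------
bin     plug-in Shannon entropies on equal-width circular histograms whose
        width follows Scott's rule with Fisher's circular s.d. of the pooled
        target phase; embedding dimension fixed at 1.
ksg     Kraskov-Stoegbauer-Grassberger algorithm 1 (k-th nearest neighbor in
        the joint space, strict strip counts with digamma corrections);
        max-norm with circular per-coordinate distance.
sym     permutation (ordinal-pattern) transfer entropy on symbolized phase
        windows; exactly invariant under monotone transforms.
kalpha  matrix-based Renyi alpha-order entropy from trace-normalized Gaussian
        Gram matrices (alpha=3 by default); phases enter through the chordal
        map theta -> (cos theta, sin theta) so the kernel respects
        periodicity.

Every backend exposes the same two surfaces: a one-shot functional API
(:func:`te_bin` etc.) and a :func:`prepare_te` evaluator that caches all
target-side structures so lag scans and trial-shuffle surrogates (which touch
only the source-trial pairing) are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .embedding import (
    EmbeddingSpec,
    TWO_PI,
    cc_select,
    delay_embed,
    ragwitz_select,
    scott_bin_width,
)
from .exceptions import (
    InsufficientSamplesError,
    MemoryGuardError,
    ShapeError,
)
from .signal_core import PhaseEnsemble

__all__ = [
    "EstimatorParams",
    "TEValue",
    "te_bin",
    "te_ksg",
    "te_sym",
    "te_kalpha",
    "dte",
    "prepare_te",
    "renyi_entropy",
]

METHODS = ("bin", "ksg", "sym", "kalpha")


@dataclass(frozen=True)
class EstimatorParams:
    """Estimator configuration shared by all backends.

    ``emb_source`` / ``emb_target`` override the automatic embedding
    selection (Ragwitz for ksg/kalpha, C-C for sym); their ``u`` field is
    ignored — the interaction lag is always passed separately.  ``max_samples``
    caps the number of pooled embedded points used by the ksg and kalpha
    backends (deterministic subsample drawn with ``seed``); the binning and
    symbolic backends always use every pooled point.  ``guard_n`` is the hard
    Gram-matrix size guard of the kalpha backend.
    """

    method: str = "bin"
    k: int = 4
    alpha: float = 3.0
    kernel_bandwidth_rule: str = "median"
    symbol_order: int = 3
    n_bins: Optional[int] = None  # fixed circular bin count; None -> Scott rule
    emb_source: Optional[EmbeddingSpec] = None
    emb_target: Optional[EmbeddingSpec] = None
    max_samples: Optional[int] = None
    guard_n: int = 6000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alpha <= 0 or self.alpha == 1:
            raise ValueError("alpha must be > 0 and != 1")
        if self.symbol_order < 2:
            raise ValueError("symbol_order must be >= 2")
        if self.kernel_bandwidth_rule != "median":
            raise ValueError("only the median bandwidth rule is implemented")


@dataclass(frozen=True)
class TEValue:
    """One directed transfer-entropy estimate (nats)."""

    value: float
    direction: tuple[str, str]
    u: int
    method: str
    n_samples_used: int


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _entropy_from_counts(counts: np.ndarray, n_total: int) -> float:
    c = counts[counts > 0].astype(float)
    p = c / n_total
    return float(-np.sum(p * np.log(p)))


def _lagged_coords(phase: np.ndarray, spec: EmbeddingSpec) -> np.ndarray:
    """``out[:, t, j] = phase[:, t - j*tau]`` (valid for ``t >= (d-1) tau``;
    earlier entries wrap and must never be indexed)."""
    r, T = phase.shape
    out = np.empty((r, T, spec.d))
    for j in range(spec.d):
        out[:, :, j] = np.roll(phase, j * spec.tau, axis=1)
    return out


def _resolve_embeddings(source: PhaseEnsemble, target: PhaseEnsemble,
                        params: EstimatorParams) -> tuple[EmbeddingSpec, EmbeddingSpec]:
    """Fill in missing embedding specs with the backend's selection rule."""
    es, et = params.emb_source, params.emb_target
    if params.method == "bin":
        return EmbeddingSpec(1, 1), EmbeddingSpec(1, 1)
    if params.method == "sym":
        if et is None:
            d, tau = cc_select(target, d_grid=(2, 3, 4, 5), seed=params.seed)
            d = max(d, 2)
            et = EmbeddingSpec(d, tau)
        es = es if es is not None else et
        return es, et
    # ksg / kalpha: Ragwitz per variable
    if et is None:
        d, tau = ragwitz_select(target, seed=params.seed)
        et = EmbeddingSpec(d, tau)
    if es is None:
        d, tau = ragwitz_select(source, seed=params.seed)
        es = EmbeddingSpec(d, tau)
    return es, et


class _PreparedBase:
    """Common pooling/alignment logic for all prepared evaluators.

    The valid target-time range ``t0 .. T-1`` is fixed from the largest lag
    that will be scanned, so TE values at different lags (and all surrogates)
    use the same number of pooled points.
    """

    method: str

    def __init__(self, source: PhaseEnsemble, target: PhaseEnsemble,
                 params: EstimatorParams, u_max: int,
                 es: EmbeddingSpec, et: EmbeddingSpec) -> None:
        if source.phase.shape != target.phase.shape:
            raise ShapeError("source and target ensembles must share shape")
        if u_max < 1:
            raise ValueError("u_max must be >= 1")
        self.params = params
        self.es, self.et = es, et
        self.r, self.T = target.phase.shape
        self.t0 = max(1 + et.history, u_max + es.history)
        self.D = self.T - self.t0
        if self.D <= 0:
            raise InsufficientSamplesError(
                f"trials of length {self.T} too short for history {self.t0}"
            )
        self.n_pooled = self.r * self.D

    def _pool_target(self, target: PhaseEnsemble,
                     yc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pooled (flattened) target-now values and target-past coordinate
        blocks, given the per-trial lagged-coordinate array ``yc``."""
        yn = target.phase[:, self.t0:]
        yp = yc[:, self.t0 - 1: self.T - 1, :]
        return yn, yp

    def te(self, u: int, perm: Optional[np.ndarray] = None) -> float:
        raise NotImplementedError

    def _check_u(self, u: int) -> None:
        if not (1 <= u + self.es.history <= self.t0):
            raise ValueError(f"lag {u} outside the prepared range (t0={self.t0})")


# ---------------------------------------------------------------------------
# binning backend
# ---------------------------------------------------------------------------

class _PreparedBin(_PreparedBase):
    method = "bin"

    def __init__(self, source, target, params, u_max, es, et):
        super().__init__(source, target, params, u_max,
                         EmbeddingSpec(1, 1), EmbeddingSpec(1, 1))
        # one bin width from the pooled target phase (Scott/Fisher rule),
        # reused for every coordinate of every marginal space
        if params.n_bins is not None:
            self.B = int(params.n_bins)
            self.h = TWO_PI / self.B
        else:
            self.h, self.B = scott_bin_width(target.phase.ravel())
        edges_code = lambda ph: np.minimum(
            ((ph + np.pi) / self.h).astype(np.int64), self.B - 1)
        cy = edges_code(target.phase)
        self.cx = edges_code(source.phase)
        # combined target code: now * B + past
        self.ct = cy[:, self.t0:] * self.B + cy[:, self.t0 - 1: self.T - 1]

    def te(self, u: int, perm: Optional[np.ndarray] = None) -> float:
        self._check_u(u)
        cx = self.cx if perm is None else self.cx[perm]
        xp = cx[:, self.t0 - u: self.T - u]
        B, n = self.B, self.n_pooled
        code = (xp.astype(np.int64) * B * B + self.ct).ravel()
        counts = np.bincount(code, minlength=B * B * B).reshape(B, B, B)
        h_joint = _entropy_from_counts(counts.ravel(), n)
        h_x_yp = _entropy_from_counts(counts.sum(axis=1).ravel(), n)   # (x, y_past)
        h_yn_yp = _entropy_from_counts(counts.sum(axis=0).ravel(), n)  # (y_now, y_past)
        h_yp = _entropy_from_counts(counts.sum(axis=(0, 1)), n)        # (y_past,)
        return h_x_yp - h_joint + h_yn_yp - h_yp


# ---------------------------------------------------------------------------
# symbolic backend
# ---------------------------------------------------------------------------

def _symbolize(phase: np.ndarray, d: int, tau: int) -> tuple[np.ndarray, int]:
    """Ordinal-pattern codes per trial.

    ``sym[:, t]`` is defined for ``t >= (d-1) tau`` (window anchored at its
    newest sample); earlier entries are 0 and must not be indexed.  Ties are
    broken by order of occurrence (stable argsort).  Codes enumerate the
    argsort sequence in base ``d`` (injective over permutations).
    """
    r, T = phase.shape
    hist = (d - 1) * tau
    spec = EmbeddingSpec(d, tau)
    sym = np.zeros((r, T), dtype=np.int64)
    weights = d ** np.arange(d)
    for i in range(r):
        emb = delay_embed(phase[i], spec, shift=0)
        order = np.argsort(emb, axis=1, kind="stable")
        sym[i, hist:] = order @ weights
    return sym, int(d ** d)


class _PreparedSym(_PreparedBase):
    method = "sym"

    def __init__(self, source, target, params, u_max, es, et):
        d, tau = et.d, et.tau
        if d < 2:
            raise ValueError("symbolic estimator needs symbol order >= 2")
        eff = EmbeddingSpec(1, 1)
        super().__init__(source, target, params, u_max, eff, eff)
        sy, _ = _symbolize(target.phase, d, tau)
        sx, _ = _symbolize(source.phase, d, tau)
        hist = (d - 1) * tau
        self.t0 = max(self.t0, hist + u_max, hist + 1)
        self.D = self.T - self.t0
        if self.D <= 0:
            raise InsufficientSamplesError("trials too short for symbolization")
        self.n_pooled = self.r * self.D
        # dense relabeling over the observed symbol alphabet
        labels = np.unique(np.concatenate([sy[:, hist:].ravel(), sx[:, hist:].ravel()]))
        self.L = len(labels)
        lut = np.zeros(labels.max() + 1, dtype=np.int64)
        lut[labels] = np.arange(self.L)
        self.sy = lut[sy]
        self.sx = lut[sx]
        self.ct = self.sy[:, self.t0:] * self.L + self.sy[:, self.t0 - 1: self.T - 1]

    def te(self, u: int, perm: Optional[np.ndarray] = None) -> float:
        self._check_u(u)
        sx = self.sx if perm is None else self.sx[perm]
        xp = sx[:, self.t0 - u: self.T - u]
        L, n = self.L, self.n_pooled
        code = (xp.astype(np.int64) * L * L + self.ct).ravel()
        counts = np.bincount(code, minlength=L * L * L).reshape(L, L, L)
        h_joint = _entropy_from_counts(counts.ravel(), n)
        h_x_yp = _entropy_from_counts(counts.sum(axis=1).ravel(), n)
        h_yn_yp = _entropy_from_counts(counts.sum(axis=0).ravel(), n)
        h_yp = _entropy_from_counts(counts.sum(axis=(0, 1)), n)
        return h_x_yp - h_joint + h_yn_yp - h_yp


# ---------------------------------------------------------------------------
# KSG backend
# ---------------------------------------------------------------------------

class _PreparedKSG(_PreparedBase):
    method = "ksg"

    def __init__(self, source, target, params, u_max, es, et):
        super().__init__(source, target, params, u_max, es, et)
        self.k = params.k
        yc = _lagged_coords(target.phase, et)
        yn, yp = self._pool_target(target, yc)
        self.xc = _lagged_coords(source.phase, es)
        n = self.n_pooled
        if params.max_samples is not None and n > params.max_samples:
            rng = np.random.default_rng(params.seed)
            flat = np.sort(rng.choice(n, params.max_samples, replace=False))
        else:
            flat = np.arange(n)
        self.sel_r = flat // self.D
        self.sel_t = flat % self.D + self.t0
        self.n_used = flat.size
        if self.n_used < self.k + 1:
            raise InsufficientSamplesError(
                f"{self.n_used} pooled points < k+1 = {self.k + 1}")
        self.yn_v = yn[self.sel_r, self.sel_t - self.t0]
        self.yp_v = yc[self.sel_r, self.sel_t - 1, :]
        ypm = np.mod(self.yp_v, TWO_PI)
        ynypm = np.mod(np.column_stack([self.yn_v, self.yp_v]), TWO_PI)
        self._tree_yp = cKDTree(ypm, boxsize=TWO_PI)
        self._tree_ynyp = cKDTree(ynypm, boxsize=TWO_PI)
        self._ypm, self._ynypm = ypm, ynypm
        self._psi = digamma(np.arange(1, self.n_used + 2).astype(float))

    def _xp(self, u: int, perm: Optional[np.ndarray]) -> np.ndarray:
        rows = self.sel_r if perm is None else perm[self.sel_r]
        return self.xc[rows, self.sel_t - u, :]

    def te(self, u: int, perm: Optional[np.ndarray] = None) -> float:
        self._check_u(u)
        xp = self._xp(u, perm)
        xpm = np.mod(xp, TWO_PI)
        joint = np.column_stack([self._ynypm, xpm])
        tree_joint = cKDTree(joint, boxsize=TWO_PI)
        dist, _ = tree_joint.query(joint, k=self.k + 1, p=np.inf)
        eps = dist[:, -1]
        r_strict = np.nextafter(eps, 0.0)  # strictly-within-eps counts
        ypxp = np.column_stack([self._ypm, xpm])
        tree_ypxp = cKDTree(ypxp, boxsize=TWO_PI)
        n_yp = self._tree_yp.query_ball_point(
            self._ypm, r_strict, p=np.inf, return_length=True) - 1
        n_ynyp = self._tree_ynyp.query_ball_point(
            self._ynypm, r_strict, p=np.inf, return_length=True) - 1
        n_ypxp = tree_ypxp.query_ball_point(
            ypxp, r_strict, p=np.inf, return_length=True) - 1
        psi = self._psi
        val = digamma(self.k) + np.mean(
            psi[n_yp] - psi[n_ynyp] - psi[n_ypxp])
        return float(val)


# ---------------------------------------------------------------------------
# kernel Renyi-alpha backend
# ---------------------------------------------------------------------------

def renyi_entropy(gram: np.ndarray, alpha: float, method: str = "auto") -> float:
    """Matrix-based Renyi alpha-order entropy of a Gram matrix (nats).

    The matrix is trace-normalized; the entropy is
    ``log(tr(M^alpha)) / (1 - alpha)`` with ``tr(M^alpha)`` evaluated from the
    eigenspectrum (``method='eig'``) or, for integer alpha, by explicit matrix
    powers (``method='trace'``).  Lies in ``[0, log N]``.
    """
    m = np.asarray(gram, dtype=float)
    tr = np.trace(m)
    if tr <= 0:
        raise ValueError("Gram matrix has non-positive trace")
    m = m / tr
    is_int = float(alpha).is_integer() and alpha >= 2
    if method == "auto":
        method = "trace" if is_int else "eig"
    if method == "trace":
        if not is_int:
            raise ValueError("trace method requires integer alpha >= 2")
        p = m.copy()
        for _ in range(int(alpha) - 2):
            p = p @ m
        tr_a = float(np.sum(p * m.T))
    else:
        lam = np.linalg.eigvalsh(m)
        if not np.all(np.isfinite(lam)):
            raise FloatingPointError("non-finite eigenvalues in Gram matrix")
        lam = np.clip(lam, 0.0, None)
        tr_a = float(np.sum(lam ** alpha))
    tr_a = max(tr_a, np.finfo(float).tiny)
    return float(np.log(tr_a) / (1.0 - alpha))


def _gram_circular(angles: np.ndarray, bandwidth_floor: float = 1e-12) -> np.ndarray:
    """Gaussian Gram matrix on angles via the chordal map.

    Squared distance between rows is ``sum_k 2 (1 - cos(a_ik - a_jk))``, the
    Euclidean distance of ``(cos, sin)`` pairs; the bandwidth is the median
    pairwise distance.
    """
    a = np.asarray(angles, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    n = a.shape[0]
    sq = np.zeros((n, n))
    for j in range(a.shape[1]):
        sq += 2.0 * (1.0 - np.cos(a[:, j][:, None] - a[:, j][None, :]))
    iu = np.triu_indices(n, k=1)
    med = np.median(np.sqrt(np.maximum(sq[iu], 0.0))) if iu[0].size else 0.0
    if med <= bandwidth_floor:
        return np.ones((n, n))
    return np.exp(-sq / (2.0 * med * med))


class _PreparedKalpha(_PreparedBase):
    method = "kalpha"

    def __init__(self, source, target, params, u_max, es, et):
        super().__init__(source, target, params, u_max, es, et)
        self.alpha = params.alpha
        n = self.n_pooled
        cap = params.max_samples
        if cap is not None and cap > params.guard_n:
            raise MemoryGuardError(
                f"max_samples {cap} exceeds the Gram-matrix guard "
                f"({params.guard_n})")
        if cap is None and n > params.guard_n:
            raise MemoryGuardError(
                f"{n} pooled samples exceed the Gram-matrix guard "
                f"({params.guard_n}); reduce trials or set max_samples")
        if cap is not None and n > cap:
            rng = np.random.default_rng(params.seed)
            flat = np.sort(rng.choice(n, cap, replace=False))
        else:
            flat = np.arange(n)
        self.n_used = flat.size
        self.sel_r = flat // self.D
        self.sel_t = flat % self.D + self.t0
        yc = _lagged_coords(target.phase, et)
        self.xc = _lagged_coords(source.phase, es)
        yn_v = target.phase[self.sel_r, self.sel_t]
        yp_v = yc[self.sel_r, self.sel_t - 1, :]
        self.K_yn = _gram_circular(yn_v[:, None])
        self.K_yp = _gram_circular(yp_v)
        self.K_ynyp = self.K_yn * self.K_yp
        self.H_yp = renyi_entropy(self.K_yp, self.alpha)
        self.H_ynyp = renyi_entropy(self.K_ynyp, self.alpha)

    def te(self, u: int, perm: Optional[np.ndarray] = None) -> float:
        self._check_u(u)
        rows = self.sel_r if perm is None else perm[self.sel_r]
        xp = self.xc[rows, self.sel_t - u, :]
        K_xp = _gram_circular(xp)
        h_ypxp = renyi_entropy(self.K_yp * K_xp, self.alpha)
        h_joint = renyi_entropy(self.K_ynyp * K_xp, self.alpha)
        return h_ypxp - h_joint + self.H_ynyp - self.H_yp


_BACKENDS = {
    "bin": _PreparedBin,
    "sym": _PreparedSym,
    "ksg": _PreparedKSG,
    "kalpha": _PreparedKalpha,
}


def prepare_te(method: str, source: PhaseEnsemble, target: PhaseEnsemble,
               params: Optional[EstimatorParams] = None,
               u_max: int = 1) -> _PreparedBase:
    """Build a prepared TE evaluator for repeated lag/surrogate evaluation.

    The returned object's ``te(u, perm)`` evaluates TE(source -> target) at
    source lag ``u`` (samples) with an optional permutation of the source's
    trial assignment (the trial-shuffle surrogate).  All target-side
    structures (bin codes, symbol sequences, target trees, target Gram
    entropies) are computed once.
    """
    params = params if params is not None else EstimatorParams(method=method)
    if params.method != method:
        params = replace(params, method=method)
    es, et = _resolve_embeddings(source, target, params)
    return _BACKENDS[method](source, target, params, u_max, es, et)


def _one_shot(method: str, source: PhaseEnsemble, target: PhaseEnsemble,
              u: int, params: Optional[EstimatorParams],
              labels: tuple[str, str]) -> TEValue:
    prep = prepare_te(method, source, target, params, u_max=max(u, 1))
    value = prep.te(u)
    n_used = getattr(prep, "n_used", prep.n_pooled)
    return TEValue(value=float(value), direction=labels, u=u,
                   method=method, n_samples_used=int(n_used))


def te_bin(source: PhaseEnsemble, target: PhaseEnsemble, u: int,
           params: Optional[EstimatorParams] = None,
           labels: tuple[str, str] = ("X", "Y")) -> TEValue:
    """Binning (histogram plug-in) ensemble phase TE, nats."""
    return _one_shot("bin", source, target, u, params, labels)


def te_ksg(source: PhaseEnsemble, target: PhaseEnsemble, u: int,
           params: Optional[EstimatorParams] = None,
           labels: tuple[str, str] = ("X", "Y")) -> TEValue:
    """KSG (k-nearest-neighbor, algorithm 1) ensemble phase TE, nats."""
    return _one_shot("ksg", source, target, u, params, labels)


def te_sym(source: PhaseEnsemble, target: PhaseEnsemble, u: int,
           params: Optional[EstimatorParams] = None,
           labels: tuple[str, str] = ("X", "Y")) -> TEValue:
    """Symbolic (ordinal-pattern) ensemble phase TE, nats."""
    return _one_shot("sym", source, target, u, params, labels)


def te_kalpha(source: PhaseEnsemble, target: PhaseEnsemble, u: int,
              params: Optional[EstimatorParams] = None,
              labels: tuple[str, str] = ("X", "Y")) -> TEValue:
    """Kernel matrix-based Renyi alpha-order ensemble phase TE, nats."""
    return _one_shot("kalpha", source, target, u, params, labels)


def dte(method: str, x: PhaseEnsemble, y: PhaseEnsemble, u_xy: int, u_yx: int,
        params: Optional[EstimatorParams] = None) -> float:
    """Differential TE: ``TE(X->Y at u_xy) - TE(Y->X at u_yx)`` (nats).

    Positive values indicate net information flow from X to Y.
    """
    fwd = _one_shot(method, x, y, u_xy, params, ("X", "Y"))
    rev = _one_shot(method, y, x, u_yx, params, ("Y", "X"))
    return fwd.value - rev.value
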