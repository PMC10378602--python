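"""Delay embedding and estimator-specific parameter selection.

All state-space reconstruction in the package goes through
:func:`delay_embed`, so every estimator indexes the same target sample.  The
embedded row for time ``t`` with shift ``s`` holds

    (theta[t - s], theta[t - s - tau], ..., theta[t - s - (d - 1) tau])

i.e. delay vectors run backwards in time, newest coordinate first.  Phases are
circular, so every distance used by the selection criteria is the wrapped
angular difference per coordinate.

Three parameter-selection rules are provided:

* Scott's histogram bin-width rule with Fisher's circular standard deviation
  (binning estimator),
* the Ragwitz-Kantz locally-constant predictor criterion (k-NN estimators),
* the C-C correlation-integral method (symbolic estimator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import (
    DegenerateDistributionError,
    NoValidEmbeddingError,
    UndefinedDispersionError,
)
from .signal_core import PhaseEnsemble

TWO_PI = 2.0 * np.pi

__all__ = [
    "EmbeddingSpec",
    "delay_embed",
    "circular_std",
    "scott_bin_width",
    "ragwitz_select",
    "cc_select",
    "circ_dist",
]


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters: dimension ``d``, delay ``tau`` (samples),
    interaction lag ``u`` (samples, applies to the source variable only)."""

    d: int = 1
    tau: int = 1
    u: int = 0

    def __post_init__(self) -> None:
        if self.d < 1 or self.tau < 1 or self.u < 0:
            raise ValueError(f"invalid embedding spec {self}")

    def n_rows(self, n_samples: int) -> int:
        """Number of valid embedded rows ``D = T - tau (d - 1) - u``."""
        return n_samples - self.tau * (self.d - 1) - self.u

    @property
    def history(self) -> int:
        """Span of samples a delay vector reaches into the past."""
        return self.tau * (self.d - 1)


def delay_embed(phase_row: np.ndarray, spec: EmbeddingSpec,
                shift: int | None = None) -> np.ndarray:
    """Time-delay embed one series.

    Row ``i`` corresponds to target time ``t = t0 + i`` with
    ``t0 = shift + tau (d - 1)`` and holds the delay vector anchored at
    ``t - shift``.  With ``shift=None`` the spec's interaction lag ``u`` is
    used, so the row count equals ``T - tau (d - 1) - u``.
    """
    x = np.asarray(phase_row, dtype=float)
    if x.ndim != 1:
        raise ValueError("phase_row must be 1-D")
    if shift is None:
        shift = spec.u
    T = x.shape[0]
    D = T - shift - spec.history
    if D <= 0:
        raise NoValidEmbeddingError(
            f"series of length {T} too short for d={spec.d}, tau={spec.tau}, "
            f"shift={shift}"
        )
    # column j is theta[t - shift - j tau] for t = t0 .. T-1
    t0 = shift + spec.history
    cols = [x[t0 - shift - j * spec.tau: T - shift - j * spec.tau]
            for j in range(spec.d)]
    return np.stack(cols, axis=1)


def circ_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Wrapped absolute angular difference ``min(|a-b|, 2 pi - |a-b|)``."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % TWO_PI
    return np.minimum(d, TWO_PI - d)


def circular_std(phases: Iterable[float]) -> float:
    """Fisher's circular standard deviation ``sqrt(-2 ln Rbar)``.

    ``Rbar`` is the mean resultant length of the unit vectors at the given
    angles.  ``Rbar == 0`` (e.g. perfectly antipodal data) leaves the
    dispersion undefined.
    """
    x = np.asarray(list(phases) if not isinstance(phases, np.ndarray) else phases,
                   dtype=float).ravel()
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise UndefinedDispersionError("phases must be nonempty and finite")
    rbar = np.abs(np.exp(1j * x).mean())
    if rbar <= 1e-15:
        raise UndefinedDispersionError("mean resultant length is zero")
    if rbar >= 1.0:
        return 0.0
    return float(np.sqrt(-2.0 * np.log(rbar)))


def scott_bin_width(phases: Iterable[float]) -> tuple[float, int]:
    """Scott's bin width on circular data: ``h = 3.5 sigma / N^(1/3)``.

    Returns ``(h, n_bins)`` with ``n_bins = ceil(2 pi / h)`` equal-width bins
    anchored at ``-pi``.
    """
    x = np.asarray(list(phases) if not isinstance(phases, np.ndarray) else phases,
                   dtype=float).ravel()
    n = x.size
    if n < 2:
        raise DegenerateDistributionError("need at least two phases")
    sigma = circular_std(x)
    if sigma <= 0.0:
        raise DegenerateDistributionError("zero circular dispersion")
    h = 3.5 * sigma / n ** (1.0 / 3.0)
    h = min(h, TWO_PI)
    return float(h), int(np.ceil(TWO_PI / h))


# ---------------------------------------------------------------------------
# Ragwitz-Kantz criterion
# ---------------------------------------------------------------------------

def _to_rows(phase_ensemble) -> list[np.ndarray]:
    if isinstance(phase_ensemble, PhaseEnsemble):
        return [phase_ensemble.phase[i] for i in range(phase_ensemble.n_trials)]
    arr = np.atleast_2d(np.asarray(phase_ensemble, dtype=float))
    return [arr[i] for i in range(arr.shape[0])]


def ragwitz_select(
    phase_ensemble,
    d_grid: Sequence[int] = (1, 2, 3, 4, 5),
    tau_grid: Sequence[int] = (1, 2, 3, 4, 5),
    n_neighbors: int = 4,
    max_points: int = 2000,
    seed: int = 0,
) -> tuple[int, int]:
    """Choose ``(d, tau)`` minimizing the locally-constant one-step prediction
    error of the embedded phase series.

    For each candidate, every delay vector's successor is predicted as the
    circular mean of the successors of its ``n_neighbors`` nearest neighbours
    (max-norm, circular coordinates, leave-one-out).  The error is the mean
    squared wrapped difference, averaged over trials; ties break to the
    smallest ``d`` then smallest ``tau``.
    """
    rows = _to_rows(phase_ensemble)
    if len(d_grid) == 0 or len(tau_grid) == 0:
        raise NoValidEmbeddingError("empty candidate grid")
    rng = np.random.default_rng(seed)
    best: tuple[float, int, int] | None = None
    any_valid = False
    for d in sorted(d_grid):
        for tau in sorted(tau_grid):
            spec = EmbeddingSpec(d=d, tau=tau)
            errs = []
            for row in rows:
                T = row.shape[0]
                if T - spec.history - 1 <= n_neighbors:
                    continue
                emb = delay_embed(row, spec, shift=0)[:-1]  # states with a successor
                succ = row[spec.history + 1:]
                if emb.shape[0] > max_points:
                    idx = np.sort(rng.choice(emb.shape[0], max_points, replace=False))
                    emb, succ = emb[idx], succ[idx]
                pts = np.mod(emb, TWO_PI)
                tree = cKDTree(pts, boxsize=TWO_PI)
                k = min(n_neighbors + 1, pts.shape[0])
                _, nbr = tree.query(pts, k=k, p=np.inf)
                nbr = np.atleast_2d(nbr)[:, 1:]  # drop self
                pred = np.angle(np.exp(1j * succ[nbr]).mean(axis=1))
                errs.append(float(np.mean(circ_dist(pred, succ) ** 2)))
            if not errs:
                continue
            any_valid = True
            err = float(np.mean(errs))
            if best is None or err < best[0] - 1e-12:
                best = (err, d, tau)
    if not any_valid or best is None:
        raise NoValidEmbeddingError("no candidate leaves enough embedded rows")
    return best[1], best[2]


# ---------------------------------------------------------------------------
# C-C method
# ---------------------------------------------------------------------------

def _corr_integral(pts: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Correlation integral C(r) = fraction of point pairs within max-norm
    circular distance r, for each radius (brute force on <= a few hundred
    points)."""
    n = pts.shape[0]
    if n < 2:
        return np.zeros_like(radii)
    diff = circ_dist(pts[:, None, :], pts[None, :, :]).max(axis=2)
    iu = np.triu_indices(n, k=1)
    dvals = diff[iu]
    return np.array([np.mean(dvals < r) for r in radii])


def cc_select(
    phase_ensemble,
    d_grid: Sequence[int] = (2, 3, 4, 5),
    tau_grid: Sequence[int] = (1, 2, 3, 4, 5),
    max_points: int = 250,
    seed: int = 0,
) -> tuple[int, int]:
    """C-C method: choose ``(d, tau)`` from the correlation-integral statistic.

    For each delay ``t`` the series is split into ``t`` disjoint sub-series and

        S(d, r, t) = mean_s [ C_s(d, r, t) - C_s(1, r, t)^d ]

    is evaluated on four radii ``r_j = j sigma / 2``.  ``tau`` is the first
    local minimum of ``dS(t) = mean_d [max_j S - min_j S]``; the embedding
    window ``t_w`` minimizes ``S_cor(t) = dS(t) + |mean S(t)|`` and fixes
    ``d = round(t_w / tau) + 1`` clamped to the candidate grid.  For
    structureless (i.i.d.) data ``dS`` is flat and ``tau`` defaults to the
    smallest candidate.
    """
    rows = _to_rows(phase_ensemble)
    if len(d_grid) == 0 or len(tau_grid) == 0:
        raise NoValidEmbeddingError("empty candidate grid")
    d_grid = sorted(d_grid)
    tau_grid = sorted(tau_grid)
    if len(d_grid) == 1 and len(tau_grid) == 1:
        return d_grid[0], tau_grid[0]
    rng = np.random.default_rng(seed)
    series = np.concatenate(rows)
    sigma = circular_std(series)
    radii = np.array([0.5, 1.0, 1.5, 2.0]) * sigma
    d_stat = [d for d in d_grid if d >= 2] or [2]

    dS = np.full(len(tau_grid), np.nan)
    Sbar = np.full(len(tau_grid), np.nan)
    for it, tau in enumerate(tau_grid):
        vals_S, vals_dS = [], []
        for row in rows[: min(4, len(rows))]:
            subs = [row[s::tau] for s in range(tau)]
            for d in d_stat:
                s_dr = []
                for sub in subs:
                    spec = EmbeddingSpec(d=d, tau=1)
                    if sub.shape[0] - spec.history < 8:
                        continue
                    emb = delay_embed(sub, spec, shift=0)
                    if emb.shape[0] > max_points:
                        idx = np.sort(rng.choice(emb.shape[0], max_points,
                                                 replace=False))
                        emb = emb[idx]
                    c_d = _corr_integral(emb, radii)
                    c_1 = _corr_integral(emb[:, :1], radii)
                    s_dr.append(c_d - c_1 ** d)
                if not s_dr:
                    continue
                s_dr = np.mean(s_dr, axis=0)  # S(d, r_j, tau), averaged sub-series
                vals_S.append(s_dr.mean())
                vals_dS.append(s_dr.max() - s_dr.min())
        if vals_S:
            Sbar[it] = np.mean(vals_S)
            dS[it] = np.mean(vals_dS)
    if np.all(np.isnan(dS)):
        raise NoValidEmbeddingError("no candidate leaves enough embedded rows")

    # first interior local minimum of dS over the tau grid; a flat curve
    # (structureless data) defaults to the smallest candidate
    tau_sel = tau_grid[0]
    rng_ds = np.nanmax(dS) - np.nanmin(dS)
    if rng_ds > 0.01:
        tol = 0.05 * rng_ds
        for it in range(1, len(tau_grid) - 1):
            if np.isnan(dS[it]) or np.isnan(dS[it - 1]) or np.isnan(dS[it + 1]):
                continue
            if dS[it] < dS[it - 1] - tol and dS[it] < dS[it + 1] + tol:
                tau_sel = tau_grid[it]
                break
        else:
            it = int(np.nanargmin(dS))
            if 0 < it:  # falling curve: global minimum
                tau_sel = tau_grid[it]

    s_cor = dS + np.abs(Sbar)
    it_w = int(np.nanargmin(s_cor))
    t_w = tau_grid[it_w]
    d_sel = int(round(t_w / tau_sel)) + 1
    d_sel = min(max(d_sel, d_grid[0]), d_grid[-1])
    return d_sel, tau_sel
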