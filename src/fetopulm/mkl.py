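"""Unsupervised multiple-kernel-learning (MKL) embedding of Doppler beats.

Each data source (MPA beats, IPA beats — both conditions pooled, so a cohort
of N subjects contributes 2N observations) yields a Gaussian similarity
matrix; the sources are combined with non-negative weights beta (summing to
one) and the population is mapped to a low-dimensional space via a
kernelised graph embedding:

* affinity graph: symmetrised k-nearest-neighbour graph on the combined
  kernel, edge weights taken from the kernel;
* projection: generalized eigenproblem ``K W K a = lambda K D K a`` (W the
  graph affinity, D its degree matrix), i.e. kernelised Laplacian eigenmaps
  written in its "maximise similarity" form — coordinates ``y = K a`` with
  the trivial stationary eigenvector dropped, columns ordered by decreasing
  eigenvalue;
* kernel weights: with the projection fixed, beta maximises the same
  Rayleigh quotient over the source simplex (closed 2x2 generalized
  eigenproblem for two sources), accepted only if the graph objective does
  not deteriorate — the alternation is therefore monotone by construction.

Subjects that look alike across all sources land close together; a subject's
baseline -> hyperoxygenation change becomes a displacement between its two
points in the same space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "KernelSet", "MKLEmbedding", "build_kernels", "median_bandwidth", "fit_mkl",
]


def median_bandwidth(x: np.ndarray) -> float:
    """Median-heuristic Gaussian bandwidth: median pairwise distance."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    sq = np.sum(x ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * x @ x.T, 0.0)
    iu = np.triu_indices(n, k=1)
    med = float(np.median(np.sqrt(d2[iu])))
    return med if med > 0 else 1.0


def gaussian_kernel(x: np.ndarray, sigma: float) -> np.ndarray:
    """k(a, b) = exp(-||a-b||^2 / (2 sigma^2)); unit diagonal, symmetric PSD."""
    x = np.asarray(x, dtype=float)
    sq = np.sum(x ** 2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * x @ x.T, 0.0)
    k = np.exp(-d2 / (2.0 * sigma ** 2))
    return 0.5 * (k + k.T)


@dataclass
class KernelSet:
    """Per-source similarity matrices over a common observation set."""

    sources: tuple
    matrices: dict
    bandwidths: dict
    index: tuple  # (subject_id, condition) per observation

    def __post_init__(self) -> None:
        n = len(self.index)
        for s in self.sources:
            k = self.matrices[s]
            if k.shape != (n, n):
                raise ValueError(f"kernel {s} has shape {k.shape}, expected {(n, n)}")
            if not np.allclose(k, k.T, atol=1e-10):
                raise ValueError(f"kernel {s} is not symmetric")
        if self.bandwidths is not None:
            for s in self.sources:
                if self.bandwidths.get(s, 1.0) <= 0:
                    raise ValueError(f"bandwidth for {s} must be positive")

    @property
    def n_obs(self) -> int:
        return len(self.index)


def build_kernels(
    beats: dict,
    index: tuple,
    bandwidth_rule: str = "median",
    z_score: bool = False,
) -> KernelSet:
    """Gaussian kernel matrix per source from fixed-length beat vectors.

    ``beats`` maps source name -> (n_obs, n_samples) array; all sources must
    cover the same observations in the same order.
    """
    sources = tuple(beats)
    n = len(index)
    mats, bws = {}, {}
    for s in sources:
        x = np.asarray(beats[s], dtype=float)
        if x.ndim != 2 or x.shape[0] != n:
            raise ValueError(
                f"source {s}: expected ({n}, m) beat matrix, got {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError(f"source {s}: non-finite beat values")
        if z_score:
            sd = x.std(axis=0)
            x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        if bandwidth_rule == "median":
            sigma = median_bandwidth(x)
        else:
            sigma = float(bandwidth_rule)
            if sigma <= 0:
                raise ValueError("bandwidth must be positive")
        mats[s] = gaussian_kernel(x, sigma)
        bws[s] = sigma
    return KernelSet(sources=sources, matrices=mats, bandwidths=bws, index=tuple(index))


def _knn_graph(k_combined: np.ndarray, k_nn: int, teleport: float = 1e-3) -> tuple:
    """Symmetrised kNN affinity (weights from the kernel) and its degrees.

    A tiny uniform "teleport" affinity connects all pairs so the graph is
    never disconnected: the stationary (constant) eigenvector then carries a
    strictly larger eigenvalue than any cluster-indicator mode and can be
    deflated deterministically.
    """
    n = k_combined.shape[0]
    w = np.zeros_like(k_combined)
    order = np.argsort(-k_combined, axis=1)
    for i in range(n):
        neigh = [j for j in order[i] if j != i][:k_nn]
        w[i, neigh] = k_combined[i, neigh]
    w = np.maximum(w, w.T)
    np.fill_diagonal(w, 0.0)
    if teleport > 0:
        pos = w[w > 0]
        w = w + teleport * (pos.mean() if pos.size else 1.0)
        np.fill_diagonal(w, 0.0)
    return w, w.sum(axis=1)


def _fix_signs(y: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|value| entry positive."""
    for j in range(y.shape[1]):
        i = int(np.argmax(np.abs(y[:, j])))
        if y[i, j] < 0:
            y[:, j] = -y[:, j]
    return y


class MKLEmbedding(TransformerMixin, BaseEstimator):
    """Unsupervised multiple-kernel graph embedding.

    Parameters
    ----------
    n_components:
        Embedding dimensionality d (default 2).
    k_nn:
        Neighbourhood size of the affinity graph.
    max_iter, tol:
        Alternating-optimisation limit and convergence tolerance on the
        kernel-weight change.
    ridge:
        Relative Tikhonov term added to the constraint matrix K D K (scaled
        by its mean diagonal) to keep the eigenproblem well posed.

    Attributes (after :meth:`fit`)
    ------------------------------
    embedding_ : (n_obs, d) coordinates, columns ordered by decreasing
        eigenvalue, deterministic sign convention.
    weights_ : dict source -> beta (non-negative, sums to 1).
    spectrum_ : retained generalized eigenvalues (decreasing).
    n_iter_, converged_, objective_ : alternation diagnostics.
    """

    def __init__(self, n_components: int = 2, k_nn: int = 5, max_iter: int = 50,
                 tol: float = 1e-4, ridge: float = 1e-8, diffusion_time: float = 2.0):
        self.n_components = n_components
        self.k_nn = k_nn
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge
        self.diffusion_time = diffusion_time

    # -- internals ----------------------------------------------------------
    def _solve_projection(self, kernels: list, beta: np.ndarray,
                          w: np.ndarray = None, deg: np.ndarray = None):
        """Projection step: top generalized eigenvectors for fixed beta.

        The affinity graph is built once from the uniform kernel combination
        and held fixed, so the alternation optimises one objective (rebuilding
        the graph each step makes the iteration limit-cycle instead)."""
        k = sum(b * km for b, km in zip(beta, kernels))
        if w is None:
            w, deg = _knn_graph(k, self.k_nn)
        kwk = k @ w @ k
        kdk = k @ (deg[:, None] * k)
        kdk = kdk + self.ridge * np.trace(kdk) / k.shape[0] * np.eye(k.shape[0])
        d = self.n_components
        n = k.shape[0]
        vals, vecs = eigh(kwk, kdk, subset_by_index=(n - d - 1, n - 1))
        vals, vecs = vals[::-1], vecs[:, ::-1]  # decreasing
        # deflate the stationary solution: with the teleport-regularised graph
        # the constant mode is strictly the top eigenpair
        return vals[1:], vecs[:, 1:], w, deg

    @staticmethod
    def _graph_objective(y: np.ndarray, w: np.ndarray, deg: np.ndarray) -> float:
        """Rayleigh quotient tr(Y' W Y) / tr(Y' D Y) (to be maximised)."""
        num = float(np.einsum("id,ij,jd->", y, w, y))
        den = float(np.einsum("id,i,id->", y, deg, y))
        return num / den if den > 0 else -math.inf

    def _solve_weights(self, kernels: list, vecs: np.ndarray,
                       w: np.ndarray, deg: np.ndarray) -> np.ndarray:
        """Weight step: maximise the graph quotient over the simplex."""
        m = len(kernels)
        ys = [km @ vecs for km in kernels]
        sw = np.empty((m, m))
        sd = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                sw[i, j] = sw[j, i] = np.einsum("id,ij,jd->", ys[i], w, ys[j])
                sd[i, j] = sd[j, i] = np.einsum("id,i,id->", ys[i], deg, ys[j])
        vals, vecs_b = eigh(sw, sd + 1e-9 * np.trace(sd) / m * np.eye(m))
        beta = vecs_b[:, -1]
        if beta.sum() < 0:
            beta = -beta
        beta = np.clip(beta, 0.0, None)
        s = beta.sum()
        return beta / s if s > 0 else np.full(m, 1.0 / m)

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y=None):
        """Fit the embedding.

        ``X`` is either a :class:`KernelSet` or a mapping source -> (n, m)
        beat matrix (kernels are then built with the median heuristic).
        """
        if isinstance(X, KernelSet):
            kset = X
        elif isinstance(X, dict):
            n = len(next(iter(X.values())))
            kset = build_kernels(X, index=tuple(range(n)))
        else:
            raise TypeError("X must be a KernelSet or a dict of beat matrices")
        kernels = [kset.matrices[s] for s in kset.sources]
        m = len(kernels)
        d = self.n_components
        if d < 1 or d > kset.n_obs - 2:
            raise ValueError(f"n_components={d} invalid for {kset.n_obs} observations")

        beta = np.full(m, 1.0 / m)
        w, deg = _knn_graph(sum(km for km in kernels) / m, self.k_nn)
        best_obj = -math.inf
        converged = False
        it = 0
        vals = vecs = None
        for it in range(1, self.max_iter + 1):
            vals, vecs, w, deg = self._solve_projection(kernels, beta, w, deg)
            k = sum(b * km for b, km in zip(beta, kernels))
            obj = self._graph_objective(k @ vecs, w, deg)
            best_obj = max(best_obj, obj)
            if m == 1:
                converged = True
                break
            beta_new = self._solve_weights(kernels, vecs, w, deg)
            k_new = sum(b * km for b, km in zip(beta_new, kernels))
            obj_new = self._graph_objective(k_new @ vecs, w, deg)
            if obj_new < obj - 1e-12:  # never accept a deterioration
                converged = True
                break
            delta = float(np.abs(beta_new - beta).max())
            beta = beta_new
            best_obj = max(best_obj, obj_new)
            if delta < self.tol:
                converged = True
                break

        k = sum(b * km for b, km in zip(beta, kernels))
        # diffusion-style scaling: each dimension weighted by its spectral
        # value to the diffusion power, so weakly separated directions shrink
        y_coords = _fix_signs(k @ vecs) * np.clip(vals, 0.0, None) ** self.diffusion_time
        self.embedding_ = y_coords
        self.spectrum_ = vals
        self.weights_ = dict(zip(kset.sources, beta))
        self.n_iter_ = it
        self.converged_ = converged
        self.objective_ = best_obj
        self.index_ = kset.index
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def transform(self, X=None):
        """Training-set coordinates (no out-of-sample extension: both
        conditions enter one joint embedding, so displacements are native)."""
        if not hasattr(self, "embedding_"):
            raise RuntimeError("MKLEmbedding is not fitted")
        if X is not None and not isinstance(X, (KernelSet, dict)):
            raise TypeError("transform accepts only the training inputs")
        return self.embedding_


def fit_mkl(kernels: KernelSet, d: int = 2, k_nn: int = 5, max_iter: int = 50,
            tol: float = 1e-4) -> MKLEmbedding:
    """Functional wrapper over :class:`MKLEmbedding`."""
    est = MKLEmbedding(n_components=d, k_nn=k_nn, max_iter=max_iter, tol=tol)
    return est.fit(kernels)


def cohort_beat_matrices(cohort: list, n_samples: int = 100) -> tuple:
    """Stack per-subject MPA/IPA beats of both conditions for embedding.

    Returns ``(beats, index)`` with ``beats['MPA-beat']``/``beats['IPA-beat']``
    of shape (2N, n_samples) and ``index`` the (subject_id, condition) pairs.
    """
    from .doppler import resample_beat

    index = []
    rows = {"MPA-beat": [], "IPA-beat": []}
    for rec in cohort:
        for cond in ("baseline", "mhox"):
            if ("MPA", cond) not in rec.waveforms or ("IPA", cond) not in rec.waveforms:
                continue
            rows["MPA-beat"].append(resample_beat(rec.waveform("MPA", cond), n_samples))
            rows["IPA-beat"].append(resample_beat(rec.waveform("IPA", cond), n_samples))
            index.append((rec.subject_id, cond))
    beats = {s: np.vstack(v) for s, v in rows.items()}
    return beats, tuple(index)
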