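"""Gaussian locally-linear mapping (GLLiM) for dictionary-based learning.

The dictionary is treated as draws from a joint Gaussian mixture over
(parameters t, signals x) in which each component k carries an affine
forward map in the low-to-high direction,

    t | k  ~  N(c_k, Gamma_k),
    x | t, k  ~  N(A_k t + b_k, Sigma_k),       Sigma_k diagonal,

fit by expectation-maximization. Because every component is jointly
Gaussian, the inverse (signal -> parameter) conditional is available in
closed form as another Gaussian mixture; prediction reports its posterior
mean and standard deviation. Fitting in the parameter-to-signal direction
keeps the number of free parameters small (L = 4 inputs against D = 64
signal samples) and is what lets the model interpolate between simulated
parameter values instead of snapping to dictionary grid points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import logsumexp

__all__ = ["GLLiM", "save_model", "load_model"]

_LOG2PI = float(np.log(2.0 * np.pi))


def _kmeans(z: np.ndarray, k: int, rng: np.random.Generator,
            n_iter: int = 50) -> np.ndarray:
    """Plain seeded k-means (k-means++ init); returns hard labels."""
    n = len(z)
    centers = np.empty((k, z.shape[1]))
    centers[0] = z[rng.integers(n)]
    d2 = np.sum((z - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        p = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers[j] = z[rng.choice(n, p=p)]
        d2 = np.minimum(d2, np.sum((z - centers[j]) ** 2, axis=1))
    labels = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        dist = ((z[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        new = dist.argmin(1)
        if np.array_equal(new, labels):
            break
        labels = new
        for j in range(k):
            sel = labels == j
            if sel.any():
                centers[j] = z[sel].mean(0)
            else:
                centers[j] = z[rng.integers(n)]
    return labels


@dataclass
class GLLiM:
    """Trained inverse-regression model mapping fingerprints to parameters."""

    n_components: int = 50
    max_iter: int = 200
    tol: float = 1e-6
    reg: float = 1e-6
    seed: int = 0

    # learned state
    pi_: Optional[np.ndarray] = None
    c_: Optional[np.ndarray] = None
    Gamma_: Optional[np.ndarray] = None
    A_: Optional[np.ndarray] = None
    b_: Optional[np.ndarray] = None
    Sigma_: Optional[np.ndarray] = None
    t_mean_: Optional[np.ndarray] = None
    t_std_: Optional[np.ndarray] = None
    x_mean_: Optional[np.ndarray] = None
    x_std_: Optional[np.ndarray] = None
    loglik_path_: list = field(default_factory=list)
    converged_: bool = False
    training_meta: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ fit

    def fit(self, params: np.ndarray, signals: np.ndarray) -> "GLLiM":
        T = np.asarray(params, dtype=np.float64)
        X = np.asarray(signals, dtype=np.float64)
        if T.ndim != 2 or X.ndim != 2 or len(T) != len(X):
            raise ValueError("params and signals must be aligned 2D arrays")
        n, L = T.shape
        D = X.shape[1]
        K = self.n_components
        if n < 10 * K:
            raise ValueError(
                f"need at least 10 x n_components = {10 * K} rows, got {n}"
            )
        rng = np.random.default_rng(self.seed)
        self.t_mean_, self.t_std_ = T.mean(0), np.maximum(T.std(0), 1e-12)
        self.x_mean_, self.x_std_ = X.mean(0), np.maximum(X.std(0), 1e-12)
        Ts = (T - self.t_mean_) / self.t_std_
        Xs = (X - self.x_mean_) / self.x_std_

        labels = _kmeans(np.hstack([Ts, Xs]), K, rng)
        r = np.zeros((n, K))
        r[np.arange(n), labels] = 1.0
        r = 0.95 * r + 0.05 / K

        pi = np.full(K, 1.0 / K)
        c = np.zeros((K, L))
        Gamma = np.tile(np.eye(L), (K, 1, 1))
        A = np.zeros((K, D, L))
        b = np.zeros((K, D))
        Sigma = np.ones((K, D))
        sigma_floor = 1e-8

        self.loglik_path_ = []
        prev_ll = -np.inf
        restarts = 0
        dropped = 0
        it = 0
        while it < self.max_iter:
            # ---- M step
            Nk = r.sum(0)
            bad = Nk < L + 2
            if bad.any():
                # first try re-seeding the starved component with jitter;
                # if that fails too, drop it (fewer effective components)
                restarts += 1
                if restarts <= 3:
                    for k in np.nonzero(bad)[0]:
                        r[:, k] = rng.uniform(0.0, 1.0, n) * (2.0 * (L + 2) / n)
                    r = r / r.sum(1, keepdims=True)
                else:
                    keep = ~bad
                    if not keep.any():
                        raise RuntimeError(
                            "EM degeneracy: every component collapsed")
                    dropped += int(bad.sum())
                    K = int(keep.sum())
                    r = r[:, keep]
                    r = r / np.maximum(r.sum(1, keepdims=True), 1e-300)
                    pi, c, Gamma = pi[keep], c[keep], Gamma[keep]
                    A, b, Sigma = A[keep], b[keep], Sigma[keep]
                    restarts = 0
                Nk = r.sum(0)
            pi = Nk / n
            Tt = np.hstack([Ts, np.ones((n, 1))])
            for k in range(K):
                w = r[:, k]
                c[k] = (w @ Ts) / Nk[k]
                dt = Ts - c[k]
                Gamma[k] = (dt.T * w) @ dt / Nk[k] + self.reg * np.eye(L)
                G = (Tt.T * w) @ Tt + self.reg * np.eye(L + 1)
                H = (Tt.T * w) @ Xs
                W = np.linalg.solve(G, H)
                A[k] = W[:L].T
                b[k] = W[L]
                resid = Xs - Ts @ W[:L] - b[k]
                Sigma[k] = np.maximum((w @ (resid**2)) / Nk[k], sigma_floor)
            # ---- E step
            logr = np.empty((n, K))
            for k in range(K):
                chol = cholesky(Gamma[k], lower=True)
                dt = solve_triangular(chol, (Ts - c[k]).T, lower=True)
                logp_t = (-0.5 * (dt**2).sum(0) - np.log(np.diag(chol)).sum()
                          - 0.5 * L * _LOG2PI)
                resid = Xs - Ts @ A[k].T - b[k]
                logp_x = (-0.5 * ((resid**2) / Sigma[k]).sum(1)
                          - 0.5 * np.log(Sigma[k]).sum() - 0.5 * D * _LOG2PI)
                logr[:, k] = np.log(pi[k] + 1e-300) + logp_t + logp_x
            ll_n = logsumexp(logr, axis=1)
            ll = float(ll_n.sum())
            self.loglik_path_.append(ll)
            r = np.exp(logr - ll_n[:, None])
            it += 1
            if np.isfinite(prev_ll) and ll - prev_ll < self.tol * abs(ll):
                self.converged_ = True
                break
            prev_ll = ll

        self.pi_, self.c_, self.Gamma_ = pi, c, Gamma
        self.A_, self.b_, self.Sigma_ = A, b, Sigma
        self.training_meta = {
            "n_train": n, "n_components": K, "n_dropped": dropped,
            "n_iter": it,
            "converged": self.converged_, "seed": self.seed,
            "final_loglik": self.loglik_path_[-1],
            "preprocessing": "per-dimension standardization",
        }
        self._prepare_inverse()
        return self

    # -------------------------------------------------------------- predict

    def _prepare_inverse(self) -> None:
        K, D, L = self.A_.shape[0], self.A_.shape[1], self.A_.shape[2]
        self._Astar = np.empty((K, L, D))
        self._bstar = np.empty((K, L))
        self._Sstar = np.empty((K, L, L))
        self._mx = np.empty((K, D))
        self._cholV = []
        for k in range(K):
            Ak, bk, Sk = self.A_[k], self.b_[k], self.Sigma_[k]
            Gk_inv = np.linalg.inv(self.Gamma_[k])
            AtSi = Ak.T / Sk
            Sstar = np.linalg.inv(Gk_inv + AtSi @ Ak)
            self._Sstar[k] = 0.5 * (Sstar + Sstar.T)
            self._Astar[k] = Sstar @ AtSi
            self._bstar[k] = Sstar @ (Gk_inv @ self.c_[k] - AtSi @ bk)
            self._mx[k] = Ak @ self.c_[k] + bk
            V = np.diag(Sk) + Ak @ self.Gamma_[k] @ Ak.T
            self._cholV.append(cho_factor(V, lower=True))

    def predict(self, signals: np.ndarray,
                return_sd: bool = True):
        """Posterior mean (and sd) of the parameters given fingerprints.

        ``signals`` is (n, D) or (D,); output is in the original parameter
        units and order used at fit time.
        """
        if self.pi_ is None:
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(signals, dtype=np.float64))
        if not np.all(np.isfinite(X)):
            raise ValueError("fingerprints must be finite")
        Xs = (X - self.x_mean_) / self.x_std_
        n = len(Xs)
        K, L, D = self._Astar.shape
        logw = np.empty((n, K))
        mu = np.empty((n, K, L))
        for k in range(K):
            dx = Xs - self._mx[k]
            sol = cho_solve(self._cholV[k], dx.T)
            quad = (dx.T * sol).sum(0)
            logdet = 2.0 * np.log(np.diag(self._cholV[k][0])).sum()
            logw[:, k] = (np.log(self.pi_[k] + 1e-300)
                          - 0.5 * (quad + logdet + D * _LOG2PI))
            mu[:, k, :] = Xs @ self._Astar[k].T + self._bstar[k]
        w = np.exp(logw - logsumexp(logw, axis=1)[:, None])
        mean_s = np.einsum("nk,nkl->nl", w, mu)
        mean = self.t_mean_ + self.t_std_ * mean_s
        if not return_sd:
            return mean
        diagS = np.stack([np.diag(self._Sstar[k]) for k in range(K)])
        second = np.einsum("nk,nkl->nl", w, mu**2 + diagS[None, :, :])
        var_s = np.maximum(second - mean_s**2, 0.0)
        sd = self.t_std_ * np.sqrt(var_s)
        return mean, sd


# ---------------------------------------------------------------------------
# persistence


def save_model(model: GLLiM, path) -> None:
    if model.pi_ is None:
        raise RuntimeError("cannot save an unfitted model")
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "gllim-1"
        f.attrs["meta_json"] = json.dumps(model.training_meta, default=str)
        for name in ("pi_", "c_", "Gamma_", "A_", "b_", "Sigma_",
                     "t_mean_", "t_std_", "x_mean_", "x_std_"):
            f.create_dataset(name, data=getattr(model, name))
        f.attrs["n_components"] = model.n_components
        f.attrs["seed"] = model.seed


def load_model(path) -> GLLiM:
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "gllim-1":
            raise ValueError("not a GLLiM model file")
        model = GLLiM(n_components=int(f.attrs["n_components"]),
                      seed=int(f.attrs["seed"]))
        for name in ("pi_", "c_", "Gamma_", "A_", "b_", "Sigma_",
                     "t_mean_", "t_std_", "x_mean_", "x_std_"):
            setattr(model, name, f[name][()])
        model.training_meta = json.loads(f.attrs["meta_json"])
    model._prepare_inverse()
    return model
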