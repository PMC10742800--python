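"""Toeplitz inverse-covariance clustering of multivariate time series.

Each cluster is a Gaussian Markov random field over a sliding window of
``w`` consecutive frames of the d-channel series: its parameter is a
(d*w) x (d*w) sparse inverse covariance constrained to be block-Toeplitz
(the d x d block coupling frames i and j depends only on j - i), so the
cross-time dependency structure is time-invariant within the cluster.
Fitting alternates two exact steps:

* **Assignment** — given per-window negative log-likelihoods, a forward
  dynamic program finds the label path minimising the total NLL plus a
  switching penalty ``beta`` per label change (temporal consistency).
* **M-step** — per cluster, the mean of its stacked windows and the
  penalised inverse covariance
  ``argmin -logdet(T) + tr(S T) + lam * ||T||_1(off-diagonal)``
  over block-Toeplitz positive-definite matrices, solved by ADMM whose
  consensus variable is projected onto the block-Toeplitz set (entries
  averaged along each block diagonal) and soft-thresholded.

Model selection over the cluster count uses BIC with the parameter
count taken as the surviving (non-zero) entries of each precision
matrix plus the cluster means.

The public surface follows the model/results idiom: build a
:class:`TICC` model around the data, call :meth:`TICC.fit`, inspect the
returned :class:`TICCResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .errors import ConfigError, ConvergenceError, TooShortError
from .kinematics import CHANNELS, PairStateSeries

__all__ = [
    "stack_windows",
    "assign_dp",
    "toeplitz_graphical_lasso",
    "TICC",
    "TICCResults",
    "fit_ticc",
    "bic_select",
]


# ---------------------------------------------------------------------------
# building blocks


def stack_windows(series: np.ndarray, w: int) -> np.ndarray:
    """Stack a (T, d) series into (T - w + 1, d * w) window vectors.

    Window t concatenates frames t .. t+w-1 (forward-looking); its label
    is attributed to frame t.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    t_total, d = x.shape
    if t_total < w:
        raise TooShortError(f"series length {t_total} shorter than window {w}")
    n = t_total - w + 1
    out = np.empty((n, d * w))
    for i in range(w):
        out[:, i * d:(i + 1) * d] = x[i: i + n]
    return out


def assign_dp(nll: np.ndarray, beta: float) -> np.ndarray:
    """Exact minimum-cost label path under a switching penalty.

    Minimises ``sum_t nll[t, z_t] + beta * sum_t 1[z_t != z_{t+1}]`` by
    forward dynamic programming with backtracking.  Cost ties break
    toward the smaller cluster index, then toward continuing the
    previous label (realised by scanning candidate predecessors in
    index order and preferring a strict improvement only).

    Parameters
    ----------
    nll : ndarray (T, k)
        Finite per-window, per-cluster negative log-likelihoods.
    beta : float
        Non-negative switching penalty.

    Returns
    -------
    ndarray of int, shape (T,)
        Optimal labels in 0..k-1.
    """
    nll = np.asarray(nll, dtype=np.float64)
    if not np.all(np.isfinite(nll)):
        raise ValueError("nll must be finite")
    t_total, k = nll.shape
    cost = nll[0].copy()
    back = np.zeros((t_total, k), dtype=np.int64)
    for t in range(1, t_total):
        best_prev = int(np.argmin(cost))  # smallest index on ties (argmin rule)
        base = cost[best_prev] + beta
        new = np.empty(k)
        for j in range(k):
            stay = cost[j]
            if stay <= base:  # prefer continuing on ties
                new[j] = stay + nll[t, j]
                back[t, j] = j
            else:
                new[j] = base + nll[t, j]
                back[t, j] = best_prev
        cost = new
    labels = np.empty(t_total, dtype=np.int64)
    labels[-1] = int(np.argmin(cost))
    for t in range(t_total - 1, 0, -1):
        labels[t - 1] = back[t, labels[t]]
    return labels


def _block_toeplitz_project(mat: np.ndarray, d: int, w: int) -> np.ndarray:
    """Average the d x d blocks of a (d*w, d*w) matrix along block diagonals."""
    blocks = mat.reshape(w, d, w, d).transpose(0, 2, 1, 3)  # (w, w, d, d)
    out = np.empty_like(blocks)
    for lag in range(-(w - 1), w):
        i = np.arange(max(0, -lag), min(w, w - lag))
        j = i + lag
        avg = blocks[i, j].mean(axis=0)
        out[i, j] = avg
    return out.transpose(0, 2, 1, 3).reshape(d * w, d * w)


def toeplitz_graphical_lasso(
    s: np.ndarray,
    lam: float,
    d: int,
    w: int,
    rho: float = 1.0,
    tol: float = 1e-5,
    max_iter: int = 1000,
    raise_on_nonconvergence: bool = True,
) -> np.ndarray:
    """Sparse block-Toeplitz inverse covariance by ADMM.

    Solves ``argmin -logdet(T) + tr(S T) + lam * ||T||_1(off-diag)``
    over symmetric positive-definite block-Toeplitz matrices.  The
    theta-update is the closed-form eigenvalue step of the graphical
    lasso ADMM; the consensus update averages entries along each
    Toeplitz block diagonal and soft-thresholds off-diagonal entries;
    convergence requires primal and dual residuals below ``tol``.

    Returns the consensus iterate, which is exactly block-Toeplitz; if
    it is not positive definite its spectrum is floored at 1e-6 by a
    ridge shift (identity is block-Toeplitz, so structure is kept).
    """
    s = np.asarray(s, dtype=np.float64)
    nsz = d * w
    if s.shape != (nsz, nsz):
        raise ValueError(f"S must be {(nsz, nsz)}, got {s.shape}")
    s = 0.5 * (s + s.T)
    z = np.diag(1.0 / np.maximum(np.diag(s), 1e-8))
    u = np.zeros_like(s)
    off_mask = ~np.eye(nsz, dtype=bool)
    converged = False
    rho = float(rho)
    for it in range(max_iter):
        # theta-update: argmin -logdet + tr(S theta) + rho/2 ||theta - z + u||^2
        m = rho * (z - u) - s
        m = 0.5 * (m + m.T)
        evals, evecs = np.linalg.eigh(m)
        theta_evals = (evals + np.sqrt(evals**2 + 4.0 * rho)) / (2.0 * rho)
        theta = (evecs * theta_evals) @ evecs.T
        # consensus update: Toeplitz-average then soft-threshold off-diagonals
        z_old = z
        z = _block_toeplitz_project(theta + u, d, w)
        if lam > 0:
            thr = lam / rho
            z_off = np.sign(z) * np.maximum(np.abs(z) - thr, 0.0)
            z = np.where(off_mask, z_off, z)
        z = 0.5 * (z + z.T)
        u = u + theta - z
        primal = np.linalg.norm(theta - z)
        dual = rho * np.linalg.norm(z - z_old)
        if primal < tol and dual < tol:
            converged = True
            break
        # residual balancing keeps the two residuals comparable so a
        # mismatched penalty parameter cannot stall the iteration
        if it % 10 == 9:
            if primal > 10 * dual:
                rho *= 2.0
                u /= 2.0
            elif dual > 10 * primal:
                rho /= 2.0
                u *= 2.0
    if not converged:
        if raise_on_nonconvergence:
            raise ConvergenceError(
                f"ADMM did not reach tol={tol} in {max_iter} iterations "
                f"(primal {primal:.2e}, dual {dual:.2e})")
        warnings.warn("ADMM not fully converged; returning last iterate",
                      stacklevel=2)
    evals = np.linalg.eigvalsh(z)
    if evals[0] < 1e-6:
        warnings.warn("precision iterate not positive definite; flooring spectrum",
                      stacklevel=2)
        z = z + (1e-6 - evals[0]) * np.eye(nsz)
    return z


def _cluster_nll(stacks: np.ndarray, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Per-window Gaussian negative log-likelihood (without the 2*pi constant)."""
    centred = stacks - mu
    quad = np.einsum("ij,jk,ik->i", centred, theta, centred)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    return 0.5 * quad - 0.5 * logdet


# ---------------------------------------------------------------------------
# model / results


class TICC:
    """Toeplitz inverse-covariance clustering model.

    Parameters
    ----------
    data : ndarray (T, d), PairStateSeries or DataFrame
        The multivariate series to segment.
    k : int
        Number of clusters (behavioural states).
    w : int
        Window length in frames — the depth of each cluster's Markov
        random field.
    lam : float
        L1 weight on off-diagonal precision entries (sparsity of the
        dependency network).
    beta : float or None
        Label-switching penalty; None uses 400 * d.
    standardize : bool
        Z-score each channel over the recording before clustering
        (the channels mix metres, radians and body lengths).
    """

    def __init__(self, data, k: int = 5, w: int = 20, lam: float = 0.11,
                 beta: float | None = None, standardize: bool = True):
        if isinstance(data, PairStateSeries):
            x = data.values
            names = list(CHANNELS)
        else:
            x = np.asarray(getattr(data, "values", data), dtype=np.float64)
            if x.ndim == 1:
                x = x[:, None]
            names = list(getattr(data, "columns", [f"ch{i}" for i in range(x.shape[1])]))
        if k < 1:
            raise ConfigError("k must be >= 1")
        if w < 1:
            raise ConfigError("w must be >= 1")
        self.raw = x
        self.channel_names = [str(c) for c in names]
        self.k = int(k)
        self.w = int(w)
        self.lam = float(lam)
        self.d = x.shape[1]
        self.beta = float(beta) if beta is not None else 400.0 * self.d
        self.standardize = bool(standardize)
        self._mean = x.mean(axis=0)
        sd = x.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        self.x = (x - self._mean) / self._sd if self.standardize else x

    # -- fitting ---------------------------------------------------------
    def fit(self, seed: int = 0, max_em_iter: int = 30,
            admm_max_iter: int = 1000, admm_tol: float = 1e-5) -> "TICCResults":
        """Run the alternating assignment / M-step optimisation.

        Deterministic given ``seed`` (which controls only the
        Gaussian-mixture initialisation of the labels).
        """
        stacks = stack_windows(self.x, self.w)
        n = len(stacks)
        if self.k > n:
            raise ConfigError(f"k={self.k} exceeds the {n} available windows")

        gmm = GaussianMixture(
            n_components=self.k, covariance_type="diag", random_state=int(seed),
            n_init=1, max_iter=100, reg_covar=1e-4)
        labels = gmm.fit_predict(stacks)

        mus = np.zeros((self.k, self.d * self.w))
        thetas = [np.eye(self.d * self.w) for _ in range(self.k)]
        objective_path: list[float] = []
        snapshot = None  # best-so-far (labels, mus, thetas, obj)
        for it in range(max_em_iter):
            labels = self._fill_empty(labels, stacks, mus, thetas, it)
            for c in range(self.k):
                members = stacks[labels == c]
                mus[c] = members.mean(axis=0)
                s = np.cov(members, rowvar=False, bias=True)
                s = np.atleast_2d(s)
                # ridge keeps S workable when a cluster holds few windows
                s = s + 1e-6 * (np.trace(s) / len(s) + 1.0) * np.eye(len(s))
                thetas[c] = toeplitz_graphical_lasso(
                    s, self.lam, self.d, self.w, tol=admm_tol,
                    max_iter=admm_max_iter, raise_on_nonconvergence=False)
            nll = np.column_stack(
                [_cluster_nll(stacks, mus[c], thetas[c]) for c in range(self.k)])
            new_labels = assign_dp(nll, self.beta)
            obj = self._objective(nll, new_labels, thetas)
            if snapshot is not None and obj > snapshot[3] + 1e-8 * (1 + abs(obj)):
                # inner ADMM is inexact; an uphill step means we have
                # converged -- keep the previous (better) iterate
                labels, mus, thetas, _ = snapshot
                break
            objective_path.append(obj)
            snapshot = (new_labels.copy(), mus.copy(),
                        [t.copy() for t in thetas], obj)
            if np.array_equal(new_labels, labels) and it > 0:
                labels = new_labels
                break
            labels = new_labels
        else:
            labels = snapshot[0]

        labels, mus, thetas = snapshot[0], snapshot[1], snapshot[2]
        nll = np.column_stack(
            [_cluster_nll(stacks, mus[c], thetas[c]) for c in range(self.k)])
        loglik = float(-np.sum(nll[np.arange(n), labels])
                       - 0.5 * n * self.d * self.w * np.log(2 * np.pi))
        frame_labels = np.concatenate(
            [labels, np.full(self.w - 1, labels[-1] if n else 0)])
        return TICCResults(
            model=self, labels=frame_labels + 1, window_labels=labels + 1,
            thetas=[t.copy() for t in thetas], mus=mus.copy(),
            loglik=loglik, objective=float(snapshot[3]),
            objective_path=objective_path, seed=int(seed), n_windows=n)

    def _fill_empty(self, labels, stacks, mus, thetas, it):
        """Re-seed empty clusters from the worst-fit windows (deterministic)."""
        labels = labels.copy()
        counts = np.bincount(labels, minlength=self.k)
        empty = np.where(counts == 0)[0]
        if len(empty) == 0:
            return labels
        if it == 0:
            fit = np.zeros(len(stacks))
        else:
            nll = np.column_stack(
                [_cluster_nll(stacks, mus[c], thetas[c]) for c in range(self.k)])
            fit = nll[np.arange(len(stacks)), labels]
        take = max(self.w, len(stacks) // (4 * self.k))
        order = np.argsort(-fit, kind="stable")
        pos = 0
        for c in empty:
            grabbed = 0
            while grabbed < take and pos < len(order):
                i = order[pos]
                pos += 1
                if counts[labels[i]] > take:  # don't empty another cluster
                    counts[labels[i]] -= 1
                    labels[i] = c
                    counts[c] += 1
                    grabbed += 1
        return labels

    def _objective(self, nll, labels, thetas):
        switches = int(np.sum(labels[1:] != labels[:-1]))
        sparsity = sum(
            self.lam * np.abs(th[~np.eye(len(th), dtype=bool)]).sum() for th in thetas)
        return float(nll[np.arange(len(labels)), labels].sum()
                     + self.beta * switches + sparsity)

    # -- model selection -------------------------------------------------
    def bic(self, results: "TICCResults") -> float:
        """BIC of a fit: -2 loglik + (surviving parameters) * log(#windows)."""
        kappa = 0
        for th in results.thetas:
            upper = np.triu(th)
            kappa += int(np.sum(np.abs(upper) > 1e-4))
        kappa += results.mus.size
        return float(-2.0 * results.loglik + kappa * np.log(max(results.n_windows, 1)))


@dataclass
class TICCResults:
    """Fitted TICC model: labels, per-cluster MRFs and diagnostics.

    Attributes
    ----------
    labels : ndarray (T,)
        Per-frame cluster labels in 1..k (window t labels frame t; the
        trailing w-1 frames inherit the last window's label).
    window_labels : ndarray (T - w + 1,)
        Labels of the stacked windows.
    thetas : list of ndarray
        Per-cluster block-Toeplitz precision matrices, (d*w, d*w).
    mus : ndarray (k, d*w)
        Per-cluster means of the stacked windows.
    loglik : float
        Unpenalised Gaussian log-likelihood under the final assignment.
    objective : float
        Final penalised objective (NLL + switching + sparsity).
    objective_path : list of float
        Objective after each EM iteration (non-increasing).
    """

    model: TICC
    labels: np.ndarray
    window_labels: np.ndarray
    thetas: list
    mus: np.ndarray
    loglik: float
    objective: float
    objective_path: list
    seed: int
    n_windows: int

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def bic(self) -> float:
        return self.model.bic(self)

    def theta_block(self, cluster: int, lag: int) -> np.ndarray:
        """The d x d precision block at a given frame lag (cluster in 1..k)."""
        d, w = self.model.d, self.model.w
        th = self.thetas[cluster - 1]
        blocks = th.reshape(w, d, w, d).transpose(0, 2, 1, 3)
        if not -w < lag < w:
            raise ValueError(f"lag must be in ({-w}, {w})")
        i = max(0, -lag)
        return blocks[i, i + lag]

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        m = self.model
        counts = np.bincount(self.labels - 1, minlength=m.k)
        switches = int(np.sum(self.labels[1:] != self.labels[:-1]))
        lines = [
            "Toeplitz inverse-covariance clustering",
            "=" * 54,
            f"channels (d):        {m.d}",
            f"window length (w):   {m.w}",
            f"clusters (k):        {m.k}",
            f"lambda (sparsity):   {m.lam:g}",
            f"beta (switching):    {m.beta:g}",
            f"windows:             {self.n_windows}",
            f"label switches:      {switches}",
            f"log-likelihood:      {self.loglik:.2f}",
            f"BIC:                 {self.bic:.2f}",
            f"seed:                {self.seed}",
            "-" * 54,
            "cluster  frames  share",
        ]
        total = len(self.labels)
        for c in range(m.k):
            lines.append(f"{c + 1:>7d}  {counts[c]:>6d}  {counts[c] / total:6.1%}")
        return "\n".join(lines)


def fit_ticc(
    series,
    k: int,
    w: int,
    lam: float = 0.11,
    beta: float | None = None,
    seed: int = 0,
    max_em_iter: int = 30,
    standardize: bool = True,
) -> TICCResults:
    """Convenience wrapper: build a :class:`TICC` model and fit it."""
    return TICC(series, k=k, w=w, lam=lam, beta=beta,
                standardize=standardize).fit(seed=seed, max_em_iter=max_em_iter)


def bic_select(
    series,
    k_candidates,
    w: int,
    lam: float = 0.11,
    beta: float | None = None,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[int, dict]:
    """Fit every candidate cluster count and return the BIC minimiser.

    Returns ``(best_k, scores)`` with ``scores[k]`` the BIC of each
    candidate.  Ties break toward the smaller k.
    """
    scores = {}
    for k in k_candidates:
        res = fit_ticc(series, k=k, w=w, lam=lam, beta=beta, seed=seed,
                       standardize=standardize)
        scores[int(k)] = res.bic
    best = min(sorted(scores), key=lambda k: scores[k])
    return best, scores
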