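"""Nonnegative matrix factorization core: NNDSVD + multiplicative updates.

Factors the weighted term-by-document matrix A (m×n) as A ≈ WH with
nonnegative W (m×k, the *feature matrix*: each column a term-usage
pattern) and H (k×n, the *coefficient matrix*: each column a document's
span over features). The cost is f(W, H) = ½‖A − WH‖_F², minimized by
the Lee–Seung multiplicative updates

    H ← H ∘ (WᵀA) ⊘ (WᵀWH + ε),   W ← W ∘ (AHᵀ) ⊘ (WHHᵀ + ε)

with ε = 1e-9 in every denominator to avoid division by zero. Within an
iteration H is updated first, then W using the new H. Iteration stops
when consecutive iterates satisfy ‖ΔW‖_F < τ_W and ‖ΔH‖_F < τ_H
(defaults 0.01 and 0.001), or after ``max_iter`` iterations.

Initialization is NNDSVD (nonnegative double singular value
decomposition): deterministic, built from the positive sections of the
rank-k truncated SVD, so repeated fits give identical factors. The
``mean_fill`` variant replaces exact zeros in the initial factors by the
mean entry of A so the multiplicative updates cannot lock them at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .corpus import Vocabulary
from .weighting import WeightedMatrix

__all__ = [
    "ConvergenceRecord",
    "NMFModel",
    "LogEntropyNMF",
    "cost",
    "multiplicative_update_step",
    "nndsvd_init",
    "fit_nmf",
    "flops_per_iteration",
    "save_model",
    "load_model",
]

DEFAULT_EPS = 1e-9
DEFAULT_TAU_W = 0.01
DEFAULT_TAU_H = 0.001
DEFAULT_MAX_ITER = 1000
#: the three default model resolutions (low / medium / high)
DEFAULT_RANKS = (10, 15, 20)


@dataclass
class ConvergenceRecord:
    iterations: int
    cost_history: list[float]
    dW_history: list[float]
    dH_history: list[float]
    converged: bool
    stop_reason: Literal["tolerance", "max_iter"]


@dataclass
class NMFModel:
    """A fitted factorization A ≈ WH plus the metadata to interpret it."""

    W: np.ndarray
    H: np.ndarray
    rank: int
    init: str
    trace: ConvergenceRecord
    vocabulary: Vocabulary | None = None
    doc_ids: list[str] | None = None
    global_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.W.shape[1] != self.rank or self.H.shape[0] != self.rank:
            raise ValueError("factor shapes inconsistent with rank")
        if self.W.min() < 0 or self.H.min() < 0:
            raise ValueError("factors must be nonnegative")


def _as_spmatrix(A):
    if isinstance(A, WeightedMatrix):
        return A.A
    return A


def cost(A, W: np.ndarray, H: np.ndarray) -> float:
    """Half the squared Frobenius norm of the residual, ½‖A − WH‖_F².

    Sparse-aware: never forms WH against a dense copy of A; uses
    ‖A‖² − 2⟨A, WH⟩ + tr((WᵀW)(HHᵀ)).
    """
    A = _as_spmatrix(A)
    m, n = A.shape
    if W.shape[0] != m or H.shape[1] != n or W.shape[1] != H.shape[0]:
        raise ValueError(
            f"shape mismatch: A {A.shape}, W {W.shape}, H {H.shape}"
        )
    if sparse.issparse(A):
        norm_a2 = float(np.sum(A.data**2))
        cross = float(np.sum((A.T @ W) * H.T))
    else:
        A = np.asarray(A, dtype=float)
        norm_a2 = float(np.sum(A**2))
        cross = float(np.sum((A.T @ W) * H.T))
    gram = float(np.sum((W.T @ W) * (H @ H.T)))
    return max(0.0, 0.5 * (norm_a2 - 2.0 * cross + gram))


def multiplicative_update_step(
    A, W: np.ndarray, H: np.ndarray, eps: float = DEFAULT_EPS
) -> tuple[np.ndarray, np.ndarray]:
    """One Lee–Seung iteration: update H with current W, then W with new H."""
    A = _as_spmatrix(A)
    WtA = (A.T @ W).T  # = WᵀA, keeps the sparse product on the left
    H = H * (WtA / (W.T @ W @ H + eps))
    AHt = A @ H.T
    W = W * (AHt / (W @ (H @ H.T) + eps))
    return W, H


def _pos(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, 0.0)


def nndsvd_init(
    A, k: int, variant: Literal["strict", "mean_fill"] = "mean_fill"
) -> tuple[np.ndarray, np.ndarray]:
    """NNDSVD initial factors (W0, H0) from the rank-k truncated SVD of A.

    The leading singular triplet contributes √σ₁·|u₁| and √σ₁·|v₁|; for
    j ≥ 2 the sign-consistent section of (u_j, v_j) with the larger norm
    product is kept, normalized, and scaled by √(σ_j · μ_j). Entries
    below machine epsilon are zeroed; with ``variant="mean_fill"`` exact
    zeros are then replaced by the mean entry of A.
    """
    A = _as_spmatrix(A)
    m, n = A.shape
    if not 0 < k <= min(m, n):
        raise ValueError(f"rank must satisfy 0 < k <= min(m, n)={min(m, n)}, got {k}")
    dense = A.toarray() if sparse.issparse(A) else np.asarray(A, dtype=float)
    U, S, Vt = np.linalg.svd(dense, full_matrices=False)

    W = np.zeros((m, k))
    H = np.zeros((k, n))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])

    for j in range(1, k):
        x, y = U[:, j], Vt[j, :]
        xp, xn = _pos(x), _pos(-x)
        yp, yn = _pos(y), _pos(-y)
        xp_n, xn_n = np.linalg.norm(xp), np.linalg.norm(xn)
        yp_n, yn_n = np.linalg.norm(yp), np.linalg.norm(yn)
        m_p, m_n = xp_n * yp_n, xn_n * yn_n
        if m_p > m_n:
            u, v, sigma = xp / xp_n, yp / yp_n, m_p
        elif m_n > 0:
            u, v, sigma = xn / xn_n, yn / yn_n, m_n
        else:  # degenerate singular pair with no usable section
            continue
        lbd = np.sqrt(S[j] * sigma)
        W[:, j] = lbd * u
        H[j, :] = lbd * v

    eps_mach = np.finfo(float).eps
    W[W < eps_mach] = 0.0
    H[H < eps_mach] = 0.0
    if variant == "mean_fill":
        avg = dense.mean()
        W[W == 0] = avg
        H[H == 0] = avg
    elif variant != "strict":
        raise ValueError(f"unknown NNDSVD variant {variant!r}")
    return W, H


def _random_init(A, k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    A = _as_spmatrix(A)
    m, n = A.shape
    mean = A.mean() if not sparse.issparse(A) else A.sum() / (m * n)
    scale = np.sqrt(max(mean, np.finfo(float).tiny) / k)
    return scale * rng.random((m, k)), scale * rng.random((k, n))


def fit_nmf(
    A,
    rank: int,
    *,
    tau_W: float = DEFAULT_TAU_W,
    tau_H: float = DEFAULT_TAU_H,
    max_iter: int = DEFAULT_MAX_ITER,
    init: str = "nndsvd_mean_fill",
    eps: float = DEFAULT_EPS,
    random_state: int | None = None,
) -> NMFModel:
    """Fit A ≈ WH by NNDSVD initialization + multiplicative updates.

    ``init`` is one of ``"nndsvd_mean_fill"`` (default), ``"nndsvd"``
    (strict, keeps initial zeros) or ``"random"`` (seeded by
    ``random_state``). Returns an :class:`NMFModel` whose trace records
    the cost and the Frobenius norms of successive-iterate differences.
    """
    spA = _as_spmatrix(A)
    if init == "nndsvd_mean_fill":
        W, H = nndsvd_init(spA, rank, variant="mean_fill")
    elif init in ("nndsvd", "nndsvd_strict"):
        W, H = nndsvd_init(spA, rank, variant="strict")
    elif init == "random":
        W, H = _random_init(spA, rank, np.random.default_rng(random_state))
    else:
        raise ValueError(f"unknown init {init!r}")

    cost_history = [cost(spA, W, H)]
    dW_hist: list[float] = []
    dH_hist: list[float] = []
    converged = False
    stop_reason = "max_iter"
    it = 0
    for it in range(1, max_iter + 1):
        W_new, H_new = multiplicative_update_step(spA, W, H, eps=eps)
        if not (np.all(np.isfinite(W_new)) and np.all(np.isfinite(H_new))):
            raise FloatingPointError(f"non-finite factor entries at iteration {it}")
        dW = float(np.linalg.norm(W_new - W))
        dH = float(np.linalg.norm(H_new - H))
        W, H = W_new, H_new
        cost_history.append(cost(spA, W, H))
        dW_hist.append(dW)
        dH_hist.append(dH)
        if dW < tau_W and dH < tau_H:
            converged = True
            stop_reason = "tolerance"
            break
    else:
        it = max_iter

    trace = ConvergenceRecord(
        iterations=it if max_iter > 0 else 0,
        cost_history=cost_history,
        dW_history=dW_hist,
        dH_history=dH_hist,
        converged=converged,
        stop_reason=stop_reason,
    )
    vocab = A.vocabulary if isinstance(A, WeightedMatrix) else None
    doc_ids = list(A.doc_ids) if isinstance(A, WeightedMatrix) else None
    gw = A.global_weights if isinstance(A, WeightedMatrix) else None
    return NMFModel(
        W=W, H=H, rank=rank, init=init, trace=trace,
        vocabulary=vocab, doc_ids=doc_ids, global_weights=gw,
    )


def flops_per_iteration(m: int, n: int, k: int) -> int:
    """Operation-count model for one multiplicative update: ∝ k·m·n.

    The four matrix products each cost Θ(kmn); the model counts a
    multiply-add per entry per product, so 4·k·m·n. Symmetric in m and
    n, linear in each argument.
    """
    if min(m, n, k) <= 0:
        raise ValueError("dimensions must be positive")
    return 4 * k * m * n


class LogEntropyNMF(TransformerMixin, BaseEstimator):
    """Scikit-learn estimator for the NNDSVD + multiplicative-update NMF.

    Operates in the sklearn orientation: ``X`` has shape (n_documents,
    n_terms), i.e. Aᵀ. After ``fit``, ``W_`` (n_terms × k) holds the
    feature term patterns and ``H_`` (k × n_documents) the document
    coefficients. ``transform`` projects documents onto the features by
    the weighted inner product X @ W_, which is how new documents are
    scored against a fitted model (no refit).
    """

    def __init__(
        self,
        n_components: int = 10,
        *,
        init: str = "nndsvd_mean_fill",
        tau_w: float = DEFAULT_TAU_W,
        tau_h: float = DEFAULT_TAU_H,
        max_iter: int = DEFAULT_MAX_ITER,
        eps: float = DEFAULT_EPS,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.init = init
        self.tau_w = tau_w
        self.tau_h = tau_h
        self.max_iter = max_iter
        self.eps = eps
        self.random_state = random_state

    def fit(self, X, y=None):
        A = sparse.csr_matrix(X).T.tocsr()
        model = fit_nmf(
            A,
            self.n_components,
            tau_W=self.tau_w,
            tau_H=self.tau_h,
            max_iter=self.max_iter,
            init=self.init,
            eps=self.eps,
            random_state=self.random_state,
        )
        self.W_ = model.W
        self.H_ = model.H
        self.components_ = model.W.T
        self.trace_ = model.trace
        self.n_iter_ = model.trace.iterations
        self.reconstruction_err_ = model.trace.cost_history[-1]
        return self

    def transform(self, X):
        check_is_fitted(self, "W_")
        return np.asarray(sparse.csr_matrix(X) @ self.W_)


def save_model(model: NMFModel, directory: str | Path) -> None:
    """Persist a model as W.mtx, H.mtx (array format) + JSON metadata."""
    from scipy.io import mmwrite

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    mmwrite(d / "W.mtx", model.W)
    mmwrite(d / "H.mtx", model.H)
    meta = {
        "rank": model.rank,
        "init": model.init,
        "doc_ids": model.doc_ids,
        "trace": {
            "iterations": model.trace.iterations,
            "converged": model.trace.converged,
            "stop_reason": model.trace.stop_reason,
            "cost_history": model.trace.cost_history,
            "dW_history": model.trace.dW_history,
            "dH_history": model.trace.dH_history,
        },
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")
    if model.vocabulary is not None:
        (d / "terms.txt").write_text(
            "\n".join(model.vocabulary.terms) + "\n", encoding="utf-8"
        )
        np.savetxt(
            d / "vocab_freq.csv",
            np.column_stack([model.vocabulary.global_freq, model.vocabulary.doc_freq]),
            fmt="%d", delimiter=",", header="global_freq,doc_freq", comments="",
        )
    if model.global_weights is not None:
        np.savetxt(
            d / "entropy.csv", model.global_weights,
            delimiter=",", header="entropy_weight", comments="",
        )


def load_model(directory: str | Path) -> NMFModel:
    from scipy.io import mmread

    d = Path(directory)
    W = np.asarray(mmread(d / "W.mtx"))
    H = np.asarray(mmread(d / "H.mtx"))
    meta = json.loads((d / "meta.json").read_text(encoding="utf-8"))
    trace = ConvergenceRecord(**meta["trace"])
    vocab = None
    if (d / "terms.txt").exists():
        terms = (d / "terms.txt").read_text(encoding="utf-8").splitlines()
        freqs = np.loadtxt(d / "vocab_freq.csv", delimiter=",", skiprows=1, ndmin=2)
        vocab = Vocabulary(terms, freqs[:, 0].astype(int), freqs[:, 1].astype(int))
    gw = None
    if (d / "entropy.csv").exists():
        gw = np.loadtxt(d / "entropy.csv", delimiter=",", skiprows=1, ndmin=1)
    return NMFModel(
        W=W, H=H, rank=meta["rank"], init=meta["init"], trace=trace,
        vocabulary=vocab, doc_ids=meta["doc_ids"], global_weights=gw,
    )
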