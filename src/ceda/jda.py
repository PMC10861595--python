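"""Joint distribution adaptation: MMD matrices, the generalized eigenproblem
and the iterative pseudo-label refinement loop.

The empirical maximum-mean-discrepancy between the source and target blocks
of the stacked sample is a quadratic form ``tr(A' X M X' A)`` in a rank-one
block matrix M.  The *marginal* matrix M0 uses all samples; one *conditional*
matrix Mc per class uses only the samples (source: true labels, target:
pseudo-labels) of that class.  Minimizing the summed discrepancy subject to
a variance-preserving constraint gives the generalized eigenproblem

    (X (M0 + sum_c Mc) X' + lam I) A  =  X H X' A Phi,

solved for the k eigenvectors of smallest eigenvalue, where H is the
centering matrix I - (1/n) 11' and X is d x n with samples as columns
(source block first).  Iterating — re-labeling the target with a 1NN
classifier trained in the embedding, then rebuilding the conditional
matrices — refines the pseudo-labels until they stabilize.

Interfaces accept samples-as-rows datasets; the d x n samples-as-columns
convention is internal to this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .datasets import DomainDataset, RunConfig
from .knn import knn1_predict

logger = logging.getLogger(__name__)

__all__ = [
    "MMDMatrixSet",
    "AdaptationResult",
    "build_marginal_mmd",
    "build_conditional_mmd",
    "centering_matrix",
    "solve_jda_eigenproblem",
    "jda_iterate",
]


def build_marginal_mmd(ns: int, nt: int) -> np.ndarray:
    """Marginal MMD block matrix over ns source samples followed by nt
    target samples: 1/ns^2 within source, 1/nt^2 within target, -1/(ns nt)
    across.  Equals the outer product v v' with v_i = 1/ns (source rows),
    -1/nt (target rows); symmetric, PSD, rank one, entries summing to 0."""
    if ns < 1 or nt < 1:
        raise ValueError("ns and nt must be positive")
    v = np.concatenate([np.full(ns, 1.0 / ns), np.full(nt, -1.0 / nt)])
    return np.outer(v, v)


def build_conditional_mmd(
    source_labels: np.ndarray,
    target_pseudo_labels: np.ndarray,
    classes: np.ndarray | list[int],
) -> list[np.ndarray]:
    """One conditional MMD matrix per class, in ascending class order.

    A class absent from either block contributes a zero matrix (logged as a
    warning) rather than a division by zero.
    """
    ys = np.asarray(source_labels)
    yt = np.asarray(target_pseudo_labels)
    cls = np.unique(np.asarray(list(classes)))
    for name, y in (("source labels", ys), ("target pseudo-labels", yt)):
        extra = np.setdiff1d(np.unique(y), cls)
        if extra.size:
            raise ValueError(f"{name} contain labels outside the class set: {extra}")
    ns, nt = len(ys), len(yt)
    mats: list[np.ndarray] = []
    for c in cls:
        ms = (ys == c).astype(float)
        mt = (yt == c).astype(float)
        nsc, ntc = ms.sum(), mt.sum()
        if nsc == 0 or ntc == 0:
            side = "source" if nsc == 0 else "target pseudo-labels"
            logger.warning("class %s absent from %s; conditional term zeroed", c, side)
            mats.append(np.zeros((ns + nt, ns + nt)))
            continue
        v = np.concatenate([ms / nsc, -mt / ntc])
        mats.append(np.outer(v, v))
    return mats


@dataclass
class MMDMatrixSet:
    """Marginal matrix M0 and per-class conditional matrices over the
    stacked source+target samples."""

    m0: np.ndarray
    mc_list: list[np.ndarray]
    ns: int
    nt: int
    class_counts: dict[int, tuple[int, int]]

    @classmethod
    def from_labels(
        cls,
        source_labels: np.ndarray,
        target_pseudo_labels: np.ndarray,
        classes: np.ndarray | list[int],
    ) -> "MMDMatrixSet":
        ys = np.asarray(source_labels)
        yt = np.asarray(target_pseudo_labels)
        counts = {
            int(c): (int(np.sum(ys == c)), int(np.sum(yt == c)))
            for c in np.unique(np.asarray(list(classes)))
        }
        return cls(
            m0=build_marginal_mmd(len(ys), len(yt)),
            mc_list=build_conditional_mmd(ys, yt, classes),
            ns=len(ys),
            nt=len(yt),
            class_counts=counts,
        )

    def total(self) -> np.ndarray:
        """M0 + sum of conditional matrices (symmetric PSD)."""
        out = self.m0.copy()
        for mc in self.mc_list:
            out += mc
        return out


def centering_matrix(n: int) -> np.ndarray:
    """H = I - (1/n) 11': symmetric, idempotent, rows summing to zero."""
    if n < 1:
        raise ValueError("n must be positive")
    return np.eye(n) - np.full((n, n), 1.0 / n)


def solve_jda_eigenproblem(
    stacked_features: np.ndarray,
    mmd_sum: np.ndarray,
    lam: float,
    k: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve (X M X' + lam I) a = X H X' a phi for the k smallest phi.

    ``stacked_features`` is d x n with samples as columns.  Both sides are
    symmetrized before the Hermitian generalized solve; the constraint side
    X H X' is computed as Xc Xc' with column-centered Xc (H is idempotent).
    Eigenvalues return ascending; each eigenvector's sign is fixed so its
    largest-magnitude component is positive.
    """
    X = np.asarray(stacked_features, dtype=float)
    if X.ndim != 2:
        raise ValueError("stacked_features must be a d x n matrix")
    d, n = X.shape
    if k < 1 or k > d:
        raise ValueError(f"k={k} must be in [1, d={d}]")
    if not lam > 0:
        raise ValueError("lam must be positive")
    M = np.asarray(mmd_sum, dtype=float)
    if M.shape != (n, n):
        raise ValueError(f"mmd_sum shape {M.shape} does not match n={n}")
    M = 0.5 * (M + M.T)
    lhs = X @ M @ X.T + lam * np.eye(d)
    Xc = X - X.mean(axis=1, keepdims=True)
    rhs = Xc @ Xc.T
    lhs = 0.5 * (lhs + lhs.T)
    rhs = 0.5 * (rhs + rhs.T)
    try:
        w, V = scipy.linalg.eigh(lhs, rhs, subset_by_index=(0, k - 1))
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(f"generalized eigensolver failed: {exc}") from exc
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V, w


@dataclass
class AdaptationResult:
    """Output of the iterative refinement loop.

    ``matrix_a`` (d x k) projects the (possibly z-scored) stacked features,
    ``embedding_z`` is A' X (k x (ns+nt), source block first), ``eigenvalues``
    are the k smallest generalized eigenvalues of the final solve,
    ``pseudo_labels`` the final target labels, and ``history`` one record
    per iteration with the pseudo-label change count and the marginal MMD
    value tr(A' X M0 X' A) in the embedding.
    """

    matrix_a: np.ndarray
    embedding_z: np.ndarray
    eigenvalues: np.ndarray
    pseudo_labels: np.ndarray
    iterations_run: int
    history: list[dict] = field(default_factory=list)


def _pooled_zscore_pair(
    Xs: np.ndarray, Xt: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both matrices with pooled mean/sd; drops zero-variance
    features with a warning."""
    stack = np.vstack([Xs, Xt])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("all features have zero pooled variance")
    if not np.all(keep):
        logger.warning(
            "dropping %d zero-variance feature(s) before adaptation",
            int(np.sum(~keep)),
        )
    return (
        (Xs[:, keep] - mean[keep]) / sd[keep],
        (Xt[:, keep] - mean[keep]) / sd[keep],
    )


def jda_iterate(
    source: DomainDataset,
    target: DomainDataset,
    config: RunConfig,
    initial_pseudo_labels: np.ndarray,
) -> AdaptationResult:
    """Run the pseudo-label refinement loop.

    Each iteration rebuilds M0 + sum Mc from the current pseudo-labels,
    solves the generalized eigenproblem, embeds all samples, trains the 1NN
    classifier on the source block and re-labels the target block.  The loop
    stops early once the pseudo-labels are unchanged between consecutive
    iterations.
    """
    if source.labels is None:
        raise ValueError("source dataset must carry labels")
    if source.n_features != target.n_features:
        raise ValueError("source and target feature dimensions differ")
    if config.max_iters < 1:
        raise ValueError("jda_iterate requires max_iters >= 1")
    ys = source.labels
    classes = np.unique(ys)
    pseudo = np.asarray(initial_pseudo_labels).astype(np.int64)
    if pseudo.shape != (target.n_samples,):
        raise ValueError("initial pseudo-labels length must equal target size")
    if np.setdiff1d(np.unique(pseudo), classes).size:
        raise ValueError("initial pseudo-labels outside the source label set")

    Xs, Xt = source.features, target.features
    if config.normalize:
        Xs, Xt = _pooled_zscore_pair(Xs, Xt)
    ns, nt = Xs.shape[0], Xt.shape[0]
    config.validate_for(Xs.shape[1], ns + nt)
    X = np.vstack([Xs, Xt]).T  # d x n, source block first
    m0 = build_marginal_mmd(ns, nt)

    history: list[dict] = []
    A = np.empty((X.shape[0], config.k))
    w = np.empty(config.k)
    Z = np.empty((config.k, ns + nt))
    for t in range(1, config.max_iters + 1):
        mmd = m0.copy()
        for mc in build_conditional_mmd(ys, pseudo, classes):
            mmd += mc
        A, w = solve_jda_eigenproblem(X, mmd, config.lam, config.k)
        Z = A.T @ X
        new_pseudo = knn1_predict(Z[:, :ns].T, ys, Z[:, ns:].T)
        changes = int(np.sum(new_pseudo != pseudo))
        marginal = float(np.trace(A.T @ (X @ m0 @ X.T) @ A))
        history.append(
            {
                "iteration": t,
                "pseudo_label_changes": changes,
                "marginal_mmd": marginal,
            }
        )
        pseudo = new_pseudo
        if changes == 0:
            break
    return AdaptationResult(
        matrix_a=A,
        embedding_z=Z,
        eigenvalues=w,
        pseudo_labels=pseudo,
        iterations_run=len(history),
        history=history,
    )
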