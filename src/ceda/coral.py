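"""Second-order (covariance) alignment of source features to a target domain.

CORrelation ALignment whitens the source features with the inverse symmetric
square root of the (regularized) source covariance and re-colors them with
the symmetric square root of the (regularized) target covariance:

    A = Cs^(-1/2) @ Ct^(1/2),     Cs = cov(Xs) + reg*I,  Ct = cov(Xt) + reg*I

so that propagating the regularized source covariance through the transform
reproduces the regularized target covariance exactly: A.T @ Cs @ A == Ct.
The diagonal loading ``reg`` (default 1.0, the original CORAL convention)
keeps both covariances invertible even with fewer samples than features.

:func:`apply_coral` is the bare linear map ``X @ A``.  :func:`coral_align`
is what the pipeline uses by default: it re-colors *centered* source
features and shifts them onto the target mean, ``(X - mu_s) @ A + mu_t``.
The whiten/re-color derivation concerns centered second moments; applying A
to uncentered features drags the source mean to ``mean(X) @ A``, an
uncontrolled side effect, which re-shifting removes (the per-domain
standardization in the usual CORAL recipe aligns the means the same way).
Set ``center_means=False`` for the strictly second-order variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import DomainDataset

__all__ = [
    "CoralTransform",
    "estimate_covariance",
    "fit_coral",
    "apply_coral",
    "coral_align",
]


@dataclass
class CoralTransform:
    """Fitted d x d source-to-target re-coloring matrix with its provenance."""

    matrix_a: np.ndarray
    reg_strength: float
    source_cov: np.ndarray
    target_cov: np.ndarray
    source_mean: np.ndarray | None = None
    target_mean: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.matrix_a.shape[0]

    @property
    def condition_number(self) -> float:
        """Condition number of the adaptation matrix (diagnostic)."""
        return float(np.linalg.cond(self.matrix_a))


def estimate_covariance(features: np.ndarray, reg_strength: float = 0.0) -> np.ndarray:
    """Sample covariance (rows = samples, divisor n-1) plus ``reg_strength``
    on the diagonal; exactly symmetric.  A single sample yields the zero
    matrix (plus regularization)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D samples-by-features matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if reg_strength < 0:
        raise ValueError("reg_strength must be nonnegative")
    n, d = X.shape
    if n == 1:
        C = np.zeros((d, d))
    else:
        Xc = X - X.mean(axis=0)
        C = Xc.T @ Xc / (n - 1)
        C = 0.5 * (C + C.T)
    return C + reg_strength * np.eye(d)


def _sym_sqrt(C: np.ndarray, inverse: bool = False) -> np.ndarray:
    """Symmetric principal (inverse) square root via eigendecomposition.

    Negative eigenvalues from floating-point noise are clipped at zero; the
    inverse root requires strictly positive spectrum.
    """
    w, V = np.linalg.eigh(0.5 * (C + C.T))
    w = np.clip(w, 0.0, None)
    if inverse:
        if w.min() <= 0:
            raise np.linalg.LinAlgError(
                "covariance not positive definite at the given reg_strength"
            )
        s = 1.0 / np.sqrt(w)
    else:
        s = np.sqrt(w)
    return (V * s) @ V.T


def fit_coral(
    source: DomainDataset | np.ndarray,
    target: DomainDataset | np.ndarray,
    reg_strength: float = 1.0,
) -> CoralTransform:
    """Fit the source-to-target re-coloring matrix from two domains.

    Raises on feature-dimension mismatch or when the regularized source
    covariance is not positive definite.
    """
    Xs = source.features if isinstance(source, DomainDataset) else np.asarray(source, float)
    Xt = target.features if isinstance(target, DomainDataset) else np.asarray(target, float)
    if Xs.shape[1] != Xt.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: source d={Xs.shape[1]}, target d={Xt.shape[1]}"
        )
    Cs = estimate_covariance(Xs, reg_strength)
    Ct = estimate_covariance(Xt, reg_strength)
    A = _sym_sqrt(Cs, inverse=True) @ _sym_sqrt(Ct)
    if not np.all(np.isfinite(A)):
        raise np.linalg.LinAlgError("CORAL transform is not finite")
    return CoralTransform(
        A, float(reg_strength), Cs, Ct,
        source_mean=Xs.mean(axis=0), target_mean=Xt.mean(axis=0),
    )


def apply_coral(transform: CoralTransform, features: np.ndarray) -> np.ndarray:
    """Re-color a samples-by-features matrix: returns ``features @ A``
    (bare linear map, no centering)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != transform.n_features:
        raise ValueError(
            f"features shape {X.shape} does not match transform dimension "
            f"{transform.n_features}"
        )
    return X @ transform.matrix_a


def coral_align(
    transform: CoralTransform,
    features: np.ndarray,
    center_means: bool = True,
) -> np.ndarray:
    """Align source features onto the target: re-color the centered features
    and shift onto the target mean, ``(X - mu_s) @ A + mu_t``.

    With ``center_means=False`` this reduces to the bare :func:`apply_coral`.
    """
    if not center_means:
        return apply_coral(transform, features)
    if transform.source_mean is None or transform.target_mean is None:
        raise ValueError("transform carries no mean vectors; refit with fit_coral")
    X = np.asarray(features, dtype=float)
    centered = X - transform.source_mean
    return apply_coral(transform, centered) + transform.target_mean
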