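"""Domain datasets, delimited-text I/O and run configuration.

A *domain* is one cohort's feature table: a real-valued ``n_samples x
n_features`` matrix with optional integer class labels.  Labels are 1-based
and contiguous (``{1, ..., C}``), matching the convention ``y in {1, ..., L}``
used throughout the adaptation machinery; for binary fall-risk data the
mapping is non-faller -> 1, faller -> 2.

Files are plain CSV with a mandatory header row.  The label column, when
present, is named by the caller and stored as integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

LABEL_COLUMN = "label"


@dataclass
class DomainDataset:
    """One domain's feature matrix with optional class labels.

    Parameters
    ----------
    features : ndarray of shape (n_samples, n_features)
        Real-valued feature matrix; must be finite.
    labels : ndarray of shape (n_samples,), optional
        Integer class labels covering ``{1, ..., C}`` for some ``C >= 2``,
        with every class represented at least once.
    feature_names : list of str, optional
        One name per feature column.
    domain_tag : str
        Free-text tag, conventionally ``"source"`` or ``"target"``.
    """

    features: np.ndarray
    labels: np.ndarray | None = None
    feature_names: list[str] | None = None
    domain_tag: str = ""

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"features must be 2-D, got shape {X.shape}")
        if X.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError("need at least one sample and one feature")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain missing or non-finite values")
        self.features = X
        if self.labels is not None:
            y = np.asarray(self.labels)
            if y.shape != (X.shape[0],):
                raise ValueError(
                    f"labels length {y.shape} does not match n_samples {X.shape[0]}"
                )
            if not np.issubdtype(y.dtype, np.integer):
                yi = y.astype(int)
                if not np.array_equal(yi, y):
                    raise ValueError("labels must be integers")
                y = yi
            y = y.astype(np.int64)
            if y.min() < 1:
                raise ValueError("labels must be 1-based positive integers")
            C = int(y.max())
            present = set(np.unique(y).tolist())
            if C < 2 or present != set(range(1, C + 1)):
                raise ValueError(
                    "labels must cover {1..C} for some C >= 2 with every class present; "
                    f"got classes {sorted(present)}"
                )
            self.labels = y
        if self.feature_names is not None:
            names = [str(n) for n in self.feature_names]
            if len(names) != X.shape[1]:
                raise ValueError(
                    f"{len(names)} feature names for {X.shape[1]} features"
                )
            self.feature_names = names

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return np.unique(self.labels)

    def without_labels(self) -> "DomainDataset":
        """Copy of the dataset with labels held back."""
        return DomainDataset(
            self.features.copy(), None, self.feature_names, self.domain_tag
        )


@dataclass
class RunConfig:
    """Hyperparameters of one adaptation run.

    ``k`` is the number of subspace bases (embedding dimension), ``lam`` the
    regularization strength of the eigenproblem, ``max_iters`` the number of
    pseudo-label refinement iterations (0 skips the refinement entirely and
    classifies straight after covariance alignment), ``normalize`` toggles
    pooled z-scoring of the stacked source+target features, ``coral_reg``
    is the diagonal loading added to both covariances before alignment, and
    ``coral_center`` makes the alignment re-color *centered* source features
    and shift them onto the target mean (off = strictly second-order).
    """

    k: int = 2
    lam: float = 1.0
    max_iters: int = 10
    seed: int = 0
    normalize: bool = True
    classifier: str = "1nn"
    coral_reg: float = 1.0
    coral_center: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if not self.lam > 0:
            raise ValueError("lam must be positive")
        if self.max_iters < 0:
            raise ValueError("max_iters must be >= 0")
        if self.classifier != "1nn":
            raise ValueError("only the '1nn' classifier is supported")
        if self.coral_reg < 0:
            raise ValueError("coral_reg must be nonnegative")

    def validate_for(self, n_features: int, n_total: int) -> None:
        """Check data-dependent constraints: k <= d and k < ns + nt."""
        if self.k > n_features:
            raise ValueError(f"k={self.k} exceeds n_features={n_features}")
        if self.k >= n_total:
            raise ValueError(f"k={self.k} must be < total sample count {n_total}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key = value`` config file ('#' starts a comment)."""
        kwargs: dict = {}
        casts = {
            "k": int,
            "lam": float,
            "max_iters": int,
            "seed": int,
            "normalize": lambda s: s.strip().lower() in ("1", "true", "yes", "on"),
            "classifier": str,
            "coral_reg": float,
            "coral_center": lambda s: s.strip().lower() in ("1", "true", "yes", "on"),
        }
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in casts:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = casts[key](value.strip())
        return cls(**kwargs)


def read_domain_table(
    path: str | Path,
    label_column: str | None = None,
    domain_tag: str = "",
) -> DomainDataset:
    """Load a domain from a CSV file with a header row.

    ``label_column``, when given, names the column holding integer class
    labels; it is removed from the feature matrix.  Any missing or
    non-numeric cell raises a load error naming its row and column.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    df = pd.read_csv(p)
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in {p}")
        labels = _parse_labels(df[label_column], p, label_column)
        feat_df = df.drop(columns=[label_column])
    else:
        labels = None
        feat_df = df
    if feat_df.shape[1] == 0:
        raise ValueError(f"{p} has no feature columns")
    for col in feat_df.columns:
        num = pd.to_numeric(feat_df[col], errors="coerce")
        bad = num.isna().to_numpy()
        if bad.any():
            row = int(np.argmax(bad))
            raise ValueError(
                f"missing or non-numeric value at row {row}, column {col!r} in {p}"
            )
        feat_df[col] = num
    X = feat_df.to_numpy(dtype=float)
    return DomainDataset(X, labels, list(feat_df.columns), domain_tag)


def _parse_labels(series: pd.Series, path: Path, column: str) -> np.ndarray:
    num = pd.to_numeric(series, errors="coerce")
    bad = num.isna().to_numpy()
    if bad.any():
        row = int(np.argmax(bad))
        raise ValueError(
            f"missing or non-numeric label at row {row}, column {column!r} in {path}"
        )
    vals = num.to_numpy(dtype=float)
    ints = np.rint(vals).astype(np.int64)
    if not np.allclose(vals, ints):
        raise ValueError(f"label column {column!r} in {path} holds non-integer values")
    return ints


def write_domain_table(data: DomainDataset, path: str | Path) -> None:
    """Write a domain to CSV; re-reading reproduces it (features to <=1e-12,
    labels exactly)."""
    names = data.feature_names or [f"f{j + 1}" for j in range(data.n_features)]
    df = pd.DataFrame(data.features, columns=names)
    if data.labels is not None:
        df[LABEL_COLUMN] = data.labels
    df.to_csv(path, index=False)
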