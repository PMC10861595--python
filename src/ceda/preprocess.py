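"""Dimension reduction and feature selection for grouped gait-feature tables.

Two reduction paths mirror common practice for wearable-sensor gait data,
where the feature table splits into a block of linear summary features
(e.g. average step time, walking velocity) and a block of nonlinear
dynamics features (e.g. recurrence quantification measures, entropy):

* group-wise PCA — a separate PCA per feature group, fitted on the pooled
  source+target data so both domains share one component space, keeping a
  chosen number of components per group (the 28+22 split with 10+12
  components yields 22 combined components);
* mutual-information filtering — rank every feature by the plug-in mutual
  information (in nats) between its quantile-binned values and the class
  label, and keep the top k.

Shared pooled z-scoring lives here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import DomainDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureGroups",
    "SelectionReport",
    "groupwise_pca",
    "mutual_info_select",
    "zscore_fit_apply",
]


@dataclass
class FeatureGroups:
    """Assignment of every feature to exactly one group, with the number of
    principal components to keep per group."""

    group_assignments: list[str]
    components_per_group: dict[str, int]

    def __post_init__(self) -> None:
        groups = set(self.group_assignments)
        if groups != set(self.components_per_group):
            raise ValueError(
                "components_per_group keys must match the groups in "
                f"group_assignments; got {sorted(groups)} vs "
                f"{sorted(self.components_per_group)}"
            )
        for g, ncomp in self.components_per_group.items():
            size = sum(1 for a in self.group_assignments if a == g)
            if not 1 <= ncomp <= size:
                raise ValueError(
                    f"group {g!r}: {ncomp} components requested for {size} features"
                )

    @property
    def group_order(self) -> list[str]:
        """Groups in order of first appearance."""
        seen: list[str] = []
        for g in self.group_assignments:
            if g not in seen:
                seen.append(g)
        return seen

    def indices(self, group: str) -> list[int]:
        return [j for j, g in enumerate(self.group_assignments) if g == group]

    @classmethod
    def from_prefixes(
        cls, feature_names: list[str], components_per_group: dict[str, int]
    ) -> "FeatureGroups":
        """Derive groups from the part of each feature name before the first
        underscore (e.g. ``lin_03`` -> group ``lin``)."""
        assignments = [str(n).split("_", 1)[0] for n in feature_names]
        return cls(assignments, components_per_group)


@dataclass
class SelectionReport:
    """Ranked outcome of a feature-selection pass."""

    selected_indices: list[int]
    scores: np.ndarray
    method: str = "mutual_information"
    feature_names: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        """Selected features as a (feature, score, rank) table."""
        names = self.feature_names or [f"f{j + 1}" for j in range(len(self.scores))]
        return pd.DataFrame(
            {
                "feature": [names[j] for j in self.selected_indices],
                "score": [float(self.scores[j]) for j in self.selected_indices],
                "rank": np.arange(1, len(self.selected_indices) + 1),
            }
        )


def groupwise_pca(
    reference: DomainDataset,
    others: list[DomainDataset],
    groups: FeatureGroups,
) -> tuple[DomainDataset, list[DomainDataset]]:
    """Per-group PCA fitted on the pooled data, applied to every dataset.

    Loadings are fitted on the features of ``reference`` and ``others``
    stacked together (unsupervised; labels never touched) so all domains
    share identical component axes.  Per group the features are mean-centered
    and projected onto the leading right-singular vectors; components are
    ordered by decreasing explained variance and the loadings are
    orthonormal.  A group of deficient rank keeps only its effective rank,
    with a warning.
    """
    datasets = [reference, *others]
    d = len(groups.group_assignments)
    for ds in datasets:
        if ds.n_features != d:
            raise ValueError(
                f"dataset has {ds.n_features} features but groups describe {d}"
            )
    pooled = np.vstack([ds.features for ds in datasets])

    blocks: list[tuple[list[int], np.ndarray, np.ndarray]] = []  # (idx, mean, loadings)
    out_names: list[str] = []
    for g in groups.group_order:
        idx = groups.indices(g)
        ncomp = groups.components_per_group[g]
        block = pooled[:, idx]
        mean = block.mean(axis=0)
        Xc = block - mean
        _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        tol = S[0] * 1e-12 if S.size and S[0] > 0 else 0.0
        rank = int(np.sum(S > tol))
        if rank < ncomp:
            logger.warning(
                "group %r has rank %d < %d requested components; truncating",
                g, rank, ncomp,
            )
            ncomp = rank
        L = Vt[:ncomp].T  # (group size, ncomp), orthonormal columns
        for j in range(ncomp):
            i = int(np.argmax(np.abs(L[:, j])))
            if L[i, j] < 0:
                L[:, j] = -L[:, j]
        blocks.append((idx, mean, L))
        out_names.extend(f"{g}_pc{j + 1}" for j in range(ncomp))

    outputs: list[DomainDataset] = []
    for ds in datasets:
        parts = [(ds.features[:, idx] - mean) @ L for idx, mean, L in blocks]
        outputs.append(
            DomainDataset(
                np.hstack(parts), ds.labels, list(out_names), ds.domain_tag
            )
        )
    return outputs[0], outputs[1:]


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per sample; ties in the data may merge bins."""
    edges = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1))
    inner = np.unique(edges[1:-1])
    return np.searchsorted(inner, x, side="right")


def _plugin_mi(bins: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) between two discrete variables."""
    bu, bi = np.unique(bins, return_inverse=True)
    yu, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((len(bu), len(yu)))
    np.add.at(joint, (bi, yi), 1.0)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    mi = float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))
    return max(mi, 0.0)


def mutual_info_select(
    data: DomainDataset,
    top_k: int,
    n_bins: int = 10,
) -> SelectionReport:
    """Rank features by mutual information with the class label; keep top k.

    Each continuous feature is discretized into ``n_bins`` equal-frequency
    (quantile) bins; the plug-in estimate of I(feature; label) in nats is
    zero iff the binned feature and the label are independent, larger values
    indicating stronger dependence.  Quantile binning makes the score
    invariant to strictly monotone rescaling of a feature.  Ties are broken
    by the lower feature index.
    """
    if data.labels is None:
        raise ValueError("mutual_info_select requires labels")
    if not 1 <= top_k <= data.n_features:
        raise ValueError(f"top_k={top_k} not in [1, {data.n_features}]")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    X, y = data.features, data.labels
    scores = np.array(
        [_plugin_mi(_quantile_bins(X[:, j], n_bins), y) for j in range(X.shape[1])]
    )
    order = np.lexsort((np.arange(len(scores)), -scores))
    return SelectionReport(
        selected_indices=[int(j) for j in order[:top_k]],
        scores=scores,
        method="mutual_information",
        feature_names=data.feature_names,
    )


@dataclass
class ZScoreRecord:
    """Pooled mean/sd used for standardization plus the retained columns."""

    mean: np.ndarray
    sd: np.ndarray
    kept_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def zscore_fit_apply(
    reference_stack: list[DomainDataset],
) -> tuple[list[DomainDataset], ZScoreRecord]:
    """Standardize a stack of datasets with pooled per-feature mean and sd.

    Features of zero pooled variance are dropped with a warning; it is an
    error for every feature to be constant.  After the transform the pooled
    mean is 0 and sd 1 per retained feature.
    """
    if not reference_stack:
        raise ValueError("need at least one dataset")
    d = reference_stack[0].n_features
    for ds in reference_stack:
        if ds.n_features != d:
            raise ValueError("datasets have differing feature counts")
    pooled = np.vstack([ds.features for ds in reference_stack])
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=0)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("all features have zero pooled variance")
    dropped = np.flatnonzero(~keep)
    if dropped.size:
        logger.warning("dropping %d constant feature(s): %s", dropped.size, dropped)
    record = ZScoreRecord(mean[keep], sd[keep], np.flatnonzero(keep))
    outs = []
    for ds in reference_stack:
        X = (ds.features[:, keep] - record.mean) / record.sd
        names = (
            [ds.feature_names[j] for j in record.kept_indices]
            if ds.feature_names
            else None
        )
        outs.append(DomainDataset(X, ds.labels, names, ds.domain_tag))
    return outs, record
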