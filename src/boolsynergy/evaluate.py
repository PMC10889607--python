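"""Prediction evaluation and mechanism clustering of PSS profiles.

Predicted and observed HSA scores are compared on a continuous scale
(Pearson r, after optional min–max rescaling to [-1, +1]) and as a binary
classification where the positive class is synergy (observed score > 0):
AUC from the ranking of predictions, sensitivity and specificity at a
decision threshold of 0.

Drug pairs are grouped into putative synergy/antagonism mechanisms by
hierarchical clustering of their selected-protein consensus-PSS vectors under
correlation distance (1 - Pearson between profiles, average linkage); each
group is summarised by the proteins whose mean PSS magnitude dominates it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvaluationReport",
    "MechanismClustering",
    "rescale_scores",
    "classify_and_score",
    "cluster_pss",
    "linkage_to_newick",
]


def rescale_scores(scores: Sequence[float] | np.ndarray) -> np.ndarray:
    """Affine min–max map of scores onto [-1, +1] (min -> -1, max -> +1)."""
    scores = np.asarray(scores, dtype=float)
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        raise ValueError("cannot rescale constant scores")
    return 2.0 * (scores - lo) / (hi - lo) - 1.0


@dataclass
class EvaluationReport:
    """Continuous and threshold classification metrics for one score set."""

    pearson_r: float
    auc: float | None
    sensitivity: float | None
    specificity: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    n_pairs: int
    threshold: float = 0.0

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n_pairs": self.n_pairs,
            "threshold": self.threshold,
        }


def classify_and_score(
    predicted: Sequence[float],
    observed: Sequence[float],
    threshold: float = 0.0,
    rescale_predictions: bool = False,
) -> EvaluationReport:
    """Score predictions against observations; synergy (observed > 0) is the
    positive class.  AUC is reported as None when only one class is present.

    With ``rescale_predictions``, predictions are min–max rescaled to [-1, +1]
    before thresholding, so the decision boundary sits at the midrange of the
    predicted scores rather than at raw 0.  Pearson r and AUC are invariant to
    this affine map; only the confusion counts depend on it.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("prediction and observation vectors do not align")
    if predicted.size < 2:
        raise ValueError("need at least two pairs to evaluate")
    if np.std(predicted) == 0:
        raise ValueError("constant predictions cannot be evaluated")
    if rescale_predictions:
        predicted = rescale_scores(predicted)

    r = float(pearsonr(predicted, observed)[0])
    labels = observed > 0
    decisions = predicted > threshold
    tp = int(np.sum(decisions & labels))
    fp = int(np.sum(decisions & ~labels))
    tn = int(np.sum(~decisions & ~labels))
    fn = int(np.sum(~decisions & labels))
    if labels.all() or not labels.any():
        auc = sens = spec = None
    else:
        auc = float(roc_auc_score(labels, predicted))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
    return EvaluationReport(
        pearson_r=r,
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_pairs=int(predicted.size),
        threshold=threshold,
    )


@dataclass
class MechanismClustering:
    """Grouping of drug-pair PSS profiles into mechanism clusters."""

    labels: pd.Series  # profile id -> group label (1..k)
    distance: pd.DataFrame  # condensed-to-square correlation distances
    linkage: np.ndarray
    signatures: dict[int, list[str]]  # group -> dominant positive-PSS proteins
    newick: str


def _correlation_distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    X = profiles.to_numpy(dtype=float)
    degenerate = np.ptp(X, axis=1) == 0  # all-equal rows have no direction
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance profile(s); their correlation "
            "distance is set to the maximum (2)",
            stacklevel=3,
        )
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if degenerate[i] or degenerate[j]:
                d = 2.0
            else:
                d = 1.0 - np.corrcoef(X[i], X[j])[0, 1]
            D[i, j] = D[j, i] = d
    return D


def cluster_pss(
    profiles: pd.DataFrame,
    k: int,
    signature_threshold: float = 0.1,
) -> MechanismClustering:
    """Cluster drug-pair PSS profiles (rows) into *k* mechanism groups.

    Correlation distance with average linkage; group signatures are the
    proteins whose within-group mean PSS exceeds *signature_threshold*.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    D = _correlation_distance_matrix(profiles)
    condensed = D[np.triu_indices(len(profiles), k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    labels = pd.Series(
        hierarchy.fcluster(Z, t=k, criterion="maxclust"),
        index=profiles.index,
        name="group",
    )
    signatures: dict[int, list[str]] = {}
    for group in sorted(labels.unique()):
        mean_profile = profiles.loc[labels[labels == group].index].mean(axis=0)
        signatures[int(group)] = [
            str(p) for p, v in mean_profile.items() if v > signature_threshold
        ]
    newick = linkage_to_newick(Z, [str(i) for i in profiles.index])
    return MechanismClustering(
        labels=labels,
        distance=pd.DataFrame(D, index=profiles.index, columns=profiles.index),
        linkage=Z,
        signatures=signatures,
        newick=newick,
    )


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = render(node.get_left(), node.dist)
        right = render(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.get_left(), tree.dist)},{render(tree.get_right(), tree.dist)});"
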