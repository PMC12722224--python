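"""Behavioral-battery indices and unsupervised cognitive classification.

Each mouse contributes a three-feature vector — open-field perimeter
proportion (anxiety control), novel-object discrimination index, and T-maze
alternation index.  Features are z-scored over the full cohort, clustered by
Ward-linkage hierarchical clustering on Euclidean distances with the
dendrogram cut at two clusters, and middle-aged mice are labeled
aging-unimpaired (AU) or aging-impaired (AI) by whether they share the
cluster holding the majority of young mice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

FEATURES = ("perimeter_proportion", "discrimination_index", "alternation_index")

YOUNG = "young"
MIDDLE_AGED = "middle-aged"


def discrimination_index(t_novel_s: float, t_familiar_s: float) -> float:
    """(novel − familiar) / (novel + familiar) exploration time, in [−1, 1]."""
    total = t_novel_s + t_familiar_s
    if total <= 0:
        raise ValueError("zero total exploration time")
    return (t_novel_s - t_familiar_s) / total


def alternation_index(choices: "list[str] | np.ndarray") -> float:
    """Spontaneous-alternation index: alternations / total number of trials.

    An alternation is a choice differing from the immediately preceding
    choice.  With the trial-count denominator the maximum attainable index
    for k trials is (k − 1) / k.
    """
    choices = list(choices)
    if len(choices) < 2:
        raise ValueError("need at least 2 trials")
    alternations = sum(a != b for a, b in zip(choices, choices[1:]))
    return alternations / len(choices)


@dataclass
class CohortFeatures:
    """Per-mouse battery features with age labels.

    ``frame`` has columns mouse_id, age_group, and the three features; the
    z-scored matrix uses the full-cohort mean and SD per feature.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("mouse_id", "age_group", *FEATURES) if c not in self.frame]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if self.frame[list(FEATURES)].isna().any().any():
            raise ValueError("missing feature values after assembly")

    def zscored(self) -> np.ndarray:
        x = self.frame[list(FEATURES)].to_numpy(float)
        sd = x.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [f for f, s in zip(FEATURES, sd) if s == 0]
            raise ValueError(f"constant feature(s), cannot z-score: {bad}")
        return (x - x.mean(axis=0)) / sd


@dataclass
class CognitiveLabels:
    mouse_id: np.ndarray
    cluster: np.ndarray  # 1 or 2
    group: np.ndarray | None  # young-average | AU | AI (after assign_groups)
    linkage: np.ndarray  # scipy condensed linkage record


def cluster_cohort(features: CohortFeatures) -> CognitiveLabels:
    """Ward hierarchical clustering of z-scored features, cut at k = 2."""
    z = features.zscored()
    if len(z) < 4:
        raise ValueError("need at least 4 mice")
    link = linkage(z, method="ward", metric="euclidean")
    cl = fcluster(link, t=2, criterion="maxclust")
    return CognitiveLabels(
        mouse_id=features.frame["mouse_id"].to_numpy(),
        cluster=cl.astype(int),
        group=None,
        linkage=link,
    )


def assign_groups(labels: CognitiveLabels, ages: "list[str] | np.ndarray") -> CognitiveLabels:
    """Map clusters to cognitive groups by the majority-young rule.

    Middle-aged mice in the cluster holding the majority of young mice are
    aging-unimpaired (AU); middle-aged mice in the other cluster are
    aging-impaired (AI).  Young mice keep the young-average label regardless
    of cluster.  An exact young-count tie between clusters is an error that
    demands manual resolution.
    """
    ages = np.asarray(ages)
    if len(ages) != len(labels.cluster):
        raise ValueError("ages and cluster labels differ in length")
    young = ages == YOUNG
    if not young.any():
        raise ValueError("no young mice: majority rule undefined")
    n1 = int(np.sum(young & (labels.cluster == 1)))
    n2 = int(np.sum(young & (labels.cluster == 2)))
    if n1 == n2:
        raise ValueError("young mice split equally between clusters; resolve manually")
    au_cluster = 1 if n1 > n2 else 2
    group = np.where(
        young, "young-average", np.where(labels.cluster == au_cluster, "AU", "AI")
    )
    return CognitiveLabels(labels.mouse_id, labels.cluster, group, labels.linkage)
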