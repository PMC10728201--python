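"""Cluster-wise specificity of pathway activity.

CWS(L, A) = 1 - sqrt(JSD(I_L, W_A)) compares a cluster's normalized
indicator vector I_L with a pathway's PAL vector W_A by Jensen-Shannon
divergence.  With base-2 logarithms JSD is bounded by 1, so CWS lies in
[0, 1]: 1 means the pathway's activity is exactly the cluster, 0 means
it is entirely outside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon


@dataclass
class ClusterLabels:
    cell_ids: list[str]
    labels: np.ndarray  # per-cell cluster identifier

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.cell_ids) != self.labels.size:
            raise ValueError("every cell must be labeled")

    @property
    def clusters(self) -> list:
        return sorted(set(self.labels.tolist()))


def cluster_indicator(labels: ClusterLabels, cluster) -> np.ndarray:
    """Normalized indicator of the cluster (sums to 1)."""
    ind = (labels.labels == cluster).astype(float)
    total = ind.sum()
    if total == 0:
        raise ValueError(f"empty cluster {cluster!r}")
    return ind / total


def cws(indicator: np.ndarray, pal_scores: np.ndarray) -> float:
    """1 - sqrt(base-2 JSD) between an indicator and a PAL vector."""
    # jensenshannon returns the JS *distance*, i.e. sqrt(JSD)
    return float(1.0 - jensenshannon(indicator, pal_scores, base=2))


def cluster_specificity(labels: ClusterLabels, pals) -> pd.DataFrame:
    """CWS for every (cluster, pathway) pair; clusters x pathways frame.

    PAL vectors must cover the same cells as the labels; scores are
    aligned by cell id.
    """
    pos = {c: i for i, c in enumerate(labels.cell_ids)}
    rows = {}
    aligned = []
    for pal in pals:
        idx = [pos[c] for c in pal.cell_ids]
        if len(idx) != len(labels.cell_ids):
            raise ValueError(
                f"PAL cells do not match labels for set {pal.set_name!r}"
            )
        w = np.empty(len(idx))
        w[idx] = pal.scores
        aligned.append((pal.set_name, w))
    for cluster in labels.clusters:
        ind = cluster_indicator(labels, cluster)
        rows[cluster] = {name: cws(ind, w) for name, w in aligned}
    return pd.DataFrame.from_dict(rows, orient="index")
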