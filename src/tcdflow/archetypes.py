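"""Cluster exemplars, archetypes and subject-group composition.

Within each cluster, member waveforms (the normalized 100-sample beats, not
the 3-feature vectors) are ranked by mean squared Euclidean distance to the
other members (self-distance excluded).  The lowest-ranked waveform is the
cluster *exemplar*; the element-wise mean of the five lowest-ranked waveforms
is the cluster *archetype* (all members are averaged when a cluster has fewer
than five).  Composition reports the percentage of member waveforms per
subject group, rounded to whole percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ClusterSummary",
    "rank_members",
    "exemplar",
    "archetype",
    "composition",
    "cluster_report",
    "N_ARCHETYPE_MEMBERS",
]

#: Number of most-central waveforms averaged into an archetype.
N_ARCHETYPE_MEMBERS = 5


def _waveform_matrix(waveforms) -> np.ndarray:
    W = np.stack(
        [w.samples if hasattr(w, "samples") else np.asarray(w, float)
         for w in waveforms]
    )
    if W.ndim != 2:
        raise ValueError("waveforms must stack into a 2-D matrix")
    return W


def _mean_intra_distances(W: np.ndarray) -> np.ndarray:
    n = len(W)
    if n == 1:
        return np.zeros(1)
    d2 = squareform(pdist(W, "sqeuclidean"))
    return d2.sum(axis=1) / (n - 1)


def rank_members(waveforms: Sequence, ids: Sequence | None = None) -> list:
    """Member ids in ascending order of mean intra-cluster squared distance.

    Ties are broken by id order.  ``ids`` defaults to 0..n-1.
    """
    W = _waveform_matrix(waveforms)
    if ids is None:
        ids = list(range(len(W)))
    if len(ids) != len(W):
        raise ValueError("ids length mismatch")
    mean_d = _mean_intra_distances(W)
    order = sorted(range(len(W)), key=lambda i: (mean_d[i], ids[i]))
    return [ids[i] for i in order]


def exemplar(waveforms: Sequence, ids: Sequence | None = None):
    """Id of the most representative member (smallest mean distance)."""
    if len(waveforms) == 0:
        raise ValueError("cluster is empty")
    return rank_members(waveforms, ids)[0]


def archetype(waveforms: Sequence, n_members: int = N_ARCHETYPE_MEMBERS) -> np.ndarray:
    """Element-wise mean of the ``min(n_members, size)`` most central members."""
    if len(waveforms) == 0:
        raise ValueError("cluster is empty")
    W = _waveform_matrix(waveforms)
    top = rank_members(W)[: min(n_members, len(W))]
    return W[top].mean(axis=0)


def composition(
    labels: np.ndarray,
    groups: Sequence[str],
    group_order: Sequence[str] = ("LVO", "IHC", "OHC"),
) -> dict[int, dict]:
    """Per-cluster membership percentages by subject group.

    Returns, per cluster id, the member count plus raw fractions and
    whole-percent roundings per group (fractions sum to 1 before rounding).
    Raises when any waveform lacks a group label.
    """
    labels = np.asarray(labels)
    groups = list(groups)
    if len(groups) != len(labels):
        raise ValueError("groups length mismatch")
    if any(g is None or (isinstance(g, float) and np.isnan(g)) for g in groups):
        raise ValueError("every waveform needs a group label")
    seen = list(dict.fromkeys(list(group_order) + sorted(set(groups))))
    out: dict[int, dict] = {}
    for c in np.unique(labels):
        members = [g for g, l in zip(groups, labels) if l == c]
        n = len(members)
        fracs = {g: members.count(g) / n for g in seen if g in set(groups) or g in group_order}
        out[int(c)] = {
            "size": n,
            "fraction": fracs,
            "percent": {g: int(round(100 * f)) for g, f in fracs.items()},
        }
    return out


@dataclass
class ClusterSummary:
    """Size, exemplar, archetype and group composition of one cluster."""

    cluster: int
    size: int
    exemplar_id: object
    archetype: np.ndarray
    fraction: dict
    percent: dict

    def to_dict(self) -> dict:
        return {
            "cluster": self.cluster,
            "size": self.size,
            "exemplar_id": self.exemplar_id,
            "archetype": self.archetype.tolist(),
            "fraction": self.fraction,
            "percent": self.percent,
        }


def cluster_report(
    waveforms: Sequence,
    labels: np.ndarray,
    groups: Sequence[str],
    ids: Sequence | None = None,
) -> list[ClusterSummary]:
    """Build per-cluster summaries from waveforms, labels and group tags."""
    W = _waveform_matrix(waveforms)
    labels = np.asarray(labels)
    if ids is None:
        ids = list(range(len(W)))
    comp = composition(labels, groups)
    out = []
    for c in sorted(comp):
        idx = np.where(labels == c)[0]
        member_ids = [ids[i] for i in idx]
        out.append(
            ClusterSummary(
                cluster=c,
                size=comp[c]["size"],
                exemplar_id=exemplar(W[idx], member_ids),
                archetype=archetype(W[idx]),
                fraction=comp[c]["fraction"],
                percent=comp[c]["percent"],
            )
        )
    return out
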