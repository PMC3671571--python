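"""Two-step cluster separation of putative trigeminothalamic projecting neurons.

Thalamic-projecting brainstem neurons should fire like the axons recorded in
the medial lemniscus (LEM).  For each of seven metric/label profile groups
(RRTF-LP, RRTF-BP, TSR-HP, TSR-BP, MRL-LP, MRL-BP, VS-LP) the tonic PrV
recordings carrying that label are k-means clustered (squared-Euclidean
distance, k chosen by the mean silhouette width over a small range) on their
raw metric values restricted to the frequency grid shared with the LEM
protocol; the cluster whose centroid lies closest to the mean LEM profile is
selected.  Neurons present in the selected cluster of every group applicable
to them form the putative projecting set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .protocol import LEM_FREQUENCIES_HZ

__all__ = [
    "PROFILE_GROUPS",
    "GroupTooSmallError",
    "ClusterResult",
    "profile_features",
    "cluster_profile_group",
    "select_lem_like",
    "intersect_members",
    "identify_projecting",
]

#: The (metric, label) profile groups entering the separation.
PROFILE_GROUPS = (
    ("RRTF", "LP"),
    ("RRTF", "BP"),
    ("TSR", "HP"),
    ("TSR", "BP"),
    ("MRL", "LP"),
    ("MRL", "BP"),
    ("VS", "LP"),
)

DEFAULT_K_RANGE = (2, 3, 4, 5)


class GroupTooSmallError(ValueError):
    """A profile group has too few members to cluster."""


@dataclass
class ClusterResult:
    """k-means outcome for one profile group."""

    profile_group: str
    k: int
    neuron_ids: list[str]
    labels: np.ndarray
    centroids: np.ndarray
    silhouette_mean: float
    selected_cluster: int | None = None
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    def members_of(self, cluster: int) -> set[str]:
        return {nid for nid, lab in zip(self.neuron_ids, self.labels) if lab == cluster}

    @property
    def selected_members(self) -> set[str]:
        if self.selected_cluster is None:
            raise ValueError("no cluster selected yet")
        return self.members_of(self.selected_cluster)


def profile_features(profiles: dict, metric: str, frequencies=LEM_FREQUENCIES_HZ) -> pd.DataFrame:
    """Raw metric values per neuron restricted to a frequency grid.

    Neurons with any undefined value on the grid are dropped (they are
    excluded from this metric's groups only).
    """
    freqs = np.asarray(frequencies, dtype=float)
    rows, ids = [], []
    for nid, prof in profiles.items():
        idx = [int(np.argmin(np.abs(prof.frequencies_hz - f))) for f in freqs]
        if np.max(np.abs(prof.frequencies_hz[idx] - freqs)) > 1e-9:
            continue  # profile not measured on this grid
        v = prof.values(metric)[idx]
        if np.all(np.isfinite(v)):
            rows.append(v)
            ids.append(nid)
    return pd.DataFrame(rows, index=ids, columns=freqs)


def cluster_profile_group(
    features: pd.DataFrame,
    k_range=DEFAULT_K_RANGE,
    seed: int = 0,
    n_init: int = 10,
    profile_group: str = "",
) -> ClusterResult:
    """k-means a profile group, choosing k by the mean silhouette width.

    Distances are squared Euclidean (k-means' native criterion; the silhouette
    is evaluated with the same metric).  Deterministic given ``seed``.
    """
    X = features.to_numpy(dtype=float)
    ids = [str(i) for i in features.index]
    ks = [k for k in k_range if 2 <= k <= len(X) - 1]
    if not ks:
        raise GroupTooSmallError(
            f"group {profile_group or '?'}: {len(X)} members cannot support k >= 2"
        )
    best = None
    sil_by_k: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        sil = float(silhouette_score(X, km.labels_, metric="sqeuclidean"))
        sil_by_k[k] = sil
        if best is None or sil > best[0]:
            best = (sil, k, km)
    sil, k, km = best
    return ClusterResult(
        profile_group=profile_group,
        k=k,
        neuron_ids=ids,
        labels=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        silhouette_mean=sil,
        silhouette_by_k=sil_by_k,
    )


def select_lem_like(result: ClusterResult, lem_mean_profile) -> int:
    """Select the cluster whose centroid is nearest the mean LEM profile.

    Squared-Euclidean distance; exact ties go to the lowest cluster id (with
    a warning).
    """
    lem = np.asarray(lem_mean_profile, dtype=float)
    d = ((result.centroids - lem) ** 2).sum(axis=1)
    chosen = int(np.argmin(d))
    if np.count_nonzero(d == d[chosen]) > 1:
        warnings.warn(
            f"group {result.profile_group}: tie in centroid distance, keeping cluster {chosen}",
            stacklevel=2,
        )
    result.selected_cluster = chosen
    return chosen


def intersect_members(selected: dict, applicability: dict) -> set[str]:
    """Neurons in the selected cluster of every group applicable to them.

    ``selected`` maps group name -> set of neuron ids in the selected cluster;
    ``applicability`` maps neuron id -> set of group names the neuron entered.
    Neurons with no applicable group are excluded.
    """
    out = set()
    for nid, groups in applicability.items():
        if groups and all(nid in selected[g] for g in groups):
            out.add(nid)
    return out


def identify_projecting(
    prv_profiles: dict,
    prv_classes: dict,
    prv_types: dict,
    lem_profiles: dict,
    lem_classes: dict,
    *,
    frequencies=LEM_FREQUENCIES_HZ,
    k_range=DEFAULT_K_RANGE,
    seed: int = 0,
    groups=PROFILE_GROUPS,
) -> tuple[set[str], dict[str, ClusterResult]]:
    """Full two-step separation of putative thalamic-projecting neurons.

    Parameters
    ----------
    prv_profiles, lem_profiles
        ``neuron_id -> MetricProfile`` for PrV and LEM recordings.
    prv_classes, lem_classes
        ``neuron_id -> {metric: ProfileClass}`` labels.
    prv_types
        ``neuron_id -> 'tonic' | 'phasic'``; only tonic neurons enter.

    Returns the putative projecting id set and the per-group cluster results.
    Groups too small to cluster, or without a LEM reference, are skipped with
    a warning.
    """
    tonic_ids = {nid for nid, t in prv_types.items() if t == "tonic"}
    results: dict[str, ClusterResult] = {}
    selected: dict[str, set[str]] = {}
    applicability: dict[str, set[str]] = {nid: set() for nid in tonic_ids}

    for metric, label in groups:
        gname = f"{metric}-{label}"
        member_profiles = {
            nid: prof
            for nid, prof in prv_profiles.items()
            if nid in tonic_ids
            and metric in prv_classes.get(nid, {})
            and prv_classes[nid][metric].label == label
        }
        feats = profile_features(member_profiles, metric, frequencies)
        lem_ids = [
            nid
            for nid in lem_profiles
            if metric in lem_classes.get(nid, {}) and lem_classes[nid][metric].label == label
        ]
        lem_feats = profile_features({nid: lem_profiles[nid] for nid in lem_ids}, metric, frequencies)
        if lem_feats.empty:
            warnings.warn(f"group {gname}: no LEM reference recordings, skipped", stacklevel=2)
            continue
        try:
            res = cluster_profile_group(feats, k_range, seed=seed, profile_group=gname)
        except GroupTooSmallError as exc:
            warnings.warn(str(exc), stacklevel=2)
            continue
        select_lem_like(res, lem_feats.to_numpy().mean(axis=0))
        results[gname] = res
        selected[gname] = res.selected_members
        for nid in res.neuron_ids:
            applicability[nid].add(gname)

    return intersect_members(selected, applicability), results
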