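"""Partitioning subjects in relative-energy space and labeling balance strategies.

Subjects' stable-eyes-open (SEO) energy spectra are clustered with Lloyd's
k-means (k-means++ seeding, best of many restarts) or, optionally, a
k-medoids variant whose centers are restricted to observed subjects.
Clusters are then mapped onto three balance-strategy archetypes by the energy
rules observed in the study population:

* group1 -- very-low-frequency dominant: mean energy over {D15, D16} > 20%;
* group2 -- broadband: every component D11..D16 strictly between 10% and 20%;
* group3 -- higher-frequency dominant: mean energy over {D11, D12} > 20%.

When a centroid satisfies several rules, dominance rules win over the range
rule with precedence group3 > group1 > group2; the evidence behind each
label is recorded so conflicts stay visible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_samples

from .errors import ParameterError
from .wavelet_features import EnergySpectrum

ARCHETYPE_LABELS = ("group1", "group2", "group3")


@dataclass
class ClusterModel:
    """Fitted partition of subjects in energy-spectrum space."""

    k: int
    centroids: np.ndarray          # (k, d)
    assignments: dict              # subject_id -> cluster index
    subject_ids: list
    labels_: np.ndarray            # cluster index per subject, input order
    wcss: float
    seed: int
    n_restarts: int
    method: str
    wcss_trace: list = field(default_factory=list)  # per-iteration WCSS, best restart


@dataclass
class GroupLabel:
    """Cluster index -> archetype name ('group1'/'group2'/'group3'/'unclassified')."""

    mapping: dict
    rule_evidence: dict


def _as_matrix(spectra, subject_ids=None):
    if len(spectra) and isinstance(spectra[0], EnergySpectrum):
        X = np.vstack([s.e for s in spectra])
        ids = [s.subject_id for s in spectra]
    else:
        X = np.asarray(spectra, dtype=float)
        if X.ndim != 2:
            raise ParameterError("spectra must be a 2-D array or EnergySpectrum list")
        ids = [str(i) for i in range(X.shape[0])]
    if subject_ids is not None:
        ids = list(subject_ids)
        if len(ids) != X.shape[0]:
            raise ParameterError("subject_ids length does not match spectra")
    return X, ids


def _sq_dists(X, centers):
    return ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)


def _kmeanspp_init(X, k, rng):
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(k - 1):
        d2 = _sq_dists(X, np.asarray(centers)).min(axis=1)
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)])
        else:
            centers.append(X[rng.choice(n, p=d2 / total)])
    return np.asarray(centers, dtype=float)


def _lloyd(X, k, rng, max_iter=300):
    centers = _kmeanspp_init(X, k, rng)
    labels = np.full(X.shape[0], -1)
    trace = []
    for _ in range(max_iter):
        d2 = _sq_dists(X, centers)
        new_labels = d2.argmin(axis=1)
        # repopulate empty clusters with the point farthest from its center
        for c in range(k):
            if not np.any(new_labels == c):
                far = d2[np.arange(len(X)), new_labels].argmax()
                new_labels[far] = c
                d2[far, :] = np.inf  # don't move the same point twice
        trace.append(float(((X - centers[new_labels]) ** 2).sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        centers = np.vstack([X[labels == c].mean(axis=0) for c in range(k)])
    wcss = float(((X - centers[labels]) ** 2).sum())
    trace.append(wcss)
    return centers, labels, wcss, trace


def _voronoi_kmedoids(X, k, rng, max_iter=300):
    n = X.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    d2_all = _sq_dists(X, X)
    labels = np.full(n, -1)
    trace = []
    for _ in range(max_iter):
        d2 = d2_all[:, medoids]
        new_labels = d2.argmin(axis=1)
        for c in range(k):
            if not np.any(new_labels == c):
                far = d2[np.arange(n), new_labels].argmax()
                new_labels[far] = c
        trace.append(float(d2_all[np.arange(n), medoids[new_labels]].sum()))
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(new_labels == c)
            within = d2_all[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = members[within.argmin()]
        if np.array_equal(new_labels, labels) and np.array_equal(new_medoids, medoids):
            break
        labels, medoids = new_labels, new_medoids
    wcss = float(d2_all[np.arange(n), medoids[labels]].sum())
    trace.append(wcss)
    return X[medoids].astype(float), labels, wcss, trace


def fit_clusters(spectra, k: int = 3, seed: int = 0, n_restarts: int = 50,
                 method: str = "kmeans", subject_ids=None) -> ClusterModel:
    """Best-of-restarts partition minimizing within-cluster sum of squares.

    Distances are squared Euclidean on the raw percent-scale vectors (the
    energy simplex is the common scale; no re-standardization).  Deterministic
    for a given ``seed``.
    """
    X, ids = _as_matrix(spectra, subject_ids)
    n = X.shape[0]
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k > n:
        raise ParameterError(f"k={k} exceeds the number of subjects ({n})")
    if method not in ("kmeans", "kmedoids"):
        raise ParameterError(f"method must be 'kmeans' or 'kmedoids', got {method!r}")
    one_run = _lloyd if method == "kmeans" else _voronoi_kmedoids
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        centers, labels, wcss, trace = one_run(X, k, rng)
        if best is None or wcss < best[2] - 1e-12:
            best = (centers, labels, wcss, trace)
    centers, labels, wcss, trace = best
    return ClusterModel(
        k=k,
        centroids=centers,
        assignments=dict(zip(ids, (int(c) for c in labels))),
        subject_ids=ids,
        labels_=labels,
        wcss=wcss,
        seed=seed,
        n_restarts=n_restarts,
        method=method,
        wcss_trace=trace,
    )


def _rule_evidence(centroid):
    c = np.asarray(centroid, dtype=float)
    d11_d16 = c[10:16]
    return {
        "d15_d16_mean": float(c[14:16].mean()),
        "d11_d12_mean": float(c[10:12].mean()),
        "d11_d16_min": float(d11_d16.min()),
        "d11_d16_max": float(d11_d16.max()),
    }


def _candidate(ev):
    """(label, margin) with precedence group3 > group1 > group2."""
    if ev["d11_d12_mean"] > 20.0:
        return "group3", ev["d11_d12_mean"] - 20.0
    if ev["d15_d16_mean"] > 20.0:
        return "group1", ev["d15_d16_mean"] - 20.0
    if ev["d11_d16_min"] > 10.0 and ev["d11_d16_max"] < 20.0:
        return "group2", min(ev["d11_d16_min"] - 10.0, 20.0 - ev["d11_d16_max"])
    return "unclassified", 0.0


def label_archetypes(model: ClusterModel, bands=None) -> GroupLabel:
    """Map each cluster centroid to a balance-strategy archetype.

    A named label is given to at most one cluster: if two centroids satisfy
    the same rule, the one with the larger margin keeps it and the other
    becomes 'unclassified'.
    """
    if model.centroids.shape[1] != 17:
        raise ParameterError(
            "archetype rules are defined on 17-component spectra "
            f"(16 details + approximation); got {model.centroids.shape[1]}"
        )
    evidence = {c: _rule_evidence(model.centroids[c]) for c in range(model.k)}
    candidates = {c: _candidate(ev) for c, ev in evidence.items()}
    mapping = {}
    for label in ARCHETYPE_LABELS:
        claimants = [c for c, (lab, _) in candidates.items() if lab == label]
        if claimants:
            winner = max(claimants, key=lambda c: candidates[c][1])
            for c in claimants:
                mapping[c] = label if c == winner else "unclassified"
    for c in range(model.k):
        mapping.setdefault(c, "unclassified")
    for c, ev in evidence.items():
        ev["label"] = mapping[c]
        ev["rule_margin"] = candidates[c][1] if mapping[c] != "unclassified" else 0.0
    return GroupLabel(mapping=mapping, rule_evidence=evidence)


def silhouette_report(model: ClusterModel, spectra, subject_ids=None) -> dict:
    """Per-subject silhouette coefficients and per-cluster means, in [-1, 1]."""
    if model.k < 2:
        raise ParameterError("silhouette is undefined for k=1")
    X, _ = _as_matrix(spectra, subject_ids)
    values = silhouette_samples(X, model.labels_)
    per_cluster = {
        int(c): float(values[model.labels_ == c].mean()) for c in range(model.k)
    }
    return {
        "per_subject": values,
        "per_cluster": per_cluster,
        "overall": float(values.mean()),
    }
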