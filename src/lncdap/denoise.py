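"""Positive-unlabeled denoising of the unknown pair set.

Every disease-lncRNA cell of the association matrix becomes a sample whose
feature is the concatenation of the two 64-dim embeddings (disease first).
Unknown pairs that persistently cluster with the positives are treated as
likely false negatives: K-means is run for 10 rounds with distinct seeds,
each round selects the cluster with the highest positive proportion, and
the intersection of the selected clusters' unknown members across rounds
forms U_noise. The remaining unknowns, U_reliable = U − U_noise, are the
denoised negative candidates. The number of clusters K is chosen by mean
silhouette over a candidate range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .datatypes import AssociationMatrix, IdentifierError

__all__ = ["PairSet", "DenoisingResult", "build_samples", "select_k", "denoise"]

#: silhouette is evaluated on the full sample set up to this size, then on
#: a seeded subsample (quadratic memory/time guard)
SILHOUETTE_CAP = 20_000


@dataclass
class PairSet:
    """All disease-lncRNA pairs with concatenated embedding features."""

    features: np.ndarray          # (n_d * n_l) x 128, disease block first
    labels: np.ndarray            # bool, True = known positive
    disease_idx: np.ndarray       # int per sample
    lncrna_idx: np.ndarray

    @property
    def positives(self) -> np.ndarray:
        return np.flatnonzero(self.labels)

    @property
    def unknowns(self) -> np.ndarray:
        return np.flatnonzero(~self.labels)

    def __len__(self) -> int:
        return self.labels.size


def build_samples(F_disease: np.ndarray, F_lncrna: np.ndarray,
                  A: AssociationMatrix) -> PairSet:
    """One sample per matrix cell; feature = concat(disease, lncRNA) embedding."""
    F_disease = np.asarray(F_disease, dtype=np.float64)
    F_lncrna = np.asarray(F_lncrna, dtype=np.float64)
    if F_disease.shape[0] != A.n_diseases:
        raise IdentifierError("disease embedding rows do not cover the association matrix")
    if F_lncrna.shape[0] != A.n_lncrnas:
        raise IdentifierError("lncRNA embedding rows do not cover the association matrix")
    d_idx, l_idx = np.meshgrid(np.arange(A.n_diseases), np.arange(A.n_lncrnas),
                               indexing="ij")
    d_idx, l_idx = d_idx.ravel(), l_idx.ravel()
    features = np.hstack([F_disease[d_idx], F_lncrna[l_idx]])
    labels = A.values[d_idx, l_idx].astype(bool)
    return PairSet(features, labels, d_idx, l_idx)


def _fit_kmeans(X: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(X)


def select_k(samples: PairSet | np.ndarray, k_range: range = range(2, 11),
             seed: int = 0) -> tuple[int, dict[int, float]]:
    """Choose K by maximum mean silhouette; ties go to the smallest K.

    Returns ``(K, {candidate: mean silhouette})``. One K-means fit per
    candidate, all with the same seed.
    """
    X = samples.features if isinstance(samples, PairSet) else np.asarray(samples)
    n = X.shape[0]
    if n < max(k_range):
        raise ValueError(f"{n} samples cannot support K up to {max(k_range)}")
    if n > SILHOUETTE_CAP:
        sub = np.random.default_rng(seed).choice(n, SILHOUETTE_CAP, replace=False)
    else:
        sub = None
    trace: dict[int, float] = {}
    for k in k_range:
        labels = _fit_kmeans(X, k, seed)
        if sub is None:
            trace[k] = float(silhouette_score(X, labels))
        else:
            trace[k] = float(silhouette_score(X[sub], labels[sub]))
    best = max(trace, key=lambda k: (trace[k], -k))
    return best, trace


@dataclass
class DenoisingResult:
    k: int
    noise_indices: np.ndarray        # sample indices, subset of unknowns
    reliable_indices: np.ndarray
    round_seeds: list[int]
    round_selected_sizes: list[int]  # |selected cluster| per round
    round_positive_rates: list[float]
    round_noise_sets: list[np.ndarray] = field(default_factory=list)
    initial_positive_rates: list[float] = field(default_factory=list)
    silhouette_trace: dict[int, float] = field(default_factory=dict)

    def noise_pairs(self, A: AssociationMatrix, samples: PairSet) -> list[tuple[str, str]]:
        return [(A.disease_ids[samples.disease_idx[i]], A.lncrna_ids[samples.lncrna_idx[i]])
                for i in self.noise_indices]


def _positive_rates(assignment: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    rates = np.zeros(k)
    for c in range(k):
        members = assignment == c
        rates[c] = labels[members].mean() if members.any() else 0.0
    return rates


def denoise(samples: PairSet, k: int, rounds: int = 10, base_seed: int = 0) -> DenoisingResult:
    """Run the repeated-clustering intersection denoiser.

    Each round clusters the full sample set (seed = base_seed + round),
    picks the cluster with the highest positive proportion (ties: larger
    cluster, then lower index) and records its unknown members; U_noise is
    the intersection across rounds. An initial clustering's per-cluster
    positive proportions are recorded for diagnostics only.
    """
    if k < 2:
        raise ValueError("K must be at least 2")
    labels = samples.labels
    if labels.all() or not labels.any():
        raise ValueError("sample set must contain both positive and unknown pairs")
    X = samples.features

    initial = _fit_kmeans(X, k, base_seed)
    initial_rates = _positive_rates(initial, labels, k).tolist()

    noise: np.ndarray | None = None
    seeds, sizes, rates_log, round_sets = [], [], [], []
    seed = base_seed
    for _ in range(rounds):
        seed += 1
        for attempt in range(10):
            assignment = _fit_kmeans(X, k, seed + attempt)
            counts = np.bincount(assignment, minlength=k)
            if (counts > 0).sum() == k:
                seed += attempt
                break
            warnings.warn(f"empty cluster with seed {seed + attempt}; re-seeding")
        rates = _positive_rates(assignment, labels, k)
        # ties: highest rate, then larger cluster, then lower index
        order = sorted(range(k), key=lambda c: (-rates[c], -counts[c], c))
        chosen = order[0]
        members = np.flatnonzero((assignment == chosen) & ~labels)
        seeds.append(seed)
        sizes.append(int(counts[chosen]))
        rates_log.append(float(rates[chosen]))
        round_sets.append(members)
        noise = members if noise is None else np.intersect1d(noise, members)
    unknowns = samples.unknowns
    reliable = np.setdiff1d(unknowns, noise)
    return DenoisingResult(k=k, noise_indices=noise, reliable_indices=reliable,
                           round_seeds=seeds, round_selected_sizes=sizes,
                           round_positive_rates=rates_log, round_noise_sets=round_sets,
                           initial_positive_rates=initial_rates)
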