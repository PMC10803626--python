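"""The six similarity views over diseases and lncRNAs.

Disease views
    DSS   ontology-based semantic similarity (shared-ancestor contributions)
    DCS   cosine similarity between association profile rows
    DGS   Gaussian interaction profile (GIP) kernel on profile rows

lncRNA views
    LFS   functional similarity (best-match averaging of DSS over the
          diseases each lncRNA is associated with)
    LGS   GIP kernel on association profile columns
    LSES  sequence similarity, 1 minus the length-normalised weighted edit
          distance (insertion/deletion cost 1, substitution cost 2)

Every view is returned as a :class:`~lncdap.datatypes.SimilarityNetwork`:
a symmetric matrix with entries in [0, 1] and unit diagonal, indexed by the
association matrix's canonical entity ordering.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .datatypes import (
    AssociationMatrix,
    DegenerateInputError,
    DiseaseDAG,
    SequenceSet,
    SimilarityNetwork,
)

__all__ = [
    "disease_semantic_similarity",
    "disease_semantic_similarity_matrix",
    "disease_cosine_similarity",
    "gip_kernel",
    "lncrna_functional_similarity",
    "lncrna_functional_similarity_matrix",
    "weighted_edit_cost",
    "lncrna_sequence_similarity",
    "compute_all_views",
]


# ---------------------------------------------------------------------------
# disease semantic similarity (DSS)

def disease_semantic_similarity(dag: DiseaseDAG, i: str, j: str) -> float:
    """Semantic similarity of two diseases from their shared DAG ancestors.

    ``sum_{d in D_i ∩ D_j} (SC_i(d) + SC_j(d)) / (SV(i) + SV(j))`` where
    ``SC`` is the per-edge-decayed semantic contribution and ``SV`` the
    summed contribution over all ancestors. Equals 1 when ``i == j`` and 0
    when the ancestor sets are disjoint.
    """
    sc_i = dag.semantic_contributions(i)
    sc_j = dag.semantic_contributions(j)
    shared = sc_i.keys() & sc_j.keys()
    if not shared:
        return 0.0
    num = sum(sc_i[d] + sc_j[d] for d in shared)
    return num / (sum(sc_i.values()) + sum(sc_j.values()))


def disease_semantic_similarity_matrix(dag: DiseaseDAG, disease_ids: list[str]) -> SimilarityNetwork:
    n = len(disease_ids)
    m = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            m[a, b] = m[b, a] = disease_semantic_similarity(dag, disease_ids[a], disease_ids[b])
    return SimilarityNetwork(m, list(disease_ids), "DSS")


# ---------------------------------------------------------------------------
# disease cosine similarity (DCS)

def disease_cosine_similarity(A: AssociationMatrix) -> SimilarityNetwork:
    """Cosine similarity between disease association profile rows.

    Diseases without any known association (all-zero rows) get similarity 0
    to every other disease and 1 to themselves.
    """
    X = A.values.astype(np.float64)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    sim = (X @ X.T) / np.outer(safe, safe)
    zero = norms == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.fill_diagonal(sim, 1.0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    return SimilarityNetwork(sim, list(A.disease_ids), "DCS")


# ---------------------------------------------------------------------------
# GIP kernel (DGS over rows, LGS over columns)

def gip_kernel(M: np.ndarray, axis: str, entity_ids: list[str],
               gamma_prime: float = 1.0) -> SimilarityNetwork:
    """Gaussian interaction profile kernel similarity.

    ``sim(i, j) = exp(-gamma * ||p_i - p_j||^2)`` over binary association
    profiles, with the bandwidth normalised by the mean squared profile
    norm: ``gamma = gamma' / mean_k ||p_k||^2``.

    Parameters
    ----------
    M
        The binary association matrix.
    axis
        ``"rows"`` for disease profiles (DGS), ``"columns"`` for lncRNA
        profiles (LGS).
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    P = np.asarray(M, dtype=np.float64)
    if axis == "columns":
        P = P.T
    sq_norms = (P ** 2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise DegenerateInputError("all profiles are zero; GIP bandwidth undefined")
    gamma = gamma_prime / mean_sq
    # ||p_i - p_j||^2 = ||p_i||^2 + ||p_j||^2 - 2 p_i.p_j
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (P @ P.T)
    np.maximum(d2, 0.0, out=d2)
    sim = np.exp(-gamma * d2)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    view = "DGS" if axis == "rows" else "LGS"
    return SimilarityNetwork(sim, list(entity_ids), view)


# ---------------------------------------------------------------------------
# lncRNA functional similarity (LFS)

def lncrna_functional_similarity(dss: np.ndarray, sets_i: np.ndarray, sets_j: np.ndarray) -> float:
    """Best-match average of disease semantic similarities between the
    disease sets of two lncRNAs; 0 if either set is empty."""
    if len(sets_i) == 0 or len(sets_j) == 0:
        return 0.0
    sub = dss[np.ix_(sets_i, sets_j)]
    return (sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (len(sets_i) + len(sets_j))


def lncrna_functional_similarity_matrix(dss: SimilarityNetwork, A: AssociationMatrix) -> SimilarityNetwork:
    if dss.entity_ids != A.disease_ids:
        raise ValueError("DSS network must be indexed by the association matrix's diseases")
    disease_sets = [np.flatnonzero(A.values[:, l]) for l in range(A.n_lncrnas)]
    n = A.n_lncrnas
    m = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            m[a, b] = m[b, a] = lncrna_functional_similarity(dss.values, disease_sets[a], disease_sets[b])
    return SimilarityNetwork(np.clip(m, 0.0, 1.0), list(A.lncrna_ids), "LFS")


# ---------------------------------------------------------------------------
# lncRNA sequence similarity (LSES)

@njit(cache=False)
def _edit_cost_kernel(a: np.ndarray, b: np.ndarray) -> np.int64:  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    prev = np.empty(m + 1, dtype=np.int64)
    curr = np.empty(m + 1, dtype=np.int64)
    for j in range(m + 1):
        prev[j] = j
    for i in range(1, n + 1):
        curr[0] = i
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = prev[j - 1] + (0 if ai == b[j - 1] else 2)
            ins = curr[j - 1] + 1
            dele = prev[j] + 1
            best = sub
            if ins < best:
                best = ins
            if dele < best:
                best = dele
            curr[j] = best
        prev, curr = curr, prev
    return prev[m]


def weighted_edit_cost(s1: str, s2: str) -> int:
    """Minimum transformation cost with insertion/deletion 1, substitution 2.

    With substitution priced at two unit indels the optimum equals
    ``len(s1) + len(s2) - 2 * LCS(s1, s2)``; it is symmetric, zero exactly
    for identical strings, and bounded by ``len(s1) + len(s2)``.
    """
    if not s1:
        return len(s2)
    if not s2:
        return len(s1)
    a = np.frombuffer(s1.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(s2.encode("ascii"), dtype=np.uint8)
    return int(_edit_cost_kernel(a, b))


def lncrna_sequence_similarity(seqs: SequenceSet, lncrna_ids: list[str],
                               raw_distance: bool = False) -> SimilarityNetwork:
    """Pairwise sequence similarity ``1 - cost / (len_i + len_j)``.

    ``raw_distance=True`` returns the normalised edit cost itself (0 for
    identical sequences) instead of its one-minus complement.
    """
    strings = [seqs[l] for l in lncrna_ids]  # raises IdentifierError if missing
    arrays = [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in strings]
    lengths = np.array([len(s) for s in strings], dtype=np.float64)
    n = len(lncrna_ids)
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            cost = _edit_cost_kernel(arrays[a], arrays[b])
            dist[a, b] = dist[b, a] = cost / (lengths[a] + lengths[b])
    values = dist if raw_distance else 1.0 - dist
    if raw_distance:
        np.fill_diagonal(values, 0.0)
    else:
        np.fill_diagonal(values, 1.0)
    return SimilarityNetwork(np.clip(values, 0.0, 1.0), list(lncrna_ids), "LSES")


# ---------------------------------------------------------------------------

def compute_all_views(A: AssociationMatrix, dag: DiseaseDAG | None = None,
                      seqs: SequenceSet | None = None,
                      views: tuple[str, ...] | None = None,
                      gamma_prime: float = 1.0,
                      lses_raw_distance: bool = False) -> dict[str, SimilarityNetwork]:
    """Compute the requested similarity views from the raw inputs.

    ``views`` defaults to all six; DSS/LFS require ``dag``, LSES requires
    ``seqs``. Returns ``{view_name: SimilarityNetwork}``.
    """
    from .datatypes import VIEW_NAMES

    wanted = tuple(views) if views is not None else VIEW_NAMES
    out: dict[str, SimilarityNetwork] = {}
    needs_dss = "DSS" in wanted or "LFS" in wanted
    dss = None
    if needs_dss:
        if dag is None:
            raise ValueError("DSS/LFS requested but no disease DAG supplied")
        dss = disease_semantic_similarity_matrix(dag, A.disease_ids)
    if "DSS" in wanted:
        out["DSS"] = dss
    if "DCS" in wanted:
        out["DCS"] = disease_cosine_similarity(A)
    if "DGS" in wanted:
        out["DGS"] = gip_kernel(A.values, "rows", A.disease_ids, gamma_prime)
    if "LFS" in wanted:
        out["LFS"] = lncrna_functional_similarity_matrix(dss, A)
    if "LGS" in wanted:
        out["LGS"] = gip_kernel(A.values, "columns", A.lncrna_ids, gamma_prime)
    if "LSES" in wanted:
        if seqs is None:
            raise ValueError("LSES requested but no sequence set supplied")
        out["LSES"] = lncrna_sequence_similarity(seqs, A.lncrna_ids, lses_raw_distance)
    return out
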