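"""Synthetic disease-lncRNA data with the structure the method assumes.

The generator plants a low-rank latent model: every disease and every
lncRNA carries (a) an *activity* flag — whether the entity participates in
associations at all, mirroring the hub-dominated degree distributions of
curated association databases — and (b) a latent *family* (one of ``rank``
factors). Association scores are inner products of the latent factor
vectors plus Gaussian noise, thresholded at the target density, so
associations concentrate on active-active pairs and are enriched within
matching families.

Around that latent truth the generator emits every input the pipeline
reads:

* an observed association matrix in which a fraction of the true positives
  are relabelled unknown ("hidden positives") to exercise the denoiser;
* a disease ontology DAG whose subtrees follow the disease families, so
  semantic similarity correlates with the latent structure;
* lncRNA sequences evolved from per-family ancestor sequences by point
  mutation, so sequence similarity correlates with the families;
* oracle latent embeddings per entity (the ideal encoder output), used to
  test downstream stages in isolation.

Everything is deterministic per master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import AssociationMatrix, DiseaseDAG, SequenceSet

__all__ = ["FixtureSpec", "FixtureBundle", "generate_fixture", "two_community_similarity"]

_NUCS = np.array(list("ACGU"))


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    n_diseases: int = 80
    n_lncrnas: int = 120
    rank: int = 4                       # number of latent families
    density: float = 0.1                # fraction of cells that are true positives
    hidden_positive_fraction: float = 0.1  # true positives relabelled unknown
    dag_depth: int = 3                  # internal chain length per family subtree
    seq_len_range: tuple[int, int] = (200, 400)
    mutation_rate_range: tuple[float, float] = (0.05, 0.3)
    seed: int = 42
    # latent geometry: activity signal dominates, families modulate
    activity_scale: float = 2.0
    family_scale: float = 0.7
    score_noise: float = 0.5
    embed_dim: int = 64
    embed_noise: float = 0.05
    in_block_rate: float = 0.9          # target positive rate inside active blocks

    def __post_init__(self) -> None:
        if not 0 < self.density < 1:
            raise ValueError("density must lie in (0, 1)")
        if not 0 <= self.hidden_positive_fraction < 1:
            raise ValueError("hidden_positive_fraction must lie in [0, 1)")
        if self.rank >= min(self.n_diseases, self.n_lncrnas):
            raise ValueError("rank must be smaller than both entity counts")
        if self.density / self.in_block_rate > 1:
            raise ValueError("density infeasible for the requested in-block rate")


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    A_true: AssociationMatrix
    A_observed: AssociationMatrix
    dag: DiseaseDAG
    sequences: SequenceSet
    hidden_pairs: list[tuple[int, int]]          # (disease idx, lncRNA idx)
    disease_families: np.ndarray
    lncrna_families: np.ndarray
    disease_active: np.ndarray
    lncrna_active: np.ndarray
    latent_disease_embedding: np.ndarray = field(repr=False, default=None)
    latent_lncrna_embedding: np.ndarray = field(repr=False, default=None)

    @property
    def hidden_pair_sample_indices(self) -> np.ndarray:
        """Row-major cell indices of the planted hidden positives."""
        n_l = self.A_true.n_lncrnas
        return np.array([d * n_l + l for d, l in self.hidden_pairs], dtype=int)


def _latent_factors(n: int, rank: int, spec: FixtureSpec, p_active: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # exact-count assignment keeps the planted active block size controlled
    # at every fixture scale (a Bernoulli draw would add O(sqrt(n)) slop)
    active = np.zeros(n, dtype=bool)
    active[rng.permutation(n)[: int(round(p_active * n))]] = True
    families = rng.integers(0, rank, size=n)
    U = np.zeros((n, 1 + rank))
    U[:, 0] = np.where(active, spec.activity_scale, 0.0)
    U[np.arange(n), 1 + families] = spec.family_scale
    return U, families, active


def _oracle_embedding(U: np.ndarray, active: np.ndarray, spec: FixtureSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """64-dim latent embedding: signed activity axis + family axes + noise."""
    n, k = U.shape
    E = rng.normal(0.0, spec.embed_noise, size=(n, spec.embed_dim))
    E[:, 0] += np.where(active, spec.activity_scale, -spec.activity_scale)
    E[:, 1:k] += U[:, 1:]
    return E


def generate_fixture(spec: FixtureSpec | None = None) -> FixtureBundle:
    """Draw a complete synthetic input bundle from the latent model."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    n_d, n_l = spec.n_diseases, spec.n_lncrnas

    # activity rate chosen so active-active cells ~ density / in_block_rate
    p_active = min(1.0, np.sqrt(spec.density / spec.in_block_rate))
    U, fam_d, act_d = _latent_factors(n_d, spec.rank, spec, p_active, rng)
    V, fam_l, act_l = _latent_factors(n_l, spec.rank, spec, p_active, rng)

    scores = U @ V.T + rng.normal(0.0, spec.score_noise, size=(n_d, n_l))
    n_pos = int(round(spec.density * n_d * n_l))
    cut = np.partition(scores.ravel(), -n_pos)[-n_pos]
    A_true = (scores >= cut).astype(np.int8)
    # exact count under ties
    extra = int(A_true.sum()) - n_pos
    if extra > 0:
        ties = np.argwhere((scores == cut) & (A_true == 1))
        for d, l in ties[:extra]:
            A_true[d, l] = 0

    pos_cells = np.argwhere(A_true == 1)
    n_hidden = int(round(spec.hidden_positive_fraction * len(pos_cells)))
    hidden_rows = rng.choice(len(pos_cells), size=n_hidden, replace=False)
    hidden_pairs = [tuple(pos_cells[i]) for i in sorted(hidden_rows)]
    A_obs = A_true.copy()
    for d, l in hidden_pairs:
        A_obs[d, l] = 0

    disease_ids = [f"disease_{i:03d}" for i in range(n_d)]
    lncrna_ids = [f"lnc_{i:03d}" for i in range(n_l)]
    dag = _build_dag(disease_ids, fam_d, spec, rng)
    seqs = _build_sequences(lncrna_ids, fam_l, spec, rng)

    E_d = _oracle_embedding(U, act_d, spec, rng)
    E_l = _oracle_embedding(V, act_l, spec, rng)

    return FixtureBundle(
        spec=spec,
        A_true=AssociationMatrix(A_true, disease_ids, lncrna_ids),
        A_observed=AssociationMatrix(A_obs, disease_ids, lncrna_ids),
        dag=dag, sequences=seqs,
        hidden_pairs=[(int(d), int(l)) for d, l in hidden_pairs],
        disease_families=fam_d, lncrna_families=fam_l,
        disease_active=act_d, lncrna_active=act_l,
        latent_disease_embedding=E_d, latent_lncrna_embedding=E_l,
    )


def _build_dag(disease_ids: list[str], families: np.ndarray, spec: FixtureSpec,
               rng: np.random.Generator) -> DiseaseDAG:
    """Root -> per-family internal chain -> diseases at a random chain depth."""
    edges: list[tuple[str, str]] = []
    root = "DOID_ROOT"
    chains: dict[int, list[str]] = {}
    for k in range(spec.rank):
        chain = [f"DOID_fam{k}_{lvl}" for lvl in range(spec.dag_depth)]
        edges.append((chain[0], root))
        for a, b in zip(chain[1:], chain):
            edges.append((a, b))
        chains[k] = chain
    for d, k in zip(disease_ids, families):
        attach = chains[int(k)][int(rng.integers(0, spec.dag_depth))]
        edges.append((d, attach))
    return DiseaseDAG(edges)


def _build_sequences(lncrna_ids: list[str], families: np.ndarray, spec: FixtureSpec,
                     rng: np.random.Generator) -> SequenceSet:
    """Per-family ancestor sequence, point-mutated per member."""
    lo, hi = spec.seq_len_range
    r0, r1 = spec.mutation_rate_range
    rates = np.linspace(r0, r1, spec.rank)
    ancestors = {}
    for k in range(spec.rank):
        length = int(rng.integers(lo, hi + 1))
        ancestors[k] = rng.choice(_NUCS, size=length)
    records = {}
    for name, k in zip(lncrna_ids, families):
        anc = ancestors[int(k)]
        seq = anc.copy()
        hits = rng.random(len(seq)) < rates[int(k)]
        seq[hits] = rng.choice(_NUCS, size=int(hits.sum()))
        records[name] = "".join(seq)
    return SequenceSet(records)


def two_community_similarity(n: int = 60, within: float = 0.8, between: float = 0.1,
                             noise: float = 0.05, seed: int = 0):
    """Block-structured similarity matrix for encoder tests (two communities)."""
    from .datatypes import SimilarityNetwork

    rng = np.random.default_rng(seed)
    half = n // 2
    m = np.full((n, n), between)
    m[:half, :half] = within
    m[half:, half:] = within
    m += rng.normal(0.0, noise, size=(n, n))
    m = (m + m.T) / 2.0
    np.clip(m, 0.0, 1.0, out=m)
    np.fill_diagonal(m, 1.0)
    ids = [f"node_{i:02d}" for i in range(n)]
    return SimilarityNetwork(m, ids, "SYN")
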