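"""Core containers for the association-prediction pipeline.

The pipeline operates on four kinds of objects: a binary disease x lncRNA
association matrix, a disease ontology DAG (for semantic similarity), a set
of lncRNA nucleotide sequences, and square per-view similarity networks.
All containers validate their invariants at construction time and use a
single canonical entity ordering taken from the association matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class IdentifierError(KeyError):
    """An entity identifier is unknown to the container it was looked up in."""


class FormatError(ValueError):
    """An input file or array does not have the expected structure."""


class DegenerateInputError(ValueError):
    """The input is structurally valid but the operation is undefined on it."""


VIEW_NAMES = ("DSS", "DCS", "DGS", "LFS", "LGS", "LSES")
DISEASE_VIEWS = ("DSS", "DCS", "DGS")
LNCRNA_VIEWS = ("LFS", "LGS", "LSES")

#: canonical nucleotide alphabet after T->U normalisation
ALPHABET = frozenset("ACGUN")


@dataclass
class AssociationMatrix:
    """Binary disease x lncRNA association matrix.

    Rows index diseases, columns index lncRNAs; ``values[i, j] == 1`` records
    a known association between ``disease_ids[i]`` and ``lncrna_ids[j]``.
    """

    values: np.ndarray
    disease_ids: list[str]
    lncrna_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise FormatError("association matrix must be 2-dimensional")
        if not np.isin(self.values, (0, 1)).all():
            raise FormatError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        if self.values.shape != (len(self.disease_ids), len(self.lncrna_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.disease_ids)} diseases x {len(self.lncrna_ids)} lncRNAs"
            )
        for ids, what in ((self.disease_ids, "disease"), (self.lncrna_ids, "lncRNA")):
            if len(set(ids)) != len(ids):
                raise FormatError(f"duplicate {what} identifiers")

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrna_ids)

    def disease_index(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise IdentifierError(f"unknown disease identifier: {disease_id!r}") from None

    def lncrna_index(self, lncrna_id: str) -> int:
        try:
            return self.lncrna_ids.index(lncrna_id)
        except ValueError:
            raise IdentifierError(f"unknown lncRNA identifier: {lncrna_id!r}") from None


class DiseaseDAG:
    """Disease ontology as a child -> parents DAG with semantic-value caches.

    Each node contributes to its own semantics with weight 1; an ancestor
    reached through k edges contributes ``decay**k`` along the best path
    (the Wang-style semantic contribution, ``SC``). The semantic value
    ``SV(d)`` is the sum of contributions over all ancestors of d, d included.
    """

    def __init__(self, edges: list[tuple[str, str]], nodes: list[str] | None = None,
                 decay: float = 0.5):
        if not 0.0 < decay < 1.0:
            raise ValueError("decay must lie in (0, 1)")
        self.decay = float(decay)
        self._parents: dict[str, set[str]] = {}
        node_set: set[str] = set(nodes or ())
        for child, parent in edges:
            node_set.add(child)
            node_set.add(parent)
            self._parents.setdefault(child, set()).add(parent)
        self.nodes = sorted(node_set)
        for n in self.nodes:
            self._parents.setdefault(n, set())
        self._check_acyclic()
        self._sc_cache: dict[str, dict[str, float]] = {}

    def _check_acyclic(self) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((c, p) for c, ps in self._parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise FormatError("disease DAG contains a cycle")

    def __contains__(self, node: str) -> bool:
        return node in self._parents

    def semantic_contributions(self, disease: str) -> dict[str, float]:
        """SC_d(t) for every ancestor t of ``disease`` (itself included)."""
        if disease not in self._parents:
            raise IdentifierError(f"unknown disease identifier: {disease!r}")
        cached = self._sc_cache.get(disease)
        if cached is not None:
            return cached
        sc = {disease: 1.0}
        frontier = [disease]
        while frontier:
            nxt = []
            for node in frontier:
                contrib = self.decay * sc[node]
                for parent in self._parents[node]:
                    if contrib > sc.get(parent, 0.0):
                        sc[parent] = contrib
                        nxt.append(parent)
            frontier = nxt
        self._sc_cache[disease] = sc
        return sc

    def ancestors(self, disease: str) -> set[str]:
        return set(self.semantic_contributions(disease))

    def semantic_value(self, disease: str) -> float:
        return sum(self.semantic_contributions(disease).values())


class SequenceSet:
    """lncRNA identifier -> nucleotide sequence map (T normalised to U)."""

    def __init__(self, records: dict[str, str]):
        self.records: dict[str, str] = {}
        for name, seq in records.items():
            seq = normalize_sequence(seq)
            if not seq:
                raise FormatError(f"empty sequence for {name!r}")
            self.records[name] = seq

    def __getitem__(self, name: str) -> str:
        try:
            return self.records[name]
        except KeyError:
            raise IdentifierError(f"no sequence for lncRNA {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return list(self.records)


def normalize_sequence(seq: str) -> str:
    """Uppercase, map T->U, and mask characters outside {A,C,G,U} as N."""
    seq = seq.upper().replace("T", "U")
    if not set(seq) <= ALPHABET:
        seq = "".join(c if c in ALPHABET else "N" for c in seq)
    return seq


@dataclass
class SimilarityNetwork:
    """Symmetric similarity matrix in [0, 1] over one entity type, one view."""

    values: np.ndarray
    entity_ids: list[str]
    view_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise FormatError(f"similarity matrix shape {self.values.shape} != ({n}, {n})")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-12:
            raise FormatError(f"{self.view_name} similarity matrix is not symmetric")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise FormatError(f"{self.view_name} entries outside [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    @property
    def n(self) -> int:
        return len(self.entity_ids)
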