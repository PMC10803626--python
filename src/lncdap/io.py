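"""Readers and writers for the pipeline's on-disk formats.

All tabular files are UTF-8, tab-separated, LF-terminated. Associations
may be given as a two-column pair list (``disease_id<TAB>lncrna_id``) or a
dense 0/1 matrix with an identifier header row and column; both readers
produce the same canonical matrix (identifiers sorted and deduplicated).
Sequences use FASTA (T normalised to U on read); the disease ontology is a
``child_id<TAB>parent_id`` edge table.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    AssociationMatrix,
    DiseaseDAG,
    FormatError,
    SequenceSet,
    SimilarityNetwork,
)

__all__ = [
    "read_associations", "write_associations",
    "read_fasta", "write_fasta",
    "read_dag", "write_dag",
    "read_similarity", "write_similarity", "write_edge_list",
    "read_embedding", "write_embedding",
    "write_metrics_json", "write_predictions",
]


def read_associations(path) -> AssociationMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty association file") from None
    if df.empty:
        raise FormatError(f"{path}: no association rows")
    if df.shape[1] == 2:
        return _from_pair_list(df, path)
    return _from_dense(path)


def _from_pair_list(df: pd.DataFrame, path: Path) -> AssociationMatrix:
    df.columns = ["disease_id", "lncrna_id"]
    n_before = len(df)
    df = df.drop_duplicates()
    if len(df) < n_before:
        warnings.warn(f"{path}: {n_before - len(df)} duplicate association rows collapsed")
    diseases = sorted(df["disease_id"].unique())
    lncrnas = sorted(df["lncrna_id"].unique())
    d_pos = {d: i for i, d in enumerate(diseases)}
    l_pos = {l: i for i, l in enumerate(lncrnas)}
    m = np.zeros((len(diseases), len(lncrnas)), dtype=np.int8)
    for d, l in zip(df["disease_id"], df["lncrna_id"]):
        m[d_pos[d], l_pos[l]] = 1
    return AssociationMatrix(m, diseases, lncrnas)


def _from_dense(path: Path) -> AssociationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise FormatError(f"{path}: dense association matrix must be 0/1")
    diseases = [str(x) for x in df.index]
    lncrnas = [str(x) for x in df.columns]
    order_d = np.argsort(diseases)
    order_l = np.argsort(lncrnas)
    return AssociationMatrix(values[np.ix_(order_d, order_l)],
                             [diseases[i] for i in order_d],
                             [lncrnas[i] for i in order_l])


def write_associations(A: AssociationMatrix, path, dense: bool = False) -> None:
    path = Path(path)
    if dense:
        df = pd.DataFrame(A.values, index=A.disease_ids, columns=A.lncrna_ids)
        df.to_csv(path, sep="\t", lineterminator="\n")
    else:
        rows = np.argwhere(A.values == 1)
        with path.open("w", newline="\n") as fh:
            fh.write("disease_id\tlncrna_id\n")
            for d, l in rows:
                fh.write(f"{A.disease_ids[d]}\t{A.lncrna_ids[l]}\n")


def read_fasta(path) -> SequenceSet:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        bad = set(seq.upper().replace("T", "U")) - set("ACGUN")
        if bad:
            warnings.warn(f"{path}: sequence {rec.id} contains {sorted(bad)}; masked as N")
        records[rec.id] = seq
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_dag(path, decay: float = 0.5) -> DiseaseDAG:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: DAG table must have two columns (child_id, parent_id)")
    df.columns = ["child_id", "parent_id"]
    return DiseaseDAG(list(zip(df["child_id"], df["parent_id"])), decay=decay)


def write_dag(dag: DiseaseDAG, path) -> None:
    with Path(path).open("w", newline="\n") as fh:
        fh.write("child_id\tparent_id\n")
        for child in dag.nodes:
            for parent in sorted(dag._parents[child]):
                fh.write(f"{child}\t{parent}\n")


def read_similarity(path, view_name: str | None = None) -> SimilarityNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(x) for x in df.index]
    if ids != [str(x) for x in df.columns]:
        raise FormatError(f"{path}: similarity row and column identifiers differ")
    name = view_name or Path(path).stem.upper()
    return SimilarityNetwork(df.to_numpy(dtype=float), ids, name)


def write_similarity(net: SimilarityNetwork, path) -> None:
    df = pd.DataFrame(net.values, index=net.entity_ids, columns=net.entity_ids)
    df.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def write_edge_list(net: SimilarityNetwork, path, threshold: float = 0.0) -> None:
    """Weighted edge list (source, target, weight): off-diagonal entries above
    the threshold plus unit self-loops."""
    with Path(path).open("w", newline="\n") as fh:
        fh.write("source\ttarget\tweight\n")
        n = net.n
        for i in range(n):
            fh.write(f"{net.entity_ids[i]}\t{net.entity_ids[i]}\t1\n")
            for j in range(n):
                if i != j and net.values[i, j] > threshold:
                    fh.write(f"{net.entity_ids[i]}\t{net.entity_ids[j]}\t"
                             f"{net.values[i, j]:.10g}\n")


def read_embedding(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(x) for x in df.index]


def write_embedding(F: np.ndarray, entity_ids: list[str], path) -> None:
    cols = [f"e{i:02d}" for i in range(F.shape[1])]
    df = pd.DataFrame(F, index=entity_ids, columns=cols)
    df.index.name = "entity_id"
    df.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def write_metrics_json(metrics: dict, path) -> None:
    with Path(path).open("w", newline="\n") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_predictions(rows: list[tuple[str, str, float]], path) -> None:
    with Path(path).open("w", newline="\n") as fh:
        fh.write("disease_id\tlncrna_id\tscore\n")
        for d, l, s in rows:
            fh.write(f"{d}\t{l}\t{s:.10g}\n")
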