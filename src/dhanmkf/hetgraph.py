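"""Head/tail node typing and the typed edge sets of the heterogeneous graph.

Sparse biomedical association networks are degree-skewed, so nodes are split
into *head* (degree > K) and *tail* (degree <= K) classes.  Endpoint classes
then type the edges: cross-type (circRNA-drug) edges fall into four
relations (head-head, head-tail, tail-head, tail-tail, circRNA side first)
and same-type similarity edges into three (head-head, mixed, tail-tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_data import AssociationMatrix

HEAD, TAIL = "head", "tail"

INTER_RELATIONS = (1, 2, 3, 4)
INTRA_RELATIONS = (1, 2, 3)


@dataclass(frozen=True)
class NodePartition:
    labels: tuple[str, ...]  # per node, "head" | "tail"
    threshold: int | None  # None for user-supplied partitions
    source: str = "degree"

    def is_head(self) -> np.ndarray:
        return np.asarray([lbl == HEAD for lbl in self.labels])


EdgeList = tuple[np.ndarray, np.ndarray]  # (src indices, dst indices)


@dataclass
class TypedEdges:
    """Relation-keyed edge lists.

    ``intra_c`` / ``intra_d`` hold directed same-type edges (both directions
    of each undirected similarity edge); ``inter`` holds circRNA->drug index
    pairs of training positives.
    """

    intra_c: dict[int, EdgeList] = field(default_factory=dict)
    intra_d: dict[int, EdgeList] = field(default_factory=dict)
    inter: dict[int, EdgeList] = field(default_factory=dict)


def classify_head_tail(degrees: np.ndarray, threshold: int) -> NodePartition:
    """Tail iff degree <= threshold; head otherwise."""
    degrees = np.asarray(degrees)
    if (degrees < 0).any():
        raise ValueError("degrees must be nonnegative")
    labels = tuple(TAIL if d <= threshold else HEAD for d in degrees.tolist())
    return NodePartition(labels=labels, threshold=threshold, source="degree")


def partition_from_labels(labels: dict[str, str], ids: tuple[str, ...]) -> NodePartition:
    """User-supplied partition (e.g. disease-annotation based) bypassing degrees."""
    return NodePartition(
        labels=tuple(labels[i] for i in ids), threshold=None, source="user-supplied"
    )


def resolve_threshold(degrees: np.ndarray, threshold: int | str) -> int:
    """Numeric threshold, or the median degree for ``'median'``."""
    if isinstance(threshold, str):
        if threshold != "median":
            raise ValueError(f"unknown threshold rule {threshold!r}")
        return int(np.median(np.asarray(degrees)))
    return int(threshold)


def build_inter_edges(
    y_train: AssociationMatrix | np.ndarray,
    part_c: NodePartition,
    part_d: NodePartition,
) -> dict[int, EdgeList]:
    """Assign each training positive to one of four relations by endpoint class."""
    values = y_train.values if isinstance(y_train, AssociationMatrix) else np.asarray(y_train)
    head_c = part_c.is_head()
    head_d = part_d.is_head()
    rows, cols = np.nonzero(values)
    # circRNA side first: (head, head)->1, (head, tail)->2, (tail, head)->3, (tail, tail)->4
    rel = np.where(
        head_c[rows],
        np.where(head_d[cols], 1, 2),
        np.where(head_d[cols], 3, 4),
    )
    edges: dict[int, EdgeList] = {}
    for r in INTER_RELATIONS:
        mask = rel == r
        if mask.any():
            edges[r] = (rows[mask].copy(), cols[mask].copy())
    return edges


def build_intra_edges(
    similarity: np.ndarray, partition: NodePartition, sparsify_k: int
) -> dict[int, EdgeList]:
    """Top-k similarity neighbors per node as undirected typed edges.

    Each node contributes its ``sparsify_k`` most-similar other nodes; the
    union is symmetrized and both directions are emitted.  Relation by
    endpoint classes: head-head -> 1, mixed -> 2, tail-tail -> 3.
    """
    s = np.asarray(similarity, dtype=float)
    n = s.shape[0]
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("intra similarity matrix must be symmetric")
    k = min(sparsify_k, n - 1)
    pairs: set[tuple[int, int]] = set()
    masked = s.copy()
    np.fill_diagonal(masked, -np.inf)
    for i in range(n):
        order = np.argsort(-masked[i], kind="stable")[:k]
        for j in order.tolist():
            pairs.add((min(i, j), max(i, j)))
    head = partition.is_head()
    edges: dict[int, list[tuple[int, int]]] = {1: [], 2: [], 3: []}
    for i, j in sorted(pairs):
        if head[i] and head[j]:
            r = 1
        elif not head[i] and not head[j]:
            r = 3
        else:
            r = 2
        edges[r].append((i, j))
        edges[r].append((j, i))
    out: dict[int, EdgeList] = {}
    for r, lst in edges.items():
        if lst:
            src = np.asarray([p[0] for p in lst], dtype=np.int64)
            dst = np.asarray([p[1] for p in lst], dtype=np.int64)
            out[r] = (src, dst)
    return out


def build_graph(
    y_train: AssociationMatrix | np.ndarray,
    s_c: np.ndarray,
    s_d: np.ndarray,
    k_circ: int | str = 27,
    k_drug: int | str = 39,
    sparsify_k: int = 10,
    part_c: NodePartition | None = None,
    part_d: NodePartition | None = None,
    collapse_relations: bool = False,
) -> tuple[TypedEdges, NodePartition, NodePartition]:
    """Assemble the typed heterogeneous graph from the training matrix.

    Degrees come from the *masked* training matrix so head/tail labels never
    leak held-out positives.  ``collapse_relations=True`` merges all intra
    and all inter relations into a single type each (the single-relation
    ablation).
    """
    values = y_train.values if isinstance(y_train, AssociationMatrix) else np.asarray(y_train)
    if part_c is None:
        deg_c = values.sum(axis=1)
        part_c = classify_head_tail(deg_c, resolve_threshold(deg_c, k_circ))
    if part_d is None:
        deg_d = values.sum(axis=0)
        part_d = classify_head_tail(deg_d, resolve_threshold(deg_d, k_drug))

    edges = TypedEdges(
        intra_c=build_intra_edges(s_c, part_c, sparsify_k),
        intra_d=build_intra_edges(s_d, part_d, sparsify_k),
        inter=build_inter_edges(values, part_c, part_d),
    )
    if collapse_relations:
        edges = TypedEdges(
            intra_c=_merge(edges.intra_c),
            intra_d=_merge(edges.intra_d),
            inter=_merge(edges.inter),
        )
    return edges, part_c, part_d


def _merge(rel_edges: dict[int, EdgeList]) -> dict[int, EdgeList]:
    if not rel_edges:
        return {}
    src = np.concatenate([e[0] for e in rel_edges.values()])
    dst = np.concatenate([e[1] for e in rel_edges.values()])
    return {1: (src, dst)}


def export_edges(edges: dict[int, EdgeList]) -> list[tuple[int, int, int]]:
    """Flatten relation-keyed edges to (src, dst, relation) rows."""
    rows: list[tuple[int, int, int]] = []
    for r, (src, dst) in sorted(edges.items()):
        rows.extend((int(i), int(j), r) for i, j in zip(src, dst))
    return rows
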