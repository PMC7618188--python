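"""Two-channel cohort graphs from lesion masks and behavioural scores.

Nodes are voxels on the analysis grid.  An edge joins two spatially
neighbouring voxels that were damaged together in at least one patient and
carries two weights accumulated over the cohort:

* a lesion co-occurrence count ``A_lesion[i,j] = sum_k A_k[i,j]`` — how many
  patients damaged both voxels;
* a task weight ``A_task[i,j] = sum_k A_k[i,j] / t_k`` — the same count with
  each patient contributing the inverse of their behavioural score ``t_k``,
  so damage in poorly-performing patients weighs more.  Patients with a
  zero score are excluded from the task sum.

Restricting edges to spatial neighbours (26-connectivity by default) keeps
the graph sparse; a ``clique`` switch exists for tiny inputs where the
all-co-lesioned-pairs variant is tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cohort import LesionCohort

_OFFSETS_26 = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ],
    dtype=np.int64,
)
_OFFSETS_6 = np.array([(1, 0, 0), (0, 1, 0), (0, 0, 1)], dtype=np.int64)


@dataclass(frozen=True)
class CohortGraph:
    """Undirected voxel graph with lesion-count and task weight channels.

    ``nodes`` are flat voxel indices on the analysis grid ``shape``;
    ``edges`` index into ``nodes``.  ``lesion_w`` are positive integer
    counts; ``task_w`` non-negative reals.  ``*_scaled`` are the min-max
    rescaled copies, present after :func:`rescale_weights`.
    """

    nodes: np.ndarray
    edges: np.ndarray
    lesion_w: np.ndarray
    task_w: np.ndarray
    shape: tuple[int, int, int]
    test: str = ""
    lesion_w_scaled: np.ndarray | None = None
    task_w_scaled: np.ndarray | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if (edges[:, 0] == edges[:, 1]).any():
            raise ValueError("self-loops are not permitted")
        if len(np.unique(edges.min(axis=1) * len(self.nodes) + edges.max(axis=1))) != len(edges):
            raise ValueError("duplicate edges")
        if (np.asarray(self.lesion_w) <= 0).any():
            raise ValueError("lesion weights must be positive counts")
        if (np.asarray(self.task_w) < 0).any():
            raise ValueError("task weights must be non-negative")
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=np.int64))
        object.__setattr__(self, "edges", edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    @property
    def is_rescaled(self) -> bool:
        return self.lesion_w_scaled is not None and self.task_w_scaled is not None


@dataclass(frozen=True)
class LayeredGraph:
    """Edge entries split into a lesion layer and a task layer.

    Each cohort-graph edge contributes one entry per nonzero channel:
    ``entry_layer`` 0 = lesion, 1 = task; ``entry_value`` is the rescaled
    weight in [0, 1] used by the description-length code; ``entry_count``
    carries the pre-rescale integer lesion count (0 for task entries) for
    reporting under the declared per-layer weight models.
    """

    nodes: np.ndarray
    edges: np.ndarray
    entry_edge: np.ndarray
    entry_layer: np.ndarray
    entry_value: np.ndarray
    entry_count: np.ndarray
    shape: tuple[int, int, int]
    test: str = ""
    weight_models: tuple[str, str] = ("poisson", "gaussian")
    is_null: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_entries(self) -> int:
        return len(self.entry_edge)

    @property
    def n_layers(self) -> int:
        return len(np.unique(self.entry_layer))


def _flat(coords: np.ndarray, shape) -> np.ndarray:
    return np.ravel_multi_index(tuple(coords.T), shape)


def lesion_adjacency(
    mask: np.ndarray, connectivity: int = 26, clique: bool = False
) -> np.ndarray:
    """Edge set of one lesion: pairs of co-lesioned voxels.

    Returns an (E, 2) array of flat voxel indices with ``i < j``.  By
    default pairs are restricted to spatial neighbours under the given
    connectivity; ``clique=True`` instead joins *all* co-lesioned pairs
    (quadratic — tiny inputs only).
    """
    mask = np.asarray(mask).astype(bool)
    shape = mask.shape
    coords = np.argwhere(mask)
    if len(coords) == 0:
        warnings.warn("empty lesion mask produces no edges", stacklevel=2)
        return np.empty((0, 2), dtype=np.int64)
    if clique:
        flat = np.sort(_flat(coords, shape))
        ii, jj = np.triu_indices(len(flat), k=1)
        return np.column_stack([flat[ii], flat[jj]])
    if connectivity == 26:
        offsets = _OFFSETS_26
    elif connectivity == 6:
        offsets = _OFFSETS_6
    else:
        raise ValueError("connectivity must be 6 or 26")
    pairs = []
    for off in offsets:
        nb = coords + off
        ok = ((nb >= 0) & (nb < np.array(shape))).all(axis=1)
        if not ok.any():
            continue
        src = coords[ok]
        dst = nb[ok]
        hit = mask[tuple(dst.T)]
        if not hit.any():
            continue
        a = _flat(src[hit], shape)
        b = _flat(dst[hit], shape)
        pairs.append(np.column_stack([np.minimum(a, b), np.maximum(a, b)]))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(pairs)


def accumulate_graph(
    cohort: LesionCohort,
    test: str,
    connectivity: int = 26,
    clique: bool = False,
) -> CohortGraph:
    """Accumulate per-patient adjacencies into the two-channel cohort graph."""
    if len(cohort) == 0:
        raise ValueError("cohort has no patients")
    scores = cohort.scores(test)
    if (scores == 0).all():
        raise ValueError("all scores are zero; task weights undefined")

    shape = cohort.template.shape
    all_pairs, all_lesion, all_task = [], [], []
    for patient, t in zip(cohort.patients, scores):
        pairs = lesion_adjacency(patient.mask, connectivity=connectivity, clique=clique)
        if len(pairs) == 0:
            continue
        all_pairs.append(pairs)
        all_lesion.append(np.ones(len(pairs)))
        inv = 1.0 / t if t != 0 else 0.0  # zero-score patients excluded from task sum
        all_task.append(np.full(len(pairs), inv))
    if not all_pairs:
        raise ValueError("no lesion produced any edge")

    pairs = np.concatenate(all_pairs)
    lesion = np.concatenate(all_lesion)
    task = np.concatenate(all_task)

    nvox = int(np.prod(shape))
    keys = pairs[:, 0] * nvox + pairs[:, 1]
    uniq, inverse = np.unique(keys, return_inverse=True)
    lesion_w = np.zeros(len(uniq))
    task_w = np.zeros(len(uniq))
    np.add.at(lesion_w, inverse, lesion)
    np.add.at(task_w, inverse, task)

    vi = uniq // nvox
    vj = uniq % nvox
    nodes, edge_idx = np.unique(np.concatenate([vi, vj]), return_inverse=True)
    edges = np.column_stack([edge_idx[: len(uniq)], edge_idx[len(uniq):]])
    return CohortGraph(
        nodes=nodes,
        edges=edges,
        lesion_w=lesion_w.astype(np.int64),
        task_w=task_w,
        shape=shape,
        test=test,
    )


def filter_nodes(
    graph: CohortGraph, top_fraction: float = 0.5, min_degree: int = 3
) -> CohortGraph:
    """Keep the best-sampled half of the graph.

    Two-stage rule: retain nodes whose (unweighted) degree reaches the
    median — the top 50% by connectedness, ties retained — then drop nodes
    left with fewer than ``min_degree`` connections (single pass).
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    deg = graph.degrees()
    cutoff = np.quantile(deg, 1.0 - top_fraction)
    keep = deg >= cutoff
    sub = _induced_subgraph(graph, keep)

    deg2 = np.zeros(int(keep.sum()), dtype=np.int64)
    if sub.n_edges:
        np.add.at(deg2, sub.edges[:, 0], 1)
        np.add.at(deg2, sub.edges[:, 1], 1)
    sub = _induced_subgraph(sub, deg2 >= min_degree)
    if sub.n_nodes == 0:
        raise ValueError("node filtering left an empty graph")
    return sub


def _induced_subgraph(graph: CohortGraph, keep: np.ndarray) -> CohortGraph:
    new_id = -np.ones(graph.n_nodes, dtype=np.int64)
    new_id[keep] = np.arange(int(keep.sum()))
    ekeep = keep[graph.edges[:, 0]] & keep[graph.edges[:, 1]]
    kwargs = {}
    if graph.lesion_w_scaled is not None:
        kwargs["lesion_w_scaled"] = graph.lesion_w_scaled[ekeep]
    if graph.task_w_scaled is not None:
        kwargs["task_w_scaled"] = graph.task_w_scaled[ekeep]
    return CohortGraph(
        nodes=graph.nodes[keep],
        edges=new_id[graph.edges[ekeep]],
        lesion_w=graph.lesion_w[ekeep],
        task_w=graph.task_w[ekeep],
        shape=graph.shape,
        test=graph.test,
        **kwargs,
    )


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.zeros_like(values, dtype=float)
    return (values - lo) / (hi - lo)


def rescale_weights(graph: CohortGraph) -> CohortGraph:
    """Min-max rescale each weight channel independently to [0, 1].

    Constant channels map to all-zero.  Raw counts are kept alongside the
    rescaled copies.
    """
    if graph.n_edges < 1:
        raise ValueError("graph has no edges")
    return replace(
        graph,
        lesion_w_scaled=_minmax(graph.lesion_w.astype(float)),
        task_w_scaled=_minmax(graph.task_w),
    )


def to_layered(graph: CohortGraph) -> LayeredGraph:
    """Split the two weight channels into layers of one layered graph.

    Layer 0 holds lesion co-occurrence entries (count-valued; declared
    Poisson-family), layer 1 the task entries (real-valued; declared
    Gaussian).  Edges with zero task weight appear in the lesion layer only.
    """
    if not graph.is_rescaled:
        raise ValueError("rescale_weights must be applied before layering")
    e = graph.n_edges
    task_nonzero = graph.task_w > 0
    edge_ids = np.arange(e, dtype=np.int64)
    entry_edge = np.concatenate([edge_ids, edge_ids[task_nonzero]])
    entry_layer = np.concatenate(
        [np.zeros(e, dtype=np.int8), np.ones(int(task_nonzero.sum()), dtype=np.int8)]
    )
    entry_value = np.concatenate(
        [graph.lesion_w_scaled, graph.task_w_scaled[task_nonzero]]
    )
    entry_count = np.concatenate(
        [graph.lesion_w, np.zeros(int(task_nonzero.sum()), dtype=np.int64)]
    )
    return LayeredGraph(
        nodes=graph.nodes,
        edges=graph.edges,
        entry_edge=entry_edge,
        entry_layer=entry_layer,
        entry_value=entry_value,
        entry_count=entry_count,
        shape=graph.shape,
        test=graph.test,
    )


def randomize_layers(layered: LayeredGraph, seed: int) -> LayeredGraph:
    """Layer-randomised null: permute layer labels over edge entries.

    The multiset of weights and the per-layer entry counts are conserved;
    only the weight-to-layer assignment is destroyed.
    """
    if layered.n_layers < 2:
        raise ValueError("layer randomisation requires two layers")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(layered.n_entries)
    return replace(layered, entry_layer=layered.entry_layer[perm], is_null=True)


# ---------------------------------------------------------------------------
# plain-text round-trip
# ---------------------------------------------------------------------------

def write_graph(graph: CohortGraph, out_dir) -> None:
    """Export as edge-list + node tables (TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vox = np.column_stack(np.unravel_index(graph.nodes, graph.shape))
    pd.DataFrame(
        {"node": np.arange(graph.n_nodes), "x": vox[:, 0], "y": vox[:, 1], "z": vox[:, 2]}
    ).to_csv(out / "nodes.tsv", sep="\t", index=False)
    edge_df = pd.DataFrame(
        {
            "node_i": graph.edges[:, 0],
            "node_j": graph.edges[:, 1],
            "lesion_weight": graph.lesion_w,
            "task_weight": graph.task_w,
        }
    )
    if graph.is_rescaled:
        edge_df["lesion_weight_scaled"] = graph.lesion_w_scaled
        edge_df["task_weight_scaled"] = graph.task_w_scaled
    edge_df.to_csv(out / "edges.tsv", sep="\t", index=False)
    meta = pd.DataFrame({"key": ["test", "shape"], "value": [graph.test, "x".join(map(str, graph.shape))]})
    meta.to_csv(out / "graph_meta.tsv", sep="\t", index=False)


def read_graph(in_dir) -> CohortGraph:
    src = Path(in_dir)
    nodes_df = pd.read_csv(src / "nodes.tsv", sep="\t")
    edges_df = pd.read_csv(src / "edges.tsv", sep="\t")
    meta = dict(pd.read_csv(src / "graph_meta.tsv", sep="\t").values)
    shape = tuple(int(s) for s in str(meta["shape"]).split("x"))
    nodes = np.ravel_multi_index(
        (nodes_df["x"].values, nodes_df["y"].values, nodes_df["z"].values), shape
    )
    kwargs = {}
    if "lesion_weight_scaled" in edges_df:
        kwargs["lesion_w_scaled"] = edges_df["lesion_weight_scaled"].values.astype(float)
        kwargs["task_w_scaled"] = edges_df["task_weight_scaled"].values.astype(float)
    return CohortGraph(
        nodes=nodes.astype(np.int64),
        edges=edges_df[["node_i", "node_j"]].values,
        lesion_w=edges_df["lesion_weight"].values.astype(np.int64),
        task_w=edges_df["task_weight"].values.astype(float),
        shape=shape,
        test=str(meta.get("test", "")),
        **kwargs,
    )
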