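"""Distance-score map (U-matrix) and threshold cluster extraction.

The distance score DS of a node is the mean Euclidean distance from its
weight vector to those of its von-Neumann lattice neighbours (4 interior,
3 edge, 2 corner), normalised so the largest score on the map equals 1.
High-DS ridges ("clefts") mark cluster borders; clusters are 4-connected
regions of interior nodes with DS at or below a threshold (default 0.72).

Because the open lattice boundary makes edge/corner neighbourhoods
artificially dense, boundary nodes never define clusters: corner nodes are
always excluded, and a populated edge node joins a cluster only when it is
4-adjacent to one of that cluster's interior member nodes.  Every node's
fate is recorded in an audit table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .som import SOMGrid
from .spectra import Spectrum, SpectrumSet

__all__ = [
    "DistanceMap", "ClusterDefinition", "distance_map", "extract_clusters",
    "select_threshold", "composition_table", "cluster_spectral_summary",
    "cluster_score_distributions", "cluster_purity",
]

_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1))  # von Neumann


@dataclass
class DistanceMap:
    """Per-node distance scores on a (y_dim, x_dim) array, max-normalised."""

    scores: np.ndarray          # indexed [y, x], y = 0 at the bottom
    x_dim: int
    y_dim: int
    neighbour_convention: str = "von_neumann"

    def score(self, x: int, y: int) -> float:
        return float(self.scores[y, x])

    def to_frame(self) -> pd.DataFrame:
        rows = [(x, y, self.score(x, y))
                for y in range(self.y_dim) for x in range(self.x_dim)]
        return pd.DataFrame(rows, columns=["col", "row", "distance_score"])


@dataclass
class ClusterDefinition:
    """One extracted cluster: its nodes and observation membership."""

    cluster_id: str
    member_nodes: list[tuple[int, int]]
    edge_nodes: list[tuple[int, int]] = field(default_factory=list)
    member_observations: list[int] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return len(self.member_observations)


def distance_map(grid: SOMGrid) -> DistanceMap:
    """Mean neighbour distance per node, normalised by the map maximum.

    A map of identical nodes (max distance zero) returns all-zero scores.
    """
    raw = np.zeros((grid.y_dim, grid.x_dim))
    for y in range(grid.y_dim):
        for x in range(grid.x_dim):
            w = grid.node_weights(x, y)
            dists = []
            for dx, dy in _OFFSETS:
                nx, ny = x + dx, y + dy
                if 0 <= nx < grid.x_dim and 0 <= ny < grid.y_dim:
                    dists.append(np.linalg.norm(w - grid.node_weights(nx, ny)))
            raw[y, x] = np.mean(dists)
    peak = raw.max()
    scores = raw / peak if peak > 0 else raw
    return DistanceMap(scores=scores, x_dim=grid.x_dim, y_dim=grid.y_dim)


def _node_kind(x: int, y: int, x_dim: int, y_dim: int) -> str:
    on_x = x in (0, x_dim - 1)
    on_y = y in (0, y_dim - 1)
    if on_x and on_y:
        return "corner"
    if on_x or on_y:
        return "edge"
    return "interior"


def extract_clusters(dmap: DistanceMap, hits: dict[tuple[int, int], list[int]],
                     threshold: float = 0.72, min_size: int = 1,
                     hole_gate: str = "none",
                     ) -> tuple[list[ClusterDefinition], pd.DataFrame]:
    """Threshold clustering with the open-boundary exclusion rules.

    1. candidate nodes: interior (non-edge, non-corner) with DS <= threshold;
    2. cluster seeds: populated candidate nodes, 4-connected; two populated
       nodes also join when they share a single adjacent unpopulated
       candidate whose distance score does not exceed either of theirs (an
       intra-cluster hole sits below its surroundings, a saddle between
       clusters sits above the cluster cores).  Longer chains of
       unpopulated nodes never connect populated regions — on an open map,
       empty low-distance nodes are interpolation artefacts of the gap
       between clusters, not evidence that the clusters touch;
    3. an unpopulated candidate becomes a member of the cluster its
       populated neighbours belong to; unanchored unpopulated candidate
       islands may still define a cluster through the populated edge nodes
       attached to them (observations pushed to the map boundary above an
       interior low-distance region);
    4. populated edge nodes with DS <= threshold attach to the unique
       adjacent cluster; edge nodes adjacent to no cluster (or whose
       interior neighbourhood is empty) are excluded;
    5. corner nodes are never included;
    6. a cluster is kept iff it holds >= ``min_size`` observations after
       edge attachment.

    Returns the clusters (ordered by descending observation count, ids
    "C1", "C2", ...) and a per-node audit table in which every lattice node
    appears exactly once.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    x_dim, y_dim = dmap.x_dim, dmap.y_dim

    def n_hits(c):
        return len(hits.get(c, []))

    candidate = {}
    for y in range(y_dim):
        for x in range(x_dim):
            candidate[(x, y)] = (_node_kind(x, y, x_dim, y_dim) == "interior"
                                 and dmap.score(x, y) <= threshold)

    def neighbours(node):
        for dx, dy in _OFFSETS:
            nb = (node[0] + dx, node[1] + dy)
            if 0 <= nb[0] < x_dim and 0 <= nb[1] < y_dim:
                yield nb

    populated = [n for n, c in candidate.items() if c and n_hits(n) > 0]
    empty = [n for n, c in candidate.items() if c and n_hits(n) == 0]

    # union-find over populated candidates; one shared empty candidate may
    # join two populated nodes, longer empty chains may not
    parent = {p: p for p in populated}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    pop_set = set(populated)
    for p in populated:
        for nb in neighbours(p):
            if nb in pop_set:
                union(p, nb)
    if hole_gate != "never":
        for w in empty:
            adj = [nb for nb in neighbours(w) if nb in pop_set]
            for i, a in enumerate(adj):
                for b in adj[i + 1:]:
                    if hole_gate == "mean" and dmap.score(*w) > 0.5 * (
                            dmap.score(*a) + dmap.score(*b)):
                        continue
                    union(a, b)

    roots: dict[tuple[int, int], int] = {}
    groups: list[list[tuple[int, int]]] = []
    for p in populated:
        r = find(p)
        if r not in roots:
            roots[r] = len(groups)
            groups.append([])
        groups[roots[r]].append(p)
    member_idx: dict[tuple[int, int], int] = {
        p: roots[find(p)] for p in populated}

    # empty candidates adjacent to one cluster join it; those between two
    # clusters are border filler
    border_nodes: set[tuple[int, int]] = set()
    leftovers = []
    for w in empty:
        adj = {member_idx[nb] for nb in neighbours(w) if nb in member_idx}
        if len(adj) == 1:
            member_idx[w] = adj.pop()
        elif len(adj) > 1:
            border_nodes.add(w)
        else:
            leftovers.append(w)

    # leftover empty islands: absorbed when adjacent to exactly one cluster,
    # border filler when between clusters, otherwise a potential
    # edge-anchored cluster seed
    leftover_set = set(leftovers)
    anchor: set[tuple[int, int]] = set(pop_set)
    while leftover_set:
        start = leftover_set.pop()
        comp = [start]
        stack = [start]
        while stack:
            node = stack.pop()
            for nb in neighbours(node):
                if nb in leftover_set:
                    leftover_set.discard(nb)
                    comp.append(nb)
                    stack.append(nb)
        adj = {member_idx[nb] for n in comp for nb in neighbours(n)
               if nb in member_idx}
        if len(adj) == 1:
            ci = adj.pop()
            for n in comp:
                member_idx[n] = ci
        elif len(adj) == 0:
            # island: may anchor observations pushed to the map boundary
            ci = len(groups)
            groups.append([])
            for n in comp:
                member_idx[n] = ci
                anchor.add(n)
        else:
            border_nodes.update(comp)

    # attach populated, sub-threshold edge nodes to a unique adjacent
    # cluster; anchoring is through populated interior members or island
    # nodes, never through assigned border filler
    attach: dict[tuple[int, int], int] = {}
    ambiguous_edges: set[tuple[int, int]] = set()
    for y in range(y_dim):
        for x in range(x_dim):
            node = (x, y)
            if (_node_kind(x, y, x_dim, y_dim) != "edge" or n_hits(node) == 0
                    or dmap.score(x, y) > threshold):
                continue
            adj = {member_idx[nb] for nb in neighbours(node)
                   if nb in anchor and nb in member_idx}
            if len(adj) == 1:
                attach[node] = adj.pop()
            elif len(adj) > 1:
                ambiguous_edges.add(node)

    clusters = []
    dropped_nodes: set[tuple[int, int]] = set()
    for ci in range(len(groups)):
        interior = sorted(n for n, c in member_idx.items() if c == ci)
        edges = sorted(n for n, c in attach.items() if c == ci)
        obs = sorted(i for n in interior + edges for i in hits.get(n, []))
        if len(obs) < max(min_size, 1):
            dropped_nodes.update(interior)
            dropped_nodes.update(edges)
            continue
        clusters.append(ClusterDefinition(
            cluster_id="", member_nodes=interior, edge_nodes=edges,
            member_observations=obs))
    clusters.sort(key=lambda c: (-c.n_obs, c.member_nodes))
    for i, c in enumerate(clusters):
        c.cluster_id = f"C{i + 1}"

    member_of: dict[tuple[int, int], str] = {}
    edge_of: dict[tuple[int, int], str] = {}
    for c in clusters:
        for n in c.member_nodes:
            member_of[n] = c.cluster_id
        for n in c.edge_nodes:
            edge_of[n] = c.cluster_id

    audit_rows = []
    for y in range(y_dim):
        for x in range(x_dim):
            node = (x, y)
            kind = _node_kind(x, y, x_dim, y_dim)
            ds = dmap.score(x, y)
            has_obs = n_hits(node) > 0
            if node in member_of:
                status, cid = "member_interior", member_of[node]
            elif node in edge_of:
                status, cid = "member_edge", edge_of[node]
            elif kind == "corner":
                status, cid = "excluded_corner", None
            elif ds > threshold:
                status, cid = "excluded_above_threshold", None
            elif kind == "edge":
                if node in ambiguous_edges:
                    status = "excluded_edge_ambiguous"
                elif has_obs:
                    status = "excluded_edge_unattached"
                else:
                    status = "excluded_edge_unpopulated"
                cid = None
            elif node in border_nodes:
                status, cid = "excluded_border", None
            elif node in dropped_nodes:
                status, cid = "excluded_small_cluster", None
            else:
                status, cid = "excluded_unpopulated_component", None
            audit_rows.append((x, y, kind, ds, n_hits(node), status, cid))
    audit = pd.DataFrame(audit_rows, columns=[
        "col", "row", "kind", "distance_score", "n_obs", "status", "cluster_id"])
    return clusters, audit


def select_threshold(dmap: DistanceMap, hits: dict[tuple[int, int], list[int]],
                     min_size: int = 10, step: float = 0.02,
                     floor: float = 0.06, hole_gate: str = "none") -> float:
    """Automatic cleft reading of the distance map.

    Scans thresholds from high to low; the chosen value is the minimum
    distance at which the map still decomposes into its maximal number of
    clusters (of at least ``min_size`` observations each): the bottom of
    the contiguous threshold band, anchored at the highest threshold
    achieving that count, over which the decomposition persists.  Lower
    values inside the band trim high-distance border nodes from the
    clusters without changing their number.  Falls back to the scan
    ceiling when no threshold yields any cluster.
    """
    grid = np.arange(1.0 - step, floor, -step)
    counts = []
    for thr in grid:
        cls, _ = extract_clusters(dmap, hits, float(thr), min_size=min_size,
                                  hole_gate=hole_gate)
        counts.append(len(cls))
    if not counts or max(counts) == 0:
        return 1.0
    max_n = max(counts)
    hi = counts.index(max_n)          # largest threshold with max count
    lo = hi
    while lo + 1 < len(counts) and counts[lo + 1] == max_n:
        lo += 1
    return float(grid[lo])


def composition_table(clusters: list[ClusterDefinition],
                      labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster class counts with subset and total percentages.

    ``subset_pct_<class>`` is 100 * count / class total rounded to a whole
    percent (the table's printed precision); ``total_pct`` is the rounded
    share of all observations.
    """
    labels = np.asarray(labels)
    class_names = sorted(pd.unique(labels).tolist())
    totals = {c: int((labels == c).sum()) for c in class_names}
    n_all = labels.shape[0]
    rows = []
    for cl in clusters:
        member = labels[cl.member_observations] if cl.member_observations else np.array([])
        row: dict = {"cluster": cl.cluster_id, "n_obs": cl.n_obs}
        for c in class_names:
            cnt = int((member == c).sum())
            row[f"count_{c}"] = cnt
            row[f"subset_pct_{c}"] = int(np.rint(100.0 * cnt / totals[c])) if totals[c] else 0
        row["total_pct"] = int(np.rint(100.0 * cl.n_obs / n_all))
        rows.append(row)
    if not rows:
        cols = ["cluster", "n_obs"]
        for c in class_names:
            cols += [f"count_{c}", f"subset_pct_{c}"]
        return pd.DataFrame(columns=cols + ["total_pct"])
    return pd.DataFrame(rows)


def cluster_spectral_summary(clusters: list[ClusterDefinition],
                             sset: SpectrumSet) -> dict[str, dict[str, Spectrum]]:
    """Mean spectrum and SE-of-mean envelope per cluster plus the grand average."""
    seen: set[int] = set()
    for c in clusters:
        overlap = seen.intersection(c.member_observations)
        if overlap:
            raise ValueError("clusters overlap in observations")
        seen.update(c.member_observations)
    out: dict[str, dict[str, Spectrum]] = {}

    def summarise(rows: np.ndarray, name: str) -> dict[str, Spectrum]:
        mu = rows.mean(axis=0)
        if rows.shape[0] > 1:
            se = rows.std(axis=0, ddof=1) / np.sqrt(rows.shape[0])
        else:
            se = np.zeros_like(mu)
        return {"mean": Spectrum(sset.axis.copy(), mu, {"group": name}),
                "se": Spectrum(sset.axis.copy(), se, {"group": name})}

    for c in clusters:
        out[c.cluster_id] = summarise(sset.intensities[c.member_observations],
                                      c.cluster_id)
    out["all"] = summarise(sset.intensities, "all")
    return out


def cluster_score_distributions(clusters: list[ClusterDefinition],
                                projection: np.ndarray) -> dict:
    """Per-cluster samples of a scalar projection plus pairwise effect sizes.

    ``projection`` maps each observation to a scalar (e.g. a PC score).  The
    separation statistic is the absolute two-sample Cohen's d with pooled SD.
    """
    projection = np.asarray(projection, float)
    samples = {c.cluster_id: projection[c.member_observations] for c in clusters}

    def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
        na, nb = a.size, b.size
        if na < 2 or nb < 2:
            return float("nan")
        pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                         / (na + nb - 2))
        if pooled == 0:
            return 0.0 if a.mean() == b.mean() else float("inf")
        return float(abs(a.mean() - b.mean()) / pooled)

    ids = [c.cluster_id for c in clusters]
    effect = {f"{a}|{b}": cohens_d(samples[a], samples[b])
              for i, a in enumerate(ids) for b in ids[i + 1:]}
    return {"samples": samples, "effect_sizes": effect}


def cluster_purity(clusters: list[ClusterDefinition],
                   truth: np.ndarray) -> pd.DataFrame:
    """Majority ground-truth label and purity per cluster."""
    truth = np.asarray(truth)
    rows = []
    for c in clusters:
        member = truth[c.member_observations]
        if member.size == 0:
            rows.append((c.cluster_id, None, float("nan"), 0))
            continue
        vals, counts = np.unique(member, return_counts=True)
        top = int(np.argmax(counts))
        rows.append((c.cluster_id, vals[top], counts[top] / member.size,
                     member.size))
    return pd.DataFrame(rows, columns=["cluster", "majority_label", "purity",
                                       "n_obs"])
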