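"""APA-regulator interaction network.

Each knockdown (regulator) is summarised by the set of genes it significantly
affects together with the direction of the shift (+1 shortened, −1
lengthened). For a pair of regulators the *concordance* over co-affected
genes measures synergy (same direction) versus antagonism (opposite
direction); the signed edge score is

    score = (2·concordance − 1) · |shared| / min(|A|, |B|)

so that a clone pair scores +1, a mirror pair −1 and an independent pair ≈ 0.
Edge significance is the hypergeometric enrichment p of the overlap. The map
is laid out with a Fruchterman–Reingold scheme in which synergy contributes
edge attraction and antagonism extra pairwise repulsion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import set_enrichment

EDGE_ALPHA = 0.05
MIN_SHARED = 5


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class RegulatorProfile:
    regulator_id: str
    affected: Mapping[str, int]  # gene_id -> +1 (shortened) / -1 (lengthened)

    def __post_init__(self):
        bad = {d for d in self.affected.values()} - {1, -1}
        if bad:
            raise NetworkError(f"directions must be +1/-1, got {bad}")


@dataclass(frozen=True)
class NetworkEdge:
    pair: tuple[str, str]
    n_shared: int
    concordance: float
    score: float
    p: float


def profile_from_gene_table(regulator_id: str, gene_df: pd.DataFrame) -> RegulatorProfile:
    """Build a profile from a per-gene summary table (``si`` + ``direction``)."""
    affected = {}
    for gene_id, row in gene_df.iterrows():
        if row["direction"] == "shortened":
            affected[gene_id] = 1
        elif row["direction"] == "lengthened":
            affected[gene_id] = -1
    return RegulatorProfile(regulator_id, affected)


def pairwise_interaction(a: RegulatorProfile, b: RegulatorProfile,
                         universe: set) -> NetworkEdge:
    """Signed synergy/antagonism edge between two regulators."""
    if not universe:
        raise NetworkError("empty gene universe")
    genes_a, genes_b = set(a.affected), set(b.affected)
    shared = genes_a & genes_b
    pair = tuple(sorted((a.regulator_id, b.regulator_id)))
    if not shared:
        return NetworkEdge(pair, 0, 0.0, 0.0, 1.0)
    concordance = sum(a.affected[g] == b.affected[g] for g in shared) / len(shared)
    weight = len(shared) / min(len(genes_a), len(genes_b))
    p = set_enrichment(genes_a & universe, universe, genes_b & universe)
    return NetworkEdge(pair, len(shared), concordance,
                       (2.0 * concordance - 1.0) * weight, p)


def build_edges(profiles: Sequence[RegulatorProfile], universe: set,
                prune_p: float | None = EDGE_ALPHA,
                prune_shared: int | None = MIN_SHARED) -> list[NetworkEdge]:
    """All pairwise edges; by default edges with p > 0.05 or < 5 shared genes
    are pruned for readability (pass ``None`` to keep everything)."""
    edges = []
    for i, a in enumerate(profiles):
        for b in profiles[i + 1:]:
            e = pairwise_interaction(a, b, universe)
            if prune_p is not None and e.p > prune_p:
                continue
            if prune_shared is not None and e.n_shared < prune_shared:
                continue
            edges.append(e)
    return edges


def layout_force_directed(nodes: Sequence[str], edges: Sequence[NetworkEdge],
                          iterations: int = 500, seed: int = 0,
                          p_cap: float = 10.0) -> dict[str, tuple[float, float]]:
    """Fruchterman–Reingold layout with signed interaction forces.

    Beyond the standard area-based repulsion and edge attraction, synergy
    edges (score > 0) attract with strength score·min(−log10 p, ``p_cap``)
    and antagonism edges (score < 0) add pairwise repulsion of the analogous
    magnitude. Deterministic under a fixed seed.
    """
    n = len(nodes)
    if n == 0:
        return {}
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-1.0, 1.0, size=(n, 2))
    if n == 1:
        return {nodes[0]: tuple(pos[0])}

    index = {v: i for i, v in enumerate(nodes)}
    attract = np.zeros((n, n))
    repel_extra = np.zeros((n, n))
    for e in edges:
        u, v = e.pair
        if u not in index or v not in index:
            continue
        sig = min(-np.log10(max(e.p, 1e-300)), p_cap)
        i, j = index[u], index[v]
        if e.score > 0:
            attract[i, j] = attract[j, i] = e.score * sig
        elif e.score < 0:
            repel_extra[i, j] = repel_extra[j, i] = -e.score * sig

    k = np.sqrt(1.0 / n)  # ideal pairwise distance for unit area
    t = 0.1
    dt = t / (iterations + 1)
    for _ in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, 1e-9)
        # standard FR repulsion k^2/d, plus antagonism-scaled extra repulsion
        rep = (k * k / dist ** 2) * (1.0 + repel_extra)
        # attraction d/k on synergy-weighted edges
        att = dist / k * attract
        coeff = (rep - att) / dist
        np.fill_diagonal(coeff, 0.0)
        disp = (delta * coeff[:, :, None]).sum(axis=1)
        length = np.maximum(np.linalg.norm(disp, axis=1), 1e-9)
        pos += disp / length[:, None] * np.minimum(length, t)[:, None]
        t -= dt
    return {v: (float(pos[i, 0]), float(pos[i, 1])) for v, i in index.items()}


def edges_to_frame(edges: Sequence[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"reg_a": e.pair[0], "reg_b": e.pair[1], "n_shared": e.n_shared,
          "concordance": e.concordance, "score": e.score, "p": e.p}
         for e in edges],
        columns=["reg_a", "reg_b", "n_shared", "concordance", "score", "p"])


def to_networkx(profiles: Sequence[RegulatorProfile], edges: Sequence[NetworkEdge]):
    """Export as a networkx Graph (for GraphML/DOT serialisation)."""
    import networkx as nx

    g = nx.Graph()
    for p in profiles:
        g.add_node(p.regulator_id, n_affected=len(p.affected))
    for e in edges:
        g.add_edge(*e.pair, n_shared=e.n_shared, concordance=e.concordance,
                   score=e.score, p=e.p)
    return g
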