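"""Seeded generators for validation inputs.

Two theoretical endpoint ensembles close the loop on the pipeline:

* GOE matrices, whose unfolded spacings follow the Wigner distribution
  (eigenvalue repulsion);
* sorted uniform levels, which are uncorrelated and whose unfolded
  spacings follow exp(-s).

Graph generators produce Erdos-Renyi, preferential-attachment, and
composite "TCNG-like" gene networks.  The TCNG-like generator emulates
the database this pipeline was designed around: ~8,000 genes,
13,000-64,000 undirected edges, per-edge frequency (inference likelihood)
factors in [0.2, 1.0].  It overlays a scale-free backbone carrying high
frequencies (0.5-1.0) on an Erdos-Renyi noise layer carrying low
frequencies (0.2-0.5): high-likelihood edges concentrate on hubs/modules
while low-likelihood edges look like a random graph.  The backbone holds
~25% of edges in ``sparse`` mode (its top frequency quartile is then
essentially the backbone) and ~5% in ``dense`` mode (every quartile is a
hairball).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .network_io import GeneNetwork

#: edge-frequency range assigned by the upstream Bayesian inference
FREQ_MIN, FREQ_MAX = 0.2, 1.0
#: backbone/noise frequency boundary in the TCNG-like composite
FREQ_SPLIT = 0.5
#: backbone edge fraction by density regime
BACKBONE_FRACTION = {"sparse": 0.25, "dense": 0.05}


def _node_name(i: int) -> str:
    return f"G{i:05d}"


def generate_goe(N: int, seed: int, scale: float = 1.0) -> np.ndarray:
    """Symmetric Gaussian matrix: off-diagonal variance 1, diagonal 2.

    Any overall ``scale`` gives identical unfolded spacing statistics
    (unfolding is affine-invariant).
    """
    if N < 2:
        raise ValueError("GOE matrix needs N >= 2")
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(N, N))
    return scale * (a + a.T) / np.sqrt(2.0)


def generate_poisson_levels(N: int, seed: int) -> np.ndarray:
    """N sorted iid uniform levels on [0, 1] — uncorrelated spectra."""
    if N < 2:
        raise ValueError("need N >= 2 levels")
    rng = np.random.default_rng(seed)
    return np.sort(rng.uniform(0.0, 1.0, size=N))


def _assign_frequencies(
    pairs: list[tuple[str, str]], rng: np.random.Generator,
    low: float = FREQ_MIN, high: float = FREQ_MAX,
) -> dict[tuple[str, str], float]:
    freqs = rng.uniform(low, high, size=len(pairs))
    return {p: float(f) for p, f in zip(pairs, freqs)}


def _from_nx(graph: nx.Graph, rng: np.random.Generator,
             low: float = FREQ_MIN, high: float = FREQ_MAX) -> GeneNetwork:
    pairs = sorted(tuple(sorted((_node_name(u), _node_name(v))))
                   for u, v in graph.edges())
    edges = _assign_frequencies(pairs, rng, low, high)
    nodes = sorted({n for p in edges for n in p})
    return GeneNetwork(nodes=nodes, edges=edges)


def generate_er_graph(n: int, q: float, seed: int) -> GeneNetwork:
    """Erdos-Renyi G(n, q) with uniform edge frequencies on [0.2, 1.0]."""
    if n < 2:
        raise ValueError("need n >= 2 nodes")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"edge probability q={q} outside [0, 1]")
    rng = np.random.default_rng(seed)
    g = nx.fast_gnp_random_graph(n, q, seed=int(rng.integers(2**31)))
    return _from_nx(g, rng)


def generate_scale_free(n: int, m: int, seed: int) -> GeneNetwork:
    """Preferential-attachment (Barabasi-Albert) network, m edges per new node."""
    if m < 1 or n <= m:
        raise ValueError("need n > m >= 1")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    return _from_nx(g, rng)


def generate_tcng_like(
    n_nodes: int, n_edges: int, density: str = "sparse", seed: int = 0
) -> GeneNetwork:
    """Composite gene-network surrogate with exactly ``n_edges`` edges.

    ``density`` is "sparse" or "dense" and sets the backbone proportion
    (see module docstring).  Edge collisions between the backbone and the
    noise layer are topped up with extra random edges so the requested
    edge count is met exactly.
    """
    if density not in BACKBONE_FRACTION:
        raise ValueError("density must be 'sparse' or 'dense'")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges exceed C({n_nodes}, 2) = {max_edges}")
    rng = np.random.default_rng(seed)

    n_backbone = int(round(BACKBONE_FRACTION[density] * n_edges))
    # scale-free backbone: m=1 attachment keeps the quartile mean degree
    # near 2, the band seen in real inferred gene subnetworks
    m = 1
    nb_nodes = min(n_nodes, n_backbone // m + m)
    g = nx.barabasi_albert_graph(nb_nodes, m, seed=int(rng.integers(2**31)))
    backbone_pairs = list(g.edges())[:n_backbone]

    edges: dict[tuple[str, str], float] = {}
    for u, v in backbone_pairs:
        key = tuple(sorted((_node_name(u), _node_name(v))))
        edges[key] = float(rng.uniform(FREQ_SPLIT, FREQ_MAX))

    # ER noise layer at low frequencies; rejection-sample to the exact count
    while len(edges) < n_edges:
        need = n_edges - len(edges)
        us = rng.integers(n_nodes, size=2 * need + 16)
        vs = rng.integers(n_nodes, size=2 * need + 16)
        for u, v in zip(us, vs):
            if u == v:
                continue
            key = tuple(sorted((_node_name(int(u)), _node_name(int(v)))))
            if key in edges:
                continue
            edges[key] = float(rng.uniform(FREQ_MIN, FREQ_SPLIT))
            if len(edges) == n_edges:
                break

    nodes = sorted({n for p in edges for n in p})
    return GeneNetwork(nodes=nodes, edges=edges)
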