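"""Synthetic gold-standard networks and matched expression data.

The generator plants a sparse, acyclic, directed regulator->target network
(edges only run from lower to higher topological rank) and simulates
expression through it as a linear Gaussian system: root genes are standard
normal per sample, every regulated gene is the weighted sum of its parents
plus additive Gaussian noise whose standard deviation is a fixed fraction
(default 10%) of the noiseless signal's standard deviation.  Regulatory
weights are drawn uniformly from [-1, -0.3] u [0.3, 1] so no planted edge is
numerically negligible at small sample sizes.

This linear-Gaussian model is a deliberate stand-in for transcriptional
kinetics: it is exactly the regime the Gaussian MI estimator and the sparse
linear regression assume, which makes planted-structure recovery a clean test
of the inference machinery rather than of model mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GoldStandardNetwork",
    "generate_network",
    "simulate_expression",
    "planted_regulator_case",
    "chain_case",
    "candidate_universe",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-network simulator.

    Attributes
    ----------
    n_genes : int
        Number of genes (>= 2).
    n_regulators : int or None
        How many genes may act as edge sources (the first `n_regulators`
        genes in topological order); None means every gene.
    avg_degree : float
        Target edges-per-gene; expected edge count is
        ``avg_degree * n_genes`` under binomial sampling over the candidate
        (lower-rank regulator, higher-rank target) pairs.
    n_samples : int
        Number of expression samples (columns).
    noise_fraction : float in [0, 1]
        Noise standard deviation as a fraction of each regulated gene's
        noiseless signal standard deviation.
    seed : int
        Seed for all randomness; identical configs give bit-identical output.
    """

    n_genes: int
    n_regulators: int | None = None
    avg_degree: float = 2.0
    n_samples: int = 20
    noise_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        n_reg = self.n_genes if self.n_regulators is None else self.n_regulators
        if not (1 <= n_reg <= self.n_genes):
            raise ValueError("n_regulators must be in [1, n_genes]")
        if self.avg_degree < 0:
            raise ValueError("avg_degree must be nonnegative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not (0.0 <= self.noise_fraction <= 1.0):
            raise ValueError("noise_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GoldStandardNetwork:
    """A known directed regulator->target network with signed edge weights.

    Invariants: no self-edges, every edge source is in `regulators`, and the
    default generator produces an acyclic edge set (feed-forward simulation).
    """

    genes: tuple
    regulators: frozenset
    edges: frozenset  # of (regulator, target) pairs
    weights: dict = field(default_factory=dict)

    def __post_init__(self):
        for r, t in self.edges:
            if r == t:
                raise ValueError(f"self-edge {r}->{t} not allowed")
            if r not in self.regulators:
                raise ValueError(f"edge source {r!r} is not a regulator")
        if set(self.weights) != set(self.edges):
            raise ValueError("weights must cover exactly the edge set")

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        g.add_weighted_edges_from(
            (r, t, self.weights[(r, t)]) for r, t in self.edges
        )
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _draw_weights(rng: np.random.Generator, size: int) -> np.ndarray:
    """Uniform on [-1, -0.3] u [0.3, 1]: magnitude floor keeps edges visible."""
    mag = rng.uniform(0.3, 1.0, size=size)
    sign = rng.choice([-1.0, 1.0], size=size)
    return mag * sign


def generate_network(config: SimulationConfig) -> GoldStandardNetwork:
    """Sample a planted acyclic network under binomial edge sampling.

    Genes are assigned a random topological order; every (regulator, target)
    pair with the regulator at lower rank is a candidate edge and is included
    independently with probability ``avg_degree * n_genes / n_candidates``.

    Raises
    ------
    ValueError
        If `avg_degree` demands more edges than the acyclic candidate-pair
        universe can hold.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = len(str(n))
    names = tuple(f"G{i + 1:0{width}d}" for i in range(n))
    order = rng.permutation(n)  # order[k] = gene index at topological rank k
    ranked = [names[i] for i in order]
    n_reg = n if config.n_regulators is None else config.n_regulators
    regulators = frozenset(ranked[:n_reg])

    candidates = [
        (ranked[i], ranked[j])
        for i in range(min(n_reg, n - 1))
        for j in range(i + 1, n)
    ]
    if config.avg_degree == 0 or not candidates:
        if config.avg_degree * n > 0:
            raise ValueError("no candidate pairs available for requested edges")
        return GoldStandardNetwork(names, regulators, frozenset(), {})

    p = config.avg_degree * n / len(candidates)
    if p > 1.0:
        raise ValueError(
            f"avg_degree {config.avg_degree} needs edge probability {p:.3f} > 1 "
            f"over {len(candidates)} acyclic candidate pairs"
        )
    keep = rng.random(len(candidates)) < p
    edges = tuple(e for e, k in zip(candidates, keep) if k)
    w = _draw_weights(rng, len(edges))
    weights = {e: float(wi) for e, wi in zip(edges, w)}
    return GoldStandardNetwork(names, regulators, frozenset(edges), weights)


def simulate_expression(
    net: GoldStandardNetwork, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate expression through an acyclic network.

    Root genes are i.i.d. standard normal per sample; each regulated gene, in
    topological order, is the weighted sum of its parents' standardized
    profiles plus Gaussian noise with standard deviation
    ``noise_fraction * std(noiseless signal)``.  Parents are standardized
    (realized mean 0, sd 1) before weighting so that every edge contributes
    variance proportional to its squared weight regardless of how deep the
    parent sits in the cascade — without this, chains of sub-unit weights
    shrink a parent's scale geometrically and planted edges deep in the
    graph become numerically negligible, which the weight floor is meant to
    prevent.

    Returns
    -------
    DataFrame, shape (n_genes, n_samples)
        Rows indexed by gene id, columns ``S1..Sm``.

    Raises
    ------
    ValueError
        If the network contains a cycle (one offending cycle is named).
    """
    g = net.to_digraph()
    try:
        topo = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
        raise ValueError(f"network contains a cycle: {path}") from None

    rng = np.random.default_rng(config.seed + 1)  # decoupled from topology draw
    m = config.n_samples
    data = {}
    for gene in topo:
        parents = list(g.predecessors(gene))
        if not parents:
            data[gene] = rng.standard_normal(m)
            continue
        signal = np.zeros(m)
        for p in parents:
            prof = data[p]
            psd = prof.std()
            if psd > 0:
                prof = (prof - prof.mean()) / psd
            signal += net.weights[(p, gene)] * prof
        sd = signal.std()
        noise_sd = config.noise_fraction * sd
        data[gene] = signal + (rng.standard_normal(m) * noise_sd if noise_sd > 0 else 0.0)
    values = np.vstack([data[gene] for gene in net.genes])
    return pd.DataFrame(
        values, index=list(net.genes), columns=[f"S{j + 1}" for j in range(m)]
    )


def planted_regulator_case(
    n_samples: int = 50, noise_fraction: float = 0.10, seed: int = 0
) -> tuple[GoldStandardNetwork, pd.DataFrame]:
    """Canonical planted fixture: one target, 3 direct / 3 indirect / 4 noise regulators.

    The target ``T`` has exactly three true parents ``D1..D3``.  Each indirect
    regulator ``I1..I3`` is the sole parent of one direct regulator, so it
    correlates with the target only through its mediator (zero direct weight
    on the target).  Noise regulators ``N1..N4`` are isolated root genes,
    independent of everything.

    This is a designed schematic, not a random draw: all six weights have
    magnitude 1 with random signs, so the three direct effects contribute
    equally to the target (a mediated gene inherits its mediator's weight as
    its scale, so unequal mediation weights would silently make some direct
    effects undetectable) and every direct regulator is comparably strong, as
    the schematic intends.
    """
    genes = ("T", "D1", "D2", "D3", "I1", "I2", "I3", "N1", "N2", "N3", "N4")
    rng = np.random.default_rng(seed)
    sign = rng.choice([-1.0, 1.0], size=6)
    edges = {
        ("I1", "D1"): sign[0],
        ("I2", "D2"): sign[1],
        ("I3", "D3"): sign[2],
        ("D1", "T"): sign[3],
        ("D2", "T"): sign[4],
        ("D3", "T"): sign[5],
    }
    net = GoldStandardNetwork(
        genes=genes,
        regulators=frozenset(g for g in genes if g != "T"),
        edges=frozenset(edges),
        weights={e: float(v) for e, v in edges.items()},
    )
    cfg = SimulationConfig(
        n_genes=len(genes),
        n_samples=n_samples,
        noise_fraction=noise_fraction,
        seed=seed,
    )
    expr = simulate_expression(net, cfg)
    return net, expr


def chain_case(
    n_samples: int = 50, noise_fraction: float = 0.10, seed: int = 0
) -> tuple[GoldStandardNetwork, pd.DataFrame]:
    """Three-gene chain A->B->C: the A->C association is purely indirect."""
    rng = np.random.default_rng(seed)
    w = _draw_weights(rng, 2)
    edges = {("A", "B"): float(w[0]), ("B", "C"): float(w[1])}
    net = GoldStandardNetwork(
        genes=("A", "B", "C"),
        regulators=frozenset({"A", "B", "C"}),
        edges=frozenset(edges),
        weights=edges,
    )
    cfg = SimulationConfig(
        n_genes=3, n_samples=n_samples, noise_fraction=noise_fraction, seed=seed
    )
    return net, simulate_expression(net, cfg)


def candidate_universe(genes, regulators=None) -> set:
    """Ordered (regulator, target) pairs the evaluation ranges over.

    All ordered non-self pairs by default; restricted to sources in
    `regulators` when a regulator list is given.  The universe is always an
    explicit argument downstream — it is never inferred from a prediction.
    """
    genes = list(genes)
    sources = genes if regulators is None else [g for g in genes if g in set(regulators)]
    return {(r, t) for r in sources for t in genes if r != t}
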