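"""Network robustness under random node loss and efficiency-based vulnerability.

Robustness: remove a fixed fraction of nodes uniformly at random and report
the proportion of surviving nodes that remain connected (degree >= 1 in the
induced subgraph), averaged over replicates. The literal "proportion of
species remaining" after removing 50% of nodes would always be 50%; the
non-isolated-survivor reading follows the robustness literature this index
descends from.

Vulnerability: global efficiency E is the mean inverse shortest-path length
over ordered node pairs (1/inf = 0 for disconnected pairs, normalized by
n(n-1)); node i's vulnerability is the relative efficiency drop
``V_i = (E - E_i) / E`` when i is deleted, and the network's headline value
is the maximum over nodes. Negative values (a removal that raises mean
efficiency) are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedVulnerabilityError, ValidationError
from .network import CoNetwork


@dataclass
class RobustnessResult:
    """Per-replicate robustness values for one network."""

    removal_fraction: float
    values: np.ndarray
    seed: int

    @property
    def replicates(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0


@dataclass
class VulnerabilityReport:
    """Global efficiency and per-node vulnerability."""

    global_efficiency: float
    node_vulnerability: pd.Series  # indexed by node, may contain negatives
    max_vulnerability: float
    max_node: str


def robustness(
    net: CoNetwork | nx.Graph,
    removal_fraction: float = 0.5,
    replicates: int = 100,
    seed: int = 0,
) -> RobustnessResult:
    """Random-removal robustness of a network.

    Per replicate, ``floor(fraction * N)`` nodes are removed uniformly at
    random; robustness is the fraction of survivors with at least one
    remaining neighbor. Values lie in [0, 1].
    """
    g = net.graph if isinstance(net, CoNetwork) else net
    if not 0.0 < removal_fraction < 1.0:
        raise ValidationError("removal_fraction must be in (0, 1)")
    n = g.number_of_nodes()
    if n < 4:
        raise InsufficientDataError("need at least 4 nodes for removal experiments")
    nodes = np.array(list(g.nodes()))
    n_remove = int(np.floor(removal_fraction * n))
    rng = np.random.default_rng(seed)
    vals = np.empty(replicates)
    for r in range(replicates):
        removed = rng.choice(n, size=n_remove, replace=False)
        survivors = np.delete(nodes, removed)
        sub = g.subgraph(survivors)
        degrees = dict(sub.degree())
        connected = sum(1 for d in degrees.values() if d >= 1)
        vals[r] = connected / len(survivors) if len(survivors) else 0.0
    return RobustnessResult(removal_fraction=removal_fraction, values=vals, seed=seed)


def robustness_difference(a: RobustnessResult, b: RobustnessResult) -> dict:
    """Two-sided Welch t-test between two networks' replicate robustness."""
    t, p = stats.ttest_ind(a.values, b.values, equal_var=False)
    return {"t": float(t), "p_value": float(p), "mean_a": a.mean, "mean_b": b.mean}


def global_efficiency(g: nx.Graph) -> float:
    """Mean inverse geodesic over ordered pairs; 0 for disconnected pairs."""
    return float(nx.global_efficiency(g))


def vulnerability(net: CoNetwork | nx.Graph) -> VulnerabilityReport:
    """Per-node vulnerability as relative contribution to global efficiency.

    ``V_i = (E - E_i) / E`` where ``E_i`` is the global efficiency of the
    graph with node i deleted (over the remaining n-1 nodes). The maximum
    over nodes is the network's vulnerability.
    """
    g = net.graph if isinstance(net, CoNetwork) else net
    if g.number_of_nodes() < 3 or g.number_of_edges() < 2:
        raise InsufficientDataError("need >= 3 nodes and >= 2 edges")
    e = global_efficiency(g)
    if e == 0.0:
        raise UndefinedVulnerabilityError("global efficiency is zero")
    vals = {}
    for node in g.nodes():
        h = g.copy()
        h.remove_node(node)
        vals[node] = (e - global_efficiency(h)) / e
    series = pd.Series(vals, name="vulnerability")
    max_node = series.idxmax()
    return VulnerabilityReport(
        global_efficiency=e,
        node_vulnerability=series,
        max_vulnerability=float(series.max()),
        max_node=str(max_node),
    )
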