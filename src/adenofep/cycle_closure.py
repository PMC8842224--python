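"""Cycle-closure correction: from noisy edge ΔΔG to anchored node ΔG.

Raw per-edge estimates on a perturbation network are generally not
cycle-consistent — the signed sum of ΔΔG around a closed cycle
(*hysteresis*) is non-zero.  Node free energies are obtained by weighted
least squares on the graph: minimize

    Σ_e w_e · (ΔG_j − ΔG_i − ΔΔG_e)²,    w_e = 1 / max(sem_e, σ_floor)²

with the gauge fixed by assigning one *anchor* compound its experimental
value.  Re-deriving edge values from the node solution zeroes the
hysteresis on every cycle by construction, which is the cycle-closure
corrected estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .fep_engine import EdgeEstimate
from .fepmap import PerturbationNetwork

__all__ = [
    "NodeEstimates",
    "CycleReport",
    "SIGMA_FLOOR",
    "enumerate_cycles",
    "cycle_hysteresis",
    "solve_node_dg",
    "corrected_edge_values",
    "cycle_report",
]

#: Weight floor (kcal/mol): prevents an edge with zero replicate scatter
#: from acquiring infinite weight in the least-squares system.
SIGMA_FLOOR = 0.05


@dataclass
class NodeEstimates:
    """Absolute per-compound ΔG_bind after cycle closure, gauge-fixed so
    the anchor sits exactly at its experimental value (stderr 0 by
    convention)."""

    dg: dict[str, float]
    stderr: dict[str, float]
    anchor_id: str
    anchor_value: float


def enumerate_cycles(network: PerturbationNetwork) -> list[list[tuple[str, str]]]:
    """Fundamental cycle basis: one cycle per non-tree (closure) edge.

    Each cycle is returned as an ordered list of *directed* edges
    (u, v) meaning traversal u→v; the list closes on itself.
    """
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(network.tree_edges)
    if not nx.is_connected(g):
        raise ValueError("spanning tree does not connect the network")
    cycles = []
    for u, v in sorted(set(network.edges) - set(network.tree_edges)):
        path = nx.shortest_path(g, v, u)  # tree path closes the loop
        walk = [(u, v)] + list(zip(path, path[1:]))
        cycles.append(walk)
    return cycles


def cycle_hysteresis(
    edges_in_cycle: Sequence[tuple[str, str]],
    edge_values: Mapping[tuple[str, str], float],
) -> float:
    """Signed ΔΔG sum around a closed walk.

    ``edge_values`` is keyed by the *stored* (sorted) pair and holds
    ΔΔG oriented low→high id; traversing an edge against that orientation
    contributes with a minus sign.  Raises if the walk is not closed.
    """
    if not edges_in_cycle:
        raise ValueError("empty edge sequence")
    for (u1, v1), (u2, v2) in zip(edges_in_cycle, edges_in_cycle[1:]):
        if v1 != u2:
            raise ValueError(f"walk breaks between ({u1},{v1}) and ({u2},{v2})")
    if edges_in_cycle[-1][1] != edges_in_cycle[0][0]:
        raise ValueError("walk is not closed")
    total = 0.0
    for u, v in edges_in_cycle:
        key = (u, v) if u <= v else (v, u)
        sign = 1.0 if key == (u, v) else -1.0
        total += sign * edge_values[key]
    return total


def _edge_arrays(
    network: PerturbationNetwork,
    edge_estimates: Mapping[tuple[str, str], EdgeEstimate],
    sigma_floor: float,
):
    edges = sorted(network.edges)
    means = np.array([edge_estimates[e].mean for e in edges])
    sems = np.array([max(edge_estimates[e].sem, sigma_floor) for e in edges])
    return edges, means, sems


def solve_node_dg(
    network: PerturbationNetwork,
    edge_estimates: Mapping[tuple[str, str], EdgeEstimate],
    anchor_id: str,
    anchor_value: float,
    sigma_floor: float = SIGMA_FLOOR,
) -> NodeEstimates:
    """Weighted least-squares node free energies anchored at one compound.

    Edge (i, j) (ids sorted) with mean m_e constrains ΔG_j − ΔG_i ≈ m_e
    with weight 1/max(sem_e, σ_floor)².  The anchor's value is imposed
    exactly; node standard errors come from the covariance of the reduced
    weighted normal equations (anchor uncertainty excluded by design, so
    FEP precision stays distinguishable from assay precision).
    """
    if anchor_id not in network.nodes:
        raise ValueError(f"anchor {anchor_id!r} not in network")
    g = network.graph()
    if not nx.is_connected(g):
        raise ValueError("network must be connected")

    nodes = [n for n in network.nodes if n != anchor_id]
    index = {n: k for k, n in enumerate(nodes)}
    edges, means, sems = _edge_arrays(network, edge_estimates, sigma_floor)

    n_e, n_n = len(edges), len(nodes)
    a = np.zeros((n_e, n_n))
    b = means.astype(float).copy()
    for row, (u, v) in enumerate(edges):
        # constraint: dg[v] - dg[u] = mean
        if u == anchor_id:
            b[row] += anchor_value
        else:
            a[row, index[u]] = -1.0
        if v == anchor_id:
            b[row] -= anchor_value
        else:
            a[row, index[v]] = 1.0
    w = 1.0 / sems
    aw = a * w[:, None]
    bw = b * w
    normal = aw.T @ aw
    try:
        cov = np.linalg.inv(normal)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise ValueError("singular normal equations (disconnected network?)") from exc
    x = cov @ (aw.T @ bw)

    dg = {anchor_id: float(anchor_value)}
    err = {anchor_id: 0.0}
    for n, k in index.items():
        dg[n] = float(x[k])
        err[n] = float(np.sqrt(max(cov[k, k], 0.0)))
    return NodeEstimates(dg=dg, stderr=err, anchor_id=anchor_id, anchor_value=anchor_value)


def corrected_edge_values(
    network: PerturbationNetwork,
    node_estimates: NodeEstimates,
    edge_estimates: Mapping[tuple[str, str], EdgeEstimate] | None = None,
) -> dict[tuple[str, str], dict[str, float]]:
    """Cycle-consistent edge ΔΔG re-derived from the node solution.

    For stored edge (i, j): corrected = ΔG_j − ΔG_i.  Residual
    (corrected − raw mean) is included when raw estimates are supplied.
    Every cycle's hysteresis over the corrected values is zero by
    construction.
    """
    out: dict[tuple[str, str], dict[str, float]] = {}
    for e in sorted(network.edges):
        u, v = e
        corrected = node_estimates.dg[v] - node_estimates.dg[u]
        entry = {"corrected": float(corrected)}
        if edge_estimates is not None:
            entry["raw_mean"] = float(edge_estimates[e].mean)
            entry["residual"] = float(corrected - edge_estimates[e].mean)
        out[e] = entry
    return out


@dataclass
class CycleReport:
    """Per-cycle hysteresis before and after cycle-closure correction."""

    cycles: list[list[tuple[str, str]]]
    hysteresis_raw: list[float]
    hysteresis_corrected: list[float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_cycles": len(self.cycles),
                "cycles": [
                    {
                        "edges": [list(e) for e in cyc],
                        "hysteresis_raw": raw,
                        "hysteresis_corrected": cor,
                    }
                    for cyc, raw, cor in zip(
                        self.cycles, self.hysteresis_raw, self.hysteresis_corrected
                    )
                ],
            },
            indent=2,
        )


def cycle_report(
    network: PerturbationNetwork,
    edge_estimates: Mapping[tuple[str, str], EdgeEstimate],
    node_estimates: NodeEstimates,
) -> CycleReport:
    cycles = enumerate_cycles(network)
    raw_vals = {e: edge_estimates[e].mean for e in network.edges}
    corr = corrected_edge_values(network, node_estimates)
    corr_vals = {e: corr[e]["corrected"] for e in network.edges}
    return CycleReport(
        cycles=cycles,
        hysteresis_raw=[cycle_hysteresis(c, raw_vals) for c in cycles],
        hysteresis_corrected=[cycle_hysteresis(c, corr_vals) for c in cycles],
    )


def write_results_csv(
    node_estimates: NodeEstimates,
    dg_exp: Mapping[str, float],
    path: str | Path,
) -> None:
    """`compound_id, dg_pred_kcal, stderr, dg_exp_kcal` results table."""
    with open(path, "w") as fh:
        fh.write("compound_id,dg_pred_kcal,stderr,dg_exp_kcal\n")
        for cid in sorted(node_estimates.dg):
            exp = dg_exp.get(cid)
            exp_s = f"{exp:.4f}" if exp is not None else ""
            fh.write(
                f"{cid},{node_estimates.dg[cid]:.4f},"
                f"{node_estimates.stderr[cid]:.4f},{exp_s}\n"
            )
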