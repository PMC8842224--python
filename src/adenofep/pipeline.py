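"""End-to-end orchestration: dataset → map → synthetic FEP → closure → metrics.

This is the programmatic counterpart of the command-line ``full-run``:
design the perturbation network over the compound selection, simulate
replicate edge estimates under a binding-mode hypothesis, solve the
cycle-closure system anchored on one experimental value, and score the
anchored predictions against experiment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from .cycle_closure import NodeEstimates, cycle_report, solve_node_dg
from .dataset import CompoundTable, Receptor, load_compound_table
from .evaluate import (
    MetricsReport,
    ModelComparison,
    bootstrap_ci,
    compare_binding_modes,
    error_metrics,
)
from .fep_engine import EdgeEstimate, aggregate_replicates
from .fepmap import PerturbationNetwork, design_network
from .synthetic_data import (
    FEP_SELECTION_18,
    SimulationConfig,
    ground_truth_from_ki,
    simulate_edge_replicates,
)

__all__ = ["PipelineConfig", "ModeResult", "default_anchor", "run_mode", "run_both_modes"]

#: Closure-edge default for the 18-compound selection: yields a
#: 28-comparison map (17 tree + 11 closure edges, 11 independent cycles).
DEFAULT_N_CLOSURE = 11


@dataclass
class PipelineConfig:
    """Fully serializable configuration for one pipeline run."""

    selection: tuple[str, ...] = FEP_SELECTION_18
    n_closure_edges: int = DEFAULT_N_CLOSURE
    fingerprint_radius: int = 2
    fingerprint_n_bits: int = 2048
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    anchor_id: str | None = None  # None -> auto (see default_anchor)
    n_boot: int = 1000
    dataset_path: str | None = None  # None -> packaged table

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selection"] = list(self.selection)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def default_anchor(
    table: CompoundTable, selection, network: PerturbationNetwork | None = None
) -> str:
    """Choose the anchor compound for absolute-ΔG gauge fixing.

    Every node's statistical error grows with its effective resistance to
    the anchor in the perturbation map, so when the map is available the
    anchor is the candidate (fitted A1 Ki required) minimizing the mean
    effective resistance to all other nodes — a structurally central
    compound; ties break on the smallest assay SEM, then id.  Without a
    map, the smallest-SEM candidate is used.
    """
    candidates = []
    for cid in selection:
        entry = table.get(cid).affinity(Receptor.A1)
        if entry.is_quantitative:
            candidates.append((cid, entry.sem_nM))
    if not candidates:
        raise ValueError("no selection member has a fitted A1 Ki")
    if network is None:
        return min(candidates, key=lambda c: (c[1], c[0]))[0]

    import numpy as np

    nodes = list(network.nodes)
    idx = {n: k for k, n in enumerate(nodes)}
    lap = np.zeros((len(nodes), len(nodes)))
    for u, v in network.edges:
        i, j = idx[u], idx[v]
        lap[i, i] += 1.0
        lap[j, j] += 1.0
        lap[i, j] -= 1.0
        lap[j, i] -= 1.0
    pinv = np.linalg.pinv(lap)
    diag = np.diag(pinv)
    # mean effective resistance from node a: mean_j (L+_aa + L+_jj - 2 L+_aj)
    mean_res = {n: float(diag[idx[n]] + diag.mean() - 2 * pinv[idx[n]].mean()) for n in nodes}
    return min(candidates, key=lambda c: (mean_res[c[0]], c[1], c[0]))[0]


@dataclass
class ModeResult:
    mode: str
    network: PerturbationNetwork
    truth: dict[str, float]
    edge_estimates: dict[tuple[str, str], EdgeEstimate]
    node_estimates: NodeEstimates
    metrics: MetricsReport

    def scored_ids(self) -> list[str]:
        return [c for c in self.node_estimates.dg if c != self.node_estimates.anchor_id]


def run_mode(
    config: PipelineConfig,
    mode: str,
    table: CompoundTable | None = None,
    network: PerturbationNetwork | None = None,
) -> ModeResult:
    """Run the pipeline under one binding-mode hypothesis.

    The anchor is scored trivially (its prediction equals its experimental
    value by construction), so metrics are computed over the remaining
    compounds only.
    """
    if table is None:
        table = load_compound_table(config.dataset_path)
    selection = table.subset(config.selection)
    if network is None:
        network = design_network(
            {r.compound_id: r.smiles for r in selection},
            n_closure_edges=config.n_closure_edges,
            radius=config.fingerprint_radius,
            n_bits=config.fingerprint_n_bits,
        )
    truth = ground_truth_from_ki(table, config.selection, config.simulation.T_kelvin)
    replicates = simulate_edge_replicates(network, truth, config.simulation, mode)
    estimates = {e: aggregate_replicates(e, vals) for e, vals in replicates.items()}
    anchor = config.anchor_id or default_anchor(table, config.selection, network)
    nodes = solve_node_dg(network, estimates, anchor, truth[anchor])

    scored = [c for c in nodes.dg if c != anchor]
    pred = {c: nodes.dg[c] for c in scored}
    exp = {c: truth[c] for c in scored}
    sems = {c: nodes.stderr[c] for c in scored}
    metrics = error_metrics(pred, exp, sems, binding_mode_label=mode)
    ci = bootstrap_ci(pred, exp, n_boot=config.n_boot, seed=config.simulation.seed)
    metrics.ci_mue = ci["mue"]
    metrics.ci_rmse = ci["rmse"]
    return ModeResult(
        mode=mode,
        network=network,
        truth=truth,
        edge_estimates=estimates,
        node_estimates=nodes,
        metrics=metrics,
    )


def run_both_modes(
    config: PipelineConfig, table: CompoundTable | None = None
) -> tuple[ModeResult, ModeResult, ModelComparison]:
    """Twin runs (same seed, same network) under mode A and mode B, plus
    the binding-mode verdict."""
    if table is None:
        table = load_compound_table(config.dataset_path)
    selection = table.subset(config.selection)
    network = design_network(
        {r.compound_id: r.smiles for r in selection},
        n_closure_edges=config.n_closure_edges,
        radius=config.fingerprint_radius,
        n_bits=config.fingerprint_n_bits,
    )
    res_a = run_mode(config, "A", table=table, network=network)
    res_b = run_mode(config, "B", table=table, network=network)
    comparison = compare_binding_modes(res_a.metrics, res_b.metrics)
    return res_a, res_b, comparison


def mode_result_report(result: ModeResult) -> dict:
    """JSON-ready summary of one mode run, including the cycle report."""
    creport = cycle_report(result.network, result.edge_estimates, result.node_estimates)
    return {
        "mode": result.mode,
        "anchor_id": result.node_estimates.anchor_id,
        "anchor_value_kcal": result.node_estimates.anchor_value,
        "metrics": result.metrics.to_dict(),
        "n_cycles": len(creport.cycles),
        "max_abs_hysteresis_raw": max(map(abs, creport.hysteresis_raw), default=0.0),
        "max_abs_hysteresis_corrected": max(
            map(abs, creport.hysteresis_corrected), default=0.0
        ),
        "node_dg": dict(sorted(result.node_estimates.dg.items())),
        "node_stderr": dict(sorted(result.node_estimates.stderr.items())),
    }
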