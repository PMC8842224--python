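"""Synthetic stand-in for the molecular-dynamics engine.

Running alchemical FEP on a GPCR requires cluster-scale MD; this module
generates statistically faithful surrogates of its outputs so the full
perturbation-network pipeline runs and is testable offline:

* ground-truth per-compound ΔG_bind derived from the experimental Ki;
* per-edge replicate ΔΔG values with a per-edge systematic bias whose
  scale depends on the assumed binding mode (a correctly posed ligand
  gives small bias, a mispose gives large bias) plus per-replicate noise;
* Crooks-consistent Gaussian work samples whose exact free energy is
  known in closed form, for exercising the BAR estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import DEFAULT_TEMPERATURE_K, GAS_CONSTANT_KCAL
from .dataset import CompoundTable, Receptor
from .fep_engine import WindowSamples
from .fepmap import PerturbationNetwork
from .sar import exp_delta_g

__all__ = [
    "SimulationConfig",
    "FEP_SELECTION_18",
    "SURROGATE_DG",
    "ground_truth_from_ki",
    "simulate_edge_replicates",
    "simulate_work_samples",
]

#: The 18-compound N-methyl-amine selection used for the perturbation
#: network study.  19ax carries no fitted A1 Ki and needs a surrogate
#: ground-truth value.
FEP_SELECTION_18 = (
    "19a", "19d", "19j", "19l", "19s", "19v", "19z", "19ab", "19ad",
    "19af", "19aj", "19am", "19ao", "19at", "19ax", "19az", "19bb", "19bd",
)

#: Surrogate ΔG_bind (kcal/mol) for compounds whose Ki was not measurable
#: at 1 μM: slightly weaker than the ΔG of the measurability bound.
SURROGATE_DG = {"19ax": -8.3}


@dataclass(frozen=True)
class SimulationConfig:
    """Noise model for the synthetic FEP engine.

    ``sigma_rep`` is the per-replicate random scatter; ``tau_mode_a`` /
    ``tau_mode_b`` are the scales of the per-edge *systematic* bias under
    the two binding-mode hypotheses (mode A: correctly posed ligand, small
    bias; mode B: misposed, large bias).  All in kcal/mol.
    """

    sigma_rep: float = 0.4
    tau_mode_a: float = 0.3
    tau_mode_b: float = 1.5
    n_replicates: int = 10
    T_kelvin: float = DEFAULT_TEMPERATURE_K
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_rep, self.tau_mode_a, self.tau_mode_b) < 0:
            raise ValueError("noise scales must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def tau(self, mode: str) -> float:
        mode = mode.upper()
        if mode == "A":
            return self.tau_mode_a
        if mode == "B":
            return self.tau_mode_b
        raise ValueError(f"binding mode must be 'A' or 'B', got {mode!r}")


def ground_truth_from_ki(
    table: CompoundTable,
    compound_ids: Sequence[str] = FEP_SELECTION_18,
    T_kelvin: float = DEFAULT_TEMPERATURE_K,
    surrogates: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Per-compound ground-truth ΔG_bind (kcal/mol) from experimental Ki.

    Compounds without a fitted A1 Ki must appear in ``surrogates``
    (default: the shipped :data:`SURROGATE_DG`); unknown ids raise.
    """
    if surrogates is None:
        surrogates = SURROGATE_DG
    truth: dict[str, float] = {}
    for cid in compound_ids:
        rec = table.get(cid)  # KeyError for unknown ids
        entry = rec.affinity(Receptor.A1)
        if entry.is_quantitative:
            truth[cid] = exp_delta_g(entry.ki_nM, T_kelvin)
        elif cid in surrogates:
            truth[cid] = float(surrogates[cid])
        else:
            raise ValueError(
                f"{cid}: no fitted A1 Ki and no surrogate ΔG supplied"
            )
    return truth


def simulate_edge_replicates(
    network: PerturbationNetwork,
    truth: Mapping[str, float],
    config: SimulationConfig,
    mode: str = "A",
) -> dict[tuple[str, str], list[float]]:
    """Replicate ΔΔG sets for every network edge under one binding mode.

    For stored edge (i, j) (ids sorted), replicate r is

        ΔΔG_r = (ΔG_j − ΔG_i) + b_e + ε_r

    with edge bias b_e ~ N(0, τ_mode²) drawn once per edge and replicate
    noise ε_r ~ N(0, σ_rep²).  Reproducible for a fixed config seed.
    """
    missing = [n for n in network.nodes if n not in truth]
    if missing:
        raise ValueError(f"truth missing for node(s): {missing}")
    tau = config.tau(mode)
    rng = np.random.default_rng(config.seed)
    out: dict[tuple[str, str], list[float]] = {}
    for u, v in sorted(network.edges):
        exact = truth[v] - truth[u]
        bias = rng.normal(0.0, tau) if tau > 0 else 0.0
        eps = (
            rng.normal(0.0, config.sigma_rep, size=config.n_replicates)
            if config.sigma_rep > 0
            else np.zeros(config.n_replicates)
        )
        out[(u, v)] = [float(exact + bias + e) for e in eps]
    return out


def simulate_work_samples(
    dg_true: float,
    sigma_w: float,
    n_samples: int,
    T_kelvin: float = DEFAULT_TEMPERATURE_K,
    seed: int = 0,
) -> WindowSamples:
    """Gaussian work samples satisfying the Crooks fluctuation relation.

    Forward work ~ N(ΔG + σ_w²/2RT, σ_w²) and reverse work
    ~ N(−ΔG + σ_w²/2RT, σ_w²): the unique Gaussian pair of equal width
    whose Crooks-consistent free energy is exactly ``dg_true``, so BAR has
    a known closed-form target (μ_F − σ_w²/2RT).
    """
    if sigma_w < 0:
        raise ValueError("sigma_w must be >= 0")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rt = GAS_CONSTANT_KCAL * T_kelvin
    dissipation = sigma_w**2 / (2.0 * rt)
    rng = np.random.default_rng(seed)
    wf = rng.normal(dg_true + dissipation, sigma_w, size=n_samples)
    wr = rng.normal(-dg_true + dissipation, sigma_w, size=n_samples)
    if sigma_w == 0:
        wf = np.full(n_samples, dg_true)
        wr = np.full(n_samples, -dg_true)
    return WindowSamples(w_forward=wf, w_reverse=wr, T_kelvin=T_kelvin)


def write_edge_replicates_csv(
    replicates: Mapping[tuple[str, str], Sequence[float]], path
) -> None:
    """Columnar edge-replicate file: node_i,node_j,replicate,ddg_kcal."""
    with open(path, "w") as fh:
        fh.write("node_i,node_j,replicate,ddg_kcal\n")
        for (u, v), vals in sorted(replicates.items()):
            for r, val in enumerate(vals):
                fh.write(f"{u},{v},{r},{val:.6f}\n")


def read_edge_replicates_csv(path) -> dict[tuple[str, str], list[float]]:
    import csv as _csv

    out: dict[tuple[str, str], list[float]] = {}
    with open(path) as fh:
        for row in _csv.DictReader(fh):
            key = tuple(sorted((row["node_i"], row["node_j"])))
            out.setdefault(key, []).append(float(row["ddg_kcal"]))
    return out
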