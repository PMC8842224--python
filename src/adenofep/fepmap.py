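"""Similarity-driven design of the alchemical perturbation network.

Ligands are nodes; each edge is one relative free energy (FEP) pair
comparison.  The map is built from Morgan-fingerprint Tanimoto similarity:
a maximum-similarity spanning tree connects every compound with the
cheapest (most similar, hence best-converging) transformations, and a
configurable number of closure edges is then added greedily so that
estimates can be checked and corrected for cycle consistency.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "Fingerprint",
    "PerturbationNetwork",
    "circular_fingerprint",
    "tanimoto",
    "design_network",
    "validate_network",
    "write_edge_csv",
    "read_edge_csv",
]

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length circular (Morgan) substructure fingerprint."""

    bits: frozenset[int]
    radius: int
    n_bits: int

    @property
    def popcount(self) -> int:
        return len(self.bits)


def circular_fingerprint(
    smiles: str, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS
) -> Fingerprint:
    """Morgan fingerprint of a structure given as SMILES.

    Deterministic: isomorphic molecules (any atom ordering) give identical
    bit sets because RDKit canonicalizes the perceived molecule.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 1 or (n_bits & (n_bits - 1)) != 0:
        raise ValueError(f"n_bits must be a power of two, got {n_bits}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable structure: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(
        bits=frozenset(bv.GetOnBits()), radius=radius, n_bits=n_bits
    )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity of two equal-length fingerprints."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} != {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0  # two empty molecules are (vacuously) identical
    return len(a.bits & b.bits) / union


@dataclass
class PerturbationNetwork:
    """Compounds as nodes, FEP pair comparisons as similarity-weighted edges.

    ``edges`` maps the unordered pair (stored as a sorted tuple) to its
    Tanimoto similarity; ``tree_edges`` is the spanning-tree subset.
    """

    nodes: list[str]
    smiles: Mapping[str, str]
    edges: dict[tuple[str, str], float]
    tree_edges: set[tuple[str, str]]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), sim in self.edges.items():
            g.add_edge(u, v, similarity=sim, edge_type="tree" if (u, v) in self.tree_edges else "closure")
        return g

    @property
    def n_cycles(self) -> int:
        return len(self.edges) - len(self.nodes) + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": self.nodes,
                "smiles": dict(self.smiles),
                "edges": [
                    {
                        "node_i": u,
                        "node_j": v,
                        "similarity": sim,
                        "edge_type": "tree" if (u, v) in self.tree_edges else "closure",
                    }
                    for (u, v), sim in sorted(self.edges.items())
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PerturbationNetwork":
        obj = json.loads(text)
        edges = {}
        tree = set()
        for e in obj["edges"]:
            key = tuple(sorted((e["node_i"], e["node_j"])))
            edges[key] = float(e["similarity"])
            if e["edge_type"] == "tree":
                tree.add(key)
        return cls(
            nodes=list(obj["nodes"]),
            smiles=obj.get("smiles", {}),
            edges=edges,
            tree_edges=tree,
        )


def _pair(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def design_network(
    compounds: Mapping[str, str] | Sequence[tuple[str, str]],
    n_closure_edges: int = 0,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> PerturbationNetwork:
    """Design a perturbation map over ``compounds`` ({id: smiles}).

    The backbone is the maximum-similarity spanning tree.  Closure edges
    are then added one at a time: among candidate non-tree pairs, edges
    whose induced cycle would place at least one currently cycle-free node
    onto a cycle take priority; within a priority class the
    highest-similarity pair wins, with ties broken lexicographically on
    (min id, max id).  The procedure is fully deterministic and invariant
    to input ordering.
    """
    comp = dict(compounds)
    ids = sorted(comp)
    if len(ids) < 2:
        raise ValueError("need at least 2 compounds to build a network")
    n_pairs = len(ids) * (len(ids) - 1) // 2
    max_closure = n_pairs - (len(ids) - 1)
    if n_closure_edges < 0 or n_closure_edges > max_closure:
        raise ValueError(
            f"n_closure_edges must be in [0, {max_closure}], got {n_closure_edges}"
        )

    fps = {i: circular_fingerprint(comp[i], radius, n_bits) for i in ids}
    sims = {
        _pair(a, b): tanimoto(fps[a], fps[b])
        for k, a in enumerate(ids)
        for b in ids[k + 1 :]
    }

    # Kruskal maximum spanning tree with a deterministic tie-break.
    order = sorted(sims.items(), key=lambda kv: (-kv[1], kv[0]))
    uf = {i: i for i in ids}

    def find(x: str) -> str:
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    tree: set[tuple[str, str]] = set()
    for (u, v), _ in order:
        ru, rv = find(u), find(v)
        if ru != rv:
            uf[ru] = rv
            tree.add((u, v))
        if len(tree) == len(ids) - 1:
            break

    edges = {e: sims[e] for e in tree}
    g = nx.Graph(list(tree))

    def uncovered_nodes() -> set[str]:
        on_cycle: set[str] = set()
        for cyc in nx.cycle_basis(g):
            on_cycle.update(cyc)
        return set(ids) - on_cycle

    for _ in range(n_closure_edges):
        uncov = uncovered_nodes()
        candidates = [p for p in sims if p not in edges]
        prioritized = []
        if uncov:
            for u, v in candidates:
                # the induced cycle is the tree/graph path between u and v
                # plus the new edge; it covers every node on that path
                path = nx.shortest_path(g, u, v)
                if uncov.intersection(path):
                    prioritized.append((u, v))
        pool = prioritized or candidates
        best = min(pool, key=lambda p: (-sims[p], p))
        edges[best] = sims[best]
        g.add_edge(*best)

    if len(ids) == 2:
        warnings.warn(
            "a 2-compound network cannot contain any cycle; "
            "cycle-closure diagnostics will be empty",
            stacklevel=2,
        )

    return PerturbationNetwork(
        nodes=ids, smiles=comp, edges=edges, tree_edges=tree
    )


def validate_network(
    network: PerturbationNetwork, require_full_cycle_coverage: bool = False
) -> dict:
    """Connectivity / cycle-coverage diagnostics for a designed map."""
    g = network.graph()
    connected = nx.is_connected(g) if len(g) else False
    on_cycle: set[str] = set()
    for cyc in nx.cycle_basis(g):
        on_cycle.update(cyc)
    uncovered = sorted(set(network.nodes) - on_cycle)
    diag = {
        "n_nodes": len(network.nodes),
        "n_edges": len(network.edges),
        "connected": connected,
        "n_independent_cycles": network.n_cycles if connected else None,
        "nodes_not_on_any_cycle": uncovered,
        "full_cycle_coverage": not uncovered,
    }
    if require_full_cycle_coverage and uncovered:
        warnings.warn(
            f"{len(uncovered)} node(s) not covered by any cycle: {uncovered}",
            stacklevel=2,
        )
    return diag


def write_edge_csv(network: PerturbationNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_i,node_j,similarity,edge_type\n")
        for (u, v), sim in sorted(network.edges.items()):
            etype = "tree" if (u, v) in network.tree_edges else "closure"
            fh.write(f"{u},{v},{sim:.6f},{etype}\n")


def read_edge_csv(path: str | Path, nodes: Iterable[str] | None = None) -> PerturbationNetwork:
    import csv as _csv

    edges: dict[tuple[str, str], float] = {}
    tree: set[tuple[str, str]] = set()
    with open(path) as fh:
        for row in _csv.DictReader(fh):
            key = _pair(row["node_i"], row["node_j"])
            edges[key] = float(row["similarity"])
            if row["edge_type"] == "tree":
                tree.add(key)
    node_list = sorted(nodes) if nodes is not None else sorted(
        {n for e in edges for n in e}
    )
    return PerturbationNetwork(nodes=node_list, smiles={}, edges=edges, tree_edges=tree)
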