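"""Instrument-convergence networks built from the pairwise RV matrix.

Instruments are nodes; an undirected edge joins two instruments whose RV
coefficient meets the cutoff.  Node attributes follow the conventional
Cytoscape rendering of such networks: feature count (node size), degree
(node colour) and technology/ion mode (node shape).  The automatic cutoff
reproduces the published policy: the highest threshold that still keeps the
required number of nodes connected, i.e. the sparsest network including
(almost) all instruments.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .blocks import Block, BlockSet
from .errors import ConfigError, DomainError
from .rv import RVMatrix


def _block_info(
    blocks: BlockSet | Sequence[Block] | Mapping[str, Mapping] | None,
) -> dict[str, dict]:
    if blocks is None:
        return {}
    if isinstance(blocks, Mapping):
        return {k: dict(v) for k, v in blocks.items()}
    items = blocks.blocks if isinstance(blocks, BlockSet) else blocks
    return {
        b.instrument_id: {
            "technology": b.technology,
            "ion_mode": b.ion_mode,
            "feature_count": b.n_features,
        }
        for b in items
    }


def build_rv_network(
    rvm: RVMatrix,
    cutoff: float,
    blocks: BlockSet | Sequence[Block] | Mapping[str, Mapping] | None = None,
) -> nx.Graph:
    """Build the convergence graph: edge (i, j) iff ``RV_ij >= cutoff``.

    Isolated instruments are kept as degree-0 nodes.  ``blocks`` (a block
    set, block list or ``{id: {attribute: value}}`` mapping) supplies the
    technology / ion-mode / feature-count node attributes.
    """
    if not 0 <= cutoff <= 1:
        raise ConfigError(f"cutoff must lie in [0, 1], got {cutoff}")
    info = _block_info(blocks)
    graph = nx.Graph(cutoff=float(cutoff), rv_variant=rvm.variant)
    for b in rvm.block_ids:
        graph.add_node(b, **info.get(b, {}))
    for a, b, value in rvm.offdiag_pairs():
        if value >= cutoff:
            graph.add_edge(a, b, rv=float(value))
    for node, degree in graph.degree():
        graph.nodes[node]["degree"] = int(degree)
    return graph


def auto_cutoff(rvm: RVMatrix, allowed_isolated: int = 0) -> float:
    """Largest observed RV cutoff leaving at most ``allowed_isolated`` nodes
    isolated.

    Candidate thresholds are restricted to the observed off-diagonal RV
    values (finite, deterministic search), and the returned value maximizes
    sparsity subject to the inclusion constraint: at the next larger
    observed value the constraint is violated.
    """
    if allowed_isolated < 0:
        raise ConfigError("allowed_isolated must be >= 0")
    k = len(rvm.block_ids)
    if k < 2:
        raise ConfigError("auto_cutoff needs at least 2 blocks")
    V = rvm.values
    off = ~np.eye(k, dtype=bool)
    candidates = np.unique(V[off])[::-1]
    for c in candidates:
        isolated = [
            rvm.block_ids[i] for i in range(k) if not (V[i, off[i]] >= c).any()
        ]
        if len(isolated) <= allowed_isolated:
            return float(c)
    raise DomainError(  # only reachable with pathological (e.g. NaN) inputs
        f"no cutoff satisfies the constraint; unavoidable isolates at the "
        f"lowest observed value: {isolated}"
    )


def export_network(
    graph: nx.Graph,
    outdir: str | Path,
    basename: str = "network",
    formats: Sequence[str] = ("graphml", "sif", "nodes"),
) -> dict[str, Path]:
    """Write Cytoscape-loadable files: GraphML, SIF and a node-attribute CSV.

    The SIF has one ``a rv b`` line per edge plus a lone line per isolated
    node, so every node is represented.  Re-reading the GraphML reconstructs
    an identical graph (see :func:`read_network_graphml`).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if "graphml" in formats:
        p = outdir / f"{basename}.graphml"
        nx.write_graphml(graph, p)
        paths["graphml"] = p
    if "sif" in formats:
        p = outdir / f"{basename}.sif"
        lines = [f"{a}\trv\t{b}" for a, b in graph.edges()]
        lines += [str(n) for n in graph.nodes() if graph.degree(n) == 0]
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        paths["sif"] = p
    if "nodes" in formats:
        p = outdir / f"{basename}_nodes.csv"
        rows = [{"id": n, **attrs} for n, attrs in graph.nodes(data=True)]
        pd.DataFrame(rows).to_csv(p, index=False, float_format="%.10g")
        paths["nodes"] = p
    return paths


def read_network_graphml(path: str | Path) -> nx.Graph:
    """Read a GraphML export back; attribute types are preserved by GraphML."""
    return nx.read_graphml(path)
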