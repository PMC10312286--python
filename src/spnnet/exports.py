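"""Writers for tabular reports and BrainNet Viewer exchange files.

The ``.edge`` format is a whitespace-delimited N x N weight matrix; the
``.node`` format has one row per node: x, y, z, color, size, label.
Both are plain text and bit-compatible with the viewer's parser.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .community import Partition
from .connectivity import ConnectivityMatrix
from .hubs import NodeProfile
from .io import AtlasTable
from .metrics import NodeMetrics
from .network import WeightedGraph

_CATEGORY_SIZE = {"connector_hub": 4, "provincial_hub": 3, "high_influence": 2, "normal": 1}


def write_matrix_tsv(cm: ConnectivityMatrix | WeightedGraph, path: str | Path) -> None:
    """N x N weight matrix as TSV with node ids as header."""
    pd.DataFrame(cm.weights, columns=list(cm.node_ids)).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def write_edge_file(weights: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(weights), fmt="%.10g", delimiter=" ")


def write_node_file(
    atlas: AtlasTable,
    path: str | Path,
    colors: dict[str, int] | None = None,
    sizes: dict[str, float] | None = None,
) -> None:
    lines = []
    for node_id, label, _hemi, x, y, z in atlas.nodes:
        color = (colors or {}).get(node_id, 1)
        size = (sizes or {}).get(node_id, 1)
        lines.append(f"{x:g} {y:g} {z:g} {color:g} {size:g} {label}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_graph_bundle(g: WeightedGraph, stem: str | Path) -> None:
    """Thresholded graph as .edge file plus a JSON provenance sidecar."""
    stem = Path(stem)
    write_edge_file(g.weights, stem.with_suffix(".edge"))
    stem.with_suffix(".json").write_text(
        json.dumps({"n_nodes": g.n_nodes, "density": g.density,
                    **{k: v for k, v in g.provenance.items()}}, indent=2, default=str)
    )


def write_partition_tsv(p: Partition, path: str | Path) -> None:
    pd.DataFrame({"node_id": p.node_ids, "module": p.labels}).to_csv(
        path, sep="\t", index=False
    )


def write_node_metrics_tsv(nm: NodeMetrics, path: str | Path) -> None:
    pd.DataFrame({"node_id": nm.node_ids, **{k: v for k, v in nm.as_dict().items()}}
                 ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_profiles_tsv(profiles: list[NodeProfile], path: str | Path) -> None:
    pd.DataFrame([p.__dict__ for p in profiles]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def brainnet_exports(
    atlas: AtlasTable,
    g: WeightedGraph,
    partition: Partition,
    profiles: list[NodeProfile],
    stem: str | Path,
) -> None:
    """Paired .node/.edge files: color = module, size = category rank."""
    colors = {n: int(m) + 1 for n, m in partition.as_dict().items()}
    sizes = {p.node_id: _CATEGORY_SIZE[p.category] for p in profiles}
    stem = Path(stem)
    write_node_file(atlas, stem.with_suffix(".node"), colors=colors, sizes=sizes)
    write_edge_file(g.weights, stem.with_suffix(".edge"))
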