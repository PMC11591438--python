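"""Output writers: legacy-ASCII VTK fields, CSV profiles, JSON reports.

The VTK writer emits an unstructured grid of the Q1 mesh with point data
(velocity, pressure, optionally concentration) — the legacy ASCII format is
read by ParaView/VisIt and needs no third-party dependency.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def write_vtk(mesh, path, point_data: dict | None = None,
              comment: str = "microtrench field export") -> None:
    """Write the quad mesh and nodal fields as legacy VTK (ASCII).

    ``point_data`` maps names to per-Q1-node arrays, scalar (n,) or
    vector (n, 2) (padded to 3D).
    """
    nodes, quads = mesh.nodes, mesh.quads
    lines = ["# vtk DataFile Version 3.0", comment[:255], "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(nodes)} double"]
    for x, y in nodes:
        lines.append(f"{x:.10e} {y:.10e} 0.0")
    lines.append(f"CELLS {len(quads)} {len(quads) * 5}")
    for q in quads:
        lines.append("4 " + " ".join(str(int(i)) for i in q))
    lines.append(f"CELL_TYPES {len(quads)}")
    lines.extend(["9"] * len(quads))       # VTK_QUAD
    if point_data:
        lines.append(f"POINT_DATA {len(nodes)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.10e}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.10e} {v[1]:.10e} 0.0" for v in arr)
    Path(path).write_text("\n".join(lines) + "\n")


def export_flow_vtk(flow, path) -> None:
    """Velocity (restricted to mesh corner nodes) + pressure point data."""
    n1 = flow.mesh.n_nodes
    write_vtk(flow.mesh, path, {
        "velocity": flow.velocity[:n1],
        "pressure": flow.pressure,
    })


def export_wss_csv(wss, path) -> None:
    wss.to_dataframe().to_csv(path, index=False)


def export_residuals_csv(flow, path) -> None:
    import pandas as pd
    pd.DataFrame(flow.residual_history).to_csv(path, index=False)


def write_report(path, payload: dict, cfg=None) -> None:
    """JSON report stamped with software version and config hash."""
    from . import __version__
    from .config import config_hash
    meta = {"software": f"microtrench {__version__}"}
    if cfg is not None:
        meta["config_hash"] = config_hash(cfg)
    Path(path).write_text(json.dumps({"meta": meta, **payload}, indent=2,
                                     sort_keys=True) + "\n")
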