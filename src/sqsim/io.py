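"""CSV/TSV/JSON input and output for configurations and analysis results."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .analysis import OccupancyResult, RDFResult
from .engine import Configuration

__all__ = [
    "configurations_to_frame",
    "frame_to_configurations",
    "write_configurations_csv",
    "read_configurations_csv",
    "write_run_metadata",
    "write_rdf_tsv",
    "write_occupancy_tsv",
    "write_xyz",
]


def configurations_to_frame(configs: Iterable[Configuration]) -> pd.DataFrame:
    rows = []
    for k, c in enumerate(configs):
        rows.append(
            pd.DataFrame(
                {
                    "realization": k,
                    "particle_index": np.arange(c.n),
                    "x": c.positions[:, 0],
                    "y": c.positions[:, 1],
                    "region": c.region_labels,
                    "final_energy": c.energies,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_configurations(df: pd.DataFrame) -> list[Configuration]:
    """Rebuild configurations from a table with at least x and y columns.

    ``realization`` groups rows into configurations (a single configuration
    is assumed when absent); ``region`` and ``final_energy`` are optional,
    which lets external CSV point sets flow into the analysis stage.
    """
    if "x" not in df.columns or "y" not in df.columns:
        raise ValueError("configuration table needs 'x' and 'y' columns")
    if "realization" not in df.columns:
        df = df.assign(realization=0)
    configs = []
    for _, grp in df.groupby("realization", sort=True):
        if "particle_index" in grp.columns:
            grp = grp.sort_values("particle_index")
        n = len(grp)
        configs.append(
            Configuration(
                positions=grp[["x", "y"]].to_numpy(dtype=float),
                region_labels=(
                    grp["region"].astype(str).to_numpy()
                    if "region" in grp.columns
                    else np.full(n, "", dtype=object).astype(str)
                ),
                energies=(
                    grp["final_energy"].to_numpy(dtype=float)
                    if "final_energy" in grp.columns
                    else np.full(n, np.nan)
                ),
                seed=0,
            )
        )
    return configs


def write_configurations_csv(path, configs: Iterable[Configuration]) -> None:
    configurations_to_frame(configs).to_csv(path, index=False)


def read_configurations_csv(path) -> list[Configuration]:
    return frame_to_configurations(pd.read_csv(path))


def write_run_metadata(path, metadata: Mapping) -> None:
    """JSON sidecar with every parameter, the seed and the code version."""
    from . import __version__

    payload = dict(metadata)
    payload.setdefault("sqsim_version", __version__)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _comment_header(params: Mapping) -> str:
    return "".join(f"# {k} = {v}\n" for k, v in params.items())


def write_rdf_tsv(path, rdf: RDFResult) -> None:
    header = _comment_header(
        {
            "dr": rdf.dr,
            "n_particles": rdf.n_particles,
            "n_configs": rdf.n_configs,
            "density": rdf.density,
            "mode": rdf.mode,
        }
    )
    df = pd.DataFrame(
        {
            "r_lower": rdf.bin_edges[:-1],
            "r_center": rdf.bin_centers,
            "pair_count": rdf.pair_counts,
            "g": rdf.g,
            "stderr": rdf.stderr,
        }
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def write_occupancy_tsv(path, occ: OccupancyResult, params: Mapping | None = None) -> None:
    df = pd.DataFrame(
        {
            "region": list(occ.labels),
            "mean_fraction": occ.mean_fractions,
            "stderr": occ.stderr,
            "area_fraction": occ.area_fractions,
        }
    )
    with open(path, "w") as fh:
        if params:
            fh.write(_comment_header(params))
        df.to_csv(fh, sep="\t", index=False)


def write_xyz(path, configs: Iterable[Configuration], comment: str = "") -> None:
    """Extended-XYZ export (z = 0) for visualization tools."""
    with open(path, "w") as fh:
        for k, c in enumerate(configs):
            fh.write(f"{c.n}\n")
            fh.write(f"realization={k} {comment}\n".strip() + "\n")
            for (x, y), lab in zip(c.positions, c.region_labels):
                fh.write(f"{lab or 'P'} {x:.10f} {y:.10f} 0.0\n")
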