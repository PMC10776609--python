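"""Result serialization: CSD tables, compartment states, summaries, metadata.

All numeric output is deterministic for a given configuration: files are
written with fixed float formatting so re-running an identical config
yields byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import pbe
from . import reactor as rx
from .config import RunConfig, config_to_dict

__all__ = ["write_results", "write_sweep", "echo_config"]

_FLOAT_FMT = "%.12e"


def echo_config(cfg: RunConfig, outdir: str | Path) -> Path:
    """Write the fully-resolved configuration next to the results."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "config_echo.yaml"
    path.write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
    return path


def _csd_frame(net: rx.Network, f: np.ndarray) -> pd.DataFrame:
    f = np.clip(f, 0.0, None)
    f_w = pbe.number_to_mass(f, net.grid, net.constants.rho_crystal,
                             net.constants.k_v)
    return pd.DataFrame({
        "class_index": np.arange(net.grid.n),
        "r_lo_m": net.grid.r_faces[:-1],
        "r_hi_m": net.grid.r_faces[1:],
        "f_number_per_m4": f,
        "f_w_kg_per_m3": f_w,
    })


def write_results(result: rx.ReactorResult, outdir: str | Path,
                  cfg: RunConfig | None = None) -> dict[str, Path]:
    """Write outlet CSD, per-compartment state table and summary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = result.network
    Y = result.Y
    paths: dict[str, Path] = {}

    csd = _csd_frame(net, Y[net.outlet_comp, net.f_slice])
    paths["outlet_csd"] = outdir / "outlet_csd.csv"
    csd.to_csv(paths["outlet_csd"], index=False, float_format=_FLOAT_FMT)

    S, B, G = rx._kinetics_of_state(net, Y)
    comp = pd.DataFrame({
        "compartment": np.arange(net.nc),
        "volume_m3": net.volumes,
        "eps_over_k_per_s": net.eps_over_k,
        "P1": Y[:, 0], "P2": Y[:, 1], "P3": Y[:, 2],
        "xi3_weighted": Y[:, 3],
        "solute_kg_m3": Y[:, 4], "methanol_kg_m3": Y[:, 5],
        "water_kg_m3": Y[:, 6],
        "T_K": Y[:, net.i_T],
        "supersaturation": S, "nucleation_per_m3_s": B, "growth_m_s": G,
    })
    paths["compartments"] = outdir / "compartments.csv"
    comp.to_csv(paths["compartments"], index=False, float_format=_FLOAT_FMT)

    summary = rx.outlet_summary(result).as_dict()
    summary.update(rx.flow_audit(result))
    summary["residence_time_s"] = net.residence_time
    summary["template"] = net.template
    paths["summary"] = outdir / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True,
                                           default=float))

    meta = {
        "jetcryst_version": __version__,
        "python": platform.python_version(),
        "converged": result.converged,
        "steady_residual": result.steady_residual,
        "n_chunks": int(len(result.times) - 1),
    }
    if cfg is not None:
        meta["config"] = config_to_dict(cfg)
        echo_config(cfg, outdir)
    paths["metadata"] = outdir / "run_metadata.json"
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True,
                                            default=float))
    return paths


def write_sweep(table: pd.DataFrame, outdir: str | Path,
                name: str = "sweep") -> Path:
    """Write a parameter-sweep summary table (header-only when empty)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{name}.csv"
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path
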