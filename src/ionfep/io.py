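"""Configuration files, XYZ snapshots, and tabular output.

Formats: TOML for run configuration and shipped parameter/reference data,
XYZ for configuration snapshots (the comment line carries the box length),
TSV with a ``#``-prefixed provenance header for tables, JSON for machine
results.  A run is reproducible from config + seed alone.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .analysis import ReferenceConstants
from .forcefield import Configuration, CutoffScheme, WaterModel, load_water_model

__all__ = [
    "RunConfig",
    "load_run_config",
    "dump_run_config",
    "write_xyz",
    "read_xyz",
    "load_reference_constants",
    "load_water_state",
    "interp_state",
    "write_tsv",
    "write_json",
]

_SITE_NAMES = ("O", "H", "H", "M")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run, serializable to TOML."""

    ion: str = "K"
    water_model: str = "tip4p"
    temperature: float = 298.15
    pressure: float = 1.0
    n_waters: int = 64
    r_iw: float = 11.5
    r_ww: float = 11.5
    n_charge_windows: int = 10
    n_lj_windows: int = 5
    n_equil: int = 20_000
    n_avg: int = 100_000
    block_trials: int = 10_000
    stride: int = 20
    seed: int = 1
    cavity_radius: float = 13.2
    cavity_points: int = 1000
    reference_file: str = ""

    def cutoffs(self) -> CutoffScheme:
        return CutoffScheme(r_iw=self.r_iw, r_ww=self.r_ww)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return RunConfig(**data)


def dump_run_config(config: RunConfig, path: str | Path) -> None:
    lines = []
    for key, value in asdict(config).items():
        if isinstance(value, str):
            lines.append(f'{key} = "{value}"')
        elif isinstance(value, bool):
            lines.append(f"{key} = {str(value).lower()}")
        else:
            lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# XYZ snapshots
# --------------------------------------------------------------------------

def write_xyz(config: Configuration, path: str | Path) -> None:
    """All water sites (O, H, H, M per molecule); comment line = box length."""
    lines = [str(4 * config.n_waters), f"box_length= {config.box_length:.10f}"]
    for mol in config.sites:
        for name, xyz in zip(_SITE_NAMES, mol):
            lines.append(f"{name} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path, model: WaterModel | None = None) -> Configuration:
    """Rebuild a configuration from an XYZ snapshot.

    Rigid-body orientations are recovered by aligning each molecule's sites
    to the model's reference geometry (orthogonal Procrustes), so a
    write/read round trip preserves site coordinates to well below 1e-6 A.
    """
    if model is None:
        model = load_water_model()
    text = Path(path).read_text().strip().splitlines()
    n_sites = int(text[0])
    if n_sites % 4 != 0:
        raise ValueError("site count is not a multiple of 4 (O, H, H, M)")
    box_length = float(text[1].split("=")[1])
    coords = np.array(
        [[float(v) for v in line.split()[1:4]] for line in text[2 : 2 + n_sites]]
    ).reshape(-1, 4, 3)
    positions = coords[:, 0, :]
    ref = model.reference_sites[1:]  # O is the origin of the molecular frame
    quats = []
    for mol in coords:
        local = mol[1:] - mol[0]
        rot, _ = Rotation.align_vectors(local, ref)
        x, y, z, w = rot.as_quat()
        quats.append([w, x, y, z])
    return Configuration(
        box_length=box_length,
        positions=positions,
        orientations=np.array(quats),
        model=model,
    )


# --------------------------------------------------------------------------
# shipped data
# --------------------------------------------------------------------------

def load_reference_constants(path: str | Path | None = None) -> ReferenceConstants:
    if path is None:
        with resources.files("ionfep.data").joinpath("reference_constants.toml").open(
            "rb"
        ) as fh:
            data = tomllib.load(fh)
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    return ReferenceConstants(
        dg_hyd_exp=data["dG_hyd_exp"],
        phi=data["phi"],
        v_star=data.get("v_star", {}),
        kb_ii=data.get("kb_ii", {}),
    )


def load_water_state() -> dict:
    """Dielectric constant and relative density of water along the isotherm."""
    with resources.files("ionfep.data").joinpath("water_state.toml").open("rb") as fh:
        return tomllib.load(fh)


def interp_state(pressure: float, state: dict | None = None) -> dict:
    """eps_r and rho_rel at a pressure, linearly interpolated in the table."""
    if state is None:
        state = load_water_state()
    rows = sorted(state["state"], key=lambda r: r["P"])
    p = np.array([r["P"] for r in rows], dtype=float)
    eps = np.array([r["eps_r"] for r in rows])
    rho = np.array([r["rho_rel"] for r in rows])
    return {
        "P": pressure,
        "eps_r": float(np.interp(pressure, p, eps)),
        "rho_rel": float(np.interp(pressure, p, rho)),
        "rho_1atm": state["rho_1atm"],
    }


# --------------------------------------------------------------------------
# tabular output
# --------------------------------------------------------------------------

def write_tsv(path: str | Path, header: list[str], rows, provenance: str = "") -> None:
    lines = []
    if provenance:
        lines.append(f"# {provenance}")
    lines.append("\t".join(header))
    for row in rows:
        lines.append("\t".join(str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
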