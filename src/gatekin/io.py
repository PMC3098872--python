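"""Readers and writers: PDB structures with charge/LJ sidecar tables,
portable binary grid containers (HDF5), columnar text exports, and run
provenance blocks."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .grids import ConfigGrid, EnergyLandscape, ProbabilityGrid
from .landscape import StructureModel

__all__ = [
    "load_structure",
    "write_structure",
    "write_grid",
    "read_grid",
    "export_grid_text",
    "write_trace_text",
    "provenance_block",
]

log = logging.getLogger("gatekin")

GRID_FORMAT_VERSION = "gatekin-grid-1"

_SIDKEYS = ["serial", "charge", "lj_sigma", "lj_epsilon", "segment"]


def load_structure(pdb_path, charge_table_path) -> StructureModel:
    """Load a PDB file plus its sidecar table of partial charges and
    Lennard-Jones parameters keyed by atom serial.

    The sidecar is whitespace/tab-separated with columns
    serial, charge (e), lj_sigma (A), lj_epsilon (kT), segment
    (segment tag 'S4S3' marks the mobile complex).  Every table row must
    resolve to a PDB atom serial.  For disordered atoms only the first
    altloc is kept (a count is logged).
    """
    from Bio.PDB import PDBParser

    pdb_path, charge_table_path = Path(pdb_path), Path(charge_table_path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("model", str(pdb_path))
    except Exception as exc:  # Biopython raises plain ValueError with line info
        raise ValueError(f"malformed PDB file {pdb_path}: {exc}") from exc

    serials, coords = [], []
    dropped = 0
    for atom in structure.get_atoms():
        if atom.is_disordered():
            children = atom.disordered_get_list()
            dropped += len(children) - 1
            atom = children[0]
        serials.append(atom.get_serial_number())
        coords.append(atom.get_coord())
    if dropped:
        log.info("dropped %d alternate locations (first altloc kept)", dropped)
    serials = np.asarray(serials, dtype=int)
    coords = np.asarray(coords, dtype=float)

    table = pd.read_csv(charge_table_path, sep=r"\s+", comment="#")
    missing_cols = [c for c in _SIDKEYS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"sidecar table missing columns {missing_cols}")
    unmatched = sorted(set(table["serial"].astype(int)) - set(serials.tolist()))
    if unmatched:
        raise ValueError(f"sidecar rows reference missing PDB serials {unmatched}")

    n = serials.size
    charges = np.full(n, np.nan)
    sig = np.full(n, np.nan)
    eps = np.full(n, np.nan)
    seg = np.array(["static"] * n, dtype=object)
    index = {s: i for i, s in enumerate(serials.tolist())}
    for row in table.itertuples(index=False):
        i = index[int(row.serial)]
        charges[i] = row.charge
        sig[i] = row.lj_sigma
        eps[i] = row.lj_epsilon
        seg[i] = str(row.segment)
    return StructureModel(
        coords=coords,
        charges=charges,
        lj_sigma=sig,
        lj_epsilon=eps,
        segment=np.asarray(seg),
        serials=serials,
    )


def write_structure(structure: StructureModel, pdb_path, charge_table_path) -> None:
    """Write a StructureModel as a PDB file (one pseudo-atom per bead)
    and its sidecar parameter table."""
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("model")
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    for i in range(structure.n_atoms):
        builder.init_residue("BEA", " ", i + 1, " ")
        builder.init_atom(
            "CA",
            structure.coords[i],
            0.0,
            1.0,
            " ",
            " CA ",
            i + 1,
            element="C",
        )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(pdb_path))

    serials = (
        structure.serials
        if structure.serials is not None
        else np.arange(1, structure.n_atoms + 1)
    )
    frame = pd.DataFrame(
        {
            "serial": serials,
            "charge": structure.charges,
            "lj_sigma": structure.lj_sigma,
            "lj_epsilon": structure.lj_epsilon,
            "segment": structure.segment,
        }
    )
    with open(charge_table_path, "w") as fh:
        fh.write("# per-atom partial charges (e) and LJ parameters (A, kT)\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def write_grid(
    obj: EnergyLandscape | ProbabilityGrid,
    path,
    time: float | None = None,
    vm: float | None = None,
) -> None:
    """Store a gridded field in a version-stamped HDF5 container with
    (time, Vm, mass) metadata where applicable."""
    kind = "landscape" if isinstance(obj, EnergyLandscape) else "probability"
    values = obj.phi_grid if kind == "landscape" else obj.values
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = GRID_FORMAT_VERSION
        fh.attrs["kind"] = kind
        if kind == "landscape":
            fh.attrs["vm_mV"] = obj.vm
        else:
            fh.attrs["mass"] = obj.mass
            if vm is not None:
                fh.attrs["vm_mV"] = vm
        if time is not None:
            fh.attrs["time_ms"] = time
        fh.create_dataset("z_values", data=obj.grid.z_values)
        fh.create_dataset("phi_values", data=obj.grid.phi_values)
        fh.create_dataset("values", data=values)


def read_grid(path, expected_grid: ConfigGrid | None = None):
    """Read a grid container back; raises on format-version mismatch or,
    when ``expected_grid`` is given, on axis mismatch."""
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("format")
        if version != GRID_FORMAT_VERSION:
            raise ValueError(
                f"unsupported grid container version {version!r} "
                f"(expected {GRID_FORMAT_VERSION})"
            )
        grid = ConfigGrid(fh["z_values"][:], fh["phi_values"][:])
        if expected_grid is not None and not grid.same_axes(expected_grid):
            raise ValueError("grid axes in file do not match the configured run")
        values = fh["values"][:]
        kind = fh.attrs["kind"]
        if kind == "landscape":
            return EnergyLandscape(grid, float(fh.attrs["vm_mV"]), values)
        return ProbabilityGrid(grid, values)


def export_grid_text(obj: EnergyLandscape | ProbabilityGrid, path) -> None:
    """Columnar text export (z, phi, value) at 1e-9 precision."""
    values = obj.phi_grid if isinstance(obj, EnergyLandscape) else obj.values
    g = obj.grid
    zz, pp = np.meshgrid(g.z_values, g.phi_values, indexing="ij")
    table = np.column_stack([zz.ravel(), pp.ravel(), values.ravel()])
    np.savetxt(path, table, fmt="%.9e", header="z_A phi_rad value")


def write_trace_text(path, columns: dict[str, np.ndarray]) -> None:
    """Columnar text for time series (trajectories, velocity traces,
    gating traces)."""
    names = list(columns)
    table = np.column_stack([np.asarray(columns[k], dtype=float) for k in names])
    np.savetxt(path, table, fmt="%.9e", header=" ".join(names))


def provenance_block(config_dict: dict, seed: int) -> dict:
    """Reproducibility metadata written next to every CLI output."""
    payload = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "seed": seed,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "gatekin": __import__("gatekin").__version__,
    }
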