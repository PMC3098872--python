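"""Deterministic toy fixtures: a two-helix bead structure with partial
charges, default run configuration and voltage protocol.

The toy structure is a caricature of the voltage-sensor geometry: a
mobile vertical "helix" of beads carrying evenly spaced positive charges
(the S4 basic residues) facing a static helix with countercharges at two
depths.  Sliding the mobile helix along z passes the charge registers
across each other, producing multiple electrostatic minima - enough
structure to exercise the full landscape -> dynamics -> gating pipeline
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import RunConfig, save_config
from .grids import ConfigGrid
from .landscape import DielectricModel, LandscapeParams, StructureModel, build_landscape_from_structure

__all__ = ["Fixture", "toy_structure", "generate_fixture"]


@dataclass
class Fixture:
    structure: StructureModel
    landscape_params: LandscapeParams
    config: RunConfig
    protocol: list[dict]
    paths: dict[str, Path] | None = None


def toy_structure(seed: int = 0) -> StructureModel:
    """Two rigid bead helices; geometry fixed, bead charges jittered
    deterministically by seed within +/-10% of their nominal values."""
    rng = np.random.default_rng(seed)
    spacing = 4.5  # A between charged beads, S4-like register
    n_mobile, n_static = 7, 6
    mobile_z = spacing * (np.arange(n_mobile) - (n_mobile - 1) / 2)
    static_z = spacing * (np.arange(n_static) - (n_static - 1) / 2)
    mobile = np.column_stack([np.zeros(n_mobile), np.zeros(n_mobile), mobile_z])
    static = np.column_stack([np.full(n_static, 8.0), np.zeros(n_static), static_z])
    coords = np.vstack([mobile, static])

    charges = np.zeros(n_mobile + n_static)
    # three positive gating charges on the mobile helix, two negative
    # countercharges on the static one
    jitter = lambda q: q * (1.0 + 0.1 * (2 * rng.random() - 1))
    for i in (1, 3, 5):
        charges[i] = jitter(1.0)
    for j in (n_mobile + 1, n_mobile + 4):
        charges[j] = jitter(-1.0)

    lj_sigma = np.full(n_mobile + n_static, 4.0)
    lj_epsilon = np.full(n_mobile + n_static, 0.2)
    segment = np.array(["S4S3"] * n_mobile + ["static"] * n_static, dtype=object)
    return StructureModel(
        coords=coords,
        charges=charges,
        lj_sigma=lj_sigma,
        lj_epsilon=lj_epsilon,
        segment=segment,
        membrane_thickness=30.0,
        membrane_z_upper=16.0,
        serials=np.arange(1, n_mobile + n_static + 1),
    )


def generate_fixture(seed: int = 0, outdir=None, check_minima: bool = True) -> Fixture:
    """Build the toy fixture and (optionally) write it to disk as
    toy.pdb + charges.tsv + config.yaml + protocol.yaml.

    Generation is deterministic given the seed; at generation time the
    structure-derived landscape at -100 mV is checked to carry at least
    two local minima (a bistable toy sensor).
    """
    structure = toy_structure(seed)
    config = RunConfig(seed=seed)
    protocol = [dict(step) for step in config.protocol]

    if check_minima:
        # coarse scan is enough to count the electrostatic registers
        grid = ConfigGrid(
            z_values=np.round(np.arange(-35, 16) * 0.4, 10),
            phi_values=np.round(np.arange(-10, 11) * 0.1, 10),
        )
        ls = build_landscape_from_structure(
            structure, grid, DielectricModel(image_series_terms=20), vm=-100.0
        )
        n_minima = len(ls.local_minima())
        if n_minima < 2:
            raise RuntimeError(
                f"toy structure produced only {n_minima} landscape minima"
            )

    paths = None
    if outdir is not None:
        from .io import write_structure

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pdb": outdir / "toy.pdb",
            "charges": outdir / "charges.tsv",
            "config": outdir / "config.yaml",
            "protocol": outdir / "protocol.yaml",
        }
        write_structure(structure, paths["pdb"], paths["charges"])
        save_config(config, paths["config"])
        import yaml

        with open(paths["protocol"], "w") as fh:
            yaml.safe_dump(protocol, fh, sort_keys=False)
    return Fixture(
        structure=structure,
        landscape_params=config.landscape,
        config=config,
        protocol=protocol,
        paths=paths,
    )
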