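"""gatekin: kinetic-theory collision statistics, averaged equations of
motion, and drift-diffusion gating dynamics for slow conformational
changes of voltage-gated ion channels."""

from .grids import ConfigGrid, EnergyLandscape, ProbabilityGrid

__version__ = "0.1.0"

__all__ = ["ConfigGrid", "EnergyLandscape", "ProbabilityGrid", "__version__"]


def __getattr__(name):
    # convenience re-exports without eager submodule imports
    import importlib

    for mod in ("kinetics", "landscape", "motion", "prob_evolution", "gating",
                "io", "config", "fixtures"):
        module = importlib.import_module(f".{mod}", __name__)
        if hasattr(module, name):
            return getattr(module, name)
    raise AttributeError(name)
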