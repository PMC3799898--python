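"""Parameter-file handling.

All model constants live in one declarative YAML file
(:data:`DEFAULT_PARAM_FILE`); everything downstream (channel kinetics,
cell assembly, wiring, background inputs) reads from the mapping returned
by :func:`load_parameters`, so a modified copy of the file swaps the whole
parameterization.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["DEFAULT_PARAM_FILE", "load_parameters", "validate_parameters"]

DEFAULT_PARAM_FILE = resources.files("ca3net.data") / "parameters.yaml"

CELL_KINDS = ("PYR", "BAS", "OLM")
RECEPTORS = ("AMPA", "NMDA", "GABA_A")


class ParameterError(ValueError):
    """Raised when the parameter file violates a structural constraint."""


def load_parameters(path: str | Path | None = None) -> dict:
    """Load and validate the model parameter file.

    Parameters
    ----------
    path:
        Optional path to an alternative YAML parameter file. When omitted,
        the packaged default is used.
    """
    if path is None:
        text = DEFAULT_PARAM_FILE.read_text()
    else:
        text = Path(path).read_text()
    params = yaml.safe_load(text)
    validate_parameters(params)
    return params


def validate_parameters(params: dict) -> None:
    """Check structural invariants of a parameter mapping.

    Raises :class:`ParameterError` on the first violation found.
    """
    for kind in CELL_KINDS:
        if kind not in params["ih"]:
            raise ParameterError(f"missing ih section for {kind}")
        ih = params["ih"][kind]
        if ih["ghbar"] <= 0:
            raise ParameterError(f"{kind}: ghbar must be > 0")
        if ih["k"] <= 0:
            raise ParameterError(f"{kind}: h_inf slope k must be > 0")
        if ih["tau_min"] <= 0 or ih["tau_amp"] <= 0:
            raise ParameterError(f"{kind}: tau_h must be positive")
        if kind not in params["cells"]:
            raise ParameterError(f"missing cell section for {kind}")
    if len(params["cells"]["PYR"]["compartments"]) != 5:
        raise ParameterError("PYR must have exactly 5 compartments")
    for kind in ("BAS", "OLM"):
        if len(params["cells"][kind]["compartments"]) != 1:
            raise ParameterError(f"{kind} must have exactly 1 compartment")
    for row in params["synapses"]:
        if not 0 < row["tau1"] < row["tau2"]:
            raise ParameterError(f"synapse row {row}: need 0 < tau1 < tau2")
        if row["gmax"] < 0 or row["convergence"] <= 0:
            raise ParameterError(f"synapse row {row}: bad gmax/convergence")
        if row["receptor"] not in RECEPTORS:
            raise ParameterError(f"unknown receptor {row['receptor']!r}")
        n_pre = params["populations"][row["pre"]]
        # sampling without replacement, self-edges excluded
        candidates = n_pre - (1 if row["pre"] == row["post"] else 0)
        if row["convergence"] > candidates:
            raise ParameterError(
                f"synapse row {row}: convergence exceeds presynaptic candidates"
            )
    for row in params["background"]:
        if row["rate"] <= 0:
            raise ParameterError(f"background row {row}: rate must be > 0")
        if not 0 < row["tau1"] < row["tau2"]:
            raise ParameterError(f"background row {row}: need 0 < tau1 < tau2")
    if params["simulation"]["dt"] <= 0:
        raise ParameterError("dt must be > 0")


def scaled_populations(params: dict, factor: float) -> dict:
    """Return a deep copy with population sizes multiplied by ``factor``.

    Convergences are kept fixed so each cell's mean synaptic input — and
    therefore firing statistics — is approximately preserved; only the
    population (and LFP dipole) count shrinks. The factor must leave every
    convergence feasible.
    """
    out = copy.deepcopy(params)
    for kind, n in out["populations"].items():
        out["populations"][kind] = max(1, int(round(n * factor)))
    # where a shrunken population can no longer supply the full convergence,
    # cap it and scale gmax up so total input conductance per cell is kept
    for row in out["synapses"]:
        n_pre = out["populations"][row["pre"]]
        candidates = n_pre - (1 if row["pre"] == row["post"] else 0)
        if row["convergence"] > candidates:
            row["gmax"] = row["gmax"] * row["convergence"] / candidates
            row["convergence"] = candidates
    validate_parameters(out)
    return out
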