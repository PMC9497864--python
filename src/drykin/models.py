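"""Registry of the seven semi-empirical thin-layer drying model forms.

Each model expresses the moisture ratio MR as a short exponential form in
time (minutes), descended from Newton's law of cooling or truncated Fick
series solutions:

==================  ===========================================  ==========
model_id            MR(t)                                        parameters
==================  ===========================================  ==========
newton              exp(-k t)                                    k
page                exp(-k t^n)                                  k, n
modified_page       exp(-(k t)^n)                                k, n
henderson_pabis     a exp(-k t)                                  a, k
logarithmic         a exp(-k t) + c                              a, k, c
verma               a exp(-k t) + (1-a) exp(-g t)                a, k, g
diffusion_approach  a exp(-k t) + (1-a) exp(-k b t)              a, k, b
==================  ===========================================  ==========

Rate constants k and g are per minute; a, b, c, n are dimensionless.
Page and Modified Page are frequently printed with the same formula in the
applied literature; here they follow the standard distinct lineages,
exp(-k t^n) and exp(-(k t)^n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.typing as npt

__all__ = ["ModelSpec", "ModelParams", "MODEL_IDS", "get_model_spec", "model_catalog", "evaluate"]

# Default initial guesses / bounds centred on the rate-constant and shape
# ranges observed in falling-rate convective drying of plant tissue.
_DEFAULTS = {
    "a": (0.9, (1e-6, 2.0)),
    "k": (0.03, (1e-6, 10.0)),
    "b": (0.3, (1e-6, 10.0)),
    "n": (1.0, (0.1, 5.0)),
    "c": (0.05, (-1.0, 1.0)),
    "g": (0.01, (1e-6, 10.0)),
}


@dataclass(frozen=True)
class ModelSpec:
    """One thin-layer model form: name, parameters, default starts/bounds."""

    model_id: str
    parameter_names: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    @property
    def default_initial(self) -> tuple[float, ...]:
        return tuple(_DEFAULTS[p][0] for p in self.parameter_names)

    @property
    def default_bounds(self) -> tuple[tuple[float, float], ...]:
        return tuple(_DEFAULTS[p][1] for p in self.parameter_names)


@dataclass(frozen=True)
class ModelParams:
    """Coefficients of one model instance (ordered as in its ModelSpec)."""

    model_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        spec = get_model_spec(self.model_id)
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) != spec.n_params:
            raise ValueError(
                f"{self.model_id} takes {spec.n_params} parameters "
                f"({', '.join(spec.parameter_names)}), got {len(self.values)}"
            )

    def as_dict(self) -> dict[str, float]:
        spec = get_model_spec(self.model_id)
        return dict(zip(spec.parameter_names, self.values))


_CATALOG: dict[str, ModelSpec] = {
    spec.model_id: spec
    for spec in (
        ModelSpec("modified_page", ("k", "n")),
        ModelSpec("verma", ("a", "k", "g")),
        ModelSpec("page", ("k", "n")),
        ModelSpec("newton", ("k",)),
        ModelSpec("logarithmic", ("a", "k", "c")),
        ModelSpec("henderson_pabis", ("a", "k")),
        ModelSpec("diffusion_approach", ("a", "k", "b")),
    )
}

MODEL_IDS: tuple[str, ...] = tuple(_CATALOG)


def get_model_spec(model_id: str) -> ModelSpec:
    try:
        return _CATALOG[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; available: {', '.join(_CATALOG)}"
        ) from None


def model_catalog() -> list[ModelSpec]:
    """All seven registered thin-layer model specs."""
    return list(_CATALOG.values())


def evaluate(params: ModelParams, times) -> npt.NDArray[np.float64]:
    """Evaluate a model's MR(t) at the given times (minutes, >= 0)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    p = params.as_dict()
    mid = params.model_id
    if mid == "newton":
        return np.exp(-p["k"] * t)
    if mid == "page":
        return np.exp(-p["k"] * t ** p["n"])
    if mid == "modified_page":
        return np.exp(-((p["k"] * t) ** p["n"]))
    if mid == "henderson_pabis":
        return p["a"] * np.exp(-p["k"] * t)
    if mid == "logarithmic":
        return p["a"] * np.exp(-p["k"] * t) + p["c"]
    if mid == "verma":
        return p["a"] * np.exp(-p["k"] * t) + (1.0 - p["a"]) * np.exp(-p["g"] * t)
    if mid == "diffusion_approach":
        return p["a"] * np.exp(-p["k"] * t) + (1.0 - p["a"]) * np.exp(-p["k"] * p["b"] * t)
    raise KeyError(f"unknown model {mid!r}")  # unreachable via public API
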