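"""Log-space parameter vectors.

All positive model quantities (rate constants, Michaelis constants,
promoted initial concentrations) are handled internally as natural
logarithms, theta = log k.  The log transform non-dimensionalizes the
parameters so that a single absolute finite-difference step and the
Euclidean structure of parameter space are meaningful across parameters
of different units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParameterVector"]


@dataclass(frozen=True)
class ParameterVector:
    """An ordered, named vector of log-transformed parameters.

    Parameters
    ----------
    names
        Unique parameter identifiers.
    values
        Natural-log values, one per name.  ``exp(values)`` must be finite
        and strictly positive (interior point of parameter space).
    """

    names: tuple[str, ...]
    values: np.ndarray = field(repr=True)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(names) != values.size:
            raise ValueError(
                f"names ({len(names)}) and values ({values.size}) must align"
            )
        if len(set(names)) != len(names):
            raise ValueError(f"parameter names must be unique: {names}")
        if not np.all(np.isfinite(values)):
            raise ValueError("log-parameters must be finite (interior point)")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "values", values)

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.index(name)])

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown parameter {name!r}; have {list(self.names)}"
            ) from None

    @property
    def k(self) -> np.ndarray:
        """Natural (linear-scale) parameter values exp(theta)."""
        return np.exp(self.values)

    def as_dict(self, *, linear: bool = False) -> dict[str, float]:
        vals = self.k if linear else self.values
        return dict(zip(self.names, (float(v) for v in vals)))

    # -- construction ------------------------------------------------------
    @classmethod
    def from_linear(cls, mapping: dict[str, float]) -> "ParameterVector":
        """Build from natural-scale (positive) values."""
        names = tuple(mapping)
        vals = np.array([mapping[n] for n in names], dtype=float)
        if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
            raise ValueError("natural parameter values must be finite and > 0")
        return cls(names, np.log(vals))

    @classmethod
    def from_log(cls, mapping: dict[str, float]) -> "ParameterVector":
        names = tuple(mapping)
        return cls(names, np.array([mapping[n] for n in names], dtype=float))

    def with_values(self, values: np.ndarray) -> "ParameterVector":
        return ParameterVector(self.names, np.asarray(values, dtype=float))

    def subset(self, names: tuple[str, ...]) -> "ParameterVector":
        return ParameterVector(
            tuple(names), np.array([self[n] for n in names])
        )
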