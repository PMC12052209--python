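"""Circuit parameterization and resource-regime selection.

The circuit is a fixed two-gene inhibition cascade: gene 1 (GFP) represses
transcription of gene 2 (RFP).  All rate constants live in concentration
units; molecule counts are obtained through the system size ``Omega``.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np

__all__ = [
    "CircuitParams",
    "ResourceMode",
    "ConcentrationState",
    "CountState",
    "PARAM_NAMES",
]

#: Canonical ordering of the parameter vector (used by the SSA kernel).
PARAM_NAMES = (
    "km01", "km1", "kp1", "dm1", "dp1", "I1", "Jm1", "Jp1",
    "km02", "km2", "kp2", "dm2", "dp2", "I2", "Jm2", "Jp2",
    "n", "Kg", "Omega",
)

_POSITIVE = {
    "km1", "kp1", "dm1", "dp1", "Jm1", "Jp1",
    "km2", "kp2", "dm2", "dp2", "Jm2", "Jp2",
    "Kg", "Omega",
}
_NONNEGATIVE = {"km01", "km02", "I1", "I2"}


class ResourceMode(enum.Enum):
    """Resource regime: how transcription/translation machinery is allocated.

    UNLIMITED   -- no machinery constraint at all.
    SHARED      -- both genes draw on common finite pools (competition).
    ORTHOGONAL  -- each gene has its own finite pool (self-saturation only).
    """

    UNLIMITED = "unlimited"
    SHARED = "shared"
    ORTHOGONAL = "orthogonal"

    @property
    def code(self) -> int:
        """Integer tag used by the compiled SSA kernel."""
        return {"unlimited": 0, "shared": 1, "orthogonal": 2}[self.value]

    @classmethod
    def coerce(cls, value: "ResourceMode | str") -> "ResourceMode":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown resource mode {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class CircuitParams:
    """All rate constants and capacities of the two-gene cascade.

    Defaults reproduce the standard parameter set used throughout the
    analysis.  ``Jp1``/``Jp2`` are the translational capacities of gene 1
    (GFP) and gene 2 (RFP); ``Kg`` and ``n`` parameterize the inhibitory
    Hill function through which GFP protein represses RFP transcription.
    """

    km01: float = 0.4
    km1: float = 8.0
    kp1: float = 15.0
    dm1: float = 1.0
    dp1: float = 1.0
    I1: float = 1.0
    Jm1: float = 40.0
    Jp1: float = 20.0
    km02: float = 1.0
    km2: float = 25.0
    kp2: float = 30.0
    dm2: float = 1.0
    dp2: float = 1.0
    I2: float = 1.0
    Jm2: float = 40.0
    Jp2: float = 2.0
    n: float = 3.0
    Kg: float = 17.0
    Omega: float = 1.5

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        for name in _NONNEGATIVE:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")

    # -- construction helpers -------------------------------------------------

    def replace(self, **changes: float) -> "CircuitParams":
        """Return a copy with the given fields changed."""
        return dataclasses.replace(self, **changes)

    def theta(self) -> np.ndarray:
        """Parameter vector in :data:`PARAM_NAMES` order (for the SSA kernel)."""
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=np.float64)

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "CircuitParams":
        unknown = set(data) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    def to_json(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: "str | Path") -> "CircuitParams":
        """Load from a flat JSON or YAML key-value file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class ConcentrationState:
    """Deterministic concentrations (m1, p1, m2, p2), all >= 0."""

    m1: float
    p1: float
    m2: float
    p2: float

    def __post_init__(self) -> None:
        for name in ("m1", "p1", "m2", "p2"):
            if getattr(self, name) < 0:
                raise ValueError(f"concentration {name} must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array([self.m1, self.p1, self.m2, self.p2], dtype=np.float64)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ConcentrationState":
        m1, p1, m2, p2 = (float(v) for v in np.asarray(x, dtype=float))
        return cls(m1, p1, m2, p2)

    def to_counts(self, params: CircuitParams) -> "CountState":
        """Round the Omega-scaled concentrations to integer molecule counts."""
        om = params.Omega
        return CountState(
            int(round(self.m1 * om)),
            int(round(self.p1 * om)),
            int(round(self.m2 * om)),
            int(round(self.p2 * om)),
        )


@dataclass(frozen=True)
class CountState:
    """Stochastic molecule counts (M1, P1, M2, P2), non-negative integers."""

    M1: int
    P1: int
    M2: int
    P2: int

    def __post_init__(self) -> None:
        for name in ("M1", "P1", "M2", "P2"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer")

    def to_array(self) -> np.ndarray:
        return np.array([self.M1, self.P1, self.M2, self.P2], dtype=np.int64)

    def to_concentrations(self, params: CircuitParams) -> ConcentrationState:
        om = params.Omega
        return ConcentrationState(
            self.M1 / om, self.P1 / om, self.M2 / om, self.P2 / om
        )
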