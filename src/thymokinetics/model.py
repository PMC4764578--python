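"""Core data types of the beta-selection kinetic model.

The model tracks four successive thymocyte compartments — DN3, DN4, ISP
(immature CD8 single positive) and DP — as population sizes ``C1..C4``.
Progenitors enter the DN3 pool at a constant influx ``K`` (cells/day); each
compartment i feeds the next at a differentiation rate ``Ki`` (1/day) and is
depleted at a net turnover rate ``Kdi`` (1/day), which lumps death and
proliferation into a single per-capita loss term:

    dC1/dt = K  - (K1 + Kd1) C1
    dC2/dt = K1 C1 - (K2 + Kd2) C2
    dC3/dt = K2 C2 - (K3 + Kd3) C3
    dC4/dt = K3 C3 - Kd4 C4

Parameter presets for the four genotypes used in the published analysis are
provided by :func:`preset_parameters`.  In the Itpkb-deficient genotypes the
three differentiation rates K1, K2, K3 are at least two-fold higher than wild
type while influx and turnover are unchanged; in the Rag2-deficient
backgrounds progenitor influx is absent (K = 0) because all thymocytes are
arrested at DN3 until anti-CD3 injection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

from .exceptions import ValidationError

__all__ = [
    "SUBSETS",
    "RateParameters",
    "CompartmentState",
    "TimeCourse",
    "preset_parameters",
    "k1_tilde",
    "PRESET_GENOTYPES",
]

#: Canonical subset labels in compartment order C1..C4.
SUBSETS = ("DN3", "DN4", "ISP", "DP")

_RATE_FIELDS = ("K", "K1", "Kd1", "K2", "Kd2", "K3", "Kd3", "Kd4")


@dataclass(frozen=True)
class RateParameters:
    """Rate constants of the four-compartment model for one genotype.

    Parameters
    ----------
    K : float
        Progenitor influx into DN3, cells/day.
    K1, K2, K3 : float
        Differentiation rates DN3->DN4, DN4->ISP, ISP->DP, 1/day.
    Kd1, Kd2, Kd3, Kd4 : float
        Net turnover (loss) rates of DN3, DN4, ISP, DP, 1/day.  Kd2 and Kd3
        default to 0: the highly proliferative DN4 and ISP stages have
        negligible net loss compared with their differentiation rates.
    label : str
        Free-text genotype tag.
    """

    K: float
    K1: float
    Kd1: float
    K2: float
    K3: float
    Kd4: float
    Kd2: float = 0.0
    Kd3: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ValidationError(f"{name} must be a real number, got {value!r}")
            if not math.isfinite(value):
                raise ValidationError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value!r}")

    # -- derived quantities -------------------------------------------------

    @property
    def k1_tilde(self) -> float:
        """Total exit rate of the DN3 compartment, K1 + Kd1 (1/day)."""
        return self.K1 + self.Kd1

    @property
    def exit_rates(self) -> np.ndarray:
        """Per-compartment total exit rates (K1+Kd1, K2+Kd2, K3+Kd3, Kd4)."""
        return np.array(
            [self.K1 + self.Kd1, self.K2 + self.Kd2, self.K3 + self.Kd3, self.Kd4]
        )

    def system_matrix(self) -> np.ndarray:
        """Lower-bidiagonal generator A of dC/dt = A C + (K, 0, 0, 0)."""
        a = self.exit_rates
        A = np.diag(-a)
        A[1, 0] = self.K1
        A[2, 1] = self.K2
        A[3, 2] = self.K3
        return A

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = {name: float(getattr(self, name)) for name in _RATE_FIELDS}
        d["label"] = self.label
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RateParameters":
        unknown = set(d) - set(_RATE_FIELDS) - {"label"}
        if unknown:
            raise ValidationError(f"unknown parameter keys: {sorted(unknown)}")
        missing = {"K", "K1", "Kd1", "K2", "K3", "Kd4"} - set(d)
        if missing:
            raise ValidationError(f"missing parameter keys: {sorted(missing)}")
        return cls(**d)

    def replace(self, **updates) -> "RateParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        d = self.to_dict()
        d.update(updates)
        return RateParameters.from_dict(d)

    def save(self, path: str | Path) -> None:
        """Write to flat JSON or YAML depending on the file suffix."""
        path = Path(path)
        d = self.to_dict()
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RateParameters":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        return cls.from_dict(d)


@dataclass(frozen=True)
class CompartmentState:
    """Population sizes of the four compartments at one time.

    ``t`` is in days; ``math.inf`` marks a steady state.  Populations are
    continuous cell numbers and must be non-negative.
    """

    t: float
    C1: float
    C2: float
    C3: float
    C4: float

    def __post_init__(self) -> None:
        if math.isnan(self.t) or self.t < 0:
            raise ValidationError(f"t must be >= 0, got {self.t!r}")
        for name in ("C1", "C2", "C3", "C4"):
            v = getattr(self, name)
            if math.isnan(v) or v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v!r}")

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.C1, self.C2, self.C3, self.C4], dtype=float)

    @classmethod
    def from_counts(cls, t: float, counts: Sequence[float]) -> "CompartmentState":
        c = np.asarray(counts, dtype=float)
        if c.shape != (4,):
            raise ValidationError(f"expected 4 compartment counts, got shape {c.shape}")
        return cls(t, *c.tolist())

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(self.t):
            d["t"] = "inf"  # unambiguous steady-state marker for serialization
        return d


@dataclass(frozen=True)
class TimeCourse:
    """An ordered trajectory of compartment states.

    ``times`` is a strictly increasing 1-D array of days; ``counts`` is the
    matching (n_times, 4) array of populations in DN3, DN4, ISP, DP order.
    ``engine`` tags provenance: "analytic", "ode" or "ssa".
    """

    times: np.ndarray
    counts: np.ndarray
    engine: str = "analytic"
    label: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", c)
        if t.ndim != 1 or c.shape != (t.size, 4):
            raise ValidationError(
                f"shape mismatch: times {t.shape} vs counts {c.shape}"
            )
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValidationError("times must be non-negative and strictly increasing")
        if np.any(c < 0):
            raise ValidationError("populations must be non-negative throughout")

    def __len__(self) -> int:
        return int(self.times.size)

    def __iter__(self) -> Iterator[CompartmentState]:
        for t, row in zip(self.times, self.counts):
            yield CompartmentState.from_counts(float(t), row)

    def state_at(self, index: int) -> CompartmentState:
        return CompartmentState.from_counts(
            float(self.times[index]), self.counts[index]
        )

    def to_frame(self, run_id: str = "run0"):
        """Tidy DataFrame: run_id, engine, genotype, time_days, subset, count."""
        import pandas as pd

        n = len(self)
        return pd.DataFrame(
            {
                "run_id": np.repeat(run_id, 4 * n),
                "engine": np.repeat(self.engine, 4 * n),
                "genotype": np.repeat(self.label, 4 * n),
                "time_days": np.repeat(self.times, 4),
                "subset": np.tile(np.array(SUBSETS), n),
                "count": self.counts.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# Genotype presets
# ---------------------------------------------------------------------------

_PRESETS = {
    "WT": RateParameters(
        K=15.4e4, K1=0.1, Kd1=0.1, K2=0.162, K3=0.07, Kd4=0.00058, label="WT"
    ),
    "Itpkb-KO": RateParameters(
        K=15.4e4, K1=0.2, Kd1=0.1, K2=0.486, K3=0.21, Kd4=0.00058, label="Itpkb-KO"
    ),
    "Rag2-WT": RateParameters(
        K=0.0, K1=0.1, Kd1=0.1, K2=0.162, K3=0.07, Kd4=0.00058, label="Rag2-WT"
    ),
    "Rag2-ItpkbKO": RateParameters(
        K=0.0, K1=0.2, Kd1=0.1, K2=0.486, K3=0.21, Kd4=0.00058, label="Rag2-ItpkbKO"
    ),
}

#: Canonical genotype names accepted by :func:`preset_parameters`.
PRESET_GENOTYPES = tuple(_PRESETS)

# Case-insensitive aliases (normalized by stripping -, _, / and lowercasing).
_ALIASES = {
    "wt": "WT",
    "wildtype": "WT",
    "itpkbko": "Itpkb-KO",
    "itpkb": "Itpkb-KO",
    "ko": "Itpkb-KO",
    "rag2wt": "Rag2-WT",
    "rag2": "Rag2-WT",
    "rag2itpkbko": "Rag2-ItpkbKO",
    "rag2ko": "Rag2-ItpkbKO",
}


def _normalize(genotype: str) -> str:
    return "".join(ch for ch in genotype.lower() if ch.isalnum())


def preset_parameters(genotype: str) -> RateParameters:
    """Return the published rate constants for one of the four genotypes.

    Accepted labels (case-insensitive, separators ignored): ``WT``,
    ``Itpkb-KO``, ``Rag2-WT`` (Rag2-/- Itpkb+/+), ``Rag2-ItpkbKO``
    (Rag2-/- Itpkb-/-).  The Rag2 presets carry K = 0 (no progenitor influx);
    Kd2 = Kd3 = 0 in all presets.
    """
    if not isinstance(genotype, str):
        raise ValidationError(f"genotype must be a string, got {genotype!r}")
    key = _normalize(genotype)
    if key not in _ALIASES:
        raise ValidationError(
            f"unknown genotype {genotype!r}; expected one of {list(PRESET_GENOTYPES)}"
        )
    return _PRESETS[_ALIASES[key]]


def k1_tilde(params: RateParameters) -> float:
    """Total DN3 exit rate K1 + Kd1 (1/day), the decay rate of the DN3 pool."""
    return params.k1_tilde
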