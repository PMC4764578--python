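"""Synthetic per-mouse thymocyte subset counts.

Emulates the two observation designs used to study beta-selection kinetics:

* ``steady_state_crosssection`` — each virtual mouse contributes the four
  subset counts (DN3, DN4, ISP, DP) of an unperturbed thymus, i.e. the
  model's fixed point for its genotype.
* ``acd3_timecourse`` — recombination-deficient mice sampled at fixed days
  after anti-CD3 injection; counts follow the influx-free transient solution
  from a pure DN3 pool.

Measurement noise is multiplicative log-normal per mouse and subset (unit
median, configurable coefficient of variation) and/or finite-event
multinomial sampling of subset proportions, mimicking a flow cytometer
recording a fixed number of events that are then rescaled to total
cellularity.  Only subset counts are emulated — no gating, compensation or
fluorescence intensities.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .analytic import solve_timecourse, steady_state_exact
from .exceptions import ValidationError
from .model import SUBSETS, CompartmentState, RateParameters

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "ObservedDataset",
    "DatasetSummary",
    "generate_dataset",
    "summarize_dataset",
]

_SCENARIOS = ("steady_state_crosssection", "acd3_timecourse")
_NOISE_KINDS = ("lognormal-cv", "multinomial-events", "both")

#: Default anti-CD3 sampling days (twice-daily bleeds over three days).
DEFAULT_ACD3_TIMES = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

#: Default initial condition for the transient scenario: a pure DN3 pool.
DEFAULT_C0 = (3e8, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class NoiseModel:
    """How observed counts deviate from model values.

    ``kind`` selects log-normal per-mouse noise ("lognormal-cv"), finite
    flow-event sampling ("multinomial-events"), or their composition
    ("both").  ``cv`` is the coefficient of variation of the unit-median
    log-normal factor; ``n_events`` the number of flow events drawn per
    mouse.
    """

    kind: str = "lognormal-cv"
    cv: float = 0.05
    n_events: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValidationError(f"kind must be one of {_NOISE_KINDS}, got {self.kind!r}")
        if self.cv < 0 or not math.isfinite(self.cv):
            raise ValidationError(f"cv must be >= 0, got {self.cv}")
        if self.n_events < 1:
            raise ValidationError(f"n_events must be >= 1, got {self.n_events}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ExperimentDesign:
    """Which virtual mice are observed, when, and under which genotypes."""

    scenario: str
    genotypes: tuple[RateParameters, ...]
    times: tuple[float, ...] = DEFAULT_ACD3_TIMES
    mice_per_group: int = 20
    c0: tuple[float, float, float, float] = DEFAULT_C0

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValidationError(
                f"scenario must be one of {_SCENARIOS}, got {self.scenario!r}"
            )
        if not self.genotypes:
            raise ValidationError("at least one genotype is required")
        object.__setattr__(self, "genotypes", tuple(self.genotypes))
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "c0", tuple(float(c) for c in self.c0))
        if self.mice_per_group < 1:
            raise ValidationError("mice_per_group must be >= 1")
        t = np.asarray(self.times)
        if t.size == 0 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be non-negative, unique and sorted")
        if len(self.c0) != 4 or any(c < 0 for c in self.c0):
            raise ValidationError("c0 must be 4 non-negative counts")
        labels = [p.label for p in self.genotypes]
        if len(set(labels)) != len(labels):
            raise ValidationError("genotype labels must be unique")
        if self.scenario == "acd3_timecourse":
            for p in self.genotypes:
                if p.K > 0:
                    raise ValidationError(
                        f"acd3_timecourse requires K = 0 (no influx); genotype "
                        f"{p.label!r} has K = {p.K}"
                    )

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "genotypes": [p.to_dict() for p in self.genotypes],
            "times": list(self.times),
            "mice_per_group": self.mice_per_group,
            "c0": list(self.c0),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        return cls(
            scenario=d["scenario"],
            genotypes=tuple(RateParameters.from_dict(g) for g in d["genotypes"]),
            times=tuple(d["times"]),
            mice_per_group=d["mice_per_group"],
            c0=tuple(d["c0"]),
        )


@dataclass(frozen=True)
class ObservedDataset:
    """Tidy per-mouse subset counts plus full generating provenance.

    ``df`` columns: mouse_id, genotype, time_days, subset, count.  For the
    steady-state design ``time_days`` is ``inf`` (the fixed point).  The
    generating design, noise model and seed are retained so any downstream
    result can be traced to its source.
    """

    df: pd.DataFrame
    design: ExperimentDesign | None = None
    noise: NoiseModel | None = None
    seed: int | None = None

    _COLUMNS = ("mouse_id", "genotype", "time_days", "subset", "count")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.df.columns)
        if missing:
            raise ValidationError(f"dataset is missing columns {sorted(missing)}")
        if len(self.df) == 0:
            raise ValidationError("dataset is empty")
        if (self.df["count"] < 0).any():
            raise ValidationError("counts must be non-negative")
        bad = set(self.df["subset"].unique()) - set(SUBSETS)
        if bad:
            raise ValidationError(f"unknown subset labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def genotype_labels(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.df["genotype"]))

    def filter(self, genotype: str) -> "ObservedDataset":
        sub = self.df[self.df["genotype"] == genotype]
        if len(sub) == 0:
            raise ValidationError(f"no rows for genotype {genotype!r}")
        return ObservedDataset(sub.reset_index(drop=True), self.design, self.noise, self.seed)

    # -- serialization ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write counts as tidy CSV plus a JSON provenance sidecar."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        meta = {
            "design": self.design.to_dict() if self.design else None,
            "noise": self.noise.to_dict() if self.noise else None,
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2) + "\n"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservedDataset":
        path = Path(path)
        df = pd.read_csv(path)
        design = noise = seed = None
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            if meta.get("design"):
                design = ExperimentDesign.from_dict(meta["design"])
            if meta.get("noise"):
                noise = NoiseModel(**meta["noise"])
            seed = meta.get("seed")
        return cls(df, design, noise, seed)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _true_counts(design: ExperimentDesign) -> dict[str, dict[float, np.ndarray]]:
    """Model-truth counts per genotype and time point."""
    truth: dict[str, dict[float, np.ndarray]] = {}
    for params in design.genotypes:
        if design.scenario == "steady_state_crosssection":
            ss = steady_state_exact(params)
            truth[params.label] = {math.inf: ss.counts}
        else:
            c0 = CompartmentState.from_counts(0.0, design.c0)
            tc = solve_timecourse(params, c0, np.asarray(design.times))
            truth[params.label] = {
                float(t): tc.counts[i] for i, t in enumerate(design.times)
            }
    return truth


def generate_dataset(
    design: ExperimentDesign,
    noise: NoiseModel,
    seed: int | None = None,
    round_counts: bool = False,
) -> ObservedDataset:
    """Draw a synthetic dataset under the given design and noise model.

    For every mouse, true subset counts are computed from the model, then
    perturbed: the log-normal route multiplies each subset count by an
    independent unit-median log-normal factor with the configured CV; the
    multinomial route draws ``n_events`` flow events from the four-subset
    proportions and rescales to total cellularity; "both" applies the
    log-normal first, then resamples events.  Deterministic under
    (design, noise, seed); ``seed`` defaults to ``noise.seed``.

    Counts are continuous by default; ``round_counts`` applies banker's
    rounding to integers.
    """
    if seed is None:
        seed = noise.seed
    rng = np.random.default_rng(int(seed))
    sigma = math.sqrt(math.log1p(noise.cv**2))  # unit-median lognormal
    truth = _true_counts(design)

    rows: list[tuple] = []
    for params in design.genotypes:
        label = params.label
        for t, true in truth[label].items():
            for m in range(design.mice_per_group):
                mouse_id = f"{label}_t{t:g}_m{m:03d}"
                counts = true.astype(float).copy()
                if noise.kind in ("lognormal-cv", "both") and noise.cv > 0:
                    counts = counts * rng.lognormal(0.0, sigma, size=4)
                if noise.kind in ("multinomial-events", "both"):
                    total = counts.sum()
                    if total > 0:
                        events = rng.multinomial(noise.n_events, counts / total)
                        counts = events * (total / noise.n_events)
                if round_counts:
                    counts = np.round(counts)  # numpy rounds half to even
                for subset, c in zip(SUBSETS, counts):
                    rows.append((mouse_id, label, t, subset, float(c)))
    df = pd.DataFrame(rows, columns=list(ObservedDataset._COLUMNS))
    return ObservedDataset(df, design=design, noise=noise, seed=int(seed))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSummary:
    """Group-level summary tables.

    ``counts``: per (genotype, time_days, subset) n, mean and SEM.
    ``dn3_dn4_ratio``: the per-mouse DN3:DN4 count ratio averaged per group
    (SEM is NaN for single-mouse groups).
    """

    counts: pd.DataFrame
    dn3_dn4_ratio: pd.DataFrame


def _sem(x: pd.Series) -> float:
    return float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")


def summarize_dataset(data: ObservedDataset) -> DatasetSummary:
    """Per-group mean +/- SEM counts and the DN3:DN4 ratio."""
    df = data.df
    counts = (
        df.groupby(["genotype", "time_days", "subset"], sort=False)["count"]
        .agg(n="size", mean="mean", sem=_sem)
        .reset_index()
    )
    wide = df.pivot_table(
        index=["genotype", "time_days", "mouse_id"],
        columns="subset",
        values="count",
        sort=False,
    )
    ratio = (wide["DN3"] / wide["DN4"]).rename("ratio").reset_index()
    ratio_summary = (
        ratio.groupby(["genotype", "time_days"], sort=False)["ratio"]
        .agg(n="size", mean="mean", sem=_sem)
        .reset_index()
    )
    return DatasetSummary(counts=counts, dn3_dn4_ratio=ratio_summary)
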