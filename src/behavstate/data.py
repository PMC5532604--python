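"""Ethograms, focal-observation tables, and quantile binning.

A focal observation is a fixed-duration (default 10-minute) record of one
animal's behavior.  Each behavior in the ethogram is either an *event*
(a count of occurrences) or an *activity* (the proportion of the focal spent
engaged in it).  The model consumes neither counts nor proportions directly:
each behavior's raw amounts are converted into a small number of ordered
levels using data-driven quantile cutpoints, so that a behavioral state can
be described by one categorical distribution per behavior.

The binning procedure, per behavior:

1. compute candidate cutpoints at the 1st, 20th, 40th, 60th, 80th and 99th
   percentiles of the behavior's column (quintiles plus outlier fences);
2. collapse duplicate cutpoints (heavily zero-inflated behaviors typically
   collapse to three levels encoding 0, 1 and >1 occurrences) and drop
   cutpoints at or above the column maximum so no bin is empty by
   construction;
3. assign value ``v`` to level 1 if ``v <= c_1`` and to level ``j+1`` if
   ``c_j < v <= c_{j+1}`` (upper bounds inclusive), with values above the
   last cutpoint in the top level.

This yields at most seven ordered levels per behavior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Ethogram",
    "FocalTable",
    "BinningScheme",
    "BinnedDataset",
    "compute_cutpoints",
    "bin_dataset",
    "DEFAULT_PERCENTILES",
]

DEFAULT_PERCENTILES = (1.0, 20.0, 40.0, 60.0, 80.0, 99.0)

_KINDS = ("event", "activity")


@dataclass(frozen=True)
class Ethogram:
    """The catalogue of behaviors recorded during focal observations.

    Each behavior is a ``(name, kind)`` pair where kind is ``"event"``
    (occurrence counts) or ``"activity"`` (duration proportions).
    """

    behaviors: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if len(self.behaviors) == 0:
            raise ValueError("ethogram must contain at least one behavior")
        names = [b[0] for b in self.behaviors]
        if len(set(names)) != len(names):
            raise ValueError("behavior names must be unique")
        for name, kind in self.behaviors:
            if kind not in _KINDS:
                raise ValueError(f"behavior {name!r} has unknown kind {kind!r}")

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.behaviors]

    @property
    def kinds(self) -> list[str]:
        return [b[1] for b in self.behaviors]

    @property
    def n_behaviors(self) -> int:
        return len(self.behaviors)

    @classmethod
    def from_records(cls, records) -> "Ethogram":
        """Build from an iterable of {"name": ..., "kind": ...} mappings."""
        return cls(tuple((r["name"], r["kind"]) for r in records))

    def to_records(self):
        return [{"name": n, "kind": k} for n, k in self.behaviors]


@dataclass
class FocalTable:
    """Raw per-focal behavior amounts, one row per focal observation."""

    animal_id: np.ndarray  # (N_obs,) str
    focal_id: np.ndarray  # (N_obs,) str
    amounts: np.ndarray  # (N_obs, B) float
    ethogram: Ethogram
    duration: float = 600.0

    def __post_init__(self):
        self.animal_id = np.asarray(self.animal_id, dtype=object)
        self.focal_id = np.asarray(self.focal_id, dtype=object)
        self.amounts = np.asarray(self.amounts, dtype=float)
        n = len(self.animal_id)
        if self.amounts.shape != (n, self.ethogram.n_behaviors):
            raise ValueError("amounts shape does not match rows x behaviors")
        if np.any(self.amounts < 0):
            raise ValueError("behavior amounts must be non-negative")
        kinds = np.array(self.ethogram.kinds)
        act = kinds == "activity"
        if act.any() and np.any(self.amounts[:, act] > 1.0 + 1e-12):
            raise ValueError("activity amounts are proportions and must be <= 1")
        ev = kinds == "event"
        if ev.any():
            ev_vals = self.amounts[:, ev]
            if not np.allclose(ev_vals, np.round(ev_vals)):
                raise ValueError("event amounts must be integer counts")
        keys = list(zip(self.animal_id, self.focal_id))
        if len(set(keys)) != n:
            raise ValueError("(animal_id, focal_id) pairs must be unique")

    @property
    def n_obs(self) -> int:
        return len(self.animal_id)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ethogram: Ethogram, duration: float = 600.0):
        missing = [b for b in ethogram.names if b not in df.columns]
        if missing:
            raise ValueError(f"focal table is missing behavior columns: {missing}")
        return cls(
            animal_id=df["animal_id"].astype(str).to_numpy(dtype=object),
            focal_id=df["focal_id"].astype(str).to_numpy(dtype=object),
            amounts=df[ethogram.names].to_numpy(dtype=float),
            ethogram=ethogram,
            duration=duration,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"animal_id": self.animal_id, "focal_id": self.focal_id})
        for j, name in enumerate(self.ethogram.names):
            df[name] = self.amounts[:, j]
        return df


def compute_cutpoints(
    column: np.ndarray,
    percentiles=DEFAULT_PERCENTILES,
    max_levels: int = 7,
    method: str = "lower",
) -> np.ndarray:
    """Quantile cutpoints for one behavior's column of raw amounts.

    Candidate cutpoints are the requested percentiles.  The default quantile
    convention is ``"lower"`` (the largest data value at or below the
    quantile position), so cutpoints are always observed data values — on
    zero-inflated count behaviors this reproduces the collapse to levels
    encoding 0, 1 and >1 occurrences, whereas interpolating conventions
    would manufacture fractional cutpoints between ties.  Any numpy quantile
    ``method`` can be requested instead.  Duplicates are collapsed, and
    cutpoints at or above the column maximum are dropped so that every bin
    can be occupied; a constant column therefore yields no cutpoints (a
    single level).
    """
    column = np.asarray(column, dtype=float)
    if column.size == 0:
        raise ValueError("cannot compute cutpoints of an empty column")
    cuts = np.percentile(column, sorted(percentiles), method=method)
    cuts = np.unique(cuts)
    cuts = cuts[cuts < column.max()]
    if cuts.size + 1 > max_levels:
        raise ValueError(
            f"{cuts.size + 1} levels exceed the maximum of {max_levels}"
        )
    return cuts


@dataclass
class BinningScheme:
    """Per-behavior cutpoints mapping raw amounts to ordered levels."""

    cutpoints: dict[str, np.ndarray]
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES
    method: str = "lower"

    def __post_init__(self):
        for name, cuts in self.cutpoints.items():
            cuts = np.asarray(cuts, dtype=float)
            if np.any(np.diff(cuts) <= 0):
                raise ValueError(f"cutpoints for {name!r} must be strictly increasing")
            self.cutpoints[name] = cuts

    def n_levels(self, behavior: str) -> int:
        return len(self.cutpoints[behavior]) + 1

    @classmethod
    def from_table(
        cls,
        table: FocalTable,
        percentiles=DEFAULT_PERCENTILES,
        max_levels: int = 7,
        method: str = "lower",
    ) -> "BinningScheme":
        cuts = {
            name: compute_cutpoints(table.amounts[:, j], percentiles, max_levels, method)
            for j, name in enumerate(table.ethogram.names)
        }
        return cls(cutpoints=cuts, percentiles=tuple(percentiles), method=method)

    def assign_levels(self, behavior: str, values: np.ndarray) -> np.ndarray:
        """Map raw amounts to 1-based levels (inclusive upper bin edges)."""
        cuts = self.cutpoints[behavior]
        return np.searchsorted(cuts, np.asarray(values, dtype=float), side="left") + 1

    def to_json(self) -> str:
        payload = {
            "percentiles": list(self.percentiles),
            "method": self.method,
            "cutpoints": {k: v.tolist() for k, v in self.cutpoints.items()},
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BinningScheme":
        payload = json.loads(text)
        return cls(
            cutpoints={k: np.asarray(v, dtype=float) for k, v in payload["cutpoints"].items()},
            percentiles=tuple(payload["percentiles"]),
            method=payload.get("method", "lower"),
        )


@dataclass
class BinnedDataset:
    """Ordered-level representation of a focal table, ready for the model.

    ``levels[f, b]`` is the 1-based level of behavior ``b`` in focal
    observation ``f``; ``animal_index[f]`` indexes into ``animal_ids``.
    """

    levels: np.ndarray  # (N_obs, B) int, 1-based
    animal_index: np.ndarray  # (N_obs,) int
    animal_ids: list[str]
    behavior_names: list[str]
    n_levels: np.ndarray  # (B,) int
    focal_id: np.ndarray | None = None
    level_counts: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.animal_index = np.asarray(self.animal_index, dtype=np.int64)
        self.n_levels = np.asarray(self.n_levels, dtype=np.int64)
        if self.levels.shape[1] != len(self.behavior_names):
            raise ValueError("levels columns must match behaviors")
        if np.any(self.levels < 1) or np.any(self.levels > self.n_levels[None, :]):
            raise ValueError("levels out of the 1..n_levels range")
        if np.any(self.n_levels < 1):
            raise ValueError("each behavior must have at least one level")
        if self.animal_index.min(initial=0) < 0 or (
            self.levels.shape[0] and self.animal_index.max() >= len(self.animal_ids)
        ):
            raise ValueError("animal_index out of range")
        if not self.level_counts:
            self.level_counts = [
                np.bincount(self.levels[:, b] - 1, minlength=self.n_levels[b])
                for b in range(self.n_behaviors)
            ]

    @property
    def n_obs(self) -> int:
        return self.levels.shape[0]

    @property
    def n_behaviors(self) -> int:
        return self.levels.shape[1]

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def focals_per_animal(self) -> np.ndarray:
        return np.bincount(self.animal_index, minlength=self.n_animals)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"animal_id": np.asarray(self.animal_ids, dtype=object)[self.animal_index]})
        if self.focal_id is not None:
            df.insert(1, "focal_id", self.focal_id)
        for b, name in enumerate(self.behavior_names):
            df[name] = self.levels[:, b]
        return df


def bin_dataset(table: FocalTable, scheme: BinningScheme) -> BinnedDataset:
    """Apply a binning scheme to a focal table.

    Every behavior in the table must have cutpoints in the scheme.  Values
    equal to a cutpoint fall in the lower bin.
    """
    names = table.ethogram.names
    missing = [n for n in names if n not in scheme.cutpoints]
    if missing:
        raise ValueError(f"binning scheme lacks cutpoints for: {missing}")
    levels = np.column_stack(
        [scheme.assign_levels(name, table.amounts[:, j]) for j, name in enumerate(names)]
    )
    animal_ids = list(dict.fromkeys(table.animal_id))  # first-appearance order
    idx = {a: i for i, a in enumerate(animal_ids)}
    animal_index = np.array([idx[a] for a in table.animal_id], dtype=np.int64)
    return BinnedDataset(
        levels=levels,
        animal_index=animal_index,
        animal_ids=animal_ids,
        behavior_names=list(names),
        n_levels=np.array([scheme.n_levels(n) for n in names], dtype=np.int64),
        focal_id=table.focal_id.copy(),
    )
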