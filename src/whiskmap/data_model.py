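"""Domain types, file I/O and validation shared by every analysis stage.

The package works in a right-handed µm frame (y increasing up in the imaged
field); all geometry is 2-D, matching single-plane imaging. Trial indexing is
0-based and distance bins are half-open ``[k*w, (k+1)*w)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

__all__ = [
    "WhiskerId",
    "WHISKER_ROWS",
    "WHISKER_ARCS",
    "ALL_WHISKERS",
    "StimulusEvent",
    "RoiRecord",
    "BarrelColumn",
    "BarrelMap",
    "NormalizedPosition",
    "AnalysisConfig",
    "TrialTable",
    "SchemaError",
    "GeometryError",
    "AnalysisError",
    "read_trial_table",
    "write_trial_table",
    "read_barrel_map",
    "write_barrel_map",
    "filter_analysis_trials",
]

WHISKER_ROWS = ("C", "D", "E")
WHISKER_ARCS = (1, 2, 3)


class SchemaError(ValueError):
    """A table or geometry file does not match the documented schema."""


class GeometryError(ValueError):
    """A barrel-map geometry invariant is violated."""


class AnalysisError(ValueError):
    """An analysis precondition (e.g. no blank trials) is violated."""


@dataclass(frozen=True, order=True)
class WhiskerId:
    """One of the 9 stimulated whiskers, rows C–E × arcs 1–3.

    ``grid`` maps the label onto 0-based (row_index, arc_index) coordinates:
    C→0, D→1, E→2 and arc n → n−1.
    """

    row: str
    arc: int

    def __post_init__(self) -> None:
        if self.row not in WHISKER_ROWS or self.arc not in WHISKER_ARCS:
            raise ValueError(f"invalid whisker {self.row}{self.arc}")

    @property
    def label(self) -> str:
        return f"{self.row}{self.arc}"

    @property
    def grid(self) -> tuple[int, int]:
        return (WHISKER_ROWS.index(self.row), self.arc - 1)

    @classmethod
    def from_label(cls, label: str) -> "WhiskerId":
        label = str(label).strip()
        if len(label) != 2 or not label[1].isdigit():
            raise ValueError(f"invalid whisker label {label!r}")
        return cls(label[0], int(label[1]))

    @classmethod
    def from_grid(cls, row_index: int, arc_index: int) -> "WhiskerId":
        return cls(WHISKER_ROWS[row_index], WHISKER_ARCS[arc_index])

    def neighbors(self) -> list["WhiskerId"]:
        """Grid-adjacent whiskers in the same row or arc (no diagonals)."""
        r, a = self.grid
        out = []
        for dr, da in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, aa = r + dr, a + da
            if 0 <= rr < 3 and 0 <= aa < 3:
                out.append(WhiskerId.from_grid(rr, aa))
        return out

    def __str__(self) -> str:
        return self.label


ALL_WHISKERS: tuple[WhiskerId, ...] = tuple(
    WhiskerId(r, a) for r in WHISKER_ROWS for a in WHISKER_ARCS
)

STIMULUS_KINDS = ("single_whisker", "all_whisker", "tone", "blank")


@dataclass(frozen=True)
class StimulusEvent:
    """A per-trial stimulus: single whisker, all-whisker, tone or blank."""

    kind: str
    whisker: WhiskerId | None = None
    tone_id: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise SchemaError(f"unknown stimulus kind {self.kind!r}")
        if (self.kind == "single_whisker") != (self.whisker is not None):
            raise SchemaError(
                "whisker must be present exactly when kind='single_whisker'"
            )


@dataclass(frozen=True)
class RoiRecord:
    """One imaged cell: position in the barrel-map µm frame plus identity."""

    roi_id: str
    field_id: str
    x: float
    y: float
    cross_session_key: str | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise SchemaError(f"non-finite position for ROI {self.roi_id}")

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class BarrelColumn:
    whisker: WhiskerId
    centroid: tuple[float, float]
    boundary: Polygon

    def __post_init__(self) -> None:
        if not self.boundary.is_valid or not self.boundary.is_simple:
            raise GeometryError(f"column {self.whisker}: polygon not simple")
        if not self.boundary.covers(Point(*self.centroid)):
            raise GeometryError(f"column {self.whisker}: centroid outside polygon")


@dataclass(frozen=True)
class BarrelMap:
    """Per-column whisker label, centroid and boundary polygon (µm frame).

    The septal region is the complement of all column polygons.
    """

    columns: tuple[BarrelColumn, ...]

    def __post_init__(self) -> None:
        labels = [c.whisker.label for c in self.columns]
        if len(set(labels)) != len(labels):
            raise SchemaError("duplicate whisker label in barrel map")

    def column(self, whisker: WhiskerId | str) -> BarrelColumn:
        label = whisker if isinstance(whisker, str) else whisker.label
        for c in self.columns:
            if c.whisker.label == label:
                return c
        raise KeyError(label)

    @property
    def whiskers(self) -> list[WhiskerId]:
        return [c.whisker for c in self.columns]


@dataclass(frozen=True)
class NormalizedPosition:
    """Polar position about a reference column, in column-radius units."""

    reference_column: WhiskerId
    radius: float
    angle: float  # degrees in [0, 360)

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if not (0.0 <= self.angle < 360.0):
            raise ValueError("angle must be in [0, 360)")


@dataclass(frozen=True)
class AnalysisConfig:
    """Fixed analysis constants; defaults are the study's printed values."""

    n_permutations: int = 10_000
    n_bootstrap: int = 10_000
    alpha: float = 0.05
    fdr_q: float = 0.05
    evoked_window_ms: tuple[float, float] = (0.0, 1000.0)
    baseline_window_ms: tuple[float, float] = (0.0, 500.0)
    inclusion_radius: float = 1.25  # column radii
    bin_width_um: float = 10.0
    cluster_fit_range_um: tuple[float, float] = (30.0, 200.0)
    cluster_window_um: float = 20.0
    subsample_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_permutations", "n_bootstrap", "alpha", "fdr_q",
                     "inclusion_radius", "bin_width_um", "cluster_window_um",
                     "subsample_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, *salt: int) -> np.random.Generator:
        return np.random.default_rng((self.seed, *salt))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

_TRIAL_META_COLUMNS = ["session_id", "trial_index", "stimulus_kind", "whisker", "lick"]


@dataclass
class TrialTable:
    """Per-trial stimulus labels plus per-ROI evoked ΔF/F for one session.

    ``trials`` holds the metadata columns (session_id, trial_index,
    stimulus_kind, whisker, lick) and ``dff`` one evoked ΔF/F column per ROI,
    row-aligned with ``trials``. Lick trials are retained but flagged;
    :func:`filter_analysis_trials` drops them for analysis.
    """

    trials: pd.DataFrame
    dff: pd.DataFrame
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in _TRIAL_META_COLUMNS:
            if col not in self.trials.columns:
                raise SchemaError(f"missing required column {col!r}")
        if len(self.trials) != len(self.dff):
            raise SchemaError("trials and dff row counts differ")
        kinds = self.trials["stimulus_kind"]
        bad = ~kinds.isin(STIMULUS_KINDS)
        if bad.any():
            raise SchemaError(
                f"unknown stimulus kind {kinds[bad].iloc[0]!r} "
                f"at trial_index {self.trials['trial_index'][bad].iloc[0]}"
            )
        sw = kinds == "single_whisker"
        whisker = self.trials["whisker"]
        has_w = whisker.notna() & (whisker.astype(str).str.len() > 0)
        if (sw & ~has_w).any():
            raise SchemaError("single_whisker trial without a whisker label")
        if (~sw & has_w).any():
            raise SchemaError("whisker label on a non-single_whisker trial")
        for label in whisker[has_w].unique():
            WhiskerId.from_label(label)  # raises on bad label
        values = self.dff.to_numpy(dtype=float)
        finite = np.isfinite(values)
        if not finite.all():
            row = int(np.argwhere(~finite)[0, 0])
            raise SchemaError(
                f"non-finite ΔF/F at trial_index "
                f"{self.trials['trial_index'].iloc[row]}"
            )

    @property
    def roi_ids(self) -> list[str]:
        return list(self.dff.columns)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def stimulus_masks(self) -> dict[str, np.ndarray]:
        """Boolean row masks per single-whisker label plus ``"blank"``."""
        kinds = self.trials["stimulus_kind"].to_numpy()
        whisker = (
            self.trials["whisker"].astype("string").fillna("").to_numpy(dtype=str)
        )
        sw = kinds == "single_whisker"
        masks = {"blank": kinds == "blank"}
        for w in ALL_WHISKERS:
            masks[w.label] = sw & (whisker == w.label)
        return masks

    def whisker_evoked(self, roi_id: str) -> dict[str, np.ndarray]:
        """Evoked ΔF/F per single-whisker stimulus for one ROI (all trials)."""
        vals = self.dff[roi_id].to_numpy(dtype=float)
        return {
            label: vals[mask]
            for label, mask in self.stimulus_masks().items()
            if label != "blank" and mask.any()
        }

    def blank_evoked(self, roi_id: str) -> np.ndarray:
        mask = (self.trials["stimulus_kind"] == "blank").to_numpy()
        return self.dff[roi_id].to_numpy(dtype=float)[mask]


def read_trial_table(path, config: AnalysisConfig | None = None) -> TrialTable:
    """Read a trial-table CSV (documented header: metadata then ROI columns)."""
    df = pd.read_csv(path, dtype={"whisker": "string"})
    for col in _TRIAL_META_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    roi_cols = [c for c in df.columns if c not in _TRIAL_META_COLUMNS]
    trials = df[_TRIAL_META_COLUMNS].copy()
    trials["lick"] = trials["lick"].astype(bool)
    trials["trial_index"] = trials["trial_index"].astype(int)
    dff = df[roi_cols].astype(float)
    return TrialTable(trials=trials, dff=dff, config=config or AnalysisConfig())


def write_trial_table(table: TrialTable, path) -> None:
    out = pd.concat(
        [table.trials.reset_index(drop=True), table.dff.reset_index(drop=True)],
        axis=1,
    )
    out.to_csv(path, index=False)


def filter_analysis_trials(table: TrialTable, task: str = "one_vs_all",
                           require_blanks: bool = True) -> TrialTable:
    """Keep analyzable trials for the given task; idempotent.

    one_vs_all keeps non-lick single-whisker and blank trials. d_vs_ce keeps
    trials without licks during the stimulus+delay period (the lick flag in
    d_vs_ce tables must already encode stimulus+delay licking).
    """
    if task not in ("one_vs_all", "d_vs_ce"):
        raise ValueError(f"unknown task {task!r}")
    keep = ~table.trials["lick"].to_numpy(dtype=bool)
    if task == "one_vs_all":
        keep &= table.trials["stimulus_kind"].isin(["single_whisker", "blank"]).to_numpy()
    filtered = TrialTable(
        trials=table.trials.loc[keep].reset_index(drop=True),
        dff=table.dff.loc[keep].reset_index(drop=True),
        config=table.config,
    )
    n_blank = int((filtered.trials["stimulus_kind"] == "blank").sum())
    if require_blanks and n_blank == 0:
        raise AnalysisError("no blank trials survive filtering; blank null undefined")
    return filtered


# ---------------------------------------------------------------------------
# Barrel-map geometry files (JSON)
# ---------------------------------------------------------------------------

def read_barrel_map(path) -> BarrelMap:
    """Read a barrel-map JSON file: per-column label, centroid, polygon (µm)."""
    with open(path) as fh:
        raw = json.load(fh)
    columns = []
    for entry in raw["columns"]:
        poly = Polygon(entry["boundary"])
        columns.append(
            BarrelColumn(
                whisker=WhiskerId.from_label(entry["whisker"]),
                centroid=tuple(entry["centroid"]),
                boundary=poly,
            )
        )
    return BarrelMap(columns=tuple(columns))


def write_barrel_map(barrel_map: BarrelMap, path) -> None:
    payload = {
        "columns": [
            {
                "whisker": c.whisker.label,
                "centroid": list(c.centroid),
                "boundary": [list(p) for p in c.boundary.exterior.coords[:-1]],
            }
            for c in barrel_map.columns
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def rois_to_frame(rois: Iterable[RoiRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "roi_id": r.roi_id,
                "field_id": r.field_id,
                "x": r.x,
                "y": r.y,
                "cross_session_key": r.cross_session_key,
            }
            for r in rois
        ]
    )


def rois_from_frame(df: pd.DataFrame) -> list[RoiRecord]:
    return [
        RoiRecord(
            roi_id=str(row.roi_id),
            field_id=str(row.field_id),
            x=float(row.x),
            y=float(row.y),
            cross_session_key=(None if pd.isna(row.cross_session_key)
                               else str(row.cross_session_key)),
        )
        for row in df.itertuples()
    ]
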