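"""Synthetic barrel maps, cell rosters and multi-session trial tables.

The generator emulates the study conditions every analysis stage assumes:
a 3×3 grid of whisker columns (hexagons with septal gaps), ~30% of cells
whisker-responsive, ~52% of columnar responsive cells tuned to their
columnar whisker, a radial tuning gradient with local (<20 µm) co-tuned
clusters, additive blank-trial noise plus multiplicative trial gain,
per-session wavering responsiveness, and bounded inter-session tuning drift
(best-whisker shifts restricted to grid-adjacent whiskers, concentrated in
non-CW-tuned cells). Every cell's true mean-response surface is recorded per
session, so recovery can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .data_model import (
    ALL_WHISKERS,
    AnalysisConfig,
    BarrelColumn,
    BarrelMap,
    RoiRecord,
    TrialTable,
    WhiskerId,
)
from .map_geometry import scaled_boundary

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "make_barrel_map",
    "sample_cells",
    "simulate_session",
    "apply_drift",
    "simulate_experiment",
]

_LABELS = tuple(w.label for w in ALL_WHISKERS)
_GRID = np.array([w.grid for w in ALL_WHISKERS], dtype=float)  # (9, 2) row, arc


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    # map geometry (µm)
    lattice_spacing_um: float = 140.0
    apothem_um: float = 60.0
    # roster
    cells_per_column: int = 50          # per column-area of the sampled region
    responsive_fraction: float = 0.30
    cw_tuned_fraction: float = 0.52
    # tuning surface
    peak_amplitude_mean: float = 0.5    # ΔF/F
    peak_amplitude_sd: float = 0.15
    decay_per_step: float = 0.25        # response falloff per grid step
    gradient_strength: float = 1.0      # spatial pull of peak toward position
    cluster_scale_um: float = 20.0
    cluster_strength: float = 0.7
    cluster_seed_fraction: float = 0.25
    suppressed_fraction: float = 0.25   # cells with one negative-response whisker
    suppression_scale: float = 0.15     # |negative mean| as fraction of peak
    # noise
    blank_noise_sd: float = 0.08        # additive ΔF/F noise, mean 0
    trial_gain_sd: float = 0.25         # lognormal sigma of multiplicative gain
    # trial structure
    trials_per_whisker: int = 40
    blank_trials: int = 100
    all_whisker_trials: int = 20
    tone_trials: int = 20
    lick_prob: float = 0.05
    # sessions and drift
    n_sessions: int = 4
    drift_noncw: float = 0.4            # per-interval BW-shift probability
    drift_cw: float = 0.05
    com_jitter_fraction: float = 0.15   # among cells that did not shift BW
    com_jitter_scale: float = 0.3       # bounded surface perturbation
    waver_dropout: float = 0.2          # responsive cell silent for a session
    waver_gain: float = 0.05            # non-responsive cell active for a session
    dropout_scale: float = 0.0          # surface gain while dropped out
    inclusion_radius: float = 1.25      # column radii, sampled region
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("responsive_fraction", "cw_tuned_fraction",
                     "cluster_strength", "suppressed_fraction", "lick_prob",
                     "drift_noncw", "drift_cw", "com_jitter_fraction",
                     "waver_dropout", "waver_gain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _hexagon(center: tuple[float, float], apothem: float) -> Polygon:
    """Regular hexagon with one apothem along +x."""
    r = apothem / np.cos(np.pi / 6)
    ang = np.radians(30 + 60 * np.arange(6))
    return Polygon(np.c_[center[0] + r * np.cos(ang),
                         center[1] + r * np.sin(ang)])


def make_barrel_map(config: SimulationConfig | None = None) -> BarrelMap:
    """9 hexagonal columns C1–E3 on a 3×3 lattice; D2 centroid at the origin.

    Arcs run along +x, rows along −y (row C above row E), so row/arc
    adjacency matches grid adjacency and gaps between hexagons form septa.
    """
    config = config or SimulationConfig()
    s = config.lattice_spacing_um
    columns = []
    for w in ALL_WHISKERS:
        r, a = w.grid
        center = ((a - 1) * s, (1 - r) * s)
        columns.append(BarrelColumn(
            whisker=w, centroid=center,
            boundary=_hexagon(center, config.apothem_um),
        ))
    return BarrelMap(columns=tuple(columns))


@dataclass
class GroundTruth:
    """True per-cell state for one session, plus static cell attributes.

    ``surface`` is the expressed true mean-response surface (n_cells, 9);
    dropped-out cells have their surface gated toward zero for that session.
    """

    column: np.ndarray                  # column label or "septal", per cell
    base_responsive: np.ndarray         # latent responsiveness class
    peak: np.ndarray                    # latent peak-whisker index (0..8)
    amplitude: np.ndarray               # peak ΔF/F
    base_surface: np.ndarray            # latent surface (n_cells, 9)
    gate: np.ndarray                    # per-session expression gate (n_cells,)
    initial_cw_tuned: np.ndarray        # CW/non-CW class at session 0

    @property
    def surface(self) -> np.ndarray:
        return self.base_surface * self.gate[:, None]

    @property
    def responsive(self) -> np.ndarray:
        return self.gate > 0.5

    @property
    def true_bw(self) -> np.ndarray:
        """Peak-whisker label per cell (from the latent surface)."""
        return np.array([_LABELS[i] for i in self.peak])

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            column=self.column.copy(),
            base_responsive=self.base_responsive.copy(),
            peak=self.peak.copy(),
            amplitude=self.amplitude.copy(),
            base_surface=self.base_surface.copy(),
            gate=self.gate.copy(),
            initial_cw_tuned=self.initial_cw_tuned.copy(),
        )


def _surface_from_peak(peak: np.ndarray, amplitude: np.ndarray,
                       decay: float) -> np.ndarray:
    """Mean-response surface: amplitude × decay^(grid distance from peak)."""
    d = np.linalg.norm(_GRID[None, :, :] - _GRID[peak][:, None, :], axis=2)
    return amplitude[:, None] * decay ** d


def sample_cells(config: SimulationConfig, barrel_map: BarrelMap,
                 rng: np.random.Generator | None = None
                 ) -> tuple[list[RoiRecord], GroundTruth]:
    """Roster positions plus ground-truth tuning for session 0.

    Positions are uniform over the region within the inclusion radius of any
    column. Peak whiskers mix a columnar bias (``cw_tuned_fraction``), a
    radial gradient (``gradient_strength``) and local cluster adoption at
    ``cluster_scale_um``; with gradient and cluster strength zero, peaks are
    independent of position.
    """
    if rng is None:
        rng = config.rng()
    n_cells = config.cells_per_column * 9
    regions = [scaled_boundary(c, config.inclusion_radius)
               for c in barrel_map.columns]
    import shapely

    minx = min(g.bounds[0] for g in regions)
    miny = min(g.bounds[1] for g in regions)
    maxx = max(g.bounds[2] for g in regions)
    maxy = max(g.bounds[3] for g in regions)
    pts = np.empty((0, 2))
    while pts.shape[0] < n_cells:
        cand = np.c_[rng.uniform(minx, maxx, 4 * n_cells),
                     rng.uniform(miny, maxy, 4 * n_cells)]
        ok = np.zeros(len(cand), dtype=bool)
        for g in regions:
            ok |= shapely.contains_xy(g, cand[:, 0], cand[:, 1])
        pts = np.vstack([pts, cand[ok]])
    pts = pts[:n_cells]
    rois = [
        RoiRecord(roi_id=f"c{i:04d}", field_id="F0",
                  x=float(pts[i, 0]), y=float(pts[i, 1]),
                  cross_session_key=f"c{i:04d}")
        for i in range(n_cells)
    ]

    # columnar assignment of the true roster
    column = np.full(n_cells, "septal", dtype=object)
    col_idx = np.full(n_cells, -1)
    for wi, col in enumerate(barrel_map.columns):
        inside = shapely.contains_xy(col.boundary, pts[:, 0], pts[:, 1])
        column[inside] = col.whisker.label
        col_idx[inside] = wi

    base_responsive = rng.random(n_cells) < config.responsive_fraction

    # distance from each cell to each column centroid, lattice-spacing units
    centroids = np.array([c.centroid for c in barrel_map.columns])
    dists = np.linalg.norm(pts[:, None, :] - centroids[None, :, :], axis=2)
    dists /= config.lattice_spacing_um

    # every cell gets a latent peak and surface; expression is gated, so a
    # wavering non-responsive cell can gain a coherent receptive field
    peak = np.zeros(n_cells, dtype=int)
    for i in range(n_cells):
        weights = np.exp(-config.gradient_strength * dists[i])
        if col_idx[i] >= 0:
            if rng.random() < config.cw_tuned_fraction:
                peak[i] = col_idx[i]
                continue
            weights = weights.copy()
            weights[col_idx[i]] = 0.0
        peak[i] = rng.choice(9, p=weights / weights.sum())

    # local cluster adoption: responsive cells near a seed adopt its peak
    if config.cluster_strength > 0 and config.cluster_seed_fraction > 0:
        resp_idx = np.flatnonzero(base_responsive)
        n_seed = int(round(config.cluster_seed_fraction * resp_idx.size))
        seeds = rng.choice(resp_idx, size=n_seed, replace=False) if n_seed else []
        adopted = peak.copy()
        for s in seeds:
            near = resp_idx[
                np.linalg.norm(pts[resp_idx] - pts[s], axis=1)
                < config.cluster_scale_um
            ]
            for j in near:
                if j != s and rng.random() < config.cluster_strength:
                    adopted[j] = peak[s]
        peak = adopted

    amplitude = np.maximum(
        rng.normal(config.peak_amplitude_mean, config.peak_amplitude_sd,
                   n_cells),
        0.05,
    )
    base_surface = _surface_from_peak(peak, amplitude, config.decay_per_step)

    # optional suppressed (negative-mean) whisker per cell
    if config.suppressed_fraction > 0:
        for i in range(n_cells):
            if rng.random() < config.suppressed_fraction:
                others = [k for k in range(9) if k != peak[i]]
                k = rng.choice(others)
                base_surface[i, k] = -config.suppression_scale * amplitude[i]

    is_columnar = col_idx >= 0
    truth = GroundTruth(
        column=column,
        base_responsive=base_responsive,
        peak=peak,
        amplitude=amplitude,
        base_surface=base_surface,
        gate=base_responsive.astype(float),
        initial_cw_tuned=is_columnar & (peak == np.maximum(col_idx, 0)),
    )
    return rois, truth


def _session_gate(truth: GroundTruth, config: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-session wavering: amplitude gating, not roster removal."""
    gate = truth.base_responsive.astype(float)
    resp = truth.base_responsive
    drop = resp & (rng.random(resp.size) < config.waver_dropout)
    gain = ~resp & (rng.random(resp.size) < config.waver_gain)
    gate[drop] = config.dropout_scale
    gate[gain] = 1.0
    return gate


def simulate_session(rois: list[RoiRecord], truth: GroundTruth,
                     config: SimulationConfig, session_index: int,
                     rng: np.random.Generator | None = None) -> TrialTable:
    """One session's trial table from the session's expressed true surfaces.

    Whisker-trial evoked ΔF/F = true mean × lognormal gain + additive blank
    noise; blank (and tone) trials draw additive noise only. Trial order is
    randomized. Cells whose latent surface is gated off respond like blanks.
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, 17, session_index))
    n_cells = len(rois)
    stim_kind: list[str] = []
    stim_whisker: list[str | None] = []
    for label in _LABELS:
        stim_kind += ["single_whisker"] * config.trials_per_whisker
        stim_whisker += [label] * config.trials_per_whisker
    stim_kind += ["blank"] * config.blank_trials
    stim_whisker += [None] * config.blank_trials
    stim_kind += ["all_whisker"] * config.all_whisker_trials
    stim_whisker += [None] * config.all_whisker_trials
    stim_kind += ["tone"] * config.tone_trials
    stim_whisker += [None] * config.tone_trials
    order = rng.permutation(len(stim_kind))
    stim_kind = [stim_kind[i] for i in order]
    stim_whisker = [stim_whisker[i] for i in order]
    n_trials = len(stim_kind)

    surface = truth.surface  # gated
    means = np.zeros((n_trials, n_cells))
    for t, (kind, w) in enumerate(zip(stim_kind, stim_whisker)):
        if kind == "single_whisker":
            means[t] = surface[:, _LABELS.index(w)]
        elif kind == "all_whisker":
            means[t] = surface.max(axis=1)
    if config.trial_gain_sd > 0:
        gain = rng.lognormal(-config.trial_gain_sd ** 2 / 2.0,
                             config.trial_gain_sd, size=(n_trials, n_cells))
    else:
        gain = 1.0
    noise = (rng.normal(0.0, config.blank_noise_sd, size=(n_trials, n_cells))
             if config.blank_noise_sd > 0 else 0.0)
    dff = means * gain + noise

    lick = rng.random(n_trials) < config.lick_prob
    trials = pd.DataFrame({
        "session_id": f"S{session_index}",
        "trial_index": np.arange(n_trials),
        "stimulus_kind": stim_kind,
        "whisker": pd.array(stim_whisker, dtype="string"),
        "lick": lick,
    })
    dff_frame = pd.DataFrame(dff, columns=[r.roi_id for r in rois])
    return TrialTable(trials=trials, dff=dff_frame)


def apply_drift(truth: GroundTruth, config: SimulationConfig,
                interval: int, rng: np.random.Generator | None = None
                ) -> tuple[GroundTruth, pd.DataFrame]:
    """One inter-session step of bounded tuning drift.

    Selected cells shift their peak to a grid-adjacent whisker in the same
    row or arc (direction resampled if it would leave the grid, never
    clamped); drift probability depends on the cell's current CW/non-CW
    class. Among non-shifting responsive cells, a fraction get a bounded
    BW-preserving surface perturbation (CoM jitter).
    """
    if rng is None:
        rng = np.random.default_rng((config.seed, 23, interval))
    new = truth.copy()
    log_rows = []
    col_to_idx = {label: i for i, label in enumerate(_LABELS)}
    for i in np.flatnonzero(truth.base_responsive):
        is_columnar = truth.column[i] != "septal"
        cw_tuned = is_columnar and truth.peak[i] == col_to_idx[truth.column[i]]
        p_shift = config.drift_cw if cw_tuned else config.drift_noncw
        u = rng.random()
        if u < p_shift:
            neighbors = ALL_WHISKERS[truth.peak[i]].neighbors()
            new_peak = _LABELS.index(rng.choice(neighbors).label)
            new.peak[i] = new_peak
            new.base_surface[i] = _surface_from_peak(
                np.array([new_peak]), truth.amplitude[i : i + 1],
                config.decay_per_step,
            )[0]
            log_rows.append({"roi": i, "kind": "BW_shift",
                             "new_bw": _LABELS[new_peak]})
        elif rng.random() < config.com_jitter_fraction:
            s = new.base_surface[i]
            pk = new.peak[i]
            jitter = 1.0 + rng.uniform(-config.com_jitter_scale,
                                       config.com_jitter_scale, 9)
            perturbed = s * jitter
            perturbed[pk] = s[pk]
            # keep the peak the argmax so BW is preserved
            cap = 0.95 * s[pk]
            mask = np.arange(9) != pk
            perturbed[mask] = np.minimum(perturbed[mask], cap)
            new.base_surface[i] = perturbed
            log_rows.append({"roi": i, "kind": "CoM_jitter", "new_bw": None})
        else:
            log_rows.append({"roi": i, "kind": "none", "new_bw": None})
    log = pd.DataFrame(log_rows, columns=["roi", "kind", "new_bw"])
    log["interval"] = interval
    return new, log


@dataclass
class SimulatedExperiment:
    """A full multi-session synthetic experiment with ground truth."""

    config: SimulationConfig
    barrel_map: BarrelMap
    rois: list[RoiRecord]
    sessions: list[TrialTable]
    truths: list[GroundTruth]           # per-session expressed truth
    change_log: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_experiment(config: SimulationConfig | None = None
                        ) -> SimulatedExperiment:
    """Generate map, roster and all sessions with drift and wavering."""
    config = config or SimulationConfig()
    rng = config.rng()
    barrel_map = make_barrel_map(config)
    rois, truth = sample_cells(config, barrel_map, rng)
    sessions = []
    truths = []
    logs = []
    current = truth
    for s in range(config.n_sessions):
        if s > 0:
            current, log = apply_drift(current, config, interval=s, rng=rng)
            logs.append(log)
        sess_truth = current.copy()
        sess_truth.gate = _session_gate(current, config, rng)
        truths.append(sess_truth)
        sessions.append(simulate_session(rois, sess_truth, config, s, rng))
    change_log = (pd.concat(logs, ignore_index=True) if logs
                  else pd.DataFrame(columns=["roi", "kind", "new_bw", "interval"]))
    return SimulatedExperiment(
        config=config, barrel_map=barrel_map, rois=rois,
        sessions=sessions, truths=truths, change_log=change_log,
    )
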