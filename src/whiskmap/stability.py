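"""Longitudinal tuning- and responsiveness-stability analysis.

A cell tracked across two sessions is classified by its responsiveness
transition (stably non-responsive, gained, lost, stably responsive) and,
when responsive in both, by its tuning change: ΔBW when a new whisker drives
significantly stronger responses than the prior best whisker (equivalently,
the prior BW is no longer an eBW), else ΔCoM when the shift in tuning
center of mass exceeds a trial-shuffle bootstrap null, else stable. The
same tests applied between alternate trials (or halves) of one session give
the within-session false-positive control.

Session pairs are classed by session-index difference Δk; a cell present in
all 4 sessions contributes 3 Δ1, 2 Δ2 and 1 Δ3 records, so population
fractions are estimated by subsampling one record per cell per interval
class (1000 repetitions, percentile 95% CI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._permutation import mc_p, null_mean_diffs
from .data_model import ALL_WHISKERS, AnalysisConfig
from .tuning import _IndicatorCache, com_from_means

__all__ = [
    "DeltaBwResult",
    "DeltaComResult",
    "StabilityRecord",
    "IntervalEstimate",
    "delta_bw_test",
    "delta_com_bootstrap",
    "classify_stability",
    "within_session_control",
    "interval_subsample",
    "group_compare",
    "predict_change",
]

_GRID_ROWS = np.array([w.grid[0] for w in ALL_WHISKERS], dtype=float)
_GRID_ARCS = np.array([w.grid[1] for w in ALL_WHISKERS], dtype=float)
_LABELS = tuple(w.label for w in ALL_WHISKERS)


@dataclass
class DeltaBwResult:
    changed: bool
    new_bw: str | None
    min_p: float


@dataclass
class DeltaComResult:
    changed: bool
    observed: float
    null_threshold: float


def delta_bw_test(trials_s2: dict[str, np.ndarray], prior_bw: str,
                  config: AnalysisConfig | None = None,
                  significant_s2=None,
                  rng: np.random.Generator | None = None,
                  cache: _IndicatorCache | None = None) -> DeltaBwResult:
    """Test whether the prior best whisker is still an eBW in session 2.

    Every whisker significant in session 2 whose mean response exceeds the
    prior BW's is tested one-sided (permutation, uncorrected) against the
    prior BW trials; any rejection at alpha means the BW changed, with the
    new BW the strongest significant session-2 whisker.
    """
    config = config or AnalysisConfig()
    if prior_bw not in trials_s2 or len(trials_s2[prior_bw]) == 0:
        raise ValueError(f"prior BW {prior_bw} not sampled in second session")
    if cache is None:
        if rng is None:
            rng = config.rng(105)
        cache = _IndicatorCache(rng, config.n_permutations)
    candidates = list(trials_s2 if significant_s2 is None else significant_s2)
    prior = np.asarray(trials_s2[prior_bw], float)
    prior_mean = prior.mean()
    min_p = 1.0
    changed = False
    for w in candidates:
        if w == prior_bw:
            continue
        vals = np.asarray(trials_s2[w], float)
        if vals.size == 0 or vals.mean() <= prior_mean:
            continue
        pooled = np.concatenate([vals, prior])
        ind = cache.get(vals.size, pooled.size)
        null = null_mean_diffs(pooled, vals.size, ind)
        p = float(mc_p(null, vals.mean() - prior_mean, "greater"))
        min_p = min(min_p, p)
        if p <= config.alpha:
            changed = True
    if not changed:
        return DeltaBwResult(False, None, min_p)
    means = {w: np.mean(trials_s2[w]) for w in candidates if len(trials_s2[w])}
    new_bw = max(means, key=lambda w: (means[w], -_LABELS.index(w)))
    return DeltaBwResult(True, new_bw, min_p)


def _mean_vector(trials: dict[str, np.ndarray], whiskers) -> np.ndarray:
    out = np.full(len(_LABELS), np.nan)
    for i, label in enumerate(_LABELS):
        if label in whiskers and len(trials.get(label, ())) > 0:
            out[i] = np.mean(trials[label])
    return out


def _com_distance(m1: np.ndarray, m2: np.ndarray) -> float:
    c1 = com_from_means(m1)
    c2 = com_from_means(m2)
    if c1 is None or c2 is None:
        return np.nan
    return float(np.hypot(c1[0] - c2[0], c1[1] - c2[1]))


def delta_com_bootstrap(trials_s1: dict[str, np.ndarray],
                        trials_s2: dict[str, np.ndarray],
                        config: AnalysisConfig | None = None,
                        rng: np.random.Generator | None = None,
                        n_iter: int | None = None,
                        alternative: str = "greater") -> DeltaComResult:
    """Trial-shuffle bootstrap test for a shift in tuning center of mass.

    The null shuffles each whisker's single trials between the two sessions
    (preserving per-session counts) and recomputes ΔCoM; the observed shift
    is called changed when it exceeds the null's 95th percentile (one-sided
    at alpha; ``alternative='two-sided'`` uses the 1−α/2 quantile). Whiskers
    sampled in only one session are excluded from both CoMs.
    """
    config = config or AnalysisConfig()
    if rng is None:
        rng = config.rng(106)
    if n_iter is None:
        n_iter = config.n_bootstrap
    common = [w for w in _LABELS
              if len(trials_s1.get(w, ())) > 0 and len(trials_s2.get(w, ())) > 0]
    if not common:
        raise ValueError("no whisker sampled in both sessions")
    m1 = _mean_vector(trials_s1, common)
    m2 = _mean_vector(trials_s2, common)
    observed = _com_distance(m1, m2)
    null_m1 = np.full((n_iter, len(_LABELS)), np.nan)
    null_m2 = np.full((n_iter, len(_LABELS)), np.nan)
    for label in common:
        a = np.asarray(trials_s1[label], float)
        b = np.asarray(trials_s2[label], float)
        pooled = np.concatenate([a, b])
        ind = rng.random((n_iter, pooled.size)).argsort(axis=1) < a.size
        indf = ind.astype(float)
        sum1 = indf @ pooled
        wi = _LABELS.index(label)
        null_m1[:, wi] = sum1 / a.size
        null_m2[:, wi] = (pooled.sum() - sum1) / b.size
    w1 = np.clip(np.nan_to_num(null_m1, nan=0.0), 0.0, None)
    w2 = np.clip(np.nan_to_num(null_m2, nan=0.0), 0.0, None)
    t1 = w1.sum(axis=1)
    t2 = w2.sum(axis=1)
    valid = (t1 > 0) & (t2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        x1 = (w1 * _GRID_ARCS).sum(axis=1) / t1
        y1 = (w1 * _GRID_ROWS).sum(axis=1) / t1
        x2 = (w2 * _GRID_ARCS).sum(axis=1) / t2
        y2 = (w2 * _GRID_ROWS).sum(axis=1) / t2
    null = np.hypot(x1 - x2, y1 - y2)[valid]
    if null.size == 0 or not np.isfinite(observed):
        return DeltaComResult(False, observed, np.nan)
    q = 1 - config.alpha if alternative == "greater" else 1 - config.alpha / 2
    threshold = float(np.quantile(null, q))
    return DeltaComResult(bool(observed > threshold), float(observed), threshold)


@dataclass
class StabilityRecord:
    """One tracked cell over one session pair."""

    cross_session_key: str
    session_i: int
    session_j: int
    interval: int                      # Δk = j − i in sessions
    transition: str                    # stable_nonresponsive|gained|lost|stable_responsive
    tuning_class: str | None           # stable | delta_bw | delta_com (responsive both)
    new_bw: str | None
    delta_com_magnitude: float


def classify_stability(cross_session_key: str, session_i: int, session_j: int,
                       responsive_i: bool, responsive_j: bool,
                       trials_i: dict[str, np.ndarray] | None,
                       trials_j: dict[str, np.ndarray] | None,
                       prior_bw: str | None = None,
                       significant_j=None,
                       config: AnalysisConfig | None = None,
                       rng: np.random.Generator | None = None,
                       cache: _IndicatorCache | None = None,
                       n_iter: int | None = None) -> StabilityRecord:
    """Responsiveness transition plus (when applicable) the tuning change class."""
    config = config or AnalysisConfig()
    if responsive_i and responsive_j:
        transition = "stable_responsive"
    elif responsive_i:
        transition = "lost"
    elif responsive_j:
        transition = "gained"
    else:
        transition = "stable_nonresponsive"
    tuning_class = None
    new_bw = None
    dcom = np.nan
    if transition == "stable_responsive":
        if trials_i is None or trials_j is None or prior_bw is None:
            raise ValueError("trial data and prior BW required when responsive in both")
        if rng is None:
            rng = config.rng(107)
        bw_res = delta_bw_test(trials_j, prior_bw, config,
                               significant_s2=significant_j, rng=rng, cache=cache)
        common = [w for w in _LABELS
                  if len(trials_i.get(w, ())) > 0 and len(trials_j.get(w, ())) > 0]
        dcom = _com_distance(_mean_vector(trials_i, common),
                             _mean_vector(trials_j, common))
        if bw_res.changed:
            tuning_class = "delta_bw"
            new_bw = bw_res.new_bw
        else:
            com_res = delta_com_bootstrap(trials_i, trials_j, config, rng,
                                          n_iter=n_iter)
            tuning_class = "delta_com" if com_res.changed else "stable"
            dcom = com_res.observed
    return StabilityRecord(
        cross_session_key=cross_session_key,
        session_i=session_i,
        session_j=session_j,
        interval=session_j - session_i,
        transition=transition,
        tuning_class=tuning_class,
        new_bw=new_bw,
        delta_com_magnitude=dcom,
    )


def _split_table(table, mode: str):
    """Two pseudo-session trial tables from one session (per-stimulus split)."""
    from .data_model import TrialTable

    trials = table.trials.reset_index(drop=True)
    key = trials["whisker"].astype("string").fillna(trials["stimulus_kind"])
    rank = trials.groupby(key.to_numpy()).cumcount().to_numpy()
    if mode == "alternate_trials":
        first = rank % 2 == 0
    elif mode == "halves":
        sizes = key.map(key.value_counts()).to_numpy()
        first = rank < sizes // 2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for mask in (first, ~first):
        out.append(TrialTable(
            trials=trials.loc[mask].reset_index(drop=True),
            dff=table.dff.reset_index(drop=True).loc[mask].reset_index(drop=True),
            config=table.config,
        ))
    return out


def within_session_control(table, mode: str = "alternate_trials",
                           config: AnalysisConfig | None = None,
                           rng: np.random.Generator | None = None,
                           n_iter: int | None = None,
                           min_trials: int = 4) -> dict:
    """False-positive control: tuning tests between two halves of one session.

    Splits the session into pseudo-sessions, recomputes responsiveness on
    each, and runs the ΔBW/ΔCoM cascade for cells responsive in both halves.
    Returns the flagged fraction (expected ≈ alpha under the no-change null),
    counts, and the per-cell classes.
    """
    from .responsiveness import compute_response_profiles
    from .tuning import find_bw_and_ebw

    config = config or table.config
    if rng is None:
        rng = config.rng(108)
    half1, half2 = _split_table(table, mode)
    prof1 = compute_response_profiles(half1, config, rng)
    prof2 = compute_response_profiles(half2, config, rng)
    cache = _IndicatorCache(rng, config.n_permutations)
    n_tested = 0
    n_flagged = 0
    n_skipped = 0
    classes: dict[str, str] = {}
    for roi_id in table.roi_ids:
        p1, p2 = prof1[roi_id], prof2[roi_id]
        if not (p1.responsive and p2.responsive):
            continue
        t1 = half1.whisker_evoked(roi_id)
        t2 = half2.whisker_evoked(roi_id)
        if min(len(v) for v in t1.values()) < min_trials or \
           min(len(v) for v in t2.values()) < min_trials:
            n_skipped += 1
            continue
        bw1, _ = find_bw_and_ebw(p1, t1, config, cache=cache)
        sig2 = [p2.whiskers[i] for i in np.flatnonzero(p2.significant_positive)]
        rec = classify_stability(
            roi_id, 0, 1, True, True, t1, t2, prior_bw=bw1,
            significant_j=sig2, config=config, rng=rng, cache=cache,
            n_iter=n_iter,
        )
        classes[roi_id] = rec.tuning_class
        n_tested += 1
        n_flagged += rec.tuning_class in ("delta_bw", "delta_com")
    return {
        "fraction_flagged": (n_flagged / n_tested) if n_tested else np.nan,
        "n_tested": n_tested,
        "n_flagged": n_flagged,
        "n_skipped": n_skipped,
        "classes": classes,
    }


@dataclass
class IntervalEstimate:
    quantity: str
    mean: float
    ci_lo: float
    ci_hi: float
    repetitions: int


def interval_subsample(records: pd.DataFrame, value_column: str,
                       config: AnalysisConfig | None = None,
                       rng: np.random.Generator | None = None,
                       by: str = "interval") -> dict[int, IntervalEstimate]:
    """Unbiased per-interval estimates by drawing one record per cell.

    A cell imaged in all sessions contributes several Δ1/Δ2 records; each
    repetition draws one uniformly per cell per interval class, and the mean
    of the drawn values is recorded. Reported: mean and percentile 95% CI
    over repetitions.
    """
    config = config or AnalysisConfig()
    if rng is None:
        rng = config.rng(109)
    reps = config.subsample_reps
    out: dict[int, IntervalEstimate] = {}
    for interval, grp in records.groupby(by):
        vals = grp[value_column].to_numpy(float)
        cells = grp["cross_session_key"].to_numpy()
        order = np.argsort(cells, kind="stable")
        vals = vals[order]
        cells = cells[order]
        _, starts, counts = np.unique(cells, return_index=True, return_counts=True)
        draws = starts[None, :] + rng.integers(
            0, counts[None, :].repeat(reps, axis=0))
        estimates = vals[draws].mean(axis=1)
        out[int(interval)] = IntervalEstimate(
            quantity=value_column,
            mean=float(estimates.mean()),
            ci_lo=float(np.percentile(estimates, 2.5)),
            ci_hi=float(np.percentile(estimates, 97.5)),
            repetitions=reps,
        )
    return out


def group_compare(a, b, test: str = "fisher_exact"):
    """Standard two-sided group comparisons; returns (statistic, p).

    ``fisher_exact``/``chi2`` take each group as (changed, total) counts;
    ``ranksum``/``ks`` take raw sample vectors.
    """
    if test == "fisher_exact":
        (ka, na), (kb, nb) = a, b
        table = np.array([[ka, na - ka], [kb, nb - kb]])
        res = stats.fisher_exact(table, alternative="two-sided")
        return float(res[0]), float(res[1])
    if test == "chi2":
        (ka, na), (kb, nb) = a, b
        table = np.array([[ka, na - ka], [kb, nb - kb]])
        chi2, p, _, expected = stats.chi2_contingency(table)
        if (expected < 1).any():
            import warnings

            warnings.warn("chi2 expected cell count < 1", stacklevel=2)
        return float(chi2), float(p)
    if test == "ranksum":
        res = stats.ranksums(np.asarray(a, float), np.asarray(b, float))
        return float(res.statistic), float(res.pvalue)
    if test == "ks":
        res = stats.ks_2samp(np.asarray(a, float), np.asarray(b, float))
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


@dataclass
class PredictChangeResult:
    coefficients: pd.Series          # standardized-covariate log-odds
    intercept: float
    cv_auc: float
    fold_aucs: list
    fold_deviances: list


_TUNING_FACTORS = ["location", "sharpness", "magnitude", "cluster_index"]
_RESPONSIVENESS_FACTORS = ["location", "sharpness", "magnitude"]


def predict_change(records: pd.DataFrame, outcome: str = "tuning_change",
                   folds: int = 10,
                   rng_seed: int = 0) -> PredictChangeResult:
    """Logistic model (binomial GLM, logit link) of change vs. initial covariates.

    Covariates are z-scored so coefficient magnitudes are comparable.
    Cells lacking a cluster index (no <20 µm neighbor) get the population
    median plus a missingness indicator. Performance is stratified
    ``folds``-fold cross-validated AUC and per-fold deviance.
    """
    if outcome == "tuning_change":
        factors = list(_TUNING_FACTORS)
    elif outcome == "responsiveness_change":
        factors = list(_RESPONSIVENESS_FACTORS)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    y = records[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; model not identifiable")
    X = records[factors].copy()
    if "cluster_index" in factors:
        missing = X["cluster_index"].isna()
        if missing.any():
            X["cluster_index"] = X["cluster_index"].fillna(
                X["cluster_index"].median())
            X["cluster_index_missing"] = missing.astype(float)
    cols = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (Xv - mu) / sd
    design = sm.add_constant(Xz)
    model = sm.GLM(y, design, family=sm.families.Binomial())
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = model.fit()
        except PerfectSeparationWarning as err:
            raise ValueError(
                "perfect separation detected; coefficients diverge") from err
    if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 50):
        raise ValueError("perfect separation detected; coefficients diverge")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    aucs, devs = [], []
    for train, test in skf.split(Xz, y):
        f = sm.GLM(y[train], design[train], family=sm.families.Binomial()).fit()
        pred = f.predict(design[test])
        eps = 1e-12
        dev = -2 * np.sum(y[test] * np.log(pred + eps)
                          + (1 - y[test]) * np.log(1 - pred + eps))
        devs.append(float(dev))
        if len(np.unique(y[test])) == 2:
            aucs.append(float(roc_auc_score(y[test], pred)))
    return PredictChangeResult(
        coefficients=pd.Series(fit.params[1:], index=cols),
        intercept=float(fit.params[0]),
        cv_auc=float(np.mean(aucs)) if aucs else np.nan,
        fold_aucs=aucs,
        fold_deviances=devs,
    )
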