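"""Scoring and selection of LN rate models: the Er fit-quality measure,
the stepped-Poisson and naturalistic-train test protocols, the four
generalization levels (M, MN, MNW, MNWS), and k-means grouping of fitted
filter parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .characterize import (ActivationFunction, kde_rate, kde_rate_from_counts,
                           measure_activation_function)
from .lnmodel import (FilterParams, LNModel, NeuronSystem, fit_ln_models,
                      predict_ode)
from .neuron_models import ModelSpec, population_counts
from .stimuli import DEFAULT_STEP_SCHEDULE, RateSchedule
from .trains import SpikeTrain

__all__ = [
    "FitQualityRecord",
    "GeneralizedModelSet",
    "ModelGroup",
    "fit_quality_Er",
    "stepped_poisson_test",
    "rgc_train_test",
    "select_optimal",
    "generalize",
    "generalization_quality",
    "cluster_models",
    "fits_dataframe",
    "sweep_er_opt",
]


@dataclass
class FitQualityRecord:
    """Er score of one LN model against one spiking-model response."""

    model: str
    noise: str
    w: float
    a0: float
    a1: float
    stimulus: str
    Er: float
    valid: bool
    n_seeds_valid: int = 0


def fit_quality_Er(r_rate: np.ndarray, r_spike: np.ndarray) -> float:
    """Fit quality Er = 1/(1 + Ebar) on a common uniform grid.

    Ebar is the mean squared difference between rate-model and spiking
    responses normalized by the variance of the spiking response; Er = 1
    is a perfect fit, 1/2 an error equal to the variance.  Returns NaN for
    a (numerically) constant spiking response.
    """
    r_rate = np.asarray(r_rate, dtype=float)
    r_spike = np.asarray(r_spike, dtype=float)
    if r_rate.shape != r_spike.shape:
        raise ValueError("traces must share a common grid")
    var = np.mean((r_spike - r_spike.mean()) ** 2)
    if var <= 1e-12 * max(1.0, r_spike.mean() ** 2):
        return float("nan")
    ebar = np.mean((r_rate - r_spike) ** 2) / var
    return 1.0 / (1.0 + ebar)


def _er_window(n_bins, bin_width, kde_width, filt: FilterParams,
               exclude_warmup: bool):
    """Index window excluding KDE edge bias and optional kernel warm-up."""
    T = n_bins * bin_width
    edge = 3.0 * kde_width
    t0 = edge
    if exclude_warmup:
        t0 = max(t0, min(filt.delay + 3.0 * filt.tau_c2, T / 3.0))
    i0 = int(np.ceil(t0 / bin_width))
    i1 = n_bins - int(np.ceil(edge / bin_width))
    if i1 - i0 < 10:
        i0, i1 = 0, n_bins
    return i0, i1


def stepped_poisson_test(model_spec: ModelSpec,
                         ln_models: Dict[Tuple[float, float], LNModel],
                         noise_preset, w: float,
                         schedule: RateSchedule = DEFAULT_STEP_SCHEDULE,
                         n_neurons: int = 4096, n_seeds: int = 5,
                         dt: float = 0.1, equilibration: float = 1000.0,
                         bin_width: float = 0.05, max_width: float = 15.0,
                         exclude_warmup: bool = True,
                         seed: int = 0) -> List[FitQualityRecord]:
    """Score LN models against the spiking response to stepped Poisson input.

    Simulates a population of ``n_neurons`` independent neurons driven by
    one Poisson process each with the piecewise-constant rate profile,
    pools the output trains, estimates r_spike by KDE and scores each LN
    model's prediction (driven by the known rate profile) with Er.  Seeds
    whose optimal KDE width exceeds ``max_width`` ms are discarded; Er is
    averaged over the remaining seeds.  Responses without spikes yield a
    missing (invalid) record rather than an exception.

    ``model_spec`` may alternatively be any object with a
    ``run(rate_full, n_trials, seed)`` method returning pooled counts
    (e.g. a surrogate Poisson responder), which is then used in place of
    the spiking-population simulation.
    """
    n_equil = int(round(equilibration / dt))
    rate_full = np.concatenate([
        np.full(n_equil, schedule.intervals[0][2]),
        schedule.rate_array(dt)])
    a_in = schedule.rate_array(bin_width)
    preds = {key: predict_ode(m, a_in, dt=bin_width)
             for key, m in ln_models.items()}

    surrogate = not isinstance(model_spec, ModelSpec)
    er_sums = {key: 0.0 for key in ln_models}
    n_valid = 0
    for s in range(n_seeds):
        run_seed = (seed + 15485863 * s) % (2**31 - 1)
        if surrogate:
            counts = model_spec.run(rate_full, n_neurons, run_seed)
        else:
            counts = population_counts(model_spec, rate_full, w,
                                       noise=noise_preset, n=n_neurons,
                                       dt=dt, equilibration=equilibration,
                                       seed=run_seed)
        if counts.sum() == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est = kde_rate_from_counts(counts, n_neurons, dt,
                                       bin_width=bin_width,
                                       max_width=max_width)
        if not est.valid:
            continue
        n_valid += 1
        for key, m in ln_models.items():
            i0, i1 = _er_window(est.rate.size, bin_width, est.width,
                                m.filter, exclude_warmup)
            er = fit_quality_Er(preds[key][i0:i1], est.rate[i0:i1])
            if np.isfinite(er):
                er_sums[key] += er

    noise_name = str(noise_preset)
    records = []
    for (a0, a1), m in ln_models.items():
        if n_valid > 0:
            er = er_sums[(a0, a1)] / n_valid
            records.append(FitQualityRecord(
                model=str(model_spec), noise=noise_name, w=w, a0=a0, a1=a1,
                stimulus="stepped", Er=float(er), valid=True,
                n_seeds_valid=n_valid))
        else:
            records.append(FitQualityRecord(
                model=str(model_spec), noise=noise_name, w=w, a0=a0, a1=a1,
                stimulus="stepped", Er=float("nan"), valid=False,
                n_seeds_valid=0))
    return records


def rgc_train_test(model_spec: ModelSpec,
                   ln_models: Dict[Tuple[float, float], LNModel],
                   noise_preset, w: float, trains: Sequence[SpikeTrain],
                   input_rate: Optional[np.ndarray] = None,
                   n_seeds: int = 5, dt: float = 0.1,
                   equilibration: float = 1000.0, bin_width: float = 0.05,
                   max_width: float = 15.0, exclude_warmup: bool = True,
                   seed: int = 0) -> List[FitQualityRecord]:
    """Score LN models on naturalistic spike-train input.

    Each train drives one model neuron directly (background noise and
    initial conditions vary with the seed); outputs are pooled and scored
    as in :func:`stepped_poisson_test`.  The LN input rate is either the
    known generator rate on the ``bin_width`` grid or, by default, the KDE
    estimate of the input trains themselves.
    """
    T = trains[0].t_stop - trains[0].t_start
    n_equil = int(round(equilibration / dt))
    n_rec = int(round(T / dt))
    n = len(trains)
    w_fixed = np.zeros((n, n_equil + n_rec))
    for i, tr in enumerate(trains):
        idx = n_equil + np.minimum(
            np.floor((tr.times - tr.t_start) / dt + 1e-9).astype(np.int64),
            n_rec - 1)
        np.add.at(w_fixed, (i, idx), 1.0)
    if input_rate is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a_in = kde_rate(list(trains), bin_width=bin_width).rate
    else:
        a_in = np.asarray(input_rate, dtype=float)
    preds = {key: predict_ode(m, a_in, dt=bin_width)
             for key, m in ln_models.items()}

    er_sums = {key: 0.0 for key in ln_models}
    n_valid = 0
    for s in range(n_seeds):
        counts = population_counts(model_spec, 0.0, w, noise=noise_preset,
                                   n=n, T=T, dt=dt,
                                   equilibration=equilibration,
                                   seed=(seed + 32452843 * s) % (2**31 - 1),
                                   fixed_weights=w_fixed)
        if counts.sum() == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est = kde_rate_from_counts(counts, n, dt, bin_width=bin_width,
                                       max_width=max_width)
        if not est.valid:
            continue
        n_valid += 1
        for key, m in ln_models.items():
            i0, i1 = _er_window(est.rate.size, bin_width, est.width,
                                m.filter, exclude_warmup)
            nmin = min(preds[key].size, est.rate.size)
            er = fit_quality_Er(preds[key][:nmin][i0:i1],
                                est.rate[:nmin][i0:i1])
            if np.isfinite(er):
                er_sums[key] += er

    noise_name = str(noise_preset)
    records = []
    for (a0, a1), m in ln_models.items():
        valid = n_valid > 0
        records.append(FitQualityRecord(
            model=str(model_spec), noise=noise_name, w=w, a0=a0, a1=a1,
            stimulus="rgc", Er=float(er_sums[(a0, a1)] / n_valid) if valid
            else float("nan"), valid=valid, n_seeds_valid=n_valid))
    return records


def select_optimal(records: Sequence[FitQualityRecord]
                   ) -> Optional[FitQualityRecord]:
    """Record with the highest Er across working points; None if all missing."""
    valid = [r for r in records if r.valid and np.isfinite(r.Er)]
    if not valid:
        return None
    return max(valid, key=lambda r: r.Er)


def fits_dataframe(fits: Dict) -> pd.DataFrame:
    """Long-format table of fitted filter parameters.

    ``fits`` maps (model, noise, w) -> {(a0, a1) -> LNModel}.
    """
    rows = []
    for (model, noise, w), models in fits.items():
        for (a0, a1), m in models.items():
            p = m.filter
            rows.append({"model": model, "noise": noise, "w": w,
                         "a0": a0, "a1": a1, "gamma1": p.gamma1,
                         "gamma2": p.gamma2, "f_c1": p.f_c1,
                         "f_c2": p.f_c2, "delay": p.delay})
    return pd.DataFrame(rows)


_PARAM_COLS = ["gamma1", "gamma2", "f_c1", "f_c2", "delay"]


def _median_params(df: pd.DataFrame) -> FilterParams:
    med = df[_PARAM_COLS].median()
    return FilterParams(med["gamma1"], med["gamma2"], med["f_c1"],
                        med["f_c2"], med["delay"])


@dataclass
class GeneralizedModelSet:
    """LN models pooled at one of the four generalization levels.

    M:    one model per variant — filter = per-parameter median over all
          conditions; activation = w * gbar(a) with gbar the spline through
          the weight-scaled pooled data g(a)/w.
    MN:   as M but per (variant, noise regime).
    MNW:  per (variant, noise, weight) — per-condition activation, filter
          medians over working points.
    MNWS: per (variant, noise, weight) — per-condition activation, filter
          of the working point with the best stepped-Poisson Er.
    """

    level: str
    filters: Dict = field(default_factory=dict)
    activations: Dict = field(default_factory=dict)

    def _key(self, model, noise, w):
        if self.level == "M":
            return model
        if self.level == "MN":
            return (model, noise)
        return (model, noise, w)

    def model_for(self, model: str, noise: str, w: float) -> LNModel:
        key = self._key(model, noise, w)
        act = self.activations[key]
        if self.level in ("M", "MN"):
            act = act.scaled(w)
        return LNModel(activation=act, filter=self.filters[key],
                       metadata={"generalization": self.level,
                                 "model": model, "noise": noise, "w": w})


def generalize(fits: Dict, activations: Dict, level: str,
               stepped_results: Optional[Sequence[FitQualityRecord]] = None
               ) -> GeneralizedModelSet:
    """Pool per-condition LN fits into one of the generalization levels.

    ``fits`` maps (model, noise, w) -> {(a0, a1) -> LNModel}; ``activations``
    maps (model, noise, w) -> ActivationFunction.  Level "MNWS" requires
    ``stepped_results`` to select the best working point per condition.
    """
    if level not in ("M", "MN", "MNW", "MNWS"):
        raise ValueError(f"unknown generalization level {level!r}")
    df = fits_dataframe(fits)
    out = GeneralizedModelSet(level=level)

    if level in ("M", "MN"):
        group_cols = ["model"] if level == "M" else ["model", "noise"]
        for key, sub in df.groupby(group_cols):
            key = key[0] if len(key) == 1 else tuple(key)
            out.filters[key] = _median_params(sub)
        # pool weight-scaled activation data over the matching conditions
        pooled: Dict = {}
        for (model, noise, w), act in activations.items():
            key = model if level == "M" else (model, noise)
            pooled.setdefault(key, []).append((act, w))
        for key, items in pooled.items():
            grid = items[0][0].a_grid
            for act, _ in items:
                if not np.array_equal(act.a_grid, grid):
                    raise ValueError("activation knot grids must agree for "
                                     "pooled generalization")
            gbar = np.mean([act.r_grid / w for act, w in items], axis=0)
            out.activations[key] = ActivationFunction(
                grid, gbar, metadata={"generalization": level})
        return out

    if level == "MNW":
        for key, sub in df.groupby(["model", "noise", "w"]):
            out.filters[tuple(key)] = _median_params(sub)
            out.activations[tuple(key)] = activations[tuple(key)]
        return out

    # MNWS
    if stepped_results is None:
        raise ValueError("MNWS generalization requires stepped_results")
    recs: Dict = {}
    for r in stepped_results:
        recs.setdefault((r.model, r.noise, r.w), []).append(r)
    for key, rlist in recs.items():
        best = select_optimal(rlist)
        if best is None:
            continue
        sub = df[(df.model == key[0]) & (df.noise == key[1])
                 & (df.w == key[2]) & (df.a0 == best.a0)
                 & (df.a1 == best.a1)]
        if sub.empty:
            continue
        row = sub.iloc[0]
        out.filters[key] = FilterParams(row.gamma1, row.gamma2, row.f_c1,
                                        row.f_c2, row.delay)
        out.activations[key] = activations[key]
    return out


def generalization_quality(Er_X: float, Er_opt: float) -> float:
    """rho_X = Er_X / Er_opt; may exceed 1 when the generalization wins."""
    if not (np.isfinite(Er_X) and np.isfinite(Er_opt)):
        return float("nan")
    if Er_opt <= 0:
        raise ValueError("Er_opt must be positive")
    return Er_X / Er_opt


@dataclass
class ModelGroup:
    """One group of model variants sharing similar filter parameters."""

    group_id: int
    cluster_index: int
    members: List[str]
    median_params: FilterParams
    n_fits: int


def cluster_models(fits_df: pd.DataFrame, k: int = 7, n_init: int = 100,
                   seed: int = 0, log_freq: bool = True):
    """Group model variants by k-means clustering of filter parameters.

    Clusters the standardized 5-dimensional vectors (gamma1, gamma2,
    log10 f_c1, log10 f_c2, delay) of all fitted conditions, counts how
    often each model variant lands in each cluster, and assigns every
    variant to its plurality cluster (ties broken by preferring larger
    clusters, then lower cluster index).  Occupied clusters become model
    groups with per-parameter medians over their member models' fits.

    Returns ``(groups, counts)`` where ``counts`` is the model-by-cluster
    count matrix (rows sum to the number of fits per model).
    """
    from sklearn.cluster import KMeans
    from sklearn.exceptions import ConvergenceWarning

    df = fits_df.dropna(subset=_PARAM_COLS).reset_index(drop=True)
    if len(df) < k:
        raise ValueError(f"need at least {k} parameter sets, got {len(df)}")
    X = df[_PARAM_COLS].to_numpy(dtype=float).copy()
    if log_freq:
        X[:, 2] = np.log10(X[:, 2])
        X[:, 3] = np.log10(X[:, 3])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) % (2**32))
    with warnings.catch_warnings():
        # duplicate parameter sets legitimately occupy fewer than k clusters
        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = km.fit_predict(Z)

    counts = pd.crosstab(df["model"], pd.Series(labels, name="cluster"))
    counts = counts.reindex(columns=range(k), fill_value=0)
    sizes = counts.sum(axis=0)
    # cluster preference: larger total first, then lower index
    order = sorted(range(k), key=lambda c: (-sizes[c], c))
    rank = {c: i for i, c in enumerate(order)}

    assignment = {}
    for model, row in counts.iterrows():
        top = row.max()
        cands = [c for c in range(k) if row[c] == top]
        assignment[model] = min(cands, key=lambda c: rank[c])

    groups = []
    gid = 0
    for c in order:
        members = sorted(m for m, cl in assignment.items() if cl == c)
        if not members:
            continue
        gid += 1
        sub = df[df.model.isin(members)]
        groups.append(ModelGroup(group_id=gid, cluster_index=c,
                                 members=members,
                                 median_params=_median_params(sub),
                                 n_fits=int(len(sub))))
    return groups, counts


def sweep_er_opt(model_class: str, variants: Sequence[str],
                 weights: Sequence[float],
                 noise_regimes: Sequence[str] = ("none", "balanced", "biased"),
                 working_points: Sequence[Tuple[float, float]] = (
                     (100.0, 50.0), (100.0, 100.0),
                     (400.0, 200.0), (400.0, 400.0)),
                 a0_grid: Optional[np.ndarray] = None,
                 activation_duration: float = 4000.0,
                 equilibration: float = 500.0,
                 tf_trials: int = 48, tf_min_duration: float = 1000.0,
                 n_starts: int = 24, n_starts_lowpass: int = 8,
                 n_neurons: int = 512, n_seeds: int = 2,
                 stepped_equilibration: float = 1000.0,
                 seed: int = 0):
    """Run the reduced fit-and-score pipeline over a grid of conditions.

    For every (variant, noise regime, weight) combination: measure the
    activation function, fit LN models at each working point, score them
    on the stepped-Poisson test and record the optimal Er.  Returns
    ``(summary, fits, activations, records)`` where ``summary`` is a
    DataFrame with one row per condition (er_opt NaN when no LN model
    could be fitted or scored).
    """
    if a0_grid is None:
        a0_grid = np.arange(0.0, 1001.0, 20.0)
    fits: Dict = {}
    activations: Dict = {}
    all_records: List[FitQualityRecord] = []
    rows = []
    cond_idx = 0
    for variant in variants:
        spec = ModelSpec(model_class, variant)
        for noise in noise_regimes:
            for w in weights:
                cond_idx += 1
                cseed = (seed + 6700417 * cond_idx) % (2**31 - 1)
                act = measure_activation_function(
                    spec, noise, w, a0_grid=a0_grid,
                    duration=activation_duration,
                    equilibration=equilibration, seed=cseed)
                activations[(str(spec), noise, w)] = act
                system = NeuronSystem(spec, noise=noise, w=w,
                                      equilibration=equilibration)
                models = fit_ln_models(system, act,
                                       working_points=working_points,
                                       n_trials=tf_trials,
                                       n_starts=n_starts,
                                       n_starts_lowpass=n_starts_lowpass,
                                       min_duration=tf_min_duration,
                                       seed=cseed + 1)
                fits[(str(spec), noise, w)] = models
                er_opt = float("nan")
                if models:
                    records = stepped_poisson_test(
                        spec, models, noise, w, n_neurons=n_neurons,
                        n_seeds=n_seeds,
                        equilibration=stepped_equilibration,
                        seed=cseed + 2)
                    all_records.extend(records)
                    best = select_optimal(records)
                    if best is not None:
                        er_opt = best.Er
                rows.append({"model_class": model_class, "variant": variant,
                             "noise": noise, "w": w, "er_opt": er_opt,
                             "n_models": len(models)})
    summary = pd.DataFrame(rows)
    return summary, fits, activations, all_records
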