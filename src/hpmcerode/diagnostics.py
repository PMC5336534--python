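"""Visual predictive checks (VPC), prediction-corrected and censored.

A VPC compares the 5th/50th/95th percentiles of observed released
HPMC, binned on time, against 95% confidence intervals of the same
percentiles computed from many datasets simulated under the model on
the identical design.  Prediction correction normalizes observed and
simulated values to the typical model prediction (no parameter
variability, prior-mean pH) at the bin median, removing design
heterogeneity so all conditions share one panel.  Censored VPC applies
the study's stopping rule (no observations after ~60% of the dose is
released) to each simulated profile, mimicking the magnetic marker
monitoring protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class VpcConfig:
    """VPC settings: number of simulated replicates, percentiles,
    confidence level, time bins, prediction correction and the
    released-fraction censor threshold (None disables censoring)."""

    n_sim: int = 1000
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0)
    ci_level: float = 95.0
    bin_edges: Optional[Sequence[float]] = None
    prediction_corrected: bool = False
    censor_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_sim < 100:
            raise ValueError("n_sim must be at least 100")


@dataclass
class VpcResult:
    """Per-bin observed percentiles and simulated-percentile CIs."""

    table: pd.DataFrame
    config: VpcConfig
    empty_bins: list[int] = field(default_factory=list)

    def coverage(self) -> float:
        """Fraction of (bin, percentile) cells where the observed
        percentile falls inside the simulated CI."""
        t = self.table
        inside = ((t["observed"] >= t["ci_lo"])
                  & (t["observed"] <= t["ci_hi"]))
        return float(inside.mean())


def prediction_correct(obs: np.ndarray, typical_pred_at_obs: np.ndarray,
                       typical_pred_at_bin_median: np.ndarray) -> np.ndarray:
    """Normalize values to the typical prediction at the bin median.

    ``obs * pred(bin median) / pred(t_obs)``; applied identically to
    observed and simulated values.  Zero typical predictions (pre-lag
    bins) must be excluded by the caller.
    """
    pred = np.asarray(typical_pred_at_obs, dtype=float)
    if np.any(pred <= 0):
        raise ValueError("prediction correction needs positive typical "
                         "predictions")
    return np.asarray(obs, float) * np.asarray(
        typical_pred_at_bin_median, float) / pred


def apply_censoring(times: np.ndarray, dv: np.ndarray, dose: float,
                    threshold_fraction: float = 0.60
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Truncate one time-ordered profile at the stopping rule.

    Retains observations up to and including the first whose released
    fraction reaches the threshold; later ones are dropped.
    """
    times = np.asarray(times, dtype=float)
    dv = np.asarray(dv, dtype=float)
    above = np.nonzero(dv / dose >= threshold_fraction)[0]
    if above.size == 0:
        return times, dv
    end = above[0] + 1
    return times[:end], dv[:end]


def _assign_bins(times: np.ndarray, edges: Optional[Sequence[float]]
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Bin index per observation and a bin id array.

    Without explicit edges each unique time is its own bin.
    """
    if edges is None:
        uniq = np.unique(times)
        idx = np.searchsorted(uniq, times)
        return idx, uniq
    edges = np.asarray(edges, dtype=float)
    idx = np.clip(np.digitize(times, edges) - 1, 0, edges.size - 2)
    return idx, edges[:-1]


def _censor_mask(pid_codes: np.ndarray, dv: np.ndarray, dose: np.ndarray,
                 threshold: float) -> np.ndarray:
    """Vectorized stopping rule over time-sorted profiles: keep rows up
    to and including each profile's first threshold crossing."""
    n = dv.size
    starts = np.flatnonzero(np.r_[True, pid_codes[1:] != pid_codes[:-1]])
    group = np.cumsum(np.r_[False, pid_codes[1:] != pid_codes[:-1]])
    pos = np.arange(n)
    above_pos = np.where(dv / dose >= threshold, pos, n)
    first = np.minimum.reduceat(above_pos, starts)
    return pos <= first[group]


def vpc(
    observed: pd.DataFrame,
    simulate: Callable[[np.random.Generator], pd.DataFrame],
    config: VpcConfig,
    rng: np.random.Generator,
    typical_pred: Optional[Callable[[pd.DataFrame], np.ndarray]] = None,
) -> VpcResult:
    """Build a VPC table.

    Parameters
    ----------
    observed : DataFrame
        Long format with columns ``profile_id, time_h, dv_mg`` and,
        when censoring is enabled, ``dose_mg``.
    simulate : callable
        ``simulate(rng) -> DataFrame`` producing one replicate with the
        same columns on the uncensored design grid; censoring and
        prediction correction are applied here, identically to the
        observed data.
    typical_pred : callable, optional
        ``typical_pred(df) -> mg`` giving the no-variability typical
        prediction for each row; required for prediction correction.
        Typical predictions depend only on (profile, time), so they are
        cached across simulation replicates; the bin-median reference
        times of the prediction correction are fixed from the observed
        data and shared by all replicates.
    """
    if config.prediction_corrected and typical_pred is None:
        raise ValueError("prediction correction requires typical_pred")

    pred_cache: dict = {}

    def get_preds(df: pd.DataFrame,
                  times: Optional[np.ndarray] = None) -> np.ndarray:
        t = df["time_h"].to_numpy() if times is None else times
        keys = list(zip(df["profile_id"].to_numpy(), t))
        missing = [i for i, k in enumerate(keys) if k not in pred_cache]
        if missing:
            sub = df.iloc[missing].copy()
            sub["time_h"] = t[missing]
            vals = np.asarray(typical_pred(sub), dtype=float)
            for i, v in zip(missing, vals):
                pred_cache[keys[i]] = float(v)
        return np.array([pred_cache[k] for k in keys])

    # reference times of the prediction correction: per-bin medians of
    # the observed (censored) data, fixed across replicates
    ref_time_of_bin: dict = {}

    def prepare(df: pd.DataFrame) -> pd.DataFrame:
        df = df.sort_values(["profile_id", "time_h"],
                            kind="stable").reset_index(drop=True)
        if config.censor_fraction is not None:
            codes = pd.factorize(df["profile_id"])[0]
            keep = _censor_mask(codes, df["dv_mg"].to_numpy(dtype=float),
                                df["dose_mg"].to_numpy(dtype=float),
                                config.censor_fraction)
            df = df[keep].reset_index(drop=True)
        idx, _ = _assign_bins(df["time_h"].to_numpy(), config.bin_edges)
        df["bin"] = idx
        if config.prediction_corrected:
            pred = get_preds(df)
            ok = pred > 0
            if not np.all(ok):
                warnings.warn("observations with zero typical prediction "
                              "excluded from prediction correction",
                              RuntimeWarning)
                df, pred = df[ok].reset_index(drop=True), pred[ok]
            if not ref_time_of_bin:
                for b, grp in df.groupby("bin"):
                    ref_time_of_bin[int(b)] = float(grp["time_h"].median())
            ref_times = df["bin"].map(ref_time_of_bin).to_numpy(float)
            pred_ref = get_preds(df, times=ref_times)
            df["dv_mg"] = prediction_correct(df["dv_mg"].to_numpy(),
                                             pred, pred_ref)
        return df

    obs = prepare(observed)
    bins = np.sort(obs["bin"].unique())

    def percentiles_by_bin(df: pd.DataFrame) -> np.ndarray:
        out = np.full((bins.size, len(config.percentiles)), np.nan)
        bin_arr = df["bin"].to_numpy()
        dv = df["dv_mg"].to_numpy()
        for i, b in enumerate(bins):
            vals = dv[bin_arr == b]
            if vals.size:
                out[i] = np.percentile(vals, config.percentiles)
        return out

    obs_pct = percentiles_by_bin(obs)
    sim_pcts = np.empty((config.n_sim, bins.size, len(config.percentiles)))
    for k in range(config.n_sim):
        sim_pcts[k] = percentiles_by_bin(prepare(simulate(rng)))

    alpha = (100.0 - config.ci_level) / 2.0
    with np.errstate(invalid="ignore"):
        ci_lo = np.nanpercentile(sim_pcts, alpha, axis=0)
        ci_hi = np.nanpercentile(sim_pcts, 100.0 - alpha, axis=0)

    rows = []
    empty = []
    counts = obs.groupby("bin")["dv_mg"].size()
    for i, b in enumerate(bins):
        n_b = int(counts.get(b, 0))
        if n_b == 0:
            empty.append(int(b))
            continue
        for j, q in enumerate(config.percentiles):
            rows.append({"bin": int(b),
                         "time_median": float(
                             obs.loc[obs["bin"] == b, "time_h"].median()),
                         "percentile": q, "n_obs": n_b,
                         "observed": obs_pct[i, j],
                         "ci_lo": ci_lo[i, j], "ci_hi": ci_hi[i, j]})
    return VpcResult(pd.DataFrame(rows), config, empty)
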