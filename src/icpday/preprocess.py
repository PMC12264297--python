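"""First-day ICP series preprocessing.

Raw chart events are irregular in time.  The pipeline regularizes them onto a
24-slot hourly grid (nearest-hour rounding, averaging duplicates), excludes
subjects with monitoring gaps of more than 6 consecutive hours, fills the
remaining gaps by linear interpolation (flat at the day's edges), and derives
the per-subject daily summaries ICP_mean (mmHg) and ICP_variance (mmHg^2,
sample variance).  For clustering, the cohort series matrix is normalized
per time-point (column z-scores by default; min-max optionally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HourlySeries",
    "round_to_hour",
    "gap_exclude",
    "impute_series",
    "summarize",
    "normalize_matrix",
    "denormalize_matrix",
    "build_series_table",
    "aggregate_first_day",
    "MAX_GAP_HOURS",
]

MAX_GAP_HOURS = 6  # a run of missing slots strictly longer than this excludes


@dataclass
class HourlySeries:
    """One subject's completed 24-point first-day series."""

    subject_id: object
    values: np.ndarray          # 24 floats, mmHg, after imputation
    observed_mask: np.ndarray   # 24 bools, True where a measurement existed
    icp_mean: float
    icp_variance: float
    excluded: bool
    exclusion_reason: str | None = None


def round_to_hour(
    events: pd.DataFrame, day_start: pd.Timestamp,
    time_col: str = "charttime", value_col: str = "icp_mmHg",
) -> tuple[np.ndarray, np.ndarray]:
    """Assign events to nearest-hour slots of the 24-h window at ``day_start``.

    Multiple events rounding to one slot are averaged; ties at the half hour
    round up; events rounding to slot 24 (i.e. within the last half hour) are
    clamped to slot 23.  Returns ``(values, observed_mask)`` of length 24; an
    empty event set yields a fully-missing series.
    """
    values = np.full(24, np.nan)
    mask = np.zeros(24, dtype=bool)
    if len(events) == 0:
        return values, mask
    hours = (
        (pd.to_datetime(events[time_col]) - pd.Timestamp(day_start))
        / pd.Timedelta(hours=1)
    ).to_numpy(dtype=float)
    if (hours < 0).any() or (hours >= 24).any():
        raise ValueError("all events must fall within the 24-h window from day_start")
    slots = np.minimum(np.floor(hours + 0.5).astype(int), 23)
    vals = pd.to_numeric(events[value_col]).to_numpy(dtype=float)
    sums = np.bincount(slots, weights=vals, minlength=24)
    counts = np.bincount(slots, minlength=24)
    mask = counts > 0
    values[mask] = sums[mask] / counts[mask]
    return values, mask


def gap_exclude(mask: np.ndarray, max_gap: int = MAX_GAP_HOURS) -> bool:
    """True iff the series is unusable: all-missing, or any run of
    consecutive missing slots (edges included) longer than ``max_gap``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (24,):
        raise ValueError("mask must have length 24")
    if not mask.any():
        return True
    run = longest = 0
    for observed in mask:
        run = 0 if observed else run + 1
        longest = max(longest, run)
    return longest > max_gap


def impute_series(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Complete a 24-slot series: linear interpolation between observed
    neighbours, flat carry at the edges.  Observed entries pass unchanged."""
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(values, dtype=float)
    if not mask.any():
        raise ValueError("cannot impute a fully-missing series")
    idx = np.arange(24)
    # np.interp is linear inside the observed range and flat beyond it
    return np.interp(idx, idx[mask], values[mask])


def summarize(completed: np.ndarray) -> tuple[float, float]:
    """(ICP_mean, ICP_variance) of a completed 24-vector; variance uses n-1."""
    completed = np.asarray(completed, dtype=float)
    return float(completed.mean()), float(completed.var(ddof=1))


def normalize_matrix(
    matrix: np.ndarray, method: str = "zscore"
) -> tuple[np.ndarray, dict]:
    """Normalize each time-point column across the cohort.

    ``zscore`` centers and scales to unit sample sd; ``minmax`` maps the
    column range to [0, 1].  Degenerate (constant) columns map to zeros.
    Returns the normalized matrix and the parameters needed to invert.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n x 24 matrix with n >= 2")
    if method == "zscore":
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        scale = np.where(sd > 0, sd, 1.0)
        Z = (X - mu) / scale
        Z[:, sd == 0] = 0.0
        return Z, {"method": "zscore", "center": mu, "scale": sd}
    if method == "minmax":
        lo, hi = X.min(axis=0), X.max(axis=0)
        rng = hi - lo
        scale = np.where(rng > 0, rng, 1.0)
        Z = (X - lo) / scale
        Z[:, rng == 0] = 0.0
        return Z, {"method": "minmax", "center": lo, "scale": rng}
    raise ValueError(f"unknown normalization method: {method!r}")


def denormalize_matrix(Z: np.ndarray, params: dict) -> np.ndarray:
    """Affine inverse of :func:`normalize_matrix` (degenerate columns return
    their constant value)."""
    scale = np.where(params["scale"] > 0, params["scale"], 0.0)
    return np.asarray(Z, float) * scale + params["center"]


def build_series_table(
    chartevents: pd.DataFrame,
    day_starts: pd.Series,
    max_gap: int = MAX_GAP_HOURS,
) -> pd.DataFrame:
    """Per-subject hourly series with exclusion flags and daily summaries.

    ``day_starts`` maps subject_id -> ICU admission timestamp.  Subjects with
    no chart events at all are kept with a 'no ICP monitoring' exclusion, so
    cohort accounting stays conserved.
    """
    recs = []
    grouped = dict(iter(chartevents.groupby("subject_id", sort=False)))
    for sid, start in day_starts.items():
        ev = grouped.get(sid)
        if ev is None or len(ev) == 0:
            values, mask = np.full(24, np.nan), np.zeros(24, bool)
        else:
            values, mask = round_to_hour(ev, pd.Timestamp(start))
        excluded = gap_exclude(mask, max_gap)
        if excluded:
            reason = "no ICP monitoring" if not mask.any() else f"monitoring gap > {max_gap} h"
            completed = np.full(24, np.nan)
            icp_mean = icp_var = np.nan
        else:
            reason = None
            completed = impute_series(values, mask)
            icp_mean, icp_var = summarize(completed)
        rec = {"subject_id": sid, "excluded": excluded, "exclusion_reason": reason,
               "icp_mean": icp_mean, "icp_variance": icp_var}
        rec.update({f"h{h:02d}": completed[h] for h in range(24)})
        rec.update({f"obs{h:02d}": bool(mask[h]) for h in range(24)})
        recs.append(rec)
    return pd.DataFrame(recs)


def series_matrix(series_table: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    """Retained subjects' completed series as an n x 24 matrix."""
    kept = series_table.loc[~series_table["excluded"]]
    cols = [f"h{h:02d}" for h in range(24)]
    return kept[cols].to_numpy(dtype=float), pd.Index(kept["subject_id"])


def aggregate_first_day(
    measurements: pd.DataFrame,
    agg_map: dict[str, str],
    subject_col: str = "subject_id",
    variable_col: str = "variable",
    value_col: str = "value",
) -> pd.DataFrame:
    """Reduce timestamped first-day covariate measurements per subject.

    ``agg_map`` assigns each variable its clinical aggregation: ``mean`` for
    vitals, ``min``/``max`` for labs, ``min`` for GCS.  Output columns are
    named ``<variable>_<agg>`` (plain ``fluid_input``/``urine_output`` sums
    combine into ``fluid_balance_ml`` when both are present).  Variables with
    no measurements for a subject come out missing, not as an error.
    """
    frames = {}
    for var, how in agg_map.items():
        sub = measurements.loc[measurements[variable_col] == var]
        if how not in ("mean", "min", "max", "sum"):
            raise ValueError(f"unsupported aggregation {how!r} for {var!r}")
        agg = sub.groupby(subject_col)[value_col].agg(how)
        frames[f"{var}_{how}" if how != "sum" else var] = agg
    out = pd.DataFrame(frames)
    if {"fluid_input", "urine_output"} <= set(out.columns):
        out["fluid_balance_ml"] = out["fluid_input"] - out["urine_output"]
    out.index.name = subject_col
    return out.reset_index()
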