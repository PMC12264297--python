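"""Kaplan-Meier estimation, log-rank testing and minimum-p cut-point search.

The cut-point procedure mirrors the X-tile style of marker dichotomization:
every distinct rounded marker value that leaves both groups large enough is
tried as a threshold, the two-group log-rank test is computed for each, and
the cut with the smallest p-value wins.  Because the minimum over many tests
is anti-conservative, a Sidak-style minimum-p correction over the number of
candidates is reported alongside the raw p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import KaplanMeierFitter

__all__ = [
    "CutpointResult",
    "km_estimate",
    "logrank",
    "scan_cutpoints",
    "dichotomize",
]


@dataclass
class CutpointResult:
    best_cut: float | None
    chi_square: float | None
    p_value: float | None
    corrected_p: float | None
    group_sizes: tuple[int, int] | None
    scan_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def found(self) -> bool:
        return self.best_cut is not None


def km_estimate(times, events) -> KaplanMeierFitter:
    """Product-limit survival estimate of ICU-stay survival.

    ``times`` are hours from ICU admission; ``events`` flag ICU death (True)
    vs censoring at discharge.  Returns the fitted estimator; evaluate with
    ``.predict(t)`` or ``.survival_function_``.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=np.asarray(events, dtype=bool))
    return kmf


def logrank(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test.

    Sums observed-minus-expected events in group 1 across distinct event
    times under the hypergeometric null, with the matching variance; the
    statistic is chi-square with 1 df.  Both groups must be non-empty.
    Returns ``(chi_square, p_value)``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group, dtype=bool)
    if not group.any() or group.all():
        raise ValueError("both groups must be non-empty")

    event_times = np.unique(times[events])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        dead = at_risk & events & (times == t)
        d = dead.sum()
        d1 = (dead & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def dichotomize(marker, cut: float) -> np.ndarray:
    """High-marker indicator: True where ``marker > cut`` (the low group is
    ``marker <= cut``, matching the '<= 14 mmHg' reporting convention)."""
    return np.asarray(marker, dtype=float) > cut


def scan_cutpoints(
    marker,
    times,
    events,
    min_group_frac: float = 0.05,
    rounding: int = 0,
) -> CutpointResult:
    """Minimum-p log-rank scan over rounded candidate thresholds.

    Candidates are the distinct values of the marker rounded to ``rounding``
    decimals (integers by default, as cut-offs are reported in whole marker
    units); a candidate is admissible when both ``marker <= c`` and
    ``marker > c`` hold at least ``min_group_frac`` of the cohort.  The best
    cut minimizes the raw log-rank p (ties: larger chi-square, then smaller
    cut).  ``corrected_p = 1 - (1 - p_min)^m`` over the m candidates tried.
    """
    marker = np.asarray(marker, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = marker.size
    if np.isnan(marker).any():
        raise ValueError("marker values must be non-missing")
    min_count = max(1, int(np.ceil(min_group_frac * n)))
    candidates = np.unique(np.round(marker, rounding))

    rows = []
    for c in candidates:
        high = marker > c
        n_high = int(high.sum())
        n_low = n - n_high
        if n_low < min_count or n_high < min_count:
            continue
        chi2, p = logrank(times, events, high)
        rows.append({"cut": float(c), "chi_square": chi2, "p_value": p,
                     "n_low": n_low, "n_high": n_high})
    table = pd.DataFrame(rows)
    if table.empty:
        return CutpointResult(None, None, None, None, None, table)
    best = table.sort_values(
        ["p_value", "chi_square", "cut"], ascending=[True, False, True], kind="stable"
    ).iloc[0]
    m = len(table)
    corrected = float(min(1.0, 1.0 - (1.0 - best["p_value"]) ** m))
    return CutpointResult(
        best_cut=float(best["cut"]),
        chi_square=float(best["chi_square"]),
        p_value=float(best["p_value"]),
        corrected_p=corrected,
        group_sizes=(int(best["n_low"]), int(best["n_high"])),
        scan_table=table,
    )
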