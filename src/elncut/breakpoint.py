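"""LOWESS smoothing and Chow-test structural-break detection.

The effect series (odds ratios, hazard ratios, mean positive nodes,
occult probability) are smoothed with a LOWESS smoother (bandwidth 2/3 by
default) and scanned for a structural break with the classic Chow F test:
for each candidate split c, two segment lines are compared against one
pooled line,

    F = ((RSS_pooled - RSS1 - RSS2) / k) / ((RSS1 + RSS2) / (n - 2k)),

with k = 2 parameters per segment, referred to F(k, n - 2k).  The scan
maximizes F over candidates; reported p-values are nominal fixed-candidate
p-values (maximum selection inflates the type-I error, which is
documented, not corrected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "SmoothedSeries",
    "BreakpointResult",
    "CutpointSelection",
    "lowess_fit",
    "chow_scan",
    "select_cutpoint",
]


@dataclass
class SmoothedSeries:
    """A series with its LOWESS fit evaluated at the observed x positions."""

    x: np.ndarray
    raw: np.ndarray
    fitted: np.ndarray
    bandwidth: float


@dataclass
class BreakpointResult:
    """Chow-scan output over one series."""

    scan: pd.DataFrame          # columns: candidate, f_stat, p_value
    selected_break: float
    f_at_break: float
    p_at_break: float
    candidate_range: tuple[float, float]
    skipped: list = field(default_factory=list)


@dataclass
class CutpointSelection:
    """Survival-priority cut point with the cross-series concordance report."""

    cutpoint: float
    survival_key: str
    breaks: dict
    spread: tuple[float, float]


def lowess_fit(x, y, bandwidth: float = 2.0 / 3.0, iterations: int = 3) -> SmoothedSeries:
    """Locally weighted regression fit evaluated at the input positions.

    ``bandwidth`` is the fraction of points in each local neighbourhood;
    ``iterations`` robustifying reweights (3 matches the classic default).
    Deterministic for fixed input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 5:
        raise ValueError(f"need at least 5 points to smooth, got {len(x)}")
    if not 0 < bandwidth <= 1:
        raise ValueError(f"bandwidth must lie in (0, 1], got {bandwidth}")
    order = np.argsort(x, kind="stable")
    fitted_sorted = _sm_lowess(y[order], x[order], frac=bandwidth, it=iterations,
                               return_sorted=False)
    fitted = np.empty_like(fitted_sorted)
    fitted[order] = fitted_sorted
    return SmoothedSeries(x=x, raw=y, fitted=fitted, bandwidth=bandwidth)


def _rss_line(x: np.ndarray, y: np.ndarray) -> float:
    # least-squares line through (x, y); residual sum of squares
    X = np.column_stack([np.ones_like(x), x])
    _, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if len(rss) == 0:  # rank-deficient (e.g. 2 points): exact fit
        beta = np.linalg.pinv(X) @ y
        return float(((y - X @ beta) ** 2).sum())
    return float(rss[0])


def chow_scan(series, candidate_range: tuple[float, float] | None = None,
              min_segment: int = 3, use_fitted: bool = True) -> BreakpointResult:
    """Scan candidate split points with the Chow F test; pick the max-F break.

    ``series`` is a :class:`SmoothedSeries` (the fitted values are scanned
    unless ``use_fitted`` is False) or an ``(x, y)`` pair.  Candidates that
    would leave a segment with fewer than ``min_segment`` points are
    recorded as skipped, never silently dropped.
    """
    if isinstance(series, SmoothedSeries):
        x = series.x
        y = series.fitted if use_fitted else series.raw
    else:
        x, y = (np.asarray(a, dtype=float) for a in series)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    n = len(x)
    if n < 2 * min_segment:
        raise ValueError(f"series of length {n} cannot hold two segments of {min_segment}")

    xs = np.unique(x)
    lo = xs[min_segment - 1] if candidate_range is None else candidate_range[0]
    hi = xs[-min_segment - 1] if candidate_range is None else candidate_range[1]
    candidates = xs[(xs >= lo) & (xs <= hi)]

    k = 2  # parameters per segment line
    rss_pooled = _rss_line(x, y)
    scale = max(float(np.var(y)) * n, 1e-12)
    rows, skipped = [], []
    for c in candidates:
        left = x <= c
        n1, n2 = int(left.sum()), int((~left).sum())
        if n1 < min_segment or n2 < min_segment or n - 2 * k <= 0:
            skipped.append(float(c))
            continue
        rss1 = _rss_line(x[left], y[left])
        rss2 = _rss_line(x[~left], y[~left])
        num = (rss_pooled - rss1 - rss2) / k
        den = (rss1 + rss2) / (n - 2 * k)
        if rss_pooled <= 1e-12 * scale:      # already a perfect single line
            f_stat, p = 0.0, 1.0
        elif den <= 1e-12 * scale / n:       # segments fit exactly, pooled does not
            f_stat, p = np.inf, 0.0
        else:
            f_stat = max(num / den, 0.0)
            p = float(stats.f.sf(f_stat, k, n - 2 * k))
        rows.append((float(c), float(f_stat), p))
    if not rows:
        raise ValueError(
            f"candidate range [{lo}, {hi}] leaves no candidate with two segments "
            f"of at least {min_segment} points")
    scan = pd.DataFrame(rows, columns=["candidate", "f_stat", "p_value"])
    # a kink point lies on both segment lines, so on noiseless input the
    # candidates c-1 and c tie; report the largest candidate at the max
    best = scan.index[scan["f_stat"] == scan["f_stat"].max()][-1]
    return BreakpointResult(
        scan=scan,
        selected_break=float(scan.loc[best, "candidate"]),
        f_at_break=float(scan.loc[best, "f_stat"]),
        p_at_break=float(scan.loc[best, "p_value"]),
        candidate_range=(float(lo), float(hi)),
        skipped=skipped,
    )


def select_cutpoint(results: dict[str, BreakpointResult],
                    survival_key: str = "survival",
                    spread_warn: float = 6.0) -> CutpointSelection:
    """Survival-priority cut-point selection with a concordance report.

    Survival drives the choice; the other series (stage-migration odds,
    occult probability, mean positive nodes) are reported as a min-max
    spread, with a warning when they disagree by more than ``spread_warn``.
    """
    if survival_key not in results:
        raise ValueError(
            f"no survival-series result under key {survival_key!r}; "
            f"got keys {sorted(results)}")
    breaks = {name: res.selected_break for name, res in results.items()}
    values = list(breaks.values())
    spread = (min(values), max(values))
    if spread[1] - spread[0] > spread_warn:
        warnings.warn(
            f"break points disagree across series by more than {spread_warn} "
            f"(range {spread[0]}-{spread[1]})", stacklevel=2)
    return CutpointSelection(
        cutpoint=results[survival_key].selected_break,
        survival_key=survival_key,
        breaks=breaks,
        spread=spread,
    )
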