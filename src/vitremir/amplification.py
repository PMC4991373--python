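"""Amplification-curve modelling: Ct calling and efficiency estimation.

A qPCR reaction in its exponential phase multiplies template by a constant
base E per cycle, so log fluorescence is linear in cycle number with slope
log10(E).  The per-reaction efficiency is estimated by the window-of-linearity
method: after baseline subtraction, a fixed-length window is slid across the
log10 trace and the window with maximal R-squared yields base = 10^slope.
Efficiency is expressed here as a percentage of perfect doubling
(percent = 100 * base / 2, so base 1.7 -> 85%, base 1.75 -> 87.5%), which is
the convention used with the 80%-efficiency exclusion cutoff downstream.

The fitting baseline is not taken as a fixed early-cycle summary: a constant
offset b is chosen to maximize the best-window R-squared of log10(F - b)
(bracketed by the median of the first five cycles).  On a noise-free
exponential trace this recovers the true base to machine precision, which a
fixed early-cycle median cannot do because the growing signal leaks into it.
Ct calling, in contrast, uses the plain median-of-first-5-cycles baseline:
the threshold sits far above baseline so the residual is immaterial there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import EstimationError, QcError

DETECTION_LIMIT = 40.0
_N_BASELINE_CYCLES = 5


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Per-reaction amplification base with its log-linear fit diagnostics."""

    base: float
    window: tuple[int, int]
    fit_r2: float

    @property
    def percent(self) -> float:
        """Efficiency as % of perfect doubling: 100 * base / 2."""
        return 100.0 * self.base / 2.0


def _as_arrays(curve) -> tuple[np.ndarray, np.ndarray]:
    """Accept a (cycles, fluorescence) pair or a long-format DataFrame slice."""
    if hasattr(curve, "columns"):
        sub = curve.sort_values("cycle")
        return sub["cycle"].to_numpy(dtype=float), sub["fluorescence"].to_numpy(dtype=float)
    cycles, fluor = curve
    return np.asarray(cycles, dtype=float), np.asarray(fluor, dtype=float)


def baseline_median(fluor: np.ndarray, n_cycles: int = _N_BASELINE_CYCLES) -> float:
    """Background fluorescence as the median of the first ``n_cycles`` cycles."""
    return float(np.median(fluor[:n_cycles]))


def call_ct(curve, threshold: float, baseline: float | None = None) -> float:
    """Fractional cycle at which baseline-subtracted fluorescence crosses ``threshold``.

    Interpolation is linear in log fluorescence between the bracketing
    cycles (consistent with exponential growth); returns NaN (undetected)
    when the trace never crosses within the 40-cycle detection limit.

    Raises QcError for a non-monotone trace with no discernible exponential
    rise leading into the crossing.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    cycles, fluor = _as_arrays(curve)
    if baseline is None:
        baseline = baseline_median(fluor)
    corrected = fluor - baseline

    in_range = cycles <= DETECTION_LIMIT
    above = (corrected >= threshold) & in_range
    if not above.any():
        return float("nan")
    k = int(np.argmax(above))
    if np.isclose(corrected[k], threshold):
        return float(cycles[k])
    if k == 0:
        return float(cycles[0])
    # require a rising stretch into the crossing: an exponential phase
    lo = max(0, k - 3)
    if not np.all(np.diff(fluor[lo : k + 1]) > 0):
        raise QcError("no exponential phase detectable before threshold crossing")
    f_lo, f_hi = corrected[k - 1], corrected[k]
    if f_lo <= 0:
        frac = (threshold - f_lo) / (f_hi - f_lo)  # linear fallback
    else:
        frac = (np.log(threshold) - np.log(f_lo)) / (np.log(f_hi) - np.log(f_lo))
    return float(cycles[k - 1] + frac * (cycles[k] - cycles[k - 1]))


def _window_fits(log_f: np.ndarray, cycles: np.ndarray, width: int) -> list[tuple[float, float, tuple[int, int]]]:
    """(r2, slope, (first_cycle, last_cycle)) for every finite window of ``width``."""
    fits = []
    n = len(log_f)
    for start in range(0, n - width + 1):
        sl = slice(start, start + width)
        x, y = cycles[sl], log_f[sl]
        if not np.all(np.isfinite(y)):
            continue
        res = stats.linregress(x, y)
        fits.append((res.rvalue**2, res.slope, (int(x[0]), int(x[-1]))))
    return fits


def _best_window(log_f: np.ndarray, cycles: np.ndarray, width: int, r2_slack: float = 0.005):
    """Steepest window among those within ``r2_slack`` of the maximal R^2.

    Pure max-R^2 selection drifts into the saturating phase, where the
    curve is still smooth (high R^2) but the log slope is biased low; the
    true exponential phase is the steepest log-linear stretch, so among
    near-equally-linear windows the one with maximal slope is taken.
    """
    fits = _window_fits(log_f, cycles, width)
    if not fits:
        return -np.inf, np.nan, (0, 0)
    r2_max = max(f[0] for f in fits)
    candidates = [f for f in fits if f[0] >= r2_max - r2_slack]
    return max(candidates, key=lambda f: f[1])


def estimate_efficiency(
    curve,
    *,
    window: int = 6,
    r2_floor: float = 0.98,
    plateau_frac: float = 0.9,
) -> EfficiencyEstimate:
    """Window-of-linearity efficiency estimate from a raw fluorescence trace.

    Parameters
    ----------
    window : sliding-window length in cycles (must be >= 4).
    r2_floor : minimum acceptable R^2 of the best window; below it the
        reaction is flagged for exclusion (EstimationError), the
        operational meaning of a "weak amplification curve".
    plateau_frac : cycles where the signal exceeds this fraction of the
        plateau are excluded from the fit.
    """
    if window < 4:
        raise ValueError("window must span at least 4 cycles")
    cycles, fluor = _as_arrays(curve)
    if len(fluor) < window + _N_BASELINE_CYCLES:
        raise EstimationError("trace too short for efficiency estimation")

    b0 = baseline_median(fluor)
    b_hi = float(min(np.min(fluor), b0)) * (1.0 - 1e-9)
    b_hi = max(b_hi, 0.0)

    def neg_best_r2(b: float) -> float:
        corrected = fluor - b
        with np.errstate(divide="ignore", invalid="ignore"):
            log_f = np.where(corrected > 0, np.log10(np.where(corrected > 0, corrected, 1.0)), np.nan)
        peak = np.nanmax(corrected)
        log_f[corrected > plateau_frac * peak] = np.nan
        r2, _, _ = _best_window(log_f, cycles, window)
        return -r2 if np.isfinite(r2) else np.inf

    # coarse grid then local refinement over the baseline offset
    grid = np.linspace(0.0, b_hi, 21) if b_hi > 0 else np.array([0.0])
    scores = np.array([neg_best_r2(b) for b in grid])
    b_best = float(grid[int(np.argmin(scores))])
    if b_hi > 0:
        lo = max(0.0, b_best - (grid[1] - grid[0]))
        hi = min(b_hi, b_best + (grid[1] - grid[0]))
        if hi > lo:
            res = optimize.minimize_scalar(neg_best_r2, bounds=(lo, hi), method="bounded")
            if res.fun <= neg_best_r2(b_best):
                b_best = float(res.x)

    corrected = fluor - b_best
    peak = np.nanmax(corrected)
    if not peak > 0:
        raise EstimationError("no exponential phase detectable")

    def transformed(fmax: float) -> np.ndarray:
        """log10 of the back-extrapolated exponential component.

        For the saturating model F = Fmax*x/(Fmax+x) the component
        x = F*Fmax/(Fmax-F) is exactly exponential, so fitting its log
        removes the plateau bias; fmax = inf degrades to the plain log.
        """
        with np.errstate(divide="ignore", invalid="ignore"):
            if np.isinf(fmax):
                y = np.where(corrected > 0, np.log10(np.abs(corrected)), np.nan)
                y[corrected > plateau_frac * peak] = np.nan
            else:
                ok = (corrected > 0) & (corrected < 0.995 * fmax)
                y = np.full_like(corrected, np.nan)
                y[ok] = np.log10(corrected[ok]) - np.log10(1.0 - corrected[ok] / fmax)
        return y

    # candidate plateaus: none (pure exponential) or slightly above the peak
    fmax_grid = [np.inf] + list(peak / np.array([0.999, 0.995, 0.99, 0.97, 0.95, 0.9, 0.8, 0.6]))
    r2, slope, win = -np.inf, np.nan, (0, 0)
    for fmax in fmax_grid:
        r2_c, slope_c, win_c = _best_window(transformed(fmax), cycles, window)
        if r2_c > r2 + 1e-12:
            r2, slope, win = r2_c, slope_c, win_c
    if not np.isfinite(r2) or not np.isfinite(slope) or slope <= 0:
        raise EstimationError("no exponential phase detectable")
    if r2 < r2_floor:
        raise EstimationError(f"weak amplification curve: best-window R^2 {r2:.4f} < {r2_floor}")
    return EfficiencyEstimate(base=float(10.0**slope), window=win, fit_r2=float(r2))


def plate_efficiency(
    estimates,
    policy: str = "mean",
    mir_ids=None,
):
    """Aggregate per-reaction bases into the base(s) used for fold changes.

    ``policy`` is 'mean' or 'median' (one base per plate/assay, the default
    single-global-base convention) or 'per_mir' (one base per miRNA,
    requires ``mir_ids`` aligned with ``estimates``).
    """
    bases = np.array([e.base if isinstance(e, EfficiencyEstimate) else float(e) for e in estimates])
    if bases.size == 0:
        raise ValueError("plate_efficiency requires a non-empty list of estimates")
    if policy == "mean":
        return float(np.mean(bases))
    if policy == "median":
        return float(np.median(bases))
    if policy == "per_mir":
        if mir_ids is None or len(mir_ids) != len(bases):
            raise ValueError("policy 'per_mir' requires mir_ids aligned with estimates")
        import pandas as pd

        return pd.Series(bases, index=pd.Index(mir_ids, name="mir_id")).groupby(level=0).mean().to_dict()
    raise ValueError(f"unknown policy {policy!r}")


def estimate_efficiencies_table(curves, **kwargs):
    """Run estimate_efficiency per reaction of a long-format curve table.

    Returns a DataFrame (reaction_id, mir_id, base, percent, fit_r2, error);
    reactions whose fit fails carry NaN base and the error message.
    """
    import pandas as pd

    rows = []
    for rid, sub in curves.groupby("reaction_id", sort=False):
        mir = sub["mir_id"].iloc[0] if "mir_id" in sub else ""
        try:
            est = estimate_efficiency(sub, **kwargs)
            rows.append(
                {"reaction_id": rid, "mir_id": mir, "base": est.base,
                 "percent": est.percent, "fit_r2": est.fit_r2, "error": ""}
            )
        except EstimationError as exc:
            rows.append(
                {"reaction_id": rid, "mir_id": mir, "base": np.nan,
                 "percent": np.nan, "fit_r2": np.nan, "error": str(exc)}
            )
    return pd.DataFrame(rows)
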