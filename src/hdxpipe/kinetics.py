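"""Single-exponential uptake kinetics and differential significance calls.

Each peptide's deuterium uptake time course is fit to

    D(t) = A * (1 - exp(-k * t))

by weighted least squares (weights 1/sigma^2 where replicate SDs are
nonzero).  The plateau A ("maximum uptake") with its fit uncertainty is the
unit of free-vs-bound comparison: the per-peptide difference
dD = A_bound - A_free with SD propagated in quadrature is classified as
protected / deprotected / not significant using a dual threshold on the
magnitude of the change and on its uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import Peptide, UptakeTable
from .peptides import exchangeable_amides

logger = logging.getLogger(__name__)

#: k * t_max below this marks the plateau as unresolved (A a lower bound).
PLATEAU_KT_MIN = 0.2


@dataclass
class FitResult:
    peptide: Peptide
    A: float                 # maximum uptake, deuterons
    k_obs: float             # observed rate, s^-1
    cov: np.ndarray          # 2x2 covariance of (A, k_obs)
    rmse: float
    n_points: int
    flags: list[str] = field(default_factory=list)

    @property
    def sd_A(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))


def _model(t, A, k):
    return A * (1.0 - np.exp(-k * t))


def fit_curve(t_s: np.ndarray, uptake: np.ndarray, sd: np.ndarray,
              n_exch: int | None = None) -> tuple[float, float, np.ndarray,
                                                  list[str]]:
    """Weighted single-exponential fit of one uptake curve.

    Returns (A, k, covariance, flags).  Bounds: A in [0, 1.2 * n_exch]
    (or a loose data-driven cap when the peptide's maximum is unknown),
    k in (0, 10] s^-1.
    """
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(uptake, dtype=float)
    s = np.asarray(sd, dtype=float)
    if len(np.unique(t)) < 3 or 0.0 not in t:
        raise ValueError("need >= 3 distinct timepoints including t = 0")
    flags: list[str] = []
    a_cap = 1.2 * n_exch if n_exch else 1.5 * max(y.max(), 1.0) + 1.0
    if y.max() <= 0:
        flags.append("all_zero")
        return 0.0, 1e-6, np.full((2, 2), np.inf), flags
    sigma = np.where(s > 0, s, 1.0)
    t_nz = t[t > 0]
    p0 = (min(y.max(), a_cap), 1.0 / np.median(t_nz))
    try:
        popt, pcov = curve_fit(
            _model, t, y, p0=p0, sigma=sigma, absolute_sigma=True,
            bounds=([0.0, 1e-9], [a_cap, 10.0]), maxfev=10000)
        A, k = float(popt[0]), float(popt[1])
    except RuntimeError:
        flags.append("no_convergence")
        A = float(y[np.argmax(t)])
        k = p0[1]
        pcov = np.full((2, 2), np.inf)
    if np.isfinite(pcov).all() and k * t.max() < PLATEAU_KT_MIN:
        flags.append("plateau_not_reached")
    return A, k, np.asarray(pcov, dtype=float), flags


def fit_exponential(table: UptakeTable, peptide: Peptide,
                    convention: str = "skip_first") -> FitResult:
    """Fit one peptide's curve from an uptake table."""
    curve = table.curve(peptide)
    if curve.empty:
        raise ValueError(f"peptide {peptide.start}-{peptide.end} "
                         f"({peptide.state}) not in table")
    n_exch = exchangeable_amides(peptide, convention)
    A, k, cov, flags = fit_curve(curve["exposure_s"].to_numpy(),
                                 curve["uptake_Da"].to_numpy(),
                                 curve["sd_Da"].to_numpy(), n_exch)
    resid = curve["uptake_Da"].to_numpy() - _model(
        curve["exposure_s"].to_numpy(), A, k)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return FitResult(peptide, A, k, cov, rmse, len(curve), flags)


def fit_table(table: UptakeTable, convention: str = "skip_first",
              ) -> list[FitResult]:
    """Fit every peptide in the table."""
    return [fit_exponential(table, p, convention) for p in table.peptides()]


@dataclass
class DifferentialCall:
    peptide: Peptide         # free-state peptide carries the span identity
    delta_D: float           # A_bound - A_free, deuterons
    sd_delta: float
    cls: str = "unclassified"
    thresholds: dict = field(default_factory=dict)


def max_uptake_difference(free: FitResult, bound: FitResult,
                          ) -> DifferentialCall:
    """Difference in fitted maximum uptake between states (bound - free)."""
    if free.peptide.span != bound.peptide.span \
            or free.peptide.protein_id != bound.peptide.protein_id:
        raise ValueError(
            f"span mismatch: free {free.peptide.span} vs "
            f"bound {bound.peptide.span}")
    delta = bound.A - free.A
    var = free.cov[0, 0] + bound.cov[0, 0]
    return DifferentialCall(free.peptide, float(delta), float(np.sqrt(var)))


def classify_significance(call: DifferentialCall, min_delta: float = 0.5,
                          m: float = 2.0) -> DifferentialCall:
    """Classify a differential call with the dual-threshold rule.

    Protected when dD <= -max(min_delta, m * sd); deprotected when
    dD >= +max(min_delta, m * sd); otherwise not significant.  Both the
    effect-size floor and the uncertainty multiple must hold.
    """
    if not np.isfinite(call.sd_delta):
        raise ValueError("sd_delta is not finite; cannot classify")
    cut = max(min_delta, m * call.sd_delta)
    if call.delta_D <= -cut:
        cls = "protected"
    elif call.delta_D >= cut:
        cls = "deprotected"
    else:
        cls = "not_significant"
    call.cls = cls
    call.thresholds = {"min_delta": min_delta, "m": m}
    return call


def differential_calls(free_fits: list[FitResult], bound_fits: list[FitResult],
                       min_delta: float = 0.5, m: float = 2.0,
                       ) -> list[DifferentialCall]:
    """Pair fits by (protein, span), difference and classify them."""
    bound_by_span = {(f.peptide.protein_id, f.peptide.span): f
                     for f in bound_fits}
    calls = []
    for f in free_fits:
        b = bound_by_span.get((f.peptide.protein_id, f.peptide.span))
        if b is None:
            continue
        call = max_uptake_difference(f, b)
        if np.isfinite(call.sd_delta):
            classify_significance(call, min_delta, m)
        else:
            call.cls = "unclassifiable"   # degenerate fit in either state
        calls.append(call)
    return calls


def fits_to_dataframe(fits: list[FitResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "protein": f.peptide.protein_id, "state": f.peptide.state,
        "start": f.peptide.start, "end": f.peptide.end,
        "A_Da": f.A, "sd_A_Da": f.sd_A, "k_obs_per_s": f.k_obs,
        "rmse": f.rmse, "n_points": f.n_points,
        "flags": ";".join(f.flags),
    } for f in fits])


def calls_to_dataframe(calls: list[DifferentialCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "protein": c.peptide.protein_id,
        "start": c.peptide.start, "end": c.peptide.end,
        "delta_D_Da": c.delta_D, "sd_delta_Da": c.sd_delta,
        "class": c.cls,
    } for c in calls])


def woods_report(calls: list[DifferentialCall]) -> str:
    """Text Woods-plot: per-peptide dD along the sequence with class marks."""
    lines = ["# start-end  dD(Da)   sd     class"]
    for c in sorted(calls, key=lambda c: (c.peptide.start, c.peptide.end)):
        mark = {"protected": "-", "deprotected": "+",
                "not_significant": "."}.get(c.cls, "?")
        lines.append(f"{c.peptide.start:4d}-{c.peptide.end:<4d} "
                     f"{c.delta_D:+7.2f} {c.sd_delta:6.2f}  {mark} {c.cls}")
    return "\n".join(lines)


def woods_plot(calls: list[DifferentialCall], path,
               min_delta: float = 0.5) -> None:
    """Scatter of dD vs sequence span with the significance band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(7, 3.2))
    colors = {"protected": "tab:red", "deprotected": "tab:blue",
              "not_significant": "0.6"}
    for c in calls:
        ax.plot([c.peptide.start, c.peptide.end], [c.delta_D] * 2,
                color=colors.get(c.cls, "k"), lw=2.5)
    ax.axhspan(-min_delta, min_delta, color="0.9", zorder=0)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("residue")
    ax.set_ylabel(r"$\Delta D$ (bound $-$ free, Da)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
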