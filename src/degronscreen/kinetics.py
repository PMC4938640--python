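"""Cycloheximide-chase quantification and half-life inference.

A chase series tracks the substrate signal and a co-detected loading control
over time after translation shutoff.  Each timepoint is normalized to its
loading control and expressed as percent of the 0-min point; the first-order
model ``P(t) = 100 * exp(-lambda * t)`` is then fitted by nonlinear least
squares with the amplitude pinned at 100 (a free-amplitude variant is
available behind a flag).  Half-life is ``ln 2 / lambda``.  Nested fitted
curves are compared with an extra-sum-of-squares F-test, and families of
comparisons can be corrected for multiplicity (Holm by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from .sequences import ValidationError

__all__ = [
    "percent_remaining",
    "FirstOrderDecay",
    "DecayFitResult",
    "CurveComparison",
    "fit_decay",
    "fit_chase_table",
    "half_life",
    "compare_decay",
    "adjust_pvalues",
    "steady_state_ratio",
]

CHASE_COLUMNS = ["replicate", "time_min", "substrate_signal", "loading_signal"]


def percent_remaining(series: pd.DataFrame) -> pd.DataFrame:
    """Loading-normalized percent remaining for one replicate chase series.

    ``P(t) = 100 * [sub(t)/load(t)] / [sub(0)/load(0)]``; ``P(0) == 100``
    exactly by construction.  The series must include t = 0 with positive
    substrate signal, and every loading signal must be positive.
    """
    missing = [c for c in ("time_min", "substrate_signal", "loading_signal") if c not in series.columns]
    if missing:
        raise ValidationError(f"chase series missing columns: {missing}")
    t = series["time_min"].to_numpy(float)
    sub = series["substrate_signal"].to_numpy(float)
    load = series["loading_signal"].to_numpy(float)
    if not (t == 0).any():
        raise ValidationError("chase series must include the 0-min timepoint")
    bad = np.nonzero(load <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"non-positive loading signal at timepoints {t[bad].tolist()}"
        )
    i0 = int(np.nonzero(t == 0)[0][0])
    if sub[i0] <= 0:
        raise ValidationError("substrate signal at t=0 must be positive")
    ratio = sub / load
    return pd.DataFrame({"time_min": t, "percent": 100.0 * ratio / ratio[i0]})


def half_life(lam: float) -> float:
    """Half-life ln(2)/lambda in minutes; ``inf`` for a stable protein.

    A non-positive decay constant means no measurable decay over the chase;
    the result is the ``inf`` sentinel and should be reported as a censored
    bound (longer than the chase window), never as a number.
    """
    if lam <= 0:
        return math.inf
    return math.log(2) / lam


def _loglinear_lambda0(t: np.ndarray, p: np.ndarray) -> float:
    # deterministic initial value: log-linear regression of ln(P/100) on t
    mask = p > 0
    if mask.sum() >= 2 and np.ptp(t[mask]) > 0:
        slope = np.polyfit(t[mask], np.log(p[mask] / 100.0), 1)[0]
        return max(1e-8, -slope)
    return 0.1


@dataclass
class DecayFitResult:
    """Fitted first-order decay for one construct/strain.

    ``lambda_`` is the pooled point estimate (all replicate points jointly);
    ``replicate_lambdas`` are per-replicate fits used for the half-life SD.
    """

    lambda_: float
    amplitude: float
    ssr: float
    df_resid: int
    n_points: int
    chase_duration: float
    replicate_lambdas: np.ndarray | None = None

    @property
    def t_half(self) -> float:
        return half_life(self.lambda_)

    @property
    def stable(self) -> bool:
        return not np.isfinite(self.t_half) or self.t_half > self.chase_duration

    @property
    def t_half_sd(self) -> float:
        if self.replicate_lambdas is None or len(self.replicate_lambdas) < 2:
            return math.nan
        th = np.array([half_life(l) for l in self.replicate_lambdas])
        th = th[np.isfinite(th)]
        return float(np.std(th, ddof=1)) if th.size >= 2 else math.nan

    def format_t_half(self) -> str:
        if self.stable:
            return f"> {self.chase_duration:g} min"
        return f"{self.t_half:.2f} min"

    def summary(self) -> str:
        lines = [
            "First-order decay fit  P(t) = {:.4g} * exp(-lambda t)".format(self.amplitude),
            f"  lambda    = {self.lambda_:.5g} /min",
            f"  t1/2      = {self.format_t_half()}",
            f"  SSR       = {self.ssr:.4g} on {self.df_resid} df ({self.n_points} points)",
        ]
        if self.replicate_lambdas is not None and len(self.replicate_lambdas) > 1:
            lines.append(
                f"  t1/2 SD   = {self.t_half_sd:.3g} min "
                f"({len(self.replicate_lambdas)} replicates)"
            )
        return "\n".join(lines)


class FirstOrderDecay:
    """Percent-remaining decay model for one construct.

    Construct either from raw ``(t, P)`` points or from a replicate chase
    table via :meth:`from_chase` (which applies :func:`percent_remaining` per
    replicate and pools the points).
    """

    def __init__(self, time, percent, replicate=None):
        t = np.asarray(time, float)
        p = np.asarray(percent, float)
        if t.size != p.size:
            raise ValidationError("time and percent must have equal length")
        if t.size < 2 or np.unique(t).size < 2:
            raise ValidationError("decay fit requires >= 2 distinct timepoints")
        if (p < 0).any():
            raise ValidationError("percent remaining must be >= 0")
        self.time = t
        self.percent = p
        self.replicate = None if replicate is None else np.asarray(replicate)

    @classmethod
    def from_chase(cls, chase: pd.DataFrame) -> "FirstOrderDecay":
        if "replicate" not in chase.columns:
            chase = chase.assign(replicate=1)
        ts, ps, reps = [], [], []
        for rep, sub in chase.groupby("replicate", sort=False):
            pr = percent_remaining(sub)
            ts.append(pr["time_min"].to_numpy())
            ps.append(pr["percent"].to_numpy())
            reps.append(np.full(len(pr), rep))
        return cls(np.concatenate(ts), np.concatenate(ps), np.concatenate(reps))

    def _fit_lambda(self, t, p, free_amplitude: bool):
        lam0 = _loglinear_lambda0(t, p)
        if free_amplitude:
            res = least_squares(
                lambda x: p - x[1] * np.exp(-x[0] * t),
                x0=[lam0, 100.0],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
            )
            lam, amp = float(res.x[0]), float(res.x[1])
            n_par = 2
        else:
            res = least_squares(
                lambda x: p - 100.0 * np.exp(-x[0] * t),
                x0=[lam0],
                bounds=([0.0], [np.inf]),
            )
            lam, amp = float(res.x[0]), 100.0
            n_par = 1
        if not res.success:
            raise RuntimeError(f"decay fit failed to converge: {res.message}")
        return lam, amp, float(np.sum(res.fun**2)), n_par

    def fit(self, free_amplitude: bool = False) -> DecayFitResult:
        """Pooled fit over all points; per-replicate fits feed the t1/2 SD."""
        lam, amp, ssr, n_par = self._fit_lambda(self.time, self.percent, free_amplitude)
        rep_lams = None
        if self.replicate is not None and np.unique(self.replicate).size > 1:
            rep_lams = []
            for rep in np.unique(self.replicate):
                m = self.replicate == rep
                if np.unique(self.time[m]).size >= 2:
                    rl, *_ = self._fit_lambda(self.time[m], self.percent[m], free_amplitude)
                    rep_lams.append(rl)
            rep_lams = np.array(rep_lams)
        return DecayFitResult(
            lambda_=lam,
            amplitude=amp,
            ssr=ssr,
            df_resid=self.time.size - n_par,
            n_points=self.time.size,
            chase_duration=float(self.time.max()),
            replicate_lambdas=rep_lams,
        )


def fit_decay(time, percent, replicate=None, free_amplitude: bool = False) -> DecayFitResult:
    """Convenience wrapper: build :class:`FirstOrderDecay` and fit it."""
    return FirstOrderDecay(time, percent, replicate).fit(free_amplitude)


def fit_chase_table(chase: pd.DataFrame) -> pd.DataFrame:
    """Fit every (strain, degron_id) group of a tidy chase table.

    Returns one row per group: lambda, t_half (inf when stable), t_half_sd,
    n_reps, ssr, chase_duration.
    """
    rows = []
    for (strain, deg), sub in chase.groupby(["strain", "degron_id"], sort=False):
        fit = FirstOrderDecay.from_chase(sub).fit()
        rows.append(
            {
                "strain": strain,
                "degron_id": deg,
                "lambda": fit.lambda_,
                "t_half": fit.t_half,
                "t_half_sd": fit.t_half_sd,
                "n_reps": int(sub["replicate"].nunique()),
                "ssr": fit.ssr,
                "chase_duration": fit.chase_duration,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CurveComparison:
    """Extra-sum-of-squares F-test of two fitted decay curves."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    lambda_a: float
    lambda_b: float
    adjusted_p: float | None = None

    def summary(self) -> str:
        adj = "" if self.adjusted_p is None else f", adjusted p = {self.adjusted_p:.3g}"
        return (
            f"F({self.df_num}, {self.df_den}) = {self.f_stat:.3g}, "
            f"p = {self.p_value:.3g}{adj} "
            f"(lambda_a = {self.lambda_a:.4g}, lambda_b = {self.lambda_b:.4g})"
        )


def compare_decay(time_a, percent_a, time_b, percent_b) -> CurveComparison:
    """Test whether two percent-remaining curves share one decay constant.

    Reduced model: one shared lambda over the pooled points (1 parameter).
    Full model: separate lambdas (2 parameters).
    ``F = [(SSR_red - SSR_full) / 1] / [SSR_full / (n_a + n_b - 2)]``.
    """
    fit_a = fit_decay(time_a, percent_a)
    fit_b = fit_decay(time_b, percent_b)
    pooled = fit_decay(
        np.concatenate([np.asarray(time_a, float), np.asarray(time_b, float)]),
        np.concatenate([np.asarray(percent_a, float), np.asarray(percent_b, float)]),
    )
    ssr_full = fit_a.ssr + fit_b.ssr
    ssr_red = pooled.ssr
    df_den = fit_a.n_points + fit_b.n_points - 2
    if df_den <= 0:
        raise ValidationError("degenerate comparison: no residual degrees of freedom")
    if ssr_full <= 0:
        f_stat = 0.0 if ssr_red <= ssr_full + 1e-12 else math.inf
    else:
        f_stat = max(0.0, (ssr_red - ssr_full) / 1.0) / (ssr_full / df_den)
    p = float(f_dist.sf(f_stat, 1, df_den)) if np.isfinite(f_stat) else 0.0
    return CurveComparison(
        f_stat=float(f_stat),
        df_num=1,
        df_den=df_den,
        p_value=p,
        lambda_a=fit_a.lambda_,
        lambda_b=fit_b.lambda_,
    )


def adjust_pvalues(pvalues, method: str = "holm") -> np.ndarray:
    """Multiple-comparison adjustment (``holm`` default, or ``bonferroni``/``bh``)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    mapped = {"holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if mapped is None:
        raise ValidationError(f"unknown correction method {method!r}")
    return multipletests(p, method=mapped)[1]


def steady_state_ratio(
    blot: pd.DataFrame, reference_id: str = "none"
) -> pd.DataFrame:
    """Loading-normalized steady-state levels relative to the reference construct.

    Within each strain, every row's ``sub/load`` ratio is divided by the mean
    ratio of the reference construct (whose mean is therefore exactly 1).
    Returns per-(strain, degron) mean ratio and SD across replicates.
    """
    for col in ("strain", "degron_id", "substrate_signal", "loading_signal"):
        if col not in blot.columns:
            raise ValidationError(f"blot table missing column {col!r}")
    if (blot["loading_signal"] <= 0).any():
        raise ValidationError("loading signals must be positive")
    out = []
    for strain, sub in blot.groupby("strain", sort=False):
        ref = sub[sub.degron_id == reference_id]
        if ref.empty:
            raise ValidationError(
                f"reference construct {reference_id!r} missing for strain {strain!r}"
            )
        ref_ratio = (ref.substrate_signal / ref.loading_signal).mean()
        ratios = sub.substrate_signal / sub.loading_signal / ref_ratio
        frame = sub.assign(ratio=ratios)
        agg = (
            frame.groupby("degron_id")["ratio"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .rename(columns={"mean": "ratio", "std": "ratio_sd", "count": "n"})
        )
        agg.insert(0, "strain", strain)
        out.append(agg)
    return pd.concat(out, ignore_index=True)
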