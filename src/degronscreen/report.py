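"""Per-degron E3-ligase dependence calls and library-wide reporting.

Dependence on an E3 ligase is called from the growth readout: a degron is
labelled *dependent* in a mutant when the adjusted growth p-value clears the
significance threshold **and** the relative growth is positive (rescue must be
directional); *independent* otherwise; *indeterminate* when the growth ratio
is undefined (degenerate normalization).  Half-life ratios (mutant / WT) from
chase fits annotate the calls, and the smallest ratio among growth-detected
degrons estimates the detection threshold of the growth assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import GrowthScreenResult
from .kinetics import DecayFitResult
from .sequences import DegronRecord, ValidationError, features_table

__all__ = [
    "LABEL_DEPENDENT",
    "LABEL_INDEPENDENT",
    "LABEL_INDETERMINATE",
    "halflife_ratio",
    "call_dependence",
    "detection_threshold",
    "DependenceAnalysis",
    "library_report",
]

LABEL_DEPENDENT = "dependent"
LABEL_INDEPENDENT = "independent"
LABEL_INDETERMINATE = "indeterminate"


def halflife_ratio(t_half_mut: float, t_half_wt: float) -> float:
    """Half-life fold change mutant / WT.

    A stable mutant (``t_half_mut == inf``) yields ``inf`` — a censored lower
    bound of ``chase_duration / t_half_wt``, to be reported as such rather
    than a number.  Accepts floats or :class:`DecayFitResult` objects.
    """
    if isinstance(t_half_mut, DecayFitResult):
        t_half_mut = t_half_mut.t_half
    if isinstance(t_half_wt, DecayFitResult):
        t_half_wt = t_half_wt.t_half
    if not np.isfinite(t_half_wt) or t_half_wt <= 0:
        raise ValidationError("WT half-life must be finite and positive")
    return float(t_half_mut / t_half_wt)


def call_dependence(
    relative_growth: float, adjusted_p: float, alpha: float = 0.05
) -> str:
    """Deterministic dependence label from the growth statistics."""
    if relative_growth is None or (
        isinstance(relative_growth, float) and math.isnan(relative_growth)
    ):
        return LABEL_INDETERMINATE
    if adjusted_p < alpha and relative_growth > 0:
        return LABEL_DEPENDENT
    return LABEL_INDEPENDENT


def detection_threshold(calls: pd.DataFrame) -> float | None:
    """Smallest finite half-life ratio among degrons detected by growth.

    Returns ``None`` when no dependent call carries a finite ratio.
    """
    if "label" not in calls.columns:
        raise ValidationError("calls table must carry a 'label' column")
    dep = calls[calls.label == LABEL_DEPENDENT]
    if "halflife_ratio" not in calls.columns or dep.empty:
        return None
    ratios = dep["halflife_ratio"].to_numpy(float)
    ratios = ratios[np.isfinite(ratios)]
    return float(ratios.min()) if ratios.size else None


@dataclass
class DependenceAnalysis:
    """Integrates a fitted growth screen with chase fits into dependence calls.

    ``fits`` is the tidy table from :func:`degronscreen.kinetics.fit_chase_table`
    (optional; without it the calls carry no half-life annotation).
    """

    growth: GrowthScreenResult
    fits: pd.DataFrame | None = None
    alpha: float = 0.05

    def calls(self) -> pd.DataFrame:
        table = self.growth.table.copy()
        table["label"] = [
            call_dependence(rg, ap, self.alpha)
            for rg, ap in zip(table.relative_growth, table.adjusted_p)
        ]
        table["t_half_wt"] = np.nan
        table["t_half_mut"] = np.nan
        table["halflife_ratio"] = np.nan
        if self.fits is not None and not self.fits.empty:
            wt = self.fits[self.fits.strain == self.growth.wt_strain].set_index("degron_id")
            mut = self.fits.set_index(["strain", "degron_id"])
            for i, row in table.iterrows():
                if row.degron_id in wt.index and (row.mutant, row.degron_id) in mut.index:
                    twt = float(wt.loc[row.degron_id, "t_half"])
                    tmut = float(mut.loc[(row.mutant, row.degron_id), "t_half"])
                    table.at[i, "t_half_wt"] = twt
                    table.at[i, "t_half_mut"] = tmut
                    table.at[i, "halflife_ratio"] = halflife_ratio(tmut, twt)
        return table

    def detection_threshold(self) -> float | None:
        return detection_threshold(self.calls())

    def summary(self) -> str:
        calls = self.calls()
        lines = [f"Dependence calls (alpha = {self.alpha})"]
        for mutant, sub in calls.groupby("mutant"):
            frac = (sub.label == LABEL_DEPENDENT).mean()
            lines.append(
                f"  {mutant}: {int((sub.label == LABEL_DEPENDENT).sum())}/{len(sub)} "
                f"dependent ({frac:.1%})"
            )
        thr = self.detection_threshold()
        if thr is not None:
            lines.append(f"  smallest growth-detected half-life ratio: {thr:.2f}")
        return "\n".join(lines)


def library_report(
    records: list[DegronRecord],
    growth: GrowthScreenResult | None = None,
    fits: pd.DataFrame | None = None,
    calls: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Library-wide report: one row per degron, plus a per-mutant summary.

    With only ``records``, emits a features-only report.  Growth, fit and call
    tables are merged in when supplied; ids present there but absent from the
    library raise a validation error naming the orphans.
    """
    features = features_table(records)
    if features.empty and (growth is None or growth.table.empty) and calls is None:
        return features, pd.DataFrame(columns=["mutant", "n_degron", "dependent_fraction"])
    known = set(features["id"]) if not features.empty else set()

    def _check_ids(df: pd.DataFrame, what: str):
        orphans = sorted(set(df.degron_id) - known)
        if orphans:
            raise ValidationError(f"{what} reference unknown degrons: {orphans}")

    report = features.rename(columns={"id": "degron_id"})
    summary_rows = []
    if calls is not None and not calls.empty:
        _check_ids(calls, "dependence calls")
        wide = calls.pivot(
            index="degron_id",
            columns="mutant",
            values=["relative_growth", "adjusted_p", "halflife_ratio", "label"],
        )
        wide.columns = [f"{mut}_{stat}" for stat, mut in wide.columns]
        report = report.merge(wide, on="degron_id", how="left")
        for mutant, sub in calls.groupby("mutant"):
            summary_rows.append(
                {
                    "mutant": mutant,
                    "n_degron": len(sub),
                    "dependent_fraction": float((sub.label == LABEL_DEPENDENT).mean()),
                }
            )
    elif growth is not None and not growth.table.empty:
        _check_ids(growth.table, "growth results")
        wide = growth.table.pivot(
            index="degron_id", columns="mutant", values=["relative_growth", "adjusted_p"]
        )
        wide.columns = [f"{mut}_{stat}" for stat, mut in wide.columns]
        report = report.merge(wide, on="degron_id", how="left")
        for mutant, sub in growth.table.groupby("mutant"):
            summary_rows.append(
                {
                    "mutant": mutant,
                    "n_degron": len(sub),
                    "dependent_fraction": float(sub.significant.mean()),
                }
            )
    if fits is not None and not fits.empty:
        _check_ids(fits, "decay fits")
        for strain, sub in fits.groupby("strain"):
            report = report.merge(
                sub.set_index("degron_id")["t_half"].rename(f"t_half_{strain}"),
                on="degron_id",
                how="left",
            )
    summary = pd.DataFrame(summary_rows, columns=["mutant", "n_degron", "dependent_fraction"])
    return report, summary
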