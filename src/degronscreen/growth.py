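"""Plate-based relative-growth analysis and nonparametric hit calling.

Colony areas are normalized within each physical plate to its two control
anchors — wells expressing the bare Ura3-HA reporter (normalized value 1) and
wells with no Ura3 at all (normalized value 0) — which removes multiplicative
plate effects.  For each degron, growth rescue in an E3-deletion mutant is
summarised as the log2 ratio of mean normalized colony size (mutant / WT) and
assessed with a Mann-Whitney U test; p-values can be corrected across the
degron grid within each mutant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .sequences import ValidationError
from .simulate import (
    ROLE_CORNER,
    ROLE_DEGRON,
    ROLE_NO_URA3,
    ROLE_REF,
    WT_STRAIN,
)

__all__ = [
    "DegeneratePlateError",
    "UndefinedGrowthError",
    "normalize_plate",
    "normalize_plates",
    "relative_growth",
    "mann_whitney_p",
    "adjust_growth_pvalues",
    "growth_heatmap_table",
    "GrowthScreen",
    "GrowthScreenResult",
]

PLATE_COLUMNS = ["plate", "strain", "well_row", "well_col", "role", "degron_id", "replicate", "area"]


class DegeneratePlateError(ValueError):
    """Reference control mean does not exceed the no-Ura3 floor mean."""


class UndefinedGrowthError(ValueError):
    """log2 growth ratio undefined (a group mean is zero or negative)."""


def _validate_plate_frame(df: pd.DataFrame) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"plate table missing columns: {missing}")
    if (df["area"] < 0).any():
        raise ValidationError("colony areas must be >= 0")


def normalize_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize one physical plate to its control anchors.

    ``normalized = (area - mean(no-Ura3)) / (mean(Ura3-HA ref) - mean(no-Ura3))``,
    clipped below at 0.  Corner wells are excluded from the control means and
    flagged for exclusion downstream.  Returns a copy with a ``normalized``
    column added.
    """
    _validate_plate_frame(plate)
    if plate["plate"].nunique() != 1 or plate["strain"].nunique() != 1:
        raise ValidationError("normalize_plate expects a single physical plate")
    ref = plate.loc[plate.role == ROLE_REF, "area"]
    floor = plate.loc[plate.role == ROLE_NO_URA3, "area"]
    if ref.empty or floor.empty:
        raise ValidationError("plate must carry both control roles")
    ref_mean, floor_mean = ref.mean(), floor.mean()
    if ref_mean <= floor_mean:
        raise DegeneratePlateError(
            f"reference mean {ref_mean:.3g} <= floor mean {floor_mean:.3g}"
        )
    out = plate.copy()
    out["normalized"] = ((out["area"] - floor_mean) / (ref_mean - floor_mean)).clip(lower=0.0)
    return out


def normalize_plates(plates: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`normalize_plate` per (plate, strain) physical plate."""
    _validate_plate_frame(plates)
    parts = [
        normalize_plate(sub) for _, sub in plates.groupby(["plate", "strain"], sort=False)
    ]
    return pd.concat(parts, ignore_index=True)


def relative_growth(norm_mut, norm_wt) -> float:
    """log2 ratio of mean normalized colony size, mutant over WT."""
    mut = np.asarray(norm_mut, float)
    wt = np.asarray(norm_wt, float)
    if mut.size == 0 or wt.size == 0:
        raise ValidationError("relative_growth requires non-empty samples")
    m_mut, m_wt = mut.mean(), wt.mean()
    if m_mut <= 0 or m_wt <= 0:
        raise UndefinedGrowthError(
            f"group mean <= 0 (mutant {m_mut:.3g}, WT {m_wt:.3g})"
        )
    return float(np.log2(m_mut / m_wt))


def mann_whitney_p(sample_a, sample_b, alternative: str = "two-sided") -> float:
    """Mann-Whitney U p-value comparing two samples.

    Uses the exact null distribution when ``min(n) <= 8`` and the pooled data
    are tie-free, and the tie-corrected normal approximation (with continuity
    correction) otherwise.  ``alternative`` follows scipy's convention and is
    evaluated for ``sample_a`` relative to ``sample_b``.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("Mann-Whitney requires non-empty samples")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return 1.0  # all observations identical: no evidence either way
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative=alternative, method=method).pvalue)


def adjust_growth_pvalues(p, method: str = "bh") -> np.ndarray:
    """Adjust a vector of growth-test p-values (``bh``, ``holm``, or ``none``)."""
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    mapped = {"bh": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}.get(method)
    if mapped is None:
        raise ValidationError(f"unknown correction method {method!r}")
    return multipletests(p, method=mapped)[1]


def growth_heatmap_table(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Degron x mutant matrix of relative growth, masked at significance.

    Cells with ``adjusted_p >= alpha`` (or undefined growth) are set to 0, the
    convention used to whiten non-significant cells in screen heatmaps.
    """
    if results.duplicated(["degron_id", "mutant"]).any():
        raise ValidationError("duplicate degron/mutant pairs in results")
    masked = results.copy()
    keep = (masked["adjusted_p"] < alpha) & masked["relative_growth"].notna()
    masked["cell"] = np.where(keep, masked["relative_growth"], 0.0)
    return masked.pivot(index="degron_id", columns="mutant", values="cell")


@dataclass
class GrowthScreenResult:
    """Fitted growth screen: one row per degron x mutant.

    ``table`` columns: degron_id, mutant, relative_growth (NaN when
    undefined), p_value, adjusted_p, n_mut, n_wt, significant.
    """

    table: pd.DataFrame
    alpha: float
    correction: str
    alternative: str
    wt_strain: str

    def heatmap_table(self, alpha: float | None = None) -> pd.DataFrame:
        return growth_heatmap_table(self.table, self.alpha if alpha is None else alpha)

    def significant_ids(self, mutant: str) -> set[str]:
        sub = self.table[(self.table.mutant == mutant) & self.table.significant]
        return set(sub.degron_id)

    def plot_heatmap(self, ax=None, alpha: float | None = None):
        """Render the masked matrix as a WT-vs-mutant growth heatmap."""
        import matplotlib.pyplot as plt

        mat = self.heatmap_table(alpha)
        if ax is None:
            _, ax = plt.subplots(
                figsize=(1 + 0.6 * mat.shape[1], 1 + 0.12 * mat.shape[0])
            )
        vmax = float(np.nanmax(np.abs(mat.values))) or 1.0
        im = ax.imshow(mat.values, cmap="PiYG_r", vmin=-vmax, vmax=vmax, aspect="auto")
        ax.set_xticks(range(mat.shape[1]), mat.columns)
        ax.set_ylabel("degron")
        ax.figure.colorbar(im, ax=ax, label="relative growth (log2 mut/WT)")
        return ax

    def summary(self) -> str:
        lines = [
            "Growth screen summary",
            f"  WT strain: {self.wt_strain}; alpha = {self.alpha}; "
            f"correction = {self.correction}; alternative = {self.alternative}",
        ]
        for mutant, sub in self.table.groupby("mutant"):
            n_sig = int(sub.significant.sum())
            lines.append(
                f"  {mutant}: {n_sig}/{len(sub)} degrons with significant growth difference"
            )
        return "\n".join(lines)


class GrowthScreen:
    """Relative-growth model over a plate table (WT vs each mutant strain).

    Parameters
    ----------
    plates:
        Tidy colony-area table with columns ``plate, strain, well_row,
        well_col, role, degron_id, replicate, area`` — the schema the
        synthetic generator emits; real data in the same shape is accepted.
    wt_strain:
        Name of the wild-type strain all mutants are compared against.
    """

    def __init__(self, plates: pd.DataFrame, wt_strain: str = WT_STRAIN):
        _validate_plate_frame(plates)
        if wt_strain not in set(plates.strain):
            raise ValidationError(f"WT strain {wt_strain!r} absent from plate table")
        self.wt_strain = wt_strain
        self.normalized = normalize_plates(plates)

    @classmethod
    def from_tsv(cls, path: str | Path, wt_strain: str = WT_STRAIN) -> "GrowthScreen":
        return cls(pd.read_csv(path, sep="\t"), wt_strain=wt_strain)

    def _degron_values(self, strain: str) -> dict[str, np.ndarray]:
        sub = self.normalized[
            (self.normalized.strain == strain)
            & (self.normalized.role == ROLE_DEGRON)
            & (self.normalized.role != ROLE_CORNER)
        ]
        return {
            deg: grp["normalized"].to_numpy()
            for deg, grp in sub.groupby("degron_id", sort=False)
        }

    def fit(
        self,
        alpha: float = 0.05,
        correction: str = "bh",
        alternative: str = "two-sided",
    ) -> GrowthScreenResult:
        """Test every degron in every mutant against WT.

        ``alternative="greater"`` tests directional rescue (mutant grows more
        than WT); correction is applied across degrons within each mutant.
        """
        wt_values = self._degron_values(self.wt_strain)
        mutants = sorted(set(self.normalized.strain) - {self.wt_strain})
        all_rows = []
        for mutant in mutants:
            mut_values = self._degron_values(mutant)
            shared = [d for d in wt_values if d in mut_values]
            rows = []
            for deg in shared:
                mut, wt = mut_values[deg], wt_values[deg]
                try:
                    rg = relative_growth(mut, wt)
                except UndefinedGrowthError:
                    rg = np.nan
                rows.append(
                    {
                        "degron_id": deg,
                        "mutant": mutant,
                        "relative_growth": rg,
                        "p_value": mann_whitney_p(mut, wt, alternative),
                        "n_mut": mut.size,
                        "n_wt": wt.size,
                    }
                )
            sub = pd.DataFrame(rows)
            sub["adjusted_p"] = adjust_growth_pvalues(sub["p_value"].values, correction)
            sub["significant"] = (sub["adjusted_p"] < alpha) & sub["relative_growth"].notna()
            all_rows.append(sub)
        table = (
            pd.concat(all_rows, ignore_index=True)
            if all_rows
            else pd.DataFrame(
                columns=[
                    "degron_id",
                    "mutant",
                    "relative_growth",
                    "p_value",
                    "n_mut",
                    "n_wt",
                    "adjusted_p",
                    "significant",
                ]
            )
        )
        return GrowthScreenResult(
            table=table,
            alpha=alpha,
            correction=correction,
            alternative=alternative,
            wt_strain=self.wt_strain,
        )
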