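"""Synthetic degron-screen generator.

Produces inputs with the statistical structure the downstream analyses assume,
so the whole pipeline is testable without any external data:

* a random genome and a degron library of translated random fragments
  (~50-400 bp, random orientation, fusion frame, three-frame stop cassette);
* per-degron first-order degradation rate constants with strain-specific
  (E3-deletion) effects: ``log lambda_i = a + b*gravy_i + c*1[run_i >= 5] + eps``
  and ``D_{i,m} ~ Bernoulli(pi_m)``, with ``lambda_{i,m} = lambda_i / f_m``
  for dependent degrons;
* quadruplicate colony areas on 96-position plates with Ura3-HA reference and
  no-Ura3 floor control wells, per-plate multiplicative effects, and
  lognormal measurement noise;
* cycloheximide-chase time courses (substrate and loading-control channels,
  independent multiplicative lognormal noise) and steady-state blot tables.

All stages are deterministic under a fixed master seed; per-stage child
streams are spawned from it with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequences import (
    DEFAULT_VECTOR_TAIL,
    DegronRecord,
    FragmentSource,
    ValidationError,
    translate_fusion,
)

__all__ = [
    "StrainEffect",
    "SimParams",
    "GroundTruth",
    "SimulatedScreen",
    "simulate_genome",
    "simulate_library",
    "assign_kinetics",
    "default_layout",
    "simulate_plates",
    "simulate_chase",
    "simulate_chases",
    "simulate_steady_state",
    "simulate_screen",
]

WT_STRAIN = "WT"

# Control-well roles on a plate
ROLE_DEGRON = "DEGRON"
ROLE_REF = "URA3_HA_REF"
ROLE_NO_URA3 = "NO_URA3"
ROLE_CORNER = "EXCLUDED_CORNER"
ROLE_EMPTY = "EMPTY"


@dataclass(frozen=True)
class StrainEffect:
    """An E3-deletion strain: dependence probability and stabilization factor.

    ``dependence_prob`` (pi_m) is the probability that a degron depends on the
    deleted ligase; ``stabilization`` (f_m >= 1) is the fold-reduction of the
    degradation rate constant for dependent degrons in that strain.
    """

    name: str
    dependence_prob: float
    stabilization: float

    def __post_init__(self):
        if not 0.0 <= self.dependence_prob <= 1.0:
            raise ValidationError(f"{self.name}: dependence_prob must be in [0, 1]")
        if self.stabilization < 1.0:
            raise ValidationError(f"{self.name}: stabilization must be >= 1")


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic screen.

    Defaults encode the study conditions the generator emulates: fragment
    sizes ~50-400 bp, quadruplicate pinning, a doa10-delta-like mutant that
    stabilizes about half the library strongly, chase timepoints spanning
    half-lives from ~1.6 to ~30 min, and 10% multiplicative measurement noise
    on both colony areas and blot channels.
    """

    genome_length: int = 100_000
    n_fragments: int = 200
    fragment_size_range: tuple[int, int] = (50, 400)
    # log-rate model: log lambda = a + b*gravy + c*1[max_run >= 5] + N(0, sigma)
    log_rate_intercept: float = math.log(0.12)
    gravy_coef: float = 0.25
    hydrophobic_run_coef: float = 0.4
    hydrophobic_run_threshold: int = 5
    rate_sigma: float = 0.5
    strains: tuple[StrainEffect, ...] = (StrainEffect("doa10", 0.5, 8.0),)
    dilution_rate: float = math.log(2) / 100.0  # min^-1, ~100 min doubling
    plate_noise_cv: float = 0.10
    plate_effect_sigma: float = 0.05
    blot_sigma: float = 0.10
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 15.0, 30.0)
    chase_replicates: int = 3
    plate_replicates: int = 4
    baseline_area_frac: float = 0.05
    a_max: float = 1000.0
    michaelis_k: float = 1.0 / 3.0  # in units of the no-degron steady state
    substrate_signal0: float = 1000.0
    loading_signal0: float = 500.0
    vector_tail: str = DEFAULT_VECTOR_TAIL
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.fragment_size_range
        if not (1 <= lo <= hi):
            raise ValidationError("fragment_size_range must satisfy 1 <= lo <= hi")
        if hi > self.genome_length:
            raise ValidationError("genome too short for requested fragment sizes")
        if min(self.timepoints) < 0:
            raise ValidationError("negative timepoint")
        if 0.0 not in self.timepoints:
            raise ValidationError("timepoints must include 0")
        for name, value in (
            ("dilution_rate", self.dilution_rate),
            ("plate_noise_cv", self.plate_noise_cv),
            ("plate_effect_sigma", self.plate_effect_sigma),
            ("blot_sigma", self.blot_sigma),
            ("rate_sigma", self.rate_sigma),
        ):
            if value < 0:
                raise ValidationError(f"{name} must be >= 0")

    def with_(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Per degron x strain truth: dependence, effective rate, steady state.

    ``table`` has one row per (degron_id, strain) including the WT rows, with
    columns ``dependent`` (bool), ``lambda_`` (min^-1) and ``steady_state``
    (no-degron construct == 1).
    """

    table: pd.DataFrame

    def lambda_for(self, degron_id: str, strain: str) -> float:
        sel = self.table[
            (self.table.degron_id == degron_id) & (self.table.strain == strain)
        ]
        if sel.empty:
            raise KeyError((degron_id, strain))
        return float(sel["lambda_"].iloc[0])

    def dependent_ids(self, strain: str) -> set[str]:
        sel = self.table[(self.table.strain == strain) & self.table.dependent]
        return set(sel.degron_id)

    @property
    def strains(self) -> list[str]:
        return [s for s in self.table.strain.unique() if s != WT_STRAIN]


def _steady_state(lam: np.ndarray | float, mu: float) -> np.ndarray | float:
    # synthesis/(degradation + dilution), scaled so a stable construct sits at 1
    return mu / (np.asarray(lam) + mu)


def simulate_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_library(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[str, list[DegronRecord]]:
    """Draw random genomic fragments and translate them in the fusion frame.

    Fragments are uniform over the genome with uniform size in
    ``fragment_size_range`` and random orientation; empty translations
    (immediate stop) are discarded, so the library size may be slightly below
    ``n_fragments``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    genome = simulate_genome(params.genome_length, rng)
    lo, hi = params.fragment_size_range
    records: list[DegronRecord] = []
    for i in range(params.n_fragments):
        size = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, params.genome_length - size + 1))
        end = start + size
        insert = genome[start:end]
        reverse = bool(rng.random() < 0.5)
        if reverse:
            insert = insert.translate(_COMPLEMENT)[::-1]
        peptide = translate_fusion(insert, params.vector_tail)
        if not peptide:
            continue
        records.append(
            DegronRecord.from_peptide(
                f"deg{i:04d}",
                peptide,
                source=FragmentSource(start=start, end=end, reverse=reverse),
            )
        )
    return genome, records


def assign_kinetics(
    records: Sequence[DegronRecord],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Assign WT degradation rates and strain-specific effects to a library."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = len(records)
    g = np.array([r.gravy for r in records])
    run = np.array([r.max_hydrophobic_run for r in records])
    eps = rng.normal(0.0, params.rate_sigma, n)
    log_lam = (
        params.log_rate_intercept
        + params.gravy_coef * g
        + params.hydrophobic_run_coef * (run >= params.hydrophobic_run_threshold)
        + eps
    )
    lam_wt = np.exp(log_lam)
    rows = []
    ids = [r.id for r in records]
    rows.append(
        pd.DataFrame(
            {
                "degron_id": ids,
                "strain": WT_STRAIN,
                "dependent": False,
                "lambda_": lam_wt,
            }
        )
    )
    for eff in params.strains:
        dep = rng.random(n) < eff.dependence_prob
        lam = np.where(dep, lam_wt / eff.stabilization, lam_wt)
        rows.append(
            pd.DataFrame(
                {
                    "degron_id": ids,
                    "strain": eff.name,
                    "dependent": dep,
                    "lambda_": lam,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table["steady_state"] = _steady_state(table["lambda_"].values, params.dilution_rate)
    return GroundTruth(table=table)


_ROWS = "ABCDEFGH"
_N_COLS = 12
# Scattered fixed positions for the six replicates of each control construct
_REF_WELLS = [("A", 6), ("C", 3), ("D", 10), ("F", 1), ("G", 7), ("H", 5)]
_NO_URA_WELLS = [("B", 2), ("B", 11), ("D", 5), ("E", 8), ("G", 3), ("H", 9)]
_CORNERS = [("A", 1), ("A", 12), ("H", 1), ("H", 12)]


def default_layout(degron_ids: Sequence[str]) -> pd.DataFrame:
    """Assign degrons and control wells to 96-position plates.

    Each plate carries the four excluded corner wells (these express the
    reference construct but are never analysed), six Ura3-HA reference wells,
    six no-Ura3 floor wells, and up to 80 degron wells filled row-major.
    Returns a tidy layout table (plate, well_row, well_col, role, degron_id).
    """
    per_plate = 8 * _N_COLS - len(_CORNERS) - len(_REF_WELLS) - len(_NO_URA_WELLS)
    rows = []
    ids = list(degron_ids)
    n_plates = max(1, math.ceil(len(ids) / per_plate))
    k = 0
    for p in range(n_plates):
        plate = f"plate{p + 1:02d}"
        for r in _ROWS:
            for c in range(1, _N_COLS + 1):
                pos = (r, c)
                if pos in _CORNERS:
                    role, deg = ROLE_CORNER, None
                elif pos in _REF_WELLS:
                    role, deg = ROLE_REF, None
                elif pos in _NO_URA_WELLS:
                    role, deg = ROLE_NO_URA3, None
                elif k < len(ids):
                    role, deg = ROLE_DEGRON, ids[k]
                    k += 1
                else:
                    role, deg = ROLE_EMPTY, None
                rows.append(
                    {
                        "plate": plate,
                        "well_row": r,
                        "well_col": c,
                        "role": role,
                        "degron_id": deg,
                    }
                )
    return pd.DataFrame(rows)


def simulate_plates(
    truth: GroundTruth,
    layout: pd.DataFrame,
    params: SimParams,
    rng: np.random.Generator | None = None,
    strains: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Simulate replicate colony areas for every strain on every layout plate.

    The expected area is a saturating (Michaelis) function of the construct's
    steady-state level ``S``:  ``A_max * (b0 + (1-b0) * S/(S+K))``, so strong
    degrons approach the no-Ura3 baseline ``A_max * b0`` and stabilization
    restores growth.  Each physical plate (layout plate x strain) carries a
    lognormal plate effect; each pinned replicate carries independent
    lognormal noise with the configured CV.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if strains is None:
        strains = [WT_STRAIN] + [s.name for s in params.strains]
    layout_ids = set(layout.loc[layout.role == ROLE_DEGRON, "degron_id"])
    truth_ids = set(truth.table.degron_id)
    orphans = sorted(layout_ids - truth_ids)
    if orphans:
        raise ValidationError(f"layout degrons missing from ground truth: {orphans}")

    ss = truth.table.set_index(["strain", "degron_id"])["steady_state"]
    b0 = params.baseline_area_frac
    K = params.michaelis_k
    out = []
    for strain in strains:
        for plate, sub in layout.groupby("plate", sort=False):
            plate_effect = rng.lognormal(0.0, params.plate_effect_sigma)
            for row in sub.itertuples(index=False):
                if row.role == ROLE_EMPTY:
                    continue
                if row.role == ROLE_DEGRON:
                    s_level = float(ss[(strain, row.degron_id)])
                elif row.role in (ROLE_REF, ROLE_CORNER):
                    s_level = 1.0  # reference construct, no degron
                else:  # NO_URA3
                    s_level = 0.0
                mean_area = params.a_max * (b0 + (1 - b0) * s_level / (s_level + K))
                noise = rng.lognormal(0.0, params.plate_noise_cv, params.plate_replicates)
                for rep, eps in enumerate(noise, start=1):
                    out.append(
                        {
                            "plate": plate,
                            "strain": strain,
                            "well_row": row.well_row,
                            "well_col": row.well_col,
                            "role": row.role,
                            "degron_id": row.degron_id,
                            "replicate": rep,
                            "area": mean_area * plate_effect * eps,
                        }
                    )
    return pd.DataFrame(out)


def simulate_chase(
    rate: float,
    params: SimParams,
    rng: np.random.Generator | None = None,
    timepoints: Sequence[float] | None = None,
    replicates: int | None = None,
) -> pd.DataFrame:
    """Simulate replicate cycloheximide-chase series for one construct.

    Substrate signal ``I(t) = I0 * exp(-rate * t) * eps_t`` and loading signal
    ``L(t) = L0 * eps'_t`` with independent multiplicative lognormal errors of
    log-scale sigma ``blot_sigma``.  Returns a tidy table (replicate,
    time_min, substrate_signal, loading_signal).
    """
    if rate < 0:
        raise ValidationError("decay rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t = np.asarray(params.timepoints if timepoints is None else timepoints, float)
    if (t < 0).any():
        raise ValidationError("negative timepoint")
    nrep = params.chase_replicates if replicates is None else replicates
    out = []
    for rep in range(1, nrep + 1):
        sub = (
            params.substrate_signal0
            * np.exp(-rate * t)
            * rng.lognormal(0.0, params.blot_sigma, t.size)
        )
        load = params.loading_signal0 * rng.lognormal(0.0, params.blot_sigma, t.size)
        out.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "time_min": t,
                    "substrate_signal": sub,
                    "loading_signal": load,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def simulate_chases(
    truth: GroundTruth,
    params: SimParams,
    rng: np.random.Generator | None = None,
    degron_ids: Iterable[str] | None = None,
    strains: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Chase tables for a set of degrons across strains (tidy, one big frame)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if strains is None:
        strains = [WT_STRAIN] + truth.strains
    if degron_ids is None:
        degron_ids = sorted(set(truth.table.degron_id))
    out = []
    for strain in strains:
        for deg in degron_ids:
            series = simulate_chase(truth.lambda_for(deg, strain), params, rng)
            series.insert(0, "degron_id", deg)
            series.insert(0, "strain", strain)
            out.append(series)
    return pd.concat(out, ignore_index=True)


def simulate_steady_state(
    truth: GroundTruth,
    params: SimParams,
    rng: np.random.Generator | None = None,
    replicates: int = 3,
    reference_id: str = "none",
) -> pd.DataFrame:
    """Steady-state blot table, including the no-degron reference construct.

    Substrate signal is proportional to the construct's steady-state level
    with multiplicative lognormal noise; the loading channel is flat.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rows = []
    table = truth.table
    for strain in [WT_STRAIN] + truth.strains:
        sub = table[table.strain == strain]
        levels = {reference_id: 1.0}
        levels.update(dict(zip(sub.degron_id, sub.steady_state)))
        for deg, level in levels.items():
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "strain": strain,
                        "degron_id": deg,
                        "replicate": rep,
                        "substrate_signal": params.substrate_signal0
                        * level
                        * rng.lognormal(0.0, params.blot_sigma),
                        "loading_signal": params.loading_signal0
                        * rng.lognormal(0.0, params.blot_sigma),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SimulatedScreen:
    """Bundle of everything one simulated screen produced."""

    params: SimParams
    genome: str
    records: list[DegronRecord]
    truth: GroundTruth
    layout: pd.DataFrame
    plates: pd.DataFrame
    chase: pd.DataFrame | None = None
    blot: pd.DataFrame | None = None


def simulate_screen(
    params: SimParams,
    seed: int | None = None,
    with_chase: bool = False,
    with_blot: bool = False,
) -> SimulatedScreen:
    """Run the full generator: library -> kinetics -> plates (-> chase, blot).

    Per-stage random streams are spawned deterministically from the master
    seed, so adding or removing a later stage never changes an earlier one.
    """
    master = params.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    rng_lib, rng_kin, rng_plate, rng_chase, rng_blot = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    genome, records = simulate_library(params, rng_lib)
    truth = assign_kinetics(records, params, rng_kin)
    layout = default_layout([r.id for r in records])
    plates = simulate_plates(truth, layout, params, rng_plate)
    chase = simulate_chases(truth, params, rng_chase) if with_chase else None
    blot = simulate_steady_state(truth, params, rng_blot) if with_blot else None
    return SimulatedScreen(
        params=params,
        genome=genome,
        records=records,
        truth=truth,
        layout=layout,
        plates=plates,
        chase=chase,
        blot=blot,
    )
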