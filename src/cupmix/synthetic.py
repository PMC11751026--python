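"""Synthetic residue campaigns with known ground truth.

Emulates the design of a year-long monitoring campaign: 9 sites (3 per
management system: arable, vegetable, viticulture) x 4 distance classes
(in-field, plus an adjacent meadow at 1/5/20 m) x 13 monthly samplings
(February of year 1 through February of year 2) x a roster of 93 current-use
pesticides (36 fungicides, 36 herbicides, 21 insecticides), in two matrices
(topsoil and vegetation).

The generative model, chosen to match the statistical structure the
downstream estimators assume:

* each compound has a per-system application calendar of pulse months and an
  in-field applied dose (ug/kg);
* soil receives the non-intercepted dose fraction and dissipates first-order
  with a per-compound half-life ``dt50`` (months);
* vegetation receives the intercepted fraction and declines geometrically
  (growth dilution + wash-off) by a per-month factor; off-field vegetation is
  additionally reset by meadow mowing events;
* off-field concentrations at distance ``x`` metres are the in-field level
  times ``exp(b_true * x)`` with a per-system drift decay ``b_true < 0``;
* observed = noiseless x multiplicative lognormal noise (mean 1, CV
  ``noise_cv``), then left-censored: below LOD -> not detected, in
  [LOD, LOQ) -> detected but reported as 0, at or above LOQ -> quantified.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .residue_io import (
    COMPOUND_COLUMNS,
    DISTANCE_CLASSES,
    EndpointTable,
    ENDPOINT_COLUMNS,
    RECORD_COLUMNS,
    ResidueTable,
    SYSTEMS,
)
from .decay import DISTANCE_M

#: month_index 0 is February of year 1; 12 is February of year 2.
MONTH_LABELS = ("Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug", "Sep",
                "Oct", "Nov", "Dec", "Jan", "Feb")


@dataclass(frozen=True)
class CompoundSpec:
    """Static properties and application calendar of one synthetic compound."""

    compound_id: str
    pclass: str
    dose_ug_kg: float
    dt50_months: float
    loq_ug_kg: float
    lod_ug_kg: float
    #: per-system tuple of application month indices; absent system = not used
    calendar: Mapping[str, tuple[int, ...]]


def _calendar_for(pclass: str, j: int) -> dict[str, tuple[int, ...]]:
    """Deterministic system assignment and pulse calendar for roster slot j.

    Application intensity is concentrated in late spring and summer (with an
    autumn herbicide window on arable land and a fungicide-heavy May-August
    programme in viticulture), so standing-vegetation compound counts peak in
    July-August. Roughly a quarter of each class is assigned to no system at
    all, mirroring a target list wider than the compounds actually in use.
    """
    cal: dict[str, tuple[int, ...]] = {}
    arable_f = (2 + j % 3, 3 + j % 3)            # spring programmes, staggered
    vegetable_f = (2 + j % 4, 4 + j % 4)         # succession plantings
    viticulture_f = (2 + j % 4, 4 + j % 4)       # May-Aug spray programme
    arable_h = (1 + j % 2, 2 + j % 2) if j % 2 == 0 else (8 + j % 2,)
    vegetable_h = (1 + j % 4, 3 + j % 4)
    arable_i = (3 + j % 3, 4 + j % 3)
    vegetable_i = (3 + j % 3, 5 + j % 3)
    if pclass == "fungicide":
        if j >= 28:           # unused tail of the target list
            return cal
        if j % 4 == 0:
            cal = {"arable": arable_f, "viticulture": viticulture_f}
        elif j % 4 == 1:
            cal = {"vegetable": vegetable_f, "viticulture": viticulture_f}
        elif j % 4 == 2:
            cal = {"viticulture": viticulture_f}
        else:
            cal = {"arable": arable_f, "vegetable": vegetable_f}
    elif pclass == "herbicide":
        if j >= 27:
            return cal
        if j % 3 == 0:
            cal = {"arable": arable_h}
        elif j % 3 == 1:
            cal = {"vegetable": vegetable_h}
        else:
            cal = {"arable": arable_h, "vegetable": vegetable_h}
        if j % 9 == 0:
            cal["viticulture"] = (2,)
    else:  # insecticide
        if j >= 14:
            return cal
        if j % 3 == 0:
            cal = {"arable": arable_i}
        elif j % 3 == 1:
            cal = {"vegetable": vegetable_i}
        else:
            cal = {"arable": arable_i, "vegetable": vegetable_i}
    return cal


def default_compounds() -> list[CompoundSpec]:
    """The default 93-compound roster (36 F, 36 H, 21 I), fixed a priori.

    Doses and half-lives are drawn once from a fixed internal seed so the
    roster is a constant of the package, independent of the campaign seed.
    """
    rng = np.random.default_rng(20210201)
    specs: list[CompoundSpec] = []
    for pclass, prefix, n in (("fungicide", "F", 36), ("herbicide", "H", 36),
                              ("insecticide", "I", 21)):
        for j in range(n):
            dose = float(np.round(np.exp(rng.normal(np.log(40.0), 0.9)), 2))
            dt50 = float(np.round(rng.uniform(0.3, 1.5), 2))
            loq = (1.0, 2.0, 5.0)[j % 3]
            specs.append(CompoundSpec(
                compound_id=f"{prefix}{j + 1:02d}",
                pclass=pclass,
                dose_ug_kg=dose,
                dt50_months=dt50,
                loq_ug_kg=loq,
                lod_ug_kg=0.3 * loq,
                calendar=_calendar_for(pclass, j),
            ))
    return specs


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of a synthetic campaign."""

    seed: int = 0
    n_sites_per_system: int = 3
    n_months: int = 13
    compounds: tuple[CompoundSpec, ...] = field(
        default_factory=lambda: tuple(default_compounds()))
    #: per-system drift decay rate (1/m), strictly negative
    drift_decay: Mapping[str, float] = field(default_factory=lambda: {
        "arable": -0.35, "vegetable": -0.47, "viticulture": -0.60})
    vegetation_interception: float = 0.75
    #: multiplicative per-month decline of standing-vegetation residues
    vegetation_dilution: float = 0.30
    #: months at which off-field meadow vegetation is mown (residues reset)
    mowing_months: tuple[int, ...] = (4, 8)
    #: assume the same calendar ran in the previous season, so persistent
    #: compounds carry a non-zero soil baseline into the first month
    soil_carryover: bool = True
    noise_cv: float = 0.3

    def __post_init__(self) -> None:
        for sys_, b in self.drift_decay.items():
            if b >= 0:
                raise ValueError(f"drift_decay[{sys_!r}] must be < 0, got {b}")
        if not (0.0 <= self.vegetation_interception <= 1.0):
            raise ValueError("vegetation_interception must be in [0, 1]")
        if not (0.0 < self.vegetation_dilution <= 1.0):
            raise ValueError("vegetation_dilution must be in (0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for spec in self.compounds:
            if spec.dt50_months <= 0:
                raise ValueError(f"{spec.compound_id}: dt50 must be > 0")
            if not (0 < spec.lod_ug_kg <= spec.loq_ug_kg):
                raise ValueError(f"{spec.compound_id}: need 0 < lod <= loq")


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free reference quantities for every downstream estimator."""

    #: per-record noiseless concentration (same keys as the residue table)
    records: pd.DataFrame
    #: per-system true drift decay (1/m)
    b_true: Mapping[str, float]
    #: (system, matrix) -> months of the planted seasonal maxima of the
    #: per-sample detected-compound count (in-field, noiseless)
    peak_months: Mapping[tuple[str, str], tuple[int, ...]]
    config: SyntheticConfig


def _soil_series(spec: CompoundSpec, months: np.ndarray, pulses: Sequence[int],
                 interception: float, carryover: bool = True) -> np.ndarray:
    """In-field topsoil course: non-intercepted pulses with first-order decay.

    With ``carryover`` the same calendar is assumed to have run in the
    previous season (pulses at t - 13), so persistent compounds carry a
    non-zero baseline into the first sampling month — fields are not
    pristine at campaign start.
    """
    out = np.zeros(len(months))
    dose = spec.dose_ug_kg * (1.0 - interception)
    all_pulses = list(pulses)
    if carryover:
        all_pulses += [t - 13 for t in pulses]
    for t in all_pulses:
        m = months >= t
        out[m] += dose * 0.5 ** ((months[m] - t) / spec.dt50_months)
    return out


def _veg_series(spec: CompoundSpec, months: np.ndarray, pulses: Sequence[int],
                interception: float, dilution: float,
                mowing: Sequence[int]) -> np.ndarray:
    """Standing-vegetation course: intercepted pulses, geometric dilution,
    and optional mowing resets (a pulse applied before a mowing event no
    longer contributes afterwards)."""
    out = np.zeros(len(months))
    dose = spec.dose_ug_kg * interception
    mow = np.asarray(sorted(mowing), dtype=int)
    for t in pulses:
        contrib = dose * dilution ** (months - t).clip(min=0)
        alive = months >= t
        if mow.size:
            # killed at month m if some mowing event lies in (t, m]
            cut = (mow[None, :] > t) & (mow[None, :] <= months[:, None])
            alive &= ~cut.any(axis=1)
        out[alive] += contrib[alive]
    return out


def generate_campaign(config: SyntheticConfig) -> tuple[ResidueTable, GroundTruth]:
    """Simulate one campaign; deterministic under ``config.seed``."""
    months = np.arange(config.n_months)
    rng = np.random.default_rng(config.seed)

    cols: dict[str, list] = {c: [] for c in
                             ("site_id", "system", "matrix", "distance_class",
                              "month_index", "compound_id")}
    noiseless_col: list[np.ndarray] = []
    loq_col: list[np.ndarray] = []
    lod_col: list[np.ndarray] = []

    n_per_block = config.n_sites_per_system * config.n_months
    for system in SYSTEMS:
        b = config.drift_decay[system]
        sites = [f"{system[:3]}{k + 1}" for k in range(config.n_sites_per_system)]
        for spec in config.compounds:
            pulses = spec.calendar.get(system, ())
            soil_in = _soil_series(spec, months, pulses,
                                   config.vegetation_interception,
                                   config.soil_carryover)
            veg_in = _veg_series(spec, months, pulses,
                                 config.vegetation_interception,
                                 config.vegetation_dilution, ())
            veg_off = _veg_series(spec, months, pulses,
                                  config.vegetation_interception,
                                  config.vegetation_dilution,
                                  config.mowing_months)
            for matrix in ("soil", "vegetation"):
                for dclass in DISTANCE_CLASSES:
                    drift = math.exp(b * DISTANCE_M[dclass])
                    if matrix == "soil":
                        base = soil_in
                    else:
                        base = veg_in if dclass == "in_field" else veg_off
                    series = base * drift
                    for site in sites:
                        cols["site_id"].append(site)
                    noiseless_col.append(np.tile(series, config.n_sites_per_system))
                    cols["system"].extend([system] * n_per_block)
                    cols["matrix"].extend([matrix] * n_per_block)
                    cols["distance_class"].extend([dclass] * n_per_block)
                    cols["month_index"].append(
                        np.tile(months, config.n_sites_per_system))
                    cols["compound_id"].extend([spec.compound_id] * n_per_block)
                    loq_col.append(np.full(n_per_block, spec.loq_ug_kg))
                    lod_col.append(np.full(n_per_block, spec.lod_ug_kg))

    site_id = np.repeat(np.array(cols["site_id"], dtype=object), config.n_months)
    month_index = np.concatenate(cols["month_index"])
    noiseless = np.concatenate(noiseless_col)
    loq = np.concatenate(loq_col)
    lod = np.concatenate(lod_col)

    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2))
        factors = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=noiseless.size))
    else:
        factors = np.ones(noiseless.size)
    observed = noiseless * factors

    status = np.where(observed >= loq, "quantified",
                      np.where(observed >= lod, "below_loq", "not_detected"))
    concentration = np.where(status == "quantified", observed, 0.0)

    records = pd.DataFrame({
        "site_id": site_id,
        "system": cols["system"],
        "matrix": cols["matrix"],
        "distance_class": cols["distance_class"],
        "month_index": month_index.astype(int),
        "compound_id": cols["compound_id"],
        "concentration_ug_kg": concentration,
        "detect_status": status,
        "loq_ug_kg": loq,
        "lod_ug_kg": lod,
    })[RECORD_COLUMNS]

    compounds = pd.DataFrame(
        [(s.compound_id, s.compound_id, s.pclass) for s in config.compounds],
        columns=COMPOUND_COLUMNS)

    truth_records = records[RECORD_COLUMNS[:6]].copy()
    truth_records["noiseless_ug_kg"] = noiseless
    truth_records["loq_ug_kg"] = loq
    truth_records["lod_ug_kg"] = lod

    peaks = _planted_peaks(truth_records)
    truth = GroundTruth(records=truth_records, b_true=dict(config.drift_decay),
                        peak_months=peaks, config=config)
    return ResidueTable(records, compounds), truth


def _planted_peaks(truth_records: pd.DataFrame) -> dict[tuple[str, str], tuple[int, ...]]:
    """Planted seasonal maxima: run the same detrend + delta-peak procedure the
    analysis uses on the *noiseless* in-field detected-compound counts, so the
    truth is the estimator's noise-free target. Falls back to the argmax tie
    set when the series is too flat to cross the delta threshold."""
    from .temporal import MonthlySeries, detect_peaks, detrend_linear

    out: dict[tuple[str, str], tuple[int, ...]] = {}
    infield = truth_records[truth_records["distance_class"] == "in_field"]
    detected = infield[infield["noiseless_ug_kg"] >= infield["lod_ug_kg"]]
    for (system, matrix), grp in detected.groupby(["system", "matrix"]):
        # noiseless replicate sites are identical, so count one site
        one = grp[grp["site_id"] == grp["site_id"].iloc[0]]
        counts = (one.groupby("month_index")["compound_id"].nunique()
                  .reindex(range(13), fill_value=0).to_numpy(float))
        series = MonthlySeries(np.arange(13), counts)
        residuals = detrend_linear(series).values
        maxima = [p.position for p in detect_peaks(residuals, 0.3).peaks
                  if p.kind == "maximum"]
        if not maxima:
            maxima = list(np.flatnonzero(counts == counts.max()))
        out[(system, matrix)] = tuple(int(m) for m in maxima)
    return out


def truth_for(estimator_name: str, truth: GroundTruth):
    """Reference values targeted by a downstream estimator.

    ``"distance_decay"`` -> per-system true drift decay b_true;
    ``"peaks"`` -> planted (system, matrix) -> peak months;
    ``"mrq"`` -> the noiseless per-record concentration table, from which an
    independent brute-force mixture sum can be computed.
    """
    if estimator_name == "distance_decay":
        return dict(truth.b_true)
    if estimator_name == "peaks":
        return dict(truth.peak_months)
    if estimator_name == "mrq":
        return truth.records.copy()
    raise KeyError(f"unknown estimator {estimator_name!r}")


def generate_endpoints(compounds: Sequence[CompoundSpec] | pd.DataFrame,
                       seed: int = 0,
                       coverage: float = 0.85) -> EndpointTable:
    """Synthetic toxicological endpoint table for a compound roster.

    Endpoint magnitudes follow the spread seen in regulatory databases:
    soil-invertebrate NOECs of 0.1-100 mg/kg, LC50s one to two orders above,
    and bee contact LD50s that are orders of magnitude lower for insecticides
    than for fungicides/herbicides. About ``coverage`` of compounds get a
    NOEC; a further slice of earthworm entries is LC50-only; bee LD50s are
    nearly complete. Deterministic under ``seed``.
    """
    if isinstance(compounds, pd.DataFrame):
        roster = list(zip(compounds["compound_id"], compounds["pclass"]))
    else:
        roster = [(s.compound_id, s.pclass) for s in compounds]
    rng = np.random.default_rng(seed)
    rows = []
    for cid, pclass in roster:
        noec_col = np.exp(rng.normal(np.log(5.0), 1.2)) if rng.random() < coverage else np.nan
        has_ew_noec = rng.random() < coverage
        noec_ew = np.exp(rng.normal(np.log(8.0), 1.2)) if has_ew_noec else np.nan
        lc50_ew = (np.exp(rng.normal(np.log(200.0), 1.0))
                   if (not has_ew_noec and rng.random() < 0.7) or rng.random() < 0.15
                   else np.nan)
        if rng.random() < 0.98:
            centre = 50.0 if pclass == "insecticide" else 5e4
            ld50 = np.exp(rng.normal(np.log(centre), 1.0))
        else:
            ld50 = np.nan
        rows.append((cid,
                     round(noec_col, 4) if np.isfinite(noec_col) else np.nan,
                     round(noec_ew, 4) if np.isfinite(noec_ew) else np.nan,
                     round(lc50_ew, 4) if np.isfinite(lc50_ew) else np.nan,
                     round(ld50, 2) if np.isfinite(ld50) else np.nan,
                     "synthetic"))
    return EndpointTable(pd.DataFrame(rows, columns=ENDPOINT_COLUMNS))


def with_noise_cv(config: SyntheticConfig, noise_cv: float) -> SyntheticConfig:
    """Convenience: same design, different measurement-noise level."""
    return replace(config, noise_cv=noise_cv)
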