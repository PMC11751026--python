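"""Additive mixture risk and hazard quotients.

Soil invertebrates (collembola, earthworms)
    Each compound's risk quotient is RQ = MEC / PNEC, with the predicted
    no-effect concentration PNEC = NOEC / 10, or LC50 / 1000 when no NOEC is
    available (NOEC preferred when both exist). The mixture risk quotient of
    a sample is the additive sum MRQ = sum RQ, categorised as negligible
    (< 0.01), low (< 0.1), medium (< 1), high (exactly 1) or very high
    (> 1).

Ground-nesting bees (surrogate solitary bee)
    Acute contact hazard per compound: HQ = (soil contact mass x MEC) /
    (honey-bee contact LD50 / 10), with a default contact mass of 2.23 g of
    soil per bee over 48 h of burrowing and the divisor 10 converting the
    honey-bee endpoint to a surrogate solitary-bee LD50. All mass terms are
    in ng, so HQ is dimensionless. The mixture hazard quotient MHQ = sum HQ
    flags a lethal hazard when strictly above 1.

Compounds detected but lacking an endpoint are excluded from the sums (not
imputed) and reported through ``coverage``; below-LOQ detections contribute
0 to the sums but count towards the coverage denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .residue_io import EndpointTable, ResidueTable, SAMPLE_KEY

ASSESSMENT_FACTOR_NOEC = 10.0
ASSESSMENT_FACTOR_LC50 = 1000.0
SOIL_CONTACT_G = 2.23
SURROGATE_DIVISOR = 10.0

CATEGORIES = ("negligible", "low", "medium", "high", "very_high")

ORGANISM_ENDPOINTS = {
    "collembola": ("noec_collembola_mg_kg", None),
    "earthworm": ("noec_earthworm_mg_kg", "lc50_earthworm_mg_kg"),
}


def pnec(endpoint_row: pd.Series | Mapping, organism: str) -> float | None:
    """Predicted no-effect concentration in mg/kg soil, or None if no endpoint.

    NOEC / 10 when a NOEC exists (preferred); otherwise LC50 / 1000.
    """
    try:
        noec_col, lc50_col = ORGANISM_ENDPOINTS[organism]
    except KeyError:
        raise KeyError(f"unknown organism {organism!r}; expected one of "
                       f"{sorted(ORGANISM_ENDPOINTS)}") from None
    noec = endpoint_row.get(noec_col)
    if noec is not None and np.isfinite(noec):
        return float(noec) / ASSESSMENT_FACTOR_NOEC
    if lc50_col is not None:
        lc50 = endpoint_row.get(lc50_col)
        if lc50 is not None and np.isfinite(lc50):
            return float(lc50) / ASSESSMENT_FACTOR_LC50
    return None


def categorize(mrq: float) -> str:
    """Risk category of an MRQ (left-closed bands; high = exactly 1)."""
    if mrq < 0:
        raise ValueError("MRQ must be >= 0")
    if mrq < 0.01:
        return "negligible"
    if mrq < 0.1:
        return "low"
    if mrq < 1.0:
        return "medium"
    if mrq == 1.0:
        return "high"
    return "very_high"


@dataclass(frozen=True)
class RiskResult:
    """Per-sample additive soil-invertebrate risk."""

    sample: tuple
    organism: str
    rq: Mapping[str, float]
    mrq: float
    rq_max: float
    rq_max_compound: str | None
    frac_rq_max: float
    category: str
    coverage: float


@dataclass(frozen=True)
class HazardResult:
    """Per-sample additive bee contact hazard."""

    sample: tuple
    hq: Mapping[str, float]
    mhq: float
    hq_max: float
    hq_max_compound: str | None
    frac_hq_max: float
    hazard: bool
    coverage: float
    soil_contact_g: float = SOIL_CONTACT_G
    surrogate_divisor: float = SURROGATE_DIVISOR


def _pnec_map_ug_kg(endpoints: EndpointTable, organism: str) -> dict[str, float]:
    out = {}
    for _, row in endpoints.data.iterrows():
        p = pnec(row, organism)
        if p is not None:
            out[row["compound_id"]] = p * 1000.0  # mg/kg -> ug/kg
    return out


def sample_mrq(sample_records: pd.DataFrame, endpoints: EndpointTable,
               organism: str, sample: tuple = ()) -> RiskResult:
    """Additive MRQ of one composite sample's records.

    ``sample_records`` holds the rows of a single (site, matrix, distance,
    month) sample; concentrations are in ug/kg, PNECs are converted from
    mg/kg to ug/kg before division.
    """
    pnecs = _pnec_map_ug_kg(endpoints, organism)
    detected = sample_records[
        sample_records["detect_status"].isin(("quantified", "below_loq"))]
    rq: dict[str, float] = {}
    for _, row in detected.iterrows():
        p = pnecs.get(row["compound_id"])
        if p is None:
            continue
        rq[row["compound_id"]] = float(row["concentration_ug_kg"]) / p
    mrq = float(sum(rq.values()))
    if rq:
        top = max(rq, key=lambda k: (rq[k], k))
        rq_max = rq[top]
    else:
        top, rq_max = None, 0.0
    n_det = detected["compound_id"].nunique()
    coverage = len(rq) / n_det if n_det else 0.0
    return RiskResult(sample=tuple(sample), organism=organism, rq=rq, mrq=mrq,
                      rq_max=rq_max, rq_max_compound=top,
                      frac_rq_max=(rq_max / mrq if mrq > 0 else 0.0),
                      category=categorize(mrq), coverage=coverage)


def bee_hq(mec_ng_g: float, ld50_bee_ng: float,
           soil_contact_g: float = SOIL_CONTACT_G,
           surrogate_divisor: float = SURROGATE_DIVISOR) -> float:
    """Acute contact hazard quotient of one compound for a ground-nesting bee.

    (soil contact mass [g] x MEC [ng/g]) / (honey-bee LD50 [ng/bee] /
    surrogate divisor); dimensionless, all mass terms in ng.
    """
    if ld50_bee_ng <= 0:
        raise ValueError("LD50 must be > 0")
    if mec_ng_g < 0:
        raise ValueError("MEC must be >= 0")
    return (soil_contact_g * mec_ng_g) / (ld50_bee_ng / surrogate_divisor)


def sample_mhq(sample_records: pd.DataFrame, endpoints: EndpointTable,
               sample: tuple = (),
               soil_contact_g: float = SOIL_CONTACT_G,
               surrogate_divisor: float = SURROGATE_DIVISOR) -> HazardResult:
    """Additive MHQ of one composite sample; hazard flagged when MHQ > 1."""
    ld50 = {row["compound_id"]: row["ld50_bee_contact_ng_bee"]
            for _, row in endpoints.data.iterrows()
            if np.isfinite(row["ld50_bee_contact_ng_bee"])}
    detected = sample_records[
        sample_records["detect_status"].isin(("quantified", "below_loq"))]
    hq: dict[str, float] = {}
    for _, row in detected.iterrows():
        l50 = ld50.get(row["compound_id"])
        if l50 is None:
            continue
        hq[row["compound_id"]] = bee_hq(float(row["concentration_ug_kg"]), l50,
                                        soil_contact_g, surrogate_divisor)
    mhq = float(sum(hq.values()))
    if hq:
        top = max(hq, key=lambda k: (hq[k], k))
        hq_max = hq[top]
    else:
        top, hq_max = None, 0.0
    n_det = detected["compound_id"].nunique()
    return HazardResult(sample=tuple(sample), hq=hq, mhq=mhq, hq_max=hq_max,
                        hq_max_compound=top,
                        frac_hq_max=(hq_max / mhq if mhq > 0 else 0.0),
                        hazard=mhq > 1.0,
                        coverage=(len(hq) / n_det if n_det else 0.0),
                        soil_contact_g=soil_contact_g,
                        surrogate_divisor=surrogate_divisor)


def risk_table(table: ResidueTable, endpoints: EndpointTable, organism: str,
               matrix: str = "soil") -> pd.DataFrame:
    """Per-sample MRQ table for one organism over one matrix (vectorised).

    Returns one row per sample with ``mrq``, ``rq_max``,
    ``rq_max_compound``, ``frac_rq_max``, ``category`` and ``coverage``.
    """
    pnecs = _pnec_map_ug_kg(endpoints, organism)
    rec = table.subset(matrix=matrix).records
    det = rec[rec["detect_status"].isin(("quantified", "below_loq"))].copy()
    det["pnec"] = det["compound_id"].map(pnecs)
    det["rq"] = det["concentration_ug_kg"] / det["pnec"]

    all_samples = rec[SAMPLE_KEY + ["system"]].drop_duplicates().set_index(SAMPLE_KEY)
    grp = det.dropna(subset=["pnec"]).groupby(SAMPLE_KEY)
    mrq = grp["rq"].sum()
    rq_max = grp["rq"].max()
    top = grp.apply(
        lambda d: d.loc[d["rq"].idxmax(), "compound_id"], include_groups=False)
    covered = grp["compound_id"].nunique()
    n_det = det.groupby(SAMPLE_KEY)["compound_id"].nunique()

    out = all_samples.copy()
    out["organism"] = organism
    out["mrq"] = mrq.reindex(out.index).fillna(0.0)
    out["rq_max"] = rq_max.reindex(out.index).fillna(0.0)
    out["rq_max_compound"] = top.reindex(out.index)
    out["frac_rq_max"] = np.where(out["mrq"] > 0, out["rq_max"] / out["mrq"], 0.0)
    out["category"] = out["mrq"].map(categorize)
    out["coverage"] = (covered.reindex(out.index) /
                       n_det.reindex(out.index)).fillna(0.0)
    return out.reset_index()


def hazard_table(table: ResidueTable, endpoints: EndpointTable,
                 matrix: str = "soil",
                 soil_contact_g: float = SOIL_CONTACT_G,
                 surrogate_divisor: float = SURROGATE_DIVISOR) -> pd.DataFrame:
    """Per-sample bee MHQ table over one matrix (vectorised)."""
    ld50 = {row["compound_id"]: row["ld50_bee_contact_ng_bee"]
            for _, row in endpoints.data.iterrows()
            if np.isfinite(row["ld50_bee_contact_ng_bee"])}
    rec = table.subset(matrix=matrix).records
    det = rec[rec["detect_status"].isin(("quantified", "below_loq"))].copy()
    det["ld50"] = det["compound_id"].map(ld50)
    det["hq"] = (soil_contact_g * det["concentration_ug_kg"]) / (
        det["ld50"] / surrogate_divisor)

    all_samples = rec[SAMPLE_KEY + ["system"]].drop_duplicates().set_index(SAMPLE_KEY)
    grp = det.dropna(subset=["ld50"]).groupby(SAMPLE_KEY)
    mhq = grp["hq"].sum()
    hq_max = grp["hq"].max()
    top = grp.apply(
        lambda d: d.loc[d["hq"].idxmax(), "compound_id"], include_groups=False)
    covered = grp["compound_id"].nunique()
    n_det = det.groupby(SAMPLE_KEY)["compound_id"].nunique()

    out = all_samples.copy()
    out["mhq"] = mhq.reindex(out.index).fillna(0.0)
    out["hq_max"] = hq_max.reindex(out.index).fillna(0.0)
    out["hq_max_compound"] = top.reindex(out.index)
    out["frac_hq_max"] = np.where(out["mhq"] > 0, out["hq_max"] / out["mhq"], 0.0)
    out["hazard"] = out["mhq"] > 1.0
    out["coverage"] = (covered.reindex(out.index) /
                       n_det.reindex(out.index)).fillna(0.0)
    return out.reset_index()


def aggregate_risk(per_sample: pd.DataFrame, value_col: str,
                   n_reps: int = 3) -> pd.DataFrame:
    """Mean and max over replicate sites per (system, month, distance class).

    ``per_sample`` is a :func:`risk_table` / :func:`hazard_table` output.
    Groups with fewer than ``n_reps`` replicates are kept but flagged
    (``incomplete`` True); groups with zero replicates do not occur by
    construction and would be omitted.
    """
    g = per_sample.groupby(["system", "month_index", "distance_class"])
    out = g[value_col].agg(mean="mean", max="max", n="count").reset_index()
    out["incomplete"] = out["n"] < n_reps
    out["mean_category"] = out["mean"].map(categorize)
    out["max_category"] = out["max"].map(categorize)
    return out
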