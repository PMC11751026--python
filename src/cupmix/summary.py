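"""Per-sample mixture summaries, detection frequencies and mixture enumeration.

Censoring conventions, applied consistently everywhere:

* a *detection* is any record that is quantified or below-LOQ — detections
  between LOD and LOQ are counted;
* *concentration arithmetic* (totals, means, maxima) uses quantified records
  only, since below-LOQ records carry concentration 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .residue_io import ResidueTable, SAMPLE_KEY

DETECTED = ("quantified", "below_loq")


def summarize_samples(table: ResidueTable) -> pd.DataFrame:
    """One row per composite sample: detection counts, class counts, totals.

    Returns a DataFrame indexed by (site_id, matrix, distance_class,
    month_index) with columns ``system``, ``n_cups_detected``,
    ``n_quantified``, ``n_fungicide``/``n_herbicide``/``n_insecticide``
    (detected per class) and ``total_concentration_ug_kg`` (quantified only).
    Samples without any detection are retained with zero counts.
    """
    rec = table.records
    pclass = rec["compound_id"].map(table.pclass_of())
    detected = rec["detect_status"].isin(DETECTED)
    quant = rec["detect_status"] == "quantified"

    g = rec.assign(
        _det=detected.astype(int),
        _quant=quant.astype(int),
        _f=(detected & (pclass == "fungicide")).astype(int),
        _h=(detected & (pclass == "herbicide")).astype(int),
        _i=(detected & (pclass == "insecticide")).astype(int),
    ).groupby(SAMPLE_KEY)

    out = g.agg(
        system=("system", "first"),
        n_cups_detected=("_det", "sum"),
        n_quantified=("_quant", "sum"),
        n_fungicide=("_f", "sum"),
        n_herbicide=("_h", "sum"),
        n_insecticide=("_i", "sum"),
        total_concentration_ug_kg=("concentration_ug_kg", "sum"),
    )
    return out


def detection_frequency(table: ResidueTable, matrix: str) -> pd.Series:
    """Percent of samples in ``matrix`` in which each compound was detected.

    100 x (samples with a quantified or below-LOQ record) / (samples in the
    matrix). Compounds in the roster without any detection report 0.
    """
    sub = table.subset(matrix=matrix)
    n_samples = sub.n_samples
    if n_samples == 0:
        raise ValueError(f"no samples in matrix {matrix!r}")
    rec = sub.records
    det = rec[rec["detect_status"].isin(DETECTED)]
    counts = det.groupby("compound_id")[SAMPLE_KEY].apply(
        lambda d: len(d.drop_duplicates()))
    freq = counts.reindex(table.compounds["compound_id"], fill_value=0)
    return (100.0 * freq / n_samples).rename("detection_frequency_pct")


def concentration_stats(table: ResidueTable, matrix: str) -> pd.DataFrame:
    """Per-compound concentration summaries over one matrix.

    Two mean variants are reported side by side, because "mean concentration"
    in monitoring tables is ambiguous: ``mean_over_quantified`` averages the
    quantified records only (the headline variant), ``mean_over_all`` spreads
    the same quantified mass over every sample in the matrix (non-detects
    contribute 0). ``max`` is over quantified records. Compounds with no
    quantified record get NaN for all three.
    """
    sub = table.subset(matrix=matrix)
    n_samples = sub.n_samples
    if n_samples == 0:
        raise ValueError(f"no samples in matrix {matrix!r}")
    rec = sub.records
    quant = rec[rec["detect_status"] == "quantified"]
    g = quant.groupby("compound_id")["concentration_ug_kg"]
    stats = pd.DataFrame({
        "mean_over_quantified": g.mean(),
        "mean_over_all": g.sum() / n_samples,
        "max": g.max(),
    })
    return stats.reindex(table.compounds["compound_id"])


@dataclass(frozen=True)
class MixtureEnumeration:
    """Unique compound combinations observed across the samples of a matrix.

    A mixture key is the sorted set of compounds detected in one sample
    (order-independent); samples without any detection are excluded from the
    enumeration but counted in ``n_empty_samples``.
    """

    n_unique: int
    counts: pd.Series            # index: "|"-joined sorted compound ids
    n_with_insecticide: int      # unique keys containing >= 1 insecticide
    most_frequent: tuple[str, int] | None
    n_empty_samples: int


def enumerate_mixtures(table: ResidueTable, matrix: str) -> MixtureEnumeration:
    """Enumerate detected-compound combinations per sample in one matrix."""
    sub = table.subset(matrix=matrix)
    rec = sub.records
    det = rec[rec["detect_status"].isin(DETECTED)]
    keys = (det.groupby(SAMPLE_KEY)["compound_id"]
            .apply(lambda s: "|".join(sorted(set(s)))))
    n_empty = sub.n_samples - len(keys)
    if keys.empty:
        return MixtureEnumeration(0, pd.Series(dtype=int), 0, None, n_empty)
    counts = keys.value_counts().sort_index().sort_values(
        ascending=False, kind="stable")
    insecticides = set(
        table.compounds.loc[table.compounds["pclass"] == "insecticide",
                            "compound_id"])
    n_with_i = sum(
        bool(insecticides.intersection(k.split("|"))) for k in counts.index)
    # ties for most frequent break lexicographically (stable sort above is
    # on descending count over a lexicographically sorted index)
    top_key = counts.index[0]
    return MixtureEnumeration(
        n_unique=len(counts),
        counts=counts,
        n_with_insecticide=int(n_with_i),
        most_frequent=(top_key, int(counts.iloc[0])),
        n_empty_samples=int(n_empty),
    )


def sample_counts_by_group(table: ResidueTable, matrix: str,
                           distance_class: str | None = None) -> pd.DataFrame:
    """Per-sample detected-CUP counts, labelled by system and month.

    Convenience view feeding the temporal and spatial analyses: one row per
    sample with ``system``, ``distance_class``, ``month_index`` and
    ``n_cups_detected``.
    """
    summ = summarize_samples(table.subset(matrix=matrix)).reset_index()
    if distance_class is not None:
        summ = summ[summ["distance_class"] == distance_class]
    return summ[["site_id", "system", "distance_class", "month_index",
                 "n_cups_detected"]].reset_index(drop=True)
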