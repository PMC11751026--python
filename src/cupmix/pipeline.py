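"""End-to-end orchestration: simulate/load -> summarise -> temporal ->
spatial -> risk, with a reproducible output manifest.

A run is fully described by a :class:`RunConfig` (loadable from a flat YAML
file). Every stage writes tidy CSVs into the output directory and the run
ends with a ``manifest.json`` listing each output file with its SHA-256
content hash, so identical config + seed reproduce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import decay, risk, summary, synthetic, temporal
from .residue_io import (
    EndpointTable,
    MATRICES,
    ResidueTable,
    SYSTEMS,
    read_endpoint_table,
    read_residue_table,
    write_endpoint_table,
    write_residue_table,
)

log = logging.getLogger("cupmix")

ALL_STAGES = ("summarize", "temporal", "spatial", "risk")


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run.

    Defaults reproduce the analysis constants: peak-detection delta 0.3,
    bee soil contact 2.23 g, surrogate LD50 divisor 10, assessment factors
    10 (NOEC) / 1000 (LC50), KL floor epsilon 1e-6.
    """

    seed: int = 0
    out_dir: str = "cupmix_out"
    stages: tuple[str, ...] = ALL_STAGES
    # inputs: either paths to an existing campaign, or synthetic generation
    residue_path: str | None = None
    compound_path: str | None = None
    endpoint_path: str | None = None
    synthetic: bool = True
    noise_cv: float = 0.3
    # temporal settings
    span: float | None = None
    span_grid: tuple[float, ...] = temporal.SPAN_GRID_DEFAULT
    loess_degree: int = 2
    epsilon: float = temporal.EPSILON_DEFAULT
    delta: float = temporal.DELTA_DEFAULT
    # spatial settings
    include_infield_residuals: bool = True
    # risk settings
    soil_contact_g: float = risk.SOIL_CONTACT_G
    surrogate_divisor: float = risk.SURROGATE_DIVISOR

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "span_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["span_grid"] = list(self.span_grid)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, outputs: list[Path]) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    outputs.append(path)


def load_inputs(config: RunConfig) -> tuple[ResidueTable, EndpointTable | None]:
    """Simulate a campaign or load one from the configured paths."""
    if config.synthetic or config.residue_path is None:
        syn = synthetic.SyntheticConfig(seed=config.seed,
                                        noise_cv=config.noise_cv)
        table, _ = synthetic.generate_campaign(syn)
        endpoints = synthetic.generate_endpoints(table.compounds,
                                                 seed=config.seed)
        return table, endpoints
    table = read_residue_table(config.residue_path, config.compound_path)
    endpoints = (read_endpoint_table(config.endpoint_path)
                 if config.endpoint_path else None)
    return table, endpoints


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Stage failures mark the manifest entry as failed and yield a non-empty
    ``failures`` list (the CLI maps that to a non-zero exit status); outputs
    of completed stages are retained.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    failures: list[str] = []
    log.info("resolved settings: %s", json.dumps(config.resolved(), sort_keys=True))

    table, endpoints = load_inputs(config)
    if config.synthetic or config.residue_path is None:
        write_residue_table(table, out_dir / "residues.csv",
                            out_dir / "compounds.csv")
        outputs += [out_dir / "residues.csv", out_dir / "compounds.csv"]
        if endpoints is not None:
            write_endpoint_table(endpoints, out_dir / "endpoints.csv")
            outputs.append(out_dir / "endpoints.csv")

    for stage in config.stages:
        try:
            if stage == "summarize":
                _stage_summarize(table, out_dir, outputs)
            elif stage == "temporal":
                _stage_temporal(table, config, out_dir, outputs)
            elif stage == "spatial":
                _stage_spatial(table, config, out_dir, outputs)
            elif stage == "risk":
                if endpoints is None or len(endpoints) == 0:
                    log.warning("risk stage skipped: no endpoint table")
                    continue
                _stage_risk(table, endpoints, config, out_dir, outputs)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:  # stage isolation: later stages still run
            log.error("stage %s failed: %s", stage, exc)
            failures.append(f"{stage}: {exc}")

    manifest = {
        "config": config.resolved(),
        "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
        "failures": failures,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return manifest


def _stage_summarize(table: ResidueTable, out_dir: Path,
                     outputs: list[Path]) -> None:
    _write_csv(summary.summarize_samples(table).reset_index(),
               out_dir / "sample_summaries.csv", outputs)
    rows = []
    for matrix in MATRICES:
        freq = summary.detection_frequency(table, matrix)
        stats = summary.concentration_stats(table, matrix)
        merged = pd.concat([freq, stats], axis=1).reset_index()
        merged.insert(0, "matrix", matrix)
        rows.append(merged)
        mix = summary.enumerate_mixtures(table, matrix)
        mix_df = (mix.counts.rename("n_samples")
                  .rename_axis("mixture").reset_index())
        mix_df.insert(0, "matrix", matrix)
        _write_csv(mix_df, out_dir / f"mixtures_{matrix}.csv", outputs)
    _write_csv(pd.concat(rows, ignore_index=True),
               out_dir / "compound_summaries.csv", outputs)


def _stage_temporal(table: ResidueTable, config: RunConfig, out_dir: Path,
                    outputs: list[Path]) -> None:
    smooth_rows, kl_rows, peak_rows = [], [], []
    for matrix in MATRICES:
        series = {s: temporal.monthly_series(table, matrix, s)
                  for s in SYSTEMS}
        kl = temporal.compare_systems(series, span=config.span,
                                      candidate_spans=config.span_grid,
                                      degree=config.loess_degree,
                                      epsilon=config.epsilon)
        kl_long = kl.reset_index(names="P").melt(
            id_vars="P", var_name="Q", value_name="kl_bits")
        kl_long.insert(0, "matrix", matrix)
        kl_rows.append(kl_long)
        for sys_name, ms in series.items():
            span = config.span or temporal.select_span_cv(
                ms, config.span_grid, config.loess_degree)
            sm = temporal.fit_loess(ms, span, config.loess_degree)
            smooth_rows.append(pd.DataFrame({
                "matrix": matrix, "system": sys_name,
                "month_index": sm.grid.astype(int),
                "raw_mean": ms.values, "fitted": sm.fitted,
                "span": span, "degree": sm.degree,
                "epsilon": config.epsilon,
            }))
            residuals = temporal.detrend_linear(ms)
            peaks = temporal.detect_peaks(residuals.values, config.delta)
            for p in peaks.peaks:
                peak_rows.append({
                    "matrix": matrix, "system": sys_name,
                    "month_index": p.position, "residual": p.value,
                    "kind": p.kind, "delta": config.delta,
                })
    _write_csv(pd.concat(smooth_rows, ignore_index=True),
               out_dir / "loess_curves.csv", outputs)
    _write_csv(pd.concat(kl_rows, ignore_index=True),
               out_dir / "kl_divergences.csv", outputs)
    _write_csv(pd.DataFrame(peak_rows),
               out_dir / "peaks.csv", outputs)


def _stage_spatial(table: ResidueTable, config: RunConfig, out_dir: Path,
                   outputs: list[Path]) -> None:
    rows = []
    for matrix in MATRICES:
        for sys_name in SYSTEMS:
            fit = decay.fit_distance_decay(
                table, matrix, sys_name,
                include_infield=config.include_infield_residuals)
            rows.append({
                "matrix": matrix, "system": sys_name,
                "a": fit.a, "b": fit.b, "c": fit.c, "rss": fit.rss,
                "converged": fit.converged, "n_obs": fit.n_obs,
                "warnings": ";".join(fit.warnings),
            })
    _write_csv(pd.DataFrame(rows), out_dir / "distance_decay.csv", outputs)


def _stage_risk(table: ResidueTable, endpoints: EndpointTable,
                config: RunConfig, out_dir: Path,
                outputs: list[Path]) -> None:
    per_sample = []
    for organism in ("collembola", "earthworm"):
        rt = risk.risk_table(table, endpoints, organism)
        per_sample.append(rt)
        agg = risk.aggregate_risk(rt, "mrq")
        agg.insert(0, "organism", organism)
        _write_csv(agg, out_dir / f"mrq_aggregated_{organism}.csv", outputs)
    _write_csv(pd.concat(per_sample, ignore_index=True),
               out_dir / "mrq_per_sample.csv", outputs)

    ht = risk.hazard_table(table, endpoints,
                           soil_contact_g=config.soil_contact_g,
                           surrogate_divisor=config.surrogate_divisor)
    _write_csv(ht, out_dir / "mhq_per_sample.csv", outputs)
    _write_csv(risk.aggregate_risk(ht, "mhq"),
               out_dir / "mhq_aggregated.csv", outputs)
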