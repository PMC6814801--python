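"""End-to-end flux pipeline: classify, filter, compute, propagate, report.

``compute_fluxes`` runs the deterministic per-segment chain (hydraulic
geometry -> energy dissipation -> k600 -> water temperature -> kCO2 ->
CO2 regression -> gradient -> areal and total flux); ``run_pipeline``
wraps it with the retention filters, the Monte Carlo ensemble, outlier
trimming, both total-flux uncertainty schemes and a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from streamco2 import co2model, fluxes, hydraulics, io, montecarlo, physchem
from streamco2.constants import DEFAULT_CONSTANTS, PhysicalConstants
from streamco2.montecarlo import PerturbationSpec
from streamco2.network import ClassificationRule, NetworkTopology, apply_filters

#: Column order of the per-segment flux CSV.
FLUX_COLUMNS = (
    "segment_id",
    "kco2_m_d",
    "pco2_uatm",
    "delta_mgC_m3",
    "areal_gC_m2_d",
    "areal_kgC_m2_yr",
    "area_m2",
    "total_gC_yr",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs, round-trippable through YAML."""

    seed: int = 0
    days_per_year: float = fluxes.DAYS_PER_YEAR
    constants: PhysicalConstants = DEFAULT_CONSTANTS
    rule: ClassificationRule = ClassificationRule()
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    co2_model: co2model.CO2RegressionModel = co2model.DEFAULT_CO2_MODEL
    output_dir: str | None = None

    def to_yaml(self, path) -> None:
        payload = {
            "seed": self.seed,
            "days_per_year": self.days_per_year,
            "constants": dataclasses.asdict(self.constants),
            "rule": {
                "min_elevation": self.rule.min_elevation,
                "roughness_schedule": [list(b) for b in self.rule.roughness_schedule],
                "max_elevation": self.rule.max_elevation,
                "max_discharge": self.rule.max_discharge,
                "max_energy_dissipation": self.rule.max_energy_dissipation,
            },
            "perturbation": dataclasses.asdict(self.perturbation),
            "co2_model": dataclasses.asdict(self.co2_model),
            "output_dir": self.output_dir,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        rule_raw = payload.get("rule", {})
        if "roughness_schedule" in rule_raw:
            rule_raw = dict(rule_raw)
            rule_raw["roughness_schedule"] = tuple(
                (float(lo), float(hi), float(thr))
                for lo, hi, thr in rule_raw["roughness_schedule"]
            )
        return cls(
            seed=payload.get("seed", 0),
            days_per_year=payload.get("days_per_year", fluxes.DAYS_PER_YEAR),
            constants=PhysicalConstants(**payload.get("constants", {})),
            rule=ClassificationRule(**rule_raw),
            perturbation=PerturbationSpec(**payload.get("perturbation", {})),
            co2_model=co2model.CO2RegressionModel(**payload.get("co2_model", {})),
            output_dir=payload.get("output_dir"),
        )


@dataclass
class PipelineResult:
    """Outputs of one pipeline run."""

    flux_table: pd.DataFrame
    summary: dict
    manifest: dict
    ensemble: montecarlo.FluxEnsemble | None = None


def compute_fluxes(
    segments: pd.DataFrame,
    model: co2model.CO2RegressionModel = co2model.DEFAULT_CO2_MODEL,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    days_per_year: float = fluxes.DAYS_PER_YEAR,
) -> pd.DataFrame:
    """Deterministic per-segment flux chain on a (pre-filtered) table."""
    q = segments["discharge_m3s"].to_numpy(dtype=float)
    slope = segments["slope_mm"].to_numpy(dtype=float)
    elev = segments["elevation_m"].to_numpy(dtype=float)
    soc = segments["soc_gkg"].to_numpy(dtype=float)
    tair = segments["tair_c"].to_numpy(dtype=float)
    length = segments["length_m"].to_numpy(dtype=float)

    geom = hydraulics.channel_geometry(q)
    ed = hydraulics.energy_dissipation(geom.velocity, slope, constants.g)
    k600 = hydraulics.k600_from_energy_dissipation(ed)
    tw = physchem.water_temperature(tair, constants)
    kco2 = physchem.k600_to_kco2(k600, tw, constants)
    patm = physchem.barometric_pressure(elev, constants)
    kh = physchem.henry_constant(tw, constants)
    c_sat = physchem.co2_saturation(patm, kh, constants)
    c_stream = co2model.predict_co2(elev, q, soc, model)
    delta = fluxes.delta_co2(c_stream, c_sat, constants.molar_mass_c)
    daily, annual = fluxes.areal_flux(kco2, delta, days_per_year)
    area = geom.width * length
    total = fluxes.total_flux(daily, geom.width, length, days_per_year)

    return pd.DataFrame(
        {
            "segment_id": segments["segment_id"].to_numpy(),
            "kco2_m_d": kco2,
            "pco2_uatm": c_stream / kh,
            "delta_mgC_m3": delta,
            "areal_gC_m2_d": daily,
            "areal_kgC_m2_yr": annual,
            "area_m2": area,
            "total_gC_yr": total,
        },
        columns=list(FLUX_COLUMNS),
    )


def run_pipeline(
    config: PipelineConfig, topology: NetworkTopology
) -> PipelineResult:
    """Classify, filter, compute fluxes, propagate errors and summarize.

    Writes the flux CSV, the regional summary and the run manifest to
    ``config.output_dir`` when set; always returns them.
    """
    segments = topology.segments
    retained, exclusions = apply_filters(segments, config.rule)
    if len(retained) == 0:
        raise ValueError("no segments retained after filtering")

    flux_table = compute_fluxes(
        retained, config.co2_model, config.constants, config.days_per_year
    )

    ensemble = montecarlo.run_ensemble(
        retained,
        config.co2_model,
        config.perturbation,
        seed=config.seed,
        constants=config.constants,
        days_per_year=config.days_per_year,
    )
    ensemble = montecarlo.trim_outliers(ensemble)
    independent = montecarlo.total_independent(ensemble)
    dependent = montecarlo.total_dependent(ensemble)
    regional = fluxes.aggregate_regional(flux_table)

    summary = {
        "n_input_segments": int(exclusions.n_input),
        "n_retained_segments": int(exclusions.n_retained),
        "exclusions": dict(exclusions.counts),
        "net_total_gC_yr": regional.net_total_gc_yr,
        "fraction_negative": regional.fraction_negative,
        "percentiles": regional.percentiles,
        "total_independent": {
            "mean_gC_yr": independent.mean,
            "p5_gC_yr": independent.p5,
            "p95_gC_yr": independent.p95,
        },
        "total_dependent": {
            "mean_gC_yr": dependent.mean,
            "p5_gC_yr": dependent.p5,
            "p95_gC_yr": dependent.p95,
        },
        "trimmed_fraction": ensemble.trimmed_fraction,
    }

    from importlib.metadata import version as _dist_version

    try:
        pkg_version = _dist_version("streamco2")
    except Exception:
        pkg_version = "unknown"
    flux_csv = flux_table.to_csv(index=False)
    manifest = {
        "package_version": pkg_version,
        "seed": int(config.seed),
        "n_iter": int(config.perturbation.n_iter),
        "trim_quantile": float(config.perturbation.trim_quantile),
        "n_input_segments": int(exclusions.n_input),
        "n_retained_segments": int(exclusions.n_retained),
        "exclusions": dict(exclusions.counts),
        "n_trimmed_draws": int(ensemble.trimmed.sum()),
        "flux_csv_sha256": hashlib.sha256(flux_csv.encode()).hexdigest(),
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "fluxes.csv").write_text(flux_csv, encoding="utf-8")
        io.write_report(summary, out / "summary.yaml")
        io.write_report(manifest, out / "manifest.yaml")
        ensemble.summary_table().to_csv(out / "ensemble_summary.csv", index=False)

    return PipelineResult(
        flux_table=flux_table, summary=summary, manifest=manifest, ensemble=ensemble
    )
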