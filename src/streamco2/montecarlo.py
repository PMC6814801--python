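"""Monte Carlo error propagation for the flux pipeline.

Every fitted relationship entering the flux chain — channel width, flow
velocity (and through it energy dissipation), water temperature, the
k600 scaling and the streamwater CO2 regression — is perturbed per
segment and per iteration by draws from its residual distribution
(lognormal for the multiplicative power-law fits, additive Gaussian for
temperature). Outliers are trimmed at a pooled upper percentile, and
network totals are summarized under two bracketing error models:
fully independent errors across segments (sum per iteration, then take
percentiles) and fully dependent errors (percentiles per segment, then
sum the percentiles).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from streamco2 import co2model, fluxes, hydraulics, physchem
from streamco2.constants import DEFAULT_CONSTANTS, PhysicalConstants

#: Default Monte Carlo iteration count.
DEFAULT_N_ITER = 10_000
#: Pooled upper quantile above which draws count as outliers.
DEFAULT_TRIM_QUANTILE = 0.995

#: Variables whose pooled upper tail defines the outlier trim.
TRIM_VARIABLES = ("slope", "co2", "areal_flux")


def _default_co2_sd() -> float:
    return co2model.residual_sd_for_r2()


@dataclass(frozen=True)
class PerturbationSpec:
    """Residual scales and run-shape of the Monte Carlo ensemble.

    ln-scale standard deviations for the multiplicative relationships
    (width, velocity, k600, CO2 concentration) and an additive
    degrees-C standard deviation for water temperature. The k600
    channel is the widest by default, reflecting that the gas-exchange
    scaling dominates the propagated uncertainty.
    """

    co2_residual_sd: float = field(default_factory=_default_co2_sd)
    k600_residual_sd: float = 0.5
    width_residual_sd: float = 0.12
    velocity_residual_sd: float = 0.12
    tw_residual_sd: float = 1.0
    n_iter: int = DEFAULT_N_ITER
    trim_quantile: float = DEFAULT_TRIM_QUANTILE

    def __post_init__(self) -> None:
        sds = (
            self.co2_residual_sd,
            self.k600_residual_sd,
            self.width_residual_sd,
            self.velocity_residual_sd,
            self.tw_residual_sd,
        )
        if any(s is None for s in sds):
            raise ValueError("all residual sds must be set")
        if any(s < 0 for s in sds):
            raise ValueError("residual sds must be non-negative")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0.5 < self.trim_quantile <= 1.0:
            raise ValueError("trim_quantile must lie in (0.5, 1]")


@dataclass(frozen=True)
class FluxEnsemble:
    """Per-segment x per-iteration Monte Carlo draws with provenance.

    Draw arrays have shape (n_segments, n_iter). ``trimmed`` is None
    before outlier removal and a boolean mask (True = removed) after.
    """

    segment_ids: np.ndarray
    slope: np.ndarray
    co2: np.ndarray
    kco2: np.ndarray
    areal_daily: np.ndarray
    total: np.ndarray
    seed: int | None
    spec: PerturbationSpec
    trimmed: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return self.total.shape[0]

    @property
    def n_iter(self) -> int:
        return self.total.shape[1]

    @property
    def trimmed_fraction(self) -> float:
        if self.trimmed is None:
            return 0.0
        return float(self.trimmed.mean())

    @classmethod
    def from_total_draws(
        cls,
        total: np.ndarray,
        spec: PerturbationSpec | None = None,
        seed: int | None = None,
    ) -> "FluxEnsemble":
        """Wrap raw per-segment total-flux draws (for analytic checks)."""
        total = np.asarray(total, dtype=float)
        n_seg = total.shape[0]
        zeros = np.zeros(total.shape)
        return cls(
            segment_ids=np.arange(n_seg),
            slope=np.zeros(n_seg),
            co2=zeros,
            kco2=zeros,
            areal_daily=total.copy(),
            total=total,
            seed=seed,
            spec=spec if spec is not None else PerturbationSpec(n_iter=total.shape[1]),
        )

    def summary_table(self) -> pd.DataFrame:
        """Per-segment mean / p5 / p95 of total flux over retained draws."""
        masked = np.ma.masked_array(
            self.total, mask=self.trimmed if self.trimmed is not None else False
        )
        rows = []
        for i, sid in enumerate(self.segment_ids):
            draws = masked[i].compressed()
            if draws.size == 0:
                rows.append((sid, np.nan, np.nan, np.nan, 0))
                continue
            rows.append(
                (
                    sid,
                    float(draws.mean()),
                    float(np.percentile(draws, 5)),
                    float(np.percentile(draws, 95)),
                    int(draws.size),
                )
            )
        return pd.DataFrame(
            rows,
            columns=["segment_id", "mean_gC_yr", "p5_gC_yr", "p95_gC_yr", "n_draws"],
        )


@dataclass(frozen=True)
class TotalEstimate:
    """Network total flux with a 5th-95th percentile interval."""

    mean: float
    p5: float
    p95: float

    @property
    def interval_width(self) -> float:
        return self.p95 - self.p5


def run_ensemble(
    segments: pd.DataFrame,
    model: co2model.CO2RegressionModel,
    spec: PerturbationSpec,
    seed: int,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    days_per_year: float = fluxes.DAYS_PER_YEAR,
) -> FluxEnsemble:
    """Propagate residual noise through the flux chain for every segment.

    For each segment and iteration: width and velocity are perturbed on
    the ln scale around their hydraulic-geometry predictions, energy
    dissipation and k600 follow from the perturbed velocity, k600 then
    receives its own ln-scale noise, water temperature an additive
    degrees-C noise (clipped to the Schmidt validity range), and the CO2
    concentration ln-scale regression noise. kCO2, the CO2 gradient and
    the areal and total fluxes are recomputed per draw.

    Draws are reproducible for a fixed ``seed`` and independent of
    segment evaluation order (one spawned RNG substream per segment and
    noise channel).
    """
    n_seg = len(segments)
    if n_seg == 0:
        raise ValueError("run_ensemble requires at least one segment")
    n_iter = spec.n_iter

    q = segments["discharge_m3s"].to_numpy(dtype=float)
    slope = segments["slope_mm"].to_numpy(dtype=float)
    elev = segments["elevation_m"].to_numpy(dtype=float)
    soc = segments["soc_gkg"].to_numpy(dtype=float)
    tair = segments["tair_c"].to_numpy(dtype=float)
    length = segments["length_m"].to_numpy(dtype=float)

    geom = hydraulics.channel_geometry(q)
    patm = physchem.barometric_pressure(elev, constants)
    tw_base = constants.tw_intercept + constants.tw_slope * tair
    ln_co2_pred = np.log(co2model.predict_co2(elev, q, soc, model))

    co2_draws = np.empty((n_seg, n_iter))
    kco2_draws = np.empty((n_seg, n_iter))
    areal_draws = np.empty((n_seg, n_iter))
    total_draws = np.empty((n_seg, n_iter))

    root = np.random.SeedSequence(seed)
    children = root.spawn(n_seg)
    for i in range(n_seg):
        ch = children[i].spawn(5)
        rng_w, rng_v, rng_tw, rng_k, rng_c = (
            np.random.Generator(np.random.PCG64(c)) for c in ch
        )
        width = geom.width[i] * np.exp(
            rng_w.normal(0.0, spec.width_residual_sd, n_iter)
        )
        velocity = geom.velocity[i] * np.exp(
            rng_v.normal(0.0, spec.velocity_residual_sd, n_iter)
        )
        tw = np.clip(
            tw_base[i] + rng_tw.normal(0.0, spec.tw_residual_sd, n_iter),
            physchem.TW_MIN,
            physchem.TW_MAX,
        )
        ed = hydraulics.energy_dissipation(velocity, slope[i], constants.g)
        k600 = hydraulics.k600_from_energy_dissipation(ed) * np.exp(
            rng_k.normal(0.0, spec.k600_residual_sd, n_iter)
        )
        kco2 = physchem.k600_to_kco2(k600, tw, constants)
        c_stream = np.exp(
            ln_co2_pred[i] + rng_c.normal(0.0, spec.co2_residual_sd, n_iter)
        )
        kh = physchem.henry_constant(tw, constants)
        c_sat = physchem.co2_saturation(patm[i], kh, constants)
        delta = fluxes.delta_co2(c_stream, c_sat, constants.molar_mass_c)
        daily, _annual = fluxes.areal_flux(kco2, delta, days_per_year)
        total = fluxes.total_flux(daily, width, length[i], days_per_year)

        co2_draws[i] = c_stream
        kco2_draws[i] = kco2
        areal_draws[i] = daily
        total_draws[i] = total

    return FluxEnsemble(
        segment_ids=segments["segment_id"].to_numpy(),
        slope=slope,
        co2=co2_draws,
        kco2=kco2_draws,
        areal_daily=areal_draws,
        total=total_draws,
        seed=seed,
        spec=spec,
    )


def trim_outliers(
    ensemble: FluxEnsemble,
    variables: tuple[str, ...] = TRIM_VARIABLES,
    trim_quantile: float | None = None,
) -> FluxEnsemble:
    """Mark draws above the pooled upper percentile of any trim variable.

    Each listed variable (``slope``, ``co2``, ``areal_flux``) is pooled
    across all segments and iterations; draws strictly above its
    ``trim_quantile`` pooled percentile are removed from all downstream
    statistics. Slope is constant across iterations, so a slope outlier
    removes the segment's entire draw set.
    """
    q = ensemble.spec.trim_quantile if trim_quantile is None else trim_quantile
    shape = ensemble.total.shape
    mask = np.zeros(shape, dtype=bool)
    pools = {
        "slope": np.broadcast_to(ensemble.slope[:, None], shape),
        "co2": ensemble.co2,
        "areal_flux": ensemble.areal_daily,
    }
    for var in variables:
        if var not in pools:
            raise ValueError(f"unknown trim variable {var!r}")
        pool = pools[var]
        threshold = np.quantile(pool, q)
        mask |= pool > threshold
    return dataclasses.replace(ensemble, trimmed=mask)


def _require_trim(ensemble: FluxEnsemble) -> np.ndarray:
    return ensemble.trimmed if ensemble.trimmed is not None else np.zeros(
        ensemble.total.shape, dtype=bool
    )


def total_independent(ensemble: FluxEnsemble) -> TotalEstimate:
    """Network total under independent per-segment errors.

    Retained draws are summed over segments within each iteration; the
    mean and the 5th/95th percentiles are taken over the n_iter totals.
    Errors average out across segments, giving a narrow interval.
    """
    mask = _require_trim(ensemble)
    contrib = np.where(mask, 0.0, ensemble.total)
    iteration_totals = contrib.sum(axis=0)
    return TotalEstimate(
        mean=float(iteration_totals.mean()),
        p5=float(np.percentile(iteration_totals, 5)),
        p95=float(np.percentile(iteration_totals, 95)),
    )


def total_dependent(ensemble: FluxEnsemble) -> TotalEstimate:
    """Network total under perfectly dependent per-segment errors.

    The mean and 5th/95th percentiles are computed per segment from its
    own retained draws, then summed separately across segments, so the
    interval scales with the sum of the per-segment spreads.
    """
    mask = _require_trim(ensemble)
    means = p5s = p95s = 0.0
    for i in range(ensemble.n_segments):
        draws = ensemble.total[i][~mask[i]]
        if draws.size == 0:
            continue
        means += float(draws.mean())
        p5s += float(np.percentile(draws, 5))
        p95s += float(np.percentile(draws, 95))
    return TotalEstimate(mean=means, p5=p5s, p95=p95s)
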