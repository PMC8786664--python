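"""Carbon-flux estimators from labelling kinetics, pools and biomass data.

All estimators report in nmol C equivalents g⁻¹ DW s⁻¹ (the canonical unit of
the comparative rate table); unit conversions are centralized here.  The
"minimum" estimators bound gross fluxes from below: total ¹³C found in a set
of metabolites at an early time point, divided by the time and corrected for
the medium ¹³C enrichment, cannot exceed the true carbon influx that fed them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinetics import LabelSeries

__all__ = [
    "PoolTable",
    "FluxEstimate",
    "min_assimilation_rate",
    "min_pepc_flux",
    "product_synthesis_rate",
    "gc_pool_flux_sum",
    "starch_rates",
    "pct_c12_supply_from_starch",
    "protein_flux",
    "psr_from_enrichment",
    "lipid_synthesis_index",
    "flux_ratio",
]

UMOL_TO_NMOL = 1e3
C_MOLAR_MASS = 12.0  # g mol⁻¹
DEFAULT_PROTEIN_C_FRACTION = 0.43


@dataclass
class PoolTable:
    """metabolite -> (pool size in µmol g⁻¹ DW, carbon count)."""

    entries: dict

    def __post_init__(self) -> None:
        for met, (pool, n_c) in self.entries.items():
            if pool <= 0:
                raise ValueError(f"{met}: pool size must be > 0")
            if n_c < 1:
                raise ValueError(f"{met}: carbon count must be >= 1")

    def pool(self, met: str) -> float:
        return self.entries[met][0]

    def n_carbons(self, met: str) -> int:
        return self.entries[met][1]

    def __contains__(self, met: str) -> bool:
        return met in self.entries


@dataclass
class FluxEstimate:
    """A named rate with uncertainty and provenance."""

    name: str
    value: float                   # nmol C eq. g⁻¹ DW s⁻¹ unless noted
    sd: float = 0.0
    estimator: str = ""
    window: tuple | None = None

    # estimators whose sign is meaningful (net rates, ratios, turnover terms)
    _SIGNED = ("ratio", "net", "starch_rates")

    def __post_init__(self) -> None:
        if self.estimator not in self._SIGNED and self.value < -1e-12:
            raise ValueError(f"{self.name}: synthesis/assimilation rate < 0")


def _labelled_carbon(series, pools: PoolTable) -> dict:
    """Per time point: sum over metabolites of E(t) * P * n_C (µmol C g⁻¹ DW)."""
    missing = [s.metabolite_id for s in series if s.metabolite_id not in pools]
    if missing:
        raise KeyError(f"metabolites missing from pool table: {missing}")
    totals: dict = {}
    for s in series:
        p = pools.pool(s.metabolite_id)
        n = pools.n_carbons(s.metabolite_id)
        for t, e in zip(s.times, s.mean):
            if t > 0:
                totals[t] = totals.get(t, 0.0) + e * p * n
    return totals


def min_assimilation_rate(series, pools: PoolTable,
                          medium_enrichment: float = 0.5,
                          name: str = "min_13C_assimilation") -> FluxEstimate:
    """Minimum gross C assimilation from early ¹³C incorporation.

    For each sampled time t, rate(t) = Σ_metab E(t)·P·n_C / t; the maximum
    over time points is kept and divided by the medium enrichment (only a
    fraction of the supplied inorganic carbon was ¹³C).
    """
    if medium_enrichment <= 0:
        raise ValueError("medium enrichment must be > 0")
    totals = _labelled_carbon(series, pools)
    if not totals:
        raise ValueError("no positive time points in series")
    rates = {t: c / t for t, c in totals.items()}
    t_best = max(rates, key=rates.get)
    value = rates[t_best] / medium_enrichment * UMOL_TO_NMOL
    return FluxEstimate(name, value, estimator="min_assimilation",
                        window=(t_best, t_best))


def min_pepc_flux(series, pools: PoolTable,
                  medium_enrichment: float = 0.5) -> FluxEstimate:
    """Minimum anaplerotic flux at PEP from ¹³C in malate and aspartate only."""
    wanted = {"MAL", "ASP", "malate", "aspartate"}
    sel = [s for s in series if s.metabolite_id in wanted]
    if not sel:
        raise ValueError("no malate/aspartate series supplied")
    est = min_assimilation_rate(sel, pools, medium_enrichment,
                                name="min_PEPC_flux")
    est.estimator = "min_pepc"
    return est


def product_synthesis_rate(series: LabelSeries, pool_size: float,
                           window=(1800.0, 7200.0),
                           carbon_ratio: int = 1,
                           name: str | None = None) -> FluxEstimate:
    """End-product synthesis rate from the slope of enrichment x pool size.

    OLS slope of E(t)·P over ``window`` (seconds; default 30–120 min),
    multiplied by ``carbon_ratio`` (C atoms per accounting unit: 12 for
    sucrose, 6 for hexoses) and converted to nmol C g⁻¹ DW s⁻¹.
    """
    mask = (series.times >= window[0]) & (series.times <= window[1])
    if mask.sum() < 3:
        raise ValueError(
            f"{series.metabolite_id}: need >= 3 points in window "
            f"[{window[0]:g}, {window[1]:g}] s")
    t = series.times[mask]
    y = series.mean[mask] * pool_size
    res = stats.linregress(t, y)
    value = res.slope * carbon_ratio * UMOL_TO_NMOL
    sd = res.stderr * carbon_ratio * UMOL_TO_NMOL
    return FluxEstimate(name or f"{series.metabolite_id}_synthesis",
                        max(0.0, value), sd=sd,
                        estimator="product_synthesis", window=window)


GC_FLUX_METABOLITES = ("pyruvate", "citrate", "glutamate", "proline", "glycine")


def gc_pool_flux_sum(series, pools: PoolTable, window=(1800.0, 7200.0),
                     expected=GC_FLUX_METABOLITES) -> FluxEstimate:
    """Minimum flux into organic/amino-acid pools: sum of per-metabolite
    level x enrichment slopes, each weighted by its own carbon count."""
    present = {s.metabolite_id for s in series}
    missing = set(expected) - present
    if missing:
        warnings.warn(f"gc_pool_flux_sum: missing metabolites {sorted(missing)}",
                      stacklevel=2)
    total, var = 0.0, 0.0
    for s in series:
        est = product_synthesis_rate(
            s, pools.pool(s.metabolite_id), window,
            carbon_ratio=pools.n_carbons(s.metabolite_id))
        total += est.value
        var += est.sd ** 2
    return FluxEstimate("gc_pool_flux_sum", total, sd=float(np.sqrt(var)),
                        estimator="gc_pool_flux_sum", window=window)


def starch_rates(starch_content: float, frac13_slope: float,
                 frac12_slope: float) -> dict:
    """Starch synthesis/degradation/net rates from fractional slopes.

    ``starch_content`` in µmol C6 (glucosyl) units g⁻¹ DW; the slopes are the
    per-second rates of change of the ¹³C and ¹²C fractional content.  Each
    rate = content × slope × 6 C per glucosyl unit, in nmol C g⁻¹ DW s⁻¹;
    net ≡ synthesis − degradation by construction.
    """
    if starch_content <= 0:
        raise ValueError("starch content must be > 0")
    if frac12_slope > 0:
        warnings.warn("positive ¹²C-starch slope: gain of unlabelled starch "
                      "during labelling", stacklevel=2)
    synthesis = starch_content * frac13_slope * 6.0 * UMOL_TO_NMOL
    degradation = -starch_content * frac12_slope * 6.0 * UMOL_TO_NMOL
    return {
        "synthesis": FluxEstimate("starch_synthesis", synthesis,
                                  estimator="starch_rates"),
        "degradation": FluxEstimate("starch_degradation", degradation,
                                    estimator="starch_rates"),
        "net": FluxEstimate("net_starch_accumulation",
                            synthesis - degradation, estimator="net"),
    }


def pct_c12_supply_from_starch(degradation: FluxEstimate,
                               assimilation: FluxEstimate) -> float:
    """Percent of ¹²C supply attributable to starch breakdown:
    100 x degradation / assimilation."""
    if assimilation.value <= 0:
        raise ZeroDivisionError("assimilation rate must be > 0")
    return 100.0 * degradation.value / assimilation.value


def protein_flux(psr: float, protein_content: float,
                 c_fraction: float = DEFAULT_PROTEIN_C_FRACTION) -> FluxEstimate:
    """Protein synthesis C flux from a fractional synthesis rate.

    psr in % h⁻¹, protein content in mg g⁻¹ DW, carbon assumed to account for
    ``c_fraction`` of protein weight.  (psr/100)·content·c_fraction is
    mg C g⁻¹ h⁻¹; divide by 12 g mol⁻¹ and 3600 s, scale to nmol.
    """
    if psr < 0 or protein_content <= 0 or not 0 < c_fraction <= 1:
        raise ValueError("invalid protein flux inputs")
    mg_c_per_h = (psr / 100.0) * protein_content * c_fraction
    value = mg_c_per_h / C_MOLAR_MASS / 3600.0 * 1e6  # mg→nmol: 1e-3 g /12 → mol
    return FluxEstimate("protein_synthesis", value, estimator="protein_flux")


def psr_from_enrichment(bound_series: LabelSeries, free_series: LabelSeries,
                        window=None, precursor: str = "mean") -> float:
    """Protein synthesis rate (% h⁻¹) from bound vs free amino-acid enrichment.

    The slope of protein-bound enrichment over time (per hour) is divided by
    the precursor (free amino acid) enrichment to correct for incomplete
    labelling of the free pool; ``precursor`` selects the correction
    denominator: the time-averaged free enrichment over the fit window
    ("mean", default) or its final value ("plateau").  Valid while bound
    enrichment remains small relative to the free pool.
    """
    shared, ia, ib = np.intersect1d(bound_series.times, free_series.times,
                                    return_indices=True)
    if window is not None:
        m = (shared >= window[0]) & (shared <= window[1])
    else:
        m = np.ones(shared.size, dtype=bool)
    if m.sum() < 3:
        raise ValueError("need >= 3 shared time points in window")
    t_h = shared[m] / 3600.0
    bound = bound_series.mean[ia][m]
    free = free_series.mean[ib][m]
    denom = float(free[-1]) if precursor == "plateau" else float(free.mean())
    if denom < 1e-6:
        raise ValueError("free amino-acid enrichment ~0: rate unidentifiable")
    slope = stats.linregress(t_h, bound).slope
    return 100.0 * slope / denom


def lipid_synthesis_index(lipid_content: float, growth_rate: float) -> float:
    """Bulk lipid synthesis index: lipid mass fraction x specific growth rate.

    lipid content in mg FA g⁻¹ DW, growth rate in h⁻¹; returns mg FA g⁻¹ DW h⁻¹.
    """
    if lipid_content < 0 or growth_rate < 0:
        raise ValueError("inputs must be >= 0")
    return lipid_content * growth_rate


def flux_ratio(numerator: FluxEstimate, denominator: FluxEstimate) -> FluxEstimate:
    """Plain ratio of two flux estimates with first-order s.d. propagation."""
    if denominator.value == 0:
        raise ZeroDivisionError(f"{denominator.name} is zero")
    r = numerator.value / denominator.value
    rel = 0.0
    if numerator.value != 0:
        rel += (numerator.sd / numerator.value) ** 2
    rel += (denominator.sd / denominator.value) ** 2
    return FluxEstimate(f"{numerator.name}/{denominator.name}", r,
                        sd=abs(r) * float(np.sqrt(rel)), estimator="ratio")
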