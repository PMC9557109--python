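"""Synthetic trial generator with analytic ground truth.

Emulates the structure of a multi-year, two-hybrid, replicated summer maize
trial: daily weather from a seasonal sinusoid with autoregressive noise,
phenology dates solved so accumulated GDD hits each hybrid's thresholds,
Gaussian LAI trajectories, linear post-silking Pn decline, fixed organ
dry-mass trajectories, ¹³C atom-% consistent with a configured organ
distribution, and yield components — all with additive zero-mean plot noise.

Every generated quantity has a closed-form ground truth (DLAI, APD, PrSDMAR,
DMR/DMRE, DMRC, HI, yield per GDD), so the full pipeline can be tested as an
identity at zero noise and as an unbiased estimator under noise.  The "±"
dispersions printed in trial reports are read as standard errors of n = 3
plots; plot noise is drawn with sd = SE·√3.
"""

from __future__ import annotations

import copy
import datetime as _dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .canopy_dynamics import HALF_LIFE_FACTOR
from .data_model_io import (
    ORGANS,
    GasExchangeObservation,
    IsotopeSample,
    LAIObservation,
    PlantSample,
    StageRecord,
    TrialDataset,
    WeatherDay,
    YieldPlot,
)
from .thermal_time import DEFAULT_TBASE, daily_gdd, stage_durations

__all__ = [
    "HybridTruth",
    "GroundTruth",
    "GenerationError",
    "UnknownViolationError",
    "default_truths",
    "generate_weather",
    "generate_trial",
    "corrupt_dataset",
    "VIOLATIONS",
]


class GenerationError(RuntimeError):
    """GDD thresholds cannot be reached within the generated season."""


class UnknownViolationError(ValueError):
    """corrupt_dataset was asked for a violation it does not know."""


# label strength: grams of tracer-mass proxy distributed over organs
_TRACER_MASS_G = 0.35
_ATOM_PCT_BASELINE = 1.082  # natural-abundance ¹³C atom-% of unlabeled tissue


@dataclass(frozen=True)
class HybridTruth:
    """Ground-truth parameters of one hybrid; defaults centred on the published trial ranges."""

    gdd_silking: float           # °C d sowing→R1
    gdd_total: float             # °C d sowing→R6
    lai_max: float               # Gaussian A, m² m⁻²
    lai_peak_day: float          # Gaussian B, d after silking
    lai_width: float             # Gaussian C, d
    pn_init: float               # Pi, µmol m⁻² s⁻¹ at silking
    pn_decline: float            # b, µmol m⁻² s⁻¹ d⁻¹
    leaf_r1: float               # g plant⁻¹
    stalk_r1: float
    leaf_r6: float
    stalk_r6: float
    grain_r6: float
    other_r6: float              # bract + cob
    c13_fractions: dict[str, float]          # organ -> fraction of tracer, sums to 1
    ears_1e4_ha: float
    grains_per_ear: float
    thousand_grain_g: float
    # plot noise scales (sd of one plot/plant draw; SE·√3 of the printed tables)
    noise: dict[str, float] = field(default_factory=lambda: {
        "lai": 0.10, "pn": 1.2, "leaf": 1.0, "stalk": 1.5, "grain": 3.0, "other": 1.0,
        "atom_pct": 0.003, "ears_1e4_ha": 0.15, "grains_per_ear": 17.0,
        "thousand_grain_g": 3.8, "moisture": 0.005, "spad": 1.5,
    })

    def __post_init__(self):
        f = self.c13_fractions
        if set(f) != set(ORGANS) or any(v < 0 for v in f.values()) or abs(sum(f.values()) - 1) > 1e-9:
            raise ValueError("c13_fractions must cover grain/other/stalk/leaf, be >= 0 and sum to 1")

    # -- closed forms -------------------------------------------------------

    @property
    def total_r1(self) -> float:
        return self.leaf_r1 + self.stalk_r1

    @property
    def total_r6(self) -> float:
        return self.leaf_r6 + self.stalk_r6 + self.grain_r6 + self.other_r6

    @property
    def dlai(self) -> float:
        return self.lai_width * HALF_LIFE_FACTOR

    @property
    def apd(self) -> float:
        return self.pn_init / (2.0 * self.pn_decline)

    @property
    def hi(self) -> float:
        return self.grain_r6 / self.total_r6

    @property
    def dmrc(self) -> float:
        to_grain = (max(self.leaf_r1 - self.leaf_r6, 0.0)
                    + max(self.stalk_r1 - self.stalk_r6, 0.0)) * self.c13_fractions["grain"]
        return 100.0 * to_grain / self.grain_r6

    @property
    def yield_kg_ha(self) -> float:
        return self.ears_1e4_ha * self.grains_per_ear * (self.thousand_grain_g / 1000.0) * 10.0

    def lai_at(self, t: float) -> float:
        return self.lai_max * math.exp(-((t - self.lai_peak_day) ** 2) / (2.0 * self.lai_width ** 2))


def default_truths() -> dict[str, HybridTruth]:
    """Two hybrids mirroring the published trial: an early (DH518-like) and a
    mid-late (DH605-like) maturity type."""
    return {
        "DH518": HybridTruth(
            gdd_silking=800.0, gdd_total=1690.0,
            lai_max=4.55, lai_peak_day=6.2, lai_width=42.3,
            pn_init=47.3, pn_decline=0.54,
            leaf_r1=36.0, stalk_r1=72.0,
            leaf_r6=30.7, stalk_r6=53.2, grain_r6=155.0, other_r6=31.1,
            c13_fractions={"grain": 0.64, "other": 0.20, "stalk": 0.10, "leaf": 0.06},
            ears_1e4_ha=6.90, grains_per_ear=510.0, thousand_grain_g=342.0,
        ),
        "DH605": HybridTruth(
            gdd_silking=900.0, gdd_total=1790.0,
            lai_max=5.13, lai_peak_day=4.9, lai_width=49.6,
            pn_init=48.5, pn_decline=0.43,
            leaf_r1=41.0, stalk_r1=77.0,
            leaf_r6=38.9, stalk_r6=58.9, grain_r6=163.0, other_r6=34.2,
            c13_fractions={"grain": 0.605, "other": 0.22, "stalk": 0.115, "leaf": 0.06},
            ears_1e4_ha=6.95, grains_per_ear=530.0, thousand_grain_g=352.0,
        ),
    }


@dataclass
class GroundTruth:
    """Analytic per-year x hybrid metric values carried alongside a generated dataset."""

    frame: pd.DataFrame  # indexed by (year, hybrid)

    def value(self, year: str, hybrid: str, metric: str) -> float:
        return float(self.frame.loc[(year, hybrid), metric])


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

_SEASON_START = (6, 1)   # June 1
_SEASON_END = (11, 10)   # November 10; >= 120 d season

def generate_weather(year: str, rng: np.random.Generator,
                     mean_level: float = 21.5, amplitude: float = 5.5,
                     peak_doy: int = 201, diurnal_range: float = 10.0,
                     noise: float = 1.0) -> list[WeatherDay]:
    """Daily Tmax/Tmin for one growing season.

    Daily mean follows a sinusoid peaking in late July plus AR(1) noise
    (phi = 0.6, innovation sd 1.5·noise); the diurnal range is 10 °C with
    mild jitter, floored at 4 °C so Tmax > Tmin always holds.
    """
    y = int(year)
    start = _dt.date(y, *_SEASON_START)
    end = _dt.date(y, *_SEASON_END)
    n = (end - start).days + 1
    days = []
    e = 0.0
    for i in range(n):
        date = start + _dt.timedelta(days=i)
        doy = date.timetuple().tm_yday
        mean = mean_level + amplitude * math.cos(2.0 * math.pi * (doy - peak_doy) / 365.0)
        e = 0.6 * e + rng.normal(0.0, 1.5) * noise
        rng_span = max(diurnal_range + rng.normal(0.0, 1.0) * noise, 4.0)
        days.append(WeatherDay(date=date, tmax=mean + e + rng_span / 2.0,
                               tmin=mean + e - rng_span / 2.0))
    return days


def _solve_phenology(year: str, hybrid: str, truth: HybridTruth,
                     weather: list[WeatherDay], sowing: _dt.date,
                     tbase: float) -> StageRecord:
    """First dates on which accumulated GDD (start-exclusive from sowing) crosses each threshold."""
    thresholds = {"v6": 0.45 * truth.gdd_silking, "v12": 0.75 * truth.gdd_silking,
                  "r1": truth.gdd_silking, "r6": truth.gdd_total}
    by_date = {w.date: w for w in weather}
    acc = 0.0
    hit: dict[str, _dt.date] = {}
    day = sowing
    last = max(by_date)
    while day < last and len(hit) < len(thresholds):
        day += _dt.timedelta(days=1)
        if day not in by_date:
            raise GenerationError(f"{year}: weather does not cover {day}")
        acc += daily_gdd(by_date[day], tbase)
        for name, thr in thresholds.items():
            if name not in hit and acc >= thr:
                hit[name] = day
    if len(hit) < len(thresholds):
        raise GenerationError(
            f"{year} {hybrid}: season ended at {acc:.0f} °C d before reaching "
            f"{max(thresholds.values()):.0f} °C d")
    r1 = hit["r1"]
    return StageRecord(year=year, hybrid=hybrid, sowing=sowing,
                       v6=hit["v6"], v12=hit["v12"], r1=r1,
                       r3=r1 + _dt.timedelta(days=25),
                       r5=r1 + _dt.timedelta(days=45),  # defined as 45 d after silking
                       r6=hit["r6"])


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------

_SOWING_OFFSETS = (0, -1, 8, 1, 2)  # days relative to June 8, cycled over years


def generate_trial(truths: dict[str, HybridTruth] | None = None,
                   years: tuple[str, ...] = ("2017", "2018", "2019", "2020", "2021"),
                   replicates: int = 3, seed: int = 0, noise: float = 1.0,
                   tbase: float = DEFAULT_TBASE,
                   density_plants_ha: float = 75_000.0) -> tuple[TrialDataset, GroundTruth]:
    """Generate a complete trial dataset plus its analytic ground truth.

    ``noise`` scales every noise sd (0 gives a deterministic, exactly
    model-consistent dataset).  Reproducible under a fixed seed.
    """
    if truths is None:
        truths = default_truths()
    if len(truths) < 2 or len(years) < 1 or replicates < 2:
        raise ValueError("need >= 2 hybrids, >= 1 year, >= 2 replicates")

    ds = TrialDataset(density_plants_ha=density_plants_ha, replicates=replicates)
    gt_rows = []

    for yi, year in enumerate(years):
        rng = np.random.default_rng([int(seed) % (2 ** 31), 1000 + yi])
        weather = generate_weather(year, rng, noise=noise)
        ds.weather[year] = weather
        sowing = _dt.date(int(year), 6, 8) + _dt.timedelta(days=_SOWING_OFFSETS[yi % len(_SOWING_OFFSETS)])

        for hybrid in sorted(truths):
            truth = truths[hybrid]
            rec = _solve_phenology(year, hybrid, truth, weather, sowing, tbase)
            ds.stages.append(rec)
            dur = stage_durations(rec, weather, tbase)
            nz = {k: v * noise for k, v in truth.noise.items()}

            stage_days = {s: (getattr(rec, s) - rec.r1).days
                          for s in ("v6", "v12", "r1", "r3", "r5", "r6")}

            # LAI per replicate at each stage
            for rep in range(1, replicates + 1):
                for stage, t in stage_days.items():
                    lai = max(truth.lai_at(t) + rng.normal(0.0, nz["lai"]), 0.0)
                    ds.lai.append(LAIObservation(year=year, hybrid=hybrid, stage=stage.upper(),
                                                 days_after_silking=float(t), lai=lai))

            # ear-leaf gas exchange at R1, R3, R5 per replicate
            for rep in range(1, replicates + 1):
                for stage in ("r1", "r3", "r5"):
                    t = float(stage_days[stage])
                    pn = max(truth.pn_init - truth.pn_decline * t + rng.normal(0.0, nz["pn"]), 0.0)
                    ds.gas_exchange.append(GasExchangeObservation(
                        year=year, hybrid=hybrid, stage=stage.upper(), days_after_silking=t,
                        pn=pn, gs=max(0.25 - 0.002 * t, 0.01), ci=180.0 + 0.5 * t,
                        spad=55.0 - 0.15 * t + rng.normal(0.0, nz["spad"])))

            # organ dry masses per replicate at R1 and R6
            for rep in range(1, replicates + 1):
                ds.plant_samples.append(PlantSample(
                    year=year, hybrid=hybrid, replicate=rep, stage="R1",
                    leaf=truth.leaf_r1 + rng.normal(0.0, nz["leaf"]),
                    stalk=truth.stalk_r1 + rng.normal(0.0, nz["stalk"])))
                ds.plant_samples.append(PlantSample(
                    year=year, hybrid=hybrid, replicate=rep, stage="R6",
                    leaf=truth.leaf_r6 + rng.normal(0.0, nz["leaf"]),
                    stalk=truth.stalk_r6 + rng.normal(0.0, nz["stalk"]),
                    grain=truth.grain_r6 + rng.normal(0.0, nz["grain"]),
                    other=truth.other_r6 + rng.normal(0.0, nz["other"])))

            # ¹³C cohort: 3 labeled + 3 reference plants, 4 organs each
            organ_truth = {"grain": truth.grain_r6, "other": truth.other_r6,
                           "stalk": truth.stalk_r6, "leaf": truth.leaf_r6}
            for plant in range(1, 4):
                for organ in ORGANS:
                    mass = max(organ_truth[organ] + rng.normal(0.0, nz[organ if organ in nz else "other"]), 1.0)
                    excess = 100.0 * truth.c13_fractions[organ] * _TRACER_MASS_G / mass
                    ds.isotope.append(IsotopeSample(
                        year=year, hybrid=hybrid, plant_id=f"L{plant}", labeled=True,
                        organ=organ, mass_g=mass,
                        atom_pct_13c=_ATOM_PCT_BASELINE + excess + rng.normal(0.0, nz["atom_pct"])))
                for organ in ORGANS:
                    mass = max(organ_truth[organ] + rng.normal(0.0, nz[organ if organ in nz else "other"]), 1.0)
                    ds.isotope.append(IsotopeSample(
                        year=year, hybrid=hybrid, plant_id=f"R{plant}", labeled=False,
                        organ=organ, mass_g=mass,
                        atom_pct_13c=_ATOM_PCT_BASELINE + rng.normal(0.0, nz["atom_pct"])))

            # yield components per plot; plot yield is the exact component product
            for rep in range(1, replicates + 1):
                ears = truth.ears_1e4_ha + rng.normal(0.0, nz["ears_1e4_ha"])
                grains = truth.grains_per_ear + rng.normal(0.0, nz["grains_per_ear"])
                tgw = truth.thousand_grain_g + rng.normal(0.0, nz["thousand_grain_g"])
                moisture = min(max(0.18 + rng.normal(0.0, nz["moisture"]), 0.05), 0.35)
                ds.yield_plots.append(YieldPlot(
                    year=year, hybrid=hybrid, replicate=rep,
                    ears_per_ha=ears * 1e4, grains_per_ear=grains, thousand_grain_g=tgw,
                    moisture=moisture, yield_kg_ha=ears * grains * (tgw / 1000.0) * 10.0))

            # analytic ground truth for this cell
            dmr_leaf = truth.leaf_r1 - truth.leaf_r6
            dmr_stalk = truth.stalk_r1 - truth.stalk_r6
            to_grain = (max(dmr_leaf, 0.0) + max(dmr_stalk, 0.0)) * truth.c13_fractions["grain"]
            sink = truth.ears_1e4_ha * truth.grains_per_ear * truth.thousand_grain_g / 1000.0
            gt_rows.append({
                "year": year, "hybrid": hybrid,
                "total_dma_r1": truth.total_r1, "total_dma_r6": truth.total_r6,
                "prsdmar": 100.0 * truth.total_r1 / truth.total_r6,
                "posdma": truth.total_r6 - truth.total_r1,
                "posdmar": 100.0 * (truth.total_r6 - truth.total_r1) / truth.total_r6,
                "cgr_pre": truth.total_r1 / dur.days_before_silking,
                "cgr_post": (truth.total_r6 - truth.total_r1) / dur.days_after_silking,
                "dmr_leaf": dmr_leaf, "dmr_stalk": dmr_stalk,
                "dmre_leaf": 100.0 * dmr_leaf / truth.leaf_r1,
                "dmre_stalk": 100.0 * dmr_stalk / truth.stalk_r1,
                "grain_c13_fraction": truth.c13_fractions["grain"],
                "dmr_to_grain": to_grain, "dmrc": truth.dmrc, "hi": truth.hi,
                "dlai": truth.dlai, "apd": truth.apd, "pi": truth.pn_init,
                "lai_max": truth.lai_max, "lai_peak_day": truth.lai_peak_day,
                "lai_width": truth.lai_width,
                "sink_capacity": sink,
                "grain_leaf": sink / 1000.0 / truth.lai_at(0.0),
                "yield_kg_ha": truth.yield_kg_ha,
                "yield_per_gdd_total": truth.yield_kg_ha / dur.total_gdd,
                "yield_per_gdd_post": truth.yield_kg_ha / dur.gdd_after_silking,
                "days_before_silking": dur.days_before_silking,
                "days_after_silking": dur.days_after_silking,
                "gdd_before_silking": dur.gdd_before_silking,
                "gdd_after_silking": dur.gdd_after_silking,
            })

    gt = GroundTruth(frame=pd.DataFrame(gt_rows).set_index(["year", "hybrid"]))
    return ds, gt


# ---------------------------------------------------------------------------
# Corruption fixtures for validator tests
# ---------------------------------------------------------------------------

VIOLATIONS = (
    "stage_order",
    "tmin_gt_tmax",
    "missing_reference_plants",
    "negative_mass",
    "grain_at_r1",
    "unbalanced_replicates",
)


def corrupt_dataset(ds: TrialDataset, violation: str, seed: int = 0) -> TrialDataset:
    """Return a deep copy of ``ds`` with one named invariant violation injected."""
    out = copy.deepcopy(ds)
    rng = np.random.default_rng(seed)

    if violation == "stage_order":
        s = out.stages[int(rng.integers(len(out.stages)))]
        out.stages[out.stages.index(s)] = replace(s, r6=s.r1 - _dt.timedelta(days=1))
    elif violation == "tmin_gt_tmax":
        year = sorted(out.weather)[0]
        i = int(rng.integers(len(out.weather[year])))
        w = out.weather[year][i]
        out.weather[year][i] = replace(w, tmin=w.tmax + 2.0)
    elif violation == "missing_reference_plants":
        key = (out.isotope[0].year, out.isotope[0].hybrid)
        out.isotope = [s for s in out.isotope
                       if not (not s.labeled and (s.year, s.hybrid) == key)]
    elif violation == "negative_mass":
        i = int(rng.integers(len(out.plant_samples)))
        out.plant_samples[i] = replace(out.plant_samples[i], leaf=-1.0)
    elif violation == "grain_at_r1":
        idx = next(i for i, p in enumerate(out.plant_samples) if p.stage == "R1")
        out.plant_samples[idx] = replace(out.plant_samples[idx], grain=12.0)
    elif violation == "unbalanced_replicates":
        out.yield_plots.pop(int(rng.integers(len(out.yield_plots))))
    else:
        raise UnknownViolationError(
            f"unknown violation {violation!r}; known: {', '.join(VIOLATIONS)}")
    return out
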