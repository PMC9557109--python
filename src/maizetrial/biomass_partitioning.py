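"""Dry-matter accumulation, remobilization, ¹³C-corrected grain contribution and harvest index.

Vegetative organs (leaf, stalk) lose dry mass between silking (R1) and
maturity (R6); that loss is remobilization (DMR), and its share of the organ's
R1 mass is the remobilization efficiency (DMRE).  Not all remobilized mass
reaches the grain: the fraction of a ¹³C pulse label recovered in grain
corrects the leaf+stalk DMR into "DMR to grain", whose share of grain dry
mass at R6 is the remobilization contribution DMRC.  The complement
100 − DMRC is the contribution of post-silking assimilation.

Sink capacity, grain/leaf ratio, harvest index and moisture-standardized
yield round out the source–sink bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .data_model_io import ORGANS, DomainError, InvariantError, IsotopeSample

__all__ = [
    "PartitionSummary",
    "IsotopeResult",
    "LabelingError",
    "pre_post_silking",
    "crop_growth_rate",
    "dmr_and_dmre",
    "c13_distribution",
    "dmr_to_grain",
    "dmrc",
    "harvest_index",
    "sink_capacity",
    "grain_leaf_ratio",
    "standardize_yield",
    "MOISTURE_STANDARD",
]

MOISTURE_STANDARD = 0.14  # kernel moisture fraction yields are standardized to


class LabelingError(ValueError):
    """The ¹³C pulse label left no positive excess — labeling failed."""


@dataclass(frozen=True)
class IsotopeResult:
    """¹³C distribution across organs of one year x hybrid; fractions sum to 1."""

    year: str
    hybrid: str
    fractions: dict[str, float]  # organ -> fraction of recovered tracer

    @property
    def grain_fraction(self) -> float:
        return self.fractions["grain"]


@dataclass
class PartitionSummary:
    """All partitioning metrics of one year x hybrid (plant basis unless noted)."""

    year: str
    hybrid: str
    total_dma_r1: float          # g plant⁻¹
    total_dma_r6: float          # g plant⁻¹
    prsdmar: float               # % of R6 total accumulated before silking
    posdma: float                # g plant⁻¹ accumulated after silking
    posdmar: float               # %
    cgr_pre: float               # g plant⁻¹ d⁻¹, sowing→R1
    cgr_post: float              # g plant⁻¹ d⁻¹, R1→R6
    dmr_leaf: float              # g
    dmr_stalk: float             # g
    dmre_leaf: float             # %
    dmre_stalk: float            # %
    dmr_to_grain: float | None   # g, ¹³C-corrected; None without isotope data
    dmrc: float | None           # %
    hi: float                    # fraction
    sink_capacity: float | None = None   # g m⁻²
    grain_leaf: float | None = None      # kg m⁻²
    yield_per_gdd_total: float | None = None   # kg ha⁻¹ (°C d)⁻¹, total-GDD denominator
    yield_per_gdd_post: float | None = None    # kg ha⁻¹ (°C d)⁻¹, post-silking denominator
    warnings: list[str] = field(default_factory=list)


def pre_post_silking(dma_r1: float, dma_r6: float) -> tuple[float, float, float, list[str]]:
    """PrSDMAR (%), PoSDMA (g plant⁻¹) and PoSDMAR (%) from total dry mass at R1 and R6.

    PrSDMAR = 100·R1/R6, PoSDMA = R6 − R1, PoSDMAR = 100·PoSDMA/R6.  A plant
    that lost mass after silking (R1 > R6) is flagged with a warning, not
    rejected.  Returns (prsdmar, posdma, posdmar, warnings).
    """
    if dma_r1 <= 0 or dma_r6 <= 0:
        raise DomainError(f"total DMA must be positive, got R1={dma_r1}, R6={dma_r6}")
    warnings = []
    if dma_r1 > dma_r6:
        warnings.append(f"total DMA declined after silking (R1 {dma_r1} > R6 {dma_r6})")
    posdma = dma_r6 - dma_r1
    return 100.0 * dma_r1 / dma_r6, posdma, 100.0 * posdma / dma_r6, warnings


def crop_growth_rate(dma_start: float, dma_end: float, days: float) -> float:
    """Average growth rate (g plant⁻¹ d⁻¹) over an interval of ``days`` days."""
    if days <= 0:
        raise DomainError(f"days must be positive, got {days}")
    return (dma_end - dma_start) / days


def dmr_and_dmre(organ_r1: float, organ_r6: float) -> tuple[float, float]:
    """Dry-matter remobilization (g) and efficiency (%) of one organ.

    DMR = mass at R1 − mass at R6 (negative if the organ gained mass; kept,
    not clipped).  DMRE = 100·DMR / mass at R1.
    """
    if organ_r1 <= 0:
        raise DomainError(f"organ mass at R1 must be positive, got {organ_r1}")
    dmr = organ_r1 - organ_r6
    return dmr, 100.0 * dmr / organ_r1


def c13_distribution(samples: Iterable[IsotopeSample]) -> IsotopeResult:
    """¹³C distribution across organs from labeled vs reference plants of one year x hybrid.

    Per organ the tracer proxy is (mean labeled atom-% − mean reference
    atom-%)/100 × mean labeled organ dry mass; negative excesses are floored
    at zero before normalization (a constant carbon fraction across organs is
    assumed).  Fractions sum to 1.
    """
    samples = list(samples)
    keys = {(s.year, s.hybrid) for s in samples}
    if len(keys) != 1:
        raise DomainError(f"samples must belong to one year x hybrid, got {sorted(keys)}")
    (year, hybrid) = keys.pop()

    labeled = [s for s in samples if s.labeled]
    reference = [s for s in samples if not s.labeled]
    if not labeled or not reference:
        raise DomainError(f"{year} {hybrid}: need both labeled and reference plants")
    organs_present = {s.organ for s in labeled}
    missing = set(ORGANS) - organs_present
    if missing:
        raise DomainError(f"{year} {hybrid}: labeled plants missing organs {sorted(missing)}")

    excess: dict[str, float] = {}
    for organ in ORGANS:
        lab = [s for s in labeled if s.organ == organ]
        ref = [s for s in reference if s.organ == organ]
        if not ref:
            raise DomainError(f"{year} {hybrid}: no reference samples for organ {organ!r}")
        d_atom = float(np.mean([s.atom_pct_13c for s in lab])) - float(np.mean([s.atom_pct_13c for s in ref]))
        mass = float(np.mean([s.mass_g for s in lab]))
        excess[organ] = max(d_atom / 100.0 * mass, 0.0)

    total = sum(excess.values())
    if total <= 0:
        raise LabelingError(f"{year} {hybrid}: no positive ¹³C excess in any organ")
    return IsotopeResult(year=year, hybrid=hybrid,
                         fractions={o: excess[o] / total for o in ORGANS})


def dmr_to_grain(dmr_leaf: float, dmr_stalk: float, grain_fraction: float) -> float:
    """Remobilized leaf+stalk dry mass reaching the grain: (DMR_leaf⁺ + DMR_stalk⁺)·f_grain.

    Negative organ DMRs (mass gain) contribute nothing; the grain ¹³C fraction
    must lie in [0, 1].
    """
    if not (0.0 <= grain_fraction <= 1.0):
        raise DomainError(f"grain fraction must be in [0, 1], got {grain_fraction}")
    return (max(dmr_leaf, 0.0) + max(dmr_stalk, 0.0)) * grain_fraction


def dmrc(dmr_to_grain_g: float, grain_dma_r6: float) -> float:
    """DMRC (%): share of grain dry mass at R6 supplied by leaf+stalk remobilization.

    The complement 100 − DMRC is the contribution of post-silking assimilation.
    """
    if grain_dma_r6 <= 0:
        raise DomainError(f"grain DMA at R6 must be positive, got {grain_dma_r6}")
    return 100.0 * dmr_to_grain_g / grain_dma_r6


def harvest_index(grain_dma: float, total_dma: float) -> float:
    """HI = grain dry mass / total aboveground dry mass at R6 (fraction)."""
    if grain_dma <= 0 or total_dma <= 0:
        raise DomainError(f"masses must be positive, got grain={grain_dma}, total={total_dma}")
    if grain_dma > total_dma:
        raise InvariantError(f"grain DMA {grain_dma} exceeds total DMA {total_dma}")
    return grain_dma / total_dma


def sink_capacity(ears_per_m2: float, grains_per_ear: float, grain_weight_g: float) -> float:
    """Sink capacity (g m⁻²) = ears m⁻² × grains per ear × single-grain weight (g).

    ``grain_weight_g`` is per kernel, i.e. 1000-grain weight divided by 1000.
    """
    if ears_per_m2 <= 0 or grains_per_ear <= 0 or grain_weight_g <= 0:
        raise DomainError("all sink-capacity factors must be positive")
    return ears_per_m2 * grains_per_ear * grain_weight_g


def grain_leaf_ratio(sink_g_m2: float, la_r1: float) -> float:
    """Grain/leaf ratio (kg m⁻²) = sink capacity / leaf area at R1."""
    if la_r1 <= 0:
        raise DomainError(f"leaf area at R1 must be positive, got {la_r1}")
    return sink_g_m2 / 1000.0 / la_r1


def standardize_yield(fresh_mass_kg_ha: float, moisture_fraction: float) -> float:
    """Convert fresh grain mass at the given moisture to kg ha⁻¹ at 14% kernel moisture."""
    if fresh_mass_kg_ha < 0:
        raise DomainError(f"mass must be non-negative, got {fresh_mass_kg_ha}")
    if not (0.0 <= moisture_fraction < 0.40):
        raise DomainError(f"moisture must be in [0, 0.40), got {moisture_fraction}")
    return fresh_mass_kg_ha * (1.0 - moisture_fraction) / (1.0 - MOISTURE_STANDARD)
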