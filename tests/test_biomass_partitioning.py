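"""Dry-matter partitioning, remobilization, ¹³C distribution and source–sink arithmetic."""

import itertools

import numpy as np
import pytest

from maizetrial import (
    InvariantError,
    IsotopeSample,
    LabelingError,
    c13_distribution,
    crop_growth_rate,
    dmr_and_dmre,
    dmr_to_grain,
    dmrc,
    grain_leaf_ratio,
    harvest_index,
    pre_post_silking,
    sink_capacity,
    standardize_yield,
)
from maizetrial.data_model_io import DomainError


class TestPrePostSilking:
    def test_forty_percent_pre_silking_split(self):
        prs, pos, posr, warns = pre_post_silking(40.0, 100.0)
        assert (prs, pos, posr) == pytest.approx((40.0, 60.0, 60.0))
        assert warns == []

    def test_ratios_always_sum_to_hundred(self):
        for r1, r6 in [(40.0, 100.0), (104.0, 261.0), (99.9, 100.0)]:
            prs, _, posr, _ = pre_post_silking(r1, r6)
            assert prs + posr == pytest.approx(100.0, abs=1e-9)

    def test_boundary_and_declining_plant(self):
        prs, pos, posr, _ = pre_post_silking(100.0, 100.0)
        assert (prs, pos, posr) == pytest.approx((100.0, 0.0, 0.0))
        prs, pos, posr, warns = pre_post_silking(110.0, 100.0)
        assert pos < 0 and warns  # flagged, not rejected


def test_crop_growth_rate():
    assert crop_growth_rate(0.0, 92.0, 46.0) == pytest.approx(2.0)
    assert crop_growth_rate(92.0, 240.0, 60.0) == pytest.approx(2.467, abs=5e-4)
    assert crop_growth_rate(50.0, 50.0, 10.0) == 0.0
    with pytest.raises(DomainError):
        crop_growth_rate(0.0, 10.0, 0.0)


class TestDmrAndDmre:
    def test_reported_stalk_remobilization(self):
        dmr, dmre = dmr_and_dmre(69.87, 52.06)
        assert dmr == pytest.approx(17.81, abs=1e-9)
        assert dmre == pytest.approx(25.49, abs=0.005)

    def test_no_change_and_organ_gain(self):
        assert dmr_and_dmre(50.0, 50.0) == pytest.approx((0.0, 0.0))
        dmr, dmre = dmr_and_dmre(50.0, 60.0)
        assert (dmr, dmre) == pytest.approx((-10.0, -20.0))  # gain kept, not clipped

    def test_requires_positive_r1_mass(self):
        with pytest.raises(DomainError):
            dmr_and_dmre(0.0, 10.0)


def _cohort(labeled_atom, ref_atom, masses, year="2020", hybrid="H"):
    organs = ["grain", "other", "stalk", "leaf"]
    samples = []
    for organ, a, m in zip(organs, labeled_atom, masses):
        samples.append(IsotopeSample(year=year, hybrid=hybrid, plant_id="L1", labeled=True,
                                     organ=organ, mass_g=m, atom_pct_13c=a))
    for organ, m in zip(organs, masses):
        samples.append(IsotopeSample(year=year, hybrid=hybrid, plant_id="R1", labeled=False,
                                     organ=organ, mass_g=m, atom_pct_13c=ref_atom))
    return samples


class TestC13Distribution:
    def test_matches_bruteforce_excess_oracle(self):
        labeled = [1.30, 1.15, 1.12, 1.10]
        masses = [140.0, 30.0, 60.0, 20.0]
        ref = 1.08
        # independent oracle: excess tracer = Δatom%/100 × mass, normalized
        excess = [(a - ref) / 100.0 * m for a, m in zip(labeled, masses)]
        expected = np.array(excess) / sum(excess)
        result = c13_distribution(_cohort(labeled, ref, masses))
        got = [result.fractions[o] for o in ("grain", "other", "stalk", "leaf")]
        assert got == pytest.approx(list(expected), abs=1e-12)
        assert sum(result.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_order_invariance(self):
        samples = _cohort([1.30, 1.15, 1.12, 1.10], 1.08, [140.0, 30.0, 60.0, 20.0])
        base = c13_distribution(samples).fractions
        for perm_seed in range(3):
            rng = np.random.default_rng(perm_seed)
            shuffled = [samples[i] for i in rng.permutation(len(samples))]
            assert c13_distribution(shuffled).fractions == pytest.approx(base)

    def test_zero_excess_is_a_labeling_failure(self):
        with pytest.raises(LabelingError):
            c13_distribution(_cohort([1.08] * 4, 1.08, [140.0, 30.0, 60.0, 20.0]))

    def test_single_organ_excess_gets_full_fraction(self):
        result = c13_distribution(_cohort([1.30, 1.08, 1.08, 1.08], 1.08,
                                          [140.0, 30.0, 60.0, 20.0]))
        assert result.fractions["grain"] == pytest.approx(1.0)

    def test_negative_excess_floored_before_normalization(self):
        result = c13_distribution(_cohort([1.30, 1.05, 1.08, 1.08], 1.08,
                                          [140.0, 30.0, 60.0, 20.0]))
        assert result.fractions["other"] == 0.0
        assert sum(result.fractions.values()) == pytest.approx(1.0)


class TestDmrToGrainAndDmrc:
    def test_reported_consistency_chain(self):
        """Leaf 5.26 g + stalk 17.81 g remobilized at grain fraction 0.6216 gives 14.34 g,
        which against 150.9 g grain is a 9.50% contribution."""
        tg = dmr_to_grain(5.26, 17.81, 0.6216)
        assert tg == pytest.approx(14.34, abs=0.005)
        assert dmrc(14.34, 150.9) == pytest.approx(9.50, abs=0.005)

    def test_floors_and_bounds(self):
        assert dmr_to_grain(-3.0, 10.0, 0.5) == pytest.approx(5.0)  # organ gain contributes nothing
        assert dmr_to_grain(4.0, 9.0, 0.0) == 0.0
        assert dmr_to_grain(10.0, 10.0, 1.0) == pytest.approx(20.0)
        with pytest.raises(DomainError):
            dmr_to_grain(5.0, 5.0, 1.2)

    def test_dmrc_zero_and_complement(self):
        assert dmrc(0.0, 150.0) == 0.0
        value = dmrc(14.34, 150.9)
        assert value <= 100.0
        assert value + (100.0 - value) == pytest.approx(100.0)
        with pytest.raises(DomainError):
            dmrc(10.0, 0.0)


class TestHarvestIndexAndSink:
    def test_harvest_index(self):
        assert harvest_index(50.0, 100.0) == pytest.approx(0.5)
        total = 263.4
        assert harvest_index(0.582 * total, total) == pytest.approx(0.582)
        with pytest.raises(InvariantError):
            harvest_index(120.0, 100.0)

    def test_sink_capacity_product_and_linearity(self):
        assert sink_capacity(6.91, 497.0, 0.355) == pytest.approx(1219.17, abs=0.01)
        assert sink_capacity(1.0, 1.0, 1.0) == 1.0
        assert sink_capacity(2 * 6.91, 497.0, 0.355) == pytest.approx(
            2 * sink_capacity(6.91, 497.0, 0.355))

    def test_grain_leaf_ratio(self):
        assert grain_leaf_ratio(1219.2, 4.56) == pytest.approx(0.267, abs=5e-4)
        assert grain_leaf_ratio(1000.0, 4.0) == pytest.approx(0.25)
        assert grain_leaf_ratio(1000.0, 1.0) == pytest.approx(1.0)
        with pytest.raises(DomainError):
            grain_leaf_ratio(1000.0, 0.0)

    def test_grain_leaf_homogeneous_in_ear_density(self):
        base = grain_leaf_ratio(sink_capacity(6.91, 497.0, 0.355), 4.56)
        doubled = grain_leaf_ratio(sink_capacity(13.82, 497.0, 0.355), 4.56)
        assert doubled == pytest.approx(2 * base)


def test_standardize_yield():
    assert standardize_yield(10000.0, 0.14) == pytest.approx(10000.0)
    assert standardize_yield(10000.0, 0.225) == pytest.approx(9011.6, abs=0.1)
    assert standardize_yield(0.0, 0.2) == 0.0
    with pytest.raises(DomainError):
        standardize_yield(10000.0, 0.40)
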