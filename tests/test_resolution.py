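"""Temporal binning, Fano factors, E/I clustering, spatial aggregation."""

import numpy as np
import pandas as pd
import pytest

from spikehd.data import TRIAL_MS, SpikeDataset
from spikehd.resolution import (
    ResolutionConfig,
    aggregate_spatial,
    bin_starts,
    bin_temporal,
    cluster_populations,
    fano_factor,
)
from conftest import build_dataset, poisson_gabor_dataset


class TestTemporalBinning:
    def test_exact_divisor_bins(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(0.2, (3, TRIAL_MS, 4)).astype(np.int32)
        bt = bin_temporal(base, 125, "exact")
        assert bt.M == 2
        assert np.array_equal(bt.counts[:, 0, :], base[:, :125, :].sum(axis=1))
        assert np.array_equal(bt.counts[:, 1, :], base[:, 125:, :].sum(axis=1))
        one = bin_temporal(base, 250, "exact")
        assert one.M == 1
        assert np.array_equal(one.counts[:, 0, :], base.sum(axis=1))

    @pytest.mark.parametrize("w", [1, 2, 5, 10, 25, 50, 125, 250])
    def test_exact_conserves_total(self, w):
        rng = np.random.default_rng(w)
        base = rng.poisson(0.1, (2, TRIAL_MS, 3)).astype(np.int32)
        assert bin_temporal(base, w, "exact").counts.sum() == base.sum()

    def test_non_divisor_exact_rejected_with_guidance(self):
        base = np.zeros((1, TRIAL_MS, 1), dtype=np.int32)
        with pytest.raises(ValueError, match="overlap"):
            bin_temporal(base, 100, "exact")
        with pytest.raises(ValueError):
            ResolutionConfig(bin_size_ms=100, bin_mode="exact")
        ResolutionConfig(bin_size_ms=100, bin_mode="crop")  # allowed

    def test_crop_discards_tail(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(0.3, (2, TRIAL_MS, 2)).astype(np.int32)
        bt = bin_temporal(base, 100, "crop")
        assert bt.M == 2
        assert np.array_equal(bt.counts[:, 0, :], base[:, :100, :].sum(axis=1))
        assert np.array_equal(bt.counts[:, 1, :], base[:, 100:200, :].sum(axis=1))
        assert bt.counts.sum() <= base.sum()

    def test_overlap_covers_whole_trial(self):
        starts = bin_starts(100, "overlap")
        assert starts[0] == 0 and starts[-1] + 100 == TRIAL_MS
        covered = np.zeros(TRIAL_MS, dtype=bool)
        for s in starts:
            covered[s:s + 100] = True
        assert covered.all()
        rng = np.random.default_rng(2)
        base = rng.poisson(0.2, (1, TRIAL_MS, 1)).astype(np.int32)
        bt = bin_temporal(base, 100, "overlap")
        for j, s in enumerate(starts):
            assert bt.counts[0, j, 0] == base[0, s:s + 100, 0].sum()
        assert bt.counts.sum() >= base.sum()  # over-counting allowed


class TestFanoFactor:
    def test_poisson_counts_give_fano_one(self):
        # 25 ms bins at rate 0.2/ms -> Poisson mean 5 per bin; 10 bins x 1000
        # trials = 1e4 pooled samples
        ds = poisson_gabor_dataset(n_units=1, reps=13, rate_per_ms=0.2, seed=4)
        f = fano_factor(ds, 25)
        assert abs(f[0] - 1.0) < 0.1

    def test_constant_counts_give_zero(self):
        ds = poisson_gabor_dataset(n_units=1, reps=1, rate_per_ms=0.0)
        counts = ds.counts.copy()
        counts[0, ::25, :] = 3  # exactly 3 per 25 ms bin, every bin
        ds = SpikeDataset(ds.units, ds.trials, counts)
        assert fano_factor(ds, 25)[0] == 0.0

    def test_alternating_counts_population_variance(self):
        ds = poisson_gabor_dataset(n_units=1, reps=2, rate_per_ms=0.0)
        counts = ds.counts.copy()
        # alternate bins of 0 and 8 spikes: mean 4, population var 16, Fano 4
        counts[0, ::50, :] = 8  # one spike burst in every other 25 ms bin
        ds = SpikeDataset(ds.units, ds.trials, counts)
        assert fano_factor(ds, 25)[0] == pytest.approx(16 / 4)

    def test_silent_unit_fano_zero(self):
        ds = poisson_gabor_dataset(n_units=1, reps=1, rate_per_ms=0.0)
        assert fano_factor(ds, 25)[0] == 0.0


class TestClusterPopulations:
    @staticmethod
    def units(n, area="VISp", start=0):
        return pd.DataFrame({"unit_id": np.arange(start, start + n), "area": area})

    def test_top_20_percent_labeled_inhibitory(self):
        labels = cluster_populations(self.units(10), np.arange(1.0, 11.0))
        assert list(np.flatnonzero(labels == "I")) == [8, 9]

    def test_ceil_rounding_five_units(self):
        labels = cluster_populations(self.units(5), np.arange(5.0))
        assert (labels == "I").sum() == 1

    def test_single_unit_area_is_inhibitory(self):
        labels = cluster_populations(self.units(1), np.array([0.0]))
        assert labels[0] == "I"

    def test_boundary_ties_broken_by_unit_id(self):
        fano = np.array([5.0, 2.0, 2.0, 2.0, 1.0])
        labels = cluster_populations(self.units(5), fano)
        assert labels[0] == "I" and (labels == "I").sum() == 1
        fano2 = np.array([2.0, 2.0, 2.0, 2.0, 1.0])
        labels2 = cluster_populations(self.units(5), fano2)
        assert labels2[0] == "I"  # lowest unit_id wins among equal Fano

    def test_per_area_fraction_invariant(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n1, n2 = rng.integers(1, 12, 2)
            units = pd.concat([self.units(n1, "VISp"), self.units(n2, "CA1", start=n1)],
                              ignore_index=True)
            labels = cluster_populations(units, rng.random(n1 + n2))
            for area, n in (("VISp", n1), ("CA1", n2)):
                frac = (labels[units["area"] == area] == "I").mean()
                assert 0.2 <= frac <= 0.2 + 1 / n + 1e-12


class TestSpatialAggregation:
    def make_bt_units(self, seed=0):
        ds = build_dataset(
            [(0, "VISp"), (1, "VISp"), (2, "VISam"), (3, "VISal")],
            [(0, "gabor", 0), (1, "gabor", 1)],
            fill={(ui, ti): np.random.default_rng(seed + ui + ti).poisson(0.2, TRIAL_MS)
                  for ui in range(4) for ti in range(2)},
        )
        bt = bin_temporal(ds.counts, 50, unit_labels=list(ds.units["unit_id"]))
        return bt, ds.units

    def test_population_level_groups(self):
        bt, units = self.make_bt_units()
        ei = np.array(["E", "I", "I", "E"])
        out = aggregate_spatial(bt, "population", units, ei)
        assert sorted(out.unit_labels) == ["VISal/E", "VISam/I", "VISp/E", "VISp/I"]
        assert out.counts.sum() == bt.counts.sum()

    def test_population_requires_labels(self):
        bt, units = self.make_bt_units()
        with pytest.raises(ValueError, match="ei_labels"):
            aggregate_spatial(bt, "population", units)

    def test_region_merges_dorsal_extrastriate(self):
        bt, units = self.make_bt_units()
        out = aggregate_spatial(bt, "region", units)
        assert set(out.unit_labels) == {"Striate cortex", "Dorsal extrastriate cortex"}
        dorsal = out.unit_labels.index("Dorsal extrastriate cortex")
        assert np.array_equal(out.counts[dorsal], bt.counts[2] + bt.counts[3])

    def test_whole_brain_is_grand_sum(self):
        bt, units = self.make_bt_units()
        out = aggregate_spatial(bt, "whole_brain", units)
        assert out.counts.shape[0] == 1
        assert np.array_equal(out.counts[0], bt.counts.sum(axis=0))

    def test_monotone_coarsening_and_idempotence(self):
        bt, units = self.make_bt_units()
        ei = np.array(["E", "I", "I", "E"])
        sizes = []
        for level in ("neuron", "population", "area", "region", "whole_brain"):
            out = aggregate_spatial(bt, level, units, ei)
            sizes.append(out.counts.shape[0])
            again = aggregate_spatial(out, level, units, ei)
            assert np.array_equal(again.counts, out.counts)
        assert sizes == sorted(sizes, reverse=True) and sizes[-1] == 1

    def test_conservation_over_random_toys(self):
        rng = np.random.default_rng(3)
        for rep in range(10):
            bt, units = self.make_bt_units(seed=rep)
            for level in ("area", "region", "whole_brain"):
                assert aggregate_spatial(bt, level, units).counts.sum() == bt.counts.sum()
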