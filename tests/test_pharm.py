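"""Hill-equation pharmacology: block fractions, fitting, bootstrap UQ."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cipasim.errors import ConfigurationError, FitError
from cipasim.pharm import (
    ChannelBlock,
    DrugRecord,
    HillCurveFitter,
    NO_BLOCK,
    assemble_sample_set,
    bootstrap_hill_samples,
    exposure_at,
    fit_hill,
    hill_block_fraction,
    mean_block_over_range,
)
from cipasim.models import HergDynamicParams
from cipasim.synthetic import generate_patch_clamp_panel


class TestHillBlockFraction:
    @pytest.mark.parametrize("conc,ic50,hill,expected", [
        (1000.0, 1000.0, 1.0, 0.5),     # half inhibition by definition
        (1000.0, 1000.0, 3.7, 0.5),     # ... for any Hill coefficient
        (0.0, 1000.0, 1.0, 0.0),        # no drug, no block
        (4000.0, 1000.0, 1.0, 0.8),     # 1/(1+0.25)
        (500.0, math.inf, 1.0, 0.0),    # no-measurable-block sentinel
    ])
    def test_closed_forms(self, conc, ic50, hill, expected):
        block = ChannelBlock("INaL", ic50, hill)
        assert hill_block_fraction(conc, block) == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True)
    @given(
        ic50=st.floats(1e-2, 1e8),
        hill=st.floats(0.05, 5.0),
        c1=st.floats(0.0, 1e9),
        c2=st.floats(0.0, 1e9),
    )
    def test_monotone_nondecreasing_in_concentration(self, ic50, hill, c1, c2):
        block = ChannelBlock("ICaL", ic50, hill)
        lo, hi = sorted((c1, c2))
        assert hill_block_fraction(lo, block) <= hill_block_fraction(hi, block)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ConfigurationError):
            hill_block_fraction(-1.0, ChannelBlock("INa", 100.0))


class TestMeanBlockOverRange:
    def test_no_block_sentinel_gives_zero(self):
        assert mean_block_over_range(NO_BLOCK("INaL"), 100.0) == 0.0

    def test_saturated_block_approaches_one(self):
        block = ChannelBlock("INaL", 1e-6, 1.0)
        assert mean_block_over_range(block, 1e4) == pytest.approx(1.0, abs=1e-6)

    def test_matches_fine_grid_quadrature(self):
        # oracle: average of the closed form over a 100k-point log grid;
        # the default 10-point grid approximates it to a few parts in 1e3
        block = ChannelBlock("ICaL", 250.0, 1.0)
        cmax = 250.0
        grid = np.geomspace(cmax, 4 * cmax, 100_000)
        oracle = np.mean(1.0 / (1.0 + block.ic50_nM / grid))
        assert mean_block_over_range(block, cmax, n_grid=10) == pytest.approx(
            oracle, rel=5e-3)

    def test_bad_range_rejected(self):
        with pytest.raises(ConfigurationError):
            mean_block_over_range(NO_BLOCK("INaL"), 100.0, lo_mult=4, hi_mult=1)


class TestHillFit:
    def test_exact_recovery_on_noise_free_data(self):
        panel = generate_patch_clamp_panel(
            ChannelBlock("INaL", 1000.0, 1.0), n_cells=4, noise_sd=0.0)
        block, diag = fit_hill(panel)
        assert block.ic50_nM == pytest.approx(1000.0, rel=1e-3)
        assert block.hill == pytest.approx(1.0, rel=1e-3)
        assert diag["rmse"] < 1e-6

    def test_single_concentration_is_underdetermined(self):
        with pytest.raises(FitError, match="distinct concentrations"):
            HillCurveFitter().fit([100.0, 100.0, 100.0], [0.1, 0.2, 0.3])

    def test_all_zero_responses_give_no_block_sentinel(self):
        est = HillCurveFitter().fit([10.0, 100.0, 1000.0], [0.0, 0.0, 0.0])
        assert est.ic50_ == math.inf
        assert np.all(est.predict([1e6]) == 0.0)

    def test_noisy_recovery_within_bootstrap_ci(self):
        # 8 cells x 5 concentrations, sd 0.05; the generating IC50 should
        # fall inside the bootstrap 95% CI in the overwhelming majority of
        # replicate experiments
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            panel = generate_patch_clamp_panel(
                ChannelBlock("INaL", 500.0, 1.5), n_cells=8, noise_sd=0.05,
                seed=1000 + rep)
            boots = bootstrap_hill_samples(panel, n=200, seed=rep)
            ic50s = np.array([b.ic50_nM for b in boots])
            lo, hi = np.percentile(ic50s, [2.5, 97.5])
            hits += lo <= 500.0 <= hi
        assert hits / n_rep >= 0.9

    def test_bootstrap_is_deterministic_given_seed(self):
        panel = generate_patch_clamp_panel(
            ChannelBlock("ICaL", 200.0, 1.0), n_cells=5, noise_sd=0.05, seed=3)
        a = bootstrap_hill_samples(panel, n=25, seed=7, current_id="ICaL")
        b = bootstrap_hill_samples(panel, n=25, seed=7, current_id="ICaL")
        assert [x.ic50_nM for x in a] == [x.ic50_nM for x in b]

    def test_bootstrap_n_zero_gives_empty(self):
        panel = generate_patch_clamp_panel(
            ChannelBlock("INaL", 200.0, 1.0), n_cells=3, noise_sd=0.0)
        assert bootstrap_hill_samples(panel, n=0, seed=0) == []

    @pytest.mark.parametrize("n_cells", [4, 16, 64])
    def test_bootstrap_median_consistency(self, n_cells):
        # median bootstrap IC50 approaches the generating value as the
        # number of cells grows; tolerance shrinks accordingly
        panel = generate_patch_clamp_panel(
            ChannelBlock("INaL", 800.0, 1.2), n_cells=n_cells, noise_sd=0.05,
            seed=42)
        boots = bootstrap_hill_samples(panel, n=100, seed=1)
        med = np.median([b.ic50_nM for b in boots])
        tol = {4: 0.35, 16: 0.20, 64: 0.10}[n_cells]
        assert med == pytest.approx(800.0, rel=tol)


class TestSampleSets:
    def _drug(self):
        herg = HergDynamicParams(kmax=100.0, ku=0.1, n=1.0, halfmax=1e5,
                                 vhalf=-10.0)
        return DrugRecord("d", 100.0, herg,
                          {"INaL": ChannelBlock("INaL", 500.0, 1.0)})

    def test_single_sample_per_channel_is_passed_exactly(self):
        drug = self._drug()
        blk = ChannelBlock("INaL", 321.0, 1.7)
        ss = assemble_sample_set(drug, herg_samples=[drug.herg],
                                 block_samples={"INaL": [blk]}, n=1, seed=0)
        herg, blocks = ss.samples[0]
        assert herg == drug.herg
        assert blocks["INaL"] == blk

    def test_cross_channel_sampling_is_independent(self):
        rng = np.random.default_rng(0)
        a = [ChannelBlock("INaL", float(v), 1.0)
             for v in rng.lognormal(6, 0.5, 200)]
        b = [ChannelBlock("ICaL", float(v), 1.0)
             for v in rng.lognormal(6, 0.5, 200)]
        ss = assemble_sample_set(self._drug(), block_samples={"INaL": a,
                                                              "ICaL": b},
                                 n=2000, seed=1)
        x = np.array([s[1]["INaL"].ic50_nM for s in ss.samples])
        y = np.array([s[1]["ICaL"].ic50_nM for s in ss.samples])
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.05

    def test_precomputed_passthrough_is_exact(self):
        drug = self._drug()
        ss = assemble_sample_set(drug, n=10, seed=5)
        again = assemble_sample_set(drug, n=10, seed=99, precomputed=ss)
        assert again.samples == ss.samples

    def test_precomputed_size_error(self):
        drug = self._drug()
        ss = assemble_sample_set(drug, n=5, seed=0)
        with pytest.raises(ConfigurationError, match="precomputed"):
            assemble_sample_set(drug, n=10, precomputed=ss)


class TestExposure:
    def test_exposure_applies_hill_multipliers(self):
        drug = DrugRecord(
            "d", 100.0, blocks={"INaL": ChannelBlock("INaL", 400.0, 1.0)})
        exp = exposure_at(drug, 400.0)
        assert exp.scale["INaL"] == pytest.approx(0.5)
        assert exposure_at(drug, 0.0).scale["INaL"] == 1.0
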