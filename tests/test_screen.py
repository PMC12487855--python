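"""Element phenotypes, gene aggregation, and hit calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screenstate import (
    EffectSpec,
    ScreenConfig,
    ScreenModel,
    call_hits,
    center_by_ntc,
    compute_log2_ratio,
    gene_scores_topk,
    simulate_library,
    simulate_screen,
)
from screenstate.exceptions import (
    InsufficientControlsError,
    MissingConditionError,
    ScreenStateError,
)


class TestLog2Ratio:
    def test_identical_vectors_give_zero(self):
        v = np.array([3, 0, 17, 5])
        assert compute_log2_ratio(v, v, 1.0) == pytest.approx(np.zeros(4))

    def test_hand_computed_two_element_case(self):
        # rel = (c+1)/(total+2): num [1/5, 4/5], den [4/5, 1/5]
        out = compute_log2_ratio([0, 3], [3, 0], 1.0)
        assert out == pytest.approx([-2.0, 2.0])

    def test_zero_count_with_zero_pseudocount_rejected(self):
        with pytest.raises(ScreenStateError, match="pseudocount"):
            compute_log2_ratio([0, 1], [1, 1], 0.0)

    def test_depth_invariance(self):
        # scaling either vector by an integer factor leaves pc=0 ratios unchanged
        num, den = np.array([8, 2, 5]), np.array([4, 4, 2])
        a = compute_log2_ratio(num, den, 0.0)
        b = compute_log2_ratio(num * 10, den * 3, 0.0)
        assert a == pytest.approx(b)


class TestCentering:
    def test_example(self, toy_library):
        # only the 4 NTCs matter for the median
        ratios = pd.Series(
            {"GA_sg1": 3.0, "NTC_1": 1.0, "NTC_2": 1.0, "NTC_3": 2.0, "NTC_4": 1.0}
        )
        out = center_by_ntc(ratios, toy_library)
        assert out["GA_sg1"] == pytest.approx(2.0)
        assert out["NTC_3"] == pytest.approx(1.0)

    def test_all_equal_gives_zeros(self, toy_library):
        ratios = pd.Series(1.7, index=toy_library.element_ids)
        assert center_by_ntc(ratios, toy_library).to_numpy() == pytest.approx(np.zeros(9))

    def test_post_centering_ntc_median_exactly_zero(self, toy_library):
        rng = np.random.default_rng(5)
        ratios = pd.Series(rng.uniform(-1, 1, 9), index=toy_library.element_ids)
        out = center_by_ntc(ratios, toy_library)
        assert float(out[toy_library.ntc_ids].median()) == 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(-5, 5, allow_nan=False))
    def test_invariant_to_additive_shift(self, shift):
        from screenstate import SgRNAElement, SgRNALibrary

        lib = SgRNALibrary(
            [SgRNAElement("GA_sg1", gene="GA")]
            + [SgRNAElement(f"NTC_{i}", gene=None, is_ntc=True) for i in range(1, 5)]
        )
        rng = np.random.default_rng(9)
        ratios = pd.Series(rng.normal(size=5), index=lib.element_ids)
        a = center_by_ntc(ratios, lib)
        b = center_by_ntc(ratios + shift, lib)
        assert a.to_numpy() == pytest.approx(b.to_numpy(), abs=1e-9)

    def test_too_few_controls(self):
        lib = simulate_library(1, 1, 0, seed=7)
        ratios = pd.Series([0.5], index=lib.element_ids)
        with pytest.raises(InsufficientControlsError):
            center_by_ntc(ratios, lib)


class TestGeneScores:
    def test_top3_by_absolute_value_with_sign(self, toy_library):
        phen = pd.Series(
            {"GA_sg1": -4.0, "GA_sg2": -3.0, "GA_sg3": 2.0, "GB_sg1": -1.0, "GB_sg2": -2.0}
        )
        scores = gene_scores_topk(phen, toy_library, top_k=3)
        assert scores["GA"] == pytest.approx(-5 / 3)
        assert scores["GB"] == pytest.approx(-1.5)  # only 2 elements: use all

    def test_absolute_tie_broken_by_element_id(self, toy_library):
        # |GA_sg2| == |GA_sg3| tie at the cut with top_k=1: GA_sg2 wins lexically
        phen = pd.Series({"GA_sg1": 0.5, "GA_sg2": -2.0, "GA_sg3": 2.0})
        assert gene_scores_topk(phen, toy_library, top_k=1)["GA"] == pytest.approx(-2.0)

    def test_ntc_never_scored(self, toy_library):
        phen = pd.Series(5.0, index=toy_library.element_ids)
        assert "NTC_1" not in gene_scores_topk(phen, toy_library, 3).index
        assert set(gene_scores_topk(phen, toy_library, 3).index) == {"GA", "GB"}


class TestCallHits:
    def test_split_by_sign(self):
        gt = pd.DataFrame(
            {"score": [-0.3, 0.2, -0.5], "q_value": [0.01, 0.04, 0.2]},
            index=["A", "B", "C"],
        )
        hs = call_hits(gt, alpha=0.05)
        assert hs.sensitizing == ["A"] and hs.resistance == ["B"]

    def test_alpha_zero_empties_everything(self):
        gt = pd.DataFrame({"score": [-1.0], "q_value": [0.0001]}, index=["A"])
        hs = call_hits(gt, alpha=0.0)
        assert not hs.sensitizing and not hs.resistance

    def test_zero_score_is_indeterminate(self):
        gt = pd.DataFrame({"score": [0.0], "q_value": [0.001]}, index=["A"])
        assert call_hits(gt, alpha=0.05).indeterminate == ["A"]


class TestPhenotypes:
    def test_doubling_normalization(self, toy_table, toy_library):
        cfg = ScreenConfig(doublings={"gamma": 5.0, "tau": 5.0, "rho": 5.0})
        res = ScreenModel(toy_table, toy_library, cfg).fit()
        ph = res.element_phenotypes
        assert ph["gamma_phenotype"].to_numpy() == pytest.approx(
            ph["gamma_centered"].to_numpy() / 5.0
        )

    def test_rho_raw_ratio_is_tau_minus_gamma(self, toy_table, toy_library):
        cfg = ScreenConfig(pseudocount=0.0)
        res = ScreenModel(toy_table, toy_library, cfg).fit()
        ph = res.element_phenotypes
        diff = ph["rho_raw"] - (ph["tau_raw"] - ph["gamma_raw"])
        assert np.abs(diff.to_numpy()).max() < 1e-12

    def test_standardized_ntc_sd_is_one(self, toy_table, toy_library):
        res = ScreenModel(toy_table, toy_library).fit()
        ph = res.element_phenotypes
        ntc = ph.loc[ph["is_ntc"], "gamma_standardized"]
        assert float(ntc.std(ddof=1)) == pytest.approx(1.0, abs=1e-9)

    def test_missing_condition_raises(self, toy_table, toy_library):
        keep = [s for s in toy_table.sample_ids if not s.startswith("drug")]
        trimmed = toy_table.counts[keep]
        from screenstate import CountTable

        t = CountTable(counts=trimmed, sample_meta=toy_table.sample_meta.loc[keep])
        model = ScreenModel(t, toy_library)
        with pytest.raises(MissingConditionError):
            model.fit(kinds=("tau",))
        # gamma alone still works
        model.fit(kinds=("gamma",))

    def test_invalid_config_rejected(self):
        with pytest.raises(ScreenStateError):
            ScreenConfig(doublings={"gamma": 0.0})
        with pytest.raises(ScreenStateError):
            ScreenConfig(alpha=1.5)
        with pytest.raises(ScreenStateError):
            ScreenConfig(top_k=0)

    def test_gamma_recovery_from_simulated_screen(self):
        """A planted growth effect of -0.2 over 10 vehicle doublings is
        recovered by the mean element gamma of that gene within 0.05."""
        lib = simulate_library(50, 5, 100, seed=11)
        scr = simulate_screen(
            lib,
            [EffectSpec("GENE00001", growth_effect=-0.2)],
            depth=1000.0,
            dispersion=0.01,
            replicates=3,
            seed=11,
        )
        res = ScreenModel(scr.counts, lib).fit(kinds=("gamma",))
        ph = res.element_phenotypes
        mean_gamma = ph.loc[ph["gene"] == "GENE00001", "gamma_phenotype"].mean()
        assert -0.25 <= mean_gamma <= -0.15

    def test_wald_pvalues_cover_elements_and_detect_effect(self, toy_library):
        lib = simulate_library(30, 5, 50, seed=3)
        scr = simulate_screen(
            lib,
            [EffectSpec("GENE00001", growth_effect=-0.4)],
            depth=1000.0,
            dispersion=0.01,
            replicates=3,
            seed=3,
        )
        res = ScreenModel(scr.counts, lib).fit(kinds=("gamma",))
        wald = res.wald_pvalues["gamma"]
        assert len(wald) == len(lib)
        hit = wald[lib.elements_of_gene("GENE00001")]
        assert (hit < 0.05).all()
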