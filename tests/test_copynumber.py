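"""Arm-event calling, CAE scoring, risk flags and the crosstab."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from caerisk.arms import ArmMap, CAE_GAIN_ARMS, CAE_LOSS_ARMS
from caerisk.copynumber import (
    ArmEventSet,
    CopyNumberProfile,
    GAIN,
    LOSS,
    NORMAL,
    NEUTRAL,
    call_bins,
    classify_molecular,
    count_cae,
    crosstab_morphology_molecular,
    derive_arm_events,
    round_half_away,
)
from caerisk.exceptions import ConfigError, DataError, ParameterError

from conftest import make_events


def profile_on_arm(arm_map, arm, calls=None, ratios=None, sample_id="s1"):
    """Bins tiling the start of one arm with given calls or log2 ratios."""
    chrom, start, end = arm_map.arm_interval(arm)
    n = len(calls) if calls is not None else len(ratios)
    width = 1_000_000
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start + width * np.arange(n),
            "end": start + width * (np.arange(n) + 1),
        }
    )
    if ratios is not None:
        bins["log2ratio"] = ratios
    if calls is not None:
        bins["call"] = calls
    return CopyNumberProfile(sample_id=sample_id, bins=bins)


class TestCallBins:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.30, GAIN), (-0.05, NORMAL), (-0.30, LOSS), (0.10, GAIN), (-0.10, LOSS), (0.0999, NORMAL)],
    )
    def test_thresholding(self, arm_map, ratio, expected):
        prof = profile_on_arm(arm_map, "8q", ratios=[ratio])
        called = call_bins(prof, 0.10, -0.10)
        assert called.bins["call"].iloc[0] == expected

    def test_idempotent(self, arm_map):
        prof = profile_on_arm(arm_map, "8q", ratios=[0.3, -0.3, 0.0])
        once = call_bins(prof)
        twice = call_bins(once)
        assert list(once.bins["call"]) == list(twice.bins["call"])

    def test_missing_ratio_without_calls_is_error(self, arm_map):
        prof = profile_on_arm(arm_map, "8q", calls=[GAIN])
        with pytest.raises(DataError):
            call_bins(CopyNumberProfile("s", prof.bins.drop(columns="call").assign(log2ratio=np.nan)))

    def test_bad_thresholds(self, arm_map):
        prof = profile_on_arm(arm_map, "8q", ratios=[0.0])
        with pytest.raises(ParameterError):
            call_bins(prof, -0.1, 0.1)

    def test_noisy_bin_accuracy_matches_closed_form(self, arm_map):
        """At noise_sd 0.05 with ±0.10 thresholds, altered bins (segment means
        +0.58 / −1.0, many noise sds beyond a threshold) call essentially
        perfectly, while a neutral bin miscalls with probability 2·Φ(−2);
        the Monte-Carlo rates over 100 simulated samples must match these
        closed-form values within 4 binomial SEs."""
        from scipy.stats import norm

        rng = np.random.default_rng(42)
        n_alt = n_alt_ok = n_norm = n_norm_ok = 0
        for _ in range(100):
            truth = rng.choice([GAIN, LOSS, NORMAL], size=60, p=[0.2, 0.2, 0.6])
            mean = np.where(truth == GAIN, 0.58, np.where(truth == LOSS, -1.0, 0.0))
            prof = profile_on_arm(arm_map, "1q", ratios=mean + rng.normal(0, 0.05, 60))
            got = call_bins(prof).bins["call"].values
            alt = truth != NORMAL
            n_alt += alt.sum()
            n_alt_ok += (got[alt] == truth[alt]).sum()
            n_norm += (~alt).sum()
            n_norm_ok += (got[~alt] == NORMAL).sum()
        assert n_alt_ok / n_alt > 0.9999  # >9 noise sds from the threshold
        p_norm_ok = 1.0 - 2.0 * norm.cdf(-2.0)
        se = np.sqrt(p_norm_ok * (1 - p_norm_ok) / n_norm)
        assert abs(n_norm_ok / n_norm - p_norm_ok) < 4 * se


class TestDeriveArmEvents:
    def test_unanimous_gain(self, arm_map):
        prof = profile_on_arm(arm_map, "13q", calls=[GAIN] * 10)
        ev = derive_arm_events(prof, arm_map)
        assert ev.status["13q"] == GAIN
        assert ev.n_gains == 1 and ev.n_losses == 0

    def test_below_fraction_is_neutral(self, arm_map):
        prof = profile_on_arm(arm_map, "13q", calls=[GAIN] * 3 + [NORMAL] * 7)
        assert derive_arm_events(prof, arm_map).status["13q"] == NEUTRAL

    def test_larger_fraction_wins_and_tie_is_neutral(self, arm_map):
        mixed = profile_on_arm(arm_map, "8q", calls=[GAIN] * 6 + [LOSS] * 4)
        assert derive_arm_events(mixed, arm_map, 0.5).status["8q"] == GAIN
        tied = profile_on_arm(arm_map, "8q", calls=[GAIN] * 5 + [LOSS] * 5)
        assert derive_arm_events(tied, arm_map, 0.5).status["8q"] == NEUTRAL

    def test_absent_arms_neutral(self, arm_map):
        prof = profile_on_arm(arm_map, "13q", calls=[GAIN] * 4)
        ev = derive_arm_events(prof, arm_map)
        assert ev.status["8p"] == NEUTRAL

    def test_bin_order_invariance(self, arm_map):
        prof = profile_on_arm(arm_map, "17p", calls=[LOSS] * 8 + [NORMAL] * 2)
        shuffled = CopyNumberProfile(
            "s1", prof.bins.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        assert derive_arm_events(prof, arm_map).status == derive_arm_events(shuffled, arm_map).status

    def test_uncalled_profile_rejected(self, arm_map):
        prof = profile_on_arm(arm_map, "8q", ratios=[0.3])
        with pytest.raises(DataError):
            derive_arm_events(prof, arm_map)

    def test_min_fraction_domain(self, arm_map):
        prof = profile_on_arm(arm_map, "8q", calls=[GAIN])
        with pytest.raises(ParameterError):
            derive_arm_events(prof, arm_map, min_fraction=0.3)

    def test_overlapping_arm_definitions_rejected(self):
        bad = pd.DataFrame(
            {"chrom": ["1", "1"], "arm": ["p", "q"], "name": ["1p", "1q"],
             "start": [0, 50], "end": [100, 150]}
        )
        with pytest.raises(ConfigError):
            ArmMap(table=bad)


class TestCaeAndFlags:
    @pytest.mark.parametrize(
        "events,expected",
        [
            (dict(q8=GAIN, q13=GAIN, p17=LOSS), 3),
            (dict(), 0),
            (dict(p8=GAIN, q13=LOSS), 0),  # wrong directions do not count
            (dict(q8=GAIN, q13=GAIN, q20=GAIN, p8=LOSS, q15=LOSS, p17=LOSS, q18=LOSS), 7),
            (dict(q8=LOSS, p8=LOSS), 1),
        ],
    )
    def test_count_cae_direction_specific(self, events, expected):
        assert count_cae(make_events(**events)) == expected

    def test_flag_thresholds(self):
        two_cae = make_events(q8=GAIN, q13=GAIN)
        assert classify_molecular(two_cae).high_cae is True
        one_cae_three_losses = make_events(p17=LOSS, p1=LOSS, q2=LOSS)
        call = classify_molecular(one_cae_three_losses)
        assert call.high_cae is False and call.high_loss is True
        mixed = make_events(q1=GAIN, q2=GAIN, p5=LOSS)
        call = classify_molecular(mixed)
        assert call.high_cna is True and call.high_gain is False and call.high_loss is False

    @given(
        st.dictionaries(
            st.sampled_from(
                [f"{c}{a}" for c in range(1, 23) for a in "pq"]
            ),
            st.sampled_from([GAIN, LOSS, NEUTRAL]),
            max_size=44,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_cae_bounded_and_dominated_by_burden(self, status):
        ev = ArmEventSet(sample_id="h", status=status)
        assert 0 <= ev.cae_count <= 7
        assert ev.cae_count <= ev.n_cna
        assert ev.n_cna == ev.n_gains + ev.n_losses
        call = classify_molecular(ev)
        assert call.high_cae == (ev.cae_count >= 2)
        if call.high_cae:
            assert ev.n_cna >= 2


class TestCrosstab:
    def test_study_shaped_counts(self):
        """85/267 AA-high, 27/262 nAA-high, 112/529 high overall."""
        rows = (
            [("advanced", True)] * 85
            + [("non_advanced", True)] * 27
            + [("advanced", False)] * 182
            + [("non_advanced", False)] * 235
        )
        df = pd.DataFrame(rows, columns=["morphology", "high_cae"])
        xt = crosstab_morphology_molecular(df)
        pct = xt.attrs["percent"]
        assert pct.loc["high", "advanced"] == 31.8
        assert pct.loc["high", "non_advanced"] == 10.3
        assert pct.loc["high", "total"] == 21.2
        counts = xt.attrs["counts"]
        assert counts.loc["total", "total"] == 529
        row_share = round_half_away(100.0 * counts.loc["high", "advanced"] / counts.loc["high", "total"], 1)
        assert row_share == 75.9

    def test_all_low(self):
        df = pd.DataFrame({"morphology": ["advanced", "non_advanced"], "high_cae": [False, False]})
        xt = crosstab_morphology_molecular(df)
        assert (xt.attrs["counts"].loc["high"] == 0).all()
        assert (xt.attrs["percent"].loc["high"] == 0.0).all()

    def test_single_subject(self):
        df = pd.DataFrame({"morphology": ["advanced"], "high_cae": [True]})
        xt = crosstab_morphology_molecular(df)
        assert xt.attrs["percent"].loc["high", "advanced"] == 100.0

    def test_missing_label_rejected(self):
        df = pd.DataFrame({"morphology": ["advanced", None], "high_cae": [True, False]})
        with pytest.raises(DataError):
            crosstab_morphology_molecular(df)


def test_round_half_away_from_zero():
    assert round_half_away(0.05, 1) == 0.1
    assert round_half_away(-0.05, 1) == -0.1
    assert round_half_away(2.25, 1) == 2.3
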