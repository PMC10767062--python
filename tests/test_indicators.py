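"""Behavioral-indicator coding rules."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from cortrack.indicators import (
    MW_MIDPOINTS,
    code_familiarity,
    code_indicators,
    code_mind_wandering,
    code_repetition,
    familiarity_agreement,
)


def toy_records(fam_answers, mw_bins):
    """2 subjects x 2 stimuli x 2 presentations x 1 epoch.

    ``fam_answers[(subject, stimulus, presentation)]`` and
    ``mw_bins[(subject, trial_index)]`` fill the questionnaire columns.
    """
    rows = []
    for subj in (0, 1):
        trial = 0
        for stim in (0, 1):
            for pres in (1, 2):
                rows.append(
                    {
                        "subject_id": subj,
                        "stimulus_id": stim,
                        "presentation": pres,
                        "epoch_index": 0,
                        "familiarity_answer": fam_answers[(subj, stim, pres)],
                        "mw_answer_bin": mw_bins[(subj, trial)],
                    }
                )
                trial += 1
    return pd.DataFrame(rows)


def uniform_answers(ans="Yes", mw="0-25%"):
    fam = {(s, m, p): ans for s in (0, 1) for m in (0, 1) for p in (1, 2)}
    bins = {(s, t): mw for s in (0, 1) for t in range(4)}
    return fam, bins


class TestFamiliarityCoding:
    def test_exhaustive_first_presentation_rule(self):
        """Every combination of first-presentation answers codes correctly,
        regardless of the second-presentation answer."""
        answers = ("Yes", "No", "NotSure")
        for a00, a01, a10, a11, second in product(answers, answers, answers, answers, answers):
            fam, bins = uniform_answers()
            fam[(0, 0, 1)], fam[(0, 1, 1)] = a00, a01
            fam[(1, 0, 1)], fam[(1, 1, 1)] = a10, a11
            for key in list(fam):
                if key[2] == 2:
                    fam[key] = second
            coded = code_familiarity(toy_records(fam, bins))
            for subj, stim, first_answer in [
                (0, 0, a00),
                (0, 1, a01),
                (1, 0, a10),
                (1, 1, a11),
            ]:
                got = coded[
                    (coded.subject_id == subj) & (coded.stimulus_id == stim)
                ]["coded_familiarity"]
                expected = "High" if first_answer == "Yes" else "Low"
                assert (got == expected).all()

    def test_second_presentation_answers_never_matter(self):
        fam, bins = uniform_answers()
        fam[(0, 0, 1)] = "Yes"
        coded_a = code_familiarity(toy_records(fam, bins))
        for key in fam:
            if key[2] == 2:
                fam[key] = "NotSure"
        coded_b = code_familiarity(toy_records(fam, bins))
        assert coded_a["coded_familiarity"].equals(coded_b["coded_familiarity"])

    def test_missing_first_presentation_is_an_error(self):
        fam, bins = uniform_answers()
        df = toy_records(fam, bins)
        df = df[~((df.subject_id == 0) & (df.stimulus_id == 0) & (df.presentation == 1))]
        with pytest.raises(ValueError, match="missing"):
            code_familiarity(df)

    def test_unknown_answer_rejected(self):
        fam, bins = uniform_answers()
        fam[(0, 0, 1)] = "Maybe"
        with pytest.raises(ValueError):
            code_familiarity(toy_records(fam, bins))


class TestMindWanderingCoding:
    def test_midpoint_arithmetic_and_split(self):
        fam, bins = uniform_answers()
        for t in range(4):
            bins[(0, t)] = "0-25%"  # subject mean 12.5
            bins[(1, t)] = "75-100%"  # subject mean 87.5; grand mean 50
        coded = code_mind_wandering(toy_records(fam, bins))
        assert (coded[coded.subject_id == 0]["coded_mw_group"] == "Low").all()
        assert (coded[coded.subject_id == 1]["coded_mw_group"] == "High").all()

    def test_two_point_split(self):
        fam, bins = uniform_answers()
        for t in range(4):
            bins[(0, t)] = "0-25%"
            bins[(1, t)] = "50-75%"
        coded = code_mind_wandering(toy_records(fam, bins))
        # means 12.5 and 62.5, grand mean 37.5
        assert set(coded[coded.subject_id == 0]["coded_mw_group"]) == {"Low"}
        assert set(coded[coded.subject_id == 1]["coded_mw_group"]) == {"High"}

    def test_tie_codes_low(self):
        fam, bins = uniform_answers(mw="25-50%")
        coded = code_mind_wandering(toy_records(fam, bins))
        assert (coded["coded_mw_group"] == "Low").all()

    def test_midpoints(self):
        assert MW_MIDPOINTS == {
            "0-25%": 12.5,
            "25-50%": 37.5,
            "50-75%": 62.5,
            "75-100%": 87.5,
        }


class TestRepetitionCoding:
    def test_mapping_and_balance(self):
        fam, bins = uniform_answers()
        coded = code_repetition(toy_records(fam, bins))
        assert (coded.loc[coded.presentation == 1, "coded_repetition"] == "First").all()
        assert (coded.loc[coded.presentation == 2, "coded_repetition"] == "Second").all()
        assert (coded["coded_repetition"] == "First").mean() == 0.5

    def test_bad_presentation_rejected(self):
        fam, bins = uniform_answers()
        df = toy_records(fam, bins)
        df.loc[0, "presentation"] = 3
        with pytest.raises(ValueError):
            code_repetition(df)


def test_coding_is_idempotent():
    fam, bins = uniform_answers()
    fam[(0, 1, 1)] = "No"
    df = toy_records(fam, bins)
    once = code_indicators(df)
    twice = code_indicators(once)
    pd.testing.assert_frame_equal(once, twice)


class TestFamiliarityAgreement:
    DESIGN = {0: "familiar", 1: "unfamiliar"}

    def test_perfect_answers(self):
        fam, bins = uniform_answers()
        for s in (0, 1):
            fam[(s, 0, 1)] = "Yes"
            fam[(s, 1, 1)] = "No"
        rates = familiarity_agreement(toy_records(fam, bins), self.DESIGN)
        assert rates["p_familiar_given_familiar"] == 1.0
        assert rates["p_unfamiliar_given_unfamiliar"] == 1.0

    def test_coin_flip_answers_near_half(self):
        rng = np.random.default_rng(0)
        rows = []
        for subj in range(200):
            for stim in (0, 1):
                rows.append(
                    {
                        "subject_id": subj,
                        "stimulus_id": stim,
                        "presentation": 1,
                        "epoch_index": 0,
                        "familiarity_answer": "Yes" if rng.random() < 0.5 else "No",
                        "mw_answer_bin": "0-25%",
                    }
                )
        rates = familiarity_agreement(pd.DataFrame(rows), self.DESIGN)
        assert rates["p_familiar_given_familiar"] == pytest.approx(0.5, abs=0.1)
        assert rates["p_unfamiliar_given_unfamiliar"] == pytest.approx(0.5, abs=0.1)

    def test_generated_confusion_rates_recovered(self):
        """A 41-subject synthetic study reproduces the configured 80%/67%
        agreement within binomial sampling error (3-sigma bound, since this
        is a single seeded draw, not an average over replicates)."""
        from cortrack.simulate import SimConfig, simulate_study

        cfg = SimConfig(
            n_subjects=41,
            n_channels=1,
            trial_duration=2.0,
            epoch_duration=2.0,
            seed=5,
        )
        study = simulate_study(cfg)
        rates = familiarity_agreement(
            study.records, study.ground_truth.true_familiarity_label
        )
        n = 41 * 4  # first presentations per designed category
        for key, p in (
            ("p_familiar_given_familiar", 0.80),
            ("p_unfamiliar_given_unfamiliar", 0.67),
        ):
            bound = 3.0 * np.sqrt(p * (1 - p) / n)
            assert abs(rates[key] - p) <= bound + 1e-9
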