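"""Combinatorial rescue screening: correctness, pruning, classification."""

import json
import math

import numpy as np
import pytest

from fragrescue import (
    AveragingMode,
    Fragment,
    InvalidLibraryError,
    PocketLibrary,
    ScreenConfig,
    classic_classification,
    prune_bound,
    required_le_for_remaining,
    screen,
)
from fragrescue.io import result_to_dict
from helpers import brute_force_screen, library_from_les, make_fragment, random_library


class TestScreenToyCases:
    def test_single_pair_rescue(self):
        lib = library_from_les({"p1": [0.5], "p2": [0.3]})
        result = screen(lib, ScreenConfig(cutoff_le_t_app=0.4))
        assert len(result.accepted) == 1
        assert result.classification["p2:p2_f1"] == "rescued"
        assert result.classification["p1:p1_f1"] == "selected"

    def test_zero_cutoff_accepts_everything(self):
        lib = library_from_les({"p1": [0.5, 0.1], "p2": [0.3, 0.05]})
        result = screen(lib, ScreenConfig(cutoff_le_t_app=0.0))
        assert len(result.accepted) == 4
        assert "rejected" not in result.classification.values()

    def test_two_by_two_mean_rule(self):
        """Acceptance is exactly {combinations with mean >= cutoff}.

        With per-pocket LEs {0.5, 0.3} and cutoff 0.4 the pair means are
        0.5, 0.4, 0.4, 0.3 — three of four pass and both 0.3 fragments are
        rescued.  With {0.5, 0.2} the cross pairs average 0.35 < 0.4, so only
        the top pair survives and nothing is rescued.
        """
        lib = library_from_les({"p1": [0.5, 0.3], "p2": [0.5, 0.3]})
        result = screen(lib, ScreenConfig(cutoff_le_t_app=0.4))
        assert len(result.accepted) == 3
        assert result.counts["rescued"] == 2

        lib2 = library_from_les({"p1": [0.5, 0.2], "p2": [0.5, 0.2]})
        result2 = screen(lib2, ScreenConfig(cutoff_le_t_app=0.4))
        assert len(result2.accepted) == 1
        assert result2.counts["rescued"] == 0
        assert result2.classification["p1:p1_f2"] == "rejected"

    def test_no_partners_no_rescue(self):
        """Every pocket maximum below the cutoff and mean of maxima below it: empty."""
        lib = library_from_les({"p1": [0.3, 0.25], "p2": [0.35, 0.2]})
        result = screen(lib, ScreenConfig(cutoff_le_t_app=0.5))
        assert result.accepted == ()
        assert set(result.classification.values()) == {"rejected"}

    def test_empty_pocket_rejected(self):
        lib = PocketLibrary({"p1": (make_fragment(0.4, 10, "p1"),), "p2": ()})
        with pytest.raises(InvalidLibraryError):
            screen(lib, ScreenConfig(cutoff_le_t_app=0.3))

    def test_all_nonbinders_rejected_input(self):
        frag = Fragment("f1", "p1", 2.0, 10)
        lib = PocketLibrary({"p1": (frag,)})
        with pytest.raises(InvalidLibraryError):
            screen(lib, ScreenConfig(cutoff_le_t_app=0.3))
        # allowed explicitly: the non-binder contributes LE 0
        result = screen(lib, ScreenConfig(cutoff_le_t_app=0.0, allow_nonbinders=True))
        assert len(result.accepted) == 1

    def test_nonbinders_dropped_by_default(self):
        lib = PocketLibrary(
            {"p1": (make_fragment(0.5, 10, "p1", "good"), Fragment("dud", "p1", 1.0, 10))}
        )
        result = screen(lib, ScreenConfig(cutoff_le_t_app=0.3))
        assert result.classification["p1:dud"] == "rejected"
        assert result.classification["p1:good"] == "selected"


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", [AveragingMode.ARITHMETIC, AveragingMode.WRMS])
    def test_matches_exhaustive_enumeration(self, mode):
        rng = np.random.default_rng(42)
        for _ in range(40):
            lib = random_library(rng)
            cutoff = float(rng.uniform(0.2, 0.5))
            config = ScreenConfig(cutoff_le_t_app=cutoff, mode=mode)
            result = screen(lib, config)
            expected_accepted, expected_cls = brute_force_screen(lib, config)
            assert {c.fragment_keys for c in result.accepted} == expected_accepted
            assert result.classification == expected_cls

    def test_pruning_actually_happens(self):
        """On a library with one dominant fragment per pocket, branches get cut."""
        lib = library_from_les(
            {p: [0.6, 0.1, 0.1, 0.1] for p in ["p1", "p2", "p3", "p4"]}
        )
        result = screen(lib, ScreenConfig(cutoff_le_t_app=0.55))
        assert result.n_pruned_branches > 0
        assert result.n_evaluated < result.n_total_combinations


class TestMonotonicity:
    def test_raising_cutoff_never_grows_accepted_set(self):
        rng = np.random.default_rng(7)
        lib = random_library(rng)
        keys = []
        for cutoff in [0.2, 0.3, 0.4, 0.5]:
            result = screen(lib, ScreenConfig(cutoff_le_t_app=cutoff))
            keys.append({c.fragment_keys for c in result.accepted})
        for lo, hi in zip(keys, keys[1:]):
            assert hi <= lo

    def test_adding_a_fragment_never_shrinks_accepted_set(self):
        lib = library_from_les({"p1": [0.5, 0.3], "p2": [0.4]})
        config = ScreenConfig(cutoff_le_t_app=0.4)
        before = {c.fragment_keys for c in screen(lib, config).accepted}
        bigger = PocketLibrary(
            {
                "p1": lib.pockets["p1"],
                "p2": lib.pockets["p2"] + (make_fragment(0.45, 9, "p2", "extra"),),
            }
        )
        after = {c.fragment_keys for c in screen(bigger, config).accepted}
        assert before <= after


class TestRequiredLe:
    def test_nothing_chosen_requires_cutoff(self):
        lib = library_from_les({"p1": [0.5], "p2": [0.5]})
        config = ScreenConfig(cutoff_le_t_app=0.4)
        assert required_le_for_remaining([], lib, config) == pytest.approx(0.4)

    def test_low_partner_raises_the_bar(self):
        lib = library_from_les({"p1": [0.3], "p2": [0.6]})
        config = ScreenConfig(cutoff_le_t_app=0.4)
        chosen = [lib.pockets["p1"][0]]
        assert required_le_for_remaining(chosen, lib, config) == pytest.approx(0.5)

    def test_fully_funded_rescue(self):
        lib = library_from_les({"p1": [0.6], "p2": [0.6], "p3": [0.1]})
        config = ScreenConfig(cutoff_le_t_app=0.4)
        chosen = [lib.pockets["p1"][0], lib.pockets["p2"][0]]
        assert required_le_for_remaining(chosen, lib, config) == pytest.approx(0.0)

    def test_unreachable_is_infinite(self):
        lib = library_from_les({"p1": [0.3], "p2": [0.35]})
        config = ScreenConfig(cutoff_le_t_app=0.9)
        chosen = [lib.pockets["p1"][0]]
        assert required_le_for_remaining(chosen, lib, config) == math.inf

    def test_wrms_mode_round_trips_through_average(self):
        lib = library_from_les({"p1": [0.3], "p2": [0.6, 0.5]}, n_heavy=10)
        config = ScreenConfig(cutoff_le_t_app=0.4, mode=AveragingMode.WRMS)
        chosen = [lib.pockets["p1"][0]]
        req = required_le_for_remaining(chosen, lib, config)
        from fragrescue import le_apparent_wrms

        assert le_apparent_wrms([0.3, req], [10.0, 10.0]).value == pytest.approx(
            0.4, rel=1e-10
        )

    def test_pruned_branch_has_no_accepted_extension(self):
        """If the requirement exceeds every remaining maximum, enumeration confirms it."""
        lib = library_from_les({"p1": [0.2, 0.3], "p2": [0.5, 0.45]})
        config = ScreenConfig(cutoff_le_t_app=0.45)
        low = lib.pockets["p1"][0]  # LE 0.2 needs a 0.7 partner; best is 0.5
        assert required_le_for_remaining([low], lib, config) == math.inf
        accepted, _ = brute_force_screen(lib, config)
        assert not any(low.key in combo for combo in accepted)


class TestPruneBound:
    def test_pocket_maximum(self):
        lib = library_from_les({"p1": [0.2, 0.5, 0.4], "p2": [0.3]})
        assert prune_bound("p1", lib) == pytest.approx(0.5)
        assert prune_bound("p2", lib) == pytest.approx(0.3)

    def test_unknown_pocket(self):
        lib = library_from_les({"p1": [0.2]})
        with pytest.raises(KeyError):
            prune_bound("nope", lib)


class TestClassification:
    def test_classic_screen_ignores_partners(self):
        lib = library_from_les({"p1": [0.5], "p2": [0.3]})
        config = ScreenConfig(cutoff_le_t_app=0.4)
        classic = classic_classification(lib, config)
        assert classic == {"p1:p1_f1": "selected", "p2:p2_f1": "rejected"}
        # the RGC screen rescues what the classical screen throws away
        rgc = screen(lib, config).classification
        assert rgc["p2:p2_f1"] == "rescued"

    def test_result_invariants(self):
        rng = np.random.default_rng(11)
        lib = random_library(rng)
        config = ScreenConfig(cutoff_le_t_app=0.35)
        result = screen(lib, config)
        in_accepted = {k for c in result.accepted for k in c.fragment_keys}
        for frag in lib.fragments():
            verdict = result.classification[frag.key]
            le = -frag.delta_g / frag.n_heavy
            if verdict == "selected":
                assert frag.key in in_accepted and le >= config.cutoff_le_t_app
            elif verdict == "rescued":
                assert frag.key in in_accepted and le < config.cutoff_le_t_app
            else:
                assert frag.key not in in_accepted

    def test_rescued_annotation_on_combination(self):
        lib = library_from_les({"p1": [0.5], "p2": [0.3]})
        result = screen(lib, ScreenConfig(cutoff_le_t_app=0.4))
        assert result.accepted[0].rescued_fragment_ids == ("p2:p2_f1",)


class TestDeterminism:
    def test_identical_inputs_identical_reports(self):
        rng = np.random.default_rng(3)
        lib = random_library(rng)
        config = ScreenConfig(cutoff_le_t_app=0.35, random_seed=5)
        a = json.dumps(result_to_dict(screen(lib, config)), sort_keys=True)
        b = json.dumps(result_to_dict(screen(lib, config)), sort_keys=True)
        assert a == b

    def test_output_ordering(self):
        lib = library_from_les({"p1": [0.5, 0.45], "p2": [0.5, 0.45]})
        result = screen(lib, ScreenConfig(cutoff_le_t_app=0.0))
        values = [c.le_t_app.value for c in result.accepted]
        assert values == sorted(values, reverse=True)

    def test_truncation_keeps_classification_complete(self):
        lib = library_from_les({"p1": [0.5, 0.45], "p2": [0.5, 0.45]})
        result = screen(
            lib, ScreenConfig(cutoff_le_t_app=0.0, max_combinations_reported=1)
        )
        assert len(result.accepted) == 1
        assert result.counts["accepted_combinations"] == 4
        assert "rejected" not in result.classification.values()
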