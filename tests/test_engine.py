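import itertools

import numpy as np
import pytest

import fvdesign as fd
from conftest import full_matrix_for
from fvdesign.fv import AA_TO_INDEX, ALPHABET, AlphabetMask, N_AA
from fvdesign.engine import (
    SENTINEL,
    DesignMatrix,
    HallucinationConfig,
    decode,
    generate_library,
    hallucinate,
    initialize_design,
    step,
)
from fvdesign.losses import LossWeights, MotifSpec, geometric_loss


class TestInitialize:
    def test_wildtype_seeding_bonus_dominates_at_zero_draw(self, toy_problem):
        """If every uniform draw were 0, the +0.5 bonus alone decides the argmax."""
        fv, region = toy_problem["fv"], toy_problem["region"]

        class ZeroRng:
            def uniform(self, lo, hi, size):
                return np.zeros(size)

        cfg = HallucinationConfig(seeding="wildtype")
        matrix = initialize_design(cfg, fv, region, ZeroRng())
        assert decode(matrix) == toy_problem["wt_sub"]

    def test_fixed_seed_reproducible(self, toy_problem):
        fv, region = toy_problem["fv"], toy_problem["region"]
        cfg = HallucinationConfig(seed=42)
        m1 = initialize_design(cfg, fv, region, np.random.default_rng(42))
        m2 = initialize_design(cfg, fv, region, np.random.default_rng(42))
        assert (m1.values == m2.values).all()

    def test_disallowed_letters_at_sentinel(self, toy_problem):
        fv, region = toy_problem["fv"], toy_problem["region"]
        cfg = HallucinationConfig()
        matrix = initialize_design(cfg, fv, region, np.random.default_rng(0))
        c = AA_TO_INDEX["C"]
        assert (matrix.values[:, c] == SENTINEL).all()

    def test_seeding_a_disallowed_wildtype_rejected(self, toy_problem):
        fv, region = toy_problem["fv"], toy_problem["region"]
        wt0 = toy_problem["wt_sub"][0]
        cfg = HallucinationConfig(seeding="wildtype", disallow=wt0)
        with pytest.raises(ValueError, match="disallowed"):
            initialize_design(cfg, fv, region, np.random.default_rng(0))

    def test_seeding_argmax_frequency_matches_monte_carlo(self, toy_problem):
        """Frequency of the wildtype letter winning the initial argmax agrees
        with a Monte-Carlo estimate of P(r + 0.5 > max of 18 U(0,1)) within
        3 combined standard errors (19 allowed letters: C is excluded)."""
        fv, region = toy_problem["fv"], toy_problem["region"]
        cfg = HallucinationConfig(seeding="wildtype")
        n_trials = 2000
        rng = np.random.default_rng(123)
        wins = np.zeros(region.n_design)
        for _ in range(n_trials):
            m = initialize_design(cfg, fv, region, rng)
            s = decode(m)
            wins += np.array([a == b for a, b in zip(s, toy_problem["wt_sub"])])
        freq = wins / n_trials

        mc_rng = np.random.default_rng(321)
        n_mc = 200_000
        r = mc_rng.uniform(size=n_mc) + 0.5
        others = mc_rng.uniform(size=(n_mc, 18)).max(axis=1)
        p_mc = (r > others).mean()
        se = np.sqrt(p_mc * (1 - p_mc) * (1 / n_trials + 1 / n_mc))
        assert np.abs(freq - p_mc).max() < 3 * se


class TestDecode:
    def region2(self):
        return fd.DesignRegion((0, 1), ())

    def test_one_hot_rows(self):
        vals = np.full((2, N_AA), -5.0)
        vals[0, AA_TO_INDEX["W"]] = 5.0
        vals[1, AA_TO_INDEX["G"]] = 5.0
        m = DesignMatrix(vals, self.region2(), np.ones((2, N_AA), bool))
        assert decode(m) == "WG"

    def test_exact_tie_breaks_alphabetically(self):
        vals = np.zeros((2, N_AA))  # every letter tied
        m = DesignMatrix(vals, self.region2(), np.ones((2, N_AA), bool))
        assert decode(m) == "AA"

    def test_matches_linear_scan_argmax(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(2, N_AA))
        m = DesignMatrix(vals, self.region2(), np.ones((2, N_AA), bool))
        expected = "".join(
            ALPHABET[max(range(N_AA), key=lambda a: vals[r, a])] for r in range(2)
        )
        assert decode(m) == expected


class TestStep:
    def test_nonzero_gradient_displacement_equals_learning_rate(self, toy_problem):
        fv, region, mask = toy_problem["fv"], toy_problem["region"], toy_problem["mask"]
        cfg = HallucinationConfig(seed=5)
        m = initialize_design(cfg, fv, region, np.random.default_rng(5))
        m2, _, _ = step(m, toy_problem["oracle"], toy_problem["target"], mask, fv, None, cfg)
        delta = np.linalg.norm(m2.values - m.values)
        assert delta == pytest.approx(cfg.learning_rate, abs=1e-9)

    def test_disallowed_columns_never_change(self, toy_problem):
        fv, region, mask = toy_problem["fv"], toy_problem["region"], toy_problem["mask"]
        cfg = HallucinationConfig(seed=6)
        m = initialize_design(cfg, fv, region, np.random.default_rng(6))
        c = AA_TO_INDEX["C"]
        for _ in range(5):
            m, _, _ = step(m, toy_problem["oracle"], toy_problem["target"], mask, fv, None, cfg)
            assert (m.values[:, c] == SENTINEL).all()


class TestHallucinate:
    def test_recovers_bruteforce_minimum(self, toy_problem, eight_letter_mask):
        """3 design positions × 8 letters: the loop reaches the 512-candidate
        brute-force geometric-loss minimum in at least 90% of seeded runs."""
        fv, region, mask = toy_problem["fv"], toy_problem["region"], toy_problem["mask"]
        oracle, target = toy_problem["oracle"], toy_problem["target"]
        letters, amask = eight_letter_mask
        best = min(
            geometric_loss(
                oracle.forward(full_matrix_for("".join(c), fv, region), mask),
                target,
                mask,
            )
            for c in itertools.product(letters, repeat=3)
        )
        hits = 0
        n_runs = 10
        for s in range(n_runs):
            cfg = HallucinationConfig(seed=s, alphabet_mask=amask)
            rec = hallucinate(cfg, oracle, target, mask, fv, region)
            loss = geometric_loss(
                oracle.forward(
                    full_matrix_for(rec.designed_subsequence, fv, region), mask
                ),
                target,
                mask,
            )
            hits += abs(loss - best) < 1e-9
        assert hits >= 0.9 * n_runs

    def test_sequence_loss_domination_returns_wildtype(self, toy_problem):
        fv, region, mask = toy_problem["fv"], toy_problem["region"], toy_problem["mask"]
        cfg = HallucinationConfig(
            seed=2, mode="seqrestricted", weights=LossWeights(1, 1000, 1)
        )
        rec = hallucinate(
            cfg, toy_problem["oracle"], toy_problem["target"], mask, fv, region
        )
        assert rec.designed_subsequence == toy_problem["wt_sub"]

    def test_one_hot_motif_with_high_weight_is_respected(self, toy_problem):
        fv, region, mask = toy_problem["fv"], toy_problem["region"], toy_problem["mask"]
        pos = region.design_positions[1]
        motif = MotifSpec.one_hot({pos: "W"})
        for s in range(3):
            cfg = HallucinationConfig(
                seed=s, mode="motif", weights=LossWeights(1, 1, 100)
            )
            rec = hallucinate(
                cfg, toy_problem["oracle"], toy_problem["target"], mask, fv, region,
                motif=motif,
            )
            assert rec.designed_subsequence[1] == "W"

    def test_descent_trend_on_trajectory(self, toy_problem):
        """Median decoded loss over the last iterations does not exceed the
        median over the first ones (discrete decoding forbids strictness)."""
        fv, region, mask = toy_problem["fv"], toy_problem["region"], toy_problem["mask"]
        cfg = HallucinationConfig(seed=9)
        rec = hallucinate(
            cfg, toy_problem["oracle"], toy_problem["target"], mask, fv, region
        )
        totals = [lv.total for lv in rec.trajectory]
        k = min(10, len(totals) // 2)
        assert np.median(totals[-k:]) <= np.median(totals[:k])

    def test_final_sequence_substitutes_design_region_only(self, toy_problem):
        fv, region, mask = toy_problem["fv"], toy_problem["region"], toy_problem["mask"]
        cfg = HallucinationConfig(seed=4)
        rec = hallucinate(
            cfg, toy_problem["oracle"], toy_problem["target"], mask, fv, region
        )
        for i in region.fixed_positions:
            assert rec.sequence.letter(i) == fv.letter(i)
        for k, i in enumerate(region.design_positions):
            assert rec.sequence.letter(i) == rec.designed_subsequence[k]


class TestLibrary:
    def test_validity_and_some_uniqueness(self, toy_problem):
        fv, region, mask = toy_problem["fv"], toy_problem["region"], toy_problem["mask"]
        cfg = HallucinationConfig(seed=0)
        recs = generate_library(
            cfg, toy_problem["oracle"], toy_problem["target"], mask, fv, region,
            n_designs=15,
        )
        assert len(recs) == 15
        assert all("C" not in r.designed_subsequence for r in recs)
        assert len({r.designed_subsequence for r in recs}) >= 1

    def test_same_seed_identical_records(self, toy_problem):
        fv, region, mask = toy_problem["fv"], toy_problem["region"], toy_problem["mask"]
        cfg = HallucinationConfig(seed=77)
        args = (toy_problem["oracle"], toy_problem["target"], mask, fv, region)
        r1 = hallucinate(cfg, *args)
        r2 = hallucinate(cfg, *args)
        assert r1.designed_subsequence == r2.designed_subsequence
        assert [lv.total for lv in r1.trajectory] == [lv.total for lv in r2.trajectory]
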