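import itertools

import numpy as np
import pandas as pd
import pytest

from episig import (
    BetaMatrix,
    Config,
    ValidationError,
    bonferroni_adjust,
    build_trials,
    derive_signature,
    generate_discovery_study,
    mann_whitney_test,
)
from episig.synthetic_data import SimulationParams

from conftest import simple_sheet, tiny_beta_matrix


def permutation_mw_oracle(x, y):
    """Brute-force two-sided Mann-Whitney p.

    Independent route: U is computed by direct pairwise comparison counts
    (not ranks), and the null is enumerated over every assignment of the
    pooled values into groups of sizes (len(x), len(y)). Two-sided by
    distance of U from its null mean n1*n2/2 (the enumeration distribution
    is symmetric, also under ties).
    """
    x, y = list(x), list(y)
    n1 = len(x)
    pooled = x + y

    def u_of(xs, ys):
        return sum(
            1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys
        )

    u_obs = u_of(x, y)
    mid = n1 * len(y) / 2.0
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        chosen = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_of(chosen, rest) - mid) >= abs(u_obs - mid) - 1e-12:
            hits += 1
        total += 1
    return u_obs, hits / total


class TestTrialDesign:
    def test_one_family_of_three_gives_three_trials(self):
        groups = ["case"] * 19 + ["control"] * 53
        fam = ["fam1"] * 3 + [None] * 69
        sheet = simple_sheet(groups, family_id=fam)
        design = build_trials(sheet)
        assert design.n_trials == 3
        assert all(len(t) == 17 for t in design.trials)
        assert len(design.controls) == 53
        # each trial holds the 16 singles plus one distinct family member
        singles = set(sheet.case_ids[3:])
        reps = [set(t) - singles for t in design.trials]
        assert all(len(r) == 1 for r in reps)
        assert set().union(*reps) == set(sheet.case_ids[:3])

    def test_no_family_means_single_trial(self):
        sheet = simple_sheet(["case"] * 19 + ["control"] * 10)
        design = build_trials(sheet)
        assert design.n_trials == 1 and len(design.trials[0]) == 19

    def test_two_families_of_two_give_four_trials(self):
        groups = ["case"] * 9 + ["control"] * 5
        fam = ["a", "a", "b", "b"] + [None] * 10
        design = build_trials(simple_sheet(groups, family_id=fam))
        assert design.n_trials == 4
        assert all(len(t) == 7 for t in design.trials)
        assert len({frozenset(t) for t in design.trials}) == 4

    def test_singleton_family_treated_as_nonfamilial(self):
        groups = ["case"] * 4 + ["control"] * 4
        fam = ["solo"] + [None] * 7
        design = build_trials(simple_sheet(groups, family_id=fam))
        assert design.n_trials == 1 and len(design.trials[0]) == 4

    def test_no_cases_is_error(self):
        with pytest.raises(ValidationError):
            build_trials(simple_sheet(["control"] * 4))


class TestMannWhitney:
    def test_separated_groups_exact_enumeration(self):
        u, p = mann_whitney_test([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments as extreme

    def test_complete_ties(self):
        u, p = mann_whitney_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert u == 4.5 and p == 1.0

    def test_empty_group_is_error(self):
        with pytest.raises(ValidationError):
            mann_whitney_test([], [0.1])

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (5, 6), (5, 7), (6, 6)])
    def test_exact_mode_matches_permutation_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            # coarse grid forces ties
            x = rng.choice([0.1, 0.2, 0.3, 0.4, 0.5], n1)
            y = rng.choice([0.2, 0.3, 0.4, 0.5, 0.6], n2)
            u, p = mann_whitney_test(x, y)
            u_ref, p_ref = permutation_mw_oracle(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_mode_exhaustive_over_small_shapes(self):
        """Every design shape up to n1+n2 = 12 that the exact branch covers
        agrees with the enumeration oracle."""
        rng = np.random.default_rng(0)
        for n1 in range(1, 8):
            for n2 in range(n1, 13 - n1):
                x = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], n1)
                y = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], n2)
                _, p = mann_whitney_test(x, y)
                _, p_ref = permutation_mw_oracle(x, y)
                assert p == pytest.approx(p_ref, abs=1e-12), (n1, n2)

    def test_asymptotic_branch_close_to_enumeration(self):
        # smallest design routed to the normal approximation
        rng = np.random.default_rng(3)
        x = rng.uniform(0.2, 0.8, 8)
        y = rng.uniform(0.3, 0.9, 8)
        _, p = mann_whitney_test(x, y)
        _, p_ref = permutation_mw_oracle(x, y)
        assert p == pytest.approx(p_ref, abs=0.02)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,q",
        [
            (1e-8, 424_586, 4.24586e-3),
            (0.5, 10, 1.0),
            (2e-7, 424_586, 0.0849172),
        ],
    )
    def test_adjustment_arithmetic(self, p, m, q):
        assert bonferroni_adjust(p, m) == pytest.approx(q, rel=1e-9)

    def test_vectorized_and_bounded(self):
        q = bonferroni_adjust([0.001, 0.5, 1.0], 100)
        assert list(q) == [0.1, 1.0, 1.0]


class TestDeriveSignature:
    def test_parameter_recovery_at_paper_scale_effects(self):
        """Recall >= 0.95, precision >= 0.99 against the simulation truth."""
        params = SimulationParams(
            n_cpgs=10_000, n_signal=500, delta_beta=0.30, concentration=150, seed=7
        )
        matrix, sheet, _, truth = generate_discovery_study(params)
        sig = derive_signature(matrix, sheet, Config())
        found = set(sig.probe_ids)
        true = set(truth.signal_probe_ids)
        assert len(found & true) / len(true) >= 0.95
        assert len(found & true) / len(found) >= 0.99

    def test_null_studies_yield_empty_signatures(self):
        """Bonferroni across three trials keeps the family-wise error rate
        below alpha: at most 1 of 20 null runs may produce any hit."""
        empty = 0
        for seed in range(20):
            params = SimulationParams(n_cpgs=10_000, n_signal=0, seed=3000 + seed)
            matrix, sheet, _, _ = generate_discovery_study(params)
            sig = derive_signature(matrix, sheet, Config())
            empty += len(sig) == 0
        assert empty >= 19

    def test_signature_members_satisfy_all_retention_rules(self, signature, config):
        s = signature.stats
        assert len(signature) > 0
        for t in (1, 2, 3):
            assert (s[f"q_trial{t}"] < config.alpha).all()
            assert (s[f"delta_trial{t}"].abs() >= config.effect_size_min).all()
        signs = np.sign(s[[f"delta_trial{t}" for t in (1, 2, 3)]])
        assert (signs.nunique(axis=1) == 1).all()
        loss = s["direction"] == "loss"
        assert (s.loc[loss, "delta_beta"] < 0).all()
        assert (s.loc[~loss, "delta_beta"] > 0).all()

    def test_label_swap_negates_deltas_keeps_pvalues(self):
        rng = np.random.default_rng(1)
        bm = tiny_beta_matrix(rng.uniform(0.05, 0.95, (50, 20)))
        sheet = simple_sheet(["case"] * 8 + ["control"] * 12)
        swapped = simple_sheet(["control"] * 8 + ["case"] * 12)
        cfg = Config(effect_size_min=0.0, alpha=0.999)
        from episig.diff_meth import full_test_table

        a = full_test_table(bm, sheet, cfg)
        b = full_test_table(bm, swapped, cfg)
        np.testing.assert_allclose(a["p_trial1"], b["p_trial1"], rtol=1e-9)
        np.testing.assert_allclose(a["delta_trial1"], -b["delta_trial1"], rtol=1e-9)

    def test_invariant_to_row_and_column_order(self, config):
        params = SimulationParams(n_cpgs=600, n_signal=60, seed=12)
        matrix, sheet, _, _ = generate_discovery_study(params)
        sig = derive_signature(matrix, sheet, config)
        rng = np.random.default_rng(0)
        rows = rng.permutation(matrix.betas.index)
        cols = rng.permutation(matrix.betas.columns)
        shuffled = BetaMatrix(matrix.betas.loc[rows, cols])
        sig2 = derive_signature(shuffled, sheet, config)
        assert set(sig.probe_ids) == set(sig2.probe_ids)
        pd.testing.assert_frame_equal(
            sig.stats.sort_index(), sig2.stats.sort_index(), rtol=1e-12
        )

    def test_effect_threshold_monotone_in_membership(self, filtered, discovery):
        matrix, _ = filtered
        _, sheet, _, _ = discovery
        loose = derive_signature(matrix, sheet, Config(effect_size_min=0.15))
        base = derive_signature(matrix, sheet, Config(effect_size_min=0.20))
        tight = derive_signature(matrix, sheet, Config(effect_size_min=0.25))
        assert set(tight.probe_ids) <= set(base.probe_ids) <= set(loose.probe_ids)
        assert len(loose) > len(tight)

    def test_effect_size_boundary_excludes_probe(self):
        """A probe perfectly separated but with |delta| below the cutoff in
        one trial is excluded; with |delta| above it in all trials, kept."""
        n_ctrl = 10
        ctrl = np.linspace(0.55, 0.65, n_ctrl)  # mean 0.60
        fam = ["f", "f"] + [None] * (6 + n_ctrl)
        sheet = simple_sheet(["case"] * 8 + ["control"] * n_ctrl, family_id=fam)
        # trial 1 uses family member s0, trial 2 uses s1
        strong = np.array([0.30, 0.30] + [0.30] * 6)       # delta -0.30 everywhere
        weak = np.array([0.52, 0.30] + [0.40] * 6)         # member s0 pulls its
        # trial's delta to -0.183 (fails) while the s1 trial reaches -0.214
        betas = np.vstack(
            [
                np.concatenate([strong, ctrl]),
                np.concatenate([weak, ctrl]),
            ]
        )
        bm = tiny_beta_matrix(betas)
        cfg = Config(alpha=0.9)  # exact p floors dominate at these sizes
        sig = derive_signature(bm, sheet, cfg)
        deltas = {}
        for trial_member, other in ((0, 1), (1, 0)):
            cases = [f"s{trial_member}"] + [f"s{j}" for j in range(2, 8)]
            deltas[trial_member] = betas[1][: 8][
                [trial_member, 2, 3, 4, 5, 6, 7]
            ].mean() - ctrl.mean()
        assert "cg0" in sig.probe_ids
        assert "cg1" not in sig.probe_ids
        assert min(abs(d) for d in deltas.values()) < 0.20 < max(
            abs(d) for d in deltas.values()
        )
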