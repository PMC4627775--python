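"""Two-factor decomposition, permutation significance, SCA and subset search."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrasca import (
    DesignTable,
    decompose,
    interaction_score_profile,
    permutation_test,
    sca,
    search_interaction,
    simulate_cohort,
)
from tests.conftest import small_config


def _design(time_labels, dose_labels):
    n = len(time_labels)
    return DesignTable(
        sample_id=tuple(f"s{i}" for i in range(n)),
        dose=tuple(dose_labels),
        time=tuple(time_labels),
    )


def _balanced_design(n_t, n_d, reps):
    t, d = [], []
    for i in range(n_t):
        for j in range(n_d):
            t += [f"T{i}"] * reps
            d += [f"D{j}"] * reps
    return _design(t, d)


def two_way_anova_ssq(x, t_labels, d_labels):
    """Textbook balanced two-way ANOVA sums of squares, feature by feature."""
    df = pd.DataFrame({"t": t_labels, "d": d_labels})
    grand = x.mean(axis=0)
    ss = dict.fromkeys(("time", "dose", "interaction", "residual"), 0.0)
    t_means = {t: x[(df["t"] == t).values].mean(axis=0) for t in df["t"].unique()}
    d_means = {d: x[(df["d"] == d).values].mean(axis=0) for d in df["d"].unique()}
    cell_means = {
        (t, d): x[((df["t"] == t) & (df["d"] == d)).values].mean(axis=0)
        for t in df["t"].unique() for d in df["d"].unique()
    }
    for i in range(x.shape[0]):
        t, d = df.iloc[i]
        ss["time"] += np.sum((t_means[t] - grand) ** 2)
        ss["dose"] += np.sum((d_means[d] - grand) ** 2)
        ss["interaction"] += np.sum(
            (cell_means[(t, d)] - t_means[t] - d_means[d] + grand) ** 2
        )
        ss["residual"] += np.sum((x[i] - cell_means[(t, d)]) ** 2)
    return ss


class TestDecompose:
    def test_balanced_2x2_matches_anova_oracle(self):
        rng = np.random.default_rng(42)
        design = _balanced_design(2, 2, 3)
        x = rng.normal(size=(12, 4))
        # analytically chosen cell structure on top of noise
        x[np.asarray(design.time) == "T1"] += 1.5
        x[np.asarray(design.dose) == "D1"] -= 0.7
        dec = decompose(x, design)
        oracle = two_way_anova_ssq(x, design.time, design.dose)
        for block in ("time", "dose", "interaction", "residual"):
            assert dec.ssq[block] == pytest.approx(oracle[block], rel=1e-10)
        # balanced design: blocks mutually orthogonal, SSQs additive
        assert dec.additivity_deviation < 1e-12
        blocks = list(dec.effects.values())
        for a in range(4):
            for b in range(a + 1, 4):
                inner = abs(np.sum(blocks[a] * blocks[b]))
                assert inner < 1e-8 * dec.ssq_total

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 4), st.integers(2, 4))
    def test_reconstruction_and_percent_sum(self, seed, n_t, n_d):
        rng = np.random.default_rng(seed)
        reps = rng.integers(2, 5, size=n_t * n_d)
        t, d = [], []
        for i in range(n_t):
            for j in range(n_d):
                r = reps[i * n_d + j]
                t += [f"T{i}"] * r
                d += [f"D{j}"] * r
        x = rng.normal(size=(len(t), rng.integers(3, 10)))
        dec = decompose(x, _design(t, d))
        assert dec.reconstruction_error() < 1e-9
        assert sum(dec.percent.values()) == pytest.approx(100.0, abs=0.01)

    def test_constant_matrix_degenerate(self):
        dec = decompose(np.full((12, 3), 2.5), _balanced_design(2, 2, 3))
        assert dec.degenerate
        assert all(math.isnan(v) for v in dec.percent.values())

    def test_empty_cell_named(self):
        design = _design(["T0"] * 4 + ["T1"] * 2, ["D0", "D1"] * 2 + ["D0"] * 2)
        with pytest.raises(ValueError, match="T1.*D1|empty"):
            decompose(np.zeros((6, 2)), design)


class TestPermutation:
    def test_p_bounds_and_saturation(self):
        matrix, design, _ = simulate_cohort(
            small_config(seed=2, time_amplitude=2.0, sigma=0.05, n_per_cell=4,
                         n_doses=3, n_times=3)
        )
        p = permutation_test(matrix, n=199, seed=1)
        for v in p.values():
            assert 1 / 200 <= v <= 1.0
        assert p["time"] == pytest.approx(1 / 200)

    def test_minimum_permutations_enforced(self):
        matrix, design, _ = simulate_cohort(
            small_config(seed=2, n_per_cell=3, n_doses=2, n_times=2,
                         n_metabolites=5)
        )
        with pytest.raises(ValueError):
            permutation_test(matrix, n=10)


class TestSca:
    def test_rank_one_block(self):
        u = np.arange(6, dtype=float)[:, None]
        v = np.array([[1.0, -2.0, 0.5]])
        sub = sca(u @ v, _balanced_design(3, 2, 1), "time")
        assert sub.explained[0] == pytest.approx(100.0)

    def test_explained_non_increasing_and_bounded(self, default_cohort):
        matrix, design, _ = default_cohort
        dec = decompose(matrix)
        sub = sca(dec.effects["time"], design, "time")
        assert np.all(np.diff(sub.explained) <= 1e-9)
        assert sub.explained.sum() <= 100.0 + 1e-6

    def test_zero_block_degenerate(self):
        sub = sca(np.zeros((4, 3)), _balanced_design(2, 2, 1), "dose")
        assert sub.degenerate


class TestInteractionProfile:
    def test_cell_means_linearity(self, default_cohort):
        matrix, design, _ = default_cohort
        dec = decompose(matrix)
        sub = sca(dec.effects["interaction"], design, "interaction")
        prof = interaction_score_profile(sub)
        # scores are constant within each cell, so cell means of scores
        # equal scores of cell means
        df = design.to_frame()
        df["score"] = sub.scores[:, 0]
        for (t, d), grp in df.groupby(["time", "dose"]):
            assert prof.loc[t, d] == pytest.approx(grp["score"].mean())

    def test_opposite_sign_interaction_profiles_cross(self):
        cfg = small_config(
            seed=9, n_doses=2, n_times=3, n_per_cell=6,
            time_amplitude=0.0, dose_amplitude=0.0,
            interaction_amplitude=0.6, affected_fraction_interaction=1.0,
            sigma=0.02,
        )
        matrix, design, _ = simulate_cohort(cfg)
        dec = decompose(matrix)
        sub = sca(dec.effects["interaction"], design, "interaction")
        prof = interaction_score_profile(sub)
        diff = prof.iloc[:, 0] - prof.iloc[:, 1]
        # a double-centered 2-dose interaction gives opposite trajectories
        assert diff.max() > 0 > diff.min()

    def test_null_profiles_flat(self):
        cfg = small_config(seed=3, time_amplitude=0.0, dose_amplitude=0.0,
                           interaction_amplitude=0.0, sigma=0.05, n_per_cell=6)
        matrix, design, _ = simulate_cohort(cfg)
        dec = decompose(matrix)
        sub = sca(dec.effects["interaction"], design, "interaction")
        prof = interaction_score_profile(sub)
        spread = np.nanstd(prof.values)
        # scores of a pure-noise interaction block stay near zero relative
        # to the data scale
        assert spread < 5 * np.sqrt(dec.ssq_total / matrix.values.size)


class TestSearch:
    def test_enumerates_416_combinations_on_5x5(self):
        matrix, design, _ = simulate_cohort(
            small_config(seed=1, n_per_cell=3, n_metabolites=8)
        )
        res = search_interaction(matrix, n_perm=0)
        assert res.n_combinations == 416
        assert res.records["k"].min() >= 3
        assert not res.records.duplicated(["time_subset", "dose_subset"]).any()

    def test_truth_injected_combination_ranks_first(self):
        cells = ((0, 2, 3), (1, 3))  # 3 times x 2 doses
        cfg = small_config(
            seed=21, n_per_cell=8, time_amplitude=0.2, dose_amplitude=0.1,
            interaction_amplitude=0.5, affected_fraction_interaction=0.5,
            interaction_cells=cells, sigma=0.05,
        )
        matrix, design, _ = simulate_cohort(cfg)
        res = search_interaction(matrix, n_perm=0)
        best = res.best()
        t_expect = ",".join(design.time_levels[i] for i in cells[0])
        d_expect = ",".join(design.dose_levels[i] for i in cells[1])
        assert best["time_subset"] == t_expect
        assert best["dose_subset"] == d_expect

    def test_empty_cell_combination_skipped(self):
        matrix, design, _ = simulate_cohort(
            small_config(seed=4, n_per_cell=3, n_doses=3, n_times=4,
                         n_metabolites=6)
        )
        # empty one whole cell
        drop = ~((np.asarray(design.time) == design.time_levels[0])
                 & (np.asarray(design.dose) == design.dose_levels[0]))
        sub = matrix.subset(drop)
        res = search_interaction(sub, k_range=(3, 4), h_range=(2, 3), n_perm=0)
        full = search_interaction(matrix, k_range=(3, 4), h_range=(2, 3), n_perm=0)
        assert res.n_combinations < full.n_combinations

    def test_small_time_subsets_rejected(self):
        matrix, design, _ = simulate_cohort(
            small_config(seed=4, n_per_cell=3, n_metabolites=6)
        )
        with pytest.raises(ValueError):
            search_interaction(matrix, k_range=(2, 3), n_perm=0)
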