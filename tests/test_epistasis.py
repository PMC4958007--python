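import math

import numpy as np
import pytest

from phagepar.data import apply_well_qc
from phagepar.epistasis import (
    CooccurrenceTest,
    MutationBackgroundLRT,
    ReversionLRT,
    WithinBetweenTest,
    cooccurrence_test,
    mutation_background_lrt,
    reversion_lrt,
    stepwise_influential,
    within_between_test,
)
from phagepar.simulate import simulate_dataset

from .conftest import key_at, make_dataset


@pytest.fixture(scope="module")
def sim(preset):
    ds, _ = simulate_dataset(preset, seed=31)
    return apply_well_qc(ds)


def brute_force_lnl(presence: dict[str, bool], groups: dict[str, str] | None
                    ) -> float:
    """Independent likelihood evaluator: plain loops over wells, MLE
    probabilities computed by counting."""
    wells = sorted(presence)
    if groups is None:
        p = sum(presence[w] for w in wells) / len(wells)
        lnl = 0.0
        for w in wells:
            q = p if presence[w] else 1 - p
            lnl += math.log(q) if q > 0 else 0.0
        return lnl
    lnl = 0.0
    for g in set(groups.values()):
        sub = {w: presence[w] for w in wells if groups[w] == g}
        lnl += brute_force_lnl(sub, None)
    return lnl


class TestWithinBetween:
    def test_identical_wells_give_ratio_one(self, annotation, preset):
        a = key_at(annotation, 100)
        wells = {f"w{i}": [{a}] for i in range(6)}
        bgs = {f"w{i}": f"bg{7 + i % 3}" for i in range(6)}
        ds = make_dataset(wells, bgs, preset.background_catalog, annotation)
        res = within_between_test(ds, n_boot=199, seed=0)
        assert res.ratio == pytest.approx(1.0)

    def test_planted_within_background_similarity(self, annotation, preset):
        rng = np.random.default_rng(1)
        pool = [key_at(annotation, p) for p in range(3000, 3120, 2)]
        wells, bgs = {}, {}
        for b, bg in enumerate(["bg7", "bg8", "bg9"]):
            shared = set(pool[b * 20:b * 20 + 3])
            for i in range(4):
                extra = set(rng.choice(pool[40:], 1))
                wells[f"{bg}w{i}"] = [shared | extra]
                bgs[f"{bg}w{i}"] = bg
        ds = make_dataset(wells, bgs, preset.background_catalog, annotation)
        res = within_between_test(ds, n_boot=999, seed=2)
        assert res.mean_within > res.mean_between
        assert res.p_value < 0.01

    def test_same_seed_reproduces(self, sim):
        a = WithinBetweenTest(sim).fit(n_perm=199, seed=9)
        b = WithinBetweenTest(sim).fit(n_perm=199, seed=9)
        assert a.p_value == b.p_value


class TestMutationBackgroundLRT:
    def test_lambda_nonnegative_and_additive(self, sim):
        res = mutation_background_lrt(sim, n_perm=199, seed=0)
        assert res.lam >= 0
        assert res.lam == pytest.approx(res.per_mutation_delta.sum())
        assert (res.per_mutation_delta >= 0).all()
        assert res.lam == pytest.approx(res.lnl_alt - res.lnl_null)

    def test_single_background_lambda_zero(self, annotation, preset):
        a, b = key_at(annotation, 100), key_at(annotation, 200)
        wells = {f"w{i}": [{a} if i % 2 else {b}] for i in range(4)}
        bgs = {f"w{i}": "bg7" for i in range(4)}
        ds = make_dataset(wells, bgs, preset.background_catalog, annotation)
        res = mutation_background_lrt(ds, n_perm=199, seed=0)
        assert res.lam == 0.0
        assert res.p_value == 1.0

    def test_background_exclusive_mutation_closed_form(self, annotation, preset):
        """A mutation present in all 8 wells of one background and none of
        the other 60: ΔlnL must equal the independently evaluated
        likelihood difference."""
        rng = np.random.default_rng(3)
        target = key_at(annotation, 3000)
        filler = [key_at(annotation, p) for p in range(3100, 3160, 2)]
        wells, bgs = {}, {}
        n_bg = 9
        per_bg = [8] + [60 // (n_bg - 1) + (i < 60 % (n_bg - 1))
                        for i in range(n_bg - 1)]
        wid = 0
        for b in range(n_bg):
            for _ in range(per_bg[b]):
                muts = {target} if b == 0 else set()
                muts |= set(rng.choice(filler, 2, replace=False))
                wells[f"w{wid:02d}"] = [muts]
                bgs[f"w{wid:02d}"] = f"bg{b + 1}"
                wid += 1
        assert wid == 68
        ds = make_dataset(wells, bgs, preset.background_catalog, annotation)
        res = mutation_background_lrt(ds, n_perm=199, seed=0)

        presence = {w: target in v[0] for w, v in wells.items()}
        delta_oracle = (brute_force_lnl(presence, bgs)
                        - brute_force_lnl(presence, None))
        assert res.per_mutation_delta[target] == pytest.approx(delta_oracle)
        # closed form: 8 ln(1/(8/68)) + 60 ln(1/(60/68))
        closed = 8 * math.log(68 / 8) + 60 * math.log(68 / 60)
        assert delta_oracle == pytest.approx(closed)

    def test_same_seed_reproduces(self, sim):
        m = MutationBackgroundLRT(sim)
        assert m.fit(199, seed=4).p_value == m.fit(199, seed=4).p_value

    def test_saturated_mutation_flagged_with_zero_delta(self, annotation, preset):
        a = key_at(annotation, 100)
        wells = {f"w{i}": [{a, key_at(annotation, 200 + 2 * i)}]
                 for i in range(4)}
        bgs = {f"w{i}": ("bg7" if i < 2 else "bg8") for i in range(4)}
        ds = make_dataset(wells, bgs, preset.background_catalog, annotation)
        res = mutation_background_lrt(ds, n_perm=199, seed=0)
        assert a in res.saturated
        assert res.per_mutation_delta[a] == 0.0


class TestStepwise:
    def test_planted_exclusive_mutation_removed_first(self, annotation, preset):
        rng = np.random.default_rng(5)
        target = key_at(annotation, 3000)
        filler = [key_at(annotation, p) for p in range(3100, 3220, 2)]
        wells, bgs = {}, {}
        wid = 0
        for b in range(4):
            for _ in range(8):
                muts = {target} if b == 0 else set()
                muts |= set(rng.choice(filler, 3, replace=False))
                wells[f"w{wid:02d}"] = [muts]
                bgs[f"w{wid:02d}"] = f"bg{b + 1}"
                wid += 1
        ds = make_dataset(wells, bgs, preset.background_catalog, annotation)
        steps = stepwise_influential(ds, alpha=0.05, n_perm=299, seed=1)
        assert steps, "planted association should be significant"
        assert steps[0][0] == target

    def test_terminates_and_keys_unique(self, sim):
        steps = MutationBackgroundLRT(sim).stepwise(alpha=0.05, n_perm=199,
                                                    seed=2)
        keys = [k for k, _ in steps]
        assert len(keys) == len(set(keys))
        if steps:
            assert steps[-1][1] >= 0.05 or np.isnan(steps[-1][1])


class TestReversionLRT:
    def test_equal_frequencies_lambda_zero(self):
        res = ReversionLRT({"a": 2, "b": 2}, {"a": 8, "b": 8}).fit()
        assert res.lam == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_background_brute_force(self):
        res = ReversionLRT({"a": 7, "b": 0}, {"a": 8, "b": 8}).fit()

        def binom_lnl(k, n, p):
            out = 0.0
            if k:
                out += k * math.log(p)
            if n - k:
                out += (n - k) * math.log(1 - p)
            return out

        pooled = binom_lnl(7, 16, 7 / 16)
        split = binom_lnl(7, 8, 7 / 8) + binom_lnl(0, 8, 0.0)
        assert res.lam == pytest.approx(split - pooled)
        assert res.df == 1
        assert res.p_value < 0.01

    def test_from_dataset_counts(self, sim):
        from phagepar.data import classify_reversions

        model = ReversionLRT.from_dataset(sim)
        flags = classify_reversions(sim)
        for b, n in zip(model.backgrounds, model.totals):
            wells = [w for w in sim.wells if w.background_id == b]
            assert n == len(wells)
        total_rev = int(model.reverted.sum())
        assert total_rev == sum(flags.values())

    def test_preset_heterogeneous_reversion_detected(self, sim):
        res = reversion_lrt(sim)
        assert res.p_value < 0.01

    def test_single_background_rejected(self):
        with pytest.raises(ValueError):
            ReversionLRT({"a": 1}, {"a": 8})


class TestCooccurrence:
    def test_planted_attraction(self, annotation, preset):
        """Two mutations always in the same isolates across 6 wells, on a
        background of independent noise mutations."""
        rng = np.random.default_rng(6)
        x, y = key_at(annotation, 3000), key_at(annotation, 3002)
        noise = [key_at(annotation, p) for p in range(3100, 3140, 2)]
        wells, bgs = {}, {}
        for i in range(12):
            isolates = []
            for j in range(4):
                muts = set(rng.choice(noise, 2, replace=False))
                if i < 6 and j < 2:
                    muts |= {x, y}
                isolates.append(muts)
            wells[f"w{i:02d}"] = isolates
            bgs[f"w{i:02d}"] = f"bg{1 + i % 9}"
        ds = make_dataset(wells, bgs, preset.background_catalog, annotation)
        res = cooccurrence_test(ds, n_rand=400, seed=2)
        row = res.full_table[((res.full_table.a == x) & (res.full_table.b == y))
                             | ((res.full_table.a == y) & (res.full_table.b == x))]
        assert len(row) == 1
        assert row.iloc[0]["observed"] > row.iloc[0]["expected"]
        assert row.iloc[0]["p"] < 0.05

    def test_planted_repulsion(self, annotation, preset):
        """Two frequent mutations that never share an isolate."""
        x, y = key_at(annotation, 3000), key_at(annotation, 3002)
        z = key_at(annotation, 3004)
        wells, bgs = {}, {}
        for i in range(12):
            isolates = [{x, z}, {y, z}, {x}, {y}]
            wells[f"w{i:02d}"] = isolates
            bgs[f"w{i:02d}"] = f"bg{1 + i % 9}"
        ds = make_dataset(wells, bgs, preset.background_catalog, annotation)
        res = cooccurrence_test(ds, n_rand=400, seed=3)
        row = res.full_table[((res.full_table.a == x) & (res.full_table.b == y))
                             | ((res.full_table.a == y) & (res.full_table.b == x))]
        assert row.iloc[0]["observed"] == 0
        assert row.iloc[0]["expected"] > 2
        assert row.iloc[0]["p"] < 0.05

    def test_singletons_excluded(self, annotation, preset):
        x = key_at(annotation, 3000)
        y = key_at(annotation, 3002)
        a, b = key_at(annotation, 3004), key_at(annotation, 3006)
        wells = {"w1": [{x, y, a, b}], "w2": [{a, b}], "w3": [{a}],
                 "w4": [{b}]}
        bgs = {w: "bg7" for w in wells}
        ds = make_dataset(wells, bgs, preset.background_catalog, annotation)
        model = CooccurrenceTest(ds)
        assert x not in model.X.columns and y not in model.X.columns
        assert {a, b} <= set(model.X.columns)

    def test_expected_matches_product_of_marginals(self, annotation, preset):
        """Two-mutation toy with full-well occupancy: under the null the
        expected co-occurrence count has the closed form
        n_wells * (w_a/n)(w_b/n) since co-located full wells always share
        isolates."""
        x, y = key_at(annotation, 3000), key_at(annotation, 3002)
        f1, f2 = key_at(annotation, 3004), key_at(annotation, 3006)
        wells, bgs = {}, {}
        for i in range(10):
            isolates = []
            for j in range(5):
                muts = {f1, f2}  # keep every mutation non-singleton
                if i < 3:
                    muts |= {x}
                if i in (3, 4, 5, 6):
                    muts |= {y}
                isolates.append(muts)
            wells[f"w{i}"] = isolates
            bgs[f"w{i}"] = f"bg{1 + i % 9}"
        ds = make_dataset(wells, bgs, preset.background_catalog, annotation)
        res = cooccurrence_test(ds, n_rand=2000, seed=4)
        row = res.full_table[((res.full_table.a == x) & (res.full_table.b == y))
                             | ((res.full_table.a == y) & (res.full_table.b == x))]
        analytic = 10 * (3 / 10) * (4 / 10)
        # binomial-ish MC error on the mean of 2000 replicates, plus slack
        mc_tol = 3 * math.sqrt(analytic / 2000) + 0.05
        assert row.iloc[0]["expected"] == pytest.approx(analytic, abs=mc_tol)

    def test_block_diagonal_counts_distinct_members(self, annotation, preset):
        wells, bgs = {}, {}
        other = key_at(annotation, 3000)
        for i in range(8):
            # each isolate carries exactly one D-promoter mutation
            isolates = [{"1910aG", other}, {"1911cT", other}]
            wells[f"w{i}"] = isolates
            bgs[f"w{i}"] = f"bg{1 + i % 9}"
        ds = make_dataset(wells, bgs, preset.background_catalog, annotation)
        res = cooccurrence_test(ds, n_rand=300, seed=5)
        diag = res.full_table[(res.full_table.a == "D-promoter")
                              & (res.full_table.b == "D-promoter")]
        assert diag.iloc[0]["observed"] == 0
        assert diag.iloc[0]["expected"] > 0

    def test_false_positive_guard_drops_single_cooccurrence(self, sim):
        res = cooccurrence_test(sim, n_rand=200, seed=6)
        dropped = res.full_table[res.full_table["dropped"]]
        assert ((dropped["p"] < 0.05) & (dropped["observed"] == 1)).all()
        assert not ((res.table["p"] < 0.05) & (res.table["observed"] == 1)).any()

    def test_same_seed_reproduces(self, sim):
        a = cooccurrence_test(sim, n_rand=150, seed=8)
        b = cooccurrence_test(sim, n_rand=150, seed=8)
        assert a.table["p"].equals(b.table["p"])
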