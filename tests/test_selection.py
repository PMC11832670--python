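"""Pool assembly: objective, annealing, model comparison, DIF, pipeline."""

import itertools
import warnings

import numpy as np
import pytest

from vocat import (
    AnnealSchedule,
    GeneratorConfig,
    Item,
    ItemBank,
    ItemFitStats,
    ModelComparison,
    ResponseMatrix,
    adjacent_spacing_sd,
    build_pool,
    compare_rasch_2pl,
    dif_analysis,
    generate_study,
    majority_vote_select,
    objective,
    simulated_annealing_select,
)
from conftest import make_rasch_matrix


def make_pool(n, seed=0):
    rng = np.random.default_rng(seed)
    bank = ItemBank([Item(item_id=f"i{j:02d}", word=f"w{j}",
                          difficulty=float(d))
                     for j, d in enumerate(np.sort(rng.normal(0, 1.5, n)))])
    stats = [ItemFitStats(item_id=f"i{j:02d}",
                          infit=float(rng.uniform(0.8, 1.2)),
                          outfit=float(rng.uniform(0.8, 1.2)),
                          mod_index=float(rng.exponential(1.0)))
             for j in range(n)]
    return bank, stats


class TestAdjacentSpacingSd:
    def test_equal_spacing_is_zero(self):
        assert adjacent_spacing_sd([-1.0, 0.0, 1.0]) == pytest.approx(0.0)

    def test_hand_computed_gaps(self):
        # gaps {1, 2}: sample SD = sqrt(((1-1.5)^2 + (2-1.5)^2) / 1)
        assert adjacent_spacing_sd([0.0, 1.0, 3.0]) == pytest.approx(
            0.7071, abs=1e-4)

    def test_permutation_invariant(self):
        assert adjacent_spacing_sd([3.0, 0.0, 1.0]) == pytest.approx(
            adjacent_spacing_sd([0.0, 1.0, 3.0]))

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            adjacent_spacing_sd([0.0, 1.0])


class TestObjective:
    def test_ideal_subset_scores_zero(self):
        bank = ItemBank([Item(item_id=f"i{j}", difficulty=float(j))
                         for j in range(4)])
        stats = [ItemFitStats(item_id=f"i{j}", infit=1.0, outfit=1.0,
                              mod_index=0.0) for j in range(4)]
        assert objective(bank.item_ids, stats, bank) == pytest.approx(0.0)

    def test_hand_computed_weighted_sum(self):
        # spacing SD 0.5, mean |infit-1| = 0.1, mean |outfit-1| = 0.2,
        # mean MI = 2  ->  -(0.5/3 + 4*0.1 + 2*0.2 + 2/100) = -0.98667
        bank = ItemBank([Item(item_id=f"i{j}", difficulty=d)
                         for j, d in enumerate([0.0, 1.0, 2.0, 4.0, 5.0,
                                                6.0, 8.0, 9.0, 10.0])])
        # gaps: 1,1,2,1,1,2,1,1 -> sample SD sqrt(3/14)... construct instead
        # via direct components: use 3 items with gaps {1, 2} -> SD 0.7071 is
        # awkward for round numbers, so check against a recomputed value
        stats = [ItemFitStats(item_id=f"i{j}", infit=1.1, outfit=0.8,
                              mod_index=2.0) for j in range(9)]
        spacing = adjacent_spacing_sd(bank.difficulties)
        expected = -(spacing / 3 + 4 * 0.1 + 2 * 0.2 + 2 / 100)
        assert objective(bank.item_ids, stats, bank) == pytest.approx(expected)

    def test_worsening_any_component_decreases_score(self):
        bank, stats = make_pool(6, seed=1)
        base = objective(bank.item_ids, stats, bank)
        worse_fit = [ItemFitStats(s.item_id, s.infit + 0.3, s.outfit,
                                  s.mod_index) for s in stats]
        worse_mi = [ItemFitStats(s.item_id, s.infit, s.outfit,
                                 s.mod_index + 5.0) for s in stats]
        assert objective(bank.item_ids, worse_fit, bank) < base
        assert objective(bank.item_ids, worse_mi, bank) < base

    def test_always_nonpositive(self):
        bank, stats = make_pool(8, seed=2)
        for subset in itertools.combinations(bank.item_ids, 4):
            assert objective(list(subset), stats, bank) <= 0.0

    def test_missing_stats_rejected(self):
        bank, stats = make_pool(5, seed=3)
        with pytest.raises(ValueError):
            objective(bank.item_ids, stats[:-1], bank)


LIGHT = AnnealSchedule(seed=7, proposals_per_temperature=40,
                       cooling_factor=0.9)


class TestSimulatedAnnealing:
    def test_full_bank_is_single_feasible_subset(self):
        bank, stats = make_pool(6, seed=4)
        res = simulated_annealing_select(bank, stats, 6, schedule=LIGHT)
        assert sorted(res.chosen) == bank.item_ids
        assert res.objective_value == pytest.approx(
            objective(bank.item_ids, stats, bank))

    @pytest.mark.parametrize("n,k", [(10, 4), (9, 5), (12, 3)])
    def test_matches_exhaustive_search(self, n, k):
        bank, stats = make_pool(n, seed=n)
        best = max(objective(list(c), stats, bank)
                   for c in itertools.combinations(bank.item_ids, k))
        res = simulated_annealing_select(bank, stats, k, schedule=LIGHT)
        assert res.objective_value == pytest.approx(best)

    def test_same_seed_reproduces_run(self):
        bank, stats = make_pool(12, seed=5)
        r1 = simulated_annealing_select(bank, stats, 5, schedule=LIGHT)
        r2 = simulated_annealing_select(bank, stats, 5, schedule=LIGHT)
        assert r1.chosen == r2.chosen
        assert r1.trace == r2.trace

    def test_result_never_worse_than_own_trace(self):
        bank, stats = make_pool(14, seed=6)
        res = simulated_annealing_select(bank, stats, 6, schedule=LIGHT)
        assert res.objective_value == pytest.approx(max(res.trace))

    def test_oversized_request_rejected(self):
        bank, stats = make_pool(5, seed=7)
        with pytest.raises(ValueError):
            simulated_annealing_select(bank, stats, 6, schedule=LIGHT)

    def test_majority_vote_is_deterministic_and_scored(self):
        bank, stats = make_pool(12, seed=8)
        r1 = majority_vote_select(bank, stats, 5, schedule=LIGHT, restarts=5)
        r2 = majority_vote_select(bank, stats, 5, schedule=LIGHT, restarts=5)
        assert r1.chosen == r2.chosen
        assert r1.objective_value == pytest.approx(
            objective(r1.chosen, stats, bank))


class TestModelComparison:
    def test_equivalence_rule(self):
        assert ModelComparison(1.0, 1.0).preferred == "equivalent"
        assert ModelComparison(3.0, 1.0).preferred == "2pl"
        assert ModelComparison(-3.0, 1.0).preferred == "rasch"
        assert ModelComparison(2.0, 1.0).preferred == "equivalent"  # boundary

    def test_rasch_data_classified_equivalent(self):
        hits = 0
        for rep in range(5):
            data, _ = make_rasch_matrix(1000, np.linspace(-2.5, 2.5, 30),
                                        seed=800 + rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mc = compare_rasch_2pl(data, seed=rep)
            hits += mc.preferred == "equivalent"
        assert hits >= 4

    def test_strong_2pl_data_detected(self):
        rng = np.random.default_rng(801)
        disc = rng.uniform(0.3, 3.0, 30)
        data, _ = make_rasch_matrix(1000, np.linspace(-2, 2, 30), seed=802,
                                    discriminations=disc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mc = compare_rasch_2pl(data, seed=1)
        assert mc.preferred == "2pl"
        assert mc.elpd_diff > 2 * mc.se_diff

    def test_too_few_folds_rejected(self):
        data, _ = make_rasch_matrix(50, np.linspace(-1, 1, 5), seed=803)
        with pytest.raises(ValueError):
            compare_rasch_2pl(data, folds=1)


def two_group_data(seed, dif_shift=None, n=1000, k=30):
    counts = {"noun": k - 2 * (k // 3), "verb": k // 3, "adjective": k // 3}
    cfg = GeneratorConfig(
        seed=seed, n_items=k, n_persons=n, word_type_counts=counts,
        misfit_fraction=0.0,
        dif_items=[dif_shift] if dif_shift else [])
    _, data, _ = generate_study(cfg)
    return data


class TestDifAnalysis:
    def test_injected_shift_is_flagged(self):
        data = two_group_data(seed=91, dif_shift=("w10", "f", 1.5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = dif_analysis(data)
        assert "w10" in report.flagged

    def test_null_flag_rate_within_nominal(self):
        flags, total = 0, 0
        for rep in range(5):
            data = two_group_data(seed=920 + rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = dif_analysis(data)
            flags += len(report.flagged)
            total += len(report.records)
        assert flags / total <= 0.10

    def test_single_person_group_rejected(self):
        data, _ = make_rasch_matrix(20, np.linspace(-1, 1, 5), seed=93)
        group = np.array(["a"] + ["b"] * 19, dtype=object)
        labelled = ResponseMatrix(data.person_ids, data.item_ids,
                                  data.responses, group=group)
        with pytest.raises(ValueError):
            dif_analysis(labelled)

    def test_wrong_group_count_rejected(self):
        data, _ = make_rasch_matrix(30, np.linspace(-1, 1, 5), seed=94)
        three = ResponseMatrix(
            data.person_ids, data.item_ids, data.responses,
            group=np.array(["a", "b", "c"] * 10, dtype=object))
        with pytest.raises(ValueError):
            dif_analysis(three)


class TestBuildPool:
    @pytest.fixture(scope="class")
    @staticmethod
    def contaminated_study():
        cfg = GeneratorConfig(
            seed=95, n_items=60, n_persons=800,
            word_type_counts={"noun": 31, "verb": 15, "adjective": 14},
            misfit_fraction=0.25)
        return generate_study(cfg)

    def test_pipeline_excludes_injected_misfits(self, contaminated_study):
        bank, data, truth = contaminated_study
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, report = build_pool(data, sizes=[20, 30], schedule=LIGHT,
                                       restarts=3, seed=1)
        misfits = set(truth["items"]["misfit_item_ids"])
        surviving = misfits & set(final.item_ids)
        assert len(misfits) - len(surviving) >= 12
        assert report["step2"]["chosen_size"] in (20, 30)

    def test_pipeline_is_deterministic(self, contaminated_study):
        _, data, _ = contaminated_study
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1, _ = build_pool(data, sizes=[20], schedule=LIGHT,
                               restarts=2, seed=3)
            f2, _ = build_pool(data, sizes=[20], schedule=LIGHT,
                               restarts=2, seed=3)
        assert f1.item_ids == f2.item_ids
        assert np.allclose(f1.difficulties, f2.difficulties)

    def test_single_full_size_returns_filtered_pool(self):
        from vocat import filter_by_fit, fit_rasch, infit_outfit

        data, _ = make_rasch_matrix(600, np.linspace(-2, 2, 15), seed=96)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = fit_rasch(data)
            retained = filter_by_fit(infit_outfit(base, data))
            final, report = build_pool(data, sizes=[len(retained)],
                                       schedule=LIGHT, restarts=2, seed=4)
        assert sorted(final.item_ids) == sorted(retained)
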