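"""The evolutionary loop: fitness, mutation, elitist selection, stopping."""

import numpy as np
import pytest

from esdfold import (
    BuiltinEngine,
    EvolutionConfig,
    PseudoEnergyParams,
    RnaSequence,
    SecondaryStructure,
    ShapeDistributionSet,
    ShapeProfile,
    Stem,
    StemCatalog,
    StructuralClass,
    classify_positions,
    run,
)
from esdfold.evolution import (
    EvolutionState,
    _Evaluator,
    evaluate_population,
    mutate,
    step,
)
from esdfold.stem_catalog import EmptyCatalogError
from conftest import random_sequence


def make_evaluator(seq, dists=None, profile=None):
    return _Evaluator(
        seq,
        BuiltinEngine(),
        dists or ShapeDistributionSet.point_masses(0.0, 0.0, 0.0),
        PseudoEnergyParams(),
        experimental_profile=profile,
    )


class TestEvaluate:
    def test_empty_structure_has_zero_fitness(self, rng):
        seq = RnaSequence("x", "GGGAAACCC")
        evaluator = make_evaluator(seq)
        [ind] = evaluate_population([SecondaryStructure(n=9)], evaluator, rng)
        assert ind.fitness.total == 0.0
        assert ind.fitness.energy == 0.0
        assert ind.fitness.pseudo == 0.0

    def test_fitness_decomposition_closed_form(self, rng):
        # point masses all 0 => PE = b * (2|stacked| + |helix-end|)
        seq = RnaSequence("x", "GGGGAAACCCC")
        from esdfold import parse_dotbracket

        ss = parse_dotbracket("((((...))))")
        evaluator = make_evaluator(seq)
        [ind] = evaluate_population([ss], evaluator, rng)
        labels = classify_positions(ss)
        stacked = labels.count(StructuralClass.STACKED)
        helix_end = labels.count(StructuralClass.HELIX_END)
        expected_pe = -0.8 * (2 * stacked + helix_end)
        assert ind.fitness.pseudo == pytest.approx(expected_pe)
        assert ind.fitness.total == pytest.approx(
            ind.fitness.energy + ind.fitness.pseudo
        )

    def test_fixed_seed_gives_identical_fitness_vector(self, two_stem_catalog):
        seq = random_sequence(24, np.random.default_rng(0))
        dists = ShapeDistributionSet.default()
        results = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            evaluator = _Evaluator(
                seq, BuiltinEngine(), dists, PseudoEnergyParams()
            )
            from esdfold import PopulationConfig, initial_population

            pop = initial_population(
                two_stem_catalog, 24, PopulationConfig(6, 2), rng
            )
            inds = evaluate_population(pop, evaluator, rng)
            results.append([i.fitness.total for i in inds])
        assert results[0] == results[1]

    def test_experimental_profile_overrides_simulation(self, rng):
        seq = RnaSequence("x", "GGGGAAACCCC")
        from esdfold import parse_dotbracket

        ss = parse_dotbracket("((((...))))")
        profile = ShapeProfile(values=np.full(11, 2.0), source="experimental")
        evaluator = make_evaluator(seq, profile=profile)
        [ind] = evaluate_population([ss], evaluator, rng)
        assert ind.profile is profile


class TestMutate:
    def test_single_stem_catalog_returns_same_pair_set(self, rng):
        seq = random_sequence(20, np.random.default_rng(1))
        stem = Stem(r=2, c=18, length=3, weight=1.0)
        catalog = StemCatalog(stems=(stem,))
        evaluator = make_evaluator(seq)
        [parent] = evaluate_population(
            [SecondaryStructure(n=20, pairs=frozenset(stem.pairs))], evaluator, rng
        )
        child = mutate(parent, catalog, evaluator, rng, generation=1)
        assert child.structure.pairs == parent.structure.pairs

    def test_pairless_structure_returned_unchanged(self, two_stem_catalog, rng):
        seq = random_sequence(24, np.random.default_rng(2))
        evaluator = make_evaluator(seq)
        [parent] = evaluate_population([SecondaryStructure(n=24)], evaluator, rng)
        assert mutate(parent, two_stem_catalog, evaluator, rng, generation=1) is parent

    def test_mutants_always_satisfy_structure_invariants(
        self, two_stem_catalog, rng
    ):
        seq = random_sequence(24, np.random.default_rng(3))
        evaluator = make_evaluator(seq)
        from esdfold import PopulationConfig, initial_population

        pop = initial_population(
            two_stem_catalog, 24, PopulationConfig(8, 2), rng
        )
        for parent in evaluate_population(pop, evaluator, rng):
            child = mutate(parent, two_stem_catalog, evaluator, rng, generation=1)
            # constructor re-validates: no shared nucleotides, no crossings
            SecondaryStructure(n=child.structure.n, pairs=child.structure.pairs)


class TestStep:
    def _initial_state(self, catalog, seq, rng, pop_size=8):
        evaluator = make_evaluator(seq)
        from esdfold import PopulationConfig, initial_population

        pop = initial_population(
            catalog, len(seq), PopulationConfig(pop_size, 2), rng
        )
        inds = sorted(
            evaluate_population(pop, evaluator, rng),
            key=lambda i: i.fitness.total,
        )
        state = EvolutionState(
            generation=0, population=inds, best=inds[0],
            history=[inds[0].fitness.total],
        )
        return state, evaluator

    def test_population_size_is_preserved(self, two_stem_catalog, rng):
        seq = random_sequence(24, np.random.default_rng(4))
        state, evaluator = self._initial_state(two_stem_catalog, seq, rng)
        new = step(state, two_stem_catalog, evaluator, rng)
        assert len(new.population) == len(state.population)
        assert new.generation == 1

    def test_elitism_never_increases_best_fitness(self, two_stem_catalog, rng):
        seq = random_sequence(24, np.random.default_rng(5))
        state, evaluator = self._initial_state(two_stem_catalog, seq, rng)
        for _ in range(5):
            new = step(state, two_stem_catalog, evaluator, rng)
            assert new.best.fitness.total <= state.best.fitness.total
            state = new
        assert state.history == sorted(state.history, reverse=True)


class TestRun:
    def test_single_stem_catalog_converges_immediately(self):
        seq = RnaSequence("x", "GGGGGAAAACCCCCAAAAA")
        stem = Stem(r=1, c=14, length=4, weight=2.0)
        catalog = StemCatalog(stems=(stem,))
        result = run(
            seq,
            engine=BuiltinEngine(),
            dists=ShapeDistributionSet.point_masses(1.0, 0.0, 0.2),
            config=EvolutionConfig(seed=0, pop_size=6, stems_per_structure=1),
            catalog=catalog,
        )
        assert result.generations <= 2
        assert result.best.structure.pairs == frozenset(stem.pairs)

    def test_full_determinism_under_seeding(self, two_stem_matrix):
        from esdfold import build_catalog

        seq = random_sequence(24, np.random.default_rng(6))
        catalog = build_catalog(two_stem_matrix)
        reports = []
        for _ in range(2):
            result = run(
                seq,
                engine=BuiltinEngine(),
                dists=ShapeDistributionSet.point_masses(1.0, 0.0, 0.2),
                config=EvolutionConfig(seed=123),
                catalog=catalog,
            )
            reports.append(result.report())
        assert reports[0] == reports[1]

    def test_history_non_increasing_with_stochastic_shape(self, two_stem_matrix):
        from esdfold import build_catalog

        seq = random_sequence(24, np.random.default_rng(7))
        catalog = build_catalog(two_stem_matrix)
        result = run(
            seq,
            engine=BuiltinEngine(),
            dists=ShapeDistributionSet.default(),
            config=EvolutionConfig(seed=5),
            catalog=catalog,
        )
        assert result.history == sorted(result.history, reverse=True)
        assert result.generations <= 100

    def test_empty_catalog_raises_actionable_error(self):
        seq = RnaSequence("x", "AAAAAAAAAA")  # no canonical pairs
        with pytest.raises(EmptyCatalogError, match="prob-floor"):
            run(seq, engine=BuiltinEngine(), config=EvolutionConfig(seed=0))

    def test_report_contains_fitness_decomposition(self, two_stem_matrix):
        from esdfold import build_catalog

        seq = random_sequence(24, np.random.default_rng(8))
        result = run(
            seq,
            engine=BuiltinEngine(),
            dists=ShapeDistributionSet.point_masses(1.0, 0.0, 0.2),
            config=EvolutionConfig(seed=1),
            catalog=build_catalog(two_stem_matrix),
        )
        report = result.report()
        assert report["fitness_total"] == pytest.approx(
            report["energy_term"] + report["pseudo_energy_term"]
        )
        assert report["engine"] == "builtin"
        assert report["seed"] == 1
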