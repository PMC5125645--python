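"""The main evolutionary loop: evaluate, mutate, select, stop.

Each candidate structure is scored by

    fitness(w) = E(d, w) + PE(d, w)

where ``E`` is the engine's free energy and ``PE`` the SHAPE pseudo-free
energy computed from a reactivity profile simulated *from the candidate
itself* (or from a fixed experimental profile when one is supplied).  A
candidate's profile and fitness are computed once, when it is created, and
cached for its lifetime: re-simulating every generation would make the
stopping rule — best fitness unchanged between consecutive generations —
almost surely never fire.

Mutation replaces one randomly chosen helix of the structure with a
roulette-drawn catalog stem (trimmed against the remainder); attempts repeat
until an improving candidate is found or an attempt cap is reached, in which
case the last candidate is handed to selection anyway.  Survivor selection is
elitist: the ``m`` lowest-fitness records among parents and mutants form the
next generation, so the best fitness never increases.  The loop stops when
the best fitness is unchanged (within a small tolerance) across two
consecutive generations, or at a generation cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assembly import PopulationConfig, initial_population, trim_stem
from .pairing_engine import (
    DEFAULT_PROB_FLOOR,
    EnergyModel,
    get_engine,
)
from .rna_model import RnaSequence, SecondaryStructure
from .shape_sim import (
    PseudoEnergyParams,
    ShapeDistributionSet,
    ShapeProfile,
    pseudo_energy_total,
    simulate_shape,
)
from .stem_catalog import EmptyCatalogError, StemCatalog, build_catalog, roulette_draw

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitnessValue:
    """Fitness decomposition; ``total`` is exactly ``energy + pseudo``."""

    energy: float
    pseudo: float

    @property
    def total(self) -> float:
        return self.energy + self.pseudo


@dataclass(frozen=True)
class Individual:
    """A structure with its cached reactivity profile and fitness."""

    structure: SecondaryStructure
    profile: ShapeProfile
    fitness: FitnessValue
    birth_generation: int


@dataclass(frozen=True)
class EvolutionConfig:
    """Run parameters; ``pop_size``/``stems_per_structure`` default from n."""

    seed: int = 0
    pop_size: int | None = None  # default: sequence length n
    stems_per_structure: int | None = None  # default: max(1, n // 5)
    min_stem_len: int = 3
    prob_floor: float = DEFAULT_PROB_FLOOR
    max_generations: int = 100
    stop_tol: float = 1e-6  # kcal/mol equality tolerance for the stopping rule
    mutation_max_attempts: int = 20
    pseudo_params: PseudoEnergyParams = field(default_factory=PseudoEnergyParams)


@dataclass
class EvolutionState:
    """Population, best-so-far record and per-generation history."""

    generation: int
    population: list[Individual]
    best: Individual
    history: list[float]  # best total fitness per generation, non-increasing


@dataclass(frozen=True)
class RunResult:
    best: Individual
    history: list[float]
    generations: int
    engine_name: str
    engine_version: str
    seed: int

    def report(self) -> dict:
        """JSON-serialisable run summary (no wall-clock fields: reproducible)."""
        return {
            "dot_bracket": self.best.structure.to_dotbracket(),
            "num_pairs": len(self.best.structure.pairs),
            "fitness_total": self.best.fitness.total,
            "energy_term": self.best.fitness.energy,
            "pseudo_energy_term": self.best.fitness.pseudo,
            "generations": self.generations,
            "best_fitness_history": list(self.history),
            "engine": self.engine_name,
            "engine_version": self.engine_version,
            "seed": self.seed,
        }


class _Evaluator:
    """Builds Individuals; holds the engine, distributions and parameters."""

    def __init__(
        self,
        seq: RnaSequence,
        engine: EnergyModel,
        dists: ShapeDistributionSet,
        params: PseudoEnergyParams,
        experimental_profile: ShapeProfile | None = None,
    ) -> None:
        if experimental_profile is not None and len(experimental_profile) != len(seq):
            raise ValueError(
                f"experimental profile length {len(experimental_profile)} != "
                f"sequence length {len(seq)}"
            )
        self.seq = seq
        self.engine = engine
        self.dists = dists
        self.params = params
        self.experimental_profile = experimental_profile

    def evaluate(
        self,
        structure: SecondaryStructure,
        rng: np.random.Generator,
        generation: int,
    ) -> Individual:
        if self.experimental_profile is not None:
            profile = self.experimental_profile
        else:
            profile = simulate_shape(structure, self.dists, rng)
        energy = self.engine.energy(self.seq, structure)
        pseudo = pseudo_energy_total(structure, profile, self.params)
        return Individual(
            structure=structure,
            profile=profile,
            fitness=FitnessValue(energy=energy, pseudo=pseudo),
            birth_generation=generation,
        )


def evaluate_population(
    structures: list[SecondaryStructure],
    evaluator: _Evaluator,
    rng: np.random.Generator,
    generation: int = 0,
) -> list[Individual]:
    return [evaluator.evaluate(s, rng, generation) for s in structures]


def mutate(
    parent: Individual,
    catalog: StemCatalog,
    evaluator: _Evaluator,
    rng: np.random.Generator,
    generation: int,
    max_attempts: int = 20,
) -> Individual:
    """Stem-replacement mutation with an improve-or-give-up retry loop.

    Each attempt deletes one helix of the parent (uniformly at random),
    roulette-draws a catalog stem, trims it against the remainder and inserts
    the surviving pairs.  The first candidate at least as fit as the parent is
    returned; after ``max_attempts`` failures the last candidate is returned
    regardless — elitist selection will discard it if it is poor.
    """
    runs = parent.structure.runs()
    if not runs:
        logger.warning("mutate called on a structure with no pairs; returned unchanged")
        return parent
    candidate = parent
    for _ in range(max_attempts):
        victim = runs[rng.integers(len(runs))]
        remaining = parent.structure.pairs - frozenset(victim)
        base = SecondaryStructure(n=parent.structure.n, pairs=remaining)
        stem = roulette_draw(catalog, rng)
        added = [p for run in trim_stem(stem, base) for p in run]
        candidate = evaluator.evaluate(base.union(added), rng, generation)
        if candidate.fitness.total <= parent.fitness.total:
            return candidate
    return candidate


def step(
    state: EvolutionState,
    catalog: StemCatalog,
    evaluator: _Evaluator,
    rng: np.random.Generator,
    max_attempts: int = 20,
) -> EvolutionState:
    """One generation: mutate every member, keep the ``m`` best of parents+mutants.

    Ties in fitness are broken in favour of parents, then insertion order, so
    the trajectory is deterministic under a fixed seed.
    """
    gen = state.generation + 1
    mutants = [
        mutate(ind, catalog, evaluator, rng, gen, max_attempts=max_attempts)
        for ind in state.population
    ]
    merged = list(state.population) + mutants  # parents first; sort is stable
    merged.sort(key=lambda ind: ind.fitness.total)
    survivors = merged[: len(state.population)]
    best = survivors[0]
    assert best.fitness.total <= state.best.fitness.total + 1e-12
    return EvolutionState(
        generation=gen,
        population=survivors,
        best=best,
        history=state.history + [best.fitness.total],
    )


def run(
    seq: RnaSequence,
    engine: EnergyModel | str = "builtin",
    dists: ShapeDistributionSet | None = None,
    config: EvolutionConfig | None = None,
    experimental_profile: ShapeProfile | None = None,
    catalog: StemCatalog | None = None,
) -> RunResult:
    """Full prediction: catalog → initial population → evolve → best structure.

    ``engine`` may be an :class:`EnergyModel` or a spec string
    (``builtin`` / ``external`` / ``file:<path>``).  ``catalog`` may be
    supplied directly to skip the engine's probability computation.
    """
    config = config or EvolutionConfig()
    if isinstance(engine, str):
        engine = get_engine(engine)
    dists = dists or ShapeDistributionSet.default()
    n = len(seq)
    if catalog is None:
        matrix = engine.pair_probabilities(seq, floor=config.prob_floor)
        catalog = build_catalog(matrix, min_len=config.min_stem_len)
    if len(catalog) == 0:
        raise EmptyCatalogError(
            "no potential stems of the required length; lower --prob-floor "
            "or --min-stem-len"
        )
    pop_config = PopulationConfig(
        pop_size=config.pop_size or n,
        stems_per_structure=config.stems_per_structure or max(1, n // 5),
    )
    rng = np.random.default_rng(config.seed)
    evaluator = _Evaluator(
        seq, engine, dists, config.pseudo_params, experimental_profile
    )
    structures = initial_population(catalog, n, pop_config, rng)
    population = evaluate_population(structures, evaluator, rng, generation=0)
    population.sort(key=lambda ind: ind.fitness.total)
    state = EvolutionState(
        generation=0,
        population=population,
        best=population[0],
        history=[population[0].fitness.total],
    )
    while state.generation < config.max_generations:
        state = step(
            state, catalog, evaluator, rng, max_attempts=config.mutation_max_attempts
        )
        if abs(state.history[-1] - state.history[-2]) < config.stop_tol:
            break
    return RunResult(
        best=state.best,
        history=state.history,
        generations=state.generation,
        engine_name=engine.name,
        engine_version=engine.version,
        seed=config.seed,
    )
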