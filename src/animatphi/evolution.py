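"""Darwinian evolution: tournament selection, lineage archiving, the line
of descent, and the elite-performer criterion.

A generational genetic algorithm (no elitism, no crossover) evolves
populations of genomes on the navigation task.  Fitness is ``Gtotal``, the
goal count summed over the evaluated action-result mapping variants.  Every
individual's parent pointer, fitness and genome hash are archived each
generation, and genomes are retained for all ancestors of the current
population, so the line of descent (LoD) -- the ancestor chain of a random
final-generation individual, capturing every mutation that reached fixation
-- can always be reconstructed, along with the most recent common ancestor
(MRCA) of the final population.

An evolved animat is an *elite performer* when its Gtotal with the internal
feedback mechanism enabled is at least twice its Gtotal with feedback
disabled (and non-zero): its performance demonstrably rests on lifetime
learning rather than on a fixed reactive strategy.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .config import ExperimentConfig
from .engine import compile_genome, evaluate_all_mappings_compiled
from .environment import ACTION_MAPPINGS, GridWorld, build_world
from .genome import mutate, random_genome


def genome_hash(genome: np.ndarray) -> str:
    return hashlib.sha256(
        np.ascontiguousarray(genome, dtype=np.int64).tobytes()
    ).hexdigest()[:16]


@dataclass
class Individual:
    id: int
    genome: np.ndarray
    parent_id: int | None
    generation: int
    fitness: float = 0.0


@dataclass
class LineageArchive:
    """Per-generation records plus a genome store pruned to the ancestry of
    the current population."""

    config_hash: str
    seed: int
    generations: list = field(default_factory=list)
    # each generation: list of (id, parent_id, fitness, genome_hash)
    genome_store: dict = field(default_factory=dict)   # id -> genome
    parent_of: dict = field(default_factory=dict)      # id -> parent id
    world: GridWorld | None = None

    @property
    def n_generations(self) -> int:
        return len(self.generations) - 1

    def record_generation(self, population):
        self.generations.append([
            (ind.id, ind.parent_id, ind.fitness, genome_hash(ind.genome))
            for ind in population
        ])
        for ind in population:
            self.genome_store[ind.id] = ind.genome
            self.parent_of[ind.id] = ind.parent_id

    def prune(self, live_ids):
        """Drop stored genomes not ancestral to ``live_ids``."""
        keep = set()
        for i in live_ids:
            node = i
            while node is not None and node not in keep:
                keep.add(node)
                node = self.parent_of.get(node)
        self.genome_store = {i: g for i, g in self.genome_store.items()
                             if i in keep}

    def ancestor_chain(self, individual_id: int) -> list[int]:
        """ids from generation 0 down to ``individual_id`` (oldest first)."""
        chain = []
        node = individual_id
        while node is not None:
            chain.append(node)
            if node not in self.parent_of:
                raise KeyError(f"broken parent pointer at id {node}")
            node = self.parent_of[node]
        return chain[::-1]

    def archive_hash(self) -> str:
        """Digest of every archived record (reproducibility checks)."""
        h = hashlib.sha256()
        for gen in self.generations:
            for rec in gen:
                h.update(repr(rec).encode())
        return h.hexdigest()


def tournament_select(population, tournament_size: int,
                      rng: np.random.Generator):
    """Draw ``tournament_size`` contenders uniformly with replacement and
    return the fittest; ties are broken uniformly at random."""
    if not population:
        raise ValueError("population is empty")
    picks = rng.integers(len(population), size=tournament_size)
    best_fit = max(population[k].fitness for k in picks)
    winners = [k for k in picks if population[k].fitness == best_fit]
    return population[winners[int(rng.integers(len(winners)))]]


def default_fitness(genome, world: GridWorld, config: ExperimentConfig,
                    rng: np.random.Generator, mapping_indices=None,
                    learning_enabled: bool = True) -> float:
    """Gtotal of one genome over the given mapping variants (engine path)."""
    cb = compile_genome(genome)
    total, _ = evaluate_all_mappings_compiled(
        cb, world, rng, lifetime=config.lifetime,
        mapping_indices=mapping_indices, learning_enabled=learning_enabled)
    return float(total)


def run_evolution(config: ExperimentConfig, seed: int | None = None,
                  world: GridWorld | None = None,
                  fitness_fn=None, progress=None) -> LineageArchive:
    """Evolve one replicate and return its lineage archive.

    One world is built per replicate and reused across generations.  When
    ``config.fitness_mappings`` is set, that many of the 24 mapping variants
    are drawn anew each generation (shared by the whole population); the
    full set is used otherwise.  ``fitness_fn(genome, world, config, rng,
    mapping_indices)`` may be injected for testing.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if world is None:
        w = config.world
        world = build_world(w.width, w.height, w.obstacle_fraction,
                            w.spawn_distance, rng=rng)
    if fitness_fn is None:
        fitness_fn = default_fitness

    archive = LineageArchive(config_hash=config.config_hash(), seed=seed,
                             world=world)
    next_id = 0
    population = []
    for _ in range(config.population_size):
        population.append(Individual(
            id=next_id, parent_id=None, generation=0,
            genome=random_genome(rng, length=config.genome_length,
                                 n_seed_codons=config.n_seed_codons)))
        next_id += 1

    n_maps = len(ACTION_MAPPINGS)
    for gen in range(config.generations + 1):
        if config.fitness_mappings and config.fitness_mappings < n_maps:
            mapping_indices = rng.choice(n_maps, size=config.fitness_mappings,
                                         replace=False).tolist()
        else:
            mapping_indices = None
        for ind in population:
            ind.fitness = fitness_fn(ind.genome, world, config, rng,
                                     mapping_indices=mapping_indices)
        archive.record_generation(population)
        if gen % 50 == 0:
            archive.prune([ind.id for ind in population])
        if progress is not None:
            progress(gen, population)
        if gen == config.generations:
            break
        offspring = []
        for _ in range(config.population_size):
            parent = tournament_select(population, config.tournament_size, rng)
            child = mutate(parent.genome, config.mutation, rng)
            offspring.append(Individual(id=next_id, parent_id=parent.id,
                                        generation=gen + 1, genome=child))
            next_id += 1
        population = offspring
    archive.prune([rec[0] for rec in archive.generations[-1]])
    return archive


@dataclass
class LodMember:
    id: int
    generation: int
    fitness: float
    genome: np.ndarray


def line_of_descent(archive: LineageArchive, rng: np.random.Generator):
    """The ancestor chain of a uniformly chosen final-generation individual,
    oldest first, plus the MRCA generation of the final population (-1 when
    the final population has not yet coalesced to a common ancestor)."""
    final = archive.generations[-1]
    pick = final[int(rng.integers(len(final)))][0]
    chain = archive.ancestor_chain(pick)

    fit = {rec[0]: rec[2] for gen in archive.generations for rec in gen}
    lod = [LodMember(id=i, generation=g, fitness=fit[i],
                     genome=archive.genome_store[i])
           for g, i in enumerate(chain)]

    # MRCA: deepest generation at which all final ancestor chains coincide
    chains = [archive.ancestor_chain(rec[0]) for rec in final]
    mrca_generation = -1
    for depth in range(min(len(c) for c in chains)):
        ids = {c[depth] for c in chains}
        if len(ids) == 1:
            mrca_generation = depth
        else:
            break
    return lod, mrca_generation


@dataclass
class EliteReport:
    gtotal_learning: float
    gtotal_frozen: float
    is_elite: bool


def elite_filter(genome, world: GridWorld, config: ExperimentConfig,
                 rng: np.random.Generator) -> EliteReport:
    """Test the two-fold learning criterion: evaluate Gtotal over all 24
    mappings with the feedback mechanism enabled and, with the same episode
    seeds, disabled."""
    seed = int(rng.integers(2**31))
    gl = default_fitness(genome, world, config, np.random.default_rng(seed),
                         learning_enabled=True)
    gf = default_fitness(genome, world, config, np.random.default_rng(seed),
                         learning_enabled=False)
    return EliteReport(gtotal_learning=gl, gtotal_frozen=gf,
                       is_elite=bool(gl >= 2.0 * gf and gl > 0))


# -- plain-text archive I/O ----------------------------------------------

def lod_to_csv(lod, mrca_generation: int) -> str:
    """LoD export: generation, fitness, genome hash (one row per member)."""
    lines = [f"# mrca_generation={mrca_generation}",
             "generation,fitness,genome_hash"]
    for m in lod:
        lines.append(f"{m.generation},{m.fitness},{genome_hash(m.genome)}")
    return "\n".join(lines) + "\n"
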