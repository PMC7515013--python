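"""Figure-analog analyses over evolved lineages.

Every analysis consumes archived evolution outputs (or freshly evaluated
brains) and emits long-format pandas tables -- (replicate, generation,
lifetime_time, metric, value) rows stamped with the config hash and seed --
so each published-figure analogue (performance with and without feedback,
action fractions, gate mutual-information change over a lifetime,
Phi_atomic against performance on the line of descent, PhiMaxH lifetime
trajectories and their slopes) is reproducible from the archive alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .brain import Brain
from .config import ExperimentConfig, PhiConfig
from .engine import compile_genome, evaluate_all_mappings_compiled
from .environment import ACTION_MAPPINGS, GridWorld, Result, run_episode
from .evolution import LineageArchive, LodMember, elite_filter
from .gates import DecomposableGate
from .phi import phi_atomic_from_trace, phi_maxh_trajectory


def action_fractions(episode_results) -> pd.Series:
    """Fraction of lifetime spent on each result type, averaged over
    episodes (mappings/replicates).  Fractions sum to 1."""
    if not episode_results:
        raise ValueError("no episodes supplied")
    lifetimes = {res.lifetime for res in episode_results}
    if len(lifetimes) != 1:
        raise ValueError("episodes must share a lifetime")
    counts = np.sum([res.action_counts for res in episode_results], axis=0)
    fractions = counts / counts.sum()
    return pd.Series(fractions, index=[r.name.lower() for r in Result])


def mean_decomposable_gate_mi(brain: Brain) -> float:
    """Mean analytic input-output mutual information over the brain's
    decomposable (including feedback) gates, in bits."""
    gates = [g for g in brain.gates if isinstance(g, DecomposableGate)]
    if not gates:
        return 0.0
    return float(np.mean([g.mutual_information() for g in gates]))


def gate_mi_lifetime(brain: Brain, world: GridWorld, mapping,
                     rng: np.random.Generator, lifetime: int = 512,
                     learning_enabled: bool = True):
    """Mean decomposable-gate MI at birth and at death of one episode.

    Returns ``(mi_birth, mi_death, delta_mi)`` with
    ``delta_mi = mi_death - mi_birth``.  Without learning (or without
    feedback gates) the tables cannot change, so ``delta_mi`` is exactly 0.
    """
    brain.reset("both")
    brain.learning_enabled = learning_enabled
    mi_birth = mean_decomposable_gate_mi(brain)
    run_episode(brain, world, mapping, rng, lifetime=lifetime,
                record_trace=False)
    mi_death = mean_decomposable_gate_mi(brain)
    return mi_birth, mi_death, mi_death - mi_birth


def phi_vs_performance(lod, world: GridWorld, config: ExperimentConfig,
                       rng: np.random.Generator, mapping_indices=None,
                       stride: int = 1) -> pd.DataFrame:
    """Per-LoD-member Phi_atomic (from behavioural state traces) against
    Gtotal, with learning enabled and disabled.

    Phi_atomic is the plug-in estimate over the concatenated transition
    pairs of all evaluated episodes.  ``stride`` subsamples the LoD.
    """
    if mapping_indices is None:
        mapping_indices = range(len(ACTION_MAPPINGS))
    rows = []
    members: list[LodMember] = list(lod)[::stride]
    for member in members:
        rec = {"id": member.id, "generation": member.generation}
        for label, learning in (("learning", True), ("frozen", False)):
            brain = Brain.from_genome(member.genome,
                                      learning_enabled=learning)
            total = 0
            phis = []
            for m in mapping_indices:
                brain.reset("both")
                brain.learning_enabled = learning
                res = run_episode(brain, world, ACTION_MAPPINGS[m], rng,
                                  lifetime=config.lifetime, record_trace=True)
                total += res.goals_reached
                phis.append(phi_atomic_from_trace(res.state_trace,
                                                  brain.n_nodes).phi_atomic)
            rec[f"gtotal_{label}"] = total
            rec[f"phi_atomic_{label}"] = float(np.mean(phis))
        rows.append(rec)
    return pd.DataFrame(rows, columns=["id", "generation",
                                       "gtotal_learning",
                                       "phi_atomic_learning",
                                       "gtotal_frozen", "phi_atomic_frozen"])


def analyze_archive(archive: LineageArchive, config: ExperimentConfig,
                    rng: np.random.Generator, lod=None,
                    lod_stride: int | None = None,
                    phi_config: PhiConfig | None = None,
                    mapping_indices=None, replicate: int = 0) -> pd.DataFrame:
    """Long-format analysis table over one replicate's line of descent.

    Metric families: ``gtotal_learning`` / ``gtotal_frozen`` (performance
    with and without the feedback mechanism), ``action_fraction_*``,
    ``gate_mi_birth`` / ``gate_mi_death`` / ``gate_mi_delta``,
    ``phi_atomic_learning`` / ``phi_atomic_frozen`` (trace-based), and
    ``phi_maxh_slope`` (lifetime trajectory trend).  Every row carries the
    config hash and seed.
    """
    from .evolution import line_of_descent

    phi_config = phi_config or config.phi
    if lod is None:
        lod, _ = line_of_descent(archive, rng)
    if lod_stride is None:
        lod_stride = max(1, len(lod) // 10)
    if mapping_indices is None:
        mapping_indices = range(min(len(ACTION_MAPPINGS),
                                    config.fitness_mappings or 24))
    world = archive.world
    rows = []

    def emit(generation, metric, value, lifetime_time=np.nan):
        rows.append({"replicate": replicate, "generation": generation,
                     "lifetime_time": lifetime_time, "metric": metric,
                     "value": float(value),
                     "config_hash": archive.config_hash,
                     "seed": archive.seed})

    for member in list(lod)[::lod_stride]:
        gen = member.generation
        episodes = []
        for label, learning in (("learning", True), ("frozen", False)):
            cb = compile_genome(member.genome)
            total, results = evaluate_all_mappings_compiled(
                cb, world, rng, lifetime=config.lifetime,
                mapping_indices=mapping_indices,
                learning_enabled=learning, record_trace=True)
            emit(gen, f"gtotal_{label}", total)
            phis = [phi_atomic_from_trace(r.state_trace, 16).phi_atomic
                    for r in results]
            emit(gen, f"phi_atomic_{label}", np.mean(phis))
            if learning:
                episodes = results

        fracs = action_fractions(episodes)
        for result_name, frac in fracs.items():
            emit(gen, f"action_fraction_{result_name}", frac)

        brain = Brain.from_genome(member.genome)
        m0 = next(iter(mapping_indices))
        mi_b, mi_d, mi_delta = gate_mi_lifetime(
            brain, world, ACTION_MAPPINGS[m0], rng, lifetime=config.lifetime)
        emit(gen, "gate_mi_birth", mi_b)
        emit(gen, "gate_mi_death", mi_d)
        emit(gen, "gate_mi_delta", mi_delta)

        traj = phi_maxh_trajectory(Brain.from_genome(member.genome), world,
                                   ACTION_MAPPINGS[m0], rng,
                                   lifetime=config.lifetime,
                                   config=phi_config)
        emit(gen, "phi_maxh_slope", traj.slope)
        for t, v in zip(traj.timesteps, traj.phi_values):
            emit(gen, "phi_maxh", v, lifetime_time=t)
    return pd.DataFrame(rows)


def elite_summary(archive: LineageArchive, config: ExperimentConfig,
                  rng: np.random.Generator) -> dict:
    """Elite test of the final line-of-descent member of one replicate."""
    from .evolution import line_of_descent

    lod, mrca = line_of_descent(archive, rng)
    report = elite_filter(lod[-1].genome, archive.world, config, rng)
    return {"generation": lod[-1].generation,
            "gtotal_learning": report.gtotal_learning,
            "gtotal_frozen": report.gtotal_frozen,
            "is_elite": report.is_elite,
            "mrca_generation": mrca}
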