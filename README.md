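# animatphi

Evolvable Markov Brains with lifetime feedback learning, a grid-navigation
learning task, Darwinian evolution with line-of-descent tracking, and
integrated-information measures (Φatomic, ΦmaxH).

## The problem

How does *lifetime learning* change a brain's ability to integrate
information? Information integration theory quantifies that ability as Φ —
how much information a system processes over and above the sum of its
parts — but measuring Φ requires complete observability of the system's
states, which rules out natural organisms. This package implements the
standard computational stand-in: *animats*, virtual organisms controlled
by Markov Brains (networks of genetically encoded probabilistic logic
gates over 16 binary nodes), extended with **decomposable feedback gates**
whose probability tables change during a lifetime under internally
generated reinforcement while remaining decomposable — the property that
makes the information-theoretic analysis valid.

Animats evolve on a lattice world where every cell's arrow points along the
shortest path to a goal, but the mapping from the four available actions
(A–D) to their effects (turn left/right, idle, forward) is one of 24
permutations that changes between episodes — so good performance requires
learning the current mapping by trial and error, within a lifetime.

## The measures

For binary nodes `X = (X^(1), …, X^(n))` observed across one time step,

    Φ_atomic = Σ_i H(X_t^(i) | X_{t+1}^(i)) − H(X_t | X_{t+1})
             = I(X_t : X_{t+1}) − Σ_i I(X_t^(i) : X_{t+1}^(i)) + Ī

(the second assembly, with the nonindependence `Ī = Σ_i H(X_t^(i)) − H(X_t)`,
is implemented independently as a permanent cross-check). Φatomic is
estimated either from recorded state traces of a behaving animat or from a
transition probability matrix (TPM). **ΦmaxH** is Φatomic of the
per-time-point TPM under a uniform (maximum-entropy) state distribution,
so it can be measured before, during and after learning; its
linear-fit slope over a lifetime is the lifetime-change proxy.

## A worked example

```python
import numpy as np
from animatphi import (desk_profile, run_evolution, line_of_descent,
                       elite_filter)

cfg = desk_profile(seed=1, generations=2000)   # pop 50, 16x16 world
archive = run_evolution(cfg, seed=1)           # ~1 minute
lod, mrca = line_of_descent(archive, np.random.default_rng(1))
print(lod[0].fitness, "->", lod[-1].fitness)   # 3.0 -> 33.0
report = elite_filter(lod[-1].genome, archive.world, cfg,
                      np.random.default_rng(2))
print(report.gtotal_learning, report.gtotal_frozen)
```

With seed 1 this prints `3.0 -> 33.0`: the line of descent climbs from a
founder reaching 3 goals (over 6 mapping variants) to a descendant
reaching 33. Evaluated over all 24 mappings, the final animat reached 103
goals with its feedback mechanism enabled against 79 with it frozen — its
performance partly rests on lifetime learning (the *elite* criterion asks
for a two-fold advantage).

The `examples/` directory has one short narrative script per capability:

| script | shows |
|---|---|
| `01_gates_and_learning.py` | factor algebra; reinforcement sharpening a gate from 0 to ~1 bit of MI |
| `02_phi_closed_forms.py` | Φatomic = 0 / 2 / 1 bits on the copy, swap and XOR systems |
| `03_navigation_task.py` | the 24 action mappings; the oracle's 16 goals/episode ceiling |
| `04_evolution_desk.py` | a desk-scale run, its line of descent and the elite test |
| `05_phimaxh_trajectory.py` | flat ΦmaxH for a static brain; a sampled trajectory and slope for an evolved learner |

A thin CLI wraps the same library calls:

```bash
animatphi evolve --profile desk --seed 1 --replicates 1 --out runs/
animatphi lod --archive runs/replicate_000 --seed 1
animatphi analyze --archive runs/replicate_000 --profile desk --seed 1 --out analysis/
animatphi fixtures --list
```

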