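"""Genetic encoding of Markov Brains and mutation operators.

A genome is a sequence of integer loci in [0, 255].  Stretches beginning
with the two-locus start codon (42, 213) encode one gate each, analogous to
genes encoding proteins.  After the codon the gene reads, in order:

1. gate type id (modulo the number of enabled gate types),
2. number of inputs ``i`` and outputs ``o`` (each ``1 + locus % 4``),
3. ``i`` input node addresses and ``o`` output node addresses
   (each ``locus % n_nodes``),
4. the payload -- for deterministic gates ``2^i`` output patterns
   (``locus % 2^o``); for decomposable gates ``2^i * o`` factors
   (``locus / 255`` clamped into ``[p_min, 1 - p_min]``); for legacy
   feedback gates ``2^i * 2^o`` raw row weights (rows normalised),
5. for feedback-capable gates a feedback block: positive and negative
   reinforcement node addresses, history length (``locus % 4``) and three
   positive plus three negative per-depth deltas (``locus / 255 * delta_max``).

Genes may overlap; a gene truncated by the genome end is skipped.  Decoding
is a pure function of the genome, so identical genomes always produce
identical brains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gates import (DELTA_MAX, MAX_HISTORY, P_MIN, DecomposableFeedbackGate,
                    DecomposableGate, DeterministicGate, FeedbackParams, Gate,
                    LegacyFeedbackGate)

logger = logging.getLogger(__name__)

START_CODON = (42, 213)
GENOME_MIN_LENGTH = 1_000
GENOME_MAX_LENGTH = 20_000
LOCUS_MAX = 255

#: default gate repertoire; legacy non-decomposable feedback gates are
#: appended only when explicitly enabled
DEFAULT_GATE_TYPES = ("deterministic", "decomposable", "decomposable_feedback")


@dataclass
class MutationRates:
    """Per-offspring mutation probabilities."""

    point: float = 0.005       # per locus
    gene_duplication: float = 0.05
    gene_deletion: float = 0.05

    def __post_init__(self):
        for name in ("point", "gene_duplication", "gene_deletion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} rate must lie in [0, 1], got {v}")


def validate_genome(genome: np.ndarray) -> np.ndarray:
    g = np.asarray(genome, dtype=np.int64)
    if g.ndim != 1:
        raise ValueError("genome must be one-dimensional")
    if np.any((g < 0) | (g > LOCUS_MAX)):
        raise ValueError("genome loci must lie in [0, 255]")
    return g


def random_genome(rng: np.random.Generator, length: int = 5_000,
                  n_seed_codons: int = 4) -> np.ndarray:
    """Uniform random genome with ``n_seed_codons`` start codons planted at
    evenly spaced positions so initial brains are rarely empty."""
    g = rng.integers(0, LOCUS_MAX + 1, size=length)
    for k in range(n_seed_codons):
        pos = (k + 1) * length // (n_seed_codons + 2)
        g[pos] = START_CODON[0]
        g[pos + 1] = START_CODON[1]
    return g


def codon_positions(genome: np.ndarray) -> np.ndarray:
    """Indices where the two-locus start codon begins."""
    g = np.asarray(genome)
    return np.flatnonzero((g[:-1] == START_CODON[0]) &
                          (g[1:] == START_CODON[1]))


class _GeneReader:
    """Sequential reader over loci; raises IndexError when truncated."""

    def __init__(self, genome: np.ndarray, pos: int):
        self.g = genome
        self.pos = pos

    def take(self, n: int = 1) -> np.ndarray:
        if self.pos + n > len(self.g):
            raise IndexError("gene truncated at genome end")
        out = self.g[self.pos:self.pos + n]
        self.pos += n
        return out

    def one(self) -> int:
        return int(self.take(1)[0])


def _decode_gene(reader: _GeneReader, n_nodes: int, gate_types, p_min: float,
                 delta_max: float) -> Gate:
    kind = gate_types[reader.one() % len(gate_types)]
    i = 1 + reader.one() % 4
    o = 1 + reader.one() % 4
    in_addrs = reader.take(i) % n_nodes
    out_addrs = reader.take(o) % n_nodes
    if kind == "deterministic":
        outputs = reader.take(2**i) % (2**o)
        return DeterministicGate(in_addrs, out_addrs, outputs)
    if kind in ("decomposable", "decomposable_feedback"):
        factors = reader.take(2**i * o).astype(float) / LOCUS_MAX
        factors = np.clip(factors, p_min, 1.0 - p_min).reshape(2**i, o)
        if kind == "decomposable":
            return DecomposableGate(in_addrs, out_addrs, factors, p_min=p_min)
        fb = _decode_feedback_block(reader, n_nodes, delta_max)
        return DecomposableFeedbackGate(in_addrs, out_addrs, factors, fb,
                                        p_min=p_min)
    if kind == "legacy_feedback":
        raw = reader.take(2**i * 2**o).astype(float).reshape(2**i, 2**o)
        rows = np.where(raw.sum(axis=1, keepdims=True) > 0, raw, 1.0)
        fb = _decode_feedback_block(reader, n_nodes, delta_max)
        return LegacyFeedbackGate(in_addrs, out_addrs, rows, fb)
    raise ValueError(f"unknown gate type {kind!r}")


def _decode_feedback_block(reader: _GeneReader, n_nodes: int,
                           delta_max: float) -> FeedbackParams:
    pos_node = reader.one() % n_nodes
    neg_node = reader.one() % n_nodes
    history = reader.one() % (MAX_HISTORY + 1)
    pos_deltas = reader.take(MAX_HISTORY).astype(float) / LOCUS_MAX * delta_max
    neg_deltas = reader.take(MAX_HISTORY).astype(float) / LOCUS_MAX * delta_max
    return FeedbackParams(pos_node, neg_node, history, pos_deltas, neg_deltas)


def decode_genome(genome, n_nodes: int = 16,
                  gate_types=DEFAULT_GATE_TYPES, p_min: float = P_MIN,
                  delta_max: float = DELTA_MAX,
                  return_spans: bool = False):
    """Decode every gene in ``genome`` into a gate list.

    Scans all positions for the start codon; genes may overlap.  Truncated
    genes at the genome end are skipped (logged at DEBUG level).
    """
    g = validate_genome(genome)
    gates: list[Gate] = []
    spans: list[tuple[int, int]] = []
    for pos in codon_positions(g):
        reader = _GeneReader(g, int(pos) + 2)
        try:
            gate = _decode_gene(reader, n_nodes, gate_types, p_min, delta_max)
        except IndexError:
            logger.debug("truncated gene at locus %d skipped", pos)
            continue
        gates.append(gate)
        spans.append((int(pos), reader.pos))
    if return_spans:
        return gates, spans
    return gates


def gene_spans(genome, n_nodes: int = 16,
               gate_types=DEFAULT_GATE_TYPES) -> list[tuple[int, int]]:
    """(start, end) locus spans of every decodable gene, codon included."""
    _, spans = decode_genome(genome, n_nodes=n_nodes, gate_types=gate_types,
                             return_spans=True)
    return spans


def mutate(genome, rates: MutationRates, rng: np.random.Generator,
           n_nodes: int = 16, gate_types=DEFAULT_GATE_TYPES) -> np.ndarray:
    """Mutated copy of ``genome``: per-locus point mutations plus optional
    whole-gene duplication and deletion, with the length clamped to
    ``[GENOME_MIN_LENGTH, GENOME_MAX_LENGTH]`` by skipping an offending
    structural mutation."""
    g = validate_genome(genome).copy()

    mask = rng.random(len(g)) < rates.point
    n_hits = int(mask.sum())
    if n_hits:
        g[mask] = rng.integers(0, LOCUS_MAX + 1, size=n_hits)

    do_dup = rng.random() < rates.gene_duplication
    do_del = rng.random() < rates.gene_deletion
    if do_dup or do_del:
        spans = gene_spans(g, n_nodes=n_nodes, gate_types=gate_types)
        if do_dup and spans:
            start, end = spans[int(rng.integers(len(spans)))]
            if len(g) + (end - start) <= GENOME_MAX_LENGTH:
                at = int(rng.integers(len(g) + 1))
                g = np.concatenate([g[:at], g[start:end], g[at:]])
        if do_del and spans:
            spans = gene_spans(g, n_nodes=n_nodes, gate_types=gate_types)
            if spans:
                start, end = spans[int(rng.integers(len(spans)))]
                if len(g) - (end - start) >= GENOME_MIN_LENGTH:
                    g = np.concatenate([g[:start], g[end:]])
    return g


def genome_to_line(genome) -> str:
    """One-genome-per-line archive format: comma-separated integers."""
    return ",".join(str(int(v)) for v in genome)


def genome_from_line(line: str) -> np.ndarray:
    return validate_genome(np.array([int(v) for v in line.strip().split(",")]))
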