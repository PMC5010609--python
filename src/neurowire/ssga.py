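"""Steady-state genetic algorithm over permutation genotypes.

One offspring per step: tournament-select two parents, order crossover,
swap mutation, decode and evaluate, replace the current worst individual
only on strict improvement (elitist steady state).  Minimization and
maximization share the engine through a sign flip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .drcmst import (
    AuxiliaryArrays,
    PermutationGenotype,
    WiringForest,
    build_auxiliary_arrays,
    decode,
    encode,
)
from .morphology import PointCloud

__all__ = ["GAConfig", "GARunResult", "ssga_optimize", "seeded_population"]

logger = logging.getLogger(__name__)


@dataclass
class GAConfig:
    """Hyperparameters of the steady-state GA.

    ``max_evaluations=None`` resolves to 50,000 for problems up to 200
    slots, scaling linearly above (250 evaluations per slot).
    """

    population_size: int = 50
    max_evaluations: int | None = None
    crossover_rate: float = 0.9
    mutation_rate: float = 0.9
    tournament_size: int = 2
    direction: str = "minimize"
    seed: int = 0
    refine: bool = True
    n_parent_candidates: int = 5

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0.0 <= self.crossover_rate <= 1.0):
            raise ValueError("crossover_rate must be in [0, 1]")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        if self.direction not in ("minimize", "maximize"):
            raise ValueError("direction must be 'minimize' or 'maximize'")
        if (
            self.max_evaluations is not None
            and self.max_evaluations < self.population_size
        ):
            raise ValueError("max_evaluations must be >= population_size")
        if self.n_parent_candidates < 1:
            raise ValueError("n_parent_candidates must be >= 1")

    def resolved_budget(self, n_slots: int) -> int:
        if self.max_evaluations is not None:
            return int(self.max_evaluations)
        return max(50_000, 250 * n_slots)

    @property
    def sign(self) -> int:
        return 1 if self.direction == "minimize" else -1

    def with_(self, **kw) -> "GAConfig":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "GAConfig":
        return cls(**{k: v for k, v in d.items() if v is not None})


@dataclass
class GARunResult:
    best_forest: WiringForest
    best_length: float
    evaluations_used: int
    history: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    best_genotype: PermutationGenotype | None = None


def seeded_population(
    cloud: PointCloud,
    aux: AuxiliaryArrays,
    include_real: bool = False,
    config: GAConfig | None = None,
) -> np.ndarray:
    """Initial population: uniform-random permutations, optionally with one
    member replaced by the encoding of the cloud's real arborization."""
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    m = aux.n_slots
    pop = np.empty((config.population_size, m), dtype=np.int64)
    for i in range(config.population_size):
        pop[i] = rng.permutation(m)
    if include_real:
        if not cloud.real_edges:
            raise ValueError("include_real requires cloud.real_edges")
        real = WiringForest(edges=list(cloud.real_edges), total_length=0.0)
        pop[0] = encode(real, aux, cloud).perm
    return pop


def _candidate_parents(
    cloud: PointCloud,
    slot_node: np.ndarray,
    child_node: np.ndarray,
    config: GAConfig,
) -> np.ndarray:
    """Per child position, the candidate parent node indices that the local
    refinement steers toward: nearest parents when minimizing wiring,
    farthest when maximizing (ranked best-first, self excluded, padded by
    repetition when fewer parents exist than requested)."""
    parent_nodes = np.unique(slot_node)
    topk = max(1, min(config.n_parent_candidates, len(parent_nodes)))
    cand = np.empty((len(child_node), topk), dtype=np.int64)
    for k, ch in enumerate(child_node):
        d = np.linalg.norm(cloud.xyz[parent_nodes] - cloud.xyz[ch], axis=1)
        order = parent_nodes[np.argsort(d)]
        if config.direction == "maximize":
            order = order[::-1]
        order = order[order != ch][:topk]
        if len(order) == 0:
            order = parent_nodes[:1]
        cand[k, : len(order)] = order
        if len(order) < topk:
            cand[k, len(order):] = order[-1]
    return cand


def ssga_optimize(
    cloud: PointCloud,
    config: GAConfig | None = None,
    aux: AuxiliaryArrays | None = None,
    include_real: bool = False,
) -> GARunResult:
    """Search the cloud's degree/role-constrained arborizations for minimal
    (or maximal) total wiring length.  Deterministic given ``config.seed``."""
    config = config or GAConfig()
    if aux is None:
        aux = build_auxiliary_arrays(cloud)
    m = aux.n_slots
    if m == 0:
        forest = WiringForest(edges=[], total_length=0.0, cloud_ref=cloud.label)
        return GARunResult(forest, 0.0, 0, np.empty((0, 2)),
                           PermutationGenotype(np.empty(0, dtype=np.int64)))
    slot_node, child_node = aux.index_arrays(cloud)
    budget = config.resolved_budget(m)
    pop = seeded_population(cloud, aux, include_real=include_real, config=config)
    cand = _candidate_parents(cloud, slot_node, child_node, config)
    history = np.empty((budget + 1, 2))
    best_perm, best_len, evals, hist_n = _kernels.ssga_loop(
        pop,
        slot_node,
        child_node,
        cloud.n,
        cloud.xyz,
        cand,
        budget,
        config.crossover_rate,
        config.mutation_rate,
        config.tournament_size,
        config.sign,
        config.refine,
        # keep the kernel RNG stream distinct from the init-population stream
        (config.seed * 2 + 1) % (2**31 - 1),
        history,
    )
    if hist_n == 0 or not np.isfinite(best_len):
        raise RuntimeError(
            f"no feasible arborization found for {cloud.label or 'cloud'}: "
            "the degree/role constraints admit no spanning forest"
        )
    genotype = PermutationGenotype(best_perm)
    forest = decode(genotype, aux, cloud)
    logger.info(
        "ssGA %s on %s: %d evaluations, best length %.3f um",
        config.direction, cloud.label or "cloud", evals, forest.total_length,
    )
    if logger.isEnabledFor(logging.DEBUG):
        for ev, length in history[:hist_n]:
            logger.debug("  eval %d: best %.3f um", int(ev), length)
    return GARunResult(
        best_forest=forest,
        best_length=forest.total_length,
        evaluations_used=evals,
        history=history[:hist_n].copy(),
        best_genotype=genotype,
    )
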