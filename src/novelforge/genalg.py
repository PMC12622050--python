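"""Fold-recombining genetic algorithm with burial-proportional selection.

Miniprotein fragments (default 800 × 40 aa) are generated de novo by
replica-exchange MCMC over the composite sequence-energy landscape; a
random subset of 100 seeds the population. Each epoch, 20 offspring are
produced by recombination (interior splice or end-to-end fusion), point
mutation, and a short Metropolis refinement on the same landscape; the
pool of 120 is then reduced back to 100 by stochastic selection with
survival weight proportional to burial fraction. Compactness is thus the
only selective force — function plays no role — letting both
nature-like and new-to-nature folds accumulate in the archive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np

from .annotate import NoveltyCall, cath_prefix, novelty_call
from .sampler import EnergyModel, SamplerConfig, metropolis_step, run_remc
from .structio import BurialFraction, ProteinSequence, ProteinStructure, burial_fraction
from .surrogates import BackendSuite, sliding_window_tm

logger = logging.getLogger(__name__)


@dataclass
class Fragment:
    sequence: ProteinSequence
    structure: ProteinStructure | None
    burial: BurialFraction | None
    origin: str


@dataclass
class Individual:
    id: str
    sequence: ProteinSequence
    structure: ProteinStructure
    burial: BurialFraction
    lineage: tuple            # (parent_ids, operator, epoch_created)
    epoch: int


@dataclass
class GAConfig:
    population_size: int = 100
    offspring_per_epoch: int = 20
    epochs: int = 200
    mutation_rate: float = 0.02
    refine_steps: int = 100
    refine_temperature: float = 1.0
    splice_probability: float = 0.5   # remainder is end-to-end fusion
    max_child_length: int = 250
    min_child_length: int = 10
    compactness_threshold: float = 0.5
    tm_threshold: float = 0.5
    annotate: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if not 0.0 <= self.splice_probability <= 1.0:
            raise ValueError("splice_probability must be in [0, 1]")


@dataclass
class EpochRecord:
    epoch: int
    mean_burial: float
    cumulative_unique_cath: int
    cumulative_novel: int
    new_novel_ids: list


@dataclass
class GAResult:
    records: list             # EpochRecord per epoch
    population: list          # surviving Individuals
    archive: list             # every Individual ever created
    annotations: dict         # id -> NoveltyCall (if annotation enabled)


# ---------------------------------------------------------------------------
# Fragment library
# ---------------------------------------------------------------------------

def generate_fragment_library(
    n: int = 800,
    length: int = 40,
    cfg: SamplerConfig | None = None,
    model: EnergyModel | None = None,
    structure_predictor=None,
    max_retries: int = 5,
) -> list:
    """n unique fragments, each the best state of an independent seeded
    replica-exchange run from a random start. Duplicates are regenerated
    (up to ``max_retries`` fresh seeds per slot, then error)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or SamplerConfig()
    fragments = []
    seen = set()
    stride = max_retries + 1
    for i in range(n):
        frag = None
        for attempt in range(stride):
            run_seed = cfg.seed + i * stride + attempt
            traj = run_remc(
                length, replace(cfg, seed=run_seed), model,
                record_interval=max(1, cfg.steps_per_replica),
            )
            seq = traj.best[0]
            if seq in seen:
                continue
            structure = burial = None
            if structure_predictor is not None:
                fid = f"frag{i}"
                try:
                    structure = structure_predictor(seq, fid)
                    burial = burial_fraction(structure)
                except Exception as exc:
                    logger.warning("predictor failed for fragment %d: %s", i, exc)
                    continue
            seen.add(seq)
            frag = Fragment(
                sequence=ProteinSequence(f"frag{i}", seq),
                structure=structure,
                burial=burial,
                origin=f"remc_seed{run_seed}",
            )
            break
        if frag is None:
            raise RuntimeError(
                f"could not generate a unique fragment for slot {i} "
                f"after {stride} attempts"
            )
        fragments.append(frag)
    return fragments


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def recombine(
    a: str,
    b: str,
    rng: np.random.Generator,
    splice_probability: float = 0.5,
    max_length: int = 250,
    min_length: int = 10,
) -> tuple:
    """Recombine two parent sequences.

    Splice: child = a[1..x] + b[y..Lb] with interior cut points
    x ∈ [1, La−1], y ∈ [2, Lb] (1-based). Fusion: child = a + b.
    Children outside [min_length, max_length] are resampled; if no draw
    satisfies the bounds, falls back to the (length-capped) fusion.

    Returns (child, operator_name).
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("parents must have length >= 2")
    for attempt in range(100):
        if rng.random() < splice_probability:
            x = int(rng.integers(1, len(a)))        # 1..La-1
            y = int(rng.integers(2, len(b) + 1))    # 2..Lb
            child, op = a[:x] + b[y - 1:], "splice"
        else:
            child, op = a + b, "fusion"
        if min_length <= len(child) <= max_length:
            return child, op
    return (a + b)[:max_length], "fusion"


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-position substitution with probability ``rate``
    (replacement always differs from the original letter)."""
    from .structio import AMINO_ACIDS

    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0:
        return seq
    flips = rng.random(len(seq)) < rate
    chars = list(seq)
    for pos in np.where(flips)[0]:
        options = [x for x in AMINO_ACIDS if x != chars[pos]]
        chars[pos] = options[int(rng.integers(len(options)))]
    return "".join(chars)


def refine(
    seq: str,
    steps: int,
    model: EnergyModel,
    rng: np.random.Generator,
    temperature: float = 1.0,
) -> str:
    """Single-temperature Metropolis descent on the sequence-energy
    landscape (the same landscape the fragment library was sampled on)."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if steps == 0:
        return seq
    from .sampler import composite_energy

    state = (seq, composite_energy(seq, model))
    for _ in range(steps):
        state, _ = metropolis_step(state, temperature, model, rng)
    return state[0]


SELECTION_EPSILON = 1e-6


def stochastic_select(
    pool: list,
    target: int,
    rng: np.random.Generator,
) -> list:
    """Weighted sampling without replacement; weight = burial + ε so that
    zero-burial individuals stay selectable. Pools at or under target are
    returned unchanged."""
    if len(pool) <= target:
        return list(pool)
    weights = np.array(
        [ind.burial.value + SELECTION_EPSILON for ind in pool], dtype=float
    )
    if np.any(weights < 0):
        raise ValueError("burial values must be >= 0")
    idx = rng.choice(len(pool), size=target, replace=False,
                     p=weights / weights.sum())
    chosen = set(int(i) for i in idx)
    return [ind for k, ind in enumerate(pool) if k in chosen]


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def _hex_id(rng: np.random.Generator, epoch: int) -> str:
    return f"{int(rng.integers(0, 16 ** 6)):06X}_R{epoch}"


def run_ga(
    cfg: GAConfig,
    backends: BackendSuite,
    library: list,
    model: EnergyModel | None = None,
) -> GAResult:
    """Run the genetic algorithm from a fragment library.

    The initial population is a random subset of ``population_size``
    fragments. Each epoch produces ``offspring_per_epoch`` offspring
    (recombine → mutate → refine → predict → burial), extends the pool,
    optionally annotates new individuals for novelty, and selects back to
    the target size. Deterministic per seed for deterministic backends.
    """
    rng = np.random.default_rng(cfg.seed)
    model = model or EnergyModel(
        likelihood_scorer=backends.likelihood_scorer,
        contact_scorer=backends.contact_scorer,
    )
    if len(library) < cfg.population_size:
        raise ValueError(
            f"library has {len(library)} fragments; "
            f"need >= population_size ({cfg.population_size})"
        )
    founders_idx = rng.choice(len(library), size=cfg.population_size,
                              replace=False)
    population = []
    for k in sorted(int(i) for i in founders_idx):
        frag = library[k]
        structure = frag.structure
        burial = frag.burial
        if structure is None:
            structure = backends.structure_predictor(
                frag.sequence.residues, frag.sequence.id
            )
            burial = burial_fraction(structure)
        population.append(Individual(
            id=frag.sequence.id,
            sequence=frag.sequence,
            structure=structure,
            burial=burial,
            lineage=((), "founder", 0),
            epoch=0,
        ))
    archive = list(population)
    annotations: dict = {}
    novel_reps: list = []          # (id, structure) of novel cluster founders
    unique_cath: set = set()
    records = []

    def annotate_individual(ind: Individual) -> NoveltyCall | None:
        if not cfg.annotate:
            return None
        hits = backends.search_engine(ind.structure)
        call = novelty_call(
            ind.id, ind.burial, hits,
            tm_threshold=cfg.tm_threshold,
            compactness_threshold=cfg.compactness_threshold,
        )
        annotations[ind.id] = call
        if call.assigned_label is not None:
            unique_cath.add(cath_prefix(call.assigned_label, "CAT"))
        return call

    if cfg.annotate:
        for ind in population:
            call = annotate_individual(ind)
            if call.novel and _is_new_cluster(ind, novel_reps, cfg.tm_threshold):
                novel_reps.append((ind.id, ind.structure))

    for epoch in range(1, cfg.epochs + 1):
        offspring = []
        for _ in range(cfg.offspring_per_epoch):
            pa, pb = (population[int(i)] for i in rng.choice(
                len(population), size=2, replace=False
            ))
            child, op = recombine(
                pa.sequence.residues, pb.sequence.residues, rng,
                cfg.splice_probability, cfg.max_child_length,
                cfg.min_child_length,
            )
            child = mutate(child, cfg.mutation_rate, rng)
            child = refine(child, cfg.refine_steps, model, rng,
                           cfg.refine_temperature)
            cid = _hex_id(rng, epoch)
            try:
                structure = backends.structure_predictor(child, cid)
                burial = burial_fraction(structure)
            except Exception as exc:
                logger.warning("offspring %s dropped (backend failure: %s)",
                               cid, exc)
                continue
            offspring.append(Individual(
                id=cid,
                sequence=ProteinSequence(cid, child),
                structure=structure,
                burial=burial,
                lineage=((pa.id, pb.id), op, epoch),
                epoch=epoch,
            ))
        archive.extend(offspring)
        new_novel_ids = []
        for ind in offspring:
            call = annotate_individual(ind)
            if call is not None and call.novel and _is_new_cluster(
                ind, novel_reps, cfg.tm_threshold
            ):
                novel_reps.append((ind.id, ind.structure))
                new_novel_ids.append(ind.id)
        pool = population + offspring
        population = stochastic_select(pool, cfg.population_size, rng)
        records.append(EpochRecord(
            epoch=epoch,
            mean_burial=float(np.mean([i.burial.value for i in population])),
            cumulative_unique_cath=len(unique_cath),
            cumulative_novel=len(novel_reps),
            new_novel_ids=new_novel_ids,
        ))
    return GAResult(records=records, population=population,
                    archive=archive, annotations=annotations)


def _is_new_cluster(ind: Individual, novel_reps: list, threshold: float) -> bool:
    """Arrival-order greedy clustering: a novel candidate founds a new
    cluster only if below the TM threshold to every existing founder."""
    for _, rep_structure in novel_reps:
        if sliding_window_tm(ind.structure, rep_structure) >= threshold:
            return False
    return True


def cumulative_census(
    archive: list,
    annotations: dict,
    pairwise_tm=None,
    tm_threshold: float = 0.5,
) -> list:
    """Per-epoch cumulative counts of unique CATH-annotated folds (CAT
    level) and novel cluster representatives.

    ``pairwise_tm(id_a, id_b)`` de-redundifies novel candidates by
    arrival-order greedy clustering; with None, every novel candidate
    counts as its own cluster. Counters are non-decreasing by construction.
    """
    for ind in archive:
        if ind.id not in annotations:
            raise ValueError(f"individual {ind.id} has no annotation")
    by_epoch: dict = {}
    for ind in archive:
        by_epoch.setdefault(ind.epoch, []).append(ind)
    unique_cath: set = set()
    novel_reps: list = []
    out = []
    for epoch in sorted(by_epoch):
        for ind in sorted(by_epoch[epoch], key=lambda i: i.id):
            call = annotations[ind.id]
            if call.assigned_label is not None:
                unique_cath.add(cath_prefix(call.assigned_label, "CAT"))
            if call.novel:
                is_new = True
                if pairwise_tm is not None:
                    for rep_id in novel_reps:
                        if pairwise_tm(ind.id, rep_id) >= tm_threshold:
                            is_new = False
                            break
                if is_new:
                    novel_reps.append(ind.id)
        out.append((epoch, len(unique_cath), len(novel_reps)))
    return out


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def records_table(records) -> str:
    lines = ["epoch\tmean_burial\tcumulative_unique_cath\tcumulative_novel\tnew_novel_ids"]
    for r in records:
        lines.append(
            f"{r.epoch}\t{r.mean_burial:.4f}\t{r.cumulative_unique_cath}\t"
            f"{r.cumulative_novel}\t{','.join(r.new_novel_ids)}"
        )
    return "\n".join(lines) + "\n"


def lineage_json(archive) -> str:
    return json.dumps({
        ind.id: {
            "parents": list(ind.lineage[0]),
            "operator": ind.lineage[1],
            "epoch": ind.epoch,
        }
        for ind in archive
    }, indent=1)
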