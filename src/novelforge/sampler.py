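"""Composite sequence-energy model and replica-exchange Metropolis MCMC.

The energy of a sequence combines two adapter-supplied signals — mean
per-residue log-likelihood under a protein language model and structural
contact density of the predicted fold — as

    E(s) = −w_lik · L̄(s) − w_con · C(s),

so lower energy means a more language-model-plausible, more contact-dense
sequence. Sampling is single-mutation Metropolis, optionally across a
ladder of temperatures with periodic neighbour replica swaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .structio import AMINO_ACIDS, ProteinSequence


@dataclass
class EnergyModel:
    likelihood_scorer: Callable[[str], float]
    contact_scorer: Callable[[str], float]
    likelihood_weight: float = 1.0
    contact_weight: float = 1.0

    def __post_init__(self):
        if self.likelihood_weight < 0 or self.contact_weight < 0:
            raise ValueError("energy weights must be non-negative")


@dataclass
class SamplerConfig:
    """Replica-exchange run settings. Temperatures must be strictly
    ascending, one per replica; default ladder is geometric over [1, 4]."""

    n_replicas: int = 4
    temperatures: tuple = ()
    steps_per_replica: int = 500
    swap_interval: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if not self.temperatures:
            if self.n_replicas == 1:
                self.temperatures = (1.0,)
            else:
                self.temperatures = tuple(
                    float(t) for t in np.geomspace(1.0, 4.0, self.n_replicas)
                )
        self.temperatures = tuple(float(t) for t in self.temperatures)
        if len(self.temperatures) != self.n_replicas:
            raise ValueError("need one temperature per replica")
        if any(t <= 0 for t in self.temperatures):
            raise ValueError("temperatures must be positive")
        if any(b <= a for a, b in zip(self.temperatures, self.temperatures[1:])):
            raise ValueError("temperatures must be strictly ascending")
        if self.swap_interval < 1:
            raise ValueError("swap_interval must be >= 1")


@dataclass
class Trajectory:
    per_replica: list            # one list of (step, sequence, energy) per replica
    swap_log: list               # (step, (i, j), accepted)
    best: tuple                  # (sequence, energy)


def composite_energy(seq: ProteinSequence | str, model: EnergyModel) -> float:
    """E = −w_lik·L̄ − w_con·C; lower is better."""
    s = seq.residues if isinstance(seq, ProteinSequence) else seq
    if model.likelihood_weight == 0.0 and model.contact_weight == 0.0:
        return 0.0
    try:
        lik = model.likelihood_scorer(s) if model.likelihood_weight else 0.0
        con = model.contact_scorer(s) if model.contact_weight else 0.0
    except Exception as exc:
        sid = seq.id if isinstance(seq, ProteinSequence) else s[:12]
        raise RuntimeError(f"scorer failure for sequence {sid!r}: {exc}") from exc
    e = -model.likelihood_weight * lik - model.contact_weight * con
    if not math.isfinite(e):
        sid = seq.id if isinstance(seq, ProteinSequence) else s[:12]
        raise RuntimeError(f"non-finite energy for sequence {sid!r}")
    return e


def random_sequence(length: int, rng: np.random.Generator,
                    alphabet: str = AMINO_ACIDS) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def propose_mutation(seq: str, rng: np.random.Generator,
                     alphabet: str = AMINO_ACIDS) -> str:
    """Single substitution: uniform position, uniform over the other
    |alphabet|−1 letters (self-mutation excluded)."""
    pos = int(rng.integers(len(seq)))
    options = [a for a in alphabet if a != seq[pos]]
    new = options[int(rng.integers(len(options)))]
    return seq[:pos] + new + seq[pos + 1:]


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(−ΔE/T))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / temperature)


def metropolis_step(
    state: tuple,
    temperature: float,
    model: EnergyModel,
    rng: np.random.Generator,
    alphabet: str = AMINO_ACIDS,
) -> tuple:
    """One single-mutation Metropolis step.

    Returns ((sequence, energy), accepted).
    """
    seq, energy = state
    proposal = propose_mutation(seq, rng, alphabet)
    e_new = composite_energy(proposal, model)
    if metropolis_accept(e_new - energy, temperature, rng):
        return (proposal, e_new), True
    return (seq, energy), False


def replica_swap_probability(ei: float, ej: float, ti: float, tj: float) -> float:
    """Acceptance probability for exchanging states between replicas at
    temperatures ti < tj: min(1, exp((1/ti − 1/tj)(ei − ej)))."""
    if ti <= 0 or tj <= 0:
        raise ValueError("temperatures must be positive")
    arg = (1.0 / ti - 1.0 / tj) * (ei - ej)
    if arg >= 0:
        return 1.0
    return math.exp(arg)


def run_remc(
    start: ProteinSequence | str | int,
    cfg: SamplerConfig,
    model: EnergyModel,
    alphabet: str = AMINO_ACIDS,
    record_interval: int = 1,
) -> Trajectory:
    """Replica-exchange MCMC over sequence space.

    ``start`` may be a sequence (all replicas start there) or an integer
    length (each replica starts from an independent random sequence).
    Neighbour swaps are attempted every ``swap_interval`` steps,
    alternating even and odd pairs. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_replicas
    if isinstance(start, int):
        seqs = [random_sequence(start, rng, alphabet) for _ in range(n)]
    else:
        s0 = start.residues if isinstance(start, ProteinSequence) else start
        seqs = [s0] * n
    states = [(s, composite_energy(s, model)) for s in seqs]
    best = min(states, key=lambda se: se[1])
    per_replica = [[(0, s, e)] for s, e in states]
    swap_log = []
    for step in range(1, cfg.steps_per_replica + 1):
        for r in range(n):
            states[r], _ = metropolis_step(
                states[r], cfg.temperatures[r], model, rng, alphabet
            )
            if states[r][1] < best[1]:
                best = states[r]
            if step % record_interval == 0:
                per_replica[r].append((step, states[r][0], states[r][1]))
        if n > 1 and step % cfg.swap_interval == 0:
            parity = (step // cfg.swap_interval) % 2
            for i in range(parity, n - 1, 2):
                p = replica_swap_probability(
                    states[i][1], states[i + 1][1],
                    cfg.temperatures[i], cfg.temperatures[i + 1],
                )
                accepted = rng.random() < p
                if accepted:
                    states[i], states[i + 1] = states[i + 1], states[i]
                swap_log.append((step, (i, i + 1), accepted))
    return Trajectory(per_replica=per_replica, swap_log=swap_log, best=best)


def trajectory_jsonl(traj: Trajectory) -> str:
    """Serialize a trajectory as JSON-lines (one record per state)."""
    import json

    lines = []
    for r, records in enumerate(traj.per_replica):
        for step, seq, e in records:
            lines.append(json.dumps(
                {"replica": r, "step": step, "sequence": seq, "energy": e}
            ))
    for step, pair, acc in traj.swap_log:
        lines.append(json.dumps(
            {"swap_step": step, "pair": list(pair), "accepted": bool(acc)}
        ))
    lines.append(json.dumps(
        {"best_sequence": traj.best[0], "best_energy": traj.best[1]}
    ))
    return "\n".join(lines) + "\n"
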