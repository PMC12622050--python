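"""Structure-first foldtuning: iterative enrichment for novel compact folds.

Each round, the current generative sequence model emits a batch of
sequences (default 10,000 at top_k 950, temperature 1.5); predicted
structures are filtered for compactness (burial fraction > 0.5) and CATH
non-assignability (no reference hit with TM-score > 0.5). Survivors are
ranked by descending burial fraction and the most compact (default 100)
become the finetuning set for the next round's model. Over rounds the
generator is steered toward compact, structurally unassignable output.

Also provides the (top_k, temperature) hyperparameter-scan harness used to
characterize the base model before foldtuning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotate import cath_prefix, novelty_call
from .structio import burial_fraction
from .surrogates import BackendSuite

logger = logging.getLogger(__name__)


@dataclass
class RoundConfig:
    n_samples: int = 10_000
    top_n: int = 100
    top_k: int = 950
    temperature: float = 1.5
    compactness_threshold: float = 0.5
    tm_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.top_n > self.n_samples:
            raise ValueError("top_n must be <= n_samples")


@dataclass
class RoundReport:
    round: int
    mean_burial: float
    n_novel: int
    n_cath: int
    structural_hit_rate: float
    selected_ids: list


@dataclass
class CampaignSummary:
    pooled_novel: int
    total_generated: int
    novel_percent: float


@dataclass
class ScanCell:
    top_k: int
    temperature: float
    n_cath_unique: int
    n_cat_unique: int
    frac_no_cath: float
    frac_compact: float
    frac_both: float


def _evaluate_batch(sequences, ids, cfg, backends):
    """Predict, measure burial, and annotate one generated batch.

    Returns (calls, burials) keyed by id, skipping (with a warning) any
    sequence whose backend evaluation fails.
    """
    calls, burials = {}, {}
    for sid, seq in zip(ids, sequences):
        try:
            structure = backends.structure_predictor(seq, sid)
            b = burial_fraction(structure)
            hits = backends.search_engine(structure)
        except Exception as exc:
            logger.warning("sample %s dropped (backend failure: %s)", sid, exc)
            continue
        calls[sid] = novelty_call(
            sid, b, hits,
            tm_threshold=cfg.tm_threshold,
            compactness_threshold=cfg.compactness_threshold,
        )
        burials[sid] = b.value
    return calls, burials


def run_round(
    generator_state,
    cfg: RoundConfig,
    backends: BackendSuite,
    round_index: int = 1,
):
    """One foldtuning round: generate → filter → rank → finetune.

    Sample ids are ``{round}_{i}`` (e.g. ``2_385``). If fewer than
    ``top_n`` candidates survive the novelty filter, finetuning uses all
    survivors and a warning is logged.

    Returns (RoundReport, sequences_by_id, new_generator_state).
    """
    gen = backends.sequence_generator
    seqs = gen.sample(generator_state, cfg.n_samples, cfg.top_k,
                      cfg.temperature, cfg.seed)
    ids = [f"{round_index}_{i}" for i in range(len(seqs))]
    seq_by_id = dict(zip(ids, seqs))
    calls, burials = _evaluate_batch(seqs, ids, cfg, backends)

    novel_ids = [sid for sid, c in calls.items() if c.novel]
    novel_ids.sort(key=lambda sid: (-burials[sid], sid))
    if len(novel_ids) < cfg.top_n:
        logger.warning(
            "round %d: only %d novel candidates for a finetuning set of %d",
            round_index, len(novel_ids), cfg.top_n,
        )
    selected = novel_ids[:cfg.top_n]
    new_state = gen.finetune(generator_state, [seq_by_id[s] for s in selected])

    n_assigned = sum(1 for c in calls.values() if c.assigned_label is not None)
    report = RoundReport(
        round=round_index,
        mean_burial=float(np.mean(list(burials.values()))) if burials else 0.0,
        n_novel=len(novel_ids),
        n_cath=n_assigned,
        structural_hit_rate=n_assigned / cfg.n_samples,
        selected_ids=selected,
    )
    return report, seq_by_id, new_state


def run_campaign(
    cfg: RoundConfig,
    backends: BackendSuite,
    rounds: int = 5,
    initial_state=None,
):
    """Thread the generator state through ``rounds`` foldtuning rounds.

    Per-round seeds are derived from ``cfg.seed``. Returns
    (reports, CampaignSummary, final_state).
    """
    from dataclasses import replace

    from .annotate import discovery_rate

    gen = backends.sequence_generator
    state = gen.initial_state() if initial_state is None else initial_state
    reports = []
    for r in range(1, rounds + 1):
        round_cfg = replace(cfg, seed=cfg.seed + 1009 * r)
        report, _, state = run_round(state, round_cfg, backends, round_index=r)
        reports.append(report)
    pooled = sum(rep.n_novel for rep in reports)
    total = cfg.n_samples * rounds
    summary = CampaignSummary(
        pooled_novel=pooled,
        total_generated=total,
        novel_percent=discovery_rate(pooled, total).percent if total else 0.0,
    )
    return reports, summary, state


def hyperparam_scan(
    grid,
    n_per_cell: int,
    backends: BackendSuite,
    cfg: RoundConfig | None = None,
    initial_state=None,
) -> list:
    """Evaluate the base generator over a (top_k, temperature) grid.

    Per cell: number of unique CATH (superfamily) and CAT (fold) labels
    among assigned samples, fraction with no CATH assignment, fraction
    compact, and the novelty rate — the fraction that is both compact and
    unassigned.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    cfg = cfg or RoundConfig(n_samples=n_per_cell, top_n=1)
    gen = backends.sequence_generator
    state = gen.initial_state() if initial_state is None else initial_state
    cells = []
    for cell_idx, (top_k, temperature) in enumerate(grid):
        seqs = gen.sample(state, n_per_cell, top_k, temperature,
                          cfg.seed + 31 * cell_idx)
        ids = [f"scan{cell_idx}_{i}" for i in range(len(seqs))]
        calls, _ = _evaluate_batch(seqs, ids, cfg, backends)
        n = len(calls)
        if n == 0:
            raise RuntimeError(f"empty scan cell (top_k={top_k}, T={temperature})")
        assigned = [c.assigned_label for c in calls.values()
                    if c.assigned_label is not None]
        n_no_cath = n - len(assigned)
        n_compact = sum(1 for c in calls.values() if c.compact)
        n_both = sum(1 for c in calls.values() if c.novel)
        cells.append(ScanCell(
            top_k=top_k,
            temperature=temperature,
            n_cath_unique=len({cath_prefix(lb, "CATH") for lb in assigned}),
            n_cat_unique=len({cath_prefix(lb, "CAT") for lb in assigned}),
            frac_no_cath=n_no_cath / n,
            frac_compact=n_compact / n,
            frac_both=n_both / n,
        ))
    return cells


def reports_table(reports) -> str:
    """TSV of round reports (columns mirror the campaign summary table)."""
    lines = ["round\tmean_burial\tn_novel\tn_cath\tstructural_hit_rate"]
    for r in reports:
        lines.append(
            f"{r.round}\t{r.mean_burial:.4f}\t{r.n_novel}\t{r.n_cath}\t"
            f"{r.structural_hit_rate:.4f}"
        )
    return "\n".join(lines) + "\n"


def scan_table(cells) -> str:
    lines = ["top_k\ttemperature\tn_cath_unique\tn_cat_unique\tfrac_no_cath\tfrac_compact\tfrac_both"]
    for c in cells:
        lines.append(
            f"{c.top_k}\t{c.temperature}\t{c.n_cath_unique}\t{c.n_cat_unique}\t"
            f"{c.frac_no_cath:.4f}\t{c.frac_compact:.4f}\t{c.frac_both:.4f}"
        )
    return "\n".join(lines) + "\n"
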