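"""Inverse-folding funnel landscapes and their classification.

To judge whether a putative novel fold is a plausible stable native state,
many sequences are designed onto its backbone (inverse folding), their
structures re-predicted, energies estimated, and similarity to the
template measured as a TM-score. A realizable fold shows a funnel: lower
per-residue energy associates with higher TM-score and no low-TM/low-energy
"trapped" subpopulation. Pathological shapes — an off-target minimum, a
multi-minimum landscape, or a flat (uncorrelated) cloud — warn of folding
problems. The traditionally by-eye verdict is made quantitative here via
a fixed rule table over four rank-based metrics; all constants are
exposed in :class:`FunnelParams`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .structio import ProteinStructure, tm_score_fixed_alignment
from .surrogates import BackendSuite

logger = logging.getLogger(__name__)

ENERGY_THRESHOLD = -2.2     # REU per residue, strict upper bound to pass
TM_THRESHOLD = 0.5          # strict lower bound to pass


@dataclass(frozen=True)
class FunnelPoint:
    design_id: str
    energy_per_residue: float
    tm_to_template: float

    @property
    def passes(self) -> bool:
        return pass_filter(self)


@dataclass
class FunnelLandscape:
    template_id: str
    points: list                  # FunnelPoint, post-clustering representatives
    n_initial: int = 200
    identity_threshold: float = 0.60


@dataclass
class FunnelParams:
    """Classifier constants (see classify_funnel for the rule table)."""

    low_energy_percentile: float = 25.0
    tm_bin_width: float = 0.1
    mode_min_points: int = 3
    flat_rho_limit: float = 0.15
    funnel_rho_limit: float = -0.3
    trapped_limit: float = 0.1
    off_target_tm: float = 0.5
    min_points: int = 10


@dataclass(frozen=True)
class FunnelVerdict:
    classification: str           # funnel | multi_minimum | off_target_minimum
                                  # | flat | ambiguous | insufficient
    spearman_rho: float
    trapped_fraction: float
    low_energy_tm_modes: int
    pass_fraction: float


def sequence_identity(a: str, b: str) -> float:
    """Exact-match fraction over equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must be equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def cluster_by_identity(seqs, threshold: float = 0.60) -> list:
    """Greedy redundancy reduction for equal-length design sets.

    In input order, the first ungrouped sequence founds a cluster and
    absorbs all later ungrouped sequences with identity ≥ threshold to it.
    Returns the founder indices (representatives).
    """
    n = len(seqs)
    if n == 0:
        return []
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("all design sequences must have equal length")
    representatives = []
    grouped = [False] * n
    for i in range(n):
        if grouped[i]:
            continue
        representatives.append(i)
        grouped[i] = True
        for j in range(i + 1, n):
            if not grouped[j] and sequence_identity(seqs[i], seqs[j]) >= threshold:
                grouped[j] = True
    return representatives


def pass_filter(p: FunnelPoint) -> bool:
    """Strict thresholds: E < −2.2 REU/aa and TM > 0.5."""
    return (p.energy_per_residue < ENERGY_THRESHOLD
            and p.tm_to_template > TM_THRESHOLD)


def build_landscape(
    template: ProteinStructure,
    backends: BackendSuite,
    n: int = 200,
    seed: int = 0,
    identity_threshold: float = 0.60,
) -> FunnelLandscape:
    """Sample n inverse-folded designs off the template, cluster at the
    identity threshold, and evaluate each representative: predicted
    structure, per-residue energy, and fixed-alignment TM to the template.
    Designs whose backend evaluation fails are dropped with a warning."""
    designs = backends.inverse_folder(template, n, seed)
    reps = cluster_by_identity(designs, identity_threshold)
    points = []
    L = template.length
    for i in reps:
        did = f"{template.id}_d{i}"
        try:
            structure = backends.structure_predictor(designs[i], did)
            energy = backends.energy_scorer(structure) / L
            tm = tm_score_fixed_alignment(structure, template).value
        except Exception as exc:
            logger.warning("design %s dropped (backend failure: %s)", did, exc)
            continue
        points.append(FunnelPoint(did, energy, tm))
    return FunnelLandscape(
        template_id=template.id,
        points=points,
        n_initial=n,
        identity_threshold=identity_threshold,
    )


def _tm_histogram_modes(tms: np.ndarray, bin_width: float,
                        min_points: int) -> int:
    """Count modes of the TM histogram: bins strictly greater than both
    neighbours (absent neighbours count as empty) with at least
    ``min_points`` points."""
    n_bins = int(np.ceil(1.0 / bin_width))
    counts, _ = np.histogram(tms, bins=n_bins, range=(0.0, 1.0 + 1e-12))
    padded = np.concatenate([[0], counts, [0]])
    modes = 0
    for k in range(1, len(padded) - 1):
        if (padded[k] > padded[k - 1] and padded[k] > padded[k + 1]
                and padded[k] >= min_points):
            modes += 1
    return modes


def classify_funnel(
    land: FunnelLandscape,
    params: FunnelParams | None = None,
) -> FunnelVerdict:
    """Classify a landscape via the fixed rule table.

    Metrics: Spearman ρ between energy and TM; the low-energy subset
    (energies at or below the 25th percentile); its trapped fraction
    (TM < 0.5); and its TM-histogram mode count. Rules applied in order:

    1. off_target_minimum — median TM of the low-energy subset < 0.5;
    2. multi_minimum — ≥ 2 TM modes in the low-energy subset;
    3. flat — |ρ| < 0.15 (all-equal energies are flat by convention);
    4. funnel — ρ ≤ −0.3 and trapped fraction < 0.1;
    5. ambiguous — anything else.

    Landscapes with fewer than 10 points are reported as "insufficient".
    Rank-based metrics make the verdict invariant to point ordering and to
    monotone affine rescaling of energies.
    """
    params = params or FunnelParams()
    points = land.points
    pass_fraction = (
        float(np.mean([p.passes for p in points])) if points else 0.0
    )
    if len(points) < params.min_points:
        return FunnelVerdict("insufficient", float("nan"), float("nan"),
                             0, pass_fraction)
    energies = np.array([p.energy_per_residue for p in points])
    tms = np.array([p.tm_to_template for p in points])

    degenerate = np.ptp(energies) == 0.0
    if degenerate:
        rho = 0.0
    else:
        rho = float(spearmanr(energies, tms).statistic)
        if not np.isfinite(rho):   # e.g. all-equal TM values
            rho = 0.0

    e_cut = np.percentile(energies, params.low_energy_percentile)
    low = tms[energies <= e_cut]
    trapped = float(np.mean(low < TM_THRESHOLD))
    modes = _tm_histogram_modes(low, params.tm_bin_width, params.mode_min_points)

    if degenerate:
        cls = "flat"
    elif float(np.median(low)) < params.off_target_tm:
        cls = "off_target_minimum"
    elif modes >= 2:
        cls = "multi_minimum"
    elif abs(rho) < params.flat_rho_limit:
        cls = "flat"
    elif rho <= params.funnel_rho_limit and trapped < params.trapped_limit:
        cls = "funnel"
    else:
        cls = "ambiguous"
    return FunnelVerdict(cls, rho, trapped, modes, pass_fraction)


def landscape_table(land: FunnelLandscape) -> str:
    lines = ["design_id\tenergy_per_residue\ttm_to_template\tpasses"]
    for p in land.points:
        lines.append(
            f"{p.design_id}\t{p.energy_per_residue:.4f}\t"
            f"{p.tm_to_template:.4f}\t{int(p.passes)}"
        )
    return "\n".join(lines) + "\n"


def verdict_json(verdict: FunnelVerdict) -> str:
    return json.dumps({
        "classification": verdict.classification,
        "spearman_rho": verdict.spearman_rho,
        "trapped_fraction": verdict.trapped_fraction,
        "low_energy_tm_modes": verdict.low_energy_tm_modes,
        "pass_fraction": verdict.pass_fraction,
    }, indent=1)
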