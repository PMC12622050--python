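"""Structure and sequence I/O, solvent accessibility, and structure comparison.

This module supplies the geometric substrate for compactness-driven fold
discovery: single-chain PDB and FASTA round-tripping, a deterministic
Shrake–Rupley solvent-accessible surface area (SASA), the burial fraction
(the compactness/globularity proxy used as the selective signal throughout
the package), Kabsch superposition, and a fixed-alignment TM-score for
equal-length structure pairs.

Conventions: coordinates in Å, residue indices 1-based, one chain per
structure, hydrogens ignored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Element-keyed van der Waals radii (Å); hydrogens are dropped at parse.
ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

# Theoretical maximum per-residue accessible surface area (Å²) on the
# Gly-X-Gly tripeptide reference scale (Tien-style theoretical values).
# The burial-fraction reference state is the sum of these over the chain:
# composition-dependent, conformation-independent.
MAX_ASA_GLY_X_GLY = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


class StructureError(ValueError):
    """Raised for malformed or unsupported structure input."""


@dataclass(frozen=True)
class ProteinSequence:
    """A canonical amino-acid sequence. X and other non-canonical letters
    are rejected at construction."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"{self.id}: non-canonical residue letter(s) {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ProteinStructure:
    """Single-chain atomic model.

    Atom arrays are aligned: ``res_index`` (1-based, contiguous 1..L),
    ``atom_names``, ``elements``, ``coords`` (N×3 Å), ``radii`` (Å).
    ``per_residue_confidence`` optionally carries pLDDT-like values in
    [0, 100].
    """

    id: str
    sequence: ProteinSequence
    res_index: np.ndarray
    atom_names: list
    elements: list
    coords: np.ndarray
    radii: np.ndarray
    per_residue_confidence: np.ndarray | None = None

    def __post_init__(self):
        self.res_index = np.asarray(self.res_index, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float)
        L = self.sequence.length
        present = np.unique(self.res_index)
        if not np.array_equal(present, np.arange(1, L + 1)):
            raise StructureError(
                f"{self.id}: residue indices must be contiguous 1..{L}; "
                f"found {present.min()}..{present.max()} "
                f"covering {present.size} residues"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"{self.id}: non-finite coordinates")
        if not np.all(self.radii > 0):
            raise StructureError(f"{self.id}: non-positive atom radius")
        if self.per_residue_confidence is not None:
            conf = np.asarray(self.per_residue_confidence, dtype=float)
            if conf.shape != (L,):
                raise StructureError(f"{self.id}: confidence length != L")
            self.per_residue_confidence = conf

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def length(self) -> int:
        return self.sequence.length

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates ordered by residue index; error if any missing."""
        out = np.full((self.length, 3), np.nan)
        for i, name in enumerate(self.atom_names):
            if name == "CA":
                out[self.res_index[i] - 1] = self.coords[i]
        if np.any(np.isnan(out)):
            missing = np.where(np.isnan(out[:, 0]))[0] + 1
            raise StructureError(
                f"{self.id}: missing CA for residue(s) {missing.tolist()}"
            )
        return out


@dataclass(frozen=True)
class SasaResult:
    per_atom_area: np.ndarray
    per_residue_area: np.ndarray
    total: float


@dataclass(frozen=True)
class BurialFraction:
    """1 − folded SASA / reference SASA, clamped to [0, 1]."""

    value: float
    folded_sasa: float
    reference_sasa: float


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass(frozen=True)
class TmScore:
    value: float
    d0: float
    aligned_length: int


# ---------------------------------------------------------------------------
# PDB and FASTA I/O
# ---------------------------------------------------------------------------

def parse_structure(text: str, structure_id: str = "structure") -> ProteinStructure:
    """Parse a single-chain PDB string into a :class:`ProteinStructure`.

    Residues are renumbered 1..L in file order. Insertion codes are
    rejected; for alternate locations the highest-occupancy altloc is kept
    (ties broken toward altloc 'A', then lexicographically). Hydrogens are
    dropped; remaining elements must be in the radius table.
    """
    pdb = PDBFile.read(io.StringIO(text))
    try:
        atoms = pdb.get_structure(
            model=1, altloc="all", extra_fields=["occupancy", "b_factor"]
        )
    except Exception as exc:  # biotite raises on malformed records
        raise StructureError(f"{structure_id}: unparseable PDB input: {exc}")
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise StructureError(f"{structure_id}: no ATOM records")
    chains = sorted(set(atoms.chain_id.tolist()))
    if len(chains) > 1:
        raise StructureError(
            f"{structure_id}: multi-chain input not supported; "
            f"found chains {{{', '.join(chains)}}}"
        )
    if np.any(atoms.ins_code != ""):
        raise StructureError(f"{structure_id}: insertion codes not supported")
    atoms = atoms[atoms.element != "H"]

    # altloc selection: per (res_id, atom_name) keep highest occupancy,
    # ties resolved toward 'A' / lexicographically smallest altloc id
    keep = np.ones(atoms.array_length(), dtype=bool)
    groups: dict = {}
    for i in range(atoms.array_length()):
        groups.setdefault((atoms.res_id[i], atoms.atom_name[i]), []).append(i)
    for idxs in groups.values():
        if len(idxs) > 1:
            best = min(
                idxs,
                key=lambda i: (-atoms.occupancy[i], atoms.altloc_id[i]),
            )
            for i in idxs:
                keep[i] = i == best
    atoms = atoms[keep]

    # renumber residues 1..L in file order
    res_ids = atoms.res_id
    order: list = []
    seen = set()
    for rid in res_ids.tolist():
        if rid not in seen:
            seen.add(rid)
            order.append(rid)
    renumber = {rid: k + 1 for k, rid in enumerate(order)}
    res_index = np.array([renumber[rid] for rid in res_ids.tolist()])

    letters = []
    for rid in order:
        name = atoms.res_name[res_ids == rid][0]
        if name not in THREE_TO_ONE:
            raise StructureError(
                f"{structure_id}: non-canonical residue {name} (res {rid})"
            )
        letters.append(THREE_TO_ONE[name])

    radii = np.empty(atoms.array_length())
    for i, el in enumerate(atoms.element.tolist()):
        if el not in ELEMENT_RADII:
            raise StructureError(f"{structure_id}: unknown element {el!r}")
        radii[i] = ELEMENT_RADII[el]

    conf = None
    if np.any(atoms.b_factor != 0.0):
        conf = np.array(
            [float(np.mean(atoms.b_factor[res_index == k + 1]))
             for k in range(len(order))]
        )
        if np.any(conf < 0) or np.any(conf > 100):
            conf = None

    return ProteinStructure(
        id=structure_id,
        sequence=ProteinSequence(structure_id, "".join(letters)),
        res_index=res_index,
        atom_names=atoms.atom_name.tolist(),
        elements=atoms.element.tolist(),
        coords=atoms.coord.copy(),
        radii=radii,
        per_residue_confidence=conf,
    )


def write_structure(s: ProteinStructure, chain_id: str = "A") -> str:
    """Serialize to PDB text (ATOM/TER/END, fixed columns)."""
    import biotite.structure as struc

    arr = struc.AtomArray(s.n_atoms)
    arr.coord = s.coords
    arr.chain_id[:] = chain_id
    arr.res_id = s.res_index
    arr.res_name = np.array(
        [ONE_TO_THREE[s.sequence.residues[i - 1]] for i in s.res_index]
    )
    arr.atom_name = np.array(s.atom_names)
    arr.element = np.array(s.elements)
    arr.hetero[:] = False
    arr.set_annotation("occupancy", np.ones(s.n_atoms))
    if s.per_residue_confidence is not None:
        arr.set_annotation(
            "b_factor", s.per_residue_confidence[s.res_index - 1]
        )
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def read_fasta(text: str) -> list:
    """Parse FASTA text into ProteinSequence records."""
    records = SeqIO.parse(io.StringIO(text), "fasta")
    return [ProteinSequence(r.id, str(r.seq)) for r in records]


def write_fasta(seqs, wrap: int = 60) -> str:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    buf = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=wrap)
    writer.write_file(records)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# SASA and burial fraction
# ---------------------------------------------------------------------------

def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²).

    Rolls a probe of ``probe_radius`` over atomic spheres; each atom's
    accessible area is the fraction of a deterministic golden-spiral test
    point set on its expanded sphere not occluded by any neighbour,
    times 4π(r+probe)².
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates in SASA input")
    if np.any(radii <= 0):
        raise ValueError("atom radii must be positive")
    if n_sphere_points < 92:
        raise ValueError("n_sphere_points must be >= 92")
    n = len(coords)
    expanded = radii + probe_radius
    sphere = golden_spiral_points(n_sphere_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    neighbor_lists = tree.query_ball_point(coords, expanded + max_r)
    areas = np.empty(n)
    from scipy.spatial.distance import cdist

    for i in range(n):
        neigh = np.array([j for j in neighbor_lists[i] if j != i], dtype=int)
        if neigh.size:
            mask = (
                np.linalg.norm(coords[neigh] - coords[i], axis=1)
                < expanded[i] + expanded[neigh]
            )
            neigh = neigh[mask]
        if neigh.size:
            pts = coords[i] + expanded[i] * sphere
            d = cdist(pts, coords[neigh])
            buried = (d < expanded[neigh][None, :]).any(axis=1)
            exposed = int((~buried).sum())
        else:
            exposed = n_sphere_points
        areas[i] = exposed / n_sphere_points * 4.0 * np.pi * expanded[i] ** 2
    return areas


def shrake_rupley_sasa(
    s: ProteinStructure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> SasaResult:
    """SASA of a structure, with per-atom and per-residue breakdown."""
    per_atom = shrake_rupley(s.coords, s.radii, probe_radius, n_sphere_points)
    per_res = np.array(
        [per_atom[s.res_index == k].sum() for k in range(1, s.length + 1)]
    )
    return SasaResult(per_atom, per_res, float(per_atom.sum()))


CA_VIRTUAL_BOND = 3.8  # Å, Cα–Cα spacing used by the pseudo-atom reference


def _ca_trimer_reference(radius: float, probe_radius: float) -> float:
    """Per-residue reference area for Cα-pseudo-atom models: the exposed
    area of the middle sphere in a linear trimer at Cα–Cα spacing — the
    single-sphere analog of the Gly-X-Gly tripeptide reference."""
    R = radius + probe_radius
    area = 4.0 * np.pi * R * R
    h = R - CA_VIRTUAL_BOND / 2.0
    if h > 0:
        area -= 2.0 * (2.0 * np.pi * R * h)
    return float(area)


def burial_fraction(
    s: ProteinStructure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> BurialFraction:
    """Fraction of the chain's reference (fully-accessible) surface area
    buried in the folded state.

    For all-atom models the reference is the sum over residues of the
    tabulated Gly-X-Gly theoretical maximum accessible area; for
    single-pseudo-atom-per-residue (Cα-only surrogate) models it is the
    analytic linear-trimer exposed area per residue. Both references are
    conformation-independent, so the value measures compactness of the
    fold, clamped to [0, 1].
    """
    if s.length < 2:
        raise ValueError(f"{s.id}: burial fraction requires L >= 2")
    ca_only = (
        s.n_atoms == s.length
        and all(name == "CA" for name in s.atom_names)
    )
    if ca_only:
        ref = sum(
            _ca_trimer_reference(r, probe_radius) for r in s.radii
        )
    else:
        ref = 0.0
        for aa in s.sequence.residues:
            if aa not in MAX_ASA_GLY_X_GLY:
                raise ValueError(f"{s.id}: no reference area for residue {aa!r}")
            ref += MAX_ASA_GLY_X_GLY[aa]
    folded = shrake_rupley_sasa(s, probe_radius, n_sphere_points).total
    value = min(1.0, max(0.0, 1.0 - folded / ref))
    return BurialFraction(value=value, folded_sasa=folded, reference_sasa=ref)


# ---------------------------------------------------------------------------
# Superposition and TM-score
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``target``
    (Kabsch, reflection-corrected)."""
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    if mobile.shape != target.shape:
        raise ValueError(
            f"coordinate sets differ in length: {len(mobile)} vs {len(target)}"
        )
    if len(mobile) < 3:
        raise ValueError("superposition requires >= 3 points")
    if not (np.all(np.isfinite(mobile)) and np.all(np.isfinite(target))):
        raise ValueError("non-finite coordinates")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(((moved - target) ** 2).sum() / len(mobile)))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def tm_d0(length: int) -> float:
    """Length-dependent TM-score normalization distance, floored at 0.5 Å."""
    if length > 15:
        return max(1.24 * (length - 15) ** (1.0 / 3.0) - 1.8, 0.5)
    return 0.5


def tm_score_fixed_alignment(
    query: ProteinStructure | np.ndarray,
    template: ProteinStructure | np.ndarray,
    d0_reference_length: int | None = None,
    seed_stride: int = 1,
) -> TmScore:
    """TM-score for an equal-length residue-i ↔ residue-i correspondence.

    Uses the standard seed-fragment iteration: for seed windows of length
    L, L/2, L/4, … 4 at every start position, superpose on the seed, then
    iteratively re-superpose on the subset of residues closer than a
    distance cutoff until the subset is stable; the reported score is the
    maximum over all seeds of (1/L)·Σ 1/(1+(dᵢ/d0)²) evaluated over all
    residues. Deterministic.

    ``seed_stride`` > 1 subsamples the seed start positions (a faster
    search over the same objective; the result is then a lower bound on
    the stride-1 score and usually equal to it).
    """
    q = query.ca_coords() if isinstance(query, ProteinStructure) else np.asarray(query, float)
    t = template.ca_coords() if isinstance(template, ProteinStructure) else np.asarray(template, float)
    if len(q) != len(t):
        raise ValueError(f"length mismatch: {len(q)} vs {len(t)}")
    L = len(q)
    if L < 3:
        raise ValueError("TM-score requires length >= 3")
    d0 = tm_d0(L if d0_reference_length is None else d0_reference_length)
    d0_sq = d0 * d0

    def score_from_subset(idx: np.ndarray) -> tuple[float, np.ndarray]:
        sup = kabsch_superpose(q[idx], t[idx])
        moved = q @ sup.rotation.T + sup.translation
        d_sq = ((moved - t) ** 2).sum(axis=1)
        return float(np.mean(1.0 / (1.0 + d_sq / d0_sq))), d_sq

    best = 0.0
    seed_len = L
    seed_lengths = []
    while seed_len >= 4:
        seed_lengths.append(seed_len)
        seed_len //= 2
    if not seed_lengths:
        seed_lengths = [L]
    for sl in seed_lengths:
        for start in range(0, L - sl + 1, max(1, seed_stride)):
            subset = np.arange(start, start + sl)
            prev: np.ndarray | None = None
            for _ in range(20):
                if len(subset) < 3:
                    break
                tm, d_sq = score_from_subset(subset)
                best = max(best, tm)
                cut = d0
                new = np.where(d_sq < cut * cut)[0]
                while len(new) < 3:
                    cut += 0.5
                    new = np.where(d_sq < cut * cut)[0]
                if prev is not None and np.array_equal(new, prev):
                    break
                prev = subset
                subset = new
    return TmScore(value=min(best, 1.0), d0=d0, aligned_length=L)


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def burial_table(entries) -> str:
    """TSV of (id, burial, folded_sasa, reference_sasa) rows."""
    lines = ["id\tburial_fraction\tfolded_sasa\treference_sasa"]
    for sid, b in entries:
        lines.append(
            f"{sid}\t{b.value:.4f}\t{b.folded_sasa:.2f}\t{b.reference_sasa:.2f}"
        )
    return "\n".join(lines) + "\n"
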