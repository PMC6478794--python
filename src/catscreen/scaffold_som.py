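"""Scaffold-diversity analysis and SOM-based hit selection.

Screened hit lists are characterized structurally by Bemis-Murcko
scaffolds (ring systems plus the linkers between them, all terminal
R-groups removed) and by carbon skeletons (scaffolds with every
heteroatom turned into carbon and every bond made single, so that
topologically equivalent ring frameworks collapse together).

For the final pick, hits and the known highly active compounds are
co-projected onto a small self-organizing map trained on CATS
descriptors; hits landing in grid cells that also contain known actives
occupy the same pharmacophore neighborhoods and are selected
greedily, cell by cell, preferring unseen scaffolds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .core_chem import Molecule
from .errors import ContractError, ValidationError

__all__ = [
    "ScaffoldRecord",
    "murcko_scaffold",
    "carbon_skeleton",
    "count_unique_scaffolds",
    "SomGrid",
    "SomProjection",
    "train_som",
    "project",
    "select_hits_by_som",
]


@dataclass(frozen=True)
class ScaffoldRecord:
    molecule_id: str
    scaffold_smiles: str  # "" for acyclic molecules
    skeleton_smiles: str


def murcko_scaffold(mol: Molecule | Chem.Mol | str) -> str:
    """Bemis-Murcko scaffold as canonical SMILES ("" if acyclic)."""
    if isinstance(mol, str):
        m = Chem.MolFromSmiles(mol)
        if m is None:
            raise ValidationError(f"unparseable SMILES: {mol!r}")
    else:
        m = mol.mol if isinstance(mol, Molecule) else mol
    scaffold = MurckoScaffold.GetScaffoldForMol(m)
    return Chem.MolToSmiles(scaffold) if scaffold.GetNumAtoms() else ""


def carbon_skeleton(scaffold_smiles: str) -> str:
    """Carbon skeleton: every heteroatom becomes carbon, every bond single.

    Aromaticity is dropped and hydrogens re-derived; the empty scaffold
    maps to the empty skeleton.
    """
    if not scaffold_smiles:
        return ""
    m = Chem.MolFromSmiles(scaffold_smiles)
    if m is None:
        raise ValidationError(f"unparseable scaffold SMILES: {scaffold_smiles!r}")
    rw = Chem.RWMol(m)
    for atom in rw.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetFormalCharge(0)
        atom.SetIsAromatic(False)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
        atom.SetNumRadicalElectrons(0)
    for bond in rw.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def count_unique_scaffolds(
    mols: Sequence[Molecule],
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Per-scaffold and per-skeleton occurrence counts.

    Ordered by count descending then SMILES ascending (deterministic).
    """
    scaffold_counts: dict[str, int] = {}
    skeleton_counts: dict[str, int] = {}
    for m in mols:
        sc = murcko_scaffold(m)
        sk = carbon_skeleton(sc)
        scaffold_counts[sc] = scaffold_counts.get(sc, 0) + 1
        skeleton_counts[sk] = skeleton_counts.get(sk, 0) + 1

    def ordered(counts):
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

    return ordered(scaffold_counts), ordered(skeleton_counts)


@dataclass
class SomGrid:
    """A trained Kohonen map: rows x cols prototype vectors.

    Cell coordinates are 1-based (row, col), matching the usual
    "cluster (r/c)" labeling of SOM plots.
    """

    rows: int
    cols: int
    codebook: np.ndarray  # (rows*cols, dim)
    metadata: dict = field(default_factory=dict)

    def cell_coords(self, flat: int) -> tuple[int, int]:
        return flat // self.cols + 1, flat % self.cols + 1

    def bmu(self, X: np.ndarray) -> np.ndarray:
        """Best-matching (nearest-prototype) flat cell index per row."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.codebook.shape[1]:
            raise ContractError(
                f"feature dimension {X.shape[1]} does not match codebook "
                f"{self.codebook.shape[1]}"
            )
        d2 = ((X[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def quantization_error(self, X: np.ndarray) -> float:
        """Mean Euclidean distance of samples to their best-matching unit."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        bmus = self.bmu(X)
        return float(np.linalg.norm(X - self.codebook[bmus], axis=1).mean())


def train_som(
    X: np.ndarray,
    rows: int = 3,
    cols: int = 5,
    epochs: int = 1000,
    learning_rate: float = 0.5,
    seed: int = 0,
) -> SomGrid:
    """Train a Kohonen self-organizing map.

    Online training: samples are presented in a seeded shuffled order;
    each step moves the best-matching unit and its Gaussian neighborhood
    toward the sample.  The learning rate decays linearly from its initial
    value to 0; the neighborhood radius decays exponentially from
    max(rows, cols)/2 to ~0.3 cells.  The codebook is initialized
    uniformly at random within the per-feature data range.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, dim = X.shape
    if n < rows * cols:
        warnings.warn(
            f"{n} samples for {rows * cols} cells; map will be sparse",
            stacklevel=2,
        )
    if np.allclose(X.std(axis=0), 0) and n > 1:
        raise ValidationError("zero-variance input; SOM training aborted")

    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    codebook = rng.uniform(lo, hi, size=(rows * cols, dim))
    grid = np.array([(i // cols, i % cols) for i in range(rows * cols)], dtype=float)
    grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(axis=2)

    sigma0 = max(rows, cols) / 2.0
    sigma_end = 0.3
    total = epochs * n
    t = 0
    for _ in range(epochs):
        for idx in rng.permutation(n):
            x = X[idx]
            frac = t / total
            lr = learning_rate * (1.0 - frac)
            sigma = sigma0 * (sigma_end / sigma0) ** frac
            bmu = int(((codebook - x) ** 2).sum(axis=1).argmin())
            h = np.exp(-grid_d2[bmu] / (2.0 * sigma**2))
            codebook += (lr * h)[:, None] * (x - codebook)
            t += 1
    return SomGrid(
        rows=rows,
        cols=cols,
        codebook=codebook,
        metadata={
            "epochs": epochs,
            "learning_rate": learning_rate,
            "sigma0": sigma0,
            "sigma_end": sigma_end,
            "seed": seed,
        },
    )


@dataclass
class SomProjection:
    """Cell assignments for a set of molecules, split by cohort."""

    cells: dict[str, int]  # molecule id -> flat cell index
    cohorts: dict[str, str]  # molecule id -> cohort label
    occupancy: dict[int, dict[str, int]]  # flat cell -> cohort -> count


def project(
    som: SomGrid,
    X: np.ndarray,
    ids: Sequence[str],
    cohorts: Sequence[str],
) -> SomProjection:
    """Assign each vector to its nearest map cell; tally per-cell cohorts."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not (len(ids) == len(cohorts) == X.shape[0]):
        raise ContractError("ids, cohorts and rows must align")
    bmus = som.bmu(X)
    occupancy: dict[int, dict[str, int]] = {}
    for cell, cohort in zip(bmus, cohorts):
        occupancy.setdefault(int(cell), {}).setdefault(cohort, 0)
        occupancy[int(cell)][cohort] += 1
    return SomProjection(
        cells={i: int(c) for i, c in zip(ids, bmus)},
        cohorts=dict(zip(ids, cohorts)),
        occupancy=occupancy,
    )


def select_hits_by_som(
    projection: SomProjection,
    predicted_pactivity: dict[str, float],
    scaffolds: dict[str, str],
    n_select: int,
    positive_cohort: str = "positive",
    hit_cohort: str = "hit",
) -> list[str]:
    """Pick hits that co-localize with known actives on the map.

    Eligible hits sit in cells containing at least one positive-cohort
    member.  Selection walks the eligible cells round-robin (cells in flat
    index order) and in each visit takes the hit with the highest
    predicted pActivity, preferring scaffolds not selected yet whenever the
    cell still offers one, until ``n_select`` picks or exhaustion.
    Deterministic: ties break on (higher pActivity, id).
    """
    eligible_cells = sorted(
        c for c, occ in projection.occupancy.items()
        if occ.get(positive_cohort, 0) >= 1
    )
    per_cell: dict[int, list[str]] = {c: [] for c in eligible_cells}
    for mol_id, cell in projection.cells.items():
        if projection.cohorts[mol_id] == hit_cohort and cell in per_cell:
            per_cell[cell].append(mol_id)
    for c in per_cell:
        per_cell[c].sort(key=lambda i: (-predicted_pactivity.get(i, -np.inf), i))

    if not any(per_cell.values()):
        warnings.warn("no hits share a cell with the positive cohort", stacklevel=2)
        return []

    selected: list[str] = []
    used_scaffolds: set[str] = set()
    while len(selected) < n_select:
        progressed = False
        for cell in eligible_cells:
            if len(selected) >= n_select:
                break
            pool = per_cell[cell]
            if not pool:
                continue
            fresh = [i for i in pool if scaffolds.get(i, "") not in used_scaffolds]
            pick = fresh[0] if fresh else pool[0]
            pool.remove(pick)
            selected.append(pick)
            used_scaffolds.add(scaffolds.get(pick, ""))
            progressed = True
        if not progressed:
            break
    return selected
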