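"""Molecule ingestion and standardization ("washing").

Raw structures from vendor catalogues or bioactivity databases arrive as
salts, mixtures and inconsistent protonation states.  Before any descriptor
is computed every molecule is washed: metal–ligand bonds in simple salts are
disconnected, the largest organic fragment is kept, strong acids are
deprotonated and strong bases protonated.  The acid/base perception is a
SMARTS rule table shipped as package data (``data/wash_rules.yaml``) so the
chemistry can be audited and edited without touching code.

The module also provides the topological (bond-count) distance matrix that
the CATS descriptor is built on.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import (
    ConfigurationError,
    DegenerateMoleculeError,
    EmptyLibraryError,
    ParseError,
)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "WashReport",
    "standardize_molecule",
    "read_library",
    "topological_distance_matrix",
]


@dataclass(frozen=True)
class Molecule:
    """A standardized, single-fragment molecule.

    ``smiles_canonical`` is authoritative: the molecule can always be
    re-built from it.  ``source`` records provenance (file and record
    number) for audit trails.
    """

    id: str
    smiles_canonical: str
    source: str = ""
    _mol: Chem.Mol = field(default=None, repr=False, compare=False, hash=False)

    @property
    def mol(self) -> Chem.Mol:
        """The parsed RDKit molecule (re-parsed from canonical SMILES if
        the cached graph is missing)."""
        if self._mol is not None:
            return self._mol
        m = Chem.MolFromSmiles(self.smiles_canonical)
        if m is None:  # pragma: no cover - canonical SMILES always re-parse
            raise ParseError(self.smiles_canonical)
        return m

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()


@dataclass
class WashReport:
    """Book-keeping for a library wash: counts and per-molecule actions."""

    n_input: int = 0
    n_kept: int = 0
    n_failed_parse: int = 0
    actions: list[tuple[str, list[str]]] = field(default_factory=list)

    def record(self, mol_id: str, applied: list[str]) -> None:
        self.actions.append((mol_id, applied))


def _load_wash_rules() -> dict:
    with resources.files("catscreen.data").joinpath("wash_rules.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    compiled = {"deprotonate": [], "protonate": []}
    for kind in ("deprotonate", "protonate"):
        for rule in raw[kind]:
            patt = Chem.MolFromSmarts(rule["smarts"])
            if patt is None:  # pragma: no cover - shipped rules are valid
                raise ConfigurationError(f"bad SMARTS in wash rule {rule['name']}")
            compiled[kind].append((rule["name"], patt))
    return compiled


_WASH_RULES: dict | None = None


def _wash_rules() -> dict:
    global _WASH_RULES
    if _WASH_RULES is None:
        _WASH_RULES = _load_wash_rules()
    return _WASH_RULES


_METAL_DISCONNECTOR = rdMolStandardize.MetalDisconnector()


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep one fragment: organic (contains carbon) preferred, then most
    heavy atoms, then most atoms overall, then smallest canonical SMILES.
    The lexicographic tail makes fragment choice deterministic."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        raise DegenerateMoleculeError(Chem.MolToSmiles(mol))

    def key(f: Chem.Mol):
        has_c = any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
        return (
            not has_c,
            -f.GetNumHeavyAtoms(),
            -f.GetNumAtoms(),
            Chem.MolToSmiles(f),
        )

    return sorted(frags, key=key)[0]


def _apply_protonation_rules(mol: Chem.Mol) -> tuple[Chem.Mol, list[str]]:
    rw = Chem.RWMol(mol)
    applied: list[str] = []
    touched: set[int] = set()
    for name, patt in _wash_rules()["deprotonate"]:
        for match in rw.GetMol().GetSubstructMatches(patt):
            idx = match[0]
            if idx in touched:
                continue
            atom = rw.GetAtomWithIdx(idx)
            if atom.GetFormalCharge() != 0 or atom.GetTotalNumHs() < 1:
                continue
            atom.SetFormalCharge(-1)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() - 1)
            atom.SetNoImplicit(True)
            touched.add(idx)
            applied.append(f"deprotonate:{name}")
    for name, patt in _wash_rules()["protonate"]:
        for match in rw.GetMol().GetSubstructMatches(patt):
            idx = match[0]
            if idx in touched:
                continue
            atom = rw.GetAtomWithIdx(idx)
            if atom.GetFormalCharge() != 0:
                continue
            atom.SetFormalCharge(1)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
            atom.SetNoImplicit(True)
            touched.add(idx)
            applied.append(f"protonate:{name}")
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out, applied


def standardize_molecule(
    raw_smiles: str, mol_id: str = "", source: str = ""
) -> tuple[Molecule, list[str]]:
    """Wash one structure; returns the Molecule and the list of actions taken.

    Pipeline: parse → disconnect metals in simple salts → keep the largest
    organic fragment → deprotonate strong acids / protonate strong bases
    (rule table) → canonical SMILES.

    Raises
    ------
    ParseError
        if ``raw_smiles`` is empty or unparseable.
    DegenerateMoleculeError
        if nothing remains after fragment selection (e.g. a bare metal ion
        is the only organic-free fragment — kept, but an empty input graph
        is rejected).
    """
    if not raw_smiles or not raw_smiles.strip():
        raise ParseError(raw_smiles)
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise ParseError(raw_smiles)
    if mol.GetNumAtoms() == 0:
        raise DegenerateMoleculeError(raw_smiles)

    applied: list[str] = []
    n_frags = len(Chem.GetMolFrags(mol))
    disconnected = _METAL_DISCONNECTOR.Disconnect(mol)
    if len(Chem.GetMolFrags(disconnected)) > n_frags:
        applied.append("disconnect-metal")
    mol = disconnected

    if len(Chem.GetMolFrags(mol)) > 1:
        mol = _largest_organic_fragment(mol)
        applied.append("keep-largest-fragment")
    Chem.SanitizeMol(mol)

    mol, proto_actions = _apply_protonation_rules(mol)
    applied.extend(proto_actions)

    smiles = Chem.MolToSmiles(mol)
    if not smiles:
        raise DegenerateMoleculeError(raw_smiles)
    return Molecule(id=mol_id or smiles, smiles_canonical=smiles, source=source, _mol=mol), applied


def _iter_smiles_records(path: Path) -> Iterator[tuple[str, str]]:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{i}"
            yield smi, mol_id


def _iter_sdf_records(path: Path) -> Iterator[tuple[str, str]]:
    suppl = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(suppl, 1):
        if mol is None:
            yield "", f"record{i}"
            continue
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        yield Chem.MolToSmiles(mol), title or f"record{i}"


def _iter_csv_records(
    path: Path, smiles_col: str, id_col: str | None
) -> Iterator[tuple[str, str]]:
    with open(path, newline="") as fh:
        reader = _csv.DictReader(fh)
        if reader.fieldnames is None or smiles_col not in reader.fieldnames:
            raise ConfigurationError(
                f"CSV {path} lacks a '{smiles_col}' column"
            )
        for i, row in enumerate(reader, 1):
            mol_id = row.get(id_col, "") if id_col else ""
            yield row[smiles_col], mol_id or f"row{i}"


def read_library(
    path: str | Path,
    format: str = "smiles",
    smiles_col: str = "smiles",
    id_col: str | None = "id",
) -> tuple[list[Molecule], WashReport]:
    """Read and wash a molecule library.

    Parse failures are logged in the report, never fatal; an input with zero
    parseable records raises :class:`EmptyLibraryError`.
    """
    path = Path(path)
    if format == "smiles":
        records: Iterable[tuple[str, str]] = _iter_smiles_records(path)
    elif format == "sdf":
        records = _iter_sdf_records(path)
    elif format == "csv":
        records = _iter_csv_records(path, smiles_col, id_col)
    else:
        raise ConfigurationError(f"unknown library format: {format!r}")

    report = WashReport()
    mols: list[Molecule] = []
    for raw, mol_id in records:
        report.n_input += 1
        try:
            mol, actions = standardize_molecule(
                raw, mol_id=mol_id, source=f"{path.name}:{report.n_input}"
            )
        except (ParseError, DegenerateMoleculeError):
            report.n_failed_parse += 1
            report.record(mol_id, ["failed"])
            continue
        report.n_kept += 1
        report.record(mol_id, actions)
        mols.append(mol)
    if report.n_input > 0 and report.n_kept == 0:
        raise EmptyLibraryError(str(path))
    return mols, report


def topological_distance_matrix(mol: Molecule | Chem.Mol) -> np.ndarray:
    """Symmetric matrix of shortest-path bond counts between heavy atoms.

    Diagonal is 0; pairs in different fragments would be ``inf`` but cannot
    occur after standardization (single connected component).
    """
    m = mol.mol if isinstance(mol, Molecule) else mol
    if m.GetNumAtoms() < 1:
        raise DegenerateMoleculeError("empty molecule")
    d = Chem.GetDistanceMatrix(m).copy()
    d[d > 1e7] = np.inf  # RDKit encodes unreachable pairs as 1e8
    return d
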