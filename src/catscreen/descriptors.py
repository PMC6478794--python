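"""Molecular representations for QSAR modeling.

Three descriptor blocks are provided:

``CATS``
    The CATS2D topological pharmacophore descriptor, implemented here from
    its definition.  Every heavy atom is assigned a subset of six
    generalized types — hydrogen-bond donor (D), acceptor (A), positively
    charged (P), negatively charged (N), hydrophobe (H) and aromatic (R) —
    by a SMARTS rule table shipped as package data.  For every unordered
    pair of types (21 pairs with repetition) the number of atom pairs at
    each topological distance bin (10 bins) is counted, giving a
    210-dimensional vector.

``MACCS``
    The public 166-key MDL MACCS substructure fingerprint (RDKit).

``PHYS2D``
    An open block of 2D physicochemical and topological descriptors
    (RDKit): size, lipophilicity, H-bonding, polar surface area,
    flexibility, ring content, and connectivity/shape indices.  It stands
    where a proprietary 2D property block would in a commercial pipeline;
    exact parity with any vendor implementation is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, Lipinski, MACCSkeys, rdMolDescriptors

from .core_chem import Molecule, topological_distance_matrix
from .errors import ConfigurationError, EmptyLibraryError

__all__ = [
    "CATS_TYPES",
    "CATS_PAIRS",
    "N_CATS_BINS",
    "DescriptorMatrix",
    "assign_cats_types",
    "cats2d",
    "cats_feature_names",
    "maccs",
    "physchem2d",
    "phys2d_feature_names",
    "featurize_library",
]

N_CATS_BINS = 10


def _load_type_rules() -> tuple[list[str], dict[str, list[Chem.Mol]]]:
    with resources.files("catscreen.data").joinpath("cats_types.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    order = list(raw["type_order"])
    rules: dict[str, list[Chem.Mol]] = {}
    for t in order:
        patts = []
        for smarts in raw["types"][t]:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:  # pragma: no cover
                raise ConfigurationError(f"bad SMARTS for CATS type {t}: {smarts}")
            patts.append(patt)
        rules[t] = patts
    return order, rules


CATS_TYPES, _TYPE_RULES = _load_type_rules()

#: the 21 unordered type pairs (with repetition) in canonical order
CATS_PAIRS: list[tuple[str, str]] = [
    (CATS_TYPES[i], CATS_TYPES[j])
    for i in range(len(CATS_TYPES))
    for j in range(i, len(CATS_TYPES))
]

_PAIR_INDEX = {frozenset(p): k for k, p in enumerate(CATS_PAIRS)}


def assign_cats_types(mol: Molecule | Chem.Mol) -> list[set[str]]:
    """Per-heavy-atom sets of generalized pharmacophore types.

    Sets may be empty (e.g. an sp3 carbon next to oxygen) or carry several
    labels (a hydroxyl oxygen is both D and A).  Assignment is a pure
    function of the rule table.
    """
    m = mol.mol if isinstance(mol, Molecule) else mol
    types: list[set[str]] = [set() for _ in range(m.GetNumAtoms())]
    for t in CATS_TYPES:
        for patt in _TYPE_RULES[t]:
            for match in m.GetSubstructMatches(patt):
                types[match[0]].add(t)
    return types


def cats_feature_names(d_start: int = 0) -> list[str]:
    return [
        f"CATS_{t1}{t2}_{d}"
        for (t1, t2) in CATS_PAIRS
        for d in range(d_start, d_start + N_CATS_BINS)
    ]


def cats2d(
    mol: Molecule | Chem.Mol, scaled: bool = False, d_start: int = 0
) -> np.ndarray:
    """CATS2D vector: 21 type pairs x 10 topological distance bins = 210.

    Distances run from ``d_start`` to ``d_start + 9`` bonds (default 0..9;
    the d = 0 bin counts single atoms carrying both types of a pair).  Each
    unordered heavy-atom pair contributes at most once per distinct
    unordered type pair.  With ``scaled`` each type-pair slice is divided
    by the summed occurrence count of its two member types (slices whose
    types are absent stay zero).
    """
    m = mol.mol if isinstance(mol, Molecule) else mol
    types = assign_cats_types(m)
    dist = topological_distance_matrix(m)
    n = m.GetNumAtoms()
    vec = np.zeros((len(CATS_PAIRS), N_CATS_BINS))
    d_lo, d_hi = d_start, d_start + N_CATS_BINS - 1

    for i in range(n):
        # single-atom contribution: one atom carrying both types of a pair
        # sits at distance 0 from itself (distinct types only)
        if d_lo == 0 and len(types[i]) > 1:
            ts = sorted(types[i])
            for a in range(len(ts)):
                for b in range(a + 1, len(ts)):
                    vec[_PAIR_INDEX[frozenset((ts[a], ts[b]))], 0] += 1
        for j in range(i + 1, n):
            d = dist[i, j]
            if not (d_lo <= d <= d_hi):
                continue
            col = int(d) - d_start
            seen: set[frozenset] = set()
            for t1 in types[i]:
                for t2 in types[j]:
                    key = frozenset((t1, t2))
                    if key not in seen:
                        seen.add(key)
                        vec[_PAIR_INDEX[key], col] += 1

    if scaled:
        counts = {t: sum(1 for s in types if t in s) for t in CATS_TYPES}
        for k, (t1, t2) in enumerate(CATS_PAIRS):
            denom = counts[t1] + counts[t2]
            if denom > 0:
                vec[k] /= denom
    return vec.ravel()


def maccs(mol: Molecule | Chem.Mol) -> np.ndarray:
    """The 166 public MACCS keys as a 0/1 vector (RDKit's bit 0 placeholder
    is dropped)."""
    m = mol.mol if isinstance(mol, Molecule) else mol
    fp = MACCSkeys.GenMACCSKeys(m)
    arr = np.zeros(166, dtype=np.int8)
    for b in fp.GetOnBits():
        if b >= 1:
            arr[b - 1] = 1
    return arr


def maccs_feature_names() -> list[str]:
    return [f"MACCS_{k}" for k in range(1, 167)]


# name -> callable; order defines the PHYS2D column layout and is frozen
_PHYS2D: list[tuple[str, object]] = [
    ("MolWt", Descriptors.MolWt),
    ("LogP", Crippen.MolLogP),
    ("MolMR", Crippen.MolMR),
    ("HBD", Lipinski.NumHDonors),
    ("HBA", Lipinski.NumHAcceptors),
    ("TPSA", rdMolDescriptors.CalcTPSA),
    ("RotatableBonds", Lipinski.NumRotatableBonds),
    ("RingCount", rdMolDescriptors.CalcNumRings),
    ("AromaticRings", rdMolDescriptors.CalcNumAromaticRings),
    ("SaturatedRings", rdMolDescriptors.CalcNumSaturatedRings),
    ("AliphaticRings", rdMolDescriptors.CalcNumAliphaticRings),
    ("AromaticHeterocycles", rdMolDescriptors.CalcNumAromaticHeterocycles),
    ("HeavyAtoms", Lipinski.HeavyAtomCount),
    ("Heteroatoms", rdMolDescriptors.CalcNumHeteroatoms),
    ("FormalCharge", Chem.GetFormalCharge),
    ("NHOHCount", Lipinski.NHOHCount),
    ("NOCount", Lipinski.NOCount),
    ("FractionCSP3", rdMolDescriptors.CalcFractionCSP3),
    ("LabuteASA", rdMolDescriptors.CalcLabuteASA),
    ("BalabanJ", GraphDescriptors.BalabanJ),
    ("BertzCT", GraphDescriptors.BertzCT),
    ("HallKierAlpha", GraphDescriptors.HallKierAlpha),
    ("Kappa1", GraphDescriptors.Kappa1),
    ("Kappa2", GraphDescriptors.Kappa2),
    ("Kappa3", GraphDescriptors.Kappa3),
    ("Chi0", GraphDescriptors.Chi0),
    ("Chi1", GraphDescriptors.Chi1),
    ("Chi0n", GraphDescriptors.Chi0n),
    ("Chi1n", GraphDescriptors.Chi1n),
    ("Chi2n", GraphDescriptors.Chi2n),
    ("Chi0v", GraphDescriptors.Chi0v),
    ("Chi1v", GraphDescriptors.Chi1v),
    ("Chi2v", GraphDescriptors.Chi2v),
    ("Chi3v", GraphDescriptors.Chi3v),
    ("Chi4v", GraphDescriptors.Chi4v),
    ("ValenceElectrons", Descriptors.NumValenceElectrons),
]


def phys2d_feature_names() -> list[str]:
    return [name for name, _ in _PHYS2D]


def physchem2d(mol: Molecule | Chem.Mol) -> np.ndarray:
    """Open 2D physicochemical/topological descriptor block (no missing
    values; every function is defined for any sanitized molecule)."""
    m = mol.mol if isinstance(mol, Molecule) else mol
    return np.array([float(fn(m)) for _, fn in _PHYS2D])


@dataclass
class DescriptorMatrix:
    """A featurized library: row ids, named columns, and the block tag."""

    ids: list[str]
    feature_names: list[str]
    block: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.feature_names)):
            raise ConfigurationError(
                f"descriptor matrix shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.feature_names)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("descriptor matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "id", self.ids)
        return df


BLOCKS = ("CATS", "MACCS", "PHYS2D")


def featurize_library(
    mols: Iterable[Molecule],
    block: str = "CATS",
    cats_scaled: bool = False,
    cats_d_start: int = 0,
) -> DescriptorMatrix:
    """Featurize a molecule stream into one descriptor block.

    Row order follows input order; feature names are stable across runs.
    """
    block = block.upper()
    if block not in BLOCKS:
        raise ConfigurationError(f"unknown descriptor block: {block!r}")
    mols = list(mols)
    if not mols:
        raise EmptyLibraryError("no molecules to featurize")
    if block == "CATS":
        names = cats_feature_names(cats_d_start)
        rows = [cats2d(m, scaled=cats_scaled, d_start=cats_d_start) for m in mols]
    elif block == "MACCS":
        names = maccs_feature_names()
        rows = [maccs(m) for m in mols]
    else:
        names = phys2d_feature_names()
        rows = [physchem2d(m) for m in mols]
    return DescriptorMatrix(
        ids=[m.id for m in mols],
        feature_names=names,
        block=block,
        values=np.vstack(rows),
    )
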