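"""Curation of bioactivity tables into modeling datasets.

A raw activity table (compound id, SMILES, endpoint type, value in nM) is
turned into a modeling dataset in four steps: wash every structure,
average replicate measurements per unique structure (arithmetic mean on
the nM scale), label at the 100 nM potency threshold for classification
and log-transform (pActivity = 9 - log10(nM) = -log10 molar) for
regression, and split 80/20 by coverage of descriptor space
(Kennard-Stone max-min selection) so the training set spans the chemistry
of the whole collection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_chem import Molecule, standardize_molecule
from .descriptors import DescriptorMatrix
from .errors import ConfigurationError, ValidationError

__all__ = [
    "ENDPOINTS",
    "ActivityRecord",
    "QsarDataset",
    "aggregate_activities",
    "label_activity",
    "to_log_activity",
    "diversity_split",
    "curate_table",
]

ENDPOINTS = ("IC50", "Ki", "KD", "EC50")

ACTIVE_THRESHOLD_NM = 100.0


@dataclass(frozen=True)
class ActivityRecord:
    """One measured endpoint for one compound, in nM."""

    compound_id: str
    smiles: str
    endpoint: str
    value_nM: float

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(
                f"endpoint {self.endpoint!r} not in {ENDPOINTS}"
            )
        if not (self.value_nM > 0):
            raise ValidationError(f"value_nM must be > 0, got {self.value_nM}")


@dataclass
class QsarDataset:
    """Descriptor matrix plus classification labels and/or log-activities."""

    ids: list[str]
    X: DescriptorMatrix
    y_class: np.ndarray | None = None  # 1 = positive (highly active)
    y_reg: np.ndarray | None = None  # pActivity
    split_tag: str = "train"

    def __post_init__(self) -> None:
        if len(self.ids) != self.X.values.shape[0]:
            raise ConfigurationError("ids do not match descriptor rows")
        for y in (self.y_class, self.y_reg):
            if y is not None and len(y) != len(self.ids):
                raise ConfigurationError("labels do not match descriptor rows")
        if self.y_reg is not None and not np.all(np.isfinite(self.y_reg)):
            raise ValidationError("pActivity must be finite")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, idx: Sequence[int], split_tag: str | None = None) -> "QsarDataset":
        idx = list(idx)
        return QsarDataset(
            ids=[self.ids[i] for i in idx],
            X=DescriptorMatrix(
                ids=[self.ids[i] for i in idx],
                feature_names=self.X.feature_names,
                block=self.X.block,
                values=self.X.values[idx],
            ),
            y_class=None if self.y_class is None else self.y_class[idx],
            y_reg=None if self.y_reg is None else self.y_reg[idx],
            split_tag=split_tag or self.split_tag,
        )


def label_activity(value_nM: float, threshold_nM: float = ACTIVE_THRESHOLD_NM) -> str:
    """'positive' (highly active) iff value <= threshold; boundary inclusive."""
    if not (value_nM > 0):
        raise ValidationError(f"activity must be > 0 nM, got {value_nM}")
    return "positive" if value_nM <= threshold_nM else "negative"


def to_log_activity(value_nM: float) -> float:
    """pActivity = 9 - log10(value in nM), i.e. -log10 of the molar value."""
    if not (value_nM > 0):
        raise ValidationError(f"activity must be > 0 nM, got {value_nM}")
    return 9.0 - math.log10(value_nM)


def from_log_activity(pactivity: float) -> float:
    """Inverse of :func:`to_log_activity` (pActivity -> nM)."""
    return 10.0 ** (9.0 - pactivity)


@dataclass
class AggregatedActivity:
    """Mean activity for one unique washed structure, with provenance."""

    smiles_canonical: str
    value_nM: float
    records: list[ActivityRecord] = field(default_factory=list)

    @property
    def compound_id(self) -> str:
        return self.records[0].compound_id


def aggregate_activities(
    records: Iterable[ActivityRecord],
) -> list[AggregatedActivity]:
    """Average replicate measurements per unique canonical structure.

    The arithmetic mean is taken on the nM scale.  Measurements with
    different endpoint types (IC50/Ki/KD/EC50) for one structure are pooled
    with a warning — the curation deliberately does not convert between
    endpoint types.
    """
    by_struct: dict[str, list[ActivityRecord]] = {}
    order: list[str] = []
    for rec in records:
        mol, _ = standardize_molecule(rec.smiles, mol_id=rec.compound_id)
        key = mol.smiles_canonical
        if key not in by_struct:
            by_struct[key] = []
            order.append(key)
        by_struct[key].append(rec)
    out = []
    for key in order:
        recs = by_struct[key]
        if len({r.endpoint for r in recs}) > 1:
            warnings.warn(
                f"structure {key} has mixed endpoint types "
                f"{sorted({r.endpoint for r in recs})}; averaging anyway",
                stacklevel=2,
            )
        out.append(
            AggregatedActivity(
                smiles_canonical=key,
                value_nM=float(np.mean([r.value_nM for r in recs])),
                records=recs,
            )
        )
    return out


def _kennard_stone(X: np.ndarray, n_select: int, seed: int) -> np.ndarray:
    """Max-min (Kennard-Stone) selection on standardized descriptors.

    Starts from the two mutually most distant points, then repeatedly adds
    the point whose minimum distance to the selected set is largest.  Ties
    are broken by a seed-controlled random permutation applied up front, so
    the result is deterministic given the seed.
    """
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)  # fixes tie-break order
    Xp = X[perm]

    sd = Xp.std(axis=0, ddof=0)
    keep = sd > 0
    Z = (Xp[:, keep] - Xp[:, keep].mean(axis=0)) / sd[keep] if keep.any() else Xp

    # pairwise squared distances (N^2; fine for curated set sizes)
    sq = np.einsum("ij,ij->i", Z, Z)
    d2 = sq[:, None] + sq[None, :] - 2 * Z @ Z.T
    np.fill_diagonal(d2, -np.inf)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    np.fill_diagonal(d2, np.inf)

    selected = [i, j]
    in_sel = np.zeros(n, dtype=bool)
    in_sel[[i, j]] = True
    mind2 = np.minimum(d2[:, i], d2[:, j])
    while len(selected) < n_select:
        mind2[in_sel] = -np.inf
        k = int(np.argmax(mind2))
        selected.append(k)
        in_sel[k] = True
        mind2 = np.minimum(mind2, d2[:, k])
    return perm[np.array(selected[:n_select])]


def diversity_split(
    dataset: QsarDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[QsarDataset, QsarDataset]:
    """Split into train/test by chemical-space coverage.

    The training set of size ``floor(train_fraction * N)`` is chosen by
    Kennard-Stone max-min selection on the standardized descriptor matrix,
    so it spans the occupied descriptor space; the remainder is the test
    set.  Deterministic given the seed (which only breaks distance ties).
    """
    if not (0 < train_fraction < 1):
        raise ConfigurationError(f"train_fraction must be in (0,1), got {train_fraction}")
    n = len(dataset)
    if n < 5:
        raise ValidationError(f"need >= 5 compounds to split, got {n}")
    n_train = int(math.floor(train_fraction * n))
    train_idx = _kennard_stone(dataset.X.values, n_train, seed)
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    test_idx = np.flatnonzero(~mask)
    return (
        dataset.subset(list(train_idx), split_tag="train"),
        dataset.subset(list(test_idx), split_tag="test"),
    )


def curate_table(
    df: pd.DataFrame,
    smiles_col: str = "smiles",
    id_col: str = "id",
    endpoint_col: str = "endpoint",
    value_col: str = "value_nm",
) -> list[ActivityRecord]:
    """Parse a CSV/TSV activity table into validated records.

    Rows with unknown endpoint types or non-positive values are dropped
    (the curation rule: keep only explicit IC50/Ki/KD/EC50 measurements).
    """
    for col in (smiles_col, endpoint_col, value_col):
        if col not in df.columns:
            raise ConfigurationError(f"activity table lacks column {col!r}")
    records = []
    for i, row in df.iterrows():
        endpoint = str(row[endpoint_col]).strip()
        try:
            value = float(row[value_col])
        except (TypeError, ValueError):
            continue
        if endpoint not in ENDPOINTS or not value > 0:
            continue
        records.append(
            ActivityRecord(
                compound_id=str(row[id_col]) if id_col in df.columns else f"row{i}",
                smiles=str(row[smiles_col]),
                endpoint=endpoint,
                value_nM=value,
            )
        )
    return records
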