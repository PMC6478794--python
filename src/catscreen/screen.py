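"""The virtual-screening cascade.

A screening library passes through three gates:

1. drug-likeness — Lipinski profile (MW > 500, logP > 5, HBD > 5,
   HBA > 10); compounds violating more than two rules are removed;
2. classification — three RF classifiers (CATS, MACCS, PHYS2D blocks)
   each vote; by default the UNION of positive votes advances (any single
   model can rescue a compound, maximizing scaffold diversity);
3. regression — the RF regressor predicts pActivity; compounds at or
   above the cutoff (default 7.0 = 100 nM) are ranked descending.

Applicability-domain verdicts are attached for reporting and can
optionally act as a fourth filter.  The module also hosts the SPR
kinetics utility K_D = k_off / k_on used to characterize confirmed hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .core_chem import Molecule
from .descriptors import featurize_library
from .errors import ContractError, ValidationError
from .models import TrainedModel

__all__ = [
    "LipinskiProfile",
    "lipinski_violations",
    "drug_likeness_filter",
    "ScreenResult",
    "cascade_screen",
    "KineticsRecord",
    "compute_kd",
]


@dataclass(frozen=True)
class LipinskiProfile:
    MW: float
    logP: float
    HBD: int
    HBA: int

    @property
    def violations(self) -> int:
        return sum(
            [self.MW > 500, self.logP > 5, self.HBD > 5, self.HBA > 10]
        )


def lipinski_violations(mol: Molecule) -> LipinskiProfile:
    """Lipinski profile with an atom-contribution logP estimate."""
    m = mol.mol
    return LipinskiProfile(
        MW=Descriptors.MolWt(m),
        logP=Crippen.MolLogP(m),
        HBD=Lipinski.NumHDonors(m),
        HBA=Lipinski.NumHAcceptors(m),
    )


def drug_likeness_filter(
    library: Iterable[Molecule], max_violations: int = 2
) -> tuple[list[Molecule], dict[str, int]]:
    """Remove molecules violating more than ``max_violations`` Lipinski
    rules; returns survivors plus stage counts."""
    kept, dropped = [], 0
    for mol in library:
        if lipinski_violations(mol).violations <= max_violations:
            kept.append(mol)
        else:
            dropped += 1
    return kept, {"input": len(kept) + dropped, "kept": len(kept), "removed": dropped}


@dataclass
class ScreenResult:
    """Outcome of the full cascade on one library."""

    table: pd.DataFrame  # id, smiles, votes_*, union_hit, pred_pactivity, ad_verdict, rank
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def hits(self) -> pd.DataFrame:
        """Final ranked hit list (regression-stage survivors)."""
        return self.table[self.table["rank"].notna()].sort_values("rank")


_EMPTY_COLUMNS = [
    "id", "smiles", "vote_1", "vote_2", "vote_3", "union_hit",
    "pred_pactivity", "ad_verdict", "rank",
]


def cascade_screen(
    library: Sequence[Molecule],
    classifiers: Sequence[TrainedModel],
    regressor: TrainedModel,
    reg_cutoff_pactivity: float = 7.0,
    max_violations: int = 2,
    combine: str = "union",
    ad_filter: bool = False,
    top_n: int | None = None,
) -> ScreenResult:
    """Run the Lipinski -> classification -> regression cascade.

    ``combine`` is "union" (default: any positive vote advances) or
    "intersection".  ``top_n`` optionally replaces the pActivity cutoff by
    a fixed-size ranked hit list.  The library is deduplicated by
    canonical SMILES before screening, so concatenated duplicates yield
    each hit once.
    """
    if combine not in ("union", "intersection"):
        raise ValidationError(f"combine must be union|intersection, got {combine!r}")
    if regressor.kind != "regressor":
        raise ContractError("regression-stage model must be a regressor")
    for c in classifiers:
        if c.kind != "classifier":
            raise ContractError("classification-stage models must be classifiers")

    seen: set[str] = set()
    unique: list[Molecule] = []
    for m in library:
        if m.smiles_canonical not in seen:
            seen.add(m.smiles_canonical)
            unique.append(m)

    counts = {"input": len(unique)}
    survivors, lip = drug_likeness_filter(unique, max_violations)
    counts["post_lipinski"] = lip["kept"]
    if not survivors:
        return ScreenResult(
            table=pd.DataFrame(columns=_EMPTY_COLUMNS),
            stage_counts={**counts, "post_classification": 0, "post_regression": 0},
        )

    votes = np.zeros((len(survivors), len(classifiers)), dtype=bool)
    for j, clf in enumerate(classifiers):
        X = featurize_library(survivors, block=clf.block)
        votes[:, j] = clf.predict(X).astype(bool)
    union_hit = votes.any(axis=1) if combine == "union" else votes.all(axis=1)
    counts["post_classification"] = int(union_hit.sum())

    Xreg = featurize_library(survivors, block=regressor.block)
    pred = regressor.predict_score(Xreg)
    # AD from the regressor's stored training mean/SD (zero-variance
    # descriptors are ignored, mirroring applicability_domain's exclusion)
    sd = np.where(regressor.train_sd > 0, regressor.train_sd, np.inf)
    s = np.abs(regressor._align(Xreg) - regressor.train_mean) / sd
    ad_verdicts = []
    for row in s:
        finite = row[np.isfinite(row)]
        if finite.size == 0 or finite.max() <= 3.0:
            ad_verdicts.append("inside")
        elif finite.min() > 3.0:
            ad_verdicts.append("outside")
        else:
            snew = finite.mean() + 1.28 * finite.std(ddof=1)
            ad_verdicts.append("inside" if snew <= 3.0 else "outside")

    eligible = union_hit.copy()
    if ad_filter:
        eligible &= np.array([v == "inside" for v in ad_verdicts])
    passed_reg = eligible & (pred >= reg_cutoff_pactivity)

    table = pd.DataFrame(
        {
            "id": [m.id for m in survivors],
            "smiles": [m.smiles_canonical for m in survivors],
            **{f"vote_{j + 1}": votes[:, j] for j in range(len(classifiers))},
            "union_hit": union_hit,
            "pred_pactivity": pred,
            "ad_verdict": ad_verdicts,
            "rank": np.nan,
        }
    )
    hit_idx = np.flatnonzero(passed_reg)
    order = hit_idx[np.argsort(-pred[hit_idx], kind="stable")]
    if top_n is not None:
        order = order[:top_n]
    table.loc[table.index[order], "rank"] = np.arange(1, len(order) + 1)
    counts["post_regression"] = int(len(order))
    return ScreenResult(table=table, stage_counts=counts)


@dataclass(frozen=True)
class KineticsRecord:
    """SPR binding kinetics: association/dissociation rates and K_D."""

    k_on: float  # 1/(M*s)
    k_off: float  # 1/s

    @property
    def K_D(self) -> float:
        return self.k_off / self.k_on


def compute_kd(k_on: float, k_off: float) -> float:
    """Dissociation equilibrium constant K_D = k_off / k_on, in molar."""
    if not (k_on > 0 and k_off > 0):
        raise ValidationError("rate constants must be positive")
    return k_off / k_on
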