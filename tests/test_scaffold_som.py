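"""Bemis-Murcko scaffolds, carbon skeletons, and the SOM selection logic."""

import numpy as np
import pytest

from catscreen.core_chem import standardize_molecule
from catscreen.errors import ContractError, ValidationError
from catscreen.scaffold_som import (
    SomProjection,
    carbon_skeleton,
    count_unique_scaffolds,
    murcko_scaffold,
    project,
    select_hits_by_som,
    train_som,
)


def _mol(smiles, mol_id=""):
    return standardize_molecule(smiles, mol_id=mol_id)[0]


class TestScaffolds:
    @pytest.mark.parametrize(
        "smiles, scaffold",
        [
            ("Cc1ccccc1", "c1ccccc1"),  # toluene: methyl is an R-group
            ("CCC", ""),  # acyclic: empty scaffold
            ("c1ccc(CCc2ccccc2)cc1", "c1ccc(CCc2ccccc2)cc1"),  # linker kept
            ("OCc1ccncc1", "c1ccncc1"),
        ],
    )
    def test_murcko_examples(self, smiles, scaffold):
        assert murcko_scaffold(_mol(smiles)) == scaffold

    @pytest.mark.parametrize(
        "scaffold, skeleton",
        [
            ("c1ccncc1", "C1CCCCC1"),  # pyridine -> cyclohexane
            ("c1ccccc1", "C1CCCCC1"),  # benzene -> cyclohexane
            ("c1ccoc1", "C1CCCC1"),  # furan -> cyclopentane
            ("", ""),
        ],
    )
    def test_skeleton_examples(self, scaffold, skeleton):
        assert carbon_skeleton(scaffold) == skeleton

    def test_scaffold_idempotent(self, random_molecules):
        for mol in random_molecules[:40]:
            sc = murcko_scaffold(mol)
            if sc:
                assert murcko_scaffold(sc) == sc

    def test_skeleton_idempotent(self, random_molecules):
        for mol in random_molecules[:40]:
            sk = carbon_skeleton(murcko_scaffold(mol))
            assert carbon_skeleton(sk) == sk

    def test_count_unique_collapse(self):
        mols = [_mol("Cc1ccccc1"), _mol("CCc1ccccc1"), _mol("Oc1ccccc1")]
        scaffolds, skeletons = count_unique_scaffolds(mols)
        assert scaffolds == [("c1ccccc1", 3)]
        assert skeletons == [("C1CCCCC1", 3)]

    def test_skeletons_merge_scaffolds(self):
        scaffolds, skeletons = count_unique_scaffolds(
            [_mol("c1ccncc1"), _mol("c1ccccc1")]
        )
        assert len(scaffolds) == 2
        assert len(skeletons) == 1

    def test_empty_list(self):
        assert count_unique_scaffolds([]) == ([], [])

    def test_skeletons_never_outnumber_scaffolds(self, random_molecules):
        scaffolds, skeletons = count_unique_scaffolds(random_molecules)
        assert len(skeletons) <= len(scaffolds)


class TestSomTraining:
    def test_grid_size(self, rng):
        X = rng.normal(size=(60, 4))
        som = train_som(X, rows=3, cols=5, epochs=30, seed=0)
        assert som.codebook.shape == (15, 4)

    def test_single_sample_fixed_point(self):
        x = np.array([[2.0, -1.0, 0.5]])
        som = train_som(x, rows=2, cols=2, epochs=50, seed=0)
        np.testing.assert_allclose(som.codebook, np.tile(x, (4, 1)), atol=1e-6)

    def test_zero_variance_multisample_aborts(self):
        X = np.tile([[1.0, 2.0]], (10, 1))
        with pytest.raises(ValidationError):
            train_som(X, rows=2, cols=2, epochs=5, seed=0)

    def test_two_clusters_separate_on_two_cells(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.3, size=(30, 5)), rng.normal(6, 0.3, size=(30, 5))]
        )
        som = train_som(X, rows=2, cols=1, epochs=100, seed=1)
        bmus = som.bmu(X)
        assert len(set(bmus[:30])) == 1
        assert len(set(bmus[30:])) == 1
        assert bmus[0] != bmus[-1]

    def test_training_reduces_quantization_error(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.5, size=(40, 6)), rng.normal(5, 0.5, size=(40, 6))]
        )
        short = train_som(X, rows=3, cols=5, epochs=1, seed=2)
        full = train_som(X, rows=3, cols=5, epochs=150, seed=2)
        assert full.quantization_error(X) <= short.quantization_error(X)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 3))
        a = train_som(X, epochs=20, seed=9)
        b = train_som(X, epochs=20, seed=9)
        np.testing.assert_array_equal(a.codebook, b.codebook)


class TestProjection:
    def test_codebook_projects_to_own_cells(self, rng):
        X = rng.normal(size=(60, 4))
        som = train_som(X, rows=3, cols=5, epochs=30, seed=0)
        ids = [f"c{i}" for i in range(15)]
        proj = project(som, som.codebook, ids, ["positive"] * 15)
        assert sorted(proj.cells.values()) == list(range(15))

    def test_occupancy_conserves_cohort_sizes(self, rng):
        X = rng.normal(size=(50, 4))
        som = train_som(X, epochs=20, seed=0)
        cohorts = ["positive"] * 20 + ["hit"] * 30
        proj = project(som, X, [f"m{i}" for i in range(50)], cohorts)
        totals = {}
        for occ in proj.occupancy.values():
            for cohort, n in occ.items():
                totals[cohort] = totals.get(cohort, 0) + n
        assert totals == {"positive": 20, "hit": 30}

    def test_duplicated_input_doubles_occupancy(self, rng):
        X = rng.normal(size=(20, 3))
        som = train_som(X, epochs=20, seed=1)
        ids1 = [f"a{i}" for i in range(20)]
        ids2 = ids1 + [f"b{i}" for i in range(20)]
        p1 = project(som, X, ids1, ["hit"] * 20)
        p2 = project(som, np.vstack([X, X]), ids2, ["hit"] * 40)
        for cell, occ in p1.occupancy.items():
            assert p2.occupancy[cell]["hit"] == 2 * occ["hit"]

    def test_dimension_mismatch_rejected(self, rng):
        som = train_som(rng.normal(size=(20, 4)), epochs=5, seed=0)
        with pytest.raises(ContractError):
            som.bmu(rng.normal(size=(3, 5)))


def _manual_projection():
    """Two positive-occupied cells with 3 hits each, one positive-free cell."""
    cells = {
        "p1": 0, "p2": 1,
        "h1": 0, "h2": 0, "h3": 0,
        "h4": 1, "h5": 1, "h6": 1,
        "h7": 2,  # positive-free cell: never selectable
    }
    cohorts = {k: ("positive" if k.startswith("p") else "hit") for k in cells}
    occupancy = {}
    for mol_id, cell in cells.items():
        occupancy.setdefault(cell, {}).setdefault(cohorts[mol_id], 0)
        occupancy[cell][cohorts[mol_id]] += 1
    return SomProjection(cells=cells, cohorts=cohorts, occupancy=occupancy)


class TestHitSelection:
    PRED = {"h1": 9.0, "h2": 8.5, "h3": 8.0, "h4": 7.9, "h5": 7.5, "h6": 7.2, "h7": 9.9}
    SCAF = {"h1": "s1", "h2": "s2", "h3": "s3", "h4": "s4", "h5": "s5", "h6": "s6", "h7": "s7"}

    def test_round_robin_two_per_cell(self):
        sel = select_hits_by_som(_manual_projection(), self.PRED, self.SCAF, 4)
        assert sel == ["h1", "h4", "h2", "h5"]
        assert len({self.SCAF[i] for i in sel}) == 4

    def test_positive_free_cell_never_selected(self):
        sel = select_hits_by_som(_manual_projection(), self.PRED, self.SCAF, 10)
        assert "h7" not in sel
        assert len(sel) == 6  # eligibility exhausted before n_select

    def test_scaffold_diversity_preferred(self):
        scaf = dict(self.SCAF, h2="s1")  # h2 shares h1's scaffold
        sel = select_hits_by_som(_manual_projection(), self.PRED, scaf, 4)
        # cell 0's second pick skips h2 (scaffold s1 already used) for h3
        assert sel == ["h1", "h4", "h3", "h5"]

    def test_no_cooccupied_cells_warns_empty(self):
        proj = _manual_projection()
        proj.occupancy = {2: {"hit": 1}, 3: {"positive": 2}}
        proj.cells = {"h7": 2, "p1": 3, "p2": 3}
        proj.cohorts = {"h7": "hit", "p1": "positive", "p2": "positive"}
        with pytest.warns(UserWarning):
            assert select_hits_by_som(proj, self.PRED, self.SCAF, 3) == []

    def test_order_invariant(self):
        proj = _manual_projection()
        shuffled = SomProjection(
            cells=dict(reversed(list(proj.cells.items()))),
            cohorts=proj.cohorts,
            occupancy=proj.occupancy,
        )
        a = select_hits_by_som(proj, self.PRED, self.SCAF, 5)
        b = select_hits_by_som(shuffled, self.PRED, self.SCAF, 5)
        assert a == b
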