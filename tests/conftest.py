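"""Shared fixtures: small hand-built pedigrees and session-scoped
simulated founder populations (built once, reused across tests)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from founderlip.pedigree import (Pedigree, PedigreeRecord, RelatednessMatrix,
                                 kinship_matrix)
from founderlip.phenotypes import TraitMatrix
from founderlip.simulate import (SimConfig, _chol_psd, generation_of,
                                 simulate_pedigree)


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree([
        PedigreeRecord("F", None, None, "male"),
        PedigreeRecord("M", None, None, "female"),
        PedigreeRecord("C", "F", "M", "male"),
    ])


@pytest.fixture
def sib_family() -> Pedigree:
    """Two founders with four full-sib offspring."""
    recs = [PedigreeRecord("F", None, None, "male"),
            PedigreeRecord("M", None, None, "female")]
    recs += [PedigreeRecord(f"C{k}", "F", "M", "male") for k in range(4)]
    return Pedigree(recs)


@pytest.fixture
def double_first_cousins() -> Pedigree:
    """Two brothers married to two sisters; one child each."""
    recs = [PedigreeRecord(i, None, None, s) for i, s in
            [("A", "male"), ("B", "female"), ("C", "male"), ("D", "female")]]
    recs += [PedigreeRecord("S1", "A", "B", "male"),
             PedigreeRecord("S2", "A", "B", "male"),
             PedigreeRecord("T1", "C", "D", "female"),
             PedigreeRecord("T2", "C", "D", "female"),
             PedigreeRecord("X", "S1", "T1", "male"),
             PedigreeRecord("Y", "S2", "T2", "female")]
    return Pedigree(recs)


@pytest.fixture
def balanced_sib_pedigree() -> tuple[Pedigree, list[str]]:
    """50 independent full-sib families of size 4 (offspring listed)."""
    recs: list[PedigreeRecord] = []
    for f in range(50):
        recs += [PedigreeRecord(f"F{f}", None, None, "male"),
                 PedigreeRecord(f"M{f}", None, None, "female")]
        recs += [PedigreeRecord(f"C{f}_{k}", f"F{f}", f"M{f}", "male")
                 for k in range(4)]
    ped = Pedigree(recs)
    return ped, [r.iid for r in recs if r.father is not None]


class FounderPopulation:
    """A simulated pedigree with cached relatedness pieces."""

    def __init__(self, seed: int, n_founders: int, generations: int,
                 mean_sibship: float, n_subjects: int):
        self.cfg = SimConfig(seed=seed, n_founders=n_founders,
                             generations=generations,
                             mean_sibship=mean_sibship)
        self.ped = simulate_pedigree(self.cfg)
        last = max(generation_of(i) for i in self.ped.ids)
        pool = [i for i in self.ped.ids if generation_of(i) >= last - 1]
        if len(pool) < n_subjects:
            raise RuntimeError("fixture pedigree too small; adjust config")
        self.subjects = pool[:n_subjects]
        self.kinship = kinship_matrix(self.ped, self.subjects)
        self.additive = RelatednessMatrix(
            self.subjects, 2.0 * self.kinship.values, "additive")
        self.additive.eigen()  # warm the cache shared across tests
        self.chol_additive = _chol_psd(self.additive.values)

    @property
    def n(self) -> int:
        return len(self.subjects)

    def trait_matrix(self, traits: dict[str, np.ndarray],
                     prepared: bool = True) -> TraitMatrix:
        vals = pd.DataFrame(traits, index=pd.Index(self.subjects, name="id"))
        tm = TraitMatrix(vals, pd.DataFrame(index=vals.index))
        if prepared:
            tm.prepared = vals
        return tm


@pytest.fixture(scope="session")
def pop200() -> FounderPopulation:
    return FounderPopulation(seed=21, n_founders=70, generations=5,
                             mean_sibship=2.6, n_subjects=200)


@pytest.fixture(scope="session")
def pop600() -> FounderPopulation:
    return FounderPopulation(seed=33, n_founders=170, generations=6,
                             mean_sibship=2.6, n_subjects=600)
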