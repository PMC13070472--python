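"""Shared fixtures: small synthetic complexes, samples and models."""

from __future__ import annotations

import numpy as np
import pytest

from igmi import (IGMIModel, MutationSpec, SampleRecord, ToySpec,
                  make_dataset, make_mutant, make_toy_complex)
from igmi.config import ModelConfig
from igmi.structure import AtomRecord, ComplexStructure, ResidueRecord


def rigid_motion(structure: ComplexStructure, seed: int = 0,
                 scale: float = 10.0) -> ComplexStructure:
    """Apply a random proper rotation + translation to every atom."""
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(0.0, scale, 3)
    residues = [
        ResidueRecord(res.chain_id, res.resseq, res.icode, res.aa,
                      [AtomRecord(a.name, a.element, q @ a.coords + t)
                       for a in res.atoms])
        for res in structure.residues
    ]
    return ComplexStructure(residues, structure.partner_split)


def moved_sample(sample: SampleRecord, seed: int = 0) -> SampleRecord:
    """The same sample after one rigid motion of both structures."""
    return SampleRecord(rigid_motion(sample.wt, seed),
                        rigid_motion(sample.mut, seed),
                        sample.mutations, sample.ddg)


@pytest.fixture(scope="session")
def toy_complex() -> ComplexStructure:
    return make_toy_complex(ToySpec(n_per_chain=20, seed=7))


@pytest.fixture(scope="session")
def toy_sample() -> SampleRecord:
    return make_dataset(1, ToySpec(n_per_chain=20), seed=5)[0]


@pytest.fixture(scope="session")
def small_dataset() -> list[SampleRecord]:
    return make_dataset(6, ToySpec(n_per_chain=20), seed=11)


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    return ModelConfig.tiny()


@pytest.fixture(scope="session")
def tiny_model(tiny_config) -> IGMIModel:
    return IGMIModel(tiny_config, seed=0)


@pytest.fixture(scope="session")
def tiny_model_f64() -> IGMIModel:
    return IGMIModel(ModelConfig.tiny(dtype="float64"), seed=0)
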