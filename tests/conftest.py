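"""Shared fixtures: tiny literal matrices and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from yorigin.datamodel import (HaplotypeMatrix, MetadataTable, SampleMetadata,
                               Window)
from yorigin.simulate import ScenarioConfig, simulate_dataset


def make_matrix(alleles, hap_ids, positions=None, chromosome="chr1",
                ancestral=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    if positions is None:
        positions = np.arange(alleles.shape[0])
    return HaplotypeMatrix(chromosome, positions, alleles, hap_ids,
                           ancestral)


def diploid_metadata(spec: dict[str, tuple[str, str]]) -> MetadataTable:
    """{sample_id: (species, sex)} -> MetadataTable."""
    return MetadataTable(SampleMetadata(k, sp, sx)
                         for k, (sp, sx) in spec.items())


@pytest.fixture(scope="session")
def small_intro_ds():
    """Introgression scenario at reduced scale: 1-Mb sex chromosome and
    autosome, default sample sizes."""
    cfg = ScenarioConfig(chrom_length=1_000_000, autosome_length=1_000_000,
                         seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_nosdr_ds():
    cfg = ScenarioConfig(scenario="no_sdr", chrom_length=400_000,
                         autosome_length=2_000_000, seed=8)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
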