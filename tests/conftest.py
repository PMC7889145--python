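"""Shared fixtures: a small fast genome and a full default simulation.

All fixture data is generated programmatically; the session-scoped
``sim40`` dataset (default genome, 40x hemizygous simulation, fully
mapped) is shared across discovery and copy-number tests to keep the
suite fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from tglocus.align import InsertModel, KmerIndex, map_pairs
from tglocus.genome import (
    GenomeConfig,
    GenomeModel,
    apply_insertion,
    build_reference,
    default_construct,
)
from tglocus.pipeline import RunConfig, _stage_seeds, build_model
from tglocus.simreads import SimConfig, simulate_reads

# 42 genes so the 10% trimmed-mean baseline excludes the four
# transgene-amplified genes even at this scale
SMALL_CFG = GenomeConfig(chrom_length=50_000, n_genes=42, gene_length=500)


@pytest.fixture(scope="session")
def small_wild() -> GenomeModel:
    """50 kb wild-type toy genome (no insertion)."""
    return build_reference(SMALL_CFG, seed=11)


@pytest.fixture(scope="session")
def small_model() -> GenomeModel:
    """50 kb genome with the default construct (inverted tail) inserted."""
    wild = build_reference(SMALL_CFG, seed=11)
    construct = default_construct(SMALL_CFG, seed=11)
    return apply_insertion(wild, construct)


@pytest.fixture(scope="session")
def small_index(small_model) -> KmerIndex:
    return KmerIndex(small_model.reference)


@dataclass
class SimDataset:
    model: GenomeModel
    pairs: list
    truth: object
    index: KmerIndex
    records: list
    im: InsertModel
    cfg: RunConfig


def _simulate_and_map(cfg: RunConfig, depth: float, mix: float) -> SimDataset:
    model = build_model(cfg)
    _, _, read_seed = _stage_seeds(cfg.seed)
    sim = SimConfig(mean_depth=depth, haplotype_mix=mix, seed=read_seed)
    pairs, truth = simulate_reads(model, sim)
    index = KmerIndex(model.reference)
    im = cfg.insert_model
    records = map_pairs(pairs, index, im)
    return SimDataset(model, pairs, truth, index, records, im, cfg)


@pytest.fixture(scope="session")
def sim40() -> SimDataset:
    """Default genome, hemizygous 40x simulation, mapped and classified."""
    return _simulate_and_map(RunConfig(seed=7), depth=40.0, mix=0.5)


@pytest.fixture(scope="session")
def sim_wildtype() -> SimDataset:
    """Wild-type-only control: no fragments drawn from haplotype B."""
    cfg = RunConfig(genome=SMALL_CFG, seed=5)
    return _simulate_and_map(cfg, depth=20.0, mix=0.0)
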