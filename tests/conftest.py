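"""Shared fixtures.

The heavy simulated worlds are session-scoped: the default-scale world
(3 chromosomes x 2 Mb, 150 genes, 40 scaffolds, 5 chimeras, 1%
divergence, seed 42) is built once and shared by the end-to-end and
acceptance tests; unit tests use a small fast world.
"""

from __future__ import annotations

import pytest

from scaftier.pipeline import curate_scaffolds, place_scaffolds
from scaftier.sim import SimConfig, simulate_world


@pytest.fixture(scope="session")
def small_world():
    cfg = SimConfig(seed=11, n_chromosomes=3, chrom_length=250_000, n_genes=36,
                    n_scaffold_fragments=12, n_chimeras=2)
    return simulate_world(cfg)


@pytest.fixture(scope="session")
def default_world():
    return simulate_world(SimConfig(seed=42))


@pytest.fixture(scope="session")
def default_curation(default_world):
    w = default_world
    return curate_scaffolds(w.scaffolds, w.exon_records, w.exon_metadata, w.synteny)


@pytest.fixture(scope="session")
def default_placement_markers(default_world, default_curation):
    w = default_world
    return place_scaffolds(default_curation.scaffolds, w.exon_records,
                           w.exon_metadata, w.markers, w.synteny, w.reference)


@pytest.fixture(scope="session")
def default_placement_no_markers(default_world, default_curation):
    w = default_world
    return place_scaffolds(default_curation.scaffolds, w.exon_records,
                           w.exon_metadata, [], w.synteny, w.reference)
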