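"""Shared fixtures: small simulated clades reused across test modules.

All simulations here are scaled-down study conditions (hundreds of kb
rather than Mb) so the suite stays fast; the acceptance tests run the
full-scale configuration separately.
"""

from __future__ import annotations

import pytest

from sinetrace.ascertainment import extract_locus, filter_full_length
from sinetrace.synthetic_data import (
    SimulationConfig,
    default_library,
    simulate_clade,
)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def clade_small():
    """Moderate-divergence clade: 5 species, 400 kb, ~70 planted loci."""
    cfg = SimulationConfig(
        ancestral_genome_length=400_000, insertion_rate=8, seed=3
    )
    return simulate_clade(cfg)


@pytest.fixture(scope="session")
def clade_mu0():
    """Zero-divergence clade with decoys, nesting and guaranteed
    termination signals: the exact-recovery limit."""
    cfg = SimulationConfig(
        ancestral_genome_length=400_000,
        insertion_rate=8,
        substitution_rate=0.0,
        decoy_rate=1.0,
        nested_fraction=0.15,
        termination_probability=1.0,
        seed=7,
    )
    return simulate_clade(cfg)


def ascertain_all(clade, flank=500):
    """Filter full-length focal elements and extract flanked loci for every
    species; ids are '<species>_<index>'."""
    loci = []
    lengths = clade.library.lengths()
    for sp, genome in clade.genomes.items():
        anns = [
            a for a in clade.annotations[sp] if a.repeat_class == "SINE/Platy"
        ]
        full = filter_full_length(anns, lengths)
        for i, a in enumerate(full, start=1):
            loci.append(
                extract_locus(genome, a, flank=flank, locus_id=f"{sp}_{i:04d}")
            )
    return loci


def truth_by_coords(clade):
    """Map (species, contig, begin, end) -> planted insertion."""
    out = {}
    for p in clade.truth.insertions:
        for sp, (c, b, e) in p.coords.items():
            out[(sp, c, b, e)] = p
    return out


@pytest.fixture(scope="session")
def loci_small(clade_small):
    return ascertain_all(clade_small)


@pytest.fixture(scope="session")
def loci_mu0(clade_mu0):
    return ascertain_all(clade_mu0)


@pytest.fixture(scope="session")
def matrix_mu0(clade_mu0, loci_mu0):
    from sinetrace.cross_genome_genotyping import build_genotype_matrix

    return build_genotype_matrix(loci_mu0, clade_mu0.genomes)
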