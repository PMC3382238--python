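"""Shared fixtures and independent oracles.

The oracle functions here recompute energies by direct term-by-term summation
with their own table lookups; they deliberately do not call
``placement_energy`` / ``window_energy`` so that equivalence tests compare two
independent code paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from amylostretch.motif_energy import EnergyConfig, default_energy_config
from amylostretch.sequence_io import AMINO_ACIDS, ProteinRecord


@pytest.fixture(scope="session")
def energy_config() -> EnergyConfig:
    return default_energy_config()


@pytest.fixture(scope="session")
def zero_contact_config() -> EnergyConfig:
    """Config whose contact table is identically zero: total == E_desol."""
    return EnergyConfig(contact_table=np.zeros((20, 20)), contact_scale=1.0)


def oracle_placement_energy(segment, start, linker, orientation, config):
    """Brute-force term-by-term energy of one placement (1-based start)."""
    m = config.strand_len
    tab = config.contact_table * config.contact_scale

    def pair(a, b):
        if a == "X" and b == "X":
            return float(np.mean([pair(x, y) for x in AMINO_ACIDS for y in AMINO_ACIDS]))
        if a == "X":
            return float(np.mean([pair(x, b) for x in AMINO_ACIDS]))
        if b == "X":
            return float(np.mean([pair(a, y) for y in AMINO_ACIDS]))
        return float(tab[AMINO_ACIDS.index(a), AMINO_ACIDS.index(b)])

    def desol(a):
        if a == "X":
            return float(np.mean([config.desolvation_table[x] for x in AMINO_ACIDS]))
        return float(config.desolvation_table[a])

    sa = segment[start - 1 : start - 1 + m]
    sb = segment[start - 1 + m + linker : start - 1 + 2 * m + linker]
    e_inter = sum(pair(r, r) for r in sa + sb)
    if orientation == "parallel":
        pairs = [(i, i) for i in range(1, m + 1)] + [(i, i + 1) for i in range(1, m)]
    else:
        pairs = [(i, m + 1 - i) for i in range(1, m + 1)] + [
            (i, m - i) for i in range(1, m)
        ]
    e_intra = sum(pair(sa[i - 1], sb[k - 1]) for i, k in pairs)
    if config.buried_rule == "all_strand":
        buried = list(range(m))
    else:
        buried = list(range(0, m, 2))
    e_desol = sum(desol(sa[i]) for i in buried) + sum(desol(sb[i]) for i in buried)
    return e_inter, e_intra, e_desol, e_inter + e_intra + e_desol


def oracle_min_energy(segment, config):
    """Brute-force minimum over an independently enumerated placement set."""
    m = config.strand_len
    best = np.inf
    for linker in range(config.max_linker + 1):
        for start in range(1, len(segment) - 2 * m - linker + 2):
            for orientation in ("parallel", "antiparallel"):
                total = oracle_placement_energy(
                    segment, start, linker, orientation, config
                )[3]
                best = min(best, total)
    return best


@pytest.fixture(scope="session")
def oracle():
    return oracle_placement_energy


@pytest.fixture(scope="session")
def oracle_min():
    return oracle_min_energy


def random_segment(rng: np.random.Generator, length: int = 27) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def toy_records() -> list[ProteinRecord]:
    return [
        ProteinRecord("p1", "ACDEFGHIKLMNPQRSTVWY", labels=tuple([1] * 5 + [0] * 15)),
        ProteinRecord("p2", "GGGGVVVVIIIITTTT", labels=tuple([0] * 8 + [1] * 8)),
    ]
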