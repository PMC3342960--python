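"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by the most literal route
available (column walks, O(n^2) pair counting, hand arithmetic) and share
no logic with the implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from teindel import SimConfig, SubfamilySpec, ChromosomeSpec, scenario_config
from teindel.simulate import simulate_genome


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_indel_scan(master: str, copy: str):
    """Literal column walk: (kind, length, master_pos[, seq]) per gap run,
    terminal runs skipped. Shares nothing with the package's caller."""
    events = []
    n = len(master)
    i = 0
    pos = 0  # master bases consumed so far
    while i < n:
        if master[i] == "-":
            j = i
            while j < n and master[j] == "-":
                j += 1
            if i != 0 and j != n:
                events.append(("insertion", j - i, pos, copy[i:j]))
            i = j
        elif copy[i] == "-":
            j = i
            while j < n and copy[j] == "-":
                j += 1
            if i != 0 and j != n:
                events.append(("deletion", j - i, pos, ""))
            pos += sum(1 for k in range(i, j) if master[k] != "-")
            i = j
        else:
            pos += 1
            i += 1
    return events


def brute_force_tau_b(x, y) -> float:
    """O(n^2) concordant/discordant pair count with the tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (conc - disc) / denom


def random_gapped_pair(rng: np.random.Generator, n_cols: int = 60):
    """A random valid alignment pair: no column gapped in both strings."""
    bases = "ACGT"
    master, copy = [], []
    for _ in range(n_cols):
        r = rng.random()
        if r < 0.12:
            master.append("-")
            copy.append(bases[rng.integers(4)])
        elif r < 0.24:
            master.append(bases[rng.integers(4)])
            copy.append("-")
        else:
            master.append(bases[rng.integers(4)])
            copy.append(bases[rng.integers(4)])
    return "".join(master), "".join(copy)


# ---------------------------------------------------------------------------
# simulated genomes (module-scoped: reused across tests)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def contraction_sim():
    return simulate_genome(scenario_config("contraction", seed=7))


@pytest.fixture(scope="session")
def null_sim():
    return simulate_genome(scenario_config("null", seed=7))


@pytest.fixture(scope="session")
def sex_sim():
    return simulate_genome(scenario_config("sex-chromosome", seed=7))


@pytest.fixture(scope="session")
def flat_family_sim():
    """One subfamily, all copies full-length, no link/truncation/nesting:
    the cleanest setting for rate-recovery checks."""
    cfg = SimConfig(
        seed=11,
        chromosomes=[ChromosomeSpec("chr1", 8_000_000)],
        subfamilies=[SubfamilySpec("CR1-sim1", 1000, 0.0, 0.0, 2000)],
        recomb_window=100_000,
        substitution_rate=0.10,
        insertion_rate=0.015,
        deletion_rate=0.05,
    )
    return simulate_genome(cfg)
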