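"""Shared fixtures, including the heavier recovery experiments.

The Monte-Carlo recovery experiments (Ka/Ks estimator on simulated codon
pairs; two-track orthology on a simulated proteome pair) are
session-scoped so that property tests and the acceptance checks share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from florevol.kaks import kaks_from_cds_pair
from florevol.orthology import assign_orthologs
from florevol.simulate import simulate_codon_pair, simulate_proteomes

N_RECOVERY_REPLICATES = 50
RECOVERY_N_CODONS = 1000
RECOVERY_BRANCH_KS = 0.5


def _recovery(omega: float, kappa: float):
    ks_list, ratio_list = [], []
    for seed in range(N_RECOVERY_REPLICATES):
        a, b = simulate_codon_pair(
            RECOVERY_N_CODONS, omega, kappa, RECOVERY_BRANCH_KS, seed
        )
        res = kaks_from_cds_pair(a, b)
        ks_list.append(res.ks)
        ratio_list.append(res.ratio)
    return np.array(ks_list), np.array(ratio_list)


@pytest.fixture(scope="session")
def kaks_recovery_purifying():
    """50 replicates at true omega=0.2, kappa=2, Ks=0.5, 1000 codons."""
    return _recovery(omega=0.2, kappa=2.0)


@pytest.fixture(scope="session")
def kaks_recovery_neutral():
    """50 replicates at true omega=1, Ks=0.5, 1000 codons.

    kappa=1 so that the transition fraction matches the estimator's
    site-weighting assumption and neutrality is the clean null.
    """
    return _recovery(omega=1.0, kappa=1.0)


@pytest.fixture(scope="session")
def proteome_recovery():
    """Two-track orthology on a 200-family proteome pair (20 lost, 30
    duplicated, 10% per-site divergence) with its generating truth."""
    queries, targets, truth = simulate_proteomes(
        n_families=200, n_lost=20, n_duplicated=30, divergence=0.1, seed=11
    )
    assignments, lost = assign_orthologs(targets, queries)
    return queries, targets, truth, assignments, lost
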