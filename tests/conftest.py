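from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from haplodyn.model import GenotypeMatrix, build_matrix
from haplodyn.simulate import SimConfig, simulate_panel, toy_config


def mk_matrix(calls, chromosome=None, position=None, groups=None,
              regimes=None, years=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from an int array (0/1/-1) with defaults:
    all SNPs on chromosome 1 at 100kb spacing, all accessions irrigated
    group1."""
    calls = np.asarray(calls, dtype=np.int8)
    n_acc, n_snp = calls.shape
    chromosome = chromosome if chromosome is not None else [1] * n_snp
    position = position if position is not None else [
        100_000 * (i + 1) for i in range(n_snp)]
    groups = groups if groups is not None else ["group1"] * n_acc
    regimes = regimes if regimes is not None else ["irrigated"] * n_acc
    years = years if years is not None else [None] * n_acc
    acc = pd.DataFrame({
        "accession_id": [f"acc{i + 1}" for i in range(n_acc)],
        "group": groups, "water_regime": regimes,
        "registration_year": pd.array(years, dtype="Int64"),
        "region": [None] * n_acc})
    snps = pd.DataFrame({
        "snp_id": [f"s{j + 1}" for j in range(n_snp)],
        "chromosome": chromosome, "position_bp": position,
        "source_panel": ["other"] * n_snp})
    return build_matrix(acc, snps, calls)


@pytest.fixture(scope="session")
def default_panel():
    """One default-condition simulated panel shared across tests."""
    return simulate_panel(seed=11)


@pytest.fixture(scope="session")
def toy_panel():
    return simulate_panel(toy_config(seed=5))
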