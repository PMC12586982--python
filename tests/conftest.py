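import numpy as np
import pandas as pd
import pytest

from histomics import synthetic
from histomics.methylome import BetaMatrix


@pytest.fixture(scope="session")
def small_pileup_cohort():
    """40 individuals, 20 duplicated, exact-genotype regime for fast matching."""
    return synthetic.make_pileup_cohort(
        n_individuals=40, n_sites=2_000, depth_mean=50, error_rate=0.01,
        n_duplicated=20, seed=11)


@pytest.fixture(scope="session")
def sv_fixture():
    return synthetic.make_sv_fixture()


@pytest.fixture(scope="session")
def beta_split():
    """One 3-class beta cohort split into reference and query halves."""
    classes = ["colorectal", "stomach", "endometrial"]
    full, labels, truth = synthetic.make_beta_cohort(
        classes, {c: 40 for c in classes}, n_probes=2_000, n_informative=500,
        effect=0.3, seed=7)
    train = [s for c in classes for s in labels.index[labels == c][:20]]
    test = [s for c in classes for s in labels.index[labels == c][20:]]
    ref = BetaMatrix(full.values[train], full.annotations)
    qry = BetaMatrix(full.values[test], full.annotations)
    return ref, labels[train], qry, labels[test]
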