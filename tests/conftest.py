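"""Shared fixtures: synthetic panels at two scales, built once per session."""

import numpy as np
import pytest

import dhselect as d
from dhselect import phenostats as ps


@pytest.fixture(scope="session")
def reference_panel():
    """379-line, 5,000-marker multi-parent DH panel (21 crosses, 42 founders)."""
    founders = d.simulate_founders(42, 5000, n_chromosomes=10, seed=11)
    return d.simulate_dh_population(founders, 21, [19] + [18] * 20, seed=12)


@pytest.fixture(scope="session")
def reference_trial(reference_panel):
    """The reference panel phenotyped for three correlated flowering traits
    (1 major + 49 minor QTLs, component targets like the reference trial),
    with variance components, BLUPs and PC covariates precomputed."""
    pop = reference_panel
    arch = d.flowering_architecture(pop, n_qtl=50, seed=13)
    book = d.simulate_phenotypes(pop, arch, seed=14)
    vcs = {t: ps.fit_variance_components(book, t) for t in book.traits}
    blups = ps.compute_blups(book, vcs)
    pcs = d.pca_covariates(pop.genotypes, 3)
    return {"pop": pop, "arch": arch, "book": book, "vcs": vcs,
            "blups": blups, "pcs": pcs}


@pytest.fixture(scope="session")
def mid_panel():
    """300-line, 2,000-marker panel used for recovery and error-control runs."""
    founders = d.simulate_founders(40, 2000, n_chromosomes=10, seed=21)
    return d.simulate_dh_population(founders, 20, 15, seed=22)


@pytest.fixture(scope="session")
def small_panel():
    """60-line, 200-marker panel for fast unit tests."""
    founders = d.simulate_founders(8, 200, n_chromosomes=4, seed=31)
    return d.simulate_dh_population(founders, 4, 15, seed=32)
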