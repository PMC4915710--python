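"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from grsmr import (
    CohortSimParams,
    InstrumentSNP,
    OutcomeAssociation,
    SummarySimParams,
    harmonize,
    simulate_cohort,
    simulate_summary,
)


def wls_origin_oracle(omega, beta, se_beta):
    """Weighted regression of beta on omega through the origin, via generic
    normal-equations linear algebra (independent of the closed-form path).

    Returns (slope, se, weighted residual sum of squares).
    """
    X = np.asarray(omega, dtype=float).reshape(-1, 1)
    y = np.asarray(beta, dtype=float)
    W = np.diag(1.0 / np.asarray(se_beta, dtype=float) ** 2)
    A = X.T @ W @ X
    b = X.T @ W @ y
    slope = np.linalg.solve(A, b)[0]
    se = float(np.sqrt(np.linalg.inv(A)[0, 0]))
    resid = y - X[:, 0] * slope
    q = float(resid @ W @ resid)
    return float(slope), se, q


def make_snp(rsid, omega, ea="A", oa="G", **kw):
    return InstrumentSNP(rsid=rsid, effect_allele=ea, other_allele=oa, omega=omega, **kw)


def make_assoc(rsid, beta, se_beta, ea="A", oa="G", **kw):
    kw.setdefault("outcome_type", "binary")
    return OutcomeAssociation(rsid=rsid, effect_allele=ea, other_allele=oa,
                              beta=beta, se_beta=se_beta, **kw)


@pytest.fixture
def small_harmonized():
    """Three aligned SNPs with hand-pickable numbers."""
    inst = [make_snp("rs1", 0.1), make_snp("rs2", 0.2), make_snp("rs3", 0.15)]
    out = [make_assoc("rs1", 0.05, 0.05), make_assoc("rs2", 0.11, 0.04),
           make_assoc("rs3", 0.07, 0.06)]
    return harmonize(inst, out, outcome_name="toy", grs_label="toy")


@pytest.fixture
def simulated_analysis():
    """One 18-SNP simulated protective analysis with its truth record."""
    params = SummarySimParams(seed=7, alpha_true=-0.15)
    instrument, outcome, truth = simulate_summary(params)
    return harmonize(instrument, outcome, grs_label="GRS_GWAS"), truth, params


@pytest.fixture(scope="session")
def simulated_cohort():
    return simulate_cohort(CohortSimParams(n_individuals=2000, seed=11))
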