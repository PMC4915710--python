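"""Synthetic summary-level and individual-level data generators.

The generators encode the statistical structure the IVW estimator assumes:
independent (uncorrelated) SNPs, per-allele effects estimated in two
independent samples (exposure GWAS and outcome GWAS), standard errors
following the per-allele GWAS variance approximation
``se^2 = 1 / (2 * eaf * (1 - eaf) * n_eff)`` with
``n_eff = n_cases * n_controls / n_total`` for binary outcomes, and an
optional pleiotropic subset of SNPs with direct outcome effects.  Defaults
are the flagship study conditions of the analysis this package implements:
an 18-SNP instrument explaining 5% of the variance of a unit-variance ln
exposure, a CRP-GWAS-scale exposure sample, and schizophrenia-scale
case/control counts.

Every draw is reproducible from a single integer seed; the exposure-side
and outcome-side noise use independent child streams of that seed, so the
two-sample structure is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .exceptions import GrsmrError
from .io import InstrumentSNP, OutcomeAssociation
from .prs import CohortData

#: Non-palindromic allele codings assigned cyclically to simulated SNPs.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


@dataclass(frozen=True)
class SummarySimParams:
    """Conditions for one simulated summary-statistics analysis.

    ``r2_target`` is the exposure variance the (true) weighted score should
    explain; reported weights add estimation noise at ``n_exposure``.
    ``alpha_true`` is the causal effect per unit ln exposure (log-OR for a
    binary outcome).  A ``pleiotropy_fraction`` of the SNPs receive direct
    outcome effects drawn N(0, ``pleiotropy_sd``).
    """

    m_snps: int = 18
    seed: int = 0
    eaf_range: tuple[float, float] = (0.05, 0.5)
    omega_sd: float = 0.1
    omega: tuple[float, ...] | None = None  # explicit true weights (pre-scaling)
    n_exposure: int = 66_185
    r2_target: float = 0.05
    alpha_true: float = 0.0
    pleiotropy_fraction: float = 0.0
    pleiotropy_sd: float = 0.25
    outcome_type: str = "binary"
    n_cases: int = 34_241
    n_controls: int = 45_604
    n_total: int | None = None
    outcome_name: str = "simulated_outcome"

    def __post_init__(self) -> None:
        if not 0.0 <= self.pleiotropy_fraction <= 1.0:
            raise GrsmrError("pleiotropy_fraction must lie in [0, 1]")
        if not 0.0 < self.r2_target < 1.0:
            raise GrsmrError("r2_target must lie in (0, 1)")
        lo, hi = self.eaf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise GrsmrError("eaf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.m_snps < 1:
            raise GrsmrError("m_snps must be >= 1")


@dataclass(frozen=True)
class CohortSimParams:
    """Conditions for one simulated individual-level cohort."""

    n_individuals: int = 3_000
    m_snps: int = 18
    seed: int = 0
    eaf_range: tuple[float, float] = (0.05, 0.5)
    grs_r2_target: float = 0.05
    alpha_true: float = -0.15
    case_fraction: float = 0.5
    n_pcs: int = 10
    pc_effect_sd: float = 0.1
    n_exposure: int = 66_185
    cohort_id: str = "sim_cohort"

    def __post_init__(self) -> None:
        if not 0.0 < self.grs_r2_target < 1.0:
            raise GrsmrError("grs_r2_target must lie in (0, 1)")
        if not 0.0 < self.case_fraction < 1.0:
            raise GrsmrError("case_fraction must lie in (0, 1)")
        if self.n_individuals < 2 or self.m_snps < 1:
            raise GrsmrError("need n_individuals >= 2 and m_snps >= 1")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _structure(rng: np.random.Generator, m: int, eaf_range: tuple[float, float],
               omega_sd: float, omega: Sequence[float] | None,
               r2_target: float) -> tuple[np.ndarray, np.ndarray]:
    """EAFs and true weights jointly scaled so the score explains r2_target
    of a unit-variance exposure: sum(omega^2 * 2 f (1-f)) = r2_target."""
    eaf = rng.uniform(eaf_range[0], eaf_range[1], size=m)
    if omega is not None:
        if len(omega) != m:
            raise GrsmrError("explicit omega list must have m_snps entries")
        w_raw = np.asarray(omega, dtype=float)
    else:
        # effect alleles coded as exposure-raising, so weights are positive
        w_raw = np.abs(rng.normal(0.0, omega_sd, size=m))
        w_raw = np.maximum(w_raw, 1e-6)
    var_raw = float(np.sum(w_raw**2 * 2.0 * eaf * (1.0 - eaf)))
    w_true = w_raw * np.sqrt(r2_target / var_raw)
    return eaf, w_true


def simulate_summary(
    p: SummarySimParams,
) -> tuple[list[InstrumentSNP], list[OutcomeAssociation], pd.DataFrame]:
    """Draw one instrument weight table, one outcome table, and the truth.

    Returns ``(instrument, outcome, truth)`` where ``truth`` records the
    latent values (true weights, pleiotropic effects, per-SNP standard
    errors) for test assertions.
    """
    rng_struct, rng_expo, rng_out = _streams(p.seed, 3)
    m = p.m_snps
    eaf, w_true = _structure(rng_struct, m, p.eaf_range, p.omega_sd, p.omega, p.r2_target)
    info = 2.0 * eaf * (1.0 - eaf)
    se_omega = 1.0 / np.sqrt(info * p.n_exposure)
    omega_hat = w_true + rng_expo.normal(0.0, se_omega)

    delta = np.zeros(m)
    n_plei = int(round(p.pleiotropy_fraction * m))
    planted = np.sort(rng_struct.choice(m, size=n_plei, replace=False)) if n_plei else np.array([], dtype=int)
    if n_plei:
        delta[planted] = rng_struct.normal(0.0, p.pleiotropy_sd, size=n_plei)

    if p.outcome_type == "binary":
        n_total = p.n_cases + p.n_controls
        n_eff = p.n_cases * p.n_controls / n_total
        n_cases, n_controls = p.n_cases, p.n_controls
    else:
        n_total = p.n_total if p.n_total is not None else p.n_cases + p.n_controls
        n_eff = n_total
        n_cases = n_controls = None
    se_beta = 1.0 / np.sqrt(info * n_eff)
    beta = p.alpha_true * w_true + delta + rng_out.normal(0.0, se_beta)

    p_exposure = 2.0 * stats.norm.sf(np.abs(omega_hat / se_omega))

    instrument, outcome = [], []
    rows = []
    for j in range(m):
        rsid = f"rs{j + 1:06d}"
        ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        instrument.append(
            InstrumentSNP(
                rsid=rsid, effect_allele=ea, other_allele=oa,
                omega=float(omega_hat[j]), omega_se=float(se_omega[j]),
                eaf=float(eaf[j]), chrom=str(j % 22 + 1), pos=(j + 1) * 100_000,
                locus_label=f"LOCUS{j + 1}",
            )
        )
        outcome.append(
            OutcomeAssociation(
                rsid=rsid, effect_allele=ea, other_allele=oa,
                beta=float(beta[j]), se_beta=float(se_beta[j]),
                outcome_name=p.outcome_name, outcome_type=p.outcome_type,
                n_total=n_total, n_cases=n_cases, n_controls=n_controls,
            )
        )
        rows.append(
            {
                "rsid": rsid, "eaf": eaf[j], "omega_true": w_true[j],
                "omega_hat": omega_hat[j], "se_omega": se_omega[j],
                "p_exposure": p_exposure[j], "delta": delta[j],
                "is_pleiotropic": bool(j in planted), "beta": beta[j],
                "se_beta": se_beta[j], "alpha_true": p.alpha_true,
            }
        )
    return instrument, outcome, pd.DataFrame(rows)


def simulate_cohort(p: CohortSimParams) -> CohortData:
    """Draw one individual-level cohort under a liability-scale causal model.

    Dosages are Binomial(2, eaf); the latent ln exposure is the true
    weighted score plus Gaussian noise scaled so the score explains
    ``grs_r2_target`` of its (unit) variance; principal components act on
    the liability with N(0, ``pc_effect_sd``) coefficients; case status is
    Bernoulli with logistic probability, the intercept solved so the
    expected case fraction matches ``case_fraction``.
    """
    rng_struct, rng_geno, rng_pheno = _streams(p.seed, 3)
    m, n = p.m_snps, p.n_individuals
    eaf, w_true = _structure(rng_struct, m, p.eaf_range, 0.1, None, p.grs_r2_target)
    dosages = rng_geno.binomial(2, eaf, size=(n, m)).astype(float)
    centered = dosages - 2.0 * eaf
    score_true = centered @ w_true  # variance ~ grs_r2_target
    exposure = score_true + rng_pheno.normal(0.0, np.sqrt(1.0 - p.grs_r2_target), size=n)

    pcs = rng_pheno.normal(size=(n, p.n_pcs)) if p.n_pcs else np.empty((n, 0))
    gamma = rng_struct.normal(0.0, p.pc_effect_sd, size=p.n_pcs) if p.n_pcs else np.empty(0)
    lin = p.alpha_true * exposure + (pcs @ gamma if p.n_pcs else 0.0)

    def excess(b: float) -> float:
        return float(np.mean(special.expit(b + lin))) - p.case_fraction

    intercept = optimize.brentq(excess, -30.0, 30.0)
    phenotype = rng_pheno.binomial(1, special.expit(intercept + lin))

    # reported exposure weights and p-values, as an exposure GWAS would give
    se_omega = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * p.n_exposure)
    omega_hat = w_true + rng_pheno.normal(0.0, se_omega)
    p_exposure = 2.0 * stats.norm.sf(np.abs(omega_hat / se_omega))

    meta = pd.DataFrame(
        {
            "rsid": [f"rs{j + 1:06d}" for j in range(m)],
            "effect_allele": [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)][0] for j in range(m)],
            "omega": omega_hat,
            "p_exposure": p_exposure,
            "eaf": eaf,
            "omega_true": w_true,
        }
    )
    return CohortData(
        cohort_id=p.cohort_id,
        dosages=dosages,
        phenotype=phenotype,
        pcs=pcs,
        snp_meta=meta,
    )


def simulate_cohorts(
    base: CohortSimParams, n_cohorts: int, seed: int | None = None
) -> list[CohortData]:
    """Independent cohorts sharing ``base`` conditions, seeds spawned from
    ``seed`` (default: ``base.seed``)."""
    root = np.random.SeedSequence(base.seed if seed is None else seed)
    out = []
    for i, child in enumerate(root.spawn(n_cohorts)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        out.append(
            simulate_cohort(
                CohortSimParams(
                    **{
                        **base.__dict__,
                        "seed": sub_seed,
                        "cohort_id": f"{base.cohort_id}_{i + 1}",
                    }
                )
            )
        )
    return out
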