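"""Polygenic scoring, logistic association, Nagelkerke R^2 and meta-analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from grsmr import (
    CohortData,
    CohortSimParams,
    DegenerateScoreError,
    EmptyScoreError,
    FitError,
    GrsmrError,
    PRSAssociation,
    associate_prs,
    compute_prs,
    meta_analyze,
    nagelkerke_delta_r2,
    simulate_cohort,
    threshold_scan,
)
from grsmr.prs import leave_one_out_prs, read_cohort, write_cohort


def _tiny_cohort(dosages, phenotype, omegas, p_exp=None, pcs=None):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    meta = pd.DataFrame(
        {
            "rsid": [f"rs{j}" for j in range(m)],
            "effect_allele": ["A"] * m,
            "omega": omegas,
            "p_exposure": p_exp if p_exp is not None else [1e-9] * m,
        }
    )
    n = dosages.shape[0]
    return CohortData(
        cohort_id="tiny",
        dosages=dosages,
        phenotype=np.asarray(phenotype),
        pcs=np.asarray(pcs, dtype=float) if pcs is not None else np.empty((n, 0)),
        snp_meta=meta,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def test_raw_score_is_weighted_dosage_sum():
    # two individuals so standardization is invertible: raw = mean + sd*z
    cohort = _tiny_cohort([[2, 1], [0, 0]], [1, 0], omegas=[0.1, 0.3])
    z = compute_prs(cohort, 1.0)
    raw = cohort.dosages @ np.array([0.1, 0.3])
    np.testing.assert_allclose(raw.mean() + raw.std() * z, raw)
    assert raw[0] == pytest.approx(0.5)


def test_score_is_standardized(simulated_cohort):
    z = compute_prs(simulated_cohort, 1.0)
    assert abs(z.mean()) < 1e-10
    assert z.std() == pytest.approx(1.0, abs=1e-10)


def test_threshold_filters_and_is_monotone(simulated_cohort):
    thresholds = [1e-4, 0.001, 0.01, 0.05, 0.1, 1.0]
    p = simulated_cohort.snp_meta["p_exposure"].to_numpy()
    counts = []
    for thr in thresholds:
        expected = int((p <= thr).sum())  # brute-force filter count
        from grsmr.prs import n_snps_at
        assert n_snps_at(simulated_cohort, thr) == expected
        counts.append(expected)
    assert counts == sorted(counts)


def test_empty_and_degenerate_scores_raise():
    cohort = _tiny_cohort([[2, 1], [0, 0]], [1, 0], omegas=[0.1, 0.3],
                          p_exp=[0.5, 0.5])
    with pytest.raises(EmptyScoreError):
        compute_prs(cohort, 1e-8)
    zero = _tiny_cohort([[2, 1], [0, 0]], [1, 0], omegas=[0.0, 0.0])
    with pytest.raises(DegenerateScoreError):
        compute_prs(zero, 1.0)


# ---------------------------------------------------------------------------
# logistic association
# ---------------------------------------------------------------------------

def _ml_logistic_oracle(y, X):
    """Independent maximum-likelihood fit by generic numeric optimization."""

    def nll(b):
        eta = X @ b
        return -np.sum(y * eta - np.logaddexp(0.0, eta))

    res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    return res.x


def test_coefficient_matches_ml_oracle_on_small_data():
    rng = np.random.default_rng(5)
    n = 20
    score = rng.normal(size=n)
    pcs = rng.normal(size=(n, 2))
    prob = special.expit(-0.3 + 0.8 * score + 0.2 * pcs[:, 0])
    y = rng.binomial(1, prob)
    cohort = _tiny_cohort(np.zeros((n, 1)) , y, omegas=[0.1], pcs=pcs)
    res = associate_prs(cohort, score, with_delta_r2=False)
    X = np.column_stack([np.ones(n), score, pcs])
    oracle = _ml_logistic_oracle(y.astype(float), X)
    assert res.beta_per_sd == pytest.approx(oracle[1], abs=1e-6)
    assert res.or_per_sd == pytest.approx(math.exp(res.beta_per_sd))


def test_single_class_phenotype_raises(simulated_cohort):
    bad = CohortData(
        cohort_id="bad",
        dosages=simulated_cohort.dosages,
        phenotype=np.ones_like(simulated_cohort.phenotype),
        pcs=simulated_cohort.pcs,
        snp_meta=simulated_cohort.snp_meta,
    )
    with pytest.raises(FitError):
        associate_prs(bad, compute_prs(bad, 1.0))


def test_null_association_p_is_uniform():
    """Score independent of phenotype -> p approximately U(0,1)."""
    from scipy import stats
    ps = []
    for r in range(150):
        c = simulate_cohort(CohortSimParams(n_individuals=800, alpha_true=0.0,
                                            seed=700_000 + r, n_pcs=4))
        ps.append(associate_prs(c, compute_prs(c, 1.0), with_delta_r2=False).p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# Nagelkerke pseudo-R^2
# ---------------------------------------------------------------------------

def test_nagelkerke_closed_form_and_monotonicity():
    assert nagelkerke_delta_r2(-5.0, -5.0, 10) == pytest.approx(0.0)
    # longhand: n=10, ll_null = 10*ln(0.5), ll_full = -5
    ll_null, ll_full, n = -6.9315, -5.0, 10
    r2_cs = 1.0 - math.exp(2.0 * (ll_null - ll_full) / n)
    expected = r2_cs / (1.0 - math.exp(2.0 * ll_null / n))
    assert nagelkerke_delta_r2(ll_null, ll_full, n) == pytest.approx(expected)
    assert expected == pytest.approx(0.427, abs=5e-3)
    vals = [nagelkerke_delta_r2(ll_null, lf, n) for lf in (-6.0, -5.0, -4.0)]
    assert vals == sorted(vals)
    with pytest.raises(GrsmrError):
        nagelkerke_delta_r2(-5.0, -6.0, 10)


def test_delta_r2_reported_from_nested_fits(simulated_cohort):
    res = associate_prs(simulated_cohort, compute_prs(simulated_cohort, 1.0))
    assert res.delta_r2_nagelkerke is not None
    assert 0.0 <= res.delta_r2_nagelkerke < 1.0


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

def test_meta_identities_and_oracle():
    one = PRSAssociation(beta_per_sd=-0.1, se=0.05, n=100, threshold=0.01)
    pooled = meta_analyze([one])
    assert pooled.beta_per_sd == pytest.approx(one.beta_per_sd)
    assert pooled.se == pytest.approx(one.se)
    # k identical cohorts: same point estimate, se / sqrt(k)
    k = 4
    pooled = meta_analyze([one] * k)
    assert pooled.beta_per_sd == pytest.approx(one.beta_per_sd)
    assert pooled.se == pytest.approx(one.se / math.sqrt(k))
    # generic instance vs direct formula re-evaluation
    rs = [
        PRSAssociation(beta_per_sd=b, se=s, n=n)
        for b, s, n in [(-0.12, 0.04, 900), (0.03, 0.09, 400), (-0.2, 0.06, 1500)]
    ]
    pooled = meta_analyze(rs)
    w = np.array([1 / r.se**2 for r in rs])
    b = np.array([r.beta_per_sd for r in rs])
    assert pooled.beta_per_sd == pytest.approx(float((w * b).sum() / w.sum()), rel=1e-12)
    assert pooled.se == pytest.approx(float(w.sum() ** -0.5), rel=1e-12)
    with pytest.raises(GrsmrError):
        meta_analyze([])


def test_split_cohort_meta_approximates_unsplit_fit():
    c = simulate_cohort(CohortSimParams(n_individuals=4000, alpha_true=-0.3, seed=42))
    score = compute_prs(c, 1.0)
    full = associate_prs(c, score, with_delta_r2=False)
    halves = []
    for sl in (slice(0, 2000), slice(2000, 4000)):
        sub = CohortData("half", c.dosages[sl], c.phenotype[sl], c.pcs[sl], c.snp_meta)
        halves.append(associate_prs(sub, compute_prs(sub, 1.0), with_delta_r2=False))
    pooled = meta_analyze(halves)
    assert abs(pooled.beta_per_sd - full.beta_per_sd) < 3 * pooled.se


# ---------------------------------------------------------------------------
# scans and cohort I/O
# ---------------------------------------------------------------------------

def test_threshold_scan_rows_and_monotone_counts(simulated_cohort):
    table = threshold_scan([simulated_cohort], [1e-4, 0.01, 1.0], with_delta_r2=False)
    assert not table.empty
    assert list(table["n_snps"]) == sorted(table["n_snps"])


def test_leave_one_out_prs_has_one_row_per_snp(simulated_cohort):
    table = leave_one_out_prs(simulated_cohort, with_delta_r2=False)
    assert len(table) == simulated_cohort.dosages.shape[1]
    assert set(table["excluded_rsid"]) == set(simulated_cohort.snp_meta["rsid"])


def test_cohort_tsv_roundtrip(tmp_path, simulated_cohort):
    paths = write_cohort(simulated_cohort, tmp_path)
    back = read_cohort(paths["dosages"], paths["pheno"], paths["snp_meta"],
                       cohort_id=simulated_cohort.cohort_id)
    np.testing.assert_allclose(back.dosages, simulated_cohort.dosages)
    np.testing.assert_array_equal(back.phenotype, simulated_cohort.phenotype)
    np.testing.assert_allclose(back.pcs, simulated_cohort.pcs)
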