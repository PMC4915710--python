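"""Cochran-Q heterogeneity, stepwise pruning and leave-one-out sensitivity."""

import numpy as np
import pytest

from grsmr import (
    InsufficientMarkersError,
    SummarySimParams,
    estimate_causal_effect,
    harmonize,
    leave_one_out,
    prune_heterogeneity,
    q_statistic,
    simulate_summary,
)

from conftest import make_assoc, make_snp, wls_origin_oracle


def _harmonized(omegas, betas, ses):
    inst = [make_snp(f"rs{i}", w) for i, w in enumerate(omegas, 1)]
    out = [make_assoc(f"rs{i}", b, s) for i, (b, s) in enumerate(zip(betas, ses), 1)]
    return harmonize(inst, out)


# ---------------------------------------------------------------------------
# Q statistic
# ---------------------------------------------------------------------------

def test_q_zero_under_exact_proportionality():
    h = _harmonized([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.05] * 3)
    het = q_statistic(h)
    assert het.q == pytest.approx(0.0, abs=1e-20)
    assert het.p_het == pytest.approx(1.0)
    assert het.df == 2


def test_q_equals_weighted_rss_from_oracle(small_harmonized):
    het = q_statistic(small_harmonized)
    _, _, q = wls_origin_oracle(
        small_harmonized.omega, small_harmonized.beta, small_harmonized.se_beta
    )
    assert het.q == pytest.approx(q, rel=1e-10)
    assert het.q == pytest.approx(sum(c for _, c in het.per_snp_contrib), rel=1e-12)


def test_q_requires_two_markers():
    h = _harmonized([0.1], [0.05], [0.05])
    with pytest.raises(InsufficientMarkersError):
        q_statistic(h)


def test_q_invariant_to_joint_reorientation(small_harmonized):
    flipped = harmonize(
        [p[0] for p in small_harmonized.pairs],
        [p[1].flipped() for p in small_harmonized.pairs],
    )
    assert q_statistic(flipped).q == pytest.approx(q_statistic(small_harmonized).q)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def test_homogeneous_set_prunes_nothing():
    h = _harmonized([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.05] * 3)
    trace = prune_heterogeneity(h)
    assert trace.steps == []
    assert trace.final_m == 3
    assert trace.final_estimate.alpha == pytest.approx(0.5)


def test_planted_outlier_removed_first():
    # 8 proportional SNPs plus one with a large direct effect
    omegas = [0.1] * 8 + [0.1]
    betas = [0.05] * 8 + [0.5]
    h = _harmonized(omegas, betas, [0.02] * 9)
    trace = prune_heterogeneity(h)
    assert trace.steps[0].removed_rsid == "rs9"
    assert trace.final_p_het >= 0.05
    assert not trace.floor_warning


def test_pruning_floor_flags_persistent_heterogeneity():
    # two mutually inconsistent markers: Q significant but floor = 2
    h = _harmonized([0.1, 0.1], [0.5, -0.5], [0.02, 0.02])
    trace = prune_heterogeneity(h)
    assert trace.final_m == 2
    assert trace.floor_warning
    assert trace.steps == []


def test_pruning_is_deterministic(simulated_analysis):
    h, _, _ = simulated_analysis
    t1 = prune_heterogeneity(h)
    t2 = prune_heterogeneity(h)
    assert t1.removed_rsids == t2.removed_rsids
    assert t1.final_estimate.alpha == t2.final_estimate.alpha


def test_pruning_tie_broken_lexicographically():
    # two identical outliers -> equal contributions -> lexicographic rsid
    inst = [make_snp("rsB", 0.1), make_snp("rsA", 0.1)] + [
        make_snp(f"rs{i}", 0.1) for i in range(3, 9)
    ]
    out = [make_assoc("rsB", 0.5, 0.02), make_assoc("rsA", 0.5, 0.02)] + [
        make_assoc(f"rs{i}", 0.05, 0.02) for i in range(3, 9)
    ]
    trace = prune_heterogeneity(harmonize(inst, out))
    assert trace.removed_rsids[0] == "rsA"


def test_refit_after_each_removal(simulated_analysis):
    """Each recorded Q matches a fresh fit on the SNPs remaining at that step."""
    h, _, _ = simulated_analysis
    # force heterogeneity by perturbing two markers
    pairs = h.pairs
    strong = harmonize(
        [p[0] for p in pairs],
        [
            make_assoc(p[1].rsid, p[1].beta + (0.3 if i < 2 else 0.0), p[1].se_beta,
                       ea=p[1].effect_allele, oa=p[1].other_allele)
            for i, p in enumerate(pairs)
        ],
    )
    trace = prune_heterogeneity(strong)
    assert trace.steps
    current = strong
    for step in trace.steps:
        het = q_statistic(current)
        assert step.q_before == pytest.approx(het.q, rel=1e-12)
        current = current.drop_rsids([step.removed_rsid])
    assert trace.final_estimate.alpha == pytest.approx(
        estimate_causal_effect(current).alpha, rel=1e-12
    )


# ---------------------------------------------------------------------------
# leave-one-out
# ---------------------------------------------------------------------------

def test_leave_one_out_matches_direct_subset_estimates(simulated_analysis):
    h, _, _ = simulated_analysis
    table = leave_one_out(h)
    assert len(table) == 18
    assert (table["m_used"] == 17).all()
    for _, row in table.head(5).iterrows():
        sub = h.drop_rsids([row["excluded_rsid"]])
        direct = estimate_causal_effect(sub)
        assert row["alpha"] == pytest.approx(direct.alpha, rel=1e-12)
        assert row["se_alpha"] == pytest.approx(direct.se_alpha, rel=1e-12)


def test_leave_one_out_constant_under_exact_proportionality():
    h = _harmonized([0.1, 0.2, 0.3, 0.4], [0.03, 0.06, 0.09, 0.12], [0.05] * 4)
    table = leave_one_out(h)
    np.testing.assert_allclose(table["alpha"], 0.3, rtol=1e-12)


# ---------------------------------------------------------------------------
# null calibration of the Q test (stochastic, seeded)
# ---------------------------------------------------------------------------

def test_q_null_rejection_rate_is_nominal():
    reps, hits = 400, 0
    for r in range(reps):
        inst, out, _ = simulate_summary(SummarySimParams(seed=300_000 + r))
        if q_statistic(harmonize(inst, out)).p_het < 0.05:
            hits += 1
    assert 0.02 <= hits / reps <= 0.08
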