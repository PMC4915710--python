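"""Heterogeneity-driven pleiotropy pruning and leave-one-out sensitivity.

A SNP that affects the outcome through a pathway other than the exposure
(pleiotropy) violates the instrumental-variable exclusion assumption and
shows up as an outsized contribution to Cochran's Q.  ``prune_heterogeneity``
removes, one SNP at a time, the largest Q contributor at the current fit,
refits, and stops as soon as heterogeneity is no longer significant (or the
instrument would fall below two markers).  ``leave_one_out`` refits the
estimate once per excluded SNP to show whether any single marker drives the
result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import InsufficientMarkersError
from .io import HarmonizedInstrument
from .model import MRResults, estimate_causal_effect, q_statistic


@dataclass(frozen=True)
class PruneStep:
    removed_rsid: str
    q_before: float
    p_het_before: float
    locus: str | None = None


@dataclass
class PruningTrace:
    """Record of a stepwise heterogeneity pruning run.

    ``floor_warning`` is set when the two-marker floor was reached while
    heterogeneity was still significant.
    """

    steps: list[PruneStep] = field(default_factory=list)
    final_estimate: MRResults | None = None
    final_m: int = 0
    final_p_het: float | None = None
    floor_warning: bool = False

    @property
    def removed_rsids(self) -> list[str]:
        return [s.removed_rsid for s in self.steps]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"step": i + 1, "removed_rsid": s.removed_rsid, "locus": s.locus,
                 "q_before": s.q_before, "p_het_before": s.p_het_before}
                for i, s in enumerate(self.steps)
            ],
            columns=["step", "removed_rsid", "locus", "q_before", "p_het_before"],
        )


def prune_heterogeneity(
    h: HarmonizedInstrument,
    p_threshold: float = 0.05,
    floor: int = 2,
) -> PruningTrace:
    """Stepwise removal of the largest Q contributor until p_het >= threshold.

    The causal effect is refitted after every removal.  Ties on the maximal
    contribution are broken by lexicographic rsid.  Pruning never goes below
    ``floor`` markers; reaching the floor while still heterogeneous sets
    ``floor_warning`` instead of raising.
    """
    if h.m_used < 2:
        raise InsufficientMarkersError("pruning requires at least 2 markers")
    loci = {snp.rsid: snp.locus_label for snp, _ in h.pairs}
    trace = PruningTrace()
    current = h
    while True:
        est = estimate_causal_effect(current)
        if current.m_used < 2:
            # degenerate: cannot test heterogeneity on one marker
            trace.floor_warning = True
            trace.final_p_het = None
            break
        het = q_statistic(current, est)
        if het.p_het >= p_threshold:
            trace.final_p_het = het.p_het
            break
        if current.m_used <= floor:
            trace.floor_warning = True
            trace.final_p_het = het.p_het
            break
        # largest contribution; ties by lexicographic rsid
        worst_rsid, _ = min(het.per_snp_contrib, key=lambda rc: (-rc[1], rc[0]))
        trace.steps.append(
            PruneStep(
                removed_rsid=worst_rsid,
                q_before=het.q,
                p_het_before=het.p_het,
                locus=loci.get(worst_rsid),
            )
        )
        current = current.drop_rsids([worst_rsid])
    trace.final_estimate = est
    trace.final_m = current.m_used
    return trace


def leave_one_out(h: HarmonizedInstrument) -> pd.DataFrame:
    """Refit the IVW estimate once per excluded SNP.

    Returns one row per excluded marker with the re-estimated effect and,
    when effect-allele frequencies are available, the residual instrument
    variance proxy ``sum(2 * eaf * (1 - eaf) * omega^2)`` over the retained
    SNPs.  The individual-level analogue (per-subset Nagelkerke delta-R^2)
    lives in :func:`grsmr.prs.leave_one_out_prs`.
    """
    if h.m_used < 2:
        raise InsufficientMarkersError("leave-one-out requires at least 2 markers")
    rows = []
    for excluded in h.rsids:
        sub = h.drop_rsids([excluded])
        est = estimate_causal_effect(sub)
        r2_proxy = None
        eafs = [(snp.eaf, snp.omega) for snp, _ in sub.pairs]
        if all(e is not None for e, _ in eafs):
            r2_proxy = float(sum(2.0 * e * (1.0 - e) * w**2 for e, w in eafs))
        row = {
            "excluded_rsid": excluded,
            "m_used": est.m_used,
            "alpha": est.alpha,
            "se_alpha": est.se_alpha,
            "p_assoc": est.p_assoc,
            "variance_explained_proxy": r2_proxy,
        }
        if h.outcome_type == "binary":
            row.update(or_point=est.or_point, or_low=est.or_low, or_high=est.or_high)
        rows.append(row)
    return pd.DataFrame(rows)
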