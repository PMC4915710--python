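"""Summary-statistics causal estimation with a genetic-risk-score instrument.

The estimator is the inverse-variance-weighted (IVW) combination of per-SNP
associations.  With per-allele exposure weights ``omega_j`` and outcome
effects ``beta_j`` (standard error ``se_j``) over M uncorrelated SNPs, the
causal effect of a one-unit increase in the ln exposure on the outcome is

    alpha    = sum(omega_j * beta_j / se_j**2) / sum(omega_j**2 / se_j**2)
    se_alpha = sqrt(1 / sum(omega_j**2 / se_j**2))

which is exactly weighted least-squares regression of ``beta`` on ``omega``
through the origin with weights ``1/se**2``.  Heterogeneity of the per-SNP
ratios about that slope — the signature of pleiotropy — is measured by
Cochran's Q, the weighted residual sum of squares, referred to a chi-square
distribution with M - 1 degrees of freedom.

The module follows the statsmodels convention: :class:`SummaryMR` is the
model, its :meth:`~SummaryMR.fit` returns :class:`MRResults` carrying the
estimate, its uncertainty, the heterogeneity diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateInstrumentError,
    EmptyInstrumentError,
    GrsmrError,
    InsufficientMarkersError,
)
from .io import HarmonizedInstrument

#: Phi^{-1}(0.975): two-sided 95% normal quantile, kept at full precision;
#: rounding happens only at presentation.
Z_95 = 1.959964

SCALE_PER_UNIT = "per_unit_lnCRP"
SCALE_PER_10SPCT = "per_10_spercent"


def f_statistic(r2: float, n: int, k: int = 1) -> float:
    """Instrument-strength F-statistic ``[r2 * (n - 1 - k)] / [(1 - r2) * k]``.

    ``r2`` is the proportion of exposure variance explained by the score,
    ``n`` the exposure-model sample size, ``k`` the number of instruments in
    the regression (1 for a single combined score).  Values above ~10
    indicate weak-instrument bias is unlikely.
    """
    if not 0.0 < r2 < 1.0:
        raise GrsmrError(f"r2 must lie in (0, 1), got {r2}")
    if k < 1:
        raise GrsmrError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise GrsmrError(f"n must exceed k + 1, got n={n}, k={k}")
    return (r2 * (n - 1 - k)) / ((1.0 - r2) * k)


@dataclass(frozen=True)
class MRResults:
    """Causal estimate for one (instrument, outcome) analysis.

    ``alpha`` is on the scale named by ``scale_note``: the default is per
    one-unit increase in the ln exposure (= per 100 sympercent); presenting
    per 10 s% means :meth:`rescale` by 0.1.  For binary outcomes ``alpha``
    is a log odds ratio and ``or_point``/``or_low``/``or_high`` its
    exponentiated 95% interval.
    """

    alpha: float
    se_alpha: float
    m_used: int
    rsids: tuple[str, ...]
    outcome_name: str = ""
    outcome_type: str = "binary"
    grs_label: str = "custom"
    scale_note: str = SCALE_PER_UNIT
    q: float | None = None
    df: int | None = None
    p_het: float | None = None
    per_snp_contrib: tuple[tuple[str, float], ...] = field(default=())

    # -- Wald inference ----------------------------------------------------
    @property
    def z(self) -> float:
        return self.alpha / self.se_alpha

    @property
    def p_assoc(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))

    def conf_int(self) -> tuple[float, float]:
        """95% confidence interval for ``alpha`` on its current scale."""
        return (self.alpha - Z_95 * self.se_alpha, self.alpha + Z_95 * self.se_alpha)

    # -- odds-ratio presentation (binary outcomes) -------------------------
    @property
    def or_point(self) -> float:
        return float(np.exp(self.alpha))

    @property
    def or_low(self) -> float:
        return float(np.exp(self.conf_int()[0]))

    @property
    def or_high(self) -> float:
        return float(np.exp(self.conf_int()[1]))

    def rescale(self, factor: float) -> "MRResults":
        """The same analysis presented per ``factor`` units of ln exposure.

        Multiplies ``alpha`` and ``se_alpha`` (hence the OR/CI); the Wald z
        and p-value are unchanged, as are Q and its p-value, which are
        properties of the data, not of the presentation scale.
        """
        if not factor > 0:
            raise GrsmrError(f"rescale factor must be > 0, got {factor}")
        note = self.scale_note
        if factor != 1.0:
            note = SCALE_PER_10SPCT if factor == 0.1 else f"x{factor:g}_{self.scale_note}"
        return MRResults(
            alpha=self.alpha * factor,
            se_alpha=self.se_alpha * factor,
            m_used=self.m_used,
            rsids=self.rsids,
            outcome_name=self.outcome_name,
            outcome_type=self.outcome_type,
            grs_label=self.grs_label,
            scale_note=note,
            q=self.q,
            df=self.df,
            p_het=self.p_het,
            per_snp_contrib=self.per_snp_contrib,
        )

    def to_row(self) -> dict:
        """Flat record for report tables (one row per analysis)."""
        row = {
            "outcome": self.outcome_name,
            "grs_label": self.grs_label,
            "m_used": self.m_used,
            "alpha": self.alpha,
            "se_alpha": self.se_alpha,
            "p_assoc": self.p_assoc,
            "q": self.q,
            "df": self.df,
            "p_het": self.p_het,
            "scale": self.scale_note,
        }
        lo, hi = self.conf_int()
        if self.outcome_type == "binary":
            row.update(effect=self.or_point, ci_low=self.or_low, ci_high=self.or_high,
                       effect_unit="OR")
        else:
            row.update(effect=self.alpha, ci_low=lo, ci_high=hi, effect_unit="unit")
        return row

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "GRS Mendelian randomization (IVW summary-statistics estimator)",
            "=" * 62,
            f"outcome:        {self.outcome_name or '<unnamed>'} ({self.outcome_type})",
            f"instrument:     {self.grs_label}, M = {self.m_used}",
            f"scale:          {self.scale_note}",
            f"alpha:          {self.alpha:+.4f}  (se {self.se_alpha:.4f})",
            f"95% CI:         [{lo:+.4f}, {hi:+.4f}]",
            f"Wald z, p:      {self.z:+.3f}, {self.p_assoc:.3g}",
        ]
        if self.outcome_type == "binary":
            lines.append(
                f"OR (95% CI):    {self.or_point:.2f} ({self.or_low:.2f} to {self.or_high:.2f})"
            )
        if self.q is not None:
            lines.append(f"Cochran Q:      {self.q:.3f} on {self.df} df, p_het = {self.p_het:.3g}")
        return "\n".join(lines)


class SummaryMR:
    """IVW Mendelian-randomization model for one harmonized analysis.

    Parameters
    ----------
    harmonized
        An allele-aligned :class:`~grsmr.io.HarmonizedInstrument`, or None
        when raw arrays are supplied.
    omega, beta, se_beta, rsids
        Raw per-SNP arrays; used only when ``harmonized`` is None.
    """

    def __init__(
        self,
        harmonized: HarmonizedInstrument | None = None,
        *,
        omega: Sequence[float] | None = None,
        beta: Sequence[float] | None = None,
        se_beta: Sequence[float] | None = None,
        rsids: Sequence[str] | None = None,
        outcome_name: str = "",
        outcome_type: str = "binary",
        grs_label: str = "custom",
    ) -> None:
        if harmonized is not None:
            self.omega = harmonized.omega
            self.beta = harmonized.beta
            self.se_beta = harmonized.se_beta
            self.rsids = tuple(harmonized.rsids)
            self.outcome_name = harmonized.outcome_name
            self.outcome_type = harmonized.outcome_type
            self.grs_label = harmonized.grs_label
        else:
            if omega is None or beta is None or se_beta is None:
                raise GrsmrError("supply either a HarmonizedInstrument or omega/beta/se_beta")
            self.omega = np.asarray(omega, dtype=float)
            self.beta = np.asarray(beta, dtype=float)
            self.se_beta = np.asarray(se_beta, dtype=float)
            if not (len(self.omega) == len(self.beta) == len(self.se_beta)):
                raise GrsmrError("omega, beta, se_beta must have equal length")
            self.rsids = tuple(rsids) if rsids is not None else tuple(
                f"snp{i+1}" for i in range(len(self.omega))
            )
            self.outcome_name = outcome_name
            self.outcome_type = outcome_type
            self.grs_label = grs_label
        if len(self.omega) == 0:
            raise EmptyInstrumentError("no SNPs in the instrument")
        if np.any(self.se_beta <= 0):
            raise GrsmrError("all se_beta must be > 0")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SummaryMR":
        """Build from a frame with columns ``rsid, omega, beta, se_beta``."""
        return cls(
            omega=df["omega"].to_numpy(),
            beta=df["beta"].to_numpy(),
            se_beta=df["se_beta"].to_numpy(),
            rsids=df["rsid"].tolist() if "rsid" in df.columns else None,
            **kwargs,
        )

    @classmethod
    def from_tables(cls, instrument, outcome, proxies=(), **harmonize_kwargs) -> "SummaryMR":
        from .io import harmonize
        return cls(harmonize(instrument, outcome, proxies, **harmonize_kwargs))

    def fit(self) -> MRResults:
        """Closed-form IVW fit; Q diagnostics included when M >= 2."""
        w = 1.0 / self.se_beta**2
        denom = float(np.sum(self.omega**2 * w))
        if denom == 0.0:
            raise DegenerateInstrumentError("all instrument weights are zero")
        alpha = float(np.sum(self.omega * self.beta * w) / denom)
        se_alpha = float(np.sqrt(1.0 / denom))
        q = df = p_het = None
        contrib: tuple[tuple[str, float], ...] = ()
        if len(self.omega) >= 2:
            per = w * (self.beta - alpha * self.omega) ** 2
            q = float(np.sum(per))
            df = len(self.omega) - 1
            p_het = float(stats.chi2.sf(q, df))
            contrib = tuple(zip(self.rsids, per.tolist()))
        return MRResults(
            alpha=alpha,
            se_alpha=se_alpha,
            m_used=len(self.omega),
            rsids=self.rsids,
            outcome_name=self.outcome_name,
            outcome_type=self.outcome_type,
            grs_label=self.grs_label,
            q=q,
            df=df,
            p_het=p_het,
            per_snp_contrib=contrib,
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def estimate_causal_effect(h: HarmonizedInstrument) -> MRResults:
    """IVW causal estimate for an allele-aligned instrument/outcome join."""
    return SummaryMR(h).fit()


def rescale_effect(e: MRResults, factor: float) -> MRResults:
    """Present ``e`` per ``factor`` units of ln exposure (0.1 = per 10 s%)."""
    return e.rescale(factor)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q about the fitted IVW slope, with per-SNP contributions."""

    q: float
    df: int
    p_het: float
    per_snp_contrib: tuple[tuple[str, float], ...]


def q_statistic(h: HarmonizedInstrument, e: MRResults | None = None) -> HeterogeneityResult:
    """Heterogeneity of per-SNP causal ratios about the IVW slope.

    ``contribution_j = (beta_j - alpha * omega_j)^2 / se_j^2``; their sum is
    Q, referred to chi-square with M - 1 df.  A small p_het flags pleiotropy.
    """
    if h.m_used < 2:
        raise InsufficientMarkersError("Q requires at least 2 markers")
    if e is None:
        e = estimate_causal_effect(h)
    w = 1.0 / h.se_beta**2
    per = w * (h.beta - e.alpha * h.omega) ** 2
    q = float(np.sum(per))
    df = h.m_used - 1
    return HeterogeneityResult(
        q=q,
        df=df,
        p_het=float(stats.chi2.sf(q, df)),
        per_snp_contrib=tuple(zip(h.rsids, per.tolist())),
    )
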