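"""Individual-level polygenic-risk-score stage.

The summary-level causal estimate is validated on cohorts with genotype
dosages: a weighted allele-dosage score is built at successive
exposure-association p-value thresholds, z-standardized within cohort,
tested against case status by logistic regression with principal-component
covariates, and the per-cohort estimates are pooled by fixed-effects
inverse-variance meta-analysis.  Reported odds ratios are per 1 SD of the
score.  Variance explained is the Nagelkerke (max-rescaled Cox–Snell)
pseudo-R^2 increment of the full model over the covariates-only model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    DegenerateScoreError,
    EmptyScoreError,
    FitError,
    GrsmrError,
)

#: Exposure p-value thresholds scanned in the individual-level stage.
DEFAULT_THRESHOLDS = (1e-4, 0.001, 0.01, 0.05, 0.1)

_Z95 = 1.959964


@dataclass
class CohortData:
    """One cohort's dosages, case/control status, and covariates.

    ``dosages`` is individuals x SNPs with entries in [0, 2] (imputed allele
    dosage of the effect allele).  ``snp_meta`` has one row per SNP column:
    ``rsid, effect_allele, omega, p_exposure``.  ``pcs`` holds up to ten
    ancestry principal components.
    """

    cohort_id: str
    dosages: np.ndarray
    phenotype: np.ndarray
    pcs: np.ndarray
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.phenotype = np.asarray(self.phenotype)
        self.pcs = np.asarray(self.pcs, dtype=float)
        n = self.dosages.shape[0]
        if self.phenotype.shape[0] != n or self.pcs.shape[0] != n:
            raise GrsmrError("dosages, phenotype and pcs must have equal row counts")
        if len(self.snp_meta) != self.dosages.shape[1]:
            raise GrsmrError("snp_meta rows must match dosage columns")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise GrsmrError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]


@dataclass(frozen=True)
class PRSAssociation:
    """One cohort's (or the pooled) score-vs-case-status association."""

    beta_per_sd: float
    se: float
    n: int
    threshold: float | None = None
    n_snps: int | None = None
    delta_r2_nagelkerke: float | None = None
    cohort_id: str = ""

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.beta_per_sd / self.se)))

    @property
    def or_per_sd(self) -> float:
        return math.exp(self.beta_per_sd)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta_per_sd - _Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta_per_sd + _Z95 * self.se)

    def to_row(self) -> dict:
        return {
            "cohort": self.cohort_id,
            "threshold": self.threshold,
            "n_snps": self.n_snps,
            "n": self.n,
            "beta_per_sd": self.beta_per_sd,
            "se": self.se,
            "p": self.p,
            "or_per_sd": self.or_per_sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "delta_r2_nagelkerke": self.delta_r2_nagelkerke,
        }


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def compute_prs(cohort: CohortData, threshold: float = 1.0,
                snp_mask: np.ndarray | None = None) -> np.ndarray:
    """Standardized weighted dosage score over SNPs passing ``threshold``.

    ``score_i = sum_j omega_j * dosage_ij`` over SNPs whose exposure
    p-value is <= ``threshold`` (optionally intersected with ``snp_mask``),
    then z-standardized within the cohort (mean 0, SD 1; population SD).
    """
    p_exp = cohort.snp_meta["p_exposure"].to_numpy(dtype=float)
    keep = p_exp <= threshold
    if snp_mask is not None:
        keep = keep & np.asarray(snp_mask, dtype=bool)
    if not keep.any():
        raise EmptyScoreError(f"no SNP passes exposure p <= {threshold}")
    omega = cohort.snp_meta["omega"].to_numpy(dtype=float)[keep]
    raw = cohort.dosages[:, keep] @ omega
    sd = float(raw.std())
    if sd == 0.0:
        raise DegenerateScoreError("polygenic score has zero variance")
    return (raw - raw.mean()) / sd


def n_snps_at(cohort: CohortData, threshold: float) -> int:
    return int((cohort.snp_meta["p_exposure"].to_numpy(dtype=float) <= threshold).sum())


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def _logit_fit(y: np.ndarray, X: np.ndarray):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    # IRLS; tolerance on the parameter change
    res = model.fit(maxiter=100, tol=1e-8, scale=1.0)
    if not res.converged:
        raise FitError("logistic IRLS did not converge within 100 iterations")
    if not np.all(np.isfinite(res.bse)):
        raise FitError("non-finite standard errors (possible separation)")
    return res


def associate_prs(
    cohort: CohortData,
    score: np.ndarray,
    threshold: float | None = None,
    with_delta_r2: bool = True,
) -> PRSAssociation:
    """Logistic association of a standardized score with case status.

    Fits ``phenotype ~ intercept + score + PCs`` by iteratively reweighted
    least squares.  The coefficient of the score is the log-OR per 1 SD.
    When ``with_delta_r2`` is set, the covariates-only model is also fitted
    and the Nagelkerke pseudo-R^2 increment reported.
    """
    y = np.asarray(cohort.phenotype, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise FitError(f"phenotype has a single class ({classes})")
    n = len(y)
    X_null = np.column_stack([np.ones(n), cohort.pcs]) if cohort.pcs.size else np.ones((n, 1))
    X_full = np.column_stack([X_null[:, :1], np.asarray(score, dtype=float), X_null[:, 1:]])
    full = _logit_fit(y, X_full)
    beta = float(full.params[1])
    se = float(full.bse[1])
    delta_r2 = None
    if with_delta_r2:
        null = _logit_fit(y, X_null)
        delta_r2 = nagelkerke_delta_r2(float(null.llf), float(full.llf), n)
    nsnp = n_snps_at(cohort, threshold) if threshold is not None else None
    return PRSAssociation(
        beta_per_sd=beta,
        se=se,
        n=n,
        threshold=threshold,
        n_snps=nsnp,
        delta_r2_nagelkerke=delta_r2,
        cohort_id=cohort.cohort_id,
    )


def nagelkerke_delta_r2(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke (max-rescaled Cox–Snell) pseudo-R^2 of full over null.

    ``R2_CS = 1 - exp(2 (ll_null - ll_full) / n)`` rescaled by its maximum
    attainable value ``1 - exp(2 ll_null / n)``.
    """
    if n < 1:
        raise GrsmrError("n must be >= 1")
    if ll_full < ll_null - 1e-8 * max(1.0, abs(ll_null)):
        raise GrsmrError(
            f"ll_full ({ll_full}) < ll_null ({ll_null}): models are not nested"
        )
    r2_cs = 1.0 - math.exp(2.0 * (ll_null - ll_full) / n)
    r2_max = 1.0 - math.exp(2.0 * ll_null / n)
    return r2_cs / r2_max


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

def meta_analyze(results: Sequence[PRSAssociation]) -> PRSAssociation:
    """Fixed-effects inverse-variance pooling of per-cohort associations.

    ``beta = sum(w_i b_i) / sum(w_i)`` with ``w_i = 1/se_i^2`` and pooled
    ``se = sum(w_i)^{-1/2}``.  Pooled Nagelkerke delta-R^2 is the
    sample-size-weighted mean of the cohort values when all are present.
    """
    if not results:
        raise GrsmrError("meta_analyze needs at least one cohort result")
    b = np.array([r.beta_per_sd for r in results])
    w = np.array([1.0 / r.se**2 for r in results])
    pooled_b = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    ns = np.array([r.n for r in results], dtype=float)
    d = [r.delta_r2_nagelkerke for r in results]
    pooled_d = float(np.sum(ns * np.array(d)) / ns.sum()) if all(x is not None for x in d) else None
    thr = {r.threshold for r in results}
    return PRSAssociation(
        beta_per_sd=pooled_b,
        se=pooled_se,
        n=int(ns.sum()),
        threshold=thr.pop() if len(thr) == 1 else None,
        n_snps=results[0].n_snps if len({r.n_snps for r in results}) == 1 else None,
        delta_r2_nagelkerke=pooled_d,
        cohort_id="pooled",
    )


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def threshold_scan(
    cohorts: Sequence[CohortData],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    with_delta_r2: bool = True,
) -> pd.DataFrame:
    """Per-threshold pooled association across cohorts.

    Cohorts in which no SNP passes a threshold are skipped for that
    threshold; a threshold with no usable cohort produces no row.
    """
    rows = []
    for thr in thresholds:
        per_cohort = []
        for c in cohorts:
            try:
                score = compute_prs(c, thr)
            except EmptyScoreError:
                continue
            per_cohort.append(associate_prs(c, score, threshold=thr,
                                            with_delta_r2=with_delta_r2))
        if not per_cohort:
            continue
        pooled = meta_analyze(per_cohort)
        pooled = replace(pooled, n_snps=max(r.n_snps or 0 for r in per_cohort))
        rows.append(pooled.to_row())
    return pd.DataFrame(rows)


def leave_one_out_prs(cohort: CohortData, with_delta_r2: bool = True) -> pd.DataFrame:
    """Refit the score association once per excluded SNP (all SNPs kept
    otherwise), reporting the per-subset Nagelkerke delta-R^2."""
    m = cohort.dosages.shape[1]
    rows = []
    for j in range(m):
        mask = np.ones(m, dtype=bool)
        mask[j] = False
        score = compute_prs(cohort, threshold=1.0, snp_mask=mask)
        res = associate_prs(cohort, score, with_delta_r2=with_delta_r2)
        row = res.to_row()
        row["excluded_rsid"] = cohort.snp_meta["rsid"].iloc[j]
        rows.append(row)
    cols = ["excluded_rsid"] + [c for c in rows[0] if c != "excluded_rsid"]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# cohort table I/O
# ---------------------------------------------------------------------------

def read_cohort(
    dosage_path: str | Path,
    pheno_path: str | Path,
    snp_meta_path: str | Path,
    cohort_id: str | None = None,
    sep: str = "\t",
) -> CohortData:
    """Assemble a :class:`CohortData` from three TSVs.

    ``dosage_path``: individuals x SNPs, first column ``individual_id``,
    remaining headers are rsids.  ``pheno_path``: ``individual_id,
    phenotype`` plus any number of ``PC*`` columns.  ``snp_meta_path``:
    ``rsid, effect_allele, omega, p_exposure``.
    """
    dos = pd.read_csv(dosage_path, sep=sep).set_index("individual_id")
    pheno = pd.read_csv(pheno_path, sep=sep).set_index("individual_id")
    meta = pd.read_csv(snp_meta_path, sep=sep)
    for col in ("rsid", "omega", "p_exposure"):
        if col not in meta.columns:
            raise GrsmrError(f"snp meta table missing column '{col}'")
    pheno = pheno.loc[dos.index]
    meta = meta.set_index("rsid").loc[list(dos.columns)].reset_index()
    pc_cols = [c for c in pheno.columns if c.upper().startswith("PC")]
    return CohortData(
        cohort_id=cohort_id or Path(dosage_path).stem,
        dosages=dos.to_numpy(dtype=float),
        phenotype=pheno["phenotype"].to_numpy(dtype=int),
        pcs=pheno[pc_cols].to_numpy(dtype=float) if pc_cols else np.empty((len(pheno), 0)),
        snp_meta=meta,
    )


def write_cohort(cohort: CohortData, outdir: str | Path, sep: str = "\t") -> dict[str, Path]:
    """Write the three cohort TSVs consumed by :func:`read_cohort`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = [f"{cohort.cohort_id}_{i+1}" for i in range(cohort.n_individuals)]
    dpath = outdir / f"{cohort.cohort_id}_dosages.tsv"
    ppath = outdir / f"{cohort.cohort_id}_pheno.tsv"
    mpath = outdir / f"{cohort.cohort_id}_snps.tsv"
    dos = pd.DataFrame(cohort.dosages, columns=cohort.snp_meta["rsid"].tolist())
    dos.insert(0, "individual_id", ids)
    dos.to_csv(dpath, sep=sep, index=False)
    ph = pd.DataFrame({"individual_id": ids, "phenotype": cohort.phenotype})
    for k in range(cohort.pcs.shape[1]):
        ph[f"PC{k+1}"] = cohort.pcs[:, k]
    ph.to_csv(ppath, sep=sep, index=False)
    cohort.snp_meta.to_csv(mpath, sep=sep, index=False)
    return {"dosages": dpath, "pheno": ppath, "snp_meta": mpath}
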