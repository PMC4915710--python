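"""Instrument and outcome summary-statistics tables, and allele harmonization.

The exposure instrument is a weighted set of SNPs: each carries a per-allele
effect ``omega`` on the natural-log exposure (here ln CRP, in ln(mg/l) per
dose of the effect allele).  Outcome tables carry per-allele effects ``beta``
(log odds ratios for binary outcomes, trait units otherwise) with standard
errors.  ``harmonize`` joins the two by rsid, reorients swapped allele
codings (flipping the sign of ``beta``), resolves missing SNPs through a
linkage-disequilibrium proxy table when one is supplied, and records every
drop with a reason so the join is auditable.

Tables are plain text: tab-separated by default, header row, ``.`` for
missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyInstrumentError,
    SchemaError,
    TableParseError,
)

logger = logging.getLogger(__name__)

_MISSING = "."

#: Allele pairs that are their own reverse complement; strand flips are
#: undetectable for these, so they are flagged (or dropped in strict mode).
_PALINDROMIC = ({"A", "T"}, {"C", "G"})


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InstrumentSNP:
    """One exposure-associated variant with its per-allele weight.

    ``omega`` is the per-allele effect on the ln exposure; ``omega_se`` its
    standard error from the exposure GWAS.  ``eaf`` is the effect-allele
    frequency, optional but required by the instrument-variance bookkeeping.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    omega: float
    omega_se: float | None = None
    eaf: float | None = None
    chrom: str | None = None
    pos: int | None = None
    locus_label: str | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise SchemaError(
                f"{self.rsid}: effect and other allele are identical "
                f"({self.effect_allele})"
            )
        if self.omega_se is not None and not self.omega_se > 0:
            raise SchemaError(f"{self.rsid}: omega_se must be > 0, got {self.omega_se}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise SchemaError(f"{self.rsid}: eaf must lie in [0, 1], got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in _PALINDROMIC


@dataclass(frozen=True)
class OutcomeAssociation:
    """One variant's per-allele association with one outcome."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se_beta: float
    outcome_name: str = ""
    outcome_type: str = "binary"  # "binary" | "quantitative"
    n_total: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if not self.se_beta > 0:
            raise SchemaError(f"{self.rsid}: se_beta must be > 0, got {self.se_beta}")
        if self.outcome_type not in ("binary", "quantitative"):
            raise SchemaError(
                f"{self.rsid}: outcome_type must be 'binary' or 'quantitative', "
                f"got {self.outcome_type!r}"
            )
        if (
            self.n_total is not None
            and self.n_cases is not None
            and self.n_controls is not None
            and self.n_cases + self.n_controls != self.n_total
        ):
            raise SchemaError(
                f"{self.rsid}: n_cases + n_controls != n_total "
                f"({self.n_cases} + {self.n_controls} != {self.n_total})"
            )

    def flipped(self) -> "OutcomeAssociation":
        """The same association reported for the opposite allele coding."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
        )


@dataclass(frozen=True)
class ProxyRecord:
    """A substitute variant in high LD with an instrument SNP."""

    original_rsid: str
    proxy_rsid: str
    r2: float
    distance_bp: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise SchemaError(
                f"proxy {self.proxy_rsid} for {self.original_rsid}: "
                f"r2 must lie in [0, 1], got {self.r2}"
            )
        if self.distance_bp < 0:
            raise SchemaError("distance_bp must be non-negative")


@dataclass
class HarmonizedInstrument:
    """Allele-aligned join of an instrument with one outcome's statistics.

    ``pairs`` holds ``(InstrumentSNP, OutcomeAssociation)`` tuples whose
    effect alleles agree (for proxy-resolved pairs the outcome record is the
    proxy variant).  ``dropped`` records ``(rsid, reason)`` for every
    instrument SNP not used; ``m_used + len(dropped)`` always equals the
    original instrument size.
    """

    pairs: list[tuple[InstrumentSNP, OutcomeAssociation]]
    dropped: list[tuple[str, str]] = field(default_factory=list)
    proxies_used: list[ProxyRecord] = field(default_factory=list)
    palindromic: list[str] = field(default_factory=list)
    unaligned_proxies: list[str] = field(default_factory=list)
    outcome_name: str = ""
    outcome_type: str = "binary"
    grs_label: str = "custom"

    @property
    def m_used(self) -> int:
        return len(self.pairs)

    @property
    def rsids(self) -> list[str]:
        return [snp.rsid for snp, _ in self.pairs]

    @property
    def omega(self) -> np.ndarray:
        return np.array([snp.omega for snp, _ in self.pairs], dtype=float)

    @property
    def beta(self) -> np.ndarray:
        return np.array([assoc.beta for _, assoc in self.pairs], dtype=float)

    @property
    def se_beta(self) -> np.ndarray:
        return np.array([assoc.se_beta for _, assoc in self.pairs], dtype=float)

    def subset(self, keep_rsids: Iterable[str]) -> "HarmonizedInstrument":
        """A copy restricted to instrument rsids in ``keep_rsids`` (order kept)."""
        keep = set(keep_rsids)
        return HarmonizedInstrument(
            pairs=[p for p in self.pairs if p[0].rsid in keep],
            dropped=list(self.dropped),
            proxies_used=list(self.proxies_used),
            palindromic=[r for r in self.palindromic if r in keep],
            unaligned_proxies=[r for r in self.unaligned_proxies if r in keep],
            outcome_name=self.outcome_name,
            outcome_type=self.outcome_type,
            grs_label=self.grs_label,
        )

    def drop_rsids(self, remove: Iterable[str]) -> "HarmonizedInstrument":
        remove = set(remove)
        return self.subset([r for r in self.rsids if r not in remove])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for snp, assoc in self.pairs:
            rows.append(
                {
                    "rsid": snp.rsid,
                    "outcome_rsid": assoc.rsid,
                    "effect_allele": snp.effect_allele,
                    "other_allele": snp.other_allele,
                    "omega": snp.omega,
                    "omega_se": snp.omega_se,
                    "beta": assoc.beta,
                    "se_beta": assoc.se_beta,
                    "locus": snp.locus_label,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "rsid", "outcome_rsid", "effect_allele", "other_allele",
                "omega", "omega_se", "beta", "se_beta", "locus",
            ],
        )


# ---------------------------------------------------------------------------
# table readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, sep: str, required: Sequence[str],
                numeric: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=[_MISSING, ""],
                     keep_default_na=False, comment="#")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column '{col}'")
    for col in numeric:
        if col not in df.columns:
            continue
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableParseError(
                f"{path.name}: non-numeric value {raw.iloc[row]!r} in column "
                f"'{col}' at data row {row + 1}"
            )
        df[col] = parsed
    return df


def _check_unique_rsid(df: pd.DataFrame, name: str) -> None:
    dup = df["rsid"][df["rsid"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"{name}: duplicated rsid '{dup.iloc[0]}'")


def _opt_float(value) -> float | None:
    return None if pd.isna(value) else float(value)


def _opt_int(value) -> int | None:
    return None if pd.isna(value) else int(value)


def read_weights(path: str | Path, sep: str = "\t") -> list[InstrumentSNP]:
    """Read an instrument weight table into :class:`InstrumentSNP` records.

    Required columns: ``rsid, effect_allele, other_allele, omega``.
    Optional: ``omega_se, eaf, chrom, pos, locus``.  Row order is preserved;
    duplicated rsids are an error; an empty table logs a warning.
    """
    df = _read_table(
        path, sep,
        required=("rsid", "effect_allele", "other_allele", "omega"),
        numeric=("omega", "omega_se", "eaf", "pos"),
    )
    if df.empty:
        logger.warning("weight table %s contains no rows", path)
        return []
    _check_unique_rsid(df, Path(path).name)
    out = []
    for _, row in df.iterrows():
        out.append(
            InstrumentSNP(
                rsid=row["rsid"],
                effect_allele=row["effect_allele"],
                other_allele=row["other_allele"],
                omega=float(row["omega"]),
                omega_se=_opt_float(row.get("omega_se")),
                eaf=_opt_float(row.get("eaf")),
                chrom=row.get("chrom") if "chrom" in df.columns and pd.notna(row.get("chrom")) else None,
                pos=_opt_int(row.get("pos")) if "pos" in df.columns else None,
                locus_label=row.get("locus") if "locus" in df.columns and pd.notna(row.get("locus")) else None,
            )
        )
    return out


def read_outcome_stats(
    path: str | Path,
    sep: str = "\t",
    outcome_name: str | None = None,
    outcome_type: str | None = None,
) -> list[OutcomeAssociation]:
    """Read an outcome summary-statistics table.

    Required columns: ``rsid, effect_allele, other_allele, beta, se_beta``.
    Optional: ``n_total, n_cases, n_controls, outcome_name, outcome_type``.
    If ``outcome_type`` is neither a column nor an argument it is inferred:
    binary when case counts are present, quantitative otherwise.
    """
    df = _read_table(
        path, sep,
        required=("rsid", "effect_allele", "other_allele", "beta", "se_beta"),
        numeric=("beta", "se_beta", "n_total", "n_cases", "n_controls"),
    )
    if df.empty:
        logger.warning("outcome table %s contains no rows", path)
        return []
    _check_unique_rsid(df, Path(path).name)
    out = []
    for _, row in df.iterrows():
        n_cases = _opt_int(row.get("n_cases")) if "n_cases" in df.columns else None
        name = outcome_name
        if name is None:
            name = row.get("outcome_name") if "outcome_name" in df.columns else ""
        otype = outcome_type
        if otype is None and "outcome_type" in df.columns and pd.notna(row.get("outcome_type")):
            otype = row["outcome_type"]
        if otype is None:
            otype = "binary" if n_cases is not None else "quantitative"
        out.append(
            OutcomeAssociation(
                rsid=row["rsid"],
                effect_allele=row["effect_allele"],
                other_allele=row["other_allele"],
                beta=float(row["beta"]),
                se_beta=float(row["se_beta"]),
                outcome_name=name or "",
                outcome_type=otype,
                n_total=_opt_int(row.get("n_total")) if "n_total" in df.columns else None,
                n_cases=n_cases,
                n_controls=_opt_int(row.get("n_controls")) if "n_controls" in df.columns else None,
            )
        )
    return out


def read_proxies(path: str | Path, sep: str = "\t") -> list[ProxyRecord]:
    """Read a proxy/LD table: ``original_rsid, proxy_rsid, r2, distance_bp``."""
    df = _read_table(
        path, sep,
        required=("original_rsid", "proxy_rsid", "r2"),
        numeric=("r2", "distance_bp"),
    )
    out = []
    for _, row in df.iterrows():
        out.append(
            ProxyRecord(
                original_rsid=row["original_rsid"],
                proxy_rsid=row["proxy_rsid"],
                r2=float(row["r2"]),
                distance_bp=_opt_int(row.get("distance_bp")) if "distance_bp" in df.columns else 0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# table writers
# ---------------------------------------------------------------------------

def write_weights(snps: Sequence[InstrumentSNP], path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "rsid": [s.rsid for s in snps],
            "chrom": [s.chrom if s.chrom is not None else _MISSING for s in snps],
            "pos": [s.pos if s.pos is not None else _MISSING for s in snps],
            "effect_allele": [s.effect_allele for s in snps],
            "other_allele": [s.other_allele for s in snps],
            "omega": [s.omega for s in snps],
            "omega_se": [s.omega_se if s.omega_se is not None else _MISSING for s in snps],
            "eaf": [s.eaf if s.eaf is not None else _MISSING for s in snps],
            "locus": [s.locus_label if s.locus_label is not None else _MISSING for s in snps],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def write_outcome_stats(assocs: Sequence[OutcomeAssociation], path: str | Path,
                        sep: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "rsid": [a.rsid for a in assocs],
            "effect_allele": [a.effect_allele for a in assocs],
            "other_allele": [a.other_allele for a in assocs],
            "beta": [a.beta for a in assocs],
            "se_beta": [a.se_beta for a in assocs],
            "n_total": [a.n_total if a.n_total is not None else _MISSING for a in assocs],
            "n_cases": [a.n_cases if a.n_cases is not None else _MISSING for a in assocs],
            "n_controls": [a.n_controls if a.n_controls is not None else _MISSING for a in assocs],
            "outcome_name": [a.outcome_name for a in assocs],
            "outcome_type": [a.outcome_type for a in assocs],
        }
    )
    df.to_csv(path, sep=sep, index=False)


def write_harmonization_audit(h: HarmonizedInstrument, path: str | Path,
                              sep: str = "\t") -> None:
    """Audit trail: one row per instrument SNP, its action and reason."""
    proxy_for = {p.original_rsid: p for p in h.proxies_used}
    rows = []
    for snp, assoc in h.pairs:
        if snp.rsid in proxy_for:
            action, reason = "proxy", f"{proxy_for[snp.rsid].proxy_rsid} r2={proxy_for[snp.rsid].r2}"
        else:
            action, reason = "kept", _MISSING
        if snp.rsid in h.palindromic:
            reason = "palindromic" if reason == _MISSING else reason + ";palindromic"
        rows.append({"rsid": snp.rsid, "action": action, "reason": reason})
    for rsid, why in h.dropped:
        rows.append({"rsid": rsid, "action": "dropped", "reason": why})
    pd.DataFrame(rows, columns=["rsid", "action", "reason"]).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _align(snp: InstrumentSNP, assoc: OutcomeAssociation) -> OutcomeAssociation | None:
    """Reorient ``assoc`` to the instrument's effect allele, or None on mismatch.

    Matching is by nucleotide identity only — no strand inference; palindromic
    SNPs are handled by the caller's flag/drop policy.
    """
    if (assoc.effect_allele, assoc.other_allele) == (snp.effect_allele, snp.other_allele):
        return assoc
    if (assoc.effect_allele, assoc.other_allele) == (snp.other_allele, snp.effect_allele):
        return assoc.flipped()
    return None


def _best_proxy(rsid: str, proxies: Sequence[ProxyRecord],
                available: dict[str, OutcomeAssociation],
                r2_min: float) -> ProxyRecord | None:
    """Eligible proxy with maximal r2 (strict r2 > r2_min); ties broken by
    smallest distance, then lexicographic proxy rsid."""
    cands = [
        p for p in proxies
        if p.original_rsid == rsid and p.r2 > r2_min and p.proxy_rsid in available
    ]
    if not cands:
        return None
    return min(cands, key=lambda p: (-p.r2, p.distance_bp, p.proxy_rsid))


def harmonize(
    instrument: Sequence[InstrumentSNP],
    outcome: Sequence[OutcomeAssociation],
    proxies: Sequence[ProxyRecord] = (),
    *,
    r2_min: float = 0.9,
    drop_palindromic: bool = False,
    outcome_name: str | None = None,
    grs_label: str = "custom",
) -> HarmonizedInstrument:
    """Join instrument weights with outcome statistics, allele-aligned.

    For each instrument SNP, in order: a direct rsid match is used if the
    outcome table has one; otherwise the best eligible proxy (r2 strictly
    above ``r2_min``) is substituted; otherwise the SNP is dropped with
    reason ``"missing"``.  Outcome records coded on the opposite allele have
    beta sign-flipped; allele sets matching neither orientation are dropped
    with reason ``"allele_mismatch"``.  Palindromic (A/T, C/G) SNPs are
    retained but flagged, or dropped when ``drop_palindromic`` is set.
    """
    if not instrument:
        raise EmptyInstrumentError("instrument contains no SNPs")
    by_rsid = {a.rsid: a for a in outcome}
    pairs: list[tuple[InstrumentSNP, OutcomeAssociation]] = []
    dropped: list[tuple[str, str]] = []
    proxies_used: list[ProxyRecord] = []
    palindromic: list[str] = []
    unaligned_proxies: list[str] = []

    inferred_name = outcome_name
    inferred_type = None
    for snp in instrument:
        if snp.is_palindromic and drop_palindromic:
            dropped.append((snp.rsid, "palindromic"))
            continue
        assoc = by_rsid.get(snp.rsid)
        via_proxy = None
        if assoc is None:
            via_proxy = _best_proxy(snp.rsid, proxies, by_rsid, r2_min)
            if via_proxy is None:
                dropped.append((snp.rsid, "missing"))
                continue
            assoc = by_rsid[via_proxy.proxy_rsid]
        aligned = _align(snp, assoc)
        if aligned is None:
            if via_proxy is None:
                dropped.append((snp.rsid, "allele_mismatch"))
                continue
            # A proxy is a different variant: its alleles need not match the
            # original's, so accept the record as supplied and flag it.
            aligned = assoc
            unaligned_proxies.append(snp.rsid)
        if via_proxy is not None:
            proxies_used.append(via_proxy)
        if snp.is_palindromic:
            palindromic.append(snp.rsid)
        pairs.append((snp, aligned))
        if inferred_name is None and aligned.outcome_name:
            inferred_name = aligned.outcome_name
        if inferred_type is None:
            inferred_type = aligned.outcome_type

    if not pairs:
        raise EmptyInstrumentError(
            f"all {len(instrument)} instrument SNPs were dropped "
            f"({', '.join(sorted({r for _, r in dropped}))})"
        )
    return HarmonizedInstrument(
        pairs=pairs,
        dropped=dropped,
        proxies_used=proxies_used,
        palindromic=palindromic,
        unaligned_proxies=unaligned_proxies,
        outcome_name=inferred_name or "",
        outcome_type=inferred_type or "binary",
        grs_label=grs_label,
    )
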