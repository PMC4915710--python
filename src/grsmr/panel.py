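"""Multi-outcome panel orchestration and significance tiering.

A panel run takes one or more instruments (each a weight table plus the
fraction of exposure variance it explains) and a set of outcome
summary-statistics tables with sample-size metadata.  For every
(instrument, outcome) pair it harmonizes, estimates the causal effect,
computes the instrument-strength F-statistic and Cochran's Q, and tiers the
association p-value against a Bonferroni threshold (global level divided by
the number of independent outcome sample sets) and a nominal 0.05 level.
A second pass re-estimates every heterogeneous analysis after stepwise
pleiotropy pruning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import GrsmrError
from .io import harmonize, read_outcome_stats, read_proxies, read_weights, write_harmonization_audit
from .model import estimate_causal_effect, f_statistic
from .pleiotropy import prune_heterogeneity

logger = logging.getLogger(__name__)

TIER_SIGNIFICANT = "significant"
TIER_NOMINAL = "nominal"
TIER_NONE = "none"


def bonferroni_threshold(global_level: float, n_tests: int) -> float:
    """``global_level / n_tests``; reports round it to 4 decimals."""
    if n_tests < 1:
        raise GrsmrError("n_tests must be >= 1")
    if not 0.0 < global_level <= 1.0:
        raise GrsmrError("global_level must lie in (0, 1]")
    return global_level / n_tests


def classify_significance(p: float, bonf: float, nominal: float = 0.05) -> str:
    """Three-tier call with inclusive boundaries: p <= bonf is significant,
    bonf < p <= nominal is nominal evidence, p > nominal is none."""
    if not 0.0 <= p <= 1.0:
        raise GrsmrError(f"p must lie in [0, 1], got {p}")
    if p <= bonf:
        return TIER_SIGNIFICANT
    if p <= nominal:
        return TIER_NOMINAL
    return TIER_NONE


@dataclass(frozen=True)
class GRSSpec:
    """One instrument: its weight table and exposure variance explained."""

    label: str
    weights_path: str
    r2: float


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome table with its panel metadata."""

    name: str
    path: str
    outcome_type: str = "binary"
    n_total: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    disease_class: str = ""


@dataclass
class PanelConfig:
    grs: list[GRSSpec]
    outcomes: list[OutcomeSpec]
    proxies_path: str | None = None
    global_level: float = 0.05
    n_tests: int | None = None  # Bonferroni denominator; default = #outcomes
    nominal_level: float = 0.05
    prune_threshold: float = 0.05
    r2_min_proxy: float = 0.9
    drop_palindromic: bool = False
    outdir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            grs=[GRSSpec(**g) for g in raw["grs"]],
            outcomes=[OutcomeSpec(**o) for o in raw["outcomes"]],
            **{k: v for k, v in raw.items() if k not in ("grs", "outcomes")},
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "grs": [g.__dict__ for g in self.grs],
                "outcomes": [o.__dict__ for o in self.outcomes],
                "proxies_path": self.proxies_path,
                "global_level": self.global_level,
                "n_tests": self.n_tests,
                "nominal_level": self.nominal_level,
                "prune_threshold": self.prune_threshold,
                "r2_min_proxy": self.r2_min_proxy,
                "drop_palindromic": self.drop_palindromic,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PanelReport:
    """Main per-analysis table, post-pruning table, and recorded failures."""

    main: pd.DataFrame
    pruned: pd.DataFrame
    failures: list[tuple[str, str, str]] = field(default_factory=list)

    def write(self, outdir: str | Path, config: PanelConfig | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.main.to_csv(outdir / "panel_results.tsv", sep="\t", index=False)
        self.pruned.to_csv(outdir / "panel_results_pruned.tsv", sep="\t", index=False)
        log = {
            "tool": "grsmr",
            "version": _version(),
            "failures": [list(f) for f in self.failures],
        }
        if config is not None:
            log["config_hash"] = config.config_hash()
            log["seed"] = config.seed
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))


def _version() -> str:
    from . import __version__
    return __version__


_MAIN_COLS = [
    "outcome", "disease_class", "grs_label", "m_used", "n", "alpha", "se_alpha",
    "effect", "ci_low", "ci_high", "effect_unit", "p_assoc", "q", "df", "p_het",
    "f_value", "bonferroni", "tier",
]


def run_panel(cfg: PanelConfig) -> PanelReport:
    """Run every (instrument, outcome) analysis and tier the results.

    Per-analysis failures are recorded and skipped so one bad table does not
    abort the panel; an entirely empty panel raises.  With ``cfg.outdir``
    set, result tables, per-analysis harmonization audits, pruning traces
    and a run log are written there.
    """
    if not cfg.grs or not cfg.outcomes:
        raise GrsmrError("panel needs at least one instrument and one outcome")
    n_tests = cfg.n_tests if cfg.n_tests is not None else len(cfg.outcomes)
    bonf = bonferroni_threshold(cfg.global_level, n_tests)
    proxies = read_proxies(cfg.proxies_path) if cfg.proxies_path else ()
    outdir = Path(cfg.outdir) if cfg.outdir else None

    main_rows, pruned_rows, failures = [], [], []
    for g in cfg.grs:
        instrument = read_weights(g.weights_path)
        for o in cfg.outcomes:
            try:
                outcome = read_outcome_stats(o.path, outcome_name=o.name,
                                             outcome_type=o.outcome_type)
                h = harmonize(
                    instrument, outcome, proxies,
                    r2_min=cfg.r2_min_proxy,
                    drop_palindromic=cfg.drop_palindromic,
                    outcome_name=o.name, grs_label=g.label,
                )
                est = estimate_causal_effect(h)
            except Exception as exc:  # noqa: BLE001 - recorded, run continues
                logger.warning("analysis (%s, %s) failed: %s", g.label, o.name, exc)
                failures.append((g.label, o.name, str(exc)))
                continue
            f_val = (
                f_statistic(g.r2, o.n_total, 1) if o.n_total else None
            )
            row = est.to_row()
            row.update(
                disease_class=o.disease_class,
                n=o.n_total,
                f_value=f_val,
                bonferroni=round(bonf, 4),
                tier=classify_significance(est.p_assoc, bonf, cfg.nominal_level),
            )
            main_rows.append(row)
            if outdir is not None:
                audits = outdir / "audits"
                audits.mkdir(parents=True, exist_ok=True)
                write_harmonization_audit(h, audits / f"{g.label}_{o.name}_harmonization.tsv")

            if est.p_het is not None and est.p_het < cfg.prune_threshold and h.m_used > 2:
                trace = prune_heterogeneity(h, cfg.prune_threshold)
                prow = trace.final_estimate.to_row()
                prow.update(
                    disease_class=o.disease_class,
                    n=o.n_total,
                    f_value=f_val,
                    bonferroni=round(bonf, 4),
                    tier=classify_significance(
                        trace.final_estimate.p_assoc, bonf, cfg.nominal_level
                    ),
                    removed=",".join(trace.removed_rsids),
                    floor_warning=trace.floor_warning,
                )
                pruned_rows.append(prow)
                if outdir is not None:
                    audits = outdir / "audits"
                    trace.to_dataframe().to_csv(
                        audits / f"{g.label}_{o.name}_pruning.tsv", sep="\t", index=False
                    )

    if not main_rows:
        raise GrsmrError("every panel analysis failed; nothing to report")
    main = pd.DataFrame(main_rows)[[c for c in _MAIN_COLS if c in main_rows[0]]]
    pruned_cols = _MAIN_COLS + ["removed", "floor_warning"]
    pruned = pd.DataFrame(pruned_rows)
    if not pruned.empty:
        pruned = pruned[[c for c in pruned_cols if c in pruned.columns]]
    report = PanelReport(main=main, pruned=pruned, failures=failures)
    if outdir is not None:
        report.write(outdir, cfg)
    return report
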