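"""End-to-end pipeline driver and report rendering.

:func:`run_pipeline` takes a :class:`RunConfig` (an input Patient CSV or a
simulation spec), builds the requested cohorts, and writes a versioned
bundle of JSON/CSV/Markdown artifacts: per-endpoint band-metrics tables,
the Bayes post-test matrix, sequential qSOFA rates, clinical-utility
summaries, survival curves, and a count reconciliation log (input →
included → excluded per reason).  Every number in a rendered table is the
corresponding metrics-module output — the renderer only formats.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bands import BANDS_DESCENDING, Band
from .bayes import DEFAULT_GRID, ThresholdPolicy, post_test_matrix, threshold_crossing
from .cohort import Cohort, build_cohort, read_patient_csv
from .metrics import (
    BandTable,
    actionable_fraction,
    band_metrics_table,
    build_band_contingency,
    lr_fold_range,
    round_half_up,
)
from .sequential import combined_rule_sensitivity, stratified_outcome_rates
from .survival import band_hazard_ratios, icu_care_survival_data, km_estimate
from .synthetic import CohortSpec, generate
from .utility import antibiotic_reclassification, lactate_zone_analysis, sepsis_crosstab

logger = logging.getLogger(__name__)

DIAGNOSTIC_ENDPOINTS = ("bacterial", "viral")


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; exactly one of input_csv / simulation."""

    input_csv: Optional[str] = None
    simulation: Optional[CohortSpec] = None
    endpoints: Sequence[str] = ("bacterial", "viral", "severity")
    adjudication: str = "consensus"
    ci_level: float = 0.80
    ci_method: str = "log_normal"
    n_boot: int = 2000
    seed: int = 0
    outdir: str = "bandeval-report"
    band_convention: str = "table"

    def validate(self) -> "RunConfig":
        if (self.input_csv is None) == (self.simulation is None):
            raise ValueError(
                "config must set exactly one of input_csv or simulation"
            )
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        return self

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # where the report lands is not what it is
        if self.simulation is not None:
            payload["simulation"] = dataclasses.asdict(self.simulation)
            payload["simulation"]["race_probs"] = dict(
                self.simulation.race_probs
            )
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def render_band_table(rows: pd.DataFrame, style: str = "table2") -> pd.DataFrame:
    """Format a band-metrics table the way the accuracy tables are printed.

    Expects the five bands ordered Very High → Very Low; percentages are
    rounded half-up to 1 d.p., likelihood ratios to 2 d.p. and shown with
    their CI.  Empty bands render as absent markers, never zeros.
    ``style`` picks the probability column label ("table2": probability of
    infection; "table3": probability of severe illness).
    """
    if len(rows) != 5 or list(rows["band"]) != [str(b) for b in BANDS_DESCENDING]:
        raise ValueError("expected five rows ordered Very High → Very Low")
    prob_label = {
        "table2": "Probability of infection (%)",
        "table3": "Probability of severe illness (%)",
    }.get(style)
    if prob_label is None:
        raise ValueError(f"unknown style {style!r}")

    def pct(x):
        return "–" if pd.isna(x) else f"{round_half_up(x, 1):g}"

    def lr_ci(row):
        if pd.isna(row["lr"]):
            return "–"
        lr = round_half_up(row["lr"], 2)
        if pd.isna(row["lr_ci_low"]):
            return f"{lr:.2f}"
        return (
            f"{lr:.2f} ({round_half_up(row['lr_ci_low'], 2):.2f}–"
            f"{round_half_up(row['lr_ci_high'], 2):.2f})"
        )

    out = pd.DataFrame(
        {
            "Band": rows["band"],
            "Positive (N)": rows["n_positive"],
            "Negative (N)": rows["n_negative"],
            "Sensitivity (%)": rows["sensitivity"].map(pct),
            "Specificity (%)": rows["specificity"].map(pct),
            "Likelihood ratio (CI)": rows.apply(lr_ci, axis=1),
            "Relative frequency (% in band)": rows["rel_freq"].map(pct),
            prob_label: rows["prob_in_band"].map(pct),
        }
    )
    return out.reset_index(drop=True)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Band):
        return str(obj)
    return obj


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute cohort build → metrics → Bayes → sequential → utility →
    survival and write the report bundle to ``config.outdir``.

    Returns the in-memory bundle.  Validation errors (bad config, missing
    input) raise before any output is written; computation failures in one
    stage are isolated and recorded in the bundle under ``errors``.
    """
    config.validate()
    if config.input_csv is not None:
        path = Path(config.input_csv)
        if not path.exists():
            raise FileNotFoundError(f"input CSV not found: {path}")
        patients = read_patient_csv(path)
        provenance = {"input_csv": str(path)}
    else:
        patients = generate(config.simulation)
        provenance = {"simulation": dataclasses.asdict(config.simulation)}

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: Dict[str, object] = {
        "version": __version__,
        "config_hash": config.digest(),
        "provenance": _jsonify(provenance),
        "n_input": len(patients),
        "endpoints": {},
        "errors": {},
    }
    counts_log: Dict[str, Dict[str, int]] = {}

    band_lrs_bacterial = None
    severity_cohort = None
    for endpoint in config.endpoints:
        try:
            cohort = build_cohort(patients, endpoint, config.adjudication)
            table = build_band_contingency(
                cohort, convention=config.band_convention
            )
            rows = band_metrics_table(
                table,
                level=config.ci_level,
                ci_method=config.ci_method,
                n_boot=config.n_boot,
                seed=config.seed,
            )
            style = "table3" if endpoint.startswith("severity") else "table2"
            rendered = render_band_table(rows, style)
            rows.to_csv(outdir / f"band_metrics_{endpoint}.csv", index=False)
            rendered.to_csv(
                outdir / f"band_metrics_{endpoint}_rendered.csv", index=False
            )
            counts_log[endpoint] = {
                "input": len(patients),
                "included": len(cohort),
                **{f"excluded_{k}": v for k, v in cohort.excluded.items()},
            }
            entry = {
                "n": len(cohort),
                "n_positive": cohort.n_positive,
                "n_negative": cohort.n_negative,
                "prevalence_pct": 100 * cohort.n_positive / len(cohort),
                "metrics": json.loads(rows.to_json(orient="records")),
                "lr_fold_range": lr_fold_range(rows),
                "actionable_pct": actionable_fraction(
                    cohort, axes=(endpoint,), convention=config.band_convention
                )[endpoint],
            }
            bundle["endpoints"][endpoint] = entry
            if endpoint == "bacterial":
                band_lrs_bacterial = rows.set_index("band")["lr"]
            if endpoint == "severity":
                severity_cohort = cohort
        except Exception as exc:  # isolate the failing stage
            logger.exception("stage %s failed", endpoint)
            bundle["errors"][endpoint] = f"{type(exc).__name__}: {exc}"

    if band_lrs_bacterial is not None:
        lrs_asc = [band_lrs_bacterial[str(b)] for b in BANDS_DESCENDING][::-1]
        matrix = post_test_matrix(
            lrs_asc, DEFAULT_GRID,
            band_names=[str(b) for b in reversed(BANDS_DESCENDING)],
        )
        matrix.to_csv(outdir / "post_test_matrix.csv")
        policy = ThresholdPolicy()
        crossings = {
            name: threshold_crossing(lr, policy)
            for name, lr in zip(matrix.columns, lrs_asc)
        }
        bundle["bayes"] = {
            "treat_threshold": policy.treat_threshold,
            "crossings": crossings,
        }

    if severity_cohort is not None:
        try:
            strata = stratified_outcome_rates(
                severity_cohort, config.band_convention
            )
            sens_alone, sens_combined = combined_rule_sensitivity(
                severity_cohort, Band.MODERATE, config.band_convention
            )
            bundle["sequential"] = {
                "per_stratum": {
                    name: {
                        "n": s.n,
                        "n_events": s.n_events,
                        "overall_rate_pct": s.overall_rate,
                        "per_band": {
                            str(b): {"n": r.n, "rate_pct": r.rate}
                            for b, r in s.per_band.items()
                        },
                    }
                    for name, s in strata.items()
                },
                "qsofa_alone_sensitivity_pct": sens_alone,
                "combined_sensitivity_pct": sens_combined,
                "combined_band_cutoff": str(Band.MODERATE),
                "cutoff_is_assumption": True,
            }
        except Exception as exc:
            logger.exception("sequential stage failed")
            bundle["errors"]["sequential"] = f"{type(exc).__name__}: {exc}"

        try:
            reclass = antibiotic_reclassification(
                build_cohort(patients, "bacterial", config.adjudication),
                config.band_convention,
            )
            pct_tab, n_tab = sepsis_crosstab(
                severity_cohort, config.band_convention
            )
            pct_tab.to_csv(outdir / "sepsis_crosstab_pct.csv")
            n_tab.to_csv(outdir / "sepsis_crosstab_n.csv")
            zones = lactate_zone_analysis(
                severity_cohort, convention=config.band_convention
            )
            bundle["utility"] = {
                "antibiotics": {
                    k: {"n_total": v.n_total, "n_flagged": v.n_flagged,
                        "pct_flagged": v.pct_flagged}
                    for k, v in reclass.items()
                },
                "lactate_zones": {
                    k: {"n": z.n, "n_severe": z.n_severe,
                        "n_severe_flagged": z.n_severe_flagged,
                        "pct_flagged": z.pct_flagged}
                    for k, z in zones.items()
                },
            }
        except Exception as exc:
            logger.exception("utility stage failed")
            bundle["errors"]["utility"] = f"{type(exc).__name__}: {exc}"

        try:
            time, event = icu_care_survival_data(severity_cohort)
            curve = km_estimate(time, event)
            pd.DataFrame(
                {"time": curve.times, "survival": curve.survival,
                 "at_risk": curve.at_risk}
            ).to_csv(outdir / "km_curve.csv", index=False)
            hrs = band_hazard_ratios(
                severity_cohort, convention=config.band_convention,
                ci_level=config.ci_level,
            )
            hrs.to_csv(outdir / "band_hazard_ratios.csv")
            bundle["survival"] = {
                "n": curve.n,
                "n_events": curve.n_events,
                "hazard_ratios": json.loads(hrs.to_json(orient="index")),
            }
        except Exception as exc:
            logger.exception("survival stage failed")
            bundle["errors"]["survival"] = f"{type(exc).__name__}: {exc}"

    bundle["counts"] = counts_log
    (outdir / "report.json").write_text(
        json.dumps(_jsonify(bundle), indent=2, sort_keys=True) + "\n"
    )
    _write_markdown(outdir, bundle, config)
    return bundle


def _write_markdown(outdir: Path, bundle: Dict[str, object], config: RunConfig):
    lines = [
        "# Band evaluation report",
        "",
        f"- software version: {bundle['version']}",
        f"- config hash: {bundle['config_hash']}",
        f"- input records: {bundle['n_input']}",
        f"- adjudication rule: {config.adjudication}",
        f"- band convention: {config.band_convention}",
        "",
    ]
    for endpoint, entry in bundle["endpoints"].items():
        lines.append(f"## Endpoint: {endpoint}")
        lines.append("")
        lines.append(
            f"n = {entry['n']} ({entry['n_positive']} positive, "
            f"{entry['n_negative']} negative); prevalence "
            f"{round_half_up(entry['prevalence_pct'], 1)}%; "
            f"LR fold range {round_half_up(entry['lr_fold_range'], 1)}; "
            f"actionable bands {round_half_up(entry['actionable_pct'], 1)}%."
        )
        lines.append("")
        rendered_path = outdir / f"band_metrics_{endpoint}_rendered.csv"
        if rendered_path.exists():
            rendered = pd.read_csv(rendered_path)
            header = "| " + " | ".join(rendered.columns) + " |"
            sep = "|" + "|".join(["---"] * len(rendered.columns)) + "|"
            lines.append(header)
            lines.append(sep)
            for _, row in rendered.iterrows():
                lines.append("| " + " | ".join(str(v) for v in row) + " |")
            lines.append("")
    if bundle.get("errors"):
        lines.append("## Stage errors")
        for stage, msg in bundle["errors"].items():
            lines.append(f"- {stage}: {msg}")
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
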