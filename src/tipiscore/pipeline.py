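"""End-to-end analysis pipeline and report rendering.

``run_full_analysis`` takes a validated cohort and produces the complete
reporting surface of a neoadjuvant-response biomarker study:

1. per-record SII/TIPI scoring and risk-group assignment (cut-off derived by
   Youden-index ROC analysis on the cohort, or fixed via config);
2. a baseline-table block: each categorical covariate cross-tabulated
   against pCR with the chi-square/Fisher selector;
3. continuous comparisons (TILs, Ki-67) by outcome;
4. the ROC/AUC/DeLong/Youden block for the TIPI score;
5. pCR rates by TIPI risk group with their association test;
6. univariable screen and the Enter-method multivariable logistic model with
   omnibus test and Nagelkerke R^2.

Reports are lossless in JSON; TSV and markdown renderings round only at
render time (3 decimals for p-values and ORs, 1 for percentages).
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    build_contingency,
    compare_continuous_by_group,
    select_and_test,
)
from .cohort import Cohort, ki67_category, tils_category
from .logistic import multivariable_model, univariable_screen
from .roc import YoudenCutoffClassifier
from .scoring import TIPIScorer

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "render_report", "DegenerateCohortError"]


class DegenerateCohortError(ValueError):
    """The cohort cannot support the analysis (single class or too small)."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline configuration (YAML-loadable).

    ``fixed_cutoff=None`` derives the TIPI risk cut-off from the data by
    Youden-index selection; a number (e.g. the published 11.41) fixes it.
    """

    fixed_cutoff: float | None = None
    sii_unit_scale: float = 1.0
    roc_candidate_rule: str = "midpoint"
    confidence_level: float = 0.95
    min_n: int = 10
    precision: dict = field(default_factory=lambda: {"p": 3, "percent": 1, "or": 3})

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "tipi" in raw and "cutoff" in raw["tipi"]:
            kwargs["fixed_cutoff"] = raw["tipi"]["cutoff"]
        if "sii" in raw and "unit_scale" in raw["sii"]:
            kwargs["sii_unit_scale"] = float(raw["sii"]["unit_scale"])
        if "roc" in raw and "candidate_rule" in raw["roc"]:
            kwargs["roc_candidate_rule"] = raw["roc"]["candidate_rule"]
        if "report" in raw and "precision" in raw["report"]:
            kwargs["precision"] = dict(raw["report"]["precision"])
        return cls(**kwargs)


@dataclass(frozen=True)
class AnalysisReport:
    baseline_table: list
    continuous_comparisons: list
    roc_block: dict
    risk_group_block: dict
    univariable_block: list
    multivariable_block: dict
    run_metadata: dict

    def to_dict(self) -> dict:
        return asdict(self)


_BASELINE_VARIABLES = (
    ("menopausal_status", ("premenopausal", "postmenopausal")),
    ("clinical_t", ("cT1", "cT2", "cT3_4")),
    ("clinical_n", ("cN0", "cN1", "cN2_3")),
    ("clinical_stage", ("IIA", "IIB", "III")),
    ("hr_status", ("negative", "positive")),
    ("her2_category", ("IHC3plus", "IHC2plus_ISHpos")),
    ("grade", ("1", "2", "3")),
    ("ki67_category", ("le20", "gt20")),
    ("tils_category", ("low", "intermediate", "high")),
    ("tipi_group", ("low", "high")),
)


def _baseline_block(df: pd.DataFrame) -> list:
    out = []
    for name, levels in _BASELINE_VARIABLES:
        table = build_contingency(df, name, levels=levels)
        if table.shape[0] < 2:
            logger.warning("baseline variable %r has one observed level; no test", name)
            test = None
        else:
            test = select_and_test(table)
        rows = []
        for label, (pos, neg) in zip(table.row_labels, table.counts):
            total = pos + neg
            rows.append(
                {
                    "level": label,
                    "total": total,
                    "total_percent": 100.0 * total / table.n,
                    "pcr_pos": pos,
                    "pcr_pos_percent": 100.0 * pos / total,
                    "pcr_neg": neg,
                    "pcr_neg_percent": 100.0 * neg / total,
                }
            )
        out.append(
            {
                "variable": name,
                "levels": rows,
                "method": test.method if test else None,
                "statistic": test.statistic if test else None,
                "p": test.p_value if test else None,
            }
        )
    return out


def run_full_analysis(cohort: Cohort, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the complete scoring-to-regression analysis on a cohort."""
    config = config or AnalysisConfig()
    cohort.require_nonempty("run_full_analysis")
    if len(cohort) < config.min_n:
        raise DegenerateCohortError(f"cohort of {len(cohort)} is below the minimum of {config.min_n}")
    df = cohort.to_dataframe()
    y = df["pcr"].astype(bool).to_numpy()
    if y.all() or not y.any():
        raise DegenerateCohortError("both pCR classes must be present")

    scored = TIPIScorer(sii_unit_scale=config.sii_unit_scale).fit_transform(df)

    clf = YoudenCutoffClassifier(
        fixed_cutoff=config.fixed_cutoff,
        level=config.confidence_level,
        rule=config.roc_candidate_rule,
    ).fit(scored["tipi"].to_numpy(), y)
    roc = clf.roc_
    cutoff = clf.cutoff_
    logger.info("TIPI cut-off %s: %.4f", "fixed" if config.fixed_cutoff is not None else "Youden-derived", cutoff)

    scored["tipi_group"] = np.where(scored["tipi"] > cutoff, "high", "low")
    scored["grade"] = scored["grade"].astype(str)
    scored["ki67_category"] = scored["ki67_percent"].map(ki67_category)
    scored["tils_category"] = scored["stromal_tils_percent"].map(tils_category)

    baseline = _baseline_block(scored)

    continuous = []
    for name in ("stromal_tils_percent", "ki67_percent"):
        cmp = compare_continuous_by_group(scored[name].to_numpy(), y)
        continuous.append(
            {
                "variable": name,
                "mean_pcr_pos": cmp.mean_pos,
                "mean_pcr_neg": cmp.mean_neg,
                "method": cmp.method,
                "statistic": cmp.statistic,
                "p": cmp.p_value,
            }
        )

    roc_block = {
        "auc": roc.auc,
        "auc_se": roc.auc_se,
        "auc_ci": list(roc.auc_ci),
        "auc_p_vs_half": roc.auc_p_vs_half,
        "confidence_level": roc.confidence_level,
        "youden_cutoff": roc.youden_cutoff,
        "youden_j": roc.youden_j,
        "cutoff_used": cutoff,
        "cutoff_source": "fixed" if config.fixed_cutoff is not None else "youden",
        "sens_at_cutoff_used": float((scored.loc[y, "tipi"] > cutoff).mean()),
        "spec_at_cutoff_used": float((scored.loc[~y, "tipi"] <= cutoff).mean()),
    }

    group_table = build_contingency(scored, "tipi_group", levels=("low", "high"))
    group_test = select_and_test(group_table) if group_table.shape[0] == 2 else None
    by_label = {label: counts for label, counts in zip(group_table.row_labels, group_table.counts)}
    risk_block: dict = {
        "cutoff": cutoff,
        "method": group_test.method if group_test else None,
        "p": group_test.p_value if group_test else None,
    }
    for label in ("low", "high"):
        pos, neg = by_label.get(label, (0, 0))
        total = pos + neg
        risk_block[label] = {
            "n": total,
            "pcr_pos": pos,
            "pcr_rate_percent": 100.0 * pos / total if total else None,
        }

    # grade must be numeric again for the design matrix
    scored["grade"] = scored["grade"].astype(int)
    uni = univariable_screen(scored).to_dict(orient="records")
    multi_fit = multivariable_model(scored)
    multi = {
        "rows": multi_fit.summary_frame().to_dict(orient="records"),
        "group_wald": {k: {"wald": v[0], "df": v[1], "p": v[2]} for k, v in multi_fit.group_wald.items()},
        "omnibus_chi2": multi_fit.omnibus_chi2,
        "omnibus_df": multi_fit.omnibus_df,
        "omnibus_p": multi_fit.omnibus_p,
        "nagelkerke_r2": multi_fit.nagelkerke_r2,
        "converged": multi_fit.converged,
    }

    metadata = {
        "package_version": __version__,
        "cohort_provenance": cohort.provenance,
        "n": len(cohort),
        "config_fixed_cutoff": config.fixed_cutoff,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return AnalysisReport(
        baseline_table=baseline,
        continuous_comparisons=continuous,
        roc_block=roc_block,
        risk_group_block=risk_block,
        univariable_block=uni,
        multivariable_block=multi,
        run_metadata=metadata,
    )


def _round(value, digits):
    if value is None:
        return ""
    return f"{value:.{digits}f}"


def render_report(report: AnalysisReport, fmt: str, precision: dict | None = None) -> str:
    """Render a report as ``json`` (lossless), ``tsv`` or ``markdown``."""
    precision = precision or {"p": 3, "percent": 1, "or": 3}
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=2, default=_json_default)
    if fmt not in ("tsv", "markdown"):
        raise ValueError(f"unknown report format {fmt!r}")
    pp, pct, por = precision["p"], precision["percent"], precision["or"]
    lines: list[str] = []
    md = fmt == "markdown"

    def emit(cells: list[str]) -> None:
        lines.append(("| " + " | ".join(cells) + " |") if md else "\t".join(cells))

    def header(title: str, cells: list[str]) -> None:
        lines.append("")
        lines.append(f"## {title}" if md else f"# {title}")
        emit(cells)
        if md:
            emit(["---"] * len(cells))

    header("Baseline characteristics by pCR", ["variable", "level", "total (%)", "pCR+ (%)", "pCR- (%)", "method", "p"])
    for block in report.baseline_table:
        for i, row in enumerate(block["levels"]):
            emit(
                [
                    block["variable"] if i == 0 else "",
                    str(row["level"]),
                    f"{row['total']} ({_round(row['total_percent'], pct)})",
                    f"{row['pcr_pos']} ({_round(row['pcr_pos_percent'], pct)})",
                    f"{row['pcr_neg']} ({_round(row['pcr_neg_percent'], pct)})",
                    (block["method"] or "") if i == 0 else "",
                    _round(block["p"], pp) if i == 0 else "",
                ]
            )

    header("Continuous comparisons by pCR", ["variable", "mean pCR+", "mean pCR-", "method", "p"])
    for row in report.continuous_comparisons:
        emit(
            [
                row["variable"],
                _round(row["mean_pcr_pos"], 1),
                _round(row["mean_pcr_neg"], 1),
                row["method"],
                _round(row["p"], pp),
            ]
        )

    rb = report.roc_block
    header("ROC analysis of the TIPI score", ["AUC", "95% CI", "p vs 0.5", "cutoff", "source", "sens", "spec"])
    emit(
        [
            _round(rb["auc"], 3),
            f"{_round(rb['auc_ci'][0], 3)}-{_round(rb['auc_ci'][1], 3)}",
            _round(rb["auc_p_vs_half"], pp),
            _round(rb["cutoff_used"], 2),
            rb["cutoff_source"],
            _round(100 * rb["sens_at_cutoff_used"], pct),
            _round(100 * rb["spec_at_cutoff_used"], pct),
        ]
    )

    gb = report.risk_group_block
    header("pCR by TIPI risk group", ["group", "n", "pCR+", "pCR rate %", "method", "p"])
    for i, grp in enumerate(("low", "high")):
        emit(
            [
                grp,
                str(gb[grp]["n"]),
                str(gb[grp]["pcr_pos"]),
                _round(gb[grp]["pcr_rate_percent"], pct),
                (gb["method"] or "") if i == 0 else "",
                _round(gb["p"], pp) if i == 0 else "",
            ]
        )

    header("Univariable logistic screen", ["term", "B", "S.E.", "Wald", "OR (95% CI)", "p"])
    for row in report.univariable_block:
        emit(
            [
                row["term"],
                _round(row["B"], 3),
                _round(row["SE"], 3),
                _round(row["Wald"], 3),
                f"{_round(row['OR'], por)} ({_round(row['OR_ci_low'], por)}-{_round(row['OR_ci_high'], por)})",
                _round(row["p"], pp),
            ]
        )

    mb = report.multivariable_block
    header("Multivariable logistic model (Enter method)", ["term", "B", "S.E.", "Wald", "OR (95% CI)", "p"])
    for row in mb["rows"]:
        if row["term"] == "intercept":
            continue
        emit(
            [
                row["term"],
                _round(row["B"], 3),
                _round(row["SE"], 3),
                _round(row["Wald"], 3),
                f"{_round(row['OR'], por)} ({_round(row['OR_ci_low'], por)}-{_round(row['OR_ci_high'], por)})",
                _round(row["p"], pp),
            ]
        )
    for gname, gw in mb["group_wald"].items():
        emit([f"{gname} (overall)", "", "", _round(gw["wald"], 3), "", _round(gw["p"], pp)])
    lines.append("")
    lines.append(
        f"Omnibus chi2 = {_round(mb['omnibus_chi2'], 3)} (df {mb['omnibus_df']}), "
        f"p = {_round(mb['omnibus_p'], pp)}; Nagelkerke R2 = {_round(mb['nagelkerke_r2'], 3)}"
    )
    return "\n".join(lines) + "\n"


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
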