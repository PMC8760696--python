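"""Human-readable report rendering and small cohort utilities.

The renderer does no arithmetic beyond percent formatting: every number in
the markdown/JSON output is traceable to a stage summary field. Output is
byte-identical across repeated runs on identical inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .coverage_qc import AmpliconQCRow
from .panel_validation import ValidationReport
from .triage import (
    NOVELTY_NOVEL,
    STATUS_RESCUED,
    STATUS_RETAINED,
    TriageDecision,
    TriageSummary,
)


@dataclass(frozen=True)
class Demographics:
    n_samples: int
    median_age: float
    age_min: float
    age_max: float

    def as_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "median_age": self.median_age,
            "age_range": [self.age_min, self.age_max],
        }


def demographics(table1: pd.DataFrame) -> Demographics:
    """Median and range of age at diagnosis from a cohort demographics table."""
    ages = pd.to_numeric(table1["age_years"])
    return Demographics(
        n_samples=len(ages),
        median_age=float(ages.median()),
        age_min=float(ages.min()),
        age_max=float(ages.max()),
    )


def _pct(value: float | None) -> str:
    return "n/a" if value is None else f"{100 * value:.1f}%"


def render_report(
    triage_decisions: Sequence[TriageDecision] | None = None,
    triage_summary: TriageSummary | None = None,
    validation: ValidationReport | None = None,
    coverage_rows: Sequence[AmpliconQCRow] | None = None,
    coverage_frac_above_warn: float | None = None,
) -> tuple[str, dict]:
    """Render available stage summaries as (markdown, json-able dict).

    At least one stage summary must be provided. The variant table is sorted
    by gene then position; VAFs print to one decimal percent; rescued and
    putative-novel variants are footnoted.
    """
    if not any(
        x is not None
        for x in (triage_decisions, triage_summary, validation, coverage_rows)
    ):
        raise ValueError("render_report needs at least one stage summary")

    md: list[str] = ["# Panel analysis report", ""]
    payload: dict = {}

    if triage_decisions is not None:
        reported = [
            d
            for d in triage_decisions
            if d.status in (STATUS_RETAINED, STATUS_RESCUED)
        ]
        reported.sort(key=lambda d: (d.gene or "~", d.key.pos, d.sample_id))
        md.append("## Retained and rescued variants")
        md.append("")
        if not reported:
            md.append("Zero variants retained.")
            md.append("")
        else:
            md.append(
                "| Gene | cDNA | Protein | Consequence | Sample | VAF (%) "
                "| Status | Sanger-eligible |"
            )
            md.append("|---|---|---|---|---|---|---|---|")
            for d in reported:
                marks = []
                if d.novelty == NOVELTY_NOVEL:
                    marks.append("[a]")
                if d.status == STATUS_RESCUED:
                    marks.append("[b]")
                md.append(
                    f"| {d.gene or '.'}{''.join(marks)} | {d.hgvs_c or '.'} | "
                    f"{d.hgvs_p or '.'} | {d.consequence or '.'} | {d.sample_id} | "
                    f"{100 * d.vaf:.1f} | {d.status} | "
                    f"{'yes' if d.sanger_eligible else 'no'} |"
                )
            md.append("")
            md.append("[a] putative novel variant")
            md.append("[b] low-VAF variant rescued on database pathogenicity")
            md.append("")

    if triage_summary is not None:
        s = triage_summary
        md.extend(
            [
                "## Triage funnel",
                "",
                f"- unique variants in: {s.n_input_unique}",
                f"- after region + population filters: {s.n_after_region_and_maf}",
                f"- retained (VAF above threshold): {s.n_retained}",
                f"- rescued pathogenic (1–5% window): {s.n_rescued}",
                "",
            ]
        )
        payload["triage"] = s.as_dict()

    if validation is not None:
        v = validation
        md.extend(
            [
                "## Reference-standard validation",
                "",
                f"- sensitivity: {_pct(v.sensitivity)} (TP={v.tp}, FN={v.fn})",
                f"- specificity: {_pct(v.specificity)} (TN={v.tn}, FP={v.fp})",
                f"- positive predictive value: {_pct(v.ppv)} (TP={v.tp}, FP={v.fp})",
            ]
        )
        for label, conc in (
            ("intra-run", v.intra_run_concordance),
            ("inter-run", v.inter_run_concordance),
        ):
            if conc:
                md.append(
                    f"- {label} concordance: {_pct(conc['mean'])} "
                    f"[range {_pct(conc['min'])}–{_pct(conc['max'])}, "
                    f"{conc['n_pairs']} pairs]"
                )
        lod = "n/a" if v.lod_vaf is None else f"{100 * v.lod_vaf:.1f}%"
        md.append(
            f"- limit of detection: lowest fully detected tier {lod}; "
            f"analysis floor {100 * v.analysis_vaf_floor:.0f}%"
        )
        md.append("")
        payload["validation"] = v.as_dict()

    if coverage_rows is not None:
        flagged = [r for r in coverage_rows if r.flag != "ok"]
        md.extend(["## Amplicon coverage", ""])
        md.append(f"- amplicons: {len(coverage_rows)}")
        if coverage_frac_above_warn is not None:
            md.append(
                f"- fraction with mean depth > 1000x: "
                f"{_pct(coverage_frac_above_warn)}"
            )
        if flagged:
            md.append("")
            md.append("| Amplicon | Mean depth | Flag |")
            md.append("|---|---|---|")
            for r in sorted(flagged, key=lambda r: r.mean_depth_overall):
                md.append(
                    f"| {r.amplicon_id} | {r.mean_depth_overall:.0f} | {r.flag} |"
                )
        md.append("")
        payload["coverage"] = {
            "n_amplicons": len(coverage_rows),
            "fraction_above_warn": coverage_frac_above_warn,
            "flagged": [
                {
                    "amplicon_id": r.amplicon_id,
                    "mean_depth": r.mean_depth_overall,
                    "flag": r.flag,
                }
                for r in sorted(flagged, key=lambda r: r.mean_depth_overall)
            ],
        }

    return "\n".join(md), payload


def write_report(markdown: str, payload: Mapping, md_path, json_path) -> None:
    with open(md_path, "w") as fh:
        fh.write(markdown)
        if not markdown.endswith("\n"):
            fh.write("\n")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
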