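"""The somatic variant filtering and prioritization cascade.

Stages, applied in order to a cohort of merged per-sample call sets:

1. **Region filter** — only exonic variants proceed; splicing, intronic,
   UTR and intergenic calls are excluded (``excluded_region``).
2. **Population filter** — a variant whose minor allele frequency is >= 1%
   in *any* of the four population databases (1000 Genomes, ExAC, ESP6500,
   gnomAD) is removed as a common polymorphism (``excluded_common``).
   Absent frequencies never trigger this rule.
3. **Artifact filter** — a call is removed as a potential sequencing error
   (``excluded_artifact``) when its VAF is below 5%, or when its key recurs
   in a majority (> 50%) of cohort samples without any database
   pathogenicity evidence. The evidence exemption is what keeps a genuine
   hotspot driver shared by most of a cohort in the call set.
4. **Pathogenic rescue** — artifact-lane calls in the 1–5% VAF window
   carrying a ClinVar pathogenic/likely-pathogenic assertion or a COSMIC
   pathogenicity flag are pulled back (``rescued_pathogenic``).

Retained and rescued variants are then classified for novelty (exact-allele
absence from dbSNP, ClinVar and COSMIC) and flagged for Sanger
confirmability (VAF >= 15%). Every (sample, variant) occurrence receives
exactly one :class:`TriageDecision` carrying the rule that fired.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .caller_merge import normalize_call
from .config import PipelineConfig
from .io_formats import (
    AnnotationRecord,
    FormatError,
    VariantCall,
    VariantKey,
    chrom_sort_key,
)

STATUS_RETAINED = "retained"
STATUS_RESCUED = "rescued_pathogenic"
STATUS_EXCLUDED_REGION = "excluded_region"
STATUS_EXCLUDED_COMMON = "excluded_common"
STATUS_EXCLUDED_ARTIFACT = "excluded_artifact"
STATUSES = (
    STATUS_RETAINED,
    STATUS_RESCUED,
    STATUS_EXCLUDED_REGION,
    STATUS_EXCLUDED_COMMON,
    STATUS_EXCLUDED_ARTIFACT,
)

NOVELTY_NOVEL = "putative_novel"
NOVELTY_REPORTED = "reported"
NOVELTY_NOT_ASSESSED = "not_assessed"


@dataclass(frozen=True)
class TriageDecision:
    """Verdict and audit trail for one variant occurrence in one sample."""

    sample_id: str
    key: VariantKey
    status: str
    reason: str
    novelty: str
    sanger_eligible: bool
    vaf: float
    gene: str | None = None
    consequence: str | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None


@dataclass
class TriageSummary:
    """Cohort-level funnel counts (unique = by normalized variant key)."""

    n_input_unique: int
    n_after_region_and_maf: int
    n_retained: int
    n_rescued: int
    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input_unique": self.n_input_unique,
            "n_after_region_and_maf": self.n_after_region_and_maf,
            "n_retained": self.n_retained,
            "n_rescued": self.n_rescued,
            "per_sample": self.per_sample,
        }


def _annotation_for(
    call: VariantCall, annotations: Mapping[VariantKey, AnnotationRecord]
) -> AnnotationRecord:
    try:
        return annotations[call.key]
    except KeyError:
        raise FormatError(
            f"no annotation record for {call.key} (sample {call.sample_id})"
        ) from None


def filter_region(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, AnnotationRecord],
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition calls into (exonic, everything else)."""
    kept, excluded = [], []
    for call in calls:
        ann = _annotation_for(call, annotations)
        (kept if ann.region_class == "exonic" else excluded).append(call)
    return kept, excluded


def filter_population(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, AnnotationRecord],
    maf_cutoff: float = 0.01,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition calls into (rare-or-unknown, common).

    Common means *any* present database MAF >= ``maf_cutoff``; records with
    no frequency data at all are kept.
    """
    kept, excluded = [], []
    for call in calls:
        ann = _annotation_for(call, annotations)
        common = any(
            v is not None and v >= maf_cutoff for v in ann.mafs.values()
        )
        (excluded if common else kept).append(call)
    return kept, excluded


def _recurrent_keys(
    calls: Sequence[VariantCall], n_cohort_samples: int, recurrence_fraction: float
) -> set[VariantKey]:
    samples_per_key: dict[VariantKey, set[str]] = defaultdict(set)
    for call in calls:
        samples_per_key[call.key].add(call.sample_id)
    return {
        key
        for key, samples in samples_per_key.items()
        if len(samples) > recurrence_fraction * n_cohort_samples
    }


def filter_artifacts(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, AnnotationRecord],
    n_cohort_samples: int,
    config: PipelineConfig | None = None,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Partition calls into (kept, artifact-suspect) at cohort level.

    A call is artifact-suspect when its VAF is below the retention threshold,
    or when its key recurs in a majority of cohort samples and carries no
    pathogenicity evidence (ClinVar P/LP or any COSMIC entry).
    """
    cfg = config or PipelineConfig()
    if n_cohort_samples <= 0:
        raise FormatError("artifact filter needs a non-empty cohort")
    recurrent = _recurrent_keys(calls, n_cohort_samples, cfg.recurrence_fraction)
    kept, excluded = [], []
    for call in calls:
        ann = _annotation_for(call, annotations)
        low_vaf = call.vaf < cfg.vaf_retain
        systematic = call.key in recurrent and not ann.has_pathogenicity_evidence
        (excluded if low_vaf or systematic else kept).append(call)
    return kept, excluded


def rescue_pathogenic(
    excluded: Sequence[VariantCall],
    annotations: Mapping[VariantKey, AnnotationRecord],
    config: PipelineConfig | None = None,
) -> list[VariantCall]:
    """From the artifact lane, pull back database-pathogenic 1–5% VAF calls."""
    cfg = config or PipelineConfig()
    rescued = []
    for call in excluded:
        ann = _annotation_for(call, annotations)
        in_window = cfg.rescue_vaf_floor <= call.vaf < cfg.vaf_retain
        pathogenic = (
            ann.clinvar_assertion in ("pathogenic", "likely_pathogenic")
            or ann.cosmic_pathogenic
        )
        if in_window and pathogenic:
            rescued.append(call)
    return rescued


def classify_novelty(ann: AnnotationRecord) -> str:
    """putative_novel iff the exact allele is absent from dbSNP, ClinVar and COSMIC.

    A cluster-level rsID hit with a different allele
    (``dbsnp_exact_allele_match == False``) does not defeat novelty.
    """
    if (
        not ann.dbsnp_exact_allele_match
        and ann.clinvar_assertion == "absent"
        and not ann.cosmic_ids
    ):
        return NOVELTY_NOVEL
    return NOVELTY_REPORTED


def flag_sanger(vaf: float, config: PipelineConfig | None = None) -> bool:
    """True iff the VAF is within Sanger sequencing's sensitivity (>= 15%)."""
    cfg = config or PipelineConfig()
    return vaf >= cfg.sanger_min_vaf


def run_triage(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, AnnotationRecord],
    config: PipelineConfig | None = None,
    n_cohort_samples: int | None = None,
) -> tuple[list[TriageDecision], TriageSummary]:
    """Run the full cascade over a cohort of calls.

    Keys are normalized first so annotation lookup and recurrence counting
    operate on one keyspace. ``n_cohort_samples`` defaults to the number of
    distinct sample ids present in ``calls`` (pass it explicitly when some
    cohort samples contributed zero calls).
    """
    cfg = config or PipelineConfig()
    calls = [normalize_call(c) for c in calls]
    if not calls:
        raise FormatError("triage received an empty cohort")
    occurrences = [(c.sample_id, c.key) for c in calls]
    if len(occurrences) != len(set(occurrences)):
        raise FormatError(
            "duplicate (sample, variant) occurrences — merge call sets first"
        )
    n_samples = n_cohort_samples or len({c.sample_id for c in calls})

    exonic, non_exonic = filter_region(calls, annotations)
    rare, common = filter_population(exonic, annotations, cfg.maf_cutoff)
    kept, artifact = filter_artifacts(rare, annotations, n_samples, cfg)
    rescued = rescue_pathogenic(artifact, annotations, cfg)
    rescued_ids = {(c.sample_id, c.key) for c in rescued}

    decisions: list[TriageDecision] = []

    def _emit(call: VariantCall, status: str, reason: str) -> None:
        ann = annotations[call.key]
        assessed = status in (STATUS_RETAINED, STATUS_RESCUED)
        decisions.append(
            TriageDecision(
                sample_id=call.sample_id,
                key=call.key,
                status=status,
                reason=reason,
                novelty=classify_novelty(ann) if assessed else NOVELTY_NOT_ASSESSED,
                sanger_eligible=flag_sanger(call.vaf, cfg) if assessed else False,
                vaf=call.vaf,
                gene=call.gene,
                consequence=call.consequence,
                hgvs_c=call.hgvs_c,
                hgvs_p=call.hgvs_p,
            )
        )

    for call in non_exonic:
        _emit(
            call,
            STATUS_EXCLUDED_REGION,
            f"region_class={annotations[call.key].region_class} (non-exonic)",
        )
    for call in common:
        hits = ", ".join(
            f"{db}={v:.4g}"
            for db, v in annotations[call.key].mafs.items()
            if v is not None and v >= cfg.maf_cutoff
        )
        _emit(call, STATUS_EXCLUDED_COMMON, f"population MAF >= {cfg.maf_cutoff:g}: {hits}")
    for call in artifact:
        if (call.sample_id, call.key) in rescued_ids:
            _emit(
                call,
                STATUS_RESCUED,
                f"vaf={call.vaf:.4f} in [{cfg.rescue_vaf_floor:g}, "
                f"{cfg.vaf_retain:g}) with database pathogenicity assertion",
            )
        elif call.vaf < cfg.vaf_retain:
            _emit(call, STATUS_EXCLUDED_ARTIFACT, f"vaf={call.vaf:.4f} < {cfg.vaf_retain:g}")
        else:
            _emit(
                call,
                STATUS_EXCLUDED_ARTIFACT,
                f"recurs in majority of {n_samples} samples without "
                "pathogenicity evidence",
            )
    for call in kept:
        _emit(call, STATUS_RETAINED, f"exonic, rare, vaf={call.vaf:.4f} >= {cfg.vaf_retain:g}")

    decisions.sort(
        key=lambda d: (chrom_sort_key(d.key.chrom), d.key.pos, d.key.alt, d.sample_id)
    )

    summary = _summarize(calls, exonic, rare, kept, rescued, decisions)
    return decisions, summary


def _summarize(calls, exonic, rare, kept, rescued, decisions) -> TriageSummary:
    unique = lambda cs: {c.key for c in cs}  # noqa: E731
    per_sample: dict[str, dict[str, int]] = {}
    for d in decisions:
        bucket = per_sample.setdefault(
            d.sample_id, {status: 0 for status in STATUSES}
        )
        bucket[d.status] += 1
    return TriageSummary(
        n_input_unique=len(unique(calls)),
        n_after_region_and_maf=len(unique(rare)),
        n_retained=len(unique(kept)),
        n_rescued=len(unique(rescued)),
        per_sample=dict(sorted(per_sample.items())),
    )


# ---------------------------------------------------------------------------
# persistence

DECISION_COLUMNS = (
    "sample_id", "gene", "chrom", "pos", "ref", "alt", "hgvs_c", "hgvs_p",
    "consequence", "vaf_percent", "status", "reason", "novelty", "sanger_eligible",
)


def write_decisions(decisions: Sequence[TriageDecision], path) -> None:
    """Deterministic TSV: one row per (sample, variant) with the full audit."""
    with open(path, "w") as fh:
        fh.write("\t".join(DECISION_COLUMNS) + "\n")
        for d in decisions:
            fh.write(
                "\t".join(
                    [
                        d.sample_id,
                        d.gene or ".",
                        d.key.chrom,
                        str(d.key.pos),
                        d.key.ref,
                        d.key.alt,
                        d.hgvs_c or ".",
                        d.hgvs_p or ".",
                        d.consequence or ".",
                        f"{100 * d.vaf:.1f}",
                        d.status,
                        d.reason,
                        d.novelty,
                        str(d.sanger_eligible).lower(),
                    ]
                )
                + "\n"
            )


def write_summary(summary: TriageSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
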