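"""Scoring of replicate runs against reference-standard truth sets.

A *detection matrix* has one row per sequenced replicate of a standard and
one cell per expected (truth) variant of that standard; calls that match no
truth variant are kept as off-truth calls. From the matrix we derive the
confusion counts, sensitivity/specificity/PPV, intra- and inter-run
concordance, and the limit of detection.

True negatives need a convention because an amplicon panel has no natural
universe of negative sites. We use the cross-standard truth-variant union:
for each replicate, every union variant absent from that standard's own
truth set is one evaluable negative site; a false positive *at* such a site
consumes it. With four standards whose union holds 26 unique variants, a
single wild-type replicate with one (novel-site) false positive yields
tn=26, fp=1 and specificity 26/27.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .caller_merge import normalize_variant
from .config import PipelineConfig
from .io_formats import (
    CALLER_SMALL,
    CALLER_STRUCTURAL,
    FormatError,
    TruthVariant,
    VariantCall,
    VariantKey,
)


def _is_insertion(key: VariantKey) -> bool:
    return len(key.alt) > len(key.ref)


def match_call_to_truth(call_key: VariantKey, truth_key: VariantKey) -> bool:
    """True when a (normalized) call hits a (normalized) truth variant.

    Exact key equality, with one tolerance: two insertions/duplications of
    identical inserted length anchored within 5 bases of each other are the
    same event (callers may place a duplication anywhere along the repeat).
    """
    call_key = normalize_variant(call_key)
    truth_key = normalize_variant(truth_key)
    if call_key == truth_key:
        return True
    if (
        _is_insertion(call_key)
        and _is_insertion(truth_key)
        and call_key.chrom == truth_key.chrom
        and abs(call_key.pos - truth_key.pos) <= 5
        and len(call_key.alt) - len(call_key.ref)
        == len(truth_key.alt) - len(truth_key.ref)
    ):
        return True
    return False


@dataclass(frozen=True)
class ReplicateCallset:
    """One sequenced replicate of one reference standard."""

    standard_id: str
    replicate_id: str
    run_id: str
    calls: tuple[VariantCall, ...]

    @property
    def label(self) -> str:
        return f"{self.standard_id}/{self.replicate_id}/{self.run_id}"


@dataclass(frozen=True)
class DetectionCell:
    truth: TruthVariant
    detected: bool
    observed_vaf: float | None
    callers: frozenset[str] = frozenset()


@dataclass(frozen=True)
class DetectionRow:
    standard_id: str
    replicate_id: str
    run_id: str
    cells: tuple[DetectionCell, ...]
    off_truth: tuple[VariantCall, ...]

    @property
    def detected_set(self) -> frozenset[TruthVariant]:
        return frozenset(c.truth for c in self.cells if c.detected)


@dataclass
class DetectionMatrix:
    rows: list[DetectionRow]
    truth_sets: dict[str, list[TruthVariant]]

    @property
    def truth_union_keys(self) -> set[VariantKey]:
        """Normalized keys of every truth variant across all standards."""
        return {
            normalize_variant(tv.key)
            for tvs in self.truth_sets.values()
            for tv in tvs
        }


def build_detection_matrix(
    truth_sets: Mapping[str, Sequence[TruthVariant]],
    replicates: Sequence[ReplicateCallset],
) -> DetectionMatrix:
    """Mark each truth variant detected/missed per replicate.

    A truth variant is detected iff any call in the replicate's merged call
    set matches it; every unmatched call is recorded off-truth.
    """
    matrix_rows: list[DetectionRow] = []
    for rep in replicates:
        if rep.standard_id not in truth_sets:
            raise FormatError(
                f"replicate {rep.label} references unknown standard "
                f"{rep.standard_id!r}"
            )
        cells = []
        matched_calls: set[int] = set()
        for tv in truth_sets[rep.standard_id]:
            hit = None
            for i, call in enumerate(rep.calls):
                if match_call_to_truth(call.key, tv.key):
                    hit = (i, call)
                    break
            if hit is None:
                cells.append(DetectionCell(truth=tv, detected=False, observed_vaf=None))
            else:
                matched_calls.add(hit[0])
                cells.append(
                    DetectionCell(
                        truth=tv,
                        detected=True,
                        observed_vaf=hit[1].vaf,
                        callers=frozenset({hit[1].caller}),
                    )
                )
        off = tuple(
            call for i, call in enumerate(rep.calls) if i not in matched_calls
        )
        matrix_rows.append(
            DetectionRow(
                standard_id=rep.standard_id,
                replicate_id=rep.replicate_id,
                run_id=rep.run_id,
                cells=tuple(cells),
                off_truth=off,
            )
        )
    return DetectionMatrix(rows=matrix_rows, truth_sets={k: list(v) for k, v in truth_sets.items()})


def compute_confusion(matrix: DetectionMatrix) -> tuple[int, int, int, int]:
    """Return (tp, fp, fn, tn) under the cross-standard negative-site convention.

    tp/fn count (truth variant x replicate) cells; fp counts off-truth calls;
    tn counts, per replicate, panel-union variants outside the standard's own
    truth set minus false positives landing at those sites.
    """
    tp = fp = fn = tn = 0
    union = matrix.truth_union_keys
    for row in matrix.rows:
        tp += sum(1 for c in row.cells if c.detected)
        fn += sum(1 for c in row.cells if not c.detected)
        fp += len(row.off_truth)
        own = {normalize_variant(tv.key) for tv in matrix.truth_sets[row.standard_id]}
        negative_sites = union - own
        fp_at_negative_sites = sum(
            1
            for call in row.off_truth
            if any(match_call_to_truth(call.key, nk) for nk in negative_sites)
        )
        tn += len(negative_sites) - fp_at_negative_sites
    return tp, fp, fn, tn


def concordance(
    set_a: Iterable[TruthVariant],
    set_b: Iterable[TruthVariant],
    mode: str = "jaccard",
    truth_total: int | None = None,
) -> float:
    """Agreement between two replicates' detected truth-variant sets.

    ``jaccard``: |A∩B| / |A∪B| (1.0 when both are empty).
    ``both_detected``: fraction of the standard's truth set detected in both
    replicates (requires ``truth_total``).
    """
    a, b = set(set_a), set(set_b)
    if mode == "jaccard":
        if not a and not b:
            return 1.0
        return len(a & b) / len(a | b)
    if mode == "both_detected":
        if truth_total is None:
            raise ValueError("both_detected mode requires truth_total")
        if truth_total == 0:
            return 1.0
        return len(a & b) / truth_total
    raise ValueError(f"unknown concordance mode {mode!r}")


def _pairwise_concordance(
    matrix: DetectionMatrix, same_run: bool, mode: str
) -> list[float]:
    values = []
    for row_a, row_b in itertools.combinations(matrix.rows, 2):
        if row_a.standard_id != row_b.standard_id:
            continue
        if same_run != (row_a.run_id == row_b.run_id):
            continue
        values.append(
            concordance(
                row_a.detected_set,
                row_b.detected_set,
                mode=mode,
                truth_total=len(matrix.truth_sets[row_a.standard_id]),
            )
        )
    return values


def limit_of_detection(matrix: DetectionMatrix) -> float:
    """Lowest expected-VAF tier whose variants are detected in every replicate."""
    tier_complete: dict[float, bool] = {}
    for row in matrix.rows:
        for cell in row.cells:
            tier = cell.truth.expected_vaf
            if tier is None:
                continue
            tier_complete[tier] = tier_complete.get(tier, True) and cell.detected
    if not tier_complete:
        raise FormatError("no expected-VAF tiers present in the truth sets")
    complete = [tier for tier, ok in tier_complete.items() if ok]
    if not complete:
        raise FormatError("no tier was fully detected in every replicate")
    return min(complete)


@dataclass
class ValidationReport:
    """Aggregate panel performance over all scored replicates."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    intra_run_concordance: dict | None
    inter_run_concordance: dict | None
    lod_vaf: float | None
    analysis_vaf_floor: float = 0.01
    counting_mode: str = "merged"
    concordance_mode: str = "jaccard"

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "intra_run_concordance": self.intra_run_concordance,
            "inter_run_concordance": self.inter_run_concordance,
            "lod_vaf": self.lod_vaf,
            "analysis_vaf_floor": self.analysis_vaf_floor,
            "counting_mode": self.counting_mode,
            "concordance_mode": self.concordance_mode,
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def _summary(values: list[float]) -> dict | None:
    if not values:
        return None
    return {
        "mean": sum(values) / len(values),
        "min": min(values),
        "max": max(values),
        "n_pairs": len(values),
    }


def _eligible_apps(key: VariantKey, large_event_length: int) -> tuple[str, ...]:
    """Which caller(s) are designed to see this event class."""
    if key.is_snv:
        return (CALLER_SMALL,)
    if key.max_allele_length > large_event_length:
        return (CALLER_STRUCTURAL,)
    return (CALLER_SMALL, CALLER_STRUCTURAL)


def _per_app_view(
    truth_sets: Mapping[str, Sequence[TruthVariant]],
    replicates: Sequence[ReplicateCallset],
    large_event_length: int,
) -> tuple[dict[str, list[TruthVariant]], list[ReplicateCallset]]:
    """Expand each replicate into one row per caller, restricted to the truth
    variants that caller is designed for (larger denominator than the merged
    view, without charging each app its designed blind spots).

    Because a merged call keeps only the winning caller's label, calls are
    attributed to an app by event-class eligibility, not by the surviving
    label: an indel both apps are designed for counts for both rows.
    """
    pseudo_truth: dict[str, list[TruthVariant]] = {}
    for std, tvs in truth_sets.items():
        for app in (CALLER_SMALL, CALLER_STRUCTURAL):
            pseudo_truth[f"{std}::{app}"] = [
                tv
                for tv in tvs
                if app in _eligible_apps(normalize_variant(tv.key), large_event_length)
            ]
    expanded = [
        ReplicateCallset(
            standard_id=f"{rep.standard_id}::{app}",
            replicate_id=rep.replicate_id,
            run_id=rep.run_id,
            calls=tuple(
                c
                for c in rep.calls
                if app in _eligible_apps(normalize_variant(c.key), large_event_length)
            ),
        )
        for rep in replicates
        for app in (CALLER_SMALL, CALLER_STRUCTURAL)
    ]
    return pseudo_truth, expanded


def validate_replicates(
    truth_sets: Mapping[str, Sequence[TruthVariant]],
    replicates: Sequence[ReplicateCallset],
    config: PipelineConfig | None = None,
) -> tuple[DetectionMatrix, ValidationReport]:
    """One-shot scoring: matrix, confusion metrics, concordances and LoD.

    ``config.counting_mode = "per_app"`` scores each caller's subset of every
    replicate as its own row, restricted to the truth variants that caller is
    designed for (indels up to the large-event cutoff count twice, once per
    app); the default ``merged`` mode scores the reconciled call set once.
    """
    cfg = config or PipelineConfig()
    if cfg.counting_mode == "per_app":
        scored_truth, scored = _per_app_view(
            truth_sets, replicates, cfg.merge_large_event_length
        )
    else:
        scored_truth, scored = dict(truth_sets), list(replicates)

    matrix = build_detection_matrix(scored_truth, scored)
    tp, fp, fn, tn = compute_confusion(matrix)
    try:
        lod = limit_of_detection(matrix)
    except FormatError:
        lod = None
    report = ValidationReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        intra_run_concordance=_summary(
            _pairwise_concordance(matrix, same_run=True, mode=cfg.concordance_mode)
        ),
        inter_run_concordance=_summary(
            _pairwise_concordance(matrix, same_run=False, mode=cfg.concordance_mode)
        ),
        lod_vaf=lod,
        analysis_vaf_floor=cfg.rescue_vaf_floor,
        counting_mode=cfg.counting_mode,
        concordance_mode=cfg.concordance_mode,
    )
    return matrix, report


def write_validation_report(report: ValidationReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
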