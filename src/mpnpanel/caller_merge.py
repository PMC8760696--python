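"""Variant normalization and dual-caller call-set reconciliation.

The panel's two callers describe the same indel in different paddings
(e.g. ``chr20:300 GAA>GAAAA`` vs ``chr20:302 A>AAA``). :func:`normalize_variant`
reduces every representation to a single fixed point using only the allele
strings themselves (no reference genome): shared context is trimmed greedily
from the left first, which shifts indels as far right as the provided context
allows, then from the right, and pure indels are re-anchored on their left
flank when that flank was part of the input. The result is idempotent and
identical for every padding of the same event drawn from one local sequence.

:func:`merge_callsets` then unions the two callers per sample. When both
report the same normalized key, the small-variant caller's VAF/depth is kept
for events up to ``large_event_length`` bases and the structural caller's
beyond that (large duplications are only reliably sized by the structural
caller); provenance records both contributors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import (
    CALLER_SMALL,
    CALLER_STRUCTURAL,
    FormatError,
    VariantCall,
    VariantKey,
    chrom_sort_key,
)

DEFAULT_LARGE_EVENT_LENGTH = 25


def normalize_variant(key: VariantKey) -> VariantKey:
    """Trim shared allele context to a canonical, idempotent representation.

    SNVs embedded in shared context are reduced to the single changed base;
    indels keep exactly one anchor base (left anchor whenever left context is
    available). Raises :class:`FormatError` if the alleles describe no change.
    """
    ref, alt, pos = key.ref, key.alt, key.pos

    # greedy left trim: within a repeat this right-shifts the event maximally
    p = 0
    while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
        p += 1
    left_context = ref[:p]
    ref, alt, pos = ref[p:], alt[p:], pos + p

    # greedy right trim on what remains
    s = 0
    while s < len(ref) and s < len(alt) and ref[len(ref) - 1 - s] == alt[len(alt) - 1 - s]:
        s += 1
    if s:
        ref, alt = ref[: len(ref) - s], alt[: len(alt) - s]

    if not ref and not alt:
        raise FormatError(f"{key}: alleles reduce to identical strings — not a variant")

    if not ref or not alt:  # pure indel: re-attach a single anchor base
        if left_context:
            anchor = left_context[-1]
            return VariantKey(key.chrom, pos - 1, anchor + ref, anchor + alt)
        # no left context available: keep one base of the trimmed suffix as a
        # right anchor (stable under re-normalization)
        if s:
            anchor = key.ref[p + len(ref)]
            return VariantKey(key.chrom, pos, ref + anchor, alt + anchor)
        raise FormatError(f"{key}: indel carries no anchor context")

    return VariantKey(key.chrom, pos, ref, alt)


def normalize_call(call: VariantCall) -> VariantCall:
    """Return ``call`` with its key normalized (other fields untouched)."""
    nkey = normalize_variant(call.key)
    if nkey == call.key:
        return call
    return VariantCall(
        sample_id=call.sample_id,
        key=nkey,
        vaf=call.vaf,
        depth=call.depth,
        alt_reads=call.alt_reads,
        caller=call.caller,
        gene=call.gene,
        hgvs_c=call.hgvs_c,
        hgvs_p=call.hgvs_p,
        consequence=call.consequence,
    )


@dataclass(frozen=True)
class MergeLogEntry:
    key: VariantKey
    contributors: frozenset[str]
    vaf_source: str


@dataclass
class MergedCallset:
    """Per-sample union of the two callers, one call per normalized key."""

    sample_id: str
    calls: list[VariantCall]
    provenance: dict[VariantKey, frozenset[str]]
    merge_log: list[MergeLogEntry] = field(default_factory=list)

    def callers_for(self, key: VariantKey) -> frozenset[str]:
        return self.provenance[key]


def _check_single_sample(calls: Sequence[VariantCall], label: str) -> str | None:
    samples = {c.sample_id for c in calls}
    if len(samples) > 1:
        raise FormatError(
            f"{label} call list mixes samples: {sorted(samples)}"
        )
    return samples.pop() if samples else None


def merge_callsets(
    small: Sequence[VariantCall],
    structural: Sequence[VariantCall],
    large_event_length: int = DEFAULT_LARGE_EVENT_LENGTH,
) -> MergedCallset:
    """Reconcile the small-variant and structural call sets of one sample.

    The merged key set is exactly the union of the normalized input key sets.
    For keys reported by both callers the retained VAF/depth come from the
    small-variant caller when ``max(|ref|, |alt|) <= large_event_length`` and
    from the structural caller otherwise.
    """
    s_sample = _check_single_sample(small, "small-variant")
    x_sample = _check_single_sample(structural, "structural")
    if s_sample and x_sample and s_sample != x_sample:
        raise FormatError(
            f"call sets belong to different samples: {s_sample!r} vs {x_sample!r}"
        )
    sample_id = s_sample or x_sample or "SAMPLE"

    by_key: dict[VariantKey, dict[str, VariantCall]] = {}
    for call in list(small) + list(structural):
        norm = normalize_call(call)
        by_key.setdefault(norm.key, {})[call.caller] = norm

    merged: list[VariantCall] = []
    provenance: dict[VariantKey, frozenset[str]] = {}
    log: list[MergeLogEntry] = []
    for key in sorted(by_key, key=lambda k: (chrom_sort_key(k.chrom), k.pos, k.alt)):
        contributors = frozenset(by_key[key])
        if contributors == {CALLER_SMALL, CALLER_STRUCTURAL}:
            winner = (
                CALLER_SMALL
                if key.max_allele_length <= large_event_length
                else CALLER_STRUCTURAL
            )
        else:
            (winner,) = contributors
        merged.append(by_key[key][winner])
        provenance[key] = contributors
        log.append(MergeLogEntry(key=key, contributors=contributors, vaf_source=winner))

    return MergedCallset(
        sample_id=sample_id, calls=merged, provenance=provenance, merge_log=log
    )


def write_merge_log(merged: MergedCallset, path) -> None:
    """TSV audit of which caller(s) contributed each merged call."""
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tpos\tref\talt\tcontributors\tvaf_source\n")
        for entry in merged.merge_log:
            fh.write(
                "\t".join(
                    [
                        merged.sample_id,
                        entry.key.chrom,
                        str(entry.key.pos),
                        entry.key.ref,
                        entry.key.alt,
                        ",".join(sorted(entry.contributors)),
                        entry.vaf_source,
                    ]
                )
                + "\n"
            )
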