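"""Packaged clinical-cohort fixtures.

Three small TSVs encode the 10-sample MPN cohort exactly as published:
per-sample demographics/clinical data, all 28 per-sample variant
occurrences (21 unique variants) with their reported VAFs and Sanger
outcomes, and the per-variant database annotations. They serve both as
regression fixtures and as a worked example for the CLI.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..io_formats import (
    CALLER_SMALL,
    AnnotationRecord,
    VariantCall,
    VariantKey,
    read_annotation_table,
)

FIXTURE_DEPTH = 5000  # nominal depth backing the reported VAF percentages


def _data_path(name: str):
    return resources.files(__package__).joinpath("data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """Demographics and clinical data for the 10 cohort samples."""
    with resources.as_file(_data_path("table1.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_cohort_calls() -> list[VariantCall]:
    """All 28 published variant occurrences as :class:`VariantCall` records.

    The published table reports VAF percentages, not read counts; calls are
    materialized at a nominal 5000x depth with consistent alt read counts.
    All occurrences carry the small-variant caller label (the merged origin
    is immaterial for triage).
    """
    with resources.as_file(_data_path("cohort_calls.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    calls = []
    for row in df.itertuples(index=False):
        vaf = float(row.vaf_percent) / 100.0
        alt = int(round(vaf * FIXTURE_DEPTH))
        calls.append(
            VariantCall(
                sample_id=row.sample_id,
                key=VariantKey(row.chrom, int(row.pos), row.ref, row.alt),
                vaf=vaf,
                depth=FIXTURE_DEPTH,
                alt_reads=alt,
                caller=CALLER_SMALL,
                gene=row.gene,
                hgvs_c=row.hgvs_c,
                hgvs_p=row.hgvs_p,
                consequence=row.consequence,
            )
        )
    return calls


def load_cohort_sanger() -> dict[tuple[str, VariantKey], str]:
    """Published Sanger outcome per occurrence: detected/undetected/na."""
    with resources.as_file(_data_path("cohort_calls.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        (row.sample_id, VariantKey(row.chrom, int(row.pos), row.ref, row.alt)): row.sanger
        for row in df.itertuples(index=False)
    }


def load_cohort_annotations() -> dict[VariantKey, AnnotationRecord]:
    """Database annotations for the 21 unique cohort variants."""
    with resources.as_file(_data_path("cohort_annotations.tsv")) as path:
        return read_annotation_table(path)
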