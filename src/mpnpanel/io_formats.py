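"""Domain types and file formats.

One coordinate convention is used everywhere inside the package: 1-based,
inclusive, VCF-native. BED input (0-based half-open) is converted on read and
back on write. Chromosome names are normalized to the ``chrN`` form; bare
``N`` is accepted on input.

Readers are strict: malformed rows raise :class:`FormatError` naming the
offending line/row rather than silently dropping data. Writers emit fully
deterministic output (fixed column order, rows sorted by chrom, pos, alt,
sample) so repeated runs are byte-identical.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

from . import PANEL_GENES

# ---------------------------------------------------------------------------
# vocabulary

CALLER_SMALL = "small_variant"
CALLER_STRUCTURAL = "structural"
CALLERS = frozenset({CALLER_SMALL, CALLER_STRUCTURAL})

REGION_CLASSES = frozenset(
    {"exonic", "splicing", "intronic", "UTR3", "UTR5", "intergenic"}
)

CLINVAR_ASSERTIONS = frozenset(
    {"pathogenic", "likely_pathogenic", "VUS", "likely_benign", "benign", "absent"}
)

CONSEQUENCES = (
    "nSNV",
    "sSNV",
    "frameshift insertion",
    "frameshift deletion",
    "nonframeshift indel",
    "stopgain",
    "duplication",
)

_CONSEQUENCE_ALIASES = {
    "nsnv": "nSNV",
    "nonsynonymous snv": "nSNV",
    "ssnv": "sSNV",
    "synonymous snv": "sSNV",
    "frameshift insertion": "frameshift insertion",
    "fs ins": "frameshift insertion",
    "frameshift deletion": "frameshift deletion",
    "fs del": "frameshift deletion",
    "nonframeshift indel": "nonframeshift indel",
    "stopgain": "stopgain",
    "duplication": "duplication",
}

_CLINVAR_ALIASES = {
    "pathogenic": "pathogenic",
    "likely pathogenic": "likely_pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "vus": "VUS",
    "uncertain significance": "VUS",
    "vus/likely benign": "VUS",
    "likely benign": "likely_benign",
    "likely_benign": "likely_benign",
    "benign": "benign",
    "absent": "absent",
    "na": "absent",
    "": "absent",
    ".": "absent",
}

SNV_CONSEQUENCES = frozenset({"nSNV", "sSNV"})
INDEL_CONSEQUENCES = frozenset(
    {"frameshift insertion", "frameshift deletion", "nonframeshift indel",
     "stopgain", "duplication"}
)

_ALLELE_RE = re.compile(r"^[ACGT]+$")

_MISSING = {"", ".", "na", "nan", "none"}


class FormatError(ValueError):
    """Raised for malformed or internally inconsistent input files."""


def normalize_chrom(chrom: str) -> str:
    """Map chromosome names onto the ``chrN`` convention (``9`` -> ``chr9``)."""
    chrom = chrom.strip()
    if not chrom:
        raise FormatError("empty chromosome name")
    if chrom.lower().startswith("chr"):
        return "chr" + chrom[3:]
    return "chr" + chrom


_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)}
_CHROM_ORDER.update({"chrX": 23, "chrY": 24, "chrM": 25, "chrMT": 25})


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural sort key: chr1..chr22, chrX, chrY, then others lexically."""
    return (_CHROM_ORDER.get(chrom, 99), chrom)


def map_consequence(text: str) -> str:
    """Map free annotation text onto the fixed consequence vocabulary.

    Matching is case- and whitespace-insensitive; unknown terms are preserved
    verbatim (they are treated as non-SNV by SNV-specific rules).
    """
    return _CONSEQUENCE_ALIASES.get(" ".join(text.lower().split()), text)


def map_clinvar(text: str) -> str:
    """Map free ClinVar text onto the fixed assertion vocabulary."""
    key = " ".join(text.lower().split())
    try:
        return _CLINVAR_ALIASES[key]
    except KeyError:
        raise FormatError(f"unrecognized ClinVar assertion: {text!r}") from None


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant: chromosome, 1-based position, ref and alt allele."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not _ALLELE_RE.match(allele):
                raise FormatError(
                    f"{name} allele must be a non-empty A/C/G/T string, got {allele!r}"
                )
        if self.ref == self.alt:
            raise FormatError(
                f"ref and alt are identical ({self.ref!r}): not a variant"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def max_allele_length(self) -> int:
        return max(len(self.ref), len(self.alt))


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sample, with caller provenance."""

    sample_id: str
    key: VariantKey
    vaf: float
    depth: int
    alt_reads: int
    caller: str
    gene: str | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    consequence: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise FormatError(f"vaf must lie in [0, 1], got {self.vaf}")
        if self.depth < 0 or self.alt_reads < 0:
            raise FormatError("read counts must be non-negative")
        if self.alt_reads > self.depth:
            raise FormatError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth})"
            )
        if self.depth > 0 and abs(self.vaf - self.alt_reads / self.depth) > 0.005:
            raise FormatError(
                f"vaf {self.vaf} inconsistent with {self.alt_reads}/{self.depth}"
            )
        if self.caller not in CALLERS:
            raise FormatError(f"unknown caller {self.caller!r}")
        if self.gene is not None and self.gene not in PANEL_GENES:
            raise FormatError(f"gene {self.gene!r} is not on the 22-gene panel")


#: frequency databases consulted for the population filter, in report order
MAF_DATABASES = ("maf_1000g", "maf_exac", "maf_esp6500", "maf_gnomad")


@dataclass(frozen=True)
class AnnotationRecord:
    """External knowledge for one variant key (wANNOVAR-style columns).

    A population MAF of ``None`` means *no frequency data*, which is distinct
    from 0: absence never triggers the common-variant exclusion and is
    flagged in reports.
    """

    key: VariantKey
    region_class: str
    maf_1000g: float | None = None
    maf_exac: float | None = None
    maf_esp6500: float | None = None
    maf_gnomad: float | None = None
    dbsnp_id: str | None = None
    dbsnp_exact_allele_match: bool = False
    clinvar_assertion: str = "absent"
    cosmic_ids: tuple[str, ...] = ()
    cosmic_pathogenic: bool = False

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise FormatError(f"unknown region class {self.region_class!r}")
        if self.clinvar_assertion not in CLINVAR_ASSERTIONS:
            raise FormatError(
                f"unknown ClinVar assertion {self.clinvar_assertion!r}"
            )
        for name in MAF_DATABASES:
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise FormatError(f"{name} must lie in [0, 1], got {v}")
        if self.cosmic_pathogenic and not self.cosmic_ids:
            raise FormatError("cosmic_pathogenic requires at least one COSMIC id")

    @property
    def mafs(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in MAF_DATABASES}

    @property
    def has_pathogenicity_evidence(self) -> bool:
        """ClinVar P/LP, a COSMIC pathogenicity assertion, or any COSMIC entry."""
        return (
            self.clinvar_assertion in ("pathogenic", "likely_pathogenic")
            or self.cosmic_pathogenic
            or bool(self.cosmic_ids)
        )


@dataclass(frozen=True)
class AmpliconRegion:
    """One panel target; coordinates are 1-based inclusive."""

    amplicon_id: str
    chrom: str
    start: int
    end: int
    gene: str | None = None
    exon_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start >= self.end:
            raise FormatError(
                f"{self.amplicon_id}: start ({self.start}) must be < end ({self.end})"
            )
        if not 50 <= self.length <= 1000:
            raise FormatError(
                f"{self.amplicon_id}: implausible amplicon length {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == normalize_chrom(chrom) and self.start <= pos <= self.end


@dataclass(frozen=True)
class CoverageRecord:
    """Mean sequencing depth of one amplicon in one sample/run."""

    amplicon_id: str
    sample_id: str
    run_id: str
    mean_depth: float

    def __post_init__(self) -> None:
        if self.mean_depth < 0 or math.isnan(self.mean_depth):
            raise FormatError(
                f"{self.amplicon_id}/{self.sample_id}: negative depth "
                f"{self.mean_depth}"
            )


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Panel gene symbol">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=HGVSC,Number=1,Type=String,Description="Transcript-level HGVS">
##INFO=<ID=HGVSP,Number=1,Type=String,Description="Protein-level HGVS">
##INFO=<ID=CALLERS,Number=.,Type=String,Description="Contributing caller(s)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Alternate allele fraction">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def _info_escape(text: str) -> str:
    return text.replace(";", "%3B").replace("=", "%3D").replace(" ", "_")


def _info_unescape(text: str) -> str:
    return text.replace("_", " ").replace("%3D", "=").replace("%3B", ";")


def write_callset(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write a single-sample call set as an uncompressed VCF v4.2 file.

    All calls must share one ``sample_id``. Output order is (chrom, pos, alt)
    and every field round-trips through :func:`read_callset`.
    """
    path = Path(path)
    samples = {c.sample_id for c in calls}
    if len(samples) > 1:
        raise FormatError(f"write_callset expects one sample, got {sorted(samples)}")
    sample = samples.pop() if samples else "SAMPLE"
    contigs = "".join(
        f"##contig=<ID={chrom}>\n"
        for chrom in sorted({c.key.chrom for c in calls}, key=chrom_sort_key)
    )
    lines = [_VCF_HEADER.format(sample=sample, contigs=contigs)]
    for call in sorted(
        calls, key=lambda c: (chrom_sort_key(c.key.chrom), c.key.pos, c.key.alt)
    ):
        info = []
        if call.gene:
            info.append(f"GENE={call.gene}")
        if call.consequence:
            info.append(f"CSQ={_info_escape(call.consequence)}")
        if call.hgvs_c:
            info.append(f"HGVSC={_info_escape(call.hgvs_c)}")
        if call.hgvs_p:
            info.append(f"HGVSP={_info_escape(call.hgvs_p)}")
        info.append(f"CALLERS={call.caller}")
        ref_reads = call.depth - call.alt_reads
        fmt = f"0/1:{call.depth}:{ref_reads},{call.alt_reads}:{call.vaf:.6f}"
        lines.append(
            "\t".join(
                [
                    call.key.chrom,
                    str(call.key.pos),
                    ".",
                    call.key.ref,
                    call.key.alt,
                    ".",
                    "PASS",
                    ";".join(info),
                    "GT:DP:AD:AF",
                    fmt,
                ]
            )
            + "\n"
        )
    path.write_text("".join(lines))


def read_callset(path: str | Path, caller_label: str) -> list[VariantCall]:
    """Read a VCF into :class:`VariantCall` records.

    Multi-allelic records are split into one call per alternate allele. VAF is
    taken from FORMAT/AF when present, otherwise derived as AD/DP; a record
    providing neither is an error naming the VCF line.

    ``caller_label`` stamps every call (the caller of origin is a property of
    the file, not of the VCF record).
    """
    path = Path(path)
    if caller_label not in CALLERS:
        raise FormatError(f"unknown caller label {caller_label!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        n_header = str(vcf.header).count("\n")
        sample_names = list(vcf.header.samples) or ["SAMPLE"]
        for idx, rec in enumerate(vcf):
            line_no = n_header + 1 + idx
            try:
                calls.extend(
                    _split_record(rec, sample_names, caller_label, line_no)
                )
            except FormatError:
                raise
            except Exception as exc:  # malformed record content
                raise FormatError(f"{path}, line {line_no}: {exc}") from exc
    return calls


def _info_get(rec, key: str):
    # pysam raises on INFO keys absent from the header; treat as missing
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _split_record(
    rec, sample_names: list[str], caller_label: str, line_no: int
) -> list[VariantCall]:
    alts = rec.alts or ()
    gene = _info_get(rec, "GENE")
    consequence = _info_get(rec, "CSQ")
    if consequence:
        consequence = map_consequence(_info_unescape(str(consequence)))
    hgvs_c = _info_get(rec, "HGVSC")
    hgvs_p = _info_get(rec, "HGVSP")
    out: list[VariantCall] = []
    for sample in sample_names:
        fmt = rec.samples[sample] if rec.samples else {}
        af = fmt.get("AF") if "AF" in (fmt or {}) else None
        ad = fmt.get("AD") if "AD" in (fmt or {}) else None
        dp = fmt.get("DP") if "DP" in (fmt or {}) else None
        if ad is not None and dp is None:
            dp = sum(a for a in ad if a is not None)
        for i, alt in enumerate(alts):
            if alt is None or alt in (".", "*"):
                continue
            key = VariantKey(rec.chrom, rec.pos, rec.ref, str(alt))
            alt_reads = None
            if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                alt_reads = int(ad[i + 1])
            if af is not None:
                vaf = float(af[i] if isinstance(af, tuple) else af)
                depth = int(dp) if dp is not None else 0
                if alt_reads is None:
                    alt_reads = int(round(vaf * depth)) if depth else 0
                elif depth > 0 and abs(vaf - alt_reads / depth) < 1e-6:
                    # htslib stores AF as float32; when AD/DP agree to within
                    # that quantization, recover the exact ratio
                    vaf = alt_reads / depth
            elif alt_reads is not None and dp is not None and int(dp) > 0:
                depth = int(dp)
                vaf = alt_reads / depth
            else:
                raise FormatError(
                    f"line {line_no}: cannot derive VAF — record carries neither "
                    f"FORMAT/AF nor FORMAT/AD+DP for sample {sample!r}"
                )
            out.append(
                VariantCall(
                    sample_id=sample,
                    key=key,
                    vaf=vaf,
                    depth=depth,
                    alt_reads=alt_reads,
                    caller=caller_label,
                    gene=str(gene) if gene else None,
                    hgvs_c=_info_unescape(str(hgvs_c)) if hgvs_c else None,
                    hgvs_p=_info_unescape(str(hgvs_p)) if hgvs_p else None,
                    consequence=consequence,
                )
            )
    return out


# ---------------------------------------------------------------------------
# BED manifest


def read_amplicon_manifest(path: str | Path) -> list[AmpliconRegion]:
    """Read a BED4(+) amplicon manifest.

    BED intervals are 0-based half-open; they are converted to the internal
    1-based inclusive convention (``chr1 43814901 43815103 AMPL117202`` becomes
    chr1:43814902–43815103). Columns 5/6, when present, are gene and exon label.
    """
    path = Path(path)
    regions: list[AmpliconRegion] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}, line {line_no}: BED4 requires >= 4 columns"
                )
            chrom, start_s, end_s, amplicon_id = fields[:4]
            try:
                bed_start, bed_end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path}, line {line_no}: non-integer coordinates"
                ) from None
            if bed_start >= bed_end:
                raise FormatError(
                    f"{path}, line {line_no}: degenerate interval "
                    f"[{bed_start}, {bed_end})"
                )
            if amplicon_id in seen:
                raise FormatError(
                    f"{path}, line {line_no}: duplicate amplicon id {amplicon_id!r}"
                )
            seen.add(amplicon_id)
            regions.append(
                AmpliconRegion(
                    amplicon_id=amplicon_id,
                    chrom=chrom,
                    start=bed_start + 1,  # BED -> 1-based inclusive
                    end=bed_end,
                    gene=fields[4] if len(fields) > 4 and fields[4] else None,
                    exon_label=fields[5] if len(fields) > 5 and fields[5] else None,
                )
            )
    return regions


def write_amplicon_manifest(
    regions: Sequence[AmpliconRegion], path: str | Path
) -> None:
    """Write amplicons as BED4+2, converting back to 0-based half-open."""
    with open(path, "w") as fh:
        for r in sorted(
            regions, key=lambda r: (chrom_sort_key(r.chrom), r.start, r.amplicon_id)
        ):
            fields = [r.chrom, str(r.start - 1), str(r.end), r.amplicon_id,
                      r.gene or "", r.exon_label or ""]
            fh.write("\t".join(fields).rstrip("\t") + "\n")


# ---------------------------------------------------------------------------
# annotation table

ANNOTATION_COLUMNS = (
    "chrom", "pos", "ref", "alt", "region_class",
    "maf_1000g", "maf_exac", "maf_esp6500", "maf_gnomad",
    "dbsnp_id", "dbsnp_exact_allele_match",
    "clinvar_assertion", "cosmic_ids", "cosmic_pathogenic",
)


def _parse_maf(raw: str, context: str) -> float | None:
    if raw.strip().lower() in _MISSING:
        return None
    try:
        value = float(raw)
    except ValueError:
        raise FormatError(f"{context}: unparseable MAF {raw!r}") from None
    if not 0.0 <= value <= 1.0:
        raise FormatError(f"{context}: MAF {value} outside [0, 1]")
    return value


def _parse_bool(raw: str, context: str) -> bool:
    token = raw.strip().lower()
    if token in {"true", "1", "yes", "y"}:
        return True
    if token in {"false", "0", "no", "n"} | _MISSING:
        return False
    raise FormatError(f"{context}: unparseable boolean {raw!r}")


def read_annotation_table(path: str | Path) -> dict[VariantKey, AnnotationRecord]:
    """Read a TSV of per-variant annotations keyed by (chrom, pos, ref, alt).

    Missing values are encoded as ``.`` or empty cells; a missing MAF is
    *absent*, never zero-filled. A key appearing twice with conflicting
    values is an error; an exact duplicate row is tolerated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing_cols)}")
    records: dict[VariantKey, AnnotationRecord] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        ctx = f"{path}, row {row_no}"
        key = VariantKey(row.chrom, int(row.pos), row.ref, row.alt)
        raw_clinvar = row.clinvar_assertion
        cosmic_raw = row.cosmic_ids.strip()
        cosmic_ids = (
            tuple(tok.strip() for tok in cosmic_raw.split(",") if tok.strip())
            if cosmic_raw.lower() not in _MISSING
            else ()
        )
        dbsnp = row.dbsnp_id.strip()
        record = AnnotationRecord(
            key=key,
            region_class=row.region_class.strip(),
            maf_1000g=_parse_maf(row.maf_1000g, ctx),
            maf_exac=_parse_maf(row.maf_exac, ctx),
            maf_esp6500=_parse_maf(row.maf_esp6500, ctx),
            maf_gnomad=_parse_maf(row.maf_gnomad, ctx),
            dbsnp_id=dbsnp if dbsnp.lower() not in _MISSING else None,
            dbsnp_exact_allele_match=_parse_bool(row.dbsnp_exact_allele_match, ctx),
            clinvar_assertion=map_clinvar(raw_clinvar),
            cosmic_ids=cosmic_ids,
            cosmic_pathogenic=_parse_bool(row.cosmic_pathogenic, ctx),
        )
        if key in records and records[key] != record:
            raise FormatError(f"{ctx}: conflicting duplicate annotation for {key}")
        records[key] = record
    return records


def write_annotation_table(
    annotations: Mapping[VariantKey, AnnotationRecord], path: str | Path
) -> None:
    rows = []
    for key in sorted(annotations, key=lambda k: (chrom_sort_key(k.chrom), k.pos, k.ref, k.alt)):
        a = annotations[key]
        rows.append(
            {
                "chrom": key.chrom,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "region_class": a.region_class,
                **{
                    name: ("." if v is None else repr(v))
                    for name, v in a.mafs.items()
                },
                "dbsnp_id": a.dbsnp_id or ".",
                "dbsnp_exact_allele_match": str(a.dbsnp_exact_allele_match).lower(),
                "clinvar_assertion": a.clinvar_assertion,
                "cosmic_ids": ",".join(a.cosmic_ids) or ".",
                "cosmic_pathogenic": str(a.cosmic_pathogenic).lower(),
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# coverage table (amplicons as rows, sample columns, wide dialect)

_RUN_SEP = "__"


def read_coverage_table(path: str | Path) -> list[CoverageRecord]:
    """Read a wide per-amplicon depth table into long-format records.

    Layout: first column ``amplicon_id``; every other column is one sample,
    optionally carrying a run label as ``<sample>__<run>``. Columns without a
    run label are assigned ``run1``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "amplicon_id":
        raise FormatError(f"{path}: first column must be 'amplicon_id'")
    records: list[CoverageRecord] = []
    for col in df.columns[1:]:
        sample_id, _, run_id = col.partition(_RUN_SEP)
        run_id = run_id or "run1"
        for _, row in df.iterrows():
            raw = row[col].strip()
            if raw in ("", "."):  # cell not measured for this sample/run
                continue
            try:
                depth = float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric depth {raw!r} at amplicon "
                    f"{row['amplicon_id']!r}, column {col!r}"
                ) from None
            try:
                records.append(
                    CoverageRecord(
                        amplicon_id=row["amplicon_id"],
                        sample_id=sample_id,
                        run_id=run_id,
                        mean_depth=depth,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}, column {col!r}: {exc}") from None
    return records


def write_coverage_table(
    records: Sequence[CoverageRecord], path: str | Path
) -> None:
    """Write long-format coverage records back to the wide dialect."""
    df = pd.DataFrame(
        [
            {
                "amplicon_id": r.amplicon_id,
                "column": f"{r.sample_id}{_RUN_SEP}{r.run_id}",
                "mean_depth": r.mean_depth,
            }
            for r in records
        ]
    )
    wide = df.pivot_table(
        index="amplicon_id", columns="column", values="mean_depth", aggfunc="first"
    )
    wide = wide.sort_index()
    wide = wide[sorted(wide.columns)]
    wide.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# truth sets

TRUTH_COLUMNS = (
    "standard_id", "chrom", "pos", "ref", "alt", "gene", "hgvs_p", "expected_vaf"
)


@dataclass(frozen=True)
class TruthVariant:
    """An expected variant of one reference standard, with its VAF tier."""

    standard_id: str
    key: VariantKey
    gene: str | None = None
    hgvs_p: str | None = None
    expected_vaf: float | None = None

    def __post_init__(self) -> None:
        if self.expected_vaf is not None and not 0.0 < self.expected_vaf <= 1.0:
            raise FormatError(
                f"expected_vaf must lie in (0, 1], got {self.expected_vaf}"
            )


def read_truth_sets(path: str | Path) -> dict[str, list[TruthVariant]]:
    """Read reference-standard truth sets from TSV, one row per expected variant.

    Negative (wild-type) standards are declared with a single row whose
    variant columns are all ``.``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing truth columns {sorted(missing)}")
    truth: dict[str, list[TruthVariant]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        std = row.standard_id
        truth.setdefault(std, [])
        if row.chrom.strip() in _MISSING:  # declared wild-type standard
            continue
        expected = _parse_maf(row.expected_vaf, f"{path}, row {row_no}")
        truth[std].append(
            TruthVariant(
                standard_id=std,
                key=VariantKey(row.chrom, int(row.pos), row.ref, row.alt),
                gene=row.gene if row.gene.strip() not in _MISSING else None,
                hgvs_p=row.hgvs_p if row.hgvs_p.strip() not in _MISSING else None,
                expected_vaf=expected,
            )
        )
    return truth


def write_truth_sets(
    truth: Mapping[str, Sequence[TruthVariant]], path: str | Path
) -> None:
    rows = []
    for std in sorted(truth):
        variants = truth[std]
        if not variants:
            rows.append(
                {c: (std if c == "standard_id" else ".") for c in TRUTH_COLUMNS}
            )
            continue
        for tv in sorted(
            variants, key=lambda t: (chrom_sort_key(t.key.chrom), t.key.pos, t.key.alt)
        ):
            rows.append(
                {
                    "standard_id": std,
                    "chrom": tv.key.chrom,
                    "pos": tv.key.pos,
                    "ref": tv.key.ref,
                    "alt": tv.key.alt,
                    "gene": tv.gene or ".",
                    "hgvs_p": tv.hgvs_p or ".",
                    "expected_vaf": "." if tv.expected_vaf is None else repr(tv.expected_vaf),
                }
            )
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)
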