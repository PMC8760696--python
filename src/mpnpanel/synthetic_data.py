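"""Seeded generators for every input the pipeline consumes.

Everything here is driven by a :class:`~mpnpanel.config.SimulationConfig`;
the same config (seed included) always produces bit-identical outputs, so
whole-pipeline runs are reproducible and testable offline.

What the generators emulate, structurally:

* a 219-amplicon, 22-gene panel whose amplicons carry GC fractions with a
  small high-GC tail — one amplicon is forced to GC ≈ 0.61 as the analogue
  of the poorly amplifying MPL exon-10 target, and two more sit in the
  1000x warning band;
* four reference standards: a wild-type negative, a 5%-tier positive
  (3 variants), a 1.3%-tier positive (9 variants) and a 20-variant myeloid
  mix that includes a 42-base duplication and an MPL hotspot SNV placed on
  the dropout amplicon;
* depth ~ LogNormal(log(target · m(gc)), sigma) where m is a logistic
  amplification-efficiency factor of GC content, normalized to ~1 at GC 0.45;
* read support ~ Binomial(depth, VAF) with a caller floor of
  ``min_alt_reads`` reads and ``vaf_floor`` fraction — at < 100x this floor
  is exactly what makes a 1.3% variant invisible;
* a 10-sample MPN-like cohort (7 samples sharing one hotspot SNV driver,
  3 carrying private exon-9-style frameshifts) with passengers, germline
  polymorphisms (population MAF >= 1%), low-VAF noise artifacts,
  cohort-recurrent systematic artifacts, and one low-VAF database-pathogenic
  variant per cohort — every planted variant carries a ground-truth label
  so triage recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Mapping, Sequence

import numpy as np

from . import PANEL_GENES
from .caller_merge import merge_callsets
from .config import SimulationConfig
from .io_formats import (
    CALLER_SMALL,
    CALLER_STRUCTURAL,
    AmpliconRegion,
    AnnotationRecord,
    CoverageRecord,
    FormatError,
    TruthVariant,
    VariantCall,
    VariantKey,
)
from .panel_validation import ReplicateCallset

BASES = "ACGT"

# GRCh37-flavoured toy coordinate namespace: one base locus per panel gene.
GENE_LOCI = {
    "ABL1": ("chr9", 133_589_000),
    "ASXL1": ("chr20", 31_015_000),
    "CALR": ("chr19", 13_049_000),
    "CBL": ("chr11", 119_076_000),
    "CEBPA": ("chr19", 33_790_000),
    "CSF3R": ("chr1", 36_931_000),
    "DNMT3A": ("chr2", 25_455_000),
    "EZH2": ("chr7", 148_504_000),
    "FLT3": ("chr13", 28_577_000),
    "IDH1": ("chr2", 209_100_000),
    "IDH2": ("chr15", 90_627_000),
    "JAK2": ("chr9", 5_021_000),
    "KIT": ("chr4", 55_524_000),
    "MPL": ("chr1", 43_803_000),
    "NPM1": ("chr5", 170_814_000),
    "PDGFRA": ("chr4", 55_095_000),
    "RUNX1": ("chr21", 36_160_000),
    "SF3B1": ("chr2", 198_254_000),
    "SRSF2": ("chr17", 74_732_000),
    "TET2": ("chr4", 106_067_000),
    "TP53": ("chr17", 7_565_000),
    "U2AF1": ("chr21", 44_513_000),
}

# recognisable fixed hotspots (kept at their real GRCh37 loci)
JAK2_V617F_KEY = VariantKey("chr9", 5_073_770, "G", "T")
MPL_W515L_KEY = VariantKey("chr1", 43_815_009, "G", "T")
JAK2_ANCHOR = ("chr9", 5_073_700, 5_073_899)
CALR_ANCHOR = ("chr19", 13_054_500, 13_054_699)
MPL_ANCHOR = ("chr1", 43_814_902, 43_815_103)  # the GC-rich dropout amplicon


@dataclass
class SyntheticPanel:
    regions: list[AmpliconRegion]
    gc: dict[str, float]
    mpl_analogue_id: str
    warn_analogue_ids: tuple[str, ...]

    def region_for(self, chrom: str, pos: int) -> AmpliconRegion | None:
        for region in self.regions:
            if region.contains(chrom, pos):
                return region
        return None

    def first_amplicon(self, gene: str) -> AmpliconRegion:
        for region in self.regions:
            if region.gene == gene:
                return region
        raise KeyError(gene)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_panel(config: SimulationConfig) -> SyntheticPanel:
    """Amplicon manifest plus per-amplicon GC content.

    219 amplicons across the 22 panel genes, lengths ~150–250. The last
    amplicons of JAK2, CALR and MPL are pinned to the fixed hotspot loci so
    the recognisable driver keys always fall inside the panel; the MPL one
    is the forced GC ≈ 0.61 dropout analogue, and the first amplicons of
    DNMT3A and TP53 sit just inside the high-GC warning band.
    """
    rng = _rng(config, 1)
    genes = sorted(PANEL_GENES)
    base_count, extra = divmod(config.n_amplicons, len(genes))
    lo, hi = config.amplicon_length_range

    regions: list[AmpliconRegion] = []
    gc: dict[str, float] = {}
    idx = 0
    per_gene_last: dict[str, int] = {}
    for g_i, gene in enumerate(genes):
        n_for_gene = base_count + (1 if g_i < extra else 0)
        chrom, cursor = GENE_LOCI[gene]
        for _ in range(n_for_gene):
            idx += 1
            length = int(rng.integers(lo, hi + 1))
            start = cursor
            end = start + length - 1
            cursor = end + int(rng.integers(100, 401))
            amplicon_id = f"AMPL{idx:05d}"
            regions.append(
                AmpliconRegion(
                    amplicon_id=amplicon_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    gene=gene,
                    exon_label=f"{gene} region {idx}",
                )
            )
            gc[amplicon_id] = float(np.clip(rng.normal(0.50, 0.035), 0.38, 0.565))
            per_gene_last[gene] = len(regions) - 1

    def _pin(gene: str, anchor: tuple[str, int, int], label: str) -> str:
        i = per_gene_last[gene]
        old = regions[i]
        regions[i] = AmpliconRegion(
            amplicon_id=old.amplicon_id,
            chrom=anchor[0],
            start=anchor[1],
            end=anchor[2],
            gene=gene,
            exon_label=label,
        )
        return old.amplicon_id

    _pin("JAK2", JAK2_ANCHOR, "JAK2 exon 14 analogue")
    _pin("CALR", CALR_ANCHOR, "CALR exon 9 analogue")
    mpl_id = _pin("MPL", MPL_ANCHOR, "MPL exon 10 analogue")
    gc[mpl_id] = 0.61

    warn_ids = []
    for gene, warn_gc in (("DNMT3A", 0.590), ("TP53", 0.588)):
        first = next(r for r in regions if r.gene == gene)
        gc[first.amplicon_id] = warn_gc
        warn_ids.append(first.amplicon_id)

    return SyntheticPanel(
        regions=regions,
        gc=gc,
        mpl_analogue_id=mpl_id,
        warn_analogue_ids=tuple(warn_ids),
    )


def panel_sequences(panel: SyntheticPanel, config: SimulationConfig) -> dict[str, str]:
    """Deterministic nucleotide sequences matching each amplicon's GC content.

    Sequences are built window-by-window so the high-GC analogue shows the
    expected profile: the majority of its 30 bp windows exceed 60% GC.
    """
    rng = _rng(config, 2)
    out: dict[str, str] = {}
    for region in panel.regions:
        target = panel.gc[region.amplicon_id]
        high_gc = target > 0.60
        seq_parts: list[str] = []
        remaining = region.length
        while remaining > 0:
            w = min(30, remaining)
            if high_gc:
                # most windows clearly GC-rich, a minority moderate, so the
                # overall fraction lands near the target while the majority
                # of windows exceed the 60% flag
                if rng.random() < 0.7:
                    window_gc = float(rng.uniform(0.63, 0.70))
                else:
                    window_gc = float(rng.uniform(0.42, 0.52))
            else:
                window_gc = float(np.clip(rng.normal(target, 0.05), 0.0, 1.0))
            n_gc = int(round(window_gc * w))
            bases = ["G" if i < n_gc else "A" for i in range(w)]
            # randomize identities and order without changing GC count
            bases = [
                (rng.choice(["G", "C"]) if b == "G" else rng.choice(["A", "T"]))
                for b in bases
            ]
            rng.shuffle(bases)
            seq_parts.append("".join(bases))
            remaining -= w
        out[region.amplicon_id] = "".join(seq_parts)
    return out


def _efficiency(gc: float, config: SimulationConfig) -> float:
    logistic = lambda g: 1.0 / (1.0 + np.exp((g - config.gc_dropout_midpoint) / config.gc_dropout_width))  # noqa: E731
    return float(logistic(gc) / logistic(0.45))


def simulate_coverage(
    panel: SyntheticPanel,
    config: SimulationConfig,
    samples: Sequence[tuple[str, str]],
) -> list[CoverageRecord]:
    """Per-amplicon mean depth for each (sample_id, run_id).

    depth ~ LogNormal(log(target_depth · m(gc)), sigma) with m the logistic
    GC-efficiency factor; sigma = 0 degenerates to exactly target · m(gc).
    """
    rng = _rng(config, 3)
    records: list[CoverageRecord] = []
    for sample_id, run_id in samples:
        for region in panel.regions:
            mu = config.target_depth * _efficiency(panel.gc[region.amplicon_id], config)
            if config.depth_dispersion == 0:
                depth = mu
            else:
                depth = float(rng.lognormal(np.log(mu), config.depth_dispersion))
            records.append(
                CoverageRecord(
                    amplicon_id=region.amplicon_id,
                    sample_id=sample_id,
                    run_id=run_id,
                    mean_depth=depth,
                )
            )
    return records


# ---------------------------------------------------------------------------
# reference standards


@dataclass(frozen=True)
class PlannedVariant:
    """A variant to be planted into a simulated sample at a true VAF."""

    key: VariantKey
    gene: str | None
    consequence: str
    true_vaf: float
    hgvs_p: str | None = None


def _snv_at(chrom: str, pos: int, ref: str = "C", alt: str = "T") -> VariantKey:
    return VariantKey(chrom, pos, ref, alt)


def _del_at(chrom: str, pos: int, n: int) -> VariantKey:
    """Deletion of n bases after an anchor, deterministic deleted sequence."""
    deleted = "".join(BASES[(pos + i) % 4] for i in range(n))
    return VariantKey(chrom, pos, "A" + deleted, "A")


def _ins_at(chrom: str, pos: int, n: int) -> VariantKey:
    inserted = "".join(BASES[(pos + 2 * i + 1) % 4] for i in range(n))
    return VariantKey(chrom, pos, "A", "A" + inserted)


def generate_reference_standards(
    config: SimulationConfig,
) -> dict[str, list[TruthVariant]]:
    """The four validation standards' truth sets.

    Mirrors the documented composition: a wild-type negative standard
    (``TruQ0``: no variants), a 5% tier with 3 variants (``TruQ1``), a 1.3%
    tier with 9 (``TruQ7``), and a 20-variant myeloid mix
    (``SeraseqMyeloid``) containing one 42-base duplication and the MPL
    hotspot SNV that sits on the dropout amplicon. Shared hotspots reuse one
    key across standards, so the cross-standard union holds 26 unique
    variants. Keys are deterministic given the config (they are placed
    inside the generated panel's amplicons).
    """
    panel = generate_panel(config)

    def off(gene: str, offset: int) -> tuple[str, int]:
        a = panel.first_amplicon(gene)
        pos = a.start + offset
        if pos > a.end:
            raise FormatError(f"offset {offset} escapes amplicon {a.amplicon_id}")
        return a.chrom, pos

    # shared hotspot keys
    flt3_di836 = _del_at(*off("FLT3", 30), 3)           # nonframeshift 3-bp del
    flt3_d835y = _snv_at(*off("FLT3", 60), "G", "T")
    idh1_r132c = _snv_at(*off("IDH1", 30), "C", "T")
    idh1_r132h = _snv_at(*off("IDH1", 31), "G", "A")
    jak2_v617f = JAK2_V617F_KEY

    dup_seq = "".join(BASES[(7 * i + 1) % 4] for i in range(42))
    flt3_chrom, flt3_dup_pos = off("FLT3", 90)
    flt3_dup42 = VariantKey(flt3_chrom, flt3_dup_pos, "A", "A" + dup_seq)

    calr_chrom = CALR_ANCHOR[0]
    calr_l367 = _del_at(calr_chrom, CALR_ANCHOR[1] + 20, 52)

    tv = lambda std, key, gene, hgvs, vaf: TruthVariant(  # noqa: E731
        standard_id=std, key=key, gene=gene, hgvs_p=hgvs, expected_vaf=vaf
    )

    truq1 = [
        tv("TruQ1", flt3_di836, "FLT3", "p.I836del", 0.05),
        tv("TruQ1", idh1_r132c, "IDH1", "p.R132C", 0.05),
        tv("TruQ1", jak2_v617f, "JAK2", "p.V617F", 0.05),
    ]
    truq7 = [
        tv("TruQ7", flt3_d835y, "FLT3", "p.D835Y", 0.013),
        tv("TruQ7", flt3_di836, "FLT3", "p.I836del", 0.013),
        tv("TruQ7", idh1_r132c, "IDH1", "p.R132C", 0.013),
        tv("TruQ7", idh1_r132h, "IDH1", "p.R132H", 0.013),
        tv("TruQ7", _snv_at(*off("IDH2", 30), "G", "A"), "IDH2", "p.R140Q", 0.013),
        tv("TruQ7", _snv_at(*off("IDH2", 60), "G", "A"), "IDH2", "p.R172K", 0.013),
        tv("TruQ7", jak2_v617f, "JAK2", "p.V617F", 0.013),
        tv("TruQ7", _snv_at(*off("KIT", 30), "A", "T"), "KIT", "p.D816V", 0.013),
        tv("TruQ7", _snv_at(*off("PDGFRA", 30), "A", "T"), "PDGFRA", "p.D842V", 0.013),
    ]
    sera = [
        tv("SeraseqMyeloid", _snv_at(*off("ABL1", 30), "C", "T"), "ABL1", "p.T315I", 0.10),
        tv("SeraseqMyeloid", _del_at(*off("ASXL1", 30), 1), "ASXL1", "p.E635fs*15", 0.10),
        tv("SeraseqMyeloid", _ins_at(*off("ASXL1", 60), 1), "ASXL1", "p.G646fs*12", 0.10),
        tv("SeraseqMyeloid", calr_l367, "CALR", "p.L367fs*46", 0.10),
        tv("SeraseqMyeloid", _snv_at(*off("CBL", 30), "G", "A"), "CBL", "p.R420Q", 0.10),
        tv("SeraseqMyeloid", _snv_at(*off("CBL", 60), "T", "C"), "CBL", "p.L380P", 0.10),
        tv("SeraseqMyeloid", _del_at(*off("CEBPA", 30), 2), "CEBPA", "p.H24fs*84", 0.10),
        tv("SeraseqMyeloid", _ins_at(*off("CEBPA", 60), 3), "CEBPA", "p.K313_V314insK", 0.10),
        tv("SeraseqMyeloid", _snv_at(*off("CSF3R", 30), "C", "T"), "CSF3R", "p.T618I", 0.10),
        tv("SeraseqMyeloid", flt3_dup42, "FLT3", "c.1759_1800dup", 0.10),
        tv("SeraseqMyeloid", flt3_d835y, "FLT3", "p.D835Y", 0.10),
        tv("SeraseqMyeloid", idh1_r132c, "IDH1", "p.R132C", 0.10),
        tv("SeraseqMyeloid", jak2_v617f, "JAK2", "p.V617F", 0.10),
        tv("SeraseqMyeloid", _del_at(*off("JAK2", 30), 6), "JAK2", "p.N542_E543del", 0.10),
        tv("SeraseqMyeloid", MPL_W515L_KEY, "MPL", "p.W515L", 0.05),
        tv("SeraseqMyeloid", _ins_at(*off("NPM1", 30), 4), "NPM1", "p.W288fs*12", 0.10),
        tv("SeraseqMyeloid", _snv_at(*off("SF3B1", 30), "A", "G"), "SF3B1", "p.K700E", 0.10),
        tv("SeraseqMyeloid", _snv_at(*off("SF3B1", 60), "G", "T"), "SF3B1", "p.K666N", 0.10),
        tv("SeraseqMyeloid", _del_at(*off("SRSF2", 30), 24), "SRSF2", "p.P95_R102del", 0.10),
        tv("SeraseqMyeloid", _snv_at(*off("U2AF1", 30), "C", "T"), "U2AF1", "p.S34F", 0.10),
    ]
    return {
        "TruQ0": [],
        "TruQ1": truq1,
        "TruQ7": truq7,
        "SeraseqMyeloid": sera,
    }


# ---------------------------------------------------------------------------
# read-support sampling


def _consequence_for_key(key: VariantKey, default_snv: str = "nSNV") -> str:
    if key.is_snv:
        return default_snv
    diff = len(key.alt) - len(key.ref)
    if diff > 25:
        return "duplication"
    if diff > 0:
        return "frameshift insertion" if diff % 3 else "nonframeshift indel"
    return "frameshift deletion" if diff % 3 else "nonframeshift indel"


def simulate_callset(
    planned: Sequence[PlannedVariant],
    panel: SyntheticPanel,
    depth_by_amplicon: Mapping[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Sample read support for planned variants and route them to callers.

    alt_reads ~ Binomial(depth, true_vaf); a variant is emitted only when it
    clears both detection floors (``min_alt_reads`` reads and ``vaf_floor``
    fraction). SNVs go to the small-variant caller only, events longer than
    the large-event cutoff to the structural caller only, other indels to
    both. Returns (small_calls, structural_calls).
    """
    small: list[VariantCall] = []
    structural: list[VariantCall] = []
    for pv in planned:
        region = panel.region_for(pv.key.chrom, pv.key.pos)
        if region is None:
            raise FormatError(f"variant {pv.key} lies outside every panel amplicon")
        depth = int(round(depth_by_amplicon[region.amplicon_id]))
        if depth <= 0:
            continue
        alt = int(rng.binomial(depth, pv.true_vaf))
        vaf = alt / depth
        if alt < config.min_alt_reads or vaf < config.vaf_floor:
            continue
        targets = []
        if pv.key.is_snv:
            targets = [CALLER_SMALL]
        elif pv.key.max_allele_length > 25:
            targets = [CALLER_STRUCTURAL]
        else:
            targets = [CALLER_SMALL, CALLER_STRUCTURAL]
        for caller in targets:
            call = VariantCall(
                sample_id=sample_id,
                key=pv.key,
                vaf=vaf,
                depth=depth,
                alt_reads=alt,
                caller=caller,
                gene=pv.gene,
                hgvs_p=pv.hgvs_p,
                consequence=pv.consequence,
            )
            (small if caller == CALLER_SMALL else structural).append(call)
    return small, structural


def simulate_replicates(
    truth_sets: Mapping[str, Sequence[TruthVariant]],
    config: SimulationConfig,
    n_runs: int = 2,
    replicates_per_run: int = 1,
    drop: Collection[tuple[str, str, str, VariantKey]] = (),
    extra_calls: Mapping[tuple[str, str, str], Sequence[PlannedVariant]] | None = None,
) -> list[ReplicateCallset]:
    """Simulate merged call sets for every (standard, replicate, run).

    Detection is deliberately *unconditional* here (observed VAF is binomial
    noise around the tier, but every truth variant is emitted), so that a run
    with no injected misses scores sensitivity 1.0 for any seed; use ``drop``
    to inject specific misses — ``(standard_id, replicate_id, run_id, key)``
    — and ``extra_calls`` to inject false positives. The coverage-driven miss
    mechanism is exercised separately through :func:`simulate_callset`.
    """
    rng = _rng(config, 4)
    extra_calls = extra_calls or {}
    drop = set(drop)
    replicates: list[ReplicateCallset] = []
    for std in sorted(truth_sets):
        for run_i in range(1, n_runs + 1):
            run_id = f"run{run_i}"
            for rep_i in range(1, replicates_per_run + 1):
                rep_id = f"rep{rep_i}"
                small: list[VariantCall] = []
                structural: list[VariantCall] = []
                sample_id = f"{std}_{run_id}_{rep_id}"
                for tvar in truth_sets[std]:
                    if (std, rep_id, run_id, tvar.key) in drop:
                        continue
                    depth = int(
                        round(
                            rng.lognormal(
                                np.log(config.target_depth), config.depth_dispersion
                            )
                        )
                    )
                    true_vaf = tvar.expected_vaf or 0.5
                    alt = max(int(rng.binomial(depth, true_vaf)), 1)
                    call_args = dict(
                        sample_id=sample_id,
                        key=tvar.key,
                        vaf=alt / depth,
                        depth=depth,
                        alt_reads=alt,
                        gene=tvar.gene,
                        hgvs_p=tvar.hgvs_p,
                        consequence=_consequence_for_key(tvar.key),
                    )
                    if tvar.key.is_snv:
                        small.append(VariantCall(caller=CALLER_SMALL, **call_args))
                    elif tvar.key.max_allele_length > 25:
                        structural.append(
                            VariantCall(caller=CALLER_STRUCTURAL, **call_args)
                        )
                    else:
                        small.append(VariantCall(caller=CALLER_SMALL, **call_args))
                        structural.append(
                            VariantCall(caller=CALLER_STRUCTURAL, **call_args)
                        )
                for pv in extra_calls.get((std, rep_id, run_id), ()):
                    depth = int(round(config.target_depth))
                    alt = max(int(round(pv.true_vaf * depth)), 1)
                    call = VariantCall(
                        sample_id=sample_id,
                        key=pv.key,
                        vaf=alt / depth,
                        depth=depth,
                        alt_reads=alt,
                        caller=CALLER_SMALL if pv.key.is_snv else CALLER_STRUCTURAL,
                        gene=pv.gene,
                        consequence=pv.consequence,
                    )
                    (small if call.caller == CALLER_SMALL else structural).append(call)
                merged = merge_callsets(small, structural)
                replicates.append(
                    ReplicateCallset(
                        standard_id=std,
                        replicate_id=rep_id,
                        run_id=run_id,
                        calls=tuple(merged.calls),
                    )
                )
    return replicates


# ---------------------------------------------------------------------------
# MPN-like cohort

LABEL_SOMATIC = "somatic"
LABEL_RESCUEABLE = "rescueable"
LABEL_GERMLINE = "germline_common"
LABEL_NON_EXONIC = "non_exonic"
LABEL_ARTIFACT = "artifact"
LABEL_SYSTEMATIC = "systematic_artifact"

#: expected triage status per ground-truth label
EXPECTED_STATUS = {
    LABEL_SOMATIC: "retained",
    LABEL_RESCUEABLE: "rescued_pathogenic",
    LABEL_GERMLINE: "excluded_common",
    LABEL_NON_EXONIC: "excluded_region",
    LABEL_ARTIFACT: "excluded_artifact",
    LABEL_SYSTEMATIC: "excluded_artifact",
}


@dataclass
class CohortSimulation:
    config: SimulationConfig
    panel: SyntheticPanel
    samples: list[str]
    calls_small: dict[str, list[VariantCall]]
    calls_structural: dict[str, list[VariantCall]]
    annotations: dict[VariantKey, AnnotationRecord]
    labels: dict[tuple[str, VariantKey], str]
    coverage: list[CoverageRecord]
    jak2_samples: tuple[str, ...]
    calr_samples: tuple[str, ...]

    def merged_calls(self) -> list[VariantCall]:
        out: list[VariantCall] = []
        for sample in self.samples:
            merged = merge_callsets(
                self.calls_small[sample], self.calls_structural[sample]
            )
            out.extend(merged.calls)
        return out


def _safe_positions(panel: SyntheticPanel, rng: np.random.Generator, n: int,
                    used: set[tuple[str, int]]) -> list[tuple[str, int, str]]:
    """Draw n distinct (chrom, pos, gene) sites on well-covered amplicons."""
    ok_regions = [
        r for r in panel.regions if panel.gc[r.amplicon_id] < 0.57
    ]
    out = []
    while len(out) < n:
        region = ok_regions[int(rng.integers(len(ok_regions)))]
        pos = int(rng.integers(region.start + 5, region.end - 60))
        if (region.chrom, pos) in used:
            continue
        used.add((region.chrom, pos))
        out.append((region.chrom, pos, region.gene))
    return out


def _random_key(chrom: str, pos: int, rng: np.random.Generator, kind: str) -> VariantKey:
    if kind == "snv":
        ref, alt = rng.choice(list(BASES), size=2, replace=False)
        return VariantKey(chrom, pos, str(ref), str(alt))
    if kind == "fs_del":
        n = int(rng.choice([1, 2, 4, 5]))
        return _del_at(chrom, pos, n)
    if kind == "fs_ins":
        n = int(rng.choice([1, 2, 4, 5]))
        return _ins_at(chrom, pos, n)
    raise ValueError(kind)


def generate_cohort(config: SimulationConfig) -> CohortSimulation:
    """An annotated MPN-like cohort with known ground truth.

    Drivers: ``n_jak2_like`` samples share the fixed hotspot SNV key;
    ``n_calr_like`` samples carry private exon-9-style frameshift deletions.
    Each sample additionally receives 0–``passenger_max`` somatic passengers
    (true VAF >= 7%), germline heterozygous polymorphisms (population MAF
    >= 1%, VAF ~ 50%), a few non-exonic calls, Poisson low-VAF noise
    artifacts (true VAF < 5% band), and the cohort-recurrent systematic
    artifact keys; one sample carries a database-pathogenic variant in the
    1–5% rescue window.
    """
    panel = generate_panel(config)
    rng = _rng(config, 5)
    samples = [f"S{i:02d}" for i in range(1, config.n_samples + 1)]
    coverage = simulate_coverage(panel, config, [(s, "run1") for s in samples])
    depth_by_sample: dict[str, dict[str, float]] = {}
    for rec in coverage:
        depth_by_sample.setdefault(rec.sample_id, {})[rec.amplicon_id] = rec.mean_depth

    order = list(rng.permutation(samples))
    jak2_samples = tuple(sorted(order[: config.n_jak2_like]))
    calr_samples = tuple(
        sorted(order[config.n_jak2_like : config.n_jak2_like + config.n_calr_like])
    )

    annotations: dict[VariantKey, AnnotationRecord] = {}
    labels: dict[tuple[str, VariantKey], str] = {}
    planned: dict[str, list[PlannedVariant]] = {s: [] for s in samples}
    # reserve the fixed hotspot loci so random sites never collide with them
    used_sites: set[tuple[str, int]] = {
        (JAK2_V617F_KEY.chrom, JAK2_V617F_KEY.pos),
        (MPL_W515L_KEY.chrom, MPL_W515L_KEY.pos),
    }

    def annotate(key: VariantKey, **kwargs) -> None:
        annotations.setdefault(
            key, AnnotationRecord(key=key, **kwargs)
        )

    # --- drivers -----------------------------------------------------------
    annotate(
        JAK2_V617F_KEY,
        region_class="exonic",
        dbsnp_id="rs77375493",
        dbsnp_exact_allele_match=True,
        clinvar_assertion="pathogenic",
        cosmic_ids=("COSM12600",),
        cosmic_pathogenic=True,
    )
    for sample in jak2_samples:
        planned[sample].append(
            PlannedVariant(
                key=JAK2_V617F_KEY,
                gene="JAK2",
                consequence="nSNV",
                true_vaf=float(rng.uniform(0.12, 0.90)),
                hgvs_p="p.Val617Phe",
            )
        )
        labels[(sample, JAK2_V617F_KEY)] = LABEL_SOMATIC
    for i, sample in enumerate(calr_samples):
        key = _del_at(CALR_ANCHOR[0], CALR_ANCHOR[1] + 20 + 7 * i, int([52, 5, 7][i % 3]))
        annotate(
            key,
            region_class="exonic",
            cosmic_ids=(f"COSM17380{i:02d}",),
            cosmic_pathogenic=True,
        )
        planned[sample].append(
            PlannedVariant(
                key=key,
                gene="CALR",
                consequence="frameshift deletion",
                true_vaf=float(rng.uniform(0.10, 0.50)),
                hgvs_p=f"p.exon9fs_{i}",
            )
        )
        labels[(sample, key)] = LABEL_SOMATIC

    # --- somatic passengers ------------------------------------------------
    n_passengers = [int(rng.integers(0, config.passenger_max + 1)) for _ in samples]
    sites = _safe_positions(panel, rng, sum(n_passengers), used_sites)
    site_iter = iter(sites)
    for sample, n_p in zip(samples, n_passengers):
        for _ in range(n_p):
            chrom, pos, gene = next(site_iter)
            kind = str(rng.choice(["snv"] * 6 + ["fs_del", "fs_ins"]))
            key = _random_key(chrom, pos, rng, kind)
            reported = bool(rng.random() < 0.5)
            annotate(
                key,
                region_class="exonic",
                cosmic_ids=(f"COSM{int(rng.integers(10**5, 10**6))}",) if reported else (),
            )
            consequence = _consequence_for_key(key, default_snv=str(rng.choice(["nSNV"] * 4 + ["sSNV"])))
            planned[sample].append(
                PlannedVariant(
                    key=key,
                    gene=gene,
                    consequence=consequence,
                    true_vaf=float(rng.uniform(0.07, 0.55)),
                )
            )
            labels[(sample, key)] = LABEL_SOMATIC

    # --- germline polymorphism pool ---------------------------------------
    pool_sites = _safe_positions(panel, rng, 20, used_sites)
    germline_pool = []
    for chrom, pos, gene in pool_sites:
        key = _random_key(chrom, pos, rng, "snv")
        annotate(
            key,
            region_class="exonic",
            maf_gnomad=float(rng.uniform(0.012, 0.40)),
            maf_1000g=float(rng.uniform(0.012, 0.40)) if rng.random() < 0.5 else None,
            dbsnp_id=f"rs{int(rng.integers(10**6, 10**8))}",
            dbsnp_exact_allele_match=True,
        )
        germline_pool.append((key, gene))
    for sample in samples:
        take = rng.choice(len(germline_pool), size=min(config.germline_het_count, len(germline_pool)), replace=False)
        for idx in sorted(take):
            key, gene = germline_pool[idx]
            planned[sample].append(
                PlannedVariant(key=key, gene=gene, consequence="nSNV", true_vaf=0.5)
            )
            labels[(sample, key)] = LABEL_GERMLINE

    # --- non-exonic calls --------------------------------------------------
    nonexonic_sites = _safe_positions(panel, rng, 5, used_sites)
    nonexonic_pool = []
    for chrom, pos, gene in nonexonic_sites:
        key = _random_key(chrom, pos, rng, "snv")
        annotate(key, region_class=str(rng.choice(["intronic", "UTR3", "UTR5", "splicing"])))
        nonexonic_pool.append((key, gene))
    for sample in samples:
        take = rng.choice(len(nonexonic_pool), size=2, replace=False)
        for idx in sorted(take):
            key, gene = nonexonic_pool[idx]
            planned[sample].append(
                PlannedVariant(key=key, gene=gene, consequence="nSNV", true_vaf=0.5)
            )
            labels[(sample, key)] = LABEL_NON_EXONIC

    # --- systematic artifacts ---------------------------------------------
    sys_sites = _safe_positions(panel, rng, config.n_systematic_artifacts, used_sites)
    n_carriers = int(round(config.systematic_artifact_fraction * len(samples)))
    for chrom, pos, gene in sys_sites:
        key = _random_key(chrom, pos, rng, "snv")
        annotate(key, region_class="exonic")
        carriers = sorted(str(s) for s in rng.choice(samples, size=n_carriers, replace=False))
        for sample in carriers:
            planned[sample].append(
                PlannedVariant(
                    key=key,
                    gene=gene,
                    consequence="nSNV",
                    true_vaf=float(rng.uniform(0.055, 0.10)),
                )
            )
            labels[(sample, key)] = LABEL_SYSTEMATIC

    # --- random low-VAF artifacts ------------------------------------------
    for sample in samples:
        n_art = int(rng.poisson(config.error_artifact_rate))
        art_sites = _safe_positions(panel, rng, n_art, used_sites)
        for chrom, pos, gene in art_sites:
            key = _random_key(chrom, pos, rng, "snv")
            annotate(key, region_class="exonic")
            vaf = float(rng.beta(config.artifact_vaf_a, config.artifact_vaf_b))
            while vaf >= config.artifact_vaf_max:
                vaf = float(rng.beta(config.artifact_vaf_a, config.artifact_vaf_b))
            planned[sample].append(
                PlannedVariant(key=key, gene=gene, consequence="nSNV", true_vaf=vaf)
            )
            labels[(sample, key)] = LABEL_ARTIFACT

    # --- one rescueable pathogenic low-VAF variant -------------------------
    rescue_sample = str(rng.choice(samples))
    chrom, pos, gene = _safe_positions(panel, rng, 1, used_sites)[0]
    rescue_key = _random_key(chrom, pos, rng, "snv")
    annotate(
        rescue_key,
        region_class="exonic",
        cosmic_ids=(f"COSM{int(rng.integers(10**5, 10**6))}",),
        cosmic_pathogenic=True,
    )
    planned[rescue_sample].append(
        PlannedVariant(
            key=rescue_key,
            gene=gene,
            consequence="stopgain",
            true_vaf=float(rng.uniform(0.020, 0.038)),
        )
    )
    labels[(rescue_sample, rescue_key)] = LABEL_RESCUEABLE

    # --- sample read support ----------------------------------------------
    calls_small: dict[str, list[VariantCall]] = {}
    calls_structural: dict[str, list[VariantCall]] = {}
    emitted: set[tuple[str, VariantKey]] = set()
    for sample in samples:
        small, structural = simulate_callset(
            planned[sample], panel, depth_by_sample[sample], config, rng, sample
        )
        calls_small[sample] = small
        calls_structural[sample] = structural
        emitted.update((sample, c.key) for c in small + structural)

    # artifacts below the detection floor never surface; drop their labels
    labels = {
        sk: lab
        for sk, lab in labels.items()
        if lab != LABEL_ARTIFACT or sk in emitted
    }

    return CohortSimulation(
        config=config,
        panel=panel,
        samples=samples,
        calls_small=calls_small,
        calls_structural=calls_structural,
        annotations=annotations,
        labels=labels,
        coverage=coverage,
        jak2_samples=jak2_samples,
        calr_samples=calr_samples,
    )
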