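"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive expected results by brute force
(single-predicate triage, direct confusion counting) so the pipeline is
always checked against an implementation that shares none of its code path.
"""

from __future__ import annotations

import numpy as np
import pytest

from mpnpanel.config import PipelineConfig, SimulationConfig
from mpnpanel.io_formats import (
    CALLER_SMALL,
    AnnotationRecord,
    VariantCall,
    VariantKey,
)

# ---------------------------------------------------------------------------
# random cohort generator (independent of mpnpanel.synthetic_data)


def random_cohort(rng: np.random.Generator, n_samples=None, n_variants=None):
    """A cohort of random calls + annotations exercising every triage lane."""
    n_samples = n_samples or int(rng.integers(2, 8))
    n_variants = n_variants if n_variants is not None else int(rng.integers(1, 101))
    samples = [f"P{i}" for i in range(n_samples)]
    keys = []
    annotations = {}
    for i in range(max(1, n_variants // 2)):
        pos = 1000 + 10 * i
        ref, alt = ("A", "T") if i % 2 else ("C", "G")
        key = VariantKey("chr1", pos, ref, alt)
        region = str(
            rng.choice(
                ["exonic"] * 6 + ["intronic", "UTR3", "UTR5", "splicing", "intergenic"]
            )
        )
        maf = None
        if rng.random() < 0.3:
            maf = float(rng.uniform(0, 0.05))
        clinvar = str(
            rng.choice(
                ["absent"] * 6
                + ["pathogenic", "likely_pathogenic", "benign", "VUS", "likely_benign"]
            )
        )
        has_cosmic = bool(rng.random() < 0.3)
        annotations[key] = AnnotationRecord(
            key=key,
            region_class=region,
            maf_gnomad=maf,
            maf_1000g=float(rng.uniform(0, 0.05)) if rng.random() < 0.2 else None,
            clinvar_assertion=clinvar,
            cosmic_ids=("COSM1",) if has_cosmic else (),
            cosmic_pathogenic=bool(has_cosmic and rng.random() < 0.5),
        )
        keys.append(key)
    calls = []
    seen = set()
    for _ in range(n_variants):
        sample = samples[int(rng.integers(n_samples))]
        key = keys[int(rng.integers(len(keys)))]
        if (sample, key) in seen:
            continue
        seen.add((sample, key))
        vaf = float(rng.uniform(0, 0.95))
        depth = 5000
        calls.append(
            VariantCall(
                sample_id=sample,
                key=key,
                vaf=vaf,
                depth=depth,
                alt_reads=int(round(vaf * depth)),
                caller=CALLER_SMALL,
                gene="JAK2",
            )
        )
    return calls, annotations, n_samples


def oracle_triage(calls, annotations, n_samples, cfg: PipelineConfig | None = None):
    """Single-predicate brute-force re-implementation of the whole cascade."""
    cfg = cfg or PipelineConfig()

    # recurrence over calls surviving region+population filters
    survivors = []
    for c in calls:
        a = annotations[c.key]
        if a.region_class != "exonic":
            continue
        if any(v is not None and v >= cfg.maf_cutoff for v in a.mafs.values()):
            continue
        survivors.append(c)
    carriers: dict[VariantKey, set[str]] = {}
    for c in survivors:
        carriers.setdefault(c.key, set()).add(c.sample_id)

    statuses = {}
    for c in calls:
        a = annotations[c.key]
        if a.region_class != "exonic":
            status = "excluded_region"
        elif any(v is not None and v >= cfg.maf_cutoff for v in a.mafs.values()):
            status = "excluded_common"
        else:
            evidence = (
                a.clinvar_assertion in ("pathogenic", "likely_pathogenic")
                or a.cosmic_pathogenic
                or bool(a.cosmic_ids)
            )
            recurrent = (
                len(carriers.get(c.key, ())) > cfg.recurrence_fraction * n_samples
            )
            if c.vaf < cfg.vaf_retain or (recurrent and not evidence):
                rescueable = (
                    cfg.rescue_vaf_floor <= c.vaf < cfg.vaf_retain
                    and (
                        a.clinvar_assertion in ("pathogenic", "likely_pathogenic")
                        or a.cosmic_pathogenic
                    )
                )
                status = "rescued_pathogenic" if rescueable else "excluded_artifact"
            else:
                status = "retained"
        statuses[(c.sample_id, c.key)] = status
    return statuses


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=20240901)


@pytest.fixture(scope="session")
def cohort_sim(sim_config):
    from mpnpanel.synthetic_data import generate_cohort

    return generate_cohort(sim_config)


@pytest.fixture(scope="session")
def panel(sim_config):
    from mpnpanel.synthetic_data import generate_panel

    return generate_panel(sim_config)


@pytest.fixture(scope="session")
def truth_sets(sim_config):
    from mpnpanel.synthetic_data import generate_reference_standards

    return generate_reference_standards(sim_config)


@pytest.fixture(scope="session")
def fixture_calls():
    from mpnpanel import fixtures

    return fixtures.load_cohort_calls()


@pytest.fixture(scope="session")
def fixture_annotations():
    from mpnpanel import fixtures

    return fixtures.load_cohort_annotations()
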