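from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pytest

from ovamir import annotate, preprocess, quantify
from ovamir.preprocess import FilterReport
from ovamir.synthetic_data import (
    SimulationConfig,
    StudyReferences,
    TruthRecord,
    build_reference_set,
    simulate_libraries,
)


@dataclass
class Study:
    config: SimulationConfig
    refs: StudyReferences
    truth: TruthRecord
    lib1: Path
    lib2: Path
    tags1: list[str]
    tags2: list[str]
    report1: FilterReport
    report2: FilterReport
    tag_table: pd.DataFrame
    annotated: pd.DataFrame


def make_study(config: SimulationConfig, outdir: Path) -> Study:
    refs = build_reference_set(config)
    lib1, lib2 = outdir / "lib1.fastq", outdir / "lib2.fastq"
    truth = simulate_libraries(config, refs, lib1, lib2)
    tags1, report1 = preprocess.clean_reads(lib1, config.adapter3, config.adapter5)
    tags2, report2 = preprocess.clean_reads(lib2, config.adapter3, config.adapter5)
    tag_table = preprocess.collapse_tags(tags1, tags2)
    annotated = annotate.annotate_table(tag_table, refs.bundle)
    return Study(config, refs, truth, lib1, lib2, tags1, tags2,
                 report1, report2, tag_table, annotated)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory) -> Study:
    """Default small two-library study shared across module tests."""
    cfg = SimulationConfig(seed=5, n_mirnas=25, library_depths=(8000, 8000))
    return make_study(cfg, tmp_path_factory.mktemp("small_study"))


@pytest.fixture(scope="session")
def noise_free_study(tmp_path_factory) -> Study:
    """Every read is a perfect adapter-ligated miRNA insert."""
    cfg = SimulationConfig(
        seed=9, n_mirnas=60, library_depths=(10_000, 10_000),
        contamination_fractions={}, n_novel_hairpins=0, de_fraction=0.0,
        abundance_sigma=0.4)
    return make_study(cfg, tmp_path_factory.mktemp("noise_free"))


@pytest.fixture(scope="session")
def expression_records(small_study) -> pd.DataFrame:
    records, _ = quantify.assign_tags_to_mirnas(
        small_study.annotated, small_study.refs.bundle.mature)
    return records
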