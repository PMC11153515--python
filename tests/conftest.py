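"""Shared fixtures: one full-scale synthetic study, computed once per session.

The default cohort mirrors the study design (24 discovery + 5 validation
cases, 200 controls, two other-disorder cohorts of 20, 10,000 probes with a
planted 296-probe mostly-hypomethylated signature) and feeds the
integration and acceptance tests; unit tests build their own tiny inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from episig import classifier, discovery, preprocess
from episig.preprocess import CellProportions
from episig.simulate import SimulationConfig, simulate_annotation, simulate_cohort

SEED = 7


@dataclass
class Study:
    config: SimulationConfig
    manifest: object
    cgis: object
    genes: object
    cohort: object
    filtered: object
    filter_report: object
    cell_props: object
    match: object
    model_sheet: object
    model_beta: object
    labels: np.ndarray
    dmp: object
    probe_set: object
    partition: object
    model: object


def _run_study(config: SimulationConfig) -> Study:
    manifest, cgis, genes = simulate_annotation(config)
    cohort = simulate_cohort(config, manifest, cgis, genes)
    filtered, report = preprocess.filter_probes(cohort.beta, manifest, cohort.detection_p)
    cell_props = preprocess.estimate_cell_proportions(filtered, cohort.cell_reference)
    sheet = cohort.sheet
    match = discovery.match_controls(
        sheet.where(group_label="case", cohort_role="discovery"),
        sheet.where(group_label="control"), ratio=4,
    )
    model_ids = match.case_ids + match.control_ids
    model_sheet = sheet.subset(model_ids)
    model_beta = filtered.select_samples(model_ids)
    dmp = discovery.differential_methylation(
        model_beta, model_sheet, CellProportions(cell_props.fractions.loc[model_ids])
    )
    labels = np.array([r.group_label for r in model_sheet.records])
    probe_set = discovery.select_episignature(dmp, model_beta, labels)
    partition = classifier.assemble_training_partition(sheet, match, seed=config.seed)
    model = classifier.train_mvp(filtered, partition, probe_set)
    return Study(
        config=config, manifest=manifest, cgis=cgis, genes=genes, cohort=cohort,
        filtered=filtered, filter_report=report, cell_props=cell_props, match=match,
        model_sheet=model_sheet, model_beta=model_beta, labels=labels, dmp=dmp,
        probe_set=probe_set, partition=partition, model=model,
    )


@pytest.fixture(scope="session")
def default_study() -> Study:
    """Full default-scale study: simulation through trained classifier."""
    return _run_study(SimulationConfig(seed=SEED))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced cohort for tests that re-run whole pipelines repeatedly."""
    return SimulationConfig(
        seed=SEED, n_probes=2_000, n_cases=10, n_validation_cases=3,
        n_controls=80, other_cohorts=(("dupA", 12, 120), ("dupB", 12, 150)),
        signature_size=150,
    )


@pytest.fixture(scope="session")
def small_study(small_config) -> Study:
    return _run_study(small_config)
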