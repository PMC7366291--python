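"""Shared fixtures: small synthetic screens and assembled result tables."""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nephroscreen import analysis, plate_io, scoring
from nephroscreen.morphometry import PARAM_NAMES
from nephroscreen.scoring import fc_col, gross_col, ratio_col, z_col
from nephroscreen import synthetic_data as synth

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@dataclass
class Screen:
    """A simulated screen plus everything scored from it."""

    design: synth.ScreenDesign
    config: synth.ScreenSimConfig
    tables: synth.ScreenTables
    per_embryo: pd.DataFrame
    per_treatment: pd.DataFrame
    table: scoring.ScreenResultTable
    flags: pd.DataFrame


def build_screen(
    n_compounds: int = 60,
    seed: int = 11,
    embryos_per_treatment: int = 8,
    biological_cv: float = 0.1,
    lethality_prob: float = 0.1,
    **config_kwargs,
) -> Screen:
    """Simulate (image-free) and score a screen end to end."""
    design = synth.design_screen(n_compounds=n_compounds, seed=seed)
    config = synth.ScreenSimConfig(
        n_compounds=n_compounds,
        effect_vectors=design.effect_vectors,
        embryos_per_treatment=embryos_per_treatment,
        biological_cv=biological_cv,
        lethality_prob=lethality_prob,
        seed=seed,
        **config_kwargs,
    )
    tables = synth.simulate_screen_tables(config)
    per_embryo, per_treatment, _ = scoring.control_fold_change(tables.features)
    comp_buf = io.StringIO()
    design.compounds.to_csv(comp_buf, index=False)
    comp_buf.seek(0)
    atc_buf = io.StringIO()
    design.atc.to_csv(atc_buf, index=False)
    atc_buf.seek(0)
    library = plate_io.load_library(comp_buf, atc_buf)
    table = scoring.assemble_results(
        per_treatment,
        tables.annotations,
        tables.gross,
        library,
        synth.treatment_map(config),
    )
    flags = scoring.flag_abnormal(table)
    return Screen(
        design=design,
        config=config,
        tables=tables,
        per_embryo=per_embryo,
        per_treatment=per_treatment,
        table=table,
        flags=flags,
    )


@pytest.fixture(scope="session")
def small_screen() -> Screen:
    """A 60-compound screen used across the unit tests."""
    return build_screen(n_compounds=60, seed=11)


@pytest.fixture(scope="session")
def reference_screen() -> Screen:
    """The reference recovery conditions: 200 compounds × 8 embryos, CV 0.1."""
    return build_screen(n_compounds=200, seed=20)


def make_result_frame(rows: list[dict]) -> scoring.ScreenResultTable:
    """Build a valid result table from sparse row dicts (defaults filled in)."""
    records = []
    for i, spec in enumerate(rows):
        row: Dict[str, object] = {
            "treatment": f"T{i:03d}",
            "compound_id": f"T{i:03d}",
            "compound_name": f"compound {i}",
            "atc_d_level": "N/A",
            "day": "day01",
            "is_control": False,
            "n_embryos": 8,
            "n_annotated": 8,
            "quantitative_missing": False,
            "mortality": 0.0,
        }
        for p in PARAM_NAMES:
            row[fc_col(p)] = 1.0
            row[z_col(p)] = 0.0
        for c in plate_io.CATEGORIES:
            row[ratio_col(c)] = 0.0
        row[ratio_col("normal_kidney")] = 1.0
        for g in plate_io.GROSS_RATIO_FIELDS:
            row[gross_col(g)] = 0.0
        row.update(spec)
        records.append(row)
    return scoring.ScreenResultTable(frame=pd.DataFrame(records))
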