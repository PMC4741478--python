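"""Shared fixtures: tiny plate maps, measurement tables and a small
synthetic run reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sirnascreen as ss

settings.register_profile("default", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("default")

ROWS = "ABCDEFGH"


def plate_map_frame(n_lib: int = 80, plate_id: str = "P001") -> pd.DataFrame:
    """One 96-well plate: n_lib library wells (cols 1-11, row-major),
    column 12 alternating NT/positive controls, remainder empty.
    Three oligos per gene."""
    rows = []
    lib_positions = [(r, c) for r in ROWS for c in range(1, 12)]
    for i, (r, c) in enumerate(lib_positions):
        if i < n_lib:
            oligo = f"oligo_{i + 1:06d}"
            gene = f"GENE{i // 3 + 1:05d}"
            rows.append((plate_id, r, c, "library", oligo, gene, f"NM_{i // 3 + 1:06d}"))
        else:
            rows.append((plate_id, r, c, "empty", "", "", ""))
    for j, r in enumerate(ROWS):
        role = "control_nt" if j % 2 == 0 else "control_pos"
        rows.append((plate_id, r, 12, role, "", "", ""))
    return pd.DataFrame(
        rows,
        columns=["plate_id", "row", "column", "role", "oligo_id",
                 "gene_symbol", "accession"],
    )


def measurement_frame(
    plate_map: pd.DataFrame,
    cell_lines=("normal", "tumor"),
    n_replicates: int = 2,
    fi_fn=None,
) -> pd.DataFrame:
    """Measurements for every well of a plate map.

    ``fi_fn(row, column, role, cell_line, replicate) -> FI`` defaults to
    a deterministic positive value.
    """
    if fi_fn is None:
        fi_fn = lambda r, c, role, line, rep: 1000.0 + 7.0 * c + 3.0 * ROWS.index(r)
    rows = []
    for rec in plate_map.itertuples():
        for line in cell_lines:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (rec.plate_id, rec.row, rec.column, line, rep,
                     fi_fn(rec.row, rec.column, rec.role, line, rep))
                )
    return pd.DataFrame(
        rows, columns=["plate_id", "row", "column", "cell_line", "replicate", "FI"]
    )


@pytest.fixture(scope="session")
def one_plate_map() -> pd.DataFrame:
    return plate_map_frame()


@pytest.fixture
def plate_map_file(tmp_path, one_plate_map):
    path = tmp_path / "plate_map.csv"
    one_plate_map.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def small_sim():
    """A small default-noise screen run through the full pipeline."""
    sim_cfg = ss.SimConfig(n_plates=6, n_oligos=480, n_genes=170, seed=7)
    cfg = ss.ScreenConfig()
    run = ss.simulate_screen(sim_cfg)
    norm = ss.normalize_run(run.measurements, run.layouts, run.annotation, cfg)
    scores = ss.build_oligo_scores(norm, sim_cfg.normal_line, sim_cfg.tumor_line)
    stats = ss.fit_d_distribution(scores["d"])
    calls = ss.call_phenotypes(scores, stats, config=cfg)
    return {
        "sim_cfg": sim_cfg,
        "cfg": cfg,
        "run": run,
        "norm": norm,
        "scores": scores,
        "stats": stats,
        "calls": calls,
    }


@pytest.fixture(scope="session")
def zero_noise_sim():
    """Same small screen with the noise switched off."""
    sim_cfg = ss.SimConfig(n_plates=6, n_oligos=480, n_genes=170,
                           noise_cv=0.0, seed=7)
    cfg = ss.ScreenConfig()
    run = ss.simulate_screen(sim_cfg)
    norm = ss.normalize_run(run.measurements, run.layouts, run.annotation, cfg)
    scores = ss.build_oligo_scores(norm, sim_cfg.normal_line, sim_cfg.tumor_line)
    stats = ss.fit_d_distribution(scores["d"])
    calls = ss.call_phenotypes(scores, stats, config=cfg)
    return {
        "sim_cfg": sim_cfg,
        "cfg": cfg,
        "run": run,
        "norm": norm,
        "scores": scores,
        "stats": stats,
        "calls": calls,
    }
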