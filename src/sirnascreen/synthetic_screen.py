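"""Synthetic arrayed-screen generator with planted ground truth.

Emulates a two-cell-line colony-formation screen: a druggable-genome
scale library (25139 oligos, 9031 genes, ~3 oligos/gene by default)
arrayed over 309 96-well plates with column 12 carrying alternating
non-targeting (NT) and lethal positive controls, read out as whole-well
fluorescence intensity (FI) with multiplicative log-normal noise and two
technical replicates per cell line.

Effect model.  Each gene belongs to one of four classes — inactive,
tumor_selective, lethal, normal_selective — and each oligo of a non-
inactive gene is independently *effective* with probability
``p_effective`` (real libraries rarely have all three oligos of a gene
work, which is why screens score genes by "n of 3" oligo support).
Every oligo additionally carries a small generic (off-target) growth
inhibition.  Silencing depth scales with the cell line's transfection
efficiency, so a line transfected less efficiently (the tumor line by
default) shows systematically weaker knockdown phenotypes — this is what
puts the bulk cloud of (%NT_normal, %NT_tumor) points off the diagonal,
as observed when the two lines transfect unequally.  The per-oligo truth
table stores the post-efficiency expected %NT per line; with zero noise
the normalized pipeline reproduces those values exactly.

FI(well) = baseline * line_efficiency * (expected %NT / 100) * lognormal(1, CV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScreenConfig
from .errors import SimulationError
from .hit_calling import PhenotypeCall
from .screen_model import ROWS, PlateLayout, WellRole

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedScreen",
    "simulate_screen",
    "simulate_confirmation",
    "evaluate_recovery",
    "CLASS_TO_CALL",
]

#: phenotype call expected for an *effective* oligo of each gene class
CLASS_TO_CALL = {
    "tumor_selective": PhenotypeCall.DIFFERENTIAL.value,
    "lethal": PhenotypeCall.LETHAL_BOTH.value,
    "normal_selective": PhenotypeCall.NORMAL_SELECTIVE.value,
    "inactive": PhenotypeCall.INACTIVE.value,
}

GENE_CLASSES = ("inactive", "tumor_selective", "lethal", "normal_selective")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the full druggable-genome scale.

    ``efficiency_*`` are transfection-efficiency factors scaling both raw
    FI and knockdown depth; the normal line transfects slightly better
    than the tumor line by default.  ``noise_cv`` is the coefficient of
    variation of the multiplicative log-normal FI noise.  Kill-depth
    ranges (in %NT points, pre-efficiency) govern how strong effective
    oligos are: tumor-selective and normal-selective effects are deep
    enough to fall far below any plausible sigma threshold, lethal
    effects push both lines to or below the 20 %NT cutoff, and the
    generic off-target inhibition (``generic_toxicity_max``) gives every
    oligo a mild, line-shared growth cost that widens the bulk d
    distribution the way real library noise does.
    """

    n_plates: int = 309
    n_rows: int = 8
    n_columns: int = 12
    n_oligos: int = 25139
    n_genes: int = 9031
    frac_tumor_selective: float = 0.02
    frac_lethal: float = 0.01
    frac_normal_selective: float = 0.005
    p_effective: float = 0.5
    normal_line: str = "normal"
    tumor_line: str = "tumor"
    efficiency_normal: float = 1.0
    efficiency_tumor: float = 0.9
    noise_cv: float = 0.15
    baseline_fi: float = 10_000.0
    pos_control_pct: float = 5.0
    n_replicates: int = 2
    generic_toxicity_max: float = 25.0
    kill_tumor_selective: tuple[float, float] = (65.0, 95.0)
    kill_lethal: tuple[float, float] = (92.0, 100.0)
    kill_normal_selective: tuple[float, float] = (85.0, 100.0)
    max_effect_pct: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.frac_tumor_selective, self.frac_lethal, self.frac_normal_selective)
        if any(f < 0 or f > 1 for f in fr) or sum(fr) > 1:
            raise SimulationError("class fractions must lie in [0,1] and sum <= 1")
        if self.noise_cv < 0:
            raise SimulationError("noise_cv must be >= 0")
        if not 0 <= self.p_effective <= 1:
            raise SimulationError("p_effective must lie in [0,1]")
        if self.n_oligos < self.n_genes:
            raise SimulationError("need at least one oligo per gene")
        if self.n_oligos > 4 * self.n_genes:
            raise SimulationError("more than 4 oligos/gene not modeled")

    @property
    def wells_per_plate(self) -> int:
        return self.n_rows * self.n_columns

    def library_capacity(self, screen: ScreenConfig) -> int:
        """Library wells per plate: everything outside the control column."""
        return self.n_rows * (self.n_columns - 1)


@dataclass
class SimTruth:
    """Planted gene classes and per-oligo effects."""

    genes: pd.DataFrame  # gene_symbol, gene_class
    oligos: pd.DataFrame  # oligo_id, gene_symbol, gene_class, effective,
    #                       effect_normal, effect_tumor

    def expected_calls(self) -> pd.DataFrame:
        """Phenotype each oligo should receive from a perfect caller."""
        call = np.where(
            self.oligos["effective"],
            self.oligos["gene_class"].map(CLASS_TO_CALL),
            PhenotypeCall.INACTIVE.value,
        )
        return pd.DataFrame({"oligo_id": self.oligos["oligo_id"], "call": call})


@dataclass
class SimulatedScreen:
    """One synthetic run: layouts, annotation, measurements and truth."""

    layouts: dict[str, PlateLayout]
    annotation: pd.DataFrame
    measurements: pd.DataFrame
    truth: SimTruth

    def plate_map_frame(self) -> pd.DataFrame:
        """Plate map in the on-disk format (with gene annotation)."""
        from .screen_model import layouts_to_frame

        df = layouts_to_frame(self.layouts)
        df = df.merge(self.annotation, on="oligo_id", how="left")
        for col in ("oligo_id", "gene_symbol", "accession"):
            df[col] = df[col].fillna("")
        return df


# ---------------------------------------------------------------------------
# generation internals


def _allocate_oligos(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Oligos per gene (1-4 each), totaling exactly n_oligos."""
    base = config.n_oligos // config.n_genes
    counts = np.full(config.n_genes, base, dtype=int)
    remainder = config.n_oligos - counts.sum()
    if remainder > 0:
        extra = rng.choice(config.n_genes, size=remainder, replace=False)
        counts[extra] += 1
    return counts


def _assign_classes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_genes
    n_ts = int(round(config.frac_tumor_selective * n))
    n_le = int(round(config.frac_lethal * n))
    n_ns = int(round(config.frac_normal_selective * n))
    order = rng.permutation(n)
    classes = np.full(n, "inactive", dtype=object)
    classes[order[:n_ts]] = "tumor_selective"
    classes[order[n_ts : n_ts + n_le]] = "lethal"
    classes[order[n_ts + n_le : n_ts + n_le + n_ns]] = "normal_selective"
    return classes


def _build_truth(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    counts = _allocate_oligos(config, rng)
    classes = _assign_classes(config, rng)
    gene_symbols = np.array(
        [f"GENE{i + 1:05d}" for i in range(config.n_genes)], dtype=object
    )
    genes = pd.DataFrame({"gene_symbol": gene_symbols, "gene_class": classes})

    n = config.n_oligos
    gene_idx = np.repeat(np.arange(config.n_genes), counts)
    oligo_ids = np.array([f"oligo_{i + 1:06d}" for i in range(n)], dtype=object)
    oligo_class = classes[gene_idx]

    g_tox = rng.uniform(0.0, config.generic_toxicity_max, size=n)
    eff_draw = rng.random(n)
    effective = (oligo_class != "inactive") & (eff_draw < config.p_effective)
    kill_ts = rng.uniform(*config.kill_tumor_selective, size=n)
    kill_le = rng.uniform(*config.kill_lethal, size=n)
    kill_ns = rng.uniform(*config.kill_normal_selective, size=n)

    kill_normal = np.zeros(n)
    kill_tumor = np.zeros(n)
    ts = effective & (oligo_class == "tumor_selective")
    le = effective & (oligo_class == "lethal")
    ns = effective & (oligo_class == "normal_selective")
    kill_tumor[ts] = kill_ts[ts]
    kill_normal[le] = kill_le[le]
    kill_tumor[le] = kill_le[le]
    kill_normal[ns] = kill_ns[ns]

    hi = config.max_effect_pct
    effect_normal = np.clip(
        100.0 - config.efficiency_normal * (g_tox + kill_normal), 0.0, hi
    )
    effect_tumor = np.clip(
        100.0 - config.efficiency_tumor * (g_tox + kill_tumor), 0.0, hi
    )

    oligos = pd.DataFrame(
        {
            "oligo_id": oligo_ids,
            "gene_symbol": gene_symbols[gene_idx],
            "gene_class": oligo_class,
            "effective": effective,
            "effect_normal": effect_normal,
            "effect_tumor": effect_tumor,
        }
    )
    return SimTruth(genes=genes, oligos=oligos)


def _library_positions(config: SimConfig, screen: ScreenConfig):
    rows = ROWS[: config.n_rows]
    return [
        (r, c)
        for r in rows
        for c in range(1, config.n_columns + 1)
        if c != screen.control_column
    ]


def _build_plates(
    oligo_ids: np.ndarray,
    config: SimConfig,
    screen: ScreenConfig,
    plate_prefix: str,
    n_plates: int | None = None,
) -> tuple[dict[str, PlateLayout], pd.DataFrame]:
    """Sequentially array oligos over plates; returns layouts + well table.

    ``n_plates=None`` uses as few plates as the oligos need.
    """
    n = len(oligo_ids)
    capacity = config.library_capacity(screen)
    if n_plates is None:
        n_plates = -(-n // capacity)
    base = n // n_plates
    rem = n % n_plates
    if base + (1 if rem else 0) > capacity:
        raise SimulationError(
            f"{n} oligos do not fit on {n_plates} plates with "
            f"{capacity} library wells each"
        )
    lib_pos = _library_positions(config, screen)
    ctrl_roles = screen.control_roles(config.n_rows)
    rows = ROWS[: config.n_rows]

    layouts: dict[str, PlateLayout] = {}
    records: list[tuple] = []
    cursor = 0
    for i in range(n_plates):
        plate_id = f"{plate_prefix}{i + 1:03d}"
        n_i = base + (1 if i < rem else 0)
        wells: dict[tuple[str, int], tuple[WellRole, str | None]] = {}
        for j, (r, c) in enumerate(lib_pos):
            if j < n_i:
                oligo = str(oligo_ids[cursor + j])
                wells[(r, c)] = (WellRole.LIBRARY, oligo)
                records.append((plate_id, r, c, WellRole.LIBRARY.value, oligo))
            else:
                wells[(r, c)] = (WellRole.EMPTY, None)
                records.append((plate_id, r, c, WellRole.EMPTY.value, None))
        for r, role in zip(rows, ctrl_roles):
            wells[(r, screen.control_column)] = (WellRole(role), None)
            records.append((plate_id, r, screen.control_column, role, None))
        layouts[plate_id] = PlateLayout(plate_id, wells)
        cursor += n_i

    well_df = pd.DataFrame(
        records, columns=["plate_id", "row", "column", "role", "oligo_id"]
    )
    return layouts, well_df


def _measure(
    well_df: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
    n_replicates: int,
) -> pd.DataFrame:
    """Draw FI for every well x cell line x replicate."""
    eff = well_df.merge(
        truth.oligos[["oligo_id", "effect_normal", "effect_tumor"]],
        on="oligo_id",
        how="left",
    )
    role = eff["role"].to_numpy()
    for col in ("effect_normal", "effect_tumor"):
        vals = eff[col].to_numpy(dtype=float)
        vals[role == WellRole.CONTROL_NT.value] = 100.0
        vals[role == WellRole.CONTROL_POS.value] = config.pos_control_pct
        vals[role == WellRole.EMPTY.value] = 0.0
        eff[col] = vals

    n_wells = len(eff)
    lines = [
        (config.normal_line, config.efficiency_normal, "effect_normal"),
        (config.tumor_line, config.efficiency_tumor, "effect_tumor"),
    ]
    if config.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
        mu = -0.5 * sigma**2  # unit-mean log-normal
        noise = rng.lognormal(mu, sigma, size=(len(lines) * n_replicates, n_wells))
    else:
        noise = np.ones((len(lines) * n_replicates, n_wells))

    chunks = []
    k = 0
    for line, line_eff, effect_col in lines:
        effect = eff[effect_col].to_numpy(dtype=float)
        for rep in range(1, n_replicates + 1):
            fi = config.baseline_fi * line_eff * (effect / 100.0) * noise[k]
            k += 1
            chunk = eff[["plate_id", "row", "column"]].copy()
            chunk["cell_line"] = line
            chunk["replicate"] = rep
            chunk["FI"] = fi
            chunks.append(chunk)
    return pd.concat(chunks, ignore_index=True)


# ---------------------------------------------------------------------------
# public operations


def simulate_screen(
    config: SimConfig | None = None,
    screen_config: ScreenConfig | None = None,
    seed: int | None = None,
) -> SimulatedScreen:
    """Generate a full synthetic screen with known truth.

    Deterministic under a fixed seed (``seed`` overrides
    ``config.seed``).  Returns layouts, library annotation, a raw
    measurement table (every well of every plate, per cell line and
    replicate) and the planted truth.
    """
    config = config or SimConfig()
    screen = screen_config or ScreenConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    truth = _build_truth(config, rng)
    layouts, well_df = _build_plates(
        truth.oligos["oligo_id"].to_numpy(),
        config,
        screen,
        plate_prefix="P",
        n_plates=config.n_plates,
    )
    measurements = _measure(well_df, truth, config, rng, config.n_replicates)

    accession = truth.oligos["gene_symbol"].str.replace(
        "GENE", "NM_9", regex=False
    )
    annotation = pd.DataFrame(
        {
            "oligo_id": truth.oligos["oligo_id"],
            "gene_symbol": truth.oligos["gene_symbol"],
            "accession": accession,
        }
    )
    return SimulatedScreen(layouts, annotation, measurements, truth)


def simulate_confirmation(
    truth: SimTruth,
    oligo_ids,
    config: SimConfig | None = None,
    screen_config: ScreenConfig | None = None,
    seed: int | None = None,
    n_replicates: int = 3,
) -> SimulatedScreen:
    """Re-array a subset of oligos and measure them with fresh noise.

    The effect structure comes from ``truth`` (same oligos, same expected
    %NT); only the noise draws are new.  The subset is arrayed on as few
    plates as it needs (plate ids ``C001``, ...), with the usual control
    column.  Default 3 replicates per line, as manual confirmation runs
    typically use.
    """
    config = config or SimConfig()
    screen = screen_config or ScreenConfig()
    ids = list(dict.fromkeys(oligo_ids))
    if not ids:
        raise SimulationError("confirmation subset is empty")
    known = set(truth.oligos["oligo_id"])
    missing = [o for o in ids if o not in known]
    if missing:
        raise SimulationError(f"oligo(s) not in the library: {missing[:5]}")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    layouts, well_df = _build_plates(
        np.asarray(ids, dtype=object), config, screen, plate_prefix="C"
    )
    measurements = _measure(well_df, truth, config, rng, n_replicates)
    sub = truth.oligos[truth.oligos["oligo_id"].isin(ids)].reset_index(drop=True)
    annotation = pd.DataFrame(
        {
            "oligo_id": sub["oligo_id"],
            "gene_symbol": sub["gene_symbol"],
            "accession": sub["gene_symbol"].str.replace("GENE", "NM_9", regex=False),
        }
    )
    return SimulatedScreen(
        layouts, annotation, measurements, SimTruth(truth.genes, sub)
    )


def evaluate_recovery(calls: pd.DataFrame, truth: SimTruth) -> pd.DataFrame:
    """Sensitivity/specificity/precision of calls against planted truth.

    ``calls`` needs ``oligo_id`` and ``call`` and must cover exactly the
    truth oligo set.  For each non-inactive class, oligo-level truth
    positives are the *effective* oligos of that class; gene-level truth
    positives are genes with >= 1 effective oligo, and a gene counts as
    detected when >= 1 of its oligos received the class's phenotype call.
    """
    t = truth.oligos
    if set(calls["oligo_id"]) != set(t["oligo_id"]):
        raise SimulationError("calls and truth cover different oligo sets")
    merged = t.merge(calls[["oligo_id", "call"]], on="oligo_id", validate="1:1")

    rows = []
    for cls in ("tumor_selective", "lethal", "normal_selective"):
        pheno = CLASS_TO_CALL[cls]
        truth_pos = (merged["gene_class"] == cls) & merged["effective"]
        pred_pos = merged["call"] == pheno
        rows.append(("oligo", cls, *_metrics(truth_pos, pred_pos)))

        gene_truth = (
            merged.assign(tp=truth_pos, pp=pred_pos)
            .groupby("gene_symbol", sort=False)[["tp", "pp"]]
            .any()
        )
        rows.append(
            ("gene", cls, *_metrics(gene_truth["tp"], gene_truth["pp"]))
        )
    return pd.DataFrame(
        rows,
        columns=["level", "gene_class", "n_positive", "sensitivity",
                 "specificity", "precision"],
    )


def _metrics(truth_pos, pred_pos) -> tuple[int, float, float, float]:
    truth_pos = np.asarray(truth_pos, dtype=bool)
    pred_pos = np.asarray(pred_pos, dtype=bool)
    tp = int((truth_pos & pred_pos).sum())
    fn = int((truth_pos & ~pred_pos).sum())
    fp = int((~truth_pos & pred_pos).sum())
    tn = int((~truth_pos & ~pred_pos).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    return tp + fn, sens, spec, prec
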