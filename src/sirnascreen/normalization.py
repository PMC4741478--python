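"""Per-plate percent-of-NT normalization and robust z*-scores.

Every raw FI value is divided by the mean FI of the non-targeting (NT)
control wells of the *same plate, cell line and replicate* and scaled to
percent, so the NT controls of every plate average to 100 %NT by
construction and plate-to-plate intensity differences cancel.  Replicate
%NT values are then averaged per oligo and cell line, and a robust
z*-score (median/MAD with the 1.4826 consistency factor) is attached per
cell line over all unflagged library oligos of the run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ScreenConfig
from .errors import NormalizationError
from .screen_model import WellRole, layouts_to_frame, match_layout

__all__ = [
    "percent_of_nt",
    "robust_z",
    "normalize_measurements",
    "normalize_run",
]

#: MAD -> SD consistency factor for a normal distribution
MAD_SCALE = 1.4826

FLAG_MISSING_REPLICATE = "missing_replicate"
FLAG_NT_FAILED = "nt_failed"


def percent_of_nt(fi: float, nt_fis) -> float:
    """FI as a percentage of the mean NT-control FI (no clipping).

    Raises :class:`NormalizationError` when no NT values are supplied or
    their mean is not positive — a plate-level normalization failure.
    """
    nt = np.asarray(nt_fis, dtype=float)
    if nt.size == 0:
        raise NormalizationError("no NT control values supplied")
    mean = nt.mean()
    if not mean > 0:
        raise NormalizationError(f"NT control mean must be > 0, got {mean}")
    return 100.0 * float(fi) / mean


def robust_z(values, x: float) -> float:
    """Robust z-score of ``x`` against ``values``: (x - med) / (1.4826 MAD).

    MAD is the median of absolute deviations from the median.  Requires
    at least 3 values and a strictly positive MAD.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise NormalizationError("robust z needs at least 3 reference values")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        raise NormalizationError("MAD is zero; robust z undefined")
    return (float(x) - med) / (MAD_SCALE * mad)


def _nt_means(matched: pd.DataFrame, layouts, config: ScreenConfig) -> pd.DataFrame:
    """Mean NT FI per (plate, cell line, replicate).

    Honors ``config.nt_wells_used`` by restricting to the first k NT
    wells of each plate in row order.
    """
    nt = matched[matched["role"] == WellRole.CONTROL_NT.value]
    if config.nt_wells_used is not None:
        layout_df = layouts_to_frame(layouts)
        keep_wells = (
            layout_df[layout_df["role"] == WellRole.CONTROL_NT.value]
            .sort_values(["plate_id", "row", "column"])
            .groupby("plate_id", sort=False)
            .head(config.nt_wells_used)[["plate_id", "row", "column"]]
        )
        nt = nt.merge(keep_wells, on=["plate_id", "row", "column"])
    means = (
        nt.groupby(["plate_id", "cell_line", "replicate"], sort=False)["FI"]
        .mean()
        .rename("nt_mean")
        .reset_index()
    )
    return means


def normalize_measurements(
    measurements: pd.DataFrame, layouts, config: ScreenConfig | None = None
) -> pd.DataFrame:
    """Attach per-well %NT to every non-empty well measurement.

    Returns the matched measurement table with ``role``, ``oligo_id``,
    ``pct_nt`` and a boolean ``nt_failed`` column.  Wells on plates whose
    NT controls are missing or average to a non-positive FI (for a given
    cell line and replicate) get ``pct_nt = NaN`` and ``nt_failed = True``
    instead of a hard failure, so one bad plate cannot sink a run.

    Raises
    ------
    NormalizationError
        If any measurement does not join to a layout well.
    """
    config = config or ScreenConfig()
    matched, orphans = match_layout(measurements, layouts)
    if len(orphans):
        wells = [
            f"{r.plate_id} {r.row}{int(r.column):02d}"
            for r in orphans.head(5).itertuples()
        ]
        raise NormalizationError(
            f"{len(orphans)} measurement(s) on wells absent from the plate "
            f"map, e.g. {wells}"
        )
    matched = matched[matched["role"] != WellRole.EMPTY.value].copy()
    means = _nt_means(matched, layouts, config)
    out = matched.merge(means, on=["plate_id", "cell_line", "replicate"], how="left")
    usable = out["nt_mean"].notna() & (out["nt_mean"] > 0)
    out["pct_nt"] = np.where(usable, 100.0 * out["FI"] / out["nt_mean"], np.nan)
    out["nt_failed"] = ~usable
    return out.drop(columns=["nt_mean"])


def normalize_run(
    measurements: pd.DataFrame,
    layouts,
    annotation: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Produce one normalized record per (library oligo, cell line).

    Output columns: ``oligo_id, cell_line, pct_nt_rep1..repK, pct_nt_mean,
    pct_nt_sd, z_star, flags``.  ``pct_nt_mean`` is the arithmetic mean of
    the per-replicate %NT values; ``pct_nt_sd`` uses the n-1 denominator
    and is NaN for a single replicate.  ``flags`` is a ``;``-joined set of
    {missing_replicate, nt_failed}; flagged records carry ``z_star = NaN``
    and are excluded from the z* reference distribution.
    """
    config = config or ScreenConfig()
    per_well = normalize_measurements(measurements, layouts, config)
    lib = per_well[per_well["role"] == WellRole.LIBRARY.value].copy()
    if lib.empty:
        raise NormalizationError("no library wells in the measurement set")

    known = set(annotation["oligo_id"])
    unknown = set(lib["oligo_id"]) - known
    if unknown:
        raise NormalizationError(
            f"{len(unknown)} measured oligo(s) missing from the annotation, "
            f"e.g. {sorted(unknown)[:5]}"
        )

    n_reps = int(lib["replicate"].max())
    # pivot (not pivot_table): NaN %NT from failed-NT plates must survive
    wide = lib.pivot(
        index=["oligo_id", "cell_line"], columns="replicate", values="pct_nt"
    )
    wide = wide.reindex(columns=range(1, n_reps + 1))
    rep_cols = [f"pct_nt_rep{r}" for r in range(1, n_reps + 1)]
    wide.columns = rep_cols
    vals = wide[rep_cols].to_numpy(dtype=float)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        wide["pct_nt_mean"] = np.nanmean(vals, axis=1)
        sd = np.nanstd(vals, axis=1, ddof=1)
    wide["pct_nt_sd"] = sd

    n_present = np.isfinite(vals).sum(axis=1)
    failed = (
        lib.groupby(["oligo_id", "cell_line"], sort=False)["nt_failed"]
        .any()
        .reindex(wide.index)
        .fillna(False)
    )
    flags = []
    for miss, fail in zip(n_present < n_reps, failed.to_numpy()):
        f = []
        if fail:
            f.append(FLAG_NT_FAILED)
        if miss:
            f.append(FLAG_MISSING_REPLICATE)
        flags.append(";".join(f))
    wide["flags"] = flags
    out = wide.reset_index()

    # robust z* per cell line over clean records
    out["z_star"] = np.nan
    for line, grp in out.groupby("cell_line", sort=False):
        clean = grp[grp["flags"] == ""]
        if len(clean) < 3:
            continue
        ref = clean["pct_nt_mean"].to_numpy()
        med = np.median(ref)
        mad = np.median(np.abs(ref - med))
        if mad == 0:
            continue
        out.loc[clean.index, "z_star"] = (
            clean["pct_nt_mean"] - med
        ) / (MAD_SCALE * mad)

    cols = ["oligo_id", "cell_line", *rep_cols, "pct_nt_mean", "pct_nt_sd",
            "z_star", "flags"]
    return out[cols].sort_values(["oligo_id", "cell_line"]).reset_index(drop=True)
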