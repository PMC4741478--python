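"""Differential-lethality scoring: the d statistic, sigma thresholds,
phenotype calls and gene-level aggregation.

Each library oligo is summarized by its replicate-mean %NT in the normal
and the tumor cell line.  The d statistic is the Euclidean distance of
the point (%NT_normal, %NT_tumor) from (100, 0) — the point of maximal
tumor-selective lethality (tumor growth abolished, normal growth
untouched).  Small d therefore means strong, selective impairment of the
tumor line.  Hits are thresholded at mu - k*sigma of the library-wide d
distribution (k = 3 in the primary screen by convention); oligos at or
below a %NT cutoff (default 20) in *both* lines are indiscriminately
lethal and take precedence over the differential call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .config import ScreenConfig
from .errors import DegenerateDistributionError, ScreenError

__all__ = [
    "PhenotypeCall",
    "ScreenStats",
    "compute_d",
    "build_oligo_scores",
    "fit_d_distribution",
    "sigma_bin",
    "call_phenotype",
    "call_phenotypes",
    "aggregate_by_gene",
    "summarize_hits",
]


class PhenotypeCall(str, Enum):
    """Per-oligo growth phenotype relative to the two cell lines."""

    DIFFERENTIAL = "differential"        # selectively lethal to the tumor line
    LETHAL_BOTH = "lethal_both"          # <= cutoff %NT in both lines
    NORMAL_SELECTIVE = "normal_selective"  # lethal to the normal line only
    INACTIVE = "inactive"


def compute_d(pct_nt_normal, pct_nt_tumor):
    """Distance of (%NT_normal, %NT_tumor) from (100, 0).

    ``d = sqrt((100 - %NT_normal)^2 + %NT_tumor^2)``.  Accepts scalars or
    arrays; inputs must be nonnegative.  d = 0 exactly at (100, 0).
    """
    n = np.asarray(pct_nt_normal, dtype=float)
    t = np.asarray(pct_nt_tumor, dtype=float)
    if (n < 0).any() or (t < 0).any():
        raise ScreenError("%NT values must be nonnegative")
    d = np.hypot(100.0 - n, t)
    return float(d) if d.ndim == 0 else d


def build_oligo_scores(
    normalized: pd.DataFrame, normal_line: str, tumor_line: str
) -> pd.DataFrame:
    """Pair each oligo's replicate-mean %NT across the two lines.

    Takes the output of :func:`~sirnascreen.normalization.normalize_run`
    and returns one row per oligo with columns ``oligo_id,
    pct_nt_normal, pct_nt_tumor, d``.  Flagged records and oligos absent
    from either line are dropped.
    """
    clean = normalized[normalized["flags"] == ""]
    pivot = clean.pivot_table(
        index="oligo_id", columns="cell_line", values="pct_nt_mean",
        aggfunc="first",
    )
    for line in (normal_line, tumor_line):
        if line not in pivot.columns:
            raise ScreenError(f"cell line {line!r} not present in normalized data")
    pivot = pivot[[normal_line, tumor_line]].dropna()
    scores = pivot.rename(
        columns={normal_line: "pct_nt_normal", tumor_line: "pct_nt_tumor"}
    ).reset_index()
    scores["d"] = compute_d(scores["pct_nt_normal"], scores["pct_nt_tumor"])
    return scores


@dataclass(frozen=True)
class ScreenStats:
    """Mean/SD of the library d distribution and derived thresholds."""

    mu: float
    sigma: float
    n: int

    def threshold(self, k: float) -> float:
        """Hit threshold mu - k*sigma; undefined when sigma = 0."""
        if self.sigma <= 0:
            raise DegenerateDistributionError(
                "d distribution has zero spread; thresholds undefined"
            )
        return self.mu - k * self.sigma

    def thresholds(self, ks) -> dict[float, float]:
        return {float(k): self.threshold(k) for k in ks}


def fit_d_distribution(d_values, ks=(2.0, 3.0)) -> ScreenStats:
    """Plain mean/SD (n-1) of library d values.

    ``ks`` is accepted for interface symmetry — thresholds are available
    from the returned stats for any k.  Controls must be excluded by the
    caller; :func:`build_oligo_scores` only ever emits library oligos.
    """
    d = np.asarray(d_values, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < 2:
        raise ScreenError("need at least 2 d values to fit a distribution")
    stats = ScreenStats(mu=float(d.mean()), sigma=float(d.std(ddof=1)), n=int(d.size))
    for k in ks:
        if k <= 0:
            raise ScreenError(f"sigma multiple must be > 0, got {k}")
    return stats


def sigma_bin(d, stats: ScreenStats):
    """Integer sigma bin: floor((d - mu) / sigma)."""
    if stats.sigma <= 0:
        raise DegenerateDistributionError("sigma = 0; sigma binning undefined")
    b = np.floor((np.asarray(d, dtype=float) - stats.mu) / stats.sigma)
    return int(b) if b.ndim == 0 else b.astype(int)


def call_phenotype(
    pct_nt_normal: float,
    pct_nt_tumor: float,
    stats: ScreenStats,
    k: float | None = None,
    config: ScreenConfig | None = None,
) -> PhenotypeCall:
    """Classify one oligo.

    Precedence: lethal in both lines (<= cutoff, inclusive) beats
    differential (d strictly below mu - k*sigma) beats normal-selective
    (lethal in the normal line only) beats inactive.
    """
    config = config or ScreenConfig()
    k = config.k_screen if k is None else k
    cutoff = config.lethal_cutoff
    if pct_nt_normal <= cutoff and pct_nt_tumor <= cutoff:
        return PhenotypeCall.LETHAL_BOTH
    if compute_d(pct_nt_normal, pct_nt_tumor) < stats.threshold(k):
        return PhenotypeCall.DIFFERENTIAL
    if pct_nt_normal <= cutoff:
        return PhenotypeCall.NORMAL_SELECTIVE
    return PhenotypeCall.INACTIVE


def call_phenotypes(
    scores: pd.DataFrame,
    stats: ScreenStats,
    k: float | None = None,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Vectorized phenotype calls for an oligo-score table.

    Returns the scores with an added ``call`` column (one call per oligo;
    the four classes partition the set).
    """
    config = config or ScreenConfig()
    k = config.k_screen if k is None else k
    cutoff = config.lethal_cutoff
    n = scores["pct_nt_normal"].to_numpy(dtype=float)
    t = scores["pct_nt_tumor"].to_numpy(dtype=float)
    d = scores["d"].to_numpy(dtype=float) if "d" in scores else compute_d(n, t)
    thr = stats.threshold(k)

    lethal = (n <= cutoff) & (t <= cutoff)
    differential = ~lethal & (d < thr)
    normal_sel = ~lethal & ~differential & (n <= cutoff)
    call = np.full(len(scores), PhenotypeCall.INACTIVE.value, dtype=object)
    call[normal_sel] = PhenotypeCall.NORMAL_SELECTIVE.value
    call[differential] = PhenotypeCall.DIFFERENTIAL.value
    call[lethal] = PhenotypeCall.LETHAL_BOTH.value

    out = scores.copy()
    out["call"] = call
    return out


def aggregate_by_gene(
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    phenotype: PhenotypeCall,
) -> pd.DataFrame:
    """Per-gene tally of oligos showing the queried phenotype.

    ``calls`` needs columns ``oligo_id`` and ``call``; every oligo must
    appear in ``annotation`` (oligo_id -> gene_symbol).  Only genes with
    at least one active oligo are returned, with ``hit_class`` formatted
    "n_active/n_oligos_total" where the denominator counts the gene's
    oligos present in ``calls``.
    """
    ann = annotation[["oligo_id", "gene_symbol"]]
    merged = calls.merge(ann, on="oligo_id", how="left", validate="m:1")
    missing = merged["gene_symbol"].isna()
    if missing.any():
        raise ScreenError(
            f"unannotated oligo(s): "
            f"{sorted(merged.loc[missing, 'oligo_id'].unique())[:5]}"
        )
    target = phenotype.value if isinstance(phenotype, PhenotypeCall) else str(phenotype)
    grp = merged.groupby("gene_symbol", sort=True)
    summary = pd.DataFrame(
        {
            "n_oligos_total": grp.size(),
            "n_active": grp["call"].apply(lambda s: int((s == target).sum())),
        }
    ).reset_index()
    summary = summary[summary["n_active"] >= 1].reset_index(drop=True)
    summary["hit_class"] = (
        summary["n_active"].astype(str) + "/" + summary["n_oligos_total"].astype(str)
    )
    return summary


def summarize_hits(
    calls: pd.DataFrame, library_size: int, config: ScreenConfig | None = None
) -> pd.DataFrame:
    """Count and percentage of oligos per phenotype class.

    Percentages are 100 * count / library_size, rounded half-even to
    ``config.rounding_digits`` (default 2), matching how screen-level hit
    rates are conventionally reported.
    """
    config = config or ScreenConfig()
    if library_size <= 0:
        raise ScreenError("library_size must be positive")
    n_oligos = calls["oligo_id"].nunique() if "oligo_id" in calls else len(calls)
    if library_size < n_oligos:
        raise ScreenError(
            f"library_size {library_size} smaller than {n_oligos} scored oligos"
        )
    counts = calls["call"].value_counts()
    rows = []
    for pheno in PhenotypeCall:
        c = int(counts.get(pheno.value, 0))
        pct = np.round(100.0 * c / library_size, config.rounding_digits)
        rows.append((pheno.value, c, pct))
    return pd.DataFrame(rows, columns=["phenotype", "count", "pct_of_library"])
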