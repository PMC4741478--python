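"""Cross-run phenotype confirmation.

A confirmation experiment re-tests a subset of library oligos under the
same conditions as the primary screen (typically with more replicates).
Phenotypes are re-called on the confirmation data at a looser sigma
multiple (k = 2 by default, against k = 3 in the screen) and an oligo is
*confirmed* when the confirmation call equals the screening call — a
strict reading that also counts reproduced inactive or lethal-in-both
phenotypes as confirmed, and counts a screen-differential oligo that
comes back lethal-in-both as NOT confirmed.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import ScreenConfig
from .errors import ScreenError
from .hit_calling import (
    PhenotypeCall,
    ScreenStats,
    call_phenotypes,
    fit_d_distribution,
)

__all__ = ["confirm_run", "summarize_confirmation", "ConfirmationSummary"]


def confirm_run(
    screen_calls: pd.DataFrame,
    confirm_scores: pd.DataFrame,
    config: ScreenConfig | None = None,
    screen_stats: ScreenStats | None = None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Re-call phenotypes on a confirmation run and match them.

    Parameters
    ----------
    screen_calls:
        Primary-screen calls (``oligo_id``, ``call``).
    confirm_scores:
        Oligo scores from the confirmation run (``oligo_id``,
        ``pct_nt_normal``, ``pct_nt_tumor``, ``d``); must be a subset of
        the screened oligos.
    screen_stats:
        d-distribution statistics of the primary screen.  Used as the
        thresholding distribution when the confirmation run is smaller
        than ``config.min_confirm_stats_n`` oligos; larger runs anchor
        the mu - k_confirm*sigma threshold on their own d distribution.
    annotation:
        Optional oligo -> gene map; adds a ``gene_symbol`` column.

    Returns one row per confirmation oligo with columns ``oligo_id,
    [gene_symbol,] screen_call, confirm_call, confirmed``.
    """
    config = config or ScreenConfig()
    extra = set(confirm_scores["oligo_id"]) - set(screen_calls["oligo_id"])
    if extra:
        raise ScreenError(
            f"oligo(s) in confirmation but absent from screening: "
            f"{sorted(extra)[:5]}"
        )
    if confirm_scores.empty:
        raise ScreenError("confirmation run is empty")

    if len(confirm_scores) >= config.min_confirm_stats_n:
        stats = fit_d_distribution(confirm_scores["d"])
    elif screen_stats is not None:
        stats = screen_stats
    else:
        raise ScreenError(
            f"confirmation run has {len(confirm_scores)} oligos "
            f"(< {config.min_confirm_stats_n}); screen_stats required"
        )

    called = call_phenotypes(confirm_scores, stats, k=config.k_confirm, config=config)
    out = called[["oligo_id", "call"]].rename(columns={"call": "confirm_call"})
    out = out.merge(
        screen_calls[["oligo_id", "call"]].rename(columns={"call": "screen_call"}),
        on="oligo_id",
        validate="1:1",
    )
    out["confirmed"] = out["screen_call"] == out["confirm_call"]
    cols = ["oligo_id", "screen_call", "confirm_call", "confirmed"]
    if annotation is not None:
        out = out.merge(
            annotation[["oligo_id", "gene_symbol"]], on="oligo_id", how="left"
        )
        cols.insert(1, "gene_symbol")
    return out[cols]


@dataclass
class ConfirmationSummary:
    """Tallies of a confirmation run."""

    tested: int
    confirmed: int
    by_screen_call: pd.DataFrame  # screen_call, tested, confirmed
    confirmed_differential_oligos: int
    confirmed_differential_genes: int | None  # None without gene annotation
    gene_tally: pd.DataFrame | None  # gene_symbol, n_confirmed_oligos


def summarize_confirmation(records: pd.DataFrame) -> ConfirmationSummary:
    """Summarize confirmation records by screening phenotype.

    ``records`` is the output of :func:`confirm_run`.  Totals satisfy
    tested = confirmed + not-confirmed per class and overall.  The
    gene-level tally of confirmed differential oligos requires a
    ``gene_symbol`` column.
    """
    if records.empty:
        raise ScreenError("no confirmation records to summarize")
    grp = records.groupby("screen_call", sort=True)
    by_class = pd.DataFrame(
        {
            "tested": grp.size(),
            "confirmed": grp["confirmed"].sum().astype(int),
        }
    ).reset_index()

    diff = records[
        (records["screen_call"] == PhenotypeCall.DIFFERENTIAL.value)
        & records["confirmed"]
    ]
    gene_tally = None
    n_genes = None
    if "gene_symbol" in records.columns:
        gene_tally = (
            diff.groupby("gene_symbol", sort=True)
            .size()
            .rename("n_confirmed_oligos")
            .reset_index()
        )
        n_genes = int(len(gene_tally))
    return ConfirmationSummary(
        tested=int(len(records)),
        confirmed=int(records["confirmed"].sum()),
        by_screen_call=by_class,
        confirmed_differential_oligos=int(len(diff)),
        confirmed_differential_genes=n_genes,
        gene_tally=gene_tally,
    )
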