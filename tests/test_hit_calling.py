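"""The d statistic, sigma thresholds, phenotype calls and gene tallies."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sirnascreen as ss
from sirnascreen.hit_calling import PhenotypeCall, ScreenStats


def naive_call(n, t, mu, sigma, k=3.0, cutoff=20.0):
    """One-record-at-a-time reference: independent of the batch path."""
    d = math.sqrt((100.0 - n) ** 2 + t**2)
    if n <= cutoff and t <= cutoff:
        return "lethal_both"
    if d < mu - k * sigma:
        return "differential"
    if n <= cutoff:
        return "normal_selective"
    return "inactive"


class TestComputeD:
    @pytest.mark.parametrize(
        "n,t,expected",
        [
            (100.0, 0.0, 0.0),     # the point of maximal tumor-selective kill
            (100.0, 100.0, 100.0),
            (0.0, 0.0, 100.0),
            (70.0, 40.0, 50.0),    # sqrt(900 + 1600)
            (95.0, 90.0, math.sqrt(25 + 8100)),
        ],
    )
    def test_values(self, n, t, expected):
        assert ss.compute_d(n, t) == pytest.approx(expected, abs=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ss.ScreenError):
            ss.compute_d(-1.0, 50.0)

    @given(
        st.floats(min_value=0, max_value=99.9),
        st.floats(min_value=0, max_value=150),
        st.floats(min_value=0.01, max_value=10),
    )
    def test_monotone_in_each_argument(self, n, t, delta):
        d0 = ss.compute_d(n, t)
        assert ss.compute_d(n, t + delta) > d0          # worse tumor survival
        assert ss.compute_d(min(n + delta, 100.0), t) <= d0
        if n + delta <= 100.0:
            assert ss.compute_d(n + delta, t) < d0      # healthier normal line

    def test_lethal_in_normal_line_forces_large_d(self):
        """%NT_normal <= 20 puts d >= 80, so with cutoff 20 and any
        threshold below 80 the lethal and differential classes cannot
        overlap even without call precedence."""
        grid_n = np.linspace(0, 20, 21)
        grid_t = np.linspace(0, 150, 31)
        nn, tt = np.meshgrid(grid_n, grid_t)
        assert (ss.compute_d(nn.ravel(), tt.ravel()) >= 80.0).all()


class TestDistribution:
    def test_sampling_oracle(self):
        """mu-3sigma of a Normal(55, 2.6) d distribution sits at 47.2, the
        conventional screen threshold for this statistic."""
        rng = np.random.default_rng(42)
        d = rng.normal(55.0, 2.6, size=1_000_000)
        stats = ss.fit_d_distribution(d)
        assert stats.mu == pytest.approx(55.0, abs=0.02)
        assert stats.sigma == pytest.approx(2.6, abs=0.02)
        assert stats.threshold(3) == pytest.approx(47.2, abs=0.05)
        assert stats.threshold(2) == pytest.approx(49.8, abs=0.05)

    def test_thresholds_decrease_in_k(self):
        stats = ss.fit_d_distribution([50.0, 55.0, 60.0, 52.0])
        assert stats.threshold(2) > stats.threshold(3)

    def test_degenerate_distribution_signalled(self):
        stats = ss.fit_d_distribution([55.0, 55.0, 55.0])
        with pytest.raises(ss.DegenerateDistributionError):
            stats.threshold(3)

    @pytest.mark.parametrize(
        "offset,expected", [(0.0, 0), (-3.5, -4), (1.0, 1), (0.5, 0), (-0.001, -1)]
    )
    def test_sigma_bin_floor_convention(self, offset, expected):
        stats = ScreenStats(mu=50.0, sigma=10.0, n=100)
        assert ss.sigma_bin(50.0 + offset * 10.0, stats) == expected


class TestCallPhenotype:
    stats = ScreenStats(mu=55.0, sigma=2.6, n=25139)  # threshold(3) = 47.2

    @pytest.mark.parametrize(
        "n,t,expected",
        [
            (100.0, 0.0, "differential"),
            (10.0, 10.0, "lethal_both"),
            (20.0, 20.0, "lethal_both"),   # inclusive cutoff
            (15.0, 80.0, "normal_selective"),
            (95.0, 90.0, "inactive"),
            (100.0, 47.3, "inactive"),     # strict threshold: d == 47.3 > 47.2
        ],
    )
    def test_examples(self, n, t, expected):
        call = ss.call_phenotype(n, t, self.stats)
        assert call.value == expected

    def test_batch_matches_naive_oracle(self):
        rng = np.random.default_rng(0)
        n = rng.uniform(0, 150, size=1000)
        t = rng.uniform(0, 150, size=1000)
        scores = pd.DataFrame(
            {"oligo_id": [f"o{i}" for i in range(1000)],
             "pct_nt_normal": n, "pct_nt_tumor": t,
             "d": ss.compute_d(n, t)}
        )
        batch = ss.call_phenotypes(scores, self.stats)["call"]
        expected = [naive_call(a, b, 55.0, 2.6) for a, b in zip(n, t)]
        assert list(batch) == expected

    def test_calls_partition_the_oligo_set(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(
            {"pct_nt_normal": rng.uniform(0, 150, 500),
             "pct_nt_tumor": rng.uniform(0, 150, 500)}
        )
        scores["d"] = ss.compute_d(scores["pct_nt_normal"], scores["pct_nt_tumor"])
        calls = ss.call_phenotypes(scores, self.stats)
        assert calls["call"].isin([p.value for p in PhenotypeCall]).all()
        assert len(calls) == 500


def _tally_frame(spec):
    """Build calls + annotation from (n_genes, n_active, n_oligos) specs."""
    calls, ann = [], []
    g = 0
    for n_genes, n_active, n_oligos in spec:
        for _ in range(n_genes):
            g += 1
            gene = f"G{g:05d}"
            for j in range(n_oligos):
                oligo = f"{gene}_o{j}"
                ann.append((oligo, gene, f"NM_{g:06d}"))
                calls.append((oligo, "differential" if j < n_active else "inactive"))
    return (
        pd.DataFrame(calls, columns=["oligo_id", "call"]),
        pd.DataFrame(ann, columns=["oligo_id", "gene_symbol", "accession"]),
    )


class TestGeneAggregation:
    def test_two_of_three(self):
        calls, ann = _tally_frame([(1, 2, 3)])
        out = ss.aggregate_by_gene(calls, ann, PhenotypeCall.DIFFERENTIAL)
        assert list(out["hit_class"]) == ["2/3"]

    def test_screen_scale_tally(self):
        """12 genes with 2/3 + 374 genes with 1/3 differential oligos give
        the screen's totals: 386 genes, 398 active oligos."""
        calls, ann = _tally_frame([(12, 2, 3), (374, 1, 3), (100, 0, 3)])
        out = ss.aggregate_by_gene(calls, ann, PhenotypeCall.DIFFERENTIAL)
        assert len(out) == 386
        assert out["n_active"].sum() == 398
        assert set(out["hit_class"]) == {"2/3", "1/3"}

    def test_lethal_gene_tally(self):
        calls, ann = _tally_frame([(163, 2, 3), (54, 3, 3), (50, 0, 3)])
        calls["call"] = calls["call"].replace("differential", "lethal_both")
        out = ss.aggregate_by_gene(calls, ann, PhenotypeCall.LETHAL_BOTH)
        assert len(out) == 217
        assert (out["hit_class"] == "3/3").sum() == 54

    def test_unannotated_oligo_rejected(self):
        calls, ann = _tally_frame([(2, 1, 3)])
        with pytest.raises(ss.ScreenError, match="unannotated"):
            ss.aggregate_by_gene(calls, ann.iloc[1:], PhenotypeCall.DIFFERENTIAL)


class TestSummarizeHits:
    @pytest.mark.parametrize(
        "n_hits,expected", [(398, 1.58), (1695, 6.74), (0, 0.0)]
    )
    def test_screen_percentages(self, n_hits, expected):
        calls = pd.DataFrame(
            {"oligo_id": [f"o{i}" for i in range(n_hits)],
             "call": ["differential"] * n_hits}
        )
        out = ss.summarize_hits(calls, library_size=25139)
        row = out[out["phenotype"] == "differential"].iloc[0]
        assert row["count"] == n_hits
        assert row["pct_of_library"] == pytest.approx(expected, abs=1e-12)

    def test_undersized_library_rejected(self):
        calls = pd.DataFrame({"oligo_id": ["a", "b"], "call": ["inactive"] * 2})
        with pytest.raises(ss.ScreenError):
            ss.summarize_hits(calls, library_size=1)
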