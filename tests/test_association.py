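"""Expression categories, qualification, correlations, fractions and TADs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fracscore import (
    DepthTrack,
    GenomeAssembly,
    IntervalSet,
    ScoreTrack,
    categorize_expression,
    categorize_expression_array,
    fraction_relative_abundance,
    pearson_fit,
    qualify_genes,
    rnap_association,
    tad_summary,
)
from fracscore.annotation import RegionWindow


class TestCategorize:
    @pytest.mark.parametrize(
        "tpm,expected",
        [
            (0.0, "Low"),  # log10(1) = 0 < 0.15
            (9.0, "Mid"),  # log10(10) = 1.0
            (2.0, None),  # log10(3) ~ 0.477 falls in the printed gap
            (10**1.5 - 1, "Mid"),  # upper Mid bound is inclusive
            (10**0.5 - 1, None),  # lower Mid bound is exclusive
            (10**2.0 - 1, None),  # High bound is exclusive
            (10**0.15 - 1, None),  # Low bound is exclusive
            (1e4, "High"),
        ],
    )
    def test_printed_boundaries(self, tpm, expected):
        assert categorize_expression(tpm) == expected

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            categorize_expression(-1.0)

    def test_partition_sweep(self):
        # fine grid over log10(TPM+1) in [0, 3]: each value maps to exactly
        # one of Low/gap/Mid/gap/High, in that order along the axis
        # off-boundary grid (exact boundary behaviour is covered above)
        y = np.linspace(0.0007, 3.0007, 3001)
        tpm = 10**y - 1
        classes = categorize_expression_array(tpm)
        boundaries = [0.15, 0.5, 1.5, 2.0]
        expected_bands = ["Low", None, "Mid", None, "High"]
        band = np.searchsorted(boundaries, y, side="right")
        for i, cls in enumerate(classes):
            assert cls == expected_bands[band[i]]

    def test_scalar_and_array_agree(self):
        tpms = [0.0, 0.5, 2.0, 9.0, 50.0, 1e4]
        assert list(categorize_expression_array(tpms)) == [
            categorize_expression(t) for t in tpms
        ]


class TestQualify:
    def test_strict_boundary(self):
        df = pd.DataFrame(
            {"gene_id": ["a", "b"], "rcpm_tss": [0.05, 0.06], "rcpm_tes": [0.06, 0.06]}
        )
        kept = qualify_genes(df)
        assert list(kept["gene_id"]) == ["b"]

    def test_toy_table_matches_brute_force(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "rcpm_tss": rng.uniform(0, 0.12, 10).round(3),
                "rcpm_tes": rng.uniform(0, 0.12, 10).round(3),
            }
        )
        kept = set(qualify_genes(df)["gene_id"])
        brute = {
            r.gene_id for r in df.itertuples() if r.rcpm_tss > 0.05 and r.rcpm_tes > 0.05
        }
        assert kept == brute


class TestPearsonFit:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3, 4])
        fit = pearson_fit(x, -2 * x + 1)
        assert fit.r == pytest.approx(-1.0)
        assert fit.slope == pytest.approx(-2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_constant_x_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_fit([1, 1, 1, 1], [0, 1, 2, 3])

    def test_textbook_covariance_formula(self):
        x = np.array([1.0, 2, 4, 5, 8])
        y = np.array([3.0, 2, 7, 6, 10])
        # independent oracle: r = cov(x,y) / (sd_x * sd_y)
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert pearson_fit(x, y).r == pytest.approx(r_hand, abs=1e-12)

    @given(
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-5, 5),
        c=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        d=st.floats(-5, 5),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_affine_invariance_up_to_sign(self, a, b, c, d):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r0 = pearson_fit(x, y).r
        r1 = pearson_fit(a * x + b, c * y + d).r
        assert r1 == pytest.approx(np.sign(a) * np.sign(c) * r0, abs=1e-8)


class TestFractionRelativeAbundance:
    def test_equal_amounts_all_zero(self):
        assert np.allclose(fraction_relative_abundance([2, 2, 2, 2, 2]), 0.0)

    def test_arithmetic_example(self):
        out = fraction_relative_abundance([1, 1, 1, 1, 1, 3])
        assert out[-1] == pytest.approx(np.log2(2.25), abs=1e-12)

    def test_conservation(self):
        a = np.array([0.5, 1.5, 2.0, 3.0, 4.0])
        out = fraction_relative_abundance(a)
        assert np.sum(2.0**out * a.mean()) == pytest.approx(a.sum())

    def test_scale_invariance(self):
        a = np.array([1.0, 2, 3, 4, 5])
        assert np.allclose(
            fraction_relative_abundance(a), fraction_relative_abundance(7.3 * a)
        )

    def test_zero_amount_offset_with_warning(self):
        with pytest.warns(UserWarning, match="epsilon"):
            out = fraction_relative_abundance([0.0, 1.0])
        assert np.isfinite(out).all()


def score_track(values):
    genome = GenomeAssembly(("chr1",), (len(values),))
    return ScoreTrack(genome, {"chr1": np.asarray(values, dtype=float)})


class TestTadSummary:
    def test_single_tad_mean_is_global_mean(self):
        rng = np.random.default_rng(5)
        v = rng.normal(-2, 1, size=1000)
        tads = IntervalSet.from_records([("chr1", 0, 1000)])
        res = tad_summary(score_track(v), tads)
        assert res.tad_table["mean_score"][0] == pytest.approx(v.mean())

    def test_constant_track_sd_zero_no_open_boundaries(self):
        v = np.full(1000, -1.0)
        tads = IntervalSet.from_records([("chr1", 0, 500), ("chr1", 500, 1000)])
        res = tad_summary(score_track(v), tads, open_threshold=-2.5)
        assert (res.tad_table["sd_score"] == 0).all()
        assert not res.boundary_table["open"].any()

    def test_toy_three_tads_direct_computation(self):
        rng = np.random.default_rng(6)
        v = rng.normal(-2.5, 1.5, size=3000)
        spans = [(0, 1000), (1000, 1800), (1800, 3000)]
        tads = IntervalSet.from_records([("chr1", s, e) for s, e in spans])
        res = tad_summary(score_track(v), tads, boundary_window=200)
        for (s, e), row in zip(spans, res.tad_table.itertuples()):
            assert row.mean_score == pytest.approx(v[s:e].mean())
            assert row.sd_score == pytest.approx(v[s:e].std())
        # boundaries deduplicated: 0, 1000, 1800, 3000
        assert list(res.boundary_table["position"]) == [0, 1000, 1800, 3000]
        b = res.boundary_table.set_index("position")
        assert b.loc[1000, "mean_score"] == pytest.approx(v[900:1100].mean())
        assert b.loc[0, "mean_score"] == pytest.approx(v[0:100].mean())

    def test_empty_tads_empty_output(self):
        res = tad_summary(score_track(np.zeros(100)), IntervalSet.from_records([]))
        assert len(res.tad_table) == 0 and len(res.boundary_table) == 0
        assert np.isnan(res.open_boundary_fraction)


class TestRnapAssociation:
    def _setup(self, rnap_values):
        genome = GenomeAssembly(("chr1",), (1000,))
        track = DepthTrack(genome, {"chr1": np.asarray(rnap_values, dtype=float)})
        wins = [RegionWindow("chr1", i * 100, i * 100 + 50, f"g{i}", "TSS") for i in range(8)]
        return track, wins

    def test_inverse_monotone_gives_negative_r(self):
        scores = pd.Series(np.linspace(-5, -1, 8), index=[f"g{i}" for i in range(8)])
        values = np.zeros(1000)
        for i in range(8):
            values[i * 100 : i * 100 + 50] = np.exp(-float(scores[f"g{i}"]))
        track, wins = self._setup(values)
        table, fit = rnap_association(track, wins, scores)
        assert len(table) == 8
        assert fit is not None and fit.r < 0

    def test_constant_rnap_table_without_fit(self):
        scores = pd.Series(np.linspace(-5, -1, 8), index=[f"g{i}" for i in range(8)])
        track, wins = self._setup(np.ones(1000))
        table, fit = rnap_association(track, wins, scores)
        assert len(table) == 8
        assert fit is None

    def test_demo_rnap_anticorrelated_beyond_noise(self, demo):
        fit = demo.fits["rnap_score"]
        assert fit is not None
        assert fit.r < -3 / np.sqrt(fit.n)
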