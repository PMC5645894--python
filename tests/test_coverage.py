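"""BPKM normalization, rank strata, annotation coverage, per-mode regression."""

import numpy as np
import pandas as pd
import pytest

from atlaskit import coverage as cov
from atlaskit.coverage import DepthTrack, Interval
from atlaskit.errors import DimensionError, DomainError, InputError


def track_of(*arrays, library_id="t"):
    return DepthTrack(
        scaffolds={f"s{i + 1}": np.asarray(a) for i, a in enumerate(arrays)},
        library_id=library_id,
    )


class TestTranscribedFraction:
    def test_extremes(self):
        assert cov.transcribed_fraction(track_of([0, 0, 0])) == 0.0
        assert cov.transcribed_fraction(track_of([1, 2, 3])) == 1.0

    def test_direct_count(self):
        assert cov.transcribed_fraction(track_of([0, 1, 0, 3])) == 0.5

    def test_empty_track_rejected(self):
        with pytest.raises(InputError):
            cov.transcribed_fraction(DepthTrack(scaffolds={}))


class TestFilterScaffolds:
    def test_threshold_application(self):
        t = track_of(np.ones(300_000, dtype=int), np.ones(150_000, dtype=int))
        kept = cov.filter_scaffolds(t)
        assert list(kept.scaffolds) == ["s1"]
        assert kept.total_mapped_bases == 300_000

    def test_identity_at_zero_and_empty_at_large(self):
        t = track_of(np.ones(10_000, dtype=int))
        assert list(cov.filter_scaffolds(t, min_len=0).scaffolds) == ["s1"]
        assert cov.filter_scaffolds(t).scaffolds == {}


class TestBpkm:
    def test_definition_at_one_billion(self):
        big = DepthTrack(scaffolds={"s": np.array([3, 10 ** 9 - 3])})
        b = cov.bpkm_normalize(big)["s"]
        assert b[0] == pytest.approx(3.0)

    def test_direct_formula(self):
        t = DepthTrack(scaffolds={"s": np.array([5, 2 * 10 ** 9 - 5])})
        assert cov.bpkm_normalize(t)["s"][0] == pytest.approx(2.5)
        assert cov.bpkm_normalize(track_of([0, 4]))["s1"][0] == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(DomainError):
            cov.bpkm_normalize(track_of([0, 0]))

    def test_scale_invariance(self, power_track):
        doubled = DepthTrack(
            scaffolds={s: a * 2 for s, a in power_track.scaffolds.items()}
        )
        b1 = cov.bpkm_normalize(power_track)
        b2 = cov.bpkm_normalize(doubled)
        for s in b1:
            np.testing.assert_array_equal(b1[s], b2[s])


class TestGroupBoundary:
    @pytest.mark.parametrize("g,expected", [(1, 400), (4, 3200), (6, 12800), (12, 819200)])
    def test_printed_cumulative_ranks(self, g, expected):
        assert cov.group_boundary(g) == expected

    def test_closed_form_matches_iterated_doubling(self):
        span = 400
        cum = 0
        for g in range(1, 20):
            cum = 400 * 2 ** (g - 1)
            assert cov.group_boundary(g) == cum

    @pytest.mark.parametrize("g", [0, 20, -3])
    def test_out_of_range(self, g):
        with pytest.raises(DomainError):
            cov.group_boundary(g)


def naive_stratify_shares(track):
    """Brute-force full-sort oracle: python sort over every nonzero base."""
    total = track.total_mapped_bases
    entries = []
    for sid in sorted(track.scaffolds):
        a = track.scaffolds[sid]
        for pos in np.nonzero(a)[0]:
            entries.append((-int(a[pos]), sid, int(pos)))
    entries.sort()
    shares = {}
    for g in range(1, 20):
        lo = 0 if g == 1 else cov.group_boundary(g - 1)
        hi = cov.group_boundary(g)
        shares[g] = sum(-d for d, _, _ in entries[lo:hi]) / total
    grouped = sum(-d for d, _, _ in entries[: cov.group_boundary(19)])
    return shares, (total - grouped) / total


class TestStratify:
    def test_uniform_depth_equal_group_means(self):
        t = track_of(np.full(5000, 7, dtype=int))
        s = cov.stratify(t)
        nonempty = s.table[s.table["n_bases"] > 0]
        assert nonempty["mean_bpkm"].nunique() == 1

    def test_single_base_point_mass(self):
        t = track_of(np.array([0, 0, 123456, 0]))
        s = cov.stratify(t)
        assert s.table.loc[1, "share"] == pytest.approx(1.0)
        assert s.remainder_share == pytest.approx(0.0)

    def test_matches_full_sort_oracle(self, power_track):
        s = cov.stratify(power_track)
        shares, remainder = naive_stratify_shares(power_track)
        for g in range(1, 20):
            assert s.table.loc[g, "share"] == pytest.approx(shares[g], abs=1e-12)
        assert s.remainder_share == pytest.approx(remainder, abs=1e-12)

    def test_shares_plus_remainder_sum_to_one(self, power_track):
        s = cov.stratify(power_track)
        assert s.shares_total() == pytest.approx(1.0, abs=1e-9)

    def test_generator_top_rank_share_cross_check(self, power_track):
        # two independent code paths: np.partition on raw depths vs stratify
        depths = np.concatenate(list(power_track.scaffolds.values()))
        top400 = np.partition(depths, -400)[-400:].sum()
        s = cov.stratify(power_track)
        assert s.table.loc[1, "share"] == pytest.approx(top400 / depths.sum(), abs=1e-12)

    def test_short_track_has_empty_tail_groups(self):
        t = track_of(np.arange(1, 101))  # 100 nonzero bases < 400
        s = cov.stratify(t)
        assert s.table.loc[1, "n_bases"] == 100
        assert (s.table.loc[2:, "mean_bpkm"] == 0).all()
        assert s.table.loc[1, "share"] == pytest.approx(1.0)


class TestStrataZscores:
    def make_summary(self, lib, group1_mean):
        table = pd.DataFrame(
            {"group": range(1, 20), "mean_bpkm": [float(group1_mean)] + [1.0] * 18}
        ).set_index("group")
        return cov.StrataSummary(
            library_id=lib, table=table, remainder_share=0.0,
            total_mapped_bases=1, n_zero_bases=0,
        )

    def test_uniform_depth_normalizes_away_scale(self):
        # uniform tracks at different absolute depths give identical BPKM strata
        panel = []
        for i, fill in enumerate([1, 5, 9]):
            t = track_of(np.full(1000, fill, dtype=int), library_id=f"L{i}")
            panel.append(cov.stratify(t))
        z = cov.strata_zscores(panel)
        assert (z.to_numpy() == 0).all()

    def test_hand_computed_group_row(self):
        panel = [self.make_summary(f"L{i}", v) for i, v in enumerate([1, 2, 3])]
        z = cov.strata_zscores(panel)
        np.testing.assert_allclose(z.loc[1].to_numpy(), [-1.0, 0.0, 1.0], atol=1e-9)
        assert abs(z.to_numpy().sum(axis=1)).max() < 1e-9

    def test_needs_two_libraries(self):
        with pytest.raises(DimensionError):
            cov.strata_zscores([self.make_summary("L0", 5)])


class TestAnnotationCoverage:
    def test_no_intervals(self):
        out = cov.annotation_coverage([], genome_size=100)
        assert out == {"gene": 0.0, "exon": 0.0, "CDS": 0.0}

    def test_strand_agnostic_union(self):
        recs = [
            Interval("s1", "exon", 1, 100, "+", "gA"),
            Interval("s1", "exon", 51, 150, "-", "gB"),
        ]
        out = cov.annotation_coverage(recs, genome_size=1000)
        assert out["exon"] == pytest.approx(0.15)

    def test_union_idempotence(self):
        one = [Interval("s1", "CDS", 10, 40)]
        five = one * 5
        a = cov.annotation_coverage(one, genome_size=500)
        b = cov.annotation_coverage(five, genome_size=500)
        assert a["CDS"] == b["CDS"] == pytest.approx(31 / 500)

    def test_gene_span_is_max_exon_edge_distance(self):
        recs = [
            Interval("s1", "exon", 11, 20, "+", "gA"),
            Interval("s1", "exon", 91, 100, "+", "gA"),
        ]
        out = cov.annotation_coverage(recs, genome_size=1000)
        assert out["gene"] == pytest.approx(90 / 1000)  # 11..100 inclusive
        assert out["exon"] == pytest.approx(20 / 1000)

    def test_out_of_bounds_names_record(self):
        with pytest.raises(InputError, match="s1"):
            cov.annotation_coverage(
                [Interval("s1", "exon", 5, 50)], genome_size=100,
                scaffold_lengths={"s1": 40},
            )


class TestRegression:
    def test_perfect_line(self):
        pts = [(x, 2 * x + 1, "S") for x in [0.0, 1.0, 2.0, 3.0]]
        fit = cov.regress_coverage(pts)["S"]
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert abs(fit.residuals.sum()) < 1e-9

    def test_residuals_sum_to_zero_with_noise(self):
        rng = np.random.default_rng(5)
        pts = [(x, 1.5 * x + 0.2 + rng.normal(0, 0.05), "P") for x in np.linspace(0, 3, 30)]
        fit = cov.regress_coverage(pts)["P"]
        assert abs(fit.residuals.sum()) < 1e-9
        assert fit.slope == pytest.approx(1.5, abs=0.1)

    def test_sparse_mode_skipped_with_warning(self):
        pts = [(0.0, 0.0, "S"), (1.0, 1.0, "S"), (2.0, 2.0, "P")]
        with pytest.warns(UserWarning, match="P"):
            fits = cov.regress_coverage(pts)
        assert "P" not in fits and "S" in fits


class TestDepthIo:
    def test_tsv_round_trip(self, tmp_path):
        t = track_of(np.array([0, 3, 0, 7]), np.array([1, 0, 0, 0]))
        path = tmp_path / "depth.tsv"
        cov.write_depth_tsv(t, path)
        back = cov.read_depth_tsv(path, {"s1": 4, "s2": 4})
        for sid in t.scaffolds:
            np.testing.assert_array_equal(back.scaffolds[sid], t.scaffolds[sid])

    def test_unknown_scaffold_rejected(self, tmp_path):
        path = tmp_path / "depth.tsv"
        path.write_text("sX\t1\t5\n")
        with pytest.raises(InputError):
            cov.read_depth_tsv(path, {"s1": 10})
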