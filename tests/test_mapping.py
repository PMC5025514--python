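"""Kosambi distances, bins, anchoring, density statistics and concordance."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyarray import (
    DHGenotypeMatrix,
    GeneticMap,
    HomoeologyTable,
    SimConfig,
    assign_physical,
    build_genetic_map,
    classify_concordance,
    compute_map_stats,
    detect_segments,
    estimate_r,
    find_bins,
    kosambi,
    kosambi_inverse,
    published_density_stats,
    simulate_dh,
)
from polyarray.mapping import PhysicalAnchor, density_stats


class TestKosambi:
    def test_zero_and_worked_example(self):
        assert kosambi(0.0) == 0.0
        assert kosambi(0.25) == pytest.approx(25 * math.log(3), abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            kosambi(0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(r=st.floats(0, 0.499, allow_nan=False))
    def test_round_trip_and_expansion_bound(self, r):
        assert kosambi_inverse(kosambi(r)) == pytest.approx(r, abs=1e-12)
        # map distance always expands the recombinant fraction: d >= 100 r
        assert kosambi(r) >= 100 * r - 1e-12

    def test_monotone_increasing(self):
        grid = np.linspace(0, 0.49, 200)
        d = [kosambi(r) for r in grid]
        assert all(b > a for a, b in zip(d, d[1:]))


class TestEstimateR:
    def test_identical_vectors(self):
        v = np.array(["A", "B", "A", "B"])
        assert estimate_r(v, v) == 0.0

    def test_hand_count(self):
        v1 = np.array(["A"] * 100)
        v2 = np.array(["B"] * 2 + ["A"] * 98)
        assert estimate_r(v1, v2) == pytest.approx(0.02)

    def test_missing_excluded_and_empty_sentinel(self):
        v1 = np.array(["A", "-", "A"])
        v2 = np.array(["-", "B", "B"])
        assert estimate_r(v1, v2) == 1.0  # only line 3 jointly typed
        assert math.isnan(estimate_r(np.array(["A", "-"]), np.array(["-", "B"])))

    def test_sampling_distribution_matches_truth(self):
        """Mean estimate over replicates of a 124-line DH cross at a true
        27.465 cM interval is within the binomial CI of r = 0.25."""
        rng = np.random.default_rng(4)
        r_true = kosambi_inverse(25 * math.log(3))
        assert r_true == pytest.approx(0.25, abs=1e-12)
        n, reps = 124, 400
        ests = []
        for _ in range(reps):
            a = rng.random(n) < 0.5
            flip = rng.random(n) < r_true
            b = a ^ flip
            v1 = np.where(a, "A", "B")
            v2 = np.where(b, "A", "B")
            ests.append(estimate_r(v1, v2))
        se = math.sqrt(r_true * (1 - r_true) / n / reps)
        assert np.mean(ests) == pytest.approx(r_true, abs=4 * se)


class TestBins:
    def _matrix(self, cols):
        data = pd.DataFrame(cols, index=[f"l{i}" for i in range(len(next(iter(cols.values()))))])
        return DHGenotypeMatrix(data, {"N1": list(cols)})

    def test_identical_vectors_share_a_bin(self):
        v = ["A", "B", "A", "B"]
        m = self._matrix({"m1": v, "m2": v, "m3": v})
        bins = find_bins(m)
        assert bins["m1"] == bins["m2"] == bins["m3"]

    def test_single_discordant_line_splits(self):
        m = self._matrix({"m1": ["A", "B", "A"], "m2": ["A", "B", "B"]})
        bins = find_bins(m)
        assert bins["m1"] != bins["m2"]

    def test_missing_is_wildcard_but_cannot_merge_alone(self):
        m = self._matrix({"m1": ["A", "-", "A"], "m2": ["A", "B", "-"]})
        assert find_bins(m)["m1"] == find_bins(m)["m2"]  # agree on line 1
        m2 = self._matrix({"m1": ["-", "-", "A"], "m2": ["A", "B", "-"]})
        bins = find_bins(m2)
        assert bins["m1"] != bins["m2"]  # no jointly typed line

    def test_bin_boundaries_equal_simulated_crossovers(self):
        cfg = SimConfig(seed=50)
        matrix, _, _, truth = simulate_dh(cfg)
        bins = find_bins(matrix)
        for lg, markers in matrix.marker_order.items():
            got = [bins[b] != bins[a] for a, b in zip(markers, markers[1:])]
            assert got == truth.recombined_pairs[lg]

    def test_within_bin_r_is_zero(self):
        cfg = SimConfig(seed=51)
        matrix, _, _, _ = simulate_dh(cfg)
        bins = find_bins(matrix)
        for lg, markers in matrix.marker_order.items():
            for a, b in zip(markers, markers[1:]):
                if bins[a] == bins[b]:
                    assert estimate_r(matrix.vector(a), matrix.vector(b)) == 0.0


class TestPhysicalAnchoring:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["query", "chrom", "start", "identity"])

    def test_high_identity_hit_anchors(self):
        a = assign_physical(self._hits([("m1", "A1", 100, 99.0)]))
        assert not a["m1"].unanchored and a["m1"].chrom == "A1"

    def test_sub_threshold_best_hit_unanchored(self):
        a = assign_physical(self._hits([("m1", "A1", 100, 84.9)]))
        assert a["m1"].unanchored

    def test_co_optimal_hits_on_homoeologs_ambiguous(self):
        a = assign_physical(
            self._hits([("m1", "A1", 100, 96.0), ("m1", "C1", 900, 96.0)])
        )
        assert a["m1"].ambiguous and not a["m1"].unanchored


class TestDensityStats:
    def test_published_totals_reproduce_at_two_decimals(self):
        _, totals = published_density_stats()
        assert totals["markers_per_cm"] == 11.99
        assert totals["cm_per_marker"] == 0.08
        assert totals["kb_per_marker"] == 14.59

    @pytest.mark.parametrize("lg,want", [("A1", 12.03), ("C5", 5.23), ("C8", 7.13)])
    def test_published_per_group_marker_density(self, lg, want):
        per_lg, _ = published_density_stats()
        got = per_lg.set_index("lg").loc[lg, "markers_per_cm"]
        assert got == want

    def test_degenerate_inputs_give_sentinels(self):
        out = density_stats(0, 0.0, 0, 0.0)
        assert all(math.isnan(v) for v in out.values())

    def test_map_stats_gap_lists(self):
        table = pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(5)],
                "lg": ["N1"] * 5,
                "cm": [0.0, 2.0, 4.0, 15.0, 18.0],  # one gap >= 9 cM
                "bin": [0, 0, 1, 2, 3],
            }
        )
        anchors = {
            f"m{i}": PhysicalAnchor(f"m{i}", "A1", bp, 99.0)
            for i, bp in enumerate([0, 100_000, 200_000, 900_000, 1_000_000])
        }
        stats = compute_map_stats(GeneticMap(table), anchors)
        assert len(stats.genetic_gaps) == 1
        assert stats.genetic_gaps.iloc[0]["gap_cm"] == pytest.approx(11.0)
        assert len(stats.physical_gaps) == 1  # 700 kb interval
        assert stats.totals["mapped_loci"] == 5


class TestConcordance:
    def test_planted_swap_fraction_recovered_exactly(self):
        cfg = SimConfig(
            seed=9, homoeologous_swap_fraction=0.05,
            lg_maps={
                f"N{i}": list(np.linspace(0, 90, 10)) for i in range(1, 5)
            },
        )
        matrix, tmap, anchors, truth = simulate_dh(cfg)
        lg_to_chrom = {lg: f"A{i+1}" for i, lg in enumerate(cfg.lg_maps)}
        records, summary = classify_concordance(
            tmap, anchors, HomoeologyTable.numbered(19), lg_to_chrom
        )
        n_markers = sum(len(m) for m in matrix.marker_order.values())
        assert summary["homoeologous"] == pytest.approx(
            len(truth.swapped_markers) / n_markers
        )
        swapped = set(records[records["status"] == "HOMOEOLOGOUS"]["marker"])
        assert swapped == set(truth.swapped_markers)

    def test_fractions_sum_to_one(self):
        cfg = SimConfig(seed=10, homoeologous_swap_fraction=0.1, translocated_blocks=1)
        _, tmap, anchors, _ = simulate_dh(cfg)
        lg_to_chrom = {lg: f"A{i+1}" for i, lg in enumerate(cfg.lg_maps)}
        _, summary = classify_concordance(
            tmap, anchors, HomoeologyTable.numbered(19), lg_to_chrom
        )
        total = summary["concordant"] + summary["homoeologous"] + summary["discordant"]
        assert total == pytest.approx(1.0)

    def test_unmapped_lg_becomes_unanchored(self):
        table = pd.DataFrame({"marker": ["m1"], "lg": ["NX"], "cm": [0.0]})
        anchors = {"m1": PhysicalAnchor("m1", "A1", 5, 99.0)}
        records, _ = classify_concordance(
            GeneticMap(table), anchors, HomoeologyTable.numbered(19), {}
        )
        assert records.iloc[0]["status"] == "UNANCHORED"


class TestSegments:
    def _records(self, statuses, chroms):
        return pd.DataFrame(
            {
                "marker": [f"m{i}" for i in range(len(statuses))],
                "lg": ["N1"] * len(statuses),
                "cm": np.arange(len(statuses), dtype=float),
                "anchor_chrom": chroms,
                "anchor_bp": np.arange(len(statuses)) * 100_000,
                "status": statuses,
            }
        )

    def test_run_of_six_wrong_markers_is_one_segment(self):
        rec = self._records(
            ["CONCORDANT"] * 2 + ["DISCORDANT"] * 6 + ["CONCORDANT"] * 2,
            ["A1"] * 2 + ["C3"] * 6 + ["A1"] * 2,
        )
        segs = detect_segments(rec, min_run=3)
        assert len(segs) == 1 and segs.iloc[0]["n_markers"] == 6
        assert segs.iloc[0]["alt_chrom"] == "C3"

    def test_isolated_discordant_marker_ignored(self):
        rec = self._records(
            ["CONCORDANT"] * 3 + ["DISCORDANT"] + ["CONCORDANT"] * 3,
            ["A1"] * 3 + ["C3"] + ["A1"] * 3,
        )
        assert len(detect_segments(rec, min_run=3)) == 0

    def test_simulated_translocated_block_recovered_within_one_marker(self):
        cfg = SimConfig(
            seed=9, translocated_blocks=2,
            lg_maps={f"N{i}": list(np.linspace(0, 100, 12)) for i in range(1, 4)},
        )
        _, tmap, anchors, truth = simulate_dh(cfg)
        lg_to_chrom = {lg: f"A{i+1}" for i, lg in enumerate(cfg.lg_maps)}
        records, _ = classify_concordance(
            tmap, anchors, HomoeologyTable.numbered(19), lg_to_chrom
        )
        segs = detect_segments(records, min_run=3)
        assert len(segs) == len(truth.translocated)
        for block in truth.translocated:
            match = segs[(segs["lg"] == block["lg"]) & (segs["alt_chrom"] == block["dest_chrom"])]
            assert len(match) == 1
            got = set(match.iloc[0]["markers"].split(","))
            want = set(block["markers"])
            assert len(got.symmetric_difference(want)) <= 1


def test_map_reconstruction_recovers_simulated_lengths():
    """Kosambi map rebuilt from a 124-line DH matrix lands within sampling
    error of the true group lengths."""
    cfg = SimConfig(seed=60)
    matrix, true_map, _, _ = simulate_dh(cfg)
    built = build_genetic_map(matrix)
    for lg in matrix.marker_order:
        want = true_map.lg_length(lg)
        got = built.lg_length(lg)
        assert got == pytest.approx(want, abs=0.35 * want + 5)
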