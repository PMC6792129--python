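"""Consensus binding-region extraction against brute-force oracles."""

from collections import defaultdict

import numpy as np
import pytest

from mik.genome_io import GeneModelIndex, GenomicInterval, InteractionRecord, PeakRecord
from mik.mibr_core import (
    build_support_profile,
    characterize_regions,
    extract_regions,
    parameter_grid,
    sequence_coverage,
    tissue_summary,
)

from conftest import make_transcript
from mik.genome_io import GeneModel


def peak(start, end, dataset, seqid="chr1", strand="+", cell_line=""):
    return PeakRecord(GenomicInterval(seqid, start, end, strand), dataset, cell_line)


def chimera(start, end, dataset, chimera_id, mirna="m1", seqid="chr1", strand="+",
            cell_line=""):
    return InteractionRecord(
        mirna, (GenomicInterval(seqid, start, end, strand),), dataset, chimera_id,
        cell_line,
    )


def brute_force_regions(intervals_with_units, min_length, min_support,
                        seqid="chr1", strand="+"):
    """Independent oracle: per-position unit sets via direct enumeration,
    then scan every candidate run of consecutive positions."""
    by_pos = defaultdict(set)
    for (start, end), unit in intervals_with_units:
        for p in range(start, end):
            by_pos[p].add(unit)
    good = sorted(p for p, units in by_pos.items() if len(units) >= min_support)
    regions = []
    run = []
    for p in good + [None]:
        if run and (p is None or p != run[-1] + 1):
            if len(run) >= min_length:
                regions.append((run[0], run[-1] + 1))
            run = []
        if p is not None:
            run.append(p)
    return regions


class TestSupportProfile:
    def test_same_dataset_peaks_deduplicate(self):
        profile = build_support_profile(
            [peak(100, 150, "GSM1"), peak(120, 170, "GSM1")]
        )
        assert len(profile.positions[("chr1", "+")][130]) == 1

    def test_peak_plus_chimera_counts_two(self):
        profile = build_support_profile(
            [peak(100, 150, "GSM1")], [chimera(120, 140, "GSM2", "c1")]
        )
        assert len(profile.positions[("chr1", "+")][130]) == 2

    def test_two_chimeras_one_dataset_count_two(self):
        profile = build_support_profile(
            [], [chimera(100, 140, "GSM1", "c1"), chimera(110, 150, "GSM1", "c2")]
        )
        assert len(profile.positions[("chr1", "+")][120]) == 2

    def test_chimera_does_not_double_count_its_parent_dataset(self):
        profile = build_support_profile(
            [peak(100, 150, "GSM1")], [chimera(100, 150, "GSM1", "c1")]
        )
        # one dataset unit + one chimera unit, per the evidence rule
        assert len(profile.positions[("chr1", "+")][120]) == 2

    def test_order_invariance_and_idempotence(self):
        peaks = [peak(0, 50, "A"), peak(30, 80, "B"), peak(60, 100, "C")]
        p1 = build_support_profile(peaks)
        p2 = build_support_profile(peaks[::-1] + [peaks[0]])
        assert p1.positions[("chr1", "+")] == p2.positions[("chr1", "+")]

    def test_unstranded_peaks_cover_both_strands(self):
        profile = build_support_profile([peak(0, 10, "A", strand=".")])
        assert 5 in profile.positions[("chr1", "+")]
        assert 5 in profile.positions[("chr1", "-")]

    def test_covered_positions_equals_union_footprint(self):
        peaks = [peak(0, 50, "A"), peak(40, 90, "B")]
        profile = build_support_profile(peaks)
        assert profile.covered_positions() == 90
        # n=1, L=1 recovers the merged footprint
        regions = extract_regions(profile, min_length=1, min_support=1)
        assert sum(r.interval.length for r in regions) == 90


class TestExtractRegions:
    def test_constant_support_run(self):
        profile = build_support_profile([peak(100, 200, "A"), peak(100, 200, "B")])
        regions = extract_regions(profile, 10, 2)
        assert [(r.interval.start, r.interval.end) for r in regions] == [(100, 200)]
        assert regions[0].support_min == regions[0].support_max == 2
        assert regions[0].datasets == {"A", "B"}

    def test_short_runs_are_dropped(self):
        # 2-supported runs of 3 nt separated by single-covered gaps
        peaks = [peak(0, 100, "A")]
        peaks += [peak(s, s + 3, "B") for s in range(10, 50, 4)]
        profile = build_support_profile(peaks)
        assert extract_regions(profile, 10, 2) == []
        assert len(extract_regions(profile, 3, 2)) == 10

    def test_maximality_flanks_below_support(self):
        profile = build_support_profile(
            [peak(0, 100, "A"), peak(20, 60, "B")]
        )
        regions = extract_regions(profile, 10, 2)
        assert [(r.interval.start, r.interval.end) for r in regions] == [(20, 60)]

    def test_merged_mode_expands_to_footprint(self):
        profile = build_support_profile(
            [peak(0, 100, "A"), peak(20, 60, "B")]
        )
        regions = extract_regions(profile, 10, 2, mode="merged")
        assert [(r.interval.start, r.interval.end) for r in regions] == [(0, 100)]

    def test_matches_brute_force_on_random_profiles(self, rng):
        """Exact agreement with the per-position enumerator on 200 random
        profiles (up to 5 kb, up to 10 evidence sources)."""
        for trial in range(200):
            n_sources = int(rng.integers(1, 11))
            span = int(rng.integers(200, 5000))
            items = []
            peaks = []
            chimeras = []
            for s in range(n_sources):
                is_chimeric = rng.random() < 0.3
                for k in range(int(rng.integers(1, 6))):
                    start = int(rng.integers(0, span - 20))
                    end = start + int(rng.integers(5, 80))
                    if is_chimeric:
                        unit = ("ch", f"D{s}", f"c{s}_{k}")
                        chimeras.append(chimera(start, end, f"D{s}", f"c{s}_{k}"))
                    else:
                        unit = ("ds", f"D{s}")
                        peaks.append(peak(start, end, f"D{s}"))
                    items.append(((start, end), unit))
            L = int(rng.integers(1, 26))
            n = int(rng.integers(1, 5))
            profile = build_support_profile(peaks, chimeras)
            got = [
                (r.interval.start, r.interval.end)
                for r in extract_regions(profile, L, n)
            ]
            assert sorted(got) == brute_force_regions(items, L, n), (
                f"trial {trial}: L={L} n={n}"
            )

    def test_refinement_under_stricter_parameters(self, rng):
        """Every (L', n') region with L'>=L, n'>=n lies inside some (L, n)
        region."""
        peaks = [
            peak(int(s), int(s) + int(l), f"D{int(d)}")
            for s, l, d in zip(
                rng.integers(0, 3000, 60), rng.integers(10, 90, 60),
                rng.integers(0, 8, 60),
            )
        ]
        profile = build_support_profile(peaks)
        loose = extract_regions(profile, 5, 2)
        strict = extract_regions(profile, 12, 3)
        for r in strict:
            assert any(
                q.interval.start <= r.interval.start and r.interval.end <= q.interval.end
                for q in loose
            )


class TestParameterGrid:
    def test_empty_profile_all_zero(self):
        grid = parameter_grid(build_support_profile([]), range(1, 5), range(1, 4))
        assert (grid.to_numpy() == 0).all()

    def test_single_run_analytic(self):
        # one run of length 12 at support 3
        peaks = [peak(100, 112, d) for d in ("A", "B", "C")]
        grid = parameter_grid(build_support_profile(peaks))
        for L in grid.index:
            for n in grid.columns:
                assert grid.loc[L, n] == (1 if L <= 12 and n <= 3 else 0)

    def test_monotonicity_on_random_profiles(self, rng):
        """Counts non-increasing in n at fixed L and in L at fixed n, on 100
        random profiles."""
        for _ in range(100):
            peaks = [
                peak(int(s), int(s) + int(l), f"D{int(d)}")
                for s, l, d in zip(
                    rng.integers(0, 1500, 25), rng.integers(5, 60, 25),
                    rng.integers(0, 6, 25),
                )
            ]
            grid = parameter_grid(
                build_support_profile(peaks), range(1, 26), range(1, 11)
            )
            arr = grid.to_numpy()
            assert (np.diff(arr, axis=1) <= 0).all()  # over n
            assert (np.diff(arr, axis=0) <= 0).all()  # over L

    def test_grid_counts_match_extract_regions(self, rng):
        peaks = [
            peak(int(s), int(s) + int(l), f"D{int(d)}")
            for s, l, d in zip(
                rng.integers(0, 800, 20), rng.integers(5, 50, 20),
                rng.integers(0, 5, 20),
            )
        ]
        profile = build_support_profile(peaks)
        for mode in ("merged", "run"):
            grid = parameter_grid(profile, range(1, 26), range(1, 6), mode=mode)
            for L in (1, 7, 25):
                for n in (1, 2, 4):
                    assert grid.loc[L, n] == len(
                        extract_regions(profile, L, n, mode=mode)
                    )


class TestCharacterization:
    def test_mirna_list_from_chimeras_only(self):
        profile = build_support_profile(
            [peak(0, 40, "GSM1")],
            [chimera(0, 40, "GSM2", "c1", mirna="a"),
             chimera(10, 30, "GSM2", "c2", mirna="b"),
             chimera(15, 35, "GSM3", "c3", mirna="a")],
        )
        regions = characterize_regions(extract_regions(profile, 10, 2))
        assert regions[0].mirnas == {"a", "b"}

    def test_peak_only_region_has_empty_mirna_list(self):
        profile = build_support_profile([peak(0, 40, "A"), peak(0, 40, "B")])
        regions = characterize_regions(extract_regions(profile, 10, 2))
        assert regions[0].mirnas == frozenset()
        assert regions[0].annotation.part == "intergenic"

    def test_gene_annotation_attached(self, coding_gene):
        profile = build_support_profile(
            [peak(1100, 1140, "A"), peak(1100, 1140, "B")]
        )
        index = GeneModelIndex([coding_gene])
        regions = characterize_regions(extract_regions(profile, 10, 2), index)
        assert regions[0].annotation.gene_id == "gA"
        assert regions[0].annotation.part == "CDS"


class TestTissueAndCoverage:
    def _region_with_lines(self, lines, start=0):
        profile = build_support_profile(
            [peak(start, start + 20, f"D{i}", cell_line=c) for i, c in enumerate(lines)]
        )
        return extract_regions(profile, 10, 2)[0]

    def test_ubiquity_boundary_at_seven_lines(self):
        lines7 = [f"L{i}" for i in range(7)]
        r7 = self._region_with_lines(lines7)
        r2 = self._region_with_lines(["L0", "L1"], start=100)
        out = tissue_summary([r7, r2], k=7)
        assert out.ubiquitous == [r7.region_id]
        assert out.shared == 2

    def test_exclusive_region(self):
        profile = build_support_profile(
            [peak(0, 20, "D0", cell_line="HEK293"),
             peak(0, 20, "D1", cell_line="HEK293")]
        )
        region = extract_regions(profile, 10, 2)[0]
        out = tissue_summary([region])
        assert out.exclusive == {"HEK293": 1}
        assert out.shared == 0 and out.ubiquitous == []

    def test_empty_input_empty_summary(self):
        out = tissue_summary([])
        assert out.exclusive == {} and out.shared == 0 and out.ubiquitous == []

    def test_coverage_union_and_genes(self):
        profile = build_support_profile(
            [peak(0, 50, "A", seqid="chrM"), peak(0, 50, "B", seqid="chrM"),
             peak(50, 100, "A", seqid="chrM"), peak(50, 100, "B", seqid="chrM")]
        )
        regions = extract_regions(profile, 10, 2)
        tx = make_transcript([("chrM", 10, 60, "+")], "gm.t1", "gm")
        gene = GeneModel("gm", "MT1", "noncoding")
        gene.transcripts[tx.transcript_id] = tx
        out = sequence_coverage(regions, "chrM", 100, GeneModelIndex([gene]))
        assert out.covered_fraction == pytest.approx(1.0)
        assert (out.genes_touched, out.genes_total) == (1, 1)

    def test_half_coverage_and_empty(self):
        profile = build_support_profile([peak(0, 50, "A"), peak(0, 50, "B")])
        regions = extract_regions(profile, 10, 2)
        assert sequence_coverage(regions, "chr1", 100).covered_fraction == 0.5
        empty = sequence_coverage([], "chr1", 100)
        assert empty.covered_fraction == 0.0 and empty.genes_touched == 0
        with pytest.raises(ValueError):
            sequence_coverage([], "chr1", 0)
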