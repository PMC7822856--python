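"""Sliding-window detection, trimming, extension, splitting, final filter."""

import numpy as np
import pytest

from rohmap import (
    MB,
    ROH,
    DetectionParams,
    FilterParams,
    SampleTable,
    SimConfig,
    detect,
    infer_sex,
    read_vcf,
    simulate,
)
from rohmap.genome_annotation import GenomeAnnotation
from rohmap.roh_detection import (
    extend,
    final_filter,
    seed_windows,
    split_on_gaps,
    trim,
)

from conftest import annot_for, hemi, het, hom, table_from_pattern

NO_MIN = FilterParams(min_surviving_variants=0)


def seed_oracle(hom_flags, window, thres):
    """Brute-force window enumeration: maximal runs of covered variants."""
    n = len(hom_flags)
    covered = [False] * n
    for i in range(n - window + 1):
        if sum(hom_flags[i : i + window]) >= thres:
            for j in range(i, i + window):
                covered[j] = True
    runs, i = [], 0
    while i < n:
        if covered[i]:
            j = i
            while j + 1 < n and covered[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


class TestSeedWindows:
    params = DetectionParams()

    def test_all_homozygous_one_candidate(self):
        table = table_from_pattern("H" * 30)
        (cand,) = seed_windows(table.calls, self.params)
        assert (cand.start, cand.end) == (1_000_000, 1_000_000 + 29 * 10_000)
        assert cand.n_variants == cand.n_homozygous == 30

    def test_alternating_never_passes(self):
        table = table_from_pattern("He" * 15)
        assert seed_windows(table.calls, self.params) == []

    def test_single_het_inside_run_does_not_break_candidate(self):
        table = table_from_pattern("H" * 20 + "e" + "H" * 20)
        (cand,) = seed_windows(table.calls, self.params)
        assert cand.n_variants == 41 and cand.n_homozygous == 40

    def test_fewer_variants_than_window_no_candidates(self):
        table = table_from_pattern("HHHHHH")  # 6 < window 7
        assert seed_windows(table.calls, self.params) == []

    def test_windows_do_not_span_chromosomes(self):
        calls = table_from_pattern("H" * 4, chrom="chr1").calls
        calls += table_from_pattern("H" * 4, chrom="chr2").calls
        assert seed_windows(SampleTable("S", calls).calls, self.params) == []

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(120):
            n = int(rng.integers(1, 120))
            flags = rng.random(n) < rng.uniform(0.2, 0.9)
            pattern = "".join("H" if f else "e" for f in flags)
            table = table_from_pattern(pattern)
            w = int(rng.integers(2, 9))
            t = int(rng.integers(1, w + 1))
            params = DetectionParams(window=w, windowthres=t)
            got = [
                (c.start, c.end) for c in seed_windows(table.calls, params)
            ]
            pos = [c.pos for c in table.calls]
            expected = [
                (pos[i], pos[j]) for i, j in seed_oracle(list(flags), w, t)
            ]
            assert got == expected


class TestTrim:
    def test_leading_het_trimmed(self):
        table = table_from_pattern("e" + "H" * 10)
        cand = ROH("chr1", 1_000_000, 1_100_000)
        trimmed = trim(cand, table.calls)
        assert trimmed.start == 1_010_000  # first homozygous call

    def test_hom_both_ends_unchanged(self):
        table = table_from_pattern("H" * 10)
        cand = ROH("chr1", 1_000_000, 1_090_000)
        trimmed = trim(cand, table.calls)
        assert (trimmed.start, trimmed.end) == (1_000_000, 1_090_000)

    def test_het_flanks_trimmed_to_hom_core(self):
        table = table_from_pattern("ee" + "H" * 30 + "e")
        cand = ROH("chr1", 1_000_000, 1_000_000 + 32 * 10_000)
        trimmed = trim(cand, table.calls)
        assert (trimmed.start, trimmed.end) == (1_020_000, 1_310_000)
        assert trimmed.n_homozygous == trimmed.n_variants == 30

    def test_no_homozygous_discarded(self):
        table = table_from_pattern("eee")
        assert trim(ROH("chr1", 1_000_000, 1_020_000), table.calls) is None


class TestExtend:
    annot = annot_for({"chr1": 200 * MB})
    params = DetectionParams()

    def test_unobstructed_extension_moves_exactly_extend_mb(self):
        table = table_from_pattern("H" * 30, start=50 * MB, spacing=10_000)
        roh = ROH("chr1", 50 * MB, 50 * MB + 29 * 10_000)
        (out,) = extend([roh], table.calls, self.annot, self.params)
        assert out.start == 49 * MB
        assert out.end == 50 * MB + 29 * 10_000 + MB

    def test_extension_stops_inside_external_het(self):
        calls = table_from_pattern("H" * 30, start=50 * MB, spacing=10_000).calls
        end = 50 * MB + 29 * 10_000
        calls.append(het("chr1", end + 200_000))
        roh = ROH("chr1", 50 * MB, end)
        (out,) = extend([roh], calls, self.annot, self.params)
        assert out.end == end + 200_000 - 1

    def test_extension_clamped_at_chromosome_limits(self):
        annot = annot_for({"chr1": 3 * MB})
        table = table_from_pattern("H" * 30, start=500_000, spacing=10_000)
        roh = ROH("chr1", 500_000, 500_000 + 29 * 10_000)
        (out,) = extend([roh], table.calls, annot, self.params)
        assert out.start == 1
        assert out.end == 1_790_000  # end + 1 Mb < chrom end

    def test_gap_of_1p5_mb_closed_by_extension_and_merged(self):
        left = table_from_pattern("H" * 30, start=40 * MB).calls
        right = table_from_pattern("H" * 30, start=41_790_000).calls
        calls = left + right
        r1 = ROH("chr1", left[0].pos, left[-1].pos)
        r2 = ROH("chr1", right[0].pos, right[-1].pos)
        out = extend([r1, r2], calls, self.annot, self.params)
        assert len(out) == 1
        assert out[0].n_variants == 60


class TestSplitOnGaps:
    params = DetectionParams()

    def test_gap_over_threshold_splits_excluding_stretch(self):
        left = table_from_pattern("H" * 30, start=10 * MB).calls
        right = table_from_pattern("H" * 30, start=21_300_000).calls  # 11 Mb gap
        roh = ROH("chr1", left[0].pos, right[-1].pos)
        out = split_on_gaps([roh], left + right, self.params)
        assert [(r.start, r.end) for r in out] == [
            (left[0].pos, left[-1].pos),
            (right[0].pos, right[-1].pos),
        ]

    def test_gap_under_threshold_kept_whole(self):
        left = table_from_pattern("H" * 30, start=10 * MB).calls
        right = table_from_pattern("H" * 30, start=19_300_000).calls  # 9 Mb gap
        roh = ROH("chr1", left[0].pos, right[-1].pos)
        out = split_on_gaps([roh], left + right, self.params)
        assert len(out) == 1 and out[0].n_variants == 60

    def test_two_gaps_give_three_pieces(self):
        a = table_from_pattern("H" * 10, start=10 * MB).calls
        b = table_from_pattern("H" * 10, start=22 * MB).calls
        c = table_from_pattern("H" * 10, start=34 * MB).calls
        roh = ROH("chr1", a[0].pos, c[-1].pos)
        out = split_on_gaps([roh], a + b + c, self.params)
        assert len(out) == 3


class TestFinalFilter:
    def _roh(self, size_mb=2.0, n_var=30, n_hom=30):
        end = int(size_mb * MB)
        return ROH("chr1", 1, end, n_variants=n_var, n_homozygous=n_hom)

    def test_good_roh_kept(self):
        assert final_filter([self._roh()], DetectionParams()) != []

    def test_minvar_boundary(self):
        params = DetectionParams()
        assert final_filter([self._roh(n_var=24, n_hom=24)], params) == []
        assert final_filter([self._roh(n_var=25, n_hom=25)], params) != []

    def test_minperc_boundary(self):
        params = DetectionParams()
        low = self._roh(n_var=1000, n_hom=879)   # 87.9 %
        ok = self._roh(n_var=1000, n_hom=880)    # 88.0 %
        assert final_filter([low], params) == []
        assert final_filter([ok], params) != []

    def test_minsize_boundary(self):
        params = DetectionParams()
        small = ROH("chr1", 1, MB - 1, 30, 30)
        exact = ROH("chr1", 1, MB, 30, 30)
        assert final_filter([small], params) == []
        assert final_filter([exact], params) != []


class TestDetectEndToEnd:
    @staticmethod
    def _sim(tmp_path, seed=3, noise=0.0):
        cfg = SimConfig(
            seed=seed,
            n_chromosomes=3,
            chrom_length=110 * MB,
            planted_segments=(("chr2", 40 * MB + 1, 50 * MB),),
            in_roh_false_het_rate=noise,
        )
        out = simulate(cfg, tmp_path / f"sim{seed}_{noise}")
        table = read_vcf(out.vcf)
        annot = GenomeAnnotation.load(
            repeats=out.repeat_bed, gaps=out.gap_bed,
            chrom_lengths=out.chrom_lengths,
        )
        return table, annot

    def test_planted_segment_recovered(self, tmp_path):
        table, annot = self._sim(tmp_path)
        rohs = detect(table, annot, FilterParams(min_surviving_variants=0))
        hits = [r for r in rohs if r.chrom == "chr2"]
        assert len(hits) == 1
        (r,) = hits
        overlap = min(r.end, 50 * MB) - max(r.start, 40 * MB + 1) + 1
        assert overlap / (10 * MB) >= 0.95

    def test_noise_calls_do_not_fragment_segment(self, tmp_path):
        table, annot = self._sim(tmp_path, noise=0.05)
        rohs = detect(table, annot, FilterParams(min_surviving_variants=0))
        hits = [r for r in rohs if r.chrom == "chr2"]
        assert len(hits) == 1  # the central fragmentation-resistance claim

    def test_zero_homozygous_input_gives_no_rohs(self):
        table = table_from_pattern("e" * 200)
        annot = annot_for({"chr1": 10 * MB})
        assert detect(table, annot, NO_MIN) == []

    def test_output_disjoint_sorted_and_threshold_compliant(self, tmp_path):
        table, annot = self._sim(tmp_path, seed=9, noise=0.1)
        params = DetectionParams()
        rohs = detect(table, annot, NO_MIN, params)
        assert rohs, "expected at least the planted segment"
        for a, b in zip(rohs, rohs[1:]):
            if a.chrom == b.chrom:
                assert a.end < b.start
        for r in rohs:
            assert r.size >= params.minsize * MB
            assert r.n_variants >= params.minvar
            assert r.perc_homozygous >= params.minperc - 1e-9

    def test_deterministic(self, tmp_path):
        table, annot = self._sim(tmp_path, seed=5)
        assert detect(table, annot, NO_MIN) == detect(table, annot, NO_MIN)

    def test_tightening_final_thresholds_never_adds_rohs(self, tmp_path):
        table, annot = self._sim(tmp_path, seed=5, noise=0.1)
        base = len(detect(table, annot, NO_MIN, DetectionParams()))
        for kwargs in (
            {"minperc": 95.0},
            {"minvar": 60},
            {"minsize": 5.0},
        ):
            tightened = len(
                detect(table, annot, NO_MIN, DetectionParams(**kwargs))
            )
            assert tightened <= base


class TestChrX:
    def _x_table(self):
        calls = [hemi("chrX", 10 * MB + i * 50_000) for i in range(40)]
        return SampleTable("S", calls)

    def test_chrx_excluded_by_default(self):
        annot = annot_for({"chrX": 155 * MB})
        assert detect(self._x_table(), annot, NO_MIN) == []

    def test_hemizygous_counts_as_homozygous_when_included(self):
        annot = annot_for({"chrX": 155 * MB})
        params = DetectionParams(include_chrX=True)
        rohs = detect(self._x_table(), annot, NO_MIN, params)
        assert len(rohs) == 1
        assert rohs[0].n_homozygous == rohs[0].n_variants == 40

    def test_female_x_treated_as_autosome(self):
        # heterozygous-rich X yields no ROH even when included
        table = table_from_pattern("He" * 40, chrom="chrX")
        annot = annot_for({"chrX": 155 * MB})
        params = DetectionParams(include_chrX=True)
        assert detect(table, annot, NO_MIN, params) == []

    def test_infer_sex_heuristic(self):
        assert infer_sex(self._x_table()) == "male"
        assert infer_sex(table_from_pattern("He" * 30, chrom="chrX")) == "female"
        assert infer_sex(table_from_pattern("H" * 5)) == "unknown"


def test_detection_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(windowthres=8, window=7)
    with pytest.raises(ValueError):
        DetectionParams(minperc=101)
    with pytest.raises(ValueError):
        DetectionParams(minsize=0)
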