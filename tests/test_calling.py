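"""Pileup counting, candidate pair filters, VCF whitelist ingestion,
replicate consensus, average-VAF and FFPE filters, cascade invariants."""

import math
from collections import Counter

import numpy as np
import pytest

from amplicall.calling import (
    AmpliconPileup,
    CandidateVariant,
    ConsensusVariant,
    FilterConfig,
    average_vaf_filter,
    call_candidates,
    call_sample,
    consensus,
    ffpe_filter,
    ingest_external_vcf,
    pair_filter_flags,
    pileup,
)
from amplicall.reads import BASES, encode_bases, trim_fragment
from amplicall.sim import SimConfig, build_synthetic_panel, simulate_sample


@pytest.fixture(scope="module")
def small_panel():
    return build_synthetic_panel(n_amplicons=4, per_pool=8, n_sites=2, seed=3)


def make_pileup(amp_id="A", chrom="c1", insert_start=100, ref="ACGT" * 5, depth=3000, alts=()):
    """Hand-built pileup: uniform ref depth, plus (offset, alt, count) spikes."""
    L = len(ref)
    ref_codes = encode_bases(ref)
    counts = np.zeros((L, 6), dtype=np.int64)
    counts[np.arange(L), ref_codes] = depth
    for off, alt, n in alts:
        counts[off, BASES.index(alt)] += n
        counts[off, ref_codes[off]] -= n
    return AmpliconPileup(
        amplicon_id=amp_id,
        chrom=chrom,
        insert_start=insert_start,
        insert_end=insert_start + L,
        ref_codes=ref_codes,
        counts=counts,
    )


class TestPileup:
    def test_error_free_reads_are_all_reference(self, small_panel):
        panel, sites = small_panel
        config = SimConfig(target_depth=200, seq_error_rate=0.0, pcr_error_per_cycle=0.0)
        s = simulate_sample(panel, [], 0.0, config, rng=1)
        for amp in panel.active:
            pu = pileup(s.batches[amp.id], amp, panel)
            ref_counts = pu.counts[np.arange(pu.length), pu.ref_codes]
            assert (ref_counts == pu.depth).all()
            assert (pu.depth > 0).all()

    def test_empty_batch_gives_zero_columns(self, small_panel):
        panel, _ = small_panel
        amp = panel.active[0]
        config = SimConfig(target_depth=200)
        s = simulate_sample(panel, [], 0.0, config, rng=1)
        batch = s.batches[amp.id]
        empty = type(batch)(
            amplicon_id=amp.id, chrom=amp.chrom, start=amp.outer_start, end=amp.outer_end,
            r1=batch.r1[:0], r2=batch.r2[:0],
        )
        pu = pileup(empty, amp, panel)
        assert pu.counts.sum() == 0 and pu.length == amp.insert_length

    def test_injected_site_vaf_within_three_sd(self, small_panel):
        panel, sites = small_panel
        config = SimConfig(target_depth=3000, seq_error_rate=0.0, pcr_error_per_cycle=0.0)
        s = simulate_sample(panel, sites, 0.10, config, rng=2, input_mass_ng=10)
        site = sites[0]
        amp = next(a for a in panel.active if a.insert_start <= site.pos < a.insert_end)
        pu = pileup(s.batches[amp.id], amp, panel)
        depth, vaf = pu.site_stats(site.pos, site.alt)
        sd = math.sqrt(0.05 * 0.95 / depth) + math.sqrt(0.05 * 0.95 / 3030)
        assert abs(vaf - 0.05) < 3 * sd

    def test_brute_force_recount_matches_pileup(self, small_panel):
        # independent oracle: tally trimmed fragment bases position by position
        panel, sites = small_panel
        amp = panel.active[0]
        config = SimConfig(target_depth=40)
        s = simulate_sample(panel, sites, 0.5, config, rng=7)
        batch = s.batches[amp.id]
        pu = pileup(batch, amp, panel)

        oracle = Counter()
        for frag in batch.to_fragments():
            t = trim_fragment(frag, 80)
            for seq, start in ((t.r1_seq, t.r1_start), (t.r2_seq, t.r2_start)):
                for i, base in enumerate(seq):
                    pos = start + i
                    if amp.insert_start <= pos < amp.insert_end:
                        oracle[(pos, base)] += 1
        for i in range(pu.length):
            pos = amp.insert_start + i
            for b, base in enumerate(BASES):
                assert pu.counts[i, b] == oracle.get((pos, base), 0)

    def test_fragment_list_path_equals_batch_path(self, small_panel):
        panel, sites = small_panel
        amp = panel.active[1]
        s = simulate_sample(panel, sites, 0.2, SimConfig(target_depth=30), rng=8)
        batch = s.batches[amp.id]
        pu_batch = pileup(batch, amp, panel)
        pu_frags = pileup(batch.to_fragments(), amp, panel)
        assert np.array_equal(pu_batch.counts, pu_frags.counts)


class TestPairFilters:
    def test_clean_candidate_passes_all_filters(self):
        plasma = make_pileup(alts=[(5, "T", 150)])  # 5% at depth 3000
        normal = make_pileup()
        cands = call_candidates(plasma, normal, FilterConfig())
        assert len(cands) == 1
        c = cands[0]
        assert c.passed and c.plasma_vaf == pytest.approx(0.05) and c.ratio == math.inf

    def test_low_ratio_flagged(self):
        plasma = make_pileup(alts=[(5, "T", 60)])  # 2%
        normal = make_pileup(alts=[(5, "T", 15)])  # 0.5% -> ratio 4
        (c,) = call_candidates(plasma, normal, FilterConfig())
        assert c.flags == {"low_ratio"}

    def test_contaminated_normal_flagged(self):
        plasma = make_pileup(alts=[(5, "T", 300)])  # 10%
        normal = make_pileup(alts=[(5, "T", 36)])  # 1.2%
        (c,) = call_candidates(plasma, normal, FilterConfig())
        assert "normal_contaminated" in c.flags

    def test_low_coverage_flagged(self):
        plasma = make_pileup(depth=90, alts=[(5, "T", 9)])
        normal = make_pileup(depth=3000)
        (c,) = call_candidates(plasma, normal, FilterConfig())
        assert "low_coverage" in c.flags

    def test_coverage_boundary_is_strict(self):
        flags_100 = pair_filter_flags(100, 0.05, 3000, 0.0, FilterConfig())
        flags_101 = pair_filter_flags(101, 0.05, 3000, 0.0, FilterConfig())
        assert "low_coverage" in flags_100 and "low_coverage" not in flags_101

    def test_candidates_below_emission_thresholds_not_emitted(self):
        cfg = FilterConfig()
        plasma = make_pileup(alts=[(2, "T", 2), (7, "T", 10)])  # 2 reads; 0.33%
        normal = make_pileup()
        assert call_candidates(plasma, normal, cfg) == []

    def test_mismatched_amplicons_rejected(self):
        with pytest.raises(ValueError):
            call_candidates(make_pileup(amp_id="A"), make_pileup(amp_id="B"), FilterConfig())


class TestExternalVcf:
    def _write_vcf(self, path, records):
        header = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=c1,length=10000>\n"
            '##FILTER=<ID=clustered_events,Description="x">\n'
            '##FILTER=<ID=panel_of_normals,Description="x">\n'
            '##FILTER=<ID=alt_allele_in_normal,Description="x">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
            '##FORMAT=<ID=AF,Number=A,Type=Float,Description="allele fraction">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL\n"
        )
        path.write_text(header + "".join(records))

    def _rec(self, pos, filt, t_af=0.05, n_af=0.0, dp=3000):
        return f"c1\t{pos}\t.\tA\tT\t.\t{filt}\t.\tDP:AF\t{dp}:{t_af}\t{dp}:{n_af}\n"

    def test_pass_retained(self, tmp_path):
        p = tmp_path / "a.vcf"
        self._write_vcf(p, [self._rec(101, "PASS")])
        cands = ingest_external_vcf(p)
        assert len(cands) == 1 and cands[0].passed and cands[0].pos == 100

    def test_whitelisted_filter_rescued(self, tmp_path):
        p = tmp_path / "b.vcf"
        self._write_vcf(p, [self._rec(101, "clustered_events")])
        assert len(ingest_external_vcf(p)) == 1

    def test_mixed_whitelisted_and_not_dropped(self, tmp_path):
        # ALL failing filters must be whitelisted
        p = tmp_path / "c.vcf"
        self._write_vcf(p, [self._rec(101, "clustered_events;panel_of_normals")])
        assert ingest_external_vcf(p) == []

    def test_retained_records_flow_through_pair_filters(self, tmp_path):
        p = tmp_path / "d.vcf"
        self._write_vcf(p, [self._rec(101, "alt_allele_in_normal", t_af=0.05, n_af=0.02)])
        (c,) = ingest_external_vcf(p)
        assert "normal_contaminated" in c.flags


def make_candidate(rep, pos=110, flags=frozenset(), vaf=0.05):
    return CandidateVariant(
        chrom="c1", pos=pos, ref="A", alt="T", amplicon_id="A", replicate=rep,
        plasma_depth=3000, plasma_vaf=vaf, normal_depth=3000, normal_vaf=0.0, flags=flags,
    )


class TestConsensus:
    @pytest.fixture
    def pileups(self):
        plasma = {
            rep: {"A": make_pileup(insert_start=100, alts=[(10, "T", 150 + 30 * rep)])}
            for rep in range(3)
        }
        normal = {"A": make_pileup(insert_start=100)}
        return plasma, normal

    def test_two_of_three_replicates_retained(self, pileups):
        plasma, normal = pileups
        cands = {0: [make_candidate(0)], 1: [make_candidate(1)], 2: []}
        out = consensus(cands, plasma, normal, FilterConfig())
        assert len(out) == 1 and out[0].replicates_called == 2

    def test_single_replicate_dropped(self, pileups):
        plasma, normal = pileups
        out = consensus({0: [], 1: [make_candidate(1)], 2: []}, plasma, normal, FilterConfig())
        assert out == []

    def test_three_of_three(self, pileups):
        plasma, normal = pileups
        cands = {r: [make_candidate(r)] for r in range(3)}
        (v,) = consensus(cands, plasma, normal, FilterConfig())
        assert v.replicates_called == 3

    def test_failing_candidates_do_not_count_toward_consensus(self, pileups):
        plasma, normal = pileups
        cands = {
            0: [make_candidate(0)],
            1: [make_candidate(1, flags=frozenset({"low_ratio"}))],
            2: [],
        }
        assert consensus(cands, plasma, normal, FilterConfig()) == []

    def test_avg_vaf_is_regenotyped_mean_over_all_replicates(self, pileups):
        plasma, normal = pileups
        # pileups carry 5%, 6%, 7% at the site; candidate called in 2 reps only
        cands = {0: [make_candidate(0)], 1: [make_candidate(1)], 2: []}
        (v,) = consensus(cands, plasma, normal, FilterConfig())
        expected = np.mean([150 / 3000, 180 / 3000, 210 / 3000])
        assert v.avg_vaf == pytest.approx(expected)
        assert v.per_replicate_vafs == pytest.approx((0.05, 0.06, 0.07))


def make_consensus(avg_vaf, normal_vaf=0.0, ref="A", alt="T"):
    return ConsensusVariant(
        chrom="c1", pos=110, ref=ref, alt=alt, amplicon_id="A",
        replicates_called=2, n_replicates=3,
        per_replicate_vafs=(avg_vaf,) * 3, avg_vaf=avg_vaf, avg_depth=3000.0,
        normal_vaf=normal_vaf,
    )


class TestAverageFilter:
    def test_low_avg_vaf_dropped(self):
        assert average_vaf_filter([make_consensus(0.008)], FilterConfig()) == []

    def test_low_avg_ratio_dropped(self):
        v = make_consensus(0.015, normal_vaf=0.004)  # ratio 3.75
        assert average_vaf_filter([v], FilterConfig()) == []
        assert "low_avg_ratio" in v.status

    def test_infinite_ratio_passes(self):
        v = make_consensus(0.05, normal_vaf=0.0)
        assert average_vaf_filter([v], FilterConfig()) == [v]

    def test_or_mode_keeps_single_passing_condition(self):
        v = make_consensus(0.015, normal_vaf=0.004)
        cfg = FilterConfig(avg_filter_mode="or")
        assert average_vaf_filter([v], cfg) == [v]


class TestFfpeFilter:
    @pytest.mark.parametrize(
        "ref,alt,vaf,is_ffpe,kept",
        [
            ("C", "T", 0.10, True, False),
            ("G", "A", 0.10, True, False),
            ("C", "T", 0.20, True, True),
            ("C", "T", 0.15, True, True),  # boundary: keep at exactly 15%
            ("A", "G", 0.10, True, True),
            ("C", "T", 0.10, False, True),
        ],
    )
    def test_deamination_rule(self, ref, alt, vaf, is_ffpe, kept):
        v = make_consensus(vaf, ref=ref, alt=alt)
        out = ffpe_filter([v], is_ffpe, FilterConfig())
        assert (v in out) is kept


@pytest.fixture(scope="module")
def call_inputs():
    panel, sites = build_synthetic_panel(n_amplicons=4, per_pool=8, n_sites=4, seed=5)
    config = SimConfig(target_depth=1500)
    reps = [
        simulate_sample(panel, sites, 0.10, config, rng=100 + r, replicate=r).batches
        for r in range(3)
    ]
    normal = simulate_sample(panel, sites, 0.0, config, role="normal", rng=200).batches
    return panel, reps, normal


class TestCascadeInvariants:
    def test_raising_thresholds_never_increases_survivors(self, call_inputs):
        panel, reps, normal = call_inputs
        base = FilterConfig()
        n_base = len(call_sample(reps, normal, panel, base).variants)
        for stricter in (
            FilterConfig(min_avg_vaf=0.03),
            FilterConfig(min_replicates=3),
            FilterConfig(min_ratio=50.0),
            FilterConfig(min_alt_reads=10),
            FilterConfig(min_alt_fraction=0.02),
            FilterConfig(min_depth=2000),
        ):
            assert len(call_sample(reps, normal, panel, stricter).variants) <= n_base

    def test_average_and_ffpe_filters_commute(self, call_inputs):
        panel, reps, normal = call_inputs
        cfg = FilterConfig()
        res = call_sample(reps, normal, panel, cfg)
        a = ffpe_filter(average_vaf_filter(list(res.consensus), cfg), True, cfg)
        b = average_vaf_filter(ffpe_filter(list(res.consensus), True, cfg), cfg)
        assert {v.key for v in a} == {v.key for v in b}

    def test_truth_sites_called_at_five_percent(self, call_inputs):
        panel, reps, normal = call_inputs
        res = call_sample(reps, normal, panel, FilterConfig())
        panel_sites = build_synthetic_panel(n_amplicons=4, per_pool=8, n_sites=4, seed=5)[1]
        called = {v.key[:2] for v in res.variants}
        for site in panel_sites:
            assert (site.chrom, site.pos) in called
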