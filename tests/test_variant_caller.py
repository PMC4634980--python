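"""Quality screening, threshold/pyro filters, MNV/Repl merging, stats."""

import numpy as np
import pytest

from conftest import make_alignment
from sporeamp._util import round_half_away
from sporeamp.mapping import AlignmentRecord
from sporeamp.variant_caller import (CallerError, CallerParams, VariantCall,
                                     build_pileup, call_variants, caller_stats,
                                     screen_bases)


def screening_oracle(quals, radius=5, min_central=20, min_neigh=15):
    """Exhaustive per-base recomputation of the screening rule."""
    out = []
    n = len(quals)
    for i in range(n):
        window = quals[max(0, i - radius): min(n, i + radius + 1)]
        out.append(quals[i] >= min_central
                   and sum(window) / len(window) >= min_neigh)
    return out


class TestScreenBases:
    def test_low_central_quality_excluded(self, small_reference):
        quals = [40] * 50
        quals[25] = 19
        rec = make_alignment("a", small_reference, 10, [("=", 50)],
                             quality=quals)
        mask = screen_bases([rec])["a"]
        assert not mask[25] and mask[24] and mask[26]

    def test_low_neighborhood_mean_excluded(self, small_reference):
        # q30 base whose 11-base window averages below 15
        quals = [12] * 50
        quals[25] = 30
        rec = make_alignment("a", small_reference, 10, [("=", 50)],
                             quality=quals)
        mask = screen_bases([rec])["a"]
        assert not mask[25]

    def test_matches_bruteforce_oracle(self, small_reference, rng):
        for k in range(20):
            n = int(rng.integers(12, 80))
            quals = [int(q) for q in rng.integers(0, 41, n)]
            rec = make_alignment(f"r{k}", small_reference, 5, [("=", n)],
                                 quality=quals)
            mask = screen_bases([rec])[f"r{k}"]
            assert list(mask) == screening_oracle(quals)

    def test_missing_qualities_rejected(self, small_reference):
        rec = AlignmentRecord("x", True, 1, [("=", 10)], 1.0, 1.0,
                              small_reference[:10], [])
        with pytest.raises(CallerError, match="qualit"):
            screen_bases([rec])


def snv_reads(reference, pos, alt, n_alt, n_ref, start=None, length=60):
    """n_ref exact reads + n_alt reads carrying an SNV, all covering pos."""
    start = start or max(1, pos - length // 2)
    out = []
    ref_piece = reference[start - 1 : start - 1 + length]
    for i in range(n_ref):
        out.append(make_alignment(f"ref{pos}_{i}", reference, start,
                                  [("=", length)]))
    off = pos - start
    alt_seq = ref_piece[:off] + alt + ref_piece[off + 1:]
    for i in range(n_alt):
        out.append(AlignmentRecord(f"alt{pos}_{i}", True, start,
                                   [("=", off), ("X", 1),
                                    ("=", length - off - 1)],
                                   1.0, 1.0, alt_seq, [35] * length))
    return out


class TestThresholds:
    def test_basic_snv_frequency(self, small_reference):
        ref = small_reference
        calls = call_variants(snv_reads(ref, 100, "T" if ref[99] != "T" else "A",
                                        5, 95), ref)
        assert len(calls) == 1
        c = calls[0]
        assert (c.type, c.count, c.coverage) == ("SNV", 5, 100)
        assert c.frequency == pytest.approx(5.0)

    def test_low_coverage_suppresses_call(self, small_reference):
        ref = small_reference
        alt = "T" if ref[99] != "T" else "A"
        calls = call_variants(snv_reads(ref, 100, alt, 4, 4), ref)
        assert calls == []

    def test_low_frequency_suppresses_call(self, small_reference):
        ref = small_reference
        alt = "T" if ref[99] != "T" else "A"
        calls = call_variants(snv_reads(ref, 100, alt, 1, 199), ref)
        assert calls == []  # 0.5% < 1%

    def test_frequency_monotonicity(self, small_reference):
        ref = small_reference
        alt = "T" if ref[99] != "T" else "A"
        reads = snv_reads(ref, 100, alt, 3, 97) + \
            snv_reads(ref, 200, "A" if ref[199] != "A" else "C", 30, 70)
        prev = None
        for mvf in (1, 2, 5, 20, 40):
            n = len(call_variants(reads, ref,
                                  CallerParams(min_variant_frequency=mvf)))
            if prev is not None:
                assert n <= prev
            prev = n

    def test_screened_bases_reduce_coverage(self, small_reference):
        ref = small_reference
        alt = "T" if ref[99] != "T" else "A"
        reads = snv_reads(ref, 100, alt, 5, 95)
        # blind 50 of the reference reads at the variant position
        for rec in reads[:50]:
            rec.qualities[100 - rec.ref_start] = 5
        calls = call_variants(reads, ref)
        assert calls[0].coverage == 50
        assert calls[0].frequency == pytest.approx(10.0)


def indel_reads(reference, anchor, deleted_len, n_alt, n_ref, length=60):
    """Reads with a deletion of ``deleted_len`` bases right of ``anchor``."""
    start = max(1, anchor - length // 2)
    out = [make_alignment(f"ref{i}", reference, start, [("=", length)])
           for i in range(n_ref)]
    off = anchor - start + 1
    ops = [("=", off), ("D", deleted_len), ("=", length - off)]
    seq = (reference[start - 1 : anchor]
           + reference[anchor + deleted_len : start - 1 + length + deleted_len])
    for i in range(n_alt):
        out.append(AlignmentRecord(f"del{i}", True, start, list(ops), 1.0, 1.0,
                                   seq, [35] * len(seq)))
    return out


class TestPyroFilter:
    @pytest.fixture()
    def run_reference(self):
        rng = np.random.default_rng(17)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        # plant an AAAA run at positions 151-154 with distinct neighbours
        return base[:150].replace("AA", "AC") + "GAAAAT" + base[156:].replace("AA", "AC")

    def test_low_frequency_homopolymer_deletion_removed(self, run_reference):
        ref = run_reference
        assert ref[151:155] == "AAAA"
        reads = indel_reads(ref, 152, 1, 2, 98)  # 2% del of one A in the run
        assert call_variants(reads, ref) == []

    def test_high_frequency_homopolymer_deletion_retained(self, run_reference):
        ref = run_reference
        reads = indel_reads(ref, 152, 1, 85, 15)
        calls = call_variants(reads, ref)
        assert len(calls) == 1 and calls[0].type == "Del"
        assert calls[0].frequency == pytest.approx(85.0)

    def test_filter_can_be_disabled(self, run_reference):
        ref = run_reference
        reads = indel_reads(ref, 152, 1, 5, 95)
        calls = call_variants(reads, ref,
                              CallerParams(pyro_filter_enabled=False))
        assert len(calls) == 1 and calls[0].type == "Del"

    def test_non_homopolymer_indel_not_filtered(self, run_reference):
        ref = run_reference
        # find an anchor whose following base is not in any >=3 run
        anchor = 40
        while ref[anchor] == ref[anchor + 1] or ref[anchor + 1] == ref[anchor + 2]:
            anchor += 1
        reads = indel_reads(ref, anchor, 1, 5, 95)
        calls = call_variants(reads, ref)
        assert len(calls) == 1 and calls[0].type == "Del"
        assert calls[0].frequency == pytest.approx(5.0)

    def test_deletion_left_aligned_in_run(self, run_reference):
        ref = run_reference
        # delete the *last* A of the run; the call must anchor left of the run
        reads = indel_reads(ref, 154, 1, 90, 10)
        calls = call_variants(reads, ref)
        assert len(calls) == 1
        assert calls[0].pos == 151  # anchor = base left of the AAAA run


class TestMnvMerging:
    def _mnv_setup(self, small_reference, linked):
        """100 reads; 10 carry alt at pos 100 and 10 at pos 101 — on the same
        reads when linked, on disjoint reads otherwise."""
        ref = small_reference
        start, length = 70, 60
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        a1, a2 = flip[ref[99]], flip[ref[100]]
        piece = ref[start - 1 : start - 1 + length]
        reads = [make_alignment(f"wt{i}", ref, start, [("=", length)])
                 for i in range(80)]
        def alt_read(rid, alts):
            s = list(piece)
            ops = []
            for off in range(length):
                pos = start + off
                if pos in alts:
                    s[off] = alts[pos]
            seq = "".join(s)
            ops = []
            for off, ch in enumerate(seq):
                kind = "=" if ch == piece[off] else "X"
                if ops and ops[-1][0] == kind:
                    ops[-1] = (kind, ops[-1][1] + 1)
                else:
                    ops.append((kind, 1))
            return AlignmentRecord(rid, True, start, ops, 1.0, 1.0, seq,
                                   [35] * length)
        if linked:
            reads += [alt_read(f"mv{i}", {100: a1, 101: a2}) for i in range(10)]
            reads += [make_alignment(f"wt2_{i}", ref, start, [("=", length)])
                      for i in range(10)]
        else:
            reads += [alt_read(f"m1_{i}", {100: a1}) for i in range(10)]
            reads += [alt_read(f"m2_{i}", {101: a2}) for i in range(10)]
        return ref, reads, a1, a2

    def test_linked_adjacent_snvs_merge_to_mnv(self, small_reference):
        ref, reads, a1, a2 = self._mnv_setup(small_reference, linked=True)
        calls = call_variants(reads, ref)
        assert [c.type for c in calls] == ["MNV"]
        c = calls[0]
        assert (c.pos, c.alt) == (100, a1 + a2)
        assert c.count == 10 and c.coverage == 100

    def test_unlinked_adjacent_snvs_stay_separate(self, small_reference):
        ref, reads, a1, a2 = self._mnv_setup(small_reference, linked=False)
        calls = call_variants(reads, ref)
        assert [c.type for c in calls] == ["SNV", "SNV"]
        assert {c.pos for c in calls} == {100, 101}

    def test_merged_constituents_not_reported(self, small_reference):
        ref, reads, a1, a2 = self._mnv_setup(small_reference, linked=True)
        calls = call_variants(reads, ref)
        snv_keys = {(c.pos, c.alt) for c in calls if c.type == "SNV"}
        assert (100, a1) not in snv_keys and (101, a2) not in snv_keys


class TestReplMerging:
    def test_same_anchor_del_plus_ins_becomes_repl(self, small_reference):
        ref = small_reference
        start, length, anchor = 70, 60, 100
        off = anchor - start + 1
        # reads delete 2 bases after the anchor and insert one 'T'
        ins_base = "T" if ref[anchor] != "T" else "G"
        seq = (ref[start - 1 : anchor] + ins_base
               + ref[anchor + 2 : start - 1 + length + 1])
        ops = [("=", off), ("I", 1), ("D", 2), ("=", length - off - 1)]
        reads = [make_alignment(f"wt{i}", ref, start, [("=", length)])
                 for i in range(60)]
        reads += [AlignmentRecord(f"rp{i}", True, start, list(ops), 1.0, 1.0,
                                  seq, [35] * len(seq)) for i in range(40)]
        calls = call_variants(reads, ref)
        repl = [c for c in calls if c.type == "Repl"]
        assert len(repl) == 1
        c = repl[0]
        # representation may be normalised (left-aligned); applying the call
        # must reproduce the variant haplotype
        applied = ref[: c.pos - 1] + c.alt + ref[c.pos - 1 + len(c.ref):]
        expected_hap = ref[:anchor] + ins_base + ref[anchor + 2:]
        assert applied == expected_hap
        assert c.count == 40
        # no residual standalone Ins/Del at that anchor
        assert not [x for x in calls if x.type in ("Ins", "Del")]


class TestInvariantsAndStats:
    def test_no_emitted_call_violates_thresholds(self, small_reference, rng):
        ref = small_reference
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        reads = []
        for k in range(150):
            s = int(rng.integers(1, 320))
            length = 70
            piece = list(ref[s - 1 : s - 1 + length])
            quals = [int(q) for q in rng.integers(8, 41, length)]
            for p in rng.integers(0, length, int(rng.integers(0, 4))):
                piece[p] = flip[piece[p]]
            ops = []
            for off, ch in enumerate(piece):
                kind = "=" if ch == ref[s - 1 + off] else "X"
                if ops and ops[-1][0] == kind:
                    ops[-1] = (kind, ops[-1][1] + 1)
                else:
                    ops.append((kind, 1))
            reads.append(AlignmentRecord(f"r{k}", True, s, ops, 1.0, 1.0,
                                         "".join(piece), quals))
        params = CallerParams()
        calls = call_variants(reads, ref, params)
        for c in calls:
            assert c.coverage >= params.min_coverage
            assert c.frequency >= params.min_variant_frequency
            assert c.count <= c.coverage
            assert round_half_away(c.frequency * c.coverage / 100) == c.count

    def test_supporting_bases_all_pass_screening(self, small_reference, rng):
        ref = small_reference
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        reads = snv_reads(ref, 150, flip[ref[149]], 20, 80)
        for rec in reads:
            rec.qualities[:] = [int(q) for q in rng.integers(10, 41, len(rec.qualities))]
        calls = call_variants(reads, ref)
        masks = screen_bases(reads)
        for c in calls:
            for rec in reads:
                if rec.read_id in c.supporting:
                    idx = c.pos - rec.ref_start
                    assert masks[rec.read_id][idx]

    def test_empty_alignments_empty_calls(self, small_reference):
        assert call_variants([], small_reference) == []

    def test_caller_stats_rounding(self):
        calls = [VariantCall(1, "SNV", "A", "T", 1, 10, 10.0),
                 VariantCall(2, "Del", "T", "", 1, 20, 5.0)]
        st = caller_stats(calls)
        assert st["average_variant_coverage"] == 15
        assert st["average_snv_coverage"] == 10

    def test_caller_stats_empty_is_absent(self):
        st = caller_stats([])
        assert st["average_variant_coverage"] is None
        assert st["average_snv_coverage"] is None

    def test_printed_per_spore_coverages_average_correctly(self):
        variant_cov = [5598, 276, 9308, 436, 4847, 3282, 4509, 2861, 3585]
        snv_cov = [4714, 226, 8707, 381, 4297, 3028, 3810, 2689, 3485]
        assert round_half_away(sum(variant_cov) / 9) == 3856
        assert round_half_away(sum(snv_cov) / 9) == 3482


class TestDetectionPower:
    def test_common_variant_called_rare_one_not(self):
        """Error-free coverage 1000: a 5% variant is called within its
        binomial interval; a 0.2% variant is never called."""
        from scipy.stats import binom
        from sporeamp.synthetic_data import (ReadSimConfig, VariantSpec,
                                             panel_from_assignments,
                                             simulate_reads)
        from sporeamp.mapping import map_all

        rng = np.random.default_rng(2)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        v5 = VariantSpec(60, "SNV", ref[59], flip[ref[59]], "spore:S", 0.05)
        v02 = VariantSpec(140, "SNV", ref[139], flip[ref[139]], "spore:S", 0.002)
        assignments = {"S": [(v5, frozenset(range(50))),
                             (v02, frozenset(range(998, 1000)))]}
        panel = panel_from_assignments(ref, {"I": ["S"]}, [v5, v02],
                                       assignments, n_nuclei=1000)
        cfg = ReadSimConfig(n_reads=1000, read_length_mean=200,
                            read_length_sd=0, substitution_errors=False,
                            homopolymer_indel_rate=0.0, seed=9)
        reads = simulate_reads(panel, "S", cfg)
        recs, _ = map_all(reads, ref)
        calls = call_variants([r for r in recs if r.mapped], ref)
        by_pos = {c.pos: c for c in calls}
        assert 60 in by_pos and 140 not in by_pos
        c = by_pos[60]
        lo = binom.ppf(0.0005, c.coverage, 0.05)
        hi = binom.ppf(0.9995, c.coverage, 0.05)
        assert lo <= c.count <= hi
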