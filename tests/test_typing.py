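"""Genotyping engine: alignment, consensus, pair scoring, calling."""

import numpy as np
import pytest

import amplitype as at
from amplitype.alleles import AlleleRecord, parse_allele_name
from amplitype.simulate import (
    DEFAULT_ERROR_MODEL, DepthModel, SampleTruth, SimTruth, intron_variant,
    make_barcode_set, make_cohort, repeat_mask_for, simulate_read,
    simulate_run,
)
from amplitype.typing_engine import (
    DepthError, TypingParams, adjudicate_with_mask, align_read,
    build_consensus, call_genotype, find_hotspots, orient_and_trim,
    rescore_masked, score_pair, shortlist_alleles, _rank_key,
)
from conftest import reads_of_sample


def hw_edit_distance(query: str, target: str) -> int:
    """Independent quadratic-DP oracle: semi-global edit distance with
    free end gaps on the target (query fully consumed)."""
    m = len(target)
    prev = [0] * (m + 1)
    for i, qc in enumerate(query, 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(prev[j - 1] + (qc != target[j - 1]),
                         prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


def _tiny_record(seq, name="B*99:01"):
    L = len(seq)
    return AlleleRecord(parse_allele_name(name), seq,
                        exon2=(0, L // 3), exon3=(L // 2, L - 1))


class TestAlignRead:
    def test_identity(self, allele_set):
        rec = allele_set[0]
        aln = align_read(rec.amplicon_seq, rec)
        assert aln.distance == 0
        assert aln.mismatch_positions == []

    def test_single_deletion(self, allele_set):
        rec = allele_set[0]
        read = rec.amplicon_seq[:500] + rec.amplicon_seq[501:]
        aln = align_read(read, rec)
        assert aln.distance == 1
        assert aln.n_ops == {"del": 1}

    def test_empty_read_rejected(self, allele_set):
        with pytest.raises(ValueError):
            align_read("", allele_set[0])

    def test_distance_components_sum(self, allele_set):
        rng = np.random.default_rng(0)
        rec = allele_set[0]
        for _ in range(20):
            sim = simulate_read(rec.amplicon_seq, DEFAULT_ERROR_MODEL, rng)
            aln = align_read(sim.seq, rec)
            assert aln.distance == sum(aln.n_ops.values())

    def test_matches_dp_oracle_on_random_pairs(self):
        """Edit distances equal an independent DP on 1,000 random pairs."""
        rng = np.random.default_rng(1)
        for _ in range(1000):
            read = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
            ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
            rec = _tiny_record(ref)
            assert align_read(read, rec).distance == hw_edit_distance(read, ref)


class TestOrientAndTrim:
    def test_plus_strand_template_trimmed_to_amplicon(self, allele_set,
                                                      barcodes):
        tpl = at.make_barcoded_template(allele_set[0], barcodes["BC01"])
        trimmed, strand = orient_and_trim(tpl.sequence)
        assert strand == "+"
        assert trimmed == allele_set[0].amplicon_seq

    def test_minus_strand_recovered(self, allele_set, barcodes):
        tpl = at.make_barcoded_template(allele_set[0], barcodes["BC01"])
        trimmed, strand = orient_and_trim(at.reverse_complement(tpl.sequence))
        assert strand == "-"
        assert trimmed == allele_set[0].amplicon_seq

    def test_primerless_read_left_untouched(self):
        seq = "ACGT" * 100
        trimmed, strand = orient_and_trim(seq)
        assert (trimmed, strand) == (seq, "?")


class TestShortlist:
    def test_error_free_reads_vote_true_pair(self, allele_set):
        a, b = allele_set[0], allele_set[3]
        reads = [a.amplicon_seq] * 5 + [b.amplicon_seq] * 5
        names = {str(r.name) for r in shortlist_alleles(reads, allele_set, k=3)}
        assert {str(a.name), str(b.name)} <= names

    def test_large_k_returns_whole_set(self, allele_set):
        reads = [allele_set[0].amplicon_seq] * 3
        out = shortlist_alleles(reads, allele_set, k=99)
        assert len(out) == len(allele_set)

    def test_no_reads_rejected(self, allele_set):
        with pytest.raises(ValueError):
            shortlist_alleles([], allele_set)

    def test_true_pair_survives_noise(self, allele_set):
        """Noisy reads at the default error model still vote the pair in."""
        rng = np.random.default_rng(2)
        a, b = allele_set[1], allele_set[6]
        hits = 0
        for _ in range(20):
            reads = [simulate_read(t.amplicon_seq, DEFAULT_ERROR_MODEL,
                                   rng).seq
                     for t in ([a] * 10 + [b] * 10)]
            names = {str(r.name)
                     for r in shortlist_alleles(reads, allele_set, k=6)}
            hits += {str(a.name), str(b.name)} <= names
        assert hits >= 19


class TestConsensus:
    def test_identity_on_error_free_reads(self, allele_set):
        rec = allele_set[0]
        cons = build_consensus([rec.amplicon_seq] * 5, rec)
        assert cons.sequence == rec.amplicon_seq
        assert cons.events == [] and cons.mixed == []

    def test_minority_substitution_outvoted(self, allele_set):
        rec = allele_set[0]
        mutated = list(rec.amplicon_seq)
        mutated[100] = "A" if mutated[100] != "A" else "C"
        reads = [rec.amplicon_seq] * 3 + ["".join(mutated)]
        cons = build_consensus(reads, rec)
        assert cons.sequence == rec.amplicon_seq

    def test_majority_substitution_wins(self, allele_set):
        rec = allele_set[0]
        mutated = list(rec.amplicon_seq)
        mutated[100] = "A" if mutated[100] != "A" else "C"
        cons = build_consensus(["".join(mutated)] * 5 + [rec.amplicon_seq],
                               rec)
        assert cons.events == [("sub", 100, mutated[100])]

    def test_fifty_fifty_mixture_flagged_mixed(self, allele_set):
        """A balanced heterozygous column stays on the reference but is
        reported as mixed — the pileup analogue of an IUPAC code."""
        rec = allele_set[0]
        mutated = list(rec.amplicon_seq)
        mutated[100] = "A" if mutated[100] != "A" else "C"
        cons = build_consensus(["".join(mutated)] * 4 + [rec.amplicon_seq] * 4,
                               rec)
        assert cons.sequence == rec.amplicon_seq
        assert [c for c, _ in cons.mixed] == [100]

    def test_noisy_consensus_converges(self, allele_set):
        """50 default-noise reads reconstruct the template outside STRs."""
        rng = np.random.default_rng(3)
        rec = allele_set[2]
        reads = [simulate_read(rec.amplicon_seq, DEFAULT_ERROR_MODEL, rng).seq
                 for _ in range(50)]
        cons = build_consensus(reads, rec)
        assert cons.sequence == rec.amplicon_seq
        assert cons.events == []


class TestScorePair:
    def test_error_free_true_pair_scores_zero(self, allele_set):
        a, b = allele_set[0], allele_set[3]
        reads = [a.amplicon_seq] * 6 + [b.amplicon_seq] * 6
        ps = score_pair(reads, a, b)
        assert ps.total == 0
        assert (ps.n_a, ps.n_b, ps.n_unassigned) == (6, 6, 0)

    def test_wrong_member_shows_planted_differences(self, allele_set):
        """Scoring the reads against a wrong allele with >= 4 planted exon
        differences surfaces at least that many mismatches."""
        a, b, c = allele_set[0], allele_set[3], allele_set[5]
        reads = [a.amplicon_seq] * 6 + [b.amplicon_seq] * 6
        ps = score_pair(reads, a, c)
        assert ps.total >= 4

    def test_symmetry(self, allele_set):
        a, b = allele_set[1], allele_set[4]
        reads = [a.amplicon_seq] * 5 + [b.amplicon_seq] * 5
        assert (score_pair(reads, a, b).total
                == score_pair(reads, b, a).total)
        assert score_pair(reads, a, b).pair == score_pair(reads, b, a).pair

    def test_dropout_demoted_to_homozygote(self, allele_set):
        a, b = allele_set[0], allele_set[3]
        reads = [a.amplicon_seq] * 19 + [b.amplicon_seq]  # 5% minor
        ps = score_pair(reads, a, b)
        assert ps.is_homozygous and ps.a == str(a.name)
        assert ps.demoted_from == (str(a.name), str(b.name))

    def test_self_pair_on_het_reads_shows_mixture(self, allele_set):
        """The homozygous hypothesis cannot explain balanced het reads."""
        a, b = allele_set[0], allele_set[3]
        reads = [a.amplicon_seq] * 6 + [b.amplicon_seq] * 6
        ps = score_pair(reads, a, a)
        assert ps.total >= 2 * 4  # both slots see the het columns


class TestCallGenotype:
    def test_simulated_het_at_depth_80(self, allele_set, ggroups):
        """Depth 80 with the default error model recovers the true pair."""
        a, b = allele_set[8], allele_set[6]  # emulates a worst-depth het
        truth = SimTruth(
            samples={"S001": SampleTruth(str(a.name), str(b.name), "BC01")},
            barcodes={"BC01": make_barcode_set(1)["BC01"]})
        run = simulate_run(truth, allele_set,
                           depth_model=DepthModel.constant(80), seed=21)
        reads = reads_of_sample(run, "S001")
        call = call_genotype(reads, allele_set, ggroups, sample_id="S001")
        assert call.best.pair == tuple(sorted((str(a.name), str(b.name))))
        assert call.zygosity == "heterozygous"

    def test_simulated_homozygote(self, allele_set, ggroups):
        truth = make_cohort(allele_set, 1, homozygote_rate=1.0, seed=5)
        run = simulate_run(truth, allele_set,
                           depth_model=DepthModel.constant(60), seed=6)
        st = truth.samples["S001"]
        call = call_genotype(reads_of_sample(run, "S001"), allele_set, ggroups)
        assert call.zygosity == "homozygous"
        assert call.best.pair == (st.allele_a, st.allele_a)

    def test_low_depth_refused_and_overridable(self, allele_set):
        reads = [allele_set[0].amplicon_seq] * 4
        with pytest.raises(DepthError):
            call_genotype(reads, allele_set)
        call = call_genotype(reads, allele_set, allow_low_depth=True)
        assert call.best.pair == (str(allele_set[0].name),) * 2

    def test_zero_error_completeness(self, allele_set, ggroups):
        """Error-free reads from any distinct pair give the exact pair,
        zero mismatches and no ambiguity."""
        for i, j in ((0, 3), (1, 6), (2, 9), (4, 5)):
            a, b = allele_set[i], allele_set[j]
            reads = [a.amplicon_seq] * 10 + [b.amplicon_seq] * 10
            call = call_genotype(reads, allele_set, ggroups,
                                 pre_trimmed=True)
            assert call.best.pair == tuple(sorted((str(a.name), str(b.name))))
            assert call.best.total == 0
            assert not call.ambiguous
            assert not call.manual_review

    def test_ggroup_tie_flagged_and_reported_as_group(self, allele_set,
                                                      ggroups):
        """An allele with an intron-only variant in the reference set makes
        two co-best pairs that collapse to one reported G-group name."""
        a1 = allele_set[0]
        a2 = intron_variant(a1, "B*07:02:55")
        b = allele_set[3]
        refs = [a1, a2, b] + list(allele_set[4:6])
        gmap = at.build_ggroups(refs)
        reads = [a1.amplicon_seq] * 10 + [b.amplicon_seq] * 10
        call = call_genotype(reads, refs, gmap, pre_trimmed=True)
        assert call.ambiguous
        assert call.best.total == 0
        assert set(call.reported) == {"B*07:02:01G", str(b.name)}

    def test_matches_bruteforce_enumeration(self, allele_set):
        """With k = |set| the ranked pair list equals exhaustive
        enumeration over all unordered pairs, independently sorted."""
        import itertools

        refs = allele_set[:6]
        rng = np.random.default_rng(4)
        a, b = refs[1], refs[4]
        reads = [simulate_read(t.amplicon_seq, DEFAULT_ERROR_MODEL, rng).seq
                 for t in ([a] * 20 + [b] * 20)]
        call = call_genotype(reads, refs, params=TypingParams(k=len(refs)),
                             pre_trimmed=True)
        oracle = {}
        for x, y in itertools.combinations_with_replacement(
                sorted(refs, key=lambda r: str(r.name)), 2):
            ps = score_pair(reads, x, y)
            oracle.setdefault(ps.pair, ps)
        expected = sorted(oracle.values(), key=_rank_key)
        assert [(p.pair, p.total) for p in call.ranked] \
            == [(p.pair, p.total) for p in expected]


class TestHotspotsAndMasking:
    def test_error_free_reads_no_hotspots(self, allele_set, repeat_mask):
        a, b = allele_set[0], allele_set[3]
        reads = [a.amplicon_seq] * 12 + [b.amplicon_seq] * 12
        call = call_genotype(reads, allele_set, pre_trimmed=True,
                             repeat_mask=repeat_mask)
        assert call.hotspots == []

    def test_hotspot_positions_within_exon_bounds(self, small_run,
                                                  allele_set, repeat_mask):
        truth, run = small_run
        by_name = {str(r.name): r for r in allele_set}
        for sample in list(truth.samples)[:3]:
            call = call_genotype(reads_of_sample(run, sample), allele_set,
                                 repeat_mask=repeat_mask)
            for h in call.hotspots:
                rec = allele_set[0]
                span = rec.exon2 if h.exon == "exon2" else rec.exon3
                assert 1 <= h.position <= span[1] - span[0]

    def test_empty_mask_identity(self, allele_set):
        a, b = allele_set[0], allele_set[3]
        reads = [a.amplicon_seq] * 6 + [b.amplicon_seq] * 6
        assert (rescore_masked(reads, a, b, {}).total
                == score_pair(reads, a, b).total)

    def test_masked_total_never_exceeds_unmasked(self, small_run, allele_set,
                                                 repeat_mask):
        truth, run = small_run
        by_name = {str(r.name): r for r in allele_set}
        for sample in list(truth.samples)[:4]:
            st = truth.samples[sample]
            reads = [orient_and_trim(r)[0]
                     for r in reads_of_sample(run, sample)]
            a, b = sorted((st.allele_a, st.allele_b))
            plain = score_pair(reads, by_name[a], by_name[b])
            masked = rescore_masked(reads, by_name[a], by_name[b],
                                    repeat_mask)
            assert masked.total <= plain.total

    def test_planted_repeat_artifact_adjudicated(self, allele_set, ggroups,
                                                 repeat_mask):
        """Samples carrying the nt-133 G variant accumulate boosted
        deletions in the (GA)3 tract; the recurring mismatch is flagged
        repeat-associated and masked rescoring recovers the true pair."""
        pairs = [(0, 5), (2, 1), (4, 3)]  # each pair has one G-133 allele
        rng_base = 31
        found_repeat_hotspot = False
        for n, (i, j) in enumerate(pairs):
            a, b = allele_set[i], allele_set[j]
            truth = SimTruth(
                samples={"S001": SampleTruth(str(a.name), str(b.name),
                                             "BC01")},
                barcodes={"BC01": make_barcode_set(1)["BC01"]})
            run = simulate_run(truth, allele_set,
                               depth_model=DepthModel.constant(120),
                               seed=rng_base + n)
            reads = reads_of_sample(run, "S001")
            call = call_genotype(reads, allele_set, ggroups,
                                 repeat_mask=repeat_mask)
            true_pair = tuple(sorted((str(a.name), str(b.name))))
            if any(h.repeat_associated for h in call.hotspots):
                found_repeat_hotspot = True
            adj_pair, adj_score = adjudicate_with_mask(
                call, reads, allele_set, repeat_mask)
            assert adj_pair == true_pair
            assert adj_score.total <= call.best.total
        assert found_repeat_hotspot
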