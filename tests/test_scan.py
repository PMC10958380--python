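"""Proteome scanning: FASTA I/O, window scanning vs a naive oracle,
nonamer completion, curation, ranking and the analytic background rate."""

import math
import random

import numpy as np
import pytest

from mimoscan.motif import (
    AMINO_ACIDS,
    Peptide,
    PositionFrequencyModel,
    build_frequency_model,
    compile_search_patterns,
    matches,
)
from mimoscan.scan import (
    CurationRuleSet,
    MotifHit,
    ProteinRecord,
    ScanError,
    annotate_hla_binding,
    complete_nonamer,
    curate_hits,
    dedup_nonamers,
    expected_background_match_rate,
    hits_from_tsv,
    hits_to_tsv,
    rank_hits,
    read_fasta,
    scan_proteome,
    write_fasta,
)
from conftest import WHEAT1


def naive_scan_oracle(sequence, motif):
    """Window-by-window re-implementation of the scanner."""
    hits = []
    for start in range(len(sequence) - 7):
        window = sequence[start:start + 8]
        if set(window) - set(AMINO_ACIDS):
            continue
        if matches(Peptide(window), motif).matched:
            hits.append(start)
    return hits


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

class TestFastaIO:
    def test_two_record_file_round_trips(self, tmp_path):
        path = tmp_path / "two.fasta"
        path.write_text(
            ">prot1 first protein\nAAALRMRR\nCRRMAAA\n>prot2\nMKVLITRA\n"
        )
        records = read_fasta(path)
        assert [r.id for r in records] == ["prot1", "prot2"]
        assert records[0].sequence == "AAALRMRRCRRMAAA"  # wrapped lines joined
        out = tmp_path / "out.fasta"
        write_fasta(records, out)
        assert read_fasta(out) == records

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert read_fasta(path) == []

    def test_malformed_header_error_names_the_line(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text("ACDEFGHIK\n>ok\nMKV\n")
        with pytest.raises(ScanError, match=":1"):
            read_fasta(path)
        path.write_text(">ok\nMKV\n>\nACD\n")
        with pytest.raises(ScanError, match=":3"):
            read_fasta(path)

    def test_stop_codons_stripped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "stops.fasta"
        path.write_text(">p\nMKVLITRA*\n")
        with caplog.at_level("WARNING"):
            records = read_fasta(path)
        assert records[0].sequence == "MKVLITRA"
        assert any("stop" in r.message for r in caplog.records)

    def test_sequences_are_uppercased(self, tmp_path):
        path = tmp_path / "lower.fasta"
        path.write_text(">p\nmkvlitra\n")
        assert read_fasta(path)[0].sequence == "MKVLITRA"


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

class TestScanProteome:
    def test_wheat1_octamer_found_at_known_offset(self, canonical_motif):
        protein = ProteinRecord(id="p", description="p", sequence="AAALRMRRCRRMAAA")
        hits = scan_proteome([protein], canonical_motif)
        assert len(hits) == 1
        assert hits[0].start == 4
        assert hits[0].octamer.sequence == "RMRRCRRM"

    def test_empty_proteome_yields_no_hits(self, canonical_motif):
        assert scan_proteome([], canonical_motif) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_naive_oracle_on_random_sequences(self, canonical_motif, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(1000))
        # salt with real instances so the comparison is not vacuous
        for pos in (100, 500, 900):
            seq = seq[:pos] + WHEAT1 + seq[pos + 9:]
        protein = ProteinRecord(id=f"r{seed}", description="", sequence=seq)
        got = [h.start for h in scan_proteome([protein], canonical_motif)]
        assert got == naive_scan_oracle(seq, canonical_motif)
        assert len(got) >= 3

    def test_ambiguity_codes_skip_the_window(self, canonical_motif):
        hit_seq = "A" + WHEAT1 + "A"
        broken = hit_seq.replace("C", "X")  # X inside the only match window
        assert scan_proteome(
            [ProteinRecord(id="ok", description="", sequence=hit_seq)], canonical_motif
        )
        assert not scan_proteome(
            [ProteinRecord(id="amb", description="", sequence=broken)], canonical_motif
        )

    def test_overlapping_hits_all_reported(self, canonical_motif):
        # RMRRCRRL + RL tail creates two overlapping octamer matches
        seq = "A" + "RMRRCRRLRL"
        expected = naive_scan_oracle(seq, canonical_motif)
        got = [h.start for h in scan_proteome(
            [ProteinRecord(id="o", description="", sequence=seq)], canonical_motif
        )]
        assert got == expected
        assert len(got) >= 2

    def test_pattern_list_scan_is_union_of_single_pattern_scans(self, canonical_motif):
        patterns = compile_search_patterns(canonical_motif, "cartesian")
        rng = random.Random(5)
        seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(2000))
        seq = seq[:50] + WHEAT1 + seq[59:]
        protein = ProteinRecord(id="u", description="", sequence=seq)
        union = set()
        for pat in patterns:
            union |= {h.start for h in scan_proteome([protein], [pat])}
        combined = {h.start for h in scan_proteome([protein], patterns)}
        assert combined == union
        # and the cartesian pattern set is equivalent to the motif itself
        assert combined == {h.start for h in scan_proteome([protein], canonical_motif)}

    def test_deterministic_order_protein_then_offset(self, canonical_motif):
        seqs = {"b": "A" + WHEAT1, "a": WHEAT1 + "A" + WHEAT1}
        proteins = [ProteinRecord(id=k, description="", sequence=v)
                    for k, v in seqs.items()]
        hits = scan_proteome(proteins, canonical_motif)
        assert [(h.protein_id, h.start) for h in hits] == \
            [("b", 2), ("a", 1), ("a", 11)]


# ---------------------------------------------------------------------------
# Nonamer completion
# ---------------------------------------------------------------------------

class TestCompleteNonamer:
    def test_p1_supplemented_from_flanking_sequence(self, canonical_motif):
        protein = ProteinRecord(id="p", description="", sequence="AAALRMRRCRRMAAA")
        [hit] = scan_proteome([protein], canonical_motif)
        done = complete_nonamer(hit, protein)
        assert done.nonamer.sequence == WHEAT1
        assert done.p1_residue == "L"

    def test_offset_zero_keeps_octamer_only_with_flag(self, canonical_motif):
        protein = ProteinRecord(id="p", description="", sequence="RMRRCRRMAAA")
        [hit] = scan_proteome([protein], canonical_motif)
        assert hit.start == 0
        done = complete_nonamer(hit, protein)
        assert done.nonamer is None
        assert "no_P1" in done.curation_flags

    def test_substring_invariant_on_random_fixtures(self, canonical_motif):
        rng = random.Random(11)
        for _ in range(20):
            seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(300))
            pos = rng.randrange(0, 291)
            seq = seq[:pos] + WHEAT1 + seq[pos + 9:]
            protein = ProteinRecord(id="x", description="", sequence=seq)
            for hit in scan_proteome([protein], canonical_motif):
                done = complete_nonamer(hit, protein)
                lo, hi = hit.start, hit.start + 8
                assert protein.sequence[lo:hi] == done.octamer.sequence
                if done.nonamer is not None:
                    assert protein.sequence[lo - 1:hi] == done.nonamer.sequence

    def test_mismatched_protein_is_an_error(self, canonical_motif):
        protein = ProteinRecord(id="p", description="", sequence="AAALRMRRCRRMAAA")
        [hit] = scan_proteome([protein], canonical_motif)
        other = ProteinRecord(id="q", description="", sequence="AAALRMRRCRRMAAA")
        with pytest.raises(ScanError):
            complete_nonamer(hit, other)


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def _hit(nonamer, protein_id="p", start=1):
    return MotifHit(
        protein_id=protein_id, start=start,
        octamer=Peptide(nonamer[1:]), nonamer=Peptide(nonamer),
        p1_residue=nonamer[0],
    )


class TestCurateHits:
    def test_arginine_at_p6_removed_with_reason(self):
        hit = _hit("LRMRRRRRM")  # P6 = R
        kept, removed = curate_hits([hit])
        assert kept == []
        assert len(removed) == 1
        assert "P6:R forbidden" in removed[0].curation_flags

    def test_empty_rule_set_is_identity(self):
        hits = [_hit(WHEAT1), _hit("LRMRRRRRM")]
        kept, removed = curate_hits(hits, CurationRuleSet(forbidden={}))
        assert removed == []
        assert [h.nonamer for h in kept] == [h.nonamer for h in hits]

    def test_partition_matches_reevaluation_oracle(self):
        rng = random.Random(3)
        hits = []
        for _ in range(50):
            seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(9))
            hits.append(_hit(seq, start=rng.randrange(1, 100)))
        rules = CurationRuleSet(forbidden={6: frozenset("R"), 3: frozenset("WC")})
        kept, removed = curate_hits(hits, rules)
        assert len(kept) + len(removed) == len(hits)
        for hit in kept:
            assert hit.nonamer.residue_at(6) != "R"
            assert hit.nonamer.residue_at(3) not in "WC"
        for hit in removed:
            assert (hit.nonamer.residue_at(6) == "R"
                    or hit.nonamer.residue_at(3) in "WC")

    def test_coordinates_never_change(self):
        hits = [_hit("LRMRRRRRM", start=17)]
        kept, removed = curate_hits(hits)
        assert removed[0].start == 17
        assert removed[0].protein_id == "p"

    def test_p1_rule_on_octamer_only_hit_kept_as_unevaluable(self, caplog):
        hit = MotifHit(protein_id="p", start=0, octamer=Peptide("RMRRCRRM"))
        rules = CurationRuleSet(forbidden={1: frozenset("L")})
        with caplog.at_level("WARNING"):
            kept, removed = curate_hits([hit], rules)
        assert removed == []
        assert "unevaluable" in kept[0].curation_flags


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

class TestRankHits:
    def test_modal_sequence_scores_highest(self):
        seqs = ["ARAARALRL"] * 3 + ["GRGGQGRRF"]
        model = build_frequency_model([Peptide(s) for s in seqs])
        hits = [_hit("ARAARALRL"), _hit("GRGGQGRRF", start=5)]
        ranked = rank_hits(hits, model)
        assert ranked[0].nonamer.sequence == "ARAARALRL"
        assert ranked[0].score >= ranked[1].score

    def test_score_difference_equals_hand_computed_log_odds(self):
        model = build_frequency_model(
            [Peptide("ARAARALRL"), Peptide("GRAARALRL")]
        )
        hits = [_hit("ARAARALRL"), _hit("GRAARALRL", start=5)]
        ranked = rank_hits(hits, model)
        # sequences differ only at P1 (A 1/2 vs G 1/2): identical scores
        assert ranked[0].score == pytest.approx(ranked[1].score)
        # hand-computed absolute score: 7 unanimous positions + P1 at 1/2,
        # each against uniform 1/20
        expected = 8 * math.log2(1.0 / 0.05) + math.log2(0.5 / 0.05)
        assert ranked[0].score == pytest.approx(expected)

    def test_input_order_does_not_affect_output_order(self):
        seqs = ["ARAARALRL", "GRGGQGRRF", "SRSSRSLRI", "LRMRRCRRM"]
        model = build_frequency_model([Peptide(s) for s in seqs])
        hits = [_hit(s, protein_id=f"p{i}", start=i) for i, s in enumerate(seqs, 1)]
        ranked_fwd = rank_hits(hits, model)
        ranked_rev = rank_hits(list(reversed(hits)), model)
        assert [(h.protein_id, h.start) for h in ranked_fwd] == \
            [(h.protein_id, h.start) for h in ranked_rev]

    def test_zero_background_frequency_is_an_instructive_error(self):
        model = build_frequency_model([Peptide(WHEAT1)])
        background = {aa: 0.0 for aa in AMINO_ACIDS}
        background["A"] = 1.0
        with pytest.raises(ScanError, match="pseudocount"):
            rank_hits([_hit(WHEAT1)], model, background)


# ---------------------------------------------------------------------------
# Analytic background rate and binding hook
# ---------------------------------------------------------------------------

class TestBackgroundRate:
    def test_published_motif_under_uniform_composition(self, canonical_motif):
        rate = expected_background_match_rate(canonical_motif)
        assert rate == pytest.approx((1 * 3 * 2 * 1 * 5) / 20**5)
        assert rate == pytest.approx(9.375e-6)

    def test_unconstrained_motif_matches_everything(self):
        from mimoscan.motif import RecognitionMotif
        assert expected_background_match_rate(RecognitionMotif({})) == 1.0

    def test_single_pattern_with_five_fixed_symbols(self):
        from mimoscan.motif import SearchPattern
        rate = expected_background_match_rate(SearchPattern("RXXRXRRL"))
        assert rate == pytest.approx((1 / 20) ** 5)

    def test_non_normalised_frequencies_rejected(self, canonical_motif):
        with pytest.raises(ScanError):
            expected_background_match_rate(
                canonical_motif, {aa: 1.0 for aa in AMINO_ACIDS}
            )


class TestBindingHook:
    def test_builtin_anchor_surrogate(self):
        good = _hit(WHEAT1)
        bad = _hit("LAMRRCRRM")  # P2 = A breaks the anchor
        annotated = annotate_hla_binding([good, bad])
        assert annotated[0].annotations["anchor_ok"] is True
        assert annotated[1].annotations["anchor_ok"] is False

    def test_failing_hook_annotates_but_never_drops(self, caplog):
        def broken(_seq):
            raise RuntimeError("server unreachable")

        with caplog.at_level("WARNING"):
            annotated = annotate_hla_binding([_hit(WHEAT1)], scorer=broken)
        assert len(annotated) == 1
        assert annotated[0].annotations.get("binding_unscored") is True

    def test_user_scorer_passes_through(self):
        annotated = annotate_hla_binding([_hit(WHEAT1)], scorer=lambda s: len(s))
        assert annotated[0].annotations["hla_binding_score"] == 9.0


class TestHitTableIO:
    def test_round_trip_preserves_hits(self, tmp_path, canonical_motif):
        protein = ProteinRecord(id="p", description="", sequence="AAALRMRRCRRMAAA")
        hits = [complete_nonamer(h, protein)
                for h in scan_proteome([protein], canonical_motif)]
        path = tmp_path / "hits.tsv"
        hits_to_tsv(hits, path)
        back = hits_from_tsv(path)
        assert [(h.protein_id, h.start, h.octamer.sequence,
                 h.nonamer.sequence if h.nonamer else None)
                for h in back] == \
            [(h.protein_id, h.start, h.octamer.sequence,
              h.nonamer.sequence if h.nonamer else None)
             for h in hits]
        # 1-based start in the file itself
        assert path.read_text().splitlines()[1].split("\t")[1] == "5"

    def test_dedup_collapses_identical_nonamers(self):
        hits = [_hit(WHEAT1, protein_id="a"), _hit(WHEAT1, protein_id="b"),
                _hit("ARAARALRL", protein_id="c")]
        groups = dedup_nonamers(hits)
        assert set(groups) == {WHEAT1, "ARAARALRL"}
        assert len(groups[WHEAT1]) == 2
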