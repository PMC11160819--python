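"""Variant matching: classification, policy, audit log, oracle agreement."""

import gzip

import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_match, classify_by_enumeration
from pgskit.genotypes import GenotypeBlock, TargetVariant
from pgskit.matching import (
    LowMatchRateError,
    MatchError,
    MatchParams,
    classify_candidate,
    match_variants,
    reverse_complement,
    write_match_log,
)
from pgskit.scoringfiles import ScoreVariant, ScoringFile, combine_scoring_files
from pgskit.simulate import SimulationConfig, inject_hazards, simulate_panel, simulate_scoring_file


def _block(variants):
    dosages = np.ones((1, len(variants)))
    return GenotypeBlock(["s1"], variants, dosages)


def _combined(score_variants, pgs_id="S1"):
    return combine_scoring_files([ScoringFile(pgs_id=pgs_id, variants=score_variants)])


class TestReverseComplement:
    @pytest.mark.parametrize(
        "allele,expected",
        [("A", "T"), ("AG", "CT"), ("ACGT", "ACGT"), ("c", "G")],
    )
    def test_examples(self, allele, expected):
        assert reverse_complement(allele) == expected

    def test_non_acgt_errors(self):
        with pytest.raises(MatchError, match="non-ACGT"):
            reverse_complement("AN")


class TestClassifyCandidate:
    def test_direct_altref(self):
        tv = TargetVariant("1", 10, "G", ("A",))
        cand = classify_candidate("A", "G", tv)
        assert cand.match_class == "altref" and not cand.is_ambiguous

    def test_strand_flips(self):
        tv = TargetVariant("1", 10, "G", ("A",))
        # revcomp(T)=A hits alt, revcomp(C)=G hits ref
        assert classify_candidate("T", "C", tv).match_class == "altref_flip"
        # revcomp(C)=G hits ref, revcomp(T)=A hits alt
        assert classify_candidate("C", "T", tv).match_class == "refalt_flip"

    def test_palindromic_refalt_flagged_ambiguous(self):
        tv = TargetVariant("1", 10, "A", ("T",))
        cand = classify_candidate("A", "T", tv)
        assert cand.match_class == "refalt" and cand.is_ambiguous

    def test_no_other_allele_classes(self):
        tv = TargetVariant("1", 10, "G", ("A",))
        assert classify_candidate("A", None, tv).match_class == "no_oa_alt"
        assert classify_candidate("G", None, tv).match_class == "no_oa_ref"
        assert classify_candidate("C", None, tv).match_class == "unmatched"

    def test_no_oa_on_palindromic_target_is_ambiguous(self):
        tv = TargetVariant("1", 10, "T", ("A",))
        assert classify_candidate("A", None, tv).is_ambiguous

    @pytest.mark.parametrize("ea,oa", [("A", "G"), ("C", "T"), ("T", "G"), ("A", "T")])
    @pytest.mark.parametrize("ref,alt", [("G", "A"), ("A", "G"), ("C", "A"), ("T", "A")])
    def test_agrees_with_enumeration_oracle(self, ea, oa, ref, alt):
        """Brute-force enumeration over orientation x strand confirms each
        classification is the unique first-firing arrangement."""
        tv = TargetVariant("1", 10, ref, (alt,))
        got = classify_candidate(ea, oa, tv)
        exp_cls, exp_amb = classify_by_enumeration(ea, oa, ref, alt)
        assert (got.match_class, got.is_ambiguous) == (exp_cls, exp_amb)


class TestMatchVariants:
    def test_all_exact_matches_pass(self):
        tvs = [TargetVariant("1", p, "G", ("A",)) for p in (10, 20, 30, 40)]
        svs = [ScoreVariant("1", p, "A", 0.5, other_allele="G") for p in (10, 20, 30, 40)]
        results, summaries = match_variants(_combined(svs), _block(tvs))
        assert summaries["S1"].match_rate == 1.0 and summaries["S1"].passed
        assert all(r.kept and r.match_class == "altref" for r in results)

    def test_half_matched_hard_stops_at_default_threshold(self):
        tvs = [TargetVariant("1", p, "G", ("A",)) for p in (10, 20)]
        svs = [ScoreVariant("1", p, "A", 0.5, other_allele="G") for p in (10, 20, 30, 40)]
        with pytest.raises(LowMatchRateError) as exc:
            match_variants(_combined(svs), _block(tvs))
        assert exc.value.summaries["S1"].match_rate == 0.5

    def test_biallelic_preferred_over_multiallelic_split(self):
        tvs = [
            TargetVariant("1", 10, "G", ("A", "T"), from_multiallelic=True),
            TargetVariant("1", 10, "G", ("T", "A"), from_multiallelic=True),
            TargetVariant("1", 10, "G", ("A",)),
        ]
        svs = [ScoreVariant("1", 10, "A", 0.5, other_allele="G")]
        results, _ = match_variants(_combined(svs), _block(tvs))
        r = results[0]
        assert r.kept and r.target_index == 2 and not r.is_multiallelic
        assert any(reason == "multiallelic" for _, _, reason in r.candidate_log)

    def test_multiallelic_only_excluded_by_default_kept_with_flag(self):
        tvs = [TargetVariant("1", 10, "G", ("A", "T"), from_multiallelic=True)]
        svs = [ScoreVariant("1", 10, "A", 0.5, other_allele="G")]
        results, _ = match_variants(
            _combined(svs), _block(tvs), raise_on_low_overlap=False
        )
        assert not results[0].kept and results[0].exclusion_reason == "multiallelic"
        results, _ = match_variants(
            _combined(svs), _block(tvs), MatchParams(keep_multiallelic=True)
        )
        assert results[0].kept

    def test_ambiguous_excluded_by_default_kept_with_flag(self):
        tvs = [TargetVariant("1", 10, "T", ("A",))]
        svs = [ScoreVariant("1", 10, "A", 0.5, other_allele="T")]
        results, _ = match_variants(
            _combined(svs), _block(tvs), raise_on_low_overlap=False
        )
        assert not results[0].kept and results[0].exclusion_reason == "ambiguous"
        results, _ = match_variants(
            _combined(svs), _block(tvs), MatchParams(keep_ambiguous=True)
        )
        assert results[0].kept and results[0].is_ambiguous

    def test_tied_candidates_keep_first_log_duplicate(self):
        tvs = [
            TargetVariant("1", 10, "G", ("A",), vid="first"),
            TargetVariant("1", 10, "G", ("A",), vid="second"),
        ]
        svs = [ScoreVariant("1", 10, "A", 0.5, other_allele="G")]
        results, _ = match_variants(_combined(svs), _block(tvs))
        r = results[0]
        assert r.kept and r.target_index == 0
        assert (1, "altref", "duplicate_best_match") in r.candidate_log

    def test_strand_symmetry(self, small_sim):
        """Reverse-complementing every score allele flips each class to its
        *_flip partner and leaves the kept set unchanged."""
        variants = small_sim.target.variants[:80]
        sf = simulate_scoring_file(variants, seed=5)
        flipped = ScoringFile(
            pgs_id=sf.pgs_id,
            variants=[
                ScoreVariant(
                    v.chr_name,
                    v.chr_position,
                    reverse_complement(v.effect_allele),
                    v.effect_weight,
                    other_allele=reverse_complement(v.other_allele),
                )
                for v in sf.variants
            ],
        )
        res_a, _ = match_variants(_combined(sf.variants), small_sim.target)
        res_b, _ = match_variants(_combined(flipped.variants), small_sim.target)
        pair = {"altref": "altref_flip", "refalt": "refalt_flip"}
        pair.update({v: k for k, v in pair.items()})
        for a, b in zip(res_a, res_b):
            assert a.kept == b.kept
            assert b.match_class == pair[a.match_class]

    def test_completeness_counts_sum_to_score_size(self, small_sim):
        sf = simulate_scoring_file(small_sim.target.variants[:100], seed=9)
        haz = inject_hazards(
            sf,
            small_sim.target,
            {"unmatched": 0.1, "make_palindromic": 0.1, "drop_other_allele": 0.1},
            seed=4,
        )
        results, summaries = match_variants(
            _combined(haz.scoring_file.variants),
            haz.target,
            raise_on_low_overlap=False,
        )
        assert len(results) == 100
        s = summaries["S1"]
        assert sum(s.class_counts.values()) == s.total == 100
        assert sum(s.reason_counts.values()) == 100

    def test_matches_brute_force_oracle_with_hazards(self):
        """On small randomized fixtures the matcher agrees with the literal
        orientation/strand enumerator on every decision."""
        for seed in range(8):
            sim = simulate_panel(
                SimulationConfig(
                    n_pops=2,
                    n_ref_per_pop=3,
                    n_target_per_pop=3,
                    m_variants=40,
                    seed=100 + seed,
                )
            )
            sf = simulate_scoring_file(sim.target.variants, seed=seed)
            haz = inject_hazards(
                sf,
                sim.target,
                {
                    "strand_flip": 0.1,
                    "allele_swap": 0.1,
                    "drop_other_allele": 0.1,
                    "make_palindromic": 0.1,
                    "make_multiallelic": 0.1,
                    "unmatched": 0.1,
                },
                seed=seed,
            )
            combined = _combined(haz.scoring_file.variants)
            params = MatchParams(keep_ambiguous=bool(seed % 2))
            results, _ = match_variants(
                combined, haz.target, params, raise_on_low_overlap=False
            )
            expected = brute_force_match(combined, haz.target, params)
            for got, exp in zip(results, expected):
                assert got.kept == exp["kept"]
                assert got.match_class == exp["match_class"]
                assert got.exclusion_reason == exp["exclusion_reason"]
                assert got.target_index == exp["target_index"]


class TestMatchLog:
    def _results(self):
        tvs = [
            TargetVariant("1", 10, "G", ("A",)),
            TargetVariant("1", 20, "G", ("A",)),
            TargetVariant("1", 30, "G", ("A",)),
            TargetVariant("1", 40, "T", ("A",)),
        ]
        svs = [
            ScoreVariant("1", 10, "A", 0.5, other_allele="G"),
            ScoreVariant("1", 20, "A", 0.5, other_allele="G"),
            ScoreVariant("1", 30, "A", 0.5, other_allele="G"),
            ScoreVariant("1", 40, "A", 0.5, other_allele="T"),
        ]
        return match_variants(
            _combined(svs), _block(tvs), raise_on_low_overlap=False
        )

    def test_rows_and_summary_counts(self, tmp_path):
        results, summaries = self._results()
        path = tmp_path / "log.tsv.gz"
        write_match_log(results, summaries, path)
        with gzip.open(path, "rt") as fh:
            lines = fh.read().splitlines()
        data = [l for l in lines if not l.startswith("#")]
        assert len(data) == 5  # header + 4 variants
        assert summaries["S1"].reason_counts == {"kept": 3, "excluded_ambiguous": 1}

    def test_empty_results_header_only(self, tmp_path):
        path = tmp_path / "log.tsv"
        write_match_log([], {}, path)
        assert path.read_text().splitlines() == [
            "\t".join(
                [
                    "chr_name", "chr_position", "effect_allele", "other_allele",
                    "match_class", "is_ambiguous", "is_multiallelic", "kept",
                    "exclusion_reason", "target_id", "candidates",
                ]
            )
        ]

    def test_rerun_is_byte_identical(self, tmp_path):
        results, summaries = self._results()
        a, b = tmp_path / "a.tsv.gz", tmp_path / "b.tsv.gz"
        write_match_log(results, summaries, a)
        write_match_log(results, summaries, b)
        assert a.read_bytes() == b.read_bytes()
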