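"""SNP calling, chemical classification, and codon-effect annotation."""

import itertools

import pytest
from Bio.Data.CodonTable import standard_dna_table

from musavar import (
    AlignmentSet,
    SUBSTITUTION_PROFILES,
    annotate_codon_effect,
    call_snps,
    classify_substitution,
    detect_deletions,
    detect_insertions,
    summarize_cultivar,
)
from musavar.errors import (
    InvalidAlignmentError,
    InvalidArgumentError,
    MissingSampleError,
    OutOfFrameError,
)

BASES = "ACGT"

# Independent genetic-code oracle: plain dict lookup, stops as "*".
_CODON_AA = dict(standard_dna_table.forward_table)
_CODON_AA.update({c: "*" for c in standard_dna_table.stop_codons})


def test_transition_transversion_partition_exhaustive():
    """The 12 ordered base pairs split into exactly 4 transitions and 8
    transversions, and each pair is exactly one of the two."""
    purines = {"A", "G"}
    tallies = {"transition": 0, "transversion": 0}
    for ref, alt in itertools.permutations(BASES, 2):
        ref_class, alt_class, subst = classify_substitution(ref, alt)
        expected = (
            "transition"
            if (ref in purines) == (alt in purines)
            else "transversion"
        )
        assert subst == expected
        assert ref_class == ("Pu" if ref in purines else "Py")
        assert alt_class == ("Pu" if alt in purines else "Py")
        tallies[subst] += 1
    assert tallies == {"transition": 4, "transversion": 8}


@pytest.mark.parametrize("bad", [("A", "A"), ("N", "G"), ("A", "-")])
def test_classification_rejects_equal_or_ambiguous(bad):
    with pytest.raises(InvalidArgumentError):
        classify_substitution(*bad)


def test_codon_effect_agrees_with_genetic_code_for_all_substitutions():
    """Brute force: every single-base substitution of every sense codon is
    synonymous exactly when the dict-lookup oracle preserves the amino
    acid."""
    for codon in _CODON_AA:
        if codon in standard_dna_table.stop_codons:
            continue
        for k in range(3):
            for alt in BASES:
                if alt == codon[k]:
                    continue
                mutated = codon[:k] + alt + codon[k + 1 :]
                _, ref_aa, alt_aa, effect = annotate_codon_effect(
                    k + 1, codon[k], alt, codon, frame_offset=1
                )
                oracle = _CODON_AA[codon] == _CODON_AA[mutated]
                assert (effect == "synonymous") == oracle, (codon, mutated)
                assert (ref_aa == alt_aa) == oracle


@pytest.mark.parametrize(
    "codon,alt_pos,alt,exp",
    [
        ("GGT", 2, "T", ("Gly", "Val", "non-synonymous")),
        ("AAA", 3, "G", ("Lys", "Lys", "synonymous")),
        ("GGA", 3, "G", ("Gly", "Gly", "synonymous")),  # 4-fold degenerate
    ],
)
def test_codon_effect_examples(codon, alt_pos, alt, exp):
    reference = "ATG" + codon  # codon of interest is codon 2
    idx, ref_aa, alt_aa, effect = annotate_codon_effect(
        3 + alt_pos, codon[alt_pos - 1], alt, reference, frame_offset=1
    )
    assert idx == 2
    assert (ref_aa, alt_aa, effect) == exp


def test_codon_index_arithmetic():
    reference = "A" * 30
    idx, *_ = annotate_codon_effect(27, "A", "G", reference, frame_offset=1)
    assert idx == 9
    idx, *_ = annotate_codon_effect(27, "A", "G", reference, frame_offset=4)
    assert idx == 8


def test_trailing_incomplete_codon_is_out_of_frame():
    with pytest.raises(OutOfFrameError):
        annotate_codon_effect(7, "A", "G", "ATGAAAA", frame_offset=1)


def test_call_snps_single_synonymous_site():
    aln = AlignmentSet(
        {"ref": "ATGAAA", "s": "ATGAAG"}, reference_label="ref"
    )
    (rec,) = call_snps(aln, "s")
    assert (rec.position, rec.ref_base, rec.alt_base) == (6, "A", "G")
    assert rec.subst_class == "transition"
    assert (rec.ref_aa, rec.alt_aa, rec.effect) == (
        "Lys",
        "Lys",
        "synonymous",
    )


def test_call_snps_identity_and_masked_columns():
    aln = AlignmentSet(
        {"ref": "ATGAAAGGG", "same": "ATGAAAGGG", "masked": "ATGN-AGGG"},
        reference_label="ref",
    )
    assert call_snps(aln, "same") == []
    assert call_snps(aln, "masked") == []  # N and gap columns yield no SNP


def test_call_snps_positions_are_ungapped_reference_coordinates():
    # reference gap shifts alignment columns but not reference coordinates
    aln = AlignmentSet(
        {"ref": "ATG--AAAT", "s": "ATGGGAACT"}, reference_label="ref"
    )
    recs = call_snps(aln, "s")
    assert [(r.position, r.ref_base, r.alt_base) for r in recs] == [
        (6, "A", "C")
    ]
    for r in recs:
        assert aln.reference_ungapped[r.position - 1] == r.ref_base


def test_unknown_sample_and_bad_alphabet():
    aln = AlignmentSet({"ref": "ATGAAA", "s": "ATGAAG"}, "ref")
    with pytest.raises(MissingSampleError):
        call_snps(aln, "nope")
    with pytest.raises(InvalidAlignmentError):
        AlignmentSet({"ref": "ATGXAA", "s": "ATGAAG"}, "ref")
    with pytest.raises(InvalidAlignmentError):
        AlignmentSet({"ref": "ATGAAA", "s": "ATGAAGC"}, "ref")


def test_detect_deletions_merges_runs():
    aln = AlignmentSet(
        {"ref": "ATGAAACCCGGG", "s": "ATG---CCC--G"}, reference_label="ref"
    )
    recs = detect_deletions(aln, "s")
    assert [(r.start, r.length, r.kind) for r in recs] == [
        (4, 3, "deletion"),
        (10, 2, "deletion"),
    ]


def test_reference_gap_is_insertion_not_deletion():
    aln = AlignmentSet(
        {"ref": "ATG---AAA", "s": "ATGCCCAAA"}, reference_label="ref"
    )
    assert detect_deletions(aln, "s") == []
    assert detect_insertions(aln, "s") == [(3, 3)]


def test_summarize_empty_spectrum():
    prof = summarize_cultivar([], "X")
    assert prof.n_snp_sites == 0
    assert prof.listed_types == ()
    assert prof.overall_class == "undefined"
    assert prof.mutation_type == "synonymous"


def test_summarize_round_trip_matches_generating_profile(implanted):
    """Calling SNPs on an implanted alignment and re-summarizing recovers
    the generating spectrum row: site count, the two listed types with
    exact counts, the dominant class, and the mutation type."""
    for name, (aln, _) in implanted.items():
        prof = SUBSTITUTION_PROFILES[name]
        snps = call_snps(aln, name)
        summary = summarize_cultivar(snps, name)
        assert summary.n_snp_sites == prof.n_snp_sites
        assert summary.listed_types == prof.listed_types
        assert summary.overall_class == prof.overall_class
        assert summary.mutation_type == prof.mutation_type


def test_round_trip_completeness(implanted):
    """call_snps recovers every implanted substitution exactly — position,
    alleles and per-site codon effect — and nothing else."""
    for name, (aln, truth) in implanted.items():
        called = [
            (r.position, r.ref_base, r.alt_base, r.effect)
            for r in call_snps(aln, name)
        ]
        assert called == truth.variant_truth
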