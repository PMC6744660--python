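"""Synthetic-data generators: determinism, conservation, truth consistency."""

import pytest
from Bio.Seq import Seq

from musavar import (
    SUBSTITUTION_PROFILES,
    call_snps,
    detect_deletions,
    generate_alignment,
    generate_cohort,
    generate_cytology,
    generate_flow_histogram,
    generate_phenology,
    generate_reference_cds,
    implant_variants,
)
from musavar.errors import (
    InvalidArgumentError,
    InvalidProfileError,
    PlacementFailureError,
)
from musavar.profiles import AminoAcidChange, SubstitutionProfile
from musavar.synthdata import _place_named_change
import numpy as np


# -- reference CDS ------------------------------------------------------


def test_reference_cds_smallest_and_determinism():
    codon = generate_reference_cds(3, seed=0)
    assert len(codon) == 3 and codon not in ("TAA", "TAG", "TGA")
    a = generate_reference_cds(300, seed=7)
    b = generate_reference_cds(300, seed=7)
    assert a == b and len(a) == 300
    assert generate_reference_cds(300, seed=8) != a


def test_reference_cds_has_no_internal_stop():
    # oracle: full translation must carry no stop symbol
    protein = str(Seq(generate_reference_cds(300, seed=7)).translate())
    assert "*" not in protein


@pytest.mark.parametrize("length", [0, 2, 301])
def test_reference_cds_rejects_bad_length(length):
    with pytest.raises(InvalidArgumentError):
        generate_reference_cds(length, seed=0)


# -- variant implantation -----------------------------------------------


def test_implant_identity_with_empty_profile(reference):
    prof = SubstitutionProfile("none", 0, (), "Pu-Pu", None, "synonymous")
    mutant, truth = implant_variants(reference, prof, seed=3)
    assert mutant == reference
    assert truth.variant_truth == [] and truth.deletion_truth == []


def test_truth_entries_are_realized_in_the_mutant(reference):
    """Truth consistency, checked by direct inspection of the sequences."""
    prof = SUBSTITUTION_PROFILES["DB1P"]
    mutant, truth = implant_variants(
        reference, prof, deletion_spec=(91, 12), seed=11
    )
    assert len(mutant) == len(reference)
    positions = [p for p, *_ in truth.variant_truth]
    assert positions == sorted(set(positions))  # strictly increasing
    for pos, ref_b, alt_b, _ in truth.variant_truth:
        assert reference[pos - 1] == ref_b
        assert mutant[pos - 1] == alt_b
    for start, length in truth.deletion_truth:
        assert mutant[start - 1 : start - 1 + length] == "-" * length
    assert len(truth.variant_truth) == prof.n_snp_sites


def test_listed_types_implanted_at_exact_counts(reference):
    prof = SUBSTITUTION_PROFILES["Agbagba"]
    _, truth = implant_variants(reference, prof, seed=11)
    pairs = [(r, a) for _, r, a, _ in truth.variant_truth]
    assert pairs.count(("G", "A")) == 26
    assert pairs.count(("A", "G")) == 12
    assert all(e == "synonymous" for *_, e in truth.variant_truth)


def test_named_amino_acid_change_is_realized(reference):
    """The mutant codon at the named-change site translates to the target
    amino acid (Gly -> Val for the DB1P spectrum)."""
    mutant, truth = implant_variants(
        reference, SUBSTITUTION_PROFILES["DB1P"], seed=11
    )
    # locate the Gly codon whose implanted change yields Val
    found = False
    for pos, ref_b, alt_b, effect in truth.variant_truth:
        ci = (pos - 1) // 3
        ref_codon = reference[3 * ci : 3 * ci + 3]
        mut_codon = mutant[3 * ci : 3 * ci + 3]
        if "-" in mut_codon:
            continue
        if (
            str(Seq(ref_codon).translate()) == "G"
            and str(Seq(mut_codon).translate()) == "V"
        ):
            found = True
    assert found


def test_two_base_codon_change_realizes_otherwise_impossible_change(reference):
    """Val -> Lys needs two base changes in one codon; the generator
    implants both and the mutant codon translates to Lys."""
    mutant, truth = implant_variants(
        reference, SUBSTITUTION_PROFILES["TB1P"], seed=11
    )
    found = False
    for ci in range(len(reference) // 3):
        ref_codon = reference[3 * ci : 3 * ci + 3]
        mut_codon = mutant[3 * ci : 3 * ci + 3]
        if "-" in mut_codon or ref_codon == mut_codon:
            continue
        if (
            str(Seq(ref_codon).translate()) == "V"
            and str(Seq(mut_codon).translate()) == "K"
        ):
            found = True
    assert found
    assert len(truth.variant_truth) == 81


def test_implant_rejects_overfull_profile(reference):
    with pytest.raises(InvalidProfileError):
        SubstitutionProfile(
            "bad", 5, (("T", "G", 46),), "Py-Pu", None, "synonymous"
        )


def test_implant_reports_placement_failure():
    # a reference with no T cannot host T>G substitutions
    prof = SubstitutionProfile(
        "bad", 4, (("T", "G", 4),), "Py-Pu", None, "non-synonymous"
    )
    with pytest.raises(PlacementFailureError):
        implant_variants("GGAGGAGGAGGA", prof, seed=0)


def test_named_change_prefers_stated_codon_index():
    # codon 2 is GGT (Gly); the profile names Gly->Val at codon 2
    reference = "ATGGGTAAA"
    prof = SubstitutionProfile(
        "x",
        1,
        (),
        "Pu-Py",
        AminoAcidChange("Gly", 2, "Val"),
        "non-synonymous",
    )
    events = _place_named_change(
        reference, prof, set(), np.random.default_rng(0)
    )
    assert events == [(5, "G", "T")]  # GGT -> GTT within codon 2


def test_deletion_round_trip(reference):
    from musavar import AlignmentSet

    mutant, truth = implant_variants(
        reference, SUBSTITUTION_PROFILES["TB3P"], deletion_spec=(91, 12), seed=2
    )
    aln = AlignmentSet({"ref": reference, "TB3P": mutant}, "ref")
    recs = detect_deletions(aln, "TB3P")
    assert [(r.start, r.length) for r in recs] == truth.deletion_truth == [
        (91, 12)
    ]


def test_generate_alignment_round_trips_against_caller():
    profiles = list(SUBSTITUTION_PROFILES.values())
    aln, truths = generate_alignment(
        profiles, length=600, seed=21, deletion_spec=(91, 12)
    )
    assert len(aln.sequences) == len(profiles) + 1
    assert len({len(s) for s in aln.sequences.values()}) == 1
    for prof in profiles:
        called = [
            (r.position, r.ref_base, r.alt_base, r.effect)
            for r in call_snps(aln, prof.cultivar)
        ]
        assert called == truths[prof.cultivar].variant_truth
        dels = [
            (r.start, r.length)
            for r in detect_deletions(aln, prof.cultivar)
        ]
        assert dels == truths[prof.cultivar].deletion_truth


# -- phenology ----------------------------------------------------------


def test_phenology_extremes_and_conservation(panel):
    always = [p for p in panel if p.ratoon_concordance_prob == 1.0]
    never = [p for p in panel if p.ratoon_concordance_prob == 0.0]
    records, truth = generate_phenology(always + never, 10, 2, seed=1)
    assert len(records) == 20 * (1 + 2)
    by_plant = truth.phenotype_truth
    for p in always:
        for pid, t in by_plant.items():
            if pid.startswith(p.label):
                assert all(b == t["plant"] for b in t["ratoon"])
    for p in never:
        for pid, t in by_plant.items():
            if pid.startswith(p.label):
                assert all(b != t["plant"] for b in t["ratoon"])


def test_phenology_determinism_and_truth_consistency(panel):
    r1, t1 = generate_phenology(panel, 5, 2, seed=9)
    r2, t2 = generate_phenology(panel, 5, 2, seed=9)
    assert r1 == r2 and t1.phenotype_truth == t2.phenotype_truth
    # every truth entry is realized in the records
    by_plant = {}
    for rec in r1:
        by_plant.setdefault(rec.plant_id, []).append(rec)
    for pid, t in t1.phenotype_truth.items():
        recs = by_plant[pid]
        assert recs[0].cycle == "plant" and recs[0].bunches == t["plant"]
        assert [r.bunches for r in recs[1:]] == t["ratoon"]


def test_phenology_rejects_empty_profiles():
    with pytest.raises(InvalidArgumentError):
        generate_phenology([], 10, 2, seed=0)


# -- flow histograms ----------------------------------------------------


def test_histogram_counts_conserved_and_deterministic():
    h1 = generate_flow_histogram(2, 3, 75.0, n_nuclei=4000, seed=5)
    h2 = generate_flow_histogram(2, 3, 75.0, n_nuclei=4000, seed=5)
    assert h1 == h2
    assert h1.total == 4000


def test_sample_peak_lands_at_scaled_channel():
    h = generate_flow_histogram(
        2, 3, 75.0, n_nuclei=20000, cv=0.03, debris_fraction=0.0, seed=4
    )
    counts = np.array(h.counts)
    # two modes: control at 75 and sample at 75 * 2/3 = 50
    assert abs(int(np.argmax(counts[:60])) + 1 - 50) <= 2
    assert abs(int(np.argmax(counts[60:])) + 61 - 75) <= 2


def test_control_ploidy_sample_gives_single_merged_peak():
    h = generate_flow_histogram(3, 3, 75.0, n_nuclei=20000, seed=6)
    from musavar import detect_peaks

    peaks = detect_peaks(h)
    assert len(peaks) == 1 and abs(peaks[0] - 75) <= 2


def test_histogram_rejects_offscale_peak():
    with pytest.raises(InvalidArgumentError):
        generate_flow_histogram(8, 3, 75.0, n_channels=128, seed=0)


def test_cohort_determinism_and_truth(panel):
    h1, t1 = generate_cohort([(2, 3), (4, 2)], seed=13)
    h2, t2 = generate_cohort([(2, 3), (4, 2)], seed=13)
    assert h1 == h2 and t1.ploidy_truth == t2.ploidy_truth
    assert len(h1) == 5
    assert sorted(t1.ploidy_truth.values()) == [2, 2, 2, 4, 4]
    with pytest.raises(InvalidArgumentError):
        generate_cohort([], seed=0)


# -- cytology -----------------------------------------------------------


def test_cytology_modal_count_matches_truth():
    obs, truth = generate_cytology(
        {"a": 2, "b": 3}, n_cells=10, miscount_prob=0.1, seed=3
    )
    from musavar import count_to_ploidy

    for o in obs:
        assert count_to_ploidy(o).ploidy == truth.ploidy_truth[o.plant_id]
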