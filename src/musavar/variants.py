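"""SNP and deletion calling from a gapped multiple sequence alignment.

Each cultivar's consensus sequence of the GTPase-protein-binding gene region
is compared column-by-column against a designated reference row of the same
alignment. A SNP is a column where both rows carry an unambiguous base
(A/C/G/T) that differs; columns with a gap or N on either side are skipped.
Every call is annotated chemically (purine Pu = {A, G} vs pyrimidine
Py = {C, T}; transition when the classes match, transversion otherwise) and
by codon effect under the standard genetic code (synonymous when the amino
acid is preserved). Runs of gaps in the sample opposite reference bases are
reported as deletions; gaps in the reference opposite sample bases are
insertions and are reported separately, never mixed into the SNP spectrum.

Coordinates are 1-based positions in the ungapped reference; the reading
frame starts at ``frame_offset`` (ungapped reference position of the first
base of codon 1, default 1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .errors import (
    InvalidAlignmentError,
    InvalidArgumentError,
    MissingSampleError,
    OutOfFrameError,
)
from .profiles import AminoAcidChange, SubstitutionProfile

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = frozenset("ACGT")
ALIGNMENT_ALPHABET = frozenset("ACGTN-")


@dataclass(frozen=True)
class SNPRecord:
    """A single-base substitution in ungapped reference coordinates.

    Codon fields are None when the position falls outside a complete codon
    of the declared reading frame.
    """

    position: int
    ref_base: str
    alt_base: str
    ref_class: str
    alt_class: str
    subst_class: str  # "transition" | "transversion"
    codon_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    effect: str | None = None  # "synonymous" | "non-synonymous"


@dataclass(frozen=True)
class IndelRecord:
    start: int  # 1-based ungapped reference coordinate of first deleted base
    length: int
    kind: str = "deletion"


@dataclass
class AlignmentSet:
    """An ordered gapped alignment with a designated reference row."""

    sequences: dict[str, str]
    reference_label: str
    frame_offset: int = 1

    def __post_init__(self) -> None:
        if not self.sequences:
            raise InvalidAlignmentError("alignment has no sequences")
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise InvalidAlignmentError(
                f"gapped rows differ in length: {sorted(lengths)}"
            )
        for label, seq in self.sequences.items():
            bad = set(seq) - ALIGNMENT_ALPHABET
            if bad:
                raise InvalidAlignmentError(
                    f"record {label!r} contains non-nucleotide characters "
                    f"{sorted(bad)}"
                )
        if self.reference_label not in self.sequences:
            raise MissingSampleError(self.reference_label)
        if self.frame_offset < 1:
            raise InvalidArgumentError("frame_offset must be >= 1 (1-based)")
        ref_ungapped = self.reference_ungapped
        if len(ref_ungapped) - (self.frame_offset - 1) < 3:
            raise InvalidAlignmentError(
                "reference holds fewer than 3 ungapped bases past the frame "
                "offset"
            )

    @property
    def reference_ungapped(self) -> str:
        return self.sequences[self.reference_label].replace("-", "")

    def require_sample(self, sample: str) -> str:
        if sample not in self.sequences:
            raise MissingSampleError(sample)
        return self.sequences[sample]


def classify_substitution(ref_base: str, alt_base: str) -> tuple[str, str, str]:
    """Chemical classification of a substitution.

    Returns ``(ref_class, alt_class, subst_class)`` with classes "Pu"/"Py"
    and subst_class "transition" (same class) or "transversion".
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base not in BASES or alt_base not in BASES:
        raise InvalidArgumentError(
            f"bases must be unambiguous A/C/G/T, got {ref_base!r}>{alt_base!r}"
        )
    if ref_base == alt_base:
        raise InvalidArgumentError("ref and alt bases are identical")
    ref_class = "Pu" if ref_base in PURINES else "Py"
    alt_class = "Pu" if alt_base in PURINES else "Py"
    subst = "transition" if ref_class == alt_class else "transversion"
    return ref_class, alt_class, subst


def translate_codon(codon: str) -> str:
    """Standard-genetic-code translation to a 3-letter amino-acid code
    ("Ter" for a stop codon)."""
    return seq3(str(Seq(codon).translate()))


def annotate_codon_effect(
    position: int,
    ref_base: str,
    alt_base: str,
    reference_ungapped: str,
    frame_offset: int = 1,
) -> tuple[int, str, str, str]:
    """Codon index and amino-acid effect of a substitution.

    The codon index is 1-based: codon 1 starts at ungapped reference
    position ``frame_offset``. The alternate amino acid is obtained by
    substituting ``alt_base`` into the reference codon alone, so multiple
    hits in one codon are each annotated against the reference.
    """
    if position < frame_offset:
        raise OutOfFrameError(
            f"position {position} precedes the reading frame at "
            f"{frame_offset}"
        )
    if not 1 <= position <= len(reference_ungapped):
        raise InvalidArgumentError(
            f"position {position} outside reference of length "
            f"{len(reference_ungapped)}"
        )
    if reference_ungapped[position - 1].upper() != ref_base.upper():
        raise InvalidArgumentError(
            f"reference holds {reference_ungapped[position - 1]!r} at "
            f"position {position}, not {ref_base!r}"
        )
    codon_index = (position - frame_offset) // 3 + 1
    start = frame_offset + 3 * (codon_index - 1)  # 1-based codon start
    if start + 2 > len(reference_ungapped):
        raise OutOfFrameError(
            f"position {position} lies in an incomplete trailing codon"
        )
    ref_codon = reference_ungapped[start - 1 : start + 2].upper()
    offset_in_codon = position - start
    alt_codon = (
        ref_codon[:offset_in_codon]
        + alt_base.upper()
        + ref_codon[offset_in_codon + 1 :]
    )
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    effect = "synonymous" if ref_aa == alt_aa else "non-synonymous"
    return codon_index, ref_aa, alt_aa, effect


def call_snps(alignment: AlignmentSet, sample: str) -> list[SNPRecord]:
    """Call substitutions of ``sample`` against the alignment's reference.

    One record per alignment column where reference and sample both hold an
    unambiguous base and differ, sorted by ascending ungapped reference
    position; gap/N columns contribute nothing. Codon annotation is filled
    whenever the site lies in a complete codon of the declared frame.
    """
    ref_gapped = alignment.sequences[alignment.reference_label]
    smp_gapped = alignment.require_sample(sample)
    ref_ungapped = alignment.reference_ungapped

    records: list[SNPRecord] = []
    ref_pos = 0  # ungapped, 1-based after increment
    for ref_c, smp_c in zip(ref_gapped, smp_gapped):
        if ref_c != "-":
            ref_pos += 1
        if ref_c not in BASES or smp_c not in BASES or ref_c == smp_c:
            continue
        ref_class, alt_class, subst = classify_substitution(ref_c, smp_c)
        try:
            codon_index, ref_aa, alt_aa, effect = annotate_codon_effect(
                ref_pos, ref_c, smp_c, ref_ungapped, alignment.frame_offset
            )
        except OutOfFrameError:
            codon_index = ref_aa = alt_aa = effect = None
        records.append(
            SNPRecord(
                position=ref_pos,
                ref_base=ref_c,
                alt_base=smp_c,
                ref_class=ref_class,
                alt_class=alt_class,
                subst_class=subst,
                codon_index=codon_index,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                effect=effect,
            )
        )
    return records


def detect_deletions(alignment: AlignmentSet, sample: str) -> list[IndelRecord]:
    """Maximal gap runs in the sample opposite non-gap reference bases."""
    ref_gapped = alignment.sequences[alignment.reference_label]
    smp_gapped = alignment.require_sample(sample)

    records: list[IndelRecord] = []
    ref_pos = 0
    run_start: int | None = None
    run_len = 0
    for ref_c, smp_c in zip(ref_gapped, smp_gapped):
        if ref_c != "-":
            ref_pos += 1
        if ref_c != "-" and smp_c == "-":
            if run_start is None:
                run_start = ref_pos
            run_len += 1
        else:
            # a reference-gap column does not break a deletion run only if
            # the sample is also gapped there; any sample base ends the run
            if smp_c != "-" or ref_c != "-":
                if run_start is not None:
                    records.append(IndelRecord(run_start, run_len))
                run_start, run_len = None, 0
    if run_start is not None:
        records.append(IndelRecord(run_start, run_len))
    return records


def detect_insertions(
    alignment: AlignmentSet, sample: str
) -> list[tuple[int, int]]:
    """Runs of sample bases opposite reference gaps, as (anchor, length).

    The anchor is the ungapped reference position immediately left of the
    inserted block (0 if the block precedes all reference bases). Reported
    separately from deletions and excluded from substitution summaries.
    """
    ref_gapped = alignment.sequences[alignment.reference_label]
    smp_gapped = alignment.require_sample(sample)
    out: list[tuple[int, int]] = []
    ref_pos = 0
    run_len = 0
    for ref_c, smp_c in zip(ref_gapped, smp_gapped):
        if ref_c == "-" and smp_c in BASES:
            run_len += 1
            continue
        if run_len:
            out.append((ref_pos, run_len))
            run_len = 0
        if ref_c != "-":
            ref_pos += 1
    if run_len:
        out.append((ref_pos, run_len))
    return out


def summarize_cultivar(
    snps: list[SNPRecord], cultivar: str
) -> SubstitutionProfile:
    """Condense a cultivar's SNP calls into a spectrum row.

    Reports the total SNP-site count, the two most frequent substitution
    types (ties broken lexicographically), the modal purine/pyrimidine
    pattern within the majority transition/transversion class, one
    representative amino-acid change (the first non-synonymous call if any,
    else the first annotated call), and whether the spectrum is wholly
    synonymous.
    """
    n = len(snps)
    if n == 0:
        return SubstitutionProfile(
            cultivar=cultivar,
            n_snp_sites=0,
            listed_types=(),
            overall_class="undefined",
            aa_change=None,
            mutation_type="synonymous",
        )

    type_counts = Counter((r.ref_base, r.alt_base) for r in snps)
    listed = sorted(type_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:2]
    listed_types = tuple((ref, alt, count) for (ref, alt), count in listed)

    n_transitions = sum(r.subst_class == "transition" for r in snps)
    majority = (
        "transition" if n_transitions >= n - n_transitions else "transversion"
    )
    patterns = Counter(
        f"{r.ref_class}-{r.alt_class}"
        for r in snps
        if r.subst_class == majority
    )
    overall_class = sorted(patterns.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]

    non_syn = [r for r in snps if r.effect == "non-synonymous"]
    annotated = [r for r in snps if r.effect is not None]
    pick = non_syn[0] if non_syn else (annotated[0] if annotated else None)
    aa_change = (
        AminoAcidChange(pick.ref_aa, pick.codon_index, pick.alt_aa)
        if pick is not None
        else None
    )
    mutation_type = "non-synonymous" if non_syn else "synonymous"
    return SubstitutionProfile(
        cultivar=cultivar,
        n_snp_sites=n,
        listed_types=listed_types,
        overall_class=overall_class,
        aa_change=aa_change,
        mutation_type=mutation_type,
    )
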