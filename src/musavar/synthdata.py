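"""Seeded synthetic data with ground truth for every pipeline stage.

No sequences, cytometry listmode files or field tables were deposited for
this study system, so each of the four input kinds is emulated here with an
explicit truth record:

* a random protein-coding reference (uniform over the 61 sense codons, so it
  carries no in-frame stop) standing in for the GTPase-protein-binding gene
  region;
* cultivar sequences derived from that reference by implanting a
  substitution spectrum (exact counts for the explicitly listed types, the
  remainder drawn from the spectrum's purine/pyrimidine class) plus an
  optional contiguous deletion;
* per-plant bunch-phenotype tables in which each ratoon observation repeats
  the plant-crop phenotype with the cultivar's concordance probability and
  otherwise reverts uniformly to one of the other bunch counts;
* DNA-content histograms built from discretized Gaussian peaks (sample peak
  at control_channel x ploidy / control_ploidy, coefficient of variation
  ``cv``) over an internal-standard peak and a geometric low-channel debris
  tail, with nucleus counts conserved exactly;
* per-cell metaphase chromosome-count tables with an occasional +/-1
  miscount.

All generators are deterministic for a fixed seed; cohort members draw
independent sub-seeds from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .concordance import PhenologyRecord, RATOON_CYCLES
from .errors import (
    InvalidArgumentError,
    InvalidProfileError,
    PlacementFailureError,
)
from .ploidy import CytologyObservation, FlowHistogram
from .profiles import (
    BASIC_CHROMOSOME_NUMBER,
    CULTIVAR_PANEL,
    CultivarProfile,
    SubstitutionProfile,
)
from .variants import AlignmentSet, annotate_codon_effect, translate_codon

SENSE_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.forward_table))

# Substitution pairs consistent with each purine/pyrimidine spectrum class.
CLASS_PAIRS: dict[str, tuple[tuple[str, str], ...]] = {
    "Pu-Pu": (("A", "G"), ("G", "A")),
    "Py-Py": (("C", "T"), ("T", "C")),
    "Pu-Py": (("A", "C"), ("A", "T"), ("G", "C"), ("G", "T")),
    "Py-Pu": (("C", "A"), ("C", "G"), ("T", "A"), ("T", "G")),
}
TRANSITION_PAIRS = CLASS_PAIRS["Pu-Pu"] + CLASS_PAIRS["Py-Py"]
TRANSVERSION_PAIRS = CLASS_PAIRS["Pu-Py"] + CLASS_PAIRS["Py-Pu"]


def _filler_pair_tiers(
    profile: SubstitutionProfile,
) -> tuple[tuple[tuple[str, str], ...], tuple[tuple[str, str], ...]]:
    """Substitution pairs for the sites beyond the explicitly listed types.

    Fillers keep the spectrum's transition/transversion character and never
    reuse a listed pair, so the listed counts stay exact. Pairs of the
    spectrum's stated purine/pyrimidine direction are preferred (first
    tier); the remaining same-character pairs are the fallback tier.
    """
    listed = {(r, a) for r, a, _ in profile.listed_types}
    directed = tuple(
        p for p in CLASS_PAIRS[profile.overall_class] if p not in listed
    )
    broad = (
        TRANSITION_PAIRS
        if profile.overall_class in ("Pu-Pu", "Py-Py")
        else TRANSVERSION_PAIRS
    )
    fallback = tuple(
        p for p in broad if p not in listed and p not in directed
    )
    return directed, fallback


@dataclass
class TruthSet:
    """Ground truth attached to a generated artifact.

    ``variant_truth`` rows are (position, ref_base, alt_base, effect) with
    1-based ungapped reference positions and per-substitution effects
    annotated against the reference codon, exactly as the caller reports
    them. ``deletion_truth`` rows are (start, length).
    """

    variant_truth: list[tuple[int, str, str, str]] = field(default_factory=list)
    deletion_truth: list[tuple[int, int]] = field(default_factory=list)
    ploidy_truth: dict[str, int] = field(default_factory=dict)
    phenotype_truth: dict[str, dict] = field(default_factory=dict)

    def validate(self, reference_length: int | None = None) -> None:
        positions = [p for p, *_ in self.variant_truth]
        if any(a >= b for a, b in zip(positions, positions[1:])):
            raise InvalidArgumentError(
                "variant positions must be strictly increasing"
            )
        if reference_length is not None and any(
            not 1 <= p <= reference_length for p in positions
        ):
            raise InvalidArgumentError("variant position outside reference")
        spans = sorted(
            (start, start + length - 1) for start, length in self.deletion_truth
        )
        if any(b0 <= a1 for (_, a1), (b0, _) in zip(spans, spans[1:])):
            raise InvalidArgumentError("deletion intervals overlap")


def generate_reference_cds(length: int, seed: int) -> str:
    """Random CDS of ``length`` bases with no internal in-frame stop codon.

    Codons are drawn uniformly from the 61 sense codons of the standard
    genetic code; deterministic for a fixed seed.
    """
    if length < 3 or length % 3 != 0:
        raise InvalidArgumentError(
            f"length must be a positive multiple of 3, got {length}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(SENSE_CODONS), size=length // 3)
    return "".join(SENSE_CODONS[i] for i in idx)


def _is_synonymous(pos: int, ref: str, alt: str, reference: str) -> bool:
    try:
        *_, effect = annotate_codon_effect(pos, ref, alt, reference, 1)
    except Exception:
        return False
    return effect == "synonymous"


def _candidate_positions(
    reference: str,
    ref_base: str,
    alt_base: str,
    blocked: set[int],
    synonymous_only: bool,
) -> list[int]:
    out = []
    for pos0, base in enumerate(reference):
        pos = pos0 + 1
        if base != ref_base or pos in blocked:
            continue
        if synonymous_only and not _is_synonymous(
            pos, ref_base, alt_base, reference
        ):
            continue
        out.append(pos)
    return out


def _place_named_change(
    reference: str,
    profile: SubstitutionProfile,
    blocked: set[int],
    rng: np.random.Generator,
) -> list[tuple[int, str, str]]:
    """Substitutions realizing the profile's named amino-acid change.

    Placed at the profile's codon index when that reference codon encodes
    the source amino acid, otherwise at the first feasible codon. A change
    that no single substitution can produce (e.g. Val -> Lys) is realized by
    the minimal multi-base change of one codon, each base recorded as its
    own substitution event.
    """
    change = profile.aa_change
    if change is None:
        return []
    n_codons = len(reference) // 3
    to_codons = sorted(
        c for c in SENSE_CODONS if translate_codon(c) == change.to_aa
    )
    if not to_codons:
        raise InvalidProfileError(f"no codon encodes {change.to_aa!r}")

    candidates = []
    if 1 <= change.codon_index <= n_codons:
        candidates.append(change.codon_index)
    candidates.extend(i for i in range(1, n_codons + 1) if i != change.codon_index)

    for ci in candidates:
        start = 3 * (ci - 1)  # 0-based
        ref_codon = reference[start : start + 3]
        if translate_codon(ref_codon) != change.from_aa:
            continue
        # minimal-distance target codon other than the reference codon
        # itself (a synonymous change still needs a base to differ)
        targets = [c for c in to_codons if c != ref_codon]
        if not targets:
            continue
        best = min(
            targets,
            key=lambda c: (sum(a != b for a, b in zip(ref_codon, c)), c),
        )
        events = [
            (start + k + 1, ref_codon[k], best[k])
            for k in range(3)
            if ref_codon[k] != best[k]
        ]
        if events and all(pos not in blocked for pos, _, _ in events):
            return events
    raise PlacementFailureError(
        f"{profile.cultivar}: no free codon realizes "
        f"{change.from_aa}->{change.to_aa}"
    )


def implant_variants(
    reference: str,
    profile: SubstitutionProfile,
    deletion_spec: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[str, TruthSet]:
    """Derive a cultivar sequence from the reference per its SNP spectrum.

    Exactly ``profile.n_snp_sites`` columns are substituted (no column twice):
    the explicitly listed types at their exact counts, one realization of the
    named amino-acid change, and the remainder drawn from substitution pairs
    of the profile's purine/pyrimidine class. For a wholly synonymous
    spectrum every substitution is placed at a silently mutable site. A
    ``deletion_spec`` of (1-based start, length) adds a contiguous gap run;
    deleted columns carry no substitutions. The returned sequence is gapped
    to the reference's length; the TruthSet records every implanted event.
    """
    reference = reference.upper()
    if set(reference) - set("ACGT"):
        raise InvalidArgumentError("reference must be ungapped A/C/G/T")
    if len(reference) < 3 * profile.n_snp_sites:
        raise InvalidArgumentError(
            f"reference of {len(reference)} bases is too short for "
            f"{profile.n_snp_sites} SNP sites (need >= 3x)"
        )
    rng = np.random.default_rng(seed)

    blocked: set[int] = set()
    deletion_truth: list[tuple[int, int]] = []
    if deletion_spec is not None:
        start, length = deletion_spec
        if length < 1 or start < 1 or start + length - 1 > len(reference):
            raise InvalidArgumentError(
                f"deletion ({start}, {length}) outside reference"
            )
        blocked.update(range(start, start + length))
        deletion_truth.append((start, length))

    synonymous_only = profile.mutation_type == "synonymous"
    events: list[tuple[int, str, str]] = []

    named = _place_named_change(reference, profile, blocked, rng)
    quotas = {(r, a): n for r, a, n in profile.listed_types}
    for pos, ref_b, alt_b in named:
        events.append((pos, ref_b, alt_b))
        blocked.add(pos)
        if quotas.get((ref_b, alt_b), 0) > 0:
            quotas[(ref_b, alt_b)] -= 1

    n_remaining = profile.n_snp_sites - len(events) - sum(quotas.values())
    if n_remaining < 0:
        raise InvalidProfileError(
            f"{profile.cultivar}: listed counts plus the named change exceed "
            f"n_snp_sites={profile.n_snp_sites}"
        )

    for (ref_b, alt_b), count in quotas.items():
        if count == 0:
            continue
        pool = _candidate_positions(
            reference, ref_b, alt_b, blocked, synonymous_only
        )
        if len(pool) < count:
            raise PlacementFailureError(
                f"{profile.cultivar}: only {len(pool)} positions admit "
                f"{ref_b}>{alt_b} (need {count})"
            )
        chosen = rng.choice(len(pool), size=count, replace=False)
        for i in chosen:
            events.append((pool[i], ref_b, alt_b))
            blocked.add(pool[i])

    if n_remaining:
        if profile.overall_class not in CLASS_PAIRS:
            raise InvalidProfileError(
                f"{profile.cultivar}: class {profile.overall_class!r} cannot "
                f"supply filler substitutions"
            )
        # A listed type is, by construction, one of the two most frequent:
        # every unlisted pair stays strictly below the smaller listed count.
        cap = (
            min(n for _, _, n in profile.listed_types) - 1
            if profile.listed_types
            else n_remaining
        )
        pair_counts: dict[tuple[str, str], int] = {}
        for pos, ref_b, alt_b in events:
            pair_counts[(ref_b, alt_b)] = pair_counts.get((ref_b, alt_b), 0) + 1
        listed_pairs = {(r, a) for r, a, _ in profile.listed_types}
        placed = 0
        for tier in _filler_pair_tiers(profile):
            if placed == n_remaining:
                break
            union: list[tuple[int, str, str]] = []
            for ref_b, alt_b in tier:
                union.extend(
                    (pos, ref_b, alt_b)
                    for pos in _candidate_positions(
                        reference, ref_b, alt_b, blocked, synonymous_only
                    )
                )
            for i in rng.permutation(len(union)):
                pos, ref_b, alt_b = union[i]
                pair = (ref_b, alt_b)
                if pos in blocked:
                    continue
                if pair not in listed_pairs and pair_counts.get(pair, 0) >= cap:
                    continue
                events.append((pos, ref_b, alt_b))
                blocked.add(pos)
                pair_counts[pair] = pair_counts.get(pair, 0) + 1
                placed += 1
                if placed == n_remaining:
                    break
        if placed < n_remaining:
            raise PlacementFailureError(
                f"{profile.cultivar}: reference exhausted after {placed} of "
                f"{n_remaining} filler substitutions"
            )

    mutant = list(reference)
    for pos, _, alt_b in events:
        mutant[pos - 1] = alt_b
    for start, length in deletion_truth:
        mutant[start - 1 : start - 1 + length] = "-" * length

    variant_truth = []
    for pos, ref_b, alt_b in sorted(events):
        try:
            *_, effect = annotate_codon_effect(pos, ref_b, alt_b, reference, 1)
        except Exception:
            effect = None
        variant_truth.append((pos, ref_b, alt_b, effect))
    truth = TruthSet(
        variant_truth=variant_truth, deletion_truth=deletion_truth
    )
    truth.validate(reference_length=len(reference))
    return "".join(mutant), truth


def generate_alignment(
    profiles: Sequence[SubstitutionProfile],
    length: int = 600,
    seed: int = 0,
    reference_label: str = "Ancestral",
    deletion_spec: tuple[int, int] | None = None,
    deletion_cultivars: Iterable[str] | None = None,
) -> tuple[AlignmentSet, dict[str, TruthSet]]:
    """One reference plus one implanted sequence per profile.

    ``deletion_spec`` (if given) is applied to ``deletion_cultivars``
    (default: every cultivar with a non-synonymous spectrum, mirroring the
    shared deletion of the dichotomous cultivars).
    """
    if not profiles:
        raise InvalidArgumentError("at least one substitution profile needed")
    reference = generate_reference_cds(length, seed)
    if deletion_cultivars is None:
        deletion_cultivars = {
            p.cultivar for p in profiles if p.mutation_type == "non-synonymous"
        }
    else:
        deletion_cultivars = set(deletion_cultivars)
    rng = np.random.default_rng(seed)
    sequences = {reference_label: reference}
    truths: dict[str, TruthSet] = {}
    for prof in profiles:
        sub_seed = int(rng.integers(0, 2**31))
        deletion = (
            deletion_spec if prof.cultivar in deletion_cultivars else None
        )
        mutant, truth = implant_variants(reference, prof, deletion, sub_seed)
        sequences[prof.cultivar] = mutant
        truths[prof.cultivar] = truth
    return (
        AlignmentSet(sequences=sequences, reference_label=reference_label),
        truths,
    )


def generate_phenology(
    profiles: Sequence[CultivarProfile],
    n_plants_per_cultivar: int = 10,
    n_ratoon_obs_per_plant: int = 2,
    seed: int = 0,
) -> tuple[list[PhenologyRecord], TruthSet]:
    """Simulated bunch-count table across plant and ratoon crop cycles.

    Every plant shows its cultivar's plant-crop phenotype in the plant crop;
    each ratoon observation independently repeats it with the cultivar's
    concordance probability and otherwise reverts to one of the two other
    bunch counts, uniformly. Observations alternate between the first and
    second ratoon cycles.
    """
    if not profiles:
        raise InvalidArgumentError("at least one cultivar profile needed")
    if n_plants_per_cultivar < 1 or n_ratoon_obs_per_plant < 1:
        raise InvalidArgumentError("plant and observation counts must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[PhenologyRecord] = []
    truth = TruthSet()
    for prof in profiles:
        for i in range(n_plants_per_cultivar):
            plant_id = f"{prof.label}-{i + 1:02d}"
            base = prof.plant_crop_bunches
            records.append(
                PhenologyRecord(plant_id, prof.label, "plant", base)
            )
            ratoon_obs = []
            for j in range(n_ratoon_obs_per_plant):
                if rng.random() < prof.ratoon_concordance_prob:
                    bunches = base
                else:
                    others = [b for b in (1, 2, 3) if b != base]
                    bunches = others[int(rng.integers(0, len(others)))]
                cycle = RATOON_CYCLES[j % 2]
                records.append(
                    PhenologyRecord(plant_id, prof.label, cycle, bunches)
                )
                ratoon_obs.append(bunches)
            truth.phenotype_truth[plant_id] = {
                "plant": base,
                "ratoon": ratoon_obs,
            }
    return records, truth


def generate_flow_histogram(
    ploidy: int,
    control_ploidy: int = 3,
    control_channel: float = 75.0,
    n_nuclei: int = 5000,
    cv: float = 0.03,
    debris_fraction: float = 0.10,
    n_channels: int = 256,
    seed: int = 0,
    plant_id: str = "sample",
) -> FlowHistogram:
    """DNA-content histogram for one plant measured with an internal control.

    The sample peak sits at control_channel x ploidy / control_ploidy with
    standard deviation cv x center; the internal-standard peak sits at
    control_channel; debris decays geometrically over the lowest 20% of
    channels. Nuclei are multinomially distributed, so counts sum to
    ``n_nuclei`` exactly. Non-debris nuclei split evenly between sample and
    control (the two peaks merge when the ploidies coincide).
    """
    if ploidy < 1 or control_ploidy < 1:
        raise InvalidArgumentError("ploidies must be >= 1")
    if not 0 < cv < 0.5:
        raise InvalidArgumentError("cv must lie in (0, 0.5)")
    if not 0 <= debris_fraction < 1:
        raise InvalidArgumentError("debris_fraction must lie in [0, 1)")
    if control_channel <= 0 or n_channels < 2 or n_nuclei < 0:
        raise InvalidArgumentError("bad channel/nucleus parameters")
    center = control_channel * ploidy / control_ploidy
    if center > n_channels or control_channel > n_channels:
        raise InvalidArgumentError(
            f"peak at channel {center:.1f} exceeds n_channels={n_channels}; "
            f"rescale control_channel"
        )

    channels = np.arange(1, n_channels + 1, dtype=float)

    def gaussian(mu: float) -> np.ndarray:
        sd = cv * mu
        w = np.exp(-0.5 * ((channels - mu) / sd) ** 2)
        return w / w.sum()

    n_debris_ch = max(1, int(0.2 * n_channels))
    debris = np.zeros(n_channels)
    debris[:n_debris_ch] = 0.7 ** np.arange(n_debris_ch)
    debris /= debris.sum()

    p = debris_fraction * debris + (1 - debris_fraction) * 0.5 * (
        gaussian(center) + gaussian(control_channel)
    )
    p /= p.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_nuclei, p)
    return FlowHistogram(
        plant_id=plant_id,
        channels=tuple(range(1, n_channels + 1)),
        counts=tuple(int(c) for c in counts),
    )


def generate_cohort(
    composition: Sequence[tuple[int, int]],
    seed: int = 0,
    **flow_params,
) -> tuple[list[FlowHistogram], TruthSet]:
    """One histogram per plant for a cohort of known ploidy composition.

    ``composition`` is a list of (ploidy, n_plants); ``flow_params`` are
    forwarded to :func:`generate_flow_histogram`. Each plant draws its own
    sub-seed from the master seed, so cohorts are reproducible as a whole.
    """
    if not composition:
        raise InvalidArgumentError("composition must be non-empty")
    if any(n < 0 for _, n in composition):
        raise InvalidArgumentError("composition counts must be >= 0")
    rng = np.random.default_rng(seed)
    histograms: list[FlowHistogram] = []
    truth = TruthSet()
    i = 0
    for ploidy, n in composition:
        for _ in range(n):
            plant_id = f"plant{i + 1:03d}"
            sub_seed = int(rng.integers(0, 2**31))
            histograms.append(
                generate_flow_histogram(
                    ploidy, seed=sub_seed, plant_id=plant_id, **flow_params
                )
            )
            truth.ploidy_truth[plant_id] = ploidy
            i += 1
    return histograms, truth


def generate_cytology(
    ploidy_by_plant: dict[str, int],
    basic_number: int = BASIC_CHROMOSOME_NUMBER,
    n_cells: int = 10,
    miscount_prob: float = 0.1,
    seed: int = 0,
) -> tuple[list[CytologyObservation], TruthSet]:
    """Per-cell metaphase chromosome-count tables with occasional miscounts.

    Each cell reports 2n = ploidy x basic_number, except with probability
    ``miscount_prob`` it is off by one chromosome (squash damage). The modal
    count per plant therefore stays exact whenever miscounts stay in the
    minority.
    """
    if n_cells < 1:
        raise InvalidArgumentError("n_cells must be >= 1")
    if not 0 <= miscount_prob < 0.5:
        raise InvalidArgumentError("miscount_prob must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    observations = []
    truth = TruthSet()
    for plant_id, ploidy in ploidy_by_plant.items():
        true_count = ploidy * basic_number
        cells = []
        for _ in range(n_cells):
            c = true_count
            if rng.random() < miscount_prob:
                c += int(rng.choice([-1, 1]))
            cells.append(c)
        observations.append(CytologyObservation(plant_id, tuple(cells)))
        truth.ploidy_truth[plant_id] = ploidy
    return observations, truth


def default_panel_profiles() -> list[CultivarProfile]:
    """The built-in six-cultivar panel in its canonical order."""
    return list(CULTIVAR_PANEL.values())
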