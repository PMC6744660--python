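"""Built-in parameter panel for the six False Horn plantain cultivars.

The study system is a single-bunching control ('Agbagba', a stable triploid)
plus five inflorescence-dichotomous cultivars: two double-bunching (DB1P,
DB2P) and three triple-bunching (TB1P-TB3P), predominantly diploid. Each
cultivar carries

* its plant-crop bunch phenotype (1, 2 or 3 bunches per pseudostem),
* the probability that a ratoon-cycle observation repeats that phenotype
  (the field-observed concordance coefficient, used directly as the
  simulation's per-observation concordance probability),
* its modal ploidy (multiplier of the Musa basic number x = 11), and
* the substitution spectrum of its GTPase-protein-binding gene region
  relative to an ancestral reference: total SNP-site count, the two most
  frequent substitution types with their counts, the dominant purine/
  pyrimidine pattern, and one named amino-acid change with its codon index.

These numbers are the defaults the synthetic generators emulate; they are
plain data, so callers can supply their own panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AminoAcidChange:
    """A named codon-level change, e.g. Gly -> Val at codon 27 (1-based)."""

    from_aa: str
    codon_index: int
    to_aa: str

    @property
    def synonymous(self) -> bool:
        return self.from_aa == self.to_aa


@dataclass(frozen=True)
class SubstitutionProfile:
    """Per-cultivar SNP spectrum against the reference.

    ``listed_types`` are the explicitly counted substitution types; they may
    under-sum ``n_snp_sites``, in which case the remainder belongs to
    ``overall_class`` (a purine/pyrimidine pattern such as "Py-Pu" that also
    fixes transition vs transversion). ``mutation_type`` is "synonymous" only
    when every substitution in the spectrum is silent.
    """

    cultivar: str
    n_snp_sites: int
    listed_types: tuple[tuple[str, str, int], ...]
    overall_class: str  # "Pu-Pu", "Py-Py", "Pu-Py" or "Py-Pu"
    aa_change: AminoAcidChange | None
    mutation_type: str  # "synonymous" | "non-synonymous"

    def __post_init__(self) -> None:
        from .errors import InvalidProfileError

        if self.n_snp_sites < 0:
            raise InvalidProfileError("n_snp_sites must be non-negative")
        listed = sum(n for _, _, n in self.listed_types)
        if listed > self.n_snp_sites:
            raise InvalidProfileError(
                f"{self.cultivar}: listed substitution counts ({listed}) "
                f"exceed n_snp_sites ({self.n_snp_sites})"
            )
        if self.overall_class not in {
            "Pu-Pu",
            "Py-Py",
            "Pu-Py",
            "Py-Pu",
            "undefined",  # empty spectrum
        }:
            raise InvalidProfileError(
                f"unknown substitution class {self.overall_class!r}"
            )
        if self.aa_change is not None:
            syn = self.aa_change.synonymous
            if syn != (self.mutation_type == "synonymous"):
                raise InvalidProfileError(
                    f"{self.cultivar}: mutation_type {self.mutation_type!r} "
                    f"inconsistent with amino-acid change "
                    f"{self.aa_change.from_aa}->{self.aa_change.to_aa}"
                )


@dataclass(frozen=True)
class CultivarProfile:
    """Everything the generators need to emulate one cultivar."""

    label: str
    plant_crop_bunches: int
    ratoon_concordance_prob: float
    ploidy_truth: int
    substitution_profile: SubstitutionProfile | None = field(default=None)

    def __post_init__(self) -> None:
        from .errors import InvalidArgumentError

        if self.plant_crop_bunches not in (1, 2, 3):
            raise InvalidArgumentError("plant_crop_bunches must be 1, 2 or 3")
        if not 0.0 <= self.ratoon_concordance_prob <= 1.0:
            raise InvalidArgumentError(
                "ratoon_concordance_prob must lie in [0, 1]"
            )
        if self.ploidy_truth < 1:
            raise InvalidArgumentError("ploidy_truth must be >= 1")


SUBSTITUTION_PROFILES: dict[str, SubstitutionProfile] = {
    "Agbagba": SubstitutionProfile(
        cultivar="Agbagba",
        n_snp_sites=55,
        listed_types=(("G", "A", 26), ("A", "G", 12)),
        overall_class="Pu-Pu",
        aa_change=AminoAcidChange("Lys", 14, "Lys"),
        mutation_type="synonymous",
    ),
    "DB1P": SubstitutionProfile(
        cultivar="DB1P",
        n_snp_sites=82,
        listed_types=(("T", "G", 46), ("C", "A", 23)),
        overall_class="Py-Pu",
        aa_change=AminoAcidChange("Gly", 27, "Val"),
        mutation_type="non-synonymous",
    ),
    "DB2P": SubstitutionProfile(
        cultivar="DB2P",
        n_snp_sites=77,
        listed_types=(("A", "C", 33), ("G", "T", 12)),
        overall_class="Pu-Py",
        aa_change=AminoAcidChange("Leu", 16, "Pro"),
        mutation_type="non-synonymous",
    ),
    "TB1P": SubstitutionProfile(
        cultivar="TB1P",
        n_snp_sites=81,
        listed_types=(("T", "A", 40), ("C", "G", 18)),
        overall_class="Py-Pu",
        aa_change=AminoAcidChange("Val", 22, "Lys"),
        mutation_type="non-synonymous",
    ),
    "TB2P": SubstitutionProfile(
        cultivar="TB2P",
        n_snp_sites=79,
        listed_types=(("A", "T", 33), ("C", "A", 19)),
        overall_class="Py-Pu",
        aa_change=AminoAcidChange("Leu", 23, "Gly"),
        mutation_type="non-synonymous",
    ),
    "TB3P": SubstitutionProfile(
        cultivar="TB3P",
        n_snp_sites=86,
        listed_types=(("G", "C", 28), ("T", "G", 21)),
        overall_class="Pu-Py",
        aa_change=AminoAcidChange("Gly", 19, "Val"),
        mutation_type="non-synonymous",
    ),
}

# Field panel: 10 plants per cultivar, bunch phenotype repeated across two
# ratoon cycles with the cultivar's observed concordance probability.
CULTIVAR_PANEL: dict[str, CultivarProfile] = {
    "Agbagba": CultivarProfile(
        "Agbagba", 1, 1.00, 3, SUBSTITUTION_PROFILES["Agbagba"]
    ),
    "DB1P": CultivarProfile("DB1P", 2, 0.65, 2, SUBSTITUTION_PROFILES["DB1P"]),
    "DB2P": CultivarProfile("DB2P", 2, 0.45, 2, SUBSTITUTION_PROFILES["DB2P"]),
    "TB1P": CultivarProfile("TB1P", 3, 0.15, 2, SUBSTITUTION_PROFILES["TB1P"]),
    "TB2P": CultivarProfile("TB2P", 3, 0.05, 2, SUBSTITUTION_PROFILES["TB2P"]),
    "TB3P": CultivarProfile("TB3P", 3, 0.00, 2, SUBSTITUTION_PROFILES["TB3P"]),
}

# Ratoon-cycle flow-cytometry cohort: 100 plants (5 dichotomous cultivars x
# 10 plants x 2 ratoon cycles), of which 95 presented diploid and 5
# tetraploid DNA-content peaks against the triploid internal control.
RATOON_COHORT_COMPOSITION: tuple[tuple[int, int], ...] = ((2, 95), (4, 5))

# Musa basic chromosome number: 2x = 22, 3x = 33.
BASIC_CHROMOSOME_NUMBER = 11
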