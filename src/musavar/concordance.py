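"""Crop-cycle concordance of bunch phenotypes.

A plantain stool fruits repeatedly: the initial plant crop is followed by
first and second ratoon crops regrown from suckers. The concordance
coefficient (CC) of a cultivar measures how faithfully the bunch phenotype
(number of bunches per pseudostem, 1-3) observed in the plant crop is
repeated in the ratoon crops:

    CC = sum_i N_ii / (sum_i N_ii + sum_ij N_ij),  i != j

where N_ii counts ratoon observations that match the same plant's plant-crop
bunch count and N_ij counts those that differ. CC = 1 means the phenotype is
fully persistent across cycles; CC ~ 0 means it recurs at random. Both ratoon
cycles are pooled into one denominator, and dead or missing ratoon
observations are excluded. CC is reported on [0, 1] by default (the scale the
per-cultivar classifications use), with an optional percent output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InvalidArgumentError, UndefinedConcordanceError

CYCLES = ("plant", "ratoon1", "ratoon2")
RATOON_CYCLES = ("ratoon1", "ratoon2")


@dataclass(frozen=True)
class PhenologyRecord:
    """One plant's bunch phenotype in one crop cycle.

    ``bunches`` is None for a dead/missing observation; such records are
    excluded from concordance. ``peduncles`` (how many stalks carry the
    bunches) is recorded but never enters the coefficient: the persistence
    classes are defined on bunch count alone.
    """

    plant_id: str
    cultivar: str
    cycle: str
    bunches: int | None
    peduncles: int | None = None

    def __post_init__(self) -> None:
        if self.cycle not in CYCLES:
            raise InvalidArgumentError(
                f"cycle must be one of {CYCLES}, got {self.cycle!r}"
            )
        if self.bunches is not None and not 1 <= self.bunches <= 3:
            raise InvalidArgumentError("bunches must be in 1..3 or None")


@dataclass(frozen=True)
class ConcordanceSummary:
    cultivar: str
    n_plants: int
    n_concordant: int
    n_discordant: int
    cc: float
    occurrence: str | None = None
    persistence: str | None = None

    @property
    def n_ratoon_obs(self) -> int:
        return self.n_concordant + self.n_discordant


def compute_concordance(
    records: Iterable[PhenologyRecord],
    cultivar: str,
    percent: bool = False,
) -> ConcordanceSummary:
    """Compute the pooled-ratoon concordance coefficient for one cultivar.

    Parameters
    ----------
    records
        Phenology records for any number of cultivars; only ``cultivar``'s
        are used. Each plant must have exactly one plant-cycle record.
    cultivar
        Label to summarize.
    percent
        If True, report CC on [0, 100] instead of [0, 1].

    Raises
    ------
    UndefinedConcordanceError
        If the cultivar has no live ratoon observations (CC is undefined,
        not zero).
    InvalidArgumentError
        If a plant has no or several plant-crop records.
    """
    mine = [r for r in records if r.cultivar == cultivar]
    plant_crop: dict[str, int] = {}
    for rec in mine:
        if rec.cycle == "plant":
            if rec.plant_id in plant_crop:
                raise InvalidArgumentError(
                    f"plant {rec.plant_id!r} has multiple plant-crop records"
                )
            if rec.bunches is None:
                raise InvalidArgumentError(
                    f"plant {rec.plant_id!r} has no plant-crop bunch count"
                )
            plant_crop[rec.plant_id] = rec.bunches

    n_concordant = 0
    n_discordant = 0
    for rec in mine:
        if rec.cycle not in RATOON_CYCLES or rec.bunches is None:
            continue  # dead/missing ratoon observations are excluded
        if rec.plant_id not in plant_crop:
            raise InvalidArgumentError(
                f"ratoon record for plant {rec.plant_id!r} has no "
                f"plant-crop record"
            )
        if rec.bunches == plant_crop[rec.plant_id]:
            n_concordant += 1
        else:
            n_discordant += 1

    total = n_concordant + n_discordant
    if total == 0:
        raise UndefinedConcordanceError(
            f"cultivar {cultivar!r} has no ratoon observations"
        )
    cc = n_concordant / total
    if percent:
        cc *= 100.0
    return ConcordanceSummary(
        cultivar=cultivar,
        n_plants=len(plant_crop),
        n_concordant=n_concordant,
        n_discordant=n_discordant,
        cc=cc,
    )


def classify_persistence(
    summary: ConcordanceSummary, threshold: float = 1.0
) -> tuple[str, str]:
    """Classify occurrence/persistence of the dichotomy from CC.

    CC >= threshold -> ("Normal", "Persistent"); anything below marks the
    phenotype as randomly recurring and non-persistent. The default
    threshold of 1.0 reflects that any reversal at all disqualifies a
    cultivar from the persistent class.
    """
    if not 0.0 <= threshold <= 1.0:
        raise InvalidArgumentError("threshold must lie in [0, 1]")
    cc = summary.cc
    if cc > 1.0:  # percent-scale summary
        cc /= 100.0
    if cc >= threshold:
        return ("Normal", "Persistent")
    return ("Random", "Non-persistent")


def summarize_cultivars(
    records: Sequence[PhenologyRecord],
    cultivars: Sequence[str] | None = None,
    threshold: float = 1.0,
) -> list[ConcordanceSummary]:
    """Concordance summaries, with classification, for each cultivar."""
    if cultivars is None:
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.cultivar, None)
        cultivars = list(seen)
    out = []
    for cv in cultivars:
        s = compute_concordance(records, cv)
        occ, per = classify_persistence(s, threshold)
        out.append(
            ConcordanceSummary(
                cultivar=s.cultivar,
                n_plants=s.n_plants,
                n_concordant=s.n_concordant,
                n_discordant=s.n_discordant,
                cc=s.cc,
                occurrence=occ,
                persistence=per,
            )
        )
    return out
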