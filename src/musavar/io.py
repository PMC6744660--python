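"""Text-format readers and writers.

Everything is plain UTF-8 text with LF line endings: gapped multi-FASTA
(60-column wrapped), phenology CSV, cytology CSV, per-plant histogram TSVs
with a manifest CSV, summary TSV tables, a minimal VCF for the SNP calls,
and truth tables. FASTA parsing goes through Biopython and then enforces the
pipeline's alphabet and label-uniqueness contracts, naming the offending
record in every error.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .concordance import ConcordanceSummary, PhenologyRecord
from .errors import FormatError
from .ploidy import CytologyObservation, FlowHistogram, PloidyCall
from .profiles import SubstitutionProfile
from .variants import ALIGNMENT_ALPHABET, IndelRecord, SNPRecord

# -- FASTA --------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered label -> uppercased sequence map from a (gapped) FASTA file."""
    path = Path(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate label {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - ALIGNMENT_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-nucleotide "
                f"characters {sorted(bad)}"
            )
        out[rec.id] = seq
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(
    sequences: dict[str, str], path: str | Path, width: int = 60
) -> None:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for label, seq in sequences.items():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- Phenology CSV ------------------------------------------------------

PHENOLOGY_HEADER = ["plant_id", "cultivar", "cycle", "bunches"]


def read_phenology_csv(path: str | Path) -> list[PhenologyRecord]:
    """Phenology table (plant_id,cultivar,cycle,bunches); an empty bunches
    field marks a dead/missing observation."""
    path = Path(path)
    records: list[PhenologyRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            c.strip() for c in reader.fieldnames
        ] != PHENOLOGY_HEADER:
            raise FormatError(
                f"{path}: expected header {','.join(PHENOLOGY_HEADER)}"
            )
        for i, row in enumerate(reader, start=2):
            raw = (row["bunches"] or "").strip()
            try:
                bunches = int(raw) if raw else None
                records.append(
                    PhenologyRecord(
                        plant_id=row["plant_id"].strip(),
                        cultivar=row["cultivar"].strip(),
                        cycle=row["cycle"].strip(),
                        bunches=bunches,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{i}: bad phenology row ({exc})")
    return records


def write_phenology_csv(
    records: Iterable[PhenologyRecord], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PHENOLOGY_HEADER)
        for r in records:
            writer.writerow(
                [r.plant_id, r.cultivar, r.cycle, "" if r.bunches is None else r.bunches]
            )


def write_concordance_table(
    summaries: Sequence[ConcordanceSummary], path: str | Path
) -> None:
    """Per-cultivar concordance table in the field-report layout."""
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "cultivar\tplant_crop_n\tratoon_n\tconcordant_n\tcc\t"
            "occurrence\tpersistence\n"
        )
        for s in summaries:
            fh.write(
                f"{s.cultivar}\t{s.n_plants}\t{s.n_ratoon_obs}\t"
                f"{s.n_concordant}\t{s.cc:.2f}\t{s.occurrence or ''}\t"
                f"{s.persistence or ''}\n"
            )


# -- Cytology CSV -------------------------------------------------------

CYTOLOGY_HEADER = ["plant_id", "cell_index", "chromosome_count"]


def read_cytology_csv(path: str | Path) -> list[CytologyObservation]:
    path = Path(path)
    per_plant: dict[str, list[int]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            c.strip() for c in reader.fieldnames
        ] != CYTOLOGY_HEADER:
            raise FormatError(
                f"{path}: expected header {','.join(CYTOLOGY_HEADER)}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                per_plant.setdefault(row["plant_id"].strip(), []).append(
                    int(row["chromosome_count"])
                )
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{i}: bad cytology row ({exc})")
    return [
        CytologyObservation(pid, tuple(counts))
        for pid, counts in per_plant.items()
    ]


def write_cytology_csv(
    observations: Iterable[CytologyObservation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CYTOLOGY_HEADER)
        for obs in observations:
            for i, count in enumerate(obs.cell_counts, start=1):
                writer.writerow([obs.plant_id, i, count])


# -- Flow histograms ----------------------------------------------------


def read_histogram_tsv(path: str | Path, plant_id: str | None = None) -> FlowHistogram:
    """channel<TAB>count file; plant_id defaults to the file stem."""
    path = Path(path)
    channels: list[int] = []
    counts: list[int] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["channel", "count"]:
            raise FormatError(f"{path}: expected header channel\\tcount")
        for i, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                ch, ct = line.split("\t")
                channels.append(int(ch))
                counts.append(int(ct))
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: bad histogram row ({exc})")
    return FlowHistogram(
        plant_id=plant_id or path.stem,
        channels=tuple(channels),
        counts=tuple(counts),
    )


def write_histogram_tsv(histogram: FlowHistogram, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("channel\tcount\n")
        for ch, ct in zip(histogram.channels, histogram.counts):
            fh.write(f"{ch}\t{ct}\n")


def write_flow_manifest(
    entries: Sequence[tuple[str, str]], path: str | Path
) -> None:
    """Manifest CSV mapping plant_id to its histogram TSV path."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["plant_id", "path"])
        writer.writerows(entries)


def read_flow_manifest(path: str | Path) -> list[FlowHistogram]:
    path = Path(path)
    histograms = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            c.strip() for c in reader.fieldnames
        ] != ["plant_id", "path"]:
            raise FormatError(f"{path}: expected header plant_id,path")
        for row in reader:
            hist_path = Path(row["path"])
            if not hist_path.is_absolute():
                hist_path = path.parent / hist_path
            histograms.append(
                read_histogram_tsv(hist_path, plant_id=row["plant_id"].strip())
            )
    return histograms


def write_ploidy_table(
    calls: Sequence[PloidyCall],
    refused: Sequence[tuple[str, str]],
    path: str | Path,
) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("plant_id\tmethod\tploidy\tchromosome_number\t"
                 "peak_channel\tratio_to_control\tstatus\n")
        for c in calls:
            fh.write(
                f"{c.plant_id}\t{c.method}\t{c.ploidy}x\t"
                f"{c.chromosome_number if c.chromosome_number is not None else ''}\t"
                f"{'' if c.peak_channel is None else f'{c.peak_channel:g}'}\t"
                f"{'' if c.ratio_to_control is None else f'{c.ratio_to_control:.3f}'}\t"
                f"called\n"
            )
        for plant_id, reason in refused:
            fh.write(f"{plant_id}\t\t\t\t\t\trefused: {reason}\n")


# -- Variant outputs ----------------------------------------------------


def write_vcf(
    snps: Sequence[SNPRecord],
    reference_label: str,
    sample: str,
    path: str | Path,
) -> None:
    """Minimal single-sample VCF: one line per substitution, INFO carrying
    the chemical class, codon index and effect. Consensus haplotypes carry
    no genotype columns."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference_label}\n")
        fh.write(f"##sample={sample}\n")
        fh.write(
            '##INFO=<ID=SUBST,Number=1,Type=String,'
            'Description="transition or transversion">\n'
        )
        fh.write(
            '##INFO=<ID=CODON,Number=1,Type=Integer,'
            'Description="1-based codon index">\n'
        )
        fh.write(
            '##INFO=<ID=EFFECT,Number=1,Type=String,'
            'Description="synonymous or non-synonymous">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in snps:
            info = [f"SUBST={r.subst_class}"]
            if r.codon_index is not None:
                info.append(f"CODON={r.codon_index}")
            if r.effect is not None:
                info.append(f"EFFECT={r.effect}")
            fh.write(
                f"{reference_label}\t{r.position}\t.\t{r.ref_base}\t"
                f"{r.alt_base}\t.\tPASS\t{';'.join(info)}\n"
            )


def read_vcf(path: str | Path) -> list[tuple[int, str, str, dict[str, str]]]:
    """Rows of (pos, ref, alt, info-dict) from a minimal VCF."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, _, info = line.rstrip("\n").split("\t")
            info_d = dict(
                kv.split("=", 1) for kv in info.split(";") if "=" in kv
            )
            rows.append((int(pos), ref, alt, info_d))
    return rows


def write_substitution_table(
    profiles: Sequence[SubstitutionProfile],
    path: str | Path,
) -> None:
    """Per-cultivar SNP-spectrum table (site counts, top substitution types,
    class, amino-acid change, mutation type)."""
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "cultivar\tn_snp_sites\ttop_substitutions\tsubstitution_class\t"
            "amino_acid_change\tmutation_type\n"
        )
        for p in profiles:
            tops = " / ".join(f"{n}{r}>{a}" for r, a, n in p.listed_types)
            aa = (
                f"{p.aa_change.from_aa} {p.aa_change.codon_index} "
                f"{p.aa_change.to_aa}"
                if p.aa_change
                else ""
            )
            fh.write(
                f"{p.cultivar}\t{p.n_snp_sites}\t{tops}\t{p.overall_class}\t"
                f"{aa}\t{p.mutation_type}\n"
            )


def write_indel_table(
    indels: dict[str, Sequence[IndelRecord]], path: str | Path
) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("cultivar\tstart\tlength\tkind\n")
        for cultivar, records in indels.items():
            for r in records:
                fh.write(f"{cultivar}\t{r.start}\t{r.length}\t{r.kind}\n")


def write_truth_tsv(rows: Sequence[Sequence], header: Sequence[str], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
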