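"""End-to-end pipeline: simulate -> concordance -> snp-call -> ploidy-call
-> report.

Every stage draws its randomness from a sub-seed derived from the master
seed and the stage name, logs its parameters, and writes plain-text
artifacts into the configured output directory. Re-running with the same
configuration reproduces the output tree byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io, ploidy, synthdata, variants
from .concordance import summarize_cultivars
from .config import RunConfig
from .errors import MusavarError
from .profiles import CULTIVAR_PANEL

log = logging.getLogger("musavar")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; return a report bundle of artifact
    paths and headline numbers. Any stage error aborts with the stage name
    attached."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "outdir": str(outdir), "stages": {}}

    for stage in config.stages:
        if stage == "report":
            continue
        log.info("stage %s: seed=%d", stage, config.stage_seed(stage))
        try:
            _STAGES[stage](config, outdir, report)
        except MusavarError as exc:
            raise MusavarError(f"stage {stage!r} failed: {exc}") from exc

    if "report" in config.stages:
        report_path = outdir / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        report["stages"]["report"] = {"path": str(report_path)}
    return report


def _simulate(config: RunConfig, outdir: Path, report: dict) -> None:
    seed = config.stage_seed("simulate")
    sim = config.simulate
    panel = list(CULTIVAR_PANEL.values())

    records, _ = synthdata.generate_phenology(
        panel,
        n_plants_per_cultivar=sim.n_plants_per_cultivar,
        n_ratoon_obs_per_plant=sim.n_ratoon_obs_per_plant,
        seed=seed,
    )
    phenology_path = outdir / "phenology.csv"
    io.write_phenology_csv(records, phenology_path)

    profiles = [
        p.substitution_profile for p in panel if p.substitution_profile
    ]
    alignment, truths = synthdata.generate_alignment(
        profiles,
        length=sim.length,
        seed=seed,
        reference_label=config.variants.reference_label,
        deletion_spec=(sim.deletion_start, sim.deletion_length),
    )
    alignment_path = outdir / "alignment.fasta"
    io.write_fasta(alignment.sequences, alignment_path)
    truth_rows = [
        (cv, pos, ref, alt, effect)
        for cv, truth in truths.items()
        for pos, ref, alt, effect in truth.variant_truth
    ]
    io.write_truth_tsv(
        truth_rows,
        ["cultivar", "position", "ref", "alt", "effect"],
        outdir / "variant_truth.tsv",
    )

    ploidy_by_plant = {
        f"{p.label}-{i + 1:02d}": p.ploidy_truth
        for p in panel
        for i in range(sim.n_plants_per_cultivar)
    }
    observations, _ = synthdata.generate_cytology(
        ploidy_by_plant,
        basic_number=config.ploidy.basic_number,
        n_cells=sim.n_cytology_cells,
        miscount_prob=sim.miscount_prob,
        seed=seed,
    )
    cytology_path = outdir / "cytology.csv"
    io.write_cytology_csv(observations, cytology_path)

    control_channel = config.ploidy.control_channel or 75.0
    histograms, cohort_truth = synthdata.generate_cohort(
        [tuple(pair) for pair in sim.composition],
        seed=seed,
        control_ploidy=config.ploidy.control_ploidy,
        control_channel=control_channel,
        n_nuclei=sim.n_nuclei,
        cv=sim.cv,
        debris_fraction=sim.debris_fraction,
        n_channels=sim.n_channels,
    )
    flow_dir = outdir / "flow"
    flow_dir.mkdir(exist_ok=True)
    manifest = []
    for h in histograms:
        hist_path = flow_dir / f"{h.plant_id}.tsv"
        io.write_histogram_tsv(h, hist_path)
        manifest.append((h.plant_id, f"flow/{h.plant_id}.tsv"))
    manifest_path = outdir / "flow_manifest.csv"
    io.write_flow_manifest(manifest, manifest_path)
    io.write_truth_tsv(
        sorted(cohort_truth.ploidy_truth.items()),
        ["plant_id", "ploidy"],
        outdir / "flow_ploidy_truth.tsv",
    )

    report["stages"]["simulate"] = {
        "phenology": str(phenology_path),
        "alignment": str(alignment_path),
        "cytology": str(cytology_path),
        "flow_manifest": str(manifest_path),
        "n_phenology_records": len(records),
        "n_flow_histograms": len(histograms),
    }


def _concordance(config: RunConfig, outdir: Path, report: dict) -> None:
    records = io.read_phenology_csv(outdir / "phenology.csv")
    summaries = summarize_cultivars(
        records, threshold=config.concordance.threshold
    )
    path = outdir / "concordance.tsv"
    io.write_concordance_table(summaries, path)
    report["stages"]["concordance"] = {
        "path": str(path),
        "cc": {s.cultivar: round(s.cc, 4) for s in summaries},
    }


def _snp_call(config: RunConfig, outdir: Path, report: dict) -> None:
    sequences = io.read_fasta(outdir / "alignment.fasta")
    aln = variants.AlignmentSet(
        sequences=sequences,
        reference_label=config.variants.reference_label,
        frame_offset=config.variants.frame_offset,
    )
    profiles = []
    indels = {}
    snp_counts = {}
    for sample in sequences:
        if sample == aln.reference_label:
            continue
        snps = variants.call_snps(aln, sample)
        profiles.append(variants.summarize_cultivar(snps, sample))
        indels[sample] = variants.detect_deletions(aln, sample)
        snp_counts[sample] = len(snps)
        io.write_vcf(
            snps, aln.reference_label, sample, outdir / f"{sample}.vcf"
        )
    spectrum_path = outdir / "substitution_spectra.tsv"
    io.write_substitution_table(profiles, spectrum_path)
    io.write_indel_table(indels, outdir / "deletions.tsv")
    report["stages"]["snp-call"] = {
        "path": str(spectrum_path),
        "n_snp_sites": snp_counts,
    }


def _ploidy_call(config: RunConfig, outdir: Path, report: dict) -> None:
    pl = config.ploidy
    observations = io.read_cytology_csv(outdir / "cytology.csv")
    counting_calls = []
    counting_refused = []
    for obs in observations:
        try:
            counting_calls.append(
                ploidy.count_to_ploidy(obs, pl.basic_number, pl.tolerance)
            )
        except MusavarError as exc:
            counting_refused.append((obs.plant_id, str(exc)))
    io.write_ploidy_table(
        counting_calls, counting_refused, outdir / "ploidy_counting.tsv"
    )

    histograms = io.read_flow_manifest(outdir / "flow_manifest.csv")
    flow_calls, flow_refused = ploidy.call_cohort_flow(
        histograms,
        control_channel=pl.control_channel,
        control_ploidy=pl.control_ploidy,
        max_rel_deviation=pl.max_rel_deviation,
        control_band_frac=pl.control_band_frac,
        smooth_window=pl.smooth_window,
        min_prominence_frac=pl.min_prominence_frac,
        min_channel_frac=pl.min_channel_frac,
    )
    io.write_ploidy_table(
        flow_calls, flow_refused, outdir / "ploidy_flow.tsv"
    )
    summary = ploidy.summarize_cohort(flow_calls, flow_refused)
    report["stages"]["ploidy-call"] = {
        "counting": str(outdir / "ploidy_counting.tsv"),
        "flow": str(outdir / "ploidy_flow.tsv"),
        "flow_tally": {f"{k}x": v for k, v in summary.tally.items()},
        "n_refused": len(summary.refused),
    }


_STAGES = {
    "simulate": _simulate,
    "concordance": _concordance,
    "snp-call": _snp_call,
    "ploidy-call": _ploidy_call,
}
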