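"""Cohort-level summaries and the end-to-end pipeline driver."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, genome as gn, indels, io, signatures, spectra, synthetic
from .stats import SummaryStat, t_test_from_summary

logger = logging.getLogger("mutaccum.reporting")


def summarize_cohort(
    calls: pd.DataFrame, sample_metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-(genotype, treatment) means and sample s.d. of per-sample counts.

    ``sample_metadata`` columns: sample, genotype, treatment. Samples with
    no calls contribute zero counts; calls from samples absent from the
    metadata are an error.
    """
    meta = sample_metadata.set_index("sample")
    unknown = set(calls["sample"]) - set(meta.index)
    if unknown:
        raise ValueError(f"calls from unknown samples: {sorted(unknown)}")
    per_sample = (
        calls.groupby(["sample", "type"]).size().unstack(fill_value=0)
        if len(calls)
        else pd.DataFrame()
    )
    rows = []
    for (genotype, treatment), grp in meta.groupby(
        ["genotype", "treatment"], sort=True
    ):
        entry = {"genotype": genotype, "treatment": treatment, "n": len(grp)}
        for mtype, label in (("SNV", "snv"), ("INS", "ins"), ("DEL", "del")):
            counts = np.array(
                [
                    per_sample.at[s, mtype]
                    if (len(per_sample) and s in per_sample.index
                        and mtype in per_sample.columns)
                    else 0
                    for s in grp.index
                ],
                dtype=float,
            )
            entry[f"{label}_mean"] = counts.mean()
            entry[f"{label}_sd"] = (
                counts.std(ddof=1) if counts.size > 1 else float("nan")
            )
        rows.append(entry)
    return pd.DataFrame(rows)


def fold_change(group_mean: float, baseline_mean: float) -> float:
    """Ratio of group mean to baseline mean."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return float(group_mean) / float(baseline_mean)


@dataclass
class RunConfig:
    """Pipeline configuration; see ``RunConfig.from_yaml`` for the layout."""

    out_dir: Path
    seed: int = 0
    baseline_genotype: str = "WT"
    reference_path: Path | None = None
    genome: dict | None = None
    counts_path: Path | None = None
    simulate: dict | None = None
    samples_path: Path | None = None
    catalog_path: Path | None = None
    target_freqs_path: Path | None = None
    caller: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, out: str | Path | None = None,
                  seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            out_dir=Path(out if out is not None else raw.get("out", "mutaccum_out")),
            seed=int(seed if seed is not None else raw.get("seed", 0)),
            baseline_genotype=raw.get("baseline_genotype", "WT"),
            reference_path=Path(raw["reference"]) if raw.get("reference") else None,
            genome=raw.get("genome"),
            counts_path=Path(raw["counts"]) if raw.get("counts") else None,
            simulate=raw.get("simulate"),
            samples_path=Path(raw["samples"]) if raw.get("samples") else None,
            catalog_path=Path(raw["catalog"]) if raw.get("catalog") else None,
            target_freqs_path=(
                Path(raw["target_triplet_freqs"])
                if raw.get("target_triplet_freqs") else None
            ),
            caller=raw.get("caller", {}),
        )
        for p in (cfg.reference_path, cfg.counts_path, cfg.samples_path,
                  cfg.catalog_path, cfg.target_freqs_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


def _cohort_spec_from_config(sim: dict, seed: int) -> synthetic.CohortSpec:
    samples = [tuple(s) for s in sim["samples"]]
    spectrum = sim.get("snv_spectrum")
    return synthetic.CohortSpec(
        samples=samples,
        snv_burden=sim.get("snv_burden", 0),
        insertion_burden=sim.get("insertion_burden", 0),
        deletion_burden=sim.get("deletion_burden", 0),
        snv_spectrum=np.asarray(spectrum, dtype=float) if spectrum else None,
        deletion_mix=tuple(sim.get("deletion_mix", (0.2, 0.4, 0.4))),
        microhomology_k=sim.get("microhomology_k"),
        germline_het_density=sim.get("germline_het_density", 0.0),
        per_sample_burdens=sim.get("per_sample_burdens", {}),
        seed=seed,
    )


def run_pipeline(config: RunConfig) -> dict:
    """simulate (optional) -> call -> spectra -> signatures -> indels ->
    summary; returns the report dict and writes everything under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}
    t0 = time.time()

    def stage(name: str) -> None:
        # timings go to the log only, so the report stays deterministic
        report["stages"].append(name)
        logger.info("stage %s done (%.1fs)", name, time.time() - t0)

    # --- reference
    if config.reference_path is not None:
        reference = io.read_fasta(config.reference_path)
    elif config.genome is not None:
        gspec = synthetic.SyntheticGenomeSpec(
            chromosome_lengths=config.genome["chromosome_lengths"],
            gc_content=config.genome.get("gc_content", 0.42),
            seed=config.genome.get("seed", config.seed),
        )
        reference = synthetic.generate_reference(gspec)
        io.write_fasta(reference, out / "reference.fa")
    else:
        raise ValueError("config needs either 'reference' or 'genome'")
    stage("reference")

    # --- counts (+ truth) and sample metadata
    if config.simulate is not None:
        cohort = _cohort_spec_from_config(config.simulate, config.seed)
        noise_cfg = config.simulate.get("noise", {})
        noise = synthetic.NoiseModel(
            mean_coverage=noise_cfg.get("mean_coverage", 25.0),
            coverage_dispersion=noise_cfg.get("coverage_dispersion", 0.0),
            per_base_error=noise_cfg.get("per_base_error", 0.002),
        )
        truth = synthetic.implant_mutations(reference, cohort)
        io.write_truth_table(truth.to_frame(), out / "truth.tsv")
        counts = synthetic.simulate_pileup_counts(
            reference, truth, noise, seed=config.seed
        )
        io.write_count_table(counts, out / "counts.tsv")
        meta = pd.DataFrame(
            [
                {"sample": s, "genotype": g,
                 "treatment": config.simulate.get("treatment", "mock")}
                for s, g in cohort.samples
            ]
        )
        sample_ids = cohort.sample_ids
    else:
        if config.counts_path is None or config.samples_path is None:
            raise ValueError("config needs 'counts' and 'samples' "
                             "when not simulating")
        counts = io.read_count_table(config.counts_path)
        meta = pd.read_csv(config.samples_path, sep="\t", dtype=str)
        sample_ids = list(meta["sample"])
    meta.to_csv(out / "samples.tsv", sep="\t", index=False)
    stage("counts")

    # --- calling
    caller_cfg = calling.CallerConfig(**config.caller)
    calls = calling.call_unique_mutations(counts, caller_cfg, sample_ids)
    io.write_calls(calls, out / "calls.tsv")
    contigs = {c: len(s) for c, s in reference.items()}
    for s in sample_ids:
        io.write_vcf(calls, s, out / f"calls.{s}.vcf", contigs=contigs)
    report["n_calls"] = {
        t: int((calls["type"] == t).sum()) for t in ("SNV", "INS", "DEL")
    }
    stage("calling")

    # --- spectra per genotype (pooled)
    source_freqs = gn.count_genome_triplets(reference, label="source")
    io.write_triplet_frequencies(source_freqs, out / "triplet_freqs.tsv")
    target_freqs = (
        io.read_triplet_frequencies(config.target_freqs_path, label="target")
        if config.target_freqs_path is not None
        else source_freqs
    )
    catalog = (
        signatures.read_catalog(config.catalog_path)
        if config.catalog_path is not None
        else signatures.load_demo_catalog()
    )
    geno_of = dict(zip(meta["sample"], meta["genotype"]))
    calls = calls.assign(genotype=[geno_of[s] for s in calls["sample"]])
    report["signatures"] = {}
    report["cg_tg_fold"] = {}
    rate_spectra: dict[str, spectra.TripletSpectrum96] = {}
    for genotype, grp in calls.groupby("genotype"):
        spec = spectra.build_spectrum(grp, reference)
        io.write_spectrum_tsv(spec.values, out / f"spectrum.{genotype}.tsv")
        if spec.values.sum() == 0:
            continue
        rates = spectra.normalize_by_genome(spec, source_freqs)
        rate_spectra[genotype] = rates
        adjusted = signatures.cross_genome_adjust(spec, source_freqs, target_freqs)
        corr = signatures.correlate_with_catalog(adjusted, catalog)
        corr.to_csv(out / f"signature_correlation.{genotype}.tsv", sep="\t")
        report["signatures"][genotype] = {
            "top": str(corr.idxmax()), "r": round(float(corr.max()), 6)
        }
        report["cg_tg_fold"][genotype] = round(
            signatures.cg_tg_overrepresentation(rates), 6
        )
    baseline = config.baseline_genotype
    if baseline in rate_spectra:
        for genotype, rates in rate_spectra.items():
            if genotype == baseline:
                continue
            try:
                sub, clipped = signatures.subtract_baseline(
                    rates, rate_spectra[baseline]
                )
            except ValueError:
                continue
            corr = signatures.correlate_with_catalog(sub, catalog)
            report["signatures"].setdefault("baseline_subtracted", {})[
                genotype
            ] = {"top": str(corr.idxmax()), "r": round(float(corr.max()), 6),
                 "clipped": clipped}
    stage("spectra")

    # --- deletions
    recs = indels.deletions_from_calls(calls, reference)
    classes = [indels.classify_deletion(r) for r in recs]
    ctable = indels.classification_table(classes)
    if len(ctable):
        ctable = ctable.assign(genotype=[geno_of[s] for s in ctable["sample"]])
        ctable.to_csv(out / "deletion_classes.tsv", sep="\t", index=False)
        cat_geno = (
            ctable.groupby(["category", "genotype"]).size().unstack(fill_value=0)
        )
        cat_geno.to_csv(out / "deletion_category_table.tsv", sep="\t")
        if (
            cat_geno.shape[0] >= 2 and cat_geno.shape[1] >= 2
            and (cat_geno.sum(axis=0) > 0).all()
            and (cat_geno.sum(axis=1) > 0).all()
        ):
            report["deletion_category_p"] = round(
                indels.compare_category_tables(cat_geno.to_numpy()), 6
            )
    stage("indels")

    # --- cohort summary, fold changes and group comparisons
    summary = summarize_cohort(calls, meta)
    summary.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
    report["summary"] = {}
    base_rows = summary[summary["genotype"] == baseline]
    for row in summary.itertuples():
        key = f"{row.genotype}/{row.treatment}"
        report["summary"][key] = {
            "n": int(row.n), "snv_mean": row.snv_mean, "snv_sd":
            None if np.isnan(row.snv_sd) else row.snv_sd,
        }
        base = base_rows[base_rows["treatment"] == row.treatment]
        if len(base) and row.genotype != baseline and base["snv_mean"].iloc[0] > 0:
            report["summary"][key]["snv_fold_vs_baseline"] = round(
                fold_change(row.snv_mean, base["snv_mean"].iloc[0]), 4
            )
            a = base.iloc[0]
            if row.n >= 2 and a["n"] >= 2 and not (
                np.isnan(row.snv_sd) or np.isnan(a["snv_sd"])
            ):
                res = t_test_from_summary(
                    SummaryStat(row.snv_mean, row.snv_sd, int(row.n)),
                    SummaryStat(a["snv_mean"], a["snv_sd"], int(a["n"])),
                )
                report["summary"][key]["snv_p_vs_baseline"] = round(
                    res.p_value, 6
                )
    stage("summary")

    io.write_json(report, out / "report.json")
    return report
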