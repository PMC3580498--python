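"""End-to-end orchestration: simulate, quantify, call, classify, report.

Ties the modules together the way the genome-wide study is organised: ChIP
samples are deduplicated, extended to fragment size, counted over promoters
and ORFs, TMM-normalized (reference: the factor's unstressed wild-type
sample) and compared on the MA scale; MNase samples are deduplicated, piled
up, RPM-normalized, TSS-aligned and quantified as +1-region occupancy; the
expression table is classified into the five gene classes; and everything is
folded into one machine-readable report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls_mod
from .coverage import (
    RegionCountTable,
    count_regions,
    dedup_reads,
    extend_reads,
    gene_regions,
    pileup,
    tmm_factor,
    to_rpm,
    trpk,
)
from .enrichment import (
    MAEnrichment,
    Z_DIFFERENTIAL,
    Z_HOG1_BINDING,
    Z_POLII_RECRUITMENT,
)
from .genome import GenomeBuild, GeneModel, ReadSet
from .nucleosome import (
    OccupancyModel,
    OccupancyResults,
    TssProfile,
    call_nucleosomes,
    compare_eviction,
    tss_profile,
)
from .report import StageError, run_report, render_text
from .simulate import (
    CLASSES,
    CONDITIONS,
    FACTORS,
    STRAINS,
    ScenarioConfig,
    SimulatedExperiment,
    simulate_experiment,
)

__all__ = [
    "ChipResults",
    "MnaseResults",
    "PipelineResults",
    "quantify_chip_sample",
    "analyze_chip",
    "analyze_mnase",
    "analyze_classification",
    "run_all",
]

DEDUP_CAP = 10


def quantify_chip_sample(
    reads: ReadSet,
    regions: pd.DataFrame,
    genome: GenomeBuild,
    fragment_length: int = 250,
    dedup_cap: int = DEDUP_CAP,
) -> RegionCountTable:
    """dedup -> extend to fragment length -> midpoint counts -> RPK."""
    deduped = dedup_reads(reads, dedup_cap)
    extended = extend_reads(deduped, fragment_length, genome)
    return count_regions(extended, regions)


@dataclass
class ChipResults:
    regions: pd.DataFrame
    tables: dict[tuple[str, str, str], RegionCountTable]  # TRPK per sample
    hog1_binding: pd.DataFrame  # region-level calls, wt stress vs unstressed
    polii_recruitment: pd.DataFrame
    differential: pd.DataFrame  # polii wt-stress vs hog1-stress
    binding: pd.DataFrame  # gene-level assignment
    gene_z: pd.DataFrame  # gene_id, hog1_z, polii_z

    def genes_with(self, calls: pd.DataFrame) -> set[str]:
        return set(calls.loc[calls["significant"], "gene_id"])


def _gene_calls(results, regions: pd.DataFrame, z_threshold: float) -> pd.DataFrame:
    calls = results.calls(z_threshold)
    return calls.merge(regions[["region_id", "gene_id", "kind"]], on="region_id")


def analyze_chip(
    exp: SimulatedExperiment,
    z_hog1: float = Z_HOG1_BINDING,
    z_polii: float = Z_POLII_RECRUITMENT,
    z_differential: float = Z_DIFFERENTIAL,
    random_state: int = 0,
) -> ChipResults:
    config = exp.config
    regions = gene_regions(exp.genes, exp.genome)
    tables: dict[tuple[str, str, str], RegionCountTable] = {}
    for factor in FACTORS:
        raw = {
            (strain, cond): quantify_chip_sample(
                exp.chip_reads[(factor, strain, cond)], regions, exp.genome,
                config.chip_fragment_length,
            )
            for strain in STRAINS
            for cond in CONDITIONS
        }
        reference = raw[("wt", "unstressed")]
        for key, table in raw.items():
            factor_tmm = tmm_factor(table, reference)
            tables[(factor, *key)] = trpk(table, factor_tmm)

    def fit(factor: str, treated_key, untreated_key, seed_shift: int):
        model = MAEnrichment(tables[(factor, *treated_key)], tables[(factor, *untreated_key)])
        return model.fit(random_state=random_state + seed_shift)

    hog1_res = fit("hog1", ("wt", "stress"), ("wt", "unstressed"), 1)
    polii_res = fit("polii", ("wt", "stress"), ("wt", "unstressed"), 2)
    diff_res = fit("polii", ("wt", "stress"), ("hog1", "stress"), 3)

    hog1_calls = _gene_calls(hog1_res, regions, z_hog1)
    polii_calls = _gene_calls(polii_res, regions, z_polii)
    diff_calls = _gene_calls(diff_res, regions, z_differential)
    gene_ids = [g.gene_id for g in exp.genes]
    binding = cls_mod.binding_assignment(hog1_calls, polii_calls, gene_ids)
    gene_z = (
        hog1_calls.groupby("gene_id")["Z"].max().rename("hog1_z").to_frame()
        .join(polii_calls.groupby("gene_id")["Z"].max().rename("polii_z"))
        .reset_index()
    )
    return ChipResults(regions, tables, hog1_calls, polii_calls, diff_calls, binding, gene_z)


@dataclass
class MnaseResults:
    tracks: dict[tuple[str, str], object]  # rpm CoverageTracks
    profiles: dict[tuple[str, str], TssProfile]
    occupancy: dict[str, OccupancyResults]  # per strain: stress vs unstressed
    group_summary: pd.DataFrame  # strain x class occupancy/eviction means
    paired_test: tuple[float, float]  # wt vs hog1 eviction over dependent genes
    nucleosome_calls: dict[str, list]  # per class, unstressed wt mean profile


def analyze_mnase(
    exp: SimulatedExperiment,
    flank: int = 1000,
    window: int = 200,
    dedup_cap: int = DEDUP_CAP,
) -> MnaseResults:
    tracks = {}
    for key, reads in exp.mnase_reads.items():
        deduped = dedup_reads(reads, dedup_cap)
        tracks[key] = to_rpm(pileup(deduped, exp.genome))
    profiles = {
        key: tss_profile(track, exp.genes, flank=flank, label="_".join(key))
        for key, track in tracks.items()
    }
    class_of = exp.class_of
    occupancy = {}
    summaries = []
    for strain in STRAINS:
        occ = OccupancyModel(
            tracks[(strain, "stress")], tracks[(strain, "unstressed")],
            exp.genes, window=window,
        ).fit()
        occupancy[strain] = occ
        summary = occ.group_summary(class_of)
        summary.insert(0, "strain", strain)
        summaries.append(summary)
    group_summary = pd.concat(summaries, ignore_index=True)

    dependent = [g.gene_id for g in exp.genes if class_of[g.gene_id] == "hog1_dependent"]
    shared = [
        g for g in dependent
        if g in set(occupancy["wt"].per_gene["gene_id"])
        and g in set(occupancy["hog1"].per_gene["gene_id"])
    ]
    paired = compare_eviction(occupancy["wt"], occupancy["hog1"], shared)

    nuc_calls = {}
    wt_t0 = profiles[("wt", "unstressed")]
    for cls in CLASSES:
        members = [g.gene_id for g in exp.genes if class_of[g.gene_id] == cls]
        if not members:
            continue
        sub = wt_t0.subset(members, label=cls)
        nuc_calls[cls] = call_nucleosomes(sub.mean_profile, offsets=sub.offsets)
    return MnaseResults(tracks, profiles, occupancy, group_summary, paired, nuc_calls)


@dataclass
class ClassificationResults:
    labels: pd.DataFrame
    class_sizes: dict[str, int]
    mean_fc: dict[str, float]


def analyze_classification(exp: SimulatedExperiment) -> ClassificationResults:
    labels = cls_mod.classify_genes(exp.expression)
    sizes = labels["label"].value_counts().to_dict()
    mean_fc = {}
    osmo = labels.loc[labels["osmoresponsive"], "gene_id"]
    rest = labels.loc[~labels["osmoresponsive"], "gene_id"]
    if len(osmo):
        mean_fc["osmoresponsive"] = cls_mod.group_mean_fc(labels, exp.expression, list(osmo))
    if len(rest):
        mean_fc["non_osmoresponsive"] = cls_mod.group_mean_fc(labels, exp.expression, list(rest))
    for cls in ("hog1_dependent", "hog1_independent"):
        top = cls_mod.top_n_by_fc(labels, exp.expression, 100, cls)
        if top:
            mean_fc[f"top100_{cls}"] = cls_mod.group_mean_fc(labels, exp.expression, top)
    return ClassificationResults(labels, sizes, mean_fc)


@dataclass
class PipelineResults:
    exp: SimulatedExperiment
    chip: ChipResults
    mnase: MnaseResults
    classification: ClassificationResults
    report: dict = field(default_factory=dict)

    @property
    def report_text(self) -> str:
        return render_text(self.report)


def run_all(config: ScenarioConfig, outdir: str | Path | None = None) -> PipelineResults:
    """Simulate the scenario and run the complete analysis."""
    exp = simulate_experiment(config)
    chip = analyze_chip(exp)
    mnase = analyze_mnase(exp)
    classification = analyze_classification(exp)

    labels = classification.labels
    hog1_bound = set(chip.binding.loc[chip.binding["hog1_bound"], "gene_id"])
    polii_rec = set(chip.binding.loc[chip.binding["polii_recruited"], "gene_id"])
    upregulated = set(labels.loc[labels["nacl_group"], "gene_id"])
    venn = cls_mod.venn_counts(hog1_bound, polii_rec, upregulated)

    triple = sorted(hog1_bound & polii_rec & upregulated)
    coloc_genes = triple if len(triple) >= 3 else sorted(hog1_bound | polii_rec | upregulated)
    gz = chip.gene_z.set_index("gene_id")
    fc = exp.expression.set_index("gene_id")["fc_wt"]
    coloc_genes = [g for g in coloc_genes if g in gz.index and g in fc.index]
    coloc = cls_mod.colocalization_stats(
        gz.loc[coloc_genes, "hog1_z"].to_numpy(),
        gz.loc[coloc_genes, "polii_z"].to_numpy(),
        fc.loc[coloc_genes].to_numpy(),
    )

    truth_class = exp.truth["class"]
    bound_frac = {}
    binding = chip.binding.set_index("gene_id")
    for cls in ("hog1_dependent", "hog1_independent"):
        members = exp.truth.loc[truth_class == cls, "gene_id"]
        if len(members):
            bound_frac[cls] = float(binding.loc[members, "hog1_bound"].mean())

    report = run_report(
        config=config,
        classification=classification,
        chip=chip,
        mnase=mnase,
        venn=venn,
        colocalization=coloc,
        truth_sizes=exp.truth["class"].value_counts().to_dict(),
        hog1_bound_fraction=bound_frac,
    )
    results = PipelineResults(exp, chip, mnase, classification, report)
    if outdir is not None:
        _write_outputs(results, Path(outdir))
    return results


def _write_outputs(results: PipelineResults, outdir: Path) -> None:
    import json

    outdir.mkdir(parents=True, exist_ok=True)
    results.classification.labels.to_csv(outdir / "gene_classes.tsv", sep="\t", index=False)
    results.chip.hog1_binding.to_csv(outdir / "hog1_binding_calls.tsv", sep="\t", index=False)
    results.chip.polii_recruitment.to_csv(outdir / "polii_recruitment_calls.tsv", sep="\t", index=False)
    results.chip.differential.to_csv(outdir / "differential_recruitment_calls.tsv", sep="\t", index=False)
    results.chip.binding.to_csv(outdir / "binding_assignment.tsv", sep="\t", index=False)
    results.mnase.group_summary.to_csv(outdir / "occupancy_groups.tsv", sep="\t", index=False)
    for strain, occ in results.mnase.occupancy.items():
        occ.to_tsv(outdir / f"occupancy_{strain}.tsv")
    with open(outdir / "report.json", "w") as fh:
        json.dump(results.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (outdir / "report.txt").write_text(results.report_text)
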