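"""Synthetic osmostress experiment generator with ground truth.

Generates a toy yeast-like genome of tiled genes in five expression classes
(Hog1-dependent, Hog1-independent, housekeeping, down-regulated, unchanged),
then ChIP-Seq reads (RNA Pol II and Hog1, wt and hog1 strains, unstressed and
stressed), MNase-Seq mononucleosome fragments with phased nucleosomes and
condition/strain-dependent eviction, and a lognormal-noise expression
fold-change table.  Every output is an exact function of (config, seed); the
ground-truth manifest records per-gene class labels, enrichment multipliers,
eviction fractions and nucleosome centre offsets.

ChIP reads are drawn from a mixture of a uniform genomic background (per-base
weight 1) and per-gene foreground over promoter + ORF whose per-base weight is
the class multiplier, so the expected read fraction of a region with
multiplier m is m*L_region / sum(w*L).  MNase fragment centres sit on a
canonical phased grid relative to the TSS (147-bp fragments, ~165-bp repeat)
with Gaussian jitter; stress thins each nucleosome's sampling weight by its
class/strain eviction fraction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeBuild, GenomicInterval, GeneModel, ReadSet, SampleTag, promoter_of
from . import io as hio

__all__ = [
    "CLASSES",
    "FACTORS",
    "STRAINS",
    "CONDITIONS",
    "ScenarioConfig",
    "ConfigError",
    "build_toy_genome",
    "build_ground_truth",
    "chip_multipliers",
    "simulate_chip_reads",
    "simulate_mnase_fragments",
    "simulate_expression_table",
    "SimulatedExperiment",
    "simulate_experiment",
    "write_experiment",
]

CLASSES = ("hog1_dependent", "hog1_independent", "housekeeping", "down_regulated", "unchanged")
FACTORS = ("polii", "hog1")
STRAINS = ("wt", "hog1")
CONDITIONS = ("unstressed", "stress")


class ConfigError(ValueError):
    """Invalid or inconsistent scenario configuration."""


def _default_n_genes() -> dict[str, int]:
    return {c: 100 for c in CLASSES}


def _default_polii_multipliers() -> dict:
    # class -> multiplier per strain x condition.  Pol II drops at housekeeping
    # and down-regulated genes upon stress equally in both strains; recruitment
    # to Hog1-dependent genes requires the kinase.
    return {
        "wt": {
            "unstressed": {"hog1_dependent": 1.0, "hog1_independent": 1.0,
                           "housekeeping": 4.0, "down_regulated": 4.0, "unchanged": 2.0},
            "stress": {"hog1_dependent": 8.0, "hog1_independent": 4.0,
                       "housekeeping": 2.0, "down_regulated": 2.0, "unchanged": 2.0},
        },
        "hog1": {
            "unstressed": {"hog1_dependent": 1.0, "hog1_independent": 1.0,
                           "housekeeping": 4.0, "down_regulated": 4.0, "unchanged": 2.0},
            "stress": {"hog1_dependent": 1.0, "hog1_independent": 4.0,
                       "housekeeping": 2.0, "down_regulated": 2.0, "unchanged": 2.0},
        },
    }


def _default_hog1_bound_fraction() -> dict[str, float]:
    # Fraction of genes per class with true Hog1 chromatin association upon
    # stress (the kinase sits on most dependent and a minority of independent
    # genes, and is absent from the other classes).
    return {"hog1_dependent": 0.85, "hog1_independent": 0.30,
            "housekeeping": 0.0, "down_regulated": 0.0, "unchanged": 0.0}


def _default_eviction() -> dict:
    # Fraction of nucleosome occupancy lost upon stress, per strain x class.
    # Dependent-gene remodeling requires Hog1; the milder independent-gene
    # eviction is kinase-independent.
    return {
        "wt": {"hog1_dependent": 0.51, "hog1_independent": 0.25,
               "housekeeping": 0.0, "down_regulated": 0.0, "unchanged": 0.0},
        "hog1": {"hog1_dependent": 0.0, "hog1_independent": 0.25,
                 "housekeeping": 0.0, "down_regulated": 0.0, "unchanged": 0.0},
    }


def _default_fc_means() -> dict[str, tuple[float, float]]:
    # (fc_wt, fc_hog1) linear fold-change means per class; chosen so the
    # classifier's thresholds hold exactly at zero noise.
    return {
        "hog1_dependent": (8.0, 2.0),
        "hog1_independent": (2.0, 2.0),
        "housekeeping": (1.05, 1.05),
        "down_regulated": (0.4, 0.4),
        "unchanged": (1.3, 1.3),
    }


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic experiment; defaults are the study scenario."""

    seed: int
    n_genes: dict[str, int] = field(default_factory=_default_n_genes)
    gene_length: int = 2000
    spacing: int = 4000
    flank_bp: int = 1000
    tss_offset: int = 50  # TSS this many bp upstream of the ORF start
    chrom_name: str = "chrS"
    chip_depth: int = 500_000
    mnase_depth: int = 500_000
    chip_fragment_length: int = 250
    chip_read_length: int = 36
    mnase_fragment_length: int = 147
    nucleosome_offsets: tuple[int, ...] = (-200, 50, 215, 380, 545)
    jitter_sd: float = 20.0
    mnase_background_fraction: float = 0.05
    chip_promoter_bias: float = 1.0
    plus1_shift_dependent: int = 0
    polii_multipliers: dict = field(default_factory=_default_polii_multipliers)
    hog1_bound_fraction: dict[str, float] = field(default_factory=_default_hog1_bound_fraction)
    hog1_bound_multiplier: float = 8.0
    eviction: dict = field(default_factory=_default_eviction)
    evicted_offsets: tuple[int, ...] | None = None  # None: eviction hits all nucleosomes
    fc_means: dict[str, tuple[float, float]] = field(default_factory=_default_fc_means)
    fc_noise_sd: float = 0.1
    pcr_duplicate_fraction: float = 0.0
    promoter_length: int = 500

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.chip_depth <= 0 or self.mnase_depth <= 0:
            raise ConfigError("read depth must be positive")
        if self.spacing < self.gene_length + 2 * self.flank_bp:
            raise ConfigError(
                f"spacing {self.spacing} < gene_length {self.gene_length} + "
                f"2*flank {2 * self.flank_bp}"
            )
        for strain, per_cond in self.polii_multipliers.items():
            for cond, per_class in per_cond.items():
                for cls, m in per_class.items():
                    if not m > 0:
                        raise ConfigError(f"multiplier polii/{strain}/{cond}/{cls} must be > 0")
        if not self.hog1_bound_multiplier > 0:
            raise ConfigError("hog1_bound_multiplier must be > 0")
        for strain, per_class in self.eviction.items():
            for cls, f in per_class.items():
                if not 0.0 <= f <= 1.0:
                    raise ConfigError(f"eviction {strain}/{cls} must lie in [0, 1]")
        for cls, n in self.n_genes.items():
            if cls not in CLASSES:
                raise ConfigError(f"unknown gene class {cls!r}")
            if n < 0:
                raise ConfigError("gene counts must be >= 0")

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["nucleosome_offsets"] = list(self.nucleosome_offsets)
        if self.evicted_offsets is not None:
            d["evicted_offsets"] = list(self.evicted_offsets)
        d["fc_means"] = {k: list(v) for k, v in self.fc_means.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "nucleosome_offsets" in d:
            d["nucleosome_offsets"] = tuple(int(x) for x in d["nucleosome_offsets"])
        if d.get("evicted_offsets") is not None:
            d["evicted_offsets"] = tuple(int(x) for x in d["evicted_offsets"])
        if "fc_means" in d:
            d["fc_means"] = {k: tuple(map(float, v)) for k, v in d["fc_means"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if seed is not None:
            d["seed"] = seed
        if "seed" not in d:
            raise ConfigError("seed is mandatory (in the file or via the seed argument)")
        return cls.from_dict(d)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def rng(self, *purpose: str) -> np.random.Generator:
        """A deterministic child generator for one named purpose."""
        salts = [zlib.crc32(p.encode()) & 0x7FFFFFFF for p in purpose]
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, *salts])


# -- genome and truth --------------------------------------------------------


def build_toy_genome(config: ScenarioConfig) -> tuple[GenomeBuild, list[GeneModel]]:
    """Tile genes with fixed spacing and alternating strands on one chromosome.

    n genes at spacing s occupy a chromosome of (n + 1) * s bp, each ORF
    centred in its slot with at least ``flank_bp`` of intergenic flank.
    """
    total = sum(config.n_genes.values())
    chrom_len = (total + 1) * config.spacing if total else config.spacing
    genome = GenomeBuild({config.chrom_name: chrom_len})
    margin = (config.spacing - config.gene_length) // 2
    genes: list[GeneModel] = []
    for i in range(total):
        orf_start = config.spacing // 2 + i * config.spacing + margin
        orf_end = orf_start + config.gene_length
        strand = "+" if i % 2 == 0 else "-"
        tss = orf_start - config.tss_offset if strand == "+" else orf_end - 1 + config.tss_offset
        genes.append(
            GeneModel(
                f"g{i:04d}",
                GenomicInterval(config.chrom_name, orf_start, orf_end, strand),
                tss,
                strand,
            )
        )
    return genome, genes


def build_ground_truth(genes: list[GeneModel], config: ScenarioConfig) -> pd.DataFrame:
    """Assign classes, Hog1-bound flags, eviction fractions and nucleosome grids.

    Class labels are a seed-determined permutation over the gene tiling so that
    class and genomic position are not confounded.
    """
    labels = [c for c in CLASSES for _ in range(config.n_genes.get(c, 0))]
    if len(labels) != len(genes):
        raise ConfigError("gene list does not match configured class counts")
    rng = config.rng("classes")
    labels = [labels[i] for i in rng.permutation(len(labels))]
    # exactly round(fraction * n) genes per class carry true Hog1 association,
    # so the configured fraction is an exact condition of the scenario
    rng_bound = config.rng("hog1_bound")
    bound_flags = np.zeros(len(genes), dtype=bool)
    label_arr = np.asarray(labels)
    for cls in CLASSES:
        members = np.flatnonzero(label_arr == cls)
        k = int(round(config.hog1_bound_fraction.get(cls, 0.0) * members.size))
        if k:
            bound_flags[rng_bound.choice(members, size=k, replace=False)] = True
    rows = []
    for i, (g, cls) in enumerate(zip(genes, labels)):
        bound = bool(bound_flags[i])
        offsets = list(config.nucleosome_offsets)
        if cls == "hog1_dependent" and config.plus1_shift_dependent and len(offsets) > 1:
            offsets[1] += config.plus1_shift_dependent
        row = {
            "gene_id": g.gene_id,
            "class": cls,
            "hog1_bound": bound,
            "eviction_wt": config.eviction["wt"].get(cls, 0.0),
            "eviction_hog1": config.eviction["hog1"].get(cls, 0.0),
            "nuc_offsets": "|".join(str(o) for o in offsets),
        }
        for strain in STRAINS:
            for cond in CONDITIONS:
                row[f"mult_polii_{strain}_{cond}"] = config.polii_multipliers[strain][cond][cls]
                row[f"mult_hog1_{strain}_{cond}"] = _hog1_multiplier(
                    config, strain, cond, bound
                )
        rows.append(row)
    return pd.DataFrame(rows)


def _hog1_multiplier(config: ScenarioConfig, strain: str, condition: str, bound: bool) -> float:
    if strain == "hog1" or condition == "unstressed" or not bound:
        return 1.0  # no Hog1 protein / no stress signal / gene not targeted
    return config.hog1_bound_multiplier


def chip_multipliers(
    factor: str, strain: str, condition: str, truth: pd.DataFrame, config: ScenarioConfig
) -> np.ndarray:
    """Per-gene foreground weight for one ChIP sample (truth row order)."""
    _check_tag(factor, strain, condition)
    return truth[f"mult_{factor}_{strain}_{condition}"].to_numpy(dtype=float)


def _check_tag(factor: str, strain: str, condition: str) -> None:
    if factor not in FACTORS and factor != "mnase":
        raise ConfigError(f"unknown factor {factor!r}")
    if strain not in STRAINS:
        raise ConfigError(f"unknown strain {strain!r}")
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}")


# -- ChIP simulation ---------------------------------------------------------


def simulate_chip_reads(
    factor: str,
    strain: str,
    condition: str,
    genes: list[GeneModel],
    truth: pd.DataFrame,
    config: ScenarioConfig,
    genome: GenomeBuild | None = None,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Simulate one ChIP-Seq sample (exactly ``chip_depth`` reads).

    Fragment centres are drawn from the background/foreground mixture; each
    fragment yields one sequencing read of ``chip_read_length`` nt anchored at
    a uniformly chosen 5' end (strand), so the pipeline's extension step
    reconstructs the fragment.
    """
    _check_tag(factor, strain, condition)
    if genome is None:
        genome, _ = build_toy_genome(config)
    if rng is None:
        rng = config.rng("chip", factor, strain, condition)
    chrom = config.chrom_name
    chrom_len = genome.length_of(chrom)
    mults = chip_multipliers(factor, strain, condition, truth, config)

    starts_w, ends_w, weights = [0], [chrom_len], [float(chrom_len)]
    bias = config.chip_promoter_bias
    for g, m in zip(genes, mults):
        if m == 1.0:
            continue
        prom = promoter_of(g, genome, config.promoter_length)
        lp, lo = len(prom), len(g.orf)
        extra = (m - 1.0) * (lp + lo)
        denom = bias * lp + lo
        for iv, w in ((prom, extra * bias * lp / denom), (g.orf, extra * lo / denom)):
            starts_w.append(iv.start)
            ends_w.append(iv.end)
            weights.append(w)
    weights = np.asarray(weights, dtype=float)
    counts = rng.multinomial(config.chip_depth, weights / weights.sum())
    centres = np.concatenate(
        [
            rng.integers(s, e, size=c)
            for s, e, c in zip(starts_w, ends_w, counts)
            if c > 0
        ]
        or [np.empty(0, dtype=np.int64)]
    )
    rng.shuffle(centres)
    return _reads_from_centres(
        centres,
        config.chip_fragment_length,
        config.chip_read_length,
        chrom,
        chrom_len,
        rng,
        SampleTag(factor, strain, condition),
        genome,
        config,
    )


def _reads_from_centres(
    centres: np.ndarray,
    fragment_length: int,
    read_length: int,
    chrom: str,
    chrom_len: int,
    rng: np.random.Generator,
    sample: SampleTag,
    genome: GenomeBuild,
    config: ScenarioConfig,
) -> ReadSet:
    n = centres.size
    half = fragment_length // 2
    frag_start = centres - half
    frag_end = frag_start + fragment_length
    minus = rng.random(n) < 0.5
    start = np.where(minus, frag_end - read_length, frag_start)
    end = start + read_length
    np.clip(start, 0, chrom_len - 1, out=start)
    np.clip(end, 1, chrom_len, out=end)
    start = np.minimum(start, end - 1)
    strand = np.where(minus, "-", "+")
    if config.pcr_duplicate_fraction > 0.0 and n:
        dup = rng.random(n) < config.pcr_duplicate_fraction
        extra = rng.geometric(0.5, size=int(dup.sum()))
        idx = np.repeat(np.flatnonzero(dup), extra)
        start = np.concatenate([start, start[idx]])
        end = np.concatenate([end, end[idx]])
        strand = np.concatenate([strand, strand[idx]])
    return ReadSet.from_arrays(
        np.full(start.size, chrom, dtype=object), start, end, strand,
        sample=sample, genome=genome,
    )


# -- MNase simulation --------------------------------------------------------


def simulate_mnase_fragments(
    strain: str,
    condition: str,
    genes: list[GeneModel],
    truth: pd.DataFrame,
    config: ScenarioConfig,
    genome: GenomeBuild | None = None,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Simulate one MNase-Seq sample of mononucleosomal fragments.

    Fragment centres sit on each gene's TSS-relative nucleosome grid plus
    Gaussian jitter; under stress each nucleosome's sampling weight is thinned
    by the gene class's strain-specific eviction fraction.  A small uniform
    background emulates sub-nucleosomal/linker contamination.  Exactly
    ``mnase_depth`` fragments (147 bp) are emitted.
    """
    _check_tag("mnase", strain, condition)
    if genome is None:
        genome, _ = build_toy_genome(config)
    if rng is None:
        rng = config.rng("mnase", strain, condition)
    chrom = config.chrom_name
    chrom_len = genome.length_of(chrom)

    centres_list, weights_list = [], []
    evic_col = truth[f"eviction_{strain}"].to_numpy(dtype=float)
    evictable = None if config.evicted_offsets is None else set(config.evicted_offsets)
    for g, evic, offsets_str in zip(genes, evic_col, truth["nuc_offsets"]):
        offsets = np.array([int(x) for x in offsets_str.split("|")], dtype=np.int64)
        genomic = g.tss + offsets if g.strand == "+" else g.tss - offsets
        w = np.ones(offsets.size)
        if condition == "stress" and evic > 0.0:
            hit = (
                np.ones(offsets.size, dtype=bool)
                if evictable is None
                else np.array([int(o) in evictable for o in offsets])
            )
            w[hit] = 1.0 - evic
        centres_list.append(genomic)
        weights_list.append(w)
    if centres_list:
        nuc_centres = np.concatenate(centres_list)
        nuc_weights = np.concatenate(weights_list)
    else:
        nuc_centres = np.empty(0, dtype=np.int64)
        nuc_weights = np.empty(0)
    n_nuc = nuc_centres.size
    bg_frac = config.mnase_background_fraction
    bg_weight = bg_frac / (1.0 - bg_frac) * max(n_nuc, 1)
    weights = np.concatenate([[bg_weight], nuc_weights])
    counts = rng.multinomial(config.mnase_depth, weights / weights.sum())
    parts = [rng.integers(0, chrom_len, size=counts[0])]
    for c, count in zip(nuc_centres, counts[1:]):
        if count:
            jit = np.round(rng.normal(0.0, config.jitter_sd, size=count)).astype(np.int64)
            parts.append(c + jit)
    centres = np.concatenate(parts)
    rng.shuffle(centres)
    frag = config.mnase_fragment_length
    return _reads_from_centres(
        centres, frag, frag, chrom, chrom_len, rng,
        SampleTag("mnase", strain, condition), genome, config,
    )


# -- expression simulation ---------------------------------------------------


def simulate_expression_table(
    genes: list[GeneModel],
    truth: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Lognormal-noise expression fold changes around class means."""
    if rng is None:
        rng = config.rng("expression")
    classes = truth["class"].to_numpy()
    mean_wt = np.array([config.fc_means[c][0] for c in classes])
    mean_hog1 = np.array([config.fc_means[c][1] for c in classes])
    sd = config.fc_noise_sd
    n = len(genes)
    noise_wt = np.exp(rng.normal(0.0, sd, size=n)) if sd > 0 else np.ones(n)
    noise_hog1 = np.exp(rng.normal(0.0, sd, size=n)) if sd > 0 else np.ones(n)
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "fc_wt": mean_wt * noise_wt,
            "fc_hog1": mean_hog1 * noise_hog1,
        }
    )


# -- whole experiment --------------------------------------------------------


@dataclass
class SimulatedExperiment:
    """All simulated inputs of one scenario plus its ground truth."""

    config: ScenarioConfig
    genome: GenomeBuild
    genes: list[GeneModel]
    truth: pd.DataFrame
    expression: pd.DataFrame
    chip_reads: dict[tuple[str, str, str], ReadSet]  # (factor, strain, condition)
    mnase_reads: dict[tuple[str, str], ReadSet]  # (strain, condition)

    def class_genes(self, cls: str) -> list[GeneModel]:
        wanted = set(self.truth.loc[self.truth["class"] == cls, "gene_id"])
        return [g for g in self.genes if g.gene_id in wanted]

    @property
    def class_of(self) -> dict[str, str]:
        return dict(zip(self.truth["gene_id"], self.truth["class"]))


def simulate_experiment(config: ScenarioConfig) -> SimulatedExperiment:
    """Run the full generator: genome, truth, all samples, expression table."""
    genome, genes = build_toy_genome(config)
    truth = build_ground_truth(genes, config)
    expression = simulate_expression_table(genes, truth, config)
    chip = {
        (factor, strain, cond): simulate_chip_reads(
            factor, strain, cond, genes, truth, config, genome=genome
        )
        for factor in FACTORS
        for strain in STRAINS
        for cond in CONDITIONS
    }
    mnase = {
        (strain, cond): simulate_mnase_fragments(
            strain, cond, genes, truth, config, genome=genome
        )
        for strain in STRAINS
        for cond in CONDITIONS
    }
    return SimulatedExperiment(config, genome, genes, truth, expression, chip, mnase)


def write_experiment(exp: SimulatedExperiment, outdir) -> None:
    """Write BED reads, gene table, expression table, truth and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (factor, strain, cond), reads in exp.chip_reads.items():
        hio.write_bed(reads, outdir / f"{factor}_{strain}_{cond}.bed")
    for (strain, cond), reads in exp.mnase_reads.items():
        hio.write_bed(reads, outdir / f"mnase_{strain}_{cond}.bed")
    hio.write_gene_table(exp.genes, outdir / "gene_table.tsv")
    hio.write_expression_table(exp.expression, outdir / "expression.tsv")
    exp.truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    exp.config.to_yaml(outdir / "config.yaml")
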