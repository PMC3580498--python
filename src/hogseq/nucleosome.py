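"""TSS-aligned nucleosome profiles, peak calling and occupancy/eviction.

MNase mononucleosome coverage is aligned to each gene's TSS (strand-flipped,
TSS +/- 1 kb), nucleosome positions are called on the smoothed mean profile,
and promoter chromatin remodeling is quantified as the percent occupancy of
the 200 bp immediately downstream of the TSS (the +1 nucleosome region) in a
treated sample relative to the strain's untreated sample (defined as 100%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .coverage import CoverageTrack, tmm_factor
from .genome import GeneModel

__all__ = [
    "TssProfile",
    "NucleosomeCall",
    "OccupancyModel",
    "OccupancyResults",
    "tss_profile",
    "call_nucleosomes",
    "occupancy_percent",
    "compare_eviction",
]


@dataclass
class TssProfile:
    """Genes x TSS-relative-offset coverage matrix (minus strand flipped)."""

    matrix: np.ndarray  # shape (n_genes, 2*flank + 1)
    offsets: np.ndarray  # -flank .. +flank
    gene_ids: list[str]
    label: str = ""

    @property
    def mean_profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def subset(self, gene_ids: list[str], label: str = "") -> "TssProfile":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids if g in index]
        return TssProfile(
            self.matrix[rows], self.offsets, [self.gene_ids[i] for i in rows], label
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.offsets).to_csv(
            path, sep="\t", index_label="gene_id"
        )


def tss_profile(
    track: CoverageTrack,
    genes: list[GeneModel],
    flank: int = 1000,
    label: str = "",
) -> TssProfile:
    """Align per-base coverage to the TSS of each gene.

    Row g at offset k holds the coverage at the position k bases downstream of
    gene g's TSS on its own strand (minus-strand rows are reversed).  Genes
    whose flanks extend past a chromosome end are dropped with a warning.
    """
    rows, kept = [], []
    dropped = 0
    for g in genes:
        vec = track[g.chrom]
        lo, hi = g.tss - flank, g.tss + flank + 1
        if lo < 0 or hi > vec.size:
            dropped += 1
            continue
        row = vec[lo:hi]
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
        kept.append(g.gene_id)
    if dropped:
        warnings.warn(f"dropped {dropped} genes without full +/-{flank} bp flanks",
                      stacklevel=2)
    if not rows:
        raise ValueError("no genes with full flanks on the track")
    return TssProfile(np.vstack(rows), np.arange(-flank, flank + 1), kept, label)


@dataclass(frozen=True)
class NucleosomeCall:
    center: int  # bp (profile coordinates, e.g. TSS-relative offset)
    width: int
    height: float
    score: float  # in [0, 1]


def call_nucleosomes(
    mean_profile: np.ndarray,
    offsets: np.ndarray | None = None,
    smooth_window: int = 75,
    min_distance: int = 120,
    min_height_frac: float = 0.25,
) -> list[NucleosomeCall]:
    """Call nucleosome positions on a (mean) occupancy profile.

    Moving-average smoothing, then local maxima whose height above the
    profile minimum exceeds ``min_height_frac`` of the profile relief
    (max - min); maxima closer than ``min_distance`` are merged keeping the
    higher.  Profiles whose relief is below ``min_height_frac`` of the maximum
    (flat or noise-only) yield no calls.  Width is the span where the smoothed
    signal stays above 50% of the peak height (capped midway to neighbouring
    calls so calls never overlap); the score combines relative height with
    the peak's centre stability.
    """
    y = np.asarray(mean_profile, dtype=float)
    if y.size < smooth_window:
        raise ValueError("profile shorter than the smoothing window")
    kernel = np.ones(smooth_window) / smooth_window
    pad = smooth_window // 2
    padded = np.pad(y, pad, mode="edge")  # avoid zero-padding damping at the ends
    sm = np.convolve(padded, kernel, mode="same")[pad:pad + y.size]
    top, bottom = float(sm.max()), float(sm.min())
    relief = top - bottom
    if top <= 0 or relief < min_height_frac * abs(top):
        return []  # flat (or noise-only) profile
    height_min = bottom + min_height_frac * relief
    peaks, _ = signal.find_peaks(sm, height=height_min, distance=min_distance)
    if peaks.size == 0:
        return []
    calls: list[NucleosomeCall] = []
    for j, p in enumerate(peaks):
        half = bottom + 0.5 * (sm[p] - bottom)
        lo = p
        while lo > 0 and sm[lo - 1] >= half:
            lo -= 1
        hi = p
        while hi < sm.size - 1 and sm[hi + 1] >= half:
            hi += 1
        if j > 0:
            lo = max(lo, (peaks[j - 1] + p) // 2 + 1)
        if j < peaks.size - 1:
            hi = min(hi, (p + peaks[j + 1]) // 2 - 1)
        width = max(hi - lo + 1, 1)
        weights = sm[lo:hi + 1] - bottom
        centroid = float(np.average(np.arange(lo, hi + 1), weights=np.maximum(weights, 0)))
        jitter = abs(float(p) - centroid)
        score = float((sm[p] - bottom) / relief * max(0.0, 1.0 - jitter / width))
        center = int(p) if offsets is None else int(offsets[p])
        calls.append(NucleosomeCall(center=center, width=int(width),
                                    height=float(sm[p]), score=min(score, 1.0)))
    return calls


class OccupancyModel:
    """Occupancy of the 200 bp downstream of the TSS, treated vs untreated.

    Both tracks must come from the same strain with equal normalization (the
    untreated sample of the strain defines 100% occupancy).  Per gene the
    window mean of the treated track is divided by the untreated window mean;
    with ``normalize="tmm"`` (default) a trimmed-mean-of-M-values factor
    computed across all gene windows first puts the treated sample on the
    untreated scale, which removes the global depth renormalization that
    large-scale eviction otherwise leaks into unchanged genes.
    """

    def __init__(
        self,
        treated: CoverageTrack,
        untreated: CoverageTrack,
        genes: list[GeneModel],
        window: int = 200,
        normalize: str = "tmm",
    ):
        self.treated = treated
        self.untreated = untreated
        self.genes = genes
        self.window = window
        if normalize not in ("tmm", "none"):
            raise ValueError(f"unknown normalize mode {normalize!r}")
        self.normalize = normalize

    def _window_means(self, track: CoverageTrack) -> np.ndarray:
        means = np.full(len(self.genes), np.nan)
        for i, g in enumerate(self.genes):
            vec = track[g.chrom]
            if g.strand == "+":
                lo, hi = g.tss, g.tss + self.window
            else:
                lo, hi = g.tss - self.window + 1, g.tss + 1
            lo, hi = max(lo, 0), min(hi, vec.size)
            if hi > lo:
                means[i] = vec[lo:hi].mean()
        return means

    def fit(self) -> "OccupancyResults":
        if not self.genes:
            raise ValueError("empty gene group")
        t = self._window_means(self.treated)
        u = self._window_means(self.untreated)
        factor = 1.0
        if self.normalize == "tmm":
            factor = tmm_factor(t, u)
        usable = np.isfinite(t) & np.isfinite(u) & (u > 0)
        if (~usable).any():
            warnings.warn(
                f"excluded {int((~usable).sum())} genes with zero/undefined untreated signal",
                stacklevel=2,
            )
        if not usable.any():
            raise ValueError("no genes with positive untreated occupancy")
        gene_ids = [g.gene_id for g in self.genes]
        occ = 100.0 * (t / factor) / u
        df = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "treated_mean": t,
                "untreated_mean": u,
                "occupancy_pct": occ,
            }
        ).loc[usable].reset_index(drop=True)
        df["eviction_pct"] = 100.0 - df["occupancy_pct"]
        return OccupancyResults(df, window=self.window, tmm=factor, model=self)


@dataclass
class OccupancyResults:
    """Per-gene occupancy/eviction percentages with group summaries."""

    per_gene: pd.DataFrame  # gene_id, treated_mean, untreated_mean, occupancy_pct, eviction_pct
    window: int
    tmm: float
    model: OccupancyModel | None = field(default=None, repr=False)

    @property
    def mean_occupancy(self) -> float:
        return float(self.per_gene["occupancy_pct"].mean())

    @property
    def mean_eviction(self) -> float:
        return float(self.per_gene["eviction_pct"].mean())

    def group_summary(self, groups: dict[str, str]) -> pd.DataFrame:
        """Mean occupancy/eviction per group (``groups`` maps gene_id -> group)."""
        df = self.per_gene.copy()
        df["group"] = df["gene_id"].map(groups)
        out = (
            df.dropna(subset=["group"])
            .groupby("group")[["occupancy_pct", "eviction_pct"]]
            .agg(["mean", "count"])
        )
        out.columns = ["occupancy_mean", "n", "eviction_mean", "_n2"]
        return out.drop(columns="_n2").reset_index()

    def eviction_of(self, gene_ids: list[str]) -> np.ndarray:
        sub = self.per_gene.set_index("gene_id").loc[gene_ids, "eviction_pct"]
        return sub.to_numpy(dtype=float)

    def summary(self) -> str:
        lines = [
            f"TSS +{self.window} bp occupancy",
            "========================",
            f"genes:            {len(self.per_gene)}",
            f"TMM factor:       {self.tmm:.4f}",
            f"mean occupancy:   {self.mean_occupancy:7.2f} %",
            f"mean eviction:    {self.mean_eviction:7.2f} %",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.per_gene.to_csv(path, sep="\t", index=False)


def occupancy_percent(
    track_treated: CoverageTrack,
    track_untreated: CoverageTrack,
    genes: list[GeneModel],
    window: int = 200,
    normalize: str = "tmm",
) -> OccupancyResults:
    """Convenience wrapper: fit an :class:`OccupancyModel` in one call."""
    return OccupancyModel(track_treated, track_untreated, genes, window, normalize).fit()


def compare_eviction(
    occ_a: OccupancyResults | np.ndarray,
    occ_b: OccupancyResults | np.ndarray,
    gene_ids: list[str] | None = None,
) -> tuple[float, float]:
    """Paired two-sided Student t-test on per-gene eviction percentages.

    Typically compares wild-type vs hog1 eviction upon stress over the same
    gene set.  Returns (t, p); identical vectors give (0.0, 1.0).
    """
    if isinstance(occ_a, OccupancyResults):
        if gene_ids is None:
            ids_a = set(occ_a.per_gene["gene_id"])
            ids_b = set(occ_b.per_gene["gene_id"])
            gene_ids = sorted(ids_a & ids_b)
            if ids_a != ids_b:
                raise ValueError("mismatched gene sets; pass gene_ids explicitly")
        a = occ_a.eviction_of(gene_ids)
        b = occ_b.eviction_of(gene_ids)
    else:
        a = np.asarray(occ_a, dtype=float)
        b = np.asarray(occ_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mismatched gene sets")
    if a.size < 3:
        raise ValueError("need at least 3 paired genes")
    if np.allclose(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
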