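"""MA transformation and A-stratified Z-score enrichment calling.

Two TRPK-normalized count tables (treated vs untreated, or wt-stress vs
hog1-stress for differential recruitment) are compared on the MA scale:
M = log2 ratio, A = mean log2 intensity.  Regions are split into equal-count
strata by A, M is standardized within its stratum, and a region is called
enriched when its Z-score exceeds a fixed threshold (one-sided by default:
the thresholds describe gained signal).

The default standardization ("technical-null") estimates each stratum's null
spread by a binomial split of the pooled raw counts — the exact technical
replicate null under Poisson sampling — and centres M at its global median,
which is robust when a substantial minority of regions is truly changed.  The
"empirical" mode standardizes against the observed stratum mean/sd, and
"robust" against the stratum median/MAD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import RegionCountTable

__all__ = [
    "Z_HOG1_BINDING",
    "Z_POLII_RECRUITMENT",
    "Z_DIFFERENTIAL",
    "MAEnrichment",
    "EnrichmentResults",
    "ma_transform",
    "zscore_stratified",
    "call_enriched",
    "differential_recruitment",
]

# One-sided Z thresholds for the three genome-wide comparisons.
Z_HOG1_BINDING = 4.0
Z_POLII_RECRUITMENT = 6.0
Z_DIFFERENTIAL = 4.0

_MAD_SCALE = 1.4826  # MAD -> sd for a normal distribution


def _as_values(table, column: str) -> np.ndarray:
    if isinstance(table, RegionCountTable):
        col = column if column in table.df.columns else "rpk"
        return table.values(col)
    return np.asarray(table, dtype=float)


def ma_transform(
    counts_a,
    counts_b,
    pseudocount: float = 0.5,
    region_ids=None,
) -> pd.DataFrame:
    """MA coordinates of treated (b) vs untreated (a) normalized counts.

    M = log2((b + pc) / (a + pc)); A = 0.5 * (log2(a + pc) + log2(b + pc)).
    Returns a frame with columns region_id, M, A (Z unset).
    """
    a = _as_values(counts_a, "trpk")
    b = _as_values(counts_b, "trpk")
    if a.shape != b.shape:
        raise ValueError("mismatched region sets between the two samples")
    if region_ids is None:
        if isinstance(counts_a, RegionCountTable):
            region_ids = counts_a.region_ids.to_numpy()
            if isinstance(counts_b, RegionCountTable) and not np.array_equal(
                region_ids, counts_b.region_ids.to_numpy()
            ):
                raise ValueError("mismatched region ids between the two samples")
        else:
            region_ids = np.arange(a.size)
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    return pd.DataFrame({"region_id": region_ids, "M": lb - la, "A": 0.5 * (la + lb)})


def _assign_strata(a_values: np.ndarray, n_strata: int, min_per_stratum: int) -> np.ndarray:
    """Equal-count strata by A; strata are merged when points are scarce."""
    n = a_values.size
    n_eff = max(1, min(n_strata, n // min_per_stratum))
    order = np.argsort(a_values, kind="stable")
    strata = np.empty(n, dtype=np.int64)
    strata[order] = (np.arange(n) * n_eff) // n
    return strata


def zscore_stratified(
    points: pd.DataFrame,
    n_strata: int = 20,
    min_per_stratum: int = 25,
    method: str = "empirical",
) -> pd.DataFrame:
    """Standardize M within equal-count A-strata (self-calibrated modes).

    ``method="empirical"`` uses the stratum mean and sd (ddof=1);
    ``method="robust"`` the stratum median and scaled MAD.  Strata with zero
    spread yield Z = 0 with a warning.  Input row order is irrelevant to the
    per-region result.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points to standardize")
    out = points.copy()
    strata = _assign_strata(out["A"].to_numpy(), n_strata, min_per_stratum)
    out["stratum"] = strata
    m = out["M"].to_numpy()
    z = np.zeros(len(out))
    for s in np.unique(strata):
        idx = strata == s
        ms = m[idx]
        if method == "empirical":
            centre, spread = float(np.mean(ms)), float(np.std(ms, ddof=1)) if ms.size > 1 else 0.0
        elif method == "robust":
            centre = float(np.median(ms))
            spread = _MAD_SCALE * float(np.median(np.abs(ms - centre)))
        else:
            raise ValueError(f"unknown method {method!r}")
        # summation noise on identical values can leave a ~1e-16 residual sd
        if spread <= 1e-12 * max(1.0, abs(centre)):
            warnings.warn(f"stratum {s}: zero M spread, Z set to 0", stacklevel=2)
            z[idx] = 0.0
        else:
            z[idx] = (ms - centre) / spread
    out["Z"] = z
    return out


def call_enriched(
    points: pd.DataFrame,
    z_threshold: float = Z_HOG1_BINDING,
    direction: str = "enriched",
) -> pd.DataFrame:
    """Threshold Z-scores into enrichment calls (strict inequality).

    One-sided by default (``Z > z_threshold``); ``direction="both"`` calls
    ``|Z| > z_threshold`` for two-sided MA analyses of down-regulation.
    """
    out = points.copy()
    z = out["Z"].to_numpy()
    if direction == "enriched":
        out["significant"] = z > z_threshold
    elif direction == "both":
        out["significant"] = np.abs(z) > z_threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    out["direction"] = np.where(out["M"] > 0, "up", np.where(out["M"] < 0, "down", "flat"))
    return out


class MAEnrichment:
    """Model for MA / Z-score enrichment between two samples.

    Parameters
    ----------
    treated, untreated:
        :class:`RegionCountTable` over identical regions (TRPK column used
        when present), or plain normalized value arrays.
    pseudocount:
        Added to both samples before the logs so that M and A stay finite.
    raw_treated, raw_untreated:
        Raw integer counts for the technical-null calibration; taken from the
        count tables automatically.
    """

    def __init__(
        self,
        treated,
        untreated,
        region_ids=None,
        pseudocount: float = 0.5,
        raw_treated=None,
        raw_untreated=None,
    ):
        self.points = ma_transform(untreated, treated, pseudocount, region_ids)
        self.pseudocount = pseudocount
        if raw_treated is None and isinstance(treated, RegionCountTable):
            raw_treated = treated.values("count")
        if raw_untreated is None and isinstance(untreated, RegionCountTable):
            raw_untreated = untreated.values("count")
        self.raw_treated = None if raw_treated is None else np.asarray(raw_treated)
        self.raw_untreated = None if raw_untreated is None else np.asarray(raw_untreated)

    def fit(
        self,
        n_strata: int = 20,
        min_per_stratum: int = 25,
        method: str = "technical-null",
        random_state: int = 0,
    ) -> "EnrichmentResults":
        if method in ("empirical", "robust"):
            points = zscore_stratified(self.points, n_strata, min_per_stratum, method)
        elif method == "technical-null":
            points = self._fit_technical_null(n_strata, min_per_stratum, random_state)
        else:
            raise ValueError(f"unknown method {method!r}")
        return EnrichmentResults(points, method=method, model=self)

    def _fit_technical_null(
        self, n_strata: int, min_per_stratum: int, random_state: int
    ) -> pd.DataFrame:
        if self.raw_treated is None or self.raw_untreated is None:
            raise ValueError(
                "technical-null calibration needs raw counts; construct the model "
                "from RegionCountTables or pass raw_treated/raw_untreated "
                "(or use method='empirical')"
            )
        out = self.points.copy()
        if len(out) < 2:
            raise ValueError("need at least 2 points to standardize")
        strata = _assign_strata(out["A"].to_numpy(), n_strata, min_per_stratum)
        out["stratum"] = strata
        rng = np.random.default_rng(random_state)
        pooled = (self.raw_treated + self.raw_untreated).astype(np.int64)
        total_t = float(max(self.raw_treated.sum(), 1))
        total_u = float(max(self.raw_untreated.sum(), 1))
        p_treated = total_t / (total_t + total_u)
        null_t = rng.binomial(pooled, p_treated)
        null_u = pooled - null_t
        pc = self.pseudocount
        # depth-balance the split so the null M is centred at ~0
        m_null = (
            np.log2(null_t + pc)
            - np.log2(null_u + pc)
            - np.log2(p_treated / (1.0 - p_treated))
        )
        m = out["M"].to_numpy()
        centre = float(np.median(m))
        z = np.zeros(len(out))
        for s in np.unique(strata):
            idx = strata == s
            spread = float(np.std(m_null[idx], ddof=1)) if idx.sum() > 1 else 0.0
            if spread == 0.0:
                warnings.warn(f"stratum {s}: zero null spread, Z set to 0", stacklevel=2)
                z[idx] = 0.0
            else:
                z[idx] = (m[idx] - centre) / spread
        out["Z"] = z
        return out


@dataclass
class EnrichmentResults:
    """Fitted MA points with Z-scores, plus calling and reporting helpers."""

    points: pd.DataFrame
    method: str
    model: MAEnrichment | None = field(default=None, repr=False)

    def calls(
        self, z_threshold: float = Z_HOG1_BINDING, direction: str = "enriched"
    ) -> pd.DataFrame:
        return call_enriched(self.points, z_threshold, direction)

    def enriched_ids(self, z_threshold: float = Z_HOG1_BINDING) -> set[str]:
        calls = self.calls(z_threshold)
        return set(calls.loc[calls["significant"], "region_id"])

    def summary(self, z_threshold: float = Z_HOG1_BINDING) -> str:
        p = self.points
        n_sig = int((p["Z"] > z_threshold).sum())
        lines = [
            "MA enrichment (A-stratified Z-scores)",
            "=====================================",
            f"regions:          {len(p)}",
            f"strata:           {p['stratum'].nunique()}",
            f"method:           {self.method}",
            f"median M:         {p['M'].median():8.4f}",
            f"Z > {z_threshold:g}:          {n_sig} ({100.0 * n_sig / max(len(p), 1):.2f}%)",
        ]
        return "\n".join(lines)

    def plot_ma(self, z_threshold: float = Z_HOG1_BINDING, ax=None):
        """MA scatter with significant regions highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.points
        sig = p["Z"] > z_threshold
        ax.scatter(p.loc[~sig, "A"], p.loc[~sig, "M"], s=4, c="0.4", label="n.s.")
        ax.scatter(p.loc[sig, "A"], p.loc[sig, "M"], s=6, c="crimson",
                   label=f"Z > {z_threshold:g}")
        ax.axhline(0.0, lw=0.5, c="k")
        ax.set_xlabel("A (mean log2 intensity)")
        ax.set_ylabel("M (log2 ratio)")
        ax.legend(frameon=False)
        return ax

    def to_tsv(self, path, z_threshold: float = Z_HOG1_BINDING) -> None:
        self.calls(z_threshold).to_csv(path, sep="\t", index=False)


def differential_recruitment(
    counts_wt_stress,
    counts_hog1_stress,
    pseudocount: float = 0.5,
    n_strata: int = 20,
    min_per_stratum: int = 25,
    z_threshold: float = Z_DIFFERENTIAL,
    method: str = "technical-null",
    random_state: int = 0,
) -> pd.DataFrame:
    """Hog1-dependent recruitment: wt-stress (treated) vs hog1-stress.

    Significant regions show higher wt than hog1 recruitment at Z above the
    threshold (one-sided).
    """
    model = MAEnrichment(counts_wt_stress, counts_hog1_stress, pseudocount=pseudocount)
    res = model.fit(n_strata=n_strata, min_per_stratum=min_per_stratum,
                    method=method, random_state=random_state)
    return res.calls(z_threshold)
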