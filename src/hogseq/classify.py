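"""Stress-response gene classification, binding assignment and summaries.

Gene classes are derived from linear expression fold changes upon stress:

- osmoresponsive: FC > 1.75 in wild type (strict);
- NaCl group: FC > 3 (strict), the strongly induced representative set;
- Hog1-dependent: osmoresponsive genes whose residual induction in a hog1
  strain is at most 75% of wild type (fc_hog1 / fc_wt <= 0.75, i.e. the
  induction depends at least 25% on the kinase);
- Hog1-independent: osmoresponsive genes whose hog1-strain induction is at
  least 90% of wild type (ratio >= 0.90); genes in the 0.75-0.90 gap are
  "neither" and excluded from dependent/independent comparisons;
- housekeeping: FC in [1, 1.1] (inclusive);
- down-regulated: FC <= 0.5 (inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_genes",
    "top_n_by_fc",
    "binding_assignment",
    "venn_counts",
    "colocalization_stats",
    "group_mean_fc",
]

FC_OSMORESPONSIVE = 1.75
FC_NACL_GROUP = 3.0
DEPENDENT_RATIO = 0.75
INDEPENDENT_RATIO = 0.90
HOUSEKEEPING_RANGE = (1.0, 1.1)
DOWN_REGULATED_FC = 0.5


def classify_genes(
    expression: pd.DataFrame,
    fc_threshold: float = FC_OSMORESPONSIVE,
    nacl_threshold: float = FC_NACL_GROUP,
    dependent_ratio: float = DEPENDENT_RATIO,
    independent_ratio: float = INDEPENDENT_RATIO,
    housekeeping_range: tuple[float, float] = HOUSEKEEPING_RANGE,
    down_threshold: float = DOWN_REGULATED_FC,
    scale: str = "linear",
) -> pd.DataFrame:
    """Label genes from an expression table (gene_id, fc_wt, fc_hog1).

    Returns a frame with boolean flags (osmoresponsive, nacl_group,
    housekeeping, down_regulated), the dependency class among osmoresponsive
    genes (hog1_dependent / hog1_independent / neither; NA otherwise) and a
    single consolidated ``label`` column.  ``scale="log2"`` computes the
    dependency ratio on the log2 scale instead of the linear one.
    """
    for col in ("gene_id", "fc_wt", "fc_hog1"):
        if col not in expression.columns:
            raise ValueError(f"expression table missing column {col!r}")
    fc_wt = expression["fc_wt"].to_numpy(dtype=float)
    fc_hog1 = expression["fc_hog1"].to_numpy(dtype=float)
    if (fc_wt <= 0).any() or (fc_hog1 <= 0).any():
        raise ValueError("fold changes must be positive")

    osmo = fc_wt > fc_threshold
    nacl = fc_wt > nacl_threshold
    housekeeping = (fc_wt >= housekeeping_range[0]) & (fc_wt <= housekeeping_range[1])
    down = fc_wt <= down_threshold

    if scale == "linear":
        ratio = fc_hog1 / fc_wt
    elif scale == "log2":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.log2(fc_hog1) / np.log2(fc_wt)
    else:
        raise ValueError(f"unknown scale {scale!r}")

    dependency = np.full(len(fc_wt), None, dtype=object)
    dependency[osmo] = "neither"
    dependency[osmo & (ratio <= dependent_ratio)] = "hog1_dependent"
    dependency[osmo & (ratio >= independent_ratio)] = "hog1_independent"

    label = np.full(len(fc_wt), "unchanged", dtype=object)
    label[down] = "down_regulated"
    label[housekeeping] = "housekeeping"
    label[osmo] = "osmoresponsive_unclassified"
    for cls in ("hog1_dependent", "hog1_independent"):
        label[dependency == cls] = cls

    return pd.DataFrame(
        {
            "gene_id": expression["gene_id"].to_numpy(),
            "osmoresponsive": osmo,
            "nacl_group": nacl,
            "dependency": dependency,
            "housekeeping": housekeeping,
            "down_regulated": down,
            "label": label,
        }
    )


def top_n_by_fc(
    labels: pd.DataFrame,
    expression: pd.DataFrame,
    n: int = 100,
    class_name: str = "hog1_dependent",
) -> list[str]:
    """The n most stress-responsive genes (by fc_wt) of one class.

    Ties break deterministically by gene_id; n larger than the class returns
    the whole class.
    """
    merged = labels.merge(expression, on="gene_id")
    members = merged.loc[merged["label"] == class_name]
    ordered = members.sort_values(["fc_wt", "gene_id"], ascending=[False, True],
                                  kind="stable")
    return ordered["gene_id"].head(max(n, 0)).tolist()


def binding_assignment(
    hog1_calls: pd.DataFrame,
    polii_calls: pd.DataFrame,
    gene_ids: list[str],
) -> pd.DataFrame:
    """Per-gene promoter/ORF Hog1 binding flags and Pol II recruitment.

    ``hog1_calls`` / ``polii_calls`` carry region-level enrichment calls with
    columns gene_id, kind (promoter|orf) and significant.  A gene is
    Hog1-bound when either region exceeds the threshold; the category records
    the promoter-vs-ORF breakdown.
    """
    def _flags(calls: pd.DataFrame, kind: str) -> set[str]:
        sub = calls.loc[(calls["kind"] == kind) & calls["significant"], "gene_id"]
        return set(sub)

    hog1_prom = _flags(hog1_calls, "promoter")
    hog1_orf = _flags(hog1_calls, "orf")
    polii_any = set(polii_calls.loc[polii_calls["significant"], "gene_id"])
    rows = []
    for g in gene_ids:
        p, o = g in hog1_prom, g in hog1_orf
        category = {
            (True, True): "both",
            (True, False): "promoter_only",
            (False, True): "orf_only",
            (False, False): "none",
        }[(p, o)]
        rows.append((g, p, o, p or o, g in polii_any, category))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "hog1_promoter", "hog1_orf", "hog1_bound",
                 "polii_recruited", "category"],
    )


def venn_counts(set_a: set, set_b: set, set_c: set) -> dict[str, int]:
    """Exact three-set overlap counts (seven cells summing to |union|)."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab": len((a & b) - c),
        "ac": len((a & c) - b),
        "bc": len((b & c) - a),
        "abc": len(a & b & c),
    }


def colocalization_stats(
    hog1_z: np.ndarray,
    polii_z: np.ndarray,
    fc: np.ndarray,
    method: str = "spearman",
) -> pd.DataFrame:
    """Pairwise rank correlations between Hog1 Z, Pol II Z and expression FC."""
    if method == "spearman":
        corr = stats.spearmanr
    elif method == "pearson":
        corr = stats.pearsonr
    else:
        raise ValueError(f"unknown method {method!r}")
    series = {"hog1_z": np.asarray(hog1_z, dtype=float),
              "polii_z": np.asarray(polii_z, dtype=float),
              "fc": np.asarray(fc, dtype=float)}
    n = len(series["hog1_z"])
    rows = []
    for x, y in (("hog1_z", "polii_z"), ("hog1_z", "fc"), ("polii_z", "fc")):
        r = corr(series[x], series[y])
        rows.append((x, y, float(r.statistic), float(r.pvalue), n))
    return pd.DataFrame(rows, columns=["var_x", "var_y", "rho", "p", "n"])


def group_mean_fc(labels: pd.DataFrame, expression: pd.DataFrame, group) -> float:
    """Arithmetic mean fc_wt over a label value or an explicit gene list."""
    if isinstance(group, str):
        members = labels.loc[labels["label"] == group, "gene_id"]
    else:
        members = pd.Series(list(group))
    sub = expression.loc[expression["gene_id"].isin(set(members)), "fc_wt"]
    if sub.empty:
        raise ValueError(f"empty gene group {group!r}")
    return float(sub.mean())
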