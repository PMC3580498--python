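"""Machine-readable run report plus a plain-text rendering.

The report is a nested dict of plain Python scalars (JSON-serializable and
byte-stable for a fixed config and seed): group sizes, Venn cells, occupancy
and eviction per group, test statistics, correlations, thresholds, seed and
config hash.
"""

from __future__ import annotations

import numpy as np

from .enrichment import Z_DIFFERENTIAL, Z_HOG1_BINDING, Z_POLII_RECRUITMENT

__all__ = ["StageError", "run_report", "render_text"]


class StageError(RuntimeError):
    """An upstream pipeline stage is missing; the message names it."""


def _round(x, nd=4):
    return round(float(x), nd)


def run_report(
    config,
    classification,
    chip,
    mnase,
    venn,
    colocalization,
    truth_sizes=None,
    hog1_bound_fraction=None,
) -> dict:
    """Assemble the structured run summary from the stage results."""
    for name, stage in (
        ("classification", classification),
        ("chip", chip),
        ("mnase", mnase),
        ("venn", venn),
        ("colocalization", colocalization),
    ):
        if stage is None:
            raise StageError(f"missing upstream output: {name}")

    binding = chip.binding
    report: dict = {
        "meta": {
            "seed": int(config.seed),
            "config_hash": config.content_hash(),
            "n_genes": int(sum(config.n_genes.values())),
            "chip_depth": int(config.chip_depth),
            "mnase_depth": int(config.mnase_depth),
            "thresholds": {
                "z_hog1_binding": Z_HOG1_BINDING,
                "z_polii_recruitment": Z_POLII_RECRUITMENT,
                "z_differential": Z_DIFFERENTIAL,
            },
        },
        "classification": {
            "recovered_sizes": {k: int(v) for k, v in sorted(classification.class_sizes.items())},
            "mean_fc": {k: _round(v) for k, v in sorted(classification.mean_fc.items())},
        },
        "chip": {
            "n_hog1_bound_genes": int(binding["hog1_bound"].sum()),
            "n_polii_recruited_genes": int(binding["polii_recruited"].sum()),
            "n_differential_regions": int(chip.differential["significant"].sum()),
            "hog1_category_counts": {
                k: int(v) for k, v in sorted(binding["category"].value_counts().items())
            },
            "venn": {k: int(v) for k, v in sorted(venn.items())},
        },
        "nucleosome": {
            "group_eviction_pct": {},
            "paired_t": _round(mnase.paired_test[0]),
            "paired_p": float(np.format_float_scientific(mnase.paired_test[1], precision=4)),
            "n_nucleosome_calls": {
                cls: len(calls) for cls, calls in sorted(mnase.nucleosome_calls.items())
            },
        },
        "colocalization": [
            {
                "pair": f"{r.var_x}~{r.var_y}",
                "rho": _round(r.rho) if np.isfinite(r.rho) else None,
                "p": float(np.format_float_scientific(r.p, precision=4))
                if np.isfinite(r.p) else None,
                "n": int(r.n),
            }
            for r in colocalization.itertuples(index=False)
        ],
    }
    for row in mnase.group_summary.itertuples(index=False):
        key = f"{row.strain}:{row.group}"
        report["nucleosome"]["group_eviction_pct"][key] = _round(row.eviction_mean, 2)
    if truth_sizes is not None:
        report["classification"]["truth_sizes"] = {
            k: int(v) for k, v in sorted(truth_sizes.items())
        }
    if hog1_bound_fraction is not None:
        report["chip"]["hog1_bound_fraction_by_truth_class"] = {
            k: _round(v) for k, v in sorted(hog1_bound_fraction.items())
        }
    return report


def render_text(report: dict) -> str:
    """Human-readable rendering of the structured report."""
    lines = []
    meta = report["meta"]
    lines.append("Osmostress chromatin pipeline report")
    lines.append("====================================")
    lines.append(f"seed {meta['seed']}  config {meta['config_hash']}  "
                 f"genes {meta['n_genes']}")
    lines.append("")
    lines.append("Gene classes (recovered):")
    for k, v in report["classification"]["recovered_sizes"].items():
        lines.append(f"  {k:28s} {v:6d}")
    lines.append("Mean fold changes:")
    for k, v in report["classification"]["mean_fc"].items():
        lines.append(f"  {k:28s} {v:8.3f}")
    lines.append("")
    chip = report["chip"]
    lines.append(f"Hog1-bound genes:        {chip['n_hog1_bound_genes']}")
    lines.append(f"Pol II recruited genes:  {chip['n_polii_recruited_genes']}")
    lines.append(f"Differential regions:    {chip['n_differential_regions']}")
    lines.append("Venn (Hog1 / Pol II / upregulated): " + ", ".join(
        f"{k}={v}" for k, v in chip["venn"].items()))
    if "hog1_bound_fraction_by_truth_class" in chip:
        for k, v in chip["hog1_bound_fraction_by_truth_class"].items():
            lines.append(f"  Hog1-bound fraction, {k}: {100 * v:.1f}%")
    lines.append("")
    nuc = report["nucleosome"]
    lines.append("Eviction (% of unstressed occupancy lost), strain:class")
    for k, v in sorted(nuc["group_eviction_pct"].items()):
        lines.append(f"  {k:32s} {v:7.2f}")
    lines.append(f"Paired t (wt vs hog1 eviction): t={nuc['paired_t']:.3f}, "
                 f"p={nuc['paired_p']:.3e}")
    lines.append("")
    lines.append("Colocalization (rank correlations):")
    for row in report["colocalization"]:
        if row["rho"] is None:
            lines.append(f"  {row['pair']:20s} rho undefined (constant input)  n={row['n']}")
        else:
            lines.append(f"  {row['pair']:20s} rho={row['rho']:+.3f}  "
                         f"p={row['p']:.3e}  n={row['n']}")
    return "\n".join(lines) + "\n"
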