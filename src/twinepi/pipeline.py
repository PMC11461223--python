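"""End-to-end runner: descriptives, SNP battery, epigenetic battery, exports.

`run_all` reads a cohort CSV and writes a reproducible artifact bundle:

* ``descriptives.csv`` — published-table-shaped summary (CpG sites + the
  five domains, epigenetic subsample by default);
* ``snp_results.csv`` — the 35-row gated association battery;
* ``epi_cells.csv`` + ``bubbles.json`` (+ ``bubbles.png``) — the 350-cell
  Barnard battery and its significant-cell bubble-chart data;
* ``manifest.json`` — config echo, versions, counts and exclusions, so
  every number in the bundle can be traced to its settings.

Any stage error aborts the run with a stage-tagged message and removes the
partial outputs already written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .association import DEFAULT_BONFERRONI_M, dominant_grouping, run_snp_battery
from .catalog import DEFAULT_CATALOG
from .cohort import Cohort, N_CPG_SITES
from .descriptives import GATE_ALPHA, describe
from .discordance import (
    ALTERNATIVES,
    BatteryCell,
    run_epigenetic_battery,
    summarize_significant,
)
from .errors import TwinEpiError, ValidationError
from .io import read_cohort_csv, write_contingency_json, write_results_csv

logger = logging.getLogger("twinepi")


@dataclass
class RunConfig:
    cohort_path: str = ""
    out_dir: str = "twinepi_out"
    gate_alpha: float = GATE_ALPHA
    bonferroni_m: int = DEFAULT_BONFERRONI_M
    grid_points: int = 1001
    alternatives: tuple[str, ...] = ALTERNATIVES
    alpha: float = 0.05
    pair_contribution: str = "both_twins"
    seed: int = 0
    log_level: str = "INFO"
    reproducible: bool = False
    bubble_png: bool = True


DESCRIBE_DEFAULT_VARS = tuple(
    [f"cpg{i}" for i in range(1, N_CPG_SITES + 1)] + list(DEFAULT_CATALOG.domains)
)


def descriptives_table(
    cohort: Cohort, variables: tuple[str, ...] = DESCRIBE_DEFAULT_VARS,
    subset: str = "epi",
) -> list[dict]:
    """Per-variable descriptive rows (M, Mdn, s, Min, Max, Sk, Ku).

    ``subset="epi"`` restricts to the epigenetic view (both co-twins of MZ
    pairs with complete methylation and traits); ``"all"`` uses every twin
    with a value for the variable.
    """
    if subset == "epi":
        twins = [t for p in cohort.mz_pairs_with_methylation for t in p.twins]
        if not twins:
            raise ValidationError("epigenetic view is empty; use subset='all'")
    elif subset == "all":
        twins = cohort.twins
    else:
        raise ValidationError(f"unknown subset: {subset!r}")
    rows = []
    for var in variables:
        if var.lower().startswith("cpg"):
            idx = int(var[3:])
            values = [
                t.methylation.site(idx)
                for t in twins
                if t.methylation is not None
                and not math.isnan(t.methylation.site(idx))
            ]
            label = f"CpG{idx}"
        else:
            key = DEFAULT_CATALOG.canonicalize(var)
            values = [
                t.traits.score(key)
                for t in twins
                if not math.isnan(t.traits.score(key))
            ]
            label = DEFAULT_CATALOG.display_name(key)
        d = describe(np.asarray(values))
        rows.append(
            {
                "variable": label, "M": round(d.m, 2), "Mdn": round(d.mdn, 2),
                "s": round(d.s, 2), "Min": round(d.min, 2),
                "Max": round(d.max, 2), "Sk": round(d.sk, 2),
                "Ku": round(d.ku, 2) if not math.isnan(d.ku) else "",
            }
        )
    return rows


def export_bubble_png(cells: list[BatteryCell], path: str | Path) -> Path:
    """Minimal static bubble-chart export of significant battery cells."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 5))
    if cells:
        xs = [f"CpG{c.cpg}" for c in cells]
        ys = [c.scale for c in cells]
        sizes = [40 + 2000 * max(0.0, 0.05 - c.p_value) for c in cells]
        colors = ["tab:blue" if c.alternative == "greater" else "tab:red"
                  for c in cells]
        ax.scatter(xs, ys, s=sizes, c=colors, alpha=0.6)
    ax.set_title("Significant methylation-trait discordance cells")
    ax.set_xlabel("CpG site")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the artifact path bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "read_cohort"
        cohort = read_cohort_csv(config.cohort_path)

        stage = "descriptives"
        desc_path = out_dir / "descriptives.csv"
        subset = "epi" if cohort.mz_pairs_with_methylation else "all"
        write_results_csv(descriptives_table(cohort, subset=subset), desc_path)
        written.append(desc_path)

        stage = "snp_battery"
        snp = run_snp_battery(
            cohort, gate_alpha=config.gate_alpha,
            bonferroni_m=config.bonferroni_m,
        )
        snp_path = out_dir / "snp_results.csv"
        write_results_csv(snp, snp_path)
        written.append(snp_path)

        stage = "epigenetic_battery"
        cells = run_epigenetic_battery(
            cohort,
            alternatives=config.alternatives,
            grid_points=config.grid_points,
            pair_contribution=config.pair_contribution,
        )
        cells_path = out_dir / "epi_cells.csv"
        write_results_csv(
            [
                {
                    "cpg": c.cpg, "scale": c.scale,
                    "alternative": c.alternative,
                    "x_high": c.table.x1, "n_high": c.table.n1,
                    "x_low": c.table.x2, "n_low": c.table.n2,
                    "n_pairs_used": c.n_pairs_used,
                    "n_pairs_excluded": c.n_pairs_excluded,
                    "p_value": c.p_value,
                }
                for c in cells
            ],
            cells_path,
        )
        written.append(cells_path)

        stage = "report"
        report = summarize_significant(cells, config.alpha)
        bubbles_path = out_dir / "bubbles.json"
        write_contingency_json(report["cells"], bubbles_path)
        written.append(bubbles_path)
        if config.bubble_png:
            png_path = out_dir / "bubbles.png"
            export_bubble_png(report["cells"], png_path)
            written.append(png_path)

        stage = "manifest"
        groups = dominant_grouping(cohort)
        manifest = {
            "package": "twinepi",
            "version": __version__,
            "config": dataclasses.asdict(config),
            "counts": {
                "n_twins": len(cohort.twins),
                "n_pairs": cohort.n_pairs,
                "n_epi_pairs": len(cohort.mz_pairs_with_methylation),
                "n_val_plus": groups.n_val,
                "n_met_plus": groups.n_met,
            },
            "epi_cells": len(cells),
            "n_significant": report["n_significant"],
            "exclusions": {
                f"cpg{cpg}": int(
                    max(c.n_pairs_excluded for c in cells if c.cpg == cpg)
                )
                for cpg in sorted({c.cpg for c in cells})
            },
        }
        if not config.reproducible:
            manifest["generated_at"] = datetime.now(timezone.utc).isoformat()
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
        written.append(manifest_path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, TwinEpiError):
            raise type(exc)(f"[{stage}] {exc}") from exc
        raise RuntimeError(f"[{stage}] {exc}") from exc
    return {p.name: p for p in written}
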