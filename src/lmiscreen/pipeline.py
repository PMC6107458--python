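"""End-to-end orchestration and result-table rendering.

``run_pipeline`` drives the retrospective analysis flow: read the peak table
and manifest, optionally total-area-normalize, log-transform, run the
single-ion screen and the dual-ion screens for each configured comparison,
run the gated group statistics for the top single ions, and write delimited
result tables plus a JSON run manifest (config echo, versions, screen
bookkeeping).  Output tables are deterministic given inputs and config.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .dual_ion import PairResult, PairScreen, canonical_method, screen_pairs
from .group_stats import compare_groups
from .peak_table import (
    CohortManifest,
    Comparison,
    PeakTable,
    log_transform,
    normalize_total_area,
    read_manifest,
    read_peak_table,
)
from .single_ion import ThresholdSearchResult, rank_single_ions

__all__ = ["PipelineConfig", "run_pipeline", "render_results_table", "format_percent"]

logger = logging.getLogger(__name__)


def format_percent(fraction: float) -> str:
    """Render a fraction as a percentage, two decimals, half-up: 0.902 -> '90.20%'."""
    q = Decimal(repr(fraction * 100)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return f"{q}%"


def parse_percent(text: str) -> float:
    return float(text.rstrip("%")) / 100.0


def _dec2(x: float) -> str:
    if x != x or math.isinf(x):
        return "inf" if x > 0 else "nan"
    return str(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


TABLE2_COLUMNS = [
    "mz", "rt", "max_threshold", "min_threshold", "difference",
    "fisher_ratio", "sensitivity", "specificity", "orientation",
]
TABLE3_4_COLUMNS = [
    "numerator_or_minuend_mz", "numerator_or_minuend_rt",
    "denominator_or_subtrahend_mz", "denominator_or_subtrahend_rt",
    "method", "threshold", "sensitivity", "specificity", "orientation",
]


def render_results_table(results: Sequence, style: str) -> str:
    """Render screening results as TSV text.

    ``style="table2"`` renders single-ion results (separating-threshold
    extremes, their difference, Fisher ratio); ``style="table3_4"`` renders
    pair results (ordered ion coordinates, threshold, performance).
    Percentages are printed to two decimals with a '%' sign.
    """
    lines: list[str] = []
    if style == "table2":
        lines.append("\t".join(TABLE2_COLUMNS))
        for r in results:
            if not isinstance(r, ThresholdSearchResult):
                raise TypeError(f"table2 expects ThresholdSearchResult, got {type(r)}")
            lines.append("\t".join([
                f"{r.ion.mz:.4f}", f"{r.ion.rt:.2f}",
                _dec2(r.tie_set_max), _dec2(r.tie_set_min),
                _dec2(r.gap) if r.gap is not None else "",
                _dec2(r.fisher_ratio) if r.fisher_ratio is not None else "",
                format_percent(r.sensitivity), format_percent(r.specificity),
                r.orientation,
            ]))
    elif style == "table3_4":
        lines.append("\t".join(TABLE3_4_COLUMNS))
        for r in results:
            if not isinstance(r, PairResult):
                raise TypeError(f"table3_4 expects PairResult, got {type(r)}")
            lines.append("\t".join([
                f"{r.numerator_or_minuend.mz:.4f}", f"{r.numerator_or_minuend.rt:.2f}",
                f"{r.denominator_or_subtrahend.mz:.4f}",
                f"{r.denominator_or_subtrahend.rt:.2f}",
                r.method, _dec2(r.threshold),
                format_percent(r.sensitivity), format_percent(r.specificity),
                r.orientation,
            ]))
    else:
        raise ValueError(f"unknown style {style!r}")
    return "\n".join(lines) + "\n"


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    table: str
    manifest: str
    out_dir: str
    comparisons: list[Comparison]
    increment: float = 0.01
    pair_methods: list[str] = field(
        default_factory=lambda: ["ratio_of_logs", "log_of_ratio"]
    )
    min_sensitivity: float = 0.90
    min_specificity: float = 0.90
    normalize: bool = False
    zero_policy: str = "skip"
    stats_top_n: int = 5
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.comparisons:
            raise ValueError("pipeline config needs at least one comparison")
        self.comparisons = [
            c if isinstance(c, Comparison)
            else Comparison(c["positive"], c["negative"], c.get("name", ""))
            for c in self.comparisons
        ]
        self.pair_methods = [canonical_method(m) for m in self.pair_methods]
        if self.increment <= 0:
            raise ValueError("increment must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "table": str(self.table),
            "manifest": str(self.manifest),
            "out_dir": str(self.out_dir),
            "comparisons": [
                {
                    "name": c.name,
                    "positive": sorted(c.positive_groups),
                    "negative": sorted(c.negative_groups),
                }
                for c in self.comparisons
            ],
            "increment": self.increment,
            "pair_methods": list(self.pair_methods),
            "min_sensitivity": self.min_sensitivity,
            "min_specificity": self.min_specificity,
            "normalize": self.normalize,
            "zero_policy": self.zero_policy,
            "stats_top_n": self.stats_top_n,
            "alpha": self.alpha,
            "seed": self.seed,
        }


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the run manifest (also written to disk).

    Any stage failure aborts with a :class:`StageError` naming the stage, and
    an ``INCOMPLETE`` marker file is left in the output directory.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "INCOMPLETE"
    marker.write_text("pipeline running\n")
    stage = "load"
    t0 = time.perf_counter()
    try:
        table = read_peak_table(config.table)
        manifest = read_manifest(config.manifest)
        run_info: dict = {
            "package": "lmiscreen",
            "version": __version__,
            "config": config.to_dict(),
            "n_ions": table.n_ions,
            "n_samples": table.n_samples,
            "comparisons": {},
        }
        if config.normalize:
            stage = "normalize"
            table = normalize_total_area(table)
        stage = "log_transform"
        if table.scale == "raw":
            table = log_transform(table)
        for comparison in config.comparisons:
            centry: dict = {"single": {}, "pairs": {}}
            stage = f"single_ion[{comparison.name}]"
            t = time.perf_counter()
            singles = rank_single_ions(table, manifest, comparison, config.increment)
            perfect = [r for r in singles if r.perfect]
            (out_dir / f"single_{comparison.name}.tsv").write_text(
                render_results_table(singles, "table2")
            )
            logger.info(
                "%s: %d ions screened, %d perfect (%.2fs)",
                stage, len(singles), len(perfect), time.perf_counter() - t,
            )
            centry["single"] = {
                "ions_screened": len(singles),
                "perfect": len(perfect),
            }
            for method in config.pair_methods:
                stage = f"dual_ion[{comparison.name},{method}]"
                t = time.perf_counter()
                screen: PairScreen = screen_pairs(
                    table, manifest, comparison, method,
                    min_sensitivity=config.min_sensitivity,
                    min_specificity=config.min_specificity,
                    increment=config.increment,
                    zero_policy=config.zero_policy,
                )
                (out_dir / f"pairs_{comparison.name}_{method}.tsv").write_text(
                    render_results_table(screen.pairs, "table3_4")
                )
                logger.info("%s: %d/%d pairs selected (%.2fs)", stage,
                            len(screen), screen.n_pairs_enumerated,
                            time.perf_counter() - t)
                centry["pairs"][method] = {
                    "pairs_enumerated": screen.n_pairs_enumerated,
                    "pairs_skipped": screen.n_pairs_skipped,
                    "pairs_screened": screen.n_pairs_enumerated
                    - screen.n_pairs_skipped,
                    "pairs_selected": len(screen),
                }
            stage = f"group_stats[{comparison.name}]"
            stats_rows = []
            top = (perfect or singles)[: config.stats_top_n]
            for res in top:
                for ga, gb in itertools.product(
                    sorted(comparison.positive_groups),
                    sorted(comparison.negative_groups),
                ):
                    if (len(manifest.members([ga])) < 3
                            or len(manifest.members([gb])) < 3):
                        continue
                    cmp_res = compare_groups(
                        table, manifest, res.ion, ga, gb, alpha=config.alpha
                    )
                    stats_rows.append(
                        "\t".join([
                            f"{res.ion.mz:.4f}", f"{res.ion.rt:.2f}", ga, gb,
                            cmp_res.test_used,
                            repr(cmp_res.statistic), repr(cmp_res.p_value),
                        ])
                    )
            header = "mz\trt\tgroup_a\tgroup_b\ttest\tstatistic\tp_value"
            (out_dir / f"stats_{comparison.name}.tsv").write_text(
                "\n".join([header, *stats_rows]) + "\n"
            )
            centry["stats_rows"] = len(stats_rows)
            run_info["comparisons"][comparison.name] = centry
        stage = "run_manifest"
        (out_dir / "run_manifest.json").write_text(
            json.dumps(run_info, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        marker.write_text(f"pipeline failed in stage {stage}: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    marker.unlink()
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return run_info
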