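"""The FPKM expression floor and per-set expression summaries.

A gene survives when its FPKM reaches the floor (default 0.21, inclusive) in
at least one population; the comparator is configurable because an exclusive
reading of the threshold also circulates. Genes absent from the matrix are
an error in strict mode and are dropped with a warning in lenient mode.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (
    ExpressionMatrix,
    GeneLocus,
    ModelValidationError,
    PipelineConfig,
    TranscriptCatalog,
    empty_catalog,
)

logger = logging.getLogger(__name__)


def gene_passes_floor(
    matrix: ExpressionMatrix, gene_id: str, floor: float, inclusive: bool = True
) -> bool:
    peak = matrix.max_fpkm(gene_id)
    return peak >= floor if inclusive else peak > floor


def filter_expressed(
    catalog: TranscriptCatalog,
    matrix: ExpressionMatrix,
    config: PipelineConfig | None = None,
) -> TranscriptCatalog:
    """Keep genes expressed at >= the floor in at least one population."""
    config = config or PipelineConfig()
    kept: list[GeneLocus] = []
    for locus in catalog.loci:
        if locus.gene_id not in matrix:
            if config.strict_expression:
                raise ModelValidationError(
                    f"gene {locus.gene_id!r} missing from the expression matrix"
                )
            logger.warning("dropping unmeasured gene %s", locus.gene_id)
            continue
        if gene_passes_floor(
            matrix, locus.gene_id, config.expression_floor, config.expression_inclusive
        ):
            kept.append(locus)
        else:
            logger.debug(
                "expression filter removed %s (max FPKM %.4f < %.4f)",
                locus.gene_id,
                matrix.max_fpkm(locus.gene_id),
                config.expression_floor,
            )
    if not kept:
        return empty_catalog()
    kept_ids = {t.transcript_id for l in kept for t in l.transcripts}
    return TranscriptCatalog(
        loci=tuple(kept),
        provenance={k: v for k, v in catalog.provenance.items() if k in kept_ids},
    )


def summarize_expression(
    matrix: ExpressionMatrix, gene_sets: Mapping[str, set[str]]
) -> pd.DataFrame:
    """Per-set distribution of per-gene peak FPKM (n, quartiles, mean).

    The tabular equivalent of a violin plot comparing gene classes (for
    example novel lincRNAs vs previously annotated ones).
    """
    rows = []
    for label in gene_sets:
        genes = sorted(gene_sets[label])
        unknown = [g for g in genes if g not in matrix]
        if unknown:
            raise ModelValidationError(
                f"gene set {label!r} contains genes absent from the matrix: "
                f"{unknown[:5]}"
            )
        peaks = np.array([matrix.max_fpkm(g) for g in genes], dtype=float)
        if peaks.size:
            q1, med, q3 = np.percentile(peaks, [25, 50, 75])
            rows.append(
                {
                    "set": label,
                    "n": peaks.size,
                    "min": peaks.min(),
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "max": peaks.max(),
                    "mean": peaks.mean(),
                }
            )
        else:
            rows.append(
                {"set": label, "n": 0, "min": np.nan, "q1": np.nan,
                 "median": np.nan, "q3": np.nan, "max": np.nan, "mean": np.nan}
            )
    return pd.DataFrame(
        rows, columns=["set", "n", "min", "q1", "median", "q3", "max", "mean"]
    )


def write_expression_summary(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, sep="\t", index=False)
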