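"""Per-cell normalization and per-section summaries.

Neural-tube tissue is too densely packed for nucleus instance segmentation,
so cell numbers are estimated by an intensity ratio: the background-
subtracted integrated DAPI intensity of an ROI divided by a per-nucleus
reference intensity measured in a sparse region where nuclei can be counted
by hand (or are known exactly, in simulations).  Spot counts divided by the
resulting (real-valued, deliberately unrounded) cell count give
spots-per-cell rates, the quantity compared across genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import RoiPolygon

__all__ = [
    "CellCountEstimate",
    "SectionSummary",
    "estimate_cell_count",
    "summarize_section",
    "summaries_to_frame",
    "abundance_ratio",
    "pool_sections",
]

logger = logging.getLogger(__name__)


@dataclass
class CellCountEstimate:
    """DAPI-ratio cell count for one ROI."""

    roi_label: str
    integrated_intensity: float
    reference_intensity_per_nucleus: float
    n_reference_nuclei: int
    estimate: float

    def __post_init__(self) -> None:
        if self.reference_intensity_per_nucleus <= 0:
            raise ValueError("per-nucleus reference intensity must be positive")
        if self.estimate < 0:
            raise ValueError("cell-count estimate cannot be negative")


@dataclass
class SectionSummary:
    """Per-section, per-ROI quantification record."""

    section_id: str
    roi_label: str
    genotype: str = ""
    region: str = ""
    cell_count: float = float("nan")
    spot_counts: dict = field(default_factory=dict)  # gene -> count (NaN = not measured)
    spots_per_cell: dict = field(default_factory=dict)
    coloc_counts: dict = field(default_factory=dict)  # class label -> count
    coloc_per_cell: dict = field(default_factory=dict)


def estimate_cell_count(dapi_sum_projection: np.ndarray, roi: RoiPolygon,
                        reference_region: RoiPolygon, n_reference_nuclei: int,
                        background_region: RoiPolygon | None = None) -> CellCountEstimate:
    """Estimate cells in an ROI from the DAPI intensity ratio.

    ``dapi_sum_projection`` is the z-sum of the DAPI channel.  The reference
    region must contain exactly ``n_reference_nuclei`` nuclei.  If a
    nucleus-free ``background_region`` is given, its median pixel value is
    subtracted from every integrated pixel first.
    """
    if n_reference_nuclei <= 0:
        raise ValueError("reference nucleus count must be positive")
    proj = np.asarray(dapi_sum_projection, dtype=float)
    if proj.ndim != 2:
        raise ValueError("expected a 2D sum projection")
    roi_mask = roi.mask(proj.shape)
    if not roi_mask.any():
        return CellCountEstimate(roi.label, 0.0, 1.0, n_reference_nuclei, 0.0)
    bg = 0.0
    if background_region is not None:
        bg_mask = background_region.mask(proj.shape)
        if bg_mask.any():
            bg = float(np.median(proj[bg_mask]))
    ref_mask = reference_region.mask(proj.shape)
    if not ref_mask.any():
        raise ValueError("reference region lies outside the image")
    integrated = float(np.clip(proj[roi_mask] - bg, 0, None).sum())
    ref_total = float(np.clip(proj[ref_mask] - bg, 0, None).sum())
    per_nucleus = ref_total / n_reference_nuclei
    if per_nucleus <= 0:
        raise ValueError("reference region has no DAPI signal above background")
    return CellCountEstimate(
        roi_label=roi.label,
        integrated_intensity=integrated,
        reference_intensity_per_nucleus=per_nucleus,
        n_reference_nuclei=n_reference_nuclei,
        estimate=integrated / per_nucleus,
    )


def summarize_section(spot_tables: Mapping[str, pd.DataFrame],
                      coloc_summary: pd.DataFrame | None,
                      cell_count: CellCountEstimate | float,
                      section_id: str, *, genotype: str = "", region: str = "",
                      genes: Mapping[str, str] | None = None) -> SectionSummary:
    """Combine spot counts, co-localization classes and the cell count.

    ``spot_tables`` maps channel label to its (accepted) spot table; a gene
    probed but absent from the mapping is marked not-measured (NaN), never
    zero.  ``genes`` optionally renames channels to gene labels.
    """
    cells = cell_count.estimate if isinstance(cell_count, CellCountEstimate) else float(cell_count)
    summary = SectionSummary(section_id=section_id,
                             roi_label=getattr(cell_count, "roi_label", ""),
                             genotype=genotype, region=region, cell_count=cells)
    for ch, table in spot_tables.items():
        gene = genes.get(ch, ch) if genes else ch
        if "accepted" in table.columns:
            count = int(table["accepted"].astype(bool).sum())
        else:
            count = len(table)
        summary.spot_counts[gene] = count
        summary.spots_per_cell[gene] = count / cells if cells > 0 else float("nan")
    if coloc_summary is not None:
        class_cols = [c for c in coloc_summary.columns if c != "total"]
        for col in class_cols:
            # memberships are per-channel; records themselves are counted once
            if col == "single":
                continue
            count = int(coloc_summary[col].max())
            summary.coloc_counts[col] = count
            summary.coloc_per_cell[col] = count / cells if cells > 0 else float("nan")
    return summary


def summaries_to_frame(summaries: Sequence[SectionSummary]) -> pd.DataFrame:
    """Flatten section summaries into a tidy table (one row per section)."""
    rows = []
    for s in summaries:
        row: dict = dict(section_id=s.section_id, roi_label=s.roi_label,
                         genotype=s.genotype, region=s.region, cell_count=s.cell_count)
        for gene, c in s.spot_counts.items():
            row[f"count:{gene}"] = c
            row[f"rate:{gene}"] = s.spots_per_cell.get(gene, float("nan"))
        for cls, c in s.coloc_counts.items():
            row[f"count:{cls}"] = c
            row[f"rate:{cls}"] = s.coloc_per_cell.get(cls, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def abundance_ratio(summaries: pd.DataFrame, gene_a: str, gene_b: str) -> pd.Series:
    """Per-section ratio of gene A over gene B spots-per-cell rates.

    Sections where the denominator is zero produce a missing value (logged
    and excluded from the returned series), not infinity.
    """
    col_a, col_b = f"rate:{gene_a}", f"rate:{gene_b}"
    for col in (col_a, col_b):
        if col not in summaries.columns:
            raise KeyError(f"no column {col!r}; was {col.split(':')[1]} measured?")
    num = summaries[col_a].astype(float)
    den = summaries[col_b].astype(float)
    zero = den == 0
    if zero.any():
        logger.info("abundance_ratio %s/%s: dropping %d sections with zero denominator",
                    gene_a, gene_b, int(zero.sum()))
    ratio = num / den.where(~zero)
    ratio.name = f"ratio:{gene_a}/{gene_b}"
    return ratio.dropna()


def pool_sections(summaries: pd.DataFrame, column: str,
                  weight: str = "equal") -> float:
    """Pool a per-section rate across sections.

    ``equal`` averages sections with equal weight (each section is one
    biological observation); ``cells`` weights by estimated cell count
    (equivalent to pooling raw counts).  Both are reported because the
    difference quantifies how section-size heterogeneity moves the average.
    """
    vals = summaries[column].astype(float)
    if weight == "equal":
        return float(vals.mean())
    if weight == "cells":
        w = summaries["cell_count"].astype(float)
        return float((vals * w).sum() / w.sum())
    raise ValueError("weight must be 'equal' or 'cells'")
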