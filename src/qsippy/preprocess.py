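"""Sample/taxon filtering and abundance normalization.

The fixed order of operations mirrors a typical gradient-amplicon
workflow: depth-outlier sample removal, rare-taxon removal, relative
abundance, then QSEQ normalization (scaling relative abundances by
per-sample total 16S copies from qPCR to obtain gene copies per ng DNA).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .gradient import DataError, FeatureTable, QpcrMeasurement

__all__ = [
    "FilterReport",
    "filter_samples_by_depth",
    "filter_rare_taxa",
    "to_relative_abundance",
    "qseq_normalize",
    "preprocess_counts",
]

log = logging.getLogger("qsippy")


@dataclass
class FilterReport:
    """Accounting of what a filtering step removed and why."""

    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    removed_taxa: list[tuple[str, str]] = field(default_factory=list)
    depth_mean: float | None = None
    depth_sd: float | None = None
    thresholds: dict = field(default_factory=dict)

    def merged_with(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            removed_samples=self.removed_samples + other.removed_samples,
            removed_taxa=self.removed_taxa + other.removed_taxa,
            depth_mean=self.depth_mean if self.depth_mean is not None else other.depth_mean,
            depth_sd=self.depth_sd if self.depth_sd is not None else other.depth_sd,
            thresholds={**self.thresholds, **other.thresholds},
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "removed_samples": self.removed_samples,
                "removed_taxa": self.removed_taxa,
                "depth_mean": self.depth_mean,
                "depth_sd": self.depth_sd,
                "thresholds": self.thresholds,
            },
            indent=1,
        )


def filter_samples_by_depth(table: FeatureTable, k: float = 2.0
                            ) -> tuple[FeatureTable, FilterReport]:
    """Drop samples whose sequencing depth is an outlier.

    Retains samples with depth within mean +/- k*SD, the mean and sample
    SD being computed once over all input samples (single pass; the
    bounds are not re-estimated after removal).
    """
    if table.unit != "read_count":
        raise ValueError("depth filtering requires a read_count table")
    if table.shape[1] < 2:
        raise ValueError("depth filtering requires at least two samples")
    depths = table.data.sum(axis=0)
    mean = float(depths.mean())
    sd = float(depths.std(ddof=1))
    if math.isinf(k):
        keep = depths.index
    else:
        lo, hi = mean - k * sd, mean + k * sd
        keep = depths.index[(depths >= lo) & (depths <= hi)]
    if len(keep) == 0:
        raise DataError("depth filter removed every sample")
    removed = [s for s in table.sample_ids if s not in set(keep)]
    report = FilterReport(
        removed_samples=[(s, f"depth {int(depths[s])} outside mean±{k}·SD") for s in removed],
        depth_mean=mean,
        depth_sd=sd,
        thresholds={"depth_k": k},
    )
    if removed:
        log.info("depth filter removed %d sample(s): %s", len(removed), removed)
    return table.select_samples([s for s in table.sample_ids if s in set(keep)]), report


def filter_rare_taxa(table: FeatureTable, min_count: int = 3,
                     min_prevalence: float = 0.02
                     ) -> tuple[FeatureTable, FilterReport]:
    """Drop rare/low-abundance taxa.

    A taxon is retained when its per-sample count reaches ``min_count``
    in at least ceil(min_prevalence * n_samples) samples.
    """
    if table.unit != "read_count":
        raise ValueError("rare-taxon filtering requires a read_count table")
    n_samples = table.shape[1]
    needed = math.ceil(min_prevalence * n_samples)
    hits = (table.data >= min_count).sum(axis=1)
    keep = hits.index[hits >= needed]
    if len(keep) == 0:
        raise DataError("rare-taxon filter removed every taxon")
    removed = [t for t in table.taxon_ids if t not in set(keep)]
    report = FilterReport(
        removed_taxa=[
            (t, f"count ≥{min_count} in {int(hits[t])} < {needed} samples")
            for t in removed
        ],
        thresholds={"min_count": min_count, "min_prevalence": min_prevalence,
                    "prevalence_samples": needed},
    )
    if removed:
        log.info("rare-taxon filter removed %d taxa", len(removed))
    return table.select_taxa([t for t in table.taxon_ids if t in set(keep)]), report


def to_relative_abundance(table: FeatureTable) -> FeatureTable:
    """Divide each sample column by its total so columns sum to 1."""
    if table.unit != "read_count":
        raise ValueError("relative-abundance transform expects a read_count table")
    sums = table.data.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise DataError(f"sample(s) with zero total counts: {zero}")
    rel = table.data.astype(float) / sums
    return FeatureTable(rel, "relative_abundance", table.taxonomy)


def qseq_normalize(table: FeatureTable,
                   qpcr: Mapping[str, QpcrMeasurement] | Mapping[str, float]
                   ) -> tuple[FeatureTable, FilterReport]:
    """QSEQ normalization: absolute abundance = relative * qPCR total.

    Each sample column is scaled by that sample's total 16S copies per ng
    DNA, so column sums equal the qPCR totals. Samples without a qPCR
    record are dropped and reported, mirroring removal for insufficient
    qPCR data.
    """
    if table.unit != "relative_abundance":
        raise ValueError("QSEQ normalization expects a relative_abundance table")
    totals = {
        s: (m.copies_per_ng_dna if isinstance(m, QpcrMeasurement) else float(m))
        for s, m in qpcr.items()
    }
    have = [s for s in table.sample_ids if s in totals]
    dropped = [s for s in table.sample_ids if s not in totals]
    if not have:
        raise DataError("no sample has qPCR data; cannot normalize")
    report = FilterReport(
        removed_samples=[(s, "insufficient qPCR data") for s in dropped],
        thresholds={"qseq": True},
    )
    if dropped:
        log.info("QSEQ dropped %d sample(s) lacking qPCR data: %s",
                 len(dropped), dropped)
    sub = table.data[have]
    scaled = sub * pd.Series({s: totals[s] for s in have})
    return FeatureTable(scaled, "copies_per_ng_dna", table.taxonomy), report


def preprocess_counts(table: FeatureTable,
                      qpcr: Mapping[str, QpcrMeasurement] | Mapping[str, float],
                      depth_k: float = 2.0, min_count: int = 3,
                      min_prevalence: float = 0.02
                      ) -> tuple[FeatureTable, FilterReport]:
    """Full preprocessing chain: depth filter -> rare-taxon filter ->
    relative abundance -> QSEQ normalization."""
    t1, r1 = filter_samples_by_depth(table, k=depth_k)
    t2, r2 = filter_rare_taxa(t1, min_count=min_count, min_prevalence=min_prevalence)
    rel = to_relative_abundance(t2)
    absolute, r3 = qseq_normalize(rel, qpcr)
    return absolute, r1.merged_with(r2).merged_with(r3)
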