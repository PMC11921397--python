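"""Active-community summaries.

Once the enrichment chain has flagged active taxa (at ASV level), this
module aggregates them to genus-level absolute abundances per replicate
core, averages across cores per treatment group, computes Shannon
diversity of each core's active community, and partitions active taxa
into the shared/unique regions of a k-set overlap (Venn) diagram.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gradient import DataError, FeatureTable

__all__ = [
    "ActiveCommunityProfile",
    "OverlapPartition",
    "total_active_abundance",
    "background_abundance",
    "shannon_diversity",
    "overlap_partition",
]

log = logging.getLogger("qsippy")

RANK_ORDER = ("genus", "family", "order", "class", "phylum", "domain")


def _taxon_label(taxon_id: str, taxonomy: pd.DataFrame | None,
                 rank: str = "genus") -> str:
    """Label a taxon at the requested rank, falling back to the finest
    resolved rank (and ultimately the taxon id itself)."""
    if taxonomy is None or taxon_id not in taxonomy.index:
        return taxon_id
    row = taxonomy.loc[taxon_id]
    start = RANK_ORDER.index(rank) if rank in RANK_ORDER else 0
    for r in RANK_ORDER[start:]:
        if r in row.index and pd.notna(row[r]) and str(row[r]).strip():
            return str(row[r])
    return taxon_id


def _phylum(taxon_id: str, taxonomy: pd.DataFrame | None) -> str | None:
    if taxonomy is None or taxon_id not in taxonomy.index:
        return None
    row = taxonomy.loc[taxon_id]
    if "phylum" in row.index and pd.notna(row["phylum"]):
        return str(row["phylum"])
    return None


@dataclass
class ActiveCommunityProfile:
    """Genus-level absolute abundance of the active community.

    ``frame`` is long-format: group, taxon (rank label), phylum, mean,
    sd, se, n_cores. ``per_core`` keeps the underlying per-core totals
    (rows = taxon label, columns = (group, core_id)).
    """

    frame: pd.DataFrame
    per_core: pd.DataFrame
    n_asvs: dict[str, int] = field(default_factory=dict)

    def shannon(self) -> pd.DataFrame:
        """Shannon diversity (nats) of each core's active community."""
        rows = []
        for (group, core) in self.per_core.columns:
            vec = self.per_core[(group, core)].to_numpy(dtype=float)
            if vec.sum() > 0:
                rows.append({"group": group, "core_id": core,
                             "shannon": shannon_diversity(vec),
                             "n_taxa": int((vec > 0).sum())})
        return pd.DataFrame(rows)


def _aggregate(table: FeatureTable, metadata: pd.DataFrame,
               active_taxa: Mapping[str, Iterable[str]],
               groups_to_sum: Sequence[str], isotopes: Sequence[str],
               rank: str, group_cols: tuple[str, ...]) -> ActiveCommunityProfile:
    md = metadata.copy()
    if "sample_id" in md.columns and md.index.name != "sample_id":
        md = md.set_index("sample_id", drop=False)
    md = md.loc[[s for s in table.sample_ids if s in md.index]]

    def gkey(row):
        return "_".join(str(row[c]) for c in group_cols) if group_cols else "all"

    md["_group"] = [gkey(md.loc[s]) for s in md.index]
    records: dict[tuple[str, str], pd.Series] = {}
    n_asvs: dict[str, int] = {}
    for group, gmd in md.groupby("_group"):
        active = set(active_taxa.get(group, ()))
        if not active:
            continue
        present = [t for t in table.taxon_ids if t in active]
        n_asvs[group] = len(present)
        gmd = gmd[gmd["isotope"].isin(isotopes)]
        for core, cmd in gmd.groupby("core_id"):
            wanted = cmd[cmd["density_group"].isin(groups_to_sum)]
            if len(wanted) == 0:
                warnings.warn(
                    f"core {core} ({group}) has none of the requested density "
                    f"groups {sorted(groups_to_sum)}; excluded",
                    stacklevel=2,
                )
                continue
            have = set(wanted["density_group"])
            missed = set(groups_to_sum) - have
            if missed:
                log.info("core %s (%s) missing density group(s) %s; summed "
                         "over %s", core, group, sorted(missed), sorted(have))
            totals = table.data.loc[present, list(wanted.index)].sum(axis=1)
            labels = [_taxon_label(t, table.taxonomy, rank) for t in present]
            records[(group, str(core))] = totals.groupby(labels).sum()

    if not records:
        raise DataError("no active taxa found in any core")
    per_core = pd.DataFrame(records).fillna(0.0)
    per_core.columns = pd.MultiIndex.from_tuples(per_core.columns,
                                                 names=["group", "core_id"])
    phyla = {}
    for t in itertools.chain.from_iterable(
            [active_taxa.get(g, ()) for g in n_asvs]):
        phyla.setdefault(_taxon_label(t, table.taxonomy, rank),
                         _phylum(t, table.taxonomy))
    rows = []
    for group in per_core.columns.get_level_values("group").unique():
        sub = per_core[group]
        n = sub.shape[1]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1) if n > 1 else pd.Series(np.nan, index=sub.index)
        se = sd / np.sqrt(n)
        for label in sub.index:
            rows.append({
                "group": group, "taxon": label, "phylum": phyla.get(label),
                "mean": float(mean[label]),
                "sd": float(sd[label]) if n > 1 else np.nan,
                "se": float(se[label]) if n > 1 else np.nan,
                "n_cores": n,
            })
    return ActiveCommunityProfile(pd.DataFrame(rows), per_core, n_asvs)


def total_active_abundance(table: FeatureTable, metadata: pd.DataFrame,
                           active_taxa: Mapping[str, Iterable[str]],
                           groups_to_sum: Sequence[str] = ("heavy", "medium"),
                           isotopes: Sequence[str] = ("13C",),
                           rank: str = "genus",
                           group_cols: tuple[str, ...] = ("wetland", "redox"),
                           ) -> ActiveCommunityProfile:
    """Total absolute abundance of active taxa per treatment group.

    Sums member-ASV abundances (copies per ng DNA) over the heavy and
    medium density groups of each labeled (13C) core — the groups lying
    above the treatment's community WAD — aggregates to the requested
    rank, then averages across replicate cores. Missing density groups
    contribute zero with a logged note.
    """
    if table.unit != "copies_per_ng_dna":
        raise ValueError("community totals require a QSEQ-normalized table")
    return _aggregate(table, metadata, active_taxa, groups_to_sum, isotopes,
                      rank, group_cols)


def background_abundance(table: FeatureTable, metadata: pd.DataFrame,
                         active_taxa: Mapping[str, Iterable[str]],
                         groups: Sequence[str] = ("heavy", "medium", "light"),
                         isotopes: Sequence[str] = ("12C", "13C"),
                         rank: str = "genus",
                         group_cols: tuple[str, ...] = ("wetland", "redox"),
                         ) -> ActiveCommunityProfile:
    """Background abundance of active taxa: all density groups, both
    isotope treatments."""
    if table.unit != "copies_per_ng_dna":
        raise ValueError("community totals require a QSEQ-normalized table")
    return _aggregate(table, metadata, active_taxa, groups, isotopes,
                      rank, group_cols)


def shannon_diversity(abundances) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) over positive entries."""
    y = np.asarray(abundances, dtype=float)
    if (y < 0).any():
        raise ValueError("abundances must be non-negative")
    y = y[y > 0]
    if y.size == 0:
        raise ValueError("Shannon diversity undefined for an all-zero vector")
    return float(stats.entropy(y))


@dataclass
class OverlapPartition:
    """Disjoint partition of a union of named taxon sets.

    ``regions`` maps a signature — the sorted ``&``-joined names of the
    sets a taxon belongs to — to the sorted member list; ``counts`` holds
    the region sizes.
    """

    set_names: tuple[str, ...]
    regions: dict[str, list[str]]

    @property
    def counts(self) -> dict[str, int]:
        return {sig: len(members) for sig, members in self.regions.items()}

    def unique_to(self, name: str) -> list[str]:
        return self.regions.get(name, [])

    def total(self) -> int:
        return sum(len(m) for m in self.regions.values())


def overlap_partition(active_sets, k_max: int = 5) -> OverlapPartition:
    """Partition named taxon sets into every shared/unique Venn region.

    Accepts a mapping name -> iterable of taxa (or a sequence of
    (name, taxa) pairs). The union is split into the 2^k - 1 disjoint
    membership regions; empty regions are included with empty lists.
    """
    if isinstance(active_sets, Mapping):
        items = list(active_sets.items())
    else:
        items = [(name, s) for name, s in active_sets]
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate set names in {names}")
    if len(names) > k_max:
        raise ValueError(f"overlap partition supports at most {k_max} sets")
    sets = {name: set(map(str, s)) for name, s in items}
    union = set().union(*sets.values()) if sets else set()
    regions: dict[str, list[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            regions["&".join(combo)] = sorted(inside - outside)
    part = OverlapPartition(tuple(names), regions)
    assert part.total() == len(union)
    return part
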