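"""Alpha-diversity summaries and the core/unique genus Venn partition."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import RelAbundanceTable
from .io import CountTable, DataError, Metadata


def alpha_diversity(rarefied: CountTable) -> pd.DataFrame:
    """Per-sample richness, Shannon entropy (nats) and Pielou evenness.

    Requires a rarefied table (uniform sample totals) so that richness and
    entropy are comparable across samples. Pielou evenness is Shannon
    divided by ln(richness); for richness <= 1 it is defined as 0.
    """
    totals = rarefied.sample_totals()
    if totals.nunique() != 1:
        raise DataError(
            "alpha_diversity requires uniform sample totals; rarefy first"
        )
    records = []
    for sample in rarefied.sample_ids:
        col = rarefied.data[sample].to_numpy(dtype=float)
        present = col[col > 0]
        richness = int(present.size)
        p = present / present.sum()
        shannon = float(-(p * np.log(p)).sum())
        pielou = shannon / np.log(richness) if richness > 1 else 0.0
        records.append(
            {
                "sample_id": sample,
                "richness": richness,
                "shannon": shannon,
                "pielou_evenness": float(pielou),
            }
        )
    return pd.DataFrame(records).set_index("sample_id")


@dataclass
class VennPartition:
    """Disjoint genus sets by exact group-membership combination.

    ``regions`` maps a sorted tuple of group labels (the groups a genus is
    present in) to the genus set exclusive to that combination. The
    shared-by-all region is keyed by the full group tuple; singleton keys
    are group-exclusive regions.
    """

    groups: tuple[str, ...]
    regions: dict[tuple[str, ...], set[str]]
    presence_fraction: float

    def region(self, *groups: str) -> set[str]:
        key = tuple(sorted(groups))
        return self.regions.get(key, set())

    @property
    def shared_by_all(self) -> set[str]:
        return self.region(*self.groups)

    def exclusive(self, group: str) -> set[str]:
        return self.region(group)

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for s in self.regions.values():
            out |= s
        return out

    def to_dict(self) -> dict[str, list[str]]:
        return {
            "&".join(key): sorted(val) for key, val in self.regions.items()
        }


def core_partition(
    rel: RelAbundanceTable,
    meta: Metadata,
    presence_fraction: float = 0.5,
    groups: list[str] | None = None,
) -> VennPartition:
    """Partition genera by the combination of groups they are present in.

    A genus is present in a group when it is detected (relative abundance
    > 0) in at least ``presence_fraction`` of that group's samples. Genera
    absent from every group are excluded from the partition.
    """
    if not 0 < presence_fraction <= 1:
        raise DataError("presence_fraction must lie in (0, 1]")
    if groups is None:
        groups = meta.group_labels
    present_in: dict[str, set[str]] = {}
    for g in groups:
        samples = [s for s in meta.samples_in_group(g) if s in rel.sample_ids]
        if not samples:
            raise DataError(f"group {g!r} has no samples in the table")
        sub = rel.data[samples]
        frac = (sub > 0).mean(axis=1)
        present_in[g] = set(sub.index[frac >= presence_fraction])

    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(sorted(groups), r):
            in_combo = set.intersection(*(present_in[g] for g in combo))
            out_groups = [g for g in groups if g not in combo]
            exclusive = in_combo - set().union(
                *(present_in[g] for g in out_groups), set()
            )
            if exclusive:
                regions[combo] = exclusive
    return VennPartition(tuple(groups), regions, presence_fraction)
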