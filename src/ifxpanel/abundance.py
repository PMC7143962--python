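"""Genus aggregation, quality filtering, TSS/Hellinger normalisation and
rarefaction of 16S feature counts.

The order of operations downstream stages expect is fixed:
``aggregate_to_genus -> filter_taxa -> tss_normalize -> hellinger`` for
relative-abundance analyses, and ``rarefy`` (on counts) for alpha diversity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import CountTable, DataError, TaxonomyMap

logger = logging.getLogger(__name__)


@dataclass
class RelAbundanceTable:
    """Taxa x samples relative abundances.

    ``transform_tag`` is ``"tss"`` (columns sum to 1) or ``"hellinger"``
    (entrywise square root of TSS values; column sums of squares equal 1).
    """

    data: pd.DataFrame
    transform_tag: str

    def __post_init__(self) -> None:
        if self.transform_tag not in ("tss", "hellinger"):
            raise DataError(f"unknown transform_tag {self.transform_tag!r}")
        vals = self.data.to_numpy(dtype=float)
        if (vals < 0).any() or (vals > 1 + 1e-9).any():
            raise DataError("relative abundances must lie in [0, 1]")
        colsum = (vals**2 if self.transform_tag == "hellinger" else vals).sum(axis=0)
        if not np.allclose(colsum, 1.0, atol=1e-9):
            raise DataError(
                f"{self.transform_tag} columns are not normalised (sums {colsum})"
            )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def aggregate_to_genus(counts: CountTable, tax: TaxonomyMap) -> CountTable:
    """Sum feature counts into genus rows.

    Features without a genus assignment pool under ``unassigned_<family>``.
    Sample totals are conserved exactly. Genus order follows first
    appearance in the feature table.
    """
    tax.require_complete(counts.taxon_ids)
    labels = [tax.genus_label(t) for t in counts.taxon_ids]
    grouped = counts.data.groupby(pd.Index(labels, name="id"), sort=False).sum()
    return CountTable(grouped)


def filter_taxa(
    counts: CountTable,
    cfg: AnalysisConfig,
    tax: TaxonomyMap | None = None,
) -> CountTable:
    """Quality-filter taxa before normalisation.

    Removes, in order: blocklisted lineages (by taxonomy when available,
    and always by row label), taxa whose pooled relative abundance is
    strictly below ``min_rel_abundance_pct`` percent of the grand total,
    and everything beyond the ``top_n_taxa`` highest mean per-sample
    relative abundances. Rows come back sorted by descending mean abundance.
    """
    df = counts.data
    terms = {b.lower() for b in cfg.taxon_blocklist}
    blocked = pd.Series(
        [t.lower() in terms for t in df.index], index=df.index, dtype=bool
    )
    if tax is not None:
        in_tax = [t for t in df.index if t in tax]
        for t in in_tax:
            if tax.matches_blocklist(t, cfg.taxon_blocklist):
                blocked.at[t] = True
    df = df.loc[~blocked]

    grand_total = df.to_numpy().sum()
    if grand_total == 0:
        raise DataError("all taxa filtered: table empty after blocklist")
    pooled_pct = df.sum(axis=1) / grand_total * 100.0
    df = df.loc[pooled_pct >= cfg.min_rel_abundance_pct]  # strict "<" removal
    if df.empty:
        raise DataError("all taxa filtered: abundance threshold removed everything")

    rel = df / counts.data.sum(axis=0)
    mean_rel = rel.mean(axis=1)
    keep = mean_rel.sort_values(ascending=False, kind="stable").index[: cfg.top_n_taxa]
    out = df.loc[keep]
    if out.empty:
        raise DataError("all taxa filtered")
    return CountTable(out)


def tss_normalize(counts: CountTable) -> RelAbundanceTable:
    """Total-sum scaling: divide each count by its sample total."""
    totals = counts.data.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise DataError(f"zero-total samples cannot be normalised: {zero}")
    return RelAbundanceTable(counts.data / totals, "tss")


def hellinger(rel: RelAbundanceTable) -> RelAbundanceTable:
    """Square-root (Hellinger) transform of TSS relative abundances."""
    if rel.transform_tag != "tss":
        raise DataError(
            f"hellinger expects a tss table, got {rel.transform_tag!r}"
        )
    return RelAbundanceTable(np.sqrt(rel.data), "hellinger")


def rarefy(counts: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Uses the multivariate hypergeometric distribution (draws of physical
    reads without replacement). Samples with fewer than ``depth`` total
    reads are dropped with a warning. Deterministic under ``seed``.
    """
    if depth < 1:
        raise DataError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = counts.sample_totals()
    kept_cols: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for sample in counts.sample_ids:
        total = int(totals[sample])
        col = counts.data[sample].to_numpy()
        if total < depth:
            dropped.append(sample)
            continue
        if total == depth:
            kept_cols[sample] = col.copy()
        else:
            kept_cols[sample] = rng.multivariate_hypergeometric(col, depth)
    if dropped:
        logger.warning(
            "rarefy: dropped %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped,
        )
    if not kept_cols:
        raise DataError(f"all samples below rarefaction depth {depth}")
    out = pd.DataFrame(kept_cols, index=counts.data.index).astype(np.int64)
    return CountTable(out)
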