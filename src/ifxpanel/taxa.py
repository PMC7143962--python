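"""Per-genus differential abundance between analysis groups (one-way ANOVA).

Tests run on transformed relative abundances — Hellinger by default for its
variance stabilisation, plain TSS as an option. Benjamini-Hochberg adjusted
p-values are reported alongside raw ones but selection uses raw p by
default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import RelAbundanceTable
from .io import DataError, Metadata


def anova_per_genus(
    rel: RelAbundanceTable,
    meta: Metadata,
    groups: list[str],
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per genus across the given groups.

    Returns a genus-indexed frame with ``f_stat``, ``p_value``, ``p_bh``
    and one ``mean_<group>`` column per group. Genera with zero total
    variance get F = 0, p = 1.
    """
    if len(groups) < 2:
        raise DataError("need at least 2 groups for ANOVA")
    group_samples: dict[str, list[str]] = {}
    for g in groups:
        ss = [s for s in meta.samples_in_group(g) if s in rel.sample_ids]
        if len(ss) < 2:
            raise DataError(f"group {g!r} has fewer than 2 samples")
        group_samples[g] = ss

    arrays = {g: rel.data[ss].to_numpy() for g, ss in group_samples.items()}
    n_genera = rel.data.shape[0]
    f = np.zeros(n_genera)
    p = np.ones(n_genera)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(*arrays.values(), axis=1)
    f_raw = np.asarray(res.statistic, dtype=float)
    p_raw = np.asarray(res.pvalue, dtype=float)
    for i in range(n_genera):
        row = np.concatenate([a[i] for a in arrays.values()])
        if np.ptp(row) == 0:  # identical in every sample: no signal
            f[i], p[i] = 0.0, 1.0
        elif np.isnan(p_raw[i]):
            # between-group variance with zero within-group variance
            f[i], p[i] = np.inf, 0.0
        else:
            f[i], p[i] = f_raw[i], p_raw[i]
    p_bh = stats.false_discovery_control(p, method="bh")

    out = pd.DataFrame(
        {"f_stat": f, "p_value": p, "p_bh": p_bh}, index=rel.data.index
    )
    out.index.name = "genus"
    for g, ss in group_samples.items():
        out[f"mean_{g}"] = rel.data[ss].mean(axis=1)
    return out


def select_diff_genera(
    stats_frame: pd.DataFrame,
    alpha: float,
    use_bh: bool = False,
) -> pd.DataFrame:
    """Genera passing the significance cut, annotated with the top group.

    ``top_group`` names the group with the largest mean transformed
    abundance ("more abundant in ..."). Rows are sorted by ascending
    p-value, F statistic breaking ties.
    """
    col = "p_bh" if use_bh else "p_value"
    sel = stats_frame.loc[stats_frame[col] < alpha].copy()
    mean_cols = [c for c in sel.columns if c.startswith("mean_")]
    if not mean_cols:
        raise DataError("stats frame lacks group mean columns")
    top = sel[mean_cols].idxmax(axis=1).str.removeprefix("mean_")
    sel["top_group"] = top
    return sel.sort_values(
        by=[col, "f_stat"], ascending=[True, False], kind="stable"
    )
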