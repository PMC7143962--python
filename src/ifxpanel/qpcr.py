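"""Delta-delta-Ct differential expression for the inflammation qPCR array.

Per-sample normalisation subtracts the mean housekeeping Ct
(dCt = Ct_gene - mean Ct_housekeeping). A two-group contrast computes
ddCt = mean dCt(a) - mean dCt(b), fold change 2**(-ddCt), and the signed
fold regulation used on PCR-array reports (fold change when >= 1, else
-1 / fold change). p-values come from a two-sample t-test on the per-sample
dCt values, Welch by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CtMatrix, DataError, Metadata


@dataclass
class DeltaCtTable:
    """Housekeeping-normalised Ct values (genes x samples, cycles)."""

    data: pd.DataFrame
    imputed: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DEGRecord:
    """One gene's differential-expression summary for a two-group contrast."""

    gene_id: str
    group_a: str
    group_b: str
    ddct: float
    fold_change: float
    fold_regulation: float
    p_value: float
    p_bh: float
    direction: str  # "up_in_a" | "down_in_a"
    low_confidence: bool = False


def delta_ct(ct: CtMatrix) -> DeltaCtTable:
    """Normalise each gene's Ct against the sample's mean housekeeping Ct."""
    hk = ct.data.loc[list(ct.housekeeping_ids)]
    hk_imputed = ct.imputed.loc[list(ct.housekeeping_ids)]
    bad = hk_imputed.any(axis=0)
    if bad.any():
        raise DataError(
            "housekeeping Ct undetermined for samples: "
            f"{list(bad.index[bad])}"
        )
    reference = hk.mean(axis=0)
    assay = ct.assay_gene_ids
    dct = ct.data.loc[assay].sub(reference, axis=1)
    return DeltaCtTable(dct, ct.imputed.loc[assay].copy())


def fold_regulation_of(fold_change: float) -> float:
    """Signed fold change: FC when >= 1, else -1/FC."""
    return fold_change if fold_change >= 1 else -1.0 / fold_change


def ddct_contrast(
    dct: DeltaCtTable,
    meta: Metadata,
    group_a: str,
    group_b: str,
    equal_var: bool = False,
) -> list[DEGRecord]:
    """Per-gene ddCt contrast between two analysis groups.

    ``equal_var=True`` selects the pooled-variance Student t-test; the
    default is Welch. Genes with more than half their wells
    ceiling-imputed in either group are marked ``low_confidence``.
    """
    samples_a = [s for s in meta.samples_in_group(group_a) if s in dct.data.columns]
    samples_b = [s for s in meta.samples_in_group(group_b) if s in dct.data.columns]
    for label, ss in ((group_a, samples_a), (group_b, samples_b)):
        if len(ss) < 2:
            raise DataError(f"group {label!r} has fewer than 2 samples")

    a = dct.data[samples_a].to_numpy()
    b = dct.data[samples_b].to_numpy()
    ddct = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant-input genes surface as NaN and are resolved below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        pvals = np.asarray(res.pvalue, dtype=float)
    # Degenerate zero-variance genes: identical values in both groups carry
    # no evidence (p = 1); differing constants are a deterministic shift.
    for i in range(len(pvals)):
        if np.isnan(pvals[i]):
            pvals[i] = 1.0 if np.isclose(ddct[i], 0.0) else 0.0
    p_bh = stats.false_discovery_control(pvals, method="bh")

    imp_a = dct.imputed[samples_a].mean(axis=1).to_numpy()
    imp_b = dct.imputed[samples_b].mean(axis=1).to_numpy()

    records = []
    for i, gene in enumerate(dct.gene_ids):
        fc = float(2.0 ** (-ddct[i]))
        records.append(
            DEGRecord(
                gene_id=gene,
                group_a=group_a,
                group_b=group_b,
                ddct=float(ddct[i]),
                fold_change=fc,
                fold_regulation=fold_regulation_of(fc),
                p_value=float(pvals[i]),
                p_bh=float(p_bh[i]),
                direction="up_in_a" if fc >= 1 else "down_in_a",
                low_confidence=bool(imp_a[i] > 0.5 or imp_b[i] > 0.5),
            )
        )
    return records


def degs_to_frame(records: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in records],
            "ddct": [r.ddct for r in records],
            "fold_change": [r.fold_change for r in records],
            "fold_regulation": [r.fold_regulation for r in records],
            "p": [r.p_value for r in records],
            "p_bh": [r.p_bh for r in records],
            "direction": [r.direction for r in records],
            "low_confidence": [r.low_confidence for r in records],
        }
    ).set_index("gene")


@dataclass
class DESelection:
    """Direction-labelled differentially expressed gene sets."""

    up: set[str]
    down: set[str]
    min_abs_fold: float
    alpha: float

    @property
    def genes(self) -> set[str]:
        return self.up | self.down

    @property
    def directions(self) -> dict[str, str]:
        d = {g: "up" for g in self.up}
        d.update({g: "down" for g in self.down})
        return d


def select_de_genes(
    records: list[DEGRecord], min_abs_fold: float, alpha: float
) -> DESelection:
    """Keep genes with |fold regulation| >= min_abs_fold and p < alpha."""
    up, down = set(), set()
    for r in records:
        if abs(r.fold_regulation) >= min_abs_fold and r.p_value < alpha:
            (up if r.direction == "up_in_a" else down).add(r.gene_id)
    return DESelection(up, down, min_abs_fold, alpha)
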