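"""Taxa-gene Spearman concordance and the consensus biomarker-panel rule.

The integration step correlates genus relative abundances against a 1/Ct
expression proxy within response strata (low Ct means high expression, so
1/Ct rises with expression). Correlations at or beyond a strength threshold
are classified strong-positive / strong-negative, collected into per-genus
sign lists, and a gene enters the paired biomarker panel when it is

(i)   strongly correlated (either sign) with *all* responder-enriched
      genera in the responder stratum,
(ii)  strongly correlated with at least k of the m non-responder-enriched
      genera (either stratum), and
(iii) differentially expressed at baseline with a recorded direction.

A curated reference fixture transcribing the sign lists of a published
infliximab-response biopsy cohort ships with the package for worked
examples and regression checks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import RelAbundanceTable
from .io import CtMatrix, DataError, Metadata

logger = logging.getLogger(__name__)

STRATA = ("responders", "non_responders")
_STRATUM_RESPONSE = {"responders": "R", "non_responders": "NONR"}


@dataclass
class ExpressionProxy:
    """1/Ct per gene and sample; monotone-decreasing in Ct."""

    data: pd.DataFrame
    imputed: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def inverse_ct(ct: CtMatrix) -> ExpressionProxy:
    """Entrywise reciprocal of Ct, housekeeping rows excluded."""
    assay = ct.assay_gene_ids
    vals = ct.data.loc[assay]
    if (vals.to_numpy() <= 0).any():
        raise DataError("Ct values must be positive to form 1/Ct")
    return ExpressionProxy(1.0 / vals, ct.imputed.loc[assay].copy())


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Spearman rank correlation with midrank ties and pairwise NaN removal.

    Returns ``(rho, n)`` where n is the number of complete pairs used.
    rho is NaN when fewer than 3 pairs remain or either vector is constant.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise DataError("spearman_rho requires equal-length vectors")
    ok = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[ok], ya[ok]
    n = int(xa.size)
    if n < 3:
        warnings.warn(f"spearman_rho: only {n} complete pairs", stacklevel=2)
        return float("nan"), n
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        warnings.warn("spearman_rho: constant vector, rho undefined", stacklevel=2)
        return float("nan"), n
    rho = stats.spearmanr(xa, ya).statistic
    return float(rho), n


def _sign_class(rho: float, threshold: float) -> str:
    if np.isnan(rho):
        return "none"
    if rho >= threshold:
        return "strong_pos"
    if rho <= -threshold:
        return "strong_neg"
    return "none"


@dataclass
class CorrelationCell:
    """Spearman rho for one (genus, gene) pair within a response stratum."""

    genus: str
    gene: str
    stratum: str
    rho: float
    n: int
    sign_class: str


def stratum_samples(
    meta: Metadata,
    stratum: str,
    disease: str = "CD",
    timepoint: str = "pre",
) -> list[str]:
    """Baseline sample ids of one response stratum."""
    if stratum not in STRATA:
        raise DataError(f"unknown stratum {stratum!r}")
    want = _STRATUM_RESPONSE[stratum]
    return [
        s.sample_id
        for s in meta
        if s.disease == disease and s.timepoint == timepoint and s.response == want
    ]


def correlation_matrix(
    rel: RelAbundanceTable,
    proxy: ExpressionProxy,
    genera: Iterable[str],
    genes: Iterable[str],
    meta: Metadata,
    stratum: str,
    threshold: float = 0.8,
    disease: str = "CD",
) -> list[CorrelationCell]:
    """One correlation cell per (genus, gene) over a stratum's samples."""
    genera = list(genera)
    genes = list(genes)
    missing_g = [g for g in genera if g not in rel.data.index]
    if missing_g:
        raise DataError(f"genera absent from abundance table: {missing_g}")
    missing_e = [e for e in genes if e not in proxy.data.index]
    if missing_e:
        raise DataError(f"genes absent from expression proxy: {missing_e}")
    samples = [
        s
        for s in stratum_samples(meta, stratum, disease=disease)
        if s in rel.sample_ids and s in proxy.sample_ids
    ]
    if len(samples) < 2:
        raise DataError(f"stratum {stratum!r} has fewer than 2 samples")
    cells = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant vectors handled via NaN rho
        for g in genera:
            gx = rel.data.loc[g, samples].to_numpy()
            for e in genes:
                ey = proxy.data.loc[e, samples].to_numpy()
                rho, n = spearman_rho(gx, ey)
                cells.append(
                    CorrelationCell(g, e, stratum, rho, n, _sign_class(rho, threshold))
                )
    return cells


def cells_to_frame(cells: list[CorrelationCell]) -> pd.DataFrame:
    """Long-format export (heatmap-ready)."""
    return pd.DataFrame(
        {
            "genus": [c.genus for c in cells],
            "gene": [c.gene for c in cells],
            "stratum": [c.stratum for c in cells],
            "rho": [c.rho for c in cells],
            "n": [c.n for c in cells],
            "sign_class": [c.sign_class for c in cells],
        }
    )


@dataclass
class SignList:
    """Genes strongly correlated with one genus in one stratum, by sign."""

    genus: str
    stratum: str
    positive_genes: set[str] = field(default_factory=set)
    negative_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.positive_genes & self.negative_genes
        if overlap:
            raise DataError(
                f"{self.genus}/{self.stratum}: genes in both sign sets: {overlap}"
            )

    @property
    def genes(self) -> set[str]:
        return self.positive_genes | self.negative_genes


def classify_strong(
    cells: list[CorrelationCell], threshold: float
) -> list[SignList]:
    """Group strong correlations into per-(genus, stratum) sign lists."""
    if not 0 < threshold <= 1:
        raise DataError("threshold must lie in (0, 1]")
    lists: dict[tuple[str, str], SignList] = {}
    for c in cells:
        key = (c.genus, c.stratum)
        sl = lists.setdefault(key, SignList(c.genus, c.stratum, set(), set()))
        cls = _sign_class(c.rho, threshold)
        if cls == "strong_pos":
            sl.positive_genes.add(c.gene)
        elif cls == "strong_neg":
            sl.negative_genes.add(c.gene)
    return list(lists.values())


def _genes_by_genus(sign_lists: Iterable[SignList]) -> dict[str, set[str]]:
    """Genus -> genes appearing in either stratum's sign list."""
    out: dict[str, set[str]] = {}
    for sl in sign_lists:
        out.setdefault(sl.genus, set()).update(sl.genes)
    return out


def consensus_genes(
    sign_lists: Iterable[SignList],
    genera_subset: Iterable[str],
    k: int,
) -> tuple[dict[str, int], set[str], set[str]]:
    """Count, per gene, how many of the given genera it correlates with.

    A gene counts toward a genus when it appears in either stratum's sign
    list for that genus. Returns ``(counts, genes with count >= k, union)``.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    by_genus = _genes_by_genus(sign_lists)
    counts: dict[str, int] = {}
    for genus in genera_subset:
        for gene in by_genus.get(genus, set()):
            counts[gene] = counts.get(gene, 0) + 1
    at_least_k = {g for g, c in counts.items() if c >= k}
    union = set(counts)
    return counts, at_least_k, union


@dataclass
class BiomarkerPanel:
    """The paired biomarker panel and the full audit trail of the rule."""

    responder_genera: set[str]
    nonresponder_genera: set[str]
    genes_up: set[str]
    genes_down: set[str]
    rule_trace: dict[str, dict]

    @property
    def genes(self) -> set[str]:
        return self.genes_up | self.genes_down

    def to_dict(self) -> dict:
        return {
            "responder_genera": sorted(self.responder_genera),
            "nonresponder_genera": sorted(self.nonresponder_genera),
            "genes_up": sorted(self.genes_up),
            "genes_down": sorted(self.genes_down),
            "rule_trace": self.rule_trace,
        }


def assemble_panel(
    sign_lists: Iterable[SignList],
    responder_genera: Iterable[str],
    nonresponder_genera: Iterable[str],
    de_directions: Mapping[str, str],
    k: int = 3,
    m: int | None = None,
) -> BiomarkerPanel:
    """Apply the consensus rule and split the panel by DE direction.

    ``de_directions`` maps candidate genes to ``"up"``/``"down"`` in
    responders at baseline; a gene meeting the correlation criteria but
    lacking a direction is excluded and recorded as such in the trace.
    """
    sign_lists = list(sign_lists)
    responder_genera = set(responder_genera)
    nonresponder_genera = set(nonresponder_genera)
    if m is None:
        m = len(nonresponder_genera)
    if m != len(nonresponder_genera):
        raise DataError(
            f"m={m} but {len(nonresponder_genera)} non-responder genera given"
        )
    if not 1 <= k <= m:
        raise DataError("need 1 <= k <= m")
    for d in de_directions.values():
        if d not in ("up", "down"):
            raise DataError(f"de_directions values must be 'up'/'down', got {d!r}")

    # Criterion (i) checks the responder stratum specifically.
    resp_lists = {
        sl.genus: sl.genes
        for sl in sign_lists
        if sl.stratum == "responders" and sl.genus in responder_genera
    }
    counts, at_least_k, _ = consensus_genes(sign_lists, nonresponder_genera, k)

    candidates: set[str] = set()
    for sl in sign_lists:
        if sl.genus in responder_genera | nonresponder_genera:
            candidates |= sl.genes

    genes_up: set[str] = set()
    genes_down: set[str] = set()
    trace: dict[str, dict] = {}
    for gene in sorted(candidates):
        resp_hits = sorted(
            g for g, genes in resp_lists.items() if gene in genes
        )
        crit_i = len(resp_hits) == len(responder_genera)
        nr_count = counts.get(gene, 0)
        crit_ii = gene in at_least_k
        direction = de_directions.get(gene)
        entry = {
            "responder_genus_hits": resp_hits,
            "criterion_all_responder_genera": crit_i,
            "nonresponder_genus_count": nr_count,
            "criterion_k_of_m": crit_ii,
            "de_direction": direction,
            "included": False,
        }
        if crit_i and crit_ii:
            if direction is None:
                entry["excluded_reason"] = "missing_de_direction"
            else:
                entry["included"] = True
                (genes_up if direction == "up" else genes_down).add(gene)
        trace[gene] = entry

    return BiomarkerPanel(
        responder_genera, nonresponder_genera, genes_up, genes_down, trace
    )


@dataclass
class ReferenceStudy:
    """The packaged fixture: curated sign lists and published counts."""

    version: str
    sign_lists: list[SignList]
    responder_genera: set[str]
    nonresponder_genera: set[str]
    baseline_de_gene_counts: dict[str, int]
    reported_panel_up: set[str]
    reported_panel_down: set[str]


def load_reference_sign_lists() -> ReferenceStudy:
    """Load the packaged reference sign-list fixture."""
    path = resources.files("ifxpanel.data").joinpath("reference_sign_lists.json")
    doc = json.loads(path.read_text())
    sign_lists = [
        SignList(
            genus=sl["genus"],
            stratum=sl["stratum"],
            positive_genes=set(sl["positive"]),
            negative_genes=set(sl["negative"]),
        )
        for sl in doc["sign_lists"]
    ]
    return ReferenceStudy(
        version=doc["version"],
        sign_lists=sign_lists,
        responder_genera=set(doc["responder_genera"]),
        nonresponder_genera=set(doc["nonresponder_genera"]),
        baseline_de_gene_counts=dict(doc["baseline_de_gene_counts"]),
        reported_panel_up=set(doc["reported_panel"]["up_in_responders"]),
        reported_panel_down=set(doc["reported_panel"]["down_in_responders"]),
    )
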