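"""Synthetic cohorts with planted group effects and taxa-gene couplings.

The generator emulates the statistical structure the pipeline assumes:

* genus counts drawn per sample as multinomial(depth, softmax(eta)), where
  eta is a base log-abundance profile plus group-specific log-fold shifts
  plus i.i.d. log-scale noise; sequencing depth follows a discretised
  log-normal;
* qPCR Ct values as a per-gene baseline plus group-specific cycle shifts
  plus Gaussian noise, with stable housekeeping genes;
* taxa-gene couplings through shared latent factors: within a stratum, a
  standard-normal factor z_s enters both a genus's log-abundance and a
  gene's Ct (as -c * z_s), so high planted abundance co-occurs with high
  1/Ct when the coupling strength is positive.

Coupling calibration: for a target rank correlation rho, both the genus
and the gene loading are set to t = sqrt(|rho| / (1 - |rho|)) times their
respective noise scales. Each side then correlates t/sqrt(1+t^2) with the
latent factor and the product equals |rho|, so the realized Spearman
correlation is approximately the planted strength.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_HOUSEKEEPING,
    CountTable,
    CtMatrix,
    DataError,
    Metadata,
    SampleMeta,
    TaxonomyMap,
)

PANEL_GENES_UP = ("IL18", "CCR3", "CXCL8", "TLR6", "TLR9", "TNFSF14")
PANEL_GENES_DOWN = ("CCR4",)
RESPONDER_GENERA = ("Parvimonas", "Hungatella")
NONRESPONDER_GENERA = (
    "Negativibacillus",
    "Faecalibacterium",
    "Eubacterium_hallii_group",
    "Blautia",
)


def parse_group_label(label: str) -> tuple[str, str, str]:
    """Invert the canonical group label into (disease, timepoint, response)."""
    if label == "HC":
        return "HC", "pre", "NA"
    parts = label.split("_")
    if len(parts) != 3:
        raise DataError(f"cannot parse group label {label!r}")
    disease, timepoint, response = parts
    return disease, timepoint.lower(), response


@dataclass(frozen=True)
class Coupling:
    """A planted association between one genus and one gene.

    ``strength`` is the target Spearman rho; ``stratum`` the group label
    whose samples carry the shared latent factor; couplings with the same
    (stratum, factor) share one factor per sample. ``genus_sign`` sets the
    genus loading's sign so mixed sign patterns across genes are possible
    (the gene loading sign is then strength's sign times genus_sign).
    """

    genus: str
    gene: str
    strength: float
    stratum: str
    factor: str = "axis1"
    genus_sign: int = 1

    def __post_init__(self) -> None:
        if not -1.0 <= self.strength <= 1.0:
            raise DataError(f"coupling strength {self.strength} outside [-1, 1]")
        if self.genus_sign not in (-1, 1):
            raise DataError("genus_sign must be -1 or +1")


def _loading_ratio(rho: float) -> float:
    """Loading/noise ratio t with t^2/(1+t^2) = |rho| (capped at 0.99)."""
    r = min(abs(rho), 0.99)
    return math.sqrt(r / (1.0 - r))


@dataclass
class CohortDesign:
    """Full specification of a synthetic cohort."""

    n_per_group: dict[str, int]
    n_taxa: int = 100
    n_genes: int = 40
    genus_names: tuple[str, ...] | None = None
    gene_names: tuple[str, ...] | None = None
    housekeeping_ids: tuple[str, ...] = DEFAULT_HOUSEKEEPING
    base_log_abundance: np.ndarray | None = None
    genus_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    couplings: tuple[Coupling, ...] = ()
    gene_group_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    depth_lognormal: tuple[float, float] = (math.log(60000.0), 0.4)
    gene_base_ct: float = 25.0
    hk_ct_mean: float = 20.0
    hk_ct_sd: float = 0.2
    noise_ct_sd: float = 0.5
    logabund_noise_sd: float = 0.5
    ct_ceiling: float = 35.0
    seed: int = 0
    # Optional annotations describing what was planted (used for scoring).
    panel_genes_up: tuple[str, ...] = ()
    panel_genes_down: tuple[str, ...] = ()
    responder_genera: tuple[str, ...] = ()
    nonresponder_genera: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.n_per_group:
            raise DataError("n_per_group must be non-empty")
        for label, n in self.n_per_group.items():
            parse_group_label(label)  # validates the label
            if n < 1:
                raise DataError(f"group {label!r} needs n >= 1")
        if self.genus_names is None:
            self.genus_names = tuple(f"Genus_{i:03d}" for i in range(self.n_taxa))
        self.genus_names = tuple(self.genus_names)
        if len(self.genus_names) != self.n_taxa:
            raise DataError("genus_names length must equal n_taxa")
        if self.gene_names is None:
            self.gene_names = tuple(f"GENE_{i:03d}" for i in range(self.n_genes))
        self.gene_names = tuple(self.gene_names)
        if len(self.gene_names) != self.n_genes:
            raise DataError("gene_names length must equal n_genes")
        if set(self.housekeeping_ids) & set(self.gene_names):
            raise DataError("housekeeping ids overlap assay gene names")
        if self.base_log_abundance is None:
            self.base_log_abundance = -0.06 * np.arange(self.n_taxa, dtype=float)
        self.base_log_abundance = np.asarray(self.base_log_abundance, dtype=float)
        if self.base_log_abundance.shape != (self.n_taxa,):
            raise DataError("base_log_abundance must have length n_taxa")
        if self.depth_lognormal[1] <= 0:
            raise DataError("depth sigma must be positive")

        genus_set = set(self.genus_names)
        gene_set = set(self.gene_names)
        groups = set(self.n_per_group)
        for (genus, group) in self.genus_effects:
            if genus not in genus_set:
                raise DataError(f"genus effect for unknown genus {genus!r}")
            if group not in groups:
                raise DataError(f"genus effect for unknown group {group!r}")
        for (gene, group) in self.gene_group_effects:
            if gene not in gene_set:
                raise DataError(f"gene effect for unknown gene {gene!r}")
            if group not in groups:
                raise DataError(f"gene effect for unknown group {group!r}")
        self.couplings = tuple(self.couplings)
        for c in self.couplings:
            if c.genus not in genus_set:
                raise DataError(f"coupling names unknown genus {c.genus!r}")
            if c.gene not in gene_set:
                raise DataError(f"coupling names unknown gene {c.gene!r}")
            if c.stratum not in groups:
                raise DataError(f"coupling stratum {c.stratum!r} absent from design")
        _resolve_loadings(self.couplings, self.noise_ct_sd, self.logabund_noise_sd)


def _resolve_loadings(
    couplings: Sequence[Coupling],
    noise_ct_sd: float,
    logabund_noise_sd: float,
) -> tuple[dict, dict]:
    """Per-(stratum, factor) genus and gene loadings; validates consistency.

    Returns ``(genus_loadings, gene_loadings)`` keyed by
    (stratum, factor, name) -> signed loading in log-abundance units /
    cycles respectively.
    """
    genus_load: dict[tuple[str, str, str], float] = {}
    gene_load: dict[tuple[str, str, str], float] = {}
    genus_signs: dict[tuple[str, str, str], int] = {}
    gene_signs: dict[tuple[str, str, str], int] = {}
    for c in couplings:
        if c.strength == 0:
            continue
        gkey = (c.stratum, c.factor, c.genus)
        ekey = (c.stratum, c.factor, c.gene)
        tau = int(np.sign(c.strength)) * c.genus_sign
        if genus_signs.setdefault(gkey, c.genus_sign) != c.genus_sign:
            raise DataError(
                f"inconsistent genus_sign for {c.genus!r} on factor {c.factor!r}"
            )
        if gene_signs.setdefault(ekey, tau) != tau:
            raise DataError(
                f"inconsistent implied sign for gene {c.gene!r} on factor "
                f"{c.factor!r}: couplings disagree"
            )
        t = _loading_ratio(c.strength)
        a = logabund_noise_sd * t * c.genus_sign
        b = noise_ct_sd * t * tau
        if abs(a) > abs(genus_load.get(gkey, 0.0)):
            genus_load[gkey] = a
        if abs(b) > abs(gene_load.get(ekey, 0.0)):
            gene_load[ekey] = b
    return genus_load, gene_load


@dataclass
class PlantedTruth:
    """Everything needed to score recovery of downstream calls."""

    genus_effects: dict[tuple[str, str], float]
    couplings: tuple[Coupling, ...]
    gene_group_effects: dict[tuple[str, str], float]
    latent_factors: dict[tuple[str, str], dict[str, float]]
    panel_genes_up: tuple[str, ...]
    panel_genes_down: tuple[str, ...]
    responder_genera: tuple[str, ...]
    nonresponder_genera: tuple[str, ...]
    seed: int

    @property
    def panel_genes(self) -> set[str]:
        return set(self.panel_genes_up) | set(self.panel_genes_down)

    def to_json(self) -> str:
        doc = {
            "seed": self.seed,
            "genus_effects": [
                {"genus": g, "group": grp, "log_fold": v}
                for (g, grp), v in self.genus_effects.items()
            ],
            "gene_group_effects": [
                {"gene": g, "group": grp, "delta_ct": v}
                for (g, grp), v in self.gene_group_effects.items()
            ],
            "couplings": [asdict(c) for c in self.couplings],
            "latent_factors": {
                f"{stratum}/{factor}": z
                for (stratum, factor), z in self.latent_factors.items()
            },
            "panel_genes_up": list(self.panel_genes_up),
            "panel_genes_down": list(self.panel_genes_down),
            "responder_genera": list(self.responder_genera),
            "nonresponder_genera": list(self.nonresponder_genera),
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def generate_cohort(
    design: CohortDesign,
) -> tuple[CountTable, TaxonomyMap, CtMatrix, Metadata, PlantedTruth]:
    """Draw one synthetic cohort. Identical seed => bit-identical outputs."""
    rng = np.random.default_rng(design.seed)

    # --- samples and metadata -------------------------------------------
    samples: list[SampleMeta] = []
    for label in design.n_per_group:  # insertion order is part of the seed
        disease, timepoint, response = parse_group_label(label)
        for i in range(design.n_per_group[label]):
            if disease == "HC":
                subject = f"HC_subj{i:02d}"
            else:
                subject = f"{disease}_{response}_subj{i:02d}"
            samples.append(
                SampleMeta(
                    sample_id=f"{label}_s{i:02d}",
                    subject_id=subject,
                    disease=disease,
                    timepoint=timepoint,
                    response=response,
                )
            )
    meta = Metadata(samples)
    sample_ids = meta.sample_ids
    group_of = {s: meta.group_of(s) for s in sample_ids}

    # --- latent factors per (stratum, factor) ---------------------------
    genus_load, gene_load = _resolve_loadings(
        design.couplings, design.noise_ct_sd, design.logabund_noise_sd
    )
    factor_keys = sorted({(c.stratum, c.factor) for c in design.couplings})
    latents: dict[tuple[str, str], dict[str, float]] = {}
    for stratum, factor in factor_keys:
        members = [s for s in sample_ids if group_of[s] == stratum]
        draws = rng.standard_normal(len(members))
        latents[(stratum, factor)] = dict(zip(members, draws.tolist()))

    genus_index = {g: i for i, g in enumerate(design.genus_names)}
    gene_list = list(design.gene_names)
    gene_index = {g: i for i, g in enumerate(gene_list)}

    # --- counts ----------------------------------------------------------
    mu, sigma = design.depth_lognormal
    n_taxa = design.n_taxa
    count_cols: dict[str, np.ndarray] = {}
    for s in sample_ids:
        grp = group_of[s]
        eta = design.base_log_abundance.copy()
        for (genus, group), shift in design.genus_effects.items():
            if group == grp:
                eta[genus_index[genus]] += shift
        eta += design.logabund_noise_sd * rng.standard_normal(n_taxa)
        for (stratum, factor, genus), a in genus_load.items():
            if stratum == grp:
                eta[genus_index[genus]] += a * latents[(stratum, factor)][s]
        p = np.exp(eta - eta.max())
        p /= p.sum()
        depth = max(1, int(round(rng.lognormal(mu, sigma))))
        count_cols[s] = rng.multinomial(depth, p)
    counts = CountTable(
        pd.DataFrame(
            count_cols,
            index=[f"ASV_{i:04d}" for i in range(n_taxa)],
            dtype=np.int64,
        )
    )

    taxonomy = TaxonomyMap(
        {
            f"ASV_{i:04d}": (
                "Bacteria",
                "Firmicutes",
                "Clostridia",
                "Clostridiales",
                f"Family_{i // 10:02d}",
                design.genus_names[i],
            )
            for i in range(n_taxa)
        }
    )

    # --- Ct matrix --------------------------------------------------------
    n_genes = design.n_genes
    ct_cols: dict[str, np.ndarray] = {}
    all_gene_rows = gene_list + list(design.housekeeping_ids)
    for s in sample_ids:
        grp = group_of[s]
        ct = np.full(n_genes, design.gene_base_ct)
        for (gene, group), shift in design.gene_group_effects.items():
            if group == grp:
                ct[gene_index[gene]] += shift
        ct += design.noise_ct_sd * rng.standard_normal(n_genes)
        for (stratum, factor, gene), b in gene_load.items():
            if stratum == grp:
                ct[gene_index[gene]] -= b * latents[(stratum, factor)][s]
        hk = design.hk_ct_mean + design.hk_ct_sd * rng.standard_normal(
            len(design.housekeeping_ids)
        )
        ct_cols[s] = np.concatenate([ct, hk])
    ct_df = pd.DataFrame(ct_cols, index=all_gene_rows)
    imputed = ct_df > design.ct_ceiling
    ct_df = ct_df.clip(upper=design.ct_ceiling)
    if (ct_df.to_numpy() <= 0).any():
        raise DataError("synthetic Ct fell below zero; reduce effect sizes")
    ct_matrix = CtMatrix(
        ct_df, tuple(design.housekeeping_ids), design.ct_ceiling, imputed
    )

    truth = PlantedTruth(
        genus_effects=dict(design.genus_effects),
        couplings=design.couplings,
        gene_group_effects=dict(design.gene_group_effects),
        latent_factors=latents,
        panel_genes_up=design.panel_genes_up,
        panel_genes_down=design.panel_genes_down,
        responder_genera=design.responder_genera,
        nonresponder_genera=design.nonresponder_genera,
        seed=design.seed,
    )
    return counts, taxonomy, ct_matrix, meta, truth


def reference_cohort_design(
    n_per_stratum: int = 5,
    n_taxa: int = 100,
    n_genes: int = 40,
    seed: int = 0,
    coupling_strength: float = 0.98,
    genus_log_fold: float = 2.0,
    panel_delta_ct: float = 6.0,
) -> CohortDesign:
    """A design mirroring the reference study's structure.

    Baseline CD responder and non-responder strata (default n = 5 each,
    as in the reference cohort), post-treatment counterparts, and nine
    healthy controls. Two genera are planted more abundant in responders
    and four in non-responders; six genes are planted upregulated in
    responders and one downregulated, each coupled to both
    responder-enriched genera and three of the four non-responder-enriched
    genera in the responder stratum, mirroring the published sign pattern.
    """
    planted_genera = RESPONDER_GENERA + NONRESPONDER_GENERA
    genus_names: list[str] = []
    # Mid-rank base abundances: after the planted log-fold boost the genera
    # sit at a few percent relative abundance (softmax stays near-linear so
    # compositional closure does not cancel shared latent-factor variation),
    # while unboosted they still draw enough reads that counting noise does
    # not drown the planted rank correlations.
    slots = {40: 0, 44: 1, 48: 2, 52: 3, 56: 4, 60: 5}
    filler = 0
    for i in range(n_taxa):
        if i in slots:
            genus_names.append(planted_genera[slots[i]])
        else:
            genus_names.append(f"Genus_{filler:03d}")
            filler += 1
    if len(genus_names) != n_taxa or set(planted_genera) - set(genus_names):
        raise DataError("n_taxa too small for the planted genera")

    panel_up = list(PANEL_GENES_UP)
    panel_down = list(PANEL_GENES_DOWN)
    distractor_de = ["TNF", "IL10"]  # DE below the panel fold cutoff
    coupled_not_de = ["IL6R"]  # correlated but not differentially expressed
    named = panel_up + panel_down + distractor_de + coupled_not_de
    if n_genes < len(named):
        raise DataError("n_genes too small for the planted genes")
    gene_names = named + [f"GENE_{i:03d}" for i in range(n_genes - len(named))]

    genus_effects: dict[tuple[str, str], float] = {}
    for g in RESPONDER_GENERA:
        genus_effects[(g, "CD_PRE_R")] = genus_log_fold
    for g in NONRESPONDER_GENERA:
        genus_effects[(g, "CD_PRE_NONR")] = genus_log_fold

    gene_group_effects: dict[tuple[str, str], float] = {}
    for g in panel_up:
        gene_group_effects[(g, "CD_PRE_R")] = -panel_delta_ct
    for g in panel_down:
        gene_group_effects[(g, "CD_PRE_R")] = panel_delta_ct
    gene_group_effects[("TNF", "CD_PRE_R")] = -1.5
    gene_group_effects[("IL10", "CD_PRE_R")] = 1.5

    # Responder-stratum couplings: one shared factor; the genus loading
    # sign is +1 for responder-enriched and -1 for non-responder-enriched
    # genera, the gene sign mirrors the published mixed pattern.
    gene_tau = {
        "CXCL8": 1, "TLR6": 1, "TLR9": 1, "TNFSF14": 1,
        "IL18": -1, "CCR3": -1, "CCR4": -1, "IL6R": -1,
    }
    couplings: list[Coupling] = []
    coupled_nr_genera = ("Negativibacillus", "Faecalibacterium", "Blautia")
    for gene, tau in gene_tau.items():
        for genus in RESPONDER_GENERA:
            couplings.append(
                Coupling(genus, gene, coupling_strength * tau, "CD_PRE_R",
                         factor="axis_r", genus_sign=1)
            )
        for genus in coupled_nr_genera:
            couplings.append(
                Coupling(genus, gene, -coupling_strength * tau, "CD_PRE_R",
                         factor="axis_r", genus_sign=-1)
            )
    # A smaller non-responder-stratum axis, echoing the published
    # non-responder sign lists (gives the fourth genus its own hits).
    couplings.append(
        Coupling("Eubacterium_hallii_group", "CCR4", 0.9, "CD_PRE_NONR",
                 factor="axis_nr", genus_sign=1)
    )
    couplings.append(
        Coupling("Hungatella", "CXCL8", 0.9, "CD_PRE_NONR",
                 factor="axis_nr", genus_sign=1)
    )

    n_per_group = {
        "CD_PRE_R": n_per_stratum,
        "CD_PRE_NONR": n_per_stratum,
        "CD_POST_R": n_per_stratum,
        "CD_POST_NONR": n_per_stratum,
        "HC": 9,
    }
    return CohortDesign(
        n_per_group=n_per_group,
        n_taxa=n_taxa,
        n_genes=n_genes,
        genus_names=tuple(genus_names),
        gene_names=tuple(gene_names),
        genus_effects=genus_effects,
        couplings=tuple(couplings),
        gene_group_effects=gene_group_effects,
        logabund_noise_sd=0.15,
        noise_ct_sd=0.3,
        seed=seed,
        panel_genes_up=tuple(panel_up),
        panel_genes_down=tuple(panel_down),
        responder_genera=RESPONDER_GENERA,
        nonresponder_genera=NONRESPONDER_GENERA,
    )


def null_design(
    n_per_group: Mapping[str, int] | None = None,
    n_taxa: int = 100,
    n_genes: int = 40,
    seed: int = 0,
) -> CohortDesign:
    """A cohort with no planted effects or couplings (calibration runs)."""
    if n_per_group is None:
        n_per_group = {"CD_PRE_R": 5, "CD_PRE_NONR": 5}
    return CohortDesign(
        n_per_group=dict(n_per_group),
        n_taxa=n_taxa,
        n_genes=n_genes,
        seed=seed,
    )
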