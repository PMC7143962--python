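"""Analysis configuration shared across all pipeline stages.

Every threshold used anywhere in the pipeline is a named field here so a
run can be replayed from its manifest. Defaults follow common practice for
genus-level 16S workflows and qPCR-array analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

#: Lineage terms removed by default: photosynthetic contaminants in 16S data.
DEFAULT_BLOCKLIST = ("Cyanobacteria", "Chloroplast")


@dataclass
class AnalysisConfig:
    """Tunable parameters for the full pipeline.

    Parameters
    ----------
    min_rel_abundance_pct
        Taxa whose pooled relative abundance (taxon total / grand total, in
        percent) is strictly below this are removed.
    top_n_taxa
        After the abundance filter, keep at most this many taxa ranked by
        mean per-sample relative abundance.
    taxon_blocklist
        Lineage terms whose taxa are always removed (case-insensitive,
        matched against every rank and the genus label).
    rarefaction_depth
        Uniform read depth for alpha-diversity rarefaction.
    rarefaction_seed
        Seed for the rarefaction subsampler.
    de_min_abs_fold
        Minimum absolute fold regulation for a gene to count as
        differentially expressed.
    de_alpha
        p-value cutoff (strict <) for differential expression.
    panel_min_abs_fold
        Stricter fold-regulation cutoff defining panel-eligible genes.
    anova_alpha, anova_alpha_strict
        The two presets used for genus differential abundance: 0.05 for
        treatment/response contrasts, 0.01 for the HC-vs-IBD contrast.
    rho_strong_threshold
        |rho| at or above which a genus-gene Spearman correlation counts as
        "strong".
    consensus_k, consensus_m
        A panel gene must correlate with >= k of the m
        non-responder-enriched genera.
    presence_fraction
        Fraction of a group's samples in which a genus must be detected to
        count as present in that group (core-microbiome Venn rule).
    """

    min_rel_abundance_pct: float = 0.01
    top_n_taxa: int = 3000
    taxon_blocklist: tuple[str, ...] = DEFAULT_BLOCKLIST
    rarefaction_depth: int = 12180
    rarefaction_seed: int = 0
    de_min_abs_fold: float = 2.0
    de_alpha: float = 0.05
    panel_min_abs_fold: float = 15.0
    anova_alpha: float = 0.05
    anova_alpha_strict: float = 0.01
    rho_strong_threshold: float = 0.8
    consensus_k: int = 3
    consensus_m: int = 4
    presence_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_rel_abundance_pct < 0:
            raise ValueError("min_rel_abundance_pct must be >= 0")
        if self.top_n_taxa < 1:
            raise ValueError("top_n_taxa must be >= 1")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        for name in ("de_alpha", "anova_alpha", "anova_alpha_strict"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0 < self.rho_strong_threshold <= 1:
            raise ValueError("rho_strong_threshold must lie in (0, 1]")
        if self.de_min_abs_fold < 1 or self.panel_min_abs_fold < 1:
            raise ValueError("fold thresholds must be >= 1")
        if not 0 < self.presence_fraction <= 1:
            raise ValueError("presence_fraction must lie in (0, 1]")
        if not (1 <= self.consensus_k <= self.consensus_m):
            raise ValueError("need 1 <= consensus_k <= consensus_m")
        self.taxon_blocklist = tuple(self.taxon_blocklist)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["taxon_blocklist"] = list(self.taxon_blocklist)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
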