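"""End-to-end orchestration: counts + Ct + metadata in, biomarker panel out.

``analyze_cohort`` is the in-memory engine used by tests and simulations;
``run_pipeline`` wraps it with file I/O, the diversity stage, structured
logging and a JSON run manifest sufficient for bit-identical replay.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .abundance import (
    RelAbundanceTable,
    aggregate_to_genus,
    filter_taxa,
    hellinger,
    rarefy,
    tss_normalize,
)
from .concordance import (
    BiomarkerPanel,
    CorrelationCell,
    SignList,
    assemble_panel,
    cells_to_frame,
    classify_strong,
    correlation_matrix,
    inverse_ct,
)
from .config import AnalysisConfig
from .diversity import alpha_diversity, core_partition
from .io import (
    CountTable,
    CtMatrix,
    DataError,
    Metadata,
    TaxonomyMap,
    check_sample_consistency,
    read_count_table,
    read_ct_matrix,
    read_metadata,
    read_taxonomy,
    write_count_table,
    write_ct_matrix,
    write_metadata,
    write_taxonomy,
)
from .qpcr import DEGRecord, ddct_contrast, degs_to_frame, delta_ct, select_de_genes
from .simulate import CohortDesign, generate_cohort, reference_cohort_design
from .taxa import anova_per_genus, select_diff_genera

logger = logging.getLogger(__name__)


@dataclass
class PanelAnalysisResult:
    """All intermediate and final products of one response-contrast run."""

    genus_stats: pd.DataFrame
    selected_genera: pd.DataFrame
    responder_genera: list[str]
    nonresponder_genera: list[str]
    deg_records: list[DEGRecord]
    de_genes: set[str]
    panel_eligible_directions: dict[str, str]
    cells: list[CorrelationCell]
    sign_lists: list[SignList]
    panel: BiomarkerPanel


def analyze_cohort(
    counts: CountTable,
    tax: TaxonomyMap,
    ct: CtMatrix,
    meta: Metadata,
    cfg: AnalysisConfig | None = None,
    group_a: str = "CD_PRE_R",
    group_b: str = "CD_PRE_NONR",
    n_responder_genera: int = 2,
    n_nonresponder_genera: int = 4,
    genera_use_bh: bool = False,
) -> PanelAnalysisResult:
    """Run the full integration analysis for one response contrast.

    ``group_a`` is the responder baseline group; genera more abundant there
    are the responder-enriched set. The most significant
    ``n_responder_genera`` / ``n_nonresponder_genera`` genera per direction
    feed the consensus rule (matching the reference study's 2 + 4
    structure).
    """
    cfg = cfg or AnalysisConfig()
    check_sample_consistency(meta, counts=counts, ct=ct)

    genus_counts = aggregate_to_genus(counts, tax)
    filtered = filter_taxa(genus_counts, cfg)
    rel = hellinger(tss_normalize(filtered))

    stats = anova_per_genus(rel, meta, [group_a, group_b])
    selected = select_diff_genera(stats, cfg.anova_alpha, use_bh=genera_use_bh)
    resp = [g for g in selected.index if selected.at[g, "top_group"] == group_a]
    nonresp = [g for g in selected.index if selected.at[g, "top_group"] == group_b]
    resp = resp[:n_responder_genera]
    nonresp = nonresp[:n_nonresponder_genera]
    if not resp or not nonresp:
        raise DataError(
            "differential-abundance stage found no genera for one direction; "
            "cannot run the consensus rule"
        )

    dct = delta_ct(ct)
    recs = ddct_contrast(dct, meta, group_a, group_b)
    de_sel = select_de_genes(recs, cfg.de_min_abs_fold, cfg.de_alpha)
    panel_sel = select_de_genes(recs, cfg.panel_min_abs_fold, cfg.de_alpha)
    if not de_sel.genes:
        raise DataError("no differentially expressed genes at the DE cutoff")

    proxy = inverse_ct(ct)
    genera = resp + nonresp
    genes = sorted(de_sel.genes)
    cells = []
    for stratum in ("responders", "non_responders"):
        cells.extend(
            correlation_matrix(
                rel, proxy, genera, genes, meta, stratum,
                threshold=cfg.rho_strong_threshold,
            )
        )
    sign_lists = classify_strong(cells, cfg.rho_strong_threshold)
    panel = assemble_panel(
        sign_lists,
        resp,
        nonresp,
        panel_sel.directions,
        k=min(cfg.consensus_k, len(nonresp)),
        m=len(nonresp),
    )
    return PanelAnalysisResult(
        genus_stats=stats,
        selected_genera=selected,
        responder_genera=resp,
        nonresponder_genera=nonresp,
        deg_records=recs,
        de_genes=de_sel.genes,
        panel_eligible_directions=panel_sel.directions,
        cells=cells,
        sign_lists=sign_lists,
        panel=panel,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


DEFAULT_PIPELINE_CONFIG: dict[str, Any] = {
    "simulate": False,
    "inputs": {},
    "simulate_design": {},
    "contrast": {"group_a": "CD_PRE_R", "group_b": "CD_PRE_NONR"},
    "n_responder_genera": 2,
    "n_nonresponder_genera": 4,
    "genera_use_bh": False,
    "analysis": {},
}


def run_pipeline(
    config_path: str | None = None,
    out_dir: str = "ifxpanel_run",
    seed: int = 0,
    config: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Execute every stage and write all artifacts plus a run manifest.

    The manifest records the config snapshot, seeds, input digests and
    per-stage output paths; re-running with the same config and seed
    reproduces stochastic stages (simulation, rarefaction) bit-identically.
    The simulation seed is ``seed``; rarefaction uses ``seed + 1``.
    """
    if config is None:
        if config_path is None:
            raise DataError("run_pipeline needs a config path or dict")
        with open(config_path) as fh:
            config = yaml.safe_load(fh) or {}
    merged = {**DEFAULT_PIPELINE_CONFIG, **config}
    cfg = AnalysisConfig.from_dict(merged.get("analysis") or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": seed,
        "rarefaction_seed": seed + 1,
        "config": {**merged, "analysis": cfg.to_dict()},
        "inputs": {},
        "outputs": {},
        "stages": [],
    }

    def stage(name: str):
        t0 = time.perf_counter()

        def done(**counts: int) -> None:
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3),
                 **counts}
            )
            logger.info("stage %s done (%.2fs) %s", name,
                        time.perf_counter() - t0, counts)

        return done

    # --- inputs -----------------------------------------------------------
    done = stage("load_inputs")
    if merged["simulate"]:
        design = reference_cohort_design(seed=seed, **merged["simulate_design"])
        counts, tax, ct, meta, truth = generate_cohort(design)
        write_count_table(counts, str(out / "counts.tsv"))
        write_taxonomy(tax, str(out / "taxonomy.tsv"))
        write_ct_matrix(ct, str(out / "ct.tsv"))
        write_metadata(meta, str(out / "metadata.tsv"))
        (out / "truth.json").write_text(truth.to_json())
        for name in ("counts.tsv", "taxonomy.tsv", "ct.tsv", "metadata.tsv"):
            manifest["inputs"][name] = _sha256(out / name)
        manifest["outputs"]["truth"] = str(out / "truth.json")
    else:
        paths = merged["inputs"]
        for key in ("counts", "taxonomy", "ct", "metadata"):
            if key not in paths:
                raise DataError(f"config missing input path {key!r}")
        counts = read_count_table(paths["counts"])
        tax = read_taxonomy(paths["taxonomy"])
        ct = read_ct_matrix(
            paths["ct"],
            tuple(paths.get("housekeeping", list(ct_default_hk()))),
        )
        meta = read_metadata(paths["metadata"])
        for key in ("counts", "taxonomy", "ct", "metadata"):
            manifest["inputs"][key] = _sha256(Path(paths[key]))
    done(n_samples=len(meta), n_taxa=len(counts.taxon_ids), n_genes=len(ct.gene_ids))

    # --- abundance + diversity -------------------------------------------
    done = stage("abundance")
    genus_counts = aggregate_to_genus(counts, tax)
    filtered = filter_taxa(genus_counts, cfg)
    rel_tss = tss_normalize(filtered)
    rel = hellinger(rel_tss)
    write_count_table(filtered, str(out / "genus_counts_filtered.tsv"))
    rel.data.to_csv(out / "relabundance_hellinger.tsv", sep="\t", index_label="id")
    manifest["outputs"]["genus_counts"] = str(out / "genus_counts_filtered.tsv")
    manifest["outputs"]["relabundance"] = str(out / "relabundance_hellinger.tsv")
    done(n_genera=len(filtered.taxon_ids))

    done = stage("diversity")
    rare = rarefy(genus_counts, cfg.rarefaction_depth, seed + 1)
    alpha = alpha_diversity(rare)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    venn = core_partition(rel_tss, meta, cfg.presence_fraction)
    (out / "venn_regions.json").write_text(
        json.dumps(venn.to_dict(), indent=2, sort_keys=True)
    )
    manifest["outputs"]["alpha_diversity"] = str(out / "alpha_diversity.tsv")
    manifest["outputs"]["venn_regions"] = str(out / "venn_regions.json")
    done(n_rarefied_samples=len(rare.sample_ids))

    # --- contrast stages --------------------------------------------------
    done = stage("panel_analysis")
    contrast = merged["contrast"]
    result = analyze_cohort(
        counts, tax, ct, meta, cfg,
        group_a=contrast["group_a"],
        group_b=contrast["group_b"],
        n_responder_genera=merged["n_responder_genera"],
        n_nonresponder_genera=merged["n_nonresponder_genera"],
        genera_use_bh=merged["genera_use_bh"],
    )
    result.genus_stats.sort_values("p_value", kind="stable").to_csv(
        out / "genus_anova.tsv", sep="\t"
    )
    degs_to_frame(result.deg_records).to_csv(out / "deg_records.tsv", sep="\t")
    cells_to_frame(result.cells).to_csv(
        out / "correlation_cells.tsv", sep="\t", index=False
    )
    (out / "panel.json").write_text(
        json.dumps(result.panel.to_dict(), indent=2, sort_keys=True)
    )
    for key, name in (
        ("genus_anova", "genus_anova.tsv"),
        ("deg_records", "deg_records.tsv"),
        ("correlation_cells", "correlation_cells.tsv"),
        ("panel", "panel.json"),
    ):
        manifest["outputs"][key] = str(out / name)
    done(
        n_de_genes=len(result.de_genes),
        n_panel_genes=len(result.panel.genes),
    )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def ct_default_hk() -> tuple[str, ...]:
    from .io import DEFAULT_HOUSEKEEPING

    return DEFAULT_HOUSEKEEPING
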