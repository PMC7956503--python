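"""Stage orchestration: one call runs the whole analysis and writes reports.

The stage order mirrors the study design: ingest the run-level protein
lists, QC the technical replicates, normalize and frequency-filter,
average to subject-level aSpC, stratify subjects by Ward clustering,
screen discriminant proteins (F-ratio) and fit the common-covariance
LDA, call DAve/DCI DEPs, nominate a marker panel and alpha-type the
subjects, then link the proteome groups to FOT impedance Z-scores.

Every stage writes a TSV; a machine-readable JSON summary records the
protein funnel (identified -> retained -> discriminants / DEPs ->
overlap -> panel) and the group assignments. Outputs are deterministic:
identical config and inputs give byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import alphatyping, differential, fotlink, ingest, markers, stratify
from .config import PipelineConfig
from .errors import PipelineError, UvepError

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """What the pipeline produced: stage log, funnel counts, output paths."""

    stages: list[str]
    summary: dict
    outdir: Path


def _stage(name: str):
    def wrap(fn):
        def inner(*a, **kw):
            try:
                out = fn(*a, **kw)
            except UvepError as exc:
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s complete", name)
            return out

        return inner

    return wrap


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute every stage per the config; see module docstring for order."""
    if cfg.run_table is None:
        raise PipelineError("ingest", "config.run_table is required")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.write(outdir / "effective_config.yaml")
    stages: list[str] = []
    summary: dict = {"funnel": {}, "stages": stages}

    # --- ingest ---------------------------------------------------------
    run_table = _stage("ingest")(ingest.read_run_table)(
        cfg.run_table, cfg.run_table_format, cfg.run_table_sidecar
    )
    aligned = _stage("align")(ingest.align_runs)(run_table)
    pairing = run_table.pairing()
    stages += ["ingest", "align"]
    summary["funnel"]["proteins_identified"] = aligned.n_proteins
    summary["n_runs"] = aligned.n_columns

    qc = _stage("qc")(ingest.replicate_qc)(
        aligned, pairing, cfg.qc_min_correlation, cfg.qc_slope_lo, cfg.qc_slope_hi
    )
    pd.DataFrame([vars(q) for q in qc]).to_csv(outdir / "replicate_qc.tsv", sep="\t", index=False)
    stages.append("qc")
    summary["qc_failures"] = [q.subject_id for q in qc if not q.passed]

    normalized = _stage("normalize")(ingest.normalize_total_spc)(aligned)
    filtered = _stage("filter")(ingest.filter_by_frequency)(normalized, cfg.min_frac)
    aspc = _stage("average")(ingest.average_replicates)(filtered, pairing)
    aspc.to_tsv(outdir / "aspc_matrix.tsv")
    stages += ["normalize", "filter", "average"]
    summary["funnel"]["proteins_retained"] = filtered.n_proteins
    summary["n_subjects"] = aspc.n_columns

    # --- stratify -------------------------------------------------------
    dendro = _stage("cluster")(stratify.cluster_subjects)(aspc, cfg.cluster_transform)
    groups = _stage("cluster")(stratify.cut_tree)(dendro, cfg.k)
    (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n", encoding="utf-8")
    pd.DataFrame(
        sorted(groups.labels.items()), columns=["subject_id", "group"]
    ).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    stages.append("cluster")
    summary["groups"] = {g: groups.members(g) for g in groups.group_names()}

    # --- markers --------------------------------------------------------
    records = _stage("markers")(markers.f_ratio_select)(aspc, groups.labels, cfg.f_min, cfg.p_max)
    markers.discriminant_table(records).to_csv(outdir / "discriminants.tsv", sep="\t", index=False)
    selected = {r.accession for r in records if r.selected}
    summary["funnel"]["discriminants"] = len(selected)

    lda_model = None
    if len(selected) >= 2:
        restricted = aspc.with_values(
            aspc.values.loc[sorted(selected)], f"restricted to {len(selected)} discriminants"
        )
        lda_model = _stage("markers")(markers.fit_lda)(restricted, groups.labels, cfg.lda_shrinkage)
        scores = lda_model.training_scores.copy()
        scores["assigned"] = pd.Series(markers.classify_lda(lda_model, restricted))
        scores.index.name = "subject_id"
        scores.to_csv(outdir / "canonical_scores.tsv", sep="\t")
    stages.append("markers")

    # --- differential ---------------------------------------------------
    deps = _stage("dep")(differential.pairwise_deps)(
        aspc, groups.labels, cfg.dave_threshold, cfg.dci_threshold
    )
    deps.to_tsv(outdir / "deps.tsv")
    panel = markers.intersect_panels(selected, deps, aspc, groups.labels)
    top = markers.select_top_markers(panel, deps, cfg.panel_size) if panel.proteins else panel
    stages.append("dep")
    summary["funnel"]["deps"] = len(deps.proteins)
    summary["funnel"]["overlap"] = len(panel.proteins)
    summary["panel"] = top.proteins

    if cfg.cd_list:
        cd = differential.read_accession_list(cfg.cd_list)
        gm = differential.group_mean_aspc(aspc, groups.labels)
        differential.cd_marker_table(deps, cd, gm, cfg.cd_dci_threshold).to_csv(
            outdir / "cd_markers.tsv", sep="\t", index=False
        )
        stages.append("cd")

    # --- typing ---------------------------------------------------------
    if top.proteins:
        profiles = _stage("type")(alphatyping.alpha_profile)(aspc, top)
        centroids = _stage("type")(alphatyping.alpha_centroids)(aspc, top, groups)
        typed = _stage("type")(alphatyping.assign_by_alpha)(profiles, centroids)
        alphatyping.alpha_table(profiles).to_csv(outdir / "alpha_profiles.tsv", sep="\t", index=False)
        agree = sum(typed.labels[s] == groups.labels[s] for s in groups.labels)
        summary["alpha_round_trip_agreement"] = agree / len(groups.labels)
        stages.append("type")

    # --- FOT linkage ----------------------------------------------------
    if cfg.fot_table:
        if not Path(cfg.fot_table).exists():
            raise PipelineError("fot", f"FOT table not found: {cfg.fot_table}")
        fot = _stage("fot")(fotlink.read_fot_table)(cfg.fot_table)
        report = _stage("fot")(fotlink.compare_groups_fot)(fot, groups, cfg.alpha)
        report["table"].to_csv(outdir / "fot_comparison.tsv", sep="\t", index=False)
        summary["fot"] = {
            row["variable"]: {
                "H": row["H"],
                "p": row["p"],
                "pairwise": {f"{a}_vs_{b}": p
                             for (a, b), p in report["pairwise"][row["variable"]].items()},
            }
            for _, row in report["table"].iterrows()
        }
        stages.append("fot")

    _check_funnel(summary["funnel"])
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return RunReport(stages=stages, summary=summary, outdir=outdir)


def _check_funnel(funnel: dict) -> None:
    """Sanity inequalities of the protein funnel; violation is a code bug."""
    if funnel["proteins_retained"] > funnel["proteins_identified"]:
        raise PipelineError("report", "retained exceeds identified")
    if funnel["overlap"] > min(funnel["discriminants"], funnel["deps"]):
        raise PipelineError("report", "overlap exceeds its parent sets")
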