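"""End-to-end orchestration: simulate → roll-up → redox / abundance →
enrichment → clustering, with TSV outputs, a run log and a machine-readable
summary."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import enrichment as en
from . import redox as rx
from . import simulate as sim
from .tables import (
    ChannelDesign,
    FormatError,
    PipelineError,
    UsageError,
    read_annotations,
    read_psm_table,
    write_annotations,
    write_table,
)

log = logging.getLogger(__name__)

MODES = ("simulate", "redox", "abundance", "enrich", "all")


@dataclass
class PipelineConfig:
    """Everything one run needs; thresholds default to the study's values."""

    out_dir: str = "results"
    mode: str = "all"
    # inputs for non-simulate modes (ignored when simulating)
    redox_psm_path: str | None = None
    redox_design_path: str | None = None
    abundance_psm_path: str | None = None
    abundance_design_path: str | None = None
    annotations_path: str | None = None
    group_map_path: str | None = None
    # analysis thresholds
    min_reps: int = 3
    ratio_threshold: float = 100.0
    missing_frac: float = 0.5
    s0: float = 1.0
    target_fdr: float = 0.02
    n_perm: int = 250
    center: str = "mean"
    universe_policy: str = "annotated-only"
    seed: int = 0
    force: bool = True
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)

    def validate(self) -> None:
        if self.mode not in MODES:
            raise UsageError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0 < self.target_fdr < 1:
            raise UsageError("target_fdr must lie in (0, 1)")
        if self.min_reps < 0 or self.n_perm < 1:
            raise UsageError("min_reps must be >= 0 and n_perm >= 1")
        if self.mode in ("redox", "abundance", "enrich"):
            needed = {
                "redox": [self.redox_psm_path, self.redox_design_path],
                "abundance": [self.abundance_psm_path, self.abundance_design_path],
                "enrich": [self.annotations_path, self.abundance_psm_path,
                           self.abundance_design_path],
            }[self.mode]
            for p in needed:
                if p is None or not Path(p).exists():
                    raise UsageError(f"mode {self.mode}: required input missing: {p}")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sim"]["annotation_scheme"] = [asdict(t) for t in self.sim.annotation_scheme]
        data["sim"]["log2fc_range"] = list(self.sim.log2fc_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "sim" in data and data["sim"] is not None:
            s = data["sim"]
            if s.get("annotation_scheme") is not None:
                s["annotation_scheme"] = tuple(sim.TermSpec(**t) for t in s["annotation_scheme"])
            if s.get("degenerate_channel") is not None:
                s["degenerate_channel"] = sim.DegenerateChannel(**s["degenerate_channel"])
            if s.get("log2fc_range") is not None:
                s["log2fc_range"] = tuple(s["log2fc_range"])
            data["sim"] = sim.SimConfig(**s)
        return cls(**data)


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logging.getLogger("redoxquant").addHandler(handler)
    logging.getLogger("redoxquant").setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write all outputs under ``out_dir``.

    Returns the machine-readable summary (also written as summary.json).
    Any stage error is re-raised annotated with the stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    summary: dict = {"seed": config.seed, "mode": config.mode}
    try:
        truth = None
        if config.mode in ("simulate", "all"):
            truth, stats = _stage("simulate", _run_simulate, config, out)
            summary["simulate"] = stats
        if config.mode in ("redox", "all"):
            _, stats = _stage("redox", _run_redox, config, out, truth)
            summary["redox"] = stats
        if config.mode in ("abundance", "all", "enrich"):
            (da_flags, norm, design), stats = _stage(
                "abundance", _run_abundance, config, out, truth)
            summary["abundance"] = stats
            _, stats = _stage("enrich", _run_enrichment, config, out, truth,
                              da_flags, norm, design)
            summary["enrich"] = stats
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=_jsonable))
        return summary
    except Exception as exc:
        (out / "summary.json").write_text(json.dumps(
            {**summary, "error": str(exc)}, indent=2, default=_jsonable))
        raise
    finally:
        logging.getLogger("redoxquant").removeHandler(handler)
        handler.close()


def _stage(name: str, fn, *args):
    t0 = time.perf_counter()
    try:
        result = fn(*args)
    except (FormatError, UsageError):
        # input problems keep their type so callers can distinguish them
        log.error("stage %s rejected its inputs", name)
        raise
    except Exception as exc:
        log.error("stage %s failed (partial outputs may exist): %s", name, exc)
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
    return result


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return None if np.isnan(x) else float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _run_simulate(config: PipelineConfig, out: Path) -> sim.SimTruth:
    cfg = config.sim
    truth = sim.simulate_ground_truth(cfg)
    iodo_psms, iodo_design = sim.simulate_iodotmt_psms(truth, cfg)
    tmt_psms, tmt_design = sim.simulate_tmt_psms(truth, cfg)
    force = config.force
    truth.write(out / "sim_truth.tsv", force=force)
    write_annotations(truth.catalog_with_compartments, out / "sim_annotations.tsv",
                      force=force)
    write_table(iodo_psms, out / "sim_iodotmt_psms.tsv", force=force)
    iodo_design.write(out / "sim_iodotmt_design.tsv", force=force)
    write_table(tmt_psms, out / "sim_tmt_psms.tsv", force=force)
    tmt_design.write(out / "sim_tmt_design.tsv", force=force)
    cfg.to_yaml(out / "sim_config.yaml")
    log.info("simulated %d proteins: %d iodoTMT PSM rows, %d TMT PSM rows",
             cfg.n_proteins, len(iodo_psms), len(tmt_psms))
    stats = {
        "n_proteins": cfg.n_proteins,
        "n_true_daps": int(truth.proteins["is_dap"].sum()),
        "n_iodotmt_psm_rows": len(iodo_psms),
        "n_tmt_psm_rows": len(tmt_psms),
    }
    return truth, stats


def _load_redox_inputs(config: PipelineConfig, out: Path):
    if config.mode == "all":
        design = ChannelDesign.read(out / "sim_iodotmt_design.tsv")
        psms = read_psm_table(out / "sim_iodotmt_psms.tsv", design)
    else:
        design = ChannelDesign.read(config.redox_design_path)
        psms = read_psm_table(config.redox_psm_path, design)
    return psms, design


def _run_redox(config: PipelineConfig, out: Path, truth) -> None:
    psms, design = _load_redox_inputs(config, out)
    matrix = rx.aggregate_psms(psms, design)
    stoich = rx.compute_stoichiometry(matrix, design)
    stoich_all, summary_all = rx.redox_comparison(stoich)
    filtered = rx.filter_by_replicate_presence(stoich, min_reps=config.min_reps)
    stoich_filt, summary_filt = rx.redox_comparison(filtered)
    corr_cols = ([c for c in stoich.columns if c.startswith("stoich_HT")]
                 + [c for c in stoich.columns if c.startswith("stoich_LT")])
    corr = rx.replicate_correlation(stoich[corr_cols])

    force = config.force
    write_table(stoich_all.reset_index(names="protein_id"),
                out / "redox_stoichiometry.tsv", force=force)
    write_table(stoich_filt.reset_index(names="protein_id"),
                out / "redox_stoichiometry_filtered.tsv", force=force)
    write_table(pd.concat([summary_all.to_frame().assign(protein_set="all"),
                           summary_filt.to_frame().assign(protein_set=f"min{config.min_reps}reps")]),
                out / "redox_summary.tsv", force=force)
    write_table(summary_all.histogram_frame(), out / "redox_fc_histogram.tsv", force=force)
    write_table(corr.reset_index(names="column"), out / "redox_correlation_matrix.tsv",
                force=force)
    log.info("redox: %d proteins quantified, %d pass >=%d-replicate filter; "
             "global paired t p %s (all) / %s (filtered)",
             len(stoich_all), len(stoich_filt), config.min_reps,
             summary_all.global_p_display, summary_filt.global_p_display)

    def _stats(s: rx.RedoxSummary) -> dict:
        return {
            "n_proteins": s.n_proteins,
            "mean_stoich_ht": s.mean_stoich_ht, "sd_stoich_ht": s.sd_stoich_ht,
            "mean_stoich_lt": s.mean_stoich_lt, "sd_stoich_lt": s.sd_stoich_lt,
            "fc_mean": s.fc_mean, "fc_sd": s.fc_sd, "fc_median": s.fc_median,
            "frac_fc_below_1": s.frac_fc_below_1,
            "global_t": s.global_t, "global_p": s.global_p,
            "global_p_display": s.global_p_display,
        }

    stats = {"all_proteins": _stats(summary_all),
             f"min_{config.min_reps}_replicates": _stats(summary_filt),
             "min_reps": config.min_reps}
    return None, stats


def _load_abundance_inputs(config: PipelineConfig, out: Path):
    if config.mode in ("all",):
        design = ChannelDesign.read(out / "sim_tmt_design.tsv")
        psms = read_psm_table(out / "sim_tmt_psms.tsv", design)
    else:
        design = ChannelDesign.read(config.abundance_design_path)
        psms = read_psm_table(config.abundance_psm_path, design)
    return psms, design


def _run_abundance(config: PipelineConfig, out: Path, truth):
    psms, design = _load_abundance_inputs(config, out)
    matrix = rx.aggregate_psms(psms, design)
    n_identified = len(matrix.proteins)

    if config.group_map_path:
        gm_df = pd.read_csv(config.group_map_path, sep="\t")
        group_map = dict(zip(gm_df["protein_id"].astype(str), gm_df["group_id"].astype(str)))
    elif truth is not None:
        group_map = truth.merge_group_map()
    else:
        group_map = {}
    matrix = ab.merge_protein_groups(matrix, group_map)

    kept, dropped, qc_report = ab.qc_channels(
        matrix, ratio_threshold=config.ratio_threshold, missing_frac=config.missing_frac)
    for ch in dropped:
        log.info("abundance: dropped channel %s", ch)
    matrix = matrix.select_channels(kept)
    matrix = ab.scale_channels(matrix)
    norm = ab.log2_and_center(matrix, center=config.center)

    result = ab.differential_abundance(
        norm, design, s0=config.s0, target_fdr=config.target_fdr,
        n_perm=config.n_perm, seed=config.seed)
    cluster = ab.hierarchical_cluster(norm)

    force = config.force
    write_table(qc_report, out / "channel_qc.tsv", force=force)
    write_table(result.table.reset_index(names="protein_id"),
                out / "abundance_results.tsv", force=force)
    write_table(result.volcano_frame(), out / "volcano.tsv", force=force)
    write_table(result.fdr_curve, out / "fdr_curve.tsv", force=force)
    write_table(cluster.z_matrix.loc[cluster.row_order, cluster.col_order]
                .reset_index(names="protein_id"),
                out / "heatmap_matrix.tsv", force=force)
    write_table(cluster.col_partition.rename_axis("channel_id").reset_index(),
                out / "cluster_column_partition.tsv", force=force)
    log.info("abundance: %d proteins identified, %d after group merge, "
             "%d channel(s) dropped (%s), %d DAPs at FDR %.3g (|d| >= %.4g)",
             n_identified, len(matrix.proteins), len(dropped),
             ",".join(dropped) or "none", result.n_significant,
             config.target_fdr, result.d_cutoff)

    flags = result.table["significant"]
    stats = {
        "n_proteins_identified": n_identified,
        "n_rows_after_merge": len(matrix.proteins),
        "channels_dropped": dropped,
        "n_tested": int(result.table["testable"].sum()),
        "n_daps": result.n_significant,
        "n_daps_up_in_ht": int((result.table["significant"]
                                & (result.table["diff"] > 0)).sum()),
        "d_cutoff": result.d_cutoff,
        "n_permutations": result.n_permutations,
        "column_clusters": {str(k): int(v)
                            for k, v in cluster.col_partition.items()},
    }
    return (flags, norm, design), stats


def _run_enrichment(config: PipelineConfig, out: Path, truth, flags, norm, design):
    if config.annotations_path:
        catalog = read_annotations(config.annotations_path)
    elif truth is not None:
        catalog = truth.catalog_with_compartments
    else:
        raise UsageError("enrichment needs an annotation catalog")

    fisher = en.fisher_enrichment(flags, catalog, universe_policy=config.universe_policy)
    sample_cols = [c for c in norm.columns
                   if c in design.channels_for(role="abundance")]
    one_d_int = en.one_d_annotation_enrichment(norm[sample_cols], catalog)
    force = config.force
    write_table(fisher, out / "fisher_enrichment.tsv", force=force)
    write_table(one_d_int, out / "one_d_enrichment.tsv", force=force)
    if len(one_d_int):
        write_table(en.one_d_score_matrix(one_d_int).reset_index(),
                    out / "one_d_score_matrix.tsv", force=force)
    n_sig = int((fisher["q_value"] <= config.target_fdr).sum()) if len(fisher) else 0
    log.info("enrichment: %d terms tested by Fisher (%d with q <= %.3g), "
             "%d (term, sample) 1D rows", len(fisher), n_sig,
             config.target_fdr, len(one_d_int))
    stats = {
        "n_terms_fisher": len(fisher),
        "n_terms_fisher_significant": n_sig,
        "fisher_significant_terms": fisher.loc[
            fisher["q_value"] <= config.target_fdr, "term"].tolist() if len(fisher) else [],
        "n_one_d_rows": len(one_d_int),
    }
    return None, stats
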