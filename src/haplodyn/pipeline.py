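"""End-to-end pipeline: simulate/load -> qc -> blocks -> scan -> ld -> novel
-> ancestry, with a structured config, per-stage outputs and a consolidated
summary. Identical config + seed gives an identical output bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as hio
from .ancestry import (PedigreeGraph, classify_admixed, founder_frequencies,
                       group_component_stats, simple_matching_distance,
                       top_founder_share)
from .blocks import blocks_frame, census_all, enumerate_blocks
from .ld import ld_pairs, ld_profile
from .model import DataError, GenotypeMatrix
from .novel import find_novel_snps, fit_accrual, novel_block_counts
from .qc import filter_informative
from .scan import (annotate_regions, compare_groups, flag_reduced_blocks,
                   merge_regions, regions_frame)
from .simulate import SimConfig, simulate_panel

log = logging.getLogger(__name__)

STAGES = ("qc", "blocks", "scan", "ld", "novel", "ancestry")

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Validated pipeline configuration with the method's default thresholds:
    5-SNP window, 0.5 reduction ratio, 50-kb LD bins capped at 2000 kb, 0.8
    admixture threshold, 0.5/0.02 QC thresholds."""

    simulation: SimConfig | None = None
    genotypes: str | None = None
    snp_meta: str | None = None
    accession_meta: str | None = None
    pedigree: str | None = None
    qmatrix: str | None = None
    annotations: str | None = None
    qc_max_missing: float = 0.5
    qc_min_maf: float = 0.02
    window: int = 5
    scan_ratio: float = 0.5
    scan_min_blocks: int = 2
    ld_bin_kb: float = 50.0
    ld_max_kb: float = 2000.0
    admix_threshold: float = 0.8
    reference_group: str = "group1"
    out_dir: str = "haplodyn_out"
    seed: int = 0
    skip: tuple[str, ...] = ()


def validate_config(source: str | Path | dict) -> RunConfig:
    """Build a RunConfig from a YAML file or dict, filling defaults and
    listing every schema violation (not just the first)."""
    if not isinstance(source, dict):
        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(source) - known
    for key in sorted(unknown):
        errors.append(f"unknown config key {key!r}")
    kwargs = {k: v for k, v in source.items() if k in known}
    sim = kwargs.get("simulation")
    if isinstance(sim, dict):
        bad = set(sim) - _SIM_FIELDS
        for key in sorted(bad):
            errors.append(f"unknown simulation key {key!r}")
        try:
            sim_cfg = SimConfig(**{k: _coerce_sim(k, v) for k, v in sim.items()
                                   if k in _SIM_FIELDS})
            sim_cfg.validate()
            kwargs["simulation"] = sim_cfg
        except DataError as exc:
            errors.append(f"simulation: {exc}")
            kwargs.pop("simulation", None)
    if "skip" in kwargs:
        kwargs["skip"] = tuple(kwargs["skip"])
        for s in kwargs["skip"]:
            if s not in STAGES:
                errors.append(f"unknown stage in skip: {s!r}")
    cfg = RunConfig(**kwargs)
    if cfg.simulation is None and cfg.genotypes is None:
        errors.append("either a simulation config or genotype inputs are required")
    if cfg.genotypes is not None and (cfg.snp_meta is None
                                      or cfg.accession_meta is None):
        errors.append("genotype input needs snp_meta and accession_meta")
    if not 0.0 < cfg.scan_ratio <= 1.0:
        errors.append(f"scan_ratio {cfg.scan_ratio} must be in (0, 1]")
    if not 0.0 <= cfg.qc_max_missing <= 1.0:
        errors.append(f"qc_max_missing {cfg.qc_max_missing} must be in [0, 1]")
    if not 0.0 <= cfg.qc_min_maf < 0.5:
        errors.append(f"qc_min_maf {cfg.qc_min_maf} must be in [0, 0.5)")
    if cfg.window < 2:
        errors.append(f"window {cfg.window} must be >= 2")
    if cfg.ld_bin_kb <= 0 or cfg.ld_max_kb <= 0:
        errors.append("ld_bin_kb and ld_max_kb must be positive")
    if not 0.0 < cfg.admix_threshold <= 1.0:
        errors.append(f"admix_threshold {cfg.admix_threshold} must be in (0, 1]")
    if cfg.scan_min_blocks < 1:
        errors.append("scan_min_blocks must be >= 1")
    if errors:
        raise ConfigError(errors)
    return cfg


def _coerce_sim(key: str, value):
    if isinstance(value, list):
        return tuple(value)
    return value


def run_pipeline(config: RunConfig) -> dict:
    """Execute all (non-skipped) stages; returns and writes the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed,
                     "thresholds": {
                         "qc_max_missing": config.qc_max_missing,
                         "qc_min_maf": config.qc_min_maf,
                         "window": config.window,
                         "scan_ratio": config.scan_ratio,
                         "scan_min_blocks": config.scan_min_blocks,
                         "ld_bin_kb": config.ld_bin_kb,
                         "ld_max_kb": config.ld_max_kb,
                         "admix_threshold": config.admix_threshold,
                     }}
    truth = None
    try:
        if config.simulation is not None:
            matrix, truth = simulate_panel(config.simulation, seed=config.seed)
            hio.write_matrix(matrix, out, prefix="panel")
            hio.write_pedigree(truth.pedigree, out / "pedigree.tsv")
            truth.q_matrix.to_csv(out / "qmatrix.tsv", sep="\t")
            summary["n_accessions"] = matrix.n_accessions
            summary["n_snps_simulated"] = matrix.n_snps
        else:
            matrix = hio.read_genotype_table(config.genotypes, config.snp_meta,
                                             config.accession_meta)
            summary["n_accessions"] = matrix.n_accessions
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("input", exc) from exc

    def stage(name: str) -> bool:
        return name not in config.skip

    groups = None
    census = None
    blocks = None

    if stage("qc"):
        try:
            matrix, report = filter_informative(matrix, config.qc_max_missing,
                                                config.qc_min_maf)
            report.dispositions.to_csv(out / "qc_report.csv", index=False)
            log.info(report.summary())
            summary["qc"] = {"n_input": report.n_input,
                             "n_informative": report.n_informative,
                             "n_removed_no_position": report.n_removed_no_position,
                             "n_removed_missing_het": report.n_removed_missing_het,
                             "n_removed_rare": report.n_removed_rare}
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("qc", exc) from exc

    if stage("blocks"):
        try:
            blocks = enumerate_blocks(matrix.snps, config.window)
            groups = {g: matrix.group_rows(g)
                      for g in ("group1", "group2", "group3")
                      if len(matrix.group_rows(g))}
            census = census_all(matrix, groups, blocks)
            blocks_frame(blocks).to_csv(out / "blocks.csv", index=False)
            census.to_csv(out / "census.csv", index=False)
            summary["blocks"] = {"n_blocks": len(blocks),
                                 "n_census_rows": len(census)}
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("blocks", exc) from exc

    if stage("scan") and census is not None and len(groups) == 3:
        try:
            by_group = {g: census[census["group"] == g] for g in groups}
            comparisons = []
            names = list(groups)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    c = compare_groups(by_group[names[i]], by_group[names[j]])
                    comparisons.append({
                        "group_a": names[i], "group_b": names[j],
                        "higher_in_a": c.n_blocks_higher_in_first,
                        "higher_in_b": c.n_blocks_higher_in_second,
                        "ties": c.n_ties, "mannwhitney_p": c.mannwhitney_p})
            import pandas as pd
            pd.DataFrame(comparisons).to_csv(out / "comparisons.csv", index=False)
            flagged = flag_reduced_blocks(by_group["group1"], by_group["group2"],
                                          by_group["group3"], config.scan_ratio)
            regions = merge_regions(flagged, blocks, config.scan_min_blocks)
            if config.annotations:
                anns = hio.read_annotations_bed(config.annotations)
                regions, n_qtl = annotate_regions(regions, anns)
                summary.setdefault("scan", {})["n_qtl_colocalized"] = n_qtl
            regions_frame(regions).to_csv(out / "regions.csv", index=False)
            hio.write_bed(regions, out / "regions.bed")
            summary.setdefault("scan", {}).update({
                "n_flagged_blocks": len(flagged), "n_regions": len(regions),
                "comparisons": comparisons})
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("scan", exc) from exc

    if stage("ld") and groups:
        try:
            import pandas as pd
            profiles = {}
            pair_tables = []
            for g, rows in groups.items():
                prof = ld_profile(matrix, rows, config.ld_bin_kb, config.ld_max_kb)
                prof.insert(0, "group", g)
                profiles[g] = prof
                pairs = ld_pairs(matrix, rows, config.ld_max_kb)
                pairs.insert(0, "group", g)
                pair_tables.append(pairs)
            pd.concat(profiles.values()).to_csv(out / "ld_profile.csv", index=False)
            pd.concat(pair_tables).to_csv(out / "ld_pairs.csv", index=False)
            summary["ld"] = {
                g: {"mean_delta_sq": float(np.nanmean(p["mean_delta_sq"]))
                    if p["n_used"].sum() else None}
                for g, p in profiles.items()}
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("ld", exc) from exc

    if stage("novel") and blocks is not None:
        try:
            novel = find_novel_snps(matrix, config.reference_group)
            novel.to_csv(out / "novel_snps.csv", index=False)
            counts = novel_block_counts(matrix, blocks, config.reference_group)
            counts.to_csv(out / "novel_counts.csv", index=False)
            summary["novel"] = {"n_novel_snps": len(novel)}
            if counts["registration_year"].notna().sum() >= 3:
                fit = fit_accrual(counts)
                with open(out / "accrual.json", "w") as fh:
                    json.dump(dataclasses.asdict(fit), fh, indent=1)
                summary["novel"].update({"accrual_slope": fit.slope,
                                         "accrual_r_squared": fit.r_squared,
                                         "accrual_p": fit.p_value})
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("novel", exc) from exc

    if stage("ancestry"):
        try:
            ped_path = config.pedigree or (
                out / "pedigree.tsv" if truth is not None else None)
            if ped_path is not None:
                ped = PedigreeGraph.from_frame(hio.read_pedigree(ped_path))
                cultivars = [c for c in ped.edges]
                freqs = founder_frequencies(ped, cultivars)
                freqs.to_csv(out / "founder_frequencies.csv", index=False)
                summary["ancestry"] = {
                    "n_founders": len(freqs),
                    "top11_share": top_founder_share(freqs, 11)}
            q_path = config.qmatrix or (
                out / "qmatrix.tsv" if truth is not None else None)
            if q_path is not None:
                q = hio.read_qmatrix(q_path)
                acc = matrix.accessions
                grouping = {
                    g: [a for a in acc.loc[(acc["group"] == g)
                                           & (acc["water_regime"] == "irrigated"),
                                           "accession_id"] if a in q.index]
                    for g in ("group1", "group2", "group3")}
                grouping["non_irrigated"] = [
                    a for a in acc.loc[acc["water_regime"] == "non_irrigated",
                                       "accession_id"] if a in q.index]
                grouping = {g: ids for g, ids in grouping.items() if len(ids) >= 2}
                if len(grouping) >= 2:
                    res = group_component_stats(q, grouping)
                    res.stats.to_csv(out / "admixture_stats.csv", index=False)
                    res.pairwise.to_csv(out / "admixture_pairwise.csv", index=False)
                flags = classify_admixed(q, config.admix_threshold)
                flags.rename("admixed").to_csv(out / "admixed.csv")
                summary.setdefault("ancestry", {})["n_admixed"] = int(flags.sum())
            dist = simple_matching_distance(matrix)
            hio.write_phylip_square(dist.to_numpy(), list(dist.index),
                                    out / "distance.phy")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("ancestry", exc) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
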