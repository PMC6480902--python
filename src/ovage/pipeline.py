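"""End-to-end orchestration: simulate/load -> RPKM -> DE -> set tests ->
positional enrichment -> TE statistics -> stage verification -> report.

Every statistic the analysis produces lands in a machine-readable
``summary.json`` plus per-stage TSVs; all randomness flows through the
single run seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    differential,
    expression_metrics,
    geneset_stats,
    positional_enrichment,
    synthetic_data,
    te_aging,
)
from .io_formats import (
    CountMatrix,
    GeneSet,
    ValidationError,
    read_bed,
    read_counts,
    read_design,
    read_gff3,
    read_gmt,
    read_stage_profiles,
    write_results,
)

logger = logging.getLogger("ovage")


class StageFailure(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One pipeline run: either a simulation or a set of input files."""

    outdir: str = "ovage_run"
    seed: int = 0
    simulate: bool = True
    sim_overrides: dict = dc_field(default_factory=dict)
    # input paths (used when simulate is False)
    counts: str | None = None
    design: str | None = None
    annotation: str | None = None
    domains: str | None = None
    gene_sets: str | None = None
    stage_profiles: str | None = None
    te_kind_prefix: str = "TE_"
    # analysis parameters
    fdr: float = 0.05
    offset: float = 0.5
    n_perm: int = 10_000
    k_up: int = 10
    k_down: int = 10
    dot_chromosome: str = synthetic_data.DOT_CHROMOSOME
    focal_set: str = "pirna"
    eggshell_set: str = "eggshell"
    directional_sets: tuple[str, ...] = ("mito_genome", "etc")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.n_perm > 0 and self.seed is None:
            raise ValidationError("a seed is required when permutations are enabled")
        if not self.simulate:
            for name in ("counts", "design", "annotation", "domains", "gene_sets"):
                path = getattr(self, name)
                if path is None:
                    raise ValidationError(f"input path {name!r} is required when simulate is false")
                if not Path(path).exists():
                    raise ValidationError(f"{name} file not found: {path}")
            if self.stage_profiles and not Path(self.stage_profiles).exists():
                raise ValidationError(f"stage_profiles file not found: {self.stage_profiles}")


def _load_inputs(config: RunConfig):
    if config.simulate:
        sim_cfg = synthetic_data.emulate_paper_marginals(
            seed=config.seed, **config.sim_overrides
        )
        sim = synthetic_data.simulate_counts(sim_cfg)
        return sim.counts, sim.design, sim.annotation, sim.domains, sim.gene_sets, sim.stage_profiles
    counts = read_counts(config.counts)
    # feature kinds: a gene_sets entry of kind mito is not recoverable from
    # TSV, so kinds come from id prefixes (TE) and the mito chromosome label
    annotation = read_gff3(config.annotation)
    kinds = pd.Series("gene", index=counts.counts.index, dtype=object)
    te_mask = np.asarray(kinds.index.astype(str).str.startswith(config.te_kind_prefix))
    on_te_contig = kinds.index.isin(
        annotation.index[annotation["chromosome"] == "TE_consensus"]
    )
    kinds[te_mask | on_te_contig] = "te_family"
    on_mito = annotation.index[annotation["chromosome"] == synthetic_data.MITO_CHROMOSOME]
    kinds[kinds.index.isin(on_mito)] = "mito"
    counts = CountMatrix(counts.counts, kinds)
    design = read_design(config.design)
    domains = read_bed(config.domains)
    gene_sets = read_gmt(config.gene_sets)
    profiles = read_stage_profiles(config.stage_profiles) if config.stage_profiles else None
    return counts, design, annotation, domains, gene_sets, profiles


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and return the summary dict.

    Writes per-stage TSVs plus ``summary.json`` and ``run_log.txt`` under
    ``config.outdir``.  Deterministic given the seed.  Stage failures raise
    :class:`StageFailure` naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": {
        "seed": config.seed, "fdr": config.fdr, "offset": config.offset,
        "n_perm": config.n_perm, "k_up": config.k_up, "k_down": config.k_down,
        "dot_chromosome": config.dot_chromosome, "simulate": config.simulate,
    }}
    timings: list[str] = []

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                timings.append(f"{name}\t{dt:.2f}s")
                if exc is not None and not isinstance(exc, StageFailure):
                    raise StageFailure(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, dt)
                return False

        return _Stage()

    with stage("load"):
        counts, design, annotation, domains, gene_sets, profiles = _load_inputs(config)
        design.validate_against(counts)
        sets_by_name = {s.name: s.restrict_to(counts.features) for s in gene_sets}
        strains = design.strains

    with stage("expression"):
        rpkm_matrix = expression_metrics.rpkm(counts, annotation)
        genic = counts.feature_kind[counts.feature_kind.isin(["gene", "mito"])].index
        summary_genic = expression_metrics.summarize_expression(
            rpkm_matrix.loc[genic], design, offset=config.offset
        )
        write_results(outdir / "expression_summary.tsv", summary_genic.table, index=False)

    with stage("differential"):
        genic_counts = CountMatrix(
            counts.counts.loc[genic], counts.feature_kind.loc[genic]
        )
        de = differential.test_age(genic_counts, design, fdr=config.fdr)
        write_results(outdir / "de_results.tsv", de.table)
        sig = de.significant_features
        pooled = summary_genic.pooled_ratios().loc[sig.intersection(summary_genic.features)]
        summary["differential"] = {
            "n_tested": int(de.table["p_age"].notna().sum()),
            "n_significant": int(len(sig)),
            "n_up": int((pooled > 0).sum()),
            "n_down": int((pooled < 0).sum()),
            "n_interaction_significant": int(
                (de.table["padj_interaction"] < config.fdr).sum()
            ),
        }

    with stage("cross_strain"):
        de_in_summary = [f for f in sig if f in summary_genic.features]
        block = {}
        if len(de_in_summary) >= 3:
            r_de, p_de = expression_metrics.cross_strain_correlation(
                summary_genic, de_in_summary
            )
            block["de_set"] = {"r": r_de, "p": p_de}
        r_all, p_all = expression_metrics.cross_strain_correlation(summary_genic)
        block["all_transcripts"] = {"r": r_all, "p": p_all}
        summary["cross_strain_correlation"] = block

    with stage("gene_sets"):
        block = {}
        focal = sets_by_name.get(config.focal_set)
        if focal and len(focal.members) >= 2:
            matches = geneset_stats.build_match_table(
                summary_genic, focal, k_up=config.k_up, k_down=config.k_down
            )
            perm = geneset_stats.matched_permutation_test(
                summary_genic, matches, focal, n_perm=config.n_perm, seed=config.seed
            )
            perm_joint = geneset_stats.matched_permutation_test(
                summary_genic, matches, focal, n_perm=config.n_perm,
                seed=config.seed, combine="all_strains",
            )
            counts_dir = geneset_stats.direction_count(summary_genic, focal)
            ct, chi2, p_top = geneset_stats.topk_enrichment(de, focal)
            block[config.focal_set] = {
                "observed_mean_log2_ratio": perm.observed,
                "permutation_p": perm.p,
                "permutation_p_raw": perm.p_raw,
                "permutation_p_all_strains": perm_joint.p,
                "n_perm": perm.n_perm,
                "direction_counts": counts_dir.to_dict(orient="index"),
                "top_decile": {
                    "table": [[ct.a, ct.b], [ct.c, ct.d]], "chi2": chi2, "p": p_top,
                },
            }
        for name in (config.eggshell_set, *config.directional_sets):
            gs = sets_by_name.get(name)
            if not gs or not gs.members:
                continue
            counts_dir = geneset_stats.direction_count(summary_genic, gs)
            entry = {"direction_counts": counts_dir.to_dict(orient="index"), "sign_test": {}}
            for strain in strains:
                n_up, n_down, _ = counts_dir.loc[strain]
                if n_up + n_down > 0:
                    entry["sign_test"][strain] = geneset_stats.sign_test(
                        int(n_down), int(n_up + n_down)
                    )
            block[name] = entry
        summary["gene_set_tests"] = block

    with stage("positional"):
        genic_ann = annotation.loc[annotation.index.intersection(genic)]
        het_flags = positional_enrichment.flag_compartment(genic_ann, domains)
        dot_flags = pd.Series(
            genic_ann["chromosome"].astype(str) == str(config.dot_chromosome),
            index=genic_ann.index,
        )
        block = {}
        for label, flags in (("heterochromatin", het_flags), ("dot_chromosome", dot_flags)):
            table = positional_enrichment.build_de_compartment_table(de, flags)
            entry = {"table": [[table.a, table.b], [table.c, table.d]]}
            try:
                chi2, dof, p = positional_enrichment.yates_chi2(table)
                entry.update({"chi2": chi2, "df": dof, "p": p})
            except ValidationError as exc:
                entry["test"] = f"refused: {exc}"
            block[label] = entry
        shift = {}
        for strain in strains:
            t, p, diff = positional_enrichment.compartment_shift_test(
                summary_genic, het_flags, strain
            )
            shift[strain] = {"t": t, "p": p, "mean_difference": diff}
        block["heterochromatin_shift_test"] = shift
        summary["positional_enrichment"] = block
        flag_bed = genic_ann[["chromosome", "start", "end"]].copy()
        flag_bed["name"] = [
            f"{g}|het={int(h)}|dot={int(d)}"
            for g, h, d in zip(genic_ann.index, het_flags, dot_flags)
        ]
        write_results(outdir / "compartment_flags.tsv", flag_bed)

    with stage("te"):
        te_features = counts.feature_kind[counts.feature_kind == "te_family"].index
        block = {}
        if len(te_features) >= 3:
            te_summary = expression_metrics.summarize_expression(
                rpkm_matrix.loc[te_features], design, offset=config.offset
            )
            for strain in strains:
                t, p = te_aging.te_global_test(te_summary, strain)
                block.setdefault("global_paired_t", {})[strain] = {"t": t, "p": p}
            r, p = te_aging.te_cross_strain_correlation(te_summary)
            block["cross_strain"] = {"r": r, "p": p}
            fam = te_aging.te_family_tests(
                counts, design, annotation, fdr=config.fdr, offset=config.offset
            )
            write_results(outdir / "te_family_results.tsv", fam)
            block["n_families"] = int(len(fam))
            block["n_age_significant"] = int(fam["significant"].sum())
            block["n_interaction_significant"] = int(
                (fam["padj_interaction"] < config.fdr).sum()
            )
        summary["te"] = block

    with stage("stage_verification"):
        block = {}
        if profiles is not None:
            shared = profiles.index.intersection(rpkm_matrix.index)
            if len(shared) >= 3:
                for sample in counts.samples:
                    vec = np.log2(rpkm_matrix.loc[shared, sample] + config.offset)
                    assign = expression_metrics.verify_stage(vec, profiles)
                    block[sample] = {
                        "stage": assign.stage,
                        "r": assign.correlations,
                        "low_confidence": assign.low_confidence,
                    }
        summary["stage_verification"] = block

    with stage("report"):
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=_jsonable)
        with open(outdir / "run_log.txt", "w") as fh:
            fh.write("stage\tseconds\n")
            fh.write("\n".join(timings) + "\n")
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
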