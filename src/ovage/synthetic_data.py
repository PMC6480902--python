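"""Synthetic stage-14 egg chamber RNA-seq datasets with known ground truth.

The generator emulates the structure of a two-strain (DGRP Ral_321 /
Ral_237), two-age (3-4 d vs 32-34 d post-eclosion) bulk RNA-seq design with
3-4 pooled-egg-chamber replicates per cell: negative-binomial counts for
~14k genic features, a mitochondrial-genome set, ~125 TE families, a
heterochromatin compartment covering a configurable fraction of genes, a
small "dot" (4th) chromosome, coordinated log2 age effects injected into
named gene sets (piRNA machinery up; mitochondrial / electron-transport
chain down; eggshell down with strain asymmetry), oogenic-stage reference
profiles, and a ground-truth table for recovery tests.

Counts for feature i in sample j are drawn NB with

    mu_ij = L_j * p_i * 2^(strain_offset_i + age_effect_i[strain_j] * old_j)

where L_j is a log-normal library size, p_i a relative abundance
proportional to expression level x gene length, and Var = mu + alpha mu^2
with a single genome-wide dispersion alpha.  A fixed seed determines every
byte of the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    CountMatrix,
    GeneSet,
    SampleDesign,
    annotation_to_bed,
    write_bed,
    write_counts,
    write_design,
    write_gff3,
    write_gmt,
    write_results,
)


class ConfigurationError(ValueError):
    """Simulation configuration violates an invariant."""


#: chromosome arm sizes (bp), roughly the D. melanogaster karyotype
CHROMOSOMES = {
    "2L": 23_500_000,
    "2R": 25_300_000,
    "3L": 28_100_000,
    "3R": 32_100_000,
    "X": 23_500_000,
}
DOT_CHROMOSOME = "4"
DOT_CHROM_SIZE = 1_350_000
MITO_CHROMOSOME = "mito"

MITO_GENES = (
    "mt:CoI", "mt:CoII", "mt:CoIII", "mt:ATPase6", "mt:ATPase8", "mt:Cyt-b",
    "mt:ND1", "mt:ND2", "mt:ND3", "mt:ND4", "mt:ND4L", "mt:ND5", "mt:ND6",
    "mt:lrRNA", "mt:srRNA",
)

TE_FAMILY_NAMES = (
    "copia", "gypsy", "297", "Tirant", "P-element", "pogo", "Juan", "roo",
    "blood", "Doc", "jockey", "I-element", "hobo", "412", "1731", "mdg1",
    "mdg3", "17.6", "Burdock", "F-element", "G-element", "HeT-A", "TART",
    "Idefix", "ZAM", "accord", "Bari1", "S-element", "Tc1", "Max",
    "springer", "diver", "invader1", "Quasimodo", "rover", "Stalker",
    "transpac", "opus", "McClintock", "Tabor",
)

STAGES = ("9-10a", "10b", "12", "14")


@dataclass
class GeneSetEffect:
    """Size and per-strain log2 age effect of one simulated gene set."""

    size: int
    age_effect: float | Mapping[str, float]
    kind: str = "gene"
    description: str = ""

    def effect_for(self, strain: str) -> float:
        if isinstance(self.age_effect, Mapping):
            return float(self.age_effect[strain])
        return float(self.age_effect)


def default_gene_sets() -> dict[str, GeneSetEffect]:
    """The focal sets of the ovarian-aging design.

    piRNA machinery (31 genes): mild coordinated up-shift with age in both
    strains.  Mitochondrial-genome transcripts: down, stronger in Ral_321.
    Nuclear electron-transport-chain genes: down in both strains.  Eggshell
    / chorion genes (the 49-gene stage panel): down with strong strain
    asymmetry.
    """
    return {
        "pirna": GeneSetEffect(31, 0.4, description="piRNA pathway machinery"),
        "mito_genome": GeneSetEffect(
            len(MITO_GENES), {"Ral_321": -0.6, "Ral_237": -0.3}, kind="mito",
            description="mitochondrial genome transcripts",
        ),
        "etc": GeneSetEffect(40, -0.3, description="nuclear electron transport chain"),
        "eggshell": GeneSetEffect(
            49, {"Ral_321": -0.8, "Ral_237": -0.25},
            description="eggshell / chorion assembly",
        ),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults follow the study design: 14,289 genic features of which 1,695
    sit in heterochromatin and 84 on the dot chromosome, two strains with 4
    and 3 replicates per age, and set sizes/effects from
    :func:`default_gene_sets`.  Library depth and dispersion are free
    parameters of the generator (the source design does not report them);
    defaults are typical for pooled-tissue bulk RNA-seq on inbred lines.
    """

    n_genes: int = 14_289
    n_te_families: int = 125
    strains: tuple[str, ...] = ("Ral_321", "Ral_237")
    ages: tuple[str, str] = ("young", "old")
    replicates_per_cell: int | Mapping[str, int] = field(
        default_factory=lambda: {"Ral_321": 4, "Ral_237": 3}
    )
    baseline_log_mean: float = 2.0  # log2 RPKM-like expression level
    baseline_log_sd: float = 2.0
    nb_dispersion: float = 0.05
    library_size_mean: float = 15e6
    library_size_cv: float = 0.2
    strain_effect_sd: float = 0.25  # per-gene log2 strain offset
    gene_sets: dict[str, GeneSetEffect] = field(default_factory=default_gene_sets)
    te_age_effect: float = 0.0  # global log2 shift of all TE families with age
    te_family_effects: dict[str, float | Mapping[str, float]] = field(default_factory=dict)
    het_fraction: float = 1_695 / 14_289
    dot_gene_count: int = 84
    gene_length_meanlog_kb: float = 0.5  # log-normal, ~1.6 kb median
    gene_length_sdlog: float = 0.6
    min_gene_length_kb: float = 0.2
    seed: int = 0

    def replicates_for(self, strain: str) -> int:
        if isinstance(self.replicates_per_cell, Mapping):
            return int(self.replicates_per_cell[strain])
        return int(self.replicates_per_cell)

    def validate(self) -> None:
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.n_genes < 10:
            raise ConfigurationError("n_genes must be >= 10")
        if self.n_te_families < 0:
            raise ConfigurationError("n_te_families must be >= 0")
        for strain in self.strains:
            if self.replicates_for(strain) < 2:
                raise ConfigurationError(f"strain {strain!r} has < 2 replicates per cell")
        if not 0 <= self.het_fraction < 1:
            raise ConfigurationError("het_fraction must be in [0, 1)")
        if self.dot_gene_count < 0 or self.dot_gene_count > self.n_genes:
            raise ConfigurationError("dot_gene_count out of range")
        if self.library_size_mean <= 0 or self.library_size_cv < 0:
            raise ConfigurationError("invalid library size parameters")
        n_in_sets = sum(s.size for s in self.gene_sets.values())
        if n_in_sets > self.n_genes // 2:
            raise ConfigurationError("gene sets cover more than half the genes")
        for name, spec in self.gene_sets.items():
            eff = spec.age_effect
            values = eff.values() if isinstance(eff, Mapping) else [eff]
            if not all(np.isfinite(list(values))):
                raise ConfigurationError(f"non-finite effect for set {name!r}")


def null_gene_sets() -> dict[str, GeneSetEffect]:
    """The default set memberships with every age effect zeroed — the global
    null used for calibration studies."""
    return {
        name: GeneSetEffect(s.size, 0.0, kind=s.kind, description=s.description)
        for name, s in default_gene_sets().items()
    }


def emulate_paper_marginals(seed: int = 0, **overrides) -> SimulationConfig:
    """Preset matching the published annotation marginals exactly:
    14,289 genes, 1,695 in heterochromatin, 84 on the dot chromosome,
    4 + 3 replicates per age for Ral_321 / Ral_237."""
    cfg = SimulationConfig(seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SimulationResult:
    counts: CountMatrix
    design: SampleDesign
    annotation: pd.DataFrame  # + het, het_class, dot columns
    domains: pd.DataFrame  # chromosome, start, end, name (pericentric|intercalary)
    gene_sets: list[GeneSet]
    stage_profiles: pd.DataFrame
    truth: pd.DataFrame


def _build_domains(rng: np.random.Generator) -> pd.DataFrame:
    """Heterochromatin blocks: one large pericentric block per arm plus
    dispersed intercalary blocks along the euchromatic span."""
    rows = []
    for chrom, size in CHROMOSOMES.items():
        peri = int(0.12 * size)
        rows.append((chrom, size - peri, size, "pericentric"))
        eu_span = size - peri - 400_000
        n_blocks = 8
        slot = eu_span // n_blocks
        for b in range(n_blocks):
            width = int(rng.integers(150_000, 400_000))
            start = b * slot + int(rng.integers(0, max(slot - width, 1)))
            rows.append((chrom, start, start + width, "intercalary"))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "name"])


def _place_genes(
    rng: np.random.Generator,
    ids: list[str],
    lengths_bp: np.ndarray,
    het_flags: np.ndarray,
    dot_flags: np.ndarray,
    mito_flags: np.ndarray,
    domains: pd.DataFrame,
) -> pd.DataFrame:
    """Assign chromosomes and coordinates so genes land inside (het) or
    outside (non-het) the emitted heterochromatin blocks."""
    chrom_names = list(CHROMOSOMES)
    chrom_sizes = np.array([CHROMOSOMES[c] for c in chrom_names], dtype=float)
    chrom_p = chrom_sizes / chrom_sizes.sum()

    het_blocks = {
        c: domains[(domains["chromosome"] == c)].reset_index(drop=True)
        for c in chrom_names
    }
    gaps: dict[str, list[tuple[int, int]]] = {}
    for c in chrom_names:
        blocks = sorted(zip(het_blocks[c]["start"], het_blocks[c]["end"]))
        prev = 0
        gaps[c] = []
        for s, e in blocks:
            if s - prev > 50_000:
                gaps[c].append((prev, s))
            prev = max(prev, e)
        if CHROMOSOMES[c] - prev > 50_000:
            gaps[c].append((prev, CHROMOSOMES[c]))

    chroms = np.empty(len(ids), dtype=object)
    starts = np.zeros(len(ids), dtype=np.int64)
    ends = np.zeros(len(ids), dtype=np.int64)
    het_class = np.array(["other"] * len(ids), dtype=object)
    mito_cursor = 100
    for i in range(len(ids)):
        length = int(lengths_bp[i])
        if mito_flags[i]:
            chroms[i] = MITO_CHROMOSOME
            length = min(length, 2_000)
            starts[i] = mito_cursor
            ends[i] = mito_cursor + length
            mito_cursor += length + 50
            continue
        if dot_flags[i]:
            chroms[i] = DOT_CHROMOSOME
            starts[i] = int(rng.integers(0, DOT_CHROM_SIZE - length))
            ends[i] = starts[i] + length
            continue
        c = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
        chroms[i] = c
        if het_flags[i]:
            blocks = het_blocks[c]
            widths = (blocks["end"] - blocks["start"]).to_numpy(dtype=float)
            j = int(rng.choice(len(blocks), p=widths / widths.sum()))
            bs, be = int(blocks.loc[j, "start"]), int(blocks.loc[j, "end"])
            length = min(length, be - bs - 2)
            starts[i] = bs + int(rng.integers(0, be - bs - length))
            het_class[i] = blocks.loc[j, "name"]
        else:
            gs = gaps[c]
            spans = np.array([e - s for s, e in gs], dtype=float)
            j = int(rng.choice(len(gs), p=spans / spans.sum()))
            s, e = gs[j]
            length = min(length, e - s - 2)
            starts[i] = s + int(rng.integers(0, e - s - length))
        ends[i] = starts[i] + length
    ann = pd.DataFrame(
        {
            "chromosome": chroms,
            "start": starts,
            "end": ends,
            "strand": rng.choice(["+", "-"], size=len(ids)),
            "length": lengths_bp.astype(np.int64),
            "het": het_flags,
            "het_class": het_class,
            "dot": dot_flags,
        },
        index=pd.Index(ids, name="feature"),
    )
    return ann


def simulate_counts(config: SimulationConfig) -> SimulationResult:
    """Draw one dataset.  See the module docstring for the count model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    strains = list(config.strains)

    # --- feature universe -------------------------------------------------
    set_specs = config.gene_sets
    mito_sets = [n for n, s in set_specs.items() if s.kind == "mito"]
    n_mito = sum(set_specs[n].size for n in mito_sets)
    gene_ids = [f"gene_{i:05d}" for i in range(config.n_genes - n_mito)]
    mito_ids = list(MITO_GENES[:n_mito])
    if len(mito_ids) < n_mito:
        mito_ids += [f"mt:extra{i}" for i in range(n_mito - len(mito_ids))]
    te_ids = [
        TE_FAMILY_NAMES[i] if i < len(TE_FAMILY_NAMES) else f"TE_fam_{i + 1:03d}"
        for i in range(config.n_te_families)
    ]
    all_ids = gene_ids + mito_ids + te_ids
    kinds = pd.Series(
        ["gene"] * len(gene_ids) + ["mito"] * len(mito_ids) + ["te_family"] * len(te_ids),
        index=all_ids,
    )

    # --- set membership (disjoint, drawn from nuclear genes) --------------
    membership: dict[str, list[str]] = {}
    available = np.array(gene_ids)
    rng.shuffle(available)
    cursor = 0
    for name, spec in set_specs.items():
        if spec.kind == "mito":
            membership[name] = mito_ids[: spec.size]
            continue
        membership[name] = list(available[cursor : cursor + spec.size])
        cursor += spec.size
    gene_sets = [
        GeneSet(name, tuple(membership[name]), description=set_specs[name].description)
        for name in set_specs
    ]

    # --- true effects ------------------------------------------------------
    age_effect = {s: pd.Series(0.0, index=all_ids) for s in strains}
    for name, spec in set_specs.items():
        for s in strains:
            age_effect[s].loc[membership[name]] = spec.effect_for(s)
    for s in strains:
        if config.te_age_effect:
            age_effect[s].loc[te_ids] = config.te_age_effect
        for fam, eff in config.te_family_effects.items():
            if fam not in te_ids:
                raise ConfigurationError(f"unknown TE family {fam!r} in te_family_effects")
            age_effect[s].loc[fam] = (
                float(eff[s]) if isinstance(eff, Mapping) else float(eff)
            )
    strain_offset = pd.Series(0.0, index=all_ids)
    if config.strain_effect_sd > 0:
        strain_offset[:] = rng.normal(0.0, config.strain_effect_sd, size=len(all_ids))

    # --- annotation --------------------------------------------------------
    n_nuclear = len(gene_ids)
    n_het = int(round(config.het_fraction * config.n_genes))
    n_dot = config.dot_gene_count
    dot_flags_nuc = np.zeros(n_nuclear, dtype=bool)
    het_flags_nuc = np.zeros(n_nuclear, dtype=bool)
    nuc_order = rng.permutation(n_nuclear)
    dot_flags_nuc[nuc_order[:n_dot]] = True
    het_candidates = nuc_order[n_dot:]
    het_flags_nuc[het_candidates[:n_het]] = True

    lengths_kb = np.exp(
        rng.normal(config.gene_length_meanlog_kb, config.gene_length_sdlog, size=len(all_ids))
    )
    lengths_kb = np.maximum(lengths_kb, config.min_gene_length_kb)
    lengths_kb[len(gene_ids) + len(mito_ids):] = np.maximum(
        np.exp(rng.normal(np.log(5.0), 0.4, size=len(te_ids))), 0.5
    )
    lengths_bp = np.round(lengths_kb * 1000).astype(np.int64)

    het_flags = np.concatenate([het_flags_nuc, np.zeros(len(mito_ids) + len(te_ids), bool)])
    dot_flags = np.concatenate([dot_flags_nuc, np.zeros(len(mito_ids) + len(te_ids), bool)])
    mito_flags = np.concatenate(
        [np.zeros(n_nuclear, bool), np.ones(len(mito_ids), bool), np.zeros(len(te_ids), bool)]
    )
    domains = _build_domains(rng)
    annotation = _place_genes(rng, all_ids, lengths_bp, het_flags, dot_flags, mito_flags, domains)
    # TE families are not genomic loci; mark them on a pseudo-contig
    te_mask = kinds == "te_family"
    annotation.loc[te_mask.to_numpy(), "chromosome"] = "TE_consensus"
    te_cursor = np.cumsum(np.concatenate([[100], lengths_bp[te_mask.to_numpy()][:-1] + 100]))
    annotation.loc[te_mask.to_numpy(), "start"] = te_cursor
    annotation.loc[te_mask.to_numpy(), "end"] = te_cursor + lengths_bp[te_mask.to_numpy()]

    # --- design ------------------------------------------------------------
    rows = []
    for strain in strains:
        for age in config.ages:
            for rep in range(1, config.replicates_for(strain) + 1):
                rows.append((f"{strain}_{age}_{rep}", strain, age, rep))
    design = SampleDesign(pd.DataFrame(rows, columns=["sample", "strain", "age", "replicate"]))
    samples = design.table

    # --- counts ------------------------------------------------------------
    level_log2 = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=len(all_ids))
    # TE families: heavier-tailed family expression
    level_log2[te_mask.to_numpy()] = rng.normal(1.0, 2.5, size=int(te_mask.sum()))
    weight = np.power(2.0, level_log2) * lengths_kb
    rel_abundance = weight / weight.sum()

    sigma2 = np.log(1.0 + config.library_size_cv**2)
    mu_ln = np.log(config.library_size_mean) - sigma2 / 2.0
    lib_sizes = np.exp(rng.normal(mu_ln, np.sqrt(sigma2), size=len(samples)))

    alpha = config.nb_dispersion
    counts = np.zeros((len(all_ids), len(samples)), dtype=np.int64)
    strain_arr = samples["strain"].to_numpy()
    old_arr = (samples["age"] == "old").to_numpy()
    for j in range(len(samples)):
        s = strain_arr[j]
        log2_mult = strain_offset.to_numpy() * (s == strains[-1])
        if old_arr[j]:
            log2_mult = log2_mult + age_effect[s].to_numpy()
        mu = lib_sizes[j] * rel_abundance * np.power(2.0, log2_mult)
        if alpha < 1e-12:
            counts[:, j] = rng.poisson(mu)
        else:
            n_param = 1.0 / alpha
            counts[:, j] = rng.negative_binomial(n_param, n_param / (n_param + mu))
    count_matrix = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(all_ids, name="feature"), columns=samples["sample"]),
        kinds,
    )

    # --- stage profiles -----------------------------------------------------
    panel_set = "eggshell" if "eggshell" in membership else list(set_specs)[0]
    panel = membership[panel_set]
    idx = [all_ids.index(g) for g in panel]
    base_log = np.log2(np.power(2.0, level_log2[idx]) + 0.5)
    profiles = {}
    for stage in STAGES:
        if stage == "14":
            profiles[stage] = base_log + rng.normal(0, 0.15, size=len(panel))
        else:
            profiles[stage] = rng.permutation(base_log) + rng.normal(0, 0.5, size=len(panel))
    stage_profiles = pd.DataFrame(profiles, index=pd.Index(panel, name="feature"))

    # --- truth --------------------------------------------------------------
    sets_col = pd.Series("", index=all_ids)
    for name, members in membership.items():
        for g in members:
            sets_col.loc[g] = (sets_col.loc[g] + ";" + name).lstrip(";")
    truth = pd.DataFrame(
        {
            "kind": kinds,
            "chromosome": annotation["chromosome"],
            "het": annotation["het"],
            "het_class": annotation["het_class"],
            "dot": annotation["dot"],
            "sets": sets_col,
            "strain_offset_log2": strain_offset,
        }
    )
    for s in strains:
        truth[f"log2_age_effect_{s}"] = age_effect[s]
    truth.index.name = "feature"

    return SimulationResult(
        counts=count_matrix,
        design=design,
        annotation=annotation,
        domains=domains,
        gene_sets=gene_sets,
        stage_profiles=stage_profiles,
        truth=truth,
    )


def write_dataset(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write the full bundle as plain-text files a fresh pipeline run can load."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomic = result.annotation[result.annotation["chromosome"] != "TE_consensus"]
    paths = {
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "annotation_gff3": outdir / "annotation.gff3",
        "annotation_bed": outdir / "annotation.bed",
        "domains": outdir / "domains.bed",
        "gene_sets": outdir / "gene_sets.gmt",
        "stage_profiles": outdir / "stage_profiles.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_counts(paths["counts"], result.counts)
    write_design(paths["design"], result.design)
    write_gff3(paths["annotation_gff3"], result.annotation)
    write_bed(paths["annotation_bed"], annotation_to_bed(genomic))
    write_bed(paths["domains"], result.domains)
    write_gmt(paths["gene_sets"], result.gene_sets)
    write_results(paths["stage_profiles"], result.stage_profiles)
    write_results(paths["truth"], result.truth)
    return paths
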