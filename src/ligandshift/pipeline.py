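"""End-to-end orchestration: demo input generation and the full analysis run.

``make_demo`` writes a self-contained synthetic input directory (reference
and variant FASTA, variant table, protein matrix, peptide observations,
AQUA measurements, truth labels, config). ``run_pipeline`` executes the
stages in study order — variant database, proteome differential expression,
repertoire filtering, core-epitope landscapes, binding/motif analysis,
pMHC categorization, targeted quantification — writing one TSV bundle.
Every output carries the configuration hash and seed in a comment header,
and identical configs produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aqua as aqua_mod
from . import categorize as cat_mod
from . import epitopes as epi_mod
from . import motifs as motif_mod
from . import repertoire as rep_mod
from .errors import ConfigError
from .proteome import differential_expression
from .simulate import (GroundTruth, SimulationConfig, default_allele_models,
                       simulate_all, simulate_aqua)
from .variants import (annotate_variant_peptides, build_search_database,
                       build_variant_sequences, read_fasta, variants_from_table,
                       write_database_fasta, write_fasta)

logger = logging.getLogger(__name__)

INPUT_FILES = {
    "reference": "reference.fasta",
    "variant_fasta": "variant.fasta",
    "variant_table": "variant_table.tsv",
    "matrix": "protein_matrix.tsv",
    "observations": "peptide_observations.tsv",
    "aqua": "aqua_measurements.tsv",
    "truth": "truth_labels.tsv",
    "config": "config.yaml",
}

SAMPLE_COLS = [f"{c}_{r}" for c in ("control", "treated") for r in (1, 2, 3)]
CONTROL_SAMPLES = SAMPLE_COLS[:3]
TREATED_SAMPLES = SAMPLE_COLS[3:]


@dataclass
class PipelineConfig:
    """Stage thresholds + paths; the defaults are the analysis defaults."""

    input_dir: str = "demo_inputs"
    output_dir: str = "demo_outputs"
    p_thresh_de: float = 0.01
    fc_thresh_de: float = 1.2  # linear fold-change
    p_thresh_epitope: float = 0.05
    log2fc_thresh_epitope: float = 1.0
    min_bio: int = 3
    min_tech: int = 1
    rank_threshold: float = 0.2
    variance_threshold: float = 0.2
    min_epitope_length_class1: int = 9
    min_epitope_lengths_class2: tuple[int, int] = (9, 13)
    gibbs_k: int = 3
    gibbs_restarts: int = 10
    welch: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("input_dir"), payload.pop("output_dir")
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["min_epitope_lengths_class2"] = list(self.min_epitope_lengths_class2)
        d["simulation"]["protein_length_range"] = list(
            self.simulation.protein_length_range
        )
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "simulation" in d:
            sim = d["simulation"]
            if "protein_length_range" in sim:
                sim["protein_length_range"] = tuple(sim["protein_length_range"])
            d["simulation"] = SimulationConfig(**sim)
        if "min_epitope_lengths_class2" in d:
            d["min_epitope_lengths_class2"] = tuple(d["min_epitope_lengths_class2"])
        return cls(**d)


def write_tsv(df: pd.DataFrame, path, config_hash: str, seed: int,
              index: bool = True) -> None:
    """TSV with a provenance comment header (config hash + seed)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# ligandshift config_sha256={config_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.8g", lineterminator="\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# demo inputs
# ---------------------------------------------------------------------------


def make_demo(outdir, **config_overrides) -> SimulationConfig:
    """Write a ready-to-run synthetic input directory.

    ``config_overrides`` update :class:`SimulationConfig` defaults; invalid
    overrides raise :class:`ConfigError`.
    """
    unknown = set(config_overrides) - set(SimulationConfig.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown simulation overrides: {sorted(unknown)}")
    config = SimulationConfig(**config_overrides)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_all(config)
    truth = study.truth
    h = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    write_fasta(truth.protein_sequences, outdir / INPUT_FILES["reference"])
    write_fasta(truth.variant_sequences, outdir / INPUT_FILES["variant_fasta"])
    write_tsv(study.variant_table, outdir / INPUT_FILES["variant_table"], h,
              config.seed, index=False)
    write_tsv(study.matrix, outdir / INPUT_FILES["matrix"], h, config.seed)
    write_tsv(study.observations, outdir / INPUT_FILES["observations"], h,
              config.seed, index=False)
    aqua_df = simulate_aqua(config, truth, study.observations)
    write_tsv(aqua_df, outdir / INPUT_FILES["aqua"], h, config.seed, index=False)

    labels = pd.DataFrame({
        "sequence": sorted(truth.peptide_mode),
        "mode": [truth.peptide_mode[s] for s in sorted(truth.peptide_mode)],
        "allele": [truth.allele_of_origin.get(s, "") for s in sorted(truth.peptide_mode)],
        "is_variant": [s in truth.variant_peptides for s in sorted(truth.peptide_mode)],
        "is_contaminant": [s in truth.contaminant_class1 for s in sorted(truth.peptide_mode)],
    })
    write_tsv(labels, outdir / INPUT_FILES["truth"], h, config.seed, index=False)
    de = pd.DataFrame(
        sorted(truth.de_proteins.items()), columns=["accession", "true_log2fc"]
    )
    write_tsv(de, outdir / "truth_de_proteins.tsv", h, config.seed, index=False)
    config.to_yaml(outdir / INPUT_FILES["config"])
    return config


# ---------------------------------------------------------------------------
# analysis stages (in-memory, shared by run_pipeline and the CLI)
# ---------------------------------------------------------------------------


def sample_abundance_table(consistent: dict[str, rep_mod.RepertoireSet]) -> pd.DataFrame:
    """Peptide x sample mean-area table from per-condition repertoire sets.

    Columns ``control_1 .. treated_3``; NaN where the peptide was absent.
    Also carries ``protein, start, end``.
    """
    frames = []
    for cond, rset in consistent.items():
        if not len(rset.peptides):
            continue
        sub = rset.peptides[["protein", "start", "end"]].copy()
        for rep in (1, 2, 3):
            sub[f"{cond}_{rep}"] = rset.peptides[f"area_rep_{rep}"]
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=["protein", "start", "end"] + SAMPLE_COLS)
    merged = frames[0]
    for other in frames[1:]:
        merged = merged.combine_first(other)
    for c in SAMPLE_COLS:
        if c not in merged.columns:
            merged[c] = np.nan
    merged.index.name = "sequence"
    return merged[["protein", "start", "end"] + SAMPLE_COLS]


@dataclass
class PipelineResult:
    """In-memory view of everything a full run produced."""

    de_table: pd.DataFrame
    repertoires: dict
    exclusives: dict
    abundance: dict
    cores: dict
    core_diff: dict
    binder_calls: pd.DataFrame
    clusters: list
    categories: dict
    category_summaries: dict
    contamination: pd.DataFrame
    aqua: pd.DataFrame
    variant_flags: pd.DataFrame


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage on the input directory and write the bundle."""
    indir, outdir = Path(cfg.input_dir), Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    seed = cfg.simulation.seed

    reference = read_fasta(indir / INPUT_FILES["reference"])
    variant_table = read_tsv(indir / INPUT_FILES["variant_table"])
    matrix = read_tsv(indir / INPUT_FILES["matrix"], index_col="accession")
    observations = read_tsv(indir / INPUT_FILES["observations"])
    aqua_df = read_tsv(indir / INPUT_FILES["aqua"])

    def save(df, name, index=True):
        write_tsv(df, outdir / name, h, seed, index=index)

    # 1 — variant proteome: target-decoy database + variant peptide flags
    variants, n_skipped = variants_from_table(variant_table)
    database = build_search_database(
        reference, build_variant_sequences(reference, variants)
    )
    write_database_fasta(database, outdir / "search_database.fasta")
    unique_peps = observations.drop_duplicates("sequence")[
        ["sequence", "protein", "start", "end"]
    ].reset_index(drop=True)
    variant_flags = annotate_variant_peptides(unique_peps, database, variants)
    save(variant_flags, "variant_peptide_flags.tsv", index=False)
    logger.info("stage variants: %d variants (%d skipped), %d/%d peptides span one",
                len(variants), n_skipped, int(variant_flags["spans_variant"].sum()),
                len(variant_flags))

    # 2 — proteome differential expression
    de_table = differential_expression(
        matrix, p_thresh=cfg.p_thresh_de, fc_thresh=cfg.fc_thresh_de, welch=cfg.welch
    )
    save(de_table, "de_table.tsv")

    # 3 — repertoires per class
    sim = cfg.simulation
    models1, models2 = default_allele_models(sim, with_background=True,
                                             sequences=reference)
    repertoires, exclusives, abundance = {}, {}, {}
    contamination = pd.DataFrame()
    for mhc_class in ("I", "II"):
        per_cond = {}
        for cond in ("control", "treated"):
            obs = observations[
                (observations["mhc_class"] == mhc_class)
                & (observations["condition"] == cond)
            ]
            per_cond[cond] = rep_mod.replicate_consistent_set(
                obs, min_bio=cfg.min_bio, min_tech=cfg.min_tech
            )
        repertoires[mhc_class] = per_cond
        parts = rep_mod.exclusive_sets(per_cond["control"], per_cond["treated"])
        exclusives[mhc_class] = parts
        save(pd.DataFrame(
            [(k, s) for k, seqs in sorted(parts.items()) for s in sorted(seqs)],
            columns=["partition", "sequence"],
        ), f"exclusive_sets_class{mhc_class}.tsv", index=False)
        abundance[mhc_class] = sample_abundance_table(per_cond)
        logger.info("stage repertoire class %s: control=%d treated=%d shared=%d",
                    mhc_class, len(parts["control_only"]), len(parts["treated_only"]),
                    len(parts["shared"]))

    short2 = [s for s in abundance["II"].index if len(s) <= 9]
    contamination = rep_mod.flag_class_crosscontamination(short2, models1, models2)
    save(contamination, "class2_contamination_flags.tsv")

    # 4 — core-epitope landscapes + differential presentation
    cores, core_diff = {}, {}
    runs = [("I", cfg.min_epitope_length_class1)] + [
        ("II", L) for L in cfg.min_epitope_lengths_class2
    ]
    for mhc_class, min_len in runs:
        key = f"{mhc_class}_min{min_len}"
        table = abundance[mhc_class].reset_index()
        found, unresolved = epi_mod.infer_core_epitopes(
            table, min_epitope_length=min_len, sample_cols=SAMPLE_COLS
        )
        if not len(found):
            cores[key] = found
            core_diff[key] = found
            continue
        imputed, _ = epi_mod.impute_missing(found, SAMPLE_COLS)
        diff = epi_mod.differential_presentation(
            imputed, CONTROL_SAMPLES, TREATED_SAMPLES,
            p_thresh=cfg.p_thresh_epitope, log2fc_thresh=cfg.log2fc_thresh_epitope,
            welch=cfg.welch,
        )
        cores[key], core_diff[key] = found, diff
        save(diff, f"core_epitopes_class{key}.tsv", index=False)
        save(unresolved, f"core_unresolved_class{key}.tsv", index=False)
        logger.info("stage epitopes %s: %d cores (%d unresolved peptides)",
                    key, len(found), len(unresolved))

    # 5 — binding calls + motif clusters on class-I cores
    class1_seqs = sorted(abundance["I"].index)
    binder_calls = motif_mod.assign_alleles(class1_seqs, models1, mhc_class="I")
    save(binder_calls, "binder_calls_classI.tsv")
    clusters = []
    nine_mers = sorted({
        c for c in cores.get(f"I_min{cfg.min_epitope_length_class1}", pd.DataFrame())
        .get("core_sequence", pd.Series(dtype=str)) if len(c) == 9
    })
    if len(nine_mers) >= 5 * cfg.gibbs_k:
        clusters = motif_mod.gibbs_cluster(
            nine_mers, k=cfg.gibbs_k, seed=seed, n_restarts=cfg.gibbs_restarts
        )
        report = pd.DataFrame({
            "cluster": range(1, len(clusters) + 1),
            "size": [len(c.members) for c in clusters],
            "kld": [c.kld for c in clusters],
            "members": [";".join(sorted(c.members)) for c in clusters],
        })
        save(report, "motif_clusters_classI.tsv", index=False)
    else:
        logger.info("stage binding: too few 9-mer cores for k=%d clustering",
                    cfg.gibbs_k)

    # 6 — integration: fractional ranks and categorization
    categories, summaries = {}, {}
    for mhc_class in ("I", "II"):
        ab = abundance[mhc_class]
        if not len(ab):
            categories[mhc_class] = pd.DataFrame()
            continue
        profiles = cat_mod.fractional_ranks(ab[SAMPLE_COLS])
        flags = contamination["contaminant"] if mhc_class == "II" else None
        assignments, excluded = cat_mod.categorize_pmhc(
            profiles, ab[["protein", "start", "end"]], de_table,
            set(matrix.index), rank_threshold=cfg.rank_threshold,
            variance_threshold=cfg.variance_threshold, contaminant_flags=flags,
        )
        categories[mhc_class] = assignments
        summaries[mhc_class] = cat_mod.category_summary(assignments)
        save(assignments, f"categories_class{mhc_class}.tsv")
        save(summaries[mhc_class], f"category_summary_class{mhc_class}.tsv", index=False)
        save(excluded, f"categories_excluded_class{mhc_class}.tsv")
        logger.info("stage integration class %s: %d categorized, %d excluded",
                    mhc_class, len(assignments), len(excluded))

    # 7 — targeted AQUA quantification
    aqua_results = aqua_mod.differential_targets(aqua_df, welch=False)
    save(aqua_results, "aqua_differential.tsv")

    return PipelineResult(
        de_table=de_table, repertoires=repertoires, exclusives=exclusives,
        abundance=abundance, cores=cores, core_diff=core_diff,
        binder_calls=binder_calls, clusters=clusters, categories=categories,
        category_summaries=summaries, contamination=contamination,
        aqua=aqua_results, variant_flags=variant_flags,
    )
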