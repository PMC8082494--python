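"""Synthetic proteome + immunopeptidome generator with ground truth.

Emulates the statistical structure of a two-condition (control vs
interferon-gamma) TMT proteome experiment coupled to MHC-I/-II ligandome
measurements of the same cells, at desk scale, together with the labels
needed for parameter-recovery testing:

* protein abundances are log-normal (log2 mean 20, sd 2 — a typical MS
  dynamic range) over six reporter channels (3 control, 3 treated), with a
  planted differentially expressed subset shifted by ``de_log2fc`` in the
  treated group;
* peptides are substrings of the simulated proteins, sampled under
  allele-specific anchor-motif preferences (class I lengths 8-12 with mode
  9; class II 13-25) and a C-terminal cleavage preference;
* ``expression_coupled`` peptides appear in both conditions with MS1 areas
  tracking their protein's per-replicate abundance; ``processing_shifted``
  peptides are drawn from non-DE proteins under a second cleavage
  preference and appear only in the treated condition (a minimal stand-in
  for immunoproteasome induction); ``protein_undetected`` peptides map to
  proteins absent from the proteome matrix;
* observations are emitted per (condition x 3 biological replicates x 3
  technical injections) with per-injection dropout, and a configurable
  fraction of class-I-style 9-mers is injected into the class-II tables as
  a carry-over contamination fixture;
* single-residue protein variants are planted and a subset of emitted
  peptides spans them.

All outputs are a pure function of the configuration (one master seed;
per-stage child seeds derived deterministically).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DependencyError
from . import AMINO_ACIDS
from .motifs import (AlleleModel, DEFAULT_CLASS1_ALLELES, DEFAULT_CLASS2_ALLELES,
                     attach_background, encode_peptide, make_synthetic_allele_models,
                     window_scores)
from .proteome import ALL_CHANNELS, CONTROL_CHANNELS, TREATED_CHANNELS
from .variants import VariantRecord, build_variant_sequences, variants_to_table

MODE_COUPLED = "expression_coupled"
MODE_SHIFTED = "processing_shifted"
MODE_UNDETECTED = "protein_undetected"

#: C-terminal cleavage preferences: constitutive vs "immunoproteasome-like"
CONSTITUTIVE_CTERM = set("LVMIF")
SHIFTED_CTERM = set("FYWK")
CLEAVAGE_BONUS = 1.5

CLASS1_LENGTHS = (8, 9, 10, 11, 12)
CLASS1_LENGTH_PROBS = (0.10, 0.55, 0.18, 0.10, 0.07)
CLASS2_LENGTHS = tuple(range(13, 26))
_w = np.array([max(1.0, 7.0 - abs(l - 15)) for l in CLASS2_LENGTHS])
CLASS2_LENGTH_PROBS = tuple(_w / _w.sum())


@dataclass
class SimulationConfig:
    """All generator knobs; defaults are the package's stated world."""

    n_proteins: int = 2000
    protein_length_range: tuple[int, int] = (150, 500)
    n_de_proteins: int = 60
    de_log2fc: float = 1.5
    channel_noise_sd: float = 0.2
    n_alleles: int = 6
    peptides_per_condition: int = 5000
    frac_processing_shift: float = 0.10
    frac_protein_undetected: float = 0.05
    missingness: float = 0.05
    n_variants: int = 50
    seed: int = 0
    # secondary structure
    abundance_log2_mean: float = 20.0
    abundance_log2_sd: float = 2.0
    peptide_noise_sd: float = 0.15
    injection_noise_sd: float = 0.10
    frac_class1_contamination: float = 0.02
    background_n: int = 10_000

    def __post_init__(self) -> None:
        for name in ("frac_processing_shift", "frac_protein_undetected",
                     "missingness", "frac_class1_contamination"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_proteins", "peptides_per_condition", "n_alleles"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.n_de_proteins < 0 or self.n_variants < 0:
            raise ConfigError("counts must be non-negative")
        if self.de_log2fc < 0:
            raise ConfigError("de_log2fc must be >= 0")
        if self.n_de_proteins > self.n_proteins:
            raise ConfigError(
                f"n_de_proteins ({self.n_de_proteins}) exceeds n_proteins "
                f"({self.n_proteins})"
            )
        lo, hi = self.protein_length_range
        if not 20 <= lo <= hi:
            raise ConfigError("protein_length_range must satisfy 20 <= min <= max")
        if self.frac_processing_shift + self.frac_protein_undetected > 1:
            raise ConfigError("mode fractions sum to more than 1")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["protein_length_range"] = list(self.protein_length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "protein_length_range" in d:
            d["protein_length_range"] = tuple(d["protein_length_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Generator labels used by parameter-recovery tests."""

    de_proteins: dict[str, float] = field(default_factory=dict)  # acc -> signed log2fc
    peptide_mode: dict[str, str] = field(default_factory=dict)
    variant_peptides: set[str] = field(default_factory=set)
    allele_of_origin: dict[str, str] = field(default_factory=dict)
    # plumbing shared between stages
    protein_sequences: dict[str, str] = field(default_factory=dict)
    detected_proteins: set[str] = field(default_factory=set)
    hidden_proteins: set[str] = field(default_factory=set)
    protein_log2: pd.DataFrame | None = None  # acc x (condition_rep) log2 abundance
    variant_records: list = field(default_factory=list)
    variant_sequences: dict[str, str] = field(default_factory=dict)
    contaminant_class1: set[str] = field(default_factory=set)
    class1_models: list = field(default_factory=list)
    class2_models: list = field(default_factory=list)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stage,))
    )


_STAGE_REFERENCE, _STAGE_PROTEOME, _STAGE_VARIANTS = 0, 1, 2
_STAGE_PEPTIDES_I, _STAGE_PEPTIDES_II, _STAGE_MODELS = 3, 4, 5
_STAGE_BACKGROUND, _STAGE_CONTAMINATION, _STAGE_AQUA = 6, 7, 8

SAMPLE_COLS = [f"{c}_{r}" for c in ("control", "treated") for r in (1, 2, 3)]


def simulate_reference(config: SimulationConfig) -> tuple[dict[str, str], set[str], set[str]]:
    """Random protein sequences: detected accessions P####, hidden H####."""
    rng = _rng(config, _STAGE_REFERENCE)
    lo, hi = config.protein_length_range
    n_hidden = (
        max(1, round(0.05 * config.n_proteins))
        if config.frac_protein_undetected > 0 else 0
    )
    aa = np.array(list(AMINO_ACIDS))
    seqs = {}
    for i in range(config.n_proteins + n_hidden):
        acc = f"P{i + 1:05d}" if i < config.n_proteins else f"H{i - config.n_proteins + 1:05d}"
        length = int(rng.integers(lo, hi + 1))
        seqs[acc] = "".join(aa[rng.integers(0, 20, size=length)])
    detected = {a for a in seqs if a.startswith("P")}
    hidden = set(seqs) - detected
    return seqs, detected, hidden


def simulate_proteome(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Six-channel protein quantification matrix plus planted-DE truth.

    Hidden proteins (sources of ``protein_undetected`` peptides) get
    per-replicate abundances in the truth tables but are absent from the
    emitted matrix.
    """
    if truth is None:
        truth = GroundTruth()
    if not truth.protein_sequences:
        seqs, detected, hidden = simulate_reference(config)
        truth.protein_sequences = seqs
        truth.detected_proteins = detected
        truth.hidden_proteins = hidden
    rng = _rng(config, _STAGE_PROTEOME)
    accs = sorted(truth.detected_proteins) + sorted(truth.hidden_proteins)
    n_all = len(accs)
    base = rng.normal(config.abundance_log2_mean, config.abundance_log2_sd, size=n_all)

    detected_sorted = sorted(truth.detected_proteins)
    de_idx = rng.choice(len(detected_sorted), size=config.n_de_proteins, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_de_proteins)
    shift = pd.Series(0.0, index=accs)
    for i, s in zip(de_idx, signs):
        shift[detected_sorted[i]] = s * config.de_log2fc
    truth.de_proteins = {
        detected_sorted[i]: float(s * config.de_log2fc) for i, s in zip(de_idx, signs)
    }

    noise = rng.normal(0.0, config.channel_noise_sd, size=(n_all, 6))
    log2 = np.empty((n_all, 6))
    for j in range(3):
        log2[:, j] = base + noise[:, j]  # control channels
        log2[:, 3 + j] = base + shift.to_numpy() + noise[:, 3 + j]
    truth.protein_log2 = pd.DataFrame(log2, index=accs, columns=SAMPLE_COLS)

    matrix = pd.DataFrame(
        2.0 ** log2[: len(detected_sorted)], index=detected_sorted, columns=ALL_CHANNELS
    )
    matrix.index.name = "accession"
    return matrix, truth


def simulate_variants(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, dict[str, str], GroundTruth]:
    """Plant single-residue substitutions on detected proteins.

    Returns (variant table, variant sequences keyed ``<acc>_var``, truth).
    """
    if not truth.protein_sequences:
        raise DependencyError("simulate the reference proteome first")
    rng = _rng(config, _STAGE_VARIANTS)
    detected = sorted(truth.detected_proteins)
    lengths = np.array([len(truth.protein_sequences[a]) for a in detected])
    if config.n_variants > int(lengths.sum()):
        raise ConfigError(
            f"n_variants ({config.n_variants}) exceeds the {int(lengths.sum())} "
            "mutable positions"
        )
    used: set[tuple[str, int]] = set()
    records: list[VariantRecord] = []
    aa = list(AMINO_ACIDS)
    while len(records) < config.n_variants:
        pi = int(rng.choice(len(detected), p=lengths / lengths.sum()))
        acc = detected[pi]
        pos = int(rng.integers(1, lengths[pi] + 1))
        if (acc, pos) in used:
            continue
        used.add((acc, pos))
        ref = truth.protein_sequences[acc][pos - 1]
        alt = aa[int(rng.integers(0, 20))]
        while alt == ref:
            alt = aa[int(rng.integers(0, 20))]
        records.append(VariantRecord(
            protein_accession=acc, position=pos, ref_aa=ref, alt_aa=alt,
            provenance=str(rng.choice(["exome", "rna", "both"], p=[0.5, 0.3, 0.2])),
            known_snp=bool(rng.random() < 0.3),
            cosmic_flag=bool(rng.random() < 0.05),
        ))
    variant_seqs = build_variant_sequences(truth.protein_sequences, records)
    truth.variant_records = records
    truth.variant_sequences = variant_seqs
    return variants_to_table(records), variant_seqs, truth


def default_allele_models(
    config: SimulationConfig, with_background: bool = False,
    sequences: dict[str, str] | None = None,
) -> tuple[list[AlleleModel], list[AlleleModel]]:
    """The generator's class-I and class-II anchor PWMs (seed-derived)."""
    names1 = list(DEFAULT_CLASS1_ALLELES[: config.n_alleles])
    names1 += [f"HLA-X*{i:02d}:01" for i in range(len(names1) + 1, config.n_alleles + 1)]
    seed1 = int(_rng(config, _STAGE_MODELS).integers(0, 2**31))
    models1 = make_synthetic_allele_models(names1, seed=seed1, anchor_positions=(1, 8))
    models2 = make_synthetic_allele_models(
        list(DEFAULT_CLASS2_ALLELES), seed=seed1 + 1, anchor_positions=(0, 3, 8),
        anchor_weight=2.0, anchors_per_position=3,
    )
    if with_background:
        seqs = sequences or {}
        bg_seed = int(_rng(config, _STAGE_BACKGROUND).integers(0, 2**31))
        for i, m in enumerate(models1 + models2):
            attach_background(m, seqs, n=config.background_n, seed=bg_seed + i)
    return models1, models2


class _CoreSampler:
    """Samples motif- and cleavage-biased core positions within proteins."""

    def __init__(self, truth: GroundTruth):
        self.truth = truth
        self._encoded: dict[str, np.ndarray] = {}
        self._probs: dict[tuple[str, str, bool], np.ndarray] = {}

    def encoded(self, acc: str) -> np.ndarray:
        if acc not in self._encoded:
            self._encoded[acc] = encode_peptide(self.truth.protein_sequences[acc])
        return self._encoded[acc]

    def core_probs(self, acc: str, model: AlleleModel, shifted: bool) -> np.ndarray:
        key = (acc, model.allele_name, shifted)
        if key not in self._probs:
            enc = self.encoded(acc)
            scores = window_scores(model, enc)
            cterm = enc[8: 8 + scores.size]
            pref = SHIFTED_CTERM if shifted else CONSTITUTIVE_CTERM
            pref_idx = np.array([AMINO_ACIDS.index(a) for a in sorted(pref)])
            bonus = np.where(np.isin(cterm, pref_idx), CLEAVAGE_BONUS, 0.0)
            w = np.exp(scores + bonus - (scores + bonus).max())
            self._probs[key] = w / w.sum()
        return self._probs[key]


def simulate_immunopeptidome(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, GroundTruth]:
    """Peptide observation tables for both MHC classes and conditions.

    Emits one row per observed injection with columns
    ``sequence, protein, start, end, condition, bio_rep, tech_rep,
    ms1_area, mhc_class``. Requires :func:`simulate_proteome` first (and
    uses variant sequences when :func:`simulate_variants` ran before it).
    """
    if truth.protein_log2 is None:
        raise DependencyError("simulate the proteome before the immunopeptidome")
    models1, models2 = default_allele_models(config)
    truth.class1_models, truth.class2_models = models1, models2
    sampler = _CoreSampler(truth)
    de_set = set(truth.de_proteins)
    detected = sorted(truth.detected_proteins)
    non_de = [a for a in detected if a not in de_set]
    hidden = sorted(truth.hidden_proteins)
    varied = {a[:-4]: s for a, s in truth.variant_sequences.items()}
    var_positions: dict[str, list[int]] = {}
    for v in truth.variant_records:
        var_positions.setdefault(v.protein_accession, []).append(v.position)
    plog = truth.protein_log2.to_dict("index")  # fast scalar lookups

    rows: list[tuple] = []
    seen: set[str] = set()

    def emit(rng, mhc_class, mode, models, lengths, length_probs) -> None:
        model = models[int(rng.integers(0, len(models)))]
        if mode == MODE_UNDETECTED:
            pool = hidden
        elif mode == MODE_SHIFTED:
            pool = non_de
        else:
            pool = detected
        for _ in range(40):  # resample on length/uniqueness collisions
            acc = pool[int(rng.integers(0, len(pool)))]
            seq = truth.protein_sequences[acc]
            L = len(seq)
            plen = int(rng.choice(lengths, p=length_probs))
            is_variant = False
            if acc in varied and rng.random() < 0.5:
                # deliberately sample a window spanning one of the protein's
                # variant positions, from the variant sequence
                pv = int(rng.choice(var_positions[acc])) - 1  # 0-based
                s_lo, s_hi = max(0, pv - plen + 1), min(pv, L - plen)
                if s_lo > s_hi:
                    continue
                start0 = int(rng.integers(s_lo, s_hi + 1))
                source = varied[acc]
                is_variant = source[start0: start0 + plen] != seq[start0: start0 + plen]
            else:
                probs = sampler.core_probs(acc, model, shifted=(mode == MODE_SHIFTED))
                c = int(rng.choice(probs.size, p=probs))  # 0-based core start
                s_lo, s_hi = max(0, c + 9 - plen), min(c, L - plen)
                if s_lo > s_hi:
                    continue
                start0 = int(rng.integers(s_lo, s_hi + 1))
                source = seq
            pep = source[start0: start0 + plen]
            if pep in seen:
                continue
            seen.add(pep)
            truth.peptide_mode[pep] = mode
            truth.allele_of_origin[pep] = model.allele_name
            if is_variant:
                truth.variant_peptides.add(pep)
            efficiency = rng.normal(0.0, 1.0)
            conditions = ("treated",) if mode == MODE_SHIFTED else ("control", "treated")
            for cond in conditions:
                for rep in (1, 2, 3):
                    rep_log2 = (
                        plog[acc][f"{cond}_{rep}"]
                        + efficiency + rng.normal(0.0, config.peptide_noise_sd)
                    )
                    for tech in (1, 2, 3):
                        if rng.random() < config.missingness:
                            continue
                        area = 2.0 ** (rep_log2 + rng.normal(0.0, config.injection_noise_sd))
                        rows.append((pep, acc, start0 + 1, start0 + plen, cond,
                                     rep, tech, area, mhc_class))
            return

    p_modes = np.array([
        config.frac_processing_shift, config.frac_protein_undetected,
        1.0 - config.frac_processing_shift - config.frac_protein_undetected,
    ])
    for mhc_class, stage, models, lengths, lprobs in (
        ("I", _STAGE_PEPTIDES_I, models1, CLASS1_LENGTHS, CLASS1_LENGTH_PROBS),
        ("II", _STAGE_PEPTIDES_II, models2, CLASS2_LENGTHS, CLASS2_LENGTH_PROBS),
    ):
        rng = _rng(config, stage)
        for _ in range(config.peptides_per_condition):
            mode = (MODE_SHIFTED, MODE_UNDETECTED, MODE_COUPLED)[
                int(rng.choice(3, p=p_modes))
            ]
            if mode == MODE_UNDETECTED and not hidden:
                mode = MODE_COUPLED
            emit(rng, mhc_class, mode, models, list(lengths), list(lprobs))

    # class-I carry-over into the class-II tables
    rng = _rng(config, _STAGE_CONTAMINATION)
    n_cont = round(config.frac_class1_contamination * config.peptides_per_condition)
    before = set(seen)
    for _ in range(n_cont):
        emit(rng, "II", MODE_COUPLED, models1, [9], [1.0])
    truth.contaminant_class1 = seen - before

    obs = pd.DataFrame(rows, columns=[
        "sequence", "protein", "start", "end", "condition", "bio_rep",
        "tech_rep", "ms1_area", "mhc_class",
    ])
    return obs, truth


def simulate_aqua(
    config: SimulationConfig,
    truth: GroundTruth,
    observations: pd.DataFrame,
    n_class1: int = 25,
    n_class2: int = 5,
    spike_fmol: float = 250.0,
) -> pd.DataFrame:
    """Heavy-standard (AQUA) measurement table for a SNP/neoantigen panel.

    The panel mirrors the targeted design: 25 class-I peptides (variant
    peptides first — the SNP/neoantigen candidates) and 5 class-II, spiked
    into two of the three biological replicates per condition, three
    injections each. Light areas follow the peptide's simulated per-sample
    abundance (a noise-floor area when it was not presented), heavy areas
    are the spiked standard with injection-level noise.
    """
    rng = _rng(config, _STAGE_AQUA)
    panel: list[str] = []
    for mhc_class, n_panel in (("I", n_class1), ("II", n_class2)):
        seqs = sorted(set(observations.loc[observations["mhc_class"] == mhc_class, "sequence"]))
        variant_first = sorted(s for s in seqs if s in truth.variant_peptides)
        others = [s for s in seqs if s not in truth.variant_peptides]
        chosen = (variant_first + others)[:n_panel]
        panel.extend(chosen)

    area = (
        observations.groupby(["sequence", "condition", "bio_rep"])["ms1_area"]
        .mean()
        .to_dict()
    )
    heavy_base = 2.0 ** 20
    floor = 2.0 ** 10
    rows = []
    for pep in panel:
        for cond in ("control", "treated"):
            for rep in (1, 2):  # only two replicates were spiked
                light_mean = area.get((pep, cond, rep), floor)
                for tech in (1, 2, 3):
                    light = light_mean * 2.0 ** rng.normal(0.0, config.injection_noise_sd)
                    heavy = heavy_base * 2.0 ** rng.normal(0.0, config.injection_noise_sd)
                    rows.append((pep, cond, rep, tech, light, heavy, spike_fmol))
    return pd.DataFrame(rows, columns=[
        "peptide", "condition", "bio_rep", "tech_rep",
        "light_area", "heavy_area", "spike_amount",
    ])


@dataclass
class SimulatedStudy:
    """Bundle of everything one simulated experiment produces."""

    config: SimulationConfig
    matrix: pd.DataFrame
    observations: pd.DataFrame
    variant_table: pd.DataFrame
    truth: GroundTruth


def simulate_all(config: SimulationConfig) -> SimulatedStudy:
    """Reference -> proteome -> variants -> immunopeptidome, one call."""
    matrix, truth = simulate_proteome(config)
    if config.n_variants > 0:
        variant_table, _, truth = simulate_variants(config, truth)
    else:
        variant_table = variants_to_table([])
    observations, truth = simulate_immunopeptidome(config, truth)
    return SimulatedStudy(config, matrix, observations, variant_table, truth)
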