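"""Allele-specific binding models, percentile ranks and motif clustering.

External neural-network binding predictors are replaced by an internal
position-weight-matrix (PWM) scorer with NetMHC-style percentile-rank
semantics: a peptide's score is compared against the score distribution of
random proteome 9-mers, and the rank is the percentage of background
peptides scoring strictly better (lower rank = stronger predicted binding).
An adapter accepting externally computed rank tables in the same schema can
be substituted without code change downstream.

Motif discovery is a simplified Gibbs clusterer: single-sequence
reassignment moves maximizing the size-weighted sum of per-cluster
Kullback-Leibler divergences (bits) from background, best of several
random restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import AMINO_ACIDS
from .errors import AlphabetError, ConfigError, DataError

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: class-I rank thresholds (percentile): strong < 0.500, weak < 2.000
STRONG_RANK_I = 0.500
WEAK_RANK_I = 2.000
#: class-II binder threshold (percentile): binder < 10
BINDER_RANK_II = 10.0


def encode_peptide(peptide: str) -> np.ndarray:
    """Encode a peptide as integer indices into the 20-letter alphabet."""
    try:
        return np.array([AA_INDEX[a] for a in peptide], dtype=np.int64)
    except KeyError as exc:
        raise AlphabetError(
            f"residue {exc.args[0]!r} in {peptide!r} is not a standard amino acid"
        ) from exc


@dataclass
class AlleleModel:
    """A per-allele log-odds PWM plus its empirical background score distribution.

    Parameters
    ----------
    allele_name:
        e.g. ``"HLA-A*02:01"``. The HLA locus is the letter following
        ``HLA-`` and is used by the repertoire locus-bias test.
    pwm:
        ``(core_length, 20)`` log-odds matrix over ``AMINO_ACIDS`` order.
    core_length:
        binding-core length (9 for both classes here).
    length_penalty:
        score penalty per residue of deviation from ``core_length``
        (class-I bulged/short ligands); 0 disables it.
    background_scores:
        sorted scores of random proteome 9-mers; set by
        :func:`attach_background`.
    """

    allele_name: str
    pwm: np.ndarray
    core_length: int = 9
    length_penalty: float = 0.0
    background_scores: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.shape != (self.core_length, 20):
            raise ConfigError(
                f"pwm for {self.allele_name} must be ({self.core_length}, 20), "
                f"got {self.pwm.shape}"
            )

    @property
    def locus(self) -> str:
        name = self.allele_name
        if name.startswith("HLA-"):
            name = name[4:]
        for sep in ("*", ":"):
            if sep in name:
                name = name.split(sep)[0]
        # class II loci are multi-letter (DRB1); class I single-letter (A/B/C)
        return name[:1] if len(name) <= 2 else name


def window_scores(model: AlleleModel, encoded: np.ndarray) -> np.ndarray:
    """Score of every core-length window of an encoded sequence (positional sums)."""
    L = model.core_length
    n = encoded.size - L + 1
    if n < 1:
        raise DataError(f"sequence shorter than core length {L}")
    scores = np.zeros(n)
    for j in range(L):
        scores += model.pwm[j, encoded[j : j + n]]
    return scores


def score_peptide(model: AlleleModel, peptide: str) -> float:
    """Log-odds score of a peptide: best core window, minus the length penalty.

    Peptides one residue shorter than the core are scored by deleting the
    single PWM position that maximizes the remaining sum (a bulged-PWM
    alignment); longer peptides use the best sliding window.
    """
    enc = encode_peptide(peptide)
    L = model.core_length
    n = enc.size
    if n >= L:
        best = float(window_scores(model, enc).max())
    elif n == L - 1:
        per_pos = model.pwm[np.arange(L)[:, None], enc[None, :]]  # (L, n) lookup
        best = -np.inf
        for d in range(L):
            rows = np.delete(np.arange(L), d)
            best = max(best, float(per_pos[rows, np.arange(n)].sum()))
    else:
        raise DataError(
            f"peptide length {n} below minimum {L - 1} for core length {L}"
        )
    return best - model.length_penalty * abs(n - L)


def attach_background(
    model: AlleleModel,
    sequences: dict[str, str] | list[str],
    n: int = 10_000,
    seed: int = 0,
) -> AlleleModel:
    """Sample ``n`` random proteome 9-mers, score them and attach sorted scores."""
    seqs = list(sequences.values()) if isinstance(sequences, dict) else list(sequences)
    pool = [s for s in seqs if len(s) >= model.core_length]
    if not pool:
        raise ConfigError("no sequence long enough to sample background 9-mers")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(s) for s in pool])
    picks = rng.choice(len(pool), size=n, p=lengths / lengths.sum())
    scores = np.empty(n)
    L = model.core_length
    for i, pi in enumerate(picks):
        s = pool[pi]
        start = rng.integers(0, len(s) - L + 1)
        scores[i] = float(window_scores(model, encode_peptide(s[start : start + L]))[0])
    model.background_scores = np.sort(scores)
    return model


def percentile_rank(score: float, model: AlleleModel) -> float:
    """Percentage of background scores strictly greater than ``score`` (in [0, 100])."""
    bg = model.background_scores
    if bg is None or bg.size == 0:
        raise ConfigError(f"model {model.allele_name} has no background scores")
    n_greater = bg.size - np.searchsorted(bg, score, side="right")
    return 100.0 * n_greater / bg.size


def peptide_rank(model: AlleleModel, peptide: str) -> float:
    return percentile_rank(score_peptide(model, peptide), model)


def rank_table(peptides: list[str], models: list[AlleleModel]) -> pd.DataFrame:
    """Percentile rank of every peptide against every allele model."""
    if not models:
        raise ConfigError("no allele models supplied")
    data = {
        m.allele_name: [peptide_rank(m, p) for p in peptides] for m in models
    }
    return pd.DataFrame(data, index=pd.Index(peptides, name="peptide"))


def assign_alleles(
    peptides: list[str],
    models: list[AlleleModel],
    mhc_class: str = "I",
    rank_overrides: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Best-allele assignment with the class-specific rank thresholds.

    Class I: strong binder rank < 0.500, weak binder rank < 2.000, else
    non-binder. Class II: binder rank < 10. Exact rank ties below the
    class-I reporting threshold (2.000) are reported for all tied alleles.
    ``rank_overrides`` (peptide x allele percentile ranks) substitutes
    externally computed predictions for the internal scorer.

    Returns a DataFrame indexed by peptide with columns
    ``best_rank``, ``alleles`` (semicolon-joined, sorted), ``binder_class``.
    """
    ranks = rank_overrides if rank_overrides is not None else rank_table(peptides, models)
    ranks = ranks.loc[peptides]
    out = []
    for pep, row in ranks.iterrows():
        best = float(row.min())
        tied = sorted(row.index[row == best])
        if mhc_class == "I":
            if best < STRONG_RANK_I:
                cls = "strong"
            elif best < WEAK_RANK_I:
                cls = "weak"
            else:
                cls = "non_binder"
            reported = tied if best < WEAK_RANK_I else tied[:1]
        elif mhc_class == "II":
            cls = "binder" if best < BINDER_RANK_II else "non_binder"
            reported = tied if best < BINDER_RANK_II else tied[:1]
        else:
            raise ConfigError(f"unknown MHC class {mhc_class!r}")
        out.append((pep, best, ";".join(reported), cls))
    return pd.DataFrame(
        out, columns=["peptide", "best_rank", "alleles", "binder_class"]
    ).set_index("peptide")


# ---------------------------------------------------------------------------
# Gibbs motif clustering
# ---------------------------------------------------------------------------


@dataclass
class MotifCluster:
    """One motif: member peptides, position probability matrix, KLD in bits."""

    members: list[str]
    pssm: np.ndarray  # (L, 20) probabilities
    kld: float


def _cluster_stats(
    counts: np.ndarray, sizes: np.ndarray, log2q: np.ndarray, pseudocount: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster PSSM and KLD from residue counts.

    counts: (k, L, 20); sizes: (k,). Pseudocount is added per residue per
    position before normalization, so each position's denominator is
    ``n + 20 * pseudocount``.
    """
    denom = (sizes + 20.0 * pseudocount)[:, None, None]
    p = (counts + pseudocount) / denom
    kld = (p * (np.log2(p) - log2q[None, None, :])).sum(axis=(1, 2))
    return p, kld


def cluster_kld(
    peptides: list[str],
    background_freqs: np.ndarray | None = None,
    pseudocount: float = 0.05,
) -> float:
    """KLD (bits, summed over positions) of one fixed-length peptide set."""
    X = np.stack([encode_peptide(p) for p in peptides])
    L = X.shape[1]
    counts = np.zeros((1, L, 20))
    for j in range(L):
        np.add.at(counts[0, j], X[:, j], 1.0)
    q = np.full(20, 0.05) if background_freqs is None else np.asarray(background_freqs)
    _, kld = _cluster_stats(counts, np.array([float(len(peptides))]), np.log2(q), pseudocount)
    return float(kld[0])


def gibbs_cluster(
    cores: list[str],
    k: int,
    seed: int = 0,
    n_restarts: int = 50,
    n_sweeps: int = 30,
    pseudocount: float = 0.05,
    background_freqs: np.ndarray | None = None,
    temperature: float = 0.25,
) -> list[MotifCluster]:
    """Partition fixed-length cores into ``k`` motif clusters by Gibbs sampling.

    The objective is the size-weighted total KLD,
    ``sum_c n_c * KLD(cluster_c || background)``; moves are single-sequence
    reassignments sampled at a fixed temperature, with a final greedy sweep;
    the best-of-restarts partition is returned. Deterministic given
    ``seed``. Clusters are sorted by decreasing size, KLD as tie-break.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    n = len(cores)
    if n < 5 * k:
        raise ConfigError(f"need at least {5 * k} cores for k={k}, got {n}")
    lengths = {len(c) for c in cores}
    if len(lengths) != 1:
        raise ConfigError(f"cores must all have the same length, got {sorted(lengths)}")
    L = lengths.pop()
    X = np.stack([encode_peptide(c) for c in cores])
    onehot = np.zeros((n, L, 20))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], X] = 1.0
    q = np.full(20, 0.05) if background_freqs is None else np.asarray(background_freqs, float)
    log2q = np.log2(q)

    def objective_terms(counts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
        _, kld = _cluster_stats(counts, sizes, log2q, pseudocount)
        return sizes * kld

    rng = np.random.default_rng(seed)
    best_obj, best_assign = -np.inf, None
    if k == 1:
        best_assign = np.zeros(n, dtype=int)
    else:
        for _ in range(n_restarts):
            assign = rng.integers(0, k, size=n)
            counts = np.zeros((k, L, 20))
            for c in range(k):
                counts[c] = onehot[assign == c].sum(axis=0)
            sizes = np.bincount(assign, minlength=k).astype(float)
            terms = objective_terms(counts, sizes)
            for sweep in range(n_sweeps + 1):
                greedy = sweep == n_sweeps
                for i in rng.permutation(n):
                    c0 = assign[i]
                    counts[c0] -= onehot[i]
                    sizes[c0] -= 1.0
                    base = objective_terms(counts, sizes)
                    cand = objective_terms(counts + onehot[i][None], sizes + 1.0)
                    # total objective if i joins cluster c: the other clusters'
                    # terms are unchanged, c's term becomes cand[c]
                    gains = base.sum() - base + cand
                    if greedy:
                        c1 = int(np.argmax(gains))
                    else:
                        w = np.exp((gains - gains.max()) / temperature)
                        c1 = int(rng.choice(k, p=w / w.sum()))
                    assign[i] = c1
                    counts[c1] += onehot[i]
                    sizes[c1] += 1.0
                terms = objective_terms(counts, sizes)
            obj = float(terms.sum())
            if obj > best_obj:
                best_obj, best_assign = obj, assign.copy()

    counts = np.zeros((k, L, 20))
    for c in range(k):
        counts[c] = onehot[best_assign == c].sum(axis=0)
    sizes = np.bincount(best_assign, minlength=k).astype(float)
    pssm, kld = _cluster_stats(counts, np.maximum(sizes, 1e-12), log2q, pseudocount)
    clusters = [
        MotifCluster(
            members=[cores[i] for i in np.flatnonzero(best_assign == c)],
            pssm=pssm[c],
            kld=float(kld[c]),
        )
        for c in range(k)
    ]
    clusters.sort(key=lambda m: (-len(m.members), -m.kld))
    return clusters


# ---------------------------------------------------------------------------
# Synthetic allele models (shared with the data generator)
# ---------------------------------------------------------------------------

#: the study cell line's six class-I alleles
DEFAULT_CLASS1_ALLELES = (
    "HLA-A*02:01",
    "HLA-A*02:05",
    "HLA-B*07:02",
    "HLA-B*50:01",
    "HLA-C*06:02",
    "HLA-C*07:02",
)
DEFAULT_CLASS2_ALLELES = ("HLA-DRB1*04:01", "HLA-DRB1*15:01")


def make_synthetic_allele_models(
    allele_names: list[str] | tuple[str, ...],
    seed: int,
    anchor_positions: tuple[int, ...] = (1, 8),
    anchor_weight: float = 3.0,
    anchors_per_position: int = 2,
) -> list[AlleleModel]:
    """Anchor-style synthetic PWMs: strong log-odds at anchor positions.

    Each allele prefers ``anchors_per_position`` residues (drawn at random,
    distinct across alleles where possible) at each 0-based anchor position
    of the 9-mer core; all other cells are 0. A minimal stand-in for real
    class-I anchor motifs (P2 / C-terminus).
    """
    rng = np.random.default_rng(seed)
    models = []
    for name in allele_names:
        pwm = np.zeros((9, 20))
        for pos in anchor_positions:
            favored = rng.choice(20, size=anchors_per_position, replace=False)
            pwm[pos, favored] = anchor_weight
            pwm[pos, np.setdiff1d(np.arange(20), favored)] = -0.5
        models.append(AlleleModel(allele_name=name, pwm=pwm))
    return models


def write_pssm(model: AlleleModel, path) -> None:
    """Write a PWM/PSSM as a position x residue TSV."""
    df = pd.DataFrame(model.pwm, columns=list(AMINO_ACIDS))
    df.index = pd.RangeIndex(1, model.core_length + 1, name="position")
    df.to_csv(path, sep="\t")


def read_pssm(path, allele_name: str) -> AlleleModel:
    df = pd.read_csv(path, sep="\t", index_col="position")
    return AlleleModel(allele_name=allele_name, pwm=df[list(AMINO_ACIDS)].to_numpy())
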