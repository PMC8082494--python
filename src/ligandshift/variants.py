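"""Variant protein construction, target-decoy databases, variant peptide flags.

Variant protein sequences are built by substituting the annotated alternate
residue at each annotated position (missense only; other consequence classes
are counted and skipped, never silently dropped). The search database is a
target-decoy FASTA: wild-type + variant + contaminant targets plus the exact
reversal of every target. A presented peptide *spans* a variant if its
interval covers an annotated position and it carries the alternate residue
there; it is *variant-exclusive* (a SNP/neoantigen candidate) if in addition
its sequence occurs in no wild-type target — the criterion that singles out
candidates like the tapasin neoantigen ALGPPPFGL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, CoordinateError, ReferenceMismatchError, UnmappedPeptideError

logger = logging.getLogger(__name__)

#: consequence classes other than missense are parsed but skipped
SUPPORTED_CONSEQUENCE = "missense"


@dataclass(frozen=True)
class VariantRecord:
    """One protein-level single-residue substitution."""

    protein_accession: str
    position: int  # 1-based residue index
    ref_aa: str
    alt_aa: str
    provenance: str = "exome"  # {exome, rna, both}
    known_snp: bool = False
    cosmic_flag: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CoordinateError(f"variant position must be >= 1, got {self.position}")
        if self.ref_aa == self.alt_aa:
            raise ConfigError(
                f"variant at {self.protein_accession}:{self.position} has ref == alt"
            )


def apply_variants(
    sequence: str, variants: list[VariantRecord], check_ref: bool = True
) -> str:
    """Substitute alternate residues at each variant position.

    With ``check_ref`` (default) the wild-type residue at each position must
    equal the record's reference residue; a mismatch raises
    :class:`ReferenceMismatchError` naming the protein and position.
    """
    residues = list(sequence)
    for v in variants:
        if v.position > len(sequence):
            raise CoordinateError(
                f"variant position {v.position} beyond {v.protein_accession} "
                f"length {len(sequence)}"
            )
        if check_ref and residues[v.position - 1] != v.ref_aa:
            raise ReferenceMismatchError(
                f"{v.protein_accession} position {v.position}: expected "
                f"{v.ref_aa!r}, sequence has {residues[v.position - 1]!r}"
            )
        residues[v.position - 1] = v.alt_aa
    return "".join(residues)


def diff_variants(wildtype: str, varied: str, accession: str = "?") -> list[VariantRecord]:
    """Recover the substitution set by per-position diff (the inverse of
    :func:`apply_variants` for substitution-only edits)."""
    if len(wildtype) != len(varied):
        raise CoordinateError("sequences differ in length; not substitution-only")
    return [
        VariantRecord(accession, i + 1, w, v)
        for i, (w, v) in enumerate(zip(wildtype, varied))
        if w != v
    ]


def build_variant_sequences(
    wildtype: dict[str, str], variants: list[VariantRecord]
) -> dict[str, str]:
    """One variant sequence per protein carrying all its substitutions.

    Returns a dict keyed ``<accession>_var``. Variants for unknown proteins
    raise; consequence filtering happens upstream.
    """
    by_protein: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_protein.setdefault(v.protein_accession, []).append(v)
    out = {}
    for acc, vs in by_protein.items():
        if acc not in wildtype:
            raise UnmappedPeptideError(f"variant references unknown protein {acc}")
        out[f"{acc}_var"] = apply_variants(wildtype[acc], vs)
    return out


@dataclass
class SearchDatabase:
    """Target-decoy database: targets (wildtype/variant/contaminant) + reversals."""

    target_entries: list[tuple[str, str, str]]  # (accession, sequence, class)
    decoy_entries: list[tuple[str, str, str]] = field(default_factory=list)
    palindromic_targets: list[str] = field(default_factory=list)

    @property
    def wildtype_sequences(self) -> dict[str, str]:
        return {a: s for a, s, c in self.target_entries if c == "wildtype"}


DECOY_PREFIX = "rev_"


def build_search_database(
    wildtype: dict[str, str],
    variant_sequences: dict[str, str] | None = None,
    contaminants: dict[str, str] | None = None,
) -> SearchDatabase:
    """Assemble targets and their full-sequence-reversal decoys.

    Palindromic targets (decoy identical to target) are flagged in
    ``palindromic_targets`` and logged — they cannot contribute to FDR
    estimation. A duplicated accession after decoy tagging raises.
    """
    targets: list[tuple[str, str, str]] = []
    for acc, seq in wildtype.items():
        targets.append((acc, seq, "wildtype"))
    for acc, seq in (variant_sequences or {}).items():
        targets.append((acc, seq, "variant"))
    for acc, seq in (contaminants or {}).items():
        targets.append((acc, seq, "contaminant"))

    decoys = [(DECOY_PREFIX + acc, seq[::-1], cls) for acc, seq, cls in targets]
    all_accs = [a for a, _, _ in targets] + [a for a, _, _ in decoys]
    if len(set(all_accs)) != len(all_accs):
        dupes = sorted({a for a in all_accs if all_accs.count(a) > 1})
        raise ConfigError(f"accession collision after decoy tagging: {dupes}")

    palindromes = [acc for acc, seq, _ in targets if seq == seq[::-1]]
    if palindromes:
        logger.warning(
            "%d palindromic target(s) whose decoy equals the target: %s",
            len(palindromes), ", ".join(palindromes),
        )
    return SearchDatabase(targets, decoys, palindromes)


def annotate_variant_peptides(
    peptides: pd.DataFrame,
    database: SearchDatabase,
    variants: list[VariantRecord],
) -> pd.DataFrame:
    """Flag peptides that span a variant and those exclusive to the variant space.

    ``peptides`` needs columns ``sequence``, ``protein``, ``start``, ``end``
    (1-based inclusive coordinates on the source protein). ``spans_variant``
    is true when the interval covers a variant position of its protein and
    the peptide carries the alternate residue at the corresponding offset;
    ``variant_exclusive`` additionally requires the sequence to be a
    substring of no wild-type target entry. Peptides whose protein (or its
    ``_var`` counterpart) is absent from the database raise.
    """
    required = {"sequence", "protein", "start", "end"}
    if not required.issubset(peptides.columns):
        raise ConfigError(f"peptide table must have columns {sorted(required)}")
    known = {acc for acc, _, _ in database.target_entries}
    wt_seqs = list(database.wildtype_sequences.values())
    by_protein: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_protein.setdefault(v.protein_accession, []).append(v)

    spans, exclusive = [], []
    for row in peptides.itertuples(index=False):
        base_acc = row.protein[:-4] if str(row.protein).endswith("_var") else row.protein
        if row.protein not in known and base_acc not in known and f"{base_acc}_var" not in known:
            raise UnmappedPeptideError(f"peptide {row.sequence} maps to unknown entry {row.protein}")
        hit = False
        for v in by_protein.get(base_acc, []):
            if row.start <= v.position <= row.end:
                offset = v.position - row.start
                if row.sequence[offset] == v.alt_aa:
                    hit = True
                    break
        spans.append(hit)
        exclusive.append(hit and not any(row.sequence in s for s in wt_seqs))
    out = peptides.copy()
    out["spans_variant"] = spans
    out["variant_exclusive"] = exclusive
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

VARIANT_TABLE_COLUMNS = ["protein", "pos", "ref_aa", "alt_aa", "provenance",
                         "known_snp", "cosmic_flag", "consequence"]


def variants_to_table(variants: list[VariantRecord]) -> pd.DataFrame:
    rows = [
        (v.protein_accession, v.position, v.ref_aa, v.alt_aa, v.provenance,
         v.known_snp, v.cosmic_flag, SUPPORTED_CONSEQUENCE)
        for v in variants
    ]
    return pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS)


def variants_from_table(table: pd.DataFrame) -> tuple[list[VariantRecord], int]:
    """Parse a variant table; returns (missense records, skipped-count).

    Non-missense consequence classes (frameshift, stop gain, in-frame indel)
    are counted and logged, not silently dropped.
    """
    records, skipped = [], 0
    has_consequence = "consequence" in table.columns
    for row in table.itertuples(index=False):
        if has_consequence and str(row.consequence) != SUPPORTED_CONSEQUENCE:
            skipped += 1
            continue
        records.append(
            VariantRecord(
                protein_accession=str(row.protein),
                position=int(row.pos),
                ref_aa=str(row.ref_aa),
                alt_aa=str(row.alt_aa),
                provenance=str(getattr(row, "provenance", "exome")),
                known_snp=bool(getattr(row, "known_snp", False)),
                cosmic_flag=bool(getattr(row, "cosmic_flag", False)),
            )
        )
    if skipped:
        logger.info("skipped %d non-%s variant(s)", skipped, SUPPORTED_CONSEQUENCE)
    return records, skipped


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=a, description="") for a, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_database_fasta(database: SearchDatabase, path) -> None:
    seqs = {acc: seq for acc, seq, _ in database.target_entries}
    seqs.update({acc: seq for acc, seq, _ in database.decoy_entries})
    write_fasta(seqs, path)
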