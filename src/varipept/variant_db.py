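"""Variant-extended protein database construction.

Applies single-nucleotide variants to transcript cDNA, translates the main
open reading frame (mORF), generates mass-preserving pseudo-reversed decoys,
digests in silico with trypsin, and labels peptides as canonical, variant,
shared or decoy. Variants are supplied as a flat table in transcript cDNA
coordinates (1-based) together with the transcript sequences and annotated
mORF bounds; only common variants (minor allele frequency above a threshold,
default 1%) are applied.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DECOY_PREFIX = "DECOY_"
DEFAULT_MAF_THRESHOLD = 0.01
DEFAULT_MIN_LEN = 8
DEFAULT_MAX_LEN = 40
DEFAULT_MAX_MISSED = 2


class RefMismatchError(ValueError):
    """The variant's stated reference allele disagrees with the cDNA."""


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    cdna: str
    morf_start: int  # 1-based inclusive
    morf_end: int  # 1-based inclusive

    def __post_init__(self):
        if not 1 <= self.morf_start <= self.morf_end <= len(self.cdna):
            raise ValueError(
                f"{self.transcript_id}: mORF {self.morf_start}-{self.morf_end} "
                f"outside cDNA of length {len(self.cdna)}"
            )
        if (self.morf_end - self.morf_start + 1) % 3:
            raise ValueError(f"{self.transcript_id}: mORF length not a multiple of 3")


@dataclass(frozen=True)
class VariantRecord:
    transcript_id: str
    cdna_pos: int  # 1-based
    ref: str
    alt: str
    maf: float

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"{self.transcript_id}:{self.cdna_pos} ref == alt")
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError("maf must be in [0, 1]")


@dataclass(frozen=True)
class VariantProteinEntry:
    accession: str
    sequence: str
    is_decoy: bool = False
    origin: str = "canonical"  # canonical | variant | contaminant
    source_variant: Optional[VariantRecord] = None


@dataclass
class PeptideEntry:
    sequence: str
    missed_cleavages: int
    proteins: List[str] = field(default_factory=list)
    label: str = "canonical"  # canonical | variant | shared | decoy


def translate_morf(t: TranscriptRecord, cdna: Optional[str] = None) -> str:
    """Translate the mORF of ``cdna`` (default: the transcript's own) with
    the standard genetic code, truncating at the first stop codon."""
    seq = (cdna if cdna is not None else t.cdna)[t.morf_start - 1 : t.morf_end]
    protein = str(Seq(seq).translate())
    stop = protein.find("*")
    return protein if stop < 0 else protein[:stop]


def apply_variant(
    t: TranscriptRecord,
    v: VariantRecord,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
) -> Optional[VariantProteinEntry]:
    """Apply a single-nucleotide substitution and translate the mORF.

    Returns ``None`` when the variant is below the MAF threshold, lies
    outside the mORF, is synonymous at the protein level, or stops
    translation before the first codon completes. A premature stop truncates
    the protein at the stop.
    """
    if v.transcript_id != t.transcript_id:
        raise ValueError("variant and transcript ids disagree")
    if not 1 <= v.cdna_pos <= len(t.cdna):
        raise RefMismatchError(
            f"{t.transcript_id}: position {v.cdna_pos} outside cDNA"
        )
    if t.cdna[v.cdna_pos - 1] != v.ref:
        raise RefMismatchError(
            f"{t.transcript_id}:{v.cdna_pos} expected ref {v.ref!r}, "
            f"cDNA has {t.cdna[v.cdna_pos - 1]!r}"
        )
    if v.maf <= maf_threshold:
        return None
    if not t.morf_start <= v.cdna_pos <= t.morf_end:
        return None
    mutated = t.cdna[: v.cdna_pos - 1] + v.alt + t.cdna[v.cdna_pos :]
    canonical = translate_morf(t)
    protein = translate_morf(t, mutated)
    if not protein or protein == canonical:
        return None
    accession = f"{t.transcript_id}:{v.cdna_pos}{v.ref}>{v.alt}"
    return VariantProteinEntry(
        accession=accession,
        sequence=protein,
        is_decoy=False,
        origin="variant",
        source_variant=v,
    )


def cleavage_sites(sequence: str) -> List[int]:
    """Tryptic cleavage positions: after K/R, suppressed before P.

    Returned positions are 0-based indices *between* residues, i.e. ``i``
    means a cut between ``sequence[i-1]`` and ``sequence[i]``.
    """
    return [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in "KR" and sequence[i] != "P"
    ]


def digest(
    sequence: str,
    max_missed: int = DEFAULT_MAX_MISSED,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> List[PeptideEntry]:
    """In-silico tryptic digestion with missed cleavages and length filter.

    Peptides are maximal tryptic fragments and concatenations of up to
    ``max_missed`` adjacent fragments; the length filter is applied last.
    """
    if max_missed < 0 or not 1 <= min_len <= max_len:
        raise ValueError("invalid digestion parameters")
    if not sequence:
        return []
    bounds = [0] + cleavage_sites(sequence) + [len(sequence)]
    out: List[PeptideEntry] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for missed in range(0, max_missed + 1):
            j = i + missed + 1
            if j > n_frag:
                break
            pep = sequence[bounds[i] : bounds[j]]
            if min_len <= len(pep) <= max_len:
                out.append(PeptideEntry(pep, missed))
    return out


def _pseudo_reverse(sequence: str, rng: Optional[np.random.Generator] = None) -> str:
    """Pseudo-reverse a protein, preserving its tryptic structure.

    Within every fully cleaved tryptic fragment, K, R and P residues stay
    in place and the remaining residues are reversed (or shuffled, when an
    ``rng`` is supplied for collision resolution). Because all residues that
    define cleavage sites keep their positions, re-digestion of the decoy
    yields fragments with exactly the residue composition (hence mass) of
    the target's fragments.
    """
    bounds = [0] + cleavage_sites(sequence) + [len(sequence)]
    pieces: List[str] = []
    for a, b in zip(bounds, bounds[1:]):
        frag = list(sequence[a:b])
        free = [i for i, aa in enumerate(frag) if aa not in "KRP"]
        residues = [frag[i] for i in free]
        if rng is None:
            residues = residues[::-1]
        else:
            residues = [residues[k] for k in rng.permutation(len(residues))]
        for i, aa in zip(free, residues):
            frag[i] = aa
        pieces.append("".join(frag))
    return "".join(pieces)


def make_decoys(
    entries: Sequence[VariantProteinEntry],
    max_shuffle_iter: int = 20,
    digestion_kwargs: Optional[dict] = None,
    seed: int = 0,
) -> List[VariantProteinEntry]:
    """Generate one mass-preserving pseudo-reversed decoy per target.

    Decoy peptides colliding with any target peptide are re-shuffled
    (residues internal to the colliding fragment) up to ``max_shuffle_iter``
    times; remaining collisions are logged and kept.
    """
    kwargs = dict(min_len=1, max_len=10**9, max_missed=0)
    if digestion_kwargs:
        kwargs.update(digestion_kwargs)
    target_peptides: Set[str] = set()
    for e in entries:
        if e.is_decoy:
            raise ValueError("make_decoys expects target entries")
        target_peptides.update(p.sequence for p in digest(e.sequence, **kwargs))
    rng = np.random.default_rng(seed)
    decoys: List[VariantProteinEntry] = []
    for e in entries:
        decoy_seq = _pseudo_reverse(e.sequence)
        for _ in range(max_shuffle_iter):
            collisions = [
                p.sequence
                for p in digest(decoy_seq, **kwargs)
                if p.sequence in target_peptides
            ]
            if not collisions:
                break
            decoy_seq = _pseudo_reverse(decoy_seq, rng=rng)
        else:
            remaining = [
                p.sequence
                for p in digest(decoy_seq, **kwargs)
                if p.sequence in target_peptides
            ]
            if remaining:
                logger.warning(
                    "decoy for %s keeps %d target-identical peptides",
                    e.accession,
                    len(remaining),
                )
        decoys.append(
            VariantProteinEntry(
                accession=DECOY_PREFIX + e.accession,
                sequence=decoy_seq,
                is_decoy=True,
                origin=e.origin,
                source_variant=e.source_variant,
            )
        )
    return decoys


def build_peptide_index(
    entries: Sequence[VariantProteinEntry],
    max_missed: int = DEFAULT_MAX_MISSED,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> Dict[str, PeptideEntry]:
    """Digest every entry and index peptides by sequence with provenance."""
    index: Dict[str, PeptideEntry] = {}
    for e in entries:
        for pep in digest(e.sequence, max_missed, min_len, max_len):
            entry = index.get(pep.sequence)
            if entry is None:
                entry = PeptideEntry(pep.sequence, pep.missed_cleavages)
                index[pep.sequence] = entry
            entry.missed_cleavages = min(entry.missed_cleavages, pep.missed_cleavages)
            if e.accession not in entry.proteins:
                entry.proteins.append(e.accession)
    return index


def label_peptides(
    target_index: Dict[str, PeptideEntry],
    canonical_peptides: Set[str],
    entries_by_accession: Dict[str, VariantProteinEntry],
) -> Dict[str, PeptideEntry]:
    """Assign canonical / variant / decoy labels at the sequence level.

    A peptide equal to any canonical-database peptide is canonical even if
    it is also reachable through a variant entry; a peptide reachable only
    through variant entries is a variant peptide; peptides found only in
    decoy entries are decoys.
    """
    for seq, entry in target_index.items():
        parents = [entries_by_accession[a] for a in entry.proteins]
        non_decoy = [p for p in parents if not p.is_decoy]
        if not non_decoy:
            entry.label = "decoy"
        elif seq in canonical_peptides:
            entry.label = "canonical"
        elif all(p.origin == "variant" for p in non_decoy):
            entry.label = "variant"
        else:
            entry.label = "canonical"
    return target_index


# ---------------------------------------------------------------------------
# Table and FASTA I/O


def read_fasta(path) -> List[VariantProteinEntry]:
    """Read a protein FASTA; accession is the first whitespace token."""
    from Bio import SeqIO

    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        entries.append(
            VariantProteinEntry(
                accession=acc,
                sequence=str(rec.seq),
                is_decoy=acc.startswith(DECOY_PREFIX),
            )
        )
    return entries


def write_fasta(entries: Iterable[VariantProteinEntry], path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.accession}\n")
            for i in range(0, len(e.sequence), 60):
                fh.write(e.sequence[i : i + 60] + "\n")


def read_transcripts(fasta_path, morf_tsv_path) -> List[TranscriptRecord]:
    """Transcript cDNA FASTA plus a TSV of mORF bounds
    (columns: transcript_id, morf_start, morf_end; 1-based inclusive).
    Transcripts without an annotated mORF are skipped with a warning."""
    from Bio import SeqIO

    bounds: Dict[str, Tuple[int, int]] = {}
    with open(morf_tsv_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            bounds[row["transcript_id"]] = (int(row["morf_start"]), int(row["morf_end"]))
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in bounds:
            logger.warning("transcript %s has no annotated mORF; skipped", rec.id)
            continue
        start, end = bounds[rec.id]
        out.append(TranscriptRecord(rec.id, str(rec.seq).upper(), start, end))
    return out


def read_variants(path) -> List[VariantRecord]:
    """TSV with header: transcript_id, cdna_pos, ref, alt, maf."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                VariantRecord(
                    row["transcript_id"],
                    int(row["cdna_pos"]),
                    row["ref"],
                    row["alt"],
                    float(row["maf"]),
                )
            )
    return out


def write_peptide_index(index: Dict[str, PeptideEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tmissed_cleavages\tlabel\tproteins\n")
        for seq in sorted(index):
            e = index[seq]
            fh.write(f"{seq}\t{e.missed_cleavages}\t{e.label}\t{';'.join(e.proteins)}\n")


def read_peptide_index(path) -> Dict[str, PeptideEntry]:
    index: Dict[str, PeptideEntry] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            index[row["sequence"]] = PeptideEntry(
                row["sequence"],
                int(row["missed_cleavages"]),
                row["proteins"].split(";") if row["proteins"] else [],
                row["label"],
            )
    return index


@dataclass
class DatabaseBuild:
    entries: List[VariantProteinEntry]  # targets + decoys
    peptide_index: Dict[str, PeptideEntry]


def build_database(
    canonical: Sequence[VariantProteinEntry],
    transcripts: Sequence[TranscriptRecord],
    variants: Sequence[VariantRecord],
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    max_missed: int = DEFAULT_MAX_MISSED,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    decoy_seed: int = 0,
) -> DatabaseBuild:
    """Full build: canonical + variant targets, decoys, labeled peptide index."""
    by_id = {t.transcript_id: t for t in transcripts}
    variant_entries: List[VariantProteinEntry] = []
    for v in variants:
        t = by_id.get(v.transcript_id)
        if t is None:
            logger.warning("variant on unknown transcript %s; skipped", v.transcript_id)
            continue
        entry = apply_variant(t, v, maf_threshold)
        if entry is not None:
            variant_entries.append(entry)
    targets = list(canonical) + variant_entries
    digestion = dict(max_missed=max_missed, min_len=min_len, max_len=max_len)
    decoys = make_decoys(targets, digestion_kwargs=digestion, seed=decoy_seed)
    entries = targets + decoys
    index = build_peptide_index(entries, max_missed, min_len, max_len)
    canonical_set = {
        p.sequence
        for e in canonical
        for p in digest(e.sequence, max_missed, min_len, max_len)
    }
    label_peptides(index, canonical_set, {e.accession: e for e in entries})
    return DatabaseBuild(entries=entries, peptide_index=index)
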