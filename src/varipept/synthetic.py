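"""Synthetic proteogenomic fixtures.

Generates, from a single seed, everything the pipeline consumes: a random
tryptic-friendly proteome with transcripts and mORF annotations, common
missense variants, an MS2 spectrum per PSM (surrogate-predicted b/y peaks
with multiplicative log-normal intensity noise, m/z jitter and uniform
chemical-noise peaks), MS1 scans carrying a triangular extracted-ion
chromatogram around every true elution time, a search-engine-style PSM
table of controlled correctness, and a truth table.

"True" PSMs pair a spectrum generated from a peptide with that same
peptide; "random" PSMs assign the spectrum of one peptide to a different
(target or decoy) peptide whose theoretical precursor m/z is recorded,
within the search tolerance, as the spectrum's precursor — emulating the
random high-scoring competitors a search engine produces. Engine scores are
drawn from two overlapping normal distributions so that the engine alone
separates correct from incorrect matches only partially.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from varipept import chem, variant_db
from varipept.predictors import surrogate_fragments, surrogate_rt
from varipept.spectra_io import (
    PSMRecord,
    SpectrumRecord,
    write_mgf,
    write_mzml,
    write_psm_table,
)

logger = logging.getLogger(__name__)

# engine-score model: correct and incorrect PSMs overlap partially
TRUE_SCORE_MEAN = 2.5
RANDOM_SCORE_MEAN = 0.0
SCORE_SD = 1.0

# chromatography emulation
GRADIENT_START_S = 150.0
GRADIENT_SPAN_S = 1500.0
MS1_INTERVAL_S = 3.0
XIC_HALF_WIDTH_S = 30.0
XIC_APEX_INTENSITY = 1e6

_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}
_CODON_TABLE = {
    codon: aa
    for aa, codon in _CODON.items()
}


@dataclass(frozen=True)
class SimConfig:
    n_proteins: int = 30
    protein_length_range: Tuple[int, int] = (100, 160)
    n_variants: int = 30
    variant_maf_range: Tuple[float, float] = (0.05, 0.5)
    n_true_psms: int = 400
    n_random_psms: int = 200
    fraction_variant_true: float = 0.15
    rt_noise_sd: float = 5.0  # seconds
    intensity_noise_cv: float = 0.2
    n_noise_peaks: int = 40
    ppm_jitter_sd: float = 3.0
    peak_dropout: float = 0.15
    planted_match_prob: float = 0.35
    planted_match_frac: Tuple[float, float] = (0.1, 0.8)
    hard_true_frac: float = 0.3
    hard_dropout_range: Tuple[float, float] = (0.4, 0.8)
    hard_score_mean: float = 0.8
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_proteins,
            self.n_variants,
            self.n_true_psms,
            self.n_random_psms,
            self.n_noise_peaks,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        if not 0.0 <= self.fraction_variant_true <= 1.0:
            raise ValueError("fraction_variant_true must be in [0, 1]")


@dataclass
class SimOutput:
    config: SimConfig
    transcripts: List[variant_db.TranscriptRecord]
    variants: List[variant_db.VariantRecord]
    canonical: List[variant_db.VariantProteinEntry]
    db: variant_db.DatabaseBuild
    psms: List[PSMRecord]
    ms2: List[SpectrumRecord]
    ms1: List[SpectrumRecord]
    truth: List[Dict]
    paths: Dict[str, Path] = field(default_factory=dict)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    # segments of plain residues ending in K/R give tryptic peptides that
    # mostly fall into the 8-40 residue search window
    plain = "ACDEFGHILMNQSTVWY"  # no K/R (sites) and no P (suppression)
    parts = ["M"]
    total = 1
    while total < length:
        seg = rng.integers(6, 12)
        body = "".join(rng.choice(list(plain), size=seg))
        site = "K" if rng.random() < 0.5 else "R"
        parts.append(body + site)
        total += seg + 1
    return "".join(parts)


def _reverse_translate(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein)


def _make_transcripts(
    rng: np.random.Generator, cfg: SimConfig
) -> Tuple[List[variant_db.TranscriptRecord], List[variant_db.VariantProteinEntry]]:
    transcripts, canonical = [], []
    lo, hi = cfg.protein_length_range
    for i in range(cfg.n_proteins):
        protein = _random_protein(rng, int(rng.integers(lo, hi + 1)))
        utr5 = "".join(rng.choice(list("ACGT"), size=9))
        utr3 = "".join(rng.choice(list("ACGT"), size=6))
        cds = _reverse_translate(protein) + "TAA"
        cdna = utr5 + cds + utr3
        tid = f"TR{i:04d}"
        transcripts.append(
            variant_db.TranscriptRecord(tid, cdna, len(utr5) + 1, len(utr5) + len(cds))
        )
        canonical.append(
            variant_db.VariantProteinEntry(accession=f"PROT{i:04d}", sequence=protein)
        )
    return transcripts, canonical


def _make_variants(
    rng: np.random.Generator,
    cfg: SimConfig,
    transcripts: Sequence[variant_db.TranscriptRecord],
) -> List[variant_db.VariantRecord]:
    variants: List[variant_db.VariantRecord] = []
    lo, hi = cfg.variant_maf_range
    for _ in range(cfg.n_variants):
        for _attempt in range(100):
            t = transcripts[rng.integers(len(transcripts))]
            protein_len = (t.morf_end - t.morf_start + 1) // 3 - 1  # minus stop
            pos_aa = int(rng.integers(1, protein_len))  # skip the initial M
            codon_start = t.morf_start + 3 * pos_aa
            offset = int(rng.integers(3))
            cdna_pos = codon_start + offset
            ref = t.cdna[cdna_pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            codon = list(t.cdna[codon_start - 1 : codon_start + 2])
            old_aa = _CODON_TABLE.get("".join(codon))
            codon[offset] = alt
            new_aa = _CODON_TABLE.get("".join(codon))
            if new_aa is None or new_aa == old_aa:
                continue  # stop-gain or synonymous: resample
            maf = float(rng.uniform(lo, hi))
            variants.append(variant_db.VariantRecord(t.transcript_id, cdna_pos, ref, alt, maf))
            break
        else:
            warnings.warn("could not place a missense variant after 100 attempts")
    return variants


def _noisy_spectrum(
    rng: np.random.Generator,
    cfg: SimConfig,
    peptide: str,
    charge: int,
    planted_from: Optional[str] = None,
    dropout: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Fragment spectrum of ``peptide`` with noise.

    ``dropout`` is the per-peak detection failure probability (default:
    ``cfg.peak_dropout``). ``planted_from`` names another peptide whose
    predicted ion m/z values are partially planted into the spectrum (with
    uncorrelated intensities). This emulates the incorrect matches a search
    engine actually reports: random competitors share a handful of fragment
    m/z values with the spectrum, otherwise the engine would never have
    scored them.
    """
    pred = surrogate_fragments(peptide, charge)
    mz = np.array([ion.mz for ion in pred.ions])
    inten = np.array([ion.intensity for ion in pred.ions])
    if dropout is None:
        dropout = cfg.peak_dropout
    if dropout > 0:
        keep = rng.random(mz.size) >= dropout
        if keep.any():
            mz, inten = mz[keep], inten[keep]
    if planted_from is not None:
        other = surrogate_fragments(planted_from, charge)
        omz = np.array([ion.mz for ion in other.ions])
        frac = rng.uniform(*cfg.planted_match_frac)
        n_plant = max(int(frac * omz.size), 1)
        chosen = rng.choice(omz.size, size=n_plant, replace=False)
        planted_int = rng.uniform(0.5, 2.0, n_plant) * float(np.median(inten))
        mz = np.concatenate([mz, omz[chosen]])
        inten = np.concatenate([inten, planted_int])
    if cfg.ppm_jitter_sd > 0:
        mz = mz * (1.0 + rng.normal(0.0, cfg.ppm_jitter_sd, mz.size) * 1e-6)
    if cfg.intensity_noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + cfg.intensity_noise_cv**2))
        inten = inten * rng.lognormal(0.0, sigma, inten.size)
    if cfg.n_noise_peaks > 0:
        noise_mz = rng.uniform(200.0, float(mz.max()) * 1.1, cfg.n_noise_peaks)
        noise_int = rng.uniform(0.0, 2.0 * float(np.median(inten)), cfg.n_noise_peaks)
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, noise_int])
    order = np.argsort(mz, kind="stable")
    return mz[order], inten[order]


def _charge_for(rng: np.random.Generator, peptide: str) -> int:
    return 2 if len(peptide) <= 12 or rng.random() < 0.5 else 3


def simulate(cfg: SimConfig, out_dir: Optional[Path] = None) -> SimOutput:
    """Generate a complete synthetic run; identical seeds give identical
    outputs. When ``out_dir`` is given, all artifacts are also written to
    the standard file formats."""
    rng = np.random.default_rng(cfg.seed)
    transcripts, canonical = _make_transcripts(rng, cfg)
    variants = _make_variants(rng, cfg, transcripts)
    db = variant_db.build_database(
        canonical, transcripts, variants, decoy_seed=int(rng.integers(2**31))
    )

    index = db.peptide_index
    canonical_pool = sorted(s for s, e in index.items() if e.label == "canonical")
    variant_pool = sorted(s for s, e in index.items() if e.label == "variant")
    decoy_pool = sorted(s for s, e in index.items() if e.label == "decoy")
    target_pool = canonical_pool + variant_pool
    if not target_pool:
        raise ValueError("simulation produced no target peptides")

    # linear map from the surrogate's hydrophobicity scale onto the gradient
    surr = {p: surrogate_rt(p).rt_predicted for p in target_pool + decoy_pool}
    lo, hi = min(surr.values()), max(surr.values())
    span = hi - lo if hi > lo else 1.0

    def true_rt(peptide: str) -> float:
        return GRADIENT_START_S + (surr[peptide] - lo) / span * GRADIENT_SPAN_S

    n_variant_true = round(cfg.fraction_variant_true * cfg.n_true_psms)
    if variant_pool == [] and n_variant_true > 0:
        warnings.warn("no variant peptides available; variant PSMs replaced by canonical")
        n_variant_true = 0

    psms: List[PSMRecord] = []
    ms2: List[SpectrumRecord] = []
    truth: List[Dict] = []
    xic_targets: List[Tuple[float, float]] = []  # (precursor theo m/z, apex rt)
    scan = 0

    def add_psm(matched_peptide, spectrum_peptide, correct):
        nonlocal scan
        scan += 1
        sid = f"scan={scan}"
        charge = _charge_for(rng, matched_peptide)
        planted = None
        dropout = None
        score_mean = RANDOM_SCORE_MEAN
        if correct:
            score_mean = TRUE_SCORE_MEAN
            # a share of correct PSMs is "hard": few detected fragments and
            # a weak engine score, the population predictor agreement rescues
            if rng.random() < cfg.hard_true_frac:
                dropout = float(rng.uniform(*cfg.hard_dropout_range))
                score_mean = cfg.hard_score_mean
        elif rng.random() < cfg.planted_match_prob:
            planted = matched_peptide
        mz_arr, int_arr = _noisy_spectrum(
            rng, cfg, spectrum_peptide, charge, planted_from=planted, dropout=dropout
        )
        theo = chem.precursor_mz(matched_peptide, charge)
        measured = theo * (1.0 + rng.normal(0.0, cfg.ppm_jitter_sd) * 1e-6)
        rt = true_rt(spectrum_peptide) + rng.normal(0.0, cfg.rt_noise_sd)
        rt = max(rt, 0.0)
        entry = index[matched_peptide]
        psms.append(
            PSMRecord(
                spectrum_id=sid,
                peptide=matched_peptide,
                modifications=(),
                charge=charge,
                engine_score=float(rng.normal(score_mean, SCORE_SD)),
                precursor_mz_measured=measured,
                rank=1,
                is_decoy=entry.label == "decoy",
                label=entry.label,
                prev_aa="K",
                next_aa="A" if entry.label != "decoy" else "G",
                proteins=tuple(entry.proteins),
            )
        )
        ms2.append(
            SpectrumRecord(
                spectrum_id=sid,
                ms_level=2,
                rt_seconds=rt,
                mz=mz_arr,
                intensity=int_arr,
                precursor_mz=measured,
                precursor_charge=charge,
            )
        )
        truth.append(
            {
                "spectrum_id": sid,
                "peptide": matched_peptide,
                "correct": int(correct),
                "label": entry.label,
                "is_decoy": int(entry.label == "decoy"),
            }
        )
        if correct:
            xic_targets.append((theo, true_rt(spectrum_peptide)))

    for i in range(cfg.n_true_psms):
        pool = variant_pool if i < n_variant_true else canonical_pool
        pep = pool[int(rng.integers(len(pool)))]
        add_psm(pep, pep, correct=True)

    # half of the random PSMs match decoy peptides, half wrong targets
    for i in range(cfg.n_random_psms):
        matched_pool = decoy_pool if (i % 2 == 0 and decoy_pool) else target_pool
        matched = matched_pool[int(rng.integers(len(matched_pool)))]
        template = None
        for _attempt in range(100):
            cand = target_pool[int(rng.integers(len(target_pool)))]
            if cand != matched:
                template = cand
                break
        if template is None:
            warnings.warn("could not draw a wrong spectrum template; PSM skipped")
            continue
        add_psm(matched, template, correct=False)

    # MS1 scans: triangular XIC around every true elution apex
    ms1: List[SpectrumRecord] = []
    if xic_targets:
        t_max = max(rt for _, rt in xic_targets) + XIC_HALF_WIDTH_S + MS1_INTERVAL_S
        n_scans = int(t_max / MS1_INTERVAL_S) + 1
        for k in range(n_scans):
            rt_scan = k * MS1_INTERVAL_S
            peaks = []
            for mz0, apex_rt in xic_targets:
                dt = abs(rt_scan - apex_rt)
                if dt <= XIC_HALF_WIDTH_S:
                    peaks.append(
                        (mz0, XIC_APEX_INTENSITY * (1.0 - dt / XIC_HALF_WIDTH_S))
                    )
            peaks = [(m, h) for m, h in peaks if h > 0]
            if not peaks:
                continue
            peaks.sort()
            ms1.append(
                SpectrumRecord(
                    spectrum_id=f"ms1={k}",
                    ms_level=1,
                    rt_seconds=rt_scan,
                    mz=np.array([m for m, _ in peaks]),
                    intensity=np.array([h for _, h in peaks]),
                )
            )

    out = SimOutput(
        config=cfg,
        transcripts=transcripts,
        variants=variants,
        canonical=canonical,
        db=db,
        psms=psms,
        ms2=ms2,
        ms1=ms1,
        truth=truth,
    )
    if out_dir is not None:
        out.paths = write_outputs(out, Path(out_dir))
    return out


def write_outputs(sim: SimOutput, out_dir: Path) -> Dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts_fasta": out_dir / "transcripts.fasta",
        "morf_tsv": out_dir / "morf.tsv",
        "variants_tsv": out_dir / "variants.tsv",
        "canonical_fasta": out_dir / "canonical.fasta",
        "db_fasta": out_dir / "db_extended.fasta",
        "peptide_index_tsv": out_dir / "peptide_index.tsv",
        "spectra_mgf": out_dir / "spectra.mgf",
        "ms1_mzml": out_dir / "ms1.mzml",
        "psms_tsv": out_dir / "psms.tsv",
        "truth_tsv": out_dir / "truth.tsv",
    }
    with open(paths["transcripts_fasta"], "w") as fh:
        for t in sim.transcripts:
            fh.write(f">{t.transcript_id}\n")
            for i in range(0, len(t.cdna), 60):
                fh.write(t.cdna[i : i + 60] + "\n")
    with open(paths["morf_tsv"], "w") as fh:
        fh.write("transcript_id\tmorf_start\tmorf_end\n")
        for t in sim.transcripts:
            fh.write(f"{t.transcript_id}\t{t.morf_start}\t{t.morf_end}\n")
    with open(paths["variants_tsv"], "w") as fh:
        fh.write("transcript_id\tcdna_pos\tref\talt\tmaf\n")
        for v in sim.variants:
            fh.write(f"{v.transcript_id}\t{v.cdna_pos}\t{v.ref}\t{v.alt}\t{v.maf:.6f}\n")
    variant_db.write_fasta(sim.canonical, paths["canonical_fasta"])
    variant_db.write_fasta(sim.db.entries, paths["db_fasta"])
    variant_db.write_peptide_index(sim.db.peptide_index, paths["peptide_index_tsv"])
    write_mgf(sim.ms2, paths["spectra_mgf"])
    write_mzml(sim.ms1, paths["ms1_mzml"])
    write_psm_table(sim.psms, paths["psms_tsv"])
    with open(paths["truth_tsv"], "w") as fh:
        fh.write("spectrum_id\tpeptide\tcorrect\tlabel\tis_decoy\n")
        for row in sim.truth:
            fh.write(
                f"{row['spectrum_id']}\t{row['peptide']}\t{row['correct']}\t"
                f"{row['label']}\t{row['is_decoy']}\n"
            )
    return paths
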