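"""Spectrum and PSM table input/output, plus retention-time apex extraction.

Reads centroided spectra from mzML or MGF (via pyteomics), writes MGF and a
minimal uncompressed mzML subset (64-bit float arrays, no compression —
enough to round-trip through standard readers), reads tab-separated PSM
exports, extracts the elution apex of a precursor from MS1 scans, and
writes Percolator PIN files. Retention times are seconds everywhere:
MGF ``RTINSECONDS`` and mzML scan start times are normalized on read.
"""

from __future__ import annotations

import base64
import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from varipept import chem

logger = logging.getLogger(__name__)

DEFAULT_APEX_PPM_TOL = 10.0
DEFAULT_APEX_WINDOW_S = 60.0

#: Column-name map for PeptideShaker-style PSM exports -> our canonical names.
PEPTIDESHAKER_COLUMN_MAP = {
    "Spectrum Title": "spectrum_id",
    "Sequence": "peptide",
    "Modified Sequence": "peptide",
    "Variable Modifications": "modifications",
    "Measured Charge": "charge",
    "Confidence [%]": "engine_score",
    "Spectrum Scan Number": "spectrum_id",
    "m/z": "precursor_mz",
    "Rank": "rank",
    "Decoy": "is_decoy",
    "Protein(s)": "proteins",
}


@dataclass
class SpectrumRecord:
    spectrum_id: str
    ms_level: int
    rt_seconds: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError(f"{self.spectrum_id}: negative intensities")


@dataclass
class PSMRecord:
    spectrum_id: str
    peptide: str
    modifications: Tuple[chem.Modification, ...]
    charge: int
    engine_score: float
    precursor_mz_measured: float
    rank: int = 1
    is_decoy: bool = False
    label: str = "canonical"
    prev_aa: str = "-"
    next_aa: str = "-"
    proteins: Tuple[str, ...] = ()

    @property
    def peptide_key(self) -> str:
        from varipept.predictors import make_key

        return make_key(self.peptide, self.modifications, self.charge)


@dataclass(frozen=True)
class ApexResult:
    spectrum_id: str
    rt_apex_seconds: float
    source: str  # "xic_apex" | "ms2_fallback"


# ---------------------------------------------------------------------------
# Spectrum reading / writing


def read_spectra(path, format: Optional[str] = None) -> List[SpectrumRecord]:
    """Read spectra from mzML or MGF (format inferred from the suffix)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mgf":
        return _read_mgf(path)
    if fmt == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unsupported spectrum format {fmt!r}")


def _read_mgf(path) -> List[SpectrumRecord]:
    from pyteomics import mgf

    out = []
    with mgf.MGF(str(path)) as reader:
        for i, spec in enumerate(reader):
            params = spec["params"]
            title = str(params.get("title", f"index={i}"))
            rt = float(params.get("rtinseconds", 0.0))
            pepmass = params.get("pepmass", (None,))
            charge = params.get("charge")
            if charge:
                charge = int(charge[0])
            if pepmass[0] is None:
                raise ValueError(f"{path}: spectrum {title} has no precursor mass")
            out.append(
                SpectrumRecord(
                    spectrum_id=title,
                    ms_level=2,
                    rt_seconds=rt,
                    mz=spec["m/z array"],
                    intensity=spec["intensity array"],
                    precursor_mz=float(pepmass[0]),
                    precursor_charge=charge,
                )
            )
    return out


def _decode_binary(element) -> np.ndarray:
    """Decode one <binaryDataArray>: 32/64-bit floats, optional zlib."""
    import zlib

    accessions = {
        cv.get("accession") for cv in element.iter() if cv.tag.endswith("cvParam")
    }
    binary = next(e for e in element.iter() if e.tag.endswith("}binary"))
    payload = base64.b64decode((binary.text or "").strip())
    if "MS:1000574" in accessions:  # zlib compression
        payload = zlib.decompress(payload)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(payload, dtype=dtype).astype(float)


def _read_mzml(path) -> List[SpectrumRecord]:
    """Minimal mzML reader (lxml): ms level, scan start time, precursor
    selected ion, and uncompressed/zlib 32/64-bit float peak arrays."""
    from lxml import etree

    out = []
    for _, spec in etree.iterparse(str(path), tag="{*}spectrum"):
        level = 0
        rt = 0.0
        prec_mz = None
        prec_z = None
        arrays: dict = {}
        for cv in spec.iter("{*}cvParam"):
            acc = cv.get("accession")
            if acc == "MS:1000511":
                level = int(cv.get("value"))
            elif acc == "MS:1000016":
                rt = float(cv.get("value"))
                if cv.get("unitName") == "minute" or cv.get("unitAccession") == "UO:0000031":
                    rt *= 60.0
            elif acc == "MS:1000744":
                prec_mz = float(cv.get("value"))
            elif acc == "MS:1000041":
                prec_z = int(cv.get("value"))
        for bda in spec.iter("{*}binaryDataArray"):
            accs = {c.get("accession") for c in bda.iter("{*}cvParam")}
            if "MS:1000514" in accs:
                arrays["mz"] = _decode_binary(bda)
            elif "MS:1000515" in accs:
                arrays["intensity"] = _decode_binary(bda)
        if level == 2 and prec_mz is None:
            raise ValueError(f"{path}: MS2 spectrum {spec.get('id')} lacks a precursor")
        out.append(
            SpectrumRecord(
                spectrum_id=str(spec.get("id")),
                ms_level=level,
                rt_seconds=rt,
                mz=arrays.get("mz", np.empty(0)),
                intensity=arrays.get("intensity", np.empty(0)),
                precursor_mz=prec_mz,
                precursor_charge=prec_z,
            )
        )
        spec.clear()
    return out


def write_mgf(records: Iterable[SpectrumRecord], path) -> None:
    """Write MS2 spectra to MGF with TITLE/PEPMASS/CHARGE/RTINSECONDS."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.ms_level != 2:
                continue
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={rec.spectrum_id}\n")
            fh.write(f"PEPMASS={rec.precursor_mz:.6f}\n")
            if rec.precursor_charge:
                fh.write(f"CHARGE={rec.precursor_charge}+\n")
            fh.write(f"RTINSECONDS={rec.rt_seconds:.3f}\n")
            for mz, inten in zip(rec.mz, rec.intensity):
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("END IONS\n\n")


def _b64(array: np.ndarray) -> str:
    return base64.b64encode(np.asarray(array, dtype="<f8").tobytes()).decode()


def write_mzml(records: Sequence[SpectrumRecord], path) -> None:
    """Write a minimal uncompressed mzML file (MS1 and MS2 supported)."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">'
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="UNIT-ONTOLOGY" URI="https://raw.githubusercontent.com/'
        'bio-ontology-research-group/unit-ontology/master/unit.obo"/></cvList>',
        '<run id="run">',
        f'<spectrumList count="{len(records)}">',
    ]
    for i, rec in enumerate(records):
        lines.append(
            f'<spectrum index="{i}" id="{rec.spectrum_id}" '
            f'defaultArrayLength="{rec.mz.size}">'
        )
        lines.append(
            f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" '
            f'value="{rec.ms_level}"/>'
        )
        lines.append(
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{rec.rt_seconds:.6f}" unitCvRef="UO" '
            'unitAccession="UO:0000010" unitName="second"/>'
            "</scan></scanList>"
        )
        if rec.ms_level == 2 and rec.precursor_mz is not None:
            charge = (
                f'<cvParam cvRef="MS" accession="MS:1000041" name="charge state" '
                f'value="{rec.precursor_charge}"/>'
                if rec.precursor_charge
                else ""
            )
            lines.append(
                '<precursorList count="1"><precursor>'
                '<selectedIonList count="1"><selectedIon>'
                f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" '
                f'value="{rec.precursor_mz:.6f}"/>'
                f"{charge}"
                "</selectedIon></selectedIonList></precursor></precursorList>"
            )
        lines.append('<binaryDataArrayList count="2">')
        for accession, name, arr in (
            ("MS:1000514", "m/z array", rec.mz),
            ("MS:1000515", "intensity array", rec.intensity),
        ):
            payload = _b64(arr)
            lines.append(
                f'<binaryDataArray encodedLength="{len(payload)}">'
                '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
                '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
                f'<cvParam cvRef="MS" accession="{accession}" name="{name}"/>'
                f"<binary>{payload}</binary></binaryDataArray>"
            )
        lines.append("</binaryDataArrayList></spectrum>")
    lines += ["</spectrumList>", "</run>", "</mzML>"]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Retention-time apex extraction


def find_rt_apex(
    ms1: Sequence[SpectrumRecord],
    precursor_mz: float,
    rt_ms2: float,
    ppm_tol: float = DEFAULT_APEX_PPM_TOL,
    window_s: float = DEFAULT_APEX_WINDOW_S,
    spectrum_id: str = "",
) -> ApexResult:
    """Apex of the precursor's extracted-ion chromatogram around ``rt_ms2``.

    Sums MS1 intensity within ``ppm_tol`` of the precursor m/z for scans
    within ``window_s`` of the MS2 time, smooths with a centered 3-point
    moving average, and returns the retention time of the maximum (earliest
    scan on ties). When no MS1 point qualifies, the MS2 time itself is
    returned with ``source="ms2_fallback"``.
    """
    if ppm_tol <= 0 or window_s <= 0:
        raise ValueError("ppm_tol and window_s must be positive")
    lo = precursor_mz * (1 - ppm_tol * 1e-6)
    hi = precursor_mz * (1 + ppm_tol * 1e-6)
    rts: List[float] = []
    xic: List[float] = []
    for scan in ms1:
        if scan.ms_level != 1 or abs(scan.rt_seconds - rt_ms2) > window_s:
            continue
        i0, i1 = np.searchsorted(scan.mz, (lo, hi))
        total = float(scan.intensity[i0:i1].sum())
        if total > 0:
            rts.append(scan.rt_seconds)
            xic.append(total)
    if not xic:
        return ApexResult(spectrum_id, rt_ms2, "ms2_fallback")
    order = np.argsort(rts, kind="stable")
    rts_arr = np.asarray(rts)[order]
    xic_arr = np.asarray(xic)[order]
    kernel = np.ones(3)
    smoothed = np.convolve(xic_arr, kernel, mode="same") / np.convolve(
        np.ones_like(xic_arr), kernel, mode="same"
    )
    return ApexResult(spectrum_id, float(rts_arr[int(np.argmax(smoothed))]), "xic_apex")


# ---------------------------------------------------------------------------
# PSM tables


def _format_mods(mods: Sequence[chem.Modification]) -> str:
    return ",".join(f"{p}:{d:.10g}" for p, d in mods)


def _parse_mods(text: str) -> Tuple[chem.Modification, ...]:
    text = (text or "").strip()
    if not text:
        return ()
    return tuple((int(p), float(d)) for p, d in (m.split(":") for m in text.split(",")))


PSM_COLUMNS = [
    "spectrum_id",
    "peptide",
    "modifications",
    "charge",
    "engine_score",
    "precursor_mz",
    "rank",
    "is_decoy",
    "label",
    "prev_aa",
    "next_aa",
    "proteins",
]


def write_psm_table(psms: Iterable[PSMRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PSM_COLUMNS)
        for p in psms:
            w.writerow(
                [
                    p.spectrum_id,
                    p.peptide,
                    _format_mods(p.modifications),
                    p.charge,
                    f"{p.engine_score:.6f}",
                    f"{p.precursor_mz_measured:.6f}",
                    p.rank,
                    int(p.is_decoy),
                    p.label,
                    p.prev_aa,
                    p.next_aa,
                    ";".join(p.proteins),
                ]
            )


def read_psm_table(path, column_map: Optional[Dict[str, str]] = None) -> List[PSMRecord]:
    """Read a tab-separated PSM table.

    ``column_map`` renames input headers to the canonical
    :data:`PSM_COLUMNS`; pass :data:`PEPTIDESHAKER_COLUMN_MAP` for
    PeptideShaker exports.
    """
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for raw in reader:
            row = dict(raw)
            if column_map:
                for src, dst in column_map.items():
                    if src in row and dst not in row:
                        row[dst] = row[src]
            out.append(
                PSMRecord(
                    spectrum_id=row["spectrum_id"],
                    peptide=row["peptide"],
                    modifications=_parse_mods(row.get("modifications", "")),
                    charge=int(row["charge"]),
                    engine_score=float(row["engine_score"]),
                    precursor_mz_measured=float(row["precursor_mz"]),
                    rank=int(row.get("rank", 1) or 1),
                    is_decoy=bool(int(row.get("is_decoy", 0) or 0)),
                    label=row.get("label", "canonical") or "canonical",
                    prev_aa=row.get("prev_aa", "-") or "-",
                    next_aa=row.get("next_aa", "-") or "-",
                    proteins=tuple(
                        x for x in (row.get("proteins", "") or "").split(";") if x
                    ),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Percolator PIN export


def _scan_number(spectrum_id: str, fallback: int) -> int:
    m = re.search(r"(\d+)\s*$", spectrum_id)
    return int(m.group(1)) if m else fallback


def write_pin(feature_vectors: Sequence, path) -> None:
    """Write feature vectors as a Percolator PIN file.

    Columns: SpecId, Label (+1 target / -1 decoy), ScanNr, one column per
    feature (schema order), Peptide flanked ``-.PEPTIDE.-``, Proteins.
    All vectors must share one schema.
    """
    feature_vectors = list(feature_vectors)
    if feature_vectors:
        schemas = {tuple(fv.values.keys()) for fv in feature_vectors}
        if len(schemas) > 1:
            raise ValueError("mixed feature schemas in one PIN file")
        names = list(feature_vectors[0].values.keys())
    else:
        names = []
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["SpecId", "Label", "ScanNr", *names, "Peptide", "Proteins"])
        for i, fv in enumerate(feature_vectors):
            peptide = fv.peptide_key.split("|")[0]
            proteins = ";".join(getattr(fv, "proteins", ()) or ()) or "-"
            w.writerow(
                [
                    fv.spectrum_id,
                    -1 if fv.is_decoy else 1,
                    _scan_number(fv.spectrum_id, i + 1),
                    *[f"{fv.values[n]:.8g}" for n in names],
                    f"-.{peptide}.-",
                    proteins,
                ]
            )
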