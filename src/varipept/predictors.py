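"""Retention-time and fragment-intensity prediction interface.

Two routes satisfy one contract: tab-separated adapter files exported from
external deep-learning predictors (DeepLC-style retention times, MS2PIP-style
fragment intensities), or the built-in deterministic surrogates below, which
let the whole pipeline run without any model download. The surrogates are
pure functions of the peptide sequence: retention time is an additive
hydrophobicity model, fragment intensities follow a smooth positional
profile. Neither claims predictive accuracy on real data — downstream
feature and rescoring code must be correct for *any* predictor obeying the
contract.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from varipept import chem

logger = logging.getLogger(__name__)

# Additive retention coefficients (arbitrary hydrophobicity units, roughly
# following reversed-phase elution order: acidic/basic residues elute early,
# large hydrophobics late).
RETENTION_COEFFICIENTS = {
    "W": 11.0,
    "F": 10.5,
    "L": 10.0,
    "I": 9.5,
    "M": 7.0,
    "V": 6.0,
    "Y": 4.5,
    "C": 2.5,
    "A": 2.0,
    "T": 1.0,
    "E": 0.5,
    "D": -0.5,
    "Q": -0.5,
    "S": -0.7,
    "G": -0.9,
    "N": -1.0,
    "P": -1.2,
    "H": -2.0,
    "R": -2.2,
    "K": -2.5,
}

#: Intercept and scale mapping hydrophobicity units onto a nominal
#: chromatographic scale in seconds (pre-calibration; downstream code always
#: recalibrates against confident identifications).
RT_INTERCEPT_S = 120.0
RT_SLOPE_S = 18.0
RT_LENGTH_TERM_S = 2.0

# Relative weights of the deterministic fragment intensity profile.
_SERIES_WEIGHT = {"b": 1.0, "y": 2.0}
_CHARGE_WEIGHT = {1: 1.0, 2: 0.3}


@dataclass(frozen=True)
class RtPrediction:
    peptide_key: str
    rt_predicted: float  # predictor scale, seconds-like, pre-calibration


@dataclass(frozen=True)
class FragmentIon:
    series: str  # "b" or "y"
    ordinal: int  # >= 1, < len(peptide)
    fragment_charge: int  # 1 or 2
    mz: float
    intensity: float  # normalized so the prediction sums to 1


@dataclass(frozen=True)
class FragmentPrediction:
    peptide_key: str
    charge: int
    ions: Tuple[FragmentIon, ...]


def make_key(
    peptide: str, modifications: Sequence[chem.Modification] = (), charge: int = 0
) -> str:
    """Unambiguous modified-peptide key: ``PEPTIDE|pos:delta,...|z``."""
    mods = ",".join(f"{p}:{d:.10g}" for p, d in sorted(modifications))
    return f"{peptide}|{mods}|{charge}"


def parse_key(key: str) -> Tuple[str, Tuple[chem.Modification, ...], int]:
    peptide, mods, charge = key.split("|")
    parsed = tuple(
        (int(p), float(d))
        for p, d in (m.split(":") for m in mods.split(",") if m)
    )
    return peptide, parsed, int(charge)


def surrogate_rt(
    peptide: str, modifications: Sequence[chem.Modification] = (), charge: int = 0
) -> RtPrediction:
    """Deterministic additive retention-time surrogate.

    Sum of per-residue retention coefficients plus a length term, mapped
    onto a nominal seconds scale. Modifications do not shift the surrogate;
    they only enter the key.
    """
    if not peptide:
        raise ValueError("empty peptide")
    chem._check_sequence(peptide)
    hydro = sum(RETENTION_COEFFICIENTS[aa] for aa in peptide)
    rt = RT_INTERCEPT_S + RT_SLOPE_S * hydro + RT_LENGTH_TERM_S * len(peptide)
    return RtPrediction(make_key(peptide, modifications, charge), rt)


def _positional_profile(ordinal: int, length: int) -> float:
    # Smooth bump peaking mid-sequence, with a floor so every ion is present.
    center = length / 2.0
    width = max(length / 4.0, 1.0)
    return 0.2 + math.exp(-((ordinal - center) ** 2) / (2.0 * width**2))


def surrogate_fragments(
    peptide: str,
    charge: int,
    modifications: Sequence[chem.Modification] = (),
) -> FragmentPrediction:
    """Deterministic b/y fragment spectrum prediction.

    Emits all b and y ions at fragment charges 1 and 2, with m/z computed
    from monoisotopic residue masses and intensities from a smooth profile
    (y over b, singly over doubly charged), normalized to unit sum.
    """
    if len(peptide) < 2:
        raise ValueError("peptide must have length >= 2 to fragment")
    chem._check_sequence(peptide)
    n = len(peptide)
    raw: List[FragmentIon] = []
    for series in ("b", "y"):
        for ordinal in range(1, n):
            for fz in (1, 2):
                mz = chem.fragment_mz(peptide, series, ordinal, fz, modifications)
                inten = (
                    _SERIES_WEIGHT[series]
                    * _CHARGE_WEIGHT[fz]
                    * _positional_profile(ordinal, n)
                )
                raw.append(FragmentIon(series, ordinal, fz, mz, inten))
    total = sum(ion.intensity for ion in raw)
    ions = tuple(
        FragmentIon(i.series, i.ordinal, i.fragment_charge, i.mz, i.intensity / total)
        for i in raw
    )
    return FragmentPrediction(make_key(peptide, modifications, charge), charge, ions)


def load_predictions(path, kind: str):
    """Load an external predictor's export in the adapter TSV format.

    ``kind="rt"``: columns ``peptide_key`` and ``rt_predicted``; returns a
    dict key -> :class:`RtPrediction`. ``kind="fragments"``: columns
    ``peptide_key, series, ordinal, fragment_charge, mz, intensity``;
    returns a dict key -> :class:`FragmentPrediction` with intensities
    renormalized to unit sum. Duplicate keys: last wins, with a warning.
    """
    import pandas as pd

    table = pd.read_csv(path, sep="\t")
    if kind == "rt":
        required = {"peptide_key", "rt_predicted"}
        if not required <= set(table.columns):
            raise ValueError(f"missing columns {required - set(table.columns)}")
        out: Dict[str, RtPrediction] = {}
        dupes = table["peptide_key"].duplicated().sum()
        if dupes:
            warnings.warn(f"{dupes} duplicate peptide keys in {path}; last wins")
        for row in table.itertuples(index=False):
            out[row.peptide_key] = RtPrediction(row.peptide_key, float(row.rt_predicted))
        return out
    if kind == "fragments":
        required = {"peptide_key", "series", "ordinal", "fragment_charge", "mz", "intensity"}
        if not required <= set(table.columns):
            raise ValueError(f"missing columns {required - set(table.columns)}")
        preds: Dict[str, FragmentPrediction] = {}
        for key, group in table.groupby("peptide_key", sort=False):
            total = group["intensity"].sum()
            ions = tuple(
                FragmentIon(
                    str(r.series),
                    int(r.ordinal),
                    int(r.fragment_charge),
                    float(r.mz),
                    float(r.intensity) / total if total > 0 else 0.0,
                )
                for r in group.itertuples(index=False)
            )
            if key in preds:
                warnings.warn(f"duplicate fragment prediction for {key}; last wins")
            _, _, charge = parse_key(key)
            preds[key] = FragmentPrediction(key, charge, ions)
        return preds
    raise ValueError(f"unknown prediction kind {kind!r}")
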