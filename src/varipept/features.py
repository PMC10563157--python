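"""PSM feature computation.

Implements the two feature schemas used for rescoring: a *standard* set of
18 search-engine-level features (score, mass error, charge indicators, ...)
and an *extended* set of 40 that adds retention-time agreement with a
calibrated predictor and fragmentation agreement with a predicted spectrum
(percentage of matched peaks, logarithmic distance, cosine and angular
similarity, cross entropy — each over b ions, y ions and all ions — plus
consecutive terminal ion runs and the matched-peak count).

Peak matching uses a relative tolerance in ppm (default 10) with greedy
unique assignment. Similarity metrics operate on intensity vectors indexed
by the predicted ions: the predicted vector holds predicted intensities and
the observed vector the matched observed intensities (0 where unmatched),
both normalized to unit sum. A PSM with no matched peak therefore has
cosine 0 and angular similarity exactly 0.5, the metric's floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from varipept import chem
from varipept.predictors import FragmentIon, FragmentPrediction
from varipept.spectra_io import ApexResult, PSMRecord

DEFAULT_PPM_TOL = 10.0
EPSILON = 1e-6  # floor inside logarithms of normalized intensities

STANDARD_FEATURES = [
    "engine_score",
    "delta_score",
    "prec_mass_error_ppm",
    "abs_prec_mass_error",
    "peptide_length",
    "missed_cleavages",
    "charge_2",
    "charge_3",
    "charge_4",
    "charge_5plus",
    "enzymatic_nterm",
    "enzymatic_cterm",
    "n_variable_mods",
    "n_matched_fragments",
    "frac_matched_intensity",
    "precursor_mz",
    "precursor_neutral_mass",
    "ln_n_candidates",
]

_SIMILARITY_NAMES = ["pct_matched", "log_distance", "cosine", "angular", "cross_entropy"]

EXTENDED_EXTRA_FEATURES = (
    ["rt_abs_error", "rt_sq_error", "rt_log_error", "rt_meas_apex_abs"]
    + [f"{m}_{g}" for g in ("b", "y", "all") for m in _SIMILARITY_NAMES]
    + ["consecutive_b", "consecutive_y", "n_matched_all"]
)

EXTENDED_FEATURES = STANDARD_FEATURES + EXTENDED_EXTRA_FEATURES

SCHEMAS = {"standard": STANDARD_FEATURES, "extended": EXTENDED_FEATURES}


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from predictor retention-time scale to the chromatogram."""

    slope: float
    intercept: float
    n_calibration_psms: int

    def predict(self, rt_predicted: float) -> float:
        return self.slope * rt_predicted + self.intercept


@dataclass
class MatchedSpectrumPair:
    matched: List[Tuple[FragmentIon, int]]  # (predicted ion, observed peak index)
    unmatched_predicted: List[FragmentIon]
    observed_unused: List[int]
    ion_group: str  # "b" | "y" | "all"
    observed_mz: np.ndarray
    observed_intensity: np.ndarray


@dataclass
class FeatureVector:
    spectrum_id: str
    peptide_key: str
    is_decoy: bool
    schema: str
    values: Dict[str, float]
    label: str = "canonical"
    proteins: Tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Peak matching


def match_peaks(
    observed_mz: np.ndarray,
    observed_intensity: np.ndarray,
    predicted: FragmentPrediction,
    ppm_tol: float = DEFAULT_PPM_TOL,
    group: str = "all",
) -> MatchedSpectrumPair:
    """Greedy unique assignment of observed peaks to predicted ions.

    Candidate pairs within ``ppm_tol`` are assigned in order of increasing
    absolute ppm error (ties: lower ordinal first); each observed peak and
    each predicted ion is used at most once.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    if group == "all":
        ions = list(predicted.ions)
    else:
        ions = [i for i in predicted.ions if i.series == group]
    observed_mz = np.asarray(observed_mz, dtype=float)
    observed_intensity = np.asarray(observed_intensity, dtype=float)

    candidates = []
    for pi, ion in enumerate(ions):
        lo = ion.mz * (1 - ppm_tol * 1e-6)
        hi = ion.mz * (1 + ppm_tol * 1e-6)
        i0 = int(np.searchsorted(observed_mz, lo, side="left"))
        i1 = int(np.searchsorted(observed_mz, hi, side="right"))
        for oi in range(i0, i1):
            err = abs(observed_mz[oi] - ion.mz) / ion.mz * 1e6
            if err <= ppm_tol:
                candidates.append((err, ion.ordinal, pi, oi))
    candidates.sort()
    used_pred: set = set()
    used_obs: set = set()
    matched: List[Tuple[FragmentIon, int]] = []
    for err, _, pi, oi in candidates:
        if pi in used_pred or oi in used_obs:
            continue
        used_pred.add(pi)
        used_obs.add(oi)
        matched.append((ions[pi], oi))
    return MatchedSpectrumPair(
        matched=matched,
        unmatched_predicted=[ion for i, ion in enumerate(ions) if i not in used_pred],
        observed_unused=[i for i in range(observed_mz.size) if i not in used_obs],
        ion_group=group,
        observed_mz=observed_mz,
        observed_intensity=observed_intensity,
    )


# ---------------------------------------------------------------------------
# Similarity metrics


def _intensity_vectors(pair: MatchedSpectrumPair) -> Tuple[np.ndarray, np.ndarray]:
    """Unit-sum observed/predicted vectors over the predicted-ion index set."""
    ions = [ion for ion, _ in pair.matched] + pair.unmatched_predicted
    pred = np.array([ion.intensity for ion in ions], dtype=float)
    obs = np.zeros_like(pred)
    for k, (_, oi) in enumerate(pair.matched):
        obs[k] = pair.observed_intensity[oi]
    if pred.sum() > 0:
        pred = pred / pred.sum()
    if obs.sum() > 0:
        obs = obs / obs.sum()
    return obs, pred


def similarity_features(pair: MatchedSpectrumPair) -> Dict[str, float]:
    """Spectral agreement metrics between observed and predicted intensities.

    Returns ``pct_matched`` (of predicted ions, in percent), ``log_distance``
    (mean absolute difference of log intensities), ``cosine``, ``angular``
    (1 - arccos(cosine)/pi, range [0.5, 1]) and ``cross_entropy``
    (-sum obs*ln(pred+eps)).
    """
    n_pred = len(pair.matched) + len(pair.unmatched_predicted)
    if n_pred == 0:
        return {
            "pct_matched": 0.0,
            "log_distance": 0.0,
            "cosine": 0.0,
            "angular": 0.5,
            "cross_entropy": 0.0,
        }
    obs, pred = _intensity_vectors(pair)
    norm = float(np.linalg.norm(obs) * np.linalg.norm(pred))
    cosine = float(obs @ pred / norm) if norm > 0 else 0.0
    cosine = min(max(cosine, 0.0), 1.0)
    angular = 1.0 - math.acos(cosine) / math.pi
    log_distance = float(np.mean(np.abs(np.log(obs + EPSILON) - np.log(pred + EPSILON))))
    cross_entropy = float(-(obs @ np.log(pred + EPSILON)))
    return {
        "pct_matched": 100.0 * len(pair.matched) / n_pred,
        "log_distance": log_distance,
        "cosine": cosine,
        "angular": angular,
        "cross_entropy": cross_entropy,
    }


def consecutive_runs(
    pair_b: MatchedSpectrumPair, pair_y: MatchedSpectrumPair
) -> Tuple[int, int]:
    """Consecutive matched b ordinals from the N terminus and y ordinals
    from the C terminus (both runs start at ordinal 1)."""

    def run(pair: MatchedSpectrumPair) -> int:
        ordinals = {ion.ordinal for ion, _ in pair.matched}
        k = 0
        while (k + 1) in ordinals:
            k += 1
        return k

    return run(pair_b), run(pair_y)


# ---------------------------------------------------------------------------
# Retention time calibration and features


def calibrate_rt(
    confident_psms: Sequence[Tuple[float, float]]
) -> CalibrationModel:
    """Ordinary least squares of RT apex on predicted RT.

    ``confident_psms`` are (rt_apex, rt_predicted) pairs for PSMs deemed
    confident (q-value <= 0.01) in a standard-feature rescoring pass.
    """
    if len(confident_psms) < 2:
        raise CalibrationError("need at least 2 confident PSMs to calibrate")
    apex = np.array([a for a, _ in confident_psms], dtype=float)
    pred = np.array([p for _, p in confident_psms], dtype=float)
    if np.ptp(pred) == 0:
        raise CalibrationError("degenerate calibration: constant predictions")
    slope, intercept = np.polyfit(pred, apex, 1)
    return CalibrationModel(float(slope), float(intercept), len(confident_psms))


def rt_features(
    psm: PSMRecord,
    apex: ApexResult,
    model: CalibrationModel,
    rt_predicted: float,
    rt_ms2: Optional[float] = None,
) -> Dict[str, float]:
    """Distances between the observed elution apex and the calibrated
    prediction, plus the measured-RT-to-apex distance."""
    delta = apex.rt_apex_seconds - model.predict(rt_predicted)
    if rt_ms2 is None:
        rt_ms2 = apex.rt_apex_seconds
    return {
        "rt_abs_error": abs(delta),
        "rt_sq_error": delta * delta,
        "rt_log_error": math.log1p(abs(delta)),
        "rt_meas_apex_abs": abs(rt_ms2 - apex.rt_apex_seconds),
    }


# ---------------------------------------------------------------------------
# Assembly


def assemble(
    psm: PSMRecord,
    schema: str,
    parts: Dict[str, float],
) -> FeatureVector:
    """Assemble a named feature vector for one PSM.

    ``parts`` must contain every feature of the chosen schema; a missing
    name raises with the feature named.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    values: Dict[str, float] = {}
    for name in SCHEMAS[schema]:
        if name not in parts:
            raise ValueError(f"missing feature {name!r} for schema {schema!r}")
        v = float(parts[name])
        if not math.isfinite(v):
            raise ValueError(f"non-finite value for feature {name!r}")
        values[name] = v
    return FeatureVector(
        spectrum_id=psm.spectrum_id,
        peptide_key=psm.peptide_key,
        is_decoy=psm.is_decoy,
        schema=schema,
        values=values,
        label=psm.label,
        proteins=psm.proteins,
    )


def standard_parts(
    psm: PSMRecord,
    pair_all: MatchedSpectrumPair,
    n_candidates: int = 1,
    delta_score: float = 0.0,
    missed_cleavages: Optional[int] = None,
) -> Dict[str, float]:
    """The search-engine-level features shared by both schemas."""
    theo_mz = chem.precursor_mz(psm.peptide, psm.charge, psm.modifications)
    err_ppm = chem.ppm_error(psm.precursor_mz_measured, theo_mz)
    if missed_cleavages is None:
        from varipept.variant_db import cleavage_sites

        missed_cleavages = len(cleavage_sites(psm.peptide))
    total_int = float(pair_all.observed_intensity.sum())
    matched_int = float(
        sum(pair_all.observed_intensity[oi] for _, oi in pair_all.matched)
    )
    return {
        "engine_score": psm.engine_score,
        "delta_score": delta_score,
        "prec_mass_error_ppm": err_ppm,
        "abs_prec_mass_error": abs(err_ppm),
        "peptide_length": float(len(psm.peptide)),
        "missed_cleavages": float(missed_cleavages),
        "charge_2": float(psm.charge == 2),
        "charge_3": float(psm.charge == 3),
        "charge_4": float(psm.charge == 4),
        "charge_5plus": float(psm.charge >= 5),
        "enzymatic_nterm": float(psm.prev_aa in ("K", "R", "-")),
        "enzymatic_cterm": float(psm.peptide[-1] in ("K", "R") or psm.next_aa == "-"),
        "n_variable_mods": float(len(psm.modifications)),
        "n_matched_fragments": float(len(pair_all.matched)),
        "frac_matched_intensity": matched_int / total_int if total_int > 0 else 0.0,
        "precursor_mz": psm.precursor_mz_measured,
        "precursor_neutral_mass": (psm.precursor_mz_measured - chem.PROTON)
        * psm.charge,
        "ln_n_candidates": math.log(max(n_candidates, 1)),
    }


def extended_parts(
    pair_b: MatchedSpectrumPair,
    pair_y: MatchedSpectrumPair,
    pair_all: MatchedSpectrumPair,
    rt_part: Dict[str, float],
) -> Dict[str, float]:
    """The 22 predictor-agreement features added by the extended schema."""
    out: Dict[str, float] = dict(rt_part)
    for group, pair in (("b", pair_b), ("y", pair_y), ("all", pair_all)):
        for name, value in similarity_features(pair).items():
            out[f"{name}_{group}"] = value
    cb, cy = consecutive_runs(pair_b, pair_y)
    out["consecutive_b"] = float(cb)
    out["consecutive_y"] = float(cy)
    out["n_matched_all"] = float(len(pair_all.matched))
    return out


def write_feature_table(feature_vectors: Sequence[FeatureVector], path) -> None:
    """Tab-separated feature table mirroring PIN column order."""
    from varipept.spectra_io import write_pin

    write_pin(feature_vectors, path)
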