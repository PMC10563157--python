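"""End-to-end orchestration of the feature and rescoring stages.

The canonical flow mirrors a two-pass rescoring protocol: standard features
are computed first and rescored; targets confident at q <= 0.01 in that
pass calibrate the retention-time predictor; the calibrated model then
feeds the extended features, and both schemas can be rescored and compared.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import pandas as pd

from varipept import features as feat
from varipept import rescoring
from varipept.predictors import (
    FragmentPrediction,
    RtPrediction,
    surrogate_fragments,
    surrogate_rt,
)
from varipept.spectra_io import (
    ApexResult,
    PSMRecord,
    SpectrumRecord,
    find_rt_apex,
)

logger = logging.getLogger(__name__)

CALIBRATION_Q = 0.01
CALIBRATION_FALLBACK_TOP_N = 50


@dataclass
class FeatureTables:
    standard: List[feat.FeatureVector]
    extended: List[feat.FeatureVector]
    calibration: feat.CalibrationModel
    standard_results: List[rescoring.RescoreResult]
    diagnostics: pd.DataFrame


def _predictions_for(
    psms: Sequence[PSMRecord],
    rt_predictions: Optional[Dict[str, RtPrediction]],
    fragment_predictions: Optional[Dict[str, FragmentPrediction]],
):
    """Fill in surrogate predictions wherever no external one is supplied."""
    rt_map: Dict[str, float] = {}
    frag_map: Dict[str, FragmentPrediction] = {}
    for psm in psms:
        key = psm.peptide_key
        if key in frag_map:
            continue
        if rt_predictions and key in rt_predictions:
            rt_map[key] = rt_predictions[key].rt_predicted
        else:
            rt_map[key] = surrogate_rt(
                psm.peptide, psm.modifications, psm.charge
            ).rt_predicted
        if fragment_predictions and key in fragment_predictions:
            frag_map[key] = fragment_predictions[key]
        else:
            frag_map[key] = surrogate_fragments(
                psm.peptide, psm.charge, psm.modifications
            )
    return rt_map, frag_map


def _per_spectrum_context(psms: Sequence[PSMRecord]):
    """Candidate counts and delta scores (to the next-best candidate)."""
    by_spectrum: Dict[str, List[PSMRecord]] = {}
    for psm in psms:
        by_spectrum.setdefault(psm.spectrum_id, []).append(psm)
    n_candidates: Dict[int, int] = {}
    delta: Dict[int, float] = {}
    for group in by_spectrum.values():
        ranked = sorted(group, key=lambda p: -p.engine_score)
        for i, psm in enumerate(ranked):
            next_best = ranked[i + 1].engine_score if i + 1 < len(ranked) else None
            delta[id(psm)] = (
                psm.engine_score - next_best if next_best is not None else 0.0
            )
            n_candidates[id(psm)] = len(group)
    return n_candidates, delta


def compute_feature_tables(
    psms: Sequence[PSMRecord],
    ms2: Sequence[SpectrumRecord],
    ms1: Sequence[SpectrumRecord] = (),
    ppm_tol: float = feat.DEFAULT_PPM_TOL,
    rescore_cfg: rescoring.RescoreConfig = rescoring.RescoreConfig(),
    rt_predictions: Optional[Dict[str, RtPrediction]] = None,
    fragment_predictions: Optional[Dict[str, FragmentPrediction]] = None,
) -> FeatureTables:
    """Compute standard and extended feature vectors for a set of PSMs.

    The retention-time calibration is fitted on targets confident at
    q <= 0.01 after a standard-feature rescoring pass; if fewer than two
    such PSMs exist, the top-scoring targets are used instead (logged).
    """
    spectra = {s.spectrum_id: s for s in ms2 if s.ms_level == 2}
    missing = [p.spectrum_id for p in psms if p.spectrum_id not in spectra]
    if missing:
        raise ValueError(f"PSMs reference unknown spectra, e.g. {missing[0]!r}")
    rt_map, frag_map = _predictions_for(psms, rt_predictions, fragment_predictions)
    n_candidates, delta = _per_spectrum_context(psms)

    pairs = {}
    apexes: Dict[int, ApexResult] = {}
    standard_fvs: List[feat.FeatureVector] = []
    for psm in psms:
        spec = spectra[psm.spectrum_id]
        pred = frag_map[psm.peptide_key]
        pair_all = feat.match_peaks(spec.mz, spec.intensity, pred, ppm_tol, "all")
        pair_b = feat.match_peaks(spec.mz, spec.intensity, pred, ppm_tol, "b")
        pair_y = feat.match_peaks(spec.mz, spec.intensity, pred, ppm_tol, "y")
        pairs[id(psm)] = (pair_b, pair_y, pair_all)
        apexes[id(psm)] = find_rt_apex(
            ms1,
            psm.precursor_mz_measured,
            spec.rt_seconds,
            spectrum_id=psm.spectrum_id,
        )
        parts = feat.standard_parts(
            psm,
            pair_all,
            n_candidates=n_candidates[id(psm)],
            delta_score=delta[id(psm)],
        )
        standard_fvs.append(feat.assemble(psm, "standard", parts))

    standard_results = rescoring.rescore(standard_fvs, rescore_cfg)
    q_by_id = {
        (r.spectrum_id, r.peptide_key): r.q_value for r in standard_results
    }
    confident = [
        (apexes[id(p)].rt_apex_seconds, rt_map[p.peptide_key])
        for p in psms
        if not p.is_decoy
        and q_by_id[(p.spectrum_id, p.peptide_key)] <= CALIBRATION_Q
    ]
    if len(confident) < 2:
        logger.warning(
            "only %d confident PSMs for calibration; using the %d top-scoring targets",
            len(confident),
            CALIBRATION_FALLBACK_TOP_N,
        )
        score_by_id = {
            (r.spectrum_id, r.peptide_key): r.score for r in standard_results
        }
        targets = sorted(
            (p for p in psms if not p.is_decoy),
            key=lambda p: -score_by_id[(p.spectrum_id, p.peptide_key)],
        )[:CALIBRATION_FALLBACK_TOP_N]
        confident = [
            (apexes[id(p)].rt_apex_seconds, rt_map[p.peptide_key]) for p in targets
        ]
    try:
        calibration = feat.calibrate_rt(confident)
    except feat.CalibrationError as exc:
        warnings.warn(f"RT calibration failed ({exc}); using the identity map")
        calibration = feat.CalibrationModel(1.0, 0.0, 0)

    extended_fvs: List[feat.FeatureVector] = []
    rows = []
    for psm, std_fv in zip(psms, standard_fvs):
        spec = spectra[psm.spectrum_id]
        pair_b, pair_y, pair_all = pairs[id(psm)]
        apex = apexes[id(psm)]
        rt_part = feat.rt_features(
            psm, apex, calibration, rt_map[psm.peptide_key], rt_ms2=spec.rt_seconds
        )
        parts = dict(std_fv.values)
        parts.update(feat.extended_parts(pair_b, pair_y, pair_all, rt_part))
        extended_fvs.append(feat.assemble(psm, "extended", parts))
        rows.append(
            {
                "spectrum_id": psm.spectrum_id,
                "peptide_key": psm.peptide_key,
                "is_decoy": psm.is_decoy,
                "label": psm.label,
                "rt_apex": apex.rt_apex_seconds,
                "apex_source": apex.source,
                "rt_predicted": rt_map[psm.peptide_key],
                "rt_residual": apex.rt_apex_seconds
                - calibration.predict(rt_map[psm.peptide_key]),
                "angular_all": parts["angular_all"],
                "engine_score": psm.engine_score,
            }
        )
    return FeatureTables(
        standard=standard_fvs,
        extended=extended_fvs,
        calibration=calibration,
        standard_results=standard_results,
        diagnostics=pd.DataFrame(rows),
    )


def rescore_both_schemas(
    tables: FeatureTables, cfg: rescoring.RescoreConfig
) -> Dict[str, List[rescoring.RescoreResult]]:
    return {
        "standard": rescoring.rescore(tables.standard, cfg),
        "extended": rescoring.rescore(tables.extended, cfg),
    }
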