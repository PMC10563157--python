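"""Semi-supervised linear PSM rescoring with target-decoy FDR control.

A cross-validated, iterative linear discriminant in the style of
Percolator: PSMs are split into folds by spectrum id; within each training
split the scorer starts from the single best-separating feature, then
repeatedly (i) selects confident targets (q <= q_train) as positives and
all decoys as negatives and (ii) refits an L2-regularized linear model.
Held-out folds are scored by the final model and the merged scores are
converted to q-values by target-decoy competition with the conservative
+1 decoy correction:

    FDR_hat(s) = (#decoys >= s + 1) / max(1, #targets >= s)
    q(s) = min over thresholds s' <= s of FDR_hat(s'), capped at 1.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from varipept.features import FeatureVector

logger = logging.getLogger(__name__)

MIN_FOLD_POSITIVES = 10


@dataclass(frozen=True)
class RescoreResult:
    spectrum_id: str
    peptide_key: str
    is_decoy: bool
    label: str
    score: float
    q_value: float


@dataclass(frozen=True)
class RescoreConfig:
    n_folds: int = 3
    n_iterations: int = 10
    q_train: float = 0.01
    seed: int = 0
    regularization: float = 1.0

    def __post_init__(self):
        if self.n_folds < 2 or self.n_iterations < 1 or self.regularization <= 0:
            raise ValueError("invalid rescoring configuration")


# ---------------------------------------------------------------------------
# Target-decoy q-values


def tdc_qvalues(scores: Sequence[float], is_decoy: Sequence[bool]) -> np.ndarray:
    """Per-PSM q-values from target-decoy competition.

    At every score threshold the estimated FDR is
    ``(#decoys >= s + 1) / max(1, #targets >= s)``; each PSM's q-value is
    the minimum estimate over all thresholds at or below its score. Decoy
    PSMs receive the q-value of their score.
    """
    scores = np.asarray(scores, dtype=float)
    decoy = np.asarray(is_decoy, dtype=bool)
    if not (~decoy).any():
        raise ValueError("need at least one target PSM")
    n = scores.size
    order = np.argsort(-scores, kind="stable")
    cum_decoys = np.cumsum(decoy[order])
    cum_targets = np.cumsum(~decoy[order])
    fdr = (cum_decoys + 1) / np.maximum(cum_targets, 1)
    # same score => same threshold: propagate the value at the last tied entry
    sorted_scores = scores[order]
    for i in range(n - 2, -1, -1):
        if sorted_scores[i] == sorted_scores[i + 1]:
            fdr[i] = fdr[i + 1]
    q_sorted = np.minimum(np.minimum.accumulate(fdr[::-1])[::-1], 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Semi-supervised rescoring


def _fold_of(spectrum_id: str, n_folds: int, seed: int) -> int:
    digest = hashlib.md5(f"{seed}:{spectrum_id}".encode()).hexdigest()
    return int(digest, 16) % n_folds


def _n_accepted(scores: np.ndarray, decoy: np.ndarray, q_threshold: float) -> int:
    q = tdc_qvalues(scores, decoy)
    return int(((q <= q_threshold) & ~decoy).sum())


def _initial_direction(
    X: np.ndarray, decoy: np.ndarray, q_train: float, engine_col: Optional[int]
) -> Tuple[np.ndarray, int]:
    """Single feature (and sign) maximizing accepted targets at q_train."""
    best = (-1, None)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            continue
        for sign in (1.0, -1.0):
            n = _n_accepted(sign * col, decoy, q_train)
            if n > best[0]:
                best = (n, sign * col)
    if best[0] <= 0:
        # no feature separates at q_train: fall back to the engine score
        j = engine_col if engine_col is not None else 0
        return X[:, j].copy(), 0
    return best[1], best[0]


def rescore(
    feature_vectors: Sequence[FeatureVector],
    cfg: RescoreConfig = RescoreConfig(),
) -> List[RescoreResult]:
    """Rescore PSM feature vectors; deterministic given ``cfg.seed``.

    Requires a single schema and both target and decoy PSMs. Folds with
    fewer than :data:`MIN_FOLD_POSITIVES` confident training positives are
    merged into their neighbor.
    """
    fvs = list(feature_vectors)
    if not fvs:
        return []
    schemas = {tuple(fv.values.keys()) for fv in fvs}
    if len(schemas) > 1:
        raise ValueError("mixed feature schemas")
    names = list(fvs[0].values.keys())
    X = np.array([[fv.values[n] for n in names] for fv in fvs], dtype=float)
    decoy = np.array([fv.is_decoy for fv in fvs], dtype=bool)
    if decoy.all() or not decoy.any():
        raise ValueError("both target and decoy PSMs are required")
    engine_col = names.index("engine_score") if "engine_score" in names else None

    if X.shape[1] == 1:
        # single-feature fixed point: nothing to learn, rank by the feature
        final = X[:, 0]
        sd = final.std()
        final = (final - final.mean()) / (sd if sd > 0 else 1.0)
        q = tdc_qvalues(final, decoy)
        return [
            RescoreResult(
                fv.spectrum_id, fv.peptide_key, fv.is_decoy, fv.label,
                float(final[i]), float(q[i]),
            )
            for i, fv in enumerate(fvs)
        ]

    n_folds = cfg.n_folds
    folds = np.array([_fold_of(fv.spectrum_id, n_folds, cfg.seed) for fv in fvs])
    final = np.zeros(len(fvs))

    # merge folds whose training half cannot supply enough confident positives
    active = list(range(n_folds))
    while len(active) > 1:
        deficient = None
        for k in active:
            train = folds != k
            direction, n_pos = _initial_direction(
                X[train], decoy[train], cfg.q_train, engine_col
            )
            if 0 < n_pos < MIN_FOLD_POSITIVES:
                deficient = k
                break
        if deficient is None:
            break
        neighbor = active[(active.index(deficient) + 1) % len(active)]
        warnings.warn(
            f"fold {deficient} has < {MIN_FOLD_POSITIVES} confident positives; "
            f"merged into fold {neighbor}"
        )
        folds[folds == deficient] = neighbor
        active.remove(deficient)

    for k in active:
        train = folds != k if len(active) > 1 else np.ones(len(fvs), bool)
        test = folds == k if len(active) > 1 else np.ones(len(fvs), bool)
        scaler = StandardScaler().fit(X[train])
        Xt = scaler.transform(X[train])
        Xe = scaler.transform(X[test])
        decoy_t = decoy[train]

        direction, n_pos = _initial_direction(Xt, decoy_t, cfg.q_train, engine_col)
        scores_train = direction
        model = None
        if n_pos > 0:
            for _ in range(cfg.n_iterations):
                q = tdc_qvalues(scores_train, decoy_t)
                positives = (~decoy_t) & (q <= cfg.q_train)
                if positives.sum() < 2:
                    break
                y = np.concatenate(
                    [np.ones(int(positives.sum())), np.zeros(int(decoy_t.sum()))]
                )
                Xfit = np.vstack([Xt[positives], Xt[decoy_t]])
                # default penalty is L2; C is the inverse regularization strength
                model = LogisticRegression(
                    C=1.0 / cfg.regularization, max_iter=1000, solver="lbfgs"
                )
                model.fit(Xfit, y)
                scores_train = model.decision_function(Xt)
        if model is not None:
            scores_test = model.decision_function(Xe)
            ref = model.decision_function(Xt)[decoy_t]
        else:
            # fallback: engine score (or first feature) ranking
            j = engine_col if engine_col is not None else 0
            scores_test = Xe[:, j]
            ref = Xt[decoy_t, j]
        sd = float(ref.std())
        final[test] = (scores_test - float(ref.mean())) / (sd if sd > 0 else 1.0)

    final = (final - final.mean()) / (final.std() if final.std() > 0 else 1.0)
    q = tdc_qvalues(final, decoy)
    return [
        RescoreResult(
            spectrum_id=fv.spectrum_id,
            peptide_key=fv.peptide_key,
            is_decoy=fv.is_decoy,
            label=fv.label,
            score=float(final[i]),
            q_value=float(q[i]),
        )
        for i, fv in enumerate(fvs)
    ]


# ---------------------------------------------------------------------------
# Peptide roll-up and run comparison


def peptide_qvalues(results: Sequence[RescoreResult]) -> List[RescoreResult]:
    """Peptide-level results: best PSM per peptide sequence, then
    target-decoy competition on the peptide scores."""
    best: Dict[Tuple[str, bool], RescoreResult] = {}
    for r in results:
        seq = r.peptide_key.split("|")[0]
        key = (seq, r.is_decoy)
        if key not in best or r.score > best[key].score:
            best[key] = r
    reps = list(best.values())
    q = tdc_qvalues([r.score for r in reps], [r.is_decoy for r in reps])
    return [
        RescoreResult(r.spectrum_id, r.peptide_key, r.is_decoy, r.label, r.score, float(qi))
        for r, qi in zip(reps, q)
    ]


def _accepted(
    results: Sequence[RescoreResult], q_threshold: float, level: str
) -> Dict[str, Set]:
    out: Dict[str, Set] = {"canonical": set(), "variant": set()}
    for r in results:
        if r.is_decoy or r.q_value > q_threshold:
            continue
        key = (r.spectrum_id, r.peptide_key) if level == "psm" else r.peptide_key.split("|")[0]
        bucket = "variant" if r.label == "variant" else "canonical"
        out[bucket].add(key)
    return out


def compare_runs(
    a: Sequence[RescoreResult],
    b: Sequence[RescoreResult],
    q_threshold: float = 0.01,
) -> Dict[str, Dict[str, Dict[str, int]]]:
    """Venn counts of accepted PSMs and peptides between two runs.

    Returns ``{level: {bucket: {"only_a", "shared", "only_b"}}}`` with
    levels ``psm``/``peptide`` and buckets ``canonical``/``variant``.
    """
    universe_a = {(r.spectrum_id, r.peptide_key) for r in a}
    universe_b = {(r.spectrum_id, r.peptide_key) for r in b}
    if universe_a != universe_b:
        raise ValueError("runs cover different PSM universes")
    out: Dict[str, Dict[str, Dict[str, int]]] = {}
    for level, roll in (("psm", a), ("peptide", None)):
        acc_a = _accepted(peptide_qvalues(a) if level == "peptide" else a, q_threshold, level)
        acc_b = _accepted(peptide_qvalues(b) if level == "peptide" else b, q_threshold, level)
        out[level] = {}
        for bucket in ("canonical", "variant"):
            sa, sb = acc_a[bucket], acc_b[bucket]
            out[level][bucket] = {
                "only_a": len(sa - sb),
                "shared": len(sa & sb),
                "only_b": len(sb - sa),
            }
    return out


def write_results(results: Sequence[RescoreResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("spectrum_id\tpeptide_key\tis_decoy\tlabel\tscore\tq_value\n")
        for r in results:
            fh.write(
                f"{r.spectrum_id}\t{r.peptide_key}\t{int(r.is_decoy)}\t{r.label}\t"
                f"{r.score:.8g}\t{r.q_value:.8g}\n"
            )


def read_results(path) -> List[RescoreResult]:
    import csv

    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                RescoreResult(
                    row["spectrum_id"],
                    row["peptide_key"],
                    bool(int(row["is_decoy"])),
                    row["label"],
                    float(row["score"]),
                    float(row["q_value"]),
                )
            )
    return out
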