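"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops and direct formula evaluation,
deliberately sharing no code with the package's vectorized implementations.
"""

import math

EPS = 1e-6


def naive_match(obs_mz, obs_int, ions, ppm_tol):
    """O(n*m) peak assignment: all candidate pairs within tolerance, taken
    in order of ppm error (ties: lower ordinal), each side used once."""
    candidates = []
    for pi, ion in enumerate(ions):
        for oi, m in enumerate(obs_mz):
            err = abs(m - ion.mz) / ion.mz * 1e6
            if err <= ppm_tol:
                candidates.append((err, ion.ordinal, pi, oi))
    candidates.sort()
    used_p, used_o, matched = set(), set(), []
    for err, _, pi, oi in candidates:
        if pi in used_p or oi in used_o:
            continue
        used_p.add(pi)
        used_o.add(oi)
        matched.append((pi, oi))
    return matched


def naive_similarity(ions, matched, obs_int):
    """Direct evaluation of the five agreement metrics."""
    n = len(ions)
    if n == 0:
        return {
            "pct_matched": 0.0,
            "log_distance": 0.0,
            "cosine": 0.0,
            "angular": 0.5,
            "cross_entropy": 0.0,
        }
    pred = [ion.intensity for ion in ions]
    total_p = sum(pred)
    if total_p > 0:
        pred = [p / total_p for p in pred]
    obs = [0.0] * n
    for pi, oi in matched:
        obs[pi] = obs_int[oi]
    total_o = sum(obs)
    if total_o > 0:
        obs = [o / total_o for o in obs]
    dot = sum(a * b for a, b in zip(obs, pred))
    na = math.sqrt(sum(a * a for a in obs))
    nb = math.sqrt(sum(b * b for b in pred))
    cosine = dot / (na * nb) if na > 0 and nb > 0 else 0.0
    cosine = min(max(cosine, 0.0), 1.0)
    return {
        "pct_matched": 100.0 * len(matched) / n,
        "log_distance": sum(
            abs(math.log(o + EPS) - math.log(p + EPS)) for o, p in zip(obs, pred)
        )
        / n,
        "cosine": cosine,
        "angular": 1.0 - math.acos(cosine) / math.pi,
        "cross_entropy": -sum(o * math.log(p + EPS) for o, p in zip(obs, pred)),
    }


def naive_rt_features(rt_apex, rt_pred, slope, intercept, rt_ms2):
    delta = rt_apex - (slope * rt_pred + intercept)
    return {
        "rt_abs_error": abs(delta),
        "rt_sq_error": delta**2,
        "rt_log_error": math.log(1.0 + abs(delta)),
        "rt_meas_apex_abs": abs(rt_ms2 - rt_apex),
    }


def naive_consecutive(matched_ordinals):
    k = 0
    while (k + 1) in matched_ordinals:
        k += 1
    return k
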