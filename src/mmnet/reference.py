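"""Published summary statistics of the source KNHANES V–VII older-adult study.

The underlying survey microdata are government-restricted and not bundled;
what IS published are stratified summary tables: per-(sex × HRQoL-group)
disease counts, the twenty strongest association rules of the poor-HRQoL
group per sex (support / confidence / lift at one printed decimal), overall
group sizes, and the multimorbidity-category × HRQoL-group cross table.
This module carries those numbers as data and provides the arithmetic to
turn them back into the integer count layer the rule engine operates on,
so the published cells act as a worked example for the whole pipeline.

All percentages here are exactly as printed (half-up rounded to 1 decimal).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from ._round import round_half_up
from .panel import DISEASES

TOTAL_N = 12657

#: Cohort size per (sex, HRQoL group).
STRATUM_SIZES: dict[tuple[str, str], int] = {
    ("male", "good"): 3098,
    ("male", "normal"): 1907,
    ("male", "poor"): 457,
    ("female", "good"): 2579,
    ("female", "normal"): 3270,
    ("female", "poor"): 1346,
}

#: Published disease counts per stratum, panel order as in DISEASES.
DISEASE_COUNTS: dict[tuple[str, str], dict[str, int]] = {
    ("male", "good"): dict(zip(DISEASES, (155, 245, 79, 291, 298, 40, 586, 558, 1440, 77, 103, 19, 126, 46, 289))),
    ("male", "normal"): dict(zip(DISEASES, (131, 359, 100, 180, 263, 75, 429, 357, 1027, 50, 79, 16, 164, 27, 196))),
    ("male", "poor"): dict(zip(DISEASES, (41, 131, 41, 46, 77, 36, 139, 88, 255, 20, 32, 7, 98, 4, 50))),
    ("female", "good"): dict(zip(DISEASES, (97, 809, 108, 128, 200, 143, 467, 791, 1390, 39, 30, 10, 96, 145, 122))),
    ("female", "normal"): dict(zip(DISEASES, (176, 1661, 189, 178, 313, 300, 684, 1106, 1938, 58, 56, 19, 148, 181, 150))),
    ("female", "poor"): dict(zip(DISEASES, (103, 845, 129, 73, 174, 176, 324, 393, 842, 25, 43, 16, 132, 83, 66))),
}

#: Published node strengths (support-sum over all 14 partners) per stratum.
NODE_STRENGTHS: dict[tuple[str, str], dict[str, float]] = {
    ("male", "good"): dict(zip(DISEASES, (0.09, 0.12, 0.04, 0.12, 0.18, 0.02, 0.31, 0.33, 0.55, 0.04, 0.07, 0.01, 0.08, 0.02, 0.12))),
    ("male", "normal"): dict(zip(DISEASES, (0.16, 0.32, 0.10, 0.17, 0.30, 0.08, 0.47, 0.42, 0.81, 0.05, 0.10, 0.03, 0.18, 0.03, 0.18))),
    ("male", "poor"): dict(zip(DISEASES, (0.23, 0.55, 0.22, 0.19, 0.42, 0.23, 0.70, 0.54, 1.11, 0.14, 0.20, 0.05, 0.48, 0.02, 0.23))),
    ("female", "good"): dict(zip(DISEASES, (0.10, 0.51, 0.09, 0.09, 0.17, 0.12, 0.39, 0.56, 0.79, 0.04, 0.04, 0.01, 0.08, 0.12, 0.08))),
    ("female", "normal"): dict(zip(DISEASES, (0.15, 0.90, 0.14, 0.11, 0.25, 0.22, 0.49, 0.76, 1.07, 0.04, 0.05, 0.02, 0.12, 0.13, 0.11))),
    ("female", "poor"): dict(zip(DISEASES, (0.25, 1.27, 0.26, 0.14, 0.39, 0.37, 0.68, 0.82, 1.36, 0.05, 0.12, 0.04, 0.29, 0.18, 0.13))),
}

#: The twenty strongest poor-HRQoL rules per sex, ordered by support:
#: (disease X, disease Y, support %, confidence X→Y %, confidence Y→X %, lift).
#: Each unordered pair is stored once; both directed rules derive from it.
TOP_RULES_POOR: dict[str, list[tuple[str, str, float, float, float, float]]] = {
    "male": [
        ("hypertension", "diabetes", 20.8, 37.3, 68.3, 1.2),
        ("hypertension", "arthritis", 15.8, 28.2, 55.0, 1.0),
        ("hypertension", "hyperlipidemia", 15.1, 27.1, 78.4, 1.4),
        ("hypertension", "stroke", 13.8, 24.7, 64.3, 1.2),
        ("hypertension", "ckd", 12.3, 22.0, 72.7, 1.3),
        ("stroke", "diabetes", 9.4, 43.9, 30.9, 1.4),
        ("hyperlipidemia", "diabetes", 8.1, 42.0, 26.6, 1.4),
        ("arthritis", "diabetes", 6.3, 22.1, 20.9, 0.7),
        ("diabetes", "ckd", 6.3, 20.9, 37.7, 1.2),
        ("hypertension", "angina_pectoris", 5.7, 10.2, 63.4, 1.1),
    ],
    "female": [
        ("hypertension", "arthritis", 41.6, 66.5, 66.3, 1.1),
        ("hypertension", "hyperlipidemia", 22.5, 36.0, 77.1, 1.2),
        ("hyperlipidemia", "arthritis", 20.1, 68.7, 32.0, 1.1),
        ("hypertension", "diabetes", 19.1, 30.5, 79.3, 1.3),
        ("arthritis", "diabetes", 15.8, 25.1, 65.4, 1.0),
        ("hyperlipidemia", "diabetes", 10.8, 36.9, 44.8, 1.5),
        ("hypertension", "ckd", 10.2, 16.3, 78.7, 1.3),
        ("arthritis", "depression", 8.8, 14.0, 67.0, 1.1),
        ("hypertension", "depression", 8.2, 13.2, 63.1, 1.0),
        ("hypertension", "stroke", 7.8, 12.5, 79.5, 1.3),
    ],
}

#: Multimorbidity-category counts (0 / 1 / 2 / ≥3 diseases) per HRQoL group.
MULTIMORBIDITY_BY_GROUP: dict[str, tuple[int, int, int, int]] = {
    "good": (1297, 1756, 1366, 1258),
    "normal": (686, 1310, 1399, 1782),
    "poor": (143, 370, 477, 813),
}


def stratum_prevalence(sex: str, hrqol: str) -> np.ndarray:
    """Published disease prevalences (proportions) for one stratum, panel order."""
    n = STRATUM_SIZES[(sex, hrqol)]
    return np.array([DISEASE_COUNTS[(sex, hrqol)][d] / n for d in DISEASES])


def overall_prevalence() -> pd.Series:
    """Overall disease prevalence (%) reconstructed by summing stratum counts."""
    totals = {
        d: sum(DISEASE_COUNTS[key][d] for key in DISEASE_COUNTS) for d in DISEASES
    }
    return pd.Series(
        {d: round_half_up(100.0 * c / TOTAL_N, 1) for d, c in totals.items()},
        name="prevalence_pct",
    )


def reconstruct_joint_count(
    n: int,
    n_x: int,
    n_y: int,
    support_pct: float,
    conf_xy_pct: float | None = None,
    conf_yx_pct: float | None = None,
    lift: float | None = None,
    window: int = 3,
) -> int:
    """Integer joint count most consistent with a printed rule row.

    The printed cells are half-up rounded to one decimal, so the naive
    nearest integer to ``support_pct/100 * n`` can disagree with the printed
    confidences by one count (e.g. a support printed from 15.750%). The
    search scans a small window of candidate counts and keeps the candidate
    whose recomputed support / confidences / lift all round back to the
    printed cells, tie-broken by closeness to ``support_pct/100 * n``.
    """
    center = support_pct / 100.0 * n
    printed: list[tuple[float, int]] = [(support_pct, 1)]  # (value, decimals-scale id)
    best: tuple[int, float, int] | None = None  # (-n_matches, distance, candidate)
    lo = max(0, int(np.floor(center)) - window)
    hi = min(min(n_x, n_y), int(np.ceil(center)) + window)
    for c in range(lo, hi + 1):
        cells = [(100.0 * c / n, support_pct)]
        if conf_xy_pct is not None:
            cells.append((100.0 * c / n_x, conf_xy_pct))
        if conf_yx_pct is not None:
            cells.append((100.0 * c / n_y, conf_yx_pct))
        if lift is not None:
            cells.append((c * n / (n_x * n_y), lift))
        n_match = sum(round_half_up(val, 1) == target for val, target in cells)
        key = (-n_match, abs(c - center), c)
        if best is None or key < best:
            best = key
    assert best is not None
    return best[2]


def poor_pair_counts(sex: str) -> "pd.DataFrame":
    """Synthetic joint-count matrix for the poor stratum of one sex.

    Published data fix the marginal counts of all 15 diseases and the joint
    counts of the ten strongest pairs; every unpublished pair is filled in
    at its independence expectation (rounded). The result is a plausible —
    explicitly synthetic — reconstruction used for fixture networks, not a
    recovery of the real joint distribution.
    """
    n = STRATUM_SIZES[(sex, "poor")]
    counts = DISEASE_COUNTS[(sex, "poor")]
    joint = pd.DataFrame(0, index=list(DISEASES), columns=list(DISEASES), dtype=int)
    for x, y in itertools.combinations(DISEASES, 2):
        c = int(round(counts[x] * counts[y] / n))
        joint.loc[x, y] = joint.loc[y, x] = min(c, counts[x], counts[y])
    for x, y, s, cxy, cyx, lf in TOP_RULES_POOR[sex]:
        c = reconstruct_joint_count(n, counts[x], counts[y], s, cxy, cyx, lf)
        joint.loc[x, y] = joint.loc[y, x] = c
    for d in DISEASES:
        joint.loc[d, d] = counts[d]
    return joint
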