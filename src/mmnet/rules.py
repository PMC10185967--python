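"""Pairwise disease association rules: support, confidence, lift.

For a directed rule X → Y within one stratum of size n with counts n_X,
n_Y and joint count n_XY:

    support    = n_XY / n           (co-occurrence prevalence, P(X,Y))
    confidence = n_XY / n_X         (P(Y | X))
    lift       = n_XY·n / (n_X·n_Y) (observed-to-expected ratio)

Rules are pairwise only (itemsets of size 2); both directed rules of an
unordered pair share support and lift and differ only in confidence. All
internal arithmetic is full precision; printed percentages are half-up
rounded at one decimal in the export layer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._round import round_half_up
from .cohort import Cohort
from .panel import DISEASES, StratumSpec

RULE_COLUMNS = ("antecedent", "consequent", "n", "n_x", "n_y", "n_xy",
                "support", "confidence", "lift")


@dataclass(frozen=True)
class PairCounts:
    """Integer count layer of one stratum: joint matrix plus marginals."""

    n: int
    marginals: pd.Series        # count per disease
    joint: pd.DataFrame         # symmetric; diagonal = marginals
    stratum: str = "all_all"

    def __post_init__(self) -> None:
        if not np.array_equal(self.joint.values, self.joint.values.T):
            raise ValueError("joint count matrix must be symmetric")
        if (np.diag(self.joint.values) != self.marginals.values).any():
            raise ValueError("joint diagonal must equal the marginal counts")


def pair_counts(cohort: Cohort, stratum: StratumSpec = StratumSpec()) -> PairCounts:
    """Joint and marginal disease counts for one stratum (X.T @ X on flags)."""
    sub = cohort.subset(stratum)
    flags = sub.disease_matrix().astype(np.int64)
    joint = flags.T @ flags
    names = list(DISEASES)
    return PairCounts(
        n=len(sub),
        marginals=pd.Series(np.diag(joint), index=names, name="count"),
        joint=pd.DataFrame(joint, index=names, columns=names),
        stratum=stratum.label,
    )


def rules_from_counts(counts: PairCounts, min_support: float = 0.0) -> pd.DataFrame:
    """Both directed rules for every unordered pair with support ≥ min_support.

    This is the single computational core: it is fed either by
    :func:`pair_counts` on a cohort or by externally reconstructed integer
    counts (e.g. published summary tables).
    """
    if not 0.0 <= min_support <= 1.0:
        raise ValueError("min_support must lie in [0, 1]")
    n = counts.n
    rows = []
    for x, y in itertools.combinations(counts.marginals.index, 2):
        n_x = int(counts.marginals[x])
        n_y = int(counts.marginals[y])
        n_xy = int(counts.joint.loc[x, y])
        support = n_xy / n
        if support < min_support:
            continue
        lift = np.nan if n_x == 0 or n_y == 0 else n_xy * n / (n_x * n_y)
        for a, b, n_a in ((x, y, n_x), (y, x, n_y)):
            rows.append(
                {
                    "antecedent": a,
                    "consequent": b,
                    "n": n,
                    "n_x": n_a,
                    "n_y": n_y if a == x else n_x,
                    "n_xy": n_xy,
                    "support": support,
                    "confidence": np.nan if n_a == 0 else n_xy / n_a,
                    "lift": lift,
                }
            )
    df = pd.DataFrame(rows, columns=list(RULE_COLUMNS))
    df = sort_rules(df)
    df.attrs["stratum"] = counts.stratum
    return df


def mine_rules(
    cohort: Cohort,
    stratum: StratumSpec = StratumSpec(),
    min_support: float = 0.0,
) -> pd.DataFrame:
    """Mine all pairwise rules of one stratum, sorted by the canonical order."""
    return rules_from_counts(pair_counts(cohort, stratum), min_support=min_support)


def _pair_key(df: pd.DataFrame) -> pd.Series:
    """Canonical unordered-pair label, used to keep rule mates adjacent."""
    return df.apply(
        lambda r: "|".join(sorted((r["antecedent"], r["consequent"]))), axis=1
    )


def sort_rules(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic rule order: support desc, lift desc, then pair and
    antecedent labels ascending (mates stay adjacent)."""
    if df.empty:
        return df.reset_index(drop=True)
    key = df.assign(_pair=_pair_key(df))
    key = key.sort_values(
        by=["support", "lift", "_pair", "antecedent"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    return key.drop(columns="_pair").reset_index(drop=True)


def top_rules(rules: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """First ``k`` directed rules by the canonical order, never splitting a
    pair: if ``k`` would cut between two mates the pair is kept whole."""
    if k < 1:
        raise ValueError("k must be at least 1")
    df = sort_rules(rules)
    if k >= len(df):
        return df
    # ceil to pair boundary
    pairs = _pair_key(df)
    kept = list(pairs.iloc[:k])
    if k < len(df) and pairs.iloc[k] == kept[-1]:
        k += 1
    out = df.iloc[:k].reset_index(drop=True)
    out.attrs.update(df.attrs)
    return out


def lift_matrix(cohort: Cohort, stratum: StratumSpec = StratumSpec()) -> pd.DataFrame:
    """Symmetric 15×15 lift matrix; diagonal and zero-marginal pairs are NaN."""
    return lift_matrix_from_counts(pair_counts(cohort, stratum))


def lift_matrix_from_counts(counts: PairCounts) -> pd.DataFrame:
    names = list(counts.marginals.index)
    m = np.asarray(counts.marginals, dtype=float)
    joint = counts.joint.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lift = joint * counts.n / np.outer(m, m)
    lift[np.outer(m, m) == 0] = np.nan
    np.fill_diagonal(lift, np.nan)
    out = pd.DataFrame(lift, index=names, columns=names)
    out.attrs["stratum"] = counts.stratum
    return out


# ---------------------------------------------------------------------------
# export layer (printed-table formatting)

def format_rules(rules: pd.DataFrame) -> pd.DataFrame:
    """Report layout: percentages half-up at 1 decimal, lift at 1 decimal."""
    out = rules.copy()
    out["support_pct"] = [round_half_up(100 * v, 1) for v in out["support"]]
    out["confidence_pct"] = [round_half_up(100 * v, 1) for v in out["confidence"]]
    out["lift"] = [np.nan if np.isnan(v) else round_half_up(v, 1) for v in out["lift"]]
    return out[["antecedent", "consequent", "n", "n_x", "n_y", "n_xy",
                "support_pct", "confidence_pct", "lift"]]


def write_rules(rules: pd.DataFrame, path: str | Path) -> None:
    format_rules(rules).to_csv(path, index=False)


def write_lift_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, index_label="disease")
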