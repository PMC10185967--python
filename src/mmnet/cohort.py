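"""Canonical cohort data model, multimorbidity counting and descriptive tables.

A :class:`Cohort` wraps one participant-per-row :class:`pandas.DataFrame`
whose required columns are the design fields (id, sex, age group, survey
weight), the 15 binary disease flags in panel order, the EQ-5D index and its
HRQoL group. Socio-demographic and behaviour covariates plus any extra
passthrough columns ride along untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._round import round_half_up
from .eq5d import DIMENSIONS, classify_hrqol
from .panel import DISEASES, POOR_CUTOFF, StratumSpec

COVARIATES = (
    "marital",
    "income",
    "working",
    "education",
    "bmi_category",
    "smoking",
    "drinking",
    "walking",
    "sleeping",
    "stress",
)

EQ5D_RESPONSE_COLUMNS = tuple(f"eq5d_{d}" for d in DIMENSIONS)

CORE_COLUMNS = (
    ("id", "sex", "age_group", "weight", "stratum_id", "cluster_id")
    + COVARIATES
    + DISEASES
    + EQ5D_RESPONSE_COLUMNS
    + ("eq5d_index", "hrqol")
)

MULTIMORBIDITY_CATEGORIES = ("0", "1", "2", ">=3")


@dataclass(frozen=True)
class ParticipantRecord:
    """One individual's covariates, disease flags, weight and HRQoL measures."""

    id: str
    sex: str
    age_group: str
    weight: float
    diseases: tuple[int, ...]
    eq5d_index: float
    hrqol: str
    covariates: dict[str, str] = field(default_factory=dict)
    eq5d_responses: Optional[tuple[int, int, int, int, int]] = None
    stratum_id: Optional[str] = None
    cluster_id: Optional[str] = None


class Cohort:
    """Participant table plus the disease panel it follows.

    Parameters
    ----------
    data:
        One row per participant; must contain the 15 disease columns (0/1),
        'sex', 'weight', 'eq5d_index' and 'hrqol'.
    provenance:
        Free-form reproducibility metadata (config hash, seed) for cohorts
        produced by the synthetic generator.
    """

    def __init__(self, data: pd.DataFrame, provenance: Optional[dict] = None):
        missing = [c for c in ("sex", "weight", "eq5d_index", "hrqol") if c not in data.columns]
        missing += [d for d in DISEASES if d not in data.columns]
        if missing:
            raise ValueError(f"cohort table is missing required columns: {missing}")
        flags = data[list(DISEASES)]
        if not flags.isin((0, 1)).all().all():
            raise ValueError("disease flags must be 0/1")
        if (data["weight"] <= 0).any():
            raise ValueError("survey weights must be strictly positive")
        self.data = data.reset_index(drop=True)
        self.provenance = dict(provenance or {})

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    def disease_matrix(self) -> np.ndarray:
        """n × 15 uint8 flag matrix in panel order."""
        return self.data[list(DISEASES)].to_numpy(dtype=np.uint8)

    def records(self) -> Iterator[ParticipantRecord]:
        has_resp = all(c in self.data.columns for c in EQ5D_RESPONSE_COLUMNS)
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            resp = None
            if has_resp and not any(pd.isna(d[c]) for c in EQ5D_RESPONSE_COLUMNS):
                resp = tuple(int(d[c]) for c in EQ5D_RESPONSE_COLUMNS)
            yield ParticipantRecord(
                id=str(d.get("id", "")),
                sex=d["sex"],
                age_group=d.get("age_group", ""),
                weight=float(d["weight"]),
                diseases=tuple(int(d[k]) for k in DISEASES),
                eq5d_index=float(d["eq5d_index"]),
                hrqol=d["hrqol"],
                covariates={k: d[k] for k in COVARIATES if k in d},
                eq5d_responses=resp,
                stratum_id=None if pd.isna(d.get("stratum_id")) else str(d.get("stratum_id")),
                cluster_id=None if pd.isna(d.get("cluster_id")) else str(d.get("cluster_id")),
            )

    def subset(self, stratum: StratumSpec) -> "Cohort":
        sub = self.data[stratum.mask(self.data)]
        if sub.empty:
            raise ValueError(f"stratum {stratum.label!r} is empty")
        return Cohort(sub, provenance={**self.provenance, "stratum": stratum.label})

    def passthrough_columns(self) -> list[str]:
        """Columns carried along that the package does not interpret."""
        return [c for c in self.data.columns if c not in CORE_COLUMNS]


# ---------------------------------------------------------------------------
# multimorbidity counting

def count_morbidities(flags: Sequence[int] | ParticipantRecord) -> tuple[int, str]:
    """Number of chronic diseases and its category ('0', '1', '2', '>=3')."""
    if isinstance(flags, ParticipantRecord):
        flags = flags.diseases
    arr = np.asarray(flags)
    if arr.shape[-1] != len(DISEASES):
        raise ValueError(f"expected {len(DISEASES)} disease flags, got {arr.shape[-1]}")
    count = int(arr.sum())
    return count, MULTIMORBIDITY_CATEGORIES[min(count, 3)]


def morbidity_categories(cohort: Cohort) -> pd.Series:
    """Per-participant multimorbidity category as a categorical Series."""
    counts = cohort.disease_matrix().sum(axis=1)
    cats = np.array(MULTIMORBIDITY_CATEGORIES, dtype=object)[np.minimum(counts, 3)]
    return pd.Series(
        pd.Categorical(cats, categories=list(MULTIMORBIDITY_CATEGORIES)),
        index=cohort.data.index,
        name="multimorbidity",
    )


def ckd_from_egfr(egfr: float, threshold: float = 60.0) -> int:
    """CKD flag from an estimated glomerular filtration rate.

    CKD is an eGFR *strictly below* 60 mL/min/1.73 m²; the boundary value
    60.0 is not CKD.
    """
    if egfr <= 0:
        raise ValueError(f"eGFR must be positive, got {egfr}")
    return int(egfr < threshold)


# ---------------------------------------------------------------------------
# descriptive tables

def prevalence_table(
    cohort: Cohort, stratum: StratumSpec = StratumSpec(), weighted: bool = False
) -> pd.DataFrame:
    """Per-disease count and percent within one stratum.

    The published stratified disease tables are unweighted counts over the
    realized sample (verified against printed cells, e.g. 139/457 → 30.4%);
    ``weighted=True`` switches to survey-weight sums for completeness.
    Returns a DataFrame indexed by disease with columns ``count``,
    ``percent`` (full precision) and ``percent_fmt`` (half-up, 1 decimal);
    the stratum size is in ``attrs['n']``.
    """
    sub = cohort.subset(stratum)
    flags = sub.disease_matrix()
    if weighted:
        w = sub.data["weight"].to_numpy()
        total = w.sum()
        counts = flags.T @ w
    else:
        total = float(len(sub))
        counts = flags.sum(axis=0).astype(float)
    pct = 100.0 * counts / total
    out = pd.DataFrame(
        {
            "count": counts if weighted else counts.astype(int),
            "percent": pct,
            "percent_fmt": [round_half_up(p, 1) for p in pct],
        },
        index=pd.Index(list(DISEASES), name="disease"),
    )
    out.attrs["n"] = int(len(sub))
    out.attrs["stratum"] = stratum.label
    out.attrs["weighted"] = weighted
    return out


def compare_groups(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Chi-square test of independence on a G × K contingency table.

    Returns ``(statistic, dof, p_value)`` without continuity correction.
    Expected cells below 1 trigger a warning but the test is still returned.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a 2-D contingency table with at least 2 rows and columns")
    if (obs < 0).any():
        raise ValueError("contingency counts must be nonnegative")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    if (expected < 1).any():
        warnings.warn(
            "chi-square approximation unreliable: expected cell count below 1",
            stacklevel=2,
        )
    return float(chi2), int(dof), float(p)


def group_comparison_pvalues(cohort: Cohort, sex: str = "all") -> pd.Series:
    """Across-HRQoL-group chi-square p-value per disease (Table-style footnote)."""
    groups = ["good", "normal", "poor"]
    tables = {
        g: prevalence_table(cohort, StratumSpec(g, sex)) for g in groups
    }
    ns = {g: tables[g].attrs["n"] for g in groups}
    pvals = {}
    for d in DISEASES:
        cont = [[tables[g].loc[d, "count"], ns[g] - tables[g].loc[d, "count"]] for g in groups]
        _, _, p = compare_groups(cont)
        pvals[d] = p
    return pd.Series(pvals, name="p_value")


# ---------------------------------------------------------------------------
# cohort file I/O (delimited text, lossless round trip)

_HEADER_COMMENT = (
    "# mmnet cohort file: CSV, one row per participant; disease flags are 0/1 "
    "in panel order; missing values are empty cells.\n"
)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as commented-header CSV (lossless for repr-exact floats)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(_HEADER_COMMENT)
        for key, val in sorted(cohort.provenance.items()):
            fh.write(f"# provenance {key}={val}\n")
        cohort.data.to_csv(fh, index=False)


def read_cohort(path: str | Path, poor_cutoff: float = POOR_CUTOFF) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort` or hand-prepared.

    Requires either an ``eq5d_index`` column or the five response columns
    (from which the index is scored upstream). Unknown disease-like columns
    raise; genuinely extra covariates are preserved as passthrough. Records
    with a missing EQ-5D index are dropped with a warning (they cannot be
    grouped), mirroring the exclusion applied in the source survey analyses.
    """
    path = Path(path)
    provenance: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.startswith("# provenance "):
                key, _, val = line[len("# provenance "):].strip().partition("=")
                provenance[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, dtype={"id": str, "stratum_id": str, "cluster_id": str})

    missing_diseases = [d for d in DISEASES if d not in df.columns]
    if missing_diseases:
        raise ValueError(
            f"cohort file lacks disease columns {missing_diseases}; "
            f"expected the full panel {list(DISEASES)}"
        )
    if "eq5d_index" not in df.columns and not all(
        c in df.columns for c in EQ5D_RESPONSE_COLUMNS
    ):
        raise ValueError(
            "cohort file must contain either an 'eq5d_index' column or the five "
            f"EQ-5D response columns {list(EQ5D_RESPONSE_COLUMNS)}"
        )
    if "eq5d_index" in df.columns:
        n_missing = int(df["eq5d_index"].isna().sum())
        if n_missing:
            warnings.warn(
                f"dropping {n_missing} records with missing EQ-5D index", stacklevel=2
            )
            df = df[df["eq5d_index"].notna()].reset_index(drop=True)
    if "hrqol" not in df.columns:
        df["hrqol"] = [classify_hrqol(v, poor_cutoff) for v in df["eq5d_index"]]
    cohort = Cohort(df, provenance=provenance)
    extra = cohort.passthrough_columns()
    if extra:
        cohort.provenance["passthrough"] = ",".join(extra)
    return cohort
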