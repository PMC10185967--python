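"""Chronic-disease panel and analysis strata.

The package analyses the 15 chronic diseases measured consistently across
KNHANES V–VII for adults aged 65+. Cancer sites are collapsed into a single
``cancer`` flag and hepatitis B/C plus cirrhosis into ``liver_disease``
upstream of this package; the collapsed flags are the inputs here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Canonical panel order (alphabetical by display name). Every disease matrix,
#: rule table and network in the package follows this order.
DISEASES: tuple[str, ...] = (
    "angina_pectoris",
    "arthritis",
    "asthma",
    "cancer",
    "ckd",
    "depression",
    "diabetes",
    "hyperlipidemia",
    "hypertension",
    "liver_disease",
    "myocardial_infarction",
    "renal_failure",
    "stroke",
    "thyroid",
    "tuberculosis",
)

DISPLAY_NAMES: dict[str, str] = {
    "angina_pectoris": "Angina pectoris",
    "arthritis": "Arthritis",
    "asthma": "Asthma",
    "cancer": "Cancer",
    "ckd": "CKD",
    "depression": "Depression",
    "diabetes": "Diabetes",
    "hyperlipidemia": "Hyperlipidemia",
    "hypertension": "Hypertension",
    "liver_disease": "Liver disease",
    "myocardial_infarction": "Myocardial infarction",
    "renal_failure": "Renal failure",
    "stroke": "Stroke",
    "thyroid": "Thyroid",
    "tuberculosis": "Tuberculosis",
}

SEXES = ("male", "female")
HRQOL_GROUPS = ("good", "normal", "poor")
AGE_GROUPS = ("65-69", "70-74", "75-79", ">=80")

#: Default poor-HRQoL cutpoint: the lowest 5% of the EQ-5D index of the full
#: adult survey population, a fixed constant in this analysis.
POOR_CUTOFF = 0.721


@dataclass(frozen=True)
class StratumSpec:
    """One analysis cell: an HRQoL group crossed with sex, either may be 'all'."""

    hrqol: str = "all"
    sex: str = "all"

    def __post_init__(self) -> None:
        if self.hrqol not in HRQOL_GROUPS + ("all",):
            raise ValueError(f"unknown HRQoL group {self.hrqol!r}")
        if self.sex not in SEXES + ("all",):
            raise ValueError(f"unknown sex {self.sex!r}")

    @property
    def label(self) -> str:
        return f"{self.sex}_{self.hrqol}"

    def mask(self, df: pd.DataFrame) -> pd.Series:
        """Boolean row mask of ``df`` (needs 'sex' and 'hrqol' columns)."""
        m = pd.Series(True, index=df.index)
        if self.hrqol != "all":
            m &= df["hrqol"] == self.hrqol
        if self.sex != "all":
            m &= df["sex"] == self.sex
        return m


def analysis_strata() -> list[StratumSpec]:
    """The six sex × HRQoL cells plus the per-HRQoL and overall marginals."""
    cells = [StratumSpec(h, s) for s in SEXES for h in HRQOL_GROUPS]
    cells += [StratumSpec(h, "all") for h in HRQOL_GROUPS]
    cells.append(StratumSpec("all", "all"))
    return cells
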