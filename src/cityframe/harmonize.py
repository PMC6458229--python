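"""Mortality-record harmonization.

Raw country death records (age, sex, education, ICD-9/10 cause, sub-city
location) are converted to a common coding: single-year and 5-year age,
male/female/missing sex, a four-level education recode, a configured
cause-of-death grouping (longest-ICD-prefix match against a cause map), and
a flag separating well-defined causes from ill-defined diseases (ICD-10 R
chapter) and injuries of undetermined intent (Y10–Y34, Y87.2). Harmonization
is record-count preserving, deterministic, and idempotent; unmapped codes
become missing and are tallied in a data-quality report.

Records are handled as pandas DataFrames with one row per death.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

MISSING = "missing"

#: 5-year age bands with an open top band
AGE5_BANDS = [f"{lo}-{lo + 4}" for lo in range(0, 85, 5)] + ["85+"]
AGE5_TOP = 85

EDUCATION_LEVELS = [
    "less than primary",
    "primary completed",
    "secondary completed",
    "more than secondary",
]

SEX_LEVELS = ["male", "female"]

ILL_FLAGS = ["well_defined", "ill_defined_disease", "ill_defined_injury"]

#: pseudo cause-group labels carried by ill-defined deaths
ILL_DEFINED_DISEASE = "_ill_defined_disease"
ILL_DEFINED_INJURY = "_ill_defined_injury"


class HarmonizationError(ValueError):
    pass


def age_to_band(age: float) -> str:
    """Map an age in years to its 5-year band label ('0-4' ... '80-84', '85+')."""
    if age >= AGE5_TOP:
        return "85+"
    lo = int(age) // 5 * 5
    return f"{lo}-{lo + 4}"


def harmonize_age(age_value: float | None, scheme: str = "single") -> tuple[float | None, str]:
    """Harmonize one age value.

    Returns ``(age_single, age5)``. Under ``scheme='single'`` the single-year
    value is retained and the band derived; under ``scheme='five_year'`` the
    value is taken as a band lower bound (single-year age left missing).
    Missing propagates; ages above 130 are rejected as probable unit errors.
    """
    if age_value is None or (isinstance(age_value, float) and np.isnan(age_value)):
        return None, MISSING
    if age_value < 0 or age_value > 130:
        raise HarmonizationError(f"implausible age {age_value}")
    if scheme == "single":
        return float(age_value), age_to_band(age_value)
    if scheme == "five_year":
        return None, age_to_band(age_value)
    raise HarmonizationError(f"unknown age scheme {scheme!r}")


def harmonize_sex(source_value, codebook: Mapping) -> str:
    """Map a source sex code to male/female/missing; unmapped codes → missing."""
    if source_value is None or (isinstance(source_value, float) and np.isnan(source_value)):
        return MISSING
    if source_value in SEX_LEVELS or source_value == MISSING:
        return str(source_value)
    v = codebook.get(source_value, codebook.get(str(source_value), MISSING))
    return v if v in SEX_LEVELS else MISSING


def recode_education(source_value, codebook: Mapping) -> str:
    """Map a source education code to the four-level recode; unmapped → missing."""
    if source_value is None or (isinstance(source_value, float) and np.isnan(source_value)):
        return MISSING
    if source_value in EDUCATION_LEVELS or source_value == MISSING:
        return str(source_value)
    v = codebook.get(source_value, codebook.get(str(source_value), MISSING))
    return v if v in EDUCATION_LEVELS else MISSING


_ICD_PATTERN = re.compile(r"^[A-Z]?\d{2,4}[A-Z]?$|^E\d{3,4}$", re.IGNORECASE)


def normalize_icd(icd_code: str) -> str:
    """Uppercase an ICD code and strip dots ('Y87.2' → 'Y872')."""
    return str(icd_code).replace(".", "").strip().upper()


def _validate_icd(code: str) -> str:
    norm = normalize_icd(code)
    if not _ICD_PATTERN.match(norm):
        raise HarmonizationError(f"malformed ICD code {code!r}")
    return norm


@dataclass
class CauseMap:
    """Prefix table mapping ICD codes to cause groups.

    ``prefixes`` maps (icd_revision, prefix) → group label; the longest
    matching prefix wins. Built from a CSV with columns
    ``prefix, revision, group``.
    """

    prefixes: dict[tuple[int, str], str] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CauseMap":
        table = {
            (int(row.revision), normalize_icd(row.prefix)): str(row.group)
            for row in frame.itertuples()
        }
        return cls(prefixes=table)

    @classmethod
    def from_csv(cls, path) -> "CauseMap":
        return cls.from_frame(pd.read_csv(path, dtype=str).astype({"revision": int}))

    def lookup(self, icd_code: str, icd_revision: int) -> str | None:
        norm = _validate_icd(icd_code)
        for k in range(len(norm), 0, -1):
            group = self.prefixes.get((icd_revision, norm[:k]))
            if group is not None:
                return group
        return None


def demo_cause_map() -> CauseMap:
    """A reduced cause-classification map (~12 groups) for demonstrations and tests.

    The full harmonized cause taxonomy is an external configuration artifact;
    analyses supply their own map via :meth:`CauseMap.from_csv`.
    """
    rows = [
        # ICD-10
        (10, "A", "infectious"), (10, "B", "infectious"),
        (10, "C", "cancer"), (10, "D0", "cancer"), (10, "D1", "cancer"),
        (10, "D2", "cancer"), (10, "D3", "cancer"), (10, "D4", "cancer"),
        (10, "E", "endocrine"),
        (10, "I", "cardiovascular"),
        (10, "J", "respiratory"),
        (10, "K", "digestive"),
        (10, "P", "perinatal"),
        (10, "V", "road injury"), (10, "W", "unintentional injury"),
        (10, "X", "unintentional injury"),
        (10, "X85", "homicide"), (10, "X86", "homicide"), (10, "X87", "homicide"),
        (10, "X88", "homicide"), (10, "X89", "homicide"), (10, "X9", "homicide"),
        (10, "Y0", "homicide"),
        (10, "X6", "suicide"), (10, "X7", "suicide"), (10, "X80", "suicide"),
        (10, "X81", "suicide"), (10, "X82", "suicide"), (10, "X83", "suicide"),
        (10, "X84", "suicide"),
        # ICD-9
        (9, "0", "infectious"), (9, "1", "cancer"),
        (9, "2", "endocrine"),
        (9, "39", "cardiovascular"), (9, "4", "cardiovascular"),
        (9, "46", "respiratory"), (9, "47", "respiratory"), (9, "48", "respiratory"),
        (9, "49", "respiratory"), (9, "5", "digestive"),
        (9, "76", "perinatal"), (9, "77", "perinatal"),
        (9, "E81", "road injury"), (9, "E88", "unintentional injury"),
        (9, "E95", "suicide"), (9, "E96", "homicide"),
    ]
    return CauseMap(prefixes={(rev, p): g for rev, p, g in rows})


def map_cause(icd_code: str, icd_revision: int, cause_map: CauseMap) -> str:
    """Group an ICD code by longest-prefix match; unmatched → missing."""
    group = cause_map.lookup(icd_code, icd_revision)
    return group if group is not None else MISSING


#: ICD-9 ill-defined sets (overridable); the published rule names only ICD-10 codes
ICD9_ILL_DISEASE_RANGE = (780, 799)
ICD9_ILL_INJURY_RANGE = (980, 989)  # E980–E989


def flag_ill_defined(
    icd_code: str,
    icd_revision: int,
    icd9_disease_range: tuple[int, int] = ICD9_ILL_DISEASE_RANGE,
    icd9_injury_range: tuple[int, int] = ICD9_ILL_INJURY_RANGE,
) -> str:
    """Classify a cause code as well-defined, ill-defined disease, or ill-defined injury.

    ICD-10: R00–R99 are ill-defined diseases; Y10–Y34 and Y87.2 are injuries
    of undetermined intent. ICD-9 defaults: 780–799 and E980–E989.
    """
    norm = _validate_icd(icd_code)
    if icd_revision == 10:
        if norm.startswith("R"):
            return "ill_defined_disease"
        if norm.startswith("Y"):
            try:
                stem = int(norm[1:3])
            except ValueError:
                return "well_defined"
            if 10 <= stem <= 34:
                return "ill_defined_injury"
            if norm[:4] == "Y872":
                return "ill_defined_injury"
        return "well_defined"
    if icd_revision == 9:
        if norm.startswith("E"):
            try:
                stem = int(norm[1:4])
            except ValueError:
                return "well_defined"
            lo, hi = icd9_injury_range
            return "ill_defined_injury" if lo <= stem <= hi else "well_defined"
        try:
            stem = int(norm[:3])
        except ValueError:
            return "well_defined"
        lo, hi = icd9_disease_range
        return "ill_defined_disease" if lo <= stem <= hi else "well_defined"
    raise HarmonizationError(f"unsupported ICD revision {icd_revision}")


PROVENANCE_FLAGS = ["age_imputed", "sex_imputed", "cause_imputed", "sampled_replicate"]

HARMONIZED_COLUMNS = [
    "country", "year", "l2_code", "age_single", "age5", "sex", "education",
    "icd_code", "icd_revision", "cause_group", "ill_flag",
] + PROVENANCE_FLAGS


def harmonize_records(
    raw: pd.DataFrame,
    sex_codebook: Mapping,
    education_codebook: Mapping,
    cause_map: CauseMap,
    age_scheme: str = "single",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harmonize a table of raw death records.

    ``raw`` needs columns ``country, year, l2_code, age, sex, education,
    icd_code, icd_revision`` (missing values as NaN/None). Returns the
    harmonized table (same row count, one row per death) and a data-quality
    report of missingness proportions per variable by country-year.
    """
    out = pd.DataFrame(index=raw.index)
    out["country"] = raw["country"]
    out["year"] = raw["year"].astype(int)
    out["l2_code"] = raw["l2_code"]

    ages = [harmonize_age(a, age_scheme) for a in raw["age"]]
    out["age_single"] = [a for a, _ in ages]
    out["age5"] = [b for _, b in ages]
    out["sex"] = [harmonize_sex(v, sex_codebook) for v in raw["sex"]]
    out["education"] = [recode_education(v, education_codebook) for v in raw["education"]]

    out["icd_code"] = [
        normalize_icd(c) if c is not None and not (isinstance(c, float) and np.isnan(c)) else None
        for c in raw["icd_code"]
    ]
    out["icd_revision"] = raw["icd_revision"].astype(int)

    groups, flags = [], []
    for code, rev in zip(out["icd_code"], out["icd_revision"]):
        if code is None or code == "":
            groups.append(MISSING)
            flags.append(MISSING)
            continue
        flag = flag_ill_defined(code, rev)
        flags.append(flag)
        if flag == "ill_defined_disease":
            groups.append(ILL_DEFINED_DISEASE)
        elif flag == "ill_defined_injury":
            groups.append(ILL_DEFINED_INJURY)
        else:
            groups.append(map_cause(code, rev, cause_map))
    out["cause_group"] = groups
    out["ill_flag"] = flags
    for flag in PROVENANCE_FLAGS:
        out[flag] = False

    report = missingness_report(out)
    return out[HARMONIZED_COLUMNS], report


def missingness_report(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Missingness proportions per variable by country-year."""
    rows = []
    for (country, year), grp in harmonized.groupby(["country", "year"]):
        n = len(grp)
        rows.append(
            {
                "country": country,
                "year": year,
                "n_records": n,
                "p_missing_age": (grp["age5"] == MISSING).mean(),
                "p_missing_sex": (grp["sex"] == MISSING).mean(),
                "p_missing_education": (grp["education"] == MISSING).mean(),
                "p_missing_cause": (grp["cause_group"] == MISSING).mean(),
                "p_missing_location": grp["l2_code"].isna().mean(),
                "p_ill_defined": grp["ill_flag"].isin(
                    ["ill_defined_disease", "ill_defined_injury"]
                ).mean(),
            }
        )
    return pd.DataFrame(rows)
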