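"""Mortality-record correction: imputation, redistribution, undercount.

Vital-registration data suffer three quality problems that bias mortality
rates if ignored. This module addresses each in turn:

1. **Missing demographics or cause** — conditional probabilistic imputation:
   a missing 5-year age band is drawn from the observed age distribution of
   deaths with the same sex and cause group (stratified by country and
   year); missing sex symmetrically from P(sex | age, cause); a missing
   cause of death is assigned to one of the two ill-defined classes
   (ill-defined disease / injury of undetermined intent) with probabilities
   estimated from observed ill-defined deaths of the same age and sex.
   Sparse donor strata back off along a fixed margin-dropping order.

2. **Ill-defined ("garbage") causes** — deaths coded to uninformative
   categories are redistributed to well-defined cause groups proportionally
   to the observed cause distribution within (country, year, age, sex),
   conserving stratum totals exactly.

3. **Undercount** — where registration completeness is c < 1, the expected
   number of unregistered deaths D_obs·(1−c)/c is drawn by stochastic
   rounding and filled by hot-deck imputation: sampling that many records
   with replacement from the observed deaths of the correction cell.

The pipeline order is: drop records with missing sub-city location → impute
demographics/cause → undercount-correct → aggregate → redistribute. All
randomness flows from one seed through named substreams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .harmonize import (
    ILL_DEFINED_DISEASE,
    ILL_DEFINED_INJURY,
    MISSING,
    PROVENANCE_FLAGS,
)

logger = logging.getLogger(__name__)

ILL_CLASSES = [ILL_DEFINED_DISEASE, ILL_DEFINED_INJURY]
UNREDISTRIBUTABLE = "_unredistributable"

AGG_KEYS = ["country", "year", "l2_code", "age5", "sex", "education", "cause_group"]


class CorrectionError(ValueError):
    pass


def substream(seed: int, name: str) -> np.random.Generator:
    """Named random substream so one stage's draws never perturb another's."""
    h = np.frombuffer(name.encode(), dtype=np.uint8)
    return np.random.default_rng(np.random.SeedSequence([int(seed), *h.tolist()]))


# ---------------------------------------------------------------------------
# step 0: location filter

def drop_missing_location(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records with missing sub-city location; audit the counts.

    Returns the retained records and a per-country-year table of dropped
    counts. Records without a location cannot be linked to any unit.
    """
    miss = records["l2_code"].isna() | (records["l2_code"] == MISSING)
    dropped = records[miss]
    audit = (
        dropped.groupby(["country", "year"]).size().rename("n_dropped").reset_index()
        if len(dropped)
        else pd.DataFrame(columns=["country", "year", "n_dropped"])
    )
    return records[~miss].copy(), audit


# ---------------------------------------------------------------------------
# step 1: conditional probabilistic imputation

def _is_missing(col: pd.Series) -> pd.Series:
    return col.isna() | (col == MISSING)


def _backoff_levels(conds: list[str]) -> list[list[str]]:
    """Stratum definitions from most to least specific.

    Full stratum (country, year, conditioners) → drop year → drop the second
    conditioner → country-level marginal.
    """
    levels = [["country", "year"] + conds, ["country"] + conds]
    if len(conds) > 1:
        levels.append(["country"] + conds[:1])
    levels.append(["country"])
    return levels


def _impute_column(
    records: pd.DataFrame,
    target: str,
    conds: list[str],
    categories: Sequence[str] | None,
    rng: np.random.Generator,
    flag: str,
    donor_mask: pd.Series | None = None,
) -> int:
    """Fill missing values of ``target`` in place from donor distributions.

    ``donor_mask`` restricts the donor pool (used for cause imputation where
    donors are ill-defined deaths only); ``categories`` restricts the values
    that may be drawn. Returns the number of imputed records.
    """
    missing_mask = _is_missing(records[target])
    if not missing_mask.any():
        return 0
    donors = records[~_is_missing(records[target])]
    if donor_mask is not None:
        donors = donors[donor_mask.reindex(donors.index, fill_value=False)]
    if categories is not None:
        donors = donors[donors[target].isin(categories)]

    levels = _backoff_levels(conds)
    # donor categorical distributions per stratum, per backoff level
    dists = []
    for level in levels:
        counts = donors.groupby(level)[target].value_counts()
        dists.append(counts)

    n_imputed = 0
    missing_rows = records[missing_mask]
    for key, grp in missing_rows.groupby(["country", "year"] + conds, dropna=False):
        key = tuple(key) if isinstance(key, tuple) else (key,)
        drawn = None
        lookup = {c: v for c, v in zip(["country", "year"] + conds, key)}
        for depth, level in enumerate(levels):
            idx = tuple(lookup[c] for c in level)
            try:
                dist = dists[depth].loc[idx if len(idx) > 1 else idx[0]]
            except KeyError:
                continue
            if isinstance(dist, pd.Series) and dist.sum() > 0:
                if depth > 0:
                    logger.debug("imputation backoff to %s for stratum %s", level, key)
                cats = dist.index.to_list()
                p = dist.to_numpy(dtype=float)
                p = p / p.sum()
                drawn = rng.choice(len(cats), size=len(grp), p=p)
                records.loc[grp.index, target] = [cats[i] for i in drawn]
                records.loc[grp.index, flag] = True
                n_imputed += len(grp)
                break
        if drawn is None:
            raise CorrectionError(
                f"no imputation donors for {target} even after full backoff "
                f"in country-year {key[:2]}"
            )
    return n_imputed


def impute_missing(records: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, dict]:
    """Conditionally impute missing age band, sex, and cause class.

    Missing ``age5`` is drawn from P(age5 | sex, cause_group) within
    country-year; missing ``sex`` from P(sex | age5, cause_group); a missing
    cause is assigned to one of the two ill-defined classes from
    P(class | age5, sex) estimated on observed ill-defined deaths. Imputed
    fields carry provenance flags; non-missing fields are never altered and
    the record count is unchanged. Reproducible given ``seed``.
    """
    out = records.copy()
    audit: dict[str, int] = {}

    audit["age_imputed"] = _impute_column(
        out, "age5", ["sex", "cause_group"], None,
        substream(seed, "impute-age"), "age_imputed",
    )
    audit["sex_imputed"] = _impute_column(
        out, "sex", ["age5", "cause_group"], ["male", "female"],
        substream(seed, "impute-sex"), "sex_imputed",
    )
    ill_donors = out["cause_group"].isin(ILL_CLASSES)
    audit["cause_imputed"] = _impute_column(
        out, "cause_group", ["age5", "sex"], ILL_CLASSES,
        substream(seed, "impute-cause"), "cause_imputed",
        donor_mask=ill_donors,
    )
    # keep ill_flag consistent with imputed cause classes
    imputed_cause = out["cause_imputed"]
    out.loc[imputed_cause & (out["cause_group"] == ILL_DEFINED_DISEASE), "ill_flag"] = (
        "ill_defined_disease"
    )
    out.loc[imputed_cause & (out["cause_group"] == ILL_DEFINED_INJURY), "ill_flag"] = (
        "ill_defined_injury"
    )
    return out, audit


# ---------------------------------------------------------------------------
# step 2: undercount correction (hot deck)

@dataclass(frozen=True)
class CompletenessFactor:
    """Registration completeness c ∈ (0, 1] with an application scope.

    ``l2_code``, ``sex`` and ``age_bands`` narrow the scope; ``None`` means
    "applies to all". When several factors match a record, the most specific
    (largest number of narrowed fields) wins.
    """

    country: str
    value: float
    l2_code: str | None = None
    sex: str | None = None
    age_bands: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.value <= 1:
            raise CorrectionError(f"completeness {self.value} outside (0, 1]")

    @property
    def specificity(self) -> int:
        return sum(x is not None for x in (self.l2_code, self.sex, self.age_bands))

    def matches(self, row) -> bool:
        if row.country != self.country:
            return False
        if self.l2_code is not None and row.l2_code != self.l2_code:
            return False
        if self.sex is not None and row.sex != self.sex:
            return False
        if self.age_bands is not None and row.age5 not in self.age_bands:
            return False
        return True


def load_completeness_factors(path) -> list[CompletenessFactor]:
    """Read factors from CSV with columns country,l2_code,sex,age_band,c."""
    frame = pd.read_csv(path, dtype=str)
    factors = []
    for row in frame.itertuples():
        bands = None
        band = getattr(row, "age_band", None)
        if isinstance(band, str) and band:
            bands = tuple(band.split("|"))
        factors.append(
            CompletenessFactor(
                country=row.country,
                value=float(row.c),
                l2_code=row.l2_code if isinstance(row.l2_code, str) and row.l2_code else None,
                sex=row.sex if isinstance(row.sex, str) and row.sex else None,
                age_bands=bands,
            )
        )
    return factors


def _resolve_factors(records: pd.DataFrame, factors: Sequence[CompletenessFactor]) -> pd.Series:
    """Index of the resolved factor per record (most specific scope wins)."""
    resolved = np.full(len(records), -1, dtype=int)
    spec = np.full(len(records), -1, dtype=int)
    for j, f in enumerate(factors):
        mask = (records["country"] == f.country).to_numpy()
        if f.l2_code is not None:
            mask &= (records["l2_code"] == f.l2_code).to_numpy()
        if f.sex is not None:
            mask &= (records["sex"] == f.sex).to_numpy()
        if f.age_bands is not None:
            mask &= records["age5"].isin(f.age_bands).to_numpy()
        tie = mask & (spec == f.specificity)
        if tie.any():
            raise CorrectionError(
                f"records resolve to two factors of equal specificity "
                f"({factors[int(resolved[tie.argmax()])]} and {f})"
            )
        better = mask & (spec < f.specificity)
        resolved[better] = j
        spec[better] = f.specificity
    if (resolved < 0).any():
        miss = records[resolved < 0].iloc[0]
        raise CorrectionError(
            f"no completeness factor matches record in {miss['country']} {miss['year']}"
        )
    return pd.Series(resolved, index=records.index)


def correct_undercount(
    records: pd.DataFrame,
    factors: Sequence[CompletenessFactor],
    seed: int,
) -> pd.DataFrame:
    """Hot-deck correction for incomplete death registration.

    For each correction cell (the records resolving to one factor), the
    expected number of unregistered deaths is M* = D_obs·(1−c)/c. The
    realized integer M is drawn by stochastic rounding (floor plus a
    Bernoulli on the fraction, unbiased across cells), and M records are
    sampled uniformly with replacement from the cell and appended as clones
    flagged ``sampled_replicate``. c = 1 leaves the data untouched.
    """
    rng = substream(seed, "undercount")
    if len(records) == 0:
        return records.copy()
    resolved = _resolve_factors(records, factors)
    replicate_blocks = [records]
    for j in sorted(resolved.unique()):
        cell = records[resolved == j]
        c = factors[j].value
        if c == 1.0:
            continue
        if len(cell) == 0:
            logger.warning("completeness %.3f for an empty cell; nothing to sample", c)
            continue
        m_star = len(cell) * (1 - c) / c
        m = int(np.floor(m_star)) + int(rng.random() < (m_star - np.floor(m_star)))
        if m == 0:
            continue
        picks = rng.integers(0, len(cell), size=m)
        clones = cell.iloc[picks].copy()
        clones["sampled_replicate"] = True
        replicate_blocks.append(clones)
    return pd.concat(replicate_blocks, ignore_index=True)


# ---------------------------------------------------------------------------
# step 3: aggregation

def aggregate_deaths(records: pd.DataFrame, redistribute: bool = True) -> pd.DataFrame:
    """Aggregate records to year × sub-city × age band × sex × education × cause.

    ``observed_count`` excludes hot-deck replicates; ``corrected_count``
    includes them. With ``redistribute=True`` the ill-defined mass is also
    moved to well-defined causes, yielding the redistributed variants of
    both columns (four count columns in total).
    """
    if len(records) == 0:
        cols = AGG_KEYS + ["observed_count", "corrected_count"]
        return pd.DataFrame(columns=cols)
    grouped = records.groupby(AGG_KEYS, dropna=False)
    table = grouped.agg(
        observed_count=("sampled_replicate", lambda s: int((~s).sum())),
        corrected_count=("sampled_replicate", "size"),
    ).reset_index()
    if redistribute:
        table = redistribute_ill_defined(table, value_cols=("observed_count", "corrected_count"))
    return table


# ---------------------------------------------------------------------------
# step 4: proportional redistribution of ill-defined deaths

REDISTRIBUTION_BACKOFF = [
    ["country", "year", "age5", "sex"],
    ["country", "year", "age5"],
    ["country", "year"],
    ["country"],
]


def redistribute_ill_defined(
    table: pd.DataFrame,
    value_cols: Sequence[str] = ("observed_count",),
) -> pd.DataFrame:
    """Redistribute ill-defined deaths proportionally to well-defined causes.

    Within each (country, year, age band, sex) stratum, counts in the two
    ill-defined pseudo-causes are allocated to well-defined cause groups in
    proportion to the groups' observed counts in that stratum, keeping the
    row's other keys (sub-city, education) fixed. Allocation is fractional
    (no rounding) and conserves stratum totals exactly. Strata with no
    well-defined deaths back off to coarser strata; mass that cannot be
    placed anywhere lands in an explicit ``_unredistributable`` bucket.

    Adds a ``<col>_redistributed`` column per input count column; ill-defined
    rows keep their original counts in the base columns and carry 0 in the
    redistributed ones.
    """
    out = table.copy()
    is_ill = out["cause_group"].isin(ILL_CLASSES)
    for col in value_cols:
        out[f"{col}_redistributed"] = out[col].astype(float)
    if not is_ill.any():
        return out

    well = out[~is_ill]
    # cause-group share tables at each backoff level
    share_tables = [
        well.groupby(level + ["cause_group"])[list(value_cols)].sum()
        for level in REDISTRIBUTION_BACKOFF
    ]

    new_rows: list[dict] = []
    for row in out[is_ill].itertuples():
        rowdict = row._asdict()
        for col in value_cols:
            rcol = f"{col}_redistributed"
            mass = rowdict[col]
            out.loc[row.Index, rcol] = 0.0
            if mass == 0:
                continue
            placed = False
            for level, shares in zip(REDISTRIBUTION_BACKOFF, share_tables):
                key = tuple(rowdict[c] for c in level)
                try:
                    dist = shares.loc[key if len(key) > 1 else key[0], col]
                except KeyError:
                    continue
                total = dist.sum()
                if total <= 0:
                    continue
                for cause, count in dist.items():
                    if count == 0:
                        continue
                    new_rows.append(
                        {
                            **{k: rowdict[k] for k in AGG_KEYS},
                            "cause_group": cause,
                            "_col": rcol,
                            "_add": mass * count / total,
                        }
                    )
                placed = True
                break
            if not placed:
                new_rows.append(
                    {
                        **{k: rowdict[k] for k in AGG_KEYS},
                        "cause_group": UNREDISTRIBUTABLE,
                        "_col": rcol,
                        "_add": float(mass),
                    }
                )
                logger.warning(
                    "unredistributable ill-defined mass %s in %s", mass,
                    {k: rowdict[k] for k in ("country", "year", "age5", "sex")},
                )
    if not new_rows:
        return out

    adds = pd.DataFrame(new_rows)
    pivot = adds.pivot_table(index=AGG_KEYS, columns="_col", values="_add", aggfunc="sum")
    pivot = pivot.reset_index()
    out = out.merge(pivot, on=AGG_KEYS, how="outer", suffixes=("", "_addon"))
    for col in value_cols:
        rcol = f"{col}_redistributed"
        addon = f"{rcol}_addon"
        if addon in out.columns:
            out[rcol] = out[rcol].fillna(0.0) + out[addon].fillna(0.0)
            out = out.drop(columns=[addon])
        out[col] = out[col].fillna(0)
    return out


def redistribute_records(records: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Integer, record-level redistribution variant.

    Each ill-defined record is probabilistically reassigned to a well-defined
    cause group drawn with the same stratum proportions the fractional
    variant uses, producing integer microdata; totals are conserved in
    expectation rather than exactly.
    """
    rng = substream(seed, "redistribute-records")
    out = records.copy()
    is_ill = out["cause_group"].isin(ILL_CLASSES)
    well = out[~is_ill & (out["cause_group"] != MISSING)]
    share_tables = [
        well.groupby(level)["cause_group"].value_counts() for level in REDISTRIBUTION_BACKOFF
    ]
    for idx, row in zip(out[is_ill].index, out[is_ill].itertuples()):
        rowdict = row._asdict()
        for level, shares in zip(REDISTRIBUTION_BACKOFF, share_tables):
            key = tuple(rowdict[c] for c in level)
            try:
                dist = shares.loc[key if len(key) > 1 else key[0]]
            except KeyError:
                continue
            if isinstance(dist, pd.Series) and dist.sum() > 0:
                p = dist.to_numpy(dtype=float)
                p = p / p.sum()
                out.loc[idx, "cause_group"] = dist.index[rng.choice(len(dist), p=p)]
                out.loc[idx, "ill_flag"] = "well_defined"
                break
    return out


# ---------------------------------------------------------------------------
# full pipeline

def run_pipeline(
    records: pd.DataFrame,
    factors: Sequence[CompletenessFactor],
    seed: int,
    redistribute_before_undercount: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Drop unlinkable records, impute, undercount-correct, aggregate, redistribute.

    Returns (corrected record file, aggregated table with four count
    columns, audit dict). With ``redistribute_before_undercount`` the
    ill-defined records are reassigned at record level (integer variant)
    before hot-deck sampling, for workflows preferring that order.
    """
    retained, drop_audit = drop_missing_location(records)
    imputed, impute_audit = impute_missing(retained, seed)
    if redistribute_before_undercount:
        imputed = redistribute_records(imputed, seed)
    corrected = correct_undercount(imputed, factors, seed)
    table = aggregate_deaths(corrected, redistribute=True)
    audit = {
        "n_input": int(len(records)),
        "n_dropped_location": int(len(records) - len(retained)),
        "n_replicates_added": int(len(corrected) - len(imputed)),
        **impute_audit,
        "unredistributable_mass": float(
            table.loc[table["cause_group"] == UNREDISTRIBUTABLE, "corrected_count_redistributed"].sum()
            if UNREDISTRIBUTABLE in table["cause_group"].values
            else 0.0
        ),
    }
    return corrected, table, audit
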