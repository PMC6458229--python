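"""Population denominators and mortality rates.

Sub-city population counts by age and sex are sometimes published only as a
one-dimensional margin (by age *or* by sex) while the full age × sex table
exists at a higher administrative level. :func:`redistribute_population`
fills the missing dimension by applying the higher level's conditional
distribution to the sub-city margin, conserving the margin exactly.

:func:`compute_rates` turns aggregated death counts and population tables
into crude and directly age-standardized rates: the standardized rate is
Σ_a w_a · (deaths_a / pop_a) · scale with w the standard population's age
weights, making rates comparable across places with different age
structures (e.g. an age-standardized homicide rate per 100,000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .harmonize import AGE5_BANDS


class DenominatorError(ValueError):
    pass


@dataclass
class StandardPopulation:
    """Age-band weights summing to 1, matching the 5-year band scheme."""

    weights: pd.Series  # index: age band label

    def __post_init__(self) -> None:
        w = self.weights
        if (w < 0).any():
            raise DenominatorError("standard population weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise DenominatorError(f"standard population weights sum to {w.sum()}, not 1")

    @classmethod
    def from_csv(cls, path) -> "StandardPopulation":
        frame = pd.read_csv(path)
        return cls(weights=frame.set_index("band")["weight"].astype(float))

    @classmethod
    def demo(cls) -> "StandardPopulation":
        """A demonstration standard with a young-leaning age pyramid.

        Shipped for examples and tests; analyses choose their own standard.
        """
        raw = np.array(
            [8.5, 8.5, 8.5, 8.5, 8.0, 8.0, 7.5, 7.0, 6.5, 6.0,
             5.5, 5.0, 4.0, 3.0, 2.0, 1.5, 1.0, 1.0]
        )
        return cls(weights=pd.Series(raw / raw.sum(), index=AGE5_BANDS))


def redistribute_population(
    l2_margin: pd.DataFrame,
    higher_level: pd.DataFrame,
    margin_dim: str,
) -> pd.DataFrame:
    """Expand a sub-city population margin to full geography × age × sex counts.

    Parameters
    ----------
    l2_margin:
        Columns ``geography, <margin_dim>, count`` — sub-city counts by one
        dimension only (``margin_dim`` is ``"sex"`` or ``"age5"``).
    higher_level:
        Columns ``age5, sex, count`` — the joint distribution observed at a
        higher administrative level covering all the sub-cities.
    margin_dim:
        Which dimension the sub-city margin carries.

    For a sex margin, count(g, a, s) = margin(g, s) · P_higher(a | s), and
    symmetrically for an age margin. The input margin is reproduced exactly
    by the output's corresponding margin and total population is conserved.
    """
    if margin_dim not in ("sex", "age5"):
        raise DenominatorError(f"margin_dim must be 'sex' or 'age5', got {margin_dim!r}")
    other_dim = "age5" if margin_dim == "sex" else "sex"

    joint = higher_level.groupby(["age5", "sex"])["count"].sum()
    margin_totals = joint.groupby(margin_dim).sum()

    rows = []
    for rec in l2_margin.itertuples():
        level = getattr(rec, margin_dim)
        total = margin_totals.get(level, 0.0)
        if total <= 0:
            if rec.count > 0:
                raise DenominatorError(
                    f"higher-level stratum {margin_dim}={level!r} has zero total "
                    f"but sub-city {rec.geography!r} reports {rec.count}"
                )
            continue
        conditional = joint.xs(level, level=margin_dim) / total
        for other_value, p in conditional.items():
            rows.append(
                {
                    "geography": rec.geography,
                    margin_dim: level,
                    other_dim: other_value,
                    "count": rec.count * p,
                }
            )
    out = pd.DataFrame(rows, columns=["geography", "age5", "sex", "count"])
    return out


def redistribute_population_ipf(
    age_margin: pd.DataFrame,
    sex_margin: pd.DataFrame,
    higher_level: pd.DataFrame,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Joint age × sex counts from both sub-city margins via IPF.

    When a sub-city publishes *both* an age margin and a sex margin but no
    joint table, iterative proportional fitting rescales the higher-level
    joint distribution to satisfy both margins simultaneously. Margins must
    agree on the total per geography.
    """
    joint = higher_level.groupby(["age5", "sex"])["count"].sum().unstack("sex")
    joint = joint.fillna(0.0)
    out_rows = []
    for g, age_grp in age_margin.groupby("geography"):
        a_target = age_grp.set_index("age5")["count"].astype(float)
        s_target = (
            sex_margin[sex_margin["geography"] == g].set_index("sex")["count"].astype(float)
        )
        if abs(a_target.sum() - s_target.sum()) > 1e-6 * max(a_target.sum(), 1.0):
            raise DenominatorError(
                f"age and sex margins disagree on total for geography {g!r}"
            )
        table = joint.reindex(index=a_target.index, columns=s_target.index).fillna(0.0)
        if (table.sum(axis=1) == 0).any() and (a_target > 0).any():
            raise DenominatorError(f"higher-level seed has empty rows needed by {g!r}")
        for _ in range(max_iter):
            table = table.mul(a_target / table.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
            table = table.mul(s_target / table.sum(axis=0).replace(0, np.nan), axis=1).fillna(0.0)
            if (table.sum(axis=1) - a_target).abs().max() < tol:
                break
        for band in table.index:
            for sex in table.columns:
                out_rows.append(
                    {"geography": g, "age5": band, "sex": sex, "count": table.loc[band, sex]}
                )
    return pd.DataFrame(out_rows, columns=["geography", "age5", "sex", "count"])


def compute_rates(
    deaths: pd.DataFrame,
    population: pd.DataFrame,
    standard: StandardPopulation,
    scale: float = 100_000,
    count_col: str = "corrected_count_redistributed",
    geography_col: str = "l2_code",
    by: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Crude and age-standardized death rates per geography (× optional keys).

    ``deaths`` is an aggregated death table with an ``age5`` column and the
    chosen count column; ``population`` has columns ``geography, age5, count``
    (a ``sex`` column, if present, is summed out unless listed in ``by``).
    Age bands with zero population and zero deaths contribute nothing;
    deaths in a zero-population band are a denominator violation and fail.
    """
    keys = [geography_col, *by]
    pop_keys = ["geography"] + [k for k in by if k in population.columns]
    pop = population.groupby(pop_keys + ["age5"])["count"].sum()

    d = deaths.groupby(keys + ["age5"])[count_col].sum().reset_index()
    rows = []
    for key, grp in d.groupby(keys):
        key = (key,) if not isinstance(key, tuple) else key
        pop_key = tuple(
            v for k, v in zip(keys, key) if k == geography_col or k in population.columns
        )
        try:
            pop_a = pop.loc[pop_key if len(pop_key) > 1 else pop_key[0]]
        except KeyError:
            raise DenominatorError(f"no population for geography {key[0]!r}")
        deaths_a = grp.set_index("age5")[count_col]

        total_deaths = deaths_a.sum()
        total_pop = pop_a.sum()
        if total_pop <= 0:
            raise DenominatorError(f"zero population for geography {key[0]!r}")
        crude = total_deaths / total_pop * scale

        std = 0.0
        for band, w in standard.weights.items():
            da = float(deaths_a.get(band, 0.0))
            pa = float(pop_a.get(band, 0.0))
            if pa <= 0:
                if da > 0:
                    raise DenominatorError(
                        f"deaths ({da}) with zero population in band {band!r} "
                        f"for geography {key[0]!r}"
                    )
                continue
            std += w * (da / pa) * scale
        rows.append({**dict(zip(keys, key)), "crude_rate": crude, "age_standardized_rate": std})
    return pd.DataFrame(rows)
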