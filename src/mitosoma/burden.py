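"""Condition-level mutation burden: frequencies, Poisson CIs, region probabilities,
age deltas, and log-link (Poisson) rate regressions."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .genome import ReferenceGenome, RegionAnnotation
from .stats import poisson_ci
from .variants import ConditionTable

logger = logging.getLogger(__name__)


@dataclass
class BurdenSummary:
    condition: tuple[str, str, str]
    mean_frequency: float
    poisson_ci: tuple[float, float]
    region_probability: dict[str, float]
    percent_bp_mutated: float


def mean_mutation_frequency(
    table: ConditionTable, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Genome-wide mutation frequency with its exact 95% Poisson interval.

    The frequency is the summed alternate-allele depth divided by the summed
    duplex depth; the interval is the chi-square (Garwood) interval for the
    total count, divided by the total depth.
    """
    total_depth = float(table.depth.sum())
    if total_depth <= 0:
        raise ValueError("zero total duplex depth")
    k = float(table.variants["alt_depth"].sum())
    lo, hi = poisson_ci(k, alpha=alpha)
    return k / total_depth, (lo / total_depth, hi / total_depth)


def region_mutation_probability(table: ConditionTable, region: RegionAnnotation, genome: ReferenceGenome) -> float:
    """Mutation probability of a region: count / (length_bp * mean duplex depth)."""
    pos = genome.region_positions(region)
    depth = table.depth[pos - 1]
    if depth.sum() <= 0:
        logger.warning("region %s has zero duplex depth; excluded", region.name)
        return np.nan
    counts = table.position_alt_depth()[pos - 1]
    return float(counts.sum() / (pos.size * depth.mean()))


def percent_bp_mutated(table: ConditionTable, positions: np.ndarray) -> float:
    """Percent of the given positions carrying at least one surviving mutation."""
    mutated = np.zeros(table.L, dtype=bool)
    if len(table.variants):
        mutated[table.variants["position"].unique() - 1] = True
    return 100.0 * mutated[positions - 1].mean()


def percent_bp_delta(
    young: ConditionTable,
    aged: ConditionTable,
    region: RegionAnnotation,
    genome: ReferenceGenome,
) -> float:
    """Aged minus young percent of region positions with >= 1 mutation.

    Expects a depth-normalised pair; counts unique mutated positions, not
    allele multiplicity.
    """
    pos = genome.region_positions(region)
    return percent_bp_mutated(aged, pos) - percent_bp_mutated(young, pos)


def _condition_frame(tables: list[ConditionTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        strain, tissue, age = t.condition
        rows.append(
            {
                "strain": strain,
                "tissue": tissue,
                "age": age,
                "count": float(t.variants["alt_depth"].sum()),
                "depth": float(t.depth.sum()),
            }
        )
    return pd.DataFrame(rows)


def age_rate_test(tables: list[ConditionTable], model: str = "age") -> pd.DataFrame:
    """Poisson log-link regression of mutation counts with a log-depth offset.

    ``model="age"`` fits, per (strain, tissue), ``count ~ age`` and reports
    the aged/young rate ratio with its Wald p-value, Bonferroni-adjusted
    across the fitted conditions.  ``model="strain_age"`` fits a single
    ``count ~ strain * age`` regression and returns its coefficient table.
    Quasi-Poisson dispersion (Pearson chi-square / df when df > 0) is
    attached as a diagnostic; zero counts are reported, not dropped.
    """
    df = _condition_frame(tables)
    df["age"] = pd.Categorical(df["age"], categories=["young", "aged"], ordered=True)
    if (df["depth"] <= 0).any():
        raise ValueError("conditions with zero depth")
    if model == "age":
        rows = []
        groups = list(df.groupby(["strain", "tissue"], observed=True))
        for (strain, tissue), g in groups:
            if g["age"].nunique() < 2:
                logger.warning("strain %s tissue %s: only one age group; skipped", strain, tissue)
                continue
            fit = smf.glm(
                "count ~ age",
                data=g,
                family=sm.families.Poisson(),
                offset=np.log(g["depth"]),
            ).fit()
            coef = fit.params.get("age[T.aged]", np.nan)
            note = "zero counts" if (g["count"] == 0).any() else ""
            rows.append(
                {
                    "strain": strain,
                    "tissue": tissue,
                    "term": "age[aged]",
                    "coef": coef,
                    "rate_ratio": np.exp(coef),
                    "se": fit.bse.get("age[T.aged]", np.nan),
                    "p": fit.pvalues.get("age[T.aged]", np.nan),
                    "dispersion": fit.pearson_chi2 / fit.df_resid if fit.df_resid > 0 else np.nan,
                    "note": note,
                }
            )
        out = pd.DataFrame(rows)
        if len(out):
            out["adj_p"] = np.minimum(out["p"] * len(out), 1.0)  # Bonferroni
        return out
    if model == "strain_age":
        fit = smf.glm(
            "count ~ C(strain) * age",
            data=df,
            family=sm.families.Poisson(),
            offset=np.log(df["depth"]),
        ).fit()
        out = pd.DataFrame(
            {
                "term": fit.params.index,
                "coef": fit.params.to_numpy(),
                "rate_ratio": np.exp(fit.params.to_numpy()),
                "se": fit.bse.to_numpy(),
                "p": fit.pvalues.to_numpy(),
            }
        )
        out["dispersion"] = fit.pearson_chi2 / fit.df_resid if fit.df_resid > 0 else np.nan
        return out
    raise ValueError(f"unknown model {model!r}")


def burden_summary(
    table: ConditionTable, genome: ReferenceGenome
) -> BurdenSummary:
    freq, ci = mean_mutation_frequency(table)
    region_prob = {
        r.name: region_mutation_probability(table, r, genome) for r in genome.regions
    }
    return BurdenSummary(
        condition=table.condition,
        mean_frequency=freq,
        poisson_ci=ci,
        region_probability=region_prob,
        percent_bp_mutated=percent_bp_mutated(table, np.arange(1, table.L + 1)),
    )
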