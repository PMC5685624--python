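"""Descriptive phenotype analyses across environments.

Summaries (mean, percentiles by linear interpolation, sample SD, CV),
Pearson trait correlations within and across environments, a one-way
environment ANOVA with its Kruskal-Wallis rank companion, and simple
threshold-based stability selection across environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError
from .io import TRAITS, PhenotypeTable


def describe(pheno: PhenotypeTable) -> pd.DataFrame:
    """Per trait x environment: n, mean, min, percentiles, max, SD (n-1), CV."""
    rows = []
    for env in pheno.environments:
        frame = pheno.env(env)
        for trait in TRAITS:
            vals = frame[trait].dropna().to_numpy(dtype=float)
            if len(vals) < 2:
                raise DataError(f"trait {trait} has < 2 values in environment {env}")
            q = np.percentile(vals, [10, 25, 50, 75, 90])  # linear interpolation
            sd = float(np.std(vals, ddof=1))
            mean = float(vals.mean())
            rows.append(
                {
                    "environment": env,
                    "trait": trait,
                    "n": len(vals),
                    "mean": mean,
                    "min": float(vals.min()),
                    "p10": q[0],
                    "p25": q[1],
                    "median": q[2],
                    "p75": q[3],
                    "p90": q[4],
                    "max": float(vals.max()),
                    "sd": sd,
                    "cv": 100.0 * sd / mean if mean != 0 else np.nan,
                }
            )
    return pd.DataFrame(rows).set_index(["environment", "trait"])


def trait_correlations(pheno: PhenotypeTable, mode: str = "within_env",
                       environment: str | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations with two-sided t-test p-values.

    within_env: trait x trait within one environment.  cross_env: every
    (envA trait, envB trait) pair matched by accession across the table's
    first two environments.
    """
    if mode == "within_env":
        env = environment or pheno.environments[0]
        frame = pheno.env(env)
        cols = list(TRAITS)
        labels = cols
        data = {c: frame[c] for c in cols}
    elif mode == "cross_env":
        envs = pheno.environments
        if len(envs) < 2:
            raise DataError("cross_env mode needs two environments")
        a, b = pheno.env(envs[0]), pheno.env(envs[1])
        common = a.index.intersection(b.index)
        data = {f"{envs[0]}_{t}": a.loc[common, t] for t in TRAITS}
        data.update({f"{envs[1]}_{t}": b.loc[common, t] for t in TRAITS})
        labels = list(data)
    else:
        raise ParameterError("mode must be 'within_env' or 'cross_env'")
    r = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    p = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if j <= i:
                continue
            paired = pd.concat([data[x], data[y]], axis=1).dropna()
            if len(paired) < 3:
                raise DataError(f"fewer than 3 paired observations for {x} vs {y}")
            xv, yv = paired.iloc[:, 0], paired.iloc[:, 1]
            if xv.std(ddof=1) == 0 or yv.std(ddof=1) == 0:
                r.loc[x, y] = r.loc[y, x] = np.nan  # undefined, flagged
                continue
            res = stats.pearsonr(xv, yv)
            r.loc[x, y] = r.loc[y, x] = res.statistic
            p.loc[x, y] = p.loc[y, x] = res.pvalue
    return r, p


def environment_anova(pheno: PhenotypeTable) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of each trait on environment, plus the
    Kruskal-Wallis chi-square companion and the sums of squares."""
    envs = pheno.environments
    if len(envs) < 2:
        raise DataError("environment ANOVA needs >= 2 environments")
    rows = []
    for trait in TRAITS:
        samples = []
        for env in envs:
            vals = pheno.env(env)[trait].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                raise DataError(f"trait {trait} absent in environment {env}")
            samples.append(vals)
        all_vals = np.concatenate(samples)
        grand = all_vals.mean()
        ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
        df_b = len(envs) - 1
        df_w = len(all_vals) - len(envs)
        F, p = stats.f_oneway(*samples)
        kw = stats.kruskal(*samples)
        rows.append(
            {
                "trait": trait,
                "F": float(F),
                "p": float(p),
                "df_between": df_b,
                "df_within": df_w,
                "ss_between": float(ss_between),
                "ss_within": float(ss_within),
                "ss_total": float(ss_between + ss_within),
                "kw_chi2": float(kw.statistic),
                "kw_p": float(kw.pvalue),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


_OPS = {
    ">": lambda v, lo, hi: v > lo,
    ">=": lambda v, lo, hi: v >= lo,
    "<=": lambda v, lo, hi: v <= lo,
    "<": lambda v, lo, hi: v < lo,
    "between": lambda v, lo, hi: (v >= lo) & (v <= hi),
}


@dataclass
class StabilityRule:
    """Threshold predicate on one trait, applied in every environment."""

    trait: str
    op: str
    lower: float
    upper: float | None = None

    def __post_init__(self):
        if self.op not in _OPS:
            raise ParameterError(f"unknown predicate {self.op!r}")
        if self.op == "between":
            if self.upper is None or self.upper < self.lower:
                raise ParameterError("'between' needs ordered bounds")

    def apply(self, values: pd.Series) -> pd.Series:
        return _OPS[self.op](values, self.lower, self.upper)


def stability_select(pheno_a: pd.DataFrame, pheno_b: pd.DataFrame,
                     rules: list[StabilityRule]) -> dict[str, set[str]]:
    """Accessions satisfying each rule in BOTH environments, plus the
    intersection over all rules under the key 'combination'.

    ``pheno_a`` / ``pheno_b`` are accession-indexed trait frames (one per
    environment, e.g. from :meth:`PhenotypeTable.env`).
    """
    out: dict[str, set[str]] = {}
    common = pheno_a.index.intersection(pheno_b.index)
    for rule in rules:
        if rule.trait not in pheno_a.columns or rule.trait not in pheno_b.columns:
            raise ParameterError(f"unknown trait in rule: {rule.trait!r}")
        ok_a = rule.apply(pheno_a.loc[common, rule.trait])
        ok_b = rule.apply(pheno_b.loc[common, rule.trait])
        ok = (ok_a & ok_b).fillna(False)
        out[rule.trait] = set(common[ok])
    sets = list(out.values())
    out["combination"] = set.intersection(*sets) if sets else set()
    return out
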