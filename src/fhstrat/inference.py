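"""Mixed-model subgroup contrasts with within-domain FDR correction.

Each outcome (CBCL t-scores, UPPS-P subscales, per-condition prediction
errors) is modelled with a linear mixed model,

    outcome ~ subgroup + sex + age + race_ethnicity
              + (1 | site) + (1 | family_id),

fit by maximum likelihood.  Subgroup enters as a categorical fixed
effect with a designated reference level; the coefficient estimate (CE)
for each non-reference level is the adjusted contrast against the
reference.  Random intercepts absorb between-site variability and the
non-independence of siblings; families never span sites in the cohorts
this package consumes, so the family intercept is fit as a variance
component nested within site.  Fixed-effect p-values use the Wald
statistic with a normal reference, appropriate at the sample sizes the
design targets.  The Benjamini-Hochberg step-up adjustment is applied
separately within each outcome domain (CBCL, UPPS-P, RPE).

The module also provides the demographic comparison table: Pearson χ²
on full contingency tables for categorical variables, two-proportion
z-tests for binary splits, and Welch t-tests for continuous variables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.proportion import proportions_ztest
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

#: outcome domains for within-domain FDR correction
DOMAINS: Dict[str, Tuple[str, ...]] = {
    "CBCL": ("cbcl_internalizing", "cbcl_externalizing", "cbcl_total"),
    "UPPS-P": ("upps_negative_urgency", "upps_positive_urgency",
               "upps_lack_premeditation", "upps_lack_perseverance",
               "upps_sensation_seeking"),
    "RPE": ("ppe_large_reward", "npe_large_reward",
            "ppe_large_loss", "npe_large_loss"),
}


@dataclass
class ModelSpec:
    outcome: str
    group_col: str = "subgroup"
    reference: str = "FHSU-N"
    covariates: Tuple[str, ...] = ("sex", "age", "race_ethnicity")
    site_col: str = "site_id"
    family_col: str = "family_id"
    standardize_outcome: bool = False


@dataclass
class LMMFit:
    """Fitted mixed model plus the spec that produced it."""

    spec: ModelSpec
    result: object  # statsmodels MixedLMResults
    variance_components: Dict[str, float]
    converged: bool


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> LMMFit:
    """Fit the mixed model for one outcome by maximum likelihood.

    Raises if the outcome is missing or non-numeric, or if fewer than
    two sites or families are present.  A singular random-effects fit
    (variance component estimated at the boundary) is reported with a
    warning, not an error; genuine non-convergence raises.
    """
    df = data.copy()
    if spec.outcome not in df.columns:
        raise ValueError(f"outcome {spec.outcome!r} not in data")
    df = df.dropna(subset=[spec.outcome])
    if not np.issubdtype(df[spec.outcome].dtype, np.number):
        raise ValueError(f"outcome {spec.outcome!r} must be numeric")
    for col, label in ((spec.site_col, "sites"), (spec.family_col, "families")):
        if df[col].nunique() < 2:
            raise ValueError(f"need at least 2 {label}")
    if spec.reference not in set(df[spec.group_col]):
        raise ValueError(f"reference level {spec.reference!r} absent")
    if spec.standardize_outcome:
        y = df[spec.outcome]
        df[spec.outcome] = (y - y.mean()) / y.std()
    covs = [c for c in spec.covariates if c in df.columns]
    terms = [f"C({spec.group_col}, Treatment('{spec.reference}'))"]
    for c in covs:
        terms.append(f"C({c})" if df[c].dtype == object else c)
    formula = f"{spec.outcome} ~ " + " + ".join(terms)
    # family intercepts as a variance component within site: valid because
    # families never span sites in these cohorts
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data=df, groups=df[spec.site_col],
                            re_formula="1",
                            vc_formula={"family": f"0 + C({spec.family_col})"})
        # Powell reaches the ML optimum reliably on the flat variance-
        # component likelihood this design produces; lbfgs then polishes
        result = model.fit(reml=False, method=["powell", "lbfgs"], maxiter=500)
    singular = any("singular" in str(w.message).lower()
                   or issubclass(w.category, ConvergenceWarning)
                   for w in caught)
    if not result.converged:
        raise RuntimeError(f"mixed model did not converge for {spec.outcome!r}")
    vc = {"site": float(result.cov_re.iloc[0, 0])}
    vc["family"] = float(result.vcomp[0]) if len(result.vcomp) else 0.0
    if singular or min(vc.values()) < 1e-8:
        logger.warning("near-singular random-effects fit for %s "
                       "(variance components %s)", spec.outcome, vc)
    return LMMFit(spec=spec, result=result, variance_components=vc,
                  converged=bool(result.converged))


def subgroup_contrasts(fit: LMMFit) -> pd.DataFrame:
    """One row per non-reference subgroup level: CE, SE, Wald p."""
    spec = fit.spec
    prefix = f"C({spec.group_col}, Treatment('{spec.reference}'))[T."
    rows = []
    params = fit.result.params
    for name in params.index:
        if not name.startswith(prefix):
            continue
        level = name[len(prefix):-1]
        rows.append({
            "outcome": spec.outcome,
            "contrast": f"{level} vs {spec.reference}",
            "level": level,
            "reference": spec.reference,
            "ce": float(params[name]),
            "se": float(fit.result.bse[name]),
            "p_raw": float(fit.result.pvalues[name]),
        })
    return pd.DataFrame(rows)


def bh_fdr(p_values: Sequence[float],
           domains: Optional[Sequence[str]] = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, separately within domains.

    adjusted p_(i) = min_{j ≥ i} ( m · p_(j) / j ), capped at 1, where
    p_(1) ≤ … ≤ p_(m) are the sorted raw p-values of one domain.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if domains is None:
        domains = np.zeros(len(p))
    domains = np.asarray(domains)
    out = np.empty_like(p)
    for dom in pd.unique(domains):
        idx = np.flatnonzero(domains == dom)
        q = p[idx]
        m = len(q)
        order = np.argsort(q, kind="mergesort")
        ranked = q[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        res = np.empty(m)
        res[order] = adj
        out[idx] = res
    return out


def run_contrast_analysis(
    data: pd.DataFrame,
    outcomes_by_domain: Mapping[str, Sequence[str]] = DOMAINS,
    group_col: str = "subgroup",
    reference: str = "FHSU-N",
    covariates: Sequence[str] = ("sex", "age", "race_ethnicity"),
    standardize_outcome: bool = False,
) -> pd.DataFrame:
    """Fit every outcome's mixed model and assemble the contrast table.

    Returns a ContrastTable-style DataFrame: one row per (outcome,
    contrast) with CE, SE, raw p, and BH-FDR-adjusted p computed within
    each outcome domain.  Outcomes absent from the data are skipped with
    a warning.
    """
    frames: List[pd.DataFrame] = []
    for domain, outcomes in outcomes_by_domain.items():
        for outcome in outcomes:
            if outcome not in data.columns:
                logger.warning("outcome %s absent; skipped", outcome)
                continue
            spec = ModelSpec(outcome=outcome, group_col=group_col,
                             reference=reference,
                             covariates=tuple(covariates),
                             standardize_outcome=standardize_outcome)
            rows = subgroup_contrasts(fit_lmm(data, spec))
            rows.insert(1, "domain", domain)
            frames.append(rows)
    table = pd.concat(frames, ignore_index=True)
    table["p_fdr"] = bh_fdr(table["p_raw"].to_numpy(), table["domain"].to_numpy())
    return table


def _percent(count: int, total: int) -> float:
    return round(100.0 * count / total, 2)


def demographic_tests(
    cohort: pd.DataFrame,
    group_col: str,
    categorical: Sequence[str] = (),
    continuous: Sequence[str] = (),
    binary: Mapping[str, str] = {},
) -> pd.DataFrame:
    """Group comparison table for demographics.

    Categorical variables: Pearson χ² (uncorrected) on the full
    contingency table, with per-group counts and percentages (rounded to
    2 decimals).  Binary variables (``binary`` maps column → the level
    counted as success): two-proportion z-test.  Continuous variables:
    Welch t-test (two groups).  Rows with any expected cell count < 1
    carry a warning flag.
    """
    groups = list(pd.unique(cohort[group_col].dropna()))
    if len(groups) < 2:
        raise ValueError("grouping must define at least two groups")
    rows = []
    for var in categorical:
        table = pd.crosstab(cohort[var], cohort[group_col])
        table = table.reindex(columns=groups, fill_value=0)
        chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
        warn = bool((expected < 1).any())
        if warn:
            logger.warning("χ² for %s: expected cell count < 1", var)
        for level, counts in table.iterrows():
            row = {"variable": var, "level": level, "test": "chi2",
                   "statistic": chi2, "df": dof, "p": p, "low_expected": warn}
            for g in groups:
                row[f"n_{g}"] = int(counts[g])
                row[f"pct_{g}"] = _percent(int(counts[g]),
                                           int(table[g].sum()))
            rows.append(row)
    for var, success in binary.items():
        if len(groups) != 2:
            raise ValueError("two-proportion z-test requires exactly 2 groups")
        counts = np.array([(cohort.loc[cohort[group_col] == g, var] == success).sum()
                           for g in groups])
        nobs = np.array([(cohort[group_col] == g).sum() for g in groups])
        z, p = proportions_ztest(counts, nobs)
        row = {"variable": var, "level": success, "test": "two_prop_z",
               "statistic": z, "df": np.nan, "p": p, "low_expected": False}
        for g, c, n in zip(groups, counts, nobs):
            row[f"n_{g}"] = int(c)
            row[f"pct_{g}"] = _percent(int(c), int(n))
        rows.append(row)
    for var in continuous:
        if len(groups) != 2:
            raise ValueError("Welch t-test requires exactly 2 groups")
        a = cohort.loc[cohort[group_col] == groups[0], var].dropna()
        b = cohort.loc[cohort[group_col] == groups[1], var].dropna()
        t, p = stats.ttest_ind(a, b, equal_var=False)
        row = {"variable": var, "level": "", "test": "welch_t",
               "statistic": t, "df": np.nan, "p": p, "low_expected": False}
        for g, v in zip(groups, (a, b)):
            row[f"n_{g}"] = int(len(v))
            row[f"mean_{g}"] = float(v.mean())
            row[f"sd_{g}"] = float(v.std())
        rows.append(row)
    return pd.DataFrame(rows)
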