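"""Synthetic cohort generator emulating a multi-site developmental study.

The generator produces the three tables the downstream pipeline consumes:

* ``cohort.csv`` — one row per participant: IDs (participant, family,
  site), demographics, FHSU status, the 33 sociodemographic profile
  features, CBCL t-scores, UPPS-P subscale scores, and the latent
  subgroup label (ground truth, synthetic data only);
* ``family_history.csv`` — relative-level alcohol/drug indicators
  consistent with each participant's FHSU status and tuned to target
  group FHD means;
* ``mid_trials.csv`` — Monetary Incentive Delay runs of 50 trials
  (10 per trial type, pseudorandom order) per participant.

Structure emulated: latent subgroups are drawn at the family level from
the configured mixing weights (siblings share their environment), the
nine discriminative features concentrate on each subgroup's modal level
with strength controlled by ``profile_separation``, the remaining 24
features follow subgroup-independent base rates, and outcomes are
population mean + subgroup shift + site intercept + family intercept +
Gaussian residual.  Families have one or two children and never span
sites.  All draws are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from fhstrat import schema as _schema
from fhstrat.config import CBCL_OUTCOMES, UPPS_OUTCOMES, GeneratorConfig
from fhstrat.family_history import CSV_COLUMNS, FamilyHistoryRecord
from fhstrat.reward import CUE_TYPES, outcome_value

SEX_CATEGORIES = ("male", "female", "other")
SEX_RATES = (0.511, 0.487, 0.002)
RACE_CATEGORIES = ("White", "Hispanic", "Black", "Asian", "Other")
RACE_RATES = (0.601, 0.186, 0.097, 0.017, 0.099)

CBCL_BOUNDS = (25.0, 100.0)
UPPS_BOUNDS = (4, 16)


#: ceiling on the modal-category probability under tilting; survey responses
#: retain irreducible noise, and a near-point-mass column would degenerate
#: into extreme standardized outliers
MAX_MODAL_MASS = 0.98


def _tilted_rates(spec: _schema.FeatureSpec, modal: Optional[str],
                  separation: float) -> np.ndarray:
    """Category weights ∝ base_rate · exp(separation · 1[category == modal]).

    The modal mass saturates at MAX_MODAL_MASS; residual mass is spread
    over the other categories in proportion to their base rates.
    """
    rates = np.asarray(spec.base_rates, dtype=float)
    if modal is None or separation == 0:
        return rates
    w = rates.copy()
    m = spec.codes[modal]
    w[m] *= np.exp(separation)
    w = w / w.sum()
    if w[m] > MAX_MODAL_MASS:
        rest = np.delete(rates, m)
        w = np.insert((1 - MAX_MODAL_MASS) * rest / rest.sum(), m, MAX_MODAL_MASS)
    return w


def _family_structure(n: int, sibling_fraction: float, n_sites: int,
                      rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Assign family and site IDs: families of size 1 or 2, never spanning sites.

    The number of participants in two-child families is the closest even
    integer to n·sibling_fraction.
    """
    n_sib = int(round(n * sibling_fraction / 2.0)) * 2
    n_families = (n - n_sib) + n_sib // 2
    sizes = np.array([2] * (n_sib // 2) + [1] * (n - n_sib), dtype=int)
    rng.shuffle(sizes)
    fam_sites = rng.integers(0, n_sites, size=n_families)
    family_id = np.repeat(np.arange(n_families), sizes)
    site_id = np.repeat(fam_sites, sizes)
    perm = rng.permutation(n)
    return family_id[perm], site_id[perm]


def generate_family_history(fhsu_status: str, fhd_target_mean: float,
                            rng: np.random.Generator) -> FamilyHistoryRecord:
    """Draw relative-level indicators consistent with status and FHD target.

    For a given per-indicator endorsement rate r, the expected FHD is
    0.5·4r + 0.25·8r = 4r when all twelve parent/grandparent indicators
    are free, and 0.5·2r + 0.25·4r = 2r when only the alcohol indicators
    are (negative status), so rates are set to target/4 and target/2
    respectively.  Positive records are guaranteed at least one endorsed
    blood-relative drug indicator: if none of the parent/grandparent
    drug indicators comes up, the "other blood relative" item (which does
    not enter the FHD score) is set.
    """
    if fhsu_status not in ("positive", "negative"):
        raise ValueError(f"invalid FHSU status {fhsu_status!r}")
    if fhsu_status == "negative":
        r = min(1.0, fhd_target_mean / 2.0)
        return FamilyHistoryRecord(
            parent_drug_problem=(False, False),
            parent_alcohol_problem=tuple(rng.random(2) < r),
            grandparent_drug_problem=(False,) * 4,
            grandparent_alcohol_problem=tuple(rng.random(4) < r),
            other_blood_relative_drug_problem=False,
        )
    r = min(1.0, fhd_target_mean / 4.0)
    pd_ = tuple(rng.random(2) < r)
    pa = tuple(rng.random(2) < r)
    gd = tuple(rng.random(4) < r)
    ga = tuple(rng.random(4) < r)
    other = bool(rng.random() < r) or not (any(pd_) or any(gd))
    return FamilyHistoryRecord(pd_, pa, gd, ga, other)


def generate_mid_runs(participant_id, hit_prob: float, n_runs: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Simulate MID runs: 50 trials each, 10 per trial type, pseudorandom order."""
    if not 0 <= hit_prob <= 1:
        raise ValueError("hit_prob must be in [0, 1]")
    rows = []
    for run in range(1, n_runs + 1):
        cues = np.repeat(np.arange(len(CUE_TYPES)), 10)
        rng.shuffle(cues)
        hits = rng.random(50) < hit_prob
        for t, (ci, hit) in enumerate(zip(cues, hits), start=1):
            cue_type = CUE_TYPES[ci]
            rows.append({
                "participant_id": participant_id,
                "run": run,
                "trial_index": t,
                "cue_type": cue_type,
                "hit": int(hit),
                "outcome": outcome_value(cue_type, bool(hit)),
            })
    return pd.DataFrame(rows)


@dataclass
class SyntheticCohort:
    """The three generated tables, joined by participant_id."""

    cohort: pd.DataFrame
    family_history: pd.DataFrame
    mid_trials: pd.DataFrame


def generate_cohort(config: GeneratorConfig,
                    include_mid: bool = True) -> SyntheticCohort:
    """Generate a full synthetic cohort under the given configuration."""
    n = config.n_participants
    rng = np.random.default_rng(config.seed)
    family_id, site_id = _family_structure(
        n, config.sibling_fraction, config.n_sites, rng)

    # family-level draws: FHSU status and latent subgroup (siblings share both)
    n_families = family_id.max() + 1
    fam_positive = rng.random(n_families) < config.fhsu_positive_fraction
    weights = np.array([p.weight for p in config.subgroup_profiles])
    fam_subgroup = rng.choice(len(weights), size=n_families, p=weights / weights.sum())
    positive = fam_positive[family_id]
    subgroup_idx = fam_subgroup[family_id]
    names = np.array(config.subgroup_names)
    true_subgroup = np.where(positive, names[subgroup_idx], "FHSU-N")

    df = pd.DataFrame({
        "participant_id": [f"P{i:06d}" for i in range(n)],
        "family_id": [f"F{f:05d}" for f in family_id],
        "site_id": [f"site{s:02d}" for s in site_id],
        "fhsu_status": np.where(positive, "positive", "negative"),
        "true_subgroup": true_subgroup,
        "sex": rng.choice(SEX_CATEGORIES, size=n, p=SEX_RATES),
        "age": rng.integers(107, 133, size=n),  # months, 9-10 years
        "race_ethnicity": rng.choice(RACE_CATEGORIES, size=n, p=RACE_RATES),
    })

    # profile features: tilt the nine discriminative features toward the
    # subgroup's modal level for FHSU-P rows; everything else from base rates
    profiles = {p.name: p for p in config.subgroup_profiles}
    # features whose modal level is shared by every profile carry no
    # between-subgroup signal; concentrating them would only produce a
    # degenerate near-constant column, so they keep their base rates
    # (whose mode agrees with the shared profile level)
    informative = {
        feat for feat in _schema.DISCRIMINATIVE_FEATURES
        if len({p.modal_levels.get(feat) for p in config.subgroup_profiles}) > 1
    }
    for spec in _schema.FEATURES:
        codes = np.empty(n, dtype=int)
        if spec.name in informative:
            for group in np.unique(true_subgroup):
                mask = true_subgroup == group
                modal = (profiles[group].modal_levels.get(spec.name)
                         if group in profiles else None)
                rates = _tilted_rates(spec, modal, config.profile_separation)
                codes[mask] = rng.choice(len(rates), size=mask.sum(), p=rates)
        else:
            rates = np.asarray(spec.base_rates)
            codes[:] = rng.choice(len(rates), size=n, p=rates)
        df[spec.name] = np.asarray(spec.categories, dtype=object)[codes]

    # outcomes: mean + subgroup shift + site + family intercepts + residual
    site_eff = rng.normal(0.0, config.site_sd, size=config.n_sites)[site_id]
    fam_eff = rng.normal(0.0, config.family_sd, size=n_families)[family_id]
    for outcome, mean in config.outcome_means.items():
        shift = np.zeros(n)
        effects = config.outcome_effects.get(outcome, {})
        for group, delta in effects.items():
            shift[true_subgroup == group] = delta
        resid = rng.normal(0.0, config.outcome_sds[outcome], size=n)
        values = mean + shift + site_eff + fam_eff + resid
        if outcome in CBCL_OUTCOMES:
            df[outcome] = np.clip(values, *CBCL_BOUNDS)
        else:
            df[outcome] = np.clip(np.round(values), *UPPS_BOUNDS).astype(int)

    # family history records tuned to group FHD targets
    fh_rows = []
    for pid, status in zip(df["participant_id"], df["fhsu_status"]):
        target = (config.fhd_target_positive if status == "positive"
                  else config.fhd_target_negative)
        rec = generate_family_history(status, target, rng)
        fh_rows.append(rec.to_row(participant_id=pid))
    fh = pd.DataFrame(fh_rows)[list(CSV_COLUMNS)]

    if include_mid:
        mid = pd.concat(
            [generate_mid_runs(pid, config.mid_hit_prob, config.mid_n_runs, rng)
             for pid in df["participant_id"]],
            ignore_index=True)
    else:
        mid = pd.DataFrame(columns=["participant_id", "run", "trial_index",
                                    "cue_type", "hit", "outcome"])
    return SyntheticCohort(cohort=df, family_history=fh, mid_trials=mid)


def apply_mcar_mask(df: pd.DataFrame, columns: Sequence[str], rate: float,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Return a copy with values in ``columns`` masked missing-completely-at-random."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    out = df.copy()
    for col in columns:
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
    return out
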