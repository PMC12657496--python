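"""Pipeline orchestration: simulate → score → cluster → rpe → compare → report.

Each stage reads/writes CSV artifacts in an output directory and the
full run is summarized in a JSON manifest listing every file written
with its SHA-256 checksum and the effective configuration, so that two
runs under the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

import fhstrat
from fhstrat import clustering as cl
from fhstrat import inference as inf
from fhstrat import reward as rw
from fhstrat.config import GeneratorConfig
from fhstrat.family_history import score_family_history_table
from fhstrat.simulate import generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fhd", "cluster", "rpe", "compare", "report")

#: artifact each stage requires -> stage that produces it
_DEPENDENCIES = {
    "fhd": [("family_history.csv", "simulate")],
    "cluster": [("cohort.csv", "simulate")],
    "rpe": [("mid_trials.csv", "simulate")],
    "compare": [("cohort.csv", "simulate"), ("clusters.csv", "cluster"),
                ("rpe_summary.csv", "rpe")],
    "report": [("cohort.csv", "simulate"), ("clusters.csv", "cluster"),
               ("contrasts.csv", "compare")],
}


@dataclass
class PipelineConfig:
    out_dir: str = "fhstrat_out"
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    # clustering
    k_range: Sequence[int] = tuple(range(2, 11))
    n_init: int = 30
    n_seeds: int = 20
    n_boot: int = 100
    encoding: str = "onehot"
    elbow_method: str = "permutation"
    # rpe
    eta: float = rw.DEFAULT_ETA
    update_mode: str = "normalized"
    # inference
    reference_subgroup: str = "FHSU-N"
    fdr_alpha: float = 0.05
    standardize_outcomes: bool = False

    def __post_init__(self):
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["subgroup_profiles"] = [
            {"name": p.name, "modal_levels": dict(p.modal_levels), "weight": p.weight}
            for p in self.generator.subgroup_profiles
        ]
        d["k_range"] = list(self.k_range)
        d["version"] = fhstrat.__version__
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class MissingArtifactError(RuntimeError):
    """An upstream artifact is absent; names the stage to run first."""


def _check_dependencies(stage: str, out: Path) -> None:
    for artifact, producer in _DEPENDENCIES.get(stage, []):
        if not (out / artifact).exists():
            raise MissingArtifactError(
                f"stage '{stage}' requires {artifact}; run stage '{producer}' first")


def run_pipeline(config: PipelineConfig,
                 stages: Optional[Sequence[str]] = None) -> dict:
    """Execute the requested stages in order and write the manifest.

    Returns the manifest dict: stage timings plus every output file with
    its checksum and the effective configuration.
    """
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[str] = []
    timings: Dict[str, float] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(name)

    for stage in stages:
        _check_dependencies(stage, out)
        t0 = time.time()
        if stage == "simulate":
            gen = dataclasses.replace(config.generator, seed=config.seed)
            syn = generate_cohort(gen)
            emit("cohort.csv", syn.cohort)
            emit("family_history.csv", syn.family_history)
            emit("mid_trials.csv", syn.mid_trials)
        elif stage == "fhd":
            fh = pd.read_csv(out / "family_history.csv")
            emit("fhd_scores.csv", score_family_history_table(fh))
        elif stage == "cluster":
            cohort = pd.read_csv(out / "cohort.csv")
            fhsup = cohort[cohort["fhsu_status"] == "positive"].reset_index(drop=True)
            X = cl.preprocess_features(fhsup, encoding=config.encoding)
            elbow = cl.select_k_elbow(X, k_range=config.k_range,
                                      n_init=min(config.n_init, 10),
                                      seed=config.seed,
                                      method=config.elbow_method)
            emit("elbow.csv", elbow.curve)
            sol = cl.fit_kmeans(X, elbow.k_star, n_init=config.n_init,
                                seed=config.seed)
            emit("clusters.csv", pd.DataFrame({
                "participant_id": X.participant_ids,
                "subgroup": [f"SG{l + 1}" for l in sol.labels],
            }))
            seed_rep = cl.seed_stability(X, elbow.k_star, n_seeds=config.n_seeds,
                                         n_init=config.n_init,
                                         base_seed=config.seed)
            boot_rep = cl.bootstrap_stability(X, elbow.k_star, n_boot=config.n_boot,
                                              n_init=config.n_init,
                                              seed=config.seed, reference=sol)
            stability = {"k_star": int(elbow.k_star),
                         "low_confidence": bool(elbow.low_confidence),
                         "distortion": float(sol.distortion),
                         **seed_rep.to_dict(), **boot_rep.to_dict()}
            (out / "stability.json").write_text(
                json.dumps(stability, indent=2, sort_keys=True))
            written.append("stability.json")
            shap_rank = cl.feature_attribution(X, sol.labels, seed=config.seed)
            emit("shap_ranking.csv", shap_rank)
            coords, evr = cl.pca_project(X)
            pca_df = pd.DataFrame(coords, columns=[f"pc{i + 1}"
                                                   for i in range(coords.shape[1])])
            pca_df.insert(0, "participant_id", X.participant_ids)
            pca_df["subgroup"] = [f"SG{l + 1}" for l in sol.labels]
            pca_df.attrs["explained_variance_ratio"] = list(map(float, evr))
            emit("pca.csv", pca_df)
        elif stage == "rpe":
            mid = pd.read_csv(out / "mid_trials.csv")
            emit("rpe_summary.csv",
                 rw.compute_rpe_summaries(mid, eta=config.eta,
                                          update_mode=config.update_mode))
        elif stage == "compare":
            data = _assemble_analysis_table(out, config)
            meta = (f"# seed={config.seed} reference={config.reference_subgroup}"
                    f" model=outcome~subgroup+sex+age+race_ethnicity"
                    f"+(1|site)+(1|family) estimation=ML"
                    f" fdr=benjamini-hochberg(within-domain)"
                    f" fhstrat={fhstrat.__version__}\n")
            contrasts = inf.run_contrast_analysis(
                data, group_col="subgroup", reference=config.reference_subgroup,
                standardize_outcome=config.standardize_outcomes)
            (out / "contrasts.csv").write_text(
                meta + contrasts.to_csv(index=False))
            written.append("contrasts.csv")
            demo = inf.demographic_tests(
                data, "subgroup",
                categorical=("sex", "race_ethnicity"))
            (out / "demographics.csv").write_text(
                meta + demo.to_csv(index=False))
            written.append("demographics.csv")
        elif stage == "report":
            _write_report(out, config)
            written.append("report.md")
        timings[stage] = round(time.time() - t0, 3)
        logger.info("stage %s done in %.1fs", stage, timings[stage])

    manifest = {
        "config": config.to_dict(),
        "stages": stages,
        "timings_sec": timings,
        "outputs": {name: _sha256(out / name) for name in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _assemble_analysis_table(out: Path, config: PipelineConfig) -> pd.DataFrame:
    """Join cohort, cluster assignments, and RPE summaries.

    FHSU-negative participants keep the reference label; FHSU-positive
    participants take their k-means subgroup.
    """
    cohort = pd.read_csv(out / "cohort.csv")
    clusters = pd.read_csv(out / "clusters.csv")
    rpe = pd.read_csv(out / "rpe_summary.csv")
    data = cohort.merge(clusters, on="participant_id", how="left")
    data["subgroup"] = data["subgroup"].fillna(config.reference_subgroup)
    return data.merge(rpe, on="participant_id", how="left")


def _write_report(out: Path, config: PipelineConfig) -> None:
    """Markdown report: subgroup profiles, outcome means ± SD, contrasts."""
    data = _assemble_analysis_table(out, config)
    contrasts = pd.read_csv(out / "contrasts.csv", comment="#")
    lines = ["# Subgroup analysis report", ""]
    stability_path = out / "stability.json"
    if stability_path.exists():
        st = json.loads(stability_path.read_text())
        lines += [
            f"Selected k = {st['k_star']} "
            f"(distortion {st['distortion']:.3f}; "
            f"bootstrap NMI {st.get('bootstrap_nmi_mean', float('nan')):.3f} ± "
            f"{st.get('bootstrap_nmi_sd', float('nan')):.3f}; "
            f"seed centroid shift {st.get('seed_mean_centroid_shift', float('nan')):.4f})",
            "",
        ]
    lines.append("## Subgroup modal profiles (discriminative features)")
    from fhstrat.schema import DISCRIMINATIVE_FEATURES
    sub = data[data["subgroup"] != config.reference_subgroup]
    prof = sub.groupby("subgroup")[list(DISCRIMINATIVE_FEATURES)].agg(
        lambda s: s.mode().iloc[0])
    lines += ["", prof.T.to_markdown(), ""]
    lines.append("## Outcome means ± SD by subgroup")
    outcome_cols = [c for cols in inf.DOMAINS.values() for c in cols
                    if c in data.columns]
    means = data.groupby("subgroup")[outcome_cols].mean().round(2)
    sds = data.groupby("subgroup")[outcome_cols].std().round(2)
    summary = means.astype(str) + " ± " + sds.astype(str)
    lines += ["", summary.T.to_markdown(), ""]
    lines.append("## Mixed-model contrasts (CE, BH-FDR within domain)")
    show = contrasts[["outcome", "domain", "contrast", "ce", "se",
                      "p_raw", "p_fdr"]].copy()
    show["significant"] = show["p_fdr"] < config.fdr_alpha
    lines += ["", show.round(4).to_markdown(index=False), ""]
    (out / "report.md").write_text("\n".join(lines))
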