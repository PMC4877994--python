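"""End-to-end orchestration of the comparison pipeline.

Stage order: synthetic generation (or CSV input) -> pyrogram quantification
-> per-subset agreement statistics -> mixture/tree pattern analysis ->
subset-specific regression -> treatment effect sizes.  A single master seed
deterministically derives an independent seed per stage (so toggling one
stage never shifts another stage's random stream), and the combined report
is a versioned JSON document.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, effects, mixpattern, samples, subsetreg, synthdata
from . import pyroquant

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

_STAGES = ("agreement", "mixture", "regression", "effects")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    idx = {"synthdata": 0, "quantify": 1, "agreement": 2, "mixture": 3,
           "regression": 4, "effects": 5}[stage]
    return int(np.random.SeedSequence(master_seed).generate_state(idx + 1)[idx]) % (2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (defaults = the study settings)."""

    seed: int = 0
    synthetic: bool = True
    samples_path: str | None = None
    pyrograms_path: str | None = None
    line1_path: str | None = None
    controls_path: str | None = None
    out_dir: str = "methaccord_out"
    stages: tuple[str, ...] = _STAGES
    n_boot: int = 1000
    tree_reps: int = 100
    tree_k_frac: float = 0.1
    qc_violation_fraction: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _load_samples(config: RunConfig) -> pd.DataFrame:
    if config.synthetic:
        synth = synthdata.default_config(
            seed=stage_seed(config.seed, "synthdata"),
            qc_violation_fraction=config.qc_violation_fraction,
        )
        sheet = synthdata.generate_samples(synth)
        if config.qc_violation_fraction > 0:
            pyro, line1, controls = synthdata.generate_pyrograms(sheet, synth)
            quantified = pyroquant.quantify(pyro, line1, controls)
            quantified["treatment"] = sheet["treatment"].to_numpy()
            sheet = quantified
        return sheet
    if config.samples_path:
        return samples.read_sheet(_existing(config.samples_path))
    pyro = pd.read_csv(_existing(config.pyrograms_path))
    line1 = pd.read_csv(_existing(config.line1_path))
    controls = pd.read_csv(_existing(config.controls_path))
    return pyroquant.quantify(pyro, line1, controls)


def _existing(path) -> Path:
    if path is None:
        raise FileNotFoundError("no input path configured and synthetic mode is off")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    return p


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; write per-stage CSV/JSON and the report.

    Returns the combined report dict (also written to
    ``<out_dir>/report.json``).  Deterministic under ``config.seed``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed,
                    "stages": list(config.stages)}
    sheet = _load_samples(config)
    samples.write_sheet(sheet, out / "samples.csv")
    kept = samples.retained(sheet)
    report["n_samples"] = int(len(sheet))
    report["n_retained"] = int(len(kept))

    if "agreement" in config.stages:
        seed = stage_seed(config.seed, "agreement")
        reports = agreement.subset_reports(kept, n_boot=config.n_boot, seed=seed)
        anova = agreement.rm_anova(kept)
        report["agreement"] = {
            "per_subset": [r.to_dict() for r in reports],
            "rm_anova": {k: v for k, v in anova.items() if k != "posthoc_wilcoxon_bonferroni"},
            "posthoc_wilcoxon_bonferroni": anova["posthoc_wilcoxon_bonferroni"],
        }
        pd.DataFrame([r.to_dict() for r in reports]).to_csv(
            out / "agreement.csv", index=False)

    diffs = (kept["line1_pct"] - kept["luma_pct"]).to_numpy()
    if "mixture" in config.stages:
        seed = stage_seed(config.seed, "mixture")
        model = mixpattern.fit_gmm(diffs, seed=seed)
        labels, _ = mixpattern.component_assignment(diffs, model)
        block = {"mixture": model.to_dict()}
        if len(set(labels)) >= 2:
            chi2 = mixpattern.association_chi2(kept["subset"], labels)
            tree = mixpattern.tissue_tree(
                kept["subset"].to_numpy(), labels, k_frac=config.tree_k_frac,
                n_rep=config.tree_reps, seed=seed)
            block["association"] = {
                "chi2": chi2["chi2"], "df": chi2["df"], "p": chi2["p"],
                "table": {str(k): v for k, v in
                          chi2["table"].to_dict(orient="index").items()},
            }
            block["tree"] = tree.to_dict()
        report["pattern"] = block

    if "regression" in config.stages:
        seed = stage_seed(config.seed, "regression")
        fit, log = subsetreg.build_final_model(kept)
        fit = subsetreg.bootstrap_ci(kept, fit.spec, n_boot=config.n_boot, seed=seed)
        report["regression"] = {"final_model": fit.to_dict(), "step_log": log}

    if "effects" in config.stages:
        # effect sizes concern the in-vitro exposure panel: subsets whose
        # labels are treatment conditions rather than donor cohorts
        cell_lines = [s for s in dict.fromkeys(kept["subset"]) if s != "blood"]
        records, rho, p = effects.pairwise_effects(kept, cell_lines=cell_lines)
        report["effects"] = {
            "n_comparisons": len(records),
            "cross_assay_spearman_rho": rho,
            "cross_assay_spearman_p": p,
        }
        pd.DataFrame([r.to_dict() for r in records]).to_csv(
            out / "effect_sizes.csv", index=False)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
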