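"""End-to-end orchestration: simulate -> correct -> harmonize -> evaluate.

All randomness flows from one base seed through named substreams (cohort,
phantom), so re-running with the same config and seed reproduces every
artifact byte for byte, and changing how many draws one stage consumes
does not perturb the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import (apply_age_sex, apply_calibration, fit_age_sex,
                          fit_phantom_calibration, prospective_correct)
from .combat import harmonize
from .config import RunConfig
from .datatypes import Cohort, PhantomScan
from .evaluation import EvaluationReport, compare_methods, hedges_g_from_summary
from .io import write_cohort, write_phantom, write_report
from .simulate import LatentTruth, generate_cohort, generate_phantom_scans

log = logging.getLogger("sbrkit")

_SUBSTREAMS = ("cohort", "phantom", "evaluation")


def substream_seeds(seed: int) -> dict[str, int]:
    """Independent child seeds (one per pipeline stage) from the base seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_SUBSTREAMS))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
        for name, child in zip(_SUBSTREAMS, children)
    }


@dataclass
class PipelineRun:
    config: dict
    seed: int
    cohorts: dict[str, Cohort]
    phantoms: list[PhantomScan]
    truth: LatentTruth
    report: EvaluationReport
    artifacts: dict[str, str] = field(default_factory=dict)
    operations: list[dict] = field(default_factory=list)


def run_full_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineRun:
    """Run the whole study on one synthetic cohort.

    Stages produced: ``original`` (simulated multisite data),
    ``age_sex_corrected`` (HC-normative linear adjustment),
    ``scanner_corrected`` (phantom calibration only), ``prospective``
    (procedure standardization + phantom calibration) and ``combat``
    (empirical-Bayes harmonization of the age/sex-corrected data with
    diagnosis protected).  Returns all cohorts plus the evaluation report;
    writes per-stage CSVs and the report JSON when ``out_dir`` is given.
    """
    seeds = substream_seeds(config.seed)
    ops: list[dict] = []

    cohort, truth = generate_cohort(config.synth, seeds["cohort"], strict=config.strict)
    ops.append({"op": "generate_cohort", "seed": seeds["cohort"],
                "n": len(cohort), "n_features": cohort.n_features})
    log.info("generated cohort: %d records, %d features", len(cohort), cohort.n_features)

    phantoms = generate_phantom_scans(config.synth, seed=seeds["phantom"])
    ops.append({"op": "generate_phantom_scans", "seed": seeds["phantom"],
                "n_scans": len(phantoms)})

    age_sex = fit_age_sex(cohort, ref_age=config.synth.ref_age)
    corrected = apply_age_sex(cohort, age_sex)
    ops.append({"op": "age_sex_correction",
                "age_slope": age_sex.age_slope.tolist(),
                "sex_offset": age_sex.sex_offset.tolist(),
                "ref_age": age_sex.ref_age})

    calib = fit_phantom_calibration(phantoms, config.reference_scanner)
    scanner_corrected = apply_calibration(corrected, calib)
    prospective = prospective_correct(corrected, calib, truth=truth)
    ops.append({"op": "phantom_calibration",
                "reference_scanner": config.reference_scanner,
                "maps": {k: [m.slope, m.intercept] for k, m in calib.maps.items()}})

    combat_cohort, combat_model = harmonize(corrected, config)
    ops.append({"op": "combat", "batch": config.batch_definition,
                "eb": combat_model.eb, "iterations": combat_model.iterations,
                "converged": combat_model.converged})

    cohorts = {
        "original": cohort,
        "age_sex_corrected": corrected,
        "scanner_corrected": scanner_corrected,
        "prospective": prospective,
        "combat": combat_cohort,
    }
    report = compare_methods(cohorts, low_is_positive=config.roc_low_positive)

    run = PipelineRun(
        config={"seed": config.seed, "batch_definition": config.batch_definition,
                "reference_scanner": config.reference_scanner, "eb": config.eb},
        seed=config.seed, cohorts=cohorts, phantoms=phantoms, truth=truth,
        report=report, operations=ops,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for stage, c in cohorts.items():
            p = out_dir / f"{stage}.csv"
            write_cohort(c, p)
            run.artifacts[stage] = str(p)
        p = out_dir / "phantom.csv"
        write_phantom(phantoms, p)
        run.artifacts["phantom"] = str(p)
        p = out_dir / "report.json"
        write_report(report, p)
        run.artifacts["report"] = str(p)
        p = out_dir / "run.json"
        with open(p, "w") as fh:
            json.dump({"config": run.config, "seed": run.seed,
                       "operations": run.operations,
                       "artifacts": run.artifacts}, fh, indent=2)
        run.artifacts["run"] = str(p)
    return run


# ---------------------------------------------------------------------------
# Published-summary reproduction

#: Group summaries (mean, SD, n) reported by the four-site DAT-SPECT
#: harmonization study this pipeline models, pooled over 72 HC / 81 PD,
#: together with the effect sizes printed alongside them.
PUBLISHED_SUMMARIES = {
    "original": {"hc": (6.13, 1.54, 72), "pd": (2.03, 1.41, 81), "printed_g": 2.76},
    "prospective": {"hc": (6.52, 1.06, 72), "pd": (2.40, 0.99, 81), "printed_g": 4.32},
    "combat": {"hc": (5.25, 0.89, 72), "pd": (2.01, 0.73, 81), "printed_g": 3.99},
}

#: The published prospective g of 4.32 cannot be re-derived from the
#: published prospective group summaries (they give ~4.0); flagged rather
#: than silently matched.
KNOWN_DISCREPANT_STAGES = ("prospective",)


def reproduce_published_summaries() -> list[dict]:
    """Recompute Hedges's g from the published group summaries.

    Returns one row per correction stage with the recomputed g, the
    published g and their deviation.  The prospective row carries a
    documented-discrepancy flag: its published effect size is not
    consistent with its published group summaries.
    """
    rows = []
    for stage, d in PUBLISHED_SUMMARIES.items():
        eff = hedges_g_from_summary(*d["hc"], *d["pd"])
        rows.append({
            "stage": stage,
            "recomputed_g": eff.g,
            "published_g": d["printed_g"],
            "deviation": eff.g - d["printed_g"],
            "discrepancy_flag": stage in KNOWN_DISCREPANT_STAGES,
        })
    return rows
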