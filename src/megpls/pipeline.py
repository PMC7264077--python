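"""End-to-end synthetic study: simulate, analyse, report.

``run_full_study`` sequences the four headline analyses on one cohort:

1. mean-centered PLS of relative power against group membership;
2. behavioral PLS against the 11 neurocognitive variables;
3. behavioral PLS against the three intensity variables (TI, CGI, CWI),
   plus the z-map correlation with analysis 1;
4. behavioral PLS against the TV-CGV ratio, plus the z-map correlation
   with analysis 2, brain-score vs volume correlations, tail-power
   associations, and the two neonatal regressions.

All randomness flows from one master seed: stage seeds are the first
words of ``SeedSequence(master).generate_state``, halved into the
signed-32-bit range, in the fixed order cohort, analysis 1..4.  Rerunning
with the same configuration reproduces every CSV byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BandPowerMatrix
from .errors import MegPLSError
from .io import cohort_config_from_dict, save_cohort, save_truth
from .pls import BehavioralPLS, MeanCenteredPLS, PLSResults
from .posthoc import (
    correlate_scores_with_volumes,
    correlate_zmaps,
    neonatal_regression,
    tail_power_association,
)
from .structural import OUTCOME_COLS, tv_cgv_ratio
from .synthetic import generate_power_cohort

INTENSITY_VARS = ["TI", "CGI", "CWI"]


def derive_stage_seeds(master_seed: int, n: int = 6) -> list[int]:
    """Deterministic per-stage seeds in [0, 2^31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s >> 1) for s in state]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


class StudyRun:
    """Container for the artifacts of one full synthetic study."""

    def __init__(self) -> None:
        self.power: BandPowerMatrix | None = None
        self.cohort: pd.DataFrame | None = None
        self.truth = None
        self.pls: dict[str, PLSResults] = {}
        self.zmap_correlations: dict[str, float] = {}
        self.score_volume_correlations: dict[str, tuple[float, float, int]] = {}
        self.tail_associations = None
        self.regressions: dict = {}
        self.manifest: dict = {}


def run_full_study(
    config: dict,
    out_dir=None,
    n_perm: int = 500,
    n_boot: int = 500,
    seed: int = 0,
) -> StudyRun:
    """Run the four-analysis synthetic study; optionally write a run directory.

    ``config`` holds the cohort-generator fields (see
    :class:`~megpls.synthetic.SyntheticCohortConfig`); the master
    ``seed`` drives the generator and every resampling stage.
    """
    seeds = derive_stage_seeds(seed)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "master_seed": seed,
        "stage_seeds": {
            "cohort": seeds[0], "pls_group": seeds[1], "pls_neurocognitive": seeds[2],
            "pls_intensity": seeds[3], "pls_volume": seeds[4],
        },
        "n_perm": n_perm,
        "n_boot": n_boot,
        "stages": {},
        "log": [],
        "outputs": [],
    }
    run = StudyRun()
    run.manifest = manifest

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None and isinstance(exc, MegPLSError):
                    raise MegPLSError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Timer()

    with stage("simulate"):
        cohort_cfg = cohort_config_from_dict(config, seed=seeds[0])
        bpm, cohort, truth = generate_power_cohort(cohort_cfg)
        cohort["tv_cgv"] = tv_cgv_ratio(cohort["TV"], cohort["CGV"])
        run.power, run.cohort, run.truth = bpm, cohort, truth

    with stage("pls_group"):
        run.pls["group"] = MeanCenteredPLS.from_band_power(bpm, cohort).fit(
            n_perm=n_perm, n_boot=n_boot, seed=seeds[1]
        )

    with stage("pls_neurocognitive"):
        model = BehavioralPLS.from_band_power(bpm, cohort, list(OUTCOME_COLS))
        _log_exclusions(manifest, "neurocognitive", bpm, model)
        run.pls["neurocognitive"] = model.fit(n_perm=n_perm, n_boot=n_boot, seed=seeds[2])

    with stage("pls_intensity"):
        model = BehavioralPLS.from_band_power(bpm, cohort, INTENSITY_VARS)
        _log_exclusions(manifest, "intensity", bpm, model)
        run.pls["intensity"] = model.fit(n_perm=n_perm, n_boot=n_boot, seed=seeds[3])

    with stage("pls_volume"):
        model = BehavioralPLS.from_band_power(bpm, cohort, ["tv_cgv"])
        _log_exclusions(manifest, "volume", bpm, model)
        run.pls["volume"] = model.fit(n_perm=n_perm, n_boot=n_boot, seed=seeds[4])

    with stage("posthoc"):
        run.zmap_correlations["group_vs_intensity"] = correlate_zmaps(
            run.pls["group"].zmap(), run.pls["intensity"].zmap()
        )
        run.zmap_correlations["neurocognitive_vs_volume"] = correlate_zmaps(
            run.pls["neurocognitive"].zmap(), run.pls["volume"].zmap()
        )
        run.score_volume_correlations = correlate_scores_with_volumes(
            run.pls["group"].brain_scores, cohort[["TV", "CGV"]]
        )
        run.tail_associations = tail_power_association(
            run.pls["volume"].zmap(), bpm, cohort["tv_cgv"].to_numpy(),
            groups=cohort["group"].to_numpy(),
        )

    with stage("regressions"):
        run.regressions["TI"] = neonatal_regression(cohort, "TI")
        run.regressions["tv_cgv"] = neonatal_regression(cohort, "tv_cgv")

    if out_dir is not None:
        _write_run_directory(run, Path(out_dir))
    return run


def _log_exclusions(manifest, analysis, bpm, model) -> None:
    dropped = sorted(set(bpm.subject_ids) - set(model.subject_ids))
    for sid in dropped:
        manifest["log"].append(
            {"analysis": analysis, "subject_id": sid, "reason": "missing behavioral data (listwise)"}
        )


def _write_run_directory(run: StudyRun, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    outputs = run.manifest["outputs"]

    run.power.to_csv(out / "band_power.csv")
    outputs.append("band_power.csv")
    save_cohort(run.cohort, out / "cohort.csv")
    outputs.append("cohort.csv")
    if run.truth is not None:
        save_truth(run.truth, out / "truth.json")
        outputs.append("truth.json")

    for name, res in run.pls.items():
        res.save(out / f"pls_{name}")
        for f in sorted((out / f"pls_{name}").iterdir()):
            outputs.append(str(f.relative_to(out)))

    pd.DataFrame(
        [{"pair": k, "pearson_r": v} for k, v in run.zmap_correlations.items()]
    ).to_csv(out / "zmap_correlations.csv", index=False)
    outputs.append("zmap_correlations.csv")

    rows = [
        {"volume": k, "pearson_r": r, "p_value": p, "n": n}
        for k, (r, p, n) in run.score_volume_correlations.items()
    ]
    pd.DataFrame(rows).to_csv(out / "brain_score_volume_correlations.csv", index=False)
    outputs.append("brain_score_volume_correlations.csv")

    rows = []
    for band, ta in run.tail_associations.items():
        rows.append({
            "band": band, "skewness": ta.skewness,
            "selected_sources": ";".join(map(str, ta.selected)),
            "scope": "pooled", "pearson_r": ta.pooled[0], "p_value": ta.pooled[1], "n": ta.pooled[2],
        })
        for lab, (r, p, n) in ta.per_group.items():
            rows.append({"band": band, "skewness": ta.skewness,
                         "selected_sources": ";".join(map(str, ta.selected)),
                         "scope": lab, "pearson_r": r, "p_value": p, "n": n})
    pd.DataFrame(rows).to_csv(out / "tail_associations.csv", index=False)
    outputs.append("tail_associations.csv")

    for name, reg in run.regressions.items():
        path = out / f"regression_{name}.csv"
        frame = reg.to_frame()
        frame.loc["__model__"] = [reg.f_statistic, reg.model_p_value]
        frame.to_csv(path)
        outputs.append(path.name)

    (out / "manifest.json").write_text(json.dumps(run.manifest, indent=2))
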