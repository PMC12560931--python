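"""End-to-end orchestration: simulate → acquire/fit → analyze → report.

The pipeline reproduces the study's analysis tables on a synthetic cohort:
per-muscle trait contrasts, sensory summaries and success probabilities,
chemistry→sensory mixed-model slopes, between-muscle trait regressions,
instrument→sensory slopes, and the instrument-vs-chemistry regression
summaries.  A single global seed fans out to fixed per-stage child streams,
so disabling one stage does not shift the randomness of the others, and
identical config + seed yields byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, chemometrics, io, relaxfit, sensory, synthetic
from .config import PipelineConfig, TRAITS, dump_config, _as_dict
from .datatypes import EchoTrain, SuccessSpec

__all__ = ["run_pipeline", "RunReport"]

SCORES = ("tenderness", "juiciness", "flavor", "overall")
NMR_PARAMS = ("p_2f", "p_21", "p_22", "T_21_ms", "T_22_ms")


@dataclasses.dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    seed: int
    version: str
    stage_status: dict = dataclasses.field(default_factory=dict)
    tables: dict = dataclasses.field(default_factory=dict)
    config: dict = dataclasses.field(default_factory=dict)
    timestamps: dict = dataclasses.field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonify)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _summary_dict(s) -> dict:
    return dataclasses.asdict(s)


def _frame_records(df: pd.DataFrame) -> list:
    return json.loads(df.reset_index().to_json(orient="records"))


def _simulate(config: PipelineConfig, outdir: Path) -> dict:
    cohort = synthetic.generate_cohort(config.cohort)
    cohort = synthetic.generate_nirs(cohort, config.cohort)
    io.write_cohort(cohort, outdir / "cohort.csv")

    ltl = cohort[cohort["muscle"] == "LTL"].reset_index(drop=True)
    nmr_rng = synthetic.stage_rng(config.seed, "nmr")
    nmr_true = synthetic.link_nmr(ltl, config.cohort.nmr, nmr_rng)
    nmr_true.to_csv(outdir / "nmr_true.csv", index=False)

    echo_frames = []
    for i, row in nmr_true.iterrows():
        params = synthetic.nmr_params_from_row(row)
        for rep in range(1, config.n_replicates + 1):
            rng = synthetic.stage_rng(
                config.seed, "echo", index=i * config.n_replicates + rep
            )
            train = synthetic.acquire_with_averaging(
                params, config.acquisition, scale=1.0, rng=rng
            )
            echo_frames.append(
                pd.DataFrame(
                    {
                        "sample_id": row["carcass_id"],
                        "replicate": rep,
                        "echo_time_ms": train.times_ms,
                        "intensity": train.intensities,
                    }
                )
            )
    echoes = pd.concat(echo_frames, ignore_index=True)
    io.write_echo_trains(echoes, outdir / "echo_trains.csv")

    sens_rng = synthetic.stage_rng(config.seed, "sensory")
    sens = synthetic.generate_sensory(cohort, config.sensory, rng=sens_rng)
    io.write_sensory(sens, outdir / "sensory.csv")
    return {"cohort": cohort, "echoes": echoes, "sensory": sens, "nmr_true": nmr_true}


def _fit(config: PipelineConfig, outdir: Path, state: dict) -> dict:
    echoes = state.get("echoes")
    if echoes is None:
        echoes = io.read_echo_trains(outdir / "echo_trains.csv")
    rows = []
    sample_fits = {}
    for sample_id, grp in echoes.groupby("sample_id", sort=True):
        fits = []
        if config.average_trains_before_fit:
            wide = grp.pivot(index="echo_time_ms", columns="replicate", values="intensity")
            train = EchoTrain(
                times_ms=wide.index.to_numpy(dtype=float),
                intensities=wide.mean(axis=1).to_numpy(),
                n_scans_averaged=wide.shape[1],
            )
            fit = relaxfit.fit_triexponential(train, config.fit_options)
            fits = [fit]
            sample_fits[sample_id] = fit
            reps = [0]
        else:
            reps = sorted(grp["replicate"].unique())
            for rep in reps:
                g = grp[grp["replicate"] == rep]
                train = EchoTrain(
                    times_ms=g["echo_time_ms"].to_numpy(dtype=float),
                    intensities=g["intensity"].to_numpy(dtype=float),
                )
                fits.append(relaxfit.fit_triexponential(train, config.fit_options))
            sample_fits[sample_id] = relaxfit.average_replicate_fits(fits)
        for rep, fit in zip(reps, fits):
            rows.append(
                {
                    "sample_id": sample_id,
                    "replicate": rep,
                    "p_2f": fit.params.p_2f,
                    "p_21": fit.params.p_21,
                    "p_22": fit.params.p_22,
                    "T_21_ms": fit.params.t_21_ms,
                    "T_22_ms": fit.params.t_22_ms,
                    "scale": fit.scale,
                    "residual_rms": fit.residual_rms,
                    "converged": fit.converged,
                }
            )
    fits_df = pd.DataFrame(rows)
    io.write_fits(fits_df, outdir / "nmr_fits.csv")
    means = pd.DataFrame(
        [
            {
                "carcass_id": sid,
                "muscle": "LTL",
                "p_2f": f.params.p_2f,
                "p_21": f.params.p_21,
                "p_22": f.params.p_22,
                "T_21_ms": f.params.t_21_ms,
                "T_22_ms": f.params.t_22_ms,
            }
            for sid, f in sample_fits.items()
        ]
    )
    means.to_csv(outdir / "nmr_sample_means.csv", index=False)
    return {"fits": fits_df, "nmr_means": means}


def _analyze(config: PipelineConfig, outdir: Path, state: dict) -> dict:
    cohort = state.get("cohort")
    if cohort is None:
        cohort = io.read_cohort(outdir / "cohort.csv")
    sens = state.get("sensory")
    if sens is None:
        sens = io.read_sensory(outdir / "sensory.csv")
    cohort = chemometrics.add_nirs_aggregates(cohort)
    tables: dict = {}

    # per-muscle chemistry contrasts
    tables["trait_contrasts"] = {
        trait: _summary_dict(chemometrics.muscle_contrast(cohort, trait))
        for trait in TRAITS
    }

    # sensory summaries and success probabilities
    score_rows = []
    for resp in SCORES:
        grp = sens.groupby("muscle")[resp]
        result, _ = sensory._fit_mixed(sens, f"{resp} ~ muscle", sensory.RANDOM_TERMS)
        p = float(result.pvalues.get("muscle[T.SM]", np.nan))
        for muscle, mean in grp.mean().items():
            score_rows.append(
                {
                    "response": resp,
                    "muscle": muscle,
                    "mean": float(mean),
                    "sem": float(grp.sem()[muscle]),
                    "p_muscle": p,
                }
            )
    tables["sensory_scores"] = score_rows
    specs = [
        SuccessSpec("off_flavor", frozenset({0})),  # success = no off-flavor
        SuccessSpec("purchase_intent", frozenset({4, 5})),
        SuccessSpec("quality_grade", frozenset({3, 4})),
    ]
    tables["success_probabilities"] = {
        spec.response: _frame_records(
            sensory.success_probability(sens, spec, random_terms=sensory.RANDOM_TERMS)
        )
        for spec in specs
    }

    # chemistry -> sensory mixed slopes
    tables["chemistry_slopes"] = {
        resp: _frame_records(sensory.fit_chemistry_slopes(sens, cohort, resp))
        for resp in SCORES
    }

    # between-muscle trait regressions
    tables["cross_muscle"] = {
        trait: _summary_dict(s)
        for trait, s in chemometrics.cross_muscle_regression(cohort).items()
    }

    # NIRS output -> sensory slopes (pooled with muscle covariate, then per muscle)
    nirs_vals = cohort[["carcass_id", "muscle", "nirs_mean"]]
    nirs_rows = {}
    for resp in SCORES:
        entries = {}
        entries["both"] = _frame_records(
            sensory.fit_single_predictor_slope(
                sens, nirs_vals, resp, "nirs_mean", include_muscle=True
            )
        )
        for muscle in ("LTL", "SM"):
            entries[muscle] = _frame_records(
                sensory.fit_single_predictor_slope(
                    sens[sens["muscle"] == muscle],
                    nirs_vals[nirs_vals["muscle"] == muscle],
                    resp,
                    "nirs_mean",
                )
            )
        nirs_rows[resp] = entries
    tables["nirs_sensory_slopes"] = nirs_rows

    # instrument vs chemistry regression summaries
    tables["regressions"] = {
        "imf_on_nirs_mean_pooled": _summary_dict(
            chemometrics.ols_regression(cohort["nirs_mean"], cohort["imf_pct"])
        )
    }
    for muscle in ("LTL", "SM"):
        sub = cohort[cohort["muscle"] == muscle]
        tables["regressions"][f"imf_on_nirs_mean_{muscle}"] = _summary_dict(
            chemometrics.ols_regression(sub["nirs_mean"], sub["imf_pct"])
        )

    # NMR tables need the fitted relaxation parameters
    nmr = state.get("nmr_means")
    if nmr is None and (outdir / "nmr_sample_means.csv").exists():
        nmr = pd.read_csv(outdir / "nmr_sample_means.csv")
    if nmr is not None:
        ltl = cohort[cohort["muscle"] == "LTL"].merge(nmr, on=["carcass_id", "muscle"])
        tables["regressions"]["imf_on_p2f_LTL"] = _summary_dict(
            chemometrics.ols_regression(ltl["p_2f"], ltl["imf_pct"])
        )
        tables["regressions"]["ph_on_p2f_LTL"] = _summary_dict(
            chemometrics.ols_regression(ltl["p_2f"], ltl["pH"])
        )
        sens_ltl = sens[sens["muscle"] == "LTL"]
        nmr_rows = {}
        for resp in SCORES:
            entries = {}
            for param in NMR_PARAMS:
                entries[param] = _frame_records(
                    sensory.fit_single_predictor_slope(
                        sens_ltl, nmr, resp, param
                    )
                )
            nmr_rows[resp] = entries
        tables["nmr_sensory_slopes"] = nmr_rows
        r_cols = ["imf_pct", "pH", "nirs_mean"] + list(NMR_PARAMS)
        r_mat, p_mat = chemometrics.pearson_matrix(ltl, r_cols)
        tables["correlation_matrix_LTL"] = {
            "columns": r_cols,
            "r": r_mat.to_numpy().tolist(),
            "p": p_mat.to_numpy().tolist(),
        }
        r_mat.to_csv(outdir / "correlations_ltl.csv")
    else:
        tables["nmr_sensory_slopes"] = "skipped (fit stage disabled)"
        tables["correlation_matrix_LTL"] = "skipped (fit stage disabled)"

    with open(outdir / "analysis_tables.json", "w") as fh:
        json.dump(tables, fh, indent=2, default=_jsonify)
    return {"tables": tables}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the enabled stages and return the machine-readable report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, version=__version__, config=_as_dict(config))
    dump_config(config, str(outdir / "config_echo.yaml"))
    state: dict = {}
    failed = False
    for stage, func in (("simulate", _simulate), ("fit", _fit), ("analyze", _analyze)):
        if stage not in config.stages or failed:
            report.stage_status[stage] = "skipped"
            continue
        report.timestamps[f"{stage}_start"] = time.time()
        try:
            state.update(func(config, outdir, state) if stage != "simulate" else func(config, outdir))
            report.stage_status[stage] = "ok"
        except Exception:
            report.stage_status[stage] = "failed: " + traceback.format_exc(limit=3)
            failed = True
        report.timestamps[f"{stage}_end"] = time.time()
    report.tables = state.get("tables", {})
    with open(outdir / "report.json", "w") as fh:
        fh.write(report.to_json())
    return report
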