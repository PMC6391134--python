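"""End-to-end analysis pipeline over a session directory.

Runs validate -> classify -> decode (ISI, optionally Poisson) -> nulls ->
consensus, writing per-stage CSV/JSON artifacts plus a manifest recording
the package version, configuration hash and every seed used.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .consensus import consensus_timecourse
from .decoder import ISIDecoderBackend, compare_to_null, cross_validated_decode
from .io import read_session
from .nulls import NullSpec, null_distribution
from .decoder import DecodingResult
from .poisson import PoissonDecoderBackend, decoder_mcc
from .responsiveness import classify_unit
from .session import filter_units

__all__ = ["run_pipeline"]


def run_pipeline(
    session_dir: str | Path,
    config: RunConfig | None = None,
    variables: tuple[str, ...] = ("stimulus", "choice"),
    with_poisson: bool = False,
    with_nulls: bool = True,
    with_consensus: bool = True,
    units: list[str] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis; returns the manifest dictionary."""
    config = config or RunConfig()
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seeds": {},
        "stages": [],
    }

    session = read_session(session_dir, pre_trial_bound=config.pre_trial_bound_s)
    session.assign_windows()
    kept = filter_units(session)
    units = units if units is not None else kept
    manifest["stages"].append("validate")
    manifest["n_trials"] = len(session.trials)
    manifest["category_counts"] = {
        f"{s}/{c}": n for (s, c), n in session.category_counts().items()
    }
    manifest["units_kept"] = kept

    reports = []
    for u in units:
        seed = int(rng.integers(2**31 - 1))
        manifest["seeds"][f"classify/{u}"] = seed
        r = classify_unit(session, u, seed=seed)
        reports.append(
            {
                "unit_id": u,
                "tone_modulated": r.tone_modulated,
                "ramp_index": r.ramp_index,
                "ramping": r.ramping,
                "zscore": r.zscore,
                "classification": r.classification,
            }
        )
    pd.DataFrame(reports).to_csv(out / "responsiveness.csv", index=False)
    manifest["stages"].append("classify")

    backend = ISIDecoderBackend(config.window_length_s, config.window_step_s, config.cv_folds)
    decode_rows, trial_tables = [], []
    for u in units:
        for variable in variables:
            seed = int(rng.integers(2**31 - 1))
            manifest["seeds"][f"decode/{u}/{variable}"] = seed
            summary, table = cross_validated_decode(
                session, [u], variable, backend,
                folds=config.folds, reps=config.reps, seed=seed,
            )
            row = {
                "unit_id": u,
                "variable": variable,
                "method": "isi",
                "mean_performance": summary.mean_performance,
                "accuracy": summary.accuracy,
                "n_trials": summary.n_trials,
                "folds": summary.folds,
                "reps": summary.n_reps,
            }
            if with_nulls:
                nseed = int(rng.integers(2**31 - 1))
                manifest["seeds"][f"null/{u}/{variable}"] = nseed
                nulls = null_distribution(
                    session, u, variable,
                    NullSpec("isi_resample", config.null_reps, nseed),
                    folds=config.folds, backend=backend,
                )
                row["p_vs_null"] = compare_to_null(summary, nulls)
            if with_poisson:
                pseed = int(rng.integers(2**31 - 1))
                manifest["seeds"][f"poisson/{u}/{variable}"] = pseed
                psum, ptable = cross_validated_decode(
                    session, [u], variable, PoissonDecoderBackend(config.cv_folds),
                    folds=config.folds, reps=config.reps, seed=pseed,
                )
                row["poisson_performance"] = psum.mean_performance

                def _results(df):
                    return [
                        DecodingResult(r.trial_id, variable, r.final_posterior_true,
                                       r.predicted, r.true_label)
                        for r in df.itertuples(index=False)
                    ]

                agr = decoder_mcc(_results(table), _results(ptable))
                row["mcc"] = agr.mcc
                row["rescaled_mcc"] = agr.rescaled_mcc
            decode_rows.append(row)
            table = table.assign(unit_id=u)
            trial_tables.append(table)
    pd.DataFrame(decode_rows).to_csv(out / "decoding_summary.csv", index=False)
    if trial_tables:
        pd.concat(trial_tables).to_csv(out / "decoding_trials.csv", index=False)
    manifest["stages"].append("decode")

    if with_consensus and len(units) >= 2:
        seed = int(rng.integers(2**31 - 1))
        manifest["seeds"]["consensus"] = seed
        tc = consensus_timecourse(
            session, units, "stimulus", "stimulus",
            window=config.consensus_window_s, step=config.consensus_step_s, seed=seed,
        )
        pd.DataFrame({"center_s": tc.centers, "consensus": tc.values}).to_csv(
            out / "consensus_stimulus.csv", index=False
        )
        manifest["stages"].append("consensus")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
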