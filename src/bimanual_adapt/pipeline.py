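"""End-to-end pipeline: simulate -> preprocess -> metrics -> models.

The pipeline processes one participant at a time (a full experiment is
~2200 trials of 1 kHz time-series, so datasets are streamed rather than
held whole) and accumulates tidy result tables:

* ``force_compensation`` — FC per clamp trial (bimanual conditions);
* ``mpe`` — maximum perpendicular error per null/force-field trial;
* ``peak_forces`` — mean lateral force around peak speed per clamp trial;
* ``fits`` — per-participant encoding-model fits with BIC and R², for
  the trained-condition set and for all bimanual conditions;
* ``predictions`` — per-model generalization predictions (FC and peak
  force) for all 12 conditions;
* ``mse`` — per-model mean squared FC prediction error over untrained
  bimanual, all-bimanual and unimanual condition sets;
* ``weights`` — encoding-weight trajectory over 96-trial windows.

Identical config + seed reproduce identical tables.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .design import CONDITIONS, GroupDesign
from .io import RunConfig, write_dataset
from .metrics import bin_series, force_compensation_for, max_perpendicular_error
from .models import (EncodingModelFit, OmegaIdentifiabilityWarning,
                     PARAMETRIC_MODELS, delta_bic, fit_all_models,
                     fit_weight_trajectory, nonparametric_reference,
                     predict_generalization, prediction_mse, stack_profiles)
from .preprocess import AlignedForceProfile, extract_clamp_profiles
from .synth import PlantConfig, TrialRecord, iter_participants

log = logging.getLogger("bimanual_adapt")

BIMANUAL = tuple(c for c in CONDITIONS if c.startswith("b"))
UNIMANUAL = tuple(c for c in CONDITIONS if c.startswith("u"))


def _fit_rows(fits: dict[str, EncodingModelFit], reference: EncodingModelFit,
              participant: int, group: str, scope: str) -> list[dict]:
    rows = []
    for name, f in {**fits, "nonparametric": reference}.items():
        rows.append({
            "participant": participant, "group": group, "scope": scope,
            "model": name, "alpha": f.alpha, "omega": f.omega,
            "sse": f.sse, "n_samples": f.n_samples, "k_params": f.k_params,
            "bic": f.bic, "r2": f.r2,
            "delta_bic": delta_bic(f, reference) if name != "nonparametric" else 0.0,
            "omega_identifiable": f.omega_identifiable,
        })
    return rows


def analyze_participant(
    trials: Sequence[TrialRecord],
    config: RunConfig,
) -> dict:
    """Per-participant stage: metrics, profiles and model fits.

    Returns a dict of intermediate results consumed by
    :func:`run_pipeline`; usable on its own for recorded datasets.
    """
    if not trials:
        raise ValueError("no trials to analyze")
    participant = trials[0].participant
    group = trials[0].group
    trained = GroupDesign(group).trained_conditions if group in (
        "evident", "ambiguous") else ()

    profiles = extract_clamp_profiles(trials)
    gen_profiles = [p for p in profiles if p.phase == "generalization"]

    fc_rows, mpe_rows, pk_rows = [], [], []
    from .preprocess import peak_force  # local import avoids cycle at module load
    for p in profiles:
        pk_rows.append({"participant": participant, "group": group,
                        "trial": p.trial, "phase": p.phase, "block": p.block,
                        "condition": p.condition,
                        "peak_force":
                            peak_force(p, config.analysis.peak_force_half_window_ms)})
        if CONDITIONS[p.condition].bimanual:
            res = force_compensation_for(p, config.field.curl_gain,
                                         intercept=config.analysis.fc_intercept)
            fc_rows.append({"participant": participant, "group": group,
                            "trial": p.trial, "phase": p.phase,
                            "block": p.block, "condition": p.condition,
                            "fc_percent": res.fc_percent})
    for t in trials:
        if t.field_type == "clamp":
            continue
        res = max_perpendicular_error(t)
        mpe_rows.append({"participant": participant, "group": group,
                         "trial": t.trial, "phase": t.phase, "block": t.block,
                         "condition": t.condition, "field_type": t.field_type,
                         "mpe_cm": res.mpe_cm})

    # Model fits on generalization-phase clamp profiles.
    scopes = {"trained": trained, "all_bimanual": BIMANUAL}
    fits_by_scope = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OmegaIdentifiabilityWarning)
        for scope, conds in scopes.items():
            if not conds:
                continue
            F, vl, vr = stack_profiles(
                gen_profiles, config.analysis.average_by_condition, conds)
            fits_by_scope[scope] = fit_all_models(
                F, vl, vr, config.field.curl_gain, participant=participant)

    # Condition-mean profiles (velocities) for generalization predictions.
    cond_profiles: dict[str, AlignedForceProfile] = {}
    observed_fc: dict[str, float] = {}
    for label in CONDITIONS:
        sub = [p for p in gen_profiles if p.condition == label]
        if not sub:
            continue
        padded = np.any([p.padded for p in sub], axis=0)
        mean_prof = AlignedForceProfile(
            force=np.mean([p.force for p in sub], axis=0),
            left_speed=np.mean([p.left_speed for p in sub], axis=0),
            right_speed=np.mean([p.right_speed for p in sub], axis=0),
            padded=padded, reference_hand=sub[0].reference_hand,
            center_ms=0.0, participant=participant, condition=label,
            phase="generalization")
        cond_profiles[label] = mean_prof
        if CONDITIONS[label].bimanual:
            observed_fc[label] = force_compensation_for(
                mean_prof, config.field.curl_gain,
                intercept=config.analysis.fc_intercept).fc_percent

    weights = None
    if config.analysis.fit_weight_trajectory:
        weights = fit_weight_trajectory(
            profiles, config.analysis.weight_block_size,
            config.field.curl_gain)
        weights.insert(0, "group", group)
        weights.insert(0, "participant", participant)

    return {"participant": participant, "group": group, "trained": trained,
            "fc": fc_rows, "mpe": mpe_rows, "peak_forces": pk_rows,
            "fits_by_scope": fits_by_scope, "cond_profiles": cond_profiles,
            "observed_fc": observed_fc, "gen_profiles": gen_profiles,
            "weights": weights}


def run_pipeline(config: RunConfig,
                 datasets: Optional[Sequence[Sequence[TrialRecord]]] = None
                 ) -> dict[str, pd.DataFrame]:
    """Run the full pipeline and write result tables.

    With ``datasets=None`` participants are simulated from the config
    (``n_participants_per_group`` per group, learner omega taken from
    ``config.omega_true``); otherwise the provided per-participant trial
    lists are analyzed as-is (analysis-only mode).  Tables are returned
    and written as CSV under ``config.output_dir`` together with a run
    log.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plant = PlantConfig(**dataclasses.asdict(config.plant)) if config.plant_enabled else None

    per_participant = []
    if datasets is None:
        for gi, group in enumerate(config.groups):
            if group not in ("evident", "ambiguous"):
                raise ValueError(f"unknown group {group!r}")
            learner = dataclasses.replace(
                config.learner, omega=float(config.omega_true[group]))
            group_seed = int(np.random.SeedSequence(
                [config.seed, gi]).generate_state(1)[0] % (2**31))
            first = 1 + gi * config.n_participants_per_group
            for trials in iter_participants(
                    group, config.n_participants_per_group, group_seed,
                    learner, config.kinematics, config.field, plant,
                    first_participant=first):
                log.info("analyzing simulated participant %d (%s)",
                         trials[0].participant, group)
                if config.write_dataset:
                    write_dataset(trials, out_dir /
                                  f"dataset_p{trials[0].participant:02d}.csv")
                per_participant.append(analyze_participant(trials, config))
    else:
        for trials in datasets:
            per_participant.append(analyze_participant(list(trials), config))

    fc_rows, mpe_rows, pk_rows, fit_rows, pred_rows, mse_rows = [], [], [], [], [], []
    weight_frames = []

    # Pooled reference gain: mean alpha over the four parametric models and
    # every participant (trained-condition fits).
    pooled_alphas = [f.alpha
                     for r in per_participant
                     for f in r["fits_by_scope"].get("trained", {}).values()]
    alpha_ref = float(np.mean(pooled_alphas)) if pooled_alphas else None

    for r in per_participant:
        fc_rows += r["fc"]
        mpe_rows += r["mpe"]
        pk_rows += r["peak_forces"]
        if r["weights"] is not None:
            weight_frames.append(r["weights"])
        for scope, fits in r["fits_by_scope"].items():
            conds = r["trained"] if scope == "trained" else BIMANUAL
            F, vl, vr = stack_profiles(r["gen_profiles"],
                                       config.analysis.average_by_condition,
                                       conds)
            reference = nonparametric_reference(
                fits.values(), F, vl, vr, config.field.curl_gain,
                alpha_override=alpha_ref, participant=r["participant"])
            fit_rows += _fit_rows(fits, reference, r["participant"],
                                  r["group"], scope)
            if scope != "trained":
                continue
            # Generalization predictions from the trained-condition fits.
            for model in PARAMETRIC_MODELS:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    preds = predict_generalization(
                        fits[model], r["cond_profiles"], config.field.curl_gain)
                for label, p in preds.items():
                    pred_rows.append({
                        "participant": r["participant"], "group": r["group"],
                        "model": model, "condition": label,
                        "predicted_fc": p.fc_percent,
                        "predicted_peak_force": p.peak_force,
                        "observed_fc": r["observed_fc"].get(label)})
                pred_fc = {c: p.fc_percent for c, p in preds.items()
                           if p.fc_percent is not None}
                for subset, include, exclude in [
                        ("untrained_bimanual", BIMANUAL, r["trained"]),
                        ("all_bimanual", BIMANUAL, ()),
                ]:
                    mse_rows.append({
                        "participant": r["participant"], "group": r["group"],
                        "model": model, "subset": subset,
                        "mse": prediction_mse(pred_fc, r["observed_fc"],
                                              exclude=exclude,
                                              include=include)})

    tables = {
        "force_compensation": pd.DataFrame(fc_rows),
        "mpe": pd.DataFrame(mpe_rows),
        "peak_forces": pd.DataFrame(pk_rows),
        "fits": pd.DataFrame(fit_rows),
        "predictions": pd.DataFrame(pred_rows),
        "mse": pd.DataFrame(mse_rows),
    }
    if weight_frames:
        tables["weights"] = pd.concat(weight_frames, ignore_index=True)

    for name, frame in tables.items():
        frame.to_csv(out_dir / f"{name}.csv", index=False)
    run_log = {"version": __version__, "seed": config.seed,
               "config": config.to_dict(),
               "alpha_reference": alpha_ref,
               "n_participants": len(per_participant)}
    import yaml
    (out_dir / "run_log.yaml").write_text(yaml.safe_dump(run_log,
                                                         sort_keys=False))
    return tables


def summarize_learning(fc_table: pd.DataFrame, bin_size: int = 12
                       ) -> pd.DataFrame:
    """Binned force-compensation learning curves per participant."""
    rows = []
    for (participant, phase), g in fc_table.sort_values("trial").groupby(
            ["participant", "phase"], sort=False):
        means, partial = bin_series(g["fc_percent"].to_numpy(), bin_size)
        for i, (m, p) in enumerate(zip(means, partial), start=1):
            rows.append({"participant": participant, "phase": phase,
                         "bin": i, "fc_percent": m, "partial": p})
    return pd.DataFrame(rows)
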