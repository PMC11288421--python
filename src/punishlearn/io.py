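"""Readers and writers for the long-format trial CSV and result files.

Trial CSV schema (UTF-8, header required): participant_id, condition
{punish_enc, accept_enc}, phase {pretest, learning, posttest},
divider_group {ingroup, outgroup}, block {1, 2 or empty}, trial_index
(1-based within participant x phase x divider_group), action {accept,
punish}, feedback {positive, negative, or empty}.  Optional columns
(culture, age, ...) are carried through untouched on read but ignored by
the models.  Feedback must be present exactly on learning rows; block
exactly on learning rows.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data import (
    ACTIONS,
    CONDITIONS,
    DataError,
    FEEDBACKS,
    GROUPS,
    PHASES,
    ParticipantDataset,
    TrialObservation,
)
from .fit import EMConfig, GroupPrior, SubjectFit
from .models import ModelSpec

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("participant_id", "condition", "phase", "divider_group",
                    "block", "trial_index", "action", "feedback")


def datasets_to_frame(datasets: Sequence[ParticipantDataset]) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        for t in ds.trials:
            rows.append({
                "participant_id": ds.participant_id,
                "condition": ds.condition,
                "phase": t.phase,
                "divider_group": t.divider_group,
                "block": t.block if t.block is not None else "",
                "trial_index": t.trial_index,
                "action": t.action if t.action is not None else "",
                "feedback": t.feedback if t.feedback is not None else "",
            })
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_trials(datasets: Sequence[ParticipantDataset],
                 path: Union[str, Path]) -> None:
    datasets_to_frame(datasets).to_csv(path, index=False)


def _cell(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def frame_to_datasets(frame: pd.DataFrame) -> List[ParticipantDataset]:
    """Validate a long-format frame and build participant datasets.

    Schema violations raise :class:`DataError` naming the offending row
    (1-based data-row numbers, header excluded).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"missing required columns: {missing}")
    datasets: Dict[str, ParticipantDataset] = {}
    seen_keys = set()
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        pid = _cell(row["participant_id"])
        condition = _cell(row["condition"])
        phase = _cell(row["phase"])
        group = _cell(row["divider_group"])
        action = _cell(row["action"])
        feedback = _cell(row["feedback"])
        block_raw = _cell(row["block"])
        if pid is None:
            raise DataError(f"row {pos}: empty participant_id")
        if condition not in CONDITIONS:
            raise DataError(f"row {pos}: unknown condition {condition!r}")
        if phase not in PHASES:
            raise DataError(f"row {pos}: unknown phase {phase!r}")
        if group not in GROUPS:
            raise DataError(f"row {pos}: unknown divider_group {group!r}")
        if action is not None and action not in ACTIONS:
            raise DataError(f"row {pos}: unknown action {action!r}")
        if phase == "learning":
            if feedback not in FEEDBACKS:
                raise DataError(f"row {pos}: learning rows need feedback, "
                                f"got {feedback!r}")
            if block_raw is None:
                raise DataError(f"row {pos}: learning rows need a block")
        else:
            if feedback is not None:
                raise DataError(f"row {pos}: feedback on a {phase} row")
            if block_raw is not None:
                raise DataError(f"row {pos}: block on a {phase} row")
        try:
            block = int(float(block_raw)) if block_raw is not None else None
            index = int(float(_cell(row["trial_index"])))
        except (TypeError, ValueError):
            raise DataError(f"row {pos}: non-integer block or trial_index")
        key = (pid, phase, group, index)
        if key in seen_keys:
            raise DataError(f"row {pos}: duplicate trial key {key}")
        seen_keys.add(key)
        try:
            trial = TrialObservation(phase=phase, divider_group=group,
                                     trial_index=index, block=block,
                                     action=action, feedback=feedback)
        except DataError as exc:
            raise DataError(f"row {pos}: {exc}") from None
        if pid not in datasets:
            datasets[pid] = ParticipantDataset(participant_id=pid,
                                               condition=condition)
        elif datasets[pid].condition != condition:
            raise DataError(f"row {pos}: participant {pid} appears under "
                            f"two conditions")
        datasets[pid].trials.append(trial)
    return list(datasets.values())


def read_trials(path: Union[str, Path]) -> List[ParticipantDataset]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.empty and set(REQUIRED_COLUMNS) <= set(frame.columns):
        return []
    return frame_to_datasets(frame)


def write_ground_truth(datasets: Sequence[ParticipantDataset],
                       spec: ModelSpec, path: Union[str, Path]) -> None:
    rows = []
    for ds in datasets:
        if ds.true_params is None:
            continue
        for name, value in ds.true_params.as_dict(spec).items():
            rows.append({"participant_id": ds.participant_id,
                         "parameter": name, "true_value": value})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fit_results(fits: Sequence[SubjectFit], spec: ModelSpec,
                      prior: GroupPrior, trace: Sequence[float],
                      config: EMConfig, out_dir: Union[str, Path],
                      stem: str = "fit") -> None:
    """Parameter CSV (one row per subject x parameter) + JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in fits:
        nat = f.natural.as_dict(spec)
        for k, name in enumerate(spec.param_names):
            rows.append({
                "participant_id": f.participant_id,
                "model_id": spec.model_id,
                "parameter": name,
                "natural": nat[name],
                "transformed": float(f.eta[k]),
                "hessian_correction": float(f.hessian_diag_inv[k]),
            })
    pd.DataFrame(rows).to_csv(out_dir / f"{stem}_parameters.csv", index=False)
    sidecar = {
        "model_id": spec.model_id,
        "parameter_names": list(spec.param_names),
        "prior": {"mu": prior.mu.tolist(), "sigma2": prior.sigma2.tolist()},
        "trace": [float(v) for v in trace],
        "config": {
            "tolerance": config.tolerance,
            "max_iterations": config.max_iterations,
            "init_mu": config.init_mu,
            "init_mu_noise_sd": config.init_mu_noise_sd,
            "init_sigma2": config.init_sigma2,
            "n_optimizer_restarts": config.n_optimizer_restarts,
            "seed": config.seed,
        },
    }
    (out_dir / f"{stem}_summary.json").write_text(
        json.dumps(sidecar, indent=2))
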