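"""End-to-end experiments on synthetic cohorts.

The recovery experiment is the package's main internal validity check:
generate an inter-state-only cohort (the class signal lives purely in the
change between states), run the full preprocessing + lead-assembly +
training pipeline, and measure test accuracy for the full network and for
an ablated variant whose inter-state stage is replaced by the identity.
If the inter-state module carries the cross-state signal (rather than
generic capacity), the ablation must cost accuracy.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import STATES
from .evaluate import confusion, metrics
from .leads import LeadLayout, assemble_tensor, split_leads
from .nn.network import CLASS_NAMES, MultiStateNet, NetworkConfig, build_network
from .preprocess import BinarizationSpec, CropRect, binarize, crop_region
from .synth import SyntheticCohortConfig, iter_cohort
from .train import TrainConfig, stratified_split, train
from . import defaults

__all__ = [
    "build_dataset", "train_and_evaluate", "run_recovery_experiment",
    "g_sensitivity", "check_group_divisibility",
]


def build_dataset(
    cfg: SyntheticCohortConfig,
    input_size: int = defaults.INPUT_SIZE,
    binarization: BinarizationSpec = BinarizationSpec(),
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate a cohort and run it through preprocessing + lead assembly.

    Returns (tensors, integer labels, metadata); label 1 is CAD.  Pages
    are processed in memory patient by patient, so memory scales with one
    patient's pages plus the assembled tensors.
    """
    width, height = cfg.page_size
    crop = CropRect(left=0, top=defaults.BANNER_HEIGHT,
                    width=width, height=height - defaults.BANNER_HEIGHT)
    layout = LeadLayout(rows=cfg.lead_layout[0], cols=cfg.lead_layout[1])
    tensors = np.empty((cfg.n_patients, input_size, input_size, 36), dtype=np.float32)
    labels = np.empty(cfg.n_patients, dtype=np.int64)
    meta_rows = []
    for i, patient in enumerate(iter_cohort(cfg)):
        patches = {
            state: split_leads(
                binarize(crop_region(patient.pages[state], crop), binarization),
                layout,
            )
            for state in STATES
        }
        tensors[i] = assemble_tensor(patches, target_size=input_size).values
        labels[i] = CLASS_NAMES.index(patient.label)
        meta_rows.append({"id": patient.patient_id, "label": patient.label,
                          "gender": patient.gender, "age": patient.age})
    return tensors, labels, pd.DataFrame(meta_rows)


def train_and_evaluate(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    net_config: NetworkConfig,
    train_config: TrainConfig,
    seed: int = 0,
) -> dict:
    """Train a fresh network and report test metrics and loss history."""
    model = build_network(net_config, seed=seed)
    history = train(model, x_train, y_train, train_config)
    predicted = [p.label for p in model.predict(x_test)]
    actual = [CLASS_NAMES[int(v)] for v in y_test]
    report = metrics(confusion(predicted, actual))
    return {
        "model": model,
        "history": history,
        "accuracy": report.accuracy,
        "metrics": report,
        "predicted": predicted,
    }


def run_recovery_experiment(
    n_patients: int = 300,
    seed: int = 0,
    input_size: int = 112,
    epochs: int = 15,
    test_fraction: float = 0.2,
    with_ablation: bool = True,
    train_config: TrainConfig | None = None,
) -> dict:
    """The synthetic end-to-end recovery experiment.

    Inter-state-only cohort, stratified train/test split, desk-scale
    training; optionally repeats the identical run with the inter-state
    stage ablated to the identity (same seeds throughout).
    """
    cohort_cfg = SyntheticCohortConfig(
        n_patients=n_patients, seed=seed, inter_state_only=True
    )
    x, y, meta = build_dataset(cohort_cfg, input_size=input_size)
    train_idx, test_idx = stratified_split(y, test_fraction=test_fraction, seed=seed)
    tcfg = (train_config or TrainConfig()).desk_scale(epochs=epochs)
    tcfg = replace(tcfg, seed=seed)
    net_cfg = NetworkConfig(input_size=input_size)
    result = {
        "n_train": len(train_idx),
        "n_test": len(test_idx),
        "metadata": meta,
    }
    full = train_and_evaluate(
        x[train_idx], y[train_idx], x[test_idx], y[test_idx], net_cfg, tcfg, seed=seed
    )
    result["full"] = full
    if with_ablation:
        ablated = train_and_evaluate(
            x[train_idx], y[train_idx], x[test_idx], y[test_idx],
            replace(net_cfg, inter_state="identity"), tcfg, seed=seed,
        )
        result["ablated"] = ablated
        result["accuracy_drop"] = full["accuracy"] - ablated["accuracy"]
    return result


def check_group_divisibility(g: int, net_config: NetworkConfig | None = None) -> None:
    """Every channel count in the schedule must be divisible by g."""
    cfg = net_config or NetworkConfig()
    channel_counts = (cfg.in_channels,) + tuple(cfg.block_channels)
    bad = [c for c in channel_counts if c % g]
    if bad:
        raise ValueError(
            f"group count g={g} does not divide channel count(s) {sorted(set(bad))}"
        )


def g_sensitivity(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
    g_values: Sequence[int],
    net_config: NetworkConfig | None = None,
    train_config: TrainConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy as a function of the inter-state group count g.

    Trains one model per g with a shared seed; raises on any g that does
    not divide every channel count in the schedule.
    """
    base = net_config or NetworkConfig()
    tcfg = train_config or TrainConfig().desk_scale()
    for g in g_values:
        check_group_divisibility(g, base)
    rows = []
    for g in g_values:
        res = train_and_evaluate(
            x_train, y_train, x_test, y_test,
            replace(base, groups=g), tcfg, seed=seed,
        )
        rows.append({"g": g, "accuracy": res["accuracy"]})
    return pd.DataFrame(rows)
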