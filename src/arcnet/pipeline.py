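"""Pipeline orchestration and result reporting.

Runs the full per-culture analysis — simulate (or ingest) → label →
spike inference → STTC adjacency per epoch → ICD refinement → change
classification → distances — and aggregates cohort-level tables for the
stepwise regression of the Arc-positive percentage.  Configuration is a
validated pydantic model; every stage logs its parameters and row counts,
and any stage failure aborts with a stage-tagged error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from .core import EPOCHS, SpikeTrain
from .errors import ConfigurationError, PipelineStageError
from .icd import (
    DEFAULT_LOCATION_MIN,
    DEFAULT_WIDTH_MIN,
    ICDDifferenceMetrics,
    icd_metrics_for_epochs,
)
from .regression import StepwiseModel, stepwise_linear_model
from .segmentation import label_culture_channels
from .sttc import (
    STTCParams,
    adjacency_matrix,
    arc_pair_fraction_vs_threshold,
    classify_correlation_changes,
    distance_by_pair_type,
    group_mean_ci,
    pair_distances,
)
from .synthetic import (
    CalciumModelParams,
    ScenarioConfig,
    SyntheticCulture,
    generate_three_epoch_dataset,
    spikes_to_fluorescence,
)
from .traces import correct_and_normalize, infer_spike_matrix, network_rate_change

logger = logging.getLogger(__name__)

RESULT_SCHEMA_VERSION = "1.0"


class PipelineConfig(BaseModel):
    """Validated run configuration (the published schema is
    ``PipelineConfig.model_json_schema()``)."""

    scenario: dict = Field(default_factory=dict)
    seed: int = 0
    delta_t_s: float = Field(default=0.05, gt=0)
    spike_source: str = Field(default="infer", pattern="^(infer|true)$")
    dff_mode: str = Field(default="dff", pattern="^(dff|subtract_only)$")
    sparsity_weight: float = Field(default=2.0, ge=0)
    width_min: float = Field(default=DEFAULT_WIDTH_MIN, ge=0)
    location_min: float = Field(default=DEFAULT_LOCATION_MIN, ge=0)
    pixel_size_um: float = Field(default=0.8, gt=0)


@dataclass
class CultureResult:
    """All per-culture outputs: rates, adjacency summaries, group CI
    means, ICD metrics/refinement call, marker percentages, change
    classification and distance summaries.  Every reported mean carries
    its n."""

    seed: int
    n_cells: int
    n_neurons: int
    rates: pd.DataFrame
    rate_changes: dict[str, float]
    ci_network_mean: dict[str, float]
    ci_normalized_change: dict[str, float]
    group_ci: dict[str, pd.DataFrame]
    icd_metrics: ICDDifferenceMetrics
    refined: bool
    marker_percentages: dict[str, float]
    labels: pd.DataFrame
    changes: pd.DataFrame
    arc_fraction_curve: pd.DataFrame
    distance_summary: pd.DataFrame
    adjacency: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    refinement_truth: bool | None = None


def _network_mean_ci(M: np.ndarray) -> tuple[float, int]:
    iu = np.triu_indices(M.shape[0], k=1)
    vals = M[iu]
    vals = vals[~np.isnan(vals)]
    return (float(vals.mean()) if vals.size else np.nan, int(vals.size))


def run_pipeline(config: PipelineConfig | dict) -> CultureResult:
    """Execute the full analysis for one synthetic culture."""
    if isinstance(config, dict):
        try:
            config = PipelineConfig(**config)
        except ValidationError as err:
            raise ConfigurationError(str(err)) from err

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        scenario = ScenarioConfig(**{**config.scenario, "seed": config.seed})
        culture = generate_three_epoch_dataset(scenario)
        logger.info("[%s] %d cells, seed %d", stage, culture.n_cells, config.seed)
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(stage, str(err)) from err

    # --- label ------------------------------------------------------------
    stage = "label"
    try:
        labels, thresholds, _fits = label_culture_channels(
            culture.marker_intensities.set_index("cell_id")
        )
        logger.info("[%s] thresholds %s", stage, thresholds)
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(stage, str(err)) from err

    neun = labels["neun_pos"].to_numpy(bool)
    neuron_idx = np.where(neun)[0]
    n_neurons = int(neun.sum())
    if n_neurons < 2:
        raise PipelineStageError("label", "fewer than 2 NeuN-positive cells")

    # --- spikes -----------------------------------------------------------
    stage = "spikes"
    try:
        trains: dict[str, list[SpikeTrain]] = {}
        for epoch in EPOCHS:
            epoch_trains = culture.spike_trains[epoch]
            if config.spike_source == "true":
                inferred = epoch_trains
            else:
                cal = CalciumModelParams(frame_rate_hz=scenario.frame_rate_hz)
                epoch_offset = {"baseline": 1, "during": 2, "after": 3}[epoch]
                fluo = spikes_to_fluorescence(
                    epoch_trains, cal, seed=config.seed * 8 + epoch_offset, epoch=epoch
                )
                corrected = correct_and_normalize(fluo, dff_mode=config.dff_mode)
                inferred = infer_spike_matrix(
                    corrected, cal, sparsity_weight=config.sparsity_weight
                )
            trains[epoch] = [inferred[i] for i in neuron_idx]
        logger.info("[%s] source=%s, %d neurons", stage, config.spike_source, n_neurons)
    except PipelineStageError:
        raise
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(stage, str(err)) from err

    # --- rates ------------------------------------------------------------
    stage = "rates"
    rate_rows = []
    for epoch in EPOCHS:
        for k, tr in enumerate(trains[epoch]):
            rate_rows.append((int(neuron_idx[k]), epoch, tr.rate_hz))
    rates = pd.DataFrame(rate_rows, columns=["cell_id", "epoch", "rate_hz"])
    rate_changes = {
        epoch: network_rate_change(trains["baseline"], trains[epoch])
        for epoch in ("during", "after")
    }

    # --- sttc -------------------------------------------------------------
    stage = "sttc"
    try:
        params = STTCParams(delta_t_s=config.delta_t_s)
        adjacency = {epoch: adjacency_matrix(trains[epoch], params) for epoch in EPOCHS}
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(stage, str(err)) from err
    ci_network_mean = {}
    for epoch in EPOCHS:
        mean, n_pairs = _network_mean_ci(adjacency[epoch])
        ci_network_mean[epoch] = mean
        logger.info("[%s] %s mean CI %.4f over %d pairs", stage, epoch, mean, n_pairs)
    base = ci_network_mean["baseline"]
    ci_normalized_change = {
        epoch: (ci_network_mean[epoch] - base) / base if base else np.nan
        for epoch in ("during", "after")
    }

    neuron_labels = labels.iloc[neuron_idx].reset_index(drop=True)
    group_ci = {
        epoch: {
            "neun_arc": group_mean_ci(adjacency[epoch], neuron_labels, "neun_arc"),
            "arc_cfos": group_mean_ci(adjacency[epoch], neuron_labels, "arc_cfos"),
        }
        for epoch in EPOCHS
    }
    group_ci = {
        f"{epoch}:{grouping}": df
        for epoch, d in group_ci.items()
        for grouping, df in d.items()
    }

    # --- icd --------------------------------------------------------------
    stage = "icd"
    try:
        icd_metrics = icd_metrics_for_epochs(
            adjacency["baseline"],
            adjacency["after"],
            width_min=config.width_min,
            location_min=config.location_min,
        )
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(stage, str(err)) from err

    # --- changes / distances ---------------------------------------------
    stage = "changes"
    try:
        centroids = culture.roi_centroids[neuron_idx]
        dist_um = pair_distances(centroids, config.pixel_size_um)
        changes = classify_correlation_changes(
            adjacency["baseline"], adjacency["after"], neuron_labels, dist_um
        )
        if (changes["change_class"] != "none").any() and neuron_labels[
            "arc_pos"
        ].any():
            curve = arc_pair_fraction_vs_threshold(changes)
        else:
            curve = pd.DataFrame(
                columns=["change_class", "threshold", "arc_arc_fraction", "n_pairs"]
            )
        distance_summary = distance_by_pair_type(dist_um, neuron_labels)
    except Exception as err:  # noqa: BLE001
        raise PipelineStageError(stage, str(err)) from err

    marker_percentages = {
        "neun": 100.0 * float(neun.mean()),
        "arc": 100.0 * float(neuron_labels["arc_pos"].mean()),
        "cfos": 100.0 * float(neuron_labels["cfos_pos"].mean()),
        "arc_or_cfos": 100.0
        * float((neuron_labels["arc_pos"] | neuron_labels["cfos_pos"]).mean()),
    }

    return CultureResult(
        seed=config.seed,
        n_cells=culture.n_cells,
        n_neurons=n_neurons,
        rates=rates,
        rate_changes=rate_changes,
        ci_network_mean=ci_network_mean,
        ci_normalized_change=ci_normalized_change,
        group_ci=group_ci,
        icd_metrics=icd_metrics,
        refined=bool(icd_metrics.refined),
        marker_percentages=marker_percentages,
        labels=labels.assign(cell_id=labels.index),
        changes=changes,
        arc_fraction_curve=curve,
        distance_summary=distance_summary,
        adjacency=adjacency,
        refinement_truth=culture.refinement_truth,
    )


def cohort_table(results: list[CultureResult]) -> pd.DataFrame:
    """Per-culture predictor/response table for the stepwise regression:
    firing rates (initial/final/change), network CI (initial/final/change),
    refinement status, and the Arc-positive fraction as response."""
    rows = []
    for r in results:
        rates = r.rates
        init = rates.loc[rates["epoch"] == "baseline", "rate_hz"].mean()
        fin = rates.loc[rates["epoch"] == "after", "rate_hz"].mean()
        rows.append(
            {
                "rate_initial": init,
                "rate_final": fin,
                "rate_change": r.rate_changes["after"],
                "ci_initial": r.ci_network_mean["baseline"],
                "ci_final": r.ci_network_mean["after"],
                "ci_change": r.ci_normalized_change["after"],
                "refined": float(r.refined),
                "arc_fraction": r.marker_percentages["arc"] / 100.0,
            }
        )
    return pd.DataFrame(rows)


def fit_cohort_regression(table: pd.DataFrame, **kwargs) -> StepwiseModel:
    """Stepwise model of the Arc-positive fraction on the cohort table."""
    return stepwise_linear_model(table, response="arc_fraction", **kwargs)


def write_result_bundle(result: CultureResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the machine-readable result bundle (summary JSON + CSVs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    summary = {
        "schema_version": RESULT_SCHEMA_VERSION,
        "seed": result.seed,
        "n_cells": result.n_cells,
        "n_neurons": result.n_neurons,
        "rate_changes": result.rate_changes,
        "ci_network_mean": result.ci_network_mean,
        "ci_normalized_change": result.ci_normalized_change,
        "icd_metrics": asdict(result.icd_metrics),
        "refined": result.refined,
        "marker_percentages": result.marker_percentages,
        "refinement_truth": result.refinement_truth,
    }
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2, default=float))
    for epoch, M in result.adjacency.items():
        p = out / f"adjacency_{epoch}.csv"
        pd.DataFrame(M).to_csv(p, index=False)
        paths[f"adjacency_{epoch}"] = p
    table_map = {
        "rates": result.rates,
        "labels": result.labels,
        "changes": result.changes,
        "arc_fraction_curve": result.arc_fraction_curve,
        "distances": result.distance_summary,
    }
    for name, df in table_map.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    group_rows = []
    for key, df in result.group_ci.items():
        epoch, grouping = key.split(":")
        tmp = df.copy()
        tmp.insert(0, "grouping", grouping)
        tmp.insert(0, "epoch", epoch)
        group_rows.append(tmp)
    p = out / "group_ci.csv"
    pd.concat(group_rows, ignore_index=True).to_csv(p, index=False)
    paths["group_ci"] = p
    return paths


def read_result_summary(out_dir: str | Path) -> dict:
    """Round-trip reader for the summary JSON of a written bundle."""
    return json.loads((Path(out_dir) / "summary.json").read_text())
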