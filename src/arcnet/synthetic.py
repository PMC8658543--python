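"""Ground-truthed synthetic cultures.

Emulates the structure of the experimental data: dissociated-culture
fields of ~10^2-10^3 neurons imaged at 5 Hz for 60 s at three epochs
(baseline, during and after chemical stimulation), with network-burst
driven pairwise correlation, a designated "refined" subset whose
correlations rise after stimulation while the rest of the network's fall,
bimodal NeuN/Arc/c-Fos marker intensities with the Arc-positive set
largely a subset of the c-Fos-positive set, and spatially clustered
Arc-positive nuclei.

The burst model is deliberately simple: network-burst onsets form a
homogeneous Poisson process; each neuron joins a burst independently with
a per-group participation probability and emits one jittered spike per
joined burst, on top of an independent Poisson background.  Participation
is the correlation dial — raising it raises expected pairwise STTC.
Across epochs the same neurons persist; only participation and background
rates change.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import EPOCHS, FluorescenceMatrix, SpikeTrain
from .errors import InvalidParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BurstModelParams:
    """Parameters of the network-burst spike-train generator.

    ``participation`` may be a scalar or a per-neuron array of
    probabilities in [0, 1] that a neuron fires in any given burst.
    """

    n_neurons: int
    duration_s: float = 60.0
    burst_rate_hz: float = 0.3
    participation: float | np.ndarray = 0.6
    jitter_sd_s: float = 0.02
    background_rate_hz: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons <= 0:
            raise InvalidParameterError("n_neurons must be positive")
        if self.duration_s <= 0:
            raise InvalidParameterError("duration_s must be positive")
        for name in ("burst_rate_hz", "background_rate_hz", "jitter_sd_s"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        p = np.asarray(self.participation, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise InvalidParameterError("participation must lie in [0, 1]")


@dataclass(frozen=True)
class CalciumModelParams:
    """AR(1) calcium-fluorescence forward model (the generative model the
    MAP spike-inference stage assumes).

    gamma is the per-frame calcium decay; the default corresponds to a
    1 s decay time constant at 5 Hz imaging, gamma = exp(-0.2/1).
    """

    gamma: float = float(np.exp(-0.2))
    amplitude: float = 1.0
    baseline: float = 1.0
    noise_sd: float = 0.03
    bleach_rate: float = 0.0
    frame_rate_hz: float = 5.0

    def __post_init__(self):
        if not (0 < self.gamma < 1):
            raise InvalidParameterError("gamma must be in (0, 1)")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.frame_rate_hz <= 0:
            raise InvalidParameterError("frame_rate_hz must be positive")
        if self.bleach_rate < 0:
            raise InvalidParameterError("bleach_rate must be >= 0")


@dataclass(frozen=True)
class FrameGeometry:
    """Pixel geometry of rendered fields (0.8 um/px at default size gives
    a 0.64 mm^2 field)."""

    width_px: int = 1007
    height_px: int = 1007
    nucleus_radius_px: int = 8
    background: float = 10.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Three-epoch synthetic-culture scenario.

    Marker defaults are tied to the reported culture statistics: 16.2% of
    cells express Arc and/or c-Fos after stimulation and 82.7% of the
    Arc-positive cells are also c-Fos-positive.  Participation schedules
    encode either refinement (a strong global correlation drop with a
    selectively increased subset) or a mild uniform drop.
    """

    n_neurons: int = 100
    glia_fraction: float = 0.15
    duration_s: float = 60.0
    frame_rate_hz: float = 5.0
    refinement: bool = True
    arc_fraction: float = 0.10
    arc_cfos_overlap: float = 0.827
    marker_union_fraction: float = 0.162
    cluster_radius_px: float = 150.0
    jitter_sd_s: float = 0.02
    burst_rate_hz: float = 0.3
    # per-epoch participation for the bulk network.  A refinement culture
    # starts well-synchronised and collapses except for the refined subset;
    # a non-refinement culture starts weakly synchronised and barely changes
    # (the *_uniform schedule), mirroring the interculture variability in
    # initial correlation state seen in real cultures.
    participation_baseline: float = 0.5
    participation_during: float = 0.6
    participation_after_refined: float = 0.95
    participation_after_bulk: float = 0.15
    participation_baseline_uniform: float = 0.22
    participation_during_uniform: float = 0.28
    participation_after_uniform: float = 0.18
    # per-epoch independent background firing
    background_baseline_hz: float = 0.2
    background_during_hz: float = 0.3
    background_after_hz: float = 0.3
    # marker intensity mixture (negative / positive component)
    neg_mean: float = 100.0
    neg_sd: float = 10.0
    pos_mean: float = 300.0
    pos_sd: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.arc_cfos_overlap <= 1):
            raise InvalidParameterError("arc_cfos_overlap must lie in [0, 1]")
        if self.arc_fraction > 1:
            raise InvalidParameterError(
                "refined subset cannot exceed the neuron count"
            )
        if self.n_neurons <= 0 or self.duration_s <= 0:
            raise InvalidParameterError("n_neurons and duration_s must be positive")


@dataclass
class SyntheticCulture:
    """A generated culture: per-epoch spike trains, ROI centroids, marker
    intensities, and the ground-truth labels every downstream stage is
    scored against."""

    spike_trains: dict[str, list[SpikeTrain]]
    roi_centroids: np.ndarray  # (n_cells, 2) as (x, y) pixels
    true_labels: pd.DataFrame
    marker_intensities: pd.DataFrame
    refinement_truth: bool
    config: ScenarioConfig

    @property
    def n_cells(self) -> int:
        return len(self.true_labels)


def generate_burst_spike_trains(params: BurstModelParams) -> list[SpikeTrain]:
    """Draw one spike train per neuron from the network-burst model.

    All randomness flows from ``params.seed`` through one substream for
    the shared burst onsets plus one substream per neuron, so trains are
    reproducible and per-neuron independent given the onsets.
    """
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(params.n_neurons + 1)
    burst_rng = np.random.default_rng(children[0])
    n_bursts = burst_rng.poisson(params.burst_rate_hz * params.duration_s)
    onsets = np.sort(burst_rng.uniform(0.0, params.duration_s, size=n_bursts))
    p = np.broadcast_to(
        np.asarray(params.participation, dtype=float), (params.n_neurons,)
    )
    trains = []
    for i in range(params.n_neurons):
        rng = np.random.default_rng(children[i + 1])
        joined = rng.random(n_bursts) < p[i]
        burst_times = onsets[joined] + rng.normal(
            0.0, params.jitter_sd_s, size=int(joined.sum())
        )
        n_bg = rng.poisson(params.background_rate_hz * params.duration_s)
        bg_times = rng.uniform(0.0, params.duration_s, size=n_bg)
        times = np.clip(
            np.concatenate([burst_times, bg_times]), 0.0, params.duration_s
        )
        trains.append(SpikeTrain(np.sort(times), params.duration_s))
    return trains


def _sample_centroids(
    n_clustered: int,
    n_total: int,
    geometry: FrameGeometry,
    cluster_radius_px: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Place nuclei centroids: the first ``n_clustered`` cells fall inside a
    disk of the given radius, the rest are uniform over the frame.  A
    best-effort minimum separation of one nucleus diameter is enforced by
    rejection."""
    margin = geometry.nucleus_radius_px + 2
    lo, hi_x = margin, geometry.width_px - margin
    hi_y = geometry.height_px - margin
    min_sep = 2.0 * geometry.nucleus_radius_px + 1.0
    r = min(cluster_radius_px, (hi_x - lo) / 2.0)
    cx = rng.uniform(lo + r, hi_x - r)
    cy = rng.uniform(lo + r, hi_y - r)
    pts: list[np.ndarray] = []
    for k in range(n_total):
        for _attempt in range(200):
            if k < n_clustered:
                rho = r * np.sqrt(rng.random())
                theta = rng.uniform(0, 2 * np.pi)
                cand = np.array([cx + rho * np.cos(theta), cy + rho * np.sin(theta)])
            else:
                cand = np.array([rng.uniform(lo, hi_x), rng.uniform(lo, hi_y)])
            if not pts:
                break
            d = np.linalg.norm(np.array(pts) - cand, axis=1)
            if np.all(d >= min_sep):
                break
        else:
            logger.warning("could not separate nucleus %d; accepting overlap", k)
        pts.append(cand)
    return np.array(pts)


def generate_three_epoch_dataset(config: ScenarioConfig) -> SyntheticCulture:
    """Generate a full three-epoch culture with ground truth.

    With ``config.refinement`` true, the designated refined subset (which
    coincides with the Arc-positive truth set) raises its burst
    participation after stimulation while the bulk network's collapses;
    otherwise participation drops mildly and uniformly.  Background firing
    rises after stimulation in both cases, so firing rates increase while
    network correlation falls.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    s_labels, s_space, s_marker, s_base, s_during, s_after = ss.generate_state(6)

    n = cfg.n_neurons
    n_glia = int(round(cfg.glia_fraction * n))
    n_arc = int(round(cfg.arc_fraction * n))
    if n_arc > n:
        raise InvalidParameterError("refined subset larger than neuron count")

    rng = np.random.default_rng(int(s_labels))
    # neurons 0..n_arc-1 are the Arc-true (refined) subset; shuffling happens
    # only in spatial placement so bookkeeping stays simple
    arc_true = np.zeros(n, dtype=bool)
    arc_true[:n_arc] = True
    cfos_true = np.zeros(n, dtype=bool)
    cfos_true[:n_arc] = rng.random(n_arc) < cfg.arc_cfos_overlap
    n_cfos_only = int(round(max(cfg.marker_union_fraction - cfg.arc_fraction, 0) * n))
    if n_cfos_only > 0 and n > n_arc:
        pick = rng.choice(np.arange(n_arc, n), size=min(n_cfos_only, n - n_arc),
                          replace=False)
        cfos_true[pick] = True

    geometry = FrameGeometry()
    space_rng = np.random.default_rng(int(s_space))
    centroids = _sample_centroids(
        n_arc, n + n_glia, geometry, cfg.cluster_radius_px, space_rng
    )

    # per-epoch participation schedules for the neuronal population
    if cfg.refinement:
        p_base = np.full(n, cfg.participation_baseline)
        p_during = np.full(n, cfg.participation_during)
        p_after = np.full(n, cfg.participation_after_bulk)
        p_after[arc_true] = cfg.participation_after_refined
    else:
        p_base = np.full(n, cfg.participation_baseline_uniform)
        p_during = np.full(n, cfg.participation_during_uniform)
        p_after = np.full(n, cfg.participation_after_uniform)

    epoch_specs = {
        "baseline": (p_base, cfg.background_baseline_hz, int(s_base)),
        "during": (p_during, cfg.background_during_hz, int(s_during)),
        "after": (p_after, cfg.background_after_hz, int(s_after)),
    }
    spike_trains: dict[str, list[SpikeTrain]] = {}
    for epoch, (p, bg, seed) in epoch_specs.items():
        params = BurstModelParams(
            n_neurons=n,
            duration_s=cfg.duration_s,
            burst_rate_hz=cfg.burst_rate_hz,
            participation=p,
            jitter_sd_s=cfg.jitter_sd_s,
            background_rate_hz=bg,
            seed=seed,
        )
        trains = generate_burst_spike_trains(params)
        # glia are silent; they appear in every epoch to keep the roster fixed
        trains += [SpikeTrain(np.array([]), cfg.duration_s) for _ in range(n_glia)]
        spike_trains[epoch] = trains

    neun_true = np.concatenate([np.ones(n, bool), np.zeros(n_glia, bool)])
    arc_all = np.concatenate([arc_true, np.zeros(n_glia, bool)])
    cfos_all = np.concatenate([cfos_true, np.zeros(n_glia, bool)])
    group = np.where(
        ~neun_true,
        "non-neuronal",
        np.where(
            arc_all,
            np.where(cfos_all, "Arc+cFos+", "Arc+cFos-"),
            np.where(cfos_all, "Arc-cFos+", "Arc-cFos-"),
        ),
    )
    true_labels = pd.DataFrame(
        {
            "cell_id": np.arange(n + n_glia),
            "neun_true": neun_true,
            "arc_true": arc_all,
            "cfos_true": cfos_all,
            "refined_true": np.concatenate(
                [arc_true if cfg.refinement else np.zeros(n, bool),
                 np.zeros(n_glia, bool)]
            ),
        }
    )
    true_labels["group"] = group

    mrng = np.random.default_rng(int(s_marker))

    def bimodal(pos_mask: np.ndarray) -> np.ndarray:
        vals = mrng.normal(cfg.neg_mean, cfg.neg_sd, size=pos_mask.size)
        vals[pos_mask] = mrng.normal(cfg.pos_mean, cfg.pos_sd, size=int(pos_mask.sum()))
        return np.maximum(vals, 0.0)

    marker_intensities = pd.DataFrame(
        {
            "cell_id": np.arange(n + n_glia),
            "dapi": mrng.normal(500.0, 50.0, size=n + n_glia),
            "neun": bimodal(neun_true),
            "arc": bimodal(arc_all),
            "cfos": bimodal(cfos_all),
        }
    )

    return SyntheticCulture(
        spike_trains=spike_trains,
        roi_centroids=centroids,
        true_labels=true_labels,
        marker_intensities=marker_intensities,
        refinement_truth=cfg.refinement,
        config=cfg,
    )


def spikes_to_fluorescence(
    trains: list[SpikeTrain],
    params: CalciumModelParams = CalciumModelParams(),
    seed: int = 0,
    epoch: str = "baseline",
) -> FluorescenceMatrix:
    """Forward-simulate fluorescence from spike trains.

    F[c, t] = amplitude * C[c, t] * exp(-bleach_rate * t) + baseline + noise,
    with C following the AR(1) recursion C_t = gamma * C_{t-1} + s_t where
    s_t counts the cell's spikes falling in frame t.
    """
    if not trains:
        raise InvalidParameterError("need at least one train")
    duration = trains[0].duration_s
    n_frames = int(np.floor(duration * params.frame_rate_hz))
    if n_frames < 2:
        raise InvalidParameterError("recording too short for >= 2 frames")
    rng = np.random.default_rng(seed)
    F = np.empty((len(trains), n_frames))
    bleach = np.exp(-params.bleach_rate * np.arange(n_frames))
    for c, tr in enumerate(trains):
        counts = np.zeros(n_frames)
        if len(tr):
            idx = np.minimum(
                (tr.times_s * params.frame_rate_hz).astype(int), n_frames - 1
            )
            np.add.at(counts, idx, 1.0)
        C = lfilter([1.0], [1.0, -params.gamma], counts)
        F[c] = params.amplitude * C * bleach + params.baseline
    if params.noise_sd > 0:
        F += rng.normal(0.0, params.noise_sd, size=F.shape)
    return FluorescenceMatrix(
        F, frame_rate_hz=params.frame_rate_hz, epoch=epoch, kind="raw"
    )


def render_synthetic_frames(
    culture: SyntheticCulture,
    fluo: FluorescenceMatrix,
    geometry: FrameGeometry = FrameGeometry(),
) -> tuple[np.ndarray, np.ndarray]:
    """Render a nuclear reference image and a calcium movie.

    The nuclear image holds one bright disk per ROI (DAPI intensity); each
    movie frame paints every ROI's pixels with that cell's fluorescence
    value over a uniform background.  Overlapping disks are permitted but
    logged as a warning.

    Returns ``(movie, nuclear_image)`` with movie shaped
    (frames, height, width).
    """
    from skimage.draw import disk as draw_disk

    pts = culture.roi_centroids
    if np.any(pts < 0) or np.any(pts[:, 0] >= geometry.width_px) or np.any(
        pts[:, 1] >= geometry.height_px
    ):
        raise InvalidParameterError("centroids must lie within the frame")
    if fluo.n_cells != len(pts):
        raise InvalidParameterError("fluorescence rows must match centroids")

    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if np.any(d < 2 * geometry.nucleus_radius_px):
        logger.warning("rendered nuclei overlap; downstream ROI counts may merge")

    shape = (geometry.height_px, geometry.width_px)
    nuclear = np.full(shape, geometry.background, dtype=float)
    masks = []
    dapi = culture.marker_intensities["dapi"].to_numpy()
    for i, (x, y) in enumerate(pts):
        rr, cc = draw_disk((y, x), geometry.nucleus_radius_px, shape=shape)
        masks.append((rr, cc))
        nuclear[rr, cc] = dapi[i]
    movie = np.full((fluo.n_frames,) + shape, geometry.background, dtype=float)
    for t in range(fluo.n_frames):
        frame = movie[t]
        for i, (rr, cc) in enumerate(masks):
            frame[rr, cc] = fluo.values[i, t]
    return movie, nuclear


# ---------------------------------------------------------------------------
# disk I/O

def write_culture(culture: SyntheticCulture, out_dir: str | Path) -> dict[str, Path]:
    """Write spikes, cell table and scenario config as CSV/JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for epoch in EPOCHS:
        for nid, tr in enumerate(culture.spike_trains[epoch]):
            for t in tr.times_s:
                rows.append((nid, epoch, t))
    spikes = pd.DataFrame(rows, columns=["neuron_id", "epoch", "time_s"])
    paths = {
        "spikes": out / "spikes.csv",
        "cells": out / "cells.csv",
        "scenario": out / "scenario.json",
    }
    spikes.to_csv(paths["spikes"], index=False)
    cells = culture.true_labels.merge(
        culture.marker_intensities, on="cell_id"
    )
    cells["x_px"] = culture.roi_centroids[:, 0]
    cells["y_px"] = culture.roi_centroids[:, 1]
    cells.to_csv(paths["cells"], index=False)
    paths["scenario"].write_text(json.dumps(asdict(culture.config), indent=2))
    return paths


def read_spike_csv(path: str | Path, duration_s: float) -> dict[str, list[SpikeTrain]]:
    """Read a spikes CSV (neuron_id, epoch, time_s) back into per-epoch
    spike-train lists; neurons with no events get empty trains."""
    df = pd.read_csv(path)
    n = int(df["neuron_id"].max()) + 1 if len(df) else 0
    out: dict[str, list[SpikeTrain]] = {}
    for epoch in df["epoch"].unique():
        sub = df[df["epoch"] == epoch]
        trains = []
        for nid in range(n):
            times = np.sort(sub.loc[sub["neuron_id"] == nid, "time_s"].to_numpy())
            trains.append(SpikeTrain(times, duration_s))
        out[str(epoch)] = trains
    return out
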