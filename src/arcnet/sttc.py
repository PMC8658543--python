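"""Spike time tiling coefficient (STTC) networks.

The STTC is a firing-rate-insensitive pairwise spike-train correlation:

    STTC = 1/2 * ( (P_A - T_B)/(1 - P_A*T_B) + (P_B - T_A)/(1 - P_B*T_A) )

where T_A is the proportion of total recording time that lies within
+/- dt of any spike of A, and P_A is the proportion of A's spikes that lie
within +/- dt of any spike of B.  An STTC value between a neuron pair is
referred to throughout as the pair's correlation index (CI).  Pairwise CIs
populate a symmetric adjacency matrix per recording epoch; undefined pairs
(empty trains, degenerate denominators) are stored as NaN and excluded
from all summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import SpikeTrain
from .errors import InvalidParameterError, UndefinedValueError

#: denominators closer to zero than this make the pair undefined
_DENOM_EPS = 1e-12

GROUP_NAMES = ("Arc+cFos+", "Arc+cFos-", "Arc-cFos+", "Arc-cFos-")


@dataclass(frozen=True)
class STTCParams:
    """Tiling half-window; the coincidence window is ``+/- delta_t_s``."""

    delta_t_s: float = 0.05

    def __post_init__(self):
        if self.delta_t_s <= 0:
            raise InvalidParameterError("delta_t_s must be positive")


def tiled_time_fraction(train: SpikeTrain, delta_t_s: float) -> float:
    """Fraction of the recording covered by the union of ``+/- dt`` tiles
    around the train's spikes, clipped to the recording boundaries.

    Empty trains cover nothing and return 0.
    """
    t = train.times_s
    if t.size == 0:
        return 0.0
    starts = np.maximum(t - delta_t_s, 0.0)
    ends = np.minimum(t + delta_t_s, train.duration_s)
    # times sorted => interval starts and ends are each nondecreasing, so the
    # union length is a single sweep over adjacent overlaps
    if t.size == 1:
        covered = ends[0] - starts[0]
    else:
        clipped_starts = np.maximum(starts[1:], ends[:-1])
        covered = (ends[0] - starts[0]) + np.maximum(
            0.0, ends[1:] - clipped_starts
        ).sum()
    return float(covered / train.duration_s)


def tiled_spike_proportion(
    a: SpikeTrain, b: SpikeTrain, delta_t_s: float
) -> float:
    """Proportion of ``a``'s spikes within ``+/- delta_t_s`` of any spike
    of ``b``.  Undefined (raises) for an empty ``a``."""
    if len(a) == 0:
        raise UndefinedValueError(
            "tiled spike proportion undefined for an empty train"
        )
    if len(b) == 0:
        return 0.0
    ta, tb = a.times_s, b.times_s
    idx = np.searchsorted(tb, ta)
    right = tb[np.minimum(idx, tb.size - 1)]
    left = tb[np.maximum(idx - 1, 0)]
    dist = np.minimum(np.abs(ta - right), np.abs(ta - left))
    return float(np.mean(dist <= delta_t_s))


def sttc(
    a: SpikeTrain, b: SpikeTrain, params: STTCParams = STTCParams()
) -> float:
    """STTC between two trains over the same recording; NaN if undefined.

    Undefined when either train is empty or either denominator
    ``1 - P*T`` falls below a small epsilon (e.g. a train tiling the whole
    recording while the other train's spikes are all coincident).
    """
    if a.duration_s != b.duration_s:
        raise InvalidParameterError(
            "trains must share a common recording duration"
        )
    if len(a) == 0 or len(b) == 0:
        return np.nan
    dt = params.delta_t_s
    pa = tiled_spike_proportion(a, b, dt)
    pb = tiled_spike_proportion(b, a, dt)
    ta = tiled_time_fraction(a, dt)
    tb = tiled_time_fraction(b, dt)
    d1 = 1.0 - pa * tb
    d2 = 1.0 - pb * ta
    if abs(d1) <= _DENOM_EPS or abs(d2) <= _DENOM_EPS:
        return np.nan
    return 0.5 * ((pa - tb) / d1 + (pb - ta) / d2)


def adjacency_matrix(
    trains: list[SpikeTrain], params: STTCParams = STTCParams()
) -> np.ndarray:
    """Symmetric n x n matrix of pairwise STTC values (CIs).

    Diagonal entries and undefined pairs are NaN; rows/columns of empty
    trains are entirely NaN.
    """
    n = len(trains)
    if n < 2:
        raise InvalidParameterError("need at least 2 trains")
    dur = trains[0].duration_s
    for tr in trains:
        if tr.duration_s != dur:
            raise InvalidParameterError("all trains must share one duration")
    dt = params.delta_t_s
    tiles = np.array([tiled_time_fraction(tr, dt) for tr in trains])
    nonempty = np.array([len(tr) > 0 for tr in trains])
    M = np.full((n, n), np.nan)
    for i in range(n):
        if not nonempty[i]:
            continue
        for j in range(i + 1, n):
            if not nonempty[j]:
                continue
            pa = tiled_spike_proportion(trains[i], trains[j], dt)
            pb = tiled_spike_proportion(trains[j], trains[i], dt)
            d1 = 1.0 - pa * tiles[j]
            d2 = 1.0 - pb * tiles[i]
            if abs(d1) <= _DENOM_EPS or abs(d2) <= _DENOM_EPS:
                continue
            M[i, j] = M[j, i] = 0.5 * (
                (pa - tiles[j]) / d1 + (pb - tiles[i]) / d2
            )
    return M


def total_flow(
    M: np.ndarray, bins: int | np.ndarray = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node strength ("total flow"): the sum of all CI incident to each
    node, missing entries contributing 0; plus a histogram of strengths.

    Returns ``(strengths, hist, bin_edges)``.
    """
    A = np.array(M, dtype=float)
    np.fill_diagonal(A, np.nan)
    strengths = np.nansum(np.where(np.isnan(A), 0.0, A), axis=1)
    hist, edges = np.histogram(strengths, bins=bins)
    return strengths, hist, edges


def _pair_means(M: np.ndarray, sets: dict[str, tuple[np.ndarray, np.ndarray]]):
    out = {}
    for name, (rows, cols) in sets.items():
        sub = M[np.ix_(rows, cols)]
        if np.array_equal(rows, cols):
            iu = np.triu_indices(len(rows), k=1)
            vals = sub[iu]
        else:
            vals = sub.ravel()
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            warnings.warn(f"group pair {name!r} has no defined CI entries")
            out[name] = (np.nan, 0)
        else:
            out[name] = (float(vals.mean()), int(vals.size))
    return out


def group_mean_ci(
    M: np.ndarray, labels: pd.DataFrame, grouping: str = "neun_arc"
) -> pd.DataFrame:
    """Mean CI per label-defined pair set.

    ``grouping='neun_arc'`` yields the 3 sets among NeuN-positive cells
    (Arc-Arc, Arc-NeuN and NeuN-NeuN, where "NeuN" denotes NeuN-positive
    but Arc-negative neurons).  ``grouping='arc_cfos'`` yields the 10
    unordered pair sets between the four Arc x c-Fos groups.

    ``labels`` must align row-wise with ``M`` and carry boolean columns
    ``neun_pos``/``arc_pos`` (and ``cfos_pos`` for 'arc_cfos').
    """
    if len(labels) != M.shape[0]:
        raise InvalidParameterError("labels must cover all matrix neurons")
    neun = labels["neun_pos"].to_numpy(bool)
    arc = labels["arc_pos"].to_numpy(bool) & neun
    if grouping == "neun_arc":
        non_arc = neun & ~arc
        sets = {
            "Arc-Arc": (np.where(arc)[0], np.where(arc)[0]),
            "Arc-NeuN": (np.where(arc)[0], np.where(non_arc)[0]),
            "NeuN-NeuN": (np.where(non_arc)[0], np.where(non_arc)[0]),
        }
    elif grouping == "arc_cfos":
        cfos = labels["cfos_pos"].to_numpy(bool) & neun
        idx = {
            "Arc+cFos+": np.where(arc & cfos)[0],
            "Arc+cFos-": np.where(arc & ~cfos)[0],
            "Arc-cFos+": np.where(neun & ~arc & cfos)[0],
            "Arc-cFos-": np.where(neun & ~arc & ~cfos)[0],
        }
        sets = {}
        for i, g1 in enumerate(GROUP_NAMES):
            for g2 in GROUP_NAMES[i:]:
                sets[f"{g1}|{g2}"] = (idx[g1], idx[g2])
    else:
        raise InvalidParameterError(f"unknown grouping {grouping!r}")
    means = _pair_means(M, sets)
    return pd.DataFrame(
        [(k, v[0], v[1]) for k, v in means.items()],
        columns=["pair_set", "mean_ci", "n_pairs"],
    )


def classify_correlation_changes(
    M_before: np.ndarray,
    M_after: np.ndarray,
    labels: pd.DataFrame | None = None,
    distances_um: np.ndarray | None = None,
) -> pd.DataFrame:
    """Classify every defined neuron pair by how its CI crossed the 0.5
    band between baseline and after stimulation.

    positive: ci_before in [0, 0.5) and ci_after in [0.5, 1];
    negative: ci_before in [0.5, 1] and ci_after in [0, 0.5); else none.
    Pairs undefined in either epoch are dropped.
    """
    if M_before.shape != M_after.shape:
        raise InvalidParameterError("matrices must share neuron order")
    n = M_before.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    before = M_before[iu, ju]
    after = M_after[iu, ju]
    ok = ~np.isnan(before) & ~np.isnan(after)
    iu, ju, before, after = iu[ok], ju[ok], before[ok], after[ok]
    positive = (before >= 0) & (before < 0.5) & (after >= 0.5) & (after <= 1)
    negative = (before >= 0.5) & (before <= 1) & (after >= 0) & (after < 0.5)
    change = np.where(positive, "positive", np.where(negative, "negative", "none"))
    rec = pd.DataFrame(
        {
            "i": iu,
            "j": ju,
            "ci_before": before,
            "ci_after": after,
            "change_class": change,
        }
    )
    if labels is not None:
        arc = (
            labels["arc_pos"].to_numpy(bool)
            & labels["neun_pos"].to_numpy(bool)
        )
        both_arc = arc[rec["i"]] & arc[rec["j"]]
        one_arc = arc[rec["i"]] ^ arc[rec["j"]]
        rec["pair_type"] = np.where(
            both_arc, "Arc-Arc", np.where(one_arc, "Arc-NeuN", "NeuN-NeuN")
        )
    if distances_um is not None:
        rec["distance_um"] = distances_um[rec["i"], rec["j"]]
    return rec


def arc_pair_fraction_vs_threshold(
    records: pd.DataFrame,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fraction of Arc-Arc pairs among qualifying pairs, per CI threshold.

    For positive-change pairs the threshold applies to the final CI; for
    negative-change pairs it applies to the initial CI.  Thresholds with no
    qualifying pair yield NaN.
    """
    if records.empty:
        raise InvalidParameterError("no pair records")
    if "pair_type" not in records:
        raise InvalidParameterError("records must carry pair_type labels")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 21)
    rows = []
    for cls, ci_col in (("positive", "ci_after"), ("negative", "ci_before")):
        sub = records[records["change_class"] == cls]
        for thr in np.asarray(thresholds, float):
            q = sub[sub[ci_col] >= thr]
            if len(q) == 0:
                frac = np.nan
            else:
                frac = float((q["pair_type"] == "Arc-Arc").mean())
            rows.append((cls, thr, frac, len(q)))
    return pd.DataFrame(
        rows, columns=["change_class", "threshold", "arc_arc_fraction", "n_pairs"]
    )


def pair_distances(
    centroids_xy_px: np.ndarray, pixel_size_um: float = 0.8
) -> np.ndarray:
    """Euclidean centroid distances in micrometres (0.8 um/px default)."""
    pts = np.asarray(centroids_xy_px, dtype=float)
    return cdist(pts, pts) * pixel_size_um


def distance_by_pair_type(
    distances_um: np.ndarray, labels: pd.DataFrame
) -> pd.DataFrame:
    """Mean pair distance per Arc-pair type (Arc-Arc, Arc-NeuN, NeuN-NeuN),
    among NeuN-positive neurons."""
    neun = labels["neun_pos"].to_numpy(bool)
    arc = labels["arc_pos"].to_numpy(bool) & neun
    n = distances_um.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = neun[iu] & neun[ju]
    iu, ju = iu[keep], ju[keep]
    both = arc[iu] & arc[ju]
    one = arc[iu] ^ arc[ju]
    ptype = np.where(both, "Arc-Arc", np.where(one, "Arc-NeuN", "NeuN-NeuN"))
    d = distances_um[iu, ju]
    df = pd.DataFrame({"pair_type": ptype, "distance_um": d})
    return (
        df.groupby("pair_type")["distance_um"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_distance_um", "count": "n_pairs"})
    )


def mean_distance_above_threshold(
    records: pd.DataFrame, thresholds: np.ndarray | None = None
) -> pd.DataFrame:
    """Average pair distance among qualifying change pairs above each CI
    threshold (final CI for positive-change, initial CI for negative-change
    pairs)."""
    if "distance_um" not in records:
        raise InvalidParameterError("records must carry distance_um")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 21)
    rows = []
    for cls, ci_col in (("positive", "ci_after"), ("negative", "ci_before")):
        sub = records[records["change_class"] == cls]
        for thr in np.asarray(thresholds, float):
            q = sub[sub[ci_col] >= thr]
            mean_d = float(q["distance_um"].mean()) if len(q) else np.nan
            rows.append((cls, thr, mean_d, len(q)))
    return pd.DataFrame(
        rows, columns=["change_class", "threshold", "mean_distance_um", "n_pairs"]
    )


def density_distribution(
    values: np.ndarray, bins: int | np.ndarray = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram-based (nonkernel) probability density estimate.

    Returns ``(density, bin_edges)``; the density integrates to 1 over the
    binned range.
    """
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise InvalidParameterError("need at least one value")
    density, edges = np.histogram(vals, bins=bins, density=True)
    return density, edges
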