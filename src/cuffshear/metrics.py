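"""The six wall-shear-stress metrics of atherogenic flow.

Per-node metrics over one cardiac cycle sampled at n uniformly spaced
exported instants (equal-weight rectangle rule; for a periodic signal on a
uniform grid this equals the trapezoid rule):

* TAWSS  - time-averaged WSS magnitude, mean_i ||tau_i||               (Pa)
* OSI    - oscillatory shear index, 0.5*(1 - ||mean tau|| / mean ||tau||),
           0 for unidirectional flow, 0.5 for pure reversal             (-)
* RRT    - relative residence time, 1/||mean tau||                  (Pa^-1)
* tSS    - transverse WSS, the time-averaged magnitude of the component
           perpendicular (within the tangent plane) to the mean-WSS
           direction                                                    (Pa)
* SAD    - shear angle deviation, the mean angle between a node's WSS
           vector and its edge-connected neighbours', averaged per
           instant then over the cycle                                 (rad)
* LSI/HSI - low/high shear index: continuous indices of atherogenically
           low/high TAWSS against thresholds calibrated from the control
           vessel's log-TAWSS distribution                              (-)

The LSI/HSI thresholds are the 25th/75th percentiles of the control TAWSS
distribution on a log scale: low = exp(m - 0.67*s), high = exp(m + 0.67*s)
with m, s the mean and sample SD of ln(TAWSS_control).  The multiplier is
used literally as 0.67 (the printed two-decimal standard-normal quartile).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import WSSFieldSeries

logger = logging.getLogger(__name__)

#: Standard-normal 75th-percentile multiplier used in threshold calibration.
LOG_QUANTILE_MULTIPLIER = 0.67

#: Canonical metric names and native units, in reporting order.
METRIC_UNITS = {
    "TAWSS": "Pa",
    "OSI": "",
    "RRT": "Pa^-1",
    "tSS": "Pa",
    "SAD": "rad",
    "LSI": "",
    "HSI": "",
}
METRICS = tuple(METRIC_UNITS)

#: Theoretical display maxima; metrics absent here (TAWSS, tSS, RRT) are
#: normalized by a cohort-observed maximum.
THEORETICAL_MAX = {"OSI": 0.5, "SAD": np.pi, "LSI": 1.0, "HSI": 1.0}


@dataclass
class MetricMap:
    """One scalar metric value per surface node."""

    metric_name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class TawssThresholds:
    """Control-calibrated low/high TAWSS cutoffs (log-quartile rule)."""

    low: float   # Pa
    high: float  # Pa
    source_mean_log: float
    source_sd_log: float

    def __post_init__(self) -> None:
        if not (0 < self.low <= self.high):
            raise ValueError("thresholds must satisfy 0 < low <= high")


def _magnitudes(field: WSSFieldSeries) -> np.ndarray:
    if field.n_export < 1:
        raise ValueError("field has no exported instants")
    return np.linalg.norm(field.vectors, axis=2)


def tawss(field: WSSFieldSeries) -> MetricMap:
    """Time-averaged WSS magnitude per node (Pa)."""
    if field.n_export < 2:
        raise ValueError("TAWSS needs at least 2 exported instants")
    return MetricMap("TAWSS", _magnitudes(field).mean(axis=1), "Pa")


def osi(field: WSSFieldSeries) -> MetricMap:
    """Oscillatory shear index, 0.5*(1 - ||mean vector||/mean magnitude).

    Nodes with identically zero WSS get OSI = 0 (logged).
    """
    mags = _magnitudes(field)
    mean_mag = mags.mean(axis=1)
    mean_vec = np.linalg.norm(field.vectors.mean(axis=1), axis=1)
    n_zero = int(np.sum(mean_mag == 0))
    if n_zero:
        logger.info("osi: %d zero-WSS node(s) set to 0", n_zero)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 0.5 * (1.0 - mean_vec / mean_mag)
    out = np.where(mean_mag > 0, out, 0.0)
    return MetricMap("OSI", np.clip(out, 0.0, 0.5), "")


def rrt(field: WSSFieldSeries) -> MetricMap:
    """Relative residence time, 1/||time-mean WSS vector|| (Pa^-1).

    Algebraically equal to 1/((1 - 2*OSI)*TAWSS).  Nodes whose mean vector
    vanishes get an infinite sentinel (capped at the display stage, logged).
    """
    mean_vec = np.linalg.norm(field.vectors.mean(axis=1), axis=1)
    n_zero = int(np.sum(mean_vec == 0))
    if n_zero:
        logger.info("rrt: %d node(s) with zero mean vector -> inf sentinel",
                    n_zero)
    with np.errstate(divide="ignore"):
        out = np.where(mean_vec > 0, 1.0 / np.where(mean_vec > 0, mean_vec, 1.0),
                       np.inf)
    return MetricMap("RRT", out, "Pa^-1")


def transwss(field: WSSFieldSeries, normals: np.ndarray) -> MetricMap:
    """Transverse WSS: mean |tau_i . q| with q = n x p normalized and p the
    unit time-mean WSS direction.  Nodes with zero mean vector get 0."""
    normals = np.asarray(normals, dtype=float)
    mean_vec = field.vectors.mean(axis=1)
    mean_norm = np.linalg.norm(mean_vec, axis=1)
    ok = mean_norm > 0
    p = np.zeros_like(mean_vec)
    p[ok] = mean_vec[ok] / mean_norm[ok, None]
    q = np.cross(normals, p)
    q_norm = np.linalg.norm(q, axis=1)
    ok &= q_norm > 0
    q[ok] /= q_norm[ok, None]
    vals = np.abs(np.einsum("nki,ni->nk", field.vectors, q)).mean(axis=1)
    vals[~ok] = 0.0
    return MetricMap("tSS", vals, "Pa")


def sad(field: WSSFieldSeries, adjacency: list) -> MetricMap:
    """Shear angle deviation (rad).

    For node j at instant i: the mean over neighbours k of the angle
    between tau_i(j) and tau_i(k); averaged over instants.  Pairs where
    either vector is zero contribute zero angle (logged).
    """
    n_nodes, n_export = field.n_nodes, field.n_export
    degrees = np.array([len(a) for a in adjacency])
    if len(adjacency) != n_nodes:
        raise ValueError("adjacency size does not match the field")
    if np.any(degrees == 0):
        raise ValueError("isolated node without neighbours")
    mags = _magnitudes(field)
    with np.errstate(invalid="ignore"):
        unit = field.vectors / mags[:, :, None]
    unit = np.where(mags[:, :, None] > 0, unit, 0.0)

    src = np.repeat(np.arange(n_nodes), degrees)
    dst = np.concatenate(adjacency)
    dots = np.einsum("eki,eki->ek", unit[src], unit[dst])
    zero_pair = (mags[src] == 0) | (mags[dst] == 0)
    n_zero = int(zero_pair.sum())
    if n_zero:
        logger.info("sad: %d zero-vector node-instant pair(s) contribute 0",
                    n_zero)
    angles = np.arccos(np.clip(dots, -1.0, 1.0))
    angles[zero_pair] = 0.0

    sums = np.zeros((n_nodes, n_export))
    np.add.at(sums, src, angles)
    per_instant = sums / degrees[:, None]
    return MetricMap("SAD", per_instant.mean(axis=1), "rad")


def fit_thresholds(
    control_tawss: MetricMap,
    multiplier: float = LOG_QUANTILE_MULTIPLIER,
) -> TawssThresholds:
    """Calibrate the low/high TAWSS cutoffs from a control vessel.

    low = exp(m - multiplier*s), high = exp(m + multiplier*s), with m the
    mean and s the sample SD (n-1 denominator) of ln(TAWSS_control); with
    multiplier 0.67 these isolate the bottom and top 25% of a log-normal
    control distribution.
    """
    vals = np.asarray(control_tawss.values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 control TAWSS values")
    if np.any(vals <= 0):
        raise ValueError("control TAWSS values must all be positive")
    logs = np.log(vals)
    m = float(logs.mean())
    s = float(logs.std(ddof=1))
    return TawssThresholds(low=float(np.exp(m - multiplier * s)),
                           high=float(np.exp(m + multiplier * s)),
                           source_mean_log=m, source_sd_log=s)


def lsi(tawss_map: MetricMap, thresholds: TawssThresholds) -> MetricMap:
    """Low shear index, max(0, (low - TAWSS)/low); 0 above the threshold."""
    vals = np.clip((thresholds.low - tawss_map.values) / thresholds.low,
                   0.0, 1.0)
    return MetricMap("LSI", vals, "")


def hsi(tawss_map: MetricMap, thresholds: TawssThresholds) -> MetricMap:
    """High shear index, max(0, (TAWSS - high)/TAWSS); 0 below the threshold
    and at zero TAWSS (logged)."""
    v = tawss_map.values
    n_zero = int(np.sum(v == 0))
    if n_zero:
        logger.info("hsi: %d zero-TAWSS node(s) set to 0", n_zero)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (v - thresholds.high) / v
    out = np.where(v > 0, out, 0.0)
    return MetricMap("HSI", np.clip(out, 0.0, 1.0), "")


def normalize_display(
    metric_map: MetricMap,
    observed_max: float | None = None,
) -> MetricMap:
    """Scale a metric map to [0, 1] for display and cross-metric comparison.

    OSI, SAD, LSI and HSI divide by their theoretical maxima (0.5, pi, 1,
    1).  TAWSS, tSS and RRT have no finite theoretical maximum and divide
    by ``observed_max`` (the maximum over all vessels of the cohort), which
    also caps RRT's infinite sentinels at 1.  The result is clipped to
    [0, 1].
    """
    name = metric_map.metric_name
    if name in THEORETICAL_MAX:
        divisor = THEORETICAL_MAX[name]
    else:
        if observed_max is None or not np.isfinite(observed_max) or observed_max <= 0:
            raise ValueError(
                f"{name} requires a positive finite observed maximum"
            )
        divisor = observed_max
    vals = np.clip(metric_map.values / divisor, 0.0, 1.0)
    return MetricMap(name, vals, "normalized")


def compute_base_metrics(
    field: WSSFieldSeries,
    normals: np.ndarray,
    adjacency: list,
) -> dict:
    """TAWSS, OSI, RRT, tSS and SAD for one vessel, keyed by metric name."""
    t = tawss(field)
    return {
        "TAWSS": t,
        "OSI": osi(field),
        "RRT": rrt(field),
        "tSS": transwss(field, normals),
        "SAD": sad(field, adjacency),
    }
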