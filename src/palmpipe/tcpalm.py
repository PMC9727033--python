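"""Time-correlated burst extraction and lifetime statistics.

Within each spatial cluster, detections are split along the time axis into
maximal runs whose consecutive frame gaps do not exceed a dark-time
tolerance; each run is a burst. A burst's lifetime is the timespan from its
first to its last detection (a single detection has lifetime 0). Bursts
shorter than a cutoff (default 100 s, strict inequality) are classified
short-lived, the rest long-lived.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SHORT = "short_lived"
LONG = "long_lived"


class BurstError(ValueError):
    pass


@dataclass
class BurstParams:
    max_gap_frames: int = 20  # dark-time tolerance separating bursts
    frame_rate: float = None  # Hz; required, no silent default
    short_lifetime_cutoff: float = 100.0  # s

    def __post_init__(self) -> None:
        if self.frame_rate is None or self.frame_rate <= 0:
            raise BurstError(
                "frame_rate is required (lifetimes are reported in seconds)"
            )
        if self.max_gap_frames < 1:
            raise BurstError("max_gap_frames must be >= 1")
        if self.short_lifetime_cutoff <= 0:
            raise BurstError("short_lifetime_cutoff must be > 0")


@dataclass
class Burst:
    cluster_id: int
    start_frame: int
    end_frame: int
    lifetime: float  # s = (end - start) / frame_rate
    n_detections: int
    region: str = "outside"
    cell_id: int = 0
    censored: bool = False  # truncated by a movie boundary


@dataclass
class LifetimeSummary:
    tau_avg_short: float  # mean lifetime of short-lived bursts, s (nan if none)
    sem_tau: float  # SEM of the short-lived lifetimes, s
    fraction_long: float
    n_bursts: int
    n_short: int
    n_long: int
    histogram_counts: np.ndarray = field(default_factory=lambda: np.empty(0))
    histogram_edges: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ClusterStats:
    clusters_per_cell: pd.DataFrame  # columns cell_id, region, n_clusters
    detections_mean: float
    detections_min: int
    detections_max: int


def extract_bursts(
    frames: Sequence[int],
    params: BurstParams,
    cluster_id: int = 0,
    region: str = "outside",
    cell_id: int = 0,
    n_frames: Optional[int] = None,
) -> list:
    """Split a cluster's detection frames into bursts at dark gaps.

    Detections are sorted; a new burst starts whenever the gap to the
    previous detection exceeds ``max_gap_frames``. With ``n_frames`` given,
    bursts touching a movie boundary (within one gap tolerance) are flagged
    as censored.
    """
    f = np.sort(np.asarray(frames, dtype=np.int64))
    if f.size == 0:
        return []
    cuts = np.nonzero(np.diff(f) > params.max_gap_frames)[0] + 1
    bursts = []
    for run in np.split(f, cuts):
        start, end = int(run[0]), int(run[-1])
        censored = False
        if n_frames is not None:
            censored = start < params.max_gap_frames or end >= n_frames - params.max_gap_frames
        bursts.append(
            Burst(
                cluster_id=cluster_id,
                start_frame=start,
                end_frame=end,
                lifetime=(end - start) / params.frame_rate,
                n_detections=int(run.size),
                region=region,
                cell_id=cell_id,
                censored=censored,
            )
        )
    return bursts


def bursts_from_clusters(
    localizations: pd.DataFrame,
    labels: np.ndarray,
    clusters,
    params: BurstParams,
    n_frames: Optional[int] = None,
) -> list:
    """Extract bursts for every spatial cluster of a localization table."""
    frames = localizations["frame"].to_numpy()
    out = []
    for c in clusters:
        out.extend(
            extract_bursts(
                frames[labels == c.cluster_id],
                params,
                cluster_id=c.cluster_id,
                region=c.region,
                cell_id=c.cell_id,
                n_frames=n_frames,
            )
        )
    return out


def classify_lifetime(burst: Burst, params: BurstParams) -> str:
    """``short_lived`` iff lifetime < cutoff (strict), else ``long_lived``."""
    return SHORT if burst.lifetime < params.short_lifetime_cutoff else LONG


def summarize_lifetimes(
    bursts: Sequence[Burst],
    params: BurstParams,
    bin_edges: Optional[np.ndarray] = None,
    include_censored: bool = True,
) -> LifetimeSummary:
    """Lifetime summary: tau_avg of short-lived bursts, SEM, long fraction.

    Censored bursts are included by default; pass
    ``include_censored=False`` to drop them.
    """
    if len(bursts) == 0:
        raise BurstError("at least one burst is required")
    use = [b for b in bursts if include_censored or not b.censored]
    if len(use) == 0:
        raise BurstError("no bursts left after censoring filter")
    lifetimes = np.array([b.lifetime for b in use])
    short = lifetimes[lifetimes < params.short_lifetime_cutoff]
    n_long = int((lifetimes >= params.short_lifetime_cutoff).sum())

    if short.size == 0:
        warnings.warn("no short-lived bursts; tau_avg_short undefined", stacklevel=2)
        tau, sem = float("nan"), float("nan")
    else:
        tau = float(short.mean())
        sem = float(short.std(ddof=1) / np.sqrt(short.size)) if short.size > 1 else 0.0

    if bin_edges is None:
        upper = max(float(lifetimes.max()), params.short_lifetime_cutoff)
        bin_edges = np.linspace(0.0, upper, 21)
    counts, edges = np.histogram(lifetimes, bins=bin_edges)
    return LifetimeSummary(
        tau_avg_short=tau,
        sem_tau=sem,
        fraction_long=n_long / len(use),
        n_bursts=len(use),
        n_short=int(short.size),
        n_long=n_long,
        histogram_counts=counts,
        histogram_edges=edges,
    )


def summarize_by_region(
    bursts: Sequence[Burst], params: BurstParams, **kwargs
) -> Dict[str, LifetimeSummary]:
    """Per-region summaries; ``outside`` bursts are excluded (logged)."""
    out: Dict[str, LifetimeSummary] = {}
    by_region: Dict[str, list] = {}
    for b in bursts:
        by_region.setdefault(b.region, []).append(b)
    excluded = by_region.pop("outside", [])
    if excluded:
        logger.info("excluding %d bursts labelled outside", len(excluded))
    for region, group in by_region.items():
        out[region] = summarize_lifetimes(group, params, **kwargs)
    return out


def cluster_stats(clusters_df: pd.DataFrame) -> ClusterStats:
    """Per-cell per-region cluster counts and detections-per-cluster stats.

    Expects columns ``cell_id``, ``region``, ``n_detections``; clusters
    labelled ``outside`` are excluded.
    """
    df = clusters_df[clusters_df["region"] != "outside"]
    if df.empty:
        return ClusterStats(
            clusters_per_cell=pd.DataFrame(columns=["cell_id", "region", "n_clusters"]),
            detections_mean=float("nan"),
            detections_min=0,
            detections_max=0,
        )
    counts = (
        df.groupby(["cell_id", "region"], observed=True)
        .size()
        .reset_index(name="n_clusters")
    )
    det = df["n_detections"]
    return ClusterStats(
        clusters_per_cell=counts,
        detections_mean=float(det.mean()),
        detections_min=int(det.min()),
        detections_max=int(det.max()),
    )


def compare_conditions(
    lifetimes_a: Sequence[float],
    lifetimes_b: Sequence[float],
    alternative: str = "two-sided",
    equal_var: bool = True,
) -> dict:
    """Unpaired t test between two groups of (short-lived) lifetimes."""
    a = np.asarray(lifetimes_a, dtype=float)
    b = np.asarray(lifetimes_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise BurstError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        warnings.warn("degenerate (zero) variance in both groups", stacklevel=2)
        if a.mean() == b.mean():
            return {"t": 0.0, "p_value": 1.0, "n_a": a.size, "n_b": b.size,
                    "mean_a": float(a.mean()), "mean_b": float(b.mean())}
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return {
        "t": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_a": int(a.size),
        "n_b": int(b.size),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }


def gap_sensitivity(
    localizations: pd.DataFrame,
    labels: np.ndarray,
    clusters,
    frame_rate: float,
    gaps: Sequence[int],
    short_lifetime_cutoff: float = 100.0,
) -> pd.DataFrame:
    """Sweep the dark-gap tolerance and report tau_avg_short per gap."""
    rows = []
    for gap in gaps:
        params = BurstParams(
            max_gap_frames=int(gap),
            frame_rate=frame_rate,
            short_lifetime_cutoff=short_lifetime_cutoff,
        )
        bursts = bursts_from_clusters(localizations, labels, clusters, params)
        if not bursts:
            rows.append({"max_gap_frames": gap, "tau_avg_short_s": float("nan"),
                         "fraction_long": float("nan"), "n_bursts": 0})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = summarize_lifetimes(bursts, params)
        rows.append(
            {
                "max_gap_frames": gap,
                "tau_avg_short_s": s.tau_avg_short,
                "fraction_long": s.fraction_long,
                "n_bursts": s.n_bursts,
            }
        )
    return pd.DataFrame(rows)


def bursts_to_frame(bursts: Sequence[Burst], params: BurstParams) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [b.cluster_id for b in bursts],
            "start_frame": [b.start_frame for b in bursts],
            "end_frame": [b.end_frame for b in bursts],
            "lifetime_s": [b.lifetime for b in bursts],
            "n_detections": [b.n_detections for b in bursts],
            "class": [classify_lifetime(b, params) for b in bursts],
            "region": [b.region for b in bursts],
            "cell_id": [b.cell_id for b in bursts],
            "censored": [b.censored for b in bursts],
        }
    )
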