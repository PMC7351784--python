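"""Scoring marker estimates against the calcaneus reference.

Per-sensor estimation error is the normalised root-mean-square error

    nRMSE = sqrt(mean((M_i - C_i)^2)) / mean(C) x 100  [%]

over matched per-stride durations, where M comes from the simulated
sensor and C from the calcaneus reference.  Events are paired by greedy
nearest-neighbour matching within half a median reference stride
period; durations are recomputed on consecutively matched events.

The module also builds ring x circumferential nRMSE maps, groups error
levels, selects best/worst sensors, regroups hemiparetic subjects by
affected / less-affected side (mirroring circumferential indices so
ventral aligns with ventral), and provides the statistics used for
population comparisons (two-sided Wilcoxon rank-sum at alpha = 1 %,
Spearman rank correlation).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .layout import SENSORS_PER_RING, SensorLayout

__all__ = [
    "MatchedStrides",
    "ErrorMap",
    "match_events",
    "nrmse",
    "rmse_count",
    "aggregate_rmse",
    "build_error_map",
    "error_levels",
    "select_extreme_sensors",
    "correct_sides",
    "mirror_sx",
    "rank_sum_test",
    "RankSumResult",
    "spearman_rho",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# event matching and nRMSE
# ---------------------------------------------------------------------------

@dataclass
class MatchedStrides:
    """One-to-one paired per-stride durations (ms) from sensor and reference."""

    sensor_durations_ms: np.ndarray  # M
    reference_durations_ms: np.ndarray  # C
    event_pairs: np.ndarray  # (n_matched_events, 2) of (t_sensor, t_reference)
    unmatched_sensor: int = 0
    unmatched_reference: int = 0

    def __post_init__(self) -> None:
        if len(self.sensor_durations_ms) != len(self.reference_durations_ms):
            raise ValueError("matched duration lists must have equal length")


def match_events(
    sensor_events: np.ndarray,
    reference_events: np.ndarray,
    window_s: float | None = None,
) -> MatchedStrides:
    """Greedy nearest-neighbour pairing of sensor and reference events.

    Pairs within ``window_s`` (default half the median reference stride
    period) are assigned in order of increasing time difference, each
    event used at most once.  Durations are recomputed between
    *consecutively matched* reference events and their sensor partners.

    Raises
    ------
    ValueError
        If either list is empty or no events match.
    """
    s = np.asarray(sensor_events, dtype=float)
    r = np.asarray(reference_events, dtype=float)
    if len(s) == 0 or len(r) == 0:
        raise ValueError("both event series must be non-empty")
    if window_s is None:
        if len(r) < 2:
            raise ValueError("cannot derive matching window from fewer than 2 reference events")
        window_s = 0.5 * float(np.median(np.diff(r)))

    pairs = [
        (abs(ts - tr), i, j)
        for i, ts in enumerate(s)
        for j, tr in enumerate(r)
        if abs(ts - tr) <= window_s
    ]
    pairs.sort(key=lambda p: (p[0], p[2], p[1]))
    used_s: set[int] = set()
    match: dict[int, int] = {}  # reference index -> sensor index
    for _, i, j in pairs:
        if i in used_s or j in match:
            continue
        used_s.add(i)
        match[j] = i
    if not match:
        raise ValueError("no events matched within the window")

    m_dur, c_dur = [], []
    for j in range(len(r) - 1):
        if j in match and (j + 1) in match:
            c_dur.append((r[j + 1] - r[j]) * 1000.0)
            m_dur.append((s[match[j + 1]] - s[match[j]]) * 1000.0)
    event_pairs = np.array(sorted((s[i], r[j]) for j, i in match.items()))
    return MatchedStrides(
        sensor_durations_ms=np.asarray(m_dur),
        reference_durations_ms=np.asarray(c_dur),
        event_pairs=event_pairs.reshape(-1, 2),
        unmatched_sensor=len(s) - len(match),
        unmatched_reference=len(r) - len(match),
    )


def nrmse(matched: MatchedStrides) -> float:
    """nRMSE (%) of matched sensor vs reference stride durations."""
    m = matched.sensor_durations_ms
    c = matched.reference_durations_ms
    if len(m) == 0:
        raise ValueError("need at least one matched stride pair")
    cbar = float(np.mean(c))
    if cbar == 0:
        raise ValueError("mean reference duration is zero")
    return float(np.sqrt(np.mean((m - c) ** 2)) / cbar * 100.0)


def rmse_count(sensor_count: int, reference_count: int) -> int:
    """Absolute stride-count difference of one trial."""
    return abs(int(sensor_count) - int(reference_count))


def aggregate_rmse(diffs: Iterable[float]) -> float:
    """RMSE across trials of per-trial differences."""
    d = np.asarray(list(diffs), dtype=float)
    return float(np.sqrt(np.mean(d**2)))


# ---------------------------------------------------------------------------
# error maps
# ---------------------------------------------------------------------------

@dataclass
class ErrorMap:
    """Per-sensor nRMSE values on the ring x circumferential grid of one
    segment/side, stored as a tidy frame (ring, sx, nrmse_pct, n_pairs)."""

    segment: str
    side: str
    table: pd.DataFrame

    _COLS = ["ring", "sx", "nrmse_pct", "n_pairs"]

    def __post_init__(self) -> None:
        missing = [c for c in self._COLS if c not in self.table.columns]
        if missing:
            raise ValueError(f"error map table missing columns {missing}")
        self.table = self.table[self._COLS].sort_values(["ring", "sx"]).reset_index(drop=True)

    def grid(self) -> pd.DataFrame:
        """Pivot to a ring x sx matrix of nRMSE values."""
        return self.table.pivot(index="ring", columns="sx", values="nrmse_pct")

    def values(self) -> np.ndarray:
        return self.table["nrmse_pct"].to_numpy()

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "segment", self.segment)
        out.insert(1, "side", self.side)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ErrorMap":
        df = pd.read_csv(path)
        return cls(segment=df["segment"].iloc[0], side=df["side"].iloc[0],
                   table=df[cls._COLS])


def build_error_map(
    layout: SensorLayout,
    scores: Mapping[str, float],
    n_pairs: Mapping[str, int] | None = None,
) -> dict[tuple[str, str], ErrorMap]:
    """Organise per-sensor nRMSE scores into per-(segment, side) maps.

    Sensors missing from ``scores`` are flagged NaN and logged.
    """
    missing = [s.id for s in layout if s.id not in scores]
    if missing:
        log.warning("%d sensors without scores flagged missing (e.g. %s)",
                    len(missing), missing[0])
    maps: dict[tuple[str, str], ErrorMap] = {}
    for key in sorted(set((s.segment, s.side) for s in layout)):
        rows = []
        for s in layout.subset(segment=key[0], side=key[1]):
            rows.append(dict(
                ring=s.ring, sx=s.sx,
                nrmse_pct=float(scores.get(s.id, np.nan)),
                n_pairs=int(n_pairs.get(s.id, 0)) if n_pairs else 0,
            ))
        maps[key] = ErrorMap(segment=key[0], side=key[1], table=pd.DataFrame(rows))
    return maps


def error_levels(values: Iterable[float] | Mapping[tuple, ErrorMap]) -> dict[str, int]:
    """Count nRMSE values per level: [0, 1) %, [1, 5] %, (5, inf) %, and <= 10 %.

    NaN (missing) cells are excluded from every count.
    """
    if isinstance(values, Mapping):
        arr = np.concatenate([m.values() for m in values.values()])
    else:
        arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    return {
        "below_1pct": int(np.sum(arr < 1.0)),
        "1_to_5pct": int(np.sum((arr >= 1.0) & (arr <= 5.0))),
        "above_5pct": int(np.sum(arr > 5.0)),
        "le_10pct": int(np.sum(arr <= 10.0)),
    }


def select_extreme_sensors(
    scores: Mapping[str, float],
    layout: SensorLayout,
) -> tuple[str, str]:
    """(best, worst) sensor ids by nRMSE; ties broken by
    (segment, ring, sx, side) lexicographic order."""
    specs = layout.by_id()
    scored = [(sid, v) for sid, v in scores.items() if np.isfinite(v)]
    if not scored:
        raise ValueError("no scored sensors")

    def key(item, sign):
        sid, v = item
        s = specs[sid]
        return (sign * v, s.segment, s.ring, s.sx, s.side)

    best = min(scored, key=lambda it: key(it, +1))[0]
    worst = min(scored, key=lambda it: key(it, -1))[0]
    return best, worst


# ---------------------------------------------------------------------------
# affected / less-affected regrouping
# ---------------------------------------------------------------------------

def mirror_sx(sx: int) -> int:
    """Mirror a circumferential index about the ventral midline (S1 fixed)."""
    return ((SENSORS_PER_RING - (sx - 1)) % SENSORS_PER_RING) + 1


def correct_sides(
    per_subject_maps: Mapping[str, Mapping[str, ErrorMap]],
    affected_labels: Mapping[str, str],
    agg: str = "mean",
) -> dict[str, ErrorMap]:
    """Regroup per-subject left/right maps into affected / less-affected.

    Left-side maps are mirrored in the circumferential index so that
    anatomical directions align (ventral with ventral, medial with
    medial) before averaging cell-wise across subjects.  Subjects
    without a label are excluded with a warning.
    """
    if agg not in ("mean", "median"):
        raise ValueError("agg must be 'mean' or 'median'")
    groups: dict[str, list[pd.DataFrame]] = {"affected": [], "less_affected": []}
    segment = side0 = None
    for subject, sides in per_subject_maps.items():
        label = affected_labels.get(subject)
        if label not in ("left", "right"):
            log.warning("subject %r has no affected-side label; excluded", subject)
            continue
        for side_key, emap in sides.items():
            group = "affected" if (
                (side_key in ("left", "L")) == (label == "left")
            ) else "less_affected"
            t = emap.table.copy()
            if side_key in ("left", "L"):
                t["sx"] = t["sx"].map(mirror_sx)
            groups[group].append(t)
            segment = emap.segment
            side0 = emap.side
    if not groups["affected"] or not groups["less_affected"]:
        raise ValueError("need at least one labelled subject per group")
    out = {}
    for group, tables in groups.items():
        cat = pd.concat(tables)
        # pandas groupby mean/median skip NaN (missing cells) by default
        g = cat.groupby(["ring", "sx"], as_index=False).agg(
            nrmse_pct=("nrmse_pct", agg), n_pairs=("n_pairs", "sum")
        )
        out[group] = ErrorMap(segment=segment, side=group, table=g)
    return out


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first sample (mid-ranks)
    p_value: float
    significant: bool
    method: str


def _midranks(values: np.ndarray) -> np.ndarray:
    return _sstats.rankdata(values, method="average")


def rank_sum_test(a, b, alpha: float = 0.01) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration of all rank assignments when both groups have at
    most 8 observations; normal approximation with tie correction
    otherwise.  Significance is judged at ``alpha`` (default 1 %).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return RankSumResult(statistic=n1 * (n1 + n2 + 1) / 2.0, p_value=1.0,
                             significant=False, method="degenerate")
    ranks = _midranks(combined)
    w = float(np.sum(ranks[:n1]))
    mu = n1 * (n1 + n2 + 1) / 2.0

    if n1 <= 8 and n2 <= 8:
        dev = abs(w - mu)
        total = math.comb(n1 + n2, n1)
        count = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            if abs(ranks[list(comb)].sum() - mu) >= dev - 1e-12:
                count += 1
        p = count / total
        method = "exact"
    else:
        n = n1 + n2
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (w - mu) / math.sqrt(var)
            p = 2.0 * _sstats.norm.sf(abs(z))
        method = "normal"
    p = min(p, 1.0)
    return RankSumResult(statistic=w, p_value=p, significant=p < alpha, method=method)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(_midranks(x)) == 0 or np.std(_midranks(y)) == 0:
        raise ValueError("zero rank variance")
    return float(_sstats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# plotting (thin)
# ---------------------------------------------------------------------------

def plot_error_map(emap: ErrorMap, path, vmax: float | None = None) -> None:
    """Save a colour-coded nRMSE heatmap of one segment/side."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = emap.grid()
    fig, ax = plt.subplots(figsize=(6, 3))
    im = ax.imshow(grid.to_numpy(), aspect="auto", cmap="viridis", vmax=vmax,
                   extent=(0.5, grid.shape[1] + 0.5, grid.shape[0] + 0.5, 0.5))
    ax.set_xlabel("circumferential index Sx")
    ax.set_ylabel("ring Rx")
    ax.set_title(f"nRMSE [%] - {emap.segment} {emap.side}")
    fig.colorbar(im, ax=ax, label="nRMSE [%]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
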