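"""Displacement-module motility index and nonparametric strain comparison.

The motility index is the per-instant displacement module

    M_k = sqrt((x_k - x_{k-1})^2 + (y_k - y_{k-1})^2)

computed from the mechanical-tracking control actions (x/y shifts in motor
steps, 1.09 um/step) or equivalently from sampled worm positions.  Three
summaries are built on it:

* the per-worm module sum, expressed as a percentage of the largest sum in
  the experiment — the "amount of movement per worm";
* relative-frequency histograms of module values per strain, in unit-width
  step bins (the [0-1) bin is where an essentially static worm lands);
* pairwise two-sided Wilcoxon rank-sum tests between strains on the
  per-worm sums, exact by enumeration for small samples and by normal
  approximation (tie and continuity corrected) otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import InsufficientSampleError, InvalidParameterError

__all__ = [
    "ModuleSeries",
    "HistogramSpec",
    "ComparisonReport",
    "displacement_modules",
    "module_sum_percent",
    "relative_frequency",
    "rank_sum_test",
    "compare_strains",
    "STEP_UM",
]

#: Millimetre value of one motor step (modules are reported in steps).
STEP_UM = 1.09

#: Exact-enumeration limits for the rank-sum test.
_EXACT_MIN_N = 8
_EXACT_TOTAL = 16


@dataclass
class ModuleSeries:
    """Per-instant displacement modules of one worm, in motor steps."""

    worm_id: int
    modules: np.ndarray
    strain: str = ""

    def __post_init__(self) -> None:
        self.modules = np.asarray(self.modules, dtype=float)
        if self.modules.ndim != 1:
            raise InvalidParameterError("modules must be a 1-D sequence")
        if np.any(self.modules < 0):
            raise InvalidParameterError("modules must be non-negative")

    @property
    def total(self) -> float:
        """Module sum — total amount of movement of this worm, steps."""
        return float(self.modules.sum())


@dataclass(frozen=True)
class HistogramSpec:
    """Module histogram bins, in steps; the last bin collects the overflow."""

    bin_edges: tuple = tuple(range(0, 11))

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise InvalidParameterError("bin_edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        e = list(self.bin_edges)
        lab = [f"[{a:g}-{b:g})" for a, b in zip(e[:-1], e[1:])]
        lab.append(f">={e[-1]:g}")
        return lab


def displacement_modules(actions, worm_id: int = 0, strain: str = "",
                         kind: str = "positions") -> ModuleSeries:
    """Eq.-of-motion-free displacement modules from positions or deltas.

    ``kind='positions'`` expects a sequence of (x_k, y_k); modules are the
    Euclidean norms of consecutive differences.  ``kind='deltas'`` expects
    the per-instant control actions (dx, dy) directly.
    """
    arr = np.asarray(actions, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidParameterError("actions must be an (n, 2) array")
    if kind == "positions":
        if len(arr) < 2:
            raise InvalidParameterError("need at least 2 position instants")
        deltas = np.diff(arr, axis=0)
    elif kind == "deltas":
        if len(arr) < 1:
            raise InvalidParameterError("need at least 1 action")
        deltas = arr
    else:
        raise InvalidParameterError(f"unknown kind {kind!r}")
    return ModuleSeries(worm_id=worm_id,
                        modules=np.linalg.norm(deltas, axis=1),
                        strain=strain)


def module_sum_percent(series: list[ModuleSeries],
                       normalization: str = "max") -> dict[int, float]:
    """Per-worm module sums as percentages.

    ``normalization='max'`` (default) anchors the most mobile worm at 100%;
    ``'group_total'`` expresses each worm as percent of the summed movement
    of all worms.
    """
    if not series:
        raise InvalidParameterError("series must be non-empty")
    sums = {s.worm_id: s.total for s in series}
    if normalization == "max":
        base = max(sums.values())
    elif normalization == "group_total":
        base = sum(sums.values())
    else:
        raise InvalidParameterError(f"unknown normalization {normalization!r}")
    if base == 0:
        return {wid: 0.0 for wid in sums}
    return {wid: 100.0 * v / base for wid, v in sums.items()}


def relative_frequency(values, spec: HistogramSpec = HistogramSpec()
                       ) -> np.ndarray:
    """Relative frequency of module values per bin (sums to 1).

    ``values`` may be a ModuleSeries, an array, or a list of ModuleSeries
    (pooled).  The final entry is the overflow bin >= the last edge.
    """
    if isinstance(values, ModuleSeries):
        data = values.modules
    elif isinstance(values, (list, tuple)) and values and isinstance(
            values[0], ModuleSeries):
        data = np.concatenate([s.modules for s in values])
    else:
        data = np.asarray(values, dtype=float)
    if data.size == 0:
        raise InvalidParameterError("need at least one module value")
    edges = np.asarray(spec.bin_edges, dtype=float)
    counts, _ = np.histogram(data, bins=np.append(edges, np.inf))
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    For min(n, m) <= 8 and n + m <= 16 the null distribution of the rank
    sum is enumerated exactly over all C(n+m, n) label assignments of the
    pooled midranks (so ties are handled exactly); larger samples use the
    normal approximation with tie and continuity corrections.  Identical
    constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    n, m = len(a), len(b)
    ranks = rankdata(np.concatenate([a, b]))  # midranks under ties
    w = float(ranks[:n].sum())
    if min(n, m) <= _EXACT_MIN_N and n + m <= _EXACT_TOTAL:
        return _exact_p(ranks, n, w)
    return _normal_approx_p(ranks, n, m, w)


def _exact_p(ranks: np.ndarray, n: int, w: float) -> float:
    total = len(ranks)
    n_splits = math.comb(total, n)
    le = ge = 0
    eps = 1e-9
    for combo in itertools.combinations(range(total), n):
        s = ranks[list(combo)].sum()
        if s <= w + eps:
            le += 1
        if s >= w - eps:
            ge += 1
    p = 2.0 * min(le, ge) / n_splits
    return min(p, 1.0)


def _normal_approx_p(ranks: np.ndarray, n: int, m: int, w: float) -> float:
    total = n + m
    mu = n * (total + 1) / 2.0
    # tie correction on the rank variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    var = n * m / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
    if var <= 0:
        return 1.0
    diff = w - mu
    # continuity correction toward the mean
    cc = 0.5 if diff != 0 else 0.0
    z = (abs(diff) - cc) / math.sqrt(var)
    return float(min(1.0, math.erfc(max(z, 0.0) / math.sqrt(2.0))))


# ---------------------------------------------------------------------------
# Strain comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Pairwise strain comparison on per-worm module sums."""

    strains: list[str]
    per_worm_sums: dict[str, dict[int, float]]  # strain -> worm -> sum
    per_worm_percent: dict[str, dict[int, float]]
    p_values: dict[tuple[str, str], float]
    histograms: dict[str, np.ndarray]
    histogram_spec: HistogramSpec = field(default_factory=HistogramSpec)

    def to_dict(self) -> dict:
        return {
            "strains": self.strains,
            "per_worm_sums": {s: {str(k): v for k, v in d.items()}
                              for s, d in self.per_worm_sums.items()},
            "per_worm_percent": {s: {str(k): v for k, v in d.items()}
                                 for s, d in self.per_worm_percent.items()},
            "p_values": {f"{a}|{b}": p for (a, b), p in self.p_values.items()},
            "histogram_labels": self.histogram_spec.labels,
            "histograms": {s: list(map(float, h))
                           for s, h in self.histograms.items()},
        }


def compare_strains(groups: dict[str, list[ModuleSeries]],
                    spec: HistogramSpec = HistogramSpec(),
                    normalization: str = "max") -> ComparisonReport:
    """Full strain comparison: sums, percentages, histograms, rank-sum tests.

    ``groups`` maps strain label to that strain's per-worm module series.
    Histograms pool all module values within a strain.  Requires at least
    two strains with at least two worms each.
    """
    if len(groups) < 2:
        raise InsufficientSampleError("need at least 2 strains")
    for name, series in groups.items():
        if len(series) < 2:
            raise InsufficientSampleError(
                f"strain {name!r} has {len(series)} worm(s); need >= 2")
    strains = list(groups)
    all_series = [s for g in groups.values() for s in g]
    percent_all = module_sum_percent(all_series, normalization=normalization)
    sums = {name: {s.worm_id: s.total for s in series}
            for name, series in groups.items()}
    percent = {name: {s.worm_id: percent_all[s.worm_id] for s in series}
               for name, series in groups.items()}
    p_values = {}
    for a, b in itertools.combinations(strains, 2):
        p_values[(a, b)] = rank_sum_test(list(sums[a].values()),
                                         list(sums[b].values()))
    histograms = {name: relative_frequency(series, spec)
                  for name, series in groups.items()}
    return ComparisonReport(strains=strains, per_worm_sums=sums,
                            per_worm_percent=percent, p_values=p_values,
                            histograms=histograms, histogram_spec=spec)


def plot_relative_frequency(report: ComparisonReport, ax=None):
    """Grouped bar chart of per-strain module-value relative frequencies."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    labels = report.histogram_spec.labels
    x = np.arange(len(labels))
    width = 0.8 / len(report.strains)
    for i, strain in enumerate(report.strains):
        ax.bar(x + (i - (len(report.strains) - 1) / 2) * width,
               report.histograms[strain], width, label=strain)
    ax.set_xticks(x, labels, rotation=45)
    ax.set_xlabel("module value rank (steps)")
    ax.set_ylabel("relative frequency")
    ax.legend()
    return ax
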