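"""Per-bioassay statistics of 3-D similarity scores.

Within one assay every tested compound is either "inactive" or
"noninactive" (anything not explicitly reported inactive).  The analysis
partitions compound pairs into noninactive-noninactive (NN) and
noninactive-inactive (NI) sets, summarises each of the six similarity
measures over both sets per assay, aggregates those summaries across
assays (overall and by assay category), and extracts outlier assays whose
NN-NI mean separation lies outside mu +/- k*sigma across all eligible
assays.  Histogram, percentile-threshold, chance-neighbor and pair-graph
connectivity utilities complete the reporting toolkit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .align import MEASURES, SimilarityRecord
from .config import DEFAULT_CONFIG, StatsConfig

log = logging.getLogger(__name__)

ASSAY_CATEGORIES = ("screening", "confirmatory", "summary", "other", "unspecified")

PAIR_CLASSES = ("nn", "ni", "diff")


# ---------------------------------------------------------------------------
# assay tables and pair partitioning


@dataclass
class AssayTable:
    """One assay: category plus the raw per-compound outcome strings."""

    aid: int
    category: str
    outcomes: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in ASSAY_CATEGORIES:
            raise ValueError(f"unknown assay category {self.category!r}")

    @classmethod
    def from_rows(cls, aid: int, category: str, rows: Iterable[tuple[int, str]]) -> "AssayTable":
        """Build from (cid, outcome) rows; a conflicting duplicate resolves to
        noninactive (any non-inactive report wins) with a logged warning."""
        outcomes: dict[int, str] = {}
        for cid, outcome in rows:
            if cid in outcomes and classify_outcome(outcomes[cid]) != classify_outcome(outcome):
                log.warning("AID %d CID %d: conflicting outcomes, keeping noninactive", aid, cid)
                if classify_outcome(outcome) == "noninactive":
                    outcomes[cid] = outcome
            else:
                outcomes[cid] = outcome
        return cls(aid=aid, category=category, outcomes=outcomes)

    def partition(self) -> tuple[list[int], list[int]]:
        """(noninactive cids, inactive cids), each sorted."""
        non, inact = [], []
        for cid in sorted(self.outcomes):
            (non if classify_outcome(self.outcomes[cid]) == "noninactive" else inact).append(cid)
        return non, inact


def classify_outcome(raw: str) -> str:
    """'inactive' only for an explicit (case-insensitive) inactive report;
    active, inconclusive, probe, unspecified etc. are all 'noninactive'."""
    if not raw:
        raise ValueError("empty outcome string")
    return "inactive" if raw.strip().lower() == "inactive" else "noninactive"


@dataclass(frozen=True)
class PairSet:
    """NN and NI pairs of one assay, each pair stored as (low cid, high cid)."""

    nn_pairs: tuple[tuple[int, int], ...]
    ni_pairs: tuple[tuple[int, int], ...]

    @property
    def n_nn(self) -> int:
        return len(self.nn_pairs)

    @property
    def n_ni(self) -> int:
        return len(self.ni_pairs)


def enumerate_pairs(assay: AssayTable, have_3d: set[int]) -> PairSet:
    """Partition an assay's compound pairs into NN and NI sets.

    Only compounds with a 3-D description participate.  NN pairs are the
    unordered pairs of distinct noninactives; NI pairs cross one
    noninactive with one inactive; inactive-inactive pairs are dropped.
    """
    non, inact = assay.partition()
    non = [c for c in non if c in have_3d]
    inact = [c for c in inact if c in have_3d]
    nn = tuple((a, b) for i, a in enumerate(non) for b in non[i + 1 :])
    ni = tuple((min(a, b), max(a, b)) for a in non for b in inact)
    return PairSet(nn_pairs=nn, ni_pairs=ni)


def filter_eligible(
    pairsets: Mapping[int, PairSet], min_nn: int = 6, min_ni: int = 6
) -> list[int]:
    """AIDs with at least min_nn NN pairs and min_ni NI pairs, sorted."""
    return sorted(
        aid for aid, ps in pairsets.items() if ps.n_nn >= min_nn and ps.n_ni >= min_ni
    )


# ---------------------------------------------------------------------------
# per-assay and cross-assay statistics


def _sd(values: np.ndarray, mode: str) -> float:
    if mode == "sample" and len(values) > 1:
        return float(np.std(values, ddof=1))
    return float(np.std(values))


@dataclass(frozen=True)
class MeasureStats:
    """NN/NI/NN-NI mean and SD of one similarity measure in one assay."""

    mu_nn: float
    sd_nn: float
    mu_ni: float
    sd_ni: float
    mu_diff: float
    sd_diff: float


@dataclass(frozen=True)
class PerAidStats:
    aid: int
    category: str
    n_nn: int
    n_ni: int
    measures: dict[str, MeasureStats]


PairKey = tuple[int, int]


def pair_key(cid_a: int, cid_b: int) -> PairKey:
    return (cid_a, cid_b) if cid_a < cid_b else (cid_b, cid_a)


def per_aid_statistics(
    assay: AssayTable,
    pairs: PairSet,
    scores: Mapping[PairKey, SimilarityRecord],
    config: StatsConfig = DEFAULT_CONFIG.stats,
) -> PerAidStats:
    """Mean/SD of each measure over the NN and NI pair scores of one assay.

    mu_diff = mu_nn - mu_ni, which equals the mean of all n_nn * n_ni
    cross differences exactly.  sd_diff defaults to
    sqrt(sd_nn^2 + sd_ni^2), the SD of that full cross-difference
    population; SDs use divisor n ("population") unless configured
    otherwise.
    """

    def lookup(pair: PairKey) -> SimilarityRecord:
        try:
            return scores[pair]
        except KeyError:
            raise KeyError(f"no similarity record for pair {pair[0]}-{pair[1]}") from None

    nn = [lookup(p) for p in pairs.nn_pairs]
    ni = [lookup(p) for p in pairs.ni_pairs]
    measures: dict[str, MeasureStats] = {}
    for m in MEASURES:
        x_nn = np.array([r.score(m) for r in nn])
        x_ni = np.array([r.score(m) for r in ni])
        mu_nn, sd_nn = float(np.mean(x_nn)), _sd(x_nn, config.sd_mode)
        mu_ni, sd_ni = float(np.mean(x_ni)), _sd(x_ni, config.sd_mode)
        if config.diff_sd_mode == "pooled":
            sd_diff = math.sqrt(sd_nn**2 / len(x_nn) + sd_ni**2 / len(x_ni))
        else:
            sd_diff = math.sqrt(sd_nn**2 + sd_ni**2)
        measures[m] = MeasureStats(mu_nn, sd_nn, mu_ni, sd_ni, mu_nn - mu_ni, sd_diff)
    return PerAidStats(
        aid=assay.aid, category=assay.category, n_nn=pairs.n_nn, n_ni=pairs.n_ni, measures=measures
    )


def aggregate(
    stats: Sequence[PerAidStats], config: StatsConfig = DEFAULT_CONFIG.stats
) -> pd.DataFrame:
    """Cross-assay summary: mean and SD of the per-assay means and SDs.

    Tidy layout, one row per (group, measure, pair class) with columns
    mu_mu (mean of per-assay means), sigma_mu, mu_sigma, sigma_sigma;
    groups are each assay category present plus "All".
    """
    if not stats:
        raise ValueError("no per-assay statistics to aggregate")
    rows = []
    groups = [c for c in ASSAY_CATEGORIES if any(s.category == c for s in stats)] + ["All"]
    for group in groups:
        members = [s for s in stats if group == "All" or s.category == group]
        for m in MEASURES:
            for pc in PAIR_CLASSES:
                mus = np.array([getattr(s.measures[m], f"mu_{pc}") for s in members])
                sds = np.array([getattr(s.measures[m], f"sd_{pc}") for s in members])
                rows.append(
                    {
                        "group": group,
                        "measure": m,
                        "pair_class": pc,
                        "n_aids": len(members),
                        "mu_mu": float(np.mean(mus)),
                        "sigma_mu": _sd(mus, config.sd_mode),
                        "mu_sigma": float(np.mean(sds)),
                        "sigma_sigma": _sd(sds, config.sd_mode),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# outliers


@dataclass(frozen=True)
class OutlierReport:
    """Outlier assays per measure, relative to mu +/- k*sigma of the
    per-assay NN-NI mean difference across all eligible assays."""

    k: float
    bounds: dict[str, tuple[float, float]]
    lower: dict[str, tuple[int, ...]]
    upper: dict[str, tuple[int, ...]]
    category_counts: pd.DataFrame

    def overlap(self, measure_a: str, measure_b: str, side: str = "upper") -> int:
        sets = self.upper if side == "upper" else self.lower
        return len(set(sets[measure_a]) & set(sets[measure_b]))


def find_outliers(
    stats: Sequence[PerAidStats],
    measure: str | None = None,
    k: float = 1.0,
) -> OutlierReport:
    """Assays whose mu(XT_NN-NI) lies outside mu +/- k*sigma across assays.

    Computed for all six measures (so cross-measure and cross-optimization
    overlaps can be read from one report); ``measure`` only validates that
    the caller's focus measure exists.  Zero variance across assays yields
    empty outlier sets with a warning.
    """
    if len(stats) < 2:
        raise ValueError("need at least two assays to define outlier bounds")
    if measure is not None and measure not in MEASURES:
        raise KeyError(f"unknown measure {measure!r}")
    bounds: dict[str, tuple[float, float]] = {}
    lower: dict[str, tuple[int, ...]] = {}
    upper: dict[str, tuple[int, ...]] = {}
    for m in MEASURES:
        diffs = np.array([s.measures[m].mu_diff for s in stats])
        mu, sigma = float(np.mean(diffs)), float(np.std(diffs))
        if sigma == 0.0:
            log.warning("zero variance of mu_diff for %s; no outliers defined", m)
            bounds[m] = (mu, mu)
            lower[m] = upper[m] = ()
            continue
        lo, hi = mu - k * sigma, mu + k * sigma
        bounds[m] = (lo, hi)
        lower[m] = tuple(s.aid for s in stats if s.measures[m].mu_diff < lo)
        upper[m] = tuple(s.aid for s in stats if s.measures[m].mu_diff > hi)

    rows = []
    groups = [c for c in ASSAY_CATEGORIES if any(s.category == c for s in stats)] + ["All"]
    for group in groups:
        members = [s for s in stats if group == "All" or s.category == group]
        aids = {s.aid for s in members}
        row: dict[str, object] = {"group": group, "n_aids": len(members)}
        for m in MEASURES:
            for side, sets in (("lower", lower), ("upper", upper)):
                n = len(aids & set(sets[m]))
                row[f"{m}_{side}"] = n
                row[f"{m}_{side}_pct"] = 100.0 * n / len(members) if members else 0.0
        rows.append(row)
    return OutlierReport(
        k=k, bounds=bounds, lower=lower, upper=upper, category_counts=pd.DataFrame(rows)
    )


def rank_outliers(stats: Sequence[PerAidStats]) -> pd.DataFrame:
    """Rank assays by the average of the ComboT NN-NI mean differences under
    the two optimization types, descending."""
    rows = [
        {
            "aid": s.aid,
            "category": s.category,
            "mu_diff_stopt": s.measures["combo_stopt"].mu_diff,
            "mu_diff_ctopt": s.measures["combo_ctopt"].mu_diff,
            "average": (s.measures["combo_stopt"].mu_diff + s.measures["combo_ctopt"].mu_diff) / 2.0,
        }
        for s in stats
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(["average", "aid"], ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# distributions, thresholds and derived quantities


@dataclass(frozen=True)
class Histogram:
    """Scores binned at fixed width with round-half-to-even bin assignment."""

    bin_width: float
    bin_index: np.ndarray       # integer bin ids, ascending
    counts: np.ndarray
    cumulative_pct: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_index * self.bin_width

    def fraction_leq(self, x: float) -> float:
        """Fraction (percent) of scores in bins at or below the bin of x."""
        idx = int(np.rint(x / self.bin_width))
        below = self.bin_index <= idx
        if not below.any():
            return 0.0
        return float(self.cumulative_pct[below][-1])


def score_histogram(scores: Iterable[float], bin_width: float = 0.01) -> Histogram:
    """Bin scores in ``bin_width`` increments; bin id is the banker's
    rounding of score/bin_width, matching C rint semantics."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite")
    idx = np.rint(arr / bin_width).astype(int)
    uniq, counts = np.unique(idx, return_counts=True)
    cum = 100.0 * np.cumsum(counts) / counts.sum() if counts.size else np.array([])
    return Histogram(bin_width=bin_width, bin_index=uniq, counts=counts, cumulative_pct=cum)


def percentile_thresholds(
    mean: float,
    sd: float,
    k_values: Sequence[float] = (1.0, 2.0),
    scores: Iterable[float] | None = None,
) -> list[tuple[float, float | None]]:
    """Thresholds mean + k*sd, and for each the fraction (percent) of the
    given scores at or below it (None when no scores are supplied)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    arr = None if scores is None else np.asarray(list(scores), dtype=float)
    out = []
    for k in k_values:
        thr = mean + k * sd
        cov = None if arr is None else float(100.0 * np.mean(arr <= thr))
        out.append((thr, cov))
    return out


def neighbor_probability(frac_below_st: float, frac_below_ct: float) -> tuple[float, float]:
    """Chance (percent) that a random pair clears both the shape and the
    color neighbor thresholds at once, assuming independence, and its
    reciprocal as "1 in N" (math.inf when the probability is zero).

    Inputs are the percentages of random pairs below each threshold.  The
    joint chance follows the tail-product convention of the archive's
    reporting - the two tail percentages are multiplied directly and the
    result quoted in percent, capped at certainty (100).
    """
    for f in (frac_below_st, frac_below_ct):
        if not 0.0 <= f <= 100.0:
            raise ValueError("fractions must be percentages in [0, 100]")
    prob = min((100.0 - frac_below_st) * (100.0 - frac_below_ct), 100.0)
    one_in = math.inf if prob == 0.0 else round(100.0 / prob)
    return prob, one_in


def zscore(x: float, mean: float, sd: float) -> float:
    """Standard score of x under the random-pair distribution."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return (x - mean) / sd


def cross_optimization_deltas(means: Mapping[str, float]) -> dict[str, float]:
    """Differences between the two optimization types' random-pair means:
    ST-opt favours ST, CT-opt favours CT, and ComboT is nearly invariant."""
    return {
        "st": means["st_stopt"] - means["st_ctopt"],
        "ct": means["ct_ctopt"] - means["ct_stopt"],
        "combo": means["combo_stopt"] - means["combo_ctopt"],
    }


def report_round(x: float, ndigits: int = 2) -> float:
    """Half-even rounding used in all human-facing reports."""
    return float(np.round(x, ndigits))


def per_cid_profile(
    cid: int,
    records: Iterable[SimilarityRecord],
    config: StatsConfig = DEFAULT_CONFIG.stats,
) -> dict[str, tuple[float, float]]:
    """Mean and SD per measure of all similarity records involving one CID."""
    involved = [r for r in records if cid in (r.cid_a, r.cid_b)]
    if not involved:
        raise ValueError(f"no records involving cid {cid}")
    return {
        m: (
            float(np.mean([r.score(m) for r in involved])),
            _sd(np.array([r.score(m) for r in involved]), config.sd_mode),
        )
        for m in MEASURES
    }


def threshold_components(
    records: Iterable[SimilarityRecord], measure: str, threshold: float
) -> list[int]:
    """Sizes (descending) of the connected components of the pair graph with
    an edge wherever the measure is at or above the threshold."""
    records = list(records)
    cids = sorted({c for r in records for c in (r.cid_a, r.cid_b)})
    index = {c: i for i, c in enumerate(cids)}
    edges = [(index[r.cid_a], index[r.cid_b]) for r in records if r.score(measure) >= threshold]
    n = len(cids)
    if n == 0:
        return []
    if edges:
        rows, cols = zip(*edges)
        adj = coo_matrix((np.ones(len(edges)), (rows, cols)), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    _, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    return sorted((int(s) for s in sizes), reverse=True)
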