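"""End-to-end study evaluation: pair enumeration, shared score cache,
per-assay statistics and cross-assay aggregation.

A compound pair tested in several assays is scored once; the cache is
keyed by (low cid, high cid) and reused everywhere, mirroring how one
global all-by-all score matrix serves every assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, MutableMapping, Sequence

import pandas as pd

from .align import SimilarityRecord, score_pair
from .assays import (
    AssayTable,
    PairSet,
    PerAidStats,
    aggregate,
    enumerate_pairs,
    filter_eligible,
    pair_key,
    per_aid_statistics,
)
from .config import DEFAULT_CONFIG, Config
from .molecules import Conformer


@dataclass
class StudyResult:
    pairsets: dict[int, PairSet]
    eligible_aids: list[int]
    records: dict[tuple[int, int], SimilarityRecord]
    per_aid: list[PerAidStats]
    aggregate: pd.DataFrame


def needed_pairs(pairsets: Mapping[int, PairSet], aids: Sequence[int]) -> list[tuple[int, int]]:
    """Union of NN and NI pairs over the given assays, sorted."""
    pairs: set[tuple[int, int]] = set()
    for aid in aids:
        ps = pairsets[aid]
        pairs.update(ps.nn_pairs)
        pairs.update(ps.ni_pairs)
    return sorted(pairs)


def score_pairs(
    conformers: Sequence[Conformer],
    pairs: Sequence[tuple[int, int]],
    config: Config = DEFAULT_CONFIG,
    cache: MutableMapping[tuple[int, int], SimilarityRecord] | None = None,
) -> dict[tuple[int, int], SimilarityRecord]:
    """Score the listed cid pairs, reusing any cached records."""
    by_cid = {c.cid: c for c in conformers}
    records = dict(cache) if cache else {}
    for a, b in pairs:
        key = pair_key(a, b)
        if key not in records:
            records[key] = score_pair(by_cid[key[0]], by_cid[key[1]], config.scoring)
    return records


def evaluate_study(
    conformers: Sequence[Conformer],
    assays: Sequence[AssayTable],
    config: Config = DEFAULT_CONFIG,
    records: MutableMapping[tuple[int, int], SimilarityRecord] | None = None,
) -> StudyResult:
    """Run the whole per-assay analysis over a set of assays.

    Enumerates NN/NI pairs per assay, keeps assays meeting the minimum
    pair counts, scores every needed pair once, and produces per-assay and
    aggregated statistics.
    """
    have_3d = {c.cid for c in conformers}
    pairsets = {a.aid: enumerate_pairs(a, have_3d) for a in assays}
    eligible = filter_eligible(pairsets, config.stats.min_nn, config.stats.min_ni)
    pairs = needed_pairs(pairsets, eligible)
    scored = score_pairs(conformers, pairs, config, cache=records)
    by_aid = {a.aid: a for a in assays}
    per_aid = [
        per_aid_statistics(by_aid[aid], pairsets[aid], scored, config.stats) for aid in eligible
    ]
    agg = aggregate(per_aid, config.stats) if per_aid else pd.DataFrame()
    return StudyResult(
        pairsets=pairsets,
        eligible_aids=eligible,
        records=scored,
        per_aid=per_aid,
        aggregate=agg,
    )
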