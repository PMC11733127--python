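"""Combinatorial media-design engine.

Given per-modification community profiles, enumerate subsets of media
modifications (up to ``max_size`` members), score each candidate
combination with three quantities —

* ``MRA_target``: mean relative abundance of the target across the
  combination's modifications,
* ``MRA_total``: 1/n times the sum of per-feature mean relative
  abundances over the union of features detected in the combination
  (the printed form of the published score; note the extra 1/n), and
* ``R_target/total = MRA_target / MRA_total``

— then rank by highest ratio, then fewest detected features m, then
highest ``MRA_target``, with a lexicographic residual tie-break, and
retain the top N.  Enumeration is lazy and memory-bounded (chunked
scoring into a bounded best-N selection), so full searches over tens
of millions of subsets stream in constant memory.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataValueError, UsageError
from .tables_io import BASE_MODIFICATION, AbundanceTable
from .diversity import DEFAULT_FLOOR

logger = logging.getLogger(__name__)

DEFAULT_MAX_SIZE = 6
DEFAULT_TOP_N = 20
_CHUNK = 2048


@dataclass(frozen=True)
class TargetSpec:
    """A design target: a set of mOTU ids or a set of KO ids."""

    kind: str  # "taxon" | "function"
    ids: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("taxon", "function"):
            raise UsageError(f"target kind must be 'taxon' or 'function', got {self.kind!r}")
        if not self.ids:
            raise UsageError("target id set must be non-empty")


@dataclass(frozen=True)
class CombinationScore:
    """Scores for one media combination (one donor or pooled)."""

    modifications: tuple[str, ...]
    n: int
    mra_target: float
    m: int
    mra_total: float
    ratio: float  # NaN when mra_total == 0
    donor_id: str = "pooled"

    def sort_key(self) -> tuple:
        ratio = self.ratio if not math.isnan(self.ratio) else -math.inf
        return (-ratio, self.m, -self.mra_target, self.modifications)


@dataclass
class DesignReport:
    """Ranked combinations for a target, per donor and pooled."""

    target: TargetSpec
    ranked: list[CombinationScore]
    per_donor: dict[str, list[CombinationScore]]
    candidate_pool: list[str]
    n_evaluated: int
    co_occurrence: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "donor_id": s.donor_id,
                "rank": i + 1,
                "modifications": "+".join(s.modifications),
                "n": s.n,
                "m": s.m,
                "mra_target": s.mra_target,
                "mra_total": s.mra_total,
                "ratio": s.ratio,
            }
            for donor_scores in (
                [("pooled", self.ranked)] + sorted(self.per_donor.items())
            )
            for i, s in enumerate(donor_scores[1])
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# target abundance
# ---------------------------------------------------------------------------

def target_abundance(table: AbundanceTable, target: TargetSpec) -> pd.Series:
    """Per-sample summed relative abundance of the target ids."""
    present = [t for t in sorted(target.ids) if t in table.data.columns]
    if not present:
        raise UsageError(
            f"none of the target ids are in the table: {sorted(target.ids)[:10]}"
        )
    return table.data[present].sum(axis=1)


# ---------------------------------------------------------------------------
# per-modification profile matrices
# ---------------------------------------------------------------------------

def _modification_matrix(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    donor: str,
    modifications: Sequence[str],
) -> pd.DataFrame:
    """Modifications x features abundance for one donor or pooled.

    Pooled mode averages donor fractions per modification.
    """
    culture = metadata[metadata["sample_type"] == "culture"]
    rows = {}
    for mod in modifications:
        if donor == "pooled":
            sel = culture.index[culture["modification_id"] == mod]
        else:
            sel = culture.index[
                (culture["modification_id"] == mod)
                & (culture["donor_id"] == donor)
            ]
        if len(sel) == 0:
            raise UsageError(
                f"missing sample for modification {mod!r}"
                + ("" if donor == "pooled" else f" (donor {donor})")
            )
        rows[mod] = table.data.loc[sel].mean(axis=0).to_numpy(dtype=float)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = table.data.columns
    return frame


def _score_rows(
    matrix: np.ndarray,
    target_cols: np.ndarray,
    combo_idx: np.ndarray,
    detection_threshold: float,
    total_prefactor: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized scores for a chunk of combinations.

    ``combo_idx`` is (C, k) row indices into ``matrix``; returns
    (mra_target, m, mra_total, ratio) arrays of length C.
    """
    sub = matrix[combo_idx]  # (C, k, F)
    colmeans = sub.mean(axis=1)  # (C, F)
    detected = (sub > detection_threshold).any(axis=1)  # (C, F)
    k = combo_idx.shape[1]
    m = detected.sum(axis=1)
    mra_target = colmeans[:, target_cols].sum(axis=1)
    total = (colmeans * detected).sum(axis=1)
    if total_prefactor:
        total = total / k
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total > 0, mra_target / total, np.nan)
    return mra_target, m, total, ratio


def score_combination(
    combo: Iterable[str],
    table: AbundanceTable,
    metadata: pd.DataFrame,
    target: TargetSpec,
    donor: str = "pooled",
    detection_threshold: float = 0.0,
    total_prefactor: bool = True,
) -> CombinationScore:
    """Score one combination of modifications for one donor (or pooled).

    ``total_prefactor=True`` applies the published 1/n factor in
    ``MRA_total``; under per-sample closure this makes
    ``MRA_total ~ 1/n`` and the ratio ~ n x ``MRA_target``, which
    favors larger combinations where the target persists.  Set it to
    ``False`` for the plain mean-of-means variant.
    """
    mods = tuple(sorted(set(combo)))
    if not mods:
        raise UsageError("combination must contain at least one modification")
    matrix = _modification_matrix(table, metadata, donor, mods)
    target_cols = np.array(
        [i for i, f in enumerate(matrix.columns) if f in target.ids], dtype=int
    )
    if len(target_cols) == 0:
        raise UsageError(
            f"no target id present in table: {sorted(target.ids)[:10]}"
        )
    idx = np.arange(len(mods))[None, :]
    mra_t, m, total, ratio = _score_rows(
        matrix.to_numpy(), target_cols, idx, detection_threshold, total_prefactor
    )
    return CombinationScore(
        modifications=mods,
        n=len(mods),
        mra_target=float(mra_t[0]),
        m=int(m[0]),
        mra_total=float(total[0]),
        ratio=float(ratio[0]),
        donor_id=donor,
    )


def count_combinations(n_modifications: int, max_size: int) -> int:
    """Number of non-empty subsets of size <= max_size (exact integer)."""
    if not 1 <= max_size <= n_modifications:
        raise UsageError("need 1 <= max_size <= n_modifications")
    return sum(math.comb(n_modifications, k) for k in range(1, max_size + 1))


def _rank_pool(
    matrix: pd.DataFrame,
    target_cols: np.ndarray,
    pool: list[str],
    max_size: int,
    top_n: int,
    detection_threshold: float,
    total_prefactor: bool,
    donor: str,
) -> tuple[list[CombinationScore], int]:
    """Stream all subsets of ``pool`` up to ``max_size``; keep best N."""
    values = matrix.to_numpy()
    row_of = {mod: i for i, mod in enumerate(matrix.index)}
    best: list[tuple] = []  # (sort_key, CombinationScore)
    evaluated = 0
    for k in range(1, min(max_size, len(pool)) + 1):
        combos = itertools.combinations(sorted(pool), k)
        while True:
            chunk = list(itertools.islice(combos, _CHUNK))
            if not chunk:
                break
            idx = np.array(
                [[row_of[m] for m in combo] for combo in chunk], dtype=int
            )
            mra_t, m_arr, total, ratio = _score_rows(
                values, target_cols, idx, detection_threshold, total_prefactor
            )
            evaluated += len(chunk)
            for c, combo in enumerate(chunk):
                score = CombinationScore(
                    modifications=combo,
                    n=k,
                    mra_target=float(mra_t[c]),
                    m=int(m_arr[c]),
                    mra_total=float(total[c]),
                    ratio=float(ratio[c]),
                    donor_id=donor,
                )
                best.append((score.sort_key(), score))
            best = heapq.nsmallest(top_n, best, key=lambda t: t[0])
    return [s for _, s in sorted(best, key=lambda t: t[0])], evaluated


def rank_combinations(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    target: TargetSpec,
    max_size: int = DEFAULT_MAX_SIZE,
    top_n: int = DEFAULT_TOP_N,
    prune: bool = True,
    per_donor: bool = True,
    detection_threshold: float = 0.0,
    total_prefactor: bool = True,
) -> DesignReport:
    """Rank media-modification combinations for a target.

    Ordering: highest ratio, then fewest detected features m, then
    highest ``MRA_target``, then lexicographic modification tuple.
    With ``prune=True`` (default) the candidate pool is restricted to
    modifications where the target is detected in at least one donor
    — mirroring designs that combine exactly the media a target grew
    on, and keeping the search desk-scale.  ``prune=False`` streams
    the full subset enumeration in constant memory.
    """
    if max_size < 1 or top_n < 1:
        raise UsageError("max_size and top_n must be >= 1")
    if table.mode == "counts":
        raise UsageError("rank_combinations requires fractions; close first")
    culture = metadata[metadata["sample_type"] == "culture"]
    if culture.empty:
        raise UsageError("no culture samples in metadata")
    all_mods = sorted(
        m for m in culture["modification_id"].unique() if m != BASE_MODIFICATION
    )
    donors = sorted(culture["donor_id"].unique())

    target_cols_tbl = [f for f in table.data.columns if f in target.ids]
    if not target_cols_tbl:
        raise UsageError(
            f"no target id present in table: {sorted(target.ids)[:10]}"
        )

    if prune:
        abund = target_abundance(table, target)
        pool = sorted(
            {
                mod
                for mod in all_mods
                for sid in culture.index[culture["modification_id"] == mod]
                if abund[sid] > detection_threshold
            }
        )
        if not pool:
            raise UsageError(
                "target undetected in all single modifications; "
                "nothing to combine (try prune=False)"
            )
    else:
        pool = all_mods
    logger.info(
        "candidate pool: %d modification(s); evaluating up to %d combinations",
        len(pool),
        count_combinations(len(pool), min(max_size, len(pool))),
    )

    def run(donor: str) -> tuple[list[CombinationScore], int]:
        matrix = _modification_matrix(table, metadata, donor, pool)
        tcols = np.array(
            [i for i, f in enumerate(matrix.columns) if f in target.ids],
            dtype=int,
        )
        return _rank_pool(
            matrix, tcols, pool, max_size, top_n,
            detection_threshold, total_prefactor, donor,
        )

    ranked, n_eval = run("pooled")
    per_donor_ranks: dict[str, list[CombinationScore]] = {}
    if per_donor:
        for donor in donors:
            per_donor_ranks[donor], _ = run(donor)
    logger.info("evaluated %d combination(s) (pooled pass)", n_eval)

    co = _co_occurrence(ranked + [s for r in per_donor_ranks.values() for s in r], pool)
    return DesignReport(
        target=target,
        ranked=ranked,
        per_donor=per_donor_ranks,
        candidate_pool=pool,
        n_evaluated=n_eval,
        co_occurrence=co,
    )


def _co_occurrence(scores: list[CombinationScore], pool: list[str]) -> pd.DataFrame:
    """Counts of modification pairs across the retained combinations."""
    counts = pd.DataFrame(0, index=pool, columns=pool)
    for score in scores:
        for a, b in itertools.combinations(score.modifications, 2):
            counts.loc[a, b] += 1
            counts.loc[b, a] += 1
        for a in score.modifications:
            counts.loc[a, a] += 1
    return counts


# ---------------------------------------------------------------------------
# validation of designed combinations
# ---------------------------------------------------------------------------

def fold_change_over_base(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    target: TargetSpec,
    sample_selector: Mapping[str, str],
    floor: float = DEFAULT_FLOOR,
) -> pd.Series:
    """Per-donor target fold-change of a chosen sample over Base.

    ``sample_selector`` maps donor id to the sample id to evaluate
    (e.g. the combination-culture sample).  Both numerator and
    denominator are floored at ``floor``; donors without a Base
    sample are excluded with a warning.
    """
    abund = target_abundance(table, target)
    culture = metadata[metadata["sample_type"] == "culture"]
    out = {}
    for donor, sid in sample_selector.items():
        base_sel = culture.index[
            (culture["donor_id"] == donor)
            & (culture["modification_id"] == BASE_MODIFICATION)
        ]
        if len(base_sel) == 0:
            warnings.warn(
                f"donor {donor} has no Base sample; excluded", stacklevel=2
            )
            continue
        num = max(float(abund[sid]), floor)
        den = max(float(abund[base_sel[0]]), floor)
        out[donor] = num / den
    return pd.Series(out, name="fold_change_over_base")


def membership_spectrum(
    combo_presence: Iterable[str],
    single_presences: Mapping[str, Iterable[str]],
    combo: Sequence[str],
) -> dict[int, float]:
    """Where do a combination's features come from?

    For each feature detected in the combination culture, count in
    how many of the combination's constituent single-modification
    cultures it was also detected; return the proportion of features
    per count 0..k.  Bucket 0 holds features seen only when the
    modifications were combined.
    """
    features = set(combo_presence)
    if not features:
        raise UsageError("combination presence set is empty")
    missing = [m for m in combo if m not in single_presences]
    if missing:
        raise UsageError(f"no single-modification presence for: {missing}")
    sets = {m: set(single_presences[m]) for m in combo}
    k = len(combo)
    counts = {i: 0 for i in range(k + 1)}
    for feature in features:
        counts[sum(feature in sets[m] for m in combo)] += 1
    total = len(features)
    return {i: counts[i] / total for i in range(k + 1)}


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard index between two modification sets."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
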