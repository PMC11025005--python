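"""Body-size change across the extinction boundary.

The statistic is the percentage reduction of the median maximum body
length between the pre- and post-boundary cohorts,

    reduction_pct = (1 - median_post / median_pre) * 100,

with uncertainty from an independent bootstrap of the two cohorts (the
spread of the statistic over resampled species lists) and significance
from a two-sided Mann-Whitney U rank test. Species are the sampling unit:
one maximum length per species per cohort, which sidesteps juvenile
specimens. Negative reductions are size increases.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError, SizeRecord, StageSequence
from .traits import TraitAssignment, lookup

logger = logging.getLogger(__name__)

#: Exact Mann-Whitney enumeration is used up to this product of sample sizes.
EXACT_MWU_LIMIT = 400


@dataclass(frozen=True)
class SizeReductionResult:
    """Per-group median size reduction with bootstrap spread and rank test."""

    group: str
    median_pre: float
    median_post: float
    reduction_pct: float
    boot_sd: float
    n_pre: int
    n_post: int
    mwu_statistic: float
    mwu_p: float


def _check_sample(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DataError(f"{name} size sample is empty")
    if not np.all(arr > 0):
        raise DataError(f"{name} sizes must all be positive")
    return arr


def median_size_reduction(pre: Sequence[float], post: Sequence[float]) -> float:
    """Percent reduction of the median size from pre- to post-boundary.

    Medians use the midpoint rule for even sample sizes, on the raw mm
    scale.
    """
    pre_a = _check_sample(pre, "pre")
    post_a = _check_sample(post, "post")
    return float((1.0 - np.median(post_a) / np.median(pre_a)) * 100.0)


def bootstrap_sd(
    pre: Sequence[float],
    post: Sequence[float],
    B: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> float:
    """Bootstrap standard deviation of the median size reduction.

    Resamples the pre and post cohorts independently, with replacement and
    at their own sizes, recomputes ``reduction_pct`` per replicate, and
    returns the sample standard deviation (ddof=1) over ``B`` replicates.
    Deterministic given a seed.
    """
    if B < 2:
        raise DataError("bootstrap needs B >= 2 replicates")
    pre_a = _check_sample(pre, "pre")
    post_a = _check_sample(post, "post")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pre_meds = np.median(
        pre_a[rng.integers(0, pre_a.size, size=(B, pre_a.size))], axis=1
    )
    post_meds = np.median(
        post_a[rng.integers(0, post_a.size, size=(B, post_a.size))], axis=1
    )
    reps = (1.0 - post_meds / pre_meds) * 100.0
    return float(np.std(reps, ddof=1))


def mann_whitney_u(
    pre: Sequence[float], post: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test between the two cohorts.

    U is computed from rank sums with midranks for ties. The p-value is
    exact (full enumeration of the null permutation distribution) when
    ``n_pre * n_post <= 400`` and there are no ties, otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    pre_a = _check_sample(pre, "pre")
    post_a = _check_sample(post, "post")
    pooled = np.concatenate([pre_a, post_a])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (pre_a.size * post_a.size <= EXACT_MWU_LIMIT) and not has_ties
    res = stats.mannwhitneyu(
        pre_a,
        post_a,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def _group_rng(pipeline_seed: int | None, group: str) -> np.random.Generator:
    """Per-group substream: stable under addition/removal of other groups."""
    digest = hashlib.blake2s(group.encode("utf-8"), digest_size=4).digest()
    key = int.from_bytes(digest, "big")
    entropy = 0 if pipeline_seed is None else int(pipeline_seed)
    return np.random.default_rng(np.random.SeedSequence([entropy, key]))


def split_cohorts(
    records: Sequence[SizeRecord],
    stages: StageSequence,
    unit: str = "species",
) -> tuple[dict[str, list[float]], dict[str, list[float]]]:
    """Split size records into per-clade pre-/post-boundary size lists.

    One maximum length per sampling unit (species by default; ``"genus"``
    takes the max over a genus's species) per cohort.
    """
    if unit not in ("species", "genus"):
        raise DataError(f"sampling unit must be species or genus, got {unit!r}")
    b = stages.boundary_index
    pre: dict[str, dict[str, float]] = {}
    post: dict[str, dict[str, float]] = {}
    for r in records:
        side = pre if stages.index(r.interval) <= b else post
        key = r.species if unit == "species" else r.genus
        clade = side.setdefault(r.clade, {})
        clade[key] = max(clade.get(key, 0.0), r.max_length)
    return (
        {c: sorted(v.values()) for c, v in pre.items()},
        {c: sorted(v.values()) for c, v in post.items()},
    )


def size_selectivity_table(
    records: Sequence[SizeRecord],
    trait_table: Sequence[TraitAssignment],
    stages: StageSequence,
    group_by: str = "clade",
    B: int = 1000,
    seed: int | None = None,
    unit: str = "species",
    carbonate_only: bool = False,
    restrict: tuple[str, str] | None = None,
) -> list[SizeReductionResult]:
    """Per-group size-reduction results.

    Parameters
    ----------
    group_by
        ``"clade"``, a trait field (``"protein_group"``, ``"circulatory"``),
        or any attribute of :class:`TraitAssignment`.
    carbonate_only
        Restrict to clades with carbonate mineralogy before grouping.
    restrict
        Optional ``(trait_field, value)`` stratum filter, e.g.
        ``("protein_group", "hemocyanin")`` for the within-hemocyanin
        circulatory comparison.
    seed
        Pipeline seed; each group draws from its own deterministic
        substream, so adding a group never perturbs the others.

    Groups missing one of the two cohorts are omitted with a log entry.
    """
    pre_by_clade, post_by_clade = split_cohorts(records, stages, unit)
    clades = sorted(set(pre_by_clade) | set(post_by_clade))

    def clade_label(clade: str) -> str | None:
        t = lookup(trait_table, clade)
        if carbonate_only and not t.is_carbonate:
            return None
        if restrict is not None and getattr(t, restrict[0]) != restrict[1]:
            return None
        return clade if group_by == "clade" else str(getattr(t, group_by))

    groups: dict[str, tuple[list[float], list[float]]] = {}
    for clade in clades:
        label = clade_label(clade)
        if label is None:
            continue
        agg = groups.setdefault(label, ([], []))
        agg[0].extend(pre_by_clade.get(clade, []))
        agg[1].extend(post_by_clade.get(clade, []))

    out: list[SizeReductionResult] = []
    for label in sorted(groups):
        pre, post = groups[label]
        if not pre or not post:
            logger.warning("group %r missing a size cohort (pre=%d, post=%d); omitted",
                           label, len(pre), len(post))
            continue
        red = median_size_reduction(pre, post)
        sd = bootstrap_sd(pre, post, B=B, seed=_group_rng(seed, label))
        u, p = mann_whitney_u(pre, post)
        out.append(
            SizeReductionResult(
                group=label,
                median_pre=float(np.median(pre)),
                median_post=float(np.median(post)),
                reduction_pct=red,
                boot_sd=sd,
                n_pre=len(pre),
                n_post=len(post),
                mwu_statistic=u,
                mwu_p=p,
            )
        )
    return out


def results_to_frame(results: Sequence[SizeReductionResult]) -> pd.DataFrame:
    """Tidy DataFrame with one row per group, log10 medians included for audit."""
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "median_pre_mm": r.median_pre,
                "median_post_mm": r.median_post,
                "log10_median_pre": np.log10(r.median_pre),
                "log10_median_post": np.log10(r.median_post),
                "reduction_pct": r.reduction_pct,
                "boot_sd": r.boot_sd,
                "n_pre": r.n_pre,
                "n_post": r.n_post,
                "mwu_statistic": r.mwu_statistic,
                "mwu_p": r.mwu_p,
            }
            for r in results
        ]
    )
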