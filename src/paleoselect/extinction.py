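"""Extinction magnitudes and sampling-standardized extinction rates.

Two families of statistics are provided:

* **Proportional extinction** of a boundary cohort — the fraction of a
  group's genera with no sampled occurrences after the boundary — with
  exact (Clopper-Pearson) or Wilson binomial confidence intervals.

* **Interval rate estimators** built from occurrence-pattern counts over
  sliding windows of a multi-interval stage sequence:

  - Foote's boundary-crosser per-capita rate
    ``q_i = -ln(N_bt / (N_bt + N_bL))``, where ``N_bt`` counts taxa whose
    sampled range crosses both boundaries of interval ``i`` and ``N_bL``
    those crossing the bottom but last appearing within ``i``;
  - Alroy's three-timer rate ``mu_i = ln(2t_i / 3t_i) + ln(p_s)`` with the
    pooled sampling-completeness correction ``p_s = sum(3t) / (sum(3t) +
    sum(pt))``;
  - Alroy's gap-filler rate
    ``mu_i = ln((2t_i + pt_i) / (3t_i + pt_i + gf_i))``.

  Here ``2t_i`` counts taxa sampled in ``i-1`` and ``i``; ``3t_i`` in
  ``i-1``, ``i`` and ``i+1``; part-timers ``pt_i`` in ``i-1`` and ``i+1``
  but not ``i``; gap-fillers ``gf_i`` in ``i-1`` and ``i+2`` but not
  ``i+1``. Negative three-timer/gap-filler values are estimator noise and
  are floored at zero with a flag rather than dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .data_model import DataError, GenusSummary, StageSequence

logger = logging.getLogger(__name__)

_CI_METHODS = {"clopper_pearson": "beta", "wilson": "wilson"}


@dataclass(frozen=True)
class IntervalCounts:
    """Occurrence-pattern and boundary-crosser tallies for one interval."""

    interval: str
    two_timer_prev: int  # 2t_i: sampled in i-1 and i
    three_timer: int  # 3t_i: sampled in i-1, i, i+1
    part_timer: int  # pt_i: sampled in i-1 and i+1 but not i
    gap_filler: int | None  # gf_i: sampled in i-1 and i+2 but not i+1
    n_bt: int  # range crosses both boundaries of i
    n_bL: int  # range crosses bottom boundary, last appearance in i
    sampled_in_bin: int

    def __post_init__(self) -> None:
        for name in ("two_timer_prev", "three_timer", "part_timer", "n_bt", "n_bL", "sampled_in_bin"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be non-negative")
        if self.gap_filler is not None and self.gap_filler < 0:
            raise DataError("gap_filler must be non-negative")
        if self.three_timer > self.two_timer_prev:
            raise DataError("three_timer cannot exceed two_timer_prev")


@dataclass(frozen=True)
class ExtinctionEstimate:
    """One group-level extinction statistic."""

    group: str
    estimator: str  # proportional | per_capita | three_timer | gap_filler
    value: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_extinct: int | None = None
    n_total: int | None = None
    floored: bool = False


def binomial_ci(
    k: int, n: int, level: float = 0.95, method: str = "clopper_pearson"
) -> tuple[float, float]:
    """Binomial confidence interval for a proportion ``k/n``.

    ``clopper_pearson`` gives the exact Beta-quantile bounds; ``wilson``
    the score-inversion interval.
    """
    if n < 1:
        raise DataError("binomial_ci needs n >= 1")
    if not 0 <= k <= n:
        raise DataError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < level < 1:
        raise DataError(f"confidence level must be in (0, 1), got {level}")
    try:
        sm_method = _CI_METHODS[method]
    except KeyError:
        raise DataError(f"unknown CI method {method!r}") from None
    low, high = proportion_confint(k, n, alpha=1 - level, method=sm_method)
    return float(low), float(high)


def _grouper(group_by):
    """Return a label function over annotated GenusSummary objects."""
    if callable(group_by):
        return group_by
    if group_by == "clade":
        return lambda s: s.clade
    trait_fields = ("protein_group", "circulatory", "mineralogy", "motility", "buffered")
    if group_by in trait_fields:
        return lambda s: getattr(s.traits, group_by)
    raise DataError(f"unknown group_by {group_by!r}")


def proportional_extinction(
    summaries: Sequence[GenusSummary],
    group_by="clade",
    level: float = 0.95,
    ci_method: str = "clopper_pearson",
) -> list[ExtinctionEstimate]:
    """Per-group proportional extinction of the boundary cohort.

    Genera with undefined boundary status are excluded from both numerator
    and denominator. Groups with an empty cohort are omitted with a log
    entry rather than reported as 0/0.
    """
    label = _grouper(group_by)
    tallies: dict[str, list[int]] = {}
    for s in summaries:
        if s.extinct_at_boundary is None:
            continue
        k_n = tallies.setdefault(str(label(s)), [0, 0])
        k_n[0] += int(s.extinct_at_boundary)
        k_n[1] += 1
    all_groups = {str(label(s)) for s in summaries}
    for g in sorted(all_groups - set(tallies)):
        logger.warning("group %r has no genera with defined boundary status; omitted", g)
    out = []
    for g in sorted(tallies):
        k, n = tallies[g]
        lo, hi = binomial_ci(k, n, level, ci_method)
        out.append(
            ExtinctionEstimate(
                group=g,
                estimator="proportional",
                value=k / n,
                ci_low=lo,
                ci_high=hi,
                n_extinct=k,
                n_total=n,
            )
        )
    return out


def mean_clade_extinction(
    summaries: Sequence[GenusSummary], clades: Sequence[str]
) -> float:
    """Unweighted mean of clade-level extinction proportions.

    Multi-clade headline figures are reported as the plain average of the
    member clades' proportions, not the pooled-genus proportion.
    """
    wanted = set(clades)
    ests = [e for e in proportional_extinction(summaries, "clade") if e.group in wanted]
    missing = wanted - {e.group for e in ests}
    if missing:
        raise DataError(f"no defined-status genera for clades: {sorted(missing)}")
    return sum(e.value for e in ests) / len(ests)


def tabulate_interval_counts(
    summaries: Sequence[GenusSummary], stages: StageSequence, interval: str | int
) -> IntervalCounts:
    """Tally 2t/3t/pt/gf and boundary-crosser counts for one interval.

    Three-timer counts need intervals ``i-1 .. i+1``; the gap-filler count
    additionally needs ``i+2`` and is ``None`` when the sequence ends at
    ``i+1``. Requesting an interval without both neighbours raises.
    """
    i = interval if isinstance(interval, int) else stages.index(interval)
    if i - 1 < 0:
        raise DataError(f"no interval before {stages.names[i]!r}; counts need i-1")
    if i + 1 >= len(stages):
        raise DataError(f"no interval after {stages.names[i]!r}; counts need i+1")
    has_gf = i + 2 < len(stages)

    two_t = three_t = pt = gf = n_bt = n_bl = sampled = 0
    for s in summaries:
        idx = set(s.interval_indices(stages))
        in_prev, in_i, in_next = (i - 1 in idx), (i in idx), (i + 1 in idx)
        if in_i:
            sampled += 1
        if in_prev and in_i:
            two_t += 1
            if in_next:
                three_t += 1
        if in_prev and in_next and not in_i:
            pt += 1
        if has_gf and in_prev and (i + 2 in idx) and not in_next:
            gf += 1
        first, last = min(idx), max(idx)
        if first < i <= last:  # crosses the bottom boundary of i
            if last > i:
                n_bt += 1
            else:
                n_bl += 1
    return IntervalCounts(
        interval=stages.names[i],
        two_timer_prev=two_t,
        three_timer=three_t,
        part_timer=pt,
        gap_filler=gf if has_gf else None,
        n_bt=n_bt,
        n_bL=n_bl,
        sampled_in_bin=sampled,
    )


def per_capita_extinction(counts: IntervalCounts) -> float | None:
    """Foote's boundary-crosser rate ``q = -ln(N_bt / (N_bt + N_bL))``.

    Returns ``None`` when no taxon ranges through the interval
    (``N_bt = 0``), where the rate is undefined rather than infinite.
    """
    if counts.n_bt == 0:
        logger.warning("per-capita rate undefined at %s (N_bt = 0)", counts.interval)
        return None
    return -math.log(counts.n_bt / (counts.n_bt + counts.n_bL))


def sampling_completeness(all_counts: Sequence[IntervalCounts]) -> float:
    """Pooled three-timer sampling completeness ``p_s = S3t / (S3t + Spt)``."""
    s3t = sum(c.three_timer for c in all_counts)
    spt = sum(c.part_timer for c in all_counts)
    if s3t == 0:
        raise DataError("sampling completeness undefined: pooled three-timer count is 0")
    return s3t / (s3t + spt)


def three_timer_extinction(
    counts: IntervalCounts, p_s: float, floor: bool = True
) -> tuple[float, bool]:
    """Alroy's completeness-corrected three-timer rate.

    Returns ``(value, floored)``; a negative raw estimate is floored at 0
    and flagged.
    """
    if counts.three_timer < 1:
        raise DataError(f"three-timer rate needs 3t >= 1 at {counts.interval}")
    if not 0 < p_s <= 1:
        raise DataError(f"p_s must be in (0, 1], got {p_s}")
    raw = math.log(counts.two_timer_prev / counts.three_timer) + math.log(p_s)
    if floor and raw < 0:
        logger.info("three-timer rate %.4f < 0 at %s; floored", raw, counts.interval)
        return 0.0, True
    return raw, False


def gap_filler_extinction(counts: IntervalCounts, floor: bool = True) -> tuple[float, bool]:
    """Alroy's gap-filler rate ``ln((2t + pt) / (3t + pt + gf))``."""
    if counts.gap_filler is None:
        raise DataError(f"gap-filler count unavailable at {counts.interval} (needs i+2)")
    denom = counts.three_timer + counts.part_timer + counts.gap_filler
    if denom < 1:
        raise DataError(f"gap-filler rate needs 3t + pt + gf >= 1 at {counts.interval}")
    num = counts.two_timer_prev + counts.part_timer
    if num == 0:
        raise DataError(f"gap-filler rate undefined at {counts.interval} (2t + pt = 0)")
    raw = math.log(num / denom)
    if floor and raw < 0:
        logger.info("gap-filler rate %.4f < 0 at %s; floored", raw, counts.interval)
        return 0.0, True
    return raw, False


def interval_rates(
    summaries: Sequence[GenusSummary],
    stages: StageSequence,
    group: str = "all",
) -> pd.DataFrame:
    """Per-interval rate-estimator table over all interior intervals.

    Rows cover intervals ``1 .. len-2`` (those with both neighbours); the
    gap-filler column is NaN where ``i+2`` is missing. Requires a stage
    sequence of at least 4 intervals.
    """
    if not stages.supports_rate_estimators:
        raise DataError(
            "rate estimators need >= 4 intervals; only proportional extinction "
            f"is computable on {stages.names}"
        )
    counts = [
        tabulate_interval_counts(summaries, stages, i)
        for i in range(1, len(stages) - 1)
    ]
    p_s = sampling_completeness(counts)
    rows = []
    for c in counts:
        q = per_capita_extinction(c)
        mu3, fl3 = three_timer_extinction(c, p_s) if c.three_timer >= 1 else (None, False)
        if c.gap_filler is not None and (c.three_timer + c.part_timer + c.gap_filler) >= 1:
            mugf, flgf = gap_filler_extinction(c)
        else:
            mugf, flgf = None, False
        rows.append(
            {
                "group": group,
                "interval": c.interval,
                "two_timer": c.two_timer_prev,
                "three_timer": c.three_timer,
                "part_timer": c.part_timer,
                "gap_filler": c.gap_filler,
                "n_bt": c.n_bt,
                "n_bL": c.n_bL,
                "sampled_in_bin": c.sampled_in_bin,
                "sampling_completeness": p_s,
                "per_capita": q,
                "three_timer_rate": mu3,
                "three_timer_floored": fl3,
                "gap_filler_rate": mugf,
                "gap_filler_floored": flgf,
            }
        )
    return pd.DataFrame(rows)


#: The stratified comparison designs: (stratum filter field, value, bin field).
STRATA_DESIGNS: Mapping[str, tuple[str, str, str]] = {
    "hemocyanin_by_circulatory": ("protein_group", "hemocyanin", "circulatory"),
    "open_circulatory_by_protein": ("circulatory", "open", "protein_group"),
}


def stratified_comparison(
    summaries: Sequence[GenusSummary],
    design: str,
    level: float = 0.95,
    ci_method: str = "clopper_pearson",
) -> list[ExtinctionEstimate]:
    """Pooled proportional extinction within a trait stratum.

    ``"hemocyanin_by_circulatory"`` compares open- vs closed-circulatory
    bins inside the hemocyanin group (open = ostracods, gastropods,
    protobranch bivalves; closed = cephalopods under the default table).
    ``"open_circulatory_by_protein"`` compares the hemerythrin, hemocyanin
    and hemoglobin bins inside the open-circulatory group. Empty bins are
    omitted with a log entry.
    """
    try:
        filt_field, filt_value, bin_field = STRATA_DESIGNS[design]
    except KeyError:
        raise DataError(
            f"unknown stratified design {design!r}; options: {sorted(STRATA_DESIGNS)}"
        ) from None
    subset = [s for s in summaries if getattr(s.traits, filt_field) == filt_value]
    if not subset:
        logger.warning("stratified design %s: stratum is empty", design)
        return []
    return proportional_extinction(subset, group_by=bin_field, level=level, ci_method=ci_method)


def estimates_to_frame(estimates: Sequence[ExtinctionEstimate]) -> pd.DataFrame:
    """Tidy DataFrame (group, estimator, value, ci_low, ci_high, n_extinct, n_total)."""
    return pd.DataFrame(
        [
            {
                "group": e.group,
                "estimator": e.estimator,
                "value": e.value,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_extinct": e.n_extinct,
                "n_total": e.n_total,
            }
            for e in estimates
        ]
    )
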