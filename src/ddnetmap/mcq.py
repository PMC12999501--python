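"""Hyperbolic discounting-rate (k) scoring for the 27-item Monetary
Choice Questionnaire.

Each item offers a smaller immediate amount ``A_imm`` now versus a larger
delayed amount ``A_del`` after ``D`` days.  Under hyperbolic discounting
``V = A / (1 + k D)`` the two options are equally valued at the item's
implied rate ``k* = (A_del/A_imm - 1) / D``; a participant with rate k
prefers the delayed reward exactly when ``k < k*``.  Scoring follows the
standard consistency-maximization convention: per reward-magnitude bin,
the estimate is the geometric mean of every candidate rate achieving the
maximal fraction of choices consistent with the hyperbolic prediction,
and the overall k is the geometric mean across bins.  All downstream
analysis uses log10(k); larger k means steeper discounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

__all__ = [
    "MCQItem",
    "ChoiceProfile",
    "DiscountResult",
    "QCThresholds",
    "implied_k",
    "candidate_grid",
    "consistency_at_k",
    "estimate_k",
    "qc_flags",
    "score_cohort",
    "default_item_bank",
    "DiscountModel",
    "DiscountResults",
]

MISSING = -1  # sentinel for a missing response in a choice vector


@dataclass(frozen=True)
class MCQItem:
    """One questionnaire item: immediate amount now vs delayed amount later."""

    item_id: str
    immediate_amount: float
    delayed_amount: float
    delay_days: int
    magnitude_bin: str = "all"

    def __post_init__(self):
        if self.immediate_amount <= 0 or self.delayed_amount <= 0:
            raise ParameterError(f"item {self.item_id}: amounts must be positive")
        if self.delayed_amount <= self.immediate_amount:
            raise ParameterError(f"item {self.item_id}: delayed amount must exceed immediate")
        if self.delay_days < 1:
            raise ParameterError(f"item {self.item_id}: delay must be >= 1 day")


@dataclass
class ChoiceProfile:
    """Binary choice vector aligned to an item bank (1 = delayed chosen)."""

    participant_id: str
    choices: list[int]  # entries in {0, 1, MISSING}

    @property
    def n_missing(self) -> int:
        return sum(1 for c in self.choices if c == MISSING)


@dataclass
class DiscountResult:
    """Per-participant discounting estimates and QC outcome."""

    participant_id: str
    k_by_bin: dict[str, float]
    k_overall: float
    log10_k: float
    consistency: float
    qc_pass: bool
    qc_reasons: list[str] = field(default_factory=list)


@dataclass
class QCThresholds:
    min_consistency: float = 0.75
    max_missing: int = 0
    flag_uniform: bool = True


def implied_k(item: MCQItem) -> float:
    """Rate at which the item's two options have equal hyperbolic value."""
    return (item.delayed_amount / item.immediate_amount - 1.0) / item.delay_days


def candidate_grid(items) -> np.ndarray:
    """Decision-relevant candidate rates for an item bank.

    Geometric midpoints between consecutive distinct implied-k values,
    plus one candidate below the minimum and one above the maximum
    (mirrored geometrically from the nearest midpoint).  These are the
    only rates at which predicted choice patterns change.
    """
    raw = np.array(sorted({implied_k(it) for it in items}))
    if raw.size == 0:
        raise ParameterError("empty item bank")
    # collapse values that are equal up to float rounding (items designed
    # to share a rate can differ by ulps), else degenerate midpoints arise
    ks = [raw[0]]
    for v in raw[1:]:
        if v / ks[-1] > 1 + 1e-9:
            ks.append(v)
    ks = np.array(ks)
    if ks.size == 1:
        return np.array([ks[0] / 2.0, ks[0] * 2.0])
    mids = np.sqrt(ks[:-1] * ks[1:])
    below = ks[0] ** 2 / mids[0]
    above = ks[-1] ** 2 / mids[-1]
    return np.concatenate([[below], mids, [above]])


def consistency_at_k(profile: ChoiceProfile, items, k: float) -> float:
    """Fraction of answered items whose choice matches the hyperbolic
    prediction at rate ``k`` (delayed iff implied_k > k; an item exactly
    at indifference counts as consistent either way)."""
    if len(profile.choices) != len(items):
        raise FormatError(f"profile {profile.participant_id}: "
                          f"{len(profile.choices)} choices for {len(items)} items")
    n_ok = 0
    n_ans = 0
    for choice, item in zip(profile.choices, items):
        if choice == MISSING:
            continue
        n_ans += 1
        ik = implied_k(item)
        if ik == k or choice == int(ik > k):
            n_ok += 1
    if n_ans == 0:
        raise ParameterError(f"profile {profile.participant_id}: all responses missing")
    return n_ok / n_ans


def _geomean(x) -> float:
    return float(np.exp(np.mean(np.log(np.asarray(x, dtype=float)))))


def estimate_k(profile: ChoiceProfile, items, grid=None) -> DiscountResult:
    """Consistency-maximization estimate of k.

    Per magnitude bin, all grid candidates achieving maximal consistency
    on that bin's items are combined by geometric mean (the classic
    per-magnitude convention).  The overall k is estimated the same way
    from the overall response pattern, i.e. the geometric mean of the
    candidates maximizing consistency across *all* answered items; on
    the decision-relevant grid this pins a noiseless chooser to its true
    interval exactly.  Deterministic; QC fields are filled by
    :func:`qc_flags` afterwards.
    """
    items = list(items)
    grid = candidate_grid(items) if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ParameterError("empty candidate grid")
    grid = np.sort(grid)
    bins: dict[str, list[int]] = {}
    for i, it in enumerate(items):
        bins.setdefault(it.magnitude_bin, []).append(i)
    k_by_bin: dict[str, float] = {}
    for bin_name, idx in bins.items():
        sub_items = [items[i] for i in idx]
        sub_choices = [profile.choices[i] for i in idx]
        if all(c == MISSING for c in sub_choices):
            continue  # bin unanswered; excluded from the overall geomean
        sub = ChoiceProfile(profile.participant_id, sub_choices)
        cons = np.array([consistency_at_k(sub, sub_items, k) for k in grid])
        best = grid[cons == cons.max()]
        k_by_bin[bin_name] = _geomean(best)
    if not k_by_bin:
        raise ParameterError(f"profile {profile.participant_id}: all responses missing")
    cons_all = np.array([consistency_at_k(profile, items, k) for k in grid])
    k_overall = _geomean(grid[cons_all == cons_all.max()])
    reasons = []
    answered = [c for c in profile.choices if c != MISSING]
    # boundary convention: an always-delayed (always-immediate) chooser is
    # only bounded by the grid, so the estimate is pinned to its extreme
    if answered and all(c == 1 for c in answered):
        reasons.append("floor_estimate")
        k_by_bin = {b: float(grid[0]) for b in k_by_bin}
        k_overall = float(grid[0])
    if answered and all(c == 0 for c in answered):
        reasons.append("ceiling_estimate")
        k_by_bin = {b: float(grid[-1]) for b in k_by_bin}
        k_overall = float(grid[-1])
    return DiscountResult(
        participant_id=profile.participant_id,
        k_by_bin=k_by_bin,
        k_overall=k_overall,
        log10_k=float(np.log10(k_overall)),
        consistency=consistency_at_k(profile, items, k_overall),
        qc_pass=True,
        qc_reasons=reasons,
    )


def qc_flags(profile: ChoiceProfile, result: DiscountResult,
             thresholds: QCThresholds | None = None) -> tuple[bool, list[str]]:
    """Exclusion flags for low concordance, missingness and uniform responding."""
    thr = thresholds or QCThresholds()
    reasons = list(result.qc_reasons)
    if result.consistency < thr.min_consistency:
        reasons.append("low_concordance")
    if profile.n_missing > thr.max_missing:
        reasons.append("excess_missing")
    answered = [c for c in profile.choices if c != MISSING]
    if thr.flag_uniform and answered and len(set(answered)) == 1 and profile.n_missing == 0:
        reasons.append("uniform_response")
    failing = {"low_concordance", "excess_missing", "uniform_response"}
    qc_pass = not (set(reasons) & failing)
    return qc_pass, reasons


def score_cohort(choice_matrix: pd.DataFrame, items,
                 thresholds: QCThresholds | None = None,
                 grid=None) -> pd.DataFrame:
    """Score every participant row of a choice matrix.

    ``choice_matrix`` has a ``participant_id`` column followed by one
    column per item (0 = immediate, 1 = delayed, blank/NA = missing).
    QC-failed participants are retained with ``qc_pass = False``.
    """
    items = list(items)
    if "participant_id" not in choice_matrix.columns:
        raise FormatError("choice matrix must have a participant_id column")
    item_cols = [c for c in choice_matrix.columns if c != "participant_id"]
    if len(item_cols) != len(items):
        raise FormatError(f"choice matrix has {len(item_cols)} item columns "
                          f"for {len(items)} items")
    grid = candidate_grid(items) if grid is None else grid
    bin_names = sorted({it.magnitude_bin for it in items})
    rows = []
    for rix, row in choice_matrix.iterrows():
        vals = []
        for c in item_cols:
            v = row[c]
            if pd.isna(v) or v == "":
                vals.append(MISSING)
            elif int(v) in (0, 1):
                vals.append(int(v))
            else:
                raise FormatError(f"row {rix} (participant {row['participant_id']}): "
                                  f"bad choice value {v!r}")
        profile = ChoiceProfile(str(row["participant_id"]), vals)
        res = estimate_k(profile, items, grid)
        res.qc_pass, res.qc_reasons = qc_flags(profile, res, thresholds)
        out = {"participant_id": res.participant_id}
        for b in bin_names:
            out[f"k_{b}"] = res.k_by_bin.get(b, np.nan)
        out.update(
            k_overall=res.k_overall,
            log10_k=res.log10_k,
            consistency=res.consistency,
            qc_pass=res.qc_pass,
            qc_reasons=";".join(res.qc_reasons),
        )
        rows.append(out)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# model / results wrapper
# ----------------------------------------------------------------------

class DiscountModel:
    """Cohort-level discounting model over an item bank.

    ``fit()`` scores every participant and returns :class:`DiscountResults`
    with the per-participant table, exclusion counts and a summary.
    """

    def __init__(self, choice_matrix: pd.DataFrame, items=None,
                 thresholds: QCThresholds | None = None):
        self.choice_matrix = choice_matrix
        self.items = list(items) if items is not None else default_item_bank()
        self.thresholds = thresholds or QCThresholds()

    def fit(self) -> "DiscountResults":
        table = score_cohort(self.choice_matrix, self.items, self.thresholds)
        return DiscountResults(self, table)


@dataclass
class DiscountResults:
    model: DiscountModel
    table: pd.DataFrame

    @property
    def n_excluded(self) -> int:
        return int((~self.table["qc_pass"]).sum())

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        for c in df.columns:
            if df[c].dtype == float:
                df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:.10g}")
        df.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        ok = self.table[self.table["qc_pass"]]
        lines = [
            "MCQ discounting results",
            "=======================",
            f"participants: {len(self.table)}   qc-passing: {len(ok)}   "
            f"excluded: {self.n_excluded}",
        ]
        if len(ok):
            lines += [
                f"log10(k): mean {ok['log10_k'].mean():.3f}  "
                f"sd {ok['log10_k'].std(ddof=1):.3f}  "
                f"range [{ok['log10_k'].min():.3f}, {ok['log10_k'].max():.3f}]",
                f"median consistency: {ok['consistency'].median():.3f}",
            ]
        reasons = self.table.loc[~self.table["qc_pass"], "qc_reasons"]
        if len(reasons):
            counts = pd.Series(
                [r for rs in reasons for r in rs.split(";") if r]).value_counts()
            lines.append("exclusion reasons: " +
                         ", ".join(f"{k}={v}" for k, v in counts.items()))
        return "\n".join(lines)


# ----------------------------------------------------------------------
# default item bank
# ----------------------------------------------------------------------

# The canonical 27-item monetary choice questionnaire: immediate amount,
# delayed amount, delay in days.  Implied rates span 1.6e-4 to 0.25 on a
# geometric ladder, with 9 items in each reward-magnitude bin (small:
# delayed $25-35, medium: $50-60, large: $75-85).
_ITEMS = [
    (1, 54, 55, 117), (2, 55, 75, 61), (3, 19, 25, 53), (4, 31, 85, 7),
    (5, 14, 25, 19), (6, 47, 50, 160), (7, 15, 35, 13), (8, 25, 60, 14),
    (9, 78, 80, 162), (10, 40, 55, 62), (11, 11, 30, 7), (12, 67, 75, 119),
    (13, 34, 35, 186), (14, 27, 50, 21), (15, 69, 85, 91), (16, 49, 60, 89),
    (17, 80, 85, 157), (18, 24, 35, 29), (19, 33, 80, 14), (20, 28, 30, 179),
    (21, 34, 50, 30), (22, 25, 30, 80), (23, 41, 75, 20), (24, 54, 60, 111),
    (25, 54, 80, 30), (26, 22, 25, 136), (27, 20, 55, 7),
]


def _magnitude_bin(delayed_amount: float) -> str:
    if delayed_amount <= 35:
        return "small"
    if delayed_amount <= 60:
        return "medium"
    return "large"


def default_item_bank() -> list[MCQItem]:
    """The standard 27-item bank with small/medium/large magnitude bins."""
    return [
        MCQItem(str(i), float(a), float(d), int(days), _magnitude_bin(d))
        for i, a, d, days in _ITEMS
    ]


def read_items_csv(path) -> list[MCQItem]:
    """Item table CSV: item_id, immediate_amount, delayed_amount, delay_days
    and optional magnitude_bin column."""
    df = pd.read_csv(path, dtype={"item_id": str})
    required = {"item_id", "immediate_amount", "delayed_amount", "delay_days"}
    if not required <= set(df.columns):
        raise FormatError(f"item table missing columns {sorted(required - set(df.columns))}")
    items = []
    for rix, row in df.iterrows():
        try:
            items.append(MCQItem(
                str(row["item_id"]), float(row["immediate_amount"]),
                float(row["delayed_amount"]), int(row["delay_days"]),
                str(row["magnitude_bin"]) if "magnitude_bin" in df.columns else "all"))
        except (ValueError, ParameterError) as exc:
            raise FormatError(f"item table row {rix}: {exc}") from exc
    return items


def write_items_csv(items, path) -> None:
    pd.DataFrame([
        {"item_id": it.item_id, "immediate_amount": it.immediate_amount,
         "delayed_amount": it.delayed_amount, "delay_days": it.delay_days,
         "magnitude_bin": it.magnitude_bin}
        for it in items
    ]).to_csv(path, index=False)
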