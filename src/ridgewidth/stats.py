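"""Longitudinal change tables and the study's statistical toolkit.

Covers: per-position width change between timepoints (positive = loss),
descriptive aggregation across subjects, one-way ANOVA with Tukey HSD
post-hoc comparisons, intraclass correlation coefficients (Shrout-Fleiss
forms) for inter- and intra-rater reliability, Bland-Altman limits of
agreement, and a-priori sample size for a two-sample t-test from the
noncentral-t power function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import PairingError, ParameterError, StatsError
from .grid import PositionLabel
from .width import WidthMeasurement

__all__ = [
    "ChangeRecord",
    "width_change",
    "records_to_frame",
    "summarize_positions",
    "AnovaTukeyResult",
    "anova_tukey",
    "RaterStudy",
    "IccEstimate",
    "AgreementResult",
    "icc",
    "BlandAltmanResult",
    "bland_altman",
    "power_ttest_two_sample",
    "sample_size_ttest",
]


# ---------------------------------------------------------------------------
# Longitudinal change
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChangeRecord:
    """Per-position width difference between timepoints.

    ``loss_mm = width_t0 - width_t1``: positive values are resorption,
    negative values apparent gain.  ``loss_mm`` is None when either timepoint
    was unmeasurable (an explicit gap, not a fabricated zero).
    """

    scan_pair_id: str
    label: PositionLabel
    width_t0_mm: float | None
    width_t1_mm: float | None

    @property
    def loss_mm(self) -> float | None:
        if self.width_t0_mm is None or self.width_t1_mm is None:
            return None
        return self.width_t0_mm - self.width_t1_mm


def width_change(
    t0: Sequence[WidthMeasurement],
    t1: Sequence[WidthMeasurement],
    scan_pair_id: str = "pair",
) -> list[ChangeRecord]:
    """Pair baseline and follow-up measurements position by position."""
    key = lambda m: (m.label.depth_mm, m.label.offset_mm)
    t0s, t1s = sorted(t0, key=key), sorted(t1, key=key)
    if [m.label for m in t0s] != [m.label for m in t1s]:
        raise PairingError(
            f"grids do not match: {[str(m.label) for m in t0s]} vs {[str(m.label) for m in t1s]}"
        )
    return [
        ChangeRecord(scan_pair_id, a.label, a.width_mm, b.width_mm)
        for a, b in zip(t0s, t1s)
    ]


def records_to_frame(records: Sequence[ChangeRecord]) -> pd.DataFrame:
    rows = [
        {
            "scan_pair_id": r.scan_pair_id,
            "offset_mm": r.label.offset_mm,
            "depth_level": r.label.depth_name,
            "depth_mm": r.label.depth_mm,
            "width_t0_mm": np.nan if r.width_t0_mm is None else r.width_t0_mm,
            "width_t1_mm": np.nan if r.width_t1_mm is None else r.width_t1_mm,
            "loss_mm": np.nan if r.loss_mm is None else r.loss_mm,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def summarize_positions(records: Sequence[ChangeRecord]) -> pd.DataFrame:
    """Mean, SD (n-1 denominator) and n of loss per (offset, depth) cell.

    Cells with a single record report SD as NaN (undefined); empty cells are
    absent rather than fabricated.
    """
    frame = records_to_frame(records).dropna(subset=["loss_mm"])
    grouped = frame.groupby(["depth_mm", "offset_mm"])["loss_mm"]
    out = grouped.agg(mean_loss_mm="mean", sd_loss_mm=lambda s: s.std(ddof=1), n="count")
    return out.reset_index()


# ---------------------------------------------------------------------------
# One-way ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey's multiple-comparison post-hoc test (95% CI).

    Used clinically to compare loss across depth levels within a position,
    but exposed generically for any named groups.
    """
    if len(groups) < 2:
        raise StatsError(f"ANOVA needs >= 2 groups, got {len(groups)}")
    arrays = {name: np.asarray(vals, dtype=np.float64) for name, vals in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise StatsError(f"group {name!r} has {arr.size} observation(s), need >= 2")
    f_stat, p_val = sps.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[name] * arr.size for name, arr in arrays.items()])
    hsd = pairwise_tukeyhsd(values, labels, alpha=0.05)
    table = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    )
    return AnovaTukeyResult(float(f_stat), float(p_val), table)


# ---------------------------------------------------------------------------
# Reliability: ICC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RaterStudy:
    """Balanced reliability design: subjects x raters x repeats widths."""

    ratings: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.ratings, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise StatsError(f"ratings must be (subjects, raters, repeats), got shape {arr.shape}")
        if arr.shape[0] < 2:
            raise StatsError("need >= 2 subjects")
        if not np.all(np.isfinite(arr)):
            raise StatsError("ratings must be complete (balanced design)")
        object.__setattr__(self, "ratings", arr)

    @property
    def n_subjects(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]

    @property
    def n_repeats(self) -> int:
        return self.ratings.shape[2]


@dataclass(frozen=True)
class IccEstimate:
    form: str  # Shrout-Fleiss form name, e.g. "ICC2"
    estimate: float
    p_value: float


@dataclass(frozen=True)
class AgreementResult:
    """Inter-rater ICC forms plus per-rater intra-rater consistency.

    The study's "single random" raters map to ICC(2,1) (two-way random,
    absolute agreement), "single fixed" to ICC(3,1) (two-way mixed,
    consistency) and the averaged-measurement counterparts to ICC(2,k) and
    ICC(3,k).  Intra-rater reliability is the two-way consistency ICC of each
    rater's repeats.
    """

    icc_single_random: IccEstimate
    icc_single_fixed: IccEstimate
    icc_average_random: IccEstimate
    icc_average_fixed: IccEstimate
    intra_rater: dict[int, IccEstimate] = field(default_factory=dict)


def _icc_forms(matrix: np.ndarray) -> dict[str, IccEstimate]:
    """All Shrout-Fleiss forms for a complete subjects x raters matrix."""
    n, k = matrix.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": matrix.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    # pingouin labels the Shrout-Fleiss forms McGraw-Wong style:
    # single/average x (one-way, Absolute agreement, Consistency)
    naming = {
        "ICC1": "ICC(1,1)",
        "ICC2": "ICC(A,1)",
        "ICC3": "ICC(C,1)",
        "ICC1k": "ICC(1,k)",
        "ICC2k": "ICC(A,k)",
        "ICC3k": "ICC(C,k)",
    }
    out = {}
    for form, label in naming.items():
        key = label if label in table.index else form
        out[form] = IccEstimate(form, float(table.loc[key, "ICC"]), float(table.loc[key, "pval"]))
    return out


def icc(study: RaterStudy) -> AgreementResult:
    """Inter-rater ICC on per-rater mean ratings (repeats averaged per rater)
    plus intra-rater ICC per rater across repeats.

    Degenerate variance decompositions (e.g. zero between-subject variance)
    are reported as computed — ICC estimates can legitimately be <= 0.
    """
    if study.n_raters < 2:
        raise StatsError("inter-rater ICC needs >= 2 raters")
    inter = _icc_forms(study.ratings.mean(axis=2))
    intra: dict[int, IccEstimate] = {}
    if study.n_repeats >= 2:
        for r in range(study.n_raters):
            forms = _icc_forms(study.ratings[:, r, :])
            intra[r] = IccEstimate("ICC3", forms["ICC3"].estimate, forms["ICC3"].p_value)
    return AgreementResult(
        icc_single_random=inter["ICC2"],
        icc_single_fixed=inter["ICC3"],
        icc_average_random=inter["ICC2k"],
        icc_average_fixed=inter["ICC3k"],
        intra_rater=intra,
    )


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    """Paired-difference agreement: differences are rater1 - rater2.

    ``loa_upper = mean_diff + 1.96 * sd_diff`` and ``loa_lower = mean_diff -
    1.96 * sd_diff`` hold exactly.  ``outliers`` are indices strictly outside
    the limits; ``boundary`` are indices within ``epsilon`` of a limit,
    flagged separately so borderline points are visible.
    """

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray
    diffs: np.ndarray
    outliers: tuple[int, ...]
    boundary: tuple[int, ...]


def bland_altman(
    rater1: Sequence[float],
    rater2: Sequence[float],
    epsilon: float = 1e-9,
) -> BlandAltmanResult:
    """Bland-Altman agreement between two raters' paired measurements."""
    a = np.asarray(rater1, dtype=np.float64)
    b = np.asarray(rater2, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError(f"paired value arrays must match: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise StatsError("Bland-Altman needs >= 2 pairs")
    diffs = a - b
    means = (a + b) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    upper = mean_diff + 1.96 * sd_diff
    lower = mean_diff - 1.96 * sd_diff
    outliers = tuple(int(i) for i in np.nonzero((diffs > upper + epsilon) | (diffs < lower - epsilon))[0])
    boundary = tuple(
        int(i)
        for i in np.nonzero(
            (np.abs(diffs - upper) <= epsilon) | (np.abs(diffs - lower) <= epsilon)
        )[0]
        if sd_diff > 0
    )
    return BlandAltmanResult(mean_diff, sd_diff, lower, upper, means, diffs, outliers, boundary)


# ---------------------------------------------------------------------------
# A-priori sample size (two-sample t-test)
# ---------------------------------------------------------------------------

def power_ttest_two_sample(n_per_group: int, d: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of the two-sample t-test with ``n`` per group and effect size d.

    Noncentral-t formulation: df = 2n - 2, noncentrality d * sqrt(n / 2).
    """
    if n_per_group < 2:
        raise ParameterError("need n >= 2 per group")
    df = 2 * n_per_group - 2
    nc = d * np.sqrt(n_per_group / 2.0)
    if tails == 2:
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
    if tails == 1:
        tcrit = sps.t.ppf(1.0 - alpha, df)
        return float(sps.nct.sf(tcrit, df, nc))
    raise ParameterError(f"tails must be 1 or 2, got {tails}")


def sample_size_ttest(d: float, alpha: float = 0.05, power: float = 0.80, tails: int = 2) -> int:
    """Smallest n per group reaching the requested two-sample t-test power."""
    if d <= 0:
        raise ParameterError(f"effect size d must be positive, got {d}")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ParameterError("alpha and power must lie in (0, 1)")
    for n in range(2, 1_000_001):
        if power_ttest_two_sample(n, d, alpha, tails) >= power:
            return n
    raise StatsError("no n <= 1e6 reaches the requested power")
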