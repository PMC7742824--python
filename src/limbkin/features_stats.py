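"""Target-position features and group statistics.

Features are the joint angles read while the arm holds the task's target
position.  The target window is detected on the task's primary channel
(shoulder abduction for tasks 1 and 3, shoulder flexion for tasks 2 and 4)
as the longest interval of at least 0.5 s in which the channel stays
within 10 % of its repetition range below the repetition maximum; manual
windows may override the detection.  The feature value per channel is the
median over the window (robust to edge transients).

Statistics follow the clinical-study design: subjects are grouped by the
FMA-UE arm subscore (score <= 22 -> more affected group 1), per-subject
features are the mean across the three repetitions, paired Wilcoxon
signed-rank tests compare the affected and non-affected arms within a
group, and Mann-Whitney U tests compare the same arm between groups, all
two-sided at alpha = 0.05 with no multiple-testing correction.
Exact-distribution p-values are used whenever the data allow (no ties and
n <= 25); zero differences are dropped and ties get mid-ranks otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import JointAngleTrace
from .errors import NoPlateauError

ALPHA = 0.05
GROUP_SCORE_CUTOFF = 22  # FMA-UE arm subscore; <= 22 is group 1

#: primary channel used for target-window detection, per task
PRIMARY_CHANNEL = {
    1: "shoulder_abduction",
    2: "shoulder_flexion",
    3: "shoulder_abduction",
    4: "shoulder_flexion",
}

FEATURE_INDEX = ["subject", "arm", "task", "repetition"]


@dataclass(frozen=True)
class TargetWindow:
    """Held target-position interval within one task repetition, seconds."""

    start: float
    end: float

    def __post_init__(self):
        if self.end - self.start < 0.5:
            raise ValueError("target window must span at least 0.5 s")


def detect_target_window(
    trace: JointAngleTrace,
    task: int,
    min_duration: float = 0.5,
    fraction: float = 0.1,
    channel: Optional[str] = None,
) -> TargetWindow:
    """Find the target-position plateau of one repetition.

    The longest interval of at least ``min_duration`` seconds where the
    primary channel stays within ``fraction`` of the repetition range
    below its maximum.  Raises :class:`NoPlateauError` when no interval
    qualifies (e.g. a monotone ramp).
    """
    channel = channel or PRIMARY_CHANNEL[task]
    y = trace[channel]
    t = trace.time
    finite = np.isfinite(y)
    if not finite.any():
        raise NoPlateauError(f"channel {channel!r} has no valid samples")
    ymax = np.nanmax(y)
    ymin = np.nanmin(y)
    # the target is the extremum the movement reaches: the maximum for a
    # flexion/abduction-type repetition, the minimum for an extension one
    if abs(ymin) > abs(ymax):
        ok = finite & (y <= ymin + fraction * (ymax - ymin))
    else:
        ok = finite & (y >= ymax - fraction * (ymax - ymin))

    best = None
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            dur = t[i - 1] - t[start]
            if dur >= min_duration and (best is None or dur > best[2]):
                best = (start, i - 1, dur)
            start = None
    if best is None:
        raise NoPlateauError(
            f"no target plateau found on {channel!r} "
            f"(>= {min_duration} s within {fraction:.0%} of the maximum)"
        )
    return TargetWindow(float(t[best[0]]), float(t[best[1]]))


def extract_features(
    trace: JointAngleTrace, window: TargetWindow, max_missing: float = 0.5
) -> Dict[str, float]:
    """Per-channel median over the target window.

    Channels with more than ``max_missing`` of their window samples missing
    yield NaN; the others are unaffected.
    """
    m = (trace.time >= window.start) & (trace.time <= window.end)
    if not m.any():
        raise ValueError("target window outside the trace")
    out: Dict[str, float] = {}
    for name, vals in trace.angles.items():
        w = vals[m]
        missing = np.isnan(w).mean()
        out[name] = float(np.nanmedian(w)) if missing <= max_missing else math.nan
    return out


def assign_groups(scores: Mapping[str, float]) -> Dict[str, str]:
    """Impairment grouping by FMA-UE arm subscore (<= 22 -> group1)."""
    out = {}
    for subject, score in scores.items():
        if score is None or (isinstance(score, float) and math.isnan(score)):
            raise ValueError(f"missing FMA-UE arm subscore for subject {subject!r}")
        out[subject] = "group1" if score <= GROUP_SCORE_CUTOFF else "group2"
    return out


def build_feature_table(rows: Iterable[Mapping]) -> pd.DataFrame:
    """Assemble a long-format feature table.

    Each row mapping must carry ``subject``, ``arm`` ('affected' or
    'non_affected'), ``task`` (1..4), ``repetition``, ``score`` (FMA-UE arm
    subscore) and one column per joint channel (degrees).
    """
    df = pd.DataFrame(list(rows))
    missing = [c for c in FEATURE_INDEX + ["score"] if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    bad_arm = set(df["arm"]) - {"affected", "non_affected"}
    if bad_arm:
        raise ValueError(f"unknown arm labels: {sorted(bad_arm)}")
    dup = df.duplicated(subset=FEATURE_INDEX)
    if dup.any():
        raise ValueError("feature table must have one row per repetition")
    return df


def _feature_channels(table: pd.DataFrame) -> List[str]:
    reserved = set(FEATURE_INDEX) | {"score"}
    return [c for c in table.columns if c not in reserved]


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray):
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; identical samples give statistic 0 and
    p = 1 by convention.  The exact null distribution is used when the
    nonzero differences are tie-free and n <= 25, otherwise the normal
    approximation with mid-ranks.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 1.0
    ranks = np.abs(d)
    exact = d.size <= 25 and np.unique(ranks).size == ranks.size
    res = sps.wilcoxon(
        d, zero_method="wilcox", alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x: np.ndarray, y: np.ndarray):
    """Two-sided Mann-Whitney U test; exact distribution when the pooled
    sample is tie-free and small (total n <= 25)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    exact = pooled.size <= 25 and np.unique(pooled).size == pooled.size
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupComparisonResult:
    comparison: str  # 'NAF1-AF1', 'NAF2-AF2', 'NAF1-NAF2', 'AF1-AF2'
    joint: str
    task: int
    test: str  # 'wilcoxon_signed_rank' or 'mann_whitney_u'
    statistic: float
    pvalue: float
    significant: bool
    n: int
    skipped_reason: str = ""


def compare_groups(
    table: pd.DataFrame, alpha: float = ALPHA
) -> List[GroupComparisonResult]:
    """Run the four group comparisons for every joint x task.

    Features are first aggregated to one value per subject/arm/task (mean
    over repetitions).  Within-group comparisons (non-affected vs affected
    arm) are paired signed-rank tests; between-group comparisons of the
    same arm are Mann-Whitney U tests.  Comparisons with fewer than two
    subjects per side are reported as skipped.
    """
    channels = _feature_channels(table)
    agg = (
        table.groupby(["subject", "arm", "task"], as_index=False)[channels + ["score"]]
        .mean()
    )
    groups = assign_groups(
        table.groupby("subject")["score"].first().to_dict()
    )
    agg["group"] = agg["subject"].map(groups)

    results: List[GroupComparisonResult] = []
    for task in sorted(agg["task"].unique()):
        sub = agg[agg["task"] == task]
        for joint in channels:
            # paired within-group: NAF vs AF
            for gi, label in ((1, "NAF1-AF1"), (2, "NAF2-AF2")):
                g = sub[sub["group"] == f"group{gi}"]
                wide = g.pivot(index="subject", columns="arm", values=joint).dropna()
                if len(wide) < 2 or "affected" not in wide or "non_affected" not in wide:
                    results.append(GroupComparisonResult(
                        label, joint, int(task), "wilcoxon_signed_rank",
                        math.nan, math.nan, False, len(wide),
                        "fewer than 2 complete pairs",
                    ))
                    continue
                stat, p = wilcoxon_signed_rank(
                    wide["non_affected"].to_numpy(), wide["affected"].to_numpy()
                )
                results.append(GroupComparisonResult(
                    label, joint, int(task), "wilcoxon_signed_rank",
                    stat, p, bool(p < alpha), len(wide),
                ))
            # unpaired between-group: same arm, group1 vs group2
            for arm, label in (("non_affected", "NAF1-NAF2"), ("affected", "AF1-AF2")):
                a = sub[(sub["group"] == "group1") & (sub["arm"] == arm)][joint].dropna()
                b = sub[(sub["group"] == "group2") & (sub["arm"] == arm)][joint].dropna()
                if len(a) < 2 or len(b) < 2:
                    results.append(GroupComparisonResult(
                        label, joint, int(task), "mann_whitney_u",
                        math.nan, math.nan, False, len(a) + len(b),
                        "fewer than 2 subjects in a group",
                    ))
                    continue
                stat, p = mann_whitney_u(a.to_numpy(), b.to_numpy())
                results.append(GroupComparisonResult(
                    label, joint, int(task), "mann_whitney_u",
                    stat, p, bool(p < alpha), len(a) + len(b),
                ))
    return results


def comparisons_to_frame(results: List[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def null_rejection_rate(
    test: str = "wilcoxon",
    n: int = 12,
    m: int = 10,
    n_reps: int = 2000,
    alpha: float = ALPHA,
    seed: int = 0,
) -> float:
    """Empirical type-I error under the null (both samples from N(0, 1)).

    ``n`` is the number of pairs for the signed-rank test or the first
    group size for Mann-Whitney (second group size ``m``).  Sizes default
    to 12 pairs / 10 vs 10, where the exact two-sided tests can attain a
    size close to 0.05.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        if test == "wilcoxon":
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            _, p = wilcoxon_signed_rank(x, y)
        elif test == "mannwhitney":
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            _, p = mann_whitney_u(x, y)
        else:
            raise ValueError(f"unknown test {test!r}")
        rejections += p < alpha
    return rejections / n_reps
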