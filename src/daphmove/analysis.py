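"""Before/after treatment comparison: compositions and paired t-tests.

The study design is paired: each subject is recorded once before and
once after treatment, so every endpoint (per-subject mean of a movement
parameter, per-subject mean fractal dimension, per-subject percentage of
each movement pattern) is compared with a one-tailed paired-sample
t-test, d = before - after:

    t = mean(d) / (sd(d) / sqrt(n)),   df = n - 1,

with the sample standard deviation (n-1 denominator) and the tail chosen
a priori per endpoint ("greater": before exceeds after, e.g. speed and
fractal dimension; "less": after exceeds before, e.g. turning rate and
the stay pattern P6). No multiple-testing correction is applied by
default, matching the reference analysis; a Bonferroni option exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES
from .som import PATTERNS

DIRECTIONS = ("greater", "less")

#: A-priori one-tailed direction per endpoint ("greater" = before > after),
#: mirroring the signs of the reference study's reported t statistics.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "speed": "greater",
    "locomotory_rate": "greater",
    "acceleration": "greater",
    "stop_number": "less",
    "stop_time": "less",
    "turning_rate": "less",
    "meander": "less",
    "fractal_dimension": "greater",
    "P1": "greater",
    "P2": "greater",
    "P3": "greater",
    "P4": "less",
    "P5": "less",
    "P6": "less",
}


class ZeroVarianceError(ValueError):
    """All paired differences are equal; the t statistic is undefined."""


@dataclass(frozen=True)
class PatternComposition:
    """Per-pattern counts and percentages of a set of classified segments."""

    phase: str | None
    counts: dict[str, int]
    percentages: dict[str, float]
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    direction: str


def composition(labels, phase: str | None = None) -> PatternComposition:
    """Tally pattern labels into counts and percentages (zero-filled)."""
    labels = list(labels)
    if not labels:
        raise ValueError("no labels given")
    unknown = sorted(set(labels) - set(PATTERNS))
    if unknown:
        raise ValueError(f"unknown pattern labels {unknown}")
    counts = {p: 0 for p in PATTERNS}
    for lab in labels:
        counts[lab] += 1
    n = len(labels)
    percentages = {p: 100.0 * c / n for p, c in counts.items()}
    return PatternComposition(phase=phase, counts=counts, percentages=percentages, n=n)


def paired_t_test(
    before,
    after,
    direction: str = "greater",
) -> PairedTestResult:
    """One-tailed paired-sample t-test on subject-paired values.

    ``direction="greater"`` tests whether before exceeds after;
    ``"less"`` the opposite. Raises :class:`ZeroVarianceError` when all
    differences are equal.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError(
            f"before/after must be equal-length 1-D arrays, got shapes "
            f"{before.shape} and {after.shape}"
        )
    n = len(before)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = before - after
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise ZeroVarianceError(
            "all paired differences are equal; t statistic undefined"
        )
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(sps.t.sf(t, df) if direction == "greater" else sps.t.cdf(t, df))
    return PairedTestResult(t=t, df=df, p=p, direction=direction)


def _per_subject_feature_means(features: pd.DataFrame) -> pd.DataFrame:
    return features.groupby("subject_id")[list(FEATURE_NAMES)].mean()


def _per_subject_percentages(labels: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for subject, sub in labels.groupby("subject_id"):
        comp = composition(sub["pattern"])
        rows[subject] = comp.percentages
    return pd.DataFrame.from_dict(rows, orient="index")[list(PATTERNS)]


def _endpoint_entry(before: np.ndarray, after: np.ndarray, direction: str, alpha: float) -> dict:
    entry = {
        "mean_before": float(np.mean(before)),
        "sd_before": float(np.std(before, ddof=1)),
        "mean_after": float(np.mean(after)),
        "sd_after": float(np.std(after, ddof=1)),
        "direction": direction,
    }
    d = np.asarray(before, float) - np.asarray(after, float)
    if np.all(d == 0.0):
        # identical phases: no evidence of change, degenerate but well posed
        entry.update(t=0.0, df=len(d) - 1, p=0.5, significant=False)
        return entry
    res = paired_t_test(before, after, direction)
    entry.update(t=res.t, df=res.df, p=res.p, significant=bool(res.p < alpha))
    return entry


def compare_phases(
    features_before: pd.DataFrame,
    features_after: pd.DataFrame,
    fd_before: pd.DataFrame,
    fd_after: pd.DataFrame,
    labels_before: pd.DataFrame,
    labels_after: pd.DataFrame,
    alpha: float = 0.01,
    directions: dict[str, str] | None = None,
    bonferroni: bool = False,
) -> dict:
    """Full before/after report over all endpoints.

    Inputs are per-phase DataFrames: feature matrices (``subject_id`` +
    the seven parameters), fractal results (``subject_id``, ``D``), and
    pattern labels (``subject_id``, ``pattern``). All three pairs must
    cover the same subjects. Returns a JSON-serializable report dict.
    """
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    subj_sets = [
        set(df["subject_id"])
        for df in (
            features_before,
            features_after,
            fd_before,
            fd_after,
            labels_before,
            labels_after,
        )
    ]
    subjects = sorted(subj_sets[0])
    if any(s != subj_sets[0] for s in subj_sets[1:]):
        raise ValueError("before/after inputs cover different subject sets")

    feat_b = _per_subject_feature_means(features_before).loc[subjects]
    feat_a = _per_subject_feature_means(features_after).loc[subjects]
    fd_b = fd_before.groupby("subject_id")["D"].mean().loc[subjects]
    fd_a = fd_after.groupby("subject_id")["D"].mean().loc[subjects]
    pct_b = _per_subject_percentages(labels_before).loc[subjects]
    pct_a = _per_subject_percentages(labels_after).loc[subjects]

    n_tests = len(FEATURE_NAMES) + 1 + len(PATTERNS)
    level = alpha / n_tests if bonferroni else alpha

    endpoints: dict[str, dict] = {}
    for name in FEATURE_NAMES:
        endpoints[name] = _endpoint_entry(
            feat_b[name].to_numpy(), feat_a[name].to_numpy(), directions[name], level
        )
    endpoints["fractal_dimension"] = _endpoint_entry(
        fd_b.to_numpy(), fd_a.to_numpy(), directions["fractal_dimension"], level
    )
    for pat in PATTERNS:
        endpoints[pat] = _endpoint_entry(
            pct_b[pat].to_numpy(), pct_a[pat].to_numpy(), directions[pat], level
        )

    comp_b = composition(labels_before["pattern"], phase="before")
    comp_a = composition(labels_after["pattern"], phase="after")
    return {
        "n_subjects": len(subjects),
        "subjects": subjects,
        "alpha": alpha,
        "bonferroni": bonferroni,
        "endpoints": endpoints,
        "composition": {
            "before": {"counts": comp_b.counts, "percentages": comp_b.percentages},
            "after": {"counts": comp_a.counts, "percentages": comp_a.percentages},
        },
    }


def summary_text(report: dict) -> str:
    """Human-readable table of a :func:`compare_phases` report."""
    lines = [
        f"Paired comparison over {report['n_subjects']} subjects "
        f"(alpha={report['alpha']:g}"
        + (", Bonferroni-corrected)" if report["bonferroni"] else ")"),
        f"{'endpoint':<20}{'before':>12}{'after':>12}{'t':>9}{'df':>4}"
        f"{'p':>10}  sig",
    ]
    for name, e in report["endpoints"].items():
        lines.append(
            f"{name:<20}{e['mean_before']:>12.3f}{e['mean_after']:>12.3f}"
            f"{e['t']:>9.2f}{e['df']:>4d}{e['p']:>10.2e}"
            f"  {'*' if e['significant'] else ''}"
        )
    lines.append("Pattern composition (% of segments):")
    for phase in ("before", "after"):
        pct = report["composition"][phase]["percentages"]
        lines.append(
            f"  {phase:<7}"
            + "  ".join(f"{p}={pct[p]:5.1f}" for p in sorted(pct))
        )
    return "\n".join(lines)
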