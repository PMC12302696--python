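"""Cohort-level hypothesis tests and the structured feasibility report.

Reporting conventions: threshold (one-sided) tests carry a two-sided 90%
confidence interval on the mean; the paired pre/post comparison carries a
95% interval on the mean difference.  Planned tests are not multiplicity-
adjusted; secondary comparisons get a Bonferroni-adjusted alpha at the
family size actually run.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .types import CohortTestResult


def _summary(values: Optional[Sequence[float]], mean, sd, n) -> tuple[float, float, int]:
    if values is not None:
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError("need at least 2 observations")
        return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)
    if mean is None or sd is None or n is None:
        raise ValueError("provide either raw values or (mean, sd, n)")
    return float(mean), float(sd), int(n)


def one_sample_t(
    values: Optional[Sequence[float]] = None,
    *,
    mean: Optional[float] = None,
    sd: Optional[float] = None,
    n: Optional[int] = None,
    threshold: float,
    direction: str = "greater",
    ci_level: float = 0.90,
) -> CohortTestResult:
    """One-sample t test of the cohort mean against a fixed threshold.

    Accepts raw values or a (mean, sd, n) summary — the latter lets published
    rounded summaries be checked without raw data.  ``direction`` picks the
    one-sided alternative (or ``two_sided``).  The CI is the conventional
    two-sided interval on the mean at ``ci_level``.
    """
    m, s, k = _summary(values, mean, sd, n)
    if k < 2:
        raise ValueError("need at least 2 observations")
    if s <= 0:
        raise ValueError("standard deviation must be positive")
    se = s / np.sqrt(k)
    t = (m - threshold) / se
    df = k - 1
    if direction == "greater":
        p = float(sps.t.sf(t, df))
    elif direction == "less":
        p = float(sps.t.cdf(t, df))
    elif direction == "two_sided":
        p = float(2 * sps.t.sf(abs(t), df))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    half = sps.t.ppf(0.5 + ci_level / 2, df) * se
    return CohortTestResult(
        t_statistic=float(t),
        degrees_of_freedom=df,
        p_value=p,
        ci_level=ci_level,
        ci_bounds=(float(m - half), float(m + half)),
        threshold=threshold,
        direction=direction,  # type: ignore[arg-type]
        estimate=m,
    )


def paired_t(
    pre_values: Sequence[float],
    post_values: Sequence[float],
    ci_level: float = 0.95,
) -> CohortTestResult:
    """Paired t test on (post - pre) differences, two-sided by default."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    if pre.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = post - pre
    sd = diff.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(diff).max())):
        raise ValueError("differences are constant; t is undefined")
    res = one_sample_t(diff, threshold=0.0, direction="two_sided", ci_level=ci_level)
    res.threshold = None
    return res


def bonferroni_alpha(family_size: int, alpha: float = 0.05) -> float:
    """Adjusted per-test alpha for a family of secondary comparisons."""
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    return alpha / family_size


# ---------------------------------------------------------------------------
# report assembly


def _mean_sd(values: Sequence[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else None,
        "n": int(arr.size),
    }


def _maybe_test(values, threshold, direction, ci_level=0.90) -> Optional[dict]:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or arr.std(ddof=1) == 0:
        return None
    return one_sample_t(arr, threshold=threshold, direction=direction,
                        ci_level=ci_level).to_dict()


def cohort_report(
    phase_data: dict[str, dict],
    config_echo: Optional[dict] = None,
) -> dict:
    """Assemble the per-phase feasibility report as a JSON-ready dict.

    ``phase_data`` maps a phase label (e.g. ``"irf"``, ``"home"``) to a dict
    that may hold: ``compliance`` ({side: [pct, ...]}), ``pre_rates`` /
    ``post_rates`` (aligned per-participant lists), ``sus`` / ``quest``
    (score lists), ``imi`` ({subscale: [scores]}), ``quest_tally``,
    ``response_curve`` (180 slot means).  Phases with no data are marked
    absent; cohort tests are suppressed below n = 2.
    """
    report: dict = {"phases": {}}
    if config_echo is not None:
        report["config"] = config_echo
    for phase, data in sorted(phase_data.items()):
        section: dict = {}
        if not data:
            report["phases"][phase] = {"absent": True}
            continue
        if "compliance" in data:
            section["compliance"] = {
                side: {
                    **_mean_sd(vals),
                    "test_vs_90pct": _maybe_test(vals, 90.0, "greater"),
                }
                for side, vals in data["compliance"].items()
            }
        if "post_rates" in data and "pre_rates" in data:
            pre = np.asarray(data["pre_rates"], dtype=float)
            post = np.asarray(data["post_rates"], dtype=float)
            section["cue_response"] = {
                "post": _mean_sd(post),
                "pre": _mean_sd(pre),
            }
            if pre.size >= 2 and (post - pre).std(ddof=1) > 0:
                section["cue_response"]["paired_test"] = paired_t(pre, post).to_dict()
            section["cue_response"]["post_vs_90pct"] = _maybe_test(post * 100, 90.0, "greater")
        if "sus" in data:
            section["sus"] = {
                **_mean_sd(data["sus"]),
                "test_vs_68": _maybe_test(data["sus"], 68.0, "greater"),
            }
        if "quest" in data:
            section["quest"] = {
                **_mean_sd(data["quest"]),
                "test_vs_3": _maybe_test(data["quest"], 3.0, "greater"),
            }
        if "imi" in data:
            section["imi"] = {}
            for sub, vals in sorted(data["imi"].items()):
                direction = "less" if sub == "pressure_tension" else "greater"
                section["imi"][sub] = {
                    **_mean_sd(vals),
                    "test_vs_4": _maybe_test(vals, 4.0, direction),
                }
        if "quest_tally" in data:
            section["quest_importance_tally"] = dict(sorted(data["quest_tally"].items()))
        if "response_curve" in data:
            curve = np.asarray(data["response_curve"], dtype=float)
            section["response_curve"] = [
                None if np.isnan(v) else round(float(v), 6) for v in curve
            ]
        report["phases"][phase] = section if section else {"absent": True}
    return report


def report_to_json(report: dict) -> str:
    """Deterministic, byte-stable JSON rendering of a report."""
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))
    return json.dumps(report, indent=2, sort_keys=True, default=_default) + "\n"


def report_to_text(report: dict) -> str:
    """Human-readable summary of the structured report."""
    lines: list[str] = []
    for phase, section in report.get("phases", {}).items():
        lines.append(f"=== phase: {phase} ===")
        if section.get("absent"):
            lines.append("  (no data)")
            continue
        comp = section.get("compliance", {})
        for side, c in comp.items():
            sd = f" +/- {c['sd']:.1f}" if c.get("sd") is not None else ""
            lines.append(f"  compliance [{side}]: {c['mean']:.1f}{sd}% (n={c['n']})")
            if c.get("test_vs_90pct"):
                t = c["test_vs_90pct"]
                lines.append(f"    vs 90%: t({t['df']}) = {t['t']:.2f}, p = {t['p']:.3g}")
        if "cue_response" in section:
            cr = section["cue_response"]
            lines.append(
                f"  post-cue response rate: {100 * cr['post']['mean']:.2f}%"
                f" | pre-cue activity rate: {100 * cr['pre']['mean']:.2f}%"
            )
            if cr.get("paired_test"):
                t = cr["paired_test"]
                lines.append(
                    f"    paired post-pre: diff = {100 * t['estimate']:.1f}%, "
                    f"t({t['df']}) = {t['t']:.3f}, p = {t['p']:.3g}"
                )
        for name, thr in (("sus", 68), ("quest", 3)):
            if name in section:
                s = section[name]
                lines.append(f"  {name.upper()}: mean {s['mean']:.1f} (n={s['n']})")
                tt = s.get(f"test_vs_{thr}")
                if tt:
                    lines.append(f"    vs {thr}: t({tt['df']}) = {tt['t']:.2f}, p = {tt['p']:.3g}")
        if "imi" in section:
            for sub, s in section["imi"].items():
                lines.append(f"  IMI {sub}: mean {s['mean']:.2f} (n={s['n']})")
        if "quest_importance_tally" in section:
            top = sorted(section["quest_importance_tally"].items(),
                         key=lambda kv: -kv[1])[:3]
            lines.append("  QUEST importance (top 3): "
                         + ", ".join(f"{k} ({v})" for k, v in top))
    return "\n".join(lines) + "\n"
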