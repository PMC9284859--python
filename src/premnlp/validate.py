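"""Validation statistics for the pipeline and the questionnaire.

Three ingredients: (1) stratified sampling plans and representativeness
rates for the human audit of topic assignments (20% of answers per
topic, minimum 10, everything if a topic holds fewer than 10); (2) the
proportion of manually identified topics matched to automatic topics;
(3) an independent-samples t-test comparing matched structured scores
(1-10) between answers classified positive and negative per question.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SamplingPlan",
    "FitJudgment",
    "GroupComparison",
    "sample_size",
    "make_sampling_plan",
    "representativeness",
    "topic_overlap",
    "compare_groups",
]


def sample_size(topic_size: int, frac: float = 0.2, min_n: int = 10) -> int:
    """Audit-sample size for a topic: all of it when smaller than
    ``min_n``, otherwise max(ceil(frac * size), min_n)."""
    if not (0.0 < frac <= 1.0):
        raise ValueError("frac must be in (0, 1]")
    if topic_size < min_n:
        return topic_size
    return max(math.ceil(frac * topic_size), min_n)


@dataclass
class SamplingPlan:
    """Per-(stratum, topic) audit samples, drawn without replacement."""

    samples: dict[tuple, list]  # (stratum_id, topic) -> doc_keys
    frac: float
    min_n: int
    seed: int


def make_sampling_plan(
    assignments: dict[tuple, dict],
    frac: float = 0.2,
    min_n: int = 10,
    seed: int = 0,
) -> SamplingPlan:
    """Draw the audit samples.

    ``assignments`` maps a stratum id (question_id, sentiment) to a
    doc_key -> topic-index map (unassigned docs, topic -1, are not
    sampled).  Deterministic given the seed.
    """
    if not (0.0 < frac <= 1.0):
        raise ValueError("frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    samples: dict[tuple, list] = {}
    for stratum_id in sorted(assignments):
        by_topic: dict[int, list] = {}
        for key in sorted(assignments[stratum_id]):
            t = assignments[stratum_id][key]
            if t < 0:
                continue
            by_topic.setdefault(t, []).append(key)
        for t in sorted(by_topic):
            members = by_topic[t]
            n = sample_size(len(members), frac, min_n)
            idx = rng.choice(len(members), size=n, replace=False)
            samples[(stratum_id, t)] = [members[i] for i in sorted(idx)]
    return SamplingPlan(samples, frac, min_n, seed)


@dataclass(frozen=True)
class FitJudgment:
    doc_key: tuple
    stratum_id: tuple
    topic: int
    judge_id: str
    fits: bool


def representativeness(
    judgments: list[FitJudgment],
    judge_id: str,
    plan: SamplingPlan | None = None,
) -> dict:
    """Fraction of audited texts the judge deemed to fit their topic.

    Rates are reported per topic, per stratum, and overall; the stratum
    and overall rates pool counts (sum of fits over sum judged), they
    are not means of per-topic rates.  If a plan is given, every planned
    (doc, topic) must be judged; gaps raise an error listing them.
    """
    mine = [j for j in judgments if j.judge_id == judge_id]
    if plan is not None:
        judged = {((j.stratum_id, j.topic), j.doc_key) for j in mine}
        gaps = [
            (st, key)
            for st, keys in plan.samples.items()
            for key in keys
            if (st, key) not in judged
        ]
        if gaps:
            raise ValueError(f"missing judgments for planned samples: {gaps[:20]}")
    per_topic_counts: dict[tuple, list[int]] = {}
    for j in mine:
        c = per_topic_counts.setdefault((j.stratum_id, j.topic), [0, 0])
        c[0] += int(j.fits)
        c[1] += 1
    per_topic = {k: f / n for k, (f, n) in per_topic_counts.items()}
    per_stratum: dict[tuple, list[int]] = {}
    for (st, _), (f, n) in per_topic_counts.items():
        c = per_stratum.setdefault(st, [0, 0])
        c[0] += f
        c[1] += n
    total_f = sum(f for f, _ in per_topic_counts.values())
    total_n = sum(n for _, n in per_topic_counts.values())
    return {
        "per_topic": per_topic,
        "per_stratum": {st: f / n for st, (f, n) in per_stratum.items()},
        "overall": total_f / total_n if total_n else float("nan"),
        "n_judged": total_n,
    }


def topic_overlap(manual_topics: list[str], matches: list[tuple[str, str]]) -> float:
    """Proportion of manual topics matched to at least one automatic topic.

    Matching itself is human input (a pairing list); duplicate matches
    of one manual topic count once.
    """
    if not manual_topics:
        raise ValueError("no manual topics")
    known = set(manual_topics)
    matched = set()
    for manual, _auto in matches:
        if manual not in known:
            raise ValueError(f"match references unknown manual topic {manual!r}")
        matched.add(manual)
    return len(matched) / len(manual_topics)


@dataclass(frozen=True)
class GroupComparison:
    """Independent-samples comparison of structured scores between the
    positive- and negative-classified groups of one question."""

    question_id: str
    n_pos: int
    n_neg: int
    mean_pos: float
    mean_neg: float
    sd_pos: float
    sd_neg: float
    t: float
    df: float
    p: float
    variant: str

    def __post_init__(self):
        assert 0.0 <= self.p <= 1.0
        assert self.df > 0
        assert self.sd_pos >= 0 and self.sd_neg >= 0


def compare_groups(
    scores_pos=None,
    scores_neg=None,
    variant: str = "pooled",
    question_id: str = "",
    summary_pos: tuple[int, float, float] | None = None,
    summary_neg: tuple[int, float, float] | None = None,
) -> GroupComparison:
    """Two-sided independent-samples t-test, pooled (Student) by default
    or Welch.

    Accepts either raw score lists or summary form (n, mean, sd) per
    group.  Pooled: sp^2 = ((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2),
    t = (m1-m2)/(sp*sqrt(1/n1+1/n2)), df = n1+n2-2.  Welch uses the
    Welch-Satterthwaite degrees of freedom.  If both groups are constant
    and equal, t = 0 and p = 1.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if summary_pos is not None and summary_neg is not None:
        n1, m1, s1 = summary_pos
        n2, m2, s2 = summary_neg
    else:
        a = np.asarray(scores_pos, dtype=float)
        b = np.asarray(scores_neg, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs >= 2 observations")
        n1, m1, s1 = len(a), float(a.mean()), float(a.std(ddof=1))
        n2, m2, s2 = len(b), float(b.mean()), float(b.std(ddof=1))
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 observations")

    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = math.sqrt(v1 + v2)
        if v1 + v2 == 0:
            df = n1 + n2 - 2
        else:
            df = (v1 + v2) ** 2 / (
                v1**2 / (n1 - 1) + v2**2 / (n2 - 1)
            )
    if se == 0.0:
        t = 0.0 if m1 == m2 else math.copysign(math.inf, m1 - m2)
        p = 1.0 if m1 == m2 else 0.0
    else:
        t = (m1 - m2) / se
        p = float(2 * stats.t.sf(abs(t), df))
    return GroupComparison(
        question_id=question_id,
        n_pos=n1,
        n_neg=n2,
        mean_pos=m1,
        mean_neg=m2,
        sd_pos=s1,
        sd_neg=s2,
        t=t,
        df=float(df),
        p=p,
        variant=variant,
    )
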