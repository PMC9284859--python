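"""Three-stage hierarchical reporting of an analysed survey.

Stage 1 gives per-question sentiment proportions (the spider-plot
view); stage 2 lists the topics per (question, sentiment) stratum with
their descriptors and answer counts; stage 3 holds the verbatim
answers behind each topic.  Percentages use the full per-question
respondent count as denominator (neutral and empty answers included),
rounded half-up to one decimal; raw counts are always carried alongside
so every displayed number can be recomputed.
"""

from __future__ import annotations

import html as html_mod
import json
import math
from dataclasses import asdict, dataclass, field

from .corpus import ResponseSet
from .sentiment import SentimentLabel

__all__ = ["Report", "build_report", "export_json", "load_json", "render_html"]

SCHEMA_VERSION = "1.0"


def pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (0.0 when total is 0)."""
    if total == 0:
        return 0.0
    return math.floor(count / total * 1000 + 0.5) / 10


@dataclass
class QuestionSummary:
    question_id: str
    n_total: int
    n_positive: int
    n_negative: int
    n_neutral: int
    n_empty: int
    pct_positive: float
    pct_negative: float

    def __post_init__(self):
        assert (
            self.n_positive + self.n_negative + self.n_neutral + self.n_empty
            == self.n_total
        )


@dataclass
class TopicEntry:
    topic: int
    descriptors: list[str]
    count: int


@dataclass
class StratumTopics:
    question_id: str
    sentiment: str
    topics: list[TopicEntry]
    n_unassigned: int
    n_docs: int

    def __post_init__(self):
        assert sum(t.count for t in self.topics) + self.n_unassigned == self.n_docs


@dataclass
class Report:
    stage1: list[QuestionSummary]
    stage2: list[StratumTopics]
    stage3: dict[str, list[dict]]  # "qid:sentiment:topic" -> verbatim answers
    manifest: dict = field(default_factory=dict)


def _stage3_key(question_id: str, sentiment: str, topic: int) -> str:
    return f"{question_id}:{sentiment}:{topic}"


def build_report(
    responses: ResponseSet,
    labels: dict[tuple[str, str], SentimentLabel],
    topic_results: list,
    manifest: dict | None = None,
) -> Report:
    """Assemble the three-stage report.

    ``labels`` must cover every response and each topic-model result's
    assignments must cover its whole stratum; gaps raise an error that
    lists the missing keys.
    """
    missing = [r.key for r in responses if r.key not in labels]
    if missing:
        raise ValueError(f"sentiment labels missing for keys: {missing[:20]}")

    stage1 = []
    for qid in responses.schema.question_ids:
        rs = responses.by_question(qid)
        n_total = len(rs)
        n_empty = sum(r.is_empty for r in rs)
        counts = {lab: 0 for lab in SentimentLabel}
        for r in rs:
            if not r.is_empty:
                counts[labels[r.key]] += 1
        stage1.append(
            QuestionSummary(
                question_id=qid,
                n_total=n_total,
                n_positive=counts[SentimentLabel.POSITIVE],
                n_negative=counts[SentimentLabel.NEGATIVE],
                n_neutral=counts[SentimentLabel.NEUTRAL],
                n_empty=n_empty,
                pct_positive=pct(counts[SentimentLabel.POSITIVE], n_total),
                pct_negative=pct(counts[SentimentLabel.NEGATIVE], n_total),
            )
        )

    by_key = {r.key: r for r in responses}
    stage2 = []
    stage3: dict[str, list[dict]] = {}
    for res in topic_results:
        st = res.stratum
        amap = res.assignment_map()
        gaps = [k for k in st.doc_keys if k not in amap]
        if gaps:
            raise ValueError(
                f"assignments missing for stratum {st.question_id}/{st.sentiment}: "
                f"{gaps[:20]}"
            )
        entries = [
            TopicEntry(topic=j, descriptors=list(res.descriptors[j]), count=c)
            for j, c in enumerate(res.topic_counts)
        ]
        entries.sort(key=lambda e: -e.count)  # stable: ties keep topic order
        stage2.append(
            StratumTopics(
                question_id=st.question_id,
                sentiment=st.sentiment,
                topics=entries,
                n_unassigned=res.n_unassigned,
                n_docs=len(st),
            )
        )
        for key in st.doc_keys:
            j = amap[key]
            if j < 0:
                continue
            stage3.setdefault(_stage3_key(st.question_id, st.sentiment, j), []).append(
                {
                    "respondent_id": key[0],
                    "question_id": key[1],
                    "text": by_key[key].text,
                }
            )
    return Report(stage1, stage2, stage3, dict(manifest or {}))


# ---------------------------------------------------------------------------
# JSON round-trip


def export_json(report: Report, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "stage1": [asdict(q) for q in report.stage1],
        "stage2": [asdict(s) for s in report.stage2],
        "stage3": report.stage3,
        "manifest": report.manifest,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False, indent=1)


def load_json(path) -> Report:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema version {payload.get('schema_version')!r}"
        )
    return Report(
        stage1=[QuestionSummary(**q) for q in payload["stage1"]],
        stage2=[
            StratumTopics(
                question_id=s["question_id"],
                sentiment=s["sentiment"],
                topics=[TopicEntry(**t) for t in s["topics"]],
                n_unassigned=s["n_unassigned"],
                n_docs=s["n_docs"],
            )
            for s in payload["stage2"]
        ],
        stage3=payload["stage3"],
        manifest=payload["manifest"],
    )


# ---------------------------------------------------------------------------
# static HTML with inline SVG spider plot


def _spider_svg(stage1: list[QuestionSummary], size: int = 360) -> str:
    """Radar chart of positive and negative percentages per question,
    both series on one 0-100% radial scale."""
    n = len(stage1)
    if n == 0:
        return "<svg/>"
    cx = cy = size / 2
    radius = size / 2 - 40
    angles = [2 * math.pi * i / n - math.pi / 2 for i in range(n)]

    def point(angle, value):
        r = radius * value / 100.0
        return (cx + r * math.cos(angle), cy + r * math.sin(angle))

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size}" '
        f'viewBox="0 0 {size} {size}">'
    ]
    for frac in (0.25, 0.5, 0.75, 1.0):
        ring = " ".join(
            f"{x:.1f},{y:.1f}" for x, y in (point(a, frac * 100) for a in angles)
        )
        parts.append(
            f'<polygon points="{ring}" fill="none" stroke="#ccc" stroke-width="1"/>'
        )
    for a, q in zip(angles, stage1):
        x, y = point(a, 100)
        parts.append(
            f'<line x1="{cx}" y1="{cy}" x2="{x:.1f}" y2="{y:.1f}" '
            'stroke="#ccc" stroke-width="1"/>'
        )
        lx, ly = point(a, 118)
        parts.append(
            f'<text x="{lx:.1f}" y="{ly:.1f}" text-anchor="middle" '
            f'font-size="12">{html_mod.escape(q.question_id)}</text>'
        )
    for attr, color, series in (
        ("pct_positive", "#2a7e43", "positive"),
        ("pct_negative", "#b03a2e", "negative"),
    ):
        pts = " ".join(
            f"{x:.1f},{y:.1f}"
            for x, y in (point(a, getattr(q, attr)) for a, q in zip(angles, stage1))
        )
        parts.append(
            f'<polygon points="{pts}" fill="{color}" fill-opacity="0.25" '
            f'stroke="{color}" stroke-width="2"><title>{series}</title></polygon>'
        )
    parts.append("</svg>")
    return "".join(parts)


def render_html(report: Report, path) -> None:
    """Write a static drill-down page: spider plot, per-stratum topic
    panels, and per-topic verbatim answer lists (details/summary)."""
    esc = html_mod.escape
    rows = "".join(
        f"<tr><td>{esc(q.question_id)}</td><td>{q.n_total}</td>"
        f"<td>{q.n_positive} ({q.pct_positive}%)</td>"
        f"<td>{q.n_negative} ({q.pct_negative}%)</td>"
        f"<td>{q.n_neutral}</td><td>{q.n_empty}</td></tr>"
        for q in report.stage1
    )
    panels = []
    for s in report.stage2:
        topic_blocks = []
        for t in s.topics:
            key = _stage3_key(s.question_id, s.sentiment, t.topic)
            texts = report.stage3.get(key, [])
            verbatims = "".join(
                f"<li>{esc(v['text'])} <small>({esc(v['respondent_id'])})</small></li>"
                for v in texts
            )
            topic_blocks.append(
                f"<details><summary>Topic {t.topic} (n={t.count}): "
                f"{esc(', '.join(t.descriptors) or '-')}</summary>"
                f"<ul>{verbatims}</ul></details>"
            )
        panels.append(
            f'<details class="stratum {esc(s.sentiment)}">'
            f"<summary>{esc(s.question_id)} — {esc(s.sentiment)} "
            f"({s.n_docs} answers, {s.n_unassigned} unassigned)</summary>"
            f"{''.join(topic_blocks)}</details>"
        )
    doc = f"""<!DOCTYPE html>
<html lang="en"><head><meta charset="utf-8">
<title>Open-ended survey report</title>
<style>
 body {{ font-family: sans-serif; max-width: 60em; margin: 2em auto; }}
 table {{ border-collapse: collapse; }} td, th {{ border: 1px solid #999; padding: .3em .6em; }}
 details {{ margin: .4em 0 .4em 1em; }}
 .positive > summary {{ color: #2a7e43; }} .negative > summary {{ color: #b03a2e; }}
 footer {{ color: #777; font-size: .8em; margin-top: 2em; }}
</style></head><body>
<h1>Open-ended survey report</h1>
<h2>Stage 1 — sentiment per question</h2>
{_spider_svg(report.stage1)}
<table><tr><th>question</th><th>n</th><th>positive</th><th>negative</th>
<th>neutral</th><th>empty</th></tr>{rows}</table>
<h2>Stages 2 and 3 — topics and verbatim answers</h2>
{''.join(panels)}
<footer>Positive and negative series share one 0&ndash;100% radial scale.
Percentages are counts over all respondents of the question (neutral and
empty included), rounded half-up to one decimal.</footer>
</body></html>
"""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(doc)
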