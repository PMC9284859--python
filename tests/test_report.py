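import json
import subprocess
import sys

import numpy as np
import pytest

from premnlp.corpus import Response, ResponseSet, SurveySchema
from premnlp.pipeline import ExperienceAnalysis
from premnlp.report import build_report, export_json, load_json, pct, render_html
from premnlp.sentiment import AnnotatedResponse, SentimentLabel
from premnlp.synthetic import (
    CorpusSpec,
    corpus_embedding_spec,
    generate_corpus,
    generate_embeddings,
    generate_scores,
)


class TestPercentages:
    def test_published_style_percentages(self):
        """359 positive and 26 negative of 534 respondents give 67.2%
        and 4.9%."""
        assert pct(359, 534) == 67.2
        assert pct(26, 534) == 4.9

    def test_half_up_rounding(self):
        assert pct(1, 800) == 0.1  # 0.125 -> 0.1
        assert pct(5, 4000) == 0.1
        assert pct(15, 10000) == 0.2  # 0.15 half-up

    def test_zero_total(self):
        assert pct(0, 0) == 0.0


def tiny_labelled_survey():
    schema = SurveySchema.from_ids(["Q1", "Q2"])
    responses = []
    labels = {}
    mix = [("positive", 6), ("negative", 2), ("neutral", 1), ("empty", 1)]
    i = 0
    for qid in schema.question_ids:
        for sentiment, n in mix:
            for _ in range(n):
                rid = f"r{i}"
                i += 1
                text = "" if sentiment == "empty" else f"{sentiment} antwoord {rid}"
                responses.append(Response(rid, qid, text))
                labels[(rid, qid)] = SentimentLabel(
                    "neutral" if sentiment == "empty" else sentiment
                )
    return ResponseSet(schema, responses), labels


class TestBuildReport:
    def test_stage1_counts_and_conservation(self):
        rs, labels = tiny_labelled_survey()
        report = build_report(rs, labels, [])
        for q in report.stage1:
            assert (
                q.n_positive + q.n_negative + q.n_neutral + q.n_empty == q.n_total
            )
            assert q.pct_positive == pct(q.n_positive, q.n_total)
        assert report.stage1[0].n_positive == 6
        assert report.stage1[0].n_empty == 1

    def test_missing_labels_listed(self):
        rs, labels = tiny_labelled_survey()
        del labels[("r0", "Q1")]
        with pytest.raises(ValueError, match="r0"):
            build_report(rs, labels, [])

    def test_all_empty_question(self):
        schema = SurveySchema.from_ids(["Q1"])
        rs = ResponseSet(schema, [Response(f"r{i}", "Q1", "") for i in range(3)])
        labels = {r.key: SentimentLabel.NEUTRAL for r in rs}
        report = build_report(rs, labels, [])
        q = report.stage1[0]
        assert q.pct_positive == 0.0 and q.pct_negative == 0.0
        assert q.n_empty == 3


@pytest.fixture(scope="module")
def fitted_results():
    spec = CorpusSpec(
        schema=SurveySchema.from_ids(["Q1", "Q2"]),
        n_respondents=150,
        proportions={"positive": 0.5, "negative": 0.3, "neutral": 0.1,
                     "empty": 0.1},
        topics_per_stratum=3,
        seed=5,
    )
    responses, truth = generate_corpus(spec)
    annotated = [
        AnnotatedResponse(r.respondent_id, r.question_id, r.text,
                          SentimentLabel(truth.sentiment[r.key]))
        for r in responses
        if not r.is_empty
    ]
    embeddings = generate_embeddings(corpus_embedding_spec(spec))
    analysis = ExperienceAnalysis(
        responses, annotated, embeddings, min_df=2, k_range=range(2, 9)
    )
    results = analysis.fit(seed=5)
    return spec, truth, results


class TestPipelineReport:
    def test_cross_stage_conservation(self, fitted_results):
        """Per stratum, stage-2 topic counts + unassigned equal the
        stage-1 count for that (question, sentiment)."""
        _, _, results = fitted_results
        stage1 = {q.question_id: q for q in results.report.stage1}
        for s in results.report.stage2:
            total = sum(t.count for t in s.topics) + s.n_unassigned
            assert total == s.n_docs
            q = stage1[s.question_id]
            expected = q.n_positive if s.sentiment == "positive" else q.n_negative
            assert s.n_docs == expected

    def test_stage2_sorted_by_count(self, fitted_results):
        _, _, results = fitted_results
        for s in results.report.stage2:
            counts = [t.count for t in s.topics]
            assert counts == sorted(counts, reverse=True)

    def test_stage3_texts_unique_within_stratum(self, fitted_results):
        _, _, results = fitted_results
        for s in results.report.stage2:
            seen = set()
            for t in s.topics:
                key = f"{s.question_id}:{s.sentiment}:{t.topic}"
                for v in results.report.stage3.get(key, []):
                    k = (v["respondent_id"], v["question_id"])
                    assert k not in seen
                    seen.add(k)

    def test_json_round_trip_lossless(self, fitted_results, tmp_path):
        _, _, results = fitted_results
        p = tmp_path / "report.json"
        export_json(results.report, p)
        loaded = load_json(p)
        assert loaded.stage1 == results.report.stage1
        assert loaded.stage2 == results.report.stage2
        assert loaded.stage3 == results.report.stage3
        assert loaded.manifest == results.report.manifest

    def test_html_structure(self, fitted_results, tmp_path):
        _, _, results = fitted_results
        p = tmp_path / "report.html"
        render_html(results.report, p)
        html = p.read_text(encoding="utf-8")
        assert "<svg" in html
        for s in results.report.stage2:
            if s.topics:
                assert f"{s.question_id} — {s.sentiment}" in html

    def test_html_renders_with_no_negative_texts(self, tmp_path):
        rs, labels = tiny_labelled_survey()
        labels = {
            k: (SentimentLabel.POSITIVE if v is SentimentLabel.NEGATIVE else v)
            for k, v in labels.items()
        }
        report = build_report(rs, labels, [])
        p = tmp_path / "r.html"
        render_html(report, p)
        assert p.exists()

    def test_summary_mentions_topics(self, fitted_results):
        _, _, results = fitted_results
        text = results.summary()
        assert "selected k" in text
        assert "Stage 1" in text

    def test_score_comparison_through_results(self, fitted_results):
        spec, truth, results = fitted_results
        scores = generate_scores(truth, seed=1)
        comparisons = results.compare_scores(scores)
        assert comparisons
        for c in comparisons:
            assert c.mean_pos > c.mean_neg  # planted shift
            assert 0 <= c.p <= 1


class TestCli:
    def run_cli(self, *args):
        return subprocess.run(
            [sys.executable, "-m", "premnlp.cli", *args],
            capture_output=True,
            text=True,
        )

    def test_unknown_subcommand_exits_2(self):
        out = self.run_cli("frobnicate")
        assert out.returncode == 2
        assert "Usage" in out.stderr or "Usage" in out.stdout

    def test_simulate_deterministic(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        for out in (a, b):
            r = self.run_cli(
                "simulate", "--seed", "7", "--n-respondents", "40",
                "--out", str(out),
            )
            assert r.returncode == 0, r.stderr
        assert (a / "responses.csv").read_bytes() == (b / "responses.csv").read_bytes()
        assert (a / "embeddings.txt").read_bytes() == (b / "embeddings.txt").read_bytes()

    def test_analyze_smoke(self, tmp_path):
        sim = tmp_path / "sim"
        r = self.run_cli(
            "simulate", "--seed", "3", "--n-respondents", "60",
            "--regime", "benchmark", "--out", str(sim),
        )
        assert r.returncode == 0, r.stderr
        out = tmp_path / "out"
        r = self.run_cli(
            "analyze",
            "--responses", str(sim / "responses.csv"),
            "--annotations", str(sim / "annotations.csv"),
            "--embeddings", str(sim / "embeddings.txt"),
            "--lexicon", str(sim / "lexicon.txt"),
            "--seed", "3", "--min-df", "2", "--out", str(out),
        )
        assert r.returncode == 0, r.stderr
        assert (out / "report.json").exists()
        assert (out / "report.html").exists()
        payload = json.loads((out / "report.json").read_text())
        assert payload["schema_version"] == "1.0"
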