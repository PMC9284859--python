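"""End-to-end analysis model for an open-ended experience survey.

`ExperienceAnalysis` bundles the data (responses, annotations,
frequency lexicon, embeddings) with the pipeline configuration;
``fit()`` runs sentiment cascade training, prediction, per-stratum
preprocessing and topic modelling, and returns an
`ExperienceResults` holding the fitted components, the three-stage
report and a ``summary()`` table — the same model/results split used
by mainstream statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .corpus import EmbeddingTable, FrequencyLexicon, ResponseSet, SurveySchema, Response
from .preprocess import NormalizerConfig, build_vector_space, preprocess_corpus
from .report import Report, build_report
from .sentiment import (
    AnnotatedResponse,
    CascadeModel,
    EvalReport,
    SentimentLabel,
    predict_sentiment,
    train_cascade,
)
from .topics import (
    DEFAULT_K_RANGE,
    Stratum,
    StratumTooSmall,
    StratumTopicModel,
    TopicModelResults,
)
from .validate import GroupComparison, compare_groups

__all__ = ["ExperienceAnalysis", "ExperienceResults"]


class ExperienceAnalysis:
    """Analysis model: survey responses plus pipeline configuration.

    Parameters
    ----------
    responses : ResponseSet
        The verbatim answers.
    annotated : list of AnnotatedResponse
        Gold sentiment labels used to train the cascade.
    embeddings : EmbeddingTable
        Word vectors for the topic-coherence score.
    lexicon : FrequencyLexicon, optional
        Frequency lexicon for spelling correction (skipped when None).
    normalizer : NormalizerConfig, optional
        Stopword / length / POS filtering configuration.
    k_range : iterable of int
        Candidate numbers of topics per stratum (default 2..15).
    min_df : int
        Minimum document frequency for n-grams (per stratum).
    use_gold_labels : bool
        Build strata from the gold labels instead of predictions
        (evaluation mode).
    """

    def __init__(
        self,
        responses: ResponseSet,
        annotated: list[AnnotatedResponse],
        embeddings: EmbeddingTable,
        lexicon: FrequencyLexicon | None = None,
        normalizer: NormalizerConfig | None = None,
        k_range=DEFAULT_K_RANGE,
        min_df: int = 1,
        split_fraction: float = 0.8,
        use_gold_labels: bool = False,
    ):
        self.responses = responses
        self.annotated = annotated
        self.embeddings = embeddings
        self.lexicon = lexicon
        self.normalizer = normalizer or NormalizerConfig()
        self.k_range = list(k_range)
        self.min_df = min_df
        self.split_fraction = split_fraction
        self.use_gold_labels = use_gold_labels

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        schema: SurveySchema,
        annotations: pd.DataFrame,
        embeddings: EmbeddingTable,
        **kwargs,
    ) -> "ExperienceAnalysis":
        """Build from pandas DataFrames: ``frame`` with columns
        respondent_id / question_id / text, ``annotations`` additionally
        with label (negative, neutral, positive)."""
        responses = ResponseSet(
            schema,
            [
                Response(str(r.respondent_id), str(r.question_id), str(r.text or ""))
                for r in frame.itertuples()
            ],
        )
        by_key = {r.key: r for r in responses}
        annotated = [
            AnnotatedResponse(
                str(a.respondent_id),
                str(a.question_id),
                by_key[(str(a.respondent_id), str(a.question_id))].text,
                SentimentLabel(a.label),
                str(getattr(a, "annotator_id", "annotator")),
            )
            for a in annotations.itertuples()
        ]
        return cls(responses, annotated, embeddings, **kwargs)

    def fit(self, seed: int = 0) -> "ExperienceResults":
        cascade, report_a, report_b = train_cascade(
            self.annotated,
            split_fraction=self.split_fraction,
            seed=seed,
        )
        labels = predict_sentiment(cascade, self.responses)
        if self.use_gold_labels:
            gold = {a.key: a.label for a in self.annotated}
            strata_labels = {**labels, **gold}
        else:
            strata_labels = labels

        topic_results: list[TopicModelResults] = []
        skipped: list[tuple[str, str, str]] = []
        for qid in self.responses.schema.question_ids:
            for sentiment in ("positive", "negative"):
                members = [
                    r
                    for r in self.responses.by_question(qid)
                    if not r.is_empty
                    and strata_labels[r.key] == SentimentLabel(sentiment)
                ]
                if not members:
                    skipped.append((qid, sentiment, "no documents"))
                    continue
                docs = preprocess_corpus(members, self.lexicon, self.normalizer)
                try:
                    space = build_vector_space(docs, min_df=self.min_df)
                    stratum = Stratum(qid, sentiment, tuple(d.doc_key for d in docs))
                    model = StratumTopicModel(
                        stratum,
                        space.matrix,
                        space.vocabulary,
                        self.embeddings,
                        k_range=self.k_range,
                    )
                    topic_results.append(model.fit(seed=seed))
                except (StratumTooSmall, ValueError) as e:
                    skipped.append((qid, sentiment, str(e)))

        manifest = {
            "seed": seed,
            "split_fraction": self.split_fraction,
            "k_range": [min(self.k_range), max(self.k_range)],
            "min_df": self.min_df,
            "strata_labels": "gold" if self.use_gold_labels else "predicted",
            "skipped_strata": [list(s) for s in skipped],
            "coherence": "mean pairwise cosine of embedded top-10 terms, "
            "averaged per topic then per model",
        }
        report = build_report(self.responses, labels, topic_results, manifest)
        return ExperienceResults(
            model=self,
            cascade=cascade,
            eval_negative=report_a,
            eval_positive_neutral=report_b,
            labels=labels,
            topic_results=topic_results,
            skipped_strata=skipped,
            report=report,
            seed=seed,
        )


@dataclass
class ExperienceResults:
    """Fitted pipeline: cascade, labels, per-stratum topic models and
    the assembled three-stage report."""

    model: ExperienceAnalysis
    cascade: CascadeModel
    eval_negative: EvalReport
    eval_positive_neutral: EvalReport
    labels: dict[tuple[str, str], SentimentLabel]
    topic_results: list[TopicModelResults]
    skipped_strata: list[tuple[str, str, str]]
    report: Report
    seed: int
    score_comparisons: list[GroupComparison] = field(default_factory=list)

    def stage1_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(q) for q in self.report.stage1])

    def compare_scores(
        self, scores, variant: str = "pooled"
    ) -> list[GroupComparison]:
        """Positive-vs-negative comparison of matched structured scores
        (1-10) per question, using the predicted sentiment labels."""
        by_question: dict[str, dict[str, list[float]]] = {}
        for s in scores:
            lab = self.labels.get((s.respondent_id, s.question_id))
            if lab in (SentimentLabel.POSITIVE, SentimentLabel.NEGATIVE):
                by_question.setdefault(s.question_id, {}).setdefault(
                    lab.value, []
                ).extend(s.matched_scores)
        out = []
        for qid in self.model.responses.schema.question_ids:
            groups = by_question.get(qid, {})
            pos, neg = groups.get("positive", []), groups.get("negative", [])
            if len(pos) >= 2 and len(neg) >= 2:
                out.append(
                    compare_groups(pos, neg, variant=variant, question_id=qid)
                )
        self.score_comparisons = out
        return out

    def summary(self) -> str:
        lines = ["Open-ended survey analysis", "=" * 60]
        lines.append("Stage 1 — sentiment per question:")
        lines.append(self.stage1_frame().to_string(index=False))
        neg = self.eval_negative.per_class.get("negative", {})
        lines.append(
            f"\nSentiment cascade (held-out): negative precision "
            f"{neg.get('precision', float('nan')):.2f}, recall "
            f"{neg.get('recall', float('nan')):.2f}, F1 {neg.get('f1', float('nan')):.2f}"
        )
        lines.append("\nStage 2 — topic models per stratum:")
        for res in self.topic_results:
            lines.append(res.summary())
        if self.skipped_strata:
            lines.append("\nSkipped strata:")
            for qid, sent, why in self.skipped_strata:
                lines.append(f"  {qid}/{sent}: {why}")
        if self.score_comparisons:
            lines.append("\nStructured-score comparisons (positive vs negative):")
            for c in self.score_comparisons:
                lines.append(
                    f"  {c.question_id}: {c.mean_pos:.1f}±{c.sd_pos:.1f} "
                    f"(n={c.n_pos}) vs {c.mean_neg:.1f}±{c.sd_neg:.1f} "
                    f"(n={c.n_neg}), t={c.t:.2f}, df={c.df:.1f}, "
                    f"p={c.p:.2g} [{c.variant}]"
                )
        return "\n".join(lines)
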