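"""Reference baselines used to certify that the synthetic dependency-path
task is not solvable from surface token statistics alone."""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression

from .corpus_io import Document
from .instance_builder import CandidateInstance, Level
from .train_eval import EvalReport, PairKey, evaluate

__all__ = ["BagOfWordsBaseline", "majority_class_report"]


class BagOfWordsBaseline:
    """Logistic regression on token counts over the instance's document."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.vocab: dict[str, int] = {}
        self.model: LogisticRegression | None = None

    def _vectorize(self, instances: list[CandidateInstance],
                   docs: list[Document], fit: bool) -> np.ndarray:
        by_id = {d.doc_id: d for d in docs}
        if fit:
            words = sorted({t.surface for d in docs for t in d.tokens})
            self.vocab = {w: i for i, w in enumerate(words)}
        X = np.zeros((len(instances), len(self.vocab) + 1))
        for row, inst in enumerate(instances):
            doc = by_id[inst.doc_id]
            lo = min(inst.chemical_mention.token_span[0],
                     inst.disease_mention.token_span[0])
            hi = max(inst.chemical_mention.token_span[1],
                     inst.disease_mention.token_span[1])
            tokens = doc.tokens
            for ti in range(max(0, lo - 10), min(len(tokens), hi + 11)):
                j = self.vocab.get(tokens[ti].surface)
                if j is not None:
                    X[row, j] += 1.0
            X[row, -1] = inst.sentence_distance
        return X

    def fit(self, instances: list[CandidateInstance],
            docs: list[Document]) -> "BagOfWordsBaseline":
        X = self._vectorize(instances, docs, fit=True)
        y = np.array([i.label for i in instances])
        self.model = LogisticRegression(max_iter=1000, random_state=self.seed)
        self.model.fit(X, y)
        return self

    def predict(self, instances: list[CandidateInstance],
                docs: list[Document]) -> dict[PairKey, Level]:
        if self.model is None:
            raise ValueError("baseline not fitted")
        X = self._vectorize(instances, docs, fit=False)
        yhat = self.model.predict(X)
        return {
            (i.doc_id, i.chemical_id, i.disease_id): i.level
            for i, y in zip(instances, yhat) if y == 1
        }

    def report(self, instances: list[CandidateInstance],
               docs: list[Document]) -> EvalReport:
        return evaluate(self.predict(instances, docs), docs, instances)


def majority_class_report(instances: list[CandidateInstance],
                          docs: list[Document]) -> EvalReport:
    """Predict the majority training label for everything (here: compute the
    report for the all-negative and all-positive rules, keep the better F)."""
    all_neg = evaluate({}, docs, instances)
    all_pos = evaluate(
        {(i.doc_id, i.chemical_id, i.disease_id): i.level for i in instances},
        docs, instances)
    return all_pos if all_pos.merged.f1 > all_neg.merged.f1 else all_neg
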