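"""Built-in matcher backends for the phenotype-mapping cascade.

The cascade treats its second and third stages as injectable services with a
single contract: ``candidates(text)`` returns ``(concept_id, similarity)``
pairs ranked by descending similarity (ties by ascending concept id). Two
deterministic, dependency-light backends are provided:

* :class:`TokenSetFuzzyMatcher` — token-set ratio string similarity over the
  concept synonym lexicon (order-insensitive, robust to inserted tokens).
* :class:`CharTfidfEmbedder` — cosine similarity between character trigram
  TF-IDF vectors of the query and every synonym.

Both operate on the same normalized surface forms the exact stage uses, and
both collapse multiple synonyms of one concept to that concept's best score.
"""

from __future__ import annotations

from difflib import SequenceMatcher
from typing import TYPE_CHECKING

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics.pairwise import cosine_similarity

if TYPE_CHECKING:  # pragma: no cover
    from .phenomap import Hierarchy


def _ratio(a: str, b: str) -> float:
    return SequenceMatcher(None, a, b).ratio()


def token_set_ratio(a: str, b: str) -> float:
    """Token-set ratio in [0, 1] on whitespace-tokenized strings.

    Compares the sorted shared-token core against each side's full sorted
    token string and the two full strings against each other, returning the
    best ratio — the classic construction that scores 1.0 whenever one
    string's tokens are a subset of the other's.
    """
    ta, tb = set(a.split()), set(b.split())
    if not ta and not tb:
        return 1.0
    if not ta or not tb:
        return 0.0
    core = " ".join(sorted(ta & tb))
    sa = (core + " " + " ".join(sorted(ta - tb))).strip()
    sb = (core + " " + " ".join(sorted(tb - ta))).strip()
    return max(_ratio(core, sa), _ratio(core, sb), _ratio(sa, sb))


def _best_per_concept(
    scored: list[tuple[str, float]],
) -> list[tuple[str, float]]:
    best: dict[str, float] = {}
    for cid, sim in scored:
        if sim > best.get(cid, -1.0):
            best[cid] = sim
    return sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))


class TokenSetFuzzyMatcher:
    """Ranked fuzzy candidates over a hierarchy's synonym lexicon."""

    def __init__(self, hierarchy: "Hierarchy") -> None:
        self._entries = sorted(
            (syn, cid) for syn, cid in hierarchy.synonyms.items()
        )

    def candidates(self, text: str) -> list[tuple[str, float]]:
        scored = [(cid, token_set_ratio(text, syn)) for syn, cid in self._entries]
        return _best_per_concept(scored)


class CharTfidfEmbedder:
    """Character-trigram TF-IDF cosine similarity against the lexicon."""

    def __init__(self, hierarchy: "Hierarchy", ngram: int = 3) -> None:
        entries = sorted((syn, cid) for syn, cid in hierarchy.synonyms.items())
        self._concepts = [cid for _, cid in entries]
        self._vectorizer = TfidfVectorizer(
            analyzer="char", ngram_range=(ngram, ngram), lowercase=False
        )
        self._matrix = self._vectorizer.fit_transform(s for s, _ in entries)

    def candidates(self, text: str) -> list[tuple[str, float]]:
        q = self._vectorizer.transform([text])
        sims = cosine_similarity(q, self._matrix).ravel()
        # round away float-order jitter so ties break on concept id, not noise
        scored = [
            (cid, float(np.round(s, 12)))
            for cid, s in zip(self._concepts, sims)
        ]
        return _best_per_concept(scored)
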