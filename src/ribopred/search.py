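"""Exhaustive feature-combination search around the learned translation rate.

Every candidate model contains New_TR plus a subset of the ten optional
sequence/protein features; subsets of each size k are enumerated exhaustively
(C(10,k) models per size, 1024 over k = 0..10).  All models share one fixed
train/test split so their test-split Spearman scores are comparable, and the
per-size winner is re-evaluated on the full dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .features import OPTIONAL_FEATURES
from .model import ModelSpec, TranslationRateModel, TranslationRateResults

__all__ = ["enumerate_subsets", "search_best", "SubsetScore", "SearchResult"]


def enumerate_subsets(
    optional_features: Sequence[str] = OPTIONAL_FEATURES,
    k_min: int = 0,
    k_max: int | None = None,
) -> Iterator[tuple[str, ...]]:
    """Yield every subset of each size exactly once, in lexicographic order.

    New_TR is implicit in every model and never appears in the subsets.
    """
    names = list(optional_features)
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names")
    if k_max is None:
        k_max = len(names)
    if k_min > k_max:
        raise ValueError("empty subset-size range")
    for k in range(k_min, k_max + 1):
        yield from combinations(names, k)


@dataclass
class SubsetScore:
    subset: tuple[str, ...]
    spearman_test: float


@dataclass
class SearchResult:
    """Per-size winners of the exhaustive subset search."""

    best_per_k: dict[int, SubsetScore]
    n_models: int
    all_scores: list[SubsetScore]
    best_overall: SubsetScore
    best_overall_total: float       # full-dataset Spearman of the winner


def _fit_subset(
    encoded: pd.DataFrame,
    blocks: Mapping[str, Sequence[str]],
    subset: Sequence[str],
    response: pd.Series,
    spec: ModelSpec,
) -> TranslationRateResults:
    cols: list[str] = list(blocks.get("New_TR", ["New_TR"]))
    for feat in subset:
        cols.extend(blocks[feat])
    model = TranslationRateModel(encoded[cols], response, spec=spec)
    return model.fit()


def search_best(
    encoded: pd.DataFrame,
    blocks: Mapping[str, Sequence[str]],
    response: pd.Series,
    spec: ModelSpec | None = None,
    k_range: Sequence[int] | None = None,
    optional_features: Sequence[str] = OPTIONAL_FEATURES,
    keep_all_scores: bool = False,
) -> SearchResult:
    """Exhaustively train New_TR + subset models and report per-size winners.

    Parameters
    ----------
    encoded : DataFrame
        One-hot encoded feature table containing a ``New_TR`` column and
        every encoded optional-feature column.
    blocks : mapping
        Feature name -> its encoded column block (from
        :func:`ribopred.features.one_hot_encode`); a categorical feature
        enters or leaves the model as its whole block.
    response : Series
        The evaluation response (PA or PA/mRNA), raw scale.
    spec : ModelSpec
        Shared algorithm/seed; the same seed fixes one split for every
        subset so scores are comparable.
    k_range : sequence of int
        Subset sizes to search (default 0..len(optional_features)).

    Ties are broken by lexicographic subset order (the enumeration order);
    the overall winner is re-evaluated on the full dataset.
    """
    spec = spec or ModelSpec()
    if k_range is None:
        k_range = range(0, len(optional_features) + 1)
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")

    best_per_k: dict[int, SubsetScore] = {}
    all_scores: list[SubsetScore] = []
    n_models = 0
    winners: dict[int, TranslationRateResults] = {}
    for k in k_range:
        best: SubsetScore | None = None
        for subset in enumerate_subsets(optional_features, k_min=k, k_max=k):
            res = _fit_subset(encoded, blocks, subset, response, spec)
            n_models += 1
            score = SubsetScore(subset=subset, spearman_test=res.spearman_test)
            if keep_all_scores:
                all_scores.append(score)
            if best is None or score.spearman_test > best.spearman_test:
                best = score
                winners[k] = res
        assert best is not None
        best_per_k[k] = best

    best_k = max(
        best_per_k, key=lambda k: (best_per_k[k].spearman_test, -k)
    )
    best_overall = best_per_k[best_k]
    best_overall_total = winners[best_k].spearman_total
    return SearchResult(
        best_per_k=best_per_k,
        n_models=n_models,
        all_scores=all_scores,
        best_overall=best_overall,
        best_overall_total=best_overall_total,
    )


def search_report(result: SearchResult) -> pd.DataFrame:
    """Per-size winners as a DataFrame (k, best_subset, spearman_test)."""
    rows = [
        {
            "k": k,
            "best_subset": "+".join(s.subset) if s.subset else "(New_TR only)",
            "spearman_test": s.spearman_test,
        }
        for k, s in sorted(result.best_per_k.items())
    ]
    return pd.DataFrame(rows).set_index("k")
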