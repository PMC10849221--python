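"""End-to-end orchestration: sequences + expression -> features -> New_TR.

This is the glue the command-line interface and the worked examples use;
each step is an ordinary call into the corresponding module, so any stage
can be run (or replaced) on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import expression as expr
from . import features as feat
from . import model as ml
from . import translation
from .sequence_io import GeneRecord

__all__ = ["PipelineResult", "run_pipeline", "prepare_response"]


@dataclass
class PipelineResult:
    """Everything the pipeline produced, stage by stage."""

    records: list[GeneRecord]
    discarded: list[tuple[str, str]]      # RBS-too-short genes
    rates: pd.DataFrame
    response: pd.DataFrame
    table: pd.DataFrame                   # features joined to rates/response
    newtr_results: dict[str, ml.TranslationRateResults]

    @property
    def n_genes(self) -> int:
        return len(self.table)


def prepare_response(
    pa_table: pd.DataFrame,
    mrna_table: pd.DataFrame,
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Replicates -> condition means -> quantile normalization -> response."""
    cond = expr.aggregate_replicates(mrna_table, dict(grouping))
    if cond.shape[1] >= 2:
        cond = expr.quantile_normalize(cond)
    return expr.build_response(pa_table, cond)


def run_pipeline(
    records: Sequence[GeneRecord],
    pa_table: pd.DataFrame,
    mrna_table: pd.DataFrame,
    grouping: Mapping[str, str],
    seed: int = 0,
    algorithm: str = "SVR_RBF",
    targets: Sequence[str] = ("pa", "pa_per_mrna"),
    simulate: bool = False,
    folding_backend: str = "nussinov",
) -> PipelineResult:
    """Run the full prediction pipeline on in-memory inputs.

    Genes whose RBS is too short for the initiation model are discarded
    before the train/test split.  One :class:`ml.TranslationRateResults` is
    fitted per requested target (PA and PA/mRNA are separate fits).
    """
    response = prepare_response(pa_table, mrna_table, grouping)
    rates, discarded = translation.compute_rate_profiles(
        records, simulate=simulate, seed=seed
    )
    table = feat.build_feature_table(
        list(records), rates=rates, responses=response,
        folding_backend=folding_backend,
    )
    results = {}
    for target in targets:
        spec = ml.ModelSpec(algorithm=algorithm, seed=seed, target=target)
        results[target] = ml.fit_new_tr(
            table[["initiation_rate", "elongation_rate"]],
            table[target],
            spec,
        )
    return PipelineResult(
        records=list(records),
        discarded=discarded,
        rates=rates,
        response=response,
        table=table,
        newtr_results=results,
    )


def encoded_search_table(
    result: PipelineResult, target: str = "pa"
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Feature table + New_TR, one-hot encoded for the subset search."""
    table = result.table.copy()
    optional = [f for f in feat.OPTIONAL_FEATURES if f in table.columns]
    sub = table[optional].copy()
    sub["New_TR"] = result.newtr_results[target].new_tr
    encoded, blocks = feat.one_hot_encode(sub)
    return encoded, blocks
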