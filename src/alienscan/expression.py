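"""Life-stage expression categorization of candidate genes.

Given a gene × stage TPM matrix (the focal organism's stages default to
thecate, swimming, chain and rosette), each candidate is called expressed in
a stage when its TPM meets a detectability threshold (default TPM ≥ 1, a
standard convention — the threshold is a user-visible parameter, not a
biological constant) and categorized as expressed in all stages, in some
but not all, or in none.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import ExpressionMatrix

logger = logging.getLogger("alienscan")

__all__ = ["ExpressionCategory", "ExpressionCall", "call_expression", "expression_summary"]

DEFAULT_TPM_THRESHOLD = 1.0
DEFAULT_STAGES = ("thecate", "swimming", "chain", "rosette")


class ExpressionCategory(str, enum.Enum):
    ALL_STAGES = "ALL_STAGES"
    SOME_STAGES = "SOME_STAGES"
    NO_STAGE = "NO_STAGE"


@dataclass
class ExpressionCall:
    gene_id: str
    stages_expressed: frozenset[str]
    category: ExpressionCategory


def call_expression(
    matrix: ExpressionMatrix, gene_id: str, tpm_threshold: float = DEFAULT_TPM_THRESHOLD
) -> ExpressionCall:
    """Stage-wise expression call for one gene (TPM ≥ threshold = expressed).

    A gene absent from the matrix is called NO_STAGE with a warning.
    """
    if gene_id not in matrix.tpm.index:
        logger.warning("gene %s absent from TPM matrix; called NO_STAGE", gene_id)
        return ExpressionCall(gene_id, frozenset(), ExpressionCategory.NO_STAGE)
    row = matrix.tpm.loc[gene_id]
    expressed = frozenset(stage for stage in matrix.stage_names if row[stage] >= tpm_threshold)
    if len(expressed) == len(matrix.stage_names):
        category = ExpressionCategory.ALL_STAGES
    elif expressed:
        category = ExpressionCategory.SOME_STAGES
    else:
        category = ExpressionCategory.NO_STAGE
    return ExpressionCall(gene_id, expressed, category)


def expression_summary(calls: Iterable[ExpressionCall]) -> dict[ExpressionCategory, int]:
    """Counts per category; the three counts sum to the number of calls."""
    counts = {cat: 0 for cat in ExpressionCategory}
    for call in calls:
        counts[call.category] += 1
    return counts
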