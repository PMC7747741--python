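"""Module scoring by average pairwise Pearson correlation and signature
selection.

Every module (grey excluded) is scored by the mean Pearson correlation
over all unordered gene pairs; the signature is the module with the
highest score, ties (scores compared after rounding at a configurable
tolerance) broken by *smaller* module size, remaining ties by palette
order.  Each signature gene carries its hyper/hypo direction from the
differential-methylation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .netmodules import GREY, ModuleAssignment
from .preprocess import GeneMatrix


@dataclass
class ModuleScore:
    color: str
    size: int
    avg_pcc: float


@dataclass
class Signature:
    """Selected module: color, member genes and per-gene direction."""

    color: str
    genes: list
    directions: dict  # gene -> "hyper" | "hypo"


def average_pairwise_pcc(values: np.ndarray) -> float:
    """Mean Pearson correlation over all unordered row pairs."""
    m = values.shape[0]
    if m < 2:
        raise ValidationError("need >= 2 genes for a pairwise correlation score")
    corr = np.corrcoef(values)
    iu = np.triu_indices(m, k=1)
    return float(corr[iu].mean())


def score_modules(g: GeneMatrix, assignment: ModuleAssignment) -> list:
    """Score every non-grey module of the assignment.

    Singleton modules have no defined score and are excluded with a
    warning.  Scores are returned in the assignment's palette (size)
    order.
    """
    gene_pos = {gid: i for i, gid in enumerate(g.gene_ids)}
    scores = []
    for color in assignment.module_colors:
        members = assignment.genes_in(color)
        if color == GREY:
            continue
        if len(members) < 2:
            warnings.warn(f"module {color!r} is a singleton; score undefined, excluded")
            continue
        try:
            rows = np.array([gene_pos[m] for m in members])
        except KeyError as exc:
            raise ValidationError(f"module gene {exc} not in matrix") from exc
        scores.append(ModuleScore(color, len(members),
                                  average_pairwise_pcc(g.values[rows])))
    return scores


def select_signature(scores: Sequence[ModuleScore], assignment: ModuleAssignment,
                     dm_directions: Mapping[str, str],
                     tie_tol: float = 1e-3) -> Signature:
    """Pick the signature module.

    Scores are compared after rounding to the nearest multiple of
    ``tie_tol`` (reported averages are printed to 3 decimals, so exact
    float comparison would never tie); the maximum wins, ties go to the
    smaller module, remaining ties to the earlier palette position.
    """
    if not scores:
        raise ValidationError("no scored modules to select from")
    keys = [round(s.avg_pcc / tie_tol) for s in scores]
    best_key = max(keys)
    tied = [s for s, k in zip(scores, keys) if k == best_key]
    tied.sort(key=lambda s: s.size)  # stable: palette order preserved within size ties
    chosen = tied[0]
    genes = assignment.genes_in(chosen.color)
    directions = {gid: dm_directions.get(gid, "") for gid in genes}
    return Signature(chosen.color, genes, directions)
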