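"""End-to-end composition helpers used by the CLI and the test-bench:
pattern labels -> overlap signature genes -> prognostic screen ->
PCA score -> cutpoint stratification."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data_io import ClinicalTable, ExpressionMatrix
from .differential_expression import OverlapDEGSet, moderated_de, overlap_degs
from .pyroptosis_score import (
    PSModel,
    PSResult,
    compute_ps,
    find_cutpoint,
    fit_ps_model,
    orient_protective,
    screen_prognostic,
)


@dataclass
class PSPipelineResult:
    deg_set: OverlapDEGSet
    prognostic_genes: list[str]
    model: PSModel
    ps: pd.Series
    stratification: PSResult


def derive_score(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    groups: dict[str, object],
    fdr_threshold: float = 0.01,
    screen_alpha: float = 0.05,
    minprop: float = 0.1,
    orient: bool = True,
    n_perm: int = 0,
    seed: int = 0,
) -> PSPipelineResult:
    """Run the signature-derivation pipeline on log2 expression.

    ``groups`` maps sample id to a pattern label (from consensus
    clustering or generator truth).  With ``orient`` the score sign is
    fixed (and recorded) so that a higher score is protective on the
    training data.
    """
    tables = moderated_de(expr, groups)
    deg_set = overlap_degs(tables, fdr_threshold=fdr_threshold)
    prognostic = screen_prognostic(expr, clinical, deg_set, alpha=screen_alpha)
    model = fit_ps_model(expr.subset_genes(prognostic))
    if orient:
        model, ps = orient_protective(model, expr, clinical)
    else:
        ps = compute_ps(model, expr)
    common = [s for s in ps.index if s in set(clinical.sample_ids)]
    strat = find_cutpoint(
        ps.loc[common], clinical.subset(common), minprop=minprop, n_perm=n_perm, seed=seed
    )
    return PSPipelineResult(
        deg_set=deg_set,
        prognostic_genes=prognostic,
        model=model,
        ps=ps,
        stratification=strat,
    )
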