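"""End-to-end orchestration of the analysis pipeline.

Chains the stages in study order: 80/20 split, optional LASSO covariate
selection, interaction Cox fit (optionally backward-eliminated),
counterfactual profiling at the decision horizon, consistency labelling,
heterogeneity tree and the inconsistency Cox association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .association import AssociationResult, fit_inconsistency_cox, subgroup_analysis
from .slearner import label_cohort
from .survival import (
    CoxInteractionModel,
    EvaluationResult,
    LassoFit,
    backward_eliminate,
    evaluate_model,
    fit_interaction_cox,
    select_covariates_lasso,
    split_cohort,
)
from .tree import CITree, grow_cit


@dataclass
class PipelineResult:
    model: CoxInteractionModel
    train: pd.DataFrame
    test: pd.DataFrame
    labelled: pd.DataFrame  # full cohort with profiles + consistency labels
    associations: list[AssociationResult]
    subgroup: list[AssociationResult]
    evaluation: list[EvaluationResult] = field(default_factory=list)
    tree: CITree | None = None
    lasso: LassoFit | None = None


def run_pipeline(
    cohort: pd.DataFrame,
    covariates: list[str],
    horizon: float = 10.0,
    split_fraction: float = 0.8,
    seed: int = 0,
    use_lasso: bool = False,
    eliminate: bool = False,
    grow_tree: bool = False,
    evaluate: bool = False,
    eval_horizons: tuple[float, ...] = (5.0, 10.0),
    interactions: list[str] | None = None,
    tree_kwargs: dict | None = None,
) -> PipelineResult:
    """Run split -> (selection) -> fit -> profile -> label -> associate."""
    train, test = split_cohort(cohort, fraction=split_fraction, seed=seed)

    lasso = None
    selected = list(covariates)
    if use_lasso:
        lasso = select_covariates_lasso(train, covariates, seed=seed)
        selected = lasso.selected

    model = fit_interaction_cox(train, selected, interactions=interactions)
    if eliminate:
        model = backward_eliminate(train, model)

    labelled = label_cohort(model, cohort, t=horizon)
    associations = fit_inconsistency_cox(labelled, adjustment=selected)
    subgroup = subgroup_analysis(labelled, adjustment=selected)

    evaluation = (
        evaluate_model(model, test, horizons=eval_horizons, seed=seed) if evaluate else []
    )
    tree = None
    if grow_tree:
        tkw = {"predictors": selected, **(tree_kwargs or {})}
        tree = grow_cit(labelled, outcome="optimal", **tkw)
    return PipelineResult(
        model=model,
        train=train,
        test=test,
        labelled=labelled,
        associations=associations,
        subgroup=subgroup,
        evaluation=evaluation,
        tree=tree,
        lasso=lasso,
    )
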