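"""End-to-end analysis: diversity profile, spatial basis, model selection,
variation partitioning, correlograms and congruence for one dataset."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .congruence import correlation_matrix, pairwise_congruence
from .diversity import INDEX_NAMES, diversity_profile
from .io import Dataset, standardize_environment
from .modeling import (
    ForwardSelector,
    fit_linear,
    table1_report,
    variance_inflation,
    variation_partition,
)
from .spatial import DbMEM, correlogram


@dataclass
class PipelineResults:
    profile: pd.DataFrame
    dbmem_basis: pd.DataFrame
    vif: pd.Series
    table1: pd.DataFrame
    partition: pd.DataFrame
    correlograms: pd.DataFrame
    congruence: pd.DataFrame
    correlation_r: pd.DataFrame
    correlation_p: pd.DataFrame
    config: AnalysisConfig
    selections: dict = field(default_factory=dict)
    validation_messages: list = field(default_factory=list)


def _empty_partition():
    from .modeling import VariationPartition

    return VariationPartition(
        a=0.0, b=0.0, c=0.0, d=1.0,
        adj_env=0.0, adj_spa=0.0, adj_full=0.0,
        p_env=None, p_spa=None, p_a=None, p_c=None,
        flags=["no predictors selected for either set"],
    )


def run_pipeline(
    dataset: Dataset,
    config: AnalysisConfig | None = None,
    validation_messages: list | None = None,
) -> PipelineResults:
    """Run the full analysis on a validated dataset.

    Stages: standardize the environment table; compute the six per-site
    diversity indices; build the dbMEM spatial basis; report VIFs; for
    each index forward-select environmental and spatial predictors
    separately, partition its variation, and compute correlograms of the
    index and of the residuals of the combined selected model; finally
    compute the percentile-band congruence and the Pearson correlation
    matrix of the indices.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(config.seed)

    env = standardize_environment(dataset.environment, config.env_transforms)
    profile = diversity_profile(dataset, config)
    mem = DbMEM(truncation_multiplier=config.truncation_multiplier).fit(
        dataset.coords
    )
    basis = mem.basis_
    vif = variance_inflation(env)

    selections: dict[str, dict] = {}
    part_rows = []
    corr_rows = []
    for index_name in INDEX_NAMES:
        y_all = profile[index_name]
        mask = y_all.notna()
        y = y_all[mask]
        if y.std() == 0 or mask.sum() < 10:
            continue
        factors = {}
        selected = {}
        for factor, cand in (("Environment", env), ("Space", basis)):
            sel = ForwardSelector(
                alpha=config.alpha,
                n_perm=config.n_perm,
                random_state=int(rng.integers(2**31)),
            ).fit(cand.loc[mask], y)
            fit = (
                fit_linear(y, cand.loc[mask, sel.selected_], index_name)
                if sel.selected_
                else None
            )
            factors[factor] = (sel, fit)
            selected[factor] = cand.loc[mask, sel.selected_]
        selections[index_name] = factors

        if selected["Environment"].shape[1] or selected["Space"].shape[1]:
            vp = variation_partition(
                y,
                selected["Environment"],
                selected["Space"],
                n_perm=config.n_perm,
                rng=rng,
            )
        else:
            vp = _empty_partition()
        part_rows.append(
            (
                index_name, vp.a, vp.b, vp.c, vp.d,
                vp.adj_env, vp.adj_spa, vp.adj_full,
                vp.p_env, vp.p_spa, vp.p_a, vp.p_c,
                "; ".join(vp.flags),
            )
        )

        cg = correlogram(
            y,
            dataset.coords.loc[mask],
            n_classes=config.moran_n_classes,
            alpha=config.alpha,
            n_perm=config.n_perm,
            rng=rng,
        )
        cg.insert(0, "series", index_name)
        corr_rows.append(cg)
        both = pd.concat(
            [selected["Environment"], selected["Space"]], axis=1
        )
        if both.shape[1]:
            resid = fit_linear(y, both, index_name).residuals
            cgr = correlogram(
                resid,
                dataset.coords.loc[mask],
                n_classes=config.moran_n_classes,
                alpha=config.alpha,
                n_perm=config.n_perm,
                rng=rng,
            )
            cgr.insert(0, "series", f"{index_name}_residuals")
            corr_rows.append(cgr)

    partition = pd.DataFrame(
        part_rows,
        columns=[
            "index", "a", "b", "c", "d",
            "adj_env", "adj_spa", "adj_full",
            "p_env", "p_spa", "p_a", "p_c", "flags",
        ],
    ).set_index("index")

    cong = pairwise_congruence(
        profile,
        indices=INDEX_NAMES,
        step=config.percentile_step,
        n_iter=config.n_perm,
        rng=rng,
    )
    corr_r, corr_p = correlation_matrix(profile, INDEX_NAMES)

    return PipelineResults(
        profile=profile,
        dbmem_basis=basis,
        vif=vif,
        table1=table1_report(selections),
        partition=partition,
        correlograms=(
            pd.concat(corr_rows, ignore_index=True)
            if corr_rows
            else pd.DataFrame()
        ),
        congruence=cong,
        correlation_r=corr_r,
        correlation_p=corr_p,
        config=config,
        selections=selections,
        validation_messages=list(validation_messages or []),
    )
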