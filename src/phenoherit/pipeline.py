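"""End-to-end orchestration: simulate -> curves -> shapes -> embedding ->
features -> imputation -> downstream associations.

This is the one-call counterpart of running each stage by hand, used by the
examples, the acceptance measurements, and the full-pipeline recovery tests.
All stage seeds are derived deterministically from the single ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analyses, gbm, shapes
from .curves import combined_sex_curve_b, summarize
from .embedding import build_corpus, train_embedding
from .features import FeatureBuilder, SingleDiseaseInputs
from .synthetic import SyntheticWorld, generate_world, simulate_events, synthesize_estimates


@dataclass
class PipelineResult:
    world: SyntheticWorld
    events: pd.DataFrame
    enrollment: pd.DataFrame
    curves: dict
    dissimilarity: shapes.ShapeDissimilarityMatrix
    clusters: shapes.ClusterSolution
    embedding: object
    summaries: pd.DataFrame
    estimates: pd.DataFrame
    model: gbm.GBMModel
    evaluation: gbm.EvaluationReport
    pooled_h2: pd.Series
    imputed_h2: pd.Series
    associations: list
    dsoc_fit: analyses.DsocRegressionResult | None
    feature_schema: object


def h2_feature_table(
    estimates: pd.DataFrame,
    inputs_by_disease: dict,
    builder: FeatureBuilder,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Feature matrix and target vector for the h2 records of an estimate
    table, restricted to diseases with available descriptors."""
    recs = estimates[estimates["estimate_type"] == "h2"]
    recs = recs[recs["disease_a"].isin(inputs_by_disease)]
    X = np.stack(
        [
            builder.build_single(
                inputs_by_disease[r.disease_a], r.data_type, r.model, r.sex, r.country
            )
            for r in recs.itertuples()
        ]
    )
    return X, recs["value"].to_numpy(float), recs.reset_index(drop=True)


def run_pipeline(
    n_diseases: int = 60,
    n_patients: int = 2500,
    seed: int = 0,
    *,
    d_lat: int = 8,
    mean_history_len: float = 4.0,
    n_per_disease: int = 5,
    se_range: tuple = (0.05, 0.10),
    embedding_epochs: int = 3,
    eval_splits: int = 10,
    k_max: int = 10,
    gbm_params: dict | None = None,
) -> PipelineResult:
    """Run the full analysis on a freshly simulated world."""
    rng = np.random.default_rng(seed)
    s_events, s_est, s_emb, s_eval = (int(v) for v in rng.integers(2**31, size=4))
    gbm_params = gbm_params or {}

    world = generate_world(n_diseases, d_lat, seed)
    events, enrollment = simulate_events(
        world, n_patients, mean_history_len=mean_history_len, seed=s_events
    )
    country = world.countries[0]

    # combined-sex Analysis-B curves per disease (desk-scale stand-in for the
    # sex-and-country stratified curve set)
    curves = {}
    for code in world.codes:
        if (events["code"] == code).any():
            curves[code] = combined_sex_curve_b(events, code, country)

    codes = list(curves)
    dmat = shapes.dissimilarity_matrix([curves[c] for c in codes])
    sol = shapes.cluster(dmat, K_max=min(k_max, len(codes)))
    cluster_by_disease = pd.Series(sol.assignment, index=codes)

    corpus = build_corpus(events)
    embedding = train_embedding(corpus, dim=20, epochs=embedding_epochs, seed=s_emb)

    summaries = summarize(events, curves=curves)
    estimates = synthesize_estimates(
        world, n_per_disease=n_per_disease, se_range=se_range, seed=s_est
    )

    meta = world.diseases.set_index("code")
    summ = summaries.set_index("disease")
    inputs = {
        code: SingleDiseaseInputs(
            curve=curves[code].values,
            embedding=embedding[code],
            category=meta.loc[code, "category"],
            sex_bias=float(summ.loc[code, "sex_bias"]),
            mean_carrier_age=float(summ.loc[code, "mean_carrier_age"]),
            onset_age=float(summ.loc[code, "onset_age"]),
        )
        for code in codes
        if code in embedding.vectors
    }
    builder = FeatureBuilder(countries=world.countries, embedding_dim=20)
    X, y, recs = h2_feature_table(estimates, inputs, builder)

    model = gbm.fit(X, y, **gbm_params)
    evaluation = gbm.evaluate(X, y, n_splits=eval_splits, seed=s_eval, **gbm_params)

    # inverse-variance pooled h2 per disease, and a model-imputed value per
    # disease under one canonical study descriptor
    pooled = {}
    for code, sub in estimates[estimates["estimate_type"] == "h2"].groupby("disease_a"):
        pooled[code] = gbm.pool_estimates(sub["value"].to_numpy(), sub["se"].to_numpy()).value
    pooled_h2 = pd.Series(pooled)

    imputed = {}
    for code, d in inputs.items():
        vec = builder.build_single(d, "family study using EHRs", "ACE", "unknown", country)
        imputed[code] = float(model.predict(vec[None, :])[0])
    imputed_h2 = pd.Series(imputed)

    assoc = analyses.onset_associations(
        summaries, h2=pooled_h2, cluster_by_disease=cluster_by_disease
    )

    dsoc_fit = None
    index_of = {c: i for i, c in enumerate(codes)}
    rows = []
    pooled_pairs = {
        (etype, a, b): gbm.pool_estimates(sub["value"].to_numpy(), sub["se"].to_numpy()).value
        for (etype, a, b), sub in estimates[
            estimates["estimate_type"].isin(["rg", "re"])
        ].groupby(["estimate_type", "disease_a", "disease_b"])
    }
    for p in world.pair_truth.itertuples():
        a, b = p.disease_a, p.disease_b
        if a in index_of and b in index_of:
            rg = pooled_pairs.get(("rg", a, b))
            re = pooled_pairs.get(("re", a, b))
            if rg is not None and re is not None:
                rows.append((dmat.D[index_of[a], index_of[b]], rg, re))
    if len(rows) >= 5:
        pairs_df = pd.DataFrame(rows, columns=["dsoc", "rg", "re"])
        try:
            dsoc_fit = analyses.dsoc_regression(pairs_df)
        except analyses.RankDeficiencyError:
            dsoc_fit = None

    return PipelineResult(
        world=world,
        events=events,
        enrollment=enrollment,
        curves=curves,
        dissimilarity=dmat,
        clusters=sol,
        embedding=embedding,
        summaries=summaries,
        estimates=estimates,
        model=model,
        evaluation=evaluation,
        pooled_h2=pooled_h2,
        imputed_h2=imputed_h2,
        associations=assoc,
        dsoc_fit=dsoc_fit,
        feature_schema=builder.single_schema,
    )
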