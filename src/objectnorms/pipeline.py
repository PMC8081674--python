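"""End-to-end synthetic study: norms -> statistics -> memory -> models.

Runs the whole analysis chain on generated data with known ground truth and
reports how well the fitted models recover it: feature-listing responses are
aggregated and filtered, conceptual-structure and image statistics are
computed, recognition trials are generated from the resulting predictor
table with known coefficients, and the item-wise memorability regressions,
cross-test correlation, and mediation are evaluated against the generator's
record.

Default scale is 1,000 concepts (50 categories x 20 members), one image and
one activation set per concept, 20 norming raters per concept and 43/31
old/new memory raters per item. Recovery runs use the linear response link
so the linear regression is the correctly specified analysis model; z-scores
of recovered coefficients, (beta_hat - beta_true) / SE, are the headline
diagnostics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import csa, images, memory, models, norms, synth

#: Generating coefficients on the transformed, z-scored predictor scale.
DEFAULT_BETA_HR = {
    "energy": -0.010, "jpeg_size": -0.015, "prop_nonwhite": 0.0,
    "hue": 0.0, "saturation": 0.0, "value": 0.0,
    "H_early": 0.020, "H_middle": -0.030, "H_late": 0.020,
    "lemma_frequency": 0.0, "name_agreement": 0.020, "NoF": 0.0,
    "CS": 0.040, "MD": -0.030, "CSxD": 0.020,
}
DEFAULT_BETA_FAR = {k: 0.6 * v for k, v in DEFAULT_BETA_HR.items()}


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=0).replace(0, 1.0)
    return (df - df.mean()) / sd


def build_predictor_table(
    seed: int,
    n_categories: int = 50,
    concepts_per_category: int = 20,
    n_raters: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """Run the norming/image/activation stages and assemble raw predictors.

    Returns (raw predictor table indexed by concept, info dict with the
    intermediate artifacts and ground truths).
    """
    rng = np.random.default_rng(seed)
    norm_cfg = synth.NormGenConfig(
        n_categories=n_categories,
        concepts_per_category=concepts_per_category,
        n_raters=n_raters,
        seed=int(rng.integers(2**31)),
    )
    responses, norm_truth = synth.generate_norms(norm_cfg)
    rules = norms.NormalizationRules(
        taxonomic_features=frozenset(norm_truth["taxonomic_features"])
    )
    raw_matrix = norms.build_production_matrix(responses, rules)
    matrix = norms.apply_cutoffs(raw_matrix, cell_cutoff=3, min_concepts=2)
    concepts = matrix.concepts

    lemma = synth.generate_lemma_frequencies(concepts, seed=int(rng.integers(2**31)))
    naming, naming_truth = synth.generate_naming_responses(
        concepts, seed=int(rng.integers(2**31))
    )
    stats = csa.concept_statistics(
        matrix, lemma_frequency=lemma, naming_responses=naming
    )

    imgs, img_truth = synth.generate_images(len(concepts), seed=int(rng.integers(2**31)))
    imgs = dict(zip(concepts, imgs.values()))
    acts, act_truth = synth.generate_activations(concepts, seed=int(rng.integers(2**31)))
    profile = images.profile_images(imgs, activations=acts)

    predictors = pd.concat(
        [
            profile[["energy", "jpeg_size", "prop_nonwhite", "hue", "saturation",
                     "value", "H_early", "H_middle", "H_late"]],
            stats[["lemma_frequency", "name_agreement", "NoF", "CS", "MD", "CSxD"]],
        ],
        axis=1,
    ).loc[concepts]
    info = {
        "norm_truth": norm_truth,
        "naming_truth": naming_truth,
        "image_truth": img_truth,
        "activation_truth": act_truth,
        "matrix": matrix,
        "raw_matrix": raw_matrix,
        "concept_stats": stats,
        "image_profile": profile,
        "category_of": norm_truth["category_of"],
    }
    return predictors, info


def run_pipeline(
    seed: int = 0,
    n_categories: int = 50,
    concepts_per_category: int = 20,
    reps: int = 5000,
    link: str = "linear",
    beta_hr: dict | None = None,
    beta_far: dict | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Full synthetic pipeline with ground-truth recovery diagnostics.

    Returns a JSON-serializable results dict; with ``out_dir`` the predictor
    table, item scores, regression/mediation tables and the results JSON are
    also written to disk.
    """
    rng = np.random.default_rng(seed)
    beta_hr = dict(DEFAULT_BETA_HR if beta_hr is None else beta_hr)
    beta_far = dict(DEFAULT_BETA_FAR if beta_far is None else beta_far)

    raw_predictors, info = build_predictor_table(
        int(rng.integers(2**31)), n_categories, concepts_per_category
    )
    normalizer = models.PredictorNormalizer()
    X = _zscore(normalizer.fit(raw_predictors).transform(raw_predictors))
    dropped = int(X.isna().any(axis=1).sum())
    X = X.dropna()

    mem_cfg = synth.MemoryGenConfig(
        beta_hr=beta_hr, beta_far=beta_far, link=link,
        seed=int(rng.integers(2**31)),
    )
    trials, mem_truth = synth.generate_memory_trials(X, mem_cfg)
    scores = memory.score_items(trials)

    results: dict = {
        "seed": seed,
        "n_concepts": len(X),
        "n_features_after_cutoff": len(info["matrix"].features),
        "n_rows_dropped_predictors": dropped,
        "transforms": {
            k: {"transform": s.transform, "lam": s.lam, "offset": s.offset}
            for k, s in normalizer.transforms_.items()
        },
        "behavioral_summary": {},
        "regressions": {},
        "mediation": {},
    }

    summary = memory.summarize_test(scores)
    for test in ("visual", "lexical"):
        results["behavioral_summary"][test] = {
            "mean_HR": float(summary.loc[test, ("mean", "HR")]),
            "mean_FAR": float(summary.loc[test, ("mean", "FAR")]),
        }
        c = scores.xs(test, level="test")["criterion_c"]
        results["behavioral_summary"][test]["mean_criterion_c"] = float(c.mean())

    hr, far, dpr = {}, {}, {}
    for test in ("visual", "lexical"):
        sub = scores.xs(test, level="test")
        hr[test] = sub["HR"].reindex(X.index)
        far[test] = sub["FAR"].reindex(X.index)
        dpr[test] = sub["dprime"].reindex(X.index)

    truth_beta = {"HR": beta_hr, "FAR": beta_far}
    fitted = {}
    for test in ("visual", "lexical"):
        for outcome, y in (("HR", hr[test]), ("FAR", far[test]), ("dprime", dpr[test])):
            model = models.MemorabilityRegression().fit(X, y)
            fitted[f"{test}_{outcome}"] = model
            entry = {
                "adj_r2": model.adj_r2_,
                "mean_vif": float(model.vif_.attrs["mean_vif"]),
                "n": model.n_,
                "t": model.tvalues_.drop("const").round(4).to_dict(),
                "beta": model.params_.drop("const").round(6).to_dict(),
            }
            if outcome in truth_beta:
                true = pd.Series(truth_beta[outcome]).reindex(model.feature_names_in_).fillna(0.0)
                z = (model.params_.drop("const") - true.to_numpy()) / model.se_.drop("const")
                entry["recovery_z"] = z.round(4).to_dict()
                entry["recovery_max_abs_z"] = float(z.abs().max())
                entry["recovery_mean_abs_z"] = float(z.abs().mean())
                if outcome == "HR":
                    entry["theoretical_r2_linear"] = mem_truth["per_test"][test][
                        "theoretical_r2_hr_linear"
                    ]
            results["regressions"][f"{test}_{outcome}"] = entry

    corr = models.correlate_tests(hr["visual"], hr["lexical"])
    results["cross_test_hr"] = {
        "r": corr.r, "n": corr.n, "p": corr.p,
        "theoretical_r": mem_truth["theoretical_cross_test_hr_corr"],
    }

    # closed-form population mediation paths from the generator's moments:
    # x = visual HR, y = lexical HR, m = one (z-scored) predictor column.
    # cov(x, y) = beta' Sigma beta + share * noise_var (binomial noise is
    # test-specific); cov(x, m) = cov(y, m) = (Sigma beta)_m; var(x) adds the
    # item noise and the visual binomial rater variance.
    Sigma = X.cov(ddof=0)
    beta_vec = pd.Series(beta_hr).reindex(X.columns).fillna(0.0)
    var_signal = float(beta_vec @ Sigma @ beta_vec)
    p_vis = np.asarray(mem_truth["per_test"]["visual"]["p_hr"])
    binom_v = float(np.mean(p_vis * (1 - p_vis)) / mem_cfg.n_raters_old)
    noise_var = mem_cfg.noise_sd**2
    share = mem_truth["latent_share"]
    sxx = var_signal + noise_var + binom_v
    sxy = var_signal + share * noise_var
    sigma_beta = Sigma @ beta_vec

    def _theoretical_paths(sxm: float, smy: float, smm: float = 1.0) -> dict:
        a = sxm / sxx
        det = sxx * smm - sxm**2
        b = (sxx * smy - sxm * sxy) / det
        c = sxy / sxx
        c_prime = (smm * sxy - sxm * smy) / det
        return {"a": a, "b": b, "c": c, "c_prime": c_prime,
                "ab": a * b, "prop_mediated": a * b / c}

    noise_col = pd.Series(
        np.random.default_rng(int(rng.integers(2**31))).normal(size=len(X)),
        index=X.index,
    )
    med_results = {}
    for name, m in (("CS", X["CS"]), ("noise", noise_col)):
        med = models.mediate(
            hr["visual"].to_numpy(), hr["lexical"].to_numpy(), m.to_numpy(),
            reps=reps, seed=int(rng.integers(2**31)),
        )
        med_results[name] = med
        s_m = float(sigma_beta.get(name, 0.0)) if name in X.columns else 0.0
        theo = _theoretical_paths(sxm=s_m, smy=s_m)
        results["mediation"][name] = {
            "a": med.a, "b": med.b, "c": med.c, "c_prime": med.c_prime,
            "ab": med.ab, "prop_mediated": med.prop_mediated, "r2": med.r2,
            "ci": [med.ci_low, med.ci_high],
            "significant": not (med.ci_low <= 0 <= med.ci_high),
            "theoretical": theo,
        }

    category_map = pd.Series(info["category_of"])
    cat = memory.category_summary(scores, category_map, min_items=5)
    results["n_categories_summarized"] = int(cat.reset_index()["category"].nunique())
    results["top_bottom"] = memory.top_bottom_items(scores, k=10)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        raw_predictors.to_csv(out / "predictors_raw.csv")
        X.to_csv(out / "predictors_transformed.csv")
        scores.to_csv(out / "item_scores.csv")
        models.regression_table(
            {k: v for k, v in fitted.items()}
        ).to_csv(out / "regression_table.csv")
        models.mediation_table(med_results).to_csv(out / "mediation_table.csv")
        info["matrix"].to_dir(out / "matrix")
        (out / "results.json").write_text(json.dumps(results, indent=1, default=str))
    return results
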