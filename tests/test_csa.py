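"""Conceptual-structure statistics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from objectnorms import csa, norms, synth


def matrix_from_pf(pf: pd.DataFrame, taxonomic=()) -> norms.ConceptFeatureMatrix:
    return norms.ConceptFeatureMatrix(
        pf=pf,
        taxonomic_mask=pd.Series([c in taxonomic for c in pf.columns], index=pf.columns),
        raters_per_concept=pd.Series(int(pf.to_numpy().max()), index=pf.index),
        cutoff_applied={"cell_cutoff": 1},
    )


# ---------------------------------------------------------------- oracles


def pearson_oracle(u, v):
    u, v = np.asarray(u, float), np.asarray(v, float)
    num = ((u - u.mean()) * (v - v.mean())).sum()
    den = np.sqrt(((u - u.mean()) ** 2).sum() * ((v - v.mean()) ** 2).sum())
    return num / den


def csa_oracle(pf: pd.DataFrame):
    """Nested-loop MD, CS, CSxD for every concept of a pf table."""
    concepts, features = list(pf.index), list(pf.columns)
    n_f = {f: sum(pf.loc[c, f] > 0 for c in concepts) for f in features}
    d_f = {f: 1.0 / n_f[f] for f in features}
    cs_f = {}
    for f in features:
        vals = []
        for g in features:
            if g == f:
                continue
            if pf[f].std() == 0 or pf[g].std() == 0:
                continue
            vals.append(pearson_oracle(pf[f], pf[g]))
        cs_f[f] = np.mean(vals) if vals else np.nan
    md, cs, slope = {}, {}, {}
    for c in concepts:
        members = [f for f in features if pf.loc[c, f] > 0]
        md[c] = np.mean([d_f[f] for f in members]) if members else np.nan
        vals = [cs_f[f] for f in members if not np.isnan(cs_f[f])]
        cs[c] = np.mean(vals) if vals else np.nan
        pairs = [(d_f[f], cs_f[f]) for f in members if not np.isnan(cs_f[f])]
        if len(pairs) >= 2 and len({round(d, 12) for d, _ in pairs}) > 1:
            d = np.array([p[0] for p in pairs])
            s = np.array([p[1] for p in pairs])
            # normal equations for the simple regression slope of s on d
            slope[c] = (((d - d.mean()) * (s - s.mean())).sum()
                        / ((d - d.mean()) ** 2).sum())
        else:
            slope[c] = np.nan
    return d_f, cs_f, md, cs, slope


# ------------------------------------------------------------------ tests


def test_distinctiveness_reciprocal_rule():
    pf = pd.DataFrame(
        {"f_unique": [3, 0, 0, 0], "f_all": [3, 4, 5, 3], "f_pair": [0, 3, 3, 0]},
        index=list("abcd"),
    )
    fs = csa.feature_distinctiveness(matrix_from_pf(pf))
    assert fs.loc["f_unique", "d_f"] == 1.0
    assert fs.loc["f_all", "d_f"] == 0.25
    assert fs.loc["f_pair", "d_f"] == 0.5
    assert (fs["d_f"] == 1.0 / fs["n_f"]).all()


def test_distinctiveness_decreases_with_spread():
    """d_f walks down 1, 1/2, 1/3, ... as a feature joins more concepts."""
    concepts = list("abcde")
    seen = []
    for k in range(1, 6):
        pf = pd.DataFrame({"f": [3 if i < k else 0 for i in range(5)],
                           "g": [3, 3, 3, 3, 3]}, index=concepts)
        fs = csa.feature_distinctiveness(matrix_from_pf(pf))
        seen.append(fs.loc["f", "d_f"])
    assert seen == [1.0, 0.5, pytest.approx(1 / 3), 0.25, 0.2]
    assert all(seen[i] > seen[i + 1] for i in range(4))


def test_mean_distinctiveness_hand_values():
    fs = pd.DataFrame({"d_f": [1.0, 0.5], "n_f": [1, 2]}, index=["u", "v"])
    pf = pd.DataFrame({"u": [3], "v": [4]}, index=["c"])
    md = csa.concept_mean_distinctiveness(matrix_from_pf(pf), fs)
    assert md["c"] == pytest.approx(0.75)

    fs2 = pd.DataFrame({"d_f": [1, 1 / 3, 1 / 3, 0.2]},
                       index=["w", "x", "y", "z"])
    pf2 = pd.DataFrame({"w": [3], "x": [3], "y": [3], "z": [3]}, index=["bee-like"])
    md2 = csa.concept_mean_distinctiveness(matrix_from_pf(pf2), fs2)
    assert md2["bee-like"] == pytest.approx((1 + 1 / 3 + 1 / 3 + 0.2) / 4)
    assert md2["bee-like"] == pytest.approx(0.4667, abs=1e-4)


def test_md_is_one_iff_all_features_unique():
    pf = pd.DataFrame({"u1": [3, 0], "u2": [4, 0], "v1": [0, 3]}, index=["a", "b"])
    m = matrix_from_pf(pf)
    md = csa.concept_mean_distinctiveness(m, csa.feature_distinctiveness(m))
    assert md["a"] == 1.0 and md["b"] == 1.0


def test_empty_concept_reports_missing_not_zero():
    pf = pd.DataFrame({"f": [3, 0], "g": [3, 0]}, index=["a", "empty"])
    m = matrix_from_pf(pf)
    md = csa.concept_mean_distinctiveness(m, csa.feature_distinctiveness(m))
    assert np.isnan(md["empty"])


def test_correlation_matrix_identical_and_affine_columns():
    base = np.array([1, 5, 2, 8, 4], dtype=float)
    pf = pd.DataFrame({"f": base, "g": base, "h": 3 * base + 2, "k": base[::-1]})
    pf.index = list("abcde")
    corr = csa.feature_correlation_matrix(matrix_from_pf(pf))
    assert corr.loc["f", "g"] == pytest.approx(1.0)
    assert corr.loc["f", "h"] == pytest.approx(1.0)
    assert np.isnan(corr.loc["f", "f"])  # diagonal masked


def test_correlation_matrix_matches_bruteforce(rng):
    pf = pd.DataFrame(
        rng.integers(0, 9, size=(5, 4)), index=list("abcde"), columns=list("wxyz")
    )
    corr = csa.feature_correlation_matrix(matrix_from_pf(pf))
    for f in "wxyz":
        for g in "wxyz":
            if f == g:
                continue
            assert corr.loc[f, g] == pytest.approx(pearson_oracle(pf[f], pf[g]), abs=1e-12)


def test_zero_variance_feature_masked():
    pf = pd.DataFrame({"f": [1, 5, 2], "flat": [3, 3, 3], "g": [2, 0, 4]},
                      index=list("abc"))
    corr = csa.feature_correlation_matrix(matrix_from_pf(pf))
    assert corr["flat"].isna().all()


def test_shared_policy_masks_disjoint_pairs():
    pf = pd.DataFrame(
        {"f": [3, 4, 0, 0], "g": [0, 0, 3, 5], "h": [2, 3, 1, 0]}, index=list("abcd")
    )
    corr = csa.feature_correlation_matrix(matrix_from_pf(pf), inclusion="shared")
    assert np.isnan(corr.loc["f", "g"])  # never co-occur
    assert not np.isnan(corr.loc["f", "h"])


def test_correlational_strength_extremes():
    # perfectly co-occurring features -> CS = 1
    base = np.array([5, 1, 3, 7], dtype=float)
    pf = pd.DataFrame({"f": base, "g": 2 * base, "h": base + 1}, index=list("abcd"))
    m = matrix_from_pf(pf)
    cs = csa.concept_correlational_strength(
        m, csa.feature_mean_correlation(csa.feature_correlation_matrix(m))
    )
    assert np.allclose(cs.to_numpy(), 1.0)


def test_correlational_strength_orthogonal_design():
    # features engineered to be pairwise uncorrelated across concepts
    pf = pd.DataFrame(
        {
            "f": [2, 2, 0, 0],
            "g": [2, 0, 2, 0],
            "h": [2, 0, 0, 2],
        },
        index=list("abcd"),
    )
    # check construction: each pair has correlation ~ -1/3; build a truly
    # orthogonal pair instead
    pf = pd.DataFrame({"f": [1, 1, 0, 0], "g": [1, 0, 1, 0]}, index=list("abcd"))
    corr = csa.feature_correlation_matrix(matrix_from_pf(pf), inclusion="all")
    assert corr.loc["f", "g"] == pytest.approx(0.0, abs=1e-12)


def test_csxd_two_point_slope():
    md_in = pd.DataFrame({"d_f": [0.2, 0.4], "n_f": [5, 2]}, index=["f", "g"])
    cs_in = pd.Series([0.4, 0.8], index=["f", "g"])
    pf = pd.DataFrame({"f": [3], "g": [3]}, index=["c"])
    slope = csa.concept_csxd(matrix_from_pf(pf), md_in, cs_in)
    assert slope["c"] == pytest.approx(2.0, abs=1e-12)


def test_csxd_constant_cs_gives_zero_slope():
    fs = pd.DataFrame({"d_f": [0.2, 0.4, 1.0]}, index=list("fgh"))
    cs = pd.Series([0.3, 0.3, 0.3], index=list("fgh"))
    pf = pd.DataFrame({"f": [3], "g": [3], "h": [3]}, index=["c"])
    slope = csa.concept_csxd(matrix_from_pf(pf), fs, cs)
    assert slope["c"] == pytest.approx(0.0, abs=1e-12)


def test_csxd_degenerate_when_d_constant():
    fs = pd.DataFrame({"d_f": [0.5, 0.5]}, index=["f", "g"])
    cs = pd.Series([0.1, 0.9], index=["f", "g"])
    pf = pd.DataFrame({"f": [3], "g": [3]}, index=["c"])
    assert np.isnan(csa.concept_csxd(matrix_from_pf(pf), fs, cs)["c"])


def test_csxd_matches_normal_equations(rng):
    d = rng.uniform(0.1, 1.0, size=6)
    s = rng.normal(0, 0.3, size=6)
    fs = pd.DataFrame({"d_f": d}, index=[f"f{i}" for i in range(6)])
    cs = pd.Series(s, index=fs.index)
    pf = pd.DataFrame({f: [3] for f in fs.index}, index=["c"])
    slope = csa.concept_csxd(matrix_from_pf(pf), fs, cs)["c"]
    expected = (((d - d.mean()) * (s - s.mean())).sum() / ((d - d.mean()) ** 2).sum())
    assert slope == pytest.approx(expected, abs=1e-10)


def test_full_statistics_match_bruteforce(small_matrix):
    """Module MD/CS/CSxD equal nested-loop recomputation to 1e-10."""
    pf = small_matrix.pf
    _, _, md_o, cs_o, slope_o = csa_oracle(pf)
    fs = csa.feature_distinctiveness(small_matrix)
    cs_f = csa.feature_mean_correlation(csa.feature_correlation_matrix(small_matrix))
    md = csa.concept_mean_distinctiveness(small_matrix, fs)
    cs = csa.concept_correlational_strength(small_matrix, cs_f)
    slope = csa.concept_csxd(small_matrix, fs, cs_f)
    for c in pf.index:
        assert md[c] == pytest.approx(md_o[c], abs=1e-10)
        assert cs[c] == pytest.approx(cs_o[c], abs=1e-10)
        if np.isnan(slope_o[c]):
            assert np.isnan(slope[c])
        else:
            assert slope[c] == pytest.approx(slope_o[c], abs=1e-10)


def test_statistics_invariant_to_permutation(small_matrix, rng):
    stats = csa.concept_statistics(small_matrix)
    perm_c = rng.permutation(small_matrix.pf.index)
    perm_f = rng.permutation(small_matrix.pf.columns)
    shuffled = norms.ConceptFeatureMatrix(
        pf=small_matrix.pf.loc[perm_c, perm_f],
        taxonomic_mask=small_matrix.taxonomic_mask.loc[perm_f],
        raters_per_concept=small_matrix.raters_per_concept.loc[perm_c],
        cutoff_applied=small_matrix.cutoff_applied,
    )
    stats2 = csa.concept_statistics(shuffled).loc[stats.index]
    pd.testing.assert_frame_equal(stats, stats2, check_like=True)


def test_number_of_features_excludes_taxonomic():
    pf = pd.DataFrame(
        {"has wings": [5, 4], "is an insect": [3, 3], "does fly": [4, 0]},
        index=["bee", "wasp"],
    )
    m = matrix_from_pf(pf, taxonomic=("is an insect",))
    nof = csa.number_of_features(m)
    assert nof["bee"] == 2 and nof["wasp"] == 1


def test_nof_empty_concept_is_zero():
    pf = pd.DataFrame({"f": [3, 0]}, index=["a", "b"])
    assert csa.number_of_features(matrix_from_pf(pf))["b"] == 0


@pytest.mark.parametrize(
    "responses,modal,agreement",
    [
        (["bee"] * 20 + ["wasp"] * 5, "bee", 0.80),
        (["bee"] * 25, "bee", 1.0),
        (["couch"] * 10 + ["sofa"] * 10 + ["don't know"] * 5, "couch", 0.40),
        (["don't know"] * 4, "don't know", 1.0),
    ],
)
def test_name_agreement_cases(responses, modal, agreement):
    got_modal, got_agree = csa.name_agreement(responses)
    assert got_modal == modal
    assert got_agree == pytest.approx(agreement)


def test_name_agreement_requires_responses():
    with pytest.raises(ValueError):
        csa.name_agreement([])


def test_shared_pool_construction_properties():
    """Planted structure is recovered: members of feature-sharing categories
    have lower mean distinctiveness than concepts built from (near-)disjoint
    pools, and feature pairs that truly co-occur (same shared pool) are far
    more correlated than pairs drawn from different categories."""
    shared_cfg = synth.NormGenConfig(
        n_categories=3, concepts_per_category=5, p_shared=4.0, p_distinct=0.5,
        category_weight_jitter=0.0, p_taxonomic=0.0, seed=7,
    )
    disjoint_cfg = synth.NormGenConfig(
        n_categories=3, concepts_per_category=5, p_shared=0.0, p_distinct=1.0,
        distinctive_per_concept=6, distinctive_sharing=2,
        category_weight_jitter=0.0, p_taxonomic=0.0, seed=7,
    )
    stats, matrices, truths = {}, {}, {}
    for name, cfg in (("shared", shared_cfg), ("disjoint", disjoint_cfg)):
        responses, truth = synth.generate_norms(cfg)
        m = norms.apply_cutoffs(
            norms.build_production_matrix(responses), cell_cutoff=3, min_concepts=2
        )
        stats[name], matrices[name], truths[name] = csa.concept_statistics(m), m, truth
    assert stats["shared"]["MD"].mean() < stats["disjoint"]["MD"].mean()

    corr = csa.feature_correlation_matrix(matrices["shared"])
    membership = truths["shared"]["feature_concepts"]
    cat_of_feature = {
        f: truths["shared"]["category_of"][membership[f][0]] for f in corr.index
    }
    within, across = [], []
    feats = list(corr.index)
    for i, f in enumerate(feats):
        for g in feats[i + 1:]:
            r = corr.loc[f, g]
            if np.isnan(r):
                continue
            (within if cat_of_feature[f] == cat_of_feature[g] else across).append(r)
    assert np.mean(within) > np.mean(across) + 0.3
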