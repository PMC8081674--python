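"""Conceptual-structure statistics over a production-frequency matrix.

Implements the feature-based statistics of the conceptual structure account:

* distinctiveness ``d_f = 1 / n_f`` where ``n_f`` is the number of concepts a
  feature occurs in,
* per-concept mean distinctiveness (MD),
* feature correlational strength ``cs_f`` (a feature's average pairwise
  Pearson correlation with all other features across concepts) and its
  per-concept mean (CS),
* CSxD, the within-concept unstandardized least-squares slope of ``cs_f`` on
  ``d_f``,
* NoF, the count of non-taxonomic features per concept,

plus simple semantic attributes (picture-naming agreement). Correlations are
computed on production-frequency vectors, not on binarized occurrence.
Degenerate concepts (no features, or undefined statistics) report missing
values, never imputed zeros.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd

from .norms import ConceptFeatureMatrix

logger = logging.getLogger(__name__)

DONT_KNOW = "don't know"


def feature_distinctiveness(m: ConceptFeatureMatrix) -> pd.DataFrame:
    """Per-feature concept counts and distinctiveness.

    Returns a DataFrame indexed by feature with columns ``n_f`` (number of
    concepts in which the feature occurs, pf > 0) and ``d_f = 1 / n_f``.
    """
    n_f = (m.pf > 0).sum(axis=0)
    if (n_f == 0).any():
        orphan = list(n_f.index[n_f == 0])
        raise ValueError(f"features occur in zero concepts (should be dropped): {orphan[:5]}")
    return pd.DataFrame({"n_f": n_f.astype(int), "d_f": 1.0 / n_f})


def concept_mean_distinctiveness(
    m: ConceptFeatureMatrix, fs: pd.DataFrame
) -> pd.Series:
    """MD per concept: unweighted mean of member features' d_f.

    Concepts with zero features get NaN (degenerate), never 0.
    """
    present = m.pf > 0
    d = fs["d_f"].reindex(m.pf.columns).to_numpy()
    counts = present.sum(axis=1).to_numpy()
    sums = present.to_numpy() @ d
    with np.errstate(invalid="ignore", divide="ignore"):
        md = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(md, index=m.pf.index, name="MD")


def feature_correlation_matrix(
    m: ConceptFeatureMatrix, inclusion: str = "all"
) -> pd.DataFrame:
    """Pearson correlations between feature pf vectors across all concepts.

    ``inclusion`` is the pair-inclusion policy for downstream averaging:

    * ``"all"`` — every defined pairwise correlation enters (default),
    * ``"shared"`` — pairs of features that never co-occur in any concept are
      masked (NaN), a thresholded variant used in parts of the norms
      literature.

    Zero-variance features yield undefined (NaN) correlations and are masked
    with a log message. The diagonal is set to NaN so it can never leak into
    averages.
    """
    if m.pf.shape[1] < 2 or m.pf.shape[0] < 3:
        raise ValueError("need >= 2 features and >= 3 concepts for correlations")
    if inclusion not in ("all", "shared"):
        raise ValueError(f"unknown inclusion policy {inclusion!r}")
    X = m.pf.to_numpy(dtype=float)
    sd = X.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.info("masking %d zero-variance features in correlations", degenerate.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.nan)
    if inclusion == "shared":
        present = (X > 0).astype(float)
        shared = present.T @ present
        corr[shared == 0] = np.nan
    return pd.DataFrame(corr, index=m.pf.columns, columns=m.pf.columns)


def feature_mean_correlation(corr: pd.DataFrame) -> pd.Series:
    """cs_f: each feature's mean correlation with all other (unmasked) features."""
    with np.errstate(invalid="ignore"):
        cs = np.nanmean(corr.to_numpy(), axis=1)
    return pd.Series(cs, index=corr.index, name="cs_f")


def concept_correlational_strength(
    m: ConceptFeatureMatrix, cs_f: pd.Series
) -> pd.Series:
    """CS per concept: unweighted mean of member features' cs_f.

    Concepts whose member features all have masked cs_f get NaN.
    """
    present = (m.pf > 0).to_numpy()
    cs = cs_f.reindex(m.pf.columns).to_numpy()
    out = np.full(present.shape[0], np.nan)
    for i in range(present.shape[0]):
        vals = cs[present[i]]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            out[i] = vals.mean()
    return pd.Series(out, index=m.pf.index, name="CS")


def concept_csxd(
    m: ConceptFeatureMatrix, fs: pd.DataFrame, cs_f: pd.Series
) -> pd.Series:
    """CSxD per concept: within-concept slope of cs_f regressed on d_f.

    Unstandardized least-squares slope cov(d, cs)/var(d) over the concept's
    member features. Undefined (NaN) when fewer than two members have defined
    statistics or when the members' d_f values are all identical.
    """
    present = (m.pf > 0).to_numpy()
    d = fs["d_f"].reindex(m.pf.columns).to_numpy()
    cs = cs_f.reindex(m.pf.columns).to_numpy()
    out = np.full(present.shape[0], np.nan)
    for i in range(present.shape[0]):
        sel = present[i] & ~np.isnan(cs) & ~np.isnan(d)
        dd, cc = d[sel], cs[sel]
        if dd.size < 2 or np.var(dd) == 0:
            continue
        out[i] = np.cov(dd, cc, ddof=0)[0, 1] / np.var(dd)
    return pd.Series(out, index=m.pf.index, name="CSxD")


def number_of_features(m: ConceptFeatureMatrix) -> pd.Series:
    """NoF per concept: count of non-taxonomic features with pf > 0."""
    nontax = ~m.taxonomic_mask.to_numpy()
    present = (m.pf > 0).to_numpy()
    return pd.Series((present & nontax).sum(axis=1), index=m.pf.index, name="NoF")


def name_agreement(responses: list[str]) -> tuple[str, float]:
    """Modal name and naming agreement for one image.

    Agreement is (modal-name count) / (total responses); "don't know"
    responses stay in the denominator but are never the modal name unless
    they are the only response type. Responses are case-folded; ties are
    broken lexicographically (and logged).
    """
    if not responses:
        raise ValueError("need at least one naming response")
    folded = [str(r).strip().lower() for r in responses]
    counts = Counter(folded)
    candidates = {k: v for k, v in counts.items() if k != DONT_KNOW}
    pool = candidates if candidates else dict(counts)
    top = max(pool.values())
    winners = sorted(k for k, v in pool.items() if v == top)
    if len(winners) > 1:
        logger.info("modal-name tie among %s; lexicographic pick %r", winners, winners[0])
    modal = winners[0]
    return modal, pool[modal] / len(folded)


def concept_statistics(
    m: ConceptFeatureMatrix,
    inclusion: str = "all",
    lemma_frequency: pd.Series | None = None,
    naming_responses: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Assemble the per-concept statistics table (NoF, MD, CS, CSxD, ...).

    Optionally merges externally supplied lemma frequencies and computes
    naming agreement from per-concept naming responses. A ``degenerate``
    column flags concepts with any undefined core statistic.
    """
    fs = feature_distinctiveness(m)
    corr = feature_correlation_matrix(m, inclusion=inclusion)
    cs_f = feature_mean_correlation(corr)
    out = pd.DataFrame(
        {
            "NoF": number_of_features(m),
            "MD": concept_mean_distinctiveness(m, fs),
            "CS": concept_correlational_strength(m, cs_f),
            "CSxD": concept_csxd(m, fs, cs_f),
        }
    )
    if lemma_frequency is not None:
        out["lemma_frequency"] = lemma_frequency.reindex(out.index)
    if naming_responses is not None:
        modal, agree = {}, {}
        for concept in out.index:
            resp = naming_responses.get(concept)
            if resp:
                modal[concept], agree[concept] = name_agreement(resp)
        out["modal_name"] = pd.Series(modal).reindex(out.index)
        out["name_agreement"] = pd.Series(agree).reindex(out.index)
    out["degenerate"] = out[["MD", "CS", "CSxD"]].isna().any(axis=1)
    return out


def feature_statistics_table(
    m: ConceptFeatureMatrix, inclusion: str = "all"
) -> pd.DataFrame:
    """Per-feature table (n_f, d_f, cs_f) for export."""
    fs = feature_distinctiveness(m)
    cs_f = feature_mean_correlation(feature_correlation_matrix(m, inclusion=inclusion))
    fs = fs.copy()
    fs["cs_f"] = cs_f
    return fs
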