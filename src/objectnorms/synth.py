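"""Synthetic study-data generators with known ground truth.

Every pipeline stage is exercisable without any external download: feature
norming responses with a planted category structure, object images with
analytically known statistics, network-layer activation vectors with
controlled entropy, and old/new recognition trials whose item memorability is
a known function of the predictor table.

Design of the norming generator: concepts belong to categories; members of a
category sample features from a category-shared pool (with weight
``p_shared``) and from their own distinctive features (weight
``p_distinct``); every rater lists exactly five features per concept,
matching the feature-listing task format, with at least 20 raters per
concept by default. The planted structure makes conceptual-structure
statistics checkable: shared-pool categories must come out with lower mean
distinctiveness and higher correlational strength than concepts built from
disjoint feature pools.

Design of the memory generator: per item, the probability of responding
"old" to an old item is a link function of ``intercept + beta'x + noise``,
and analogously for new items with separate coefficients; raters are
binomial at the configured counts (defaults 43 old / 31 new raters per item,
typical crowd-sourced test sizes). Visual and lexical outcomes share the
predictor signal and a configurable fraction of the item noise so the
cross-test hit-rate correlation can be steered to a target. The default link
is logistic (keeps rates in [0, 1]); a linear link is available for
parameter-recovery experiments where the analysis model (linear regression
on rates) must match the generative model.

All generators are bit-reproducible under a fixed seed and return a
machine-readable ground-truth record next to the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

#: Canonical predictor roster for the memorability regressions.
PREDICTOR_ROSTER = (
    "energy", "jpeg_size", "prop_nonwhite", "hue", "saturation", "value",
    "H_early", "H_middle", "H_late",
    "lemma_frequency", "name_agreement", "NoF", "CS", "MD", "CSxD",
)

_RELATION_CYCLE = ("has", "is", "does", "is_made_of")


# ---------------------------------------------------------------------------
# norming responses


@dataclass(frozen=True)
class NormGenConfig:
    n_categories: int = 6
    concepts_per_category: int = 5
    shared_pool_size: int = 10
    distinctive_per_concept: int = 4
    distinctive_sharing: int = 2  # category members sharing each "distinctive" feature
    n_raters: int = 20
    p_shared: float = 2.0  # sampling weight of shared-pool features
    p_distinct: float = 1.0  # sampling weight of a concept's own features
    category_weight_jitter: float = 0.5  # per-category spread of the shared weight
    features_per_response: int = 5
    p_taxonomic: float = 0.3  # chance a rater lists the category taxonomic feature
    seed: int = 0

    def __post_init__(self):
        if min(self.p_shared, self.p_distinct) < 0:
            raise ValueError("sampling weights must be non-negative")
        if self.shared_pool_size + self.distinctive_per_concept < self.features_per_response:
            raise ValueError("feature pools too small for the per-response quota")
        if not 1 <= self.distinctive_sharing <= self.concepts_per_category:
            raise ValueError("distinctive_sharing must be in [1, concepts_per_category]")


def generate_norms(cfg: NormGenConfig) -> tuple[pd.DataFrame, dict]:
    """Synthetic feature-listing responses plus ground-truth feature structure.

    Returns ``(responses, truth)``: responses has columns participant_id,
    concept, relation, feature; truth records each feature's true concept
    membership, the category map, and the taxonomic feature labels.

    "Distinctive" features are shared by ``distinctive_sharing`` adjacent
    category members (default 2) so they survive the standard occurs-in->=2-
    concepts cutoff while keeping high distinctiveness; set it to 1 for truly
    unique features. The shared-pool sampling weight is jittered per category
    so categories differ in how feature-shared their members are, giving the
    conceptual-structure statistics realistic between-item variance.
    """
    rng = np.random.default_rng(cfg.seed)
    concepts, category_of = [], {}
    shared: dict[str, list[tuple[str, str]]] = {}
    cat_weight: dict[str, float] = {}
    # distinctive feature -> member concept names
    distinct_members: dict[tuple[str, str], list[str]] = {}
    taxo_of: dict[str, tuple[str, str]] = {}
    for ci in range(cfg.n_categories):
        cat = f"cat{ci}"
        shared[cat] = [
            (_RELATION_CYCLE[k % 4], f"shared {cat} trait{k}")
            for k in range(cfg.shared_pool_size)
        ]
        jitter = np.exp(rng.uniform(-cfg.category_weight_jitter, cfg.category_weight_jitter))
        cat_weight[cat] = cfg.p_shared * jitter
        members = [f"{cat}_obj{oj}" for oj in range(cfg.concepts_per_category)]
        for oj, name in enumerate(members):
            concepts.append(name)
            category_of[name] = cat
            taxo_of[name] = ("is", f"a {cat} kind")
            for k in range(cfg.distinctive_per_concept):
                feat = (_RELATION_CYCLE[k % 4], f"own {name} trait{k}")
                owners = [
                    members[(oj + d) % cfg.concepts_per_category]
                    for d in range(cfg.distinctive_sharing)
                ]
                distinct_members[feat] = owners

    # invert: concept -> its distinctive-feature inventory
    distinct_of: dict[str, list[tuple[str, str]]] = {c: [] for c in concepts}
    for feat, owners in distinct_members.items():
        for c in owners:
            distinct_of[c].append(feat)

    rows = []
    for concept in concepts:
        cat = category_of[concept]
        inventory = shared[cat] + distinct_of[concept]
        weights = np.array(
            [cat_weight[cat]] * len(shared[cat])
            + [cfg.p_distinct] * len(distinct_of[concept]),
            dtype=float,
        )
        if weights.sum() == 0:
            weights[:] = 1.0
        probs = weights / weights.sum()
        for r in range(cfg.n_raters):
            pid = f"rater{r}"
            picks = rng.choice(len(inventory), size=cfg.features_per_response,
                               replace=False, p=probs)
            listed = [inventory[i] for i in picks]
            if rng.random() < cfg.p_taxonomic:
                listed[-1] = taxo_of[concept]
            for rel, text in listed:
                rows.append((pid, concept, rel, text))
    responses = pd.DataFrame(
        rows, columns=["participant_id", "concept", "relation", "feature"]
    )
    from .norms import feature_label  # local import to avoid cycle at module load

    membership: dict[str, list[str]] = {}
    for cat, feats in shared.items():
        members = [c for c in concepts if category_of[c] == cat]
        for rel, text in feats:
            membership[feature_label(rel, text)] = members
    for (rel, text), owners in distinct_members.items():
        membership[feature_label(rel, text)] = list(owners)
    taxonomic_labels = sorted({feature_label(r, t) for r, t in taxo_of.values()})
    truth = {
        "category_of": category_of,
        "feature_concepts": membership,
        "taxonomic_features": taxonomic_labels,
        "category_shared_weight": cat_weight,
        "config": dict(cfg.__dict__),
    }
    return responses, truth


def generate_naming_responses(
    concepts: list[str], n_raters: int = 25, mean_agreement: float = 0.75, seed: int = 0
) -> tuple[dict[str, list[str]], dict]:
    """Picture-naming responses per concept with a planted agreement level.

    The modal name is the concept label; the remainder split between a
    distractor name and "don't know".
    """
    rng = np.random.default_rng(seed)
    kappa = 12.0
    out, truth = {}, {}
    for concept in concepts:
        p = rng.beta(mean_agreement * kappa, (1 - mean_agreement) * kappa)
        resp = []
        for _ in range(n_raters):
            u = rng.random()
            if u < p:
                resp.append(concept)
            elif u < p + (1 - p) / 2:
                resp.append(f"not-{concept}")
            else:
                resp.append("don't know")
        out[concept] = resp
        truth[concept] = p
    return out, {"true_agreement": truth}


# ---------------------------------------------------------------------------
# images


def generate_images(
    n: int,
    size: int = 300,
    noise_sd_max: float = 0.08,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Colored geometric shapes on white canvases with known statistics.

    Each image is a colored disk or axis-aligned rectangle on a white
    ``size x size`` canvas, optionally perturbed by clipped Gaussian pixel
    noise. Shape color saturation and value vary independently of shape area
    so the simple image statistics are related but not collinear. The
    ground-truth table records the analytic hue, the exact shape area
    fraction, and the noise level.
    """
    rng = np.random.default_rng(seed)
    images: dict[str, np.ndarray] = {}
    records = []
    yy, xx = np.mgrid[0:size, 0:size]
    for i in range(n):
        image_id = f"img{i:04d}"
        hue = rng.random()
        sat = rng.uniform(0.5, 1.0)
        val = rng.uniform(0.4, 1.0)
        rgb = _hsv_to_rgb(hue, sat, val)
        canvas = np.ones((size, size, 3), dtype=float)
        shape = "disk" if rng.random() < 0.5 else "rect"
        if shape == "disk":
            r = rng.integers(size // 8, size // 3)
            cy, cx = rng.integers(r, size - r, size=2)
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        else:
            h = rng.integers(size // 8, size // 2)
            w = rng.integers(size // 8, size // 2)
            y0 = rng.integers(0, size - h)
            x0 = rng.integers(0, size - w)
            mask = (yy >= y0) & (yy < y0 + h) & (xx >= x0) & (xx < x0 + w)
        canvas[mask] = rgb
        noise_sd = rng.random() * noise_sd_max
        if noise_sd > 0:
            # texture the object only; the white background stays clean, as in
            # background-removed object photographs
            noise = rng.normal(0, noise_sd, (int(mask.sum()), 3))
            canvas[mask] = np.clip(canvas[mask] + noise, 0, 1)
        images[image_id] = (canvas * 255).round().astype(np.uint8)
        records.append(
            {
                "image_id": image_id,
                "true_hue": hue,
                "true_saturation": sat,
                "true_value": val,
                "shape": shape,
                "area_fraction": float(mask.mean()),
                "noise_sd": noise_sd,
            }
        )
    return images, pd.DataFrame(records).set_index("image_id")


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6) % 6
    f = h * 6 - int(h * 6)
    p, q, t = v * (1 - s), v * (1 - f * s), v * (1 - (1 - f) * s)
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb)


# ---------------------------------------------------------------------------
# layer activations


def generate_activations(
    image_ids: list[str],
    layer_sizes: dict[str, int] | None = None,
    alpha_range: tuple[float, float] = (0.05, 20.0),
    layer_jitter: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, tuple[list[str], np.ndarray]], pd.DataFrame]:
    """Dirichlet activation vectors with per-item concentration ground truth.

    Per item, a base concentration alpha is drawn log-uniformly from
    ``alpha_range``; each layer perturbs it by an independent log-normal
    factor (``layer_jitter`` log-SD) so layers carry related but not
    collinear information, as successive network layers do. The expected
    entropy of the activation distribution increases monotonically with
    alpha (uniform in the limit alpha -> inf, one-hot as alpha -> 0).
    """
    if layer_sizes is None:
        layer_sizes = {"early": 96, "middle": 256, "late": 64}
    rng = np.random.default_rng(seed)
    lo, hi = alpha_range
    alphas = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(image_ids)))
    layers = {}
    for layer, K in layer_sizes.items():
        layer_alpha = alphas * np.exp(rng.normal(0, layer_jitter, size=len(image_ids)))
        arr = np.empty((len(image_ids), K))
        for i, alpha in enumerate(layer_alpha):
            arr[i] = rng.dirichlet(np.full(K, alpha))
        # arbitrary positive per-image scaling: entropy is scale-invariant
        arr *= rng.uniform(0.5, 50.0, size=(len(image_ids), 1))
        layers[layer] = (list(image_ids), arr)
    truth = pd.DataFrame({"alpha": alphas}, index=pd.Index(image_ids, name="image_id"))
    return layers, truth


# ---------------------------------------------------------------------------
# memory trials


@dataclass(frozen=True)
class MemoryGenConfig:
    """Generative settings for old/new recognition trials.

    ``beta_hr``/``beta_far`` map predictor name -> coefficient on the linear
    predictor scale; ``intercept_hr``/``intercept_far`` are per-test baseline
    response probabilities at predictors = 0 (defaults at the typical scale
    of crowd-sourced visual/lexical recognition tests: hit rates near 0.55
    with a much higher lexical than visual false-alarm baseline).
    ``noise_sd`` is the item-level noise on the linear predictor;
    ``latent_share`` in [0, 1] is the fraction of that noise variance shared
    between the visual and lexical tests (set directly or solved from
    ``cross_test_target``).
    """

    beta_hr: dict[str, float] = field(default_factory=dict)
    beta_far: dict[str, float] = field(default_factory=dict)
    intercept_hr: float | dict = field(
        default_factory=lambda: {"visual": 0.56, "lexical": 0.55}
    )
    intercept_far: float | dict = field(
        default_factory=lambda: {"visual": 0.27, "lexical": 0.44}
    )
    noise_sd: float = 0.06
    n_raters_old: int = 43
    n_raters_new: int = 31
    link: str = "logistic"
    cross_test_target: float | None = 0.33
    latent_share: float | None = None
    rt_mean_ms: float = 1200.0
    rt_sd_ms: float = 150.0
    seed: int = 0

    def __post_init__(self):
        if self.link not in ("logistic", "linear"):
            raise ValueError("link must be 'logistic' or 'linear'")
        if self.latent_share is not None and not 0 <= self.latent_share <= 1:
            raise ValueError("latent_share must be in [0, 1]")


def _apply_link(intercept: float, eta: np.ndarray, link: str) -> np.ndarray:
    if link == "logistic":
        return expit(logit(intercept) + eta)
    return np.clip(intercept + eta, 0.01, 0.99)


def _per_test(value: float | dict, test: str) -> float:
    return float(value[test]) if isinstance(value, dict) else float(value)


def _solve_latent_share(
    var_signal: float, noise_sd: float, p0: float, n_old: int, target: float
) -> float:
    """Latent-noise share hitting a target item-level cross-test HR correlation.

    Uses the closed-form attenuation of the latent correlation by binomial
    rater noise, approximating the binomial variance at the baseline rate.
    """
    v_noise = noise_sd**2
    binom = p0 * (1 - p0) / n_old
    total = var_signal + v_noise + binom
    needed = target * total - var_signal
    if v_noise == 0:
        return 0.0
    return float(np.clip(needed / v_noise, 0.0, 1.0))


def generate_memory_trials(
    predictors: pd.DataFrame, cfg: MemoryGenConfig
) -> tuple[pd.DataFrame, dict]:
    """Recognition trials for both tests from an item x predictor table.

    Returns ``(trials, truth)``; trials has one row per (participant, item,
    test) with columns participant_id, item_id, test, status, response,
    rt_ms. The truth record holds the per-item response probabilities, the
    generating coefficients, the theoretical R2 of a linear rate regression,
    and the theoretical cross-test hit-rate correlation.
    """
    X = predictors.astype(float)
    if X.isna().any().any():
        raise ValueError("predictor table must be finite")
    rng = np.random.default_rng(cfg.seed)
    items = list(X.index.astype(str))
    n = len(items)

    def signal(beta: dict[str, float]) -> np.ndarray:
        eta = np.zeros(n)
        for name, b in beta.items():
            if name not in X.columns:
                raise ValueError(f"beta names unknown predictor {name!r}")
            eta += b * X[name].to_numpy()
        return eta

    sig_hr = signal(cfg.beta_hr)
    sig_far = signal(cfg.beta_far)
    var_signal = float(np.var(sig_hr))

    p0_hr = _per_test(cfg.intercept_hr, "visual")
    share = cfg.latent_share
    if share is None:
        target = cfg.cross_test_target if cfg.cross_test_target is not None else 0.0
        share = _solve_latent_share(
            var_signal, cfg.noise_sd, p0_hr, cfg.n_raters_old, target
        )

    z_shared = rng.normal(size=n)
    rows_pid, rows_item, rows_test, rows_status, rows_resp = [], [], [], [], []
    truth: dict = {
        "latent_share": share,
        "link": cfg.link,
        "beta_hr": dict(cfg.beta_hr),
        "beta_far": dict(cfg.beta_far),
        "items": items,
        "per_test": {},
    }
    for test in ("visual", "lexical"):
        z_own = rng.normal(size=n)
        noise = cfg.noise_sd * (np.sqrt(share) * z_shared + np.sqrt(1 - share) * z_own)
        p_hr = _apply_link(_per_test(cfg.intercept_hr, test), sig_hr + noise, cfg.link)
        noise_far = cfg.noise_sd * rng.normal(size=n)
        p_far = _apply_link(_per_test(cfg.intercept_far, test), sig_far + noise_far, cfg.link)

        hits = rng.binomial(cfg.n_raters_old, p_hr)
        fas = rng.binomial(cfg.n_raters_new, p_far)
        for status, counts, n_raters in (
            ("old", hits, cfg.n_raters_old),
            ("new", fas, cfg.n_raters_new),
        ):
            for i, item in enumerate(items):
                k = counts[i]
                rows_pid.extend(f"{test}_{status}_p{j}" for j in range(n_raters))
                rows_item.extend([item] * n_raters)
                rows_test.extend([test] * n_raters)
                rows_status.extend([status] * n_raters)
                rows_resp.extend(["old"] * k + ["new"] * (n_raters - k))
        binom_var = float(np.mean(p_hr * (1 - p_hr)) / cfg.n_raters_old)
        theo_r2 = var_signal / (var_signal + cfg.noise_sd**2 + binom_var)
        truth["per_test"][test] = {
            "p_hr": p_hr.tolist(),
            "p_far": p_far.tolist(),
            "theoretical_r2_hr_linear": theo_r2,
        }
    v = np.array(truth["per_test"]["visual"]["p_hr"])
    binom = p0_hr * (1 - p0_hr) / cfg.n_raters_old
    lat = var_signal + share * cfg.noise_sd**2
    truth["theoretical_cross_test_hr_corr"] = float(
        lat / (var_signal + cfg.noise_sd**2 + binom)
    )
    truth["mean_p_hr_visual"] = float(v.mean())

    trials = pd.DataFrame(
        {
            "participant_id": rows_pid,
            "item_id": rows_item,
            "test": rows_test,
            "status": rows_status,
            "response": rows_resp,
        }
    )
    trials["rt_ms"] = np.maximum(
        rng.normal(cfg.rt_mean_ms, cfg.rt_sd_ms, size=len(trials)), 200.0
    )
    return trials, truth


# ---------------------------------------------------------------------------
# direct predictor / mediation constructions


def generate_predictor_table(
    n_items: int, seed: int = 0, roster: tuple[str, ...] = PREDICTOR_ROSTER,
    correlation: float = 0.2,
) -> pd.DataFrame:
    """Z-scored predictor table with mild equicorrelation, roster-named.

    A stand-in for the merged image + semantic predictor table when a test
    only needs the design matrix, not the upstream pipeline.
    """
    rng = np.random.default_rng(seed)
    p = len(roster)
    cov = np.full((p, p), correlation)
    np.fill_diagonal(cov, 1.0)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n_items, method="cholesky")
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    idx = pd.Index([f"item{i:04d}" for i in range(n_items)], name="item_id")
    return pd.DataFrame(X, index=idx, columns=list(roster))


def generate_mediation_data(
    n: int,
    prop_mediated: float = 0.47,
    total_effect: float = 0.41,
    a_path: float = 0.5,
    noise_sd: float = 0.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Triples (x, m, y) with a planted mediated fraction of the x -> y effect.

    Construction: ab = prop_mediated * total_effect, c' = total_effect - ab,
    m = a*x + e_m, y = c'*x + b*m + e_y with independent Gaussian noise, so
    the population paths are exactly the planted values.
    """
    rng = np.random.default_rng(seed)
    ab = prop_mediated * total_effect
    c_prime = total_effect - ab
    b_path = ab / a_path
    x = rng.normal(size=n)
    m = a_path * x + noise_sd * rng.normal(size=n)
    y = c_prime * x + b_path * m + noise_sd * rng.normal(size=n)
    truth = {
        "a": a_path, "b": b_path, "c": total_effect, "c_prime": c_prime,
        "ab": ab, "prop_mediated": prop_mediated,
    }
    return x, m, y, truth


def generate_lemma_frequencies(
    concepts: list[str], seed: int = 0
) -> pd.Series:
    """Log-normal corpus-frequency stand-ins (counts per million, skewed)."""
    rng = np.random.default_rng(seed)
    vals = np.exp(rng.normal(2.5, 1.2, size=len(concepts)))
    return pd.Series(vals, index=concepts, name="lemma_frequency")
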