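"""Concept property-norm preprocessing.

Raw feature-listing responses (one row per participant x concept x listed
feature) are cleaned with declarative normalization rules and aggregated into
a concept x feature *production frequency* (pf) matrix: pf[c, f] is the number
of distinct raters who listed feature f for concept c. Features are identified
by their full label including the relation word ("has wings"), since relation
words are part of feature identity ("has wings" != "is wings").

Cleaning is fully rule-driven so that runs are reproducible: adverb removal,
spelling correction, plural stripping, synonym/morphological collapsing and
feature splitting are all supplied as data, never hard-coded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised relation tokens, checked longest-prefix first so that
#: "is made of" is not mis-parsed as "is".
RELATIONS = ("is_made_of", "is", "has", "does", "other")

_RELATION_PREFIXES = (
    ("is made of ", "is_made_of"),
    ("is ", "is"),
    ("has ", "has"),
    ("does ", "does"),
)

_MAX_NORMALIZE_PASSES = 8


def feature_label(relation: str, text: str) -> str:
    """Render a (relation, text) pair as a canonical feature label string."""
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}")
    if relation == "other":
        return text
    return f"{relation.replace('_', ' ')} {text}"


def parse_feature_label(label: str) -> tuple[str, str]:
    """Split a feature label into (relation, text); unmatched prefixes -> other."""
    for prefix, rel in _RELATION_PREFIXES:
        if label.startswith(prefix):
            return rel, label[len(prefix):]
    return "other", label


@dataclass(frozen=True)
class NormalizationRules:
    """Declarative feature-cleaning rules.

    Parameters
    ----------
    adverb_list : frozenset of tokens deleted wherever they occur
        ("really", "very", ...).
    spelling_map : token-level misspelling -> correction.
    plural_map : token-level plural -> singular ("wings" stays "wings" unless
        listed; the map is explicit, no stemmer is applied).
    synonym_map : full-label variant -> canonical full label; covers both
        synonym collapsing ("does travel in packs" -> "does travel in groups")
        and morphological mapping ("is used by cooks" -> "is used in cooking").
    split_rules : full label -> ordered list of output labels
        ("has a round face" -> ["has a round face", "has a face"]).
    taxonomic_features : full labels flagged as taxonomic category statements
        ("is an insect"); carried into the matrix mask, not dropped here.
    """

    adverb_list: frozenset[str] = frozenset()
    spelling_map: dict[str, str] = field(default_factory=dict)
    plural_map: dict[str, str] = field(default_factory=dict)
    synonym_map: dict[str, str] = field(default_factory=dict)
    split_rules: dict[str, tuple[str, ...]] = field(default_factory=dict)
    taxonomic_features: frozenset[str] = frozenset()

    def __post_init__(self):
        # canonical targets must not themselves be variants -> idempotence
        variants = set(self.synonym_map)
        for canon in self.synonym_map.values():
            if canon in variants and self.synonym_map[canon] != canon:
                raise ValueError(
                    f"synonym target {canon!r} is itself mapped elsewhere"
                )
        for pat, outs in self.split_rules.items():
            if len(outs) == 0:
                raise ValueError(f"split rule {pat!r} has no outputs")

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormalizationRules":
        """Load rules from a CSV with columns (type, pattern, replacement).

        type in {adverb, spelling, plural, synonym, split, taxonomic}; split
        replacements are '|'-separated output labels.
        """
        df = pd.read_csv(path, dtype=str).fillna("")
        adverbs, taxo = set(), set()
        spelling, plural, syn, split = {}, {}, {}, {}
        for _, row in df.iterrows():
            kind = row["type"].strip().lower()
            pat = row["pattern"].strip().lower()
            rep = row.get("replacement", "").strip().lower()
            if kind == "adverb":
                adverbs.add(pat)
            elif kind == "spelling":
                spelling[pat] = rep
            elif kind == "plural":
                plural[pat] = rep
            elif kind == "synonym":
                syn[pat] = rep
            elif kind == "split":
                split[pat] = tuple(s.strip() for s in rep.split("|") if s.strip())
            elif kind == "taxonomic":
                taxo.add(pat)
            else:
                raise ValueError(f"unknown rule type {kind!r}")
        return cls(
            adverb_list=frozenset(adverbs),
            spelling_map=spelling,
            plural_map=plural,
            synonym_map=syn,
            split_rules=split,
            taxonomic_features=frozenset(taxo),
        )


def _clean_tokens(label: str, rules: NormalizationRules) -> str:
    toks = label.lower().split()
    toks = [rules.spelling_map.get(t, t) for t in toks]
    toks = [t for t in toks if t not in rules.adverb_list]
    toks = [rules.plural_map.get(t, t) for t in toks]
    return " ".join(toks)


def _normalize_pass(label: str, rules: NormalizationRules) -> list[str]:
    label = _clean_tokens(label, rules)
    label = rules.synonym_map.get(label, label)
    if label in rules.split_rules:
        return list(rules.split_rules[label])
    return [label]


def normalize_feature(
    feature_text: str, relation: str, rules: NormalizationRules
) -> list[tuple[str, str]]:
    """Normalize one raw feature response to canonical (relation, text) pairs.

    Token-level cleaning (spelling, adverbs, plurals) runs before full-label
    synonym collapsing and splitting; the whole chain is iterated to a fixed
    point so normalization is idempotent. Splitting may yield several output
    features, in rule order. An empty result after cleaning signals a
    discarded response (logged, returns []).
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}")
    text = " ".join(str(feature_text).split())
    if not text:
        logger.warning("discarding empty feature response")
        return []
    labels = [feature_label(relation, text.lower())]
    for _ in range(_MAX_NORMALIZE_PASSES):
        out: list[str] = []
        for lab in labels:
            out.extend(_normalize_pass(lab, rules))
        # de-duplicate while preserving order (splits can converge)
        out = list(dict.fromkeys(out))
        if out == labels:
            break
        labels = out
    else:
        raise ValueError(f"normalization did not converge for {feature_text!r}")
    results = []
    relation_words = {"is", "has", "does", "is made of"}
    for lab in labels:
        if lab.strip() in relation_words:
            logger.warning("discarding feature emptied by cleaning: %r", feature_text)
            continue
        rel, txt = parse_feature_label(lab)
        if not txt.strip():
            logger.warning("discarding feature emptied by cleaning: %r", feature_text)
            continue
        results.append((rel, txt))
    return results


@dataclass
class ConceptFeatureMatrix:
    """Concept x feature production-frequency matrix with metadata.

    Attributes
    ----------
    pf : DataFrame, index = concepts, columns = full feature labels, integer
        counts of distinct raters listing the feature.
    taxonomic_mask : boolean Series over features.
    raters_per_concept : integer Series over concepts.
    cutoff_applied : dict of the cutoff parameters, or None before filtering.
    flagged_concepts : concepts retaining fewer than the minimum feature count
        after filtering (reported, not silently dropped).
    """

    pf: pd.DataFrame
    taxonomic_mask: pd.Series
    raters_per_concept: pd.Series
    cutoff_applied: dict | None = None
    flagged_concepts: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.pf.index.name = "concept"
        self.pf.columns.name = "feature"
        self.taxonomic_mask = self.taxonomic_mask.reindex(self.pf.columns).fillna(False).astype(bool)
        over = self.pf.gt(self.raters_per_concept.reindex(self.pf.index), axis=0)
        if over.to_numpy().any():
            raise ValueError("pf cell exceeds the concept's rater count")
        if self.pf.columns.duplicated().any():
            raise ValueError("duplicate feature labels")

    @property
    def concepts(self) -> list[str]:
        return list(self.pf.index)

    @property
    def features(self) -> list[str]:
        return list(self.pf.columns)

    def normalized(self) -> pd.DataFrame:
        """Per-concept normalized view: pf divided by the concept's rater count."""
        return self.pf.div(self.raters_per_concept, axis=0)

    # -- persistence (sparse triplet CSV + JSON sidecar) -------------------
    def to_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trip = self.pf.stack()
        trip = trip[trip > 0].rename("pf").reset_index()
        trip.columns = ["concept", "feature", "pf"]
        trip.to_csv(out / "matrix.csv", index=False)
        sidecar = {
            "concepts": self.concepts,
            "features": self.features,
            "taxonomic_features": [f for f, t in self.taxonomic_mask.items() if t],
            "raters_per_concept": self.raters_per_concept.to_dict(),
            "cutoff_applied": self.cutoff_applied,
            "flagged_concepts": self.flagged_concepts,
        }
        (out / "matrix.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "ConceptFeatureMatrix":
        src = Path(in_dir)
        trip = pd.read_csv(src / "matrix.csv")
        meta = json.loads((src / "matrix.json").read_text())
        pf = (
            trip.pivot_table(index="concept", columns="feature", values="pf",
                             aggfunc="sum", fill_value=0)
            .reindex(index=meta["concepts"], columns=meta["features"], fill_value=0)
            .astype(int)
        )
        taxo = pd.Series(
            [f in set(meta["taxonomic_features"]) for f in meta["features"]],
            index=meta["features"],
        )
        cfm = cls(
            pf=pf,
            taxonomic_mask=taxo,
            raters_per_concept=pd.Series(meta["raters_per_concept"]).reindex(meta["concepts"]),
            cutoff_applied=meta["cutoff_applied"],
            flagged_concepts=meta["flagged_concepts"],
        )
        return cfm


def build_production_matrix(
    responses: pd.DataFrame, rules: NormalizationRules | None = None
) -> ConceptFeatureMatrix:
    """Aggregate raw responses into an unfiltered production-frequency matrix.

    ``responses`` needs columns ``participant_id, concept, relation, feature``.
    Each response is normalized (possibly expanding into several features via
    splitting); a participant listing the same canonical feature more than
    once for one concept counts once — pf is a head-count across raters.

    Raises
    ------
    ValueError
        on an unknown relation token, reporting the offending row index.
    """
    rules = rules if rules is not None else NormalizationRules()
    required = {"participant_id", "concept", "relation", "feature"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"responses missing columns: {sorted(missing)}")

    bad = ~responses["relation"].isin(RELATIONS)
    if bad.any():
        idx = responses.index[bad][0]
        raise ValueError(
            f"unknown relation {responses.loc[idx, 'relation']!r} at row {idx}"
        )

    records = []
    for row in responses.itertuples(index=False):
        for rel, txt in normalize_feature(row.feature, row.relation, rules):
            records.append((row.participant_id, row.concept, feature_label(rel, txt)))
    if not records:
        raise ValueError("no usable responses after normalization")
    long = pd.DataFrame(records, columns=["participant_id", "concept", "label"])
    long = long.drop_duplicates()

    pf = (
        long.groupby(["concept", "label"])["participant_id"]
        .nunique()
        .unstack(fill_value=0)
        .astype(int)
    )
    raters = responses.groupby("concept")["participant_id"].nunique()
    raters = raters.reindex(pf.index)
    taxo = pd.Series(
        [lab in rules.taxonomic_features for lab in pf.columns], index=pf.columns
    )
    return ConceptFeatureMatrix(pf=pf, taxonomic_mask=taxo, raters_per_concept=raters)


def apply_cutoffs(
    m: ConceptFeatureMatrix,
    cell_cutoff: int = 3,
    min_concepts: int = 2,
    drop_taxonomic: bool = True,
    min_features_per_concept: int = 3,
) -> ConceptFeatureMatrix:
    """Filter a production matrix by the standard norming cut-offs.

    Order of operations: (1) cells with pf below ``cell_cutoff`` are zeroed;
    (2) taxonomic features are dropped when ``drop_taxonomic``; (3) features
    left with no surviving cell, or occurring in fewer than ``min_concepts``
    concepts, are dropped; (4) concepts retaining fewer than
    ``min_features_per_concept`` features are flagged (kept in the matrix so
    callers decide exclusion).
    """
    if cell_cutoff < 1:
        raise ValueError("cell_cutoff must be >= 1")
    if m.cutoff_applied is not None:
        raise ValueError("cutoffs already applied to this matrix")

    pf = m.pf.where(m.pf >= cell_cutoff, 0)
    keep = pd.Series(True, index=pf.columns)
    if drop_taxonomic:
        keep &= ~m.taxonomic_mask
    n_concepts = (pf > 0).sum(axis=0)
    keep &= n_concepts >= max(min_concepts, 1)
    keep &= n_concepts > 0
    pf = pf.loc[:, keep[keep].index]

    nof = (pf > 0).sum(axis=1)
    flagged = list(nof.index[nof < min_features_per_concept])
    if len(flagged) == len(pf.index) and len(pf.columns) == 0:
        logger.warning("all concepts flagged: no feature survived the cutoffs")

    return ConceptFeatureMatrix(
        pf=pf,
        taxonomic_mask=m.taxonomic_mask.reindex(pf.columns).fillna(False),
        raters_per_concept=m.raters_per_concept,
        cutoff_applied={
            "cell_cutoff": cell_cutoff,
            "min_concepts": min_concepts,
            "drop_taxonomic": drop_taxonomic,
            "min_features_per_concept": min_features_per_concept,
        },
        flagged_concepts=flagged,
    )


def read_responses(path: str | Path) -> pd.DataFrame:
    """Read a raw-response delimited file (CSV or TSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    return df
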