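"""Cross-species feature mapping, TLM-gene discovery methods, leave-one-out
candidate ranking, and gene-set overrepresentation analysis.

Five discovery methods predict whether a fission-yeast gene belongs to the
telomere-length-maintenance (TLM) network:

1. label transfer — a pombe gene is called TLM iff its budding-yeast
   ortholog is a known TLM gene (no model);
2. cross-species transfer — train on budding-yeast features mapped onto
   the shared feature space, apply to pombe;
3. within-species — train and evaluate on pombe features alone;
4. like 3, augmented with the ortholog's budding-yeast feature block
   (zero-imputed when a gene has no ortholog);
5. like 3, plus the network-propagation proximity-to-anchors feature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .evaluation import (
    CVRecordSet,
    ModelSpec,
    decision_scores,
    fit_fold_pipeline,
    repeated_stratified_cv,
    roc_auc,
)
from .features import FeatureDescriptor, FeatureTable, merge_feature_tables
from .orthology import OrthologTable
from .propagation import PPINetwork, anchor_proximity
from .types import GeneId, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class FeatureMapping:
    """One-to-one pairing of budding-yeast and fission-yeast descriptors."""

    pairs: list[tuple[FeatureDescriptor, FeatureDescriptor]]

    def __post_init__(self) -> None:
        sc = [a for a, _ in self.pairs]
        sp = [b for _, b in self.pairs]
        if len(set(sc)) != len(sc) or len(set(sp)) != len(sp):
            raise ValueError("feature mapping must be one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def reverse(self) -> "FeatureMapping":
        return FeatureMapping(pairs=[(b, a) for a, b in self.pairs])


def _unique_go_ids(complexes: GeneSetCollection) -> dict[str, str]:
    """set_id -> GO id, keeping only complexes whose GO id is unique."""
    counts: dict[str, int] = {}
    for gs in complexes:
        if gs.external_id:
            counts[gs.external_id] = counts.get(gs.external_id, 0) + 1
    out: dict[str, str] = {}
    for gs in complexes:
        if not gs.external_id:
            continue
        if counts[gs.external_id] > 1:
            warnings.warn(
                f"complex {gs.set_id!r} shares GO id {gs.external_id} with "
                "another complex; excluded from cross-species mapping",
                stacklevel=3,
            )
            continue
        out[gs.set_id] = gs.external_id
    return out


def map_cross_species_features(
    defs_sc: list[FeatureDescriptor],
    kegg_sp: GeneSetCollection,
    complexes_sc: GeneSetCollection,
    complexes_sp: GeneSetCollection,
) -> FeatureMapping:
    """Map budding-yeast feature descriptors onto fission-yeast ones.

    KEGG pathway features join on the identical pathway id (the naming
    convention is shared between species); complex features join on a GO
    accession that is unique within each species' complex catalog.
    Unmatched features are dropped (count logged).
    """
    kegg_ids = set(kegg_sp.sets)
    go_sc = _unique_go_ids(complexes_sc)
    go_sp_rev = {go: sid for sid, go in _unique_go_ids(complexes_sp).items()}
    pairs: list[tuple[FeatureDescriptor, FeatureDescriptor]] = []
    dropped = 0
    for f in defs_sc:
        if f.family == "gi_proportion" and f.set_id in kegg_ids:
            pairs.append(
                (f, FeatureDescriptor(source=f.source, set_id=f.set_id, family=f.family))
            )
        elif f.family == "membership" and f.set_id in go_sc and go_sc[f.set_id] in go_sp_rev:
            pairs.append(
                (
                    f,
                    FeatureDescriptor(
                        source=f.source,
                        set_id=go_sp_rev[go_sc[f.set_id]],
                        family=f.family,
                    ),
                )
            )
        else:
            dropped += 1
    if dropped:
        logger.info("cross-species mapping dropped %d unmatched features", dropped)
    if not pairs:
        raise ValueError("no features could be mapped across species")
    return FeatureMapping(pairs=pairs)


class Method(IntEnum):
    ORTHOLOG_TRANSFER = 1
    CROSS_SPECIES = 2
    WITHIN_SPECIES = 3
    ORTHOLOG_FEATURES = 4
    ANCHOR_PROPAGATION = 5


@dataclass
class MethodInputs:
    """Everything the five discovery methods may need."""

    features_sp: FeatureTable  # pombe KEGG + complex features, full universe
    features_sc: FeatureTable  # cerevisiae KEGG + complex features
    tlm_sp: set[GeneId]
    tlm_sc: set[GeneId]
    orthologs: OrthologTable
    mapping: FeatureMapping | None = None
    ppi_sp: PPINetwork | None = None
    anchors_sp: set[GeneId] = field(default_factory=set)


def tlm_labels(universe: list[GeneId], tlm: set[GeneId]) -> np.ndarray:
    return np.array([1 if g in tlm else 0 for g in universe])


def method1_predictions(inputs: MethodInputs) -> pd.DataFrame:
    """Label transfer: a pombe gene is predicted TLM iff its resolved
    budding-yeast ortholog is TLM.  Deterministic; no model is fitted."""
    mapping = inputs.orthologs.mapping()
    rows = []
    for g in inputs.features_sp.samples:
        ortholog = mapping.get(g)
        pred = 1 if (ortholog is not None and ortholog in inputs.tlm_sc) else 0
        rows.append(
            dict(
                gene=g.systematic_name,
                predicted_tlm=pred,
                score=float(pred),
                true_tlm=1 if g in inputs.tlm_sp else 0,
                ortholog=ortholog.systematic_name if ortholog else "",
            )
        )
    return pd.DataFrame(rows)


def build_method_dataset(
    method: int | Method, inputs: MethodInputs
) -> tuple[FeatureTable, np.ndarray, str]:
    """Assemble (X, y, feature_set_id) for methods 2-5 (method 1 needs no
    dataset; see :func:`method1_predictions`)."""
    method = Method(method)
    if method is Method.ORTHOLOG_TRANSFER:
        raise ValueError("method 1 is modeless; call method1_predictions")
    if method is Method.CROSS_SPECIES:
        if inputs.mapping is None:
            raise ValueError("method 2 requires a cross-species feature mapping")
        sc_feats = [a for a, _ in inputs.mapping.pairs]
        x = inputs.features_sc.restrict_features(sc_feats)
        y = tlm_labels(x.samples, inputs.tlm_sc)
        return x, y, "mapped_sc"
    x = inputs.features_sp
    if method is Method.ORTHOLOG_FEATURES:
        mapping = inputs.orthologs.mapping()
        sc_index = inputs.features_sc.sample_index()
        block = np.zeros((x.n_samples, inputs.features_sc.n_features))
        for i, g in enumerate(x.samples):
            ortholog = mapping.get(g)
            if ortholog is not None and ortholog in sc_index:
                block[i] = inputs.features_sc.values[sc_index[ortholog]]
        ortho_feats = [
            FeatureDescriptor(source=f.source, set_id=f"ortholog:{f.set_id}",
                              family=f.family)
            for f in inputs.features_sc.features
        ]
        x = FeatureTable(
            samples=list(x.samples),
            features=list(x.features) + ortho_feats,
            values=np.hstack([x.values, block]),
        )
        return x, tlm_labels(x.samples, inputs.tlm_sp), "sp_plus_ortholog"
    if method is Method.ANCHOR_PROPAGATION:
        if inputs.ppi_sp is None or not inputs.anchors_sp:
            raise ValueError("method 5 requires a PPI network and anchor genes")
        scores = anchor_proximity(inputs.ppi_sp, inputs.anchors_sp)
        col = np.array([scores.get(g, 0.0) for g in x.samples])[:, None]
        prop = FeatureDescriptor(source="PPI", set_id="anchor_rwr", family="propagation")
        x = FeatureTable(
            samples=list(x.samples),
            features=list(x.features) + [prop],
            values=np.hstack([x.values, col]),
        )
        return x, tlm_labels(x.samples, inputs.tlm_sp), "sp_plus_anchor"
    return x, tlm_labels(x.samples, inputs.tlm_sp), "sp_only"


def evaluate_method(
    method: int | Method,
    inputs: MethodInputs,
    model_spec: ModelSpec = ModelSpec("LRCV", class_weight="balanced"),
    repeats: int = 5,
    folds: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict[str, float]:
    """AUC / recall / precision for a discovery method.

    Methods 3-5 are scored by repeated stratified CV with held-out pooled
    predictions; method 2 trains on budding yeast and scores the full
    fission-yeast gene set; method 1 is direct label transfer.
    """
    method = Method(method)
    if method is Method.ORTHOLOG_TRANSFER:
        frame = method1_predictions(inputs)
        y, pred, score = frame.true_tlm.values, frame.predicted_tlm.values, frame.score.values
    elif method is Method.CROSS_SPECIES:
        x_train, y_train, _ = build_method_dataset(method, inputs)
        model, transform, _ = fit_fold_pipeline(
            x_train, y_train, np.arange(x_train.n_samples), model_spec, seed
        )
        sp_feats = [b for _, b in inputs.mapping.pairs]
        x_target = inputs.features_sp.restrict_features(sp_feats)
        x_mat = transform(x_target.values)
        score = decision_scores(model, x_mat)
        y = tlm_labels(x_target.samples, inputs.tlm_sp)
        pred = (score >= threshold).astype(int)
    else:
        x, y_all, fsid = build_method_dataset(method, inputs)
        records = repeated_stratified_cv(
            x, y_all, model_spec, repeats=repeats, folds=folds, seed=seed,
            feature_set_id=fsid, collect_probabilities=True,
        )
        idx_all, score_all, y_pool = [], [], []
        for test_idx, scores, y_fold in records.heldout_probabilities.values():
            idx_all.append(test_idx)
            score_all.append(scores)
            y_pool.append(y_fold)
        score = np.concatenate(score_all)
        y = np.concatenate(y_pool)
        pred = (score >= threshold).astype(int)
        auc = float(np.median(records.values("AUC")))
        tp = int(np.sum((y == 1) & (pred == 1)))
        recall = tp / max(int(np.sum(y == 1)), 1)
        precision = tp / max(int(np.sum(pred == 1)), 1)
        return {"AUC": auc, "recall": recall, "precision": precision}
    tp = int(np.sum((y == 1) & (pred == 1)))
    return {
        "AUC": roc_auc(score, y),
        "recall": tp / max(int(np.sum(y == 1)), 1),
        "precision": tp / max(int(np.sum(pred == 1)), 1),
    }


def loo_rank_candidates(
    x: FeatureTable,
    y: np.ndarray,
    known_tlm: set[GeneId],
    ortholog_map: dict[GeneId, GeneId] | None = None,
    tlm_sc: set[GeneId] | None = None,
    model_spec: ModelSpec = ModelSpec("LRCV", class_weight="balanced"),
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-out candidate ranking.

    For each gene the full pipeline (scaler, feature selection, model) is
    refitted on the remaining genes and the held-out gene's TLM probability
    recorded.  Genes already known to be TLM are excluded from the output,
    which is sorted by decreasing probability (ties by systematic name) and
    annotated with each gene's resolved budding-yeast ortholog and whether
    that ortholog is a known TLM gene.
    """
    n = x.n_samples
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    y = np.asarray(y).astype(int)
    probs = np.empty(n)
    all_idx = np.arange(n)
    for i in range(n):
        train_idx = np.delete(all_idx, i)
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("single-class training fold in leave-one-out")
        model, transform, _ = fit_fold_pipeline(x, y, train_idx, model_spec, seed)
        probs[i] = decision_scores(model, transform(x.values[i:i + 1]))[0]
    ortholog_map = ortholog_map or {}
    tlm_sc = tlm_sc or set()
    rows = []
    for i, g in enumerate(x.samples):
        if g in known_tlm:
            continue
        ortholog = ortholog_map.get(g)
        rows.append(
            dict(
                gene=g.systematic_name,
                probability=float(probs[i]),
                ortholog=ortholog.systematic_name if ortholog else "",
                ortholog_is_tlm=bool(ortholog is not None and ortholog in tlm_sc),
            )
        )
    frame = pd.DataFrame(rows).sort_values(
        ["probability", "gene"], ascending=[False, True], kind="stable"
    )
    return frame.reset_index(drop=True)


MAX_ENRICHMENT_TERM_SIZE = 250


def enrich_terms(
    candidates: set[GeneId],
    background: set[GeneId],
    terms: GeneSetCollection,
    max_term_size: int = MAX_ENRICHMENT_TERM_SIZE,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation of candidates in each term.

    Terms with more than ``max_term_size`` background genes are skipped
    (broad-term guard).  Benjamini-Hochberg q-values are computed across
    the tested terms; ``significant`` flags q < alpha.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    if not candidates <= background:
        raise ValueError("candidates must be a subset of the background")
    n_bg = len(background)
    n_cand = len(candidates)
    rows = []
    for gs in terms:
        in_bg = set(gs.members) & background
        if not in_bg or len(in_bg) > max_term_size:
            continue
        a = len(candidates & in_bg)
        b = n_cand - a
        c = len(in_bg) - a
        d = n_bg - n_cand - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            dict(
                term_id=gs.set_id,
                n_candidates_in_term=a,
                n_background_in_term=len(in_bg),
                odds_ratio=float(odds),
                p_value=float(p),
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "n_candidates_in_term", "n_background_in_term",
                "odds_ratio", "p_value", "q_value", "significant",
            ]
        )
    frame = pd.DataFrame(rows)
    _, q_values, _, _ = multipletests(frame.p_value.values, method="fdr_bh")
    frame["q_value"] = q_values
    frame["significant"] = frame.q_value < alpha
    return frame.sort_values(["q_value", "p_value", "term_id"]).reset_index(drop=True)
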