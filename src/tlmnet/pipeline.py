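"""End-to-end wiring of the pipeline stages on a synthetic world.

These helpers assemble the standard task datasets from a
:class:`~tlmnet.synthetic.SyntheticWorld` exactly as the flat-file route
would: pathway features from the GI matrix, complex-membership features,
merged feature tables for the short/long phenotype task, and the
:class:`~tlmnet.prediction.MethodInputs` bundle for the TLM-discovery
methods.
"""

from __future__ import annotations

import numpy as np

from .features import (
    FeatureTable,
    gi_proportion_features,
    membership_features,
    merge_feature_tables,
)
from .orthology import OrthologTable, resolve_orthologs
from .prediction import MethodInputs, map_cross_species_features
from .synthetic import SpeciesWorld, SyntheticWorld
from .types import PhenotypeLabels, Species


def phenotype_task(world: SyntheticWorld, species: Species | str = Species.CEREVISIAE
                   ) -> tuple[FeatureTable, PhenotypeLabels]:
    """Short/long classification dataset: pathway GI-proportion features
    merged with complex-membership features over the labeled TLM genes."""
    sw = world.species_world(species)
    labeled = [g for g in sw.gi.genes_rows if g in sw.labels.labels]
    kegg = gi_proportion_features(sw.gi, sw.pathways).restrict_samples(labeled)
    membership = membership_features(sw.complexes, labeled, restrict_to_members=True)
    merged = merge_feature_tables(kegg, membership)
    labels = PhenotypeLabels(
        labels={g: sw.labels.labels[g] for g in merged.samples}
    )
    return merged, labels


def _discovery_features(sw: SpeciesWorld) -> FeatureTable:
    """Pathway + complex features over the full gene universe (all-zero
    complex rows kept, matching the discovery-task construction)."""
    kegg = gi_proportion_features(sw.gi, sw.pathways)
    membership = membership_features(
        sw.complexes, list(sw.gi.genes_rows), restrict_to_members=False
    )
    return merge_feature_tables(kegg, membership)


def discovery_inputs(
    world: SyntheticWorld, orthologs: OrthologTable | None = None
) -> MethodInputs:
    """Bundle everything the five TLM-discovery methods consume.

    Known TLM genes are the *emitted* (unmasked) labels; masked TLM genes
    stay hidden so rankings can be scored on recovering them.
    """
    if orthologs is None:
        orthologs = resolve_orthologs(world.ortholog_candidates, world.sequences)
    features_sp = _discovery_features(world.pombe)
    features_sc = _discovery_features(world.cerevisiae)
    mapping = map_cross_species_features(
        features_sc.features,
        kegg_sp=world.pombe.pathways,
        complexes_sc=world.cerevisiae.complexes,
        complexes_sp=world.pombe.complexes,
    )
    return MethodInputs(
        features_sp=features_sp,
        features_sc=features_sc,
        tlm_sp=set(world.pombe.labels.labels),
        tlm_sc=set(world.cerevisiae.labels.labels),
        orthologs=orthologs,
        mapping=mapping,
        ppi_sp=world.pombe.ppi,
        anchors_sp=set(world.pombe.anchors),
    )


def pooled_heldout_scores(record_set) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool (sample index, score, label) triples over all held-out folds of
    a CV run executed with ``collect_probabilities=True``."""
    idx, scores, ys = [], [], []
    for test_idx, s, y in record_set.heldout_probabilities.values():
        idx.append(test_idx)
        scores.append(s)
        ys.append(y)
    return np.concatenate(idx), np.concatenate(scores), np.concatenate(ys)
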