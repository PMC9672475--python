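"""Feature construction for telomere-phenotype classification.

Two feature families are derived from curated gene sets:

* ``gi_proportion`` — for a sample gene g and a gene set S (a KEGG pathway
  or a GO BP term), the fraction of S whose members have a non-zero
  genetic-interaction score with g.
* ``membership`` — a 0/1 indicator of whether g belongs to a protein
  complex (or GO CC term).

Feature tables can be merged on their shared samples, standardized with
statistics learned on a training split only, and reduced to the top-k
features ranked by a Bernoulli naive-Bayes importance so that the feature
count never exceeds the number of training samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.naive_bayes import BernoulliNB
from sklearn.preprocessing import StandardScaler

from .types import GeneId, GeneSetCollection, GIMatrix, PhenotypeLabels, SetSource

CONSTANT_SD_EPS = 1e-12

# GO term size bounds: broader terms carry little phenotype-specific signal.
MIN_SET_SIZE = 3
MAX_SET_SIZE = 30


@dataclass(frozen=True)
class FeatureDescriptor:
    source: str
    set_id: str
    family: str  # gi_proportion | membership | propagation

    def __post_init__(self) -> None:
        if self.family not in ("gi_proportion", "membership", "propagation"):
            raise ValueError(f"unknown feature family {self.family!r}")


@dataclass
class FeatureTable:
    samples: list[GeneId]
    features: list[FeatureDescriptor]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.features)):
            raise ValueError("values shape does not match samples x features")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature descriptors")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def sample_index(self) -> dict[GeneId, int]:
        return {g: i for i, g in enumerate(self.samples)}

    def restrict_features(self, keep: list[FeatureDescriptor]) -> "FeatureTable":
        idx = {f: j for j, f in enumerate(self.features)}
        cols = [idx[f] for f in keep]
        return FeatureTable(
            samples=list(self.samples),
            features=list(keep),
            values=self.values[:, cols],
        )

    def restrict_samples(self, keep: list[GeneId]) -> "FeatureTable":
        idx = self.sample_index()
        rows = [idx[g] for g in keep]
        return FeatureTable(
            samples=list(keep),
            features=list(self.features),
            values=self.values[rows, :],
        )


@dataclass
class ScalerState:
    """Per-feature mean/sd learned on a training split (sd<eps treated as 1)."""

    mean: np.ndarray
    sd: np.ndarray
    features: list[FeatureDescriptor]


def filter_gene_sets(
    sets: GeneSetCollection,
    background: set[GeneId],
    min_size: int = MIN_SET_SIZE,
    max_size: int = MAX_SET_SIZE,
) -> GeneSetCollection:
    """Intersect each set with the background, then keep sets whose
    intersected size lies in [min_size, max_size]."""
    if not background:
        raise ValueError("background gene set is empty")
    from .types import GeneSet  # local to avoid polluting module namespace

    out = GeneSetCollection(source=sets.source)
    for gs in sets:
        members = tuple(m for m in gs.members if m in background)
        if min_size <= len(members) <= max_size:
            out.add(
                GeneSet(
                    set_id=gs.set_id,
                    name=gs.name,
                    members=members,
                    external_id=gs.external_id,
                )
            )
    return out


def gi_proportion_features(gi: GIMatrix, sets: GeneSetCollection) -> FeatureTable:
    """For every sample gene (GI row) and set S, the fraction of S with a
    non-zero GI score against the gene.  Set members absent from the GI
    columns count as zero-score."""
    nonzero = (gi.scores != 0).tocsc()
    n = len(gi.genes_rows)
    columns: list[np.ndarray] = []
    features: list[FeatureDescriptor] = []
    for gs in sets:
        if not gs.members:
            raise ValueError(f"empty gene set {gs.set_id!r}")
        member_cols = [gi.col_index(m) for m in gs.members if gi.has_col(m)]
        if member_cols:
            counts = np.asarray(
                nonzero[:, member_cols].sum(axis=1), dtype=float
            ).ravel()
        else:
            counts = np.zeros(n)
        columns.append(counts / len(gs.members))
        features.append(
            FeatureDescriptor(
                source=sets.source.value,
                set_id=gs.set_id,
                family="gi_proportion",
            )
        )
    values = np.column_stack(columns) if columns else np.zeros((n, 0))
    return FeatureTable(samples=list(gi.genes_rows), features=features, values=values)


def membership_features(
    sets: GeneSetCollection,
    samples: list[GeneId],
    restrict_to_members: bool = True,
) -> FeatureTable:
    """0/1 complex-membership indicators.

    With ``restrict_to_members`` (the default, matching the phenotype
    task), genes belonging to no set are dropped from the sample list; the
    discovery task keeps all samples and allows all-zero rows.
    """
    member_sets = {gs.set_id: set(gs.members) for gs in sets}
    if restrict_to_members:
        samples = [g for g in samples if any(g in ms for ms in member_sets.values())]
    features = [
        FeatureDescriptor(source=sets.source.value, set_id=sid, family="membership")
        for sid in member_sets
    ]
    values = np.zeros((len(samples), len(features)))
    for j, (sid, ms) in enumerate(member_sets.items()):
        for i, g in enumerate(samples):
            if g in ms:
                values[i, j] = 1.0
    return FeatureTable(samples=samples, features=features, values=values)


def merge_feature_tables(a: FeatureTable, b: FeatureTable) -> FeatureTable:
    """Merge two tables on the intersection of their samples; features are
    concatenated (a's first)."""
    shared = set(a.samples) & set(b.samples)
    if not shared:
        raise ValueError("feature tables share no samples")
    samples = [g for g in a.samples if g in shared]
    if set(a.features) & set(b.features):
        raise ValueError("feature tables share descriptors; cannot merge")
    bi = b.sample_index()
    ai = a.sample_index()
    rows_a = [ai[g] for g in samples]
    rows_b = [bi[g] for g in samples]
    values = np.hstack([a.values[rows_a, :], b.values[rows_b, :]])
    return FeatureTable(
        samples=samples, features=list(a.features) + list(b.features), values=values
    )


def standardize(
    train: FeatureTable, apply_to: FeatureTable
) -> tuple[ScalerState, FeatureTable]:
    """Standardize ``apply_to`` with mean/sd learned from ``train`` only.

    Constant training features (sd below eps) map to all-zero columns.
    """
    if train.features != apply_to.features:
        raise ValueError("feature mismatch between train and apply_to tables")
    scaler = StandardScaler().fit(train.values)
    sd = np.sqrt(scaler.var_)
    state = ScalerState(
        mean=scaler.mean_.copy(), sd=np.where(sd < CONSTANT_SD_EPS, 1.0, sd),
        features=list(train.features),
    )
    transformed = (apply_to.values - state.mean) / state.sd
    return state, FeatureTable(
        samples=list(apply_to.samples),
        features=list(apply_to.features),
        values=transformed,
    )


def _positive_label(y: PhenotypeLabels | np.ndarray) -> str:
    kinds = set(y.labels.values()) if isinstance(y, PhenotypeLabels) else set(y)
    if kinds <= {"short", "long"}:
        return "long"
    if kinds <= {"tlm", "non_tlm"}:
        return "tlm"
    raise ValueError(f"unrecognized label vocabulary {sorted(map(str, kinds))}")


def labels_to_binary(
    y: PhenotypeLabels, samples: list[GeneId], positive: str | None = None
) -> np.ndarray:
    """Encode labels as 0/1 over ``samples`` (positive class = 'long' or 'tlm')."""
    positive = positive or _positive_label(y)
    missing = [g for g in samples if g not in y.labels]
    if missing:
        raise KeyError(f"{len(missing)} samples lack labels, e.g. {missing[0]}")
    return np.array([1 if y.labels[g] == positive else 0 for g in samples])


def select_top_features(
    train: FeatureTable,
    y: PhenotypeLabels | np.ndarray,
    k: int,
) -> list[FeatureDescriptor]:
    """Rank features by a Bernoulli naive-Bayes importance and keep the top k.

    Training values are binarized at 0 (after standardization, positive
    means above the training average); the importance of feature i is the
    add-one-smoothed log P(x_i = 1 | positive class).  Ties keep table
    order.  With k >= n_features every feature is returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(y, PhenotypeLabels):
        y_bin = labels_to_binary(y, train.samples)
    else:
        y_bin = np.asarray(y)
        if y_bin.dtype.kind in "UO":
            pos = _positive_label(y_bin)
            y_bin = (y_bin == pos).astype(int)
    if len(np.unique(y_bin)) < 2:
        raise ValueError("feature selection requires both classes in y")
    if train.n_features <= k:
        return list(train.features)
    x_bin = (train.values > 0).astype(int)
    nb = BernoulliNB(alpha=1.0, binarize=None).fit(x_bin, y_bin)
    pos_idx = int(np.where(nb.classes_ == 1)[0][0])
    importance = nb.feature_log_prob_[pos_idx]
    order = np.argsort(-importance, kind="stable")
    return [train.features[j] for j in sorted(order[:k])]
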