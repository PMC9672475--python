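"""Core domain types shared by every pipeline stage.

The pipeline reasons about genes from two yeast species (budding yeast
*Saccharomyces cerevisiae* and fission yeast *Schizosaccharomyces pombe*),
their pairwise genetic-interaction (GI) scores, curated gene-set
collections (pathways, GO terms, protein complexes), telomere-length
phenotype labels, and protein sequences used for ortholog resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.sparse as sp

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")


class Species(str, Enum):
    CEREVISIAE = "cerevisiae"
    POMBE = "pombe"


@dataclass(frozen=True, order=True)
class GeneId:
    """A gene identified by species and systematic name."""

    species: Species
    systematic_name: str

    def __post_init__(self) -> None:
        if not self.systematic_name:
            raise ValueError("systematic_name must be non-empty")
        if not isinstance(self.species, Species):
            object.__setattr__(self, "species", Species(self.species))


class GIValueKind(str, Enum):
    SCORED = "scored"
    BINARY = "binary"


@dataclass
class GIMatrix:
    """Sparse gene x gene genetic-interaction score matrix.

    Rows are the sample genes (the genes whose interaction profiles act as
    features); columns span every gene seen interacting with a row gene.
    ``value_kind`` records whether scores are real SGA epsilon scores
    (``scored``) or presence/absence indicators (``binary``).
    """

    genes_rows: list[GeneId]
    genes_cols: list[GeneId]
    scores: sp.csr_matrix
    value_kind: GIValueKind

    def __post_init__(self) -> None:
        self.value_kind = GIValueKind(self.value_kind)
        self.scores = sp.csr_matrix(self.scores)
        if self.scores.shape != (len(self.genes_rows), len(self.genes_cols)):
            raise ValueError("score matrix shape does not match gene lists")
        if self.scores.nnz and not np.all(np.isfinite(self.scores.data)):
            raise ValueError("GI scores must be finite")
        if self.value_kind is GIValueKind.BINARY and self.scores.nnz:
            if not np.all(np.isin(self.scores.data, (0.0, 1.0))):
                raise ValueError("binary GI matrix may only store 0/1 scores")
        self._row_index = {g: i for i, g in enumerate(self.genes_rows)}
        self._col_index = {g: j for j, g in enumerate(self.genes_cols)}
        if len(self._row_index) != len(self.genes_rows):
            raise ValueError("duplicate row gene")
        if len(self._col_index) != len(self.genes_cols):
            raise ValueError("duplicate column gene")

    def row_index(self, gene: GeneId) -> int:
        return self._row_index[gene]

    def col_index(self, gene: GeneId) -> int:
        return self._col_index[gene]

    def has_row(self, gene: GeneId) -> bool:
        return gene in self._row_index

    def has_col(self, gene: GeneId) -> bool:
        return gene in self._col_index


class SetSource(str, Enum):
    KEGG = "KEGG"
    GO_BP = "GO_BP"
    GO_CC = "GO_CC"
    COMPLEX = "COMPLEX"


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: tuple[GeneId, ...]
    external_id: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.set_id!r} has duplicate members")


@dataclass
class GeneSetCollection:
    """Named gene sets from one source (KEGG, GO BP, GO CC, or a complex catalog)."""

    source: SetSource
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.source = SetSource(self.source)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.set_id in self.sets:
            raise ValueError(f"duplicate set_id {gene_set.set_id!r}")
        self.sets[gene_set.set_id] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


# Raw telomere-length categories from knockout / hypomorphic-allele screens.
SHORT_RAW = {"very short", "short", "slightly short", "DAmP Short"}
LONG_RAW = {"slightly long", "long", "very long", "DAmP Long"}
NORMAL_RAW = "normal"
RAW_VOCABULARY = SHORT_RAW | LONG_RAW | {NORMAL_RAW}


@dataclass
class PhenotypeLabels:
    """Reduced per-gene phenotype labels.

    For the phenotype task labels are ``short``/``long``; for the gene
    discovery task they are ``tlm``/``non_tlm``.  ``raw_labels`` optionally
    keeps the unreduced category strings each gene was observed with.
    """

    labels: dict[GeneId, str]
    raw_labels: dict[GeneId, list[str]] | None = None

    def __post_init__(self) -> None:
        kinds = set(self.labels.values())
        if not kinds <= {"short", "long"} and not kinds <= {"tlm", "non_tlm"}:
            raise ValueError(f"inconsistent label vocabulary: {sorted(kinds)}")

    def genes(self) -> list[GeneId]:
        return list(self.labels)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ProteinSequence:
    gene: GeneId
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.gene.systematic_name}")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"illegal residue(s) {sorted(bad)} in record "
                f"{self.gene.systematic_name}"
            )

    def __len__(self) -> int:
        return len(self.residues)
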