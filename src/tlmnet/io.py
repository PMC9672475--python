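"""Flat-file readers/writers and phenotype label reduction.

All tabular dialects are UTF-8, tab-separated with a mandatory header
line.  Gene sets travel as GMT (set_id, description, members...); an
optional external accession (e.g. a GO id for a protein complex) is
carried in the description field after a ``|`` separator.  Protein
sequences travel as FASTA.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from Bio import SeqIO

from .types import (
    LONG_RAW,
    NORMAL_RAW,
    RAW_VOCABULARY,
    SHORT_RAW,
    GeneId,
    GeneSet,
    GeneSetCollection,
    GIMatrix,
    GIValueKind,
    PhenotypeLabels,
    ProteinSequence,
    SetSource,
    Species,
)

P_VALUE_CUTOFF = 0.05  # lenient significance threshold for scored GI edges


def _parse_species(tag: str | Species) -> Species:
    try:
        return Species(tag)
    except ValueError:
        raise ValueError(f"unknown species tag {tag!r}") from None


def _rows(path: str | Path, expected_header: list[str]):
    """Yield (line_number, row) from a headered TSV, validating the header."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if header != expected_header:
            raise ValueError(
                f"{path}: expected header {expected_header}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(expected_header):
                raise ValueError(
                    f"{path}: malformed row at line {lineno}: "
                    f"expected {len(expected_header)} fields, got {len(row)}"
                )
            yield lineno, row


def read_gi_edges(
    path: str | Path,
    dialect: str | GIValueKind,
    species: str | Species,
) -> GIMatrix:
    """Assemble a genetic-interaction matrix from an edge list.

    The ``scored`` dialect (columns gene_a, gene_b, score, p_value) keeps
    only edges with p < 0.05; among repeated measurements of the same
    (gene_a, gene_b) pair the edge with the smallest p-value wins, ties
    broken by larger |score| and then by file order.  The ``binary``
    dialect (columns gene_a, gene_b) stores 1 for every listed pair.

    Row/column gene order is sorted by systematic name, so the assembled
    matrix is independent of the order of input rows.
    """
    dialect = GIValueKind(dialect)
    species = _parse_species(species)
    # best[(a, b)] = (p, -|score|, lineno, score); min() implements the
    # lowest-p rule with the documented tie-breaks.
    best: dict[tuple[str, str], tuple[float, float, int, float]] = {}
    if dialect is GIValueKind.SCORED:
        for lineno, (a, b, score_s, p_s) in _rows(
            path, ["gene_a", "gene_b", "score", "p_value"]
        ):
            try:
                score, p = float(score_s), float(p_s)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric score/p_value at line {lineno}"
                ) from None
            if not (np.isfinite(score) and np.isfinite(p)):
                raise ValueError(f"{path}: non-finite score/p_value at line {lineno}")
            if p >= P_VALUE_CUTOFF:
                continue
            cand = (p, -abs(score), lineno, score)
            key = (a, b)
            if key not in best or cand < best[key]:
                best[key] = cand
    else:
        for lineno, (a, b) in _rows(path, ["gene_a", "gene_b"]):
            best.setdefault((a, b), (0.0, 0.0, lineno, 1.0))

    rows = sorted({a for a, _ in best})
    cols = sorted({b for _, b in best})
    ri = {g: i for i, g in enumerate(rows)}
    ci = {g: j for j, g in enumerate(cols)}
    data = np.array([v[3] for v in best.values()], dtype=float)
    ii = np.array([ri[a] for a, _ in best], dtype=int)
    jj = np.array([ci[b] for _, b in best], dtype=int)
    mat = sp.csr_matrix((data, (ii, jj)), shape=(len(rows), len(cols)))
    return GIMatrix(
        genes_rows=[GeneId(species, g) for g in rows],
        genes_cols=[GeneId(species, g) for g in cols],
        scores=mat,
        value_kind=dialect,
    )


def reduce_phenotypes(raw: dict[GeneId, list[str]]) -> PhenotypeLabels:
    """Reduce raw telomere-length categories to binary short/long labels.

    Any short-flavoured category (including the hypomorphic 'DAmP Short')
    maps to ``short`` and any long-flavoured one to ``long``.  A gene
    observed as both normal and a length variant takes the variant label;
    genes observed only as normal carry no phenotype and are excluded.  A
    gene observed with both short and long variants is a curation conflict
    and raises.
    """
    labels: dict[GeneId, str] = {}
    kept_raw: dict[GeneId, list[str]] = {}
    for gene, cats in raw.items():
        unknown = set(cats) - RAW_VOCABULARY
        if unknown:
            raise ValueError(
                f"{gene.systematic_name}: unknown raw categories {sorted(unknown)}"
            )
        is_short = any(c in SHORT_RAW for c in cats)
        is_long = any(c in LONG_RAW for c in cats)
        if is_short and is_long:
            raise ValueError(
                f"{gene.systematic_name}: conflicting short and long phenotypes"
            )
        if is_short:
            labels[gene] = "short"
        elif is_long:
            labels[gene] = "long"
        else:
            continue  # normal-only genes are not part of the binary task
        kept_raw[gene] = list(cats)
    return PhenotypeLabels(labels=labels, raw_labels=kept_raw)


def read_gene_sets(
    path: str | Path,
    source: str | SetSource,
    species: str | Species,
) -> GeneSetCollection:
    """Read a GMT gene-set file.

    A description of the form ``name|ACCESSION`` carries an external id
    (used to give protein complexes a GO accession).  Duplicate members
    within one line are dropped with a warning; an empty member list or a
    repeated set_id is an error.
    """
    species = _parse_species(species)
    coll = GeneSetCollection(source=SetSource(source))
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: gene set has an empty member list"
                )
            set_id, desc = fields[0], fields[1]
            name, _, ext = desc.partition("|")
            members: list[GeneId] = []
            seen: set[str] = set()
            for m in fields[2:]:
                if not m:
                    continue
                if m in seen:
                    warnings.warn(
                        f"{path}: line {lineno}: duplicate member {m!r} in set "
                        f"{set_id!r} dropped",
                        stacklevel=2,
                    )
                    continue
                seen.add(m)
                members.append(GeneId(species, m))
            if not members:
                raise ValueError(
                    f"{path}: line {lineno}: gene set {set_id!r} has no members"
                )
            coll.add(
                GeneSet(
                    set_id=set_id,
                    name=name,
                    members=tuple(members),
                    external_id=ext or None,
                )
            )
    return coll


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT (inverse of :func:`read_gene_sets`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            desc = gs.name if gs.external_id is None else f"{gs.name}|{gs.external_id}"
            members = "\t".join(m.systematic_name for m in gs.members)
            fh.write(f"{gs.set_id}\t{desc}\t{members}\n")


def read_labels(path: str | Path, species: str | Species) -> dict[GeneId, list[str]]:
    """Read raw phenotype categories (columns gene, raw_label).

    A gene may appear on several lines; all its categories are collected
    for :func:`reduce_phenotypes`.
    """
    species = _parse_species(species)
    raw: dict[GeneId, list[str]] = {}
    for _, (gene, cat) in _rows(path, ["gene", "raw_label"]):
        raw.setdefault(GeneId(species, gene), []).append(cat)
    return raw


def read_anchor_genes(path: str | Path, species: str | Species) -> list[GeneId]:
    """Read a one-gene-per-line anchor list; blank lines are skipped."""
    species = _parse_species(species)
    anchors: list[GeneId] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            name = line.strip()
            if name:
                anchors.append(GeneId(species, name))
    return anchors


def read_ortholog_candidates(path: str | Path) -> list[tuple[GeneId, GeneId]]:
    """Read fission->budding ortholog candidates (columns pombe_gene,
    cerevisiae_gene).  A pombe gene listed on several lines keeps every
    candidate; ambiguity is resolved later by alignment score."""
    pairs: list[tuple[GeneId, GeneId]] = []
    for _, (sp_gene, sc_gene) in _rows(path, ["pombe_gene", "cerevisiae_gene"]):
        pairs.append(
            (GeneId(Species.POMBE, sp_gene), GeneId(Species.CEREVISIAE, sc_gene))
        )
    return pairs


def read_fasta(
    path: str | Path, species: str | Species
) -> dict[GeneId, ProteinSequence]:
    species = _parse_species(species)
    sequences: dict[GeneId, ProteinSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        gene = GeneId(species, record.id)
        try:
            seq = ProteinSequence(gene=gene, residues=str(record.seq).upper())
        except ValueError as exc:
            raise ValueError(f"{path}: record {record.id!r}: {exc}") from None
        sequences[gene] = seq
    return sequences


def write_fasta(sequences: dict[GeneId, ProteinSequence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(sequences, key=lambda g: g.systematic_name):
            fh.write(f">{gene.systematic_name}\n{sequences[gene].residues}\n")


def read_ppi_edges(
    path: str | Path, species: str | Species
) -> list[tuple[GeneId, GeneId]]:
    """Read an undirected PPI edge list (columns gene_a, gene_b)."""
    species = _parse_species(species)
    edges: list[tuple[GeneId, GeneId]] = []
    for _, (a, b) in _rows(path, ["gene_a", "gene_b"]):
        edges.append((GeneId(species, a), GeneId(species, b)))
    return edges
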