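"""Synthetic two-species worlds with planted telomere-maintenance structure.

Every file the pipeline consumes (GI edge lists, GMT gene sets, phenotype
labels, PPI edges, anchor lists, ortholog candidates, protein FASTA) can be
generated here with known ground truth, so each stage is testable without
any external database:

* a fraction of genes are TLM, each with a short or long knockout phenotype
  (the short/long balance is parameterized per species, since the two
  yeasts have opposite majority phenotypes);
* pathways and GO terms are phenotype-associated or neutral; TLM genes
  interact (non-zero GI) with members of their phenotype's associated sets
  at an elevated rate over the background density;
* protein complexes are predominantly one phenotype, so membership
  indicators separate the classes;
* TLM genes attach preferentially to anchor genes in the PPI network;
* ortholog pairs conserve TLM status and phenotype with tunable
  probabilities, and ambiguous candidates carry mutated sequences whose
  alignment scores identify the true partner;
* a fraction of TLM genes are "masked": their labels are withheld from the
  emitted files (ground truth keeps them) so discovery methods can be
  scored on recovering them.

All randomness flows through per-stage generators keyed by (seed, stage
name), so adding a stage never perturbs earlier stages' draws and the same
seed always emits byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .io import write_fasta, write_gene_sets
from .propagation import PPINetwork
from .types import (
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

AA20 = "ACDEFGHIKLMNPQRSTVWY"

SHORT_VARIANTS = ("short", "very short", "slightly short", "DAmP Short")
LONG_VARIANTS = ("long", "very long", "slightly long", "DAmP Long")


@dataclass(frozen=True)
class WorldParams:
    """Generator settings; the defaults define the benchmark conditions."""

    n_genes: int = 400
    n_pathways: int = 20
    n_complexes: int = 25
    n_go_terms: int = 30
    set_size_min: int = 4
    set_size_max: int = 14
    fraction_tlm: float = 0.30
    p_short_tlm_cerevisiae: float = 0.62  # budding yeast: short majority
    p_short_tlm_pombe: float = 0.25  # fission yeast: long majority
    gi_signal: float = 0.6  # P(non-zero GI to an associated-set member)
    gi_background: float = 0.02
    associated_pathway_fraction: float = 0.6
    associated_complex_fraction: float = 0.8
    complex_tlm_fraction: float = 0.6  # share of an associated complex drawn from TLM genes
    complex_purity: float = 0.85  # majority-phenotype share among those TLM members
    ppi_density: float = 0.02
    anchor_edge_prob: float = 0.35
    n_anchors: int = 10
    ortholog_coverage: float = 0.8
    tlm_conservation: float = 0.5  # P(pombe gene is TLM | its ortholog is TLM)
    phenotype_conservation: float = 0.6  # P(same phenotype | both TLM)
    ambiguous_fraction: float = 0.15
    seq_length_min: int = 60
    seq_length_max: int = 120
    mutation_rate: float = 0.05
    decoy_mutation_rate: float = 0.30
    masked_tlm_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.fraction_tlm, self.p_short_tlm_cerevisiae, self.p_short_tlm_pombe,
            self.gi_signal, self.gi_background, self.associated_pathway_fraction,
            self.associated_complex_fraction, self.complex_tlm_fraction,
            self.complex_purity, self.ppi_density, self.anchor_edge_prob,
            self.ortholog_coverage, self.tlm_conservation,
            self.phenotype_conservation, self.ambiguous_fraction,
            self.mutation_rate, self.decoy_mutation_rate, self.masked_tlm_fraction,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.fraction_tlm * self.n_genes < 20:
            raise ValueError(
                "fraction_tlm * n_genes must be >= 20 for stable stratification"
            )
        if self.set_size_max > self.n_genes:
            raise ValueError("set sizes exceed the number of genes")


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


@dataclass
class SpeciesWorld:
    species: Species
    genes: list[GeneId]
    tlm_phenotype: dict[GeneId, str]  # true phenotype, masked genes included
    masked: set[GeneId]
    raw_labels: dict[GeneId, list[str]]  # emitted (unmasked) raw categories
    labels: PhenotypeLabels  # emitted reduced labels
    pathways: GeneSetCollection
    go_terms: GeneSetCollection
    complexes: GeneSetCollection
    gi: GIMatrix
    gi_edge_rows: list[tuple]  # rows of the emitted GI file, decoys included
    ppi: PPINetwork
    anchors: list[GeneId]

    @property
    def tlm_genes(self) -> set[GeneId]:
        return set(self.tlm_phenotype)

    @property
    def unmasked_tlm(self) -> set[GeneId]:
        return self.tlm_genes - self.masked


@dataclass
class SyntheticWorld:
    params: WorldParams
    cerevisiae: SpeciesWorld
    pombe: SpeciesWorld
    ortholog_candidates: list[tuple[GeneId, GeneId]]
    true_orthologs: dict[GeneId, GeneId]  # pombe -> correct cerevisiae partner
    sequences: dict[GeneId, ProteinSequence]
    associated_sets: dict[str, dict[str, list[str]]]  # species -> phenotype -> set ids

    def species_world(self, species: Species | str) -> SpeciesWorld:
        return self.cerevisiae if Species(species) is Species.CEREVISIAE else self.pombe


def _gene_names(species: Species, n: int) -> list[GeneId]:
    prefix = "SCG" if species is Species.CEREVISIAE else "SPG"
    return [GeneId(species, f"{prefix}{i:04d}") for i in range(n)]


def _sample_sets(
    rng: np.random.Generator,
    genes: list[GeneId],
    n_sets: int,
    prefix: str,
    source: SetSource,
    size_lo: int,
    size_hi: int,
    external_prefix: str | None = None,
    extra_sizes: tuple[int, ...] = (),
) -> GeneSetCollection:
    """Random gene sets; ``extra_sizes`` appends sets of fixed sizes (used
    to plant out-of-bounds GO terms that size filtering must remove)."""
    coll = GeneSetCollection(source=source)
    sizes = list(rng.integers(size_lo, size_hi + 1, size=n_sets)) + list(extra_sizes)
    for k, size in enumerate(sizes):
        members = tuple(
            genes[i] for i in sorted(rng.choice(len(genes), size=size, replace=False))
        )
        ext = None
        if external_prefix is not None and k < n_sets + len(extra_sizes) - 1:
            ext = f"{external_prefix}{k:05d}"
        coll.add(
            GeneSet(set_id=f"{prefix}{k:04d}", name=f"{prefix} set {k}",
                    members=members, external_id=ext)
        )
    return coll


def _assign_phenotype_associations(
    rng: np.random.Generator, set_ids: list[str], fraction: float
) -> dict[str, list[str]]:
    n_assoc = int(round(fraction * len(set_ids)))
    chosen = list(rng.permutation(set_ids)[:n_assoc])
    assoc = {"short": [], "long": []}
    for i, sid in enumerate(sorted(chosen)):
        assoc["short" if i % 2 == 0 else "long"].append(sid)
    return assoc


def _sample_gi(
    rng: np.random.Generator,
    genes: list[GeneId],
    tlm_phenotype: dict[GeneId, str],
    signal_targets: dict[str, np.ndarray],
    params: WorldParams,
) -> np.ndarray:
    """Boolean interaction mask: background density everywhere, elevated
    rate from a TLM gene to its phenotype's associated-set members."""
    n = len(genes)
    mask = rng.random((n, n)) < params.gi_background
    for i, g in enumerate(genes):
        ph = tlm_phenotype.get(g)
        if ph is None:
            continue
        targets = signal_targets[ph]
        mask[i, targets] |= rng.random(targets.size) < params.gi_signal
    # the assembled matrix spans every gene on both axes, so guarantee each
    # gene at least one outgoing and one incoming interaction
    for i in np.flatnonzero(~mask.any(axis=1)):
        mask[i, rng.integers(n)] = True
    for j in np.flatnonzero(~mask.any(axis=0)):
        mask[rng.integers(n), j] = True
    return mask


def _scored_edge_rows(
    rng: np.random.Generator, genes: list[GeneId], mask: np.ndarray
) -> tuple[list[tuple], sp.csr_matrix]:
    """Emit scored edge rows (with sub-threshold decoys and duplicate
    measurements) and the matrix the reader should reconstruct."""
    n = len(genes)
    ii, jj = np.nonzero(mask)
    scores = np.round(rng.normal(0.0, 0.3, size=ii.size), 4)
    scores[scores == 0.0] = 0.1
    pvals = np.round(rng.uniform(0.0005, 0.049, size=ii.size), 5)
    rows: list[tuple] = []
    for k in range(ii.size):
        rows.append(
            (genes[ii[k]].systematic_name, genes[jj[k]].systematic_name,
             scores[k], pvals[k])
        )
    # duplicate measurements with strictly larger p (must lose the
    # lowest-p contest) and decoy edges with p >= 0.05 (must be dropped)
    n_dup = min(200, ii.size)
    dup_idx = rng.choice(ii.size, size=n_dup, replace=False)
    for k in dup_idx:
        rows.append(
            (genes[ii[k]].systematic_name, genes[jj[k]].systematic_name,
             round(float(rng.normal(0.0, 0.3)), 4),
             round(float(pvals[k] + rng.uniform(0.001, 0.9)), 5))
        )
    n_noise = max(1, ii.size // 10)
    for _ in range(n_noise):
        rows.append(
            (genes[rng.integers(n)].systematic_name,
             genes[rng.integers(n)].systematic_name,
             round(float(rng.normal(0.0, 0.3)), 4),
             round(float(rng.uniform(0.05, 0.999)), 5))
        )
    order = rng.permutation(len(rows))
    rows = [rows[k] for k in order]
    matrix = sp.csr_matrix((scores, (ii, jj)), shape=(n, n))
    return rows, matrix


def _binary_edge_rows(
    genes: list[GeneId], mask: np.ndarray
) -> tuple[list[tuple], sp.csr_matrix]:
    ii, jj = np.nonzero(mask)
    rows = [
        (genes[i].systematic_name, genes[j].systematic_name) for i, j in zip(ii, jj)
    ]
    matrix = sp.csr_matrix(
        (np.ones(ii.size), (ii, jj)), shape=(len(genes), len(genes))
    )
    return rows, matrix


def _sample_ppi(
    rng: np.random.Generator,
    genes: list[GeneId],
    tlm: set[GeneId],
    anchors: list[GeneId],
    params: WorldParams,
) -> PPINetwork:
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    upper = np.triu(rng.random((n, n)) < params.ppi_density, k=1)
    adj = upper | upper.T
    anchor_idx = np.array([idx[a] for a in anchors])
    for g in tlm:
        i = idx[g]
        hits = anchor_idx[rng.random(anchor_idx.size) < params.anchor_edge_prob]
        adj[i, hits] = True
        adj[hits, i] = True
    np.fill_diagonal(adj, False)
    return PPINetwork(nodes=list(genes), adjacency=sp.csr_matrix(adj.astype(float)))


def _raw_label_rows(
    rng: np.random.Generator, phenotype: dict[GeneId, str], masked: set[GeneId]
) -> dict[GeneId, list[str]]:
    """Raw category strings for unmasked TLM genes; one long gene is also
    observed as 'normal' to exercise the normal/variant reduction rule."""
    raw: dict[GeneId, list[str]] = {}
    dual_done = False
    for g in sorted(phenotype, key=lambda x: x.systematic_name):
        if g in masked:
            continue
        variants = SHORT_VARIANTS if phenotype[g] == "short" else LONG_VARIANTS
        cats = [variants[rng.integers(len(variants))]]
        if not dual_done and phenotype[g] == "long":
            cats.append("normal")
            dual_done = True
        raw[g] = cats
    return raw


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = AA20.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _generate_species(
    species: Species,
    params: WorldParams,
    tlm_phenotype: dict[GeneId, str],
    genes: list[GeneId],
) -> tuple[SpeciesWorld, dict[str, list[str]]]:
    tag = species.value
    rng_sets = _rng(params.seed, f"{tag}:sets")
    pathways = _sample_sets(
        rng_sets, genes, params.n_pathways, "path", SetSource.KEGG,
        params.set_size_min, params.set_size_max,
    )
    go_terms = _sample_sets(
        rng_sets, genes, params.n_go_terms, "GOBP:", SetSource.GO_BP,
        params.set_size_min, params.set_size_max,
        extra_sizes=(2, 35),  # out-of-bounds terms the size filter must drop
    )
    assoc = {"short": [], "long": []}
    path_assoc = _assign_phenotype_associations(
        _rng(params.seed, f"{tag}:assoc_path"), list(pathways.sets), params.associated_pathway_fraction
    )
    go_assoc = _assign_phenotype_associations(
        _rng(params.seed, f"{tag}:assoc_go"),
        [s for s in go_terms.sets][: params.n_go_terms],
        params.associated_pathway_fraction,
    )
    for ph in ("short", "long"):
        assoc[ph] = path_assoc[ph] + go_assoc[ph]

    # phenotype-biased protein complexes
    rng_cplx = _rng(params.seed, f"{tag}:complexes")
    complexes = GeneSetCollection(source=SetSource.COMPLEX)
    tlm_by_ph = {
        ph: [g for g, p in tlm_phenotype.items() if p == ph] for ph in ("short", "long")
    }
    non_tlm = [g for g in genes if g not in tlm_phenotype]
    n_assoc_cplx = int(round(params.associated_complex_fraction * params.n_complexes))
    for k in range(params.n_complexes):
        size = int(rng_cplx.integers(4, 11))
        members: list[GeneId] = []
        if k < n_assoc_cplx:
            ph = "short" if k % 2 == 0 else "long"
            other = "long" if ph == "short" else "short"
            n_tlm = max(2, int(round(size * params.complex_tlm_fraction)))
            for _ in range(n_tlm):
                pool = tlm_by_ph[ph if rng_cplx.random() < params.complex_purity else other]
                if not pool:
                    pool = tlm_by_ph[other] or non_tlm
                members.append(pool[rng_cplx.integers(len(pool))])
            assoc[ph].append(f"cplx{k:04d}")
        else:
            n_tlm = 0
        while len(set(members)) < size:
            members.append(non_tlm[rng_cplx.integers(len(non_tlm))])
        uniq = sorted(set(members), key=lambda g: g.systematic_name)
        # every complex but the last carries a GO accession shared across
        # species, supporting cross-species feature mapping
        ext = f"GO:08{k:05d}" if k < params.n_complexes - 1 else None
        complexes.add(
            GeneSet(set_id=f"cplx{k:04d}", name=f"complex {k}",
                    members=tuple(uniq), external_id=ext)
        )

    # genetic interactions
    gene_index = {g: i for i, g in enumerate(genes)}
    signal_targets = {}
    for ph in ("short", "long"):
        cols: set[int] = set()
        for coll in (pathways, go_terms):
            for sid in assoc[ph]:
                if sid in coll.sets:
                    cols.update(gene_index[m] for m in coll.sets[sid].members)
        signal_targets[ph] = np.array(sorted(cols), dtype=int)
    mask = _sample_gi(
        _rng(params.seed, f"{tag}:gi"), genes, tlm_phenotype, signal_targets, params
    )
    if species is Species.CEREVISIAE:
        edge_rows, matrix = _scored_edge_rows(
            _rng(params.seed, f"{tag}:gi_scores"), genes, mask
        )
        kind = GIValueKind.SCORED
    else:
        edge_rows, matrix = _binary_edge_rows(genes, mask)
        kind = GIValueKind.BINARY
    gi = GIMatrix(
        genes_rows=list(genes), genes_cols=list(genes), scores=matrix, value_kind=kind
    )

    # masking, labels, anchors, PPI
    rng_mask = _rng(params.seed, f"{tag}:mask")
    tlm_sorted = sorted(tlm_phenotype, key=lambda g: g.systematic_name)
    masked = {g for g in tlm_sorted if rng_mask.random() < params.masked_tlm_fraction}
    raw = _raw_label_rows(_rng(params.seed, f"{tag}:raw_labels"), tlm_phenotype, masked)
    labels = PhenotypeLabels(
        labels={g: tlm_phenotype[g] for g in raw}, raw_labels=raw
    )
    rng_anchor = _rng(params.seed, f"{tag}:anchors")
    unmasked = sorted(set(tlm_sorted) - masked, key=lambda g: g.systematic_name)
    anchor_pos = rng_anchor.choice(len(unmasked), size=params.n_anchors, replace=False)
    anchors = [unmasked[i] for i in sorted(anchor_pos)]
    ppi = _sample_ppi(
        _rng(params.seed, f"{tag}:ppi"), genes, set(tlm_phenotype), anchors, params
    )
    world = SpeciesWorld(
        species=species, genes=genes, tlm_phenotype=tlm_phenotype, masked=masked,
        raw_labels=raw, labels=labels, pathways=pathways, go_terms=go_terms,
        complexes=complexes, gi=gi, gi_edge_rows=edge_rows, ppi=ppi, anchors=anchors,
    )
    return world, assoc


def generate_world(params: WorldParams) -> SyntheticWorld:
    """Sample a full two-species world with planted TLM structure."""
    sc_genes = _gene_names(Species.CEREVISIAE, params.n_genes)
    sp_genes = _gene_names(Species.POMBE, params.n_genes)

    # budding-yeast phenotypes
    rng_tlm = _rng(params.seed, "cerevisiae:tlm")
    sc_phenotype: dict[GeneId, str] = {}
    for g in sc_genes:
        if rng_tlm.random() < params.fraction_tlm:
            sc_phenotype[g] = (
                "short" if rng_tlm.random() < params.p_short_tlm_cerevisiae else "long"
            )

    # ortholog skeleton: a random one-to-one pairing over the covered genes
    rng_orth = _rng(params.seed, "orthologs")
    n_orth = int(round(params.ortholog_coverage * params.n_genes))
    sp_covered = [sp_genes[i] for i in sorted(rng_orth.choice(params.n_genes, n_orth, replace=False))]
    sc_partner_idx = rng_orth.permutation(params.n_genes)[:n_orth]
    true_orthologs = {
        sp_g: sc_genes[j] for sp_g, j in zip(sp_covered, sc_partner_idx)
    }

    # fission-yeast phenotypes: conserve TLM status/phenotype through the
    # ortholog map, with a base rate tuned to keep the overall TLM fraction
    rng_sp = _rng(params.seed, "pombe:tlm")
    n_conserved_exp = params.ortholog_coverage * params.fraction_tlm * params.tlm_conservation
    denom = 1.0 - params.ortholog_coverage * params.fraction_tlm
    base_rate = max(0.0, min(1.0, (params.fraction_tlm - n_conserved_exp) / denom))
    sp_phenotype: dict[GeneId, str] = {}
    for g in sp_genes:
        ortholog = true_orthologs.get(g)
        if ortholog is not None and ortholog in sc_phenotype:
            if rng_sp.random() < params.tlm_conservation:
                same = rng_sp.random() < params.phenotype_conservation
                ph_sc = sc_phenotype[ortholog]
                sp_phenotype[g] = ph_sc if same else ("long" if ph_sc == "short" else "short")
        elif rng_sp.random() < base_rate:
            sp_phenotype[g] = (
                "short" if rng_sp.random() < params.p_short_tlm_pombe else "long"
            )

    cerevisiae, assoc_sc = _generate_species(
        Species.CEREVISIAE, params, sc_phenotype, sc_genes
    )
    pombe, assoc_sp = _generate_species(Species.POMBE, params, sp_phenotype, sp_genes)

    # candidate table with ambiguous decoys, plus sequences
    rng_seq = _rng(params.seed, "sequences")
    candidates: list[tuple[GeneId, GeneId]] = []
    sequences: dict[GeneId, ProteinSequence] = {}
    # true pairs first: each pair descends from a private ancestor, so the
    # true partner always outscores any unrelated decoy
    for sp_g in sp_covered:
        sc_g = true_orthologs[sp_g]
        length = int(rng_seq.integers(params.seq_length_min, params.seq_length_max + 1))
        ancestor = "".join(AA20[i] for i in rng_seq.integers(0, 20, size=length))
        sequences[sp_g] = ProteinSequence(sp_g, _mutate(rng_seq, ancestor, params.mutation_rate))
        sequences[sc_g] = ProteinSequence(
            sc_g, _mutate(rng_seq, ancestor, params.mutation_rate)
        )
        candidates.append((sp_g, sc_g))
    rng_decoy = _rng(params.seed, "decoys")
    for sp_g in sp_covered:
        if rng_decoy.random() >= params.ambiguous_fraction:
            continue
        decoy = sc_genes[int(rng_decoy.integers(len(sc_genes)))]
        if decoy == true_orthologs[sp_g]:
            continue
        if decoy not in sequences:
            dl = int(rng_decoy.integers(params.seq_length_min, params.seq_length_max + 1))
            sequences[decoy] = ProteinSequence(
                decoy, "".join(AA20[i] for i in rng_decoy.integers(0, 20, size=dl))
            )
        candidates.append((sp_g, decoy))

    return SyntheticWorld(
        params=params,
        cerevisiae=cerevisiae,
        pombe=pombe,
        ortholog_candidates=candidates,
        true_orthologs=true_orthologs,
        sequences=sequences,
        associated_sets={"cerevisiae": assoc_sc, "pombe": assoc_sp},
    )


def _write_tsv(path: Path, header: list[str], rows: list[tuple]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_world(world: SyntheticWorld, directory: str | Path) -> dict[str, str]:
    """Emit every pipeline input file plus a ground-truth JSON.

    Returns a manifest of relative path -> SHA-256.  On any failure the
    files written so far are removed before the error propagates.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = directory / name
        writer(path)
        written.append(path)

    try:
        emit("cerevisiae_gi.tsv", lambda p: _write_tsv(
            p, ["gene_a", "gene_b", "score", "p_value"], world.cerevisiae.gi_edge_rows
        ))
        emit("pombe_gi.tsv", lambda p: _write_tsv(
            p, ["gene_a", "gene_b"], world.pombe.gi_edge_rows
        ))
        for sw in (world.cerevisiae, world.pombe):
            tag = sw.species.value
            emit(f"{tag}_pathways.gmt", lambda p, sw=sw: write_gene_sets(sw.pathways, p))
            emit(f"{tag}_go_bp.gmt", lambda p, sw=sw: write_gene_sets(sw.go_terms, p))
            emit(f"{tag}_complexes.gmt", lambda p, sw=sw: write_gene_sets(sw.complexes, p))
            label_rows = [
                (g.systematic_name, cat)
                for g in sorted(sw.raw_labels, key=lambda x: x.systematic_name)
                for cat in sw.raw_labels[g]
            ]
            emit(f"{tag}_labels.tsv", lambda p, rows=label_rows: _write_tsv(
                p, ["gene", "raw_label"], rows
            ))
            tri = sp.triu(sw.ppi.adjacency, k=1).tocoo()
            ppi_rows = sorted(
                (sw.ppi.nodes[i].systematic_name, sw.ppi.nodes[j].systematic_name)
                for i, j in zip(tri.row, tri.col)
            )
            emit(f"{tag}_ppi.tsv", lambda p, rows=ppi_rows: _write_tsv(
                p, ["gene_a", "gene_b"], rows
            ))
            emit(f"{tag}_anchors.txt", lambda p, sw=sw: p.write_text(
                "".join(a.systematic_name + "\n" for a in sw.anchors), encoding="utf-8"
            ))
        cand_rows = [
            (sp_g.systematic_name, sc_g.systematic_name)
            for sp_g, sc_g in world.ortholog_candidates
        ]
        emit("ortholog_candidates.tsv", lambda p: _write_tsv(
            p, ["pombe_gene", "cerevisiae_gene"], cand_rows
        ))
        for species in (Species.CEREVISIAE, Species.POMBE):
            seqs = {
                g: s for g, s in world.sequences.items() if g.species is species
            }
            emit(f"{species.value}_proteins.fasta", lambda p, s=seqs: write_fasta(s, p))
        truth = {
            "params": asdict(world.params),
            "associated_sets": world.associated_sets,
            "masked_tlm": {
                sw.species.value: sorted(g.systematic_name for g in sw.masked)
                for sw in (world.cerevisiae, world.pombe)
            },
            "true_phenotypes": {
                sw.species.value: {
                    g.systematic_name: ph for g, ph in sorted(
                        sw.tlm_phenotype.items(), key=lambda kv: kv[0].systematic_name
                    )
                }
                for sw in (world.cerevisiae, world.pombe)
            },
            "true_orthologs": {
                sp_g.systematic_name: sc_g.systematic_name
                for sp_g, sc_g in sorted(
                    world.true_orthologs.items(), key=lambda kv: kv[0].systematic_name
                )
            },
        }
        emit("ground_truth.json", lambda p: p.write_text(
            json.dumps(truth, indent=1, sort_keys=True), encoding="utf-8"
        ))
    except BaseException:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    manifest: dict[str, str] = {}
    for path in written:
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return manifest
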