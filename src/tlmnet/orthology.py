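"""Ortholog resolution and cross-species phenotype conservation.

A curated fission->budding candidate table may list several budding-yeast
candidates for one fission-yeast gene.  Ambiguity is resolved by local
(Smith-Waterman) protein alignment under BLOSUM62 with affine gaps (open
11, extend 1 — the NCBI BLAST protein defaults): the highest-scoring
candidate wins.  Conservation statistics then ask how often an ortholog
pair is telomere-length-maintenance (TLM) in both species, and whether the
short/long knockout phenotype is preserved across the pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import binomtest

from .types import GeneId, PhenotypeLabels, ProteinSequence, Species


@dataclass(frozen=True)
class AlignmentParams:
    matrix_name: str = "BLOSUM62"
    gap_open_cost: float = 11.0
    gap_extend_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open_cost <= 0 or self.gap_extend_cost <= 0:
            raise ValueError("gap costs must be positive")


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    # A gap of length L costs open + (L-1)*extend, the BLAST convention.
    aligner.open_gap_score = -params.gap_open_cost
    aligner.extend_gap_score = -params.gap_extend_cost
    return aligner


def sw_local_align(
    a: ProteinSequence,
    b: ProteinSequence,
    params: AlignmentParams = AlignmentParams(),
) -> float:
    """Maximum Smith-Waterman local-alignment score (floored at 0)."""
    aligner = _make_aligner(params)
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    for seq in (a, b):
        bad = set(seq.residues) - alphabet
        if bad:
            raise ValueError(
                f"residues {sorted(bad)} of {seq.gene.systematic_name} "
                f"not in the {params.matrix_name} alphabet"
            )
    return float(aligner.score(a.residues, b.residues))


@dataclass(frozen=True)
class OrthologPair:
    pombe_gene: GeneId
    cerevisiae_gene: GeneId
    alignment_score: float  # NaN for unambiguous pairs (no alignment needed)
    was_ambiguous: bool


@dataclass
class OrthologTable:
    pairs: list[OrthologPair]

    def __post_init__(self) -> None:
        seen = set()
        for p in self.pairs:
            if p.pombe_gene in seen:
                raise ValueError(
                    f"pombe gene {p.pombe_gene.systematic_name} resolved twice"
                )
            seen.add(p.pombe_gene)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def mapping(self) -> dict[GeneId, GeneId]:
        return {p.pombe_gene: p.cerevisiae_gene for p in self.pairs}


def resolve_orthologs(
    candidates: list[tuple[GeneId, GeneId]],
    sequences: dict[GeneId, ProteinSequence],
    params: AlignmentParams = AlignmentParams(),
) -> OrthologTable:
    """Resolve many-to-one candidates to one budding-yeast ortholog per
    fission-yeast gene.

    Unambiguous genes pass through without alignment.  For ambiguous genes
    every candidate (and the pombe gene itself) must have a sequence; the
    candidate with the maximal local-alignment score wins, ties going to
    the lexicographically smaller systematic name.
    """
    by_pombe: dict[GeneId, list[GeneId]] = {}
    for sp_gene, sc_gene in candidates:
        by_pombe.setdefault(sp_gene, []).append(sc_gene)
    pairs: list[OrthologPair] = []
    for sp_gene in sorted(by_pombe, key=lambda g: g.systematic_name):
        cands = sorted(set(by_pombe[sp_gene]), key=lambda g: g.systematic_name)
        if len(cands) == 1:
            pairs.append(
                OrthologPair(sp_gene, cands[0], float("nan"), was_ambiguous=False)
            )
            continue
        if sp_gene not in sequences:
            raise KeyError(
                f"no sequence for ambiguous pombe gene {sp_gene.systematic_name}"
            )
        best: tuple[float, GeneId] | None = None
        best_score = -math.inf
        for sc_gene in cands:
            if sc_gene not in sequences:
                raise KeyError(
                    f"no sequence for candidate {sc_gene.systematic_name} "
                    f"of {sp_gene.systematic_name}"
                )
            score = sw_local_align(sequences[sp_gene], sequences[sc_gene], params)
            if score > best_score:  # ties keep the earlier (lex-smaller) name
                best_score = score
                best = (score, sc_gene)
        assert best is not None
        pairs.append(OrthologPair(sp_gene, best[1], best[0], was_ambiguous=True))
    return OrthologTable(pairs=pairs)


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConservationReport:
    """Counts and percentages of TLM status / phenotype conservation
    across resolved ortholog pairs."""

    n_orthologs: int
    n_tlm_both: int
    n_tlm_either: int
    n_phenotype_preserved: int
    n_short_preserved: int
    n_long_preserved: int
    preservation_p_value: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.n_phenotype_preserved != self.n_short_preserved + self.n_long_preserved:
            raise ValueError("preserved counts do not add up")

    def _pct(self, num: int, den: int, decimals: int) -> float:
        if den == 0:
            return 0.0
        return _round_half_up(100.0 * num / den, decimals)

    def pct_tlm_both(self, decimals: int = 2) -> float:
        """Percent of ortholog pairs that are TLM in both species."""
        return self._pct(self.n_tlm_both, self.n_orthologs, decimals)

    def pct_tlm_both_of_either(self, decimals: int = 2) -> float:
        """Among pairs TLM in at least one species, percent TLM in both."""
        return self._pct(self.n_tlm_both, self.n_tlm_either, decimals)

    def pct_phenotype_preserved(self, decimals: int = 2) -> float:
        """Among both-TLM pairs, percent with the same short/long phenotype."""
        return self._pct(self.n_phenotype_preserved, self.n_tlm_both, decimals)

    def pct_short_preserved(self, decimals: int = 2) -> float:
        return self._pct(self.n_short_preserved, self.n_tlm_both, decimals)

    def pct_long_preserved(self, decimals: int = 2) -> float:
        return self._pct(self.n_long_preserved, self.n_tlm_both, decimals)

    @property
    def preservation_defined(self) -> bool:
        return self.n_tlm_both > 0


def conservation_stats(
    orthologs: OrthologTable,
    labels_sp: PhenotypeLabels,
    labels_sc: PhenotypeLabels,
) -> ConservationReport:
    """Cross-species TLM conservation over resolved ortholog pairs.

    A gene is TLM in a species iff it carries a short/long label there.
    The significance of phenotype preservation among both-TLM pairs is
    assessed with a two-sided binomial test against a 0.5 match
    probability (the underlying study reports a significance level without
    naming a test; the binomial test is this package's stand-in choice).
    """
    n_total = 0
    n_both = n_either = n_preserved = n_short = n_long = 0
    for pair in orthologs:
        if (
            pair.pombe_gene.species is not Species.POMBE
            or pair.cerevisiae_gene.species is not Species.CEREVISIAE
        ):
            warnings.warn(
                f"ortholog pair ({pair.pombe_gene.systematic_name}, "
                f"{pair.cerevisiae_gene.systematic_name}) has unexpected "
                "species; skipped",
                stacklevel=2,
            )
            continue
        n_total += 1
        ph_sp = labels_sp.labels.get(pair.pombe_gene)
        ph_sc = labels_sc.labels.get(pair.cerevisiae_gene)
        if ph_sp is not None or ph_sc is not None:
            n_either += 1
        if ph_sp is not None and ph_sc is not None:
            n_both += 1
            if ph_sp == ph_sc:
                n_preserved += 1
                if ph_sp == "short":
                    n_short += 1
                else:
                    n_long += 1
    if n_both > 0:
        p_value = binomtest(n_preserved, n_both, 0.5, alternative="two-sided").pvalue
    else:
        p_value = float("nan")
    return ConservationReport(
        n_orthologs=n_total,
        n_tlm_both=n_both,
        n_tlm_either=n_either,
        n_phenotype_preserved=n_preserved,
        n_short_preserved=n_short,
        n_long_preserved=n_long,
        preservation_p_value=float(p_value),
    )
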