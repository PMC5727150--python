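"""Pivot-anchored ortholog families and the persistent genome.

Orthologs between a pivot proteome and every other proteome are called as
reciprocal best hits (RBH) under end-gap-free (semi-global) alignment:
each protein is the other's unique best-scoring partner, and the pair
survives two filters — similarity at least ``min_similarity`` (default
37%) over the alignment core, and relative length difference at most
``max_length_diff`` (default 20%).  Families are keyed by pivot protein
(the intersection of pairwise ortholog lists), the *persistent* families
are those present in at least ``quorum`` (default 90%) of genomes, and
their per-family alignment blocks are concatenated — genomes missing a
family contribute a stretch of gaps — into the alignment a species tree
can be built from.

Conventions (both configurable, both logged in the run manifest):

* *similarity* is the fraction of core columns (terminal gaps excluded)
  whose residue pair has a positive substitution score; internal-gap
  columns count as dissimilar.  BLOSUM62 with gap open -11 / extend -1 by
  default.
* *relative length difference* uses the longer sequence as denominator:
  ``|La - Lb| / max(La, Lb)``.

Multiple alignment is pivot-anchored: every member is aligned pairwise to
the pivot and merged on pivot coordinates, with member insertions stacked
in gap-padded columns.  This is an approximation to a proper progressive
MSA, valid here because every persistent family contains the pivot;
externally computed alignments can be supplied instead.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologyParams",
    "PairwiseAlignment",
    "OrthologFamily",
    "AlignmentBlock",
    "PersistentGenome",
    "RBHResult",
    "align_semiglobal",
    "similarity",
    "reciprocal_best_hits",
    "build_families",
    "persistent_filter",
    "quorum_threshold",
    "pivot_anchored_msa",
    "trim_columns",
    "concatenate",
    "build_persistent_genome",
]

GAP = "-"


@dataclass(frozen=True)
class OrthologyParams:
    """Thresholds and scoring parameters for the orthology stage."""

    min_similarity: float = 0.37
    max_length_diff: float = 0.20
    quorum: float = 0.90
    gap_open: float = -11.0
    gap_extend: float = -1.0
    substitution_matrix: str = "BLOSUM62"
    max_gap_fraction_per_column: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_similarity <= 1:
            raise ValueError("min_similarity must be in (0, 1]")
        if not 0 <= self.max_length_diff < 1:
            raise ValueError("max_length_diff must be in [0, 1)")
        if not 0 < self.quorum <= 1:
            raise ValueError("quorum must be in (0, 1]")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap scores must be nonpositive")
        if not 0 <= self.max_gap_fraction_per_column <= 1:
            raise ValueError("max_gap_fraction_per_column must be in [0, 1]")

    def matrix(self):
        return substitution_matrices.load(self.substitution_matrix)

    def manifest(self) -> dict:
        return {
            "min_similarity": self.min_similarity,
            "max_length_diff": self.max_length_diff,
            "length_diff_denominator": "longer sequence",
            "similarity_definition": "positive-score core columns / core length",
            "quorum": self.quorum,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "substitution_matrix": self.substitution_matrix,
            "max_gap_fraction_per_column": self.max_gap_fraction_per_column,
        }


def _aligner(params: OrthologyParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = params.matrix()
    al.mode = "global"
    al.open_gap_score = params.gap_open
    al.extend_gap_score = params.gap_extend
    # terminal gaps in either sequence are free (end-gap-free alignment)
    al.end_insertion_score = 0.0
    al.end_deletion_score = 0.0
    return al


def _check_sequence(seq: str, alphabet: str, who: str) -> None:
    if not seq:
        raise ValueError(f"{who}: empty sequence")
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"{who}: invalid residue(s) {sorted(bad)}")


@dataclass
class PairwiseAlignment:
    """One end-gap-free global alignment with its similarity statistics.

    ``core_start``/``core_end`` delimit (half-open, in alignment columns)
    the region excluding terminal gaps of either sequence.
    """

    aligned_a: str
    aligned_b: str
    score: float
    similarity: float
    core_start: int
    core_end: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences must have equal length")


def _core_span(aligned_a: str, aligned_b: str) -> tuple[int, int]:
    def span(s: str) -> tuple[int, int]:
        first = len(s) - len(s.lstrip(GAP))
        last = len(s.rstrip(GAP))
        return first, last

    a0, a1 = span(aligned_a)
    b0, b1 = span(aligned_b)
    return max(a0, b0), min(a1, b1)


def _similarity_from_aligned(aligned_a: str, aligned_b: str, matrix) -> tuple[float, int, int]:
    start, end = _core_span(aligned_a, aligned_b)
    if end <= start:
        raise ValueError("undefined similarity: zero-length alignment core")
    positive = 0
    for ca, cb in zip(aligned_a[start:end], aligned_b[start:end]):
        if ca != GAP and cb != GAP and matrix[ca, cb] > 0:
            positive += 1
    return positive / (end - start), start, end


def align_semiglobal(a: str, b: str, params: OrthologyParams | None = None) -> PairwiseAlignment:
    """Optimal global alignment with free terminal gaps.

    Gap of length k scores ``gap_open + (k - 1) * gap_extend`` when
    internal, 0 at either end of either sequence.  Ties in the traceback
    are broken deterministically (first optimal alignment of the
    underlying dynamic program).
    """
    params = params or OrthologyParams()
    matrix = params.matrix()
    alphabet = str(matrix.alphabet)
    _check_sequence(a, alphabet, "sequence a")
    _check_sequence(b, alphabet, "sequence b")
    al = _aligner(params)
    aln = al.align(a, b)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    try:
        sim, start, end = _similarity_from_aligned(aligned_a, aligned_b, matrix)
    except ValueError:
        # optimal alignment has no overlap (mutual terminal gaps only):
        # nothing aligns, similarity is zero by convention
        sim, start, end = 0.0, 0, 0
    return PairwiseAlignment(
        aligned_a=aligned_a, aligned_b=aligned_b, score=float(aln.score),
        similarity=sim, core_start=start, core_end=end,
    )


def similarity(alignment: PairwiseAlignment, params: OrthologyParams | None = None) -> float:
    """Positive-scoring core-column fraction of an existing alignment."""
    params = params or OrthologyParams()
    sim, _, _ = _similarity_from_aligned(
        alignment.aligned_a, alignment.aligned_b, params.matrix())
    return sim


def relative_length_difference(a: str, b: str) -> float:
    """|La - Lb| / max(La, Lb) — longer-sequence denominator."""
    return abs(len(a) - len(b)) / max(len(a), len(b))


@dataclass
class RBHResult:
    """Reciprocal-best-hit pairs plus the pairs filtered out, with reasons."""

    pairs: list[tuple[str, str]]
    filtered: list[tuple[str, str, str]] = field(default_factory=list)


def _best_hits(ids_a, ids_b, scores: np.ndarray) -> dict[str, str | None]:
    """Unique best partner in b for each a (None on a score tie)."""
    out: dict[str, str | None] = {}
    for i, pid in enumerate(ids_a):
        row = scores[i]
        m = row.max()
        winners = np.flatnonzero(row == m)
        out[pid] = ids_b[winners[0]] if len(winners) == 1 else None
    return out


def reciprocal_best_hits(pivot_proteome: dict[str, str],
                         other_proteome: dict[str, str],
                         params: OrthologyParams | None = None) -> RBHResult:
    """RBH pairs between two proteomes, after similarity and length filters.

    A pair is kept when each protein is the other's *unique* best-scoring
    partner (score ties make the hit ambiguous and drop it, logged), the
    core similarity is >= ``min_similarity`` and the relative length
    difference is <= ``max_length_diff``.  Filtered pairs are returned
    with the reason.
    """
    params = params or OrthologyParams()
    if not pivot_proteome or not other_proteome:
        raise ValueError("both proteomes must be nonempty")
    al = _aligner(params)
    ids_p = list(pivot_proteome)
    ids_o = list(other_proteome)
    scores = np.empty((len(ids_p), len(ids_o)))
    for i, pid in enumerate(ids_p):
        for j, oid in enumerate(ids_o):
            scores[i, j] = al.score(pivot_proteome[pid], other_proteome[oid])
    best_po = _best_hits(ids_p, ids_o, scores)
    best_op = _best_hits(ids_o, ids_p, scores.T)
    pairs: list[tuple[str, str]] = []
    filtered: list[tuple[str, str, str]] = []
    for pid in ids_p:
        oid = best_po[pid]
        if oid is None:
            filtered.append((pid, "", "ambiguous-best-hit-tie"))
            logger.info("RBH: %s has tied best hits; skipped", pid)
            continue
        if best_op[oid] is None:
            filtered.append((pid, oid, "ambiguous-best-hit-tie"))
            logger.info("RBH: %s has tied best hits; skipped", oid)
            continue
        if best_op[oid] != pid:
            continue
        a, b = pivot_proteome[pid], other_proteome[oid]
        if relative_length_difference(a, b) > params.max_length_diff:
            filtered.append((pid, oid, "length-difference"))
            continue
        aln = align_semiglobal(a, b, params)
        if aln.similarity < params.min_similarity:
            filtered.append((pid, oid, "low-similarity"))
            continue
        pairs.append((pid, oid))
    return RBHResult(pairs=pairs, filtered=filtered)


@dataclass
class OrthologFamily:
    """One ortholog family: a pivot protein and its RBH partners.

    ``members`` maps genome_id -> protein_id, at most one per genome; the
    pivot genome is always a member.
    """

    family_id: str
    pivot_protein_id: str
    members: dict[str, str]

    def __len__(self) -> int:
        return len(self.members)


def build_families(pivot: str, all_proteomes: dict[str, dict[str, str]],
                   params: OrthologyParams | None = None) -> list[OrthologFamily]:
    """Ortholog families keyed by pivot protein, across all proteomes.

    Runs RBH between the pivot proteome and every other proteome; a family
    is emitted for each pivot protein with at least one partner.
    """
    params = params or OrthologyParams()
    if pivot not in all_proteomes:
        raise ValueError(f"pivot genome {pivot!r} not among proteomes")
    pivot_prot = all_proteomes[pivot]
    members: dict[str, dict[str, str]] = {pid: {pivot: pid} for pid in pivot_prot}
    for gid, proteome in all_proteomes.items():
        if gid == pivot:
            continue
        if not proteome:
            continue
        rbh = reciprocal_best_hits(pivot_prot, proteome, params)
        for pid, oid in rbh.pairs:
            members[pid][gid] = oid
    families = []
    for k, (pid, mem) in enumerate(members.items(), start=1):
        if len(mem) >= 2:
            families.append(OrthologFamily(
                family_id=f"F{k:04d}", pivot_protein_id=pid, members=dict(mem)))
    return families


def persistent_filter(families: list[OrthologFamily], n_genomes: int,
                      quorum: float = 0.90) -> list[OrthologFamily]:
    """Families present in at least ceil(quorum * n_genomes) genomes."""
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    threshold = math.ceil(quorum * n_genomes - 1e-9)
    return [f for f in families if len(f) >= threshold]


def quorum_threshold(n_genomes: int, quorum: float = 0.90) -> int:
    """Minimum member count for a family to pass the quorum."""
    return math.ceil(quorum * n_genomes - 1e-9)


@dataclass
class AlignmentBlock:
    """A rectangular gapped block: genome_id -> row, all rows equal length."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows.values()}
        if len(widths) > 1:
            raise ValueError("block rows have unequal lengths")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def genomes(self) -> list[str]:
        return list(self.rows)


def pivot_anchored_msa(family: OrthologFamily,
                       sequences: dict[str, dict[str, str]],
                       params: OrthologyParams | None = None) -> AlignmentBlock:
    """Merge member-vs-pivot pairwise alignments on pivot coordinates.

    Every member is aligned to the pivot sequence; columns are the pivot
    positions, plus insertion slots (before each pivot position and after
    the last) padded to the longest insertion any member places there.
    Ungapping any row recovers the member's input sequence.
    """
    params = params or OrthologyParams()
    pivot_genome = next(
        g for g, pid in family.members.items() if pid == family.pivot_protein_id)
    try:
        pivot_seq = sequences[pivot_genome][family.pivot_protein_id]
    except KeyError as exc:
        raise ValueError(f"pivot sequence missing for family {family.family_id}") from exc
    L = len(pivot_seq)
    # per member: matched[i] = residue aligned to pivot position i (or gap);
    # inserts[i] = member residues falling before pivot position i (slot L =
    # after the last position)
    matched: dict[str, list[str]] = {}
    inserts: dict[str, list[str]] = {}
    for genome, pid in family.members.items():
        try:
            seq = sequences[genome][pid]
        except KeyError as exc:
            raise ValueError(
                f"member sequence {pid!r} of genome {genome!r} missing") from exc
        if genome == pivot_genome:
            matched[genome] = list(pivot_seq)
            inserts[genome] = [""] * (L + 1)
            continue
        aln = align_semiglobal(pivot_seq, seq, params)
        mrow = [GAP] * L
        irow = [""] * (L + 1)
        ppos = 0
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca != GAP and cb != GAP:
                mrow[ppos] = cb
                ppos += 1
            elif ca != GAP:
                ppos += 1
            else:  # insertion relative to pivot
                irow[ppos] += cb
        matched[genome] = mrow
        inserts[genome] = irow
    slot_width = [max(len(inserts[g][i]) for g in family.members)
                  for i in range(L + 1)]
    rows: dict[str, str] = {}
    for genome in family.members:
        parts: list[str] = []
        for i in range(L):
            parts.append(inserts[genome][i].ljust(slot_width[i], GAP))
            parts.append(matched[genome][i])
        parts.append(inserts[genome][L].ljust(slot_width[L], GAP))
        rows[genome] = "".join(parts)
    return AlignmentBlock(rows=rows)


def trim_columns(block: AlignmentBlock, max_gap_fraction: float = 0.5) -> AlignmentBlock:
    """Drop columns whose gap fraction exceeds the threshold; order kept."""
    if not block.rows:
        return block
    genomes = block.genomes
    arr = np.array([list(block.rows[g]) for g in genomes])
    gap_frac = (arr == GAP).mean(axis=0)
    keep = gap_frac <= max_gap_fraction
    if not keep.any():
        warnings.warn("all columns trimmed; block is now empty")
    rows = {g: "".join(arr[i, keep]) for i, g in enumerate(genomes)}
    return AlignmentBlock(rows=rows)


@dataclass
class PersistentGenome:
    """Concatenated persistent-family alignment across a genome set.

    ``concat`` maps genome_id -> equal-length gapped sequence; genomes
    missing a family carry all-gap stretches over that family's span.
    ``block_spans`` gives each family's half-open column span.
    """

    families: list[OrthologFamily]
    concat: dict[str, str]
    block_spans: dict[str, tuple[int, int]]

    @property
    def length(self) -> int:
        return len(next(iter(self.concat.values()))) if self.concat else 0


def concatenate(blocks: list[tuple[str, AlignmentBlock]], genomes,
                families: list[OrthologFamily] | None = None) -> PersistentGenome:
    """Join family blocks in order; absent genomes filled with gap stretches."""
    genomes = list(genomes)
    spans: dict[str, tuple[int, int]] = {}
    parts: dict[str, list[str]] = {g: [] for g in genomes}
    offset = 0
    for fam_id, block in blocks:
        w = block.width
        spans[fam_id] = (offset, offset + w)
        for g in genomes:
            parts[g].append(block.rows.get(g, GAP * w))
        offset += w
    concat = {g: "".join(p) for g, p in parts.items()}
    return PersistentGenome(families=families or [], concat=concat, block_spans=spans)


def build_persistent_genome(all_proteomes: dict[str, dict[str, str]], pivot: str,
                            params: OrthologyParams | None = None) -> PersistentGenome:
    """Full orthology stage: families -> quorum filter -> MSA -> trim -> concat."""
    params = params or OrthologyParams()
    families = build_families(pivot, all_proteomes, params)
    persistent = persistent_filter(families, len(all_proteomes), params.quorum)
    blocks = []
    for fam in persistent:
        block = pivot_anchored_msa(fam, all_proteomes, params)
        block = trim_columns(block, params.max_gap_fraction_per_column)
        if block.width:
            blocks.append((fam.family_id, block))
    return concatenate(blocks, sorted(all_proteomes), families=persistent)
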