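"""Insert alignment categorization and pairwise homology calls.

Insert sequences extracted from parsed reads are aligned to small reference
sets (e.g. the source plasmid and a genomic background), filtered on the
fraction of matching bases, de-duplicated on read-frame overlap, fixed up
across circular-reference junctions, and categorized as *not mapped*, a
*simple* (unique) alignment, or a *composite* alignment (two or more
non-overlapping segments) — the composite class marks structurally rearranged
off-products.

Pairwise insert homology is called against an empirical shuffled null: the
threshold is the maximum local-alignment score over ``n_null`` draws of one
insert versus a single-shuffle of another, so a score above it has an
empirical false-discovery level of about 1/``n_null``.  An analytic
expectation for the fraction of insert pairs sharing a plasmid origin under
even random fragmentation is provided for cross-checking.

The module consumes :class:`AlignmentSegment` records from any mapper; the
built-in aligner (affine-gap local alignment, match +2 / mismatch -2 /
gap open -3 / gap extend -1 by default) supports desk-scale reference sets
without an external binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .design import revcomp


@dataclass(frozen=True)
class Reference:
    """One alignment reference; only circular references receive the
    junction fix."""

    seq: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentSegment:
    """One filtered local alignment of an insert to a reference.

    ``match_fraction`` is matching bases / alignment length including gaps.
    Read coordinates are 0-based half-open on the insert.
    """

    read_id: str
    ref_id: str
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    strand: str
    match_fraction: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.read_start < self.read_end:
            raise ValueError("read_start must be < read_end")
        if not 0.0 <= self.match_fraction <= 1.0:
            raise ValueError("match_fraction must lie in [0, 1]")

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start


@dataclass
class InsertCategory:
    read_id: str
    category: str  # not_mapped | simple | composite
    refs: Tuple[str, ...] = ()
    n_segments: int = 0
    circular_fixed: bool = False


@dataclass
class HomologyCall:
    id_a: str
    id_b: str
    score: float
    threshold: float
    homologous: bool
    null_n: int = 1000

    @property
    def fdr_level(self) -> float:
        return 1.0 / self.null_n


def make_aligner(
    match: float = 2, mismatch: float = -2, gap_open: float = -3, gap_extend: float = -1
):
    """Affine-gap local aligner (Smith-Waterman) over DNA strings."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def make_mapping_aligner():
    """Stricter local aligner used for insert-to-reference decomposition
    (match +2 / mismatch -4 / gap open -6 / gap extend -2).

    Mapping needs heavier mismatch and gap penalties than homology scoring:
    with the permissive homology scheme a local alignment can extend across a
    chimeric junction by gap-hopping through unrelated sequence, merging what
    a production mapper reports as two segments.
    """
    return make_aligner(2, -4, -6, -2)


def local_alignment_score(a: str, b: str, aligner=None) -> float:
    """Best local alignment score between two sequences."""
    if not a or not b:
        return 0.0
    aligner = aligner or make_aligner()
    return float(aligner.score(a, b))


def align_to_references(
    read_id: str,
    insert: str,
    refs: Dict[str, Reference],
    aligner=None,
    min_segment_len: int = 50,
    max_segments: int = 8,
) -> List[AlignmentSegment]:
    """Decompose an insert into local-alignment segments against references.

    Greedy best-first: the highest-scoring local alignment across all
    references and strands is recorded, then the unaligned read flanks are
    recursed on, until no flank of at least ``min_segment_len`` yields a
    segment of that length.  ``min_segment_len`` (default 50 nt) suppresses
    the short spurious local alignments random sequence produces, mirroring
    a production mapper's minimal reportable alignment.  Suitable for
    desk-scale references; external mappers can be substituted by
    constructing segments directly.
    """
    aligner = aligner or make_mapping_aligner()
    segments: List[AlignmentSegment] = []

    def recurse(sub: str, offset: int) -> None:
        if len(sub) < min_segment_len or len(segments) >= max_segments:
            return
        best = None
        for ref_id, ref in refs.items():
            for strand, target in (("+", ref.seq), ("-", revcomp(ref.seq))):
                score = aligner.score(sub, target)
                if best is None or score > best[0]:
                    best = (score, ref_id, strand, target)
        if best is None or best[0] < 2 * min_segment_len * 0.5:
            return
        score, ref_id, strand, target = best
        aln = aligner.align(sub, target)[0]
        blocks_q, blocks_t = aln.aligned
        rs, re = int(blocks_q[0][0]), int(blocks_q[-1][1])
        ts, te = int(blocks_t[0][0]), int(blocks_t[-1][1])
        if re - rs < min_segment_len:
            return
        counts = aln.counts()
        aln_len = counts.identities + counts.mismatches + counts.gaps
        ref_len = len(refs[ref_id])
        if strand == "-":
            ts, te = ref_len - te, ref_len - ts
        segments.append(
            AlignmentSegment(
                read_id=read_id,
                ref_id=ref_id,
                read_start=offset + rs,
                read_end=offset + re,
                ref_start=ts,
                ref_end=te,
                strand=strand,
                match_fraction=counts.identities / aln_len if aln_len else 0.0,
                score=score,
            )
        )
        recurse(sub[:rs], offset)
        recurse(sub[re:], offset + re)

    recurse(insert, 0)
    return sorted(segments, key=lambda s: s.read_start)


def segments_from_paf(path) -> List[AlignmentSegment]:
    """Load AlignmentSegments from a PAF file produced by an external mapper.

    Uses the standard first 12 columns; match_fraction is residue matches /
    alignment block length (column 10 / column 11), the PAF equivalent of
    matching bases over alignment length including gaps.
    """
    out: List[AlignmentSegment] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            nmatch, alnlen = int(f[9]), int(f[10])
            out.append(
                AlignmentSegment(
                    read_id=f[0],
                    ref_id=f[5],
                    read_start=int(f[2]),
                    read_end=int(f[3]),
                    ref_start=int(f[7]),
                    ref_end=int(f[8]),
                    strand=f[4],
                    match_fraction=nmatch / alnlen if alnlen else 0.0,
                    score=float(nmatch),
                )
            )
    return out


def filter_segments(
    segments: Iterable[AlignmentSegment], min_match_fraction: float = 0.65
) -> List[AlignmentSegment]:
    """Retain segments with match_fraction strictly above the floor; per
    (read, read_start) keep only the best match_fraction segment."""
    kept = [s for s in segments if s.match_fraction > min_match_fraction]
    best: Dict[Tuple[str, int], AlignmentSegment] = {}
    for s in kept:
        key = (s.read_id, s.read_start)
        cur = best.get(key)
        if cur is None or s.match_fraction > cur.match_fraction:
            best[key] = s
    return sorted(best.values(), key=lambda s: (s.read_id, s.read_start))


def _overlap_fraction(a: AlignmentSegment, b: AlignmentSegment) -> float:
    """Read-frame overlap / shorter segment length (declared convention; the
    empirical overlap distribution is near-bimodal at 0%/100%, so the
    denominator choice is immaterial in practice)."""
    ov = min(a.read_end, b.read_end) - max(a.read_start, b.read_start)
    if ov <= 0:
        return 0.0
    return ov / min(a.read_span, b.read_span)


def resolve_redundancy(
    segments: Sequence[AlignmentSegment], overlap_threshold: float = 0.5
) -> List[AlignmentSegment]:
    """Drop read-frame-redundant segments of one read.

    Segments overlapping by more than ``overlap_threshold`` are redundant and
    the better match_fraction wins; the output is mutually at-most-threshold
    overlapping.  Greedy from the best segment down, which maximizes retained
    quality for the near-bimodal overlap structure seen in practice.
    """
    ranked = sorted(
        segments, key=lambda s: (-s.match_fraction, -s.score, s.read_start)
    )
    kept: List[AlignmentSegment] = []
    for s in ranked:
        if all(_overlap_fraction(s, k) <= overlap_threshold for k in kept):
            kept.append(s)
    return sorted(kept, key=lambda s: s.read_start)


def apply_circular_fix(
    segments: Sequence[AlignmentSegment],
    refs: Dict[str, Reference],
    margin: int = 5,
) -> Tuple[bool, str]:
    """Re-categorize two-segment reads spanning a circular junction as simple.

    Applies only to reads with exactly two disjoint segments on the same
    circular reference where one segment starts within ``margin`` nt of the
    reference start and/or one ends within ``margin`` nt of its end.  Never
    converts simple to composite.  Returns (fixed, category_hint).
    """
    if len(segments) != 2:
        return False, "unchanged"
    a, b = segments
    if a.ref_id != b.ref_id:
        return False, "unchanged"
    ref = refs.get(a.ref_id)
    if ref is None or not ref.circular:
        return False, "unchanged"
    if _overlap_fraction(a, b) > 0:
        return False, "unchanged"
    n = len(ref)
    touches_start = any(s.ref_start <= margin for s in segments)
    touches_end = any(n - s.ref_end <= margin for s in segments)
    if touches_start or touches_end:
        return True, "simple"
    return False, "unchanged"


def categorize_insert(
    segments: Sequence[AlignmentSegment],
    refs: Dict[str, Reference],
    read_id: Optional[str] = None,
) -> InsertCategory:
    """Call not_mapped / simple / composite from non-redundant segments.

    Input order is irrelevant.  Two disjoint segments across a circular
    reference junction collapse to simple (circular_fixed).
    """
    segments = sorted(segments, key=lambda s: s.read_start)
    rid = read_id if read_id is not None else (segments[0].read_id if segments else "")
    if not segments:
        return InsertCategory(read_id=rid, category="not_mapped")
    refs_used = tuple(sorted({s.ref_id for s in segments}))
    if len(segments) == 1:
        return InsertCategory(rid, "simple", refs_used, 1)
    fixed, hint = apply_circular_fix(segments, refs)
    if fixed:
        return InsertCategory(rid, "simple", refs_used, 1, circular_fixed=True)
    return InsertCategory(rid, "composite", refs_used, len(segments))


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """One uniform permutation of the bases (a '1-shuffle')."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return rng.permutation(arr).tobytes().decode()


def homology_threshold(
    inserts: Sequence[str],
    n_null: int = 1000,
    seed: int = 0,
    aligner=None,
) -> float:
    """Null score threshold: max local-alignment score over ``n_null`` draws
    of one sampled insert versus a single-shuffle of a second sampled insert.

    Scores above the threshold have an empirical FDR of about 1/``n_null``.
    Deterministic under seed; requires at least two distinct inserts.
    """
    inserts = [s for s in inserts if s]
    if len(inserts) < 2:
        raise ValueError("need at least two distinct inserts for the null")
    rng = np.random.default_rng(seed)
    aligner = aligner or make_aligner()
    best = 0.0
    n = len(inserts)
    for _ in range(n_null):
        i = int(rng.integers(n))
        j = int(rng.integers(n - 1))
        j = j if j < i else j + 1
        shuf = shuffle_sequence(inserts[j], rng)
        best = max(best, float(aligner.score(inserts[i], shuf)))
    return best


def call_homology(
    insert_a: str,
    insert_b: str,
    threshold: float,
    id_a: str = "a",
    id_b: str = "b",
    aligner=None,
    null_n: int = 1000,
) -> HomologyCall:
    """Compare a pair of inserts' local alignment score to the null threshold.

    The raw score is always reported so score-cutoff enrichment analyses stay
    reproducible under any scoring scheme.
    """
    score = local_alignment_score(insert_a, insert_b, aligner)
    return HomologyCall(
        id_a=id_a, id_b=id_b, score=score, threshold=threshold,
        homologous=score > threshold, null_n=null_n,
    )


def expected_homology_fraction(
    f_plasmid: float, insert_len: float, plasmid_len: float
) -> float:
    """Expected fraction of insert pairs sharing a plasmid origin under even
    random fragmentation: f_plasmid^2 * (insert_len / plasmid_len).

    ``f_plasmid`` is the fraction of library inserts derived from the plasmid;
    two random inserts both come from it with probability f^2 and then overlap
    with probability ~ insert length over plasmid length.
    """
    if not 0.0 <= f_plasmid <= 1.0:
        raise ValueError("f_plasmid must lie in [0, 1]")
    if insert_len <= 0 or plasmid_len <= 0:
        raise ValueError("lengths must be positive")
    if insert_len > plasmid_len:
        raise ValueError("insert_len cannot exceed plasmid_len")
    return f_plasmid * f_plasmid * (insert_len / plasmid_len)
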