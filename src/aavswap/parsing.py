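"""Signpost-anchored parsing of long reads into per-read barcode features.

Raw ONT reads of barcoded cargoes are converted into :class:`ParsedRead`
records by (1) locating the four constant signpost sequences on both strands,
(2) validating their orientation and order, (3) extracting BC1, BC2, the
internal insert index and the insert from signpost-relative positions,
(4) demultiplexing on the index, (5) exact-matching barcodes against the
validated pair dictionary and (6) classifying BC-to-BC and ITR-to-ITR
lengths.  Hairpin dimer artifacts are detected first and parsed from their
forward pass.

Signpost hits use an infix edit-distance search (edlib); identity is defined
as (signpost length - edit distance) / signpost length, a conservative proxy
for the fraction of matching bases, thresholded at 0.75 by default.  All
coordinates are 0-based half-open on the read's forward strand; minus-strand
reads are reverse-complemented into the construct frame before feature
extraction, which makes every reported feature strand-invariant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import edlib
import numpy as np
import pandas as pd

from .design import DIMER_HAIRPIN, SIGNPOSTS, SIGNPOST_IDS, LibraryDesign, revcomp
from .dictionary import PairDictionary


@dataclass
class SignpostHit:
    """Best hit of one signpost on one strand of a read."""

    signpost_id: str
    read_start: int  # 0-based half-open on the raw read
    read_end: int
    strand: str  # '+' or '-'
    identity: float
    score: int  # signpost length - edit distance
    n_locations: int = 1  # distinct non-overlapping best-score locations

    def __post_init__(self) -> None:
        if not self.read_start < self.read_end:
            raise ValueError("read_start must be < read_end")


@dataclass
class ParsedRead:
    """Extracted features of one long read (forward-construct frame)."""

    read_id: str
    strand: Optional[str] = None
    bc1: Optional[str] = None
    bc2: Optional[str] = None
    index_obs: Optional[str] = None
    library_id: Optional[str] = None
    insert_seq: Optional[str] = None
    bc_to_bc_len: Optional[int] = None
    read_len: int = 0
    pass_len: int = 0
    full_bc_to_bc: Optional[bool] = None
    full_itr_to_itr: Optional[bool] = None
    is_dimer: bool = False
    bc1_valid: Optional[bool] = None
    bc2_valid: Optional[bool] = None
    concordant: Optional[bool] = None
    reject_reason: Optional[str] = None


@dataclass
class LengthWindows:
    """Closed [low, high] windows for full-length calls."""

    bc_to_bc: Optional[Tuple[float, float]] = None
    itr_to_itr: Optional[Dict[str, Tuple[float, float]]] = None


def _compile_queries(
    signposts: Dict[str, str], min_identity: float
) -> List[Tuple[str, str, str, int]]:
    """(signpost_id, strand, query, max_edits) for both strands."""
    out = []
    for sid, seq in signposts.items():
        k = int(math.floor((1.0 - min_identity) * len(seq)))
        out.append((sid, "+", seq, k))
        out.append((sid, "-", revcomp(seq), k))
    return out


def _merge_locations(locs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Collapse overlapping best-score locations into representatives."""
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(locs):
        if merged and s <= merged[-1][1]:
            continue
        merged.append((s, e))
    return merged


def locate_signposts(
    read: str,
    signposts: Optional[Dict[str, str]] = None,
    min_identity: float = 0.75,
    _queries: Optional[List[Tuple[str, str, str, int]]] = None,
) -> List[SignpostHit]:
    """Best local hit of each signpost on each strand, if identity >= threshold.

    At most one hit per signpost per strand is returned; when the best edit
    distance is achieved at two or more non-overlapping locations the hit
    carries ``n_locations >= 2`` (ambiguity, rejected downstream).  Absent
    hits are simply missing from the list.
    """
    queries = _queries if _queries is not None else _compile_queries(
        signposts or SIGNPOSTS, min_identity
    )
    hits: List[SignpostHit] = []
    for sid, strand, query, k in queries:
        res = edlib.align(query, read, mode="HW", task="locations", k=k)
        d = res["editDistance"]
        if d < 0:
            continue
        locs = _merge_locations([(s, e + 1) for s, e in res["locations"]])
        s, e = locs[0]
        hits.append(
            SignpostHit(
                signpost_id=sid,
                read_start=s,
                read_end=e,
                strand=strand,
                identity=(len(query) - d) / len(query),
                score=len(query) - d,
                n_locations=len(locs),
            )
        )
    return hits


def validate_layout(hits: Sequence[SignpostHit]) -> Tuple[bool, Optional[str], str]:
    """Check signpost completeness, orientation concordance and barcode order.

    For each signpost the best hit across strands (higher identity wins) is
    selected; a cross-strand identity tie or a multi-location best hit makes
    the signpost ambiguous.  The read passes iff all four signposts have an
    unambiguous best hit, all on the same strand, positioned in construct
    order (BC1 block before BC2 block on '+', reversed on '-').

    Returns (passed, strand, reason).
    """
    best: Dict[str, SignpostHit] = {}
    for h in hits:
        cur = best.get(h.signpost_id)
        if cur is None or h.identity > cur.identity:
            best[h.signpost_id] = h
        elif h.identity == cur.identity and h.strand != cur.strand:
            best[h.signpost_id] = SignpostHit(
                h.signpost_id, h.read_start, h.read_end, h.strand,
                h.identity, h.score, n_locations=cur.n_locations + h.n_locations,
            )
    missing = [sid for sid in SIGNPOST_IDS if sid not in best]
    if missing:
        return False, None, "signpost_missing"
    chosen = [best[sid] for sid in SIGNPOST_IDS]
    if any(h.n_locations > 1 for h in chosen):
        return False, None, "signpost_ambiguous"
    strands = {h.strand for h in chosen}
    if len(strands) > 1:
        return False, None, "strand_discordant"
    strand = strands.pop()
    starts = [h.read_start for h in chosen]
    ordered = all(a < b for a, b in zip(starts, starts[1:]))
    reversed_ = all(a > b for a, b in zip(starts, starts[1:]))
    if (strand == "+" and ordered) or (strand == "-" and reversed_):
        return True, strand, "ok"
    return False, strand, "order_violation"


def extract_features(
    read: str,
    hits: Sequence[SignpostHit],
    design: LibraryDesign,
) -> Dict[str, object]:
    """Extract barcodes, index, insert and BC-to-BC length in the forward frame.

    Requires a passing layout.  Minus-strand reads are reverse-complemented
    and hit coordinates mirrored before extraction, so the returned features
    are identical for a read and its reverse complement.  The index window
    sits ``index_spacer_nt`` left of the right BC2-upstream signpost; the
    insert ends a further R2-handle length to the left.

    Raises ``ValueError`` on negative intervals (overlapping signposts).
    """
    passed, strand, reason = validate_layout(hits)
    if not passed:
        raise ValueError(f"layout did not validate: {reason}")
    best = {h.signpost_id: h for h in hits if h.strand == strand}
    if strand == "-":
        n = len(read)
        read = revcomp(read)
        best = {
            sid: SignpostHit(sid, n - h.read_end, n - h.read_start, "+",
                             h.identity, h.score, h.n_locations)
            for sid, h in best.items()
        }
    sp1, sp2, sp3, sp4 = (best[sid] for sid in SIGNPOST_IDS)
    idx_len = design.index_length
    spacer = design.index_spacer_nt
    r2_len = len(design.r2_handle)
    idx_start = sp3.read_start - spacer - idx_len
    insert_end = idx_start - r2_len
    intervals = {
        "bc1": (sp1.read_end, sp2.read_start),
        "bc2": (sp3.read_end, sp4.read_start),
        "index": (idx_start, idx_start + idx_len),
        "insert": (sp2.read_end, insert_end),
    }
    for name, (s, e) in intervals.items():
        if s < 0 or e < s:
            raise ValueError(f"negative {name} interval (overlapping signposts)")
    return {
        "strand": strand,
        "bc1": read[intervals["bc1"][0]:intervals["bc1"][1]],
        "bc2": read[intervals["bc2"][0]:intervals["bc2"][1]],
        "index_obs": read[intervals["index"][0]:intervals["index"][1]],
        "insert_seq": read[intervals["insert"][0]:intervals["insert"][1]],
        "bc_to_bc_len": sp4.read_start - sp1.read_end,
    }


def demultiplex(
    index_obs: str, index_table: Dict[str, str]
) -> Tuple[str, int, Optional[int]]:
    """Assign a library by Levenshtein distance to the configured indices.

    Unambiguous iff the best distance is <= 1 and the runner-up is at least 2
    edits further.  Returns (library_id or 'ambiguous', best, second_best).
    """
    dists = sorted(
        (edlib.align(idx, index_obs, mode="NW", task="distance")["editDistance"], lib)
        for lib, idx in index_table.items()
    )
    best_d, best_lib = dists[0]
    second = dists[1][0] if len(dists) > 1 else None
    if best_d <= 1 and (second is None or second - best_d >= 2):
        return best_lib, best_d, second
    return "ambiguous", best_d, second


def match_dictionary(
    bc1: str, bc2: str, pair_dict: PairDictionary
) -> Tuple[bool, bool, Optional[bool]]:
    """Exact membership tests; concordance defined only when both are valid."""
    v1 = bc1 in pair_dict.valid_bc1
    v2 = bc2 in pair_dict.valid_bc2
    conc = ((bc1, bc2) in pair_dict.pairs) if (v1 and v2) else None
    return v1, v2, conc


def derive_length_window(
    control_lengths: Sequence[float], lo: float = 0.01, hi: float = 0.99
) -> Tuple[float, float]:
    """Empirical [lo, hi] quantile window (nearest-rank convention).

    Derived from zero-swap control reads (size-selected digested plasmid
    inserts); warns below 100 observations, errors on an empty set.
    """
    arr = np.sort(np.asarray(control_lengths, dtype=float))
    if arr.size == 0:
        raise ValueError("empty control length set")
    if arr.size < 100:
        warnings.warn(f"only {arr.size} control lengths; window will be noisy")

    def nearest_rank(q: float) -> float:
        return float(arr[max(int(math.ceil(q * arr.size)), 1) - 1])

    return nearest_rank(lo), nearest_rank(hi)


def classify_read_lengths(
    bc_to_bc_len: Optional[float],
    read_len: float,
    windows: LengthWindows,
    library_id: Optional[str] = None,
) -> Tuple[Optional[bool], Optional[bool]]:
    """Closed-interval full-length calls; undefined when a window is missing."""
    full_bc = None
    if windows.bc_to_bc is not None and bc_to_bc_len is not None:
        lo, hi = windows.bc_to_bc
        full_bc = bool(lo <= bc_to_bc_len <= hi)
    full_itr = None
    if windows.itr_to_itr is not None and library_id in windows.itr_to_itr:
        lo, hi = windows.itr_to_itr[library_id]
        full_itr = bool(lo <= read_len <= hi)
    return full_bc, full_itr


def detect_dimer(
    read: str,
    expected_len: float,
    hairpin: str = DIMER_HAIRPIN,
    max_hairpin_dist: int = 2,
    min_len_ratio: float = 1.6,
    mid_tolerance: float = 0.25,
    max_flank_divergence: float = 0.35,
) -> Tuple[bool, Optional[int]]:
    """Detect forward+reverse-pass dimer artifacts joined at a hairpin.

    A read is a dimer when (a) it is about twice the expected length,
    (b) the hairpin (either orientation, <= ``max_hairpin_dist`` edits) sits
    near the midpoint and (c) the two flanks are reverse-complement-similar.
    Returns (is_dimer, split_point); ``read[:split_point]`` is the forward
    pass used for downstream parsing.
    """
    n = len(read)
    if n < min_len_ratio * expected_len:
        return False, None
    best = None
    for probe in (hairpin, revcomp(hairpin)):
        res = edlib.align(probe, read, mode="HW", task="locations", k=max_hairpin_dist)
        if res["editDistance"] >= 0:
            s, e = res["locations"][0]
            cand = (res["editDistance"], s, e + 1)
            if best is None or cand < best:
                best = cand
    if best is None:
        return False, None
    _, s, e = best
    center = (s + e) / 2
    if abs(center - n / 2) > mid_tolerance * n:
        return False, None
    a, b = read[:s], read[e:]
    m = min(len(a), len(b))
    if m == 0:
        return False, None
    d = edlib.align(a[-m:], revcomp(b)[-m:], mode="NW", task="distance")["editDistance"]
    if d / m > max_flank_divergence:
        return False, None
    return True, s


def parse_reads(
    reads: Iterable[Tuple[str, str]],
    designs: Union[LibraryDesign, Sequence[LibraryDesign], Dict[str, LibraryDesign]],
    pair_dict: Optional[PairDictionary] = None,
    windows: Optional[LengthWindows] = None,
    min_identity: float = 0.75,
    detect_dimers: bool = True,
    expected_len: Optional[float] = None,
) -> Tuple[pd.DataFrame, Dict[str, object]]:
    """Parse long reads end to end; returns (table, retention cascade).

    The table has one row per input read including a ``reject_reason`` for
    failures and a ``qualifies`` flag marking reads that enter the swap-tally
    denominator: layout pass, unambiguous demultiplex, separately valid BC1
    and BC2, and full BC-to-BC length (when a window is supplied).

    The cascade dict reports ``n_input``, ordered retained counts after each
    filter, and a reason breakdown whose counts sum to ``n_input``.
    """
    if isinstance(designs, LibraryDesign):
        designs = [designs]
    if isinstance(designs, dict):
        design_map = dict(designs)
    else:
        design_map = {d.library_id: d for d in designs}
    ref = next(iter(design_map.values()))
    for d in design_map.values():
        if (
            d.signposts != ref.signposts
            or len(d.r2_handle) != len(ref.r2_handle)
            or d.index_spacer_nt != ref.index_spacer_nt
        ):
            raise ValueError("all designs must share signposts and index geometry")
    index_table = {lib: d.insert_index for lib, d in design_map.items()}
    signposts = dict(zip(SIGNPOST_IDS, ref.signposts))
    queries = _compile_queries(signposts, min_identity)
    if expected_len is None:
        expected_len = ref.itr_to_itr_target_nt
    windows = windows or LengthWindows()

    rows: List[dict] = []
    reasons: Dict[str, int] = {}
    retained = {"input": 0, "layout": 0, "extracted": 0, "demultiplexed": 0}
    if pair_dict is not None:
        retained["bc_valid"] = 0
    if windows.bc_to_bc is not None:
        retained["full_bc_to_bc"] = 0

    for read_id, seq in reads:
        retained["input"] += 1
        row: dict = {
            "read_id": read_id, "strand": None, "bc1": None, "bc2": None,
            "index_obs": None, "library_id": None, "insert_seq": None,
            "bc_to_bc_len": None, "read_len": len(seq), "pass_len": len(seq),
            "full_bc_to_bc": None, "full_itr_to_itr": None, "is_dimer": False,
            "bc1_valid": None, "bc2_valid": None, "concordant": None,
            "reject_reason": None, "qualifies": False,
        }
        rows.append(row)

        work = seq
        if detect_dimers:
            is_dimer, split = detect_dimer(seq, expected_len)
            if is_dimer:
                row["is_dimer"] = True
                work = seq[:split]
                row["pass_len"] = len(work)

        hits = locate_signposts(work, min_identity=min_identity, _queries=queries)
        passed, strand, reason = validate_layout(hits)
        if not passed:
            row["reject_reason"] = reason
            reasons[reason] = reasons.get(reason, 0) + 1
            continue
        retained["layout"] += 1
        try:
            feats = extract_features(work, hits, ref)
        except ValueError:
            row["reject_reason"] = "negative_interval"
            reasons["negative_interval"] = reasons.get("negative_interval", 0) + 1
            continue
        row.update(feats)
        retained["extracted"] += 1

        lib, _, _ = demultiplex(row["index_obs"], index_table)
        row["library_id"] = lib
        if lib == "ambiguous":
            row["reject_reason"] = "demux_ambiguous"
            reasons["demux_ambiguous"] = reasons.get("demux_ambiguous", 0) + 1
            continue
        retained["demultiplexed"] += 1

        row["full_bc_to_bc"], row["full_itr_to_itr"] = classify_read_lengths(
            row["bc_to_bc_len"], row["pass_len"], windows, lib
        )

        if pair_dict is not None:
            v1, v2, conc = match_dictionary(row["bc1"], row["bc2"], pair_dict)
            row["bc1_valid"], row["bc2_valid"], row["concordant"] = v1, v2, conc
            if not (v1 and v2):
                row["reject_reason"] = "bc_invalid"
                reasons["bc_invalid"] = reasons.get("bc_invalid", 0) + 1
                continue
            retained["bc_valid"] += 1

        if windows.bc_to_bc is not None:
            if not row["full_bc_to_bc"]:
                row["reject_reason"] = "not_full_bc_to_bc"
                reasons["not_full_bc_to_bc"] = reasons.get("not_full_bc_to_bc", 0) + 1
                continue
            retained["full_bc_to_bc"] += 1

        if pair_dict is not None:
            row["qualifies"] = True
            reasons["qualifying"] = reasons.get("qualifying", 0) + 1
        else:
            reasons["parsed"] = reasons.get("parsed", 0) + 1

    df = pd.DataFrame(rows)
    cascade = {
        "n_input": retained["input"],
        "retained": retained,
        "reasons": reasons,
        "quantile_convention": "nearest-rank",
    }
    return df, cascade
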