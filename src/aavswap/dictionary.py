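"""Validated BC1-BC2 pair dictionary from association-read tallies.

The filter cascade mirrors stringent dual-barcode dictionary construction:

1. pile up reads per exact (BC1, BC2) pair;
2. classify each barcode's total representation (summed over pairs with >=
   ``pileup_min`` reads) into low / mid / high count classes — representation
   is typically trimodal, with low counts reflecting sequencing or PCR errors
   and high counts reflecting clonal jackpotting;
3. drop a dominant artifact barcode and its Levenshtein-2 neighborhood;
4. drop barcodes with long G homopolymers or truncation signatures;
5. prune mid-count barcodes within Levenshtein 2 of any high-count barcode
   (likely sequencing errors off abundant clones);
6. error-correct high-count barcodes by connected components of the
   Levenshtein<=2 graph, keeping each component's most abundant member and
   discarding ambiguous components (max/min fold-change < 10);
7. keep pairs with >= 2 reads, both barcodes separately valid, and > 99% of
   each barcode's reads concentrated on that single pair (both sides).

Low-count barcodes are excluded outright, never corrected toward mid/high.
All comparisons are case-insensitive after uppercase normalization; sequences
containing N never match anything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd

from .seqdist import pairs_within_radius, within


@dataclass
class PairDictionary:
    """The validated set of unique BC1-BC2 pairs plus separately-valid sets.

    ``pairs`` supports exact concordance lookups; ``valid_bc1``/``valid_bc2``
    support the separate validity tests that define the swap-tally
    denominator.  ``provenance`` records counts retained at each filter step.
    """

    valid_bc1: Set[str]
    valid_bc2: Set[str]
    pairs: Set[Tuple[str, str]]
    uniqueness_threshold: float = 0.99
    provenance: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for b1, b2 in self.pairs:
            if b1 not in self.valid_bc1 or b2 not in self.valid_bc2:
                raise ValueError("pair contains a barcode missing from its valid set")

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]], **kw) -> "PairDictionary":
        pairs = {(a.upper(), b.upper()) for a, b in pairs}
        return cls(
            valid_bc1={a for a, _ in pairs},
            valid_bc2={b for _, b in pairs},
            pairs=pairs,
            **kw,
        )

    def to_tsv(self, pairs_path, bc1_path=None, bc2_path=None) -> None:
        pd.DataFrame(sorted(self.pairs), columns=["bc1", "bc2"]).to_csv(
            pairs_path, sep="\t", index=False
        )
        if bc1_path:
            pd.Series(sorted(self.valid_bc1), name="bc1").to_csv(
                bc1_path, sep="\t", index=False
            )
        if bc2_path:
            pd.Series(sorted(self.valid_bc2), name="bc2").to_csv(
                bc2_path, sep="\t", index=False
            )

    @classmethod
    def from_tsv(cls, pairs_path, **kw) -> "PairDictionary":
        df = pd.read_csv(pairs_path, sep="\t", dtype=str)
        return cls.from_pairs(zip(df["bc1"], df["bc2"]), **kw)

    def write_provenance(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance, fh, indent=2)


def tally_pairs(
    records: Union[pd.DataFrame, Iterable[Tuple[str, str]]],
    bc1_len: int = 15,
    bc2_len: int = 16,
) -> Tuple[pd.DataFrame, int]:
    """Pile up reads per exact (bc1, bc2) pair.

    Accepts a DataFrame with ``bc1_obs``/``bc2_obs`` columns or an iterable of
    (bc1, bc2).  Barcodes are uppercase-normalized; records whose barcode has
    the wrong length are skipped and counted in the returned rejects tally.
    Output columns: bc1, bc2, reads — order-invariant (sorted).
    """
    if isinstance(records, pd.DataFrame):
        b1 = records["bc1_obs"].astype(str).str.upper()
        b2 = records["bc2_obs"].astype(str).str.upper()
    else:
        pairs = [(a.upper(), b.upper()) for a, b in records]
        b1 = pd.Series([a for a, _ in pairs], dtype=str)
        b2 = pd.Series([b for _, b in pairs], dtype=str)
    ok = (b1.str.len() == bc1_len) & (b2.str.len() == bc2_len)
    n_rejected = int((~ok).sum())
    df = (
        pd.DataFrame({"bc1": b1[ok], "bc2": b2[ok]})
        .groupby(["bc1", "bc2"], sort=True)
        .size()
        .rename("reads")
        .reset_index()
    )
    return df, n_rejected


def barcode_totals(
    pair_counts: pd.DataFrame, side: str, pileup_min: int = 3
) -> pd.Series:
    """Total reads per barcode on one side, over pairs with >= pileup_min reads."""
    if side not in ("bc1", "bc2"):
        raise ValueError("side must be 'bc1' or 'bc2'")
    sub = pair_counts[pair_counts["reads"] >= pileup_min]
    return sub.groupby(side)["reads"].sum().sort_values(ascending=False)


def classify_abundance(
    totals: Union[pd.Series, Dict[str, int]],
    high_cutoff: int,
    low_max: int = 5,
) -> pd.DataFrame:
    """Partition barcodes into low (<= low_max), high (>= high_cutoff), mid.

    ``totals`` are per-barcode read totals (already restricted to pairs above
    the pile-up floor).  ``high_cutoff`` must exceed ``low_max``; it is not a
    universal constant — the representation histogram is trimodal and the
    mid/high valley is dataset-dependent (see :func:`propose_high_cutoff`).
    """
    if high_cutoff <= low_max:
        raise ValueError("high_cutoff must be > low_max")
    s = pd.Series(totals, dtype=float)
    cls = np.where(s <= low_max, "low", np.where(s >= high_cutoff, "high", "mid"))
    return pd.DataFrame({"barcode": s.index, "total_reads": s.to_numpy(int), "class": cls})


def propose_high_cutoff(
    totals: Union[pd.Series, Dict[str, int]],
    low_max: int = 5,
    n_bins: int = 60,
) -> int:
    """Propose a mid/high boundary at the valley of the log10-total histogram.

    Heuristic helper only: finds the sparsest histogram bin above the main
    (mid-count) mode and returns its center as a count cutoff.  Falls back to
    100x the median when the histogram has no interior valley.
    """
    s = pd.Series(totals, dtype=float)
    s = s[s > low_max]
    fallback = int(max(10 * low_max, 100 * (s.median() if len(s) else low_max)))
    if len(s) < 10:
        return fallback
    logs = np.log10(s.to_numpy())
    hist, edges = np.histogram(logs, bins=n_bins)
    mode = int(np.argmax(hist))
    if mode >= n_bins - 2:
        return fallback
    valley = mode + 1 + int(np.argmin(hist[mode + 1:]))
    if valley >= n_bins - 1 or hist[valley] == hist[mode]:
        return fallback
    return int(round(10 ** ((edges[valley] + edges[valley + 1]) / 2)))


def remove_dominant(
    totals: Union[pd.Series, Dict[str, int]],
    dominant: Optional[str] = None,
    radius: int = 2,
) -> Set[str]:
    """Remove a dominant artifact barcode and its Levenshtein neighborhood.

    ``dominant`` defaults to the most abundant barcode.  Returns the removed
    set: the dominant plus every barcode within ``radius`` edits of it.
    """
    s = pd.Series(totals, dtype=float)
    if len(s) == 0:
        return set()
    if dominant is None:
        dominant = str(s.idxmax())
    return {str(b) for b in s.index if within(str(b), dominant, radius)}


def neighborhood_saturation(
    barcodes: Iterable[str],
    probe: str,
    n_shuffles: int = 20,
    radius: int = 2,
    seed: int = 0,
) -> float:
    """Mean number of observed barcodes within ``radius`` of single-shuffles of
    ``probe`` — a saturation check for the dominant-neighborhood removal (small
    values mean the barcode space is far from saturated at this tolerance)."""
    rng = np.random.default_rng(seed)
    barcodes = list(barcodes)
    counts = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(probe))
        shuf = "".join(probe[i] for i in perm)
        counts.append(sum(within(b, shuf, radius) for b in barcodes))
    return float(np.mean(counts))


def filter_artifacts(
    barcodes: Iterable[str],
    trunc_signature: str,
    max_homopolymer_g: int = 10,
) -> Set[str]:
    """Barcodes with >= ``max_homopolymer_g`` consecutive Gs or containing the
    side's post-barcode truncation signature as a substring."""
    run = "G" * max_homopolymer_g
    return {b for b in barcodes if run in b or trunc_signature in b}


#: Post-barcode truncation signatures detected next to each barcode.
TRUNC_SIGNATURE_BC1 = "ATTAAAC"
TRUNC_SIGNATURE_BC2 = "TAGCGCG"


def prune_mid_by_high(
    mid: Iterable[str], high: Iterable[str], radius: int = 2
) -> Tuple[Set[str], Set[str]]:
    """Remove mid-count barcodes within ``radius`` of any high-count barcode.

    Returns (kept, removed).  The high set used is the *pre-correction* one.
    """
    high = list(high)
    kept, removed = set(), set()
    for m in mid:
        if any(within(m, h, radius) for h in high):
            removed.add(m)
        else:
            kept.add(m)
    if kept & set(high):
        raise ValueError("mid and high sets must be disjoint")
    return kept, removed


def correct_high_counts(
    high_counts: Union[pd.Series, Dict[str, int]],
    radius: int = 2,
    min_fold: float = 10.0,
) -> Tuple[Set[str], Set[str]]:
    """Error-correct high-count barcodes via a Levenshtein connected-component
    graph.

    Barcodes within ``radius`` edits are connected; each component contributes
    its most abundant member.  Components of size >= 2 whose max/min count
    fold-change is below ``min_fold`` are discarded entirely as ambiguous
    clusters, as are components whose maximum is tied (conservative
    tie-break).  Returns (representatives, discarded).
    """
    s = pd.Series(high_counts, dtype=float)
    if (s <= 0).any():
        raise ValueError("counts must be > 0")
    seqs = list(map(str, s.index))
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    g.add_edges_from(pairs_within_radius(seqs, radius))
    reps: Set[str] = set()
    discarded: Set[str] = set()
    for comp in nx.connected_components(g):
        members = [seqs[i] for i in comp]
        counts = s.loc[members]
        if len(members) >= 2 and counts.max() / counts.min() < min_fold:
            discarded |= set(members)
            continue
        top = counts.max()
        winners = counts[counts == top]
        if len(winners) > 1:  # ambiguous argmax
            discarded |= set(members)
            continue
        reps.add(str(winners.index[0]))
        discarded |= set(members) - {str(winners.index[0])}
    return reps, discarded


def build_pair_dictionary(
    pair_counts: pd.DataFrame,
    valid_bc1: Set[str],
    valid_bc2: Set[str],
    min_pair_reads: int = 2,
    uniqueness: float = 0.99,
    denominator_floor: int = 2,
    provenance: Optional[Dict[str, int]] = None,
) -> PairDictionary:
    """Unique-pairing filter: keep pairs with >= ``min_pair_reads`` reads, both
    barcodes separately valid, and strictly more than ``uniqueness`` of each
    barcode's reads concentrated on this single pair, on both sides.

    The uniqueness denominator counts a barcode's reads over all pairs above
    the fixed ``denominator_floor`` (default 2, matching the default pair
    floor); keeping it independent of ``min_pair_reads`` makes retention
    monotone in both ``uniqueness`` and ``min_pair_reads``.

    Emits a warning (not an error) when the result is empty.
    """
    prov = dict(provenance or {})
    prov["pairs_input"] = len(pair_counts)
    denom = pair_counts[pair_counts["reads"] >= denominator_floor]
    tot1 = denom.groupby("bc1")["reads"].sum()
    tot2 = denom.groupby("bc2")["reads"].sum()
    df = pair_counts[pair_counts["reads"] >= min_pair_reads]
    prov["pairs_min_reads"] = len(df)
    df = df[df["bc1"].isin(valid_bc1) & df["bc2"].isin(valid_bc2)]
    prov["pairs_both_valid"] = len(df)
    if len(df):
        frac1 = df["reads"] / df["bc1"].map(tot1).fillna(np.inf)
        frac2 = df["reads"] / df["bc2"].map(tot2).fillna(np.inf)
        df = df[(frac1 > uniqueness) & (frac2 > uniqueness)]
    prov["pairs_unique"] = len(df)
    pairs = set(zip(df["bc1"], df["bc2"]))
    if not pairs:
        import warnings

        warnings.warn("pair dictionary is empty after filtering")
    return PairDictionary(
        valid_bc1=set(valid_bc1),
        valid_bc2=set(valid_bc2),
        pairs=pairs,
        uniqueness_threshold=uniqueness,
        provenance=prov,
    )


def build_dictionary(
    pair_counts: pd.DataFrame,
    high_cutoff: int,
    low_max: int = 5,
    pileup_min: int = 3,
    dominant_bc2: Optional[str] = "auto",
    dominant_radius: int = 2,
    max_homopolymer_g: int = 10,
    prune_radius: int = 2,
    min_fold: float = 10.0,
    min_pair_reads: int = 2,
    uniqueness: float = 0.99,
) -> PairDictionary:
    """Run the full per-side filter cascade and the unique-pairing filter.

    ``dominant_bc2='auto'`` removes the most abundant BC2 and its
    neighborhood (the artifact-barcode filter); pass ``None`` to skip, or an
    explicit sequence.  Mid-count pruning uses the pre-correction high set.
    """
    prov: Dict[str, int] = {}
    valid_sides: Dict[str, Set[str]] = {}
    for side, trunc_sig in (("bc1", TRUNC_SIGNATURE_BC1), ("bc2", TRUNC_SIGNATURE_BC2)):
        totals = barcode_totals(pair_counts, side, pileup_min=pileup_min)
        prov[f"{side}_barcodes_total"] = len(totals)
        removed: Set[str] = set()
        if side == "bc2" and dominant_bc2 is not None and len(totals):
            dom = None if dominant_bc2 == "auto" else dominant_bc2
            removed |= remove_dominant(totals, dominant=dom, radius=dominant_radius)
        prov[f"{side}_dominant_removed"] = len(removed)
        artifacts = filter_artifacts(
            set(totals.index) - removed, trunc_sig, max_homopolymer_g
        )
        prov[f"{side}_artifact_removed"] = len(artifacts)
        removed |= artifacts
        totals = totals.drop(index=[b for b in removed if b in totals.index])

        classes = classify_abundance(totals, high_cutoff=high_cutoff, low_max=low_max)
        by_class = classes.groupby("class")["barcode"]
        mid = set(by_class.get_group("mid")) if "mid" in by_class.groups else set()
        high = set(by_class.get_group("high")) if "high" in by_class.groups else set()
        prov[f"{side}_low"] = len(classes) - len(mid) - len(high)
        prov[f"{side}_mid"] = len(mid)
        prov[f"{side}_high"] = len(high)

        mid_kept, mid_pruned = prune_mid_by_high(mid, high, radius=prune_radius)
        prov[f"{side}_mid_pruned"] = len(mid_pruned)
        if high:
            reps, _ = correct_high_counts(
                totals.loc[sorted(high)], radius=prune_radius, min_fold=min_fold
            )
        else:
            reps = set()
        prov[f"{side}_high_corrected"] = len(reps)
        valid_sides[side] = mid_kept | reps
        prov[f"{side}_valid"] = len(valid_sides[side])

    return build_pair_dictionary(
        pair_counts,
        valid_sides["bc1"],
        valid_sides["bc2"],
        min_pair_reads=min_pair_reads,
        uniqueness=uniqueness,
        provenance=prov,
    )


def extract_pairs_from_fastq(
    read1_path,
    read2_path,
    bc1_window: Tuple[int, int] = (0, 15),
    bc2_window: Tuple[int, int] = (20, 36),
) -> pd.DataFrame:
    """Extract (bc1_obs, bc2_obs) from a paired-end association run.

    By default BC1 is taken from read 2 (first 15 of a 16-cycle window — the
    barcode is 15 nt though the read window spans 16 cycles, a deliberate
    truncation) and BC2 from read 1 cycles 21-36; both windows are 0-based
    half-open and configurable to match other run layouts.
    """
    from Bio import SeqIO

    b1s, b2s = [], []
    with open(read1_path) as fh1, open(read2_path) as fh2:
        for r1, r2 in zip(SeqIO.parse(fh1, "fastq"), SeqIO.parse(fh2, "fastq")):
            b1s.append(str(r2.seq)[bc1_window[0]:bc1_window[1]].upper())
            b2s.append(str(r1.seq)[bc2_window[0]:bc2_window[1]].upper())
    return pd.DataFrame({"bc1_obs": b1s, "bc2_obs": b2s})
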