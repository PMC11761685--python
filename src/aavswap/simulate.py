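"""Ground-truth simulator for association short reads and packaged long reads.

The generator emulates the structure of a pool-packaged dual-barcode AAV
experiment so every downstream stage is testable without external data:

* a complex dictionary of unique BC1-BC2 pairs, optionally with jackpotted
  clones and a dominant artifact BC2;
* short association reads exposing per-template BC1/BC2 observations with
  per-base substitution errors;
* packaged long reads with the full signpost layout, library insert indices,
  a controllable barcode-swap process (phenomenological ``label_swap`` or a
  mechanistic homology-tract ``template_switch`` model), truncated/composite
  off-products, parental carryover, hairpin-dimer artifacts, random strand,
  and ONT-like substitution/indel noise applied after truth labeling.

Truth always refers to the template, never the noisy observation.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .design import (
    DIMER_HAIRPIN,
    LibraryDesign,
    SHARED_ADAPTER_NT,
    build_cargo_with_fillers,
    default_designs,
    revcomp,
)
from .seqdist import NeighborIndex

_BASE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i
_IDX_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

OFFPRODUCT_CLASSES = ("none", "truncated", "composite", "parental")


@dataclass
class SimulationConfig:
    """Parameters of one packaged-library simulation.

    ``swap_rate`` is the per-read swap probability in ``label_swap`` mode and
    the per-base crossover probability inside shared homology tracts in
    ``template_switch`` mode (so the realized swap rate becomes length- and
    homology-dependent).  All probabilities are validated to [0, 1] and the
    off-product fractions must sum to at most 1.
    """

    n_reads: int
    swap_rate: float = 0.0
    mechanism: str = "label_swap"
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    frac_truncated: float = 0.0
    frac_composite: float = 0.0
    frac_parental: float = 0.0
    frac_dimer: float = 0.0
    jackpot_fraction: float = 0.0
    dominant_bc2: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.mechanism not in ("label_swap", "template_switch"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        for name in (
            "swap_rate", "sub_rate", "ins_rate", "del_rate", "frac_truncated",
            "frac_composite", "frac_parental", "frac_dimer", "jackpot_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_truncated + self.frac_composite + self.frac_parental > 1.0:
            raise ValueError("off-product fractions sum to more than 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Per-pair and per-read truth tables.

    ``pairs`` has columns pair_id, bc1, bc2, clone_weight.  ``reads`` (filled
    by :func:`simulate_packaged_reads`) has read_id, library_id,
    true_bc1_pair_id, true_bc2_pair_id, is_swap, offproduct, is_dimer, strand.
    A read is a swap iff its two barcodes trace to different truth pairs.
    """

    pairs: pd.DataFrame
    reads: Optional[pd.DataFrame] = None


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _IDX_TO_BASE[rng.integers(0, 4, size=length)].tobytes().decode()


def generate_barcode_truth(
    n_pairs: int,
    bc1_len: int = 15,
    bc2_len: int = 16,
    min_pairwise_dist: int = 0,
    seed: int = 0,
    max_attempts_per_barcode: int = 5000,
) -> GroundTruth:
    """Draw ``n_pairs`` unique BC1-BC2 pairs with a minimum pairwise distance.

    Rejection sampling with a pigeonhole Levenshtein index: each candidate
    barcode is accepted only if no previously accepted barcode on the same
    side lies within ``min_pairwise_dist - 1``.  Candidates carrying the
    artifact signatures (10+ consecutive Gs or the side's post-barcode
    truncation signature) are also rejected: such barcodes are removed by the
    dictionary filters by design, so they can never be members of a validated
    dictionary.  Raises ``RuntimeError`` when the space is too saturated to
    place another barcode within the attempt budget.
    """
    from .dictionary import TRUNC_SIGNATURE_BC1, TRUNC_SIGNATURE_BC2

    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    def make_side(length: int, signature: str) -> List[str]:
        idx: Optional[NeighborIndex] = None
        seen: set = set()
        if min_pairwise_dist >= 2:
            idx = NeighborIndex(min_pairwise_dist - 1, length)
        out: List[str] = []
        for i in range(n_pairs):
            for _ in range(max_attempts_per_barcode):
                bc = _random_seq(rng, length)
                if "G" * 10 in bc or signature in bc:
                    continue
                if idx is not None:
                    if idx.has_neighbor(bc):
                        continue
                    idx.add(bc)
                elif min_pairwise_dist == 1:
                    if bc in seen:
                        continue
                    seen.add(bc)
                out.append(bc)
                break
            else:
                raise RuntimeError(
                    f"could not place barcode {i + 1}/{n_pairs} of length {length} "
                    f"at min distance {min_pairwise_dist} after "
                    f"{max_attempts_per_barcode} attempts"
                )
        return out

    bc1s = make_side(bc1_len, TRUNC_SIGNATURE_BC1)
    bc2s = make_side(bc2_len, TRUNC_SIGNATURE_BC2)
    pairs = pd.DataFrame(
        {
            "pair_id": [f"P{i:06d}" for i in range(n_pairs)],
            "bc1": bc1s,
            "bc2": bc2s,
            "clone_weight": 1.0,
        }
    )
    return GroundTruth(pairs=pairs)


def _seqs_to_idx_matrix(seqs: Sequence[str], length: int) -> np.ndarray:
    buf = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return _BASE_TO_IDX[buf].reshape(len(seqs), length)


def _idx_matrix_to_seqs(mat: np.ndarray) -> np.ndarray:
    byts = np.ascontiguousarray(_IDX_TO_BASE[mat])
    return np.char.decode(byts.view(f"S{mat.shape[1]}").ravel(), "ascii")


def simulate_association_reads(
    truth: GroundTruth,
    mean_depth: float,
    jackpot_fraction: float = 0.0,
    jackpot_fold: float = 1000.0,
    dominant_bc2: Optional[str] = None,
    dominant_frac: float = 0.025,
    error_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate short association reads exposing (bc1_obs, bc2_obs) per read.

    Per-pair depths are Poisson(``mean_depth`` x clone weight); a
    ``jackpot_fraction`` of pairs receives weight ``jackpot_fold`` (clonal
    over-representation).  ``dominant_bc2`` replaces the BC2 observation of a
    ``dominant_frac`` share of reads, emulating the dominant artifact barcode.
    Substitution errors are applied per base at ``error_rate``.  Jackpot
    weights are recorded back into ``truth.pairs['clone_weight']``.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(seed)
    pairs = truth.pairs
    n_pairs = len(pairs)
    l1 = len(pairs["bc1"].iat[0])
    l2 = len(pairs["bc2"].iat[0])

    weights = np.ones(n_pairs)
    n_jack = int(round(jackpot_fraction * n_pairs))
    if n_jack > 0:
        jack = rng.choice(n_pairs, size=n_jack, replace=False)
        weights[jack] = jackpot_fold
    truth.pairs["clone_weight"] = weights

    counts = rng.poisson(mean_depth * weights)
    pair_idx = np.repeat(np.arange(n_pairs), counts)
    n_reads = pair_idx.size

    mat1 = _seqs_to_idx_matrix(pairs["bc1"].tolist(), l1)[pair_idx]
    mat2 = _seqs_to_idx_matrix(pairs["bc2"].tolist(), l2)[pair_idx]

    if dominant_bc2 is not None and dominant_frac > 0:
        dom_mask = rng.random(n_reads) < dominant_frac
        mat2[dom_mask] = _seqs_to_idx_matrix([dominant_bc2], l2)[0]

    for mat in (mat1, mat2):
        if error_rate > 0:
            err = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
            mat[err] = (mat[err] + shift[err]) % 4

    return pd.DataFrame(
        {
            "bc1_obs": _idx_matrix_to_seqs(mat1),
            "bc2_obs": _idx_matrix_to_seqs(mat2),
            "pair_id": pairs["pair_id"].to_numpy()[pair_idx],
        }
    )


def _noisy_idx(
    idx_arr: np.ndarray,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply independent per-base substitution/insertion/deletion events."""
    n = idx_arr.size
    keep = rng.random(n) >= del_rate if del_rate > 0 else np.ones(n, dtype=bool)
    work = idx_arr
    if sub_rate > 0:
        sub = keep & (rng.random(n) < sub_rate)
        shift = rng.integers(1, 4, size=n).astype(np.uint8)
        work = idx_arr.copy()
        work[sub] = (work[sub] + shift[sub]) % 4
    if ins_rate > 0:
        ins = rng.random(n + 1) < ins_rate
    else:
        ins = np.zeros(n + 1, dtype=bool)
    counts = ins[:n].astype(np.int64) + keep
    total = int(counts.sum()) + int(ins[n])
    out = np.empty(total, dtype=np.uint8)
    ends = np.cumsum(counts)
    starts = ends - counts
    n_ins = int(ins.sum())
    if n_ins:
        ins_bases = rng.integers(0, 4, size=n_ins).astype(np.uint8)
        pos = starts[ins[:n]]
        if ins[n]:
            out[-1] = ins_bases[-1]
            out[pos] = ins_bases[:-1]
        else:
            out[pos] = ins_bases
    out[ends[keep] - 1] = work[keep]
    return out


def apply_ont_noise(
    seq: str,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    seed: Union[int, np.random.Generator] = 0,
) -> str:
    """Apply ONT-like noise: independent per-base substitutions, insertions
    (before each position) and deletions.  Deterministic under seed."""
    for name, r in (("sub_rate", sub_rate), ("ins_rate", ins_rate), ("del_rate", del_rate)):
        if not 0.0 <= r < 1.0:
            raise ValueError(f"{name}={r} outside [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not seq:
        return seq
    arr = _BASE_TO_IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    return _IDX_TO_BASE[_noisy_idx(arr, sub_rate, ins_rate, del_rate, rng)].tobytes().decode()


def simulate_packaged_reads(
    designs: Union[LibraryDesign, Sequence[LibraryDesign]],
    truth: GroundTruth,
    config: SimulationConfig,
) -> Tuple[List[Tuple[str, str]], GroundTruth]:
    """Simulate packaged long reads with per-read ground truth.

    Each read takes a truth pair (uniformly), its library design (round-robin
    across ``designs``), and is made discordant per the configured mechanism:

    * ``label_swap`` — with probability ``swap_rate`` the BC2 is replaced by a
      uniformly chosen *other* pair's BC2 (exact per-read rate control);
    * ``template_switch`` — a partner pair is drawn and a crossover occurs
      inside the tract shared by the two templates (whole insert + 67 nt of
      adapter handles for homologous libraries, only the 67 nt of handles for
      non-homologous ones) with per-base probability ``swap_rate``.  This is
      an invented mechanistic model of template switching, not an observed
      mechanism; it reproduces length- and homology-dependent swapping.

    Off-products (truncated / composite / parental carryover) and hairpin
    dimers are injected per config; strand is uniform; ONT noise is applied
    last.  Truth labels refer to the pre-noise template.
    """
    if isinstance(designs, LibraryDesign):
        designs = [designs]
    main_designs = [d for d in designs if d.insert_class != "parental"]
    if not main_designs:
        raise ValueError("at least one non-parental design required")
    if len(truth.pairs) == 0:
        raise ValueError("truth has no pairs")
    parental = next(
        (d for d in designs if d.insert_class == "parental"),
        default_designs(main_designs[0].itr_to_itr_target_nt)["parental"],
    )

    rng = np.random.default_rng(config.seed)
    pairs = truth.pairs
    n_pairs = len(pairs)
    bc1s = pairs["bc1"].to_numpy()
    bc2s = pairs["bc2"].to_numpy()
    pair_ids = pairs["pair_id"].to_numpy()

    # Nominal fillers are fixed per design so truncated off-products stay short.
    fillers: Dict[str, Tuple[str, str]] = {}
    hom_inserts: Dict[str, str] = {}
    for d in list(main_designs) + [parental]:
        total = d.itr_to_itr_target_nt - d.fixed_overhead_nt - d.insert_length_nt
        if total < 0:
            raise ValueError(f"design {d.library_id} exceeds its ITR-to-ITR target")
        left = total // 2
        filler = ("CTCCT" * (total // 5 + 2))
        fillers[d.library_id] = (filler[:left], filler[: total - left])
        if d.insert_class == "homologous":
            hom_inserts[d.library_id] = _random_seq(rng, d.insert_length_nt)

    nonhom_cache: Dict[Tuple[str, int], str] = {}

    def member_insert(d: LibraryDesign, j: int) -> str:
        if d.insert_class == "homologous":
            return hom_inserts[d.library_id]
        if d.insert_class == "parental":
            return ""
        key = (d.library_id, j)
        if key not in nonhom_cache:
            nonhom_cache[key] = _random_seq(rng, d.insert_length_nt)
        return nonhom_cache[key]

    if (
        config.mechanism == "template_switch"
        and config.swap_rate > 0
        and all(
            d.insert_class == "parental" or SHARED_ADAPTER_NT == 0 for d in main_designs
        )
    ):
        warnings.warn("template_switch with zero shared tract: no swaps will occur")

    reads: List[Tuple[str, str]] = []
    rows: List[tuple] = []
    cum_trunc = config.frac_truncated
    cum_comp = cum_trunc + config.frac_composite
    cum_par = cum_comp + config.frac_parental

    for i in range(config.n_reads):
        read_id = f"R{i:07d}"
        design = main_designs[i % len(main_designs)]
        j = int(rng.integers(n_pairs))
        bc1, bc2 = bc1s[j], bc2s[j]
        j2 = j

        u = rng.random()
        if u < cum_trunc:
            offproduct = "truncated"
        elif u < cum_comp:
            offproduct = "composite"
        elif u < cum_par:
            offproduct = "parental"
            design = parental
        else:
            offproduct = "none"

        # Swap decision (parental carryover has no insert homology tract but
        # still shares the adapter scaffold; label_swap applies regardless).
        if n_pairs > 1 and config.swap_rate > 0:
            if config.mechanism == "label_swap":
                if rng.random() < config.swap_rate:
                    j2 = int(rng.integers(n_pairs - 1))
                    j2 = j2 if j2 < j else j2 + 1
                    bc2 = bc2s[j2]
            else:  # template_switch
                partner = int(rng.integers(n_pairs - 1))
                partner = partner if partner < j else partner + 1
                shared = SHARED_ADAPTER_NT
                if design.insert_class == "homologous":
                    shared += design.insert_length_nt
                p_switch = 1.0 - (1.0 - config.swap_rate) ** shared
                if rng.random() < p_switch:
                    j2 = partner
                    bc2 = bc2s[j2]

        insert = member_insert(design, j)
        if offproduct == "truncated" and insert:
            frac = rng.uniform(0.2, 0.6)
            insert = insert[: max(1, int(len(insert) * frac))]
        elif offproduct == "composite" and insert:
            a = insert[: int(len(insert) * 0.6)]
            b = revcomp(insert[: int(len(insert) * 0.5)])
            insert = a + b

        fl, fr = fillers[design.library_id]
        seq = build_cargo_with_fillers(design, bc1, bc2, insert, fl, fr)

        is_dimer = bool(rng.random() < config.frac_dimer)
        if is_dimer:
            seq = seq + DIMER_HAIRPIN + revcomp(seq)

        strand = "+" if rng.integers(2) == 0 else "-"
        if strand == "-":
            seq = revcomp(seq)

        if config.sub_rate or config.ins_rate or config.del_rate:
            arr = _BASE_TO_IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]
            arr = _noisy_idx(arr, config.sub_rate, config.ins_rate, config.del_rate, rng)
            seq = _IDX_TO_BASE[arr].tobytes().decode()

        reads.append((read_id, seq))
        rows.append(
            (read_id, design.library_id, pair_ids[j], pair_ids[j2],
             j != j2, offproduct, is_dimer, strand)
        )

    reads_df = pd.DataFrame(
        rows,
        columns=[
            "read_id", "library_id", "true_bc1_pair_id", "true_bc2_pair_id",
            "is_swap", "offproduct", "is_dimer", "strand",
        ],
    )
    return reads, GroundTruth(pairs=truth.pairs, reads=reads_df)


# ---------------------------------------------------------------------------
# Plain-text output helpers

def write_fastq(reads: Sequence[Tuple[str, str]], path, quality_char: str = "I") -> None:
    """Write (read_id, sequence) records as FASTQ with uniform dummy qualities."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_truth(truth: GroundTruth, pairs_path, reads_path=None) -> None:
    truth.pairs.to_csv(pairs_path, sep="\t", index=False)
    if reads_path is not None and truth.reads is not None:
        truth.reads.to_csv(reads_path, sep="\t", index=False)


def write_config(config: SimulationConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
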