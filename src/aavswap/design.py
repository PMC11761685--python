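"""Library design constants and the assembled cargo layout.

The assay reads a doubly barcoded AAV cargo: a left 15-nt barcode (BC1) and a
right 16-nt barcode (BC2), each flanked by constant "signpost" sequences, with
a library-specific insert plus a 10-nt internal index between the two barcode
blocks.  Everything downstream (parsing, demultiplexing, swap tallies) is
anchored on these four signposts, so their sequences and the relative layout
live here as the single source of truth.

Forward-strand cargo layout (left to right)::

    [filler_L][SP1][BC1][SP2 = Nextera R1 handle][insert]
        [R2 handle][index][spacer][SP3][BC2][SP4][filler_R]

Fillers pad the construct to a fixed ITR-to-ITR footprint (~2.3 kb) so that
libraries with different insert sizes produce equally sized genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import edlib

# The four constant signpost sequences flanking the barcodes.
SIGNPOST_IDS: Tuple[str, str, str, str] = (
    "left_bc1_up",
    "left_bc1_down",
    "right_bc2_up",
    "right_bc2_down",
)

SIGNPOSTS: Dict[str, str] = {
    "left_bc1_up": "CGCGTTTAAT",
    "left_bc1_down": "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG",  # Nextera R1 handle, 33 nt
    "right_bc2_up": "GATCCGTCGATCGACTGAGT",
    "right_bc2_down": "TAGCGCGCCATTAGGCATGA",
}

#: Nextera R1 mosaic-end adapter (identical to the left BC1 downstream signpost).
NEXTERA_R1 = SIGNPOSTS["left_bc1_down"]
#: Partial Nextera R2 mosaic-end adapter appended by the indexed reverse primer.
NEXTERA_R2_PARTIAL = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"  # 34 nt
#: Total adapter-handle homology shared by any two tagmented (non-homologous) inserts.
SHARED_ADAPTER_NT = len(NEXTERA_R1) + len(NEXTERA_R2_PARTIAL)  # 33 + 34 = 67

#: Hairpin sequence found at the junction of read-dimer artifacts.
DIMER_HAIRPIN = "GCGGACCGAGCGGCCGC"

#: 10-nt internal insert indices used for demultiplexing, one per insert class.
INSERT_INDEX: Dict[str, str] = {
    "parental": "CTCTTCAGAT",
    "short_homologous": "AGACTCAAGT",
    "short_non_homologous": "GAGACGGTCA",
    "mid_homologous": "AGACGATCTG",
    "mid_non_homologous": "GAGACCCTAA",
    "long_homologous": "AGACATTGGC",
    "long_non_homologous": "GAGACCATCG",
}

#: Insert lengths (nt) of the homologous libraries; non-homologous libraries are
#: size-matched to these.
INSERT_LENGTH_NT = {"short": 127, "mid": 739, "long": 2034}

#: Fixed full ITR-to-ITR read-length windows (nt) used for full-length calls.
ITR_WINDOWS: Dict[str, Tuple[int, int]] = {
    "plasmid_parental": (800, 1050),
    "plasmid": (2000, 2500),
    "aav": (2250, 2750),
    "aav_multi_mid": (1100, 1400),
    "aav_multi_short": (500, 750),
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (uppercase preserved, N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CargoLayoutError(ValueError):
    """Raised when a cargo cannot be assembled at the requested footprint."""


@dataclass(frozen=True)
class LibraryDesign:
    """Design constants for one barcoded insert library.

    Parameters
    ----------
    library_id
        Free-text sample/library identifier.
    insert_class
        ``homologous`` (one insert sequence shared by every member),
        ``non_homologous`` (per-member size-matched inserts sharing only the
        adapter handles) or ``parental`` (no insert).
    insert_length_nt
        Nominal insert length, excluding the adapter handles.
    insert_index
        10-nt internal index used for demultiplexing.
    signposts
        The four constant anchors, ordered left-BC1-up, left-BC1-down,
        right-BC2-up, right-BC2-down.
    index_spacer_nt
        Distance between the index and the right BC2-upstream signpost; the
        exact geometry of the assembled map is configurable because only the
        signpost-relative offsets matter to the parser.
    """

    library_id: str
    insert_class: str
    insert_length_nt: int
    insert_index: str
    signposts: Tuple[str, str, str, str] = tuple(SIGNPOSTS[k] for k in SIGNPOST_IDS)
    bc1_length: int = 15
    bc2_length: int = 16
    r2_handle: str = NEXTERA_R2_PARTIAL
    index_spacer_nt: int = 0
    itr_to_itr_target_nt: int = 2300

    def __post_init__(self) -> None:
        if self.insert_class not in ("homologous", "non_homologous", "parental"):
            raise ValueError(f"unknown insert_class {self.insert_class!r}")
        if len(self.signposts) != 4:
            raise ValueError("signposts must be an ordered 4-tuple")

    @property
    def index_length(self) -> int:
        return len(self.insert_index)

    @property
    def fixed_overhead_nt(self) -> int:
        """Length of all constant components (everything except insert + fillers)."""
        return (
            sum(len(s) for s in self.signposts)
            + self.bc1_length
            + self.bc2_length
            + len(self.r2_handle)
            + self.index_length
            + self.index_spacer_nt
        )

    @property
    def filler_length_nt(self) -> int:
        """Total filler needed to reach the ITR-to-ITR target."""
        return self.itr_to_itr_target_nt - self.fixed_overhead_nt - self.insert_length_nt

    def signpost(self, signpost_id: str) -> str:
        return self.signposts[SIGNPOST_IDS.index(signpost_id)]


def default_designs(itr_to_itr_target_nt: int = 2300) -> Dict[str, LibraryDesign]:
    """The seven study libraries: parental plus {short,mid,long} x {hom,non-hom}."""
    designs = {
        "parental": LibraryDesign(
            "parental", "parental", 0, INSERT_INDEX["parental"],
            itr_to_itr_target_nt=itr_to_itr_target_nt,
        )
    }
    for size in ("short", "mid", "long"):
        for cls in ("homologous", "non_homologous"):
            key = f"{size}_{cls}"
            designs[key] = LibraryDesign(
                key, cls, INSERT_LENGTH_NT[size], INSERT_INDEX[key],
                itr_to_itr_target_nt=itr_to_itr_target_nt,
            )
    return designs


def validate_index_separation(
    designs: Sequence[LibraryDesign], min_dist: int = 3
) -> int:
    """Check that all configured insert indices are mutually >= min_dist apart.

    Returns the minimum pairwise Levenshtein distance; raises ``ValueError``
    when two indices are too close for the demultiplexing rule (best distance
    <= 1 with a gap >= 2 to the runner-up) to be unambiguous on exact indices.
    """
    indices = [d.insert_index for d in designs]
    best = None
    for i, a in enumerate(indices):
        for b in indices[i + 1:]:
            d = edlib.align(a, b)["editDistance"]
            best = d if best is None else min(best, d)
            if d < min_dist:
                raise ValueError(
                    f"insert indices {a} and {b} are Levenshtein {d} apart (< {min_dist})"
                )
    return best if best is not None else min_dist


def build_cargo(
    design: LibraryDesign,
    bc1: str,
    bc2: str,
    insert: str = "",
    return_layout: bool = False,
):
    """Assemble the forward-strand cargo sequence for one library member.

    The two fillers absorb ``design.itr_to_itr_target_nt - fixed - len(insert)``
    nt, split as evenly as possible (left gets the floor).  Filler bases are a
    fixed non-informative 'A'-free pattern so they can never create spurious
    homopolymer or signpost hits; callers that want realistic filler pass their
    own sequence through :func:`build_cargo_with_fillers`.

    Raises :class:`CargoLayoutError` when the components already exceed the
    target so a non-negative filler is impossible.
    """
    total_filler = design.itr_to_itr_target_nt - design.fixed_overhead_nt - len(insert)
    if total_filler < 0:
        raise CargoLayoutError(
            f"components ({design.fixed_overhead_nt + len(insert)} nt) exceed "
            f"ITR-to-ITR target {design.itr_to_itr_target_nt} nt"
        )
    left = total_filler // 2
    filler_l = _filler(left)
    filler_r = _filler(total_filler - left)
    return build_cargo_with_fillers(
        design, bc1, bc2, insert, filler_l, filler_r, return_layout=return_layout
    )


def build_cargo_with_fillers(
    design: LibraryDesign,
    bc1: str,
    bc2: str,
    insert: str,
    filler_left: str,
    filler_right: str,
    return_layout: bool = False,
):
    """Assemble a cargo with explicit filler sequences.

    When ``return_layout`` is true, also returns a dict of 0-based half-open
    intervals for each component on the assembled forward strand.
    """
    if len(bc1) != design.bc1_length or len(bc2) != design.bc2_length:
        raise ValueError("barcode length does not match design")
    sp1, sp2, sp3, sp4 = design.signposts
    parts = [
        ("filler_left", filler_left),
        ("left_bc1_up", sp1),
        ("bc1", bc1),
        ("left_bc1_down", sp2),
        ("insert", insert),
        ("r2_handle", design.r2_handle),
        ("index", design.insert_index),
        ("spacer", "T" * design.index_spacer_nt),
        ("right_bc2_up", sp3),
        ("bc2", bc2),
        ("right_bc2_down", sp4),
        ("filler_right", filler_right),
    ]
    seq = "".join(p for _, p in parts)
    if not return_layout:
        return seq
    layout = {}
    pos = 0
    for name, p in parts:
        layout[name] = (pos, pos + len(p))
        pos += len(p)
    return seq, layout


def _filler(n: int) -> str:
    # Periodic CT pattern: never matches a signpost, no G homopolymers.
    return ("CTCCT" * (n // 5 + 1))[:n]
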