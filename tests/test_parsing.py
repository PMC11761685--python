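"""Signpost location, layout validation, feature extraction, demux, lengths."""

import numpy as np
import pytest

import aavswap as av
from aavswap.design import SIGNPOST_IDS, SIGNPOSTS
from aavswap.parsing import LengthWindows

from conftest import dp_levenshtein

BC1 = "ACGTACGTACGTACG"
BC2 = "TGCATGCATGCATGCA"


@pytest.fixture(scope="module")
def cargo(designs=None):
    d = av.default_designs()["mid_homologous"]
    insert = ("ACGGTTCA" * 100)[: d.insert_length_nt]
    seq, layout = av.build_cargo(d, BC1, BC2, insert, return_layout=True)
    return d, seq, layout, insert


class TestLocate:
    def test_exact_roundtrip(self, cargo):
        d, seq, layout, _ = cargo
        hits = {h.signpost_id: h for h in av.locate_signposts(seq) if h.strand == "+"}
        for sid in SIGNPOST_IDS:
            assert hits[sid].identity == 1.0
            assert (hits[sid].read_start, hits[sid].read_end) == layout[sid]

    def test_identity_threshold_counted_mismatches(self):
        """20-nt signpost with 2 subs: identity 0.9 kept; 6 subs: dropped."""
        sp = SIGNPOSTS["right_bc2_up"]  # 20 nt
        assert len(sp) == 20
        background = "CT" * 200

        def mutate(s, n):
            out = list(s)
            for i in range(n):
                out[2 * i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[2 * i]]
            return "".join(out)

        read2 = background + mutate(sp, 2) + background
        hits = [h for h in av.locate_signposts(read2) if h.signpost_id == "right_bc2_up"]
        assert hits and max(h.identity for h in hits) == pytest.approx(0.9)
        read6 = background + mutate(sp, 6) + background
        hits6 = [
            h for h in av.locate_signposts(read6)
            if h.signpost_id == "right_bc2_up" and h.identity >= 0.75
        ]
        assert not hits6

    def test_reverse_complement_mirrored(self, cargo):
        d, seq, layout, _ = cargo
        rc = av.revcomp(seq)
        n = len(seq)
        hits = {h.signpost_id: h for h in av.locate_signposts(rc) if h.strand == "-"}
        for sid in SIGNPOST_IDS:
            s, e = layout[sid]
            assert (hits[sid].read_start, hits[sid].read_end) == (n - e, n - s)


class TestLayout:
    def test_canonical_pass(self, cargo):
        _, seq, _, _ = cargo
        ok, strand, reason = av.validate_layout(av.locate_signposts(seq))
        assert ok and strand == "+" and reason == "ok"

    def test_rc_pass_minus(self, cargo):
        _, seq, _, _ = cargo
        ok, strand, _ = av.validate_layout(av.locate_signposts(av.revcomp(seq)))
        assert ok and strand == "-"

    def test_missing_signpost_fails(self, cargo):
        d, seq, layout, _ = cargo
        s, e = layout["left_bc1_up"]
        broken = seq[:s] + "T" * (e - s) + seq[e:]
        ok, _, reason = av.validate_layout(av.locate_signposts(broken))
        assert not ok and reason == "signpost_missing"

    def test_order_violation(self, cargo):
        """BC2 block upstream of BC1 on +: fail; its RC: pass on -."""
        d, _, _, _ = cargo
        sp1, sp2, sp3, sp4 = d.signposts
        fill = "CT" * 30
        scrambled = fill + sp3 + BC2 + sp4 + fill + sp1 + BC1 + sp2 + fill
        ok, _, reason = av.validate_layout(av.locate_signposts(scrambled))
        assert not ok and reason == "order_violation"
        ok2, strand2, _ = av.validate_layout(
            av.locate_signposts(av.revcomp(scrambled))
        )
        assert not ok2

    def test_mixed_strand_fails(self, cargo):
        d, seq, layout, _ = cargo
        s, e = layout["right_bc2_down"]
        flipped = seq[:s] + av.revcomp(seq[s:e]) + seq[e:]
        ok, _, reason = av.validate_layout(av.locate_signposts(flipped))
        assert not ok and reason in ("strand_discordant", "signpost_missing")


class TestExtract:
    def test_noiseless_roundtrip(self, cargo):
        d, seq, _, insert = cargo
        hits = av.locate_signposts(seq)
        feats = av.extract_features(seq, hits, d)
        assert feats["bc1"] == BC1
        assert feats["bc2"] == BC2
        assert feats["index_obs"] == d.insert_index
        assert feats["insert_seq"] == insert

    def test_rc_invariance(self, cargo):
        d, seq, _, _ = cargo
        rc = av.revcomp(seq)
        f1 = av.extract_features(seq, av.locate_signposts(seq), d)
        f2 = av.extract_features(rc, av.locate_signposts(rc), d)
        f2.pop("strand"), f1.pop("strand")
        assert f1 == f2

    def test_insertion_shifts_bc_to_bc_len(self, cargo):
        d, seq, layout, _ = cargo
        mid = (layout["insert"][0] + layout["insert"][1]) // 2
        edited = seq[:mid] + "A" + seq[mid:]
        f0 = av.extract_features(seq, av.locate_signposts(seq), d)
        f1 = av.extract_features(edited, av.locate_signposts(edited), d)
        assert f1["bc_to_bc_len"] == f0["bc_to_bc_len"] + 1
        assert f1["bc1"] == BC1 and f1["bc2"] == BC2


class TestDemux:
    def test_exact_index(self):
        lib, best, second = av.demultiplex("AGACTCAAGT", av.INSERT_INDEX)
        assert lib == "short_homologous" and best == 0

    def test_equidistant_ambiguous(self):
        table = {"a": "AAAAAAAAAA", "b": "AAAAAAAATT"}
        lib, best, second = av.demultiplex("AAAAAAAAGG", table)
        assert best == second == 2 and lib == "ambiguous"

    def test_one_substitution_all_seven(self):
        """Every index mutated by 1 substitution still demultiplexes, verified
        against an exhaustive DP distance matrix."""
        for lib, idx in av.INSERT_INDEX.items():
            mutated = ("T" if idx[4] != "T" else "A").join([idx[:4], idx[5:]])
            assert len(mutated) == 10
            got, best, second = av.demultiplex(mutated, av.INSERT_INDEX)
            assert got == lib
            dists = sorted(
                dp_levenshtein(mutated, other) for other in av.INSERT_INDEX.values()
            )
            assert dists[0] <= 1 and dists[1] - dists[0] >= 2


class TestDictionaryMatch:
    def test_concordant_discordant_invalid(self, small_pdict, small_truth):
        p = small_truth.pairs
        b1, b2 = p["bc1"].iat[0], p["bc2"].iat[0]
        assert av.match_dictionary(b1, b2, small_pdict) == (True, True, True)
        # swap signature: both valid, discordant
        assert av.match_dictionary(b1, p["bc2"].iat[1], small_pdict) == (
            True, True, False,
        )
        mut = ("A" if b1[0] != "A" else "C") + b1[1:]
        v1, v2, conc = av.match_dictionary(mut, b2, small_pdict)
        assert (v1, v2, conc) == (False, True, None)


class TestLengthWindows:
    def test_degenerate(self):
        assert av.derive_length_window([500.0] * 200) == (500.0, 500.0)

    def test_nearest_rank_oracle(self):
        lengths = list(range(1, 101))
        lo, hi = av.derive_length_window(lengths)
        # nearest-rank: ceil(0.01*100)=1st, ceil(0.99*100)=99th order statistic
        assert (lo, hi) == (1, 99)

    def test_uniform_quantiles(self, rng):
        x = rng.uniform(2000, 2400, size=10_000)
        lo, hi = av.derive_length_window(x)
        assert abs(lo - 2004) < 4 and abs(hi - 2396) < 4

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            av.derive_length_window([])

    def test_closed_interval_boundary(self):
        w = LengthWindows(bc_to_bc=(100, 200), itr_to_itr={"lib": (500, 750)})
        full_bc, full_itr = av.classify_read_lengths(100, 600, w, "lib")
        assert full_bc is True and full_itr is True
        assert av.classify_read_lengths(99, 751, w, "lib") == (False, False)

    def test_missing_library_window_undefined(self):
        w = LengthWindows(bc_to_bc=(100, 200), itr_to_itr={"lib": (500, 750)})
        _, full_itr = av.classify_read_lengths(150, 600, w, "other")
        assert full_itr is None


class TestDimer:
    def test_constructed_dimer_split(self, cargo):
        d, seq, _, _ = cargo
        dimer = seq + av.DIMER_HAIRPIN + av.revcomp(seq)
        is_dimer, split = av.detect_dimer(dimer, expected_len=len(seq))
        assert is_dimer and split == len(seq)
        # forward pass parses normally
        feats = av.extract_features(
            dimer[:split], av.locate_signposts(dimer[:split]), d
        )
        assert feats["bc1"] == BC1

    def test_normal_read_not_dimer(self, cargo):
        _, seq, _, _ = cargo
        assert av.detect_dimer(seq, expected_len=len(seq)) == (False, None)

    def test_long_read_without_hairpin_not_dimer(self, cargo):
        _, seq, _, _ = cargo
        assert av.detect_dimer(seq + seq, expected_len=len(seq))[0] is False

    def test_noisy_dimers_detected(self, cargo):
        """>= 95% of dimers with 5% substitution noise are still detected."""
        _, seq, _, _ = cargo
        dimer = seq + av.DIMER_HAIRPIN + av.revcomp(seq)
        detected = sum(
            av.detect_dimer(
                av.apply_ont_noise(dimer, 0.05, 0, 0, seed=s), expected_len=len(seq)
            )[0]
            for s in range(200)
        )
        assert detected >= 190


class TestParsePipeline:
    def test_strand_invariance_of_tallies(self, small_truth, designs, small_pdict):
        """Reverse-complementing every read changes no downstream tally."""
        d = designs["short_homologous"]
        cfg = av.SimulationConfig(n_reads=400, swap_rate=0.25, seed=40)
        reads, _ = av.simulate_packaged_reads(d, small_truth, cfg)
        flipped = [(rid, av.revcomp(s)) for rid, s in reads]
        df1, _ = av.parse_reads(reads, d, small_pdict)
        df2, _ = av.parse_reads(flipped, d, small_pdict)
        cols = ["bc1", "bc2", "index_obs", "bc_to_bc_len", "concordant"]
        assert df1[cols].equals(df2[cols])
        t1 = av.tally_swaps(df1)[0]
        t2 = av.tally_swaps(df2)[0]
        assert (t1.n_concordant, t1.n_discordant) == (t2.n_concordant, t2.n_discordant)

    def test_noiseless_completeness(self, small_truth, designs, small_pdict):
        """Noise-free non-off-product reads all pass layout and demux to the
        true library."""
        libs = [designs[k] for k in ("short_homologous", "mid_non_homologous")]
        cfg = av.SimulationConfig(n_reads=300, swap_rate=0.1, seed=41)
        reads, truth = av.simulate_packaged_reads(libs, small_truth, cfg)
        df, cascade = av.parse_reads(reads, libs, small_pdict)
        assert cascade["retained"]["layout"] == len(reads)
        merged = df.merge(truth.reads, on="read_id", suffixes=("", "_true"))
        assert (merged["library_id"] == merged["library_id_true"]).all()
        assert (merged["concordant"] != merged["is_swap"]).all()

    def test_cascade_sum_consistency(self, small_truth, designs, small_pdict):
        cfg = av.SimulationConfig(
            n_reads=500, swap_rate=0.2, sub_rate=0.02, ins_rate=0.005,
            del_rate=0.005, frac_truncated=0.1, frac_dimer=0.05, seed=42,
        )
        d = designs["mid_homologous"]
        reads, _ = av.simulate_packaged_reads(d, small_truth, cfg)
        ctrl, _ = av.simulate_packaged_reads(
            d, small_truth, av.SimulationConfig(n_reads=300, seed=43)
        )
        ctrl_df, _ = av.parse_reads(ctrl, d)
        window = av.derive_length_window(ctrl_df["bc_to_bc_len"].dropna())
        df, cascade = av.parse_reads(
            reads, d, small_pdict, windows=LengthWindows(bc_to_bc=window)
        )
        assert sum(cascade["reasons"].values()) == cascade["n_input"] == len(reads)
        retained = list(cascade["retained"].values())
        assert retained == sorted(retained, reverse=True)
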