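"""Unit tests for seed construction: hashing, masks, windows, protocols."""

import numpy as np
import pytest

from strobeseed.seeding import (
    Protocol,
    SeedParams,
    SpacedMask,
    apply_spaced_mask,
    combine_strobe_hashes,
    generate_hybridstrobes,
    generate_kmers,
    generate_minstrobes,
    generate_randstrobes,
    generate_seeds,
    generate_spaced_kmers,
    hash_dna,
    make_spaced_mask,
    precompute_strobe_hashes,
    strobemer_window,
)

from oracles import naive_strobemer_positions


def all_protocol_params(k=18):
    assert k % 6 == 0
    return {
        "kmer": SeedParams(Protocol.KMER, k=k),
        "spaced_dense": SeedParams(
            Protocol.SPACED, mask=make_spaced_mask(k, "dense", 7)
        ),
        "spaced_sparse": SeedParams(
            Protocol.SPACED, mask=make_spaced_mask(k, "sparse", 7)
        ),
        "minstrobe": SeedParams(Protocol.MINSTROBE, n=2, ell=k // 2, w_min=10, w_max=20),
        "randstrobe": SeedParams(Protocol.RANDSTROBE, n=3, ell=k // 3, w_min=10, w_max=20),
        "hybridstrobe": SeedParams(
            Protocol.HYBRIDSTROBE, n=2, ell=k // 2, w_min=10, w_max=20, x=3
        ),
    }


class TestHashing:
    def test_identical_substrings_hash_equal(self, random_dna):
        s = random_dna(60, seed=3) + random_dna(60, seed=3)
        H = precompute_strobe_hashes(s, 9)
        assert H[0] == H[60]
        assert len(H) == len(s) - 9 + 1

    def test_matches_direct_per_position_hashing(self, random_dna):
        s = random_dna(40, seed=5)
        H = precompute_strobe_hashes(s, 7)
        direct = [hash_dna(s[i : i + 7]) for i in range(len(s) - 6)]
        assert list(H) == direct
        rev = s[::-1]
        assert list(precompute_strobe_hashes(rev, 7)) != direct

    def test_boundaries(self):
        assert len(precompute_strobe_hashes("ACGTACG", 7)) == 1
        assert len(precompute_strobe_hashes("ACG", 7)) == 0

    def test_deterministic_across_calls(self, random_dna):
        s = random_dna(100, seed=11)
        a = precompute_strobe_hashes(s, 10)
        b = precompute_strobe_hashes(s, 10)
        assert np.array_equal(a, b)


class TestKmers:
    @pytest.mark.parametrize(
        "length,k,expected", [(100, 18, 83), (18, 18, 1), (10, 18, 0), (0, 5, 0)]
    )
    def test_seed_count(self, random_dna, length, k, expected):
        s = random_dna(length, seed=1)
        assert len(generate_kmers(s, k)) == expected

    def test_self_alignment_is_positional(self, random_dna):
        s = random_dna(80, seed=2)
        seeds = generate_kmers(s, 20)
        for i, seed in enumerate(seeds):
            assert seed.positions == (i,)
            assert (seed.span_start, seed.span_end) == (i, i + 20)

    def test_ambiguous_bases_skip_overlapping_seeds(self, random_dna):
        s = random_dna(30, seed=4) + "N" + random_dna(30, seed=5)
        seeds = generate_kmers(s, 10)
        # 61 - 10 + 1 = 52 starts, minus the 10 windows covering the N
        assert len(seeds) == 42
        assert all("N" not in s[p.span_start : p.span_end] for p in seeds)


class TestSpaced:
    def test_dense_and_sparse_spans(self):
        assert make_spaced_mask(4, "dense", 0).L == 6
        assert make_spaced_mask(4, "sparse", 0).L == 12
        assert make_spaced_mask(18, "dense", 0).L == 27

    def test_mask_invariants_and_determinism(self):
        m1 = make_spaced_mask(12, "sparse", 42)
        m2 = make_spaced_mask(12, "sparse", 42)
        assert m1 == m2
        assert m1.k == 12
        assert m1.bits[0] == 1 and m1.bits[-1] == 1
        with pytest.raises(ValueError):
            make_spaced_mask(1, "dense", 0)

    def test_k2_mask_has_endpoints_only(self):
        m = make_spaced_mask(2, "dense", 0)
        assert sum(m.bits) == 2 and m.bits[0] == 1 and m.bits[-1] == 1

    def test_worked_example(self):
        mask = SpacedMask.from_string("101011")
        assert apply_spaced_mask("AGGTCA", 0, mask) == "AGCA"

    def test_all_ones_mask_reduces_to_kmer(self, random_dna):
        s = random_dna(30, seed=9)
        mask = SpacedMask.from_string("1" * 8)
        assert apply_spaced_mask(s, 3, mask) == s[3:11]
        spaced = generate_spaced_kmers(s, mask)
        kmers = generate_kmers(s, 8)
        assert np.array_equal(spaced.hashes, kmers.hashes)

    def test_manual_index_selection(self):
        assert apply_spaced_mask("ACGT", 0, SpacedMask.from_string("1001")) == "AT"

    def test_window_out_of_range(self):
        with pytest.raises(ValueError):
            apply_spaced_mask("ACGT", 2, SpacedMask.from_string("101"))

    def test_tail_degenerates_to_contiguous_kmer(self, random_dna):
        s = random_dna(40, seed=10)
        mask = make_spaced_mask(12, "sparse", 3)  # L = 36
        seeds = generate_spaced_kmers(s, mask)
        assert len(seeds) == 40 - 12 + 1
        tail = seeds[-1]
        assert tail.positions == tuple(range(28, 40))  # contiguous
        assert tail.hash == hash_dna(s[28:40])


class TestWindows:
    def test_total_span_formula(self):
        p = SeedParams(Protocol.MINSTROBE, n=3, ell=3, w_min=3, w_max=5)
        assert p.span == 13

    def test_printed_interval(self):
        p = SeedParams(Protocol.RANDSTROBE, n=2, ell=9, w_min=10, w_max=20)
        assert strobemer_window(0, 2, p, 100) == (10, 20)

    def test_order3_second_and_third_windows(self):
        p = SeedParams(Protocol.RANDSTROBE, n=3, ell=6, w_min=10, w_max=20)
        assert strobemer_window(5, 2, p, 200) == (15, 25)
        assert strobemer_window(5, 3, p, 200) == (35, 45)

    def test_degenerate_tail_is_contiguous_kmer(self, random_dna):
        p = SeedParams(Protocol.MINSTROBE, n=2, ell=9, w_min=10, w_max=20)
        seq_len = 100
        i = seq_len - p.k  # only k letters left
        lo, hi = strobemer_window(i, 2, p, seq_len)
        assert lo == hi == i + 9
        s = random_dna(seq_len, seed=6)
        seeds = generate_minstrobes(s, p)
        last = seeds[-1]
        assert last.positions == (i, i + 9)

    def test_no_seed_beyond_last_start(self):
        p = SeedParams(Protocol.MINSTROBE, n=2, ell=9, w_min=10, w_max=20)
        with pytest.raises(ValueError):
            strobemer_window(83, 2, p, 100)


class TestStrobemerProtocols:
    @pytest.mark.parametrize("name", list(all_protocol_params()))
    def test_one_seed_per_position(self, random_dna, name):
        params = all_protocol_params()[name]
        for L in (100, 46, 18, 17, 0):
            s = random_dna(L, seed=L)
            assert len(generate_seeds(s, params)) == max(0, L - 18 + 1)

    @pytest.mark.parametrize(
        "proto,n,ell,w_min,w_max,x",
        [
            ("minstrobe", 2, 9, 10, 20, 3),
            ("minstrobe", 3, 6, 10, 20, 3),
            ("randstrobe", 2, 9, 10, 20, 3),
            ("randstrobe", 3, 6, 10, 20, 3),
            ("hybridstrobe", 2, 9, 10, 20, 3),
            ("hybridstrobe", 3, 6, 10, 20, 3),
            ("randstrobe", 2, 15, 1, 40, 3),  # overlapping strobes allowed
            ("hybridstrobe", 2, 9, 12, 50, 5),
        ],
    )
    def test_matches_per_window_recomputation_oracle(
        self, random_dna, proto, n, ell, w_min, w_max, x
    ):
        params = SeedParams(proto, n=n, ell=ell, w_min=w_min, w_max=w_max, x=x)
        s = random_dna(200, seed=len(proto) * 100 + n * 10 + w_min + w_max)
        seeds = generate_seeds(s, params)
        expected = naive_strobemer_positions(s, params)
        got = [tuple(int(v) for v in row) for row in seeds.positions]
        assert got == expected

    def test_window_of_width_one_fixes_spacing(self, random_dna):
        s = random_dna(120, seed=8)
        for proto in ("minstrobe", "randstrobe"):
            params = SeedParams(proto, n=2, ell=9, w_min=15, w_max=15)
            seeds = generate_seeds(s, params)
            full = [p for p in seeds if p.positions[1] - p.positions[0] == 15]
            # all full-span seeds have the fixed offset
            n_full = 120 - params.span + 1
            assert len(full) >= n_full

    def test_hybridstrobe_x1_equals_minstrobes(self, random_dna):
        s = random_dna(300, seed=12)
        hyb = generate_hybridstrobes(
            s, SeedParams("hybridstrobe", n=2, ell=9, w_min=10, w_max=30, x=1)
        )
        mins = generate_minstrobes(
            s, SeedParams("minstrobe", n=2, ell=9, w_min=10, w_max=30)
        )
        assert np.array_equal(hyb.positions, mins.positions)
        assert np.array_equal(hyb.hashes, mins.hashes)

    def test_hybridstrobe_degenerate_subwindows_rejected(self):
        with pytest.raises(ValueError, match="subwindow"):
            SeedParams("hybridstrobe", n=2, ell=3, w_min=3, w_max=5, x=3)

    def test_determinism(self, random_dna):
        s = random_dna(500, seed=13)
        p = SeedParams("randstrobe", n=2, ell=9, w_min=10, w_max=50)
        a = generate_randstrobes(s, p)
        b = generate_randstrobes(s, p)
        assert np.array_equal(a.hashes, b.hashes)
        assert np.array_equal(a.positions, b.positions)

    def test_minstrobes_share_minimizers_more_than_randstrobes(self, random_dna):
        s = random_dna(1000, seed=14)
        p_min = SeedParams("minstrobe", n=2, ell=9, w_min=10, w_max=50)
        p_rand = SeedParams("randstrobe", n=2, ell=9, w_min=10, w_max=50)

        def sharing_rate(seeds):
            second = seeds.positions[:, 1]
            return float(np.mean(second[1:] == second[:-1]))

        assert sharing_rate(generate_minstrobes(s, p_min)) > sharing_rate(
            generate_randstrobes(s, p_rand)
        )

    def test_narrow_tail_off_drops_tail_seeds(self, random_dna):
        s = random_dna(100, seed=15)
        p_on = SeedParams("minstrobe", n=2, ell=9, w_min=10, w_max=20)
        p_off = SeedParams("minstrobe", n=2, ell=9, w_min=10, w_max=20, narrow_tail=False)
        on = generate_minstrobes(s, p_on)
        off = generate_minstrobes(s, p_off)
        assert len(on) == 83
        assert len(off) == 100 - p_on.span + 1
        assert np.array_equal(off.positions, on.positions[: len(off)])

    def test_strobes_skip_ambiguous_letters(self, random_dna):
        s = random_dna(60, seed=16) + "N" + random_dna(60, seed=17)
        p = SeedParams("randstrobe", n=2, ell=9, w_min=10, w_max=20)
        seeds = generate_randstrobes(s, p)
        for seed in seeds:
            for pos in seed.positions:
                assert "N" not in s[pos : pos + 9]


class TestCombine:
    def test_printed_arithmetic(self):
        assert combine_strobe_hashes([6, 6]) == 6 // 2 + 6 // 3  # = 5
        assert combine_strobe_hashes([4, 6]) == 4 // 2 + 6 // 3  # = 4
        assert combine_strobe_hashes([6, 4]) == 6 // 2 + 4 // 3  # = 4
        assert combine_strobe_hashes([30, 24, 10]) == 10 + 6 + 2

    def test_asymmetry(self):
        assert combine_strobe_hashes([100, 7]) != combine_strobe_hashes([7, 100])

    def test_no_overflow_at_max(self):
        m = 2**64 - 1
        exact = m // 2 + m // 3
        assert combine_strobe_hashes([m, m]) == exact
        assert exact < 2**64
        assert combine_strobe_hashes([m, m, m]) == m // 3 + m // 4 + m // 5

    def test_matches_generated_seed_hashes(self, random_dna):
        s = random_dna(150, seed=18)
        p = SeedParams("minstrobe", n=3, ell=6, w_min=7, w_max=25)
        seeds = generate_minstrobes(s, p)
        H = precompute_strobe_hashes(s, 6)
        for seed in list(seeds)[:10]:
            parts = [int(H[pos]) for pos in seed.positions]
            assert seed.hash == combine_strobe_hashes(parts)

    def test_rejects_single_strobe(self):
        with pytest.raises(ValueError):
            combine_strobe_hashes([1])


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(protocol="kmer", k=0),
            dict(protocol="minstrobe", n=1, ell=9, w_min=10, w_max=20),
            dict(protocol="minstrobe", n=2, ell=0, w_min=10, w_max=20),
            dict(protocol="randstrobe", n=2, ell=9, w_min=0, w_max=20),
            dict(protocol="randstrobe", n=2, ell=9, w_min=21, w_max=20),
            dict(protocol="spaced"),
            dict(protocol="hybridstrobe", n=2, ell=9, w_min=10, w_max=20, x=0),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SeedParams(**kwargs)

    def test_k_consistency_for_strobemers(self):
        p = SeedParams("minstrobe", n=2, ell=9, w_min=10, w_max=20)
        assert p.k == 18
        with pytest.raises(ValueError):
            SeedParams("minstrobe", n=2, ell=9, w_min=10, w_max=20, k=17)


def test_seed_tsv_serialization(tmp_path, random_dna):
    s = random_dna(60, seed=19)
    seeds = generate_seeds(s, SeedParams("randstrobe", n=2, ell=9, w_min=10, w_max=20), seq_id="q1")
    out = tmp_path / "seeds.tsv"
    seeds.to_tsv(out)
    lines = out.read_text().strip().split("\n")
    assert lines[0].split("\t") == ["seq_id", "positions", "span_start", "span_end", "hash"]
    assert len(lines) == len(seeds) + 1
    first = lines[1].split("\t")
    assert first[0] == "q1"
    assert first[1] == ",".join(str(p) for p in seeds[0].positions)
    assert int(first[4], 16) == seeds[0].hash
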