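"""Mutation tables, Boolean encodings, projection, and Hamming distance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apopnet.spectra import (
    MUTATION_TYPES,
    BooleanSpectrum,
    GeneParameterMap,
    MutationTable,
    SpectrumAlignmentError,
    binarize,
    combine,
    hamming,
    parse_mutation_table,
    project_to_parameters,
    read_gene_parameter_map,
    write_gene_parameter_map,
)


def make_table(counts: dict[str, tuple[int, int, int]]) -> MutationTable:
    df = pd.DataFrame.from_dict(
        counts, orient="index", columns=list(MUTATION_TYPES))
    df.index.name = "gene"
    return MutationTable("test", df)


class TestParse:
    def test_preaggregated_dialect_sums_repeated_genes(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("gene\tmissense\tsynonymous\tnonsense\n"
                     "TP53\t2\t0\t1\nTP53\t1\t1\t0\nKRAS\t0\t0\t0\n")
        t = parse_mutation_table(p, "breast")
        assert t.counts.loc["TP53"].tolist() == [3, 1, 1]
        assert t.counts.loc["KRAS"].tolist() == [0, 0, 0]

    def test_empty_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        t = parse_mutation_table(p, "breast")
        assert t.genes == []

    def test_per_sample_dialect_equals_preaggregated(self, tmp_path, rng):
        genes = [f"G{i}" for i in range(12)]
        rows = []
        agg = {g: [0, 0, 0] for g in genes}
        for _ in range(200):
            g = genes[int(rng.integers(len(genes)))]
            k = int(rng.integers(3))
            rows.append((g, MUTATION_TYPES[k]))
            agg[g][k] += 1
        pa = tmp_path / "a.tsv"
        pa.write_text("gene\tmissense\tsynonymous\tnonsense\n" + "".join(
            f"{g}\t{c[0]}\t{c[1]}\t{c[2]}\n" for g, c in agg.items()))
        pb = tmp_path / "b.tsv"
        pb.write_text("gene\tmutation_type\n" + "".join(
            f"{g}\t{t}\n" for g, t in rows))
        ta = parse_mutation_table(pa, "x")
        tb = parse_mutation_table(pb, "x")
        pd.testing.assert_frame_equal(
            ta.counts.sort_index(), tb.counts.sort_index()[ta.counts.columns])

    def test_unknown_mutation_type_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\tmutation_type\nTP53\tmissense\nKRAS\tframeshift\n")
        with pytest.raises(ValueError, match=r":3.*frameshift"):
            parse_mutation_table(p, "x")

    def test_malformed_count_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\tmissense\tsynonymous\tnonsense\nTP53\t1\tzero\t0\n")
        with pytest.raises(ValueError, match=":2"):
            parse_mutation_table(p, "x")


class TestBinarizeCombine:
    def test_threshold_at_one_count(self):
        t = make_table({"A": (0, 0, 0), "B": (1, 0, 0), "C": (17, 0, 0)})
        assert binarize(t, "missense").bits.tolist() == [False, True, True]

    def test_all_zero_table(self):
        t = make_table({"A": (0, 0, 0), "B": (0, 0, 0)})
        for mt in MUTATION_TYPES:
            assert not binarize(t, mt).bits.any()

    def test_binarize_matches_loop_oracle(self, rng):
        counts = {f"G{i}": tuple(int(x) for x in rng.integers(0, 4, 3))
                  for i in range(30)}
        t = make_table(counts)
        for k, mt in enumerate(MUTATION_TYPES):
            expected = [counts[g][k] >= 1 for g in t.genes]
            assert binarize(t, mt).bits.tolist() == expected

    @pytest.mark.parametrize("bits,expected", [
        ((1, 0, 0), False),
        ((1, 1, 0), True),
        ((0, 1, 1), True),
        ((1, 1, 1), True),
        ((0, 0, 0), False),
    ])
    def test_three_type_at_least_two_rule(self, bits, expected):
        t = make_table({"G": bits})
        assert combine(t, "three_at_least_2").bits[0] == expected

    def test_three_at_least_one_is_or_of_types(self, rng):
        counts = {f"G{i}": tuple(int(x) for x in rng.integers(0, 2, 3))
                  for i in range(25)}
        t = make_table(counts)
        ors = (binarize(t, "missense").bits | binarize(t, "synonymous").bits
               | binarize(t, "nonsense").bits)
        assert combine(t, "three_at_least_1").bits.tolist() == ors.tolist()

    def test_two_of_rule_is_or_of_the_pair(self):
        t = make_table({"A": (1, 0, 0), "B": (0, 5, 0), "C": (0, 0, 2)})
        got = combine(t, "two_of:missense,nonsense").bits.tolist()
        assert got == [True, False, True]

    def test_rules_are_monotone(self, rng):
        counts = {f"G{i}": tuple(int(x) for x in rng.integers(0, 2, 3))
                  for i in range(40)}
        t = make_table(counts)
        weak = combine(t, "three_at_least_1").bits
        strong = combine(t, "three_at_least_2").bits
        assert np.all(weak >= strong)

    def test_unknown_rule_rejected(self):
        t = make_table({"A": (1, 0, 0)})
        with pytest.raises(ValueError):
            combine(t, "four_of_three")


class TestProjection:
    def test_many_to_one_mapping(self):
        gs = BooleanSpectrum(["G1"], [True])
        gmap = GeneParameterMap(entries={"p1": ["G1"], "p2": ["G1"]})
        out = project_to_parameters(gs, gmap, ["p1", "p2"])
        assert out.bits.tolist() == [True, True]

    def test_excluded_parameters_dropped(self):
        gs = BooleanSpectrum(["G1"], [True])
        gmap = GeneParameterMap(entries={"p1": ["G1"]}, excluded={"p_prod"})
        out = project_to_parameters(gs, gmap, ["p1", "p_prod"])
        assert out.ids == ["p1"]

    def test_unmapped_parameter_is_an_error(self):
        gs = BooleanSpectrum(["G1"], [True])
        gmap = GeneParameterMap(entries={"p1": ["G1"]})
        with pytest.raises(ValueError, match="p2"):
            project_to_parameters(gs, gmap, ["p1", "p2"])

    def test_one_to_many_requires_flag_and_ors_bits(self):
        gs = BooleanSpectrum(["G1", "G2"], [False, True])
        gmap = GeneParameterMap(entries={"p1": ["G1", "G2"]})
        with pytest.raises(ValueError):
            project_to_parameters(gs, gmap, ["p1"])
        out = project_to_parameters(gs, gmap, ["p1"], allow_multi=True)
        assert out.bits.tolist() == [True]

    def test_bijective_map_preserves_bit_counts(self, rng):
        n = 20
        bits = rng.random(n) < 0.5
        gs = BooleanSpectrum([f"G{i}" for i in range(n)], bits)
        gmap = GeneParameterMap(entries={f"p{i}": [f"G{i}"] for i in range(n)})
        out = project_to_parameters(gs, gmap, [f"p{i}" for i in range(n)])
        assert out.bits.sum() == bits.sum()

    def test_composition_matches_lookup_oracle(self, rng):
        genes = [f"G{i}" for i in range(15)]
        bits = rng.random(15) < 0.4
        gs = BooleanSpectrum(genes, bits)
        params = [f"p{i}" for i in range(25)]
        assignment = {p: genes[int(rng.integers(15))] for p in params}
        gmap = GeneParameterMap(entries={p: [g] for p, g in assignment.items()})
        out = project_to_parameters(gs, gmap, params)
        expected = [bool(bits[genes.index(assignment[p])]) for p in params]
        assert out.bits.tolist() == expected


class TestHamming:
    def test_identity_and_complement(self):
        a = BooleanSpectrum([f"k{i}" for i in range(106)],
                            np.arange(106) % 2 == 0)
        b = BooleanSpectrum(a.ids, ~a.bits)
        assert hamming(a, a).hd == 0
        assert hamming(a, b).hd == 106
        assert hamming(a, b).n == 106

    def test_matches_loop_oracle_on_random_pairs(self, rng):
        for _ in range(500):
            n = int(rng.integers(1, 40))
            ids = [f"x{i}" for i in range(n)]
            a = BooleanSpectrum(ids, rng.random(n) < 0.5)
            b = BooleanSpectrum(ids, rng.random(n) < 0.5)
            expected = sum(int(x != y) for x, y in zip(a.bits, b.bits))
            got = hamming(a, b)
            assert got.hd == expected == len(got.mismatches)

    def test_id_mismatch_refused(self):
        a = BooleanSpectrum(["p1", "p2"], [True, False])
        b = BooleanSpectrum(["p2", "p1"], [False, True])
        with pytest.raises(SpectrumAlignmentError):
            hamming(a, b)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()),
                    min_size=1, max_size=30))
    def test_symmetry_and_triangle_inequality(self, triples):
        ids = [f"i{k}" for k in range(len(triples))]
        a = BooleanSpectrum(ids, [t[0] for t in triples])
        b = BooleanSpectrum(ids, [t[1] for t in triples])
        c = BooleanSpectrum(ids, [t[2] for t in triples])
        assert hamming(a, b).hd == hamming(b, a).hd
        assert hamming(a, c).hd <= hamming(a, b).hd + hamming(b, c).hd


class TestGeneMapIO:
    def test_round_trip(self, tmp_path):
        gmap = GeneParameterMap(entries={"p1": ["G1"], "p2": ["G1", "G2"]},
                                excluded={"p3"})
        path = tmp_path / "map.tsv"
        write_gene_parameter_map(gmap, path)
        back = read_gene_parameter_map(path)
        assert back.entries == gmap.entries
        assert back.excluded == gmap.excluded
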