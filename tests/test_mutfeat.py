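import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multisurv import mutfeat
from multisurv.formats import FeatureMatrix, GeneSetCollection
from multisurv.mutfeat import (
    MutationCatalogue,
    build_catalogues,
    classify_dbs78,
    classify_id83,
    classify_sbs96,
    dbs78_categories,
    fit_signatures,
    gene_mutation_matrix,
    geneset_aggregate,
    id83_categories,
    revcomp,
    sbs96_categories,
)
from tests.conftest import make_variant


class TestSchemes:
    def test_scheme_sizes_and_uniqueness(self):
        for cats, n in ((sbs96_categories(), 96), (dbs78_categories(), 78),
                        (id83_categories(), 83)):
            assert len(cats) == n
            assert len(set(cats)) == n


class TestSbs96:
    def test_pyrimidine_reference_kept_as_is(self):
        v = make_variant(ref="T", alt="C")
        assert classify_sbs96(v, "GTT") == "G[T>C]T"

    def test_purine_reference_reverse_complemented(self):
        v = make_variant(ref="A", alt="G")
        assert classify_sbs96(v, "CAT") == "A[T>C]G"

    def test_non_snv_not_applicable(self):
        v = make_variant(ref="AT", alt="A")
        assert classify_sbs96(v, "CAT") is None

    def test_ambiguous_context_unclassifiable(self):
        v = make_variant(ref="C", alt="T")
        assert classify_sbs96(v, "NCT") is None

    @settings(max_examples=200, deadline=None)
    @given(st.sampled_from("ACGT"), st.sampled_from("ACGT"), st.sampled_from("ACGT"),
           st.sampled_from("ACGT"))
    def test_strand_involution(self, ref, alt, five, three):
        """A variant and its reverse complement classify identically."""
        if ref == alt:
            return
        v = make_variant(ref=ref, alt=alt)
        w = make_variant(ref=revcomp(ref), alt=revcomp(alt))
        ctx = five + ref + three
        cat = classify_sbs96(v, ctx)
        assert cat == classify_sbs96(w, revcomp(ctx))
        assert cat in set(sbs96_categories())


class TestDbs78:
    def test_worked_example(self):
        assert classify_dbs78(make_variant(ref="AC", alt="GA")) == "AC>GA"

    def test_reverse_complement_maps_to_same_category(self):
        assert classify_dbs78(make_variant(ref="GT", alt="TC")) == "AC>GA"

    def test_exhaustive_canonicalization(self):
        """Brute force over all 16 x 9 true doublets: involution under revcomp,
        membership in the fixed scheme, and exactly 78 distinct categories."""
        cats = set()
        for ref in map("".join, itertools.product("ACGT", repeat=2)):
            for alt in map("".join, itertools.product("ACGT", repeat=2)):
                if alt[0] == ref[0] or alt[1] == ref[1]:
                    continue
                cat = classify_dbs78(make_variant(ref=ref, alt=alt))
                twin = classify_dbs78(make_variant(ref=revcomp(ref), alt=revcomp(alt)))
                assert cat == twin
                cats.add(cat)
        assert cats == set(dbs78_categories())

    def test_single_base_doublet_not_applicable(self):
        assert classify_dbs78(make_variant(ref="AC", alt="AT")) is None


def _oracle_id83(kind: str, seq: str, left: str, right: str) -> str:
    """Independent indel classifier working by literal string scanning."""
    def copies(flank, unit, from_right):
        c = 0
        s = flank
        while True:
            probe = s[:len(unit)] if from_right else s[-len(unit):]
            if len(s) >= len(unit) and probe == unit:
                c += 1
                s = s[len(unit):] if from_right else s[:-len(unit)]
            else:
                return c

    n_units = copies(right, seq, True) + copies(left, seq, False)
    if len(seq) == 1:
        base = seq if seq in "CT" else {"A": "T", "G": "C"}[seq]
        if kind == "Del":
            return f"1:Del:{base}:{min(1 + n_units, 6)}"
        return f"1:Ins:{base}:{min(n_units, 5)}"
    length = min(len(seq), 5)
    if kind == "Ins":
        return f"{length}:Ins:R:{min(n_units, 5)}"
    if n_units >= 1:
        return f"{length}:Del:R:{min(1 + n_units, 6)}"
    mh = 0
    for i in range(1, len(seq)):
        if right.startswith(seq[:i]):
            mh = max(mh, i)
        if left.endswith(seq[i:]):
            mh = max(mh, len(seq) - i)
    if mh:
        return f"{length}:Del:M:{min(mh, 5 if length >= 5 else length - 1)}"
    return f"{length}:Del:R:1"


class TestId83:
    def test_single_base_deletion_in_homopolymer(self):
        # delete one T out of TTTT: run of length 4 including the deleted base
        v = make_variant(ref="AT", alt="A")
        assert classify_id83(v, "GGGGGGA", "TTTGGGGGG") == "1:Del:T:4"

    def test_deletion_with_microhomology(self):
        # 4-bp deletion ACGT whose prefix AC reappears right of the breakpoint
        v = make_variant(ref="GACGT", alt="G")
        assert classify_id83(v, "CCCCCCG", "ACTTCCCCCCCCCCCCCCCCCCCC") == "4:Del:M:2"

    def test_substitution_not_applicable(self):
        assert classify_id83(make_variant(ref="A", alt="T"), "AAAA", "AAAA") is None

    def test_truncated_flank_raises(self):
        v = make_variant(ref="AT", alt="A")
        with pytest.raises(ValueError, match="flank"):
            classify_id83(v, "A", "TT")

    @settings(max_examples=300, deadline=None)
    @given(st.booleans(), st.text("ACGT", min_size=1, max_size=6),
           st.text("ACGT", min_size=40, max_size=60),
           st.text("ACGT", min_size=40, max_size=60))
    def test_matches_string_scanning_oracle(self, deletion, seq, left, right):
        kind = "Del" if deletion else "Ins"
        anchor = left[-1]
        if deletion:
            v = make_variant(ref=anchor + seq, alt=anchor)
        else:
            v = make_variant(ref=anchor, alt=anchor + seq)
        got = classify_id83(v, left, right)
        assert got == _oracle_id83(kind, seq, left, right)
        assert got in set(id83_categories())


class TestBuildCatalogues:
    def test_counts_conserved(self, tiny_genome):
        chrom = tiny_genome["chr1"]
        pos = next(i + 1 for i in range(1, len(chrom) - 1)
                   if chrom[i - 1:i + 2] == "ACG" or chrom[i - 1:i + 2] == "CGT")
        ctx = chrom[pos - 2:pos + 1]
        ref = ctx[1]
        alt = "T" if ref != "T" else "G"
        variants = [make_variant(ref=ref, alt=alt, pos=pos, chrom="chr1")] * 3
        cats = build_catalogues(variants, tiny_genome)
        sbs = cats["SBS96"].counts
        assert sbs.loc["S1"].sum() == 3
        assert sbs.loc["S1"].max() == 3  # all three in the same category
        assert cats["ID83"].counts.values.sum() == 0
        assert cats["DBS78"].counts.values.sum() == 0

    def test_zero_variant_sample_gets_zero_row(self, tiny_genome):
        cats = build_catalogues([], tiny_genome, samples=["S9"])
        assert cats["SBS96"].counts.loc["S9"].sum() == 0

    def test_signature_draws_recover_spectrum(self, tiny_genome):
        """Variants drawn from one signature give a catalogue proportional to it."""
        from multisurv.simulate import draw_signature_variants

        rng = np.random.default_rng(5)
        cats_ids = sbs96_categories()
        probs = rng.dirichlet(np.full(96, 0.3))
        sig = pd.Series(probs, index=cats_ids)
        variants = draw_signature_variants(tiny_genome, sig, 3000, "S1", rng)
        cat = build_catalogues(variants, tiny_genome)["SBS96"].counts.loc["S1"]
        assert cat.sum() == 3000
        observed = cat.to_numpy() / 3000
        cos = observed @ probs / (np.linalg.norm(observed) * np.linalg.norm(probs))
        assert cos > 0.98


class TestFitSignatures:
    @pytest.fixture
    def signatures(self):
        cats = sbs96_categories()
        s = pd.DataFrame(0.0, index=cats, columns=["sigA", "sigB"])
        s.iloc[:48, 0] = 1 / 48  # disjoint supports
        s.iloc[48:, 1] = 1 / 48
        return s

    def _catalogue(self, row):
        cats = sbs96_categories()
        return MutationCatalogue("SBS96", pd.DataFrame([row], index=["S1"], columns=cats))

    def test_exact_single_signature(self, signatures):
        row = 100 * signatures["sigA"].to_numpy()
        exp = fit_signatures(self._catalogue(row), signatures)
        assert exp.exposures.loc["S1", "sigA"] == pytest.approx(100)
        assert exp.exposures.loc["S1", "sigB"] == pytest.approx(0)
        assert exp.reconstruction_error["S1"] == pytest.approx(0, abs=1e-9)

    def test_two_signature_mixture_matches_grid_oracle(self, signatures):
        S = signatures.to_numpy()
        row = 60 * signatures["sigA"].to_numpy() + 40 * signatures["sigB"].to_numpy()
        # independent oracle: exhaustive grid over exposures
        grid = np.linspace(0, 100, 201)
        best, best_err = None, np.inf
        for a in grid:
            for b in grid:
                err = np.linalg.norm(row - S @ [a, b])
                if err < best_err:
                    best, best_err = (a, b), err
        exp = fit_signatures(self._catalogue(row), signatures)
        assert exp.exposures.loc["S1"].to_numpy() == pytest.approx(best, abs=0.5)
        assert exp.exposures.loc["S1"].to_numpy() == pytest.approx([60, 40], abs=1e-6)

    def test_zero_row_zero_exposures(self, signatures):
        exp = fit_signatures(self._catalogue(np.zeros(96)), signatures)
        assert (exp.exposures.loc["S1"] == 0).all()

    def test_category_mismatch_rejected(self, signatures):
        bad = signatures.iloc[::-1]
        with pytest.raises(ValueError, match="categories"):
            fit_signatures(self._catalogue(np.zeros(96)), bad)

    def test_nonnegative_cone_exact_reconstruction(self, signatures):
        """Any non-negative combination of the signatures is fit with zero error."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rng.uniform(0, 200, 2)
            row = a * signatures["sigA"].to_numpy() + b * signatures["sigB"].to_numpy()
            exp = fit_signatures(self._catalogue(row), signatures)
            assert exp.reconstruction_error["S1"] == pytest.approx(0, abs=1e-8)


class TestGeneMatrix:
    def test_protein_altering_rule(self, gene_models):
        variants = [
            make_variant(pos=60, gene="EGFR", classification="Missense_Mutation"),
            make_variant(pos=70, gene="EGFR", classification="Missense_Mutation"),
            make_variant(pos=210, gene="KRAS", classification="Silent"),
        ]
        m = gene_mutation_matrix(variants, gene_models, protein_altering_only=True)
        assert m.values.loc["S1", "EGFR"] == 1  # two hits still binarize to 1
        assert m.values.loc["S1", "KRAS"] == 0  # synonymous does not count
        m2 = gene_mutation_matrix(variants, gene_models, protein_altering_only=False)
        assert m2.values.loc["S1", "KRAS"] == 1

    def test_coordinate_fallback_when_gene_missing(self, gene_models):
        v = make_variant(pos=220, gene="", classification="Missense_Mutation")
        m = gene_mutation_matrix([v], gene_models)
        assert m.values.loc["S1", "KRAS"] == 1

    def test_empty_variant_list_all_zero(self, gene_models):
        m = gene_mutation_matrix([], gene_models, samples=["S1", "S2"])
        assert (m.values.to_numpy() == 0).all()


def _gene_matrix() -> FeatureMatrix:
    values = pd.DataFrame(
        [[0, 1, 0.5], [1, 1, -0.5]], index=["S1", "S2"],
        columns=["EGFR", "KRAS", "TP53"])
    return FeatureMatrix(values, omics="mutation", method="gene")


class TestGenesetAggregate:
    @pytest.fixture
    def gene_matrix(self):
        return _gene_matrix()

    def test_sum_counts_mutated_members(self, gene_matrix):
        out = geneset_aggregate(gene_matrix, {"RAS": ["EGFR", "KRAS"]}, mode="sum")
        assert out.values.loc["S1", "RAS"] == 1
        assert out.values.loc["S2", "RAS"] == 2

    def test_singleton_identity_both_modes(self, gene_matrix):
        for mode in ("sum", "mean"):
            out = geneset_aggregate(gene_matrix, {"ONE": ["TP53"]}, mode=mode)
            pd.testing.assert_series_equal(out.values["ONE"], gene_matrix.values["TP53"],
                                           check_names=False)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from(["EGFR", "KRAS", "TP53"]), min_size=1, max_size=3,
                    unique=True))
    def test_sum_matches_recomputation(self, members):
        gene_matrix = _gene_matrix()
        out = geneset_aggregate(gene_matrix, {"S": members}, mode="sum")
        expected = sum(gene_matrix.values[g] for g in members)
        assert np.allclose(out.values["S"], expected)

    def test_unresolvable_set_dropped(self, gene_matrix):
        out = geneset_aggregate(gene_matrix, {"GHOST": ["NOPE"], "OK": ["EGFR"]})
        assert out.feature_ids == ["OK"]
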