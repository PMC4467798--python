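import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acrskit.amplify import amplicon_allele_variants, simulate_pcr
from acrskit.design import (
    FIXTURE_CONSTRAINTS,
    AssayDesign,
    DesignConstraints,
    DesignInfeasibleError,
    SnpSpec,
    build_primers,
    compute_tm,
    design_assays,
    enumerate_site_placements,
    genotype_key,
    validate_design,
)
from acrskit.seqcore import DEFAULT_ENZYMES, NucSeq, digest_linear

ENZ = {e.name: e for e in DEFAULT_ENZYMES}


class TestSnpSpec:
    def test_valid(self):
        s = SnpSpec("rs1", 10, frozenset("CG"))
        assert s.alleles == frozenset("CG")

    @pytest.mark.parametrize("alleles", ["C", "CGA", "CX"])
    def test_bad_alleles(self, alleles):
        with pytest.raises(ValueError):
            SnpSpec("rs1", 10, frozenset(alleles))

    def test_bad_position(self):
        with pytest.raises(ValueError):
            SnpSpec("rs1", 0, frozenset("CG"))


class TestEnumerateSitePlacements:
    def test_haeiii_over_rs713598(self, template, snps):
        pls = enumerate_site_placements(template, snps["rs713598"], ENZ["HaeIII"])
        match = [p for p in pls if p.site_span == (143, 146)]
        assert len(match) == 1
        p = match[0]
        assert p.matching_allele == "C"
        assert p.required_substitutions == ((143, "A", "G"),)
        assert p.side == "forward-primer"
        assert p.snp_slot == 3

    def test_eco47iii_over_rs1726866(self, template, snps):
        pls = enumerate_site_placements(template, snps["rs1726866"], ENZ["Eco47III"])
        match = [p for p in pls if p.site_span == (781, 786)]
        assert len(match) == 1
        p = match[0]
        assert p.matching_allele == "C"
        assert p.required_substitutions == ((781, "T", "A"), (783, "T", "C"))
        assert p.side == "forward-primer"

    def test_rsai_over_rs10246939(self, template, snps):
        pls = enumerate_site_placements(template, snps["rs10246939"], ENZ["RsaI"])
        match = [p for p in pls if p.site_span == (886, 889)]
        assert len(match) == 1
        p = match[0]
        assert p.matching_allele == "G"
        assert p.required_substitutions == ((888, "C", "A"),)
        assert p.side == "reverse-primer"

    def test_both_side_substitutions_discarded(self):
        # GGCC over the SNP with required changes flanking it on both sides
        template = NucSeq("ATATTTTTCTTTTTATATAT")
        snp = SnpSpec("x", 9, frozenset("CG"))
        pls = enumerate_site_placements(template, snp, ENZ["HaeIII"])
        assert all(
            {("L" if pos < snp.position else "R") for pos, _, _ in p.required_substitutions} <= {"L"}
            or {("L" if pos < snp.position else "R") for pos, _, _ in p.required_substitutions} <= {"R"}
            for p in pls
        )
        assert (8, 11) not in [p.site_span for p in pls]

    def test_no_discriminating_placement_empty(self):
        # alleles A/T can never be told apart by GGCC (neither matches G or C)
        template = NucSeq("GGGGGGGGAGGGGGGGG")
        snp = SnpSpec("x", 9, frozenset("AT"))
        assert enumerate_site_placements(template, snp, ENZ["HaeIII"]) == []

    def test_exactly_one_allele_matches(self, template, snps):
        for enzyme in DEFAULT_ENZYMES:
            for p in enumerate_site_placements(template, snps["rs713598"], enzyme):
                code = p.pattern[p.snp_slot - 1]
                from acrskit.seqcore import IUPAC

                assert sum(a in IUPAC[code] for a in snps["rs713598"].alleles) == 1


# Allawi & SantaLucia (1997) unified NN parameters (kcal/mol, cal/mol/K).
_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_RC = str.maketrans("ACGT", "TGCA")


def _nn_tm_oracle(seq: str, na_mm: float = 50.0, dnac1_nm: float = 250.0) -> float:
    """Independent two-state NN summation with SantaLucia-98 entropy salt correction."""
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in _NN:
            pair = pair.translate(_RC)[::-1]
        h, s = _NN[pair]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        if terminal in "AT":
            dh += 2.3
            ds += 4.1
        else:
            dh += 0.1
            ds -= 2.8
    ds += 0.368 * (len(seq) - 1) * math.log(na_mm / 1000.0)
    k = dnac1_nm * 1e-9  # excess-primer model: C_T ~ primer concentration
    return 1000.0 * dh / (ds + 1.987 * math.log(k)) - 273.15


class TestComputeTm:
    def test_wallace_examples(self):
        assert compute_tm("ACGTACGT", "wallace") == 24.0
        assert compute_tm("AAAAAAAA", "wallace") == 16.0
        assert compute_tm("ACGTACGTACGT", "wallace") == 36.0

    def test_wallace_too_short(self):
        with pytest.raises(ValueError):
            compute_tm("ACGT", "wallace")

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            compute_tm("ACGTACGTACGT", "bogus")

    @pytest.mark.parametrize(
        "seq",
        ["AGCGTACGATCGATCGATCA", "ATGCCTTCGTTTTCTTGGTG", "GGGGCCCCAAAATTTTGCAT"],
    )
    def test_nearest_neighbor_matches_hand_summation(self, seq):
        assert compute_tm(seq, "nearest_neighbor") == pytest.approx(_nn_tm_oracle(seq), abs=0.1)


class TestBuildPrimers:
    def test_haeiii_forward_mutagenic(self, template, snps):
        pls = enumerate_site_placements(template, snps["rs713598"], ENZ["HaeIII"])
        p = next(x for x in pls if x.site_span == (143, 146))
        fwd, rev = build_primers(template, p, snps["rs713598"], FIXTURE_CONSTRAINTS)
        assert fwd.intended_span[1] == 144  # 3' end immediately before the SNP
        assert fwd.engineered_offsets == (2,)  # substitution at the second-last base
        assert rev.engineered_offsets == ()
        assert rev.intended_span[0] > snps["rs713598"].position

    def test_eco47iii_offsets_2_and_4(self, template, snps):
        pls = enumerate_site_placements(template, snps["rs1726866"], ENZ["Eco47III"])
        p = next(x for x in pls if x.site_span == (781, 786))
        fwd, _ = build_primers(template, p, snps["rs1726866"], FIXTURE_CONSTRAINTS)
        assert fwd.intended_span[1] == 784
        assert fwd.engineered_offsets == (2, 4)

    def test_rsai_reverse_mutagenic(self, template, snps):
        pls = enumerate_site_placements(template, snps["rs10246939"], ENZ["RsaI"])
        p = next(x for x in pls if x.site_span == (886, 889))
        fwd, rev = build_primers(template, p, snps["rs10246939"], FIXTURE_CONSTRAINTS)
        assert rev.intended_span[0] == 887  # footprint starts just past the SNP
        assert rev.engineered_offsets == (2,)
        assert fwd.engineered_offsets == ()

    def test_terminal_substitution_infeasible(self, template, snps):
        # RsaI over rs713598 at slot 1 needs a change at position 146 — the
        # base immediately flanking the SNP, i.e. 3'-offset 1 of the primer
        pls = enumerate_site_placements(template, snps["rs713598"], ENZ["RsaI"])
        p = next(x for x in pls if x.site_span == (145, 148))
        with pytest.raises(DesignInfeasibleError, match="1 nt from the 3' end"):
            build_primers(template, p, snps["rs713598"], FIXTURE_CONSTRAINTS)

    def test_primer_carries_substitutions(self, template, snps):
        pls = enumerate_site_placements(template, snps["rs713598"], ENZ["HaeIII"])
        p = next(x for x in pls if x.site_span == (143, 146))
        fwd, _ = build_primers(template, p, snps["rs713598"], FIXTURE_CONSTRAINTS)
        assert fwd.bases.bases[-2] == "G"  # the engineered base itself
        start, end = fwd.intended_span
        assert fwd.bases.bases[-2] != template.slice1(143, 143)


class TestValidateDesign:
    def test_reference_designs_pass(self, template, assays):
        for d in assays:
            diag = validate_design(template, d)
            assert diag.passed, diag.failures()

    def test_haeiii_fragments(self, assays_by_snp):
        assert assays_by_snp["rs713598"].predicted_fragments[genotype_key("C", "C")] == (47, 156)

    def test_rsai_fragments(self, assays_by_snp):
        assert assays_by_snp["rs10246939"].predicted_fragments[genotype_key("G", "G")] == (45, 149)

    def test_second_native_site_fails_clause_a(self, template, assays_by_snp):
        d = assays_by_snp["rs713598"]
        bases = list(template.bases)
        bases[199:203] = "GGCC"  # inject a second HaeIII site inside the amplicon
        mutated = NucSeq("".join(bases), name="mutated")
        diag = validate_design(mutated, d)
        assert not diag.passed
        clause = {cid: (ok, detail) for cid, ok, detail in diag.clauses}
        ok, detail = clause["cut_allele_single_site"]
        assert not ok
        assert "103" in detail and "46" in detail  # both site coordinates listed


class TestDesignAssays:
    def test_empty_catalog_rejected(self, template, snps):
        with pytest.raises(ValueError, match="empty"):
            design_assays(template, snps["rs713598"], [])

    def test_rediscovery_rs713598(self, template, snps):
        designs = design_assays(template, snps["rs713598"], list(DEFAULT_ENZYMES), FIXTURE_CONSTRAINTS)
        assert designs and designs[0].enzyme_name == "HaeIII"
        assert designs[0].n_engineered_mismatches == 1
        assert any(
            d.enzyme_name == "HaeIII"
            and d.placement.site_span == (143, 146)
            and d.fwd.engineered_offsets == (2,)
            for d in designs
        )

    def test_rediscovery_rs1726866(self, template, snps):
        designs = design_assays(template, snps["rs1726866"], list(DEFAULT_ENZYMES), FIXTURE_CONSTRAINTS)
        assert [d.enzyme_name for d in designs] == ["Eco47III"]
        assert designs[0].n_engineered_mismatches == 2
        assert designs[0].fwd.engineered_offsets == (2, 4)

    def test_rediscovery_rs10246939(self, template, snps):
        designs = design_assays(template, snps["rs10246939"], list(DEFAULT_ENZYMES), FIXTURE_CONSTRAINTS)
        assert [d.enzyme_name for d in designs] == ["RsaI"]
        assert designs[0].n_engineered_mismatches == 1
        assert designs[0].rev.engineered_offsets == (2,)

    def test_hopeless_snp_returns_empty(self):
        template = NucSeq("G" * 200 + "A" + "G" * 200)
        snp = SnpSpec("x", 201, frozenset("AT"))
        assert design_assays(template, snp, list(DEFAULT_ENZYMES), FIXTURE_CONSTRAINTS) == []

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_roundtrip_soundness_random_templates(self, seed):
        rng = random.Random(seed)
        bases = "".join(rng.choice("ACGT") for _ in range(420))
        template = NucSeq(bases)
        pos = 210
        ref = bases[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        snp = SnpSpec("rnd", pos, frozenset((ref, alt)))
        for d in design_assays(template, snp, list(DEFAULT_ENZYMES), FIXTURE_CONSTRAINTS):
            # re-derive fragments independently through amplify + seqcore
            amp = simulate_pcr(template, d.fwd, d.rev, max_mismatches=2)
            variants = amplicon_allele_variants(amp, snp)
            per_allele = {
                a: tuple(sorted(digest_linear(v, d.placement.enzyme).fragments))
                for a, v in variants.items()
            }
            a, b = sorted(snp.alleles)
            assert d.predicted_fragments[genotype_key(a, a)] == per_allele[a]
            assert d.predicted_fragments[genotype_key(b, b)] == per_allele[b]
            assert d.predicted_fragments[genotype_key(a, b)] == tuple(
                sorted(per_allele[a] + per_allele[b])
            )
            assert per_allele[a] != per_allele[b]  # allele discrimination, re-checked

    def test_heterozygote_is_union_of_homozygotes(self, assays):
        for d in assays:
            a, b = sorted(d.snp.alleles)
            assert d.predicted_fragments[genotype_key(a, b)] == tuple(
                sorted(d.predicted_fragments[genotype_key(a, a)] + d.predicted_fragments[genotype_key(b, b)])
            )

    @pytest.mark.parametrize("snp_id", ["rs713598", "rs1726866", "rs10246939"])
    def test_monotonicity(self, template, snps, snp_id):
        snp = snps[snp_id]
        base = design_assays(template, snp, list(DEFAULT_ENZYMES), FIXTURE_CONSTRAINTS)
        keyset = lambda ds: {(d.enzyme_name, d.placement.site_span, d.placement.required_substitutions) for d in ds}
        tighter_mm = design_assays(
            template, snp, list(DEFAULT_ENZYMES),
            DesignConstraints(**{**FIXTURE_CONSTRAINTS.__dict__, "max_engineered_mismatches": 1}),
        )
        tighter_frag = design_assays(
            template, snp, list(DEFAULT_ENZYMES),
            DesignConstraints(**{**FIXTURE_CONSTRAINTS.__dict__, "min_fragment": 60}),
        )
        assert keyset(tighter_mm) <= keyset(base)
        assert keyset(tighter_frag) <= keyset(base)
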