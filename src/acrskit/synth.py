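"""Fixture reconstruction and cohort simulation.

The reference assays pin short template spans (primer footprints with their
engineered bases reverted, the SNP-adjacent site bases); everything else is
seeded random filler, rejection-sampled so that no allele-state amplicon
gains an unplanned recognition site for any catalog enzyme.  The true gene
sequence is therefore never needed: every observable the assays produce
(product sizes, cut positions, fragment lengths) is fixed by the pins.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

from .amplify import Primer, amplicon_allele_variants, simulate_pcr
from .design import (
    AssayDesign,
    DesignConstraints,
    Placement,
    SnpSpec,
    _predict_fragments,
    compute_tm,
    genotype_key,
    validate_design,
)
from .genotyping import AVI, PAV, SNP_ORDER, Cohort, ObservedBands, Subject
from .seqcore import DEFAULT_ENZYMES, Enzyme, NucSeq, find_sites, revcomp

__all__ = [
    "TemplateSpec",
    "CohortSpec",
    "GenerationError",
    "FIXTURE_PRIMERS",
    "FIXTURE_SNPS",
    "default_template_spec",
    "build_reference_template",
    "reference_assays",
    "simulate_cohort",
]


class GenerationError(RuntimeError):
    pass


# The three shipped primer pairs (5'->3' as synthesized), their template
# footprints, and the 3'-anchored offsets of their engineered mismatches.
FIXTURE_PRIMERS: dict[str, Primer] = {
    "1Fmut": Primer(
        NucSeq("ATGCCTTCGTTTTCTTGGTGAATTTTTGGGATGTAGTGAAGAGGCGG", name="1Fmut"),
        "forward",
        intended_span=(98, 144),
        engineered_offsets=(2,),
    ),
    "1R": Primer(
        NucSeq("CATCCATAGCATGATGATGGCTTGGTA", name="1R"),
        "reverse",
        intended_span=(274, 300),
    ),
    "2Fmut": Primer(
        NucSeq("AAGTCTCTTGTCTCCTTTTTCTGCTTCTTTGTGATATCATCCAGCG", name="2Fmut"),
        "forward",
        intended_span=(739, 784),
        engineered_offsets=(2, 4),
    ),
    "2Rmut": Primer(
        NucSeq("ATGGTCATCACAGCTCTCCTCAACTTGGCATTGCCTGAGATCAGTA", name="2Rmut"),
        "reverse",
        intended_span=(887, 932),
        engineered_offsets=(2,),
    ),
}

FIXTURE_SNPS: tuple[SnpSpec, ...] = (
    SnpSpec("rs713598", 145, frozenset("CG"), cut_allele="C"),
    SnpSpec("rs1726866", 785, frozenset("CT"), cut_allele="C"),
    SnpSpec("rs10246939", 886, frozenset("GA"), cut_allele="G"),
)

# reference allele written into the generated template at each SNP
_REF_ALLELE = {"rs713598": "C", "rs1726866": "C", "rs10246939": "G"}


@dataclass(frozen=True)
class DesignedSite:
    enzyme_name: str
    site_span: tuple[int, int]  # template coordinates
    snp_id: str
    cut_allele: str


@dataclass(frozen=True)
class AmpliconConstraint:
    span: tuple[int, int]
    product_overrides: tuple[tuple[int, str], ...]  # primer-encoded bases (template pos, base)
    snp_ids: tuple[str, ...]
    designed_sites: tuple[DesignedSite, ...]


@dataclass(frozen=True)
class TemplateSpec:
    length: int = 1000
    constrained_regions: tuple[tuple[int, str, str], ...] = ()  # (start, sequence, label)
    snps: tuple[SnpSpec, ...] = FIXTURE_SNPS
    amplicons: tuple[AmpliconConstraint, ...] = ()
    forbidden_motifs: tuple[Enzyme, ...] = DEFAULT_ENZYMES
    rng_seed: int = 17


def _primer_top(primer: Primer) -> str:
    return primer.bases.bases if primer.orientation == "forward" else revcomp(primer.bases).bases


def _engineered_template_positions(primer: Primer) -> list[int]:
    """Template positions of a fixture primer's engineered bases."""
    start, end = primer.intended_span
    out = []
    for off in primer.engineered_offsets:
        if primer.orientation == "forward":
            out.append(end - off + 1)
        else:
            out.append(start + off - 1)
    return out


def default_template_spec(seed: int = 17, length: int = 1000) -> TemplateSpec:
    """The shipped fixture: pins derived from the four printed primers.

    Footprint spans carry the primer sequence with engineered bases reverted
    to the original template base; the site-completing bases flanking each
    SNP are pinned explicitly.
    """
    reverted = {"1Fmut": {143: "A"}, "1R": {}, "2Fmut": {781: "T", 783: "T"}, "2Rmut": {888: "C"}}
    pins: list[tuple[int, str, str]] = []
    for name, primer in FIXTURE_PRIMERS.items():
        start, end = primer.intended_span
        seq = list(_primer_top(primer))
        for pos, base in reverted[name].items():
            seq[pos - start] = base
        pins.append((start, "".join(seq), name))
    pins.append((146, "C", "HaeIII-site-3'-flank"))
    pins.append((786, "T", "Eco47III-site-3'-flank"))
    overrides1 = tuple((p, _primer_top(FIXTURE_PRIMERS["1Fmut"])[p - 98]) for p in [143])
    overrides2 = tuple(
        (p, _primer_top(FIXTURE_PRIMERS["2Fmut"])[p - 739]) for p in [781, 783]
    ) + tuple((p, _primer_top(FIXTURE_PRIMERS["2Rmut"])[p - 887]) for p in [888])
    amplicons = (
        AmpliconConstraint(
            span=(98, 300),
            product_overrides=overrides1,
            snp_ids=("rs713598",),
            designed_sites=(DesignedSite("HaeIII", (143, 146), "rs713598", "C"),),
        ),
        AmpliconConstraint(
            span=(739, 932),
            product_overrides=overrides2,
            snp_ids=("rs1726866", "rs10246939"),
            designed_sites=(
                DesignedSite("Eco47III", (781, 786), "rs1726866", "C"),
                DesignedSite("RsaI", (886, 889), "rs10246939", "G"),
            ),
        ),
    )
    return TemplateSpec(
        length=length,
        constrained_regions=tuple(pins),
        snps=FIXTURE_SNPS,
        amplicons=amplicons,
        forbidden_motifs=DEFAULT_ENZYMES,
        rng_seed=seed,
    )


def _allele_states(snps: list[SnpSpec]):
    states = [{}]
    for snp in snps:
        states = [dict(s, **{snp.id: a}) for s in states for a in sorted(snp.alleles)]
    return states


def _check_amplicon(template: list[str], spec: TemplateSpec, amp: AmpliconConstraint):
    """Windows (template coordinate sets) of unplanned or missing sites."""
    start, end = amp.span
    snps = {s.id: s for s in spec.snps}
    violations: list[set[int]] = []
    for state in _allele_states([snps[i] for i in amp.snp_ids]):
        product = template[start - 1 : end]
        for pos, base in amp.product_overrides:
            product[pos - start] = base
        for sid, allele in state.items():
            product[snps[sid].position - start] = allele
        seq = NucSeq("".join(product))
        for enzyme in spec.forbidden_motifs:
            expected = {
                d.site_span[0] - start + 1
                for d in amp.designed_sites
                if d.enzyme_name == enzyme.name and state.get(d.snp_id) == d.cut_allele
            }
            hits = {h.start for h in find_sites(seq, enzyme)}
            for h in hits - expected:
                violations.append(set(range(start + h - 1, start + h - 1 + len(enzyme.site))))
            for miss in expected - hits:
                violations.append(set(range(start + miss - 1, start + miss - 1 + len(enzyme.site))))
    return violations


def build_reference_template(spec: TemplateSpec | None = None) -> NucSeq:
    """A template satisfying every pin, with motif-free rejection-sampled filler.

    Deterministic for a fixed spec (seed included).  Raises
    :class:`GenerationError` when pinned spans conflict or when a forbidden
    motif is forced entirely by pinned/SNP bases (naming the positions).
    """
    if spec is None:
        spec = default_template_spec()
    arr: list[str | None] = [None] * spec.length
    owner: list[str | None] = [None] * spec.length
    for start, seq, label in spec.constrained_regions:
        if start < 1 or start + len(seq) - 1 > spec.length:
            raise GenerationError(f"pinned span {label!r} ({start}..{start + len(seq) - 1}) outside template")
        for i, base in enumerate(seq.upper()):
            idx = start - 1 + i
            if arr[idx] is not None and arr[idx] != base:
                raise GenerationError(
                    f"pinned spans conflict at position {idx + 1}: {owner[idx]!r} wants "
                    f"{arr[idx]} but {label!r} wants {base}"
                )
            arr[idx] = base
            owner[idx] = label
    for snp in spec.snps:
        ref = _REF_ALLELE.get(snp.id, sorted(snp.alleles)[0])
        idx = snp.position - 1
        if arr[idx] is not None and arr[idx] != ref:
            raise GenerationError(
                f"SNP {snp.id} reference allele {ref} conflicts with pin {owner[idx]!r} at {snp.position}"
            )
        arr[idx] = ref
        owner[idx] = snp.id
    rng = random.Random(spec.rng_seed)
    filler = [i for i, b in enumerate(arr) if b is None]
    for i in filler:
        arr[i] = rng.choice("ACGT")
    filler_set = set(i + 1 for i in filler)  # 1-based
    for _ in range(2000):
        violations: list[set[int]] = []
        for amp in spec.amplicons:
            violations.extend(_check_amplicon(arr, spec, amp))
        if not violations:
            break
        resampled = False
        for window in violations:
            free = sorted(window & filler_set)
            if not free:
                raise GenerationError(
                    f"forbidden or missing motif forced by pinned bases at positions {sorted(window)}"
                )
            for pos in free:
                arr[pos - 1] = rng.choice("ACGT")
                resampled = True
        assert resampled
    else:
        raise GenerationError("rejection sampling did not converge after 2000 rounds")
    return NucSeq("".join(arr), name="TAS2R38_synthetic")


def reference_assays(template: NucSeq) -> tuple[AssayDesign, AssayDesign, AssayDesign]:
    """The three shipped assays instantiated on a template, fragments re-derived
    by full PCR + digest simulation (never hard-coded)."""
    enzymes = {e.name: e for e in DEFAULT_ENZYMES}
    specs = [
        # snp, enzyme, site_span, slot, subs (template pos, old, new), side, fwd, rev
        (FIXTURE_SNPS[0], "HaeIII", (143, 146), 3, ((143, "A", "G"),), "forward-primer", "1Fmut", "1R"),
        (FIXTURE_SNPS[1], "Eco47III", (781, 786), 5, ((781, "T", "A"), (783, "T", "C")), "forward-primer", "2Fmut", "2Rmut"),
        (FIXTURE_SNPS[2], "RsaI", (886, 889), 1, ((888, "C", "A"),), "reverse-primer", "2Fmut", "2Rmut"),
    ]
    out = []
    for snp, ename, span, slot, subs, side, fname, rname in specs:
        enzyme = enzymes[ename]
        placement = Placement(
            enzyme=enzyme,
            site_span=span,
            snp_slot=slot,
            matching_allele=snp.cut_allele,
            required_substitutions=subs,
            side=side,
            pattern=enzyme.site,
        )
        fwd, rev = FIXTURE_PRIMERS[fname], FIXTURE_PRIMERS[rname]
        candidate = AssayDesign(
            snp=snp,
            placement=placement,
            fwd=fwd,
            rev=rev,
            amplicon_length=0,
            predicted_fragments={},
            tm_fwd=compute_tm(fwd, method="nearest_neighbor"),
            tm_rev=compute_tm(rev, method="nearest_neighbor"),
            n_engineered_mismatches=len(subs),
            enzyme_name=ename,
        )
        fragments, amp = _predict_fragments(template, candidate)
        diag = validate_design(template, candidate)
        out.append(
            replace(candidate, amplicon_length=len(amp), predicted_fragments=fragments, diagnostics=diag)
        )
    return tuple(out)


@dataclass(frozen=True)
class CohortSpec:
    n: int = 60
    ratio: tuple[int, int, int] | None = (20, 20, 20)  # super : medium : non
    pav_freq: float | None = None
    ca6_model: dict | None = None  # class -> CA6 A-allele frequency
    noise_sd: float = 0.0
    dropout: float = 0.0
    detect_floor: int = 40
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if (self.ratio is None) == (self.pav_freq is None):
            raise ValueError("specify exactly one of ratio or pav_freq")
        if self.pav_freq is not None and not (0.0 <= self.pav_freq <= 1.0):
            raise ValueError("pav_freq must lie in [0, 1]")


_CLASS_DIPLOTYPE = {"super": (PAV, PAV), "medium": (PAV, AVI), "non": (AVI, AVI)}


def simulate_cohort(spec: CohortSpec, designs) -> tuple[Cohort, list[ObservedBands]]:
    """Draw a cohort and render each subject's band patterns through the assays.

    Ratio mode assigns deterministic class counts; frequency mode samples two
    haplotypes per subject (Hardy-Weinberg).  Band noise: integer Gaussian
    jitter on every fragment plus Bernoulli dropout of sub-floor fragments.
    """
    rng = random.Random(spec.rng_seed)
    by_snp = {d.snp.id: d for d in designs}
    missing = [s for s in SNP_ORDER if s not in by_snp]
    if missing:
        raise ValueError(f"designs must cover all three sites; missing {missing}")
    diplotypes: list[tuple[tuple, tuple]] = []
    if spec.ratio is not None:
        total = sum(spec.ratio)
        if total <= 0 or any(r < 0 for r in spec.ratio):
            raise ValueError(f"invalid ratio {spec.ratio}")
        if (spec.n * spec.ratio[0]) % total or (spec.n * spec.ratio[1]) % total or (spec.n * spec.ratio[2]) % total:
            raise ValueError(f"n={spec.n} not divisible by ratio {spec.ratio}")
        for cls, r in zip(("super", "medium", "non"), spec.ratio):
            diplotypes.extend([_CLASS_DIPLOTYPE[cls]] * (spec.n * r // total))
    else:
        for _ in range(spec.n):
            h1 = PAV if rng.random() < spec.pav_freq else AVI
            h2 = PAV if rng.random() < spec.pav_freq else AVI
            diplotypes.append(tuple(sorted((h1, h2), reverse=True)))
    subjects: list[Subject] = []
    bands: list[ObservedBands] = []
    for i, (h1, h2) in enumerate(diplotypes, start=1):
        sid = f"S{i:04d}"
        genotypes = {
            snp_id: genotype_key(h1[k], h2[k]) for k, snp_id in enumerate(SNP_ORDER)
        }
        n_pav = (h1 == PAV) + (h2 == PAV)
        cls = ("non", "medium", "super")[n_pav]
        ca6 = None
        if spec.ca6_model is not None:
            fa = spec.ca6_model.get(cls, 0.5)
            alleles = sorted("A" if rng.random() < fa else "G" for _ in range(2))
            ca6 = "".join(alleles)
        subjects.append(Subject(sid, genotypes, ca6=ca6, phenotype=cls))
        for snp_id in SNP_ORDER:
            design = by_snp[snp_id]
            pattern = design.predicted_fragments[genotypes[snp_id]]
            observed = []
            for frag in pattern:
                if frag < spec.detect_floor and rng.random() < spec.dropout:
                    continue
                size = frag + (round(rng.gauss(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0)
                observed.append(max(1, size))
            bands.append(
                ObservedBands(sid, design.enzyme_name, tuple(observed), includes_uncut_lane=True)
            )
    return Cohort(tuple(subjects)), bands
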