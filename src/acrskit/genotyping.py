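"""From band patterns to genotypes, diplotypes, taster classes, and exact tests.

The diplotype model is deliberately two-haplotype: C145/C785/G886 composes
the taster haplotype (PAV) and G145/T785/A886 the non-taster haplotype
(AVI).  Genotype triples that force a third haplotype are flagged, never
coerced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import product

__all__ = [
    "ObservedBands",
    "GenotypeCall",
    "DiplotypeCall",
    "Subject",
    "Cohort",
    "PAV",
    "AVI",
    "SNP_ORDER",
    "haplotype_name",
    "call_snp_genotype",
    "call_diplotype",
    "classify_taster",
    "allele_frequencies",
    "fisher_exact_2x2",
    "hwe_exact",
]

SNP_ORDER = ("rs713598", "rs1726866", "rs10246939")
PAV = ("C", "C", "G")
AVI = ("G", "T", "A")

# allele -> amino-acid letter at each of the three sites
_RESIDUE = (
    {"C": "P", "G": "A"},
    {"C": "A", "T": "V"},
    {"G": "V", "A": "I"},
)


def haplotype_name(hap: tuple[str, str, str]) -> str:
    """Residue-triple label for an allele triple, e.g. ('C','C','G') -> 'PAV'."""
    letters = []
    for table, allele in zip(_RESIDUE, hap):
        letters.append(table.get(allele, "?"))
    return "".join(letters)


@dataclass(frozen=True)
class ObservedBands:
    sample_id: str
    enzyme: str
    fragments: tuple[int, ...]
    includes_uncut_lane: bool = False

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fragments):
            raise ValueError(f"{self.sample_id}: fragment sizes must be positive")
        object.__setattr__(self, "fragments", tuple(self.fragments))


@dataclass(frozen=True)
class GenotypeCall:
    snp_id: str
    genotype: str | None  # canonical "X/Y", or None for no-call
    evidence: str = ""
    confidence: str = "no-call"  # exact | tolerant | no-call
    candidates: tuple[str, ...] = ()

    @property
    def is_call(self) -> bool:
        return self.genotype is not None


@dataclass(frozen=True)
class DiplotypeCall:
    haplotypes: tuple[str, str] | None  # e.g. ("PAV", "AVI"), sorted; None if undetermined
    canonical: bool
    taster_class: str  # super | medium | non-taster | undetermined
    implied_haplotypes: tuple[str, ...] = ()

    @property
    def label(self) -> str:
        if self.haplotypes is None:
            return "undetermined"
        return "/".join(self.haplotypes)


@dataclass(frozen=True)
class Subject:
    sample_id: str
    genotypes: dict  # snp id -> "X/Y"
    ca6: str | None = None  # "AA" | "AG" | "GG"
    phenotype: str | None = None  # super | medium | non


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[Subject, ...]

    def __len__(self) -> int:
        return len(self.subjects)


def _match_multiset(observed, expected, tol: int) -> bool:
    if len(observed) != len(expected):
        return False
    return all(abs(o - e) <= tol for o, e in zip(sorted(observed), sorted(expected)))


def call_snp_genotype(
    design,
    bands: ObservedBands,
    size_tolerance_bp: int = 5,
    detect_floor: int = 40,
) -> GenotypeCall:
    """Match an observed fragment multiset against the assay's three patterns.

    Exact matching first.  When nothing matches and an uncut lane corroborates
    the product size, patterns are retried with sub-floor fragments removed
    (small fragments run off or are eluted; the 47/45 bp fragments of the
    reference assays sit at the gel's detection limit) and a successful match
    is reported with confidence "tolerant".  Ties and failures are no-calls
    carrying the candidate set.
    """
    if size_tolerance_bp < 0:
        raise ValueError("tolerance must be >= 0")
    if bands.enzyme != design.enzyme_name:
        return GenotypeCall(design.snp.id, None, evidence=f"enzyme mismatch: {bands.enzyme} vs {design.enzyme_name}")
    patterns = design.predicted_fragments
    exact = [g for g, p in patterns.items() if _match_multiset(bands.fragments, p, size_tolerance_bp)]
    if len(exact) == 1:
        return GenotypeCall(design.snp.id, exact[0], evidence=f"matched {patterns[exact[0]]}", confidence="exact")
    if len(exact) > 1:
        return GenotypeCall(design.snp.id, None, evidence="ambiguous exact match", candidates=tuple(sorted(exact)))
    if bands.includes_uncut_lane:
        tolerant = []
        for g, p in patterns.items():
            reduced = tuple(f for f in p if f >= detect_floor)
            if reduced != tuple(p) and _match_multiset(bands.fragments, reduced, size_tolerance_bp):
                tolerant.append(g)
        if len(tolerant) == 1:
            g = tolerant[0]
            return GenotypeCall(
                design.snp.id,
                g,
                evidence=f"matched {patterns[g]} minus sub-{detect_floor}bp fragment(s)",
                confidence="tolerant",
            )
        if len(tolerant) > 1:
            return GenotypeCall(design.snp.id, None, evidence="ambiguous tolerant match", candidates=tuple(sorted(tolerant)))
    return GenotypeCall(
        design.snp.id,
        None,
        evidence=f"no pattern within ±{size_tolerance_bp} bp of {sorted(bands.fragments)}",
        candidates=tuple(sorted(patterns)),
    )


def call_diplotype(g145: GenotypeCall, g785: GenotypeCall, g886: GenotypeCall) -> DiplotypeCall:
    """Phase three genotype calls under the two-haplotype (PAV/AVI) model.

    Any phasing resolving to haplotypes drawn from {PAV, AVI} is canonical
    and unique; otherwise the call is flagged non-canonical with the
    minimal implied haplotype set (phasings needing the fewest novel
    haplotypes).
    """
    calls = (g145, g785, g886)
    if any(not c.is_call for c in calls):
        return DiplotypeCall(None, False, "undetermined")
    site_pairs = [tuple(c.genotype.split("/")) for c in calls]
    pairs: set[tuple[tuple, tuple]] = set()
    for assignment in product((0, 1), repeat=3):
        h1 = tuple(site_pairs[i][assignment[i]] for i in range(3))
        h2 = tuple(site_pairs[i][1 - assignment[i]] for i in range(3))
        pairs.add(tuple(sorted((h1, h2))))
    canonical_set = {PAV, AVI}
    canonical_pairs = [p for p in pairs if set(p) <= canonical_set]
    if canonical_pairs:
        h1, h2 = canonical_pairs[0]
        names = tuple(sorted((haplotype_name(h1), haplotype_name(h2)), reverse=True))  # PAV before AVI
        return DiplotypeCall(names, True, _base_class(names))
    best = min(pairs, key=lambda p: (sum(h not in canonical_set for h in p), p))
    min_novel = sum(h not in canonical_set for h in best)
    implied = sorted(
        {haplotype_name(h) for p in pairs for h in p
         if sum(x not in canonical_set for x in p) == min_novel}
    )
    names = tuple(sorted((haplotype_name(best[0]), haplotype_name(best[1])), reverse=True))
    return DiplotypeCall(names, False, "undetermined", implied_haplotypes=tuple(implied))


def _base_class(names: tuple[str, str]) -> str:
    key = "/".join(sorted(names, reverse=True))
    return {"PAV/PAV": "super", "PAV/AVI": "medium", "AVI/AVI": "non-taster"}[key]


def classify_taster(diplotype: DiplotypeCall, ca6_genotype: str | None = None) -> tuple[str, str]:
    """(taster_class, annotation).  The CA6 co-genotype annotates, never overrides."""
    if not diplotype.canonical or diplotype.haplotypes is None:
        return "undetermined", "non-canonical or missing diplotype"
    cls = _base_class(diplotype.haplotypes)
    annotation = ""
    if ca6_genotype is not None:
        if ca6_genotype not in ("AA", "AG", "GG"):
            raise ValueError(f"invalid CA6 genotype {ca6_genotype!r}")
        if cls == "medium" and "A" in ca6_genotype:
            annotation = "super-compatible (PAV + CA6 A-allele)"
    return cls, annotation


def allele_frequencies(cohort: Cohort, locus: str) -> tuple[dict, dict]:
    """(allele frequency map, genotype count map) at one locus.

    ``locus`` is a SNP id present in the subjects' genotype maps, or "ca6".
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    geno_counts: dict[str, int] = {}
    allele_counts: dict[str, int] = {}
    n_called = 0
    for s in cohort.subjects:
        g = s.ca6 if locus == "ca6" else s.genotypes.get(locus)
        if g is None:
            continue
        alleles = tuple(g.split("/")) if "/" in g else tuple(g)
        key = "/".join(sorted(alleles))
        geno_counts[key] = geno_counts.get(key, 0) + 1
        for a in alleles:
            allele_counts[a] = allele_counts.get(a, 0) + 1
        n_called += 1
    if n_called == 0:
        raise ValueError(f"no subject carries a call at locus {locus!r}")
    total = sum(allele_counts.values())
    freqs = {a: c / total for a, c in sorted(allele_counts.items())}
    return freqs, geno_counts


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums hypergeometric probabilities of all tables (at fixed margins) whose
    probability does not exceed the observed table's.  Exact rational
    arithmetic: the comparison is between integer numerators over a common
    denominator, so there are no floating-point tie artifacts.
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("negative counts")
    n = sum(cells)
    if n < 1:
        raise ValueError("table total must be >= 1")
    r1, r2, c1 = a + b, c + d, a + c
    obs = math.comb(r1, a) * math.comb(r2, c)
    num = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        term = math.comb(r1, x) * math.comb(r2, c1 - x)
        if term <= obs:
            num += term
    return float(Fraction(num, math.comb(n, c1)))


def hwe_exact(genotype_counts: tuple[int, int, int]) -> float:
    """Exact Hardy-Weinberg test conditional on the observed allele counts.

    The conditional distribution over heterozygote counts (same parity as
    the minor-allele count) is built by an exact rational recurrence
    w(k+2)/w(k) = 4·nAA·nBB / ((k+1)(k+2)); the p-value sums configurations
    no more probable than the observed one.
    """
    n_aa, n_ab, n_bb = genotype_counts
    if min(genotype_counts) < 0:
        raise ValueError("negative counts")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("total must be >= 1")
    n_a = 2 * n_aa + n_ab
    k_max = min(n_a, 2 * n - n_a)
    weights: dict[int, Fraction] = {}
    k = n_a % 2
    aa = (n_a - k) // 2
    bb = n - aa - k
    w = Fraction(1)
    while k <= k_max:
        weights[k] = w
        if k + 2 > k_max:
            break
        w = w * Fraction(4 * aa * bb, (k + 1) * (k + 2))
        k += 2
        aa -= 1
        bb -= 1
    total = sum(weights.values())
    obs = weights[n_ab]
    p = sum(v for v in weights.values() if v <= obs) / total
    return float(p)
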