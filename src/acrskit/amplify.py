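"""In-silico PCR with mismatch-tolerant, 3'-anchored primer binding.

The amplicon inherits every primer-encoded substitution — the mechanism that
creates an artificial restriction site in every cycle's product.  The binding
model is deliberately simple: end-to-end alignment, no indels, a bounded
mismatch count, a matching 3'-terminal base, and a configurable run of
perfect 3' matches in which engineered positions are exempt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqcore import NucSeq, revcomp

__all__ = [
    "Primer",
    "BindingSite",
    "Amplicon",
    "AmplificationError",
    "NoAmplificationError",
    "AmbiguousAmplificationError",
    "DesignViolationError",
    "find_primer_binding",
    "simulate_pcr",
    "amplicon_allele_variants",
]


class AmplificationError(RuntimeError):
    pass


class NoAmplificationError(AmplificationError):
    pass


class AmbiguousAmplificationError(AmplificationError):
    def __init__(self, msg: str, candidates: list[tuple[int, int]]):
        super().__init__(msg)
        self.candidates = candidates


class DesignViolationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Primer:
    """A synthesized oligo, written 5'→3'.

    ``engineered_offsets`` lists 3'-anchored offsets (1 = terminal base) of
    deliberate template mismatches; they are exempt from the 3' perfect-run
    requirement during binding-site search.
    """

    bases: NucSeq
    orientation: str  # "forward" | "reverse"
    intended_span: tuple[int, int] | None = None
    engineered_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if not (15 <= len(self.bases) <= 60):
            raise ValueError(f"primer length {len(self.bases)} outside 15..60")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class BindingSite:
    """One extendable placement of a primer on the template top strand."""

    span: tuple[int, int]
    mismatches: tuple[tuple[int, str, str], ...]  # (template_pos, template_base, primer_base)
    three_prime_terminal_match: bool


@dataclass(frozen=True)
class Amplicon:
    """An in-silico PCR product mapped back to template coordinates."""

    bases: NucSeq
    template_span: tuple[int, int]
    substitutions: tuple[tuple[int, str, str], ...]  # (amplicon_pos, template_base, product_base)
    snp_offsets: dict = field(default_factory=dict)  # snp id -> 1-based amplicon position
    primer_footprints: tuple[tuple[int, int], ...] = ()  # template coords, (fwd, rev)

    def __len__(self) -> int:
        return len(self.bases)

    def to_template_pos(self, amplicon_pos: int) -> int:
        return self.template_span[0] + amplicon_pos - 1

    def to_amplicon_pos(self, template_pos: int) -> int:
        return template_pos - self.template_span[0] + 1


def _aligned_primer_top(primer: Primer) -> str:
    """Primer bases expressed on the template top strand, 5'→3' of the template."""
    if primer.orientation == "forward":
        return primer.bases.bases
    return revcomp(primer.bases).bases


def _offsets_top(primer: Primer) -> dict[int, bool]:
    """Map 0-based index within the top-strand footprint -> is engineered."""
    n = len(primer)
    eng = set(primer.engineered_offsets)
    out = {}
    for i in range(n):
        # primer position (5'->3') for top-strand index i
        p = i + 1 if primer.orientation == "forward" else n - i
        out[i] = (n - p + 1) in eng  # 3'-anchored offset
    return out


def find_primer_binding(
    template: NucSeq,
    primer: Primer,
    max_mismatches: int = 2,
    min_3prime_perfect: int = 1,
) -> list[BindingSite]:
    """All template loci where the primer can anneal and extend.

    A locus qualifies when the end-to-end alignment has at most
    ``max_mismatches`` mismatches, the 3'-terminal base matches, and at least
    ``min_3prime_perfect`` consecutive 3' bases match, ignoring engineered
    positions when counting the run.  Results are sorted by position.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    n, m = len(template), len(primer)
    if m > n:
        raise ValueError(f"primer ({m} nt) longer than template ({n} nt)")
    top = _aligned_primer_top(primer)
    engineered = _offsets_top(primer)
    sites: list[BindingSite] = []
    for start0 in range(n - m + 1):
        window = template.bases[start0 : start0 + m]
        mism = [
            (start0 + i + 1, window[i], top[i])
            for i in range(m)
            if window[i] != top[i]
        ]
        if len(mism) > max_mismatches:
            continue
        mismatch_idx = {p - start0 - 1 for p, _, _ in mism}
        # indices in top-strand footprint order nearest the 3' end
        idx_3to5 = range(m - 1, -1, -1) if primer.orientation == "forward" else range(m)
        terminal_idx = m - 1 if primer.orientation == "forward" else 0
        if terminal_idx in mismatch_idx:
            continue
        run = 0
        for i in idx_3to5:
            if i in mismatch_idx:
                if engineered[i]:
                    continue  # engineered position: exempt, run not broken
                break
            run += 1
        if run < min_3prime_perfect:
            continue
        sites.append(
            BindingSite(
                span=(start0 + 1, start0 + m),
                mismatches=tuple(mism),
                three_prime_terminal_match=True,
            )
        )
    return sites


def simulate_pcr(
    template: NucSeq,
    fwd: Primer,
    rev: Primer,
    max_mismatches: int = 2,
    min_3prime_perfect: int = 1,
    size_bounds: tuple[int, int] = (50, 5000),
    snps=(),
) -> Amplicon:
    """Amplify: one forward site, one reverse site, converging, size in bounds.

    The amplicon equals the template span with each primer footprint
    overwritten by the primer's own bases; substitutions (engineered or
    accidental) are recorded in amplicon coordinates.  ``snps`` is an
    iterable of objects with ``id`` and ``position`` whose amplicon offsets
    are recorded when they fall inside the span.
    """
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise ValueError("simulate_pcr needs one forward and one reverse primer")
    fsites = find_primer_binding(template, fwd, max_mismatches, min_3prime_perfect)
    rsites = find_primer_binding(template, rev, max_mismatches, min_3prime_perfect)
    lo, hi = size_bounds
    products = [
        (f, r)
        for f in fsites
        for r in rsites
        if f.span[1] < r.span[0] and lo <= r.span[1] - f.span[0] + 1 <= hi
    ]
    if not products:
        raise NoAmplificationError(
            f"no product: {len(fsites)} forward site(s), {len(rsites)} reverse site(s), "
            f"none converging within {lo}..{hi} bp"
        )
    if len(products) > 1:
        spans = [(f.span[0], r.span[1]) for f, r in products]
        raise AmbiguousAmplificationError(
            f"{len(products)} candidate products: {spans}", spans
        )
    fsite, rsite = products[0]
    start, end = fsite.span[0], rsite.span[1]
    seq = list(template.slice1(start, end))
    subs: list[tuple[int, str, str]] = []
    for primer, site in ((fwd, fsite), (rev, rsite)):
        top = _aligned_primer_top(primer)
        for i, base in enumerate(top):
            pos = site.span[0] + i  # template coordinate
            off = pos - start  # 0-based amplicon index
            if seq[off] != base:
                subs.append((off + 1, seq[off], base))
                seq[off] = base
    subs.sort()
    snp_offsets = {}
    for snp in snps:
        if start <= snp.position <= end:
            snp_offsets[snp.id] = snp.position - start + 1
    return Amplicon(
        bases=NucSeq("".join(seq), name=f"amplicon_{start}_{end}"),
        template_span=(start, end),
        substitutions=tuple(subs),
        snp_offsets=snp_offsets,
        primer_footprints=(fsite.span, rsite.span),
    )


def amplicon_allele_variants(amplicon: Amplicon, snp) -> dict[str, NucSeq]:
    """One amplicon sequence per SNP allele, differing only at the SNP offset.

    Raises :class:`DesignViolationError` when the SNP sits under a primer
    footprint (a primer there would overwrite genotype information).
    """
    start, end = amplicon.template_span
    if not (start <= snp.position <= end):
        raise DesignViolationError(
            f"SNP {snp.id} at {snp.position} outside amplicon span {start}..{end}"
        )
    off = amplicon.to_amplicon_pos(snp.position)
    for fs, fe in amplicon.primer_footprints:
        if fs <= snp.position <= fe:
            raise DesignViolationError(
                f"SNP {snp.id} at {snp.position} lies under the primer footprint "
                f"{fs}..{fe}; genotype information would be erased"
            )
    variants: dict[str, NucSeq] = {}
    for allele in sorted(snp.alleles):
        seq = list(amplicon.bases.bases)
        seq[off - 1] = allele
        variants[allele] = NucSeq("".join(seq), name=f"{amplicon.bases.name}_{snp.id}_{allele}")
    return variants
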