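"""Sequence substrate: alphabet, IUPAC matching, site scanning, linear digestion.

Coordinates are 1-based, fully closed intervals throughout the package.
Templates are strict A/C/G/T; degenerate IUPAC letters are legal only in
enzyme recognition patterns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "AlphabetError",
    "NucSeq",
    "Enzyme",
    "SiteHit",
    "DigestResult",
    "DEFAULT_ENZYMES",
    "revcomp",
    "iupac_match",
    "find_sites",
    "digest_linear",
    "load_enzyme_tsv",
]

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class AlphabetError(ValueError):
    """Raised when a sequence or pattern contains an illegal character."""


@dataclass(frozen=True)
class NucSeq:
    """A concrete nucleotide sequence (A/C/G/T only), uppercased on ingest."""

    bases: str
    name: str = ""

    def __post_init__(self) -> None:
        up = self.bases.upper()
        bad = set(up) - set("ACGT")
        if bad:
            raise AlphabetError(
                f"non-ACGT character(s) {sorted(bad)} in sequence "
                f"{self.name or '<unnamed>'!r}"
            )
        if len(up) < 1:
            raise AlphabetError("empty sequence")
        object.__setattr__(self, "bases", up)

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, i) -> str:
        return self.bases[i]

    def __iter__(self) -> Iterator[str]:
        return iter(self.bases)

    def slice1(self, start: int, end: int) -> str:
        """Substring by 1-based closed interval [start, end]."""
        if not (1 <= start <= end <= len(self.bases)):
            raise IndexError(f"interval {start}..{end} outside 1..{len(self.bases)}")
        return self.bases[start - 1 : end]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition pattern plus top-strand cut offset.

    ``cut_offset`` counts site bases before the top-strand scission, so
    HaeIII (GG^CC) has site "GGCC" and cut_offset 2.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        up = self.site.upper()
        bad = set(up) - set(IUPAC)
        if bad:
            raise AlphabetError(f"invalid IUPAC code(s) {sorted(bad)} in site {self.site!r}")
        if len(up) < 4:
            raise ValueError(f"recognition site {up!r} shorter than 4 bp")
        if not (0 <= self.cut_offset <= len(up)):
            raise ValueError(f"cut_offset {self.cut_offset} outside [0, {len(up)}]")
        object.__setattr__(self, "site", up)

    @property
    def is_palindromic(self) -> bool:
        return revcomp_pattern(self.site) == self.site


@dataclass(frozen=True)
class SiteHit:
    """One recognition-site occurrence on a template (top-strand coordinates)."""

    start: int
    strand: str
    cut_after: int


@dataclass(frozen=True)
class DigestResult:
    """Outcome of digesting one linear molecule."""

    fragments: tuple[int, ...]
    cut_positions: tuple[int, ...]

    def fragment_multiset(self) -> Counter:
        return Counter(self.fragments)


DEFAULT_ENZYMES: tuple[Enzyme, ...] = (
    Enzyme("HaeIII", "GGCC", 2),
    Enzyme("Eco47III", "AGCGCT", 3),
    Enzyme("RsaI", "GTAC", 2),
)


def revcomp(seq: NucSeq) -> NucSeq:
    """Reverse complement of a concrete sequence; an involution."""
    return NucSeq(seq.bases.translate(_COMPLEMENT)[::-1], name=seq.name)


def revcomp_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern string."""
    up = pattern.upper()
    bad = set(up) - set(IUPAC)
    if bad:
        raise AlphabetError(f"invalid IUPAC code(s) {sorted(bad)} in pattern {pattern!r}")
    return up.translate(_COMPLEMENT)[::-1]


def iupac_match(template_base: str, pattern_code: str) -> bool:
    """True iff ``template_base`` belongs to the IUPAC expansion of ``pattern_code``."""
    if template_base not in "ACGT":
        raise AlphabetError(f"template base {template_base!r} is not a concrete base")
    try:
        return template_base in IUPAC[pattern_code.upper()]
    except KeyError:
        raise AlphabetError(f"invalid IUPAC code {pattern_code!r}") from None


def _scan(bases: str, pattern: str) -> list[int]:
    """1-based start positions where `pattern` (IUPAC) matches `bases`."""
    hits = []
    L = len(pattern)
    sets = [IUPAC[c] for c in pattern]
    for i in range(len(bases) - L + 1):
        window = bases[i : i + L]
        if all(b in s for b, s in zip(window, sets)):
            hits.append(i + 1)
    return hits


def find_sites(seq: NucSeq, enzyme: Enzyme) -> list[SiteHit]:
    """All recognition-site occurrences of ``enzyme`` in ``seq``, both strands.

    Palindromic sites report a single +-strand hit per locus.  ``cut_after``
    is the 1-based top-strand position after which the strand is severed:
    ``start + cut_offset - 1`` on the + strand and
    ``start + len(site) - cut_offset - 1`` on the − strand.
    """
    hits: list[SiteHit] = []
    L = len(enzyme.site)
    for start in _scan(seq.bases, enzyme.site):
        hits.append(SiteHit(start, "+", start + enzyme.cut_offset - 1))
    if not enzyme.is_palindromic:
        rc = revcomp_pattern(enzyme.site)
        for start in _scan(seq.bases, rc):
            hits.append(SiteHit(start, "-", start + L - enzyme.cut_offset - 1))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def digest_linear(seq: NucSeq, enzyme: Enzyme) -> DigestResult:
    """Fragment lengths from a complete digest of one linear molecule.

    Cuts inside the molecule (0 < cut_after < len) partition it into maximal
    runs; fragment lengths always sum to the input length.
    """
    n = len(seq)
    cuts = sorted({h.cut_after for h in find_sites(seq, enzyme) if 0 < h.cut_after < n})
    bounds = [0, *cuts, n]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(fragments=fragments, cut_positions=tuple(cuts))


def load_enzyme_tsv(path) -> list[Enzyme]:
    """Read an enzyme catalog TSV: columns name, site, cut_offset; '#' comments."""
    enzymes: list[Enzyme] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}")
            name, site, off = parts
            try:
                enzymes.append(Enzyme(name, site, int(off)))
            except (ValueError, AlphabetError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return enzymes
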