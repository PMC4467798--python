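"""Readers and writers: FASTA, minimal VCF, enzyme/bands/calls TSV, design JSON.

Parsers reject malformed input with file/line context rather than coercing.
All coordinates in reports are 1-based closed intervals.
"""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplify import Primer
from .design import AssayDesign, Diagnostics, Placement, SnpSpec
from .genotyping import ObservedBands, Subject, Cohort
from .seqcore import Enzyme, NucSeq

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_vcf_minimal",
    "write_design_report",
    "read_design_report",
    "read_design_report_tsv",
    "read_bands_tsv",
    "write_bands_tsv",
    "write_calls_tsv",
    "write_cohort_tsv",
    "read_ca6_tsv",
]


def read_fasta(path) -> list[NucSeq]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return [NucSeq(str(r.seq), name=r.id) for r in records]


def write_fasta(seqs, path, wrap: int = 60) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.name or f"seq{i+1}", description="") for i, s in enumerate(seqs)]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_vcf_minimal(path) -> list[SnpSpec]:
    """Minimal VCF: tab-separated CHROM POS ID REF ALT [...]; header lines '#'.

    Only biallelic single-base substitutions pass; anything else is rejected
    with its line number.
    """
    snps: list[SnpSpec] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 tab-separated columns, got {len(parts)}")
            _chrom, pos_s, vid, ref, alt = parts[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: POS {pos_s!r} is not an integer") from None
            if "," in alt:
                raise ValueError(f"{path}:{lineno}: multiallelic record (ALT {alt!r}) rejected")
            if len(ref) != 1 or len(alt) != 1 or ref.upper() not in "ACGT" or alt.upper() not in "ACGT":
                raise ValueError(f"{path}:{lineno}: not a SNP (REF {ref!r}, ALT {alt!r})")
            snps.append(SnpSpec(vid, pos, frozenset((ref.upper(), alt.upper()))))
    return snps


def _primer_dict(p: Primer) -> dict:
    return {
        "sequence": p.bases.bases,
        "name": p.bases.name,
        "orientation": p.orientation,
        "footprint": list(p.intended_span) if p.intended_span else None,
        "engineered_offsets_3prime": list(p.engineered_offsets),
    }


def _primer_from_dict(d: dict) -> Primer:
    return Primer(
        NucSeq(d["sequence"], name=d.get("name", "")),
        d["orientation"],
        intended_span=tuple(d["footprint"]) if d.get("footprint") else None,
        engineered_offsets=tuple(d.get("engineered_offsets_3prime", ())),
    )


def design_to_dict(d: AssayDesign) -> dict:
    return {
        "snp": {
            "id": d.snp.id,
            "position": d.snp.position,
            "alleles": sorted(d.snp.alleles),
            "cut_allele": d.snp.cut_allele,
        },
        "enzyme": {
            "name": d.placement.enzyme.name,
            "site": d.placement.enzyme.site,
            "cut_offset": d.placement.enzyme.cut_offset,
        },
        "placement": {
            "site_span": list(d.placement.site_span),
            "snp_slot": d.placement.snp_slot,
            "matching_allele": d.placement.matching_allele,
            "required_substitutions": [list(s) for s in d.placement.required_substitutions],
            "side": d.placement.side,
            "pattern": d.placement.pattern,
        },
        "fwd_primer": _primer_dict(d.fwd),
        "rev_primer": _primer_dict(d.rev),
        "amplicon_length": d.amplicon_length,
        "predicted_fragments": {g: list(f) for g, f in sorted(d.predicted_fragments.items())},
        "tm_fwd": round(d.tm_fwd, 2),
        "tm_rev": round(d.tm_rev, 2),
        "n_engineered_mismatches": d.n_engineered_mismatches,
        "diagnostics": {
            "passed": d.diagnostics.passed,
            "clauses": [list(c) for c in d.diagnostics.clauses],
        }
        if d.diagnostics
        else None,
    }


def design_from_dict(obj: dict) -> AssayDesign:
    snp = SnpSpec(
        obj["snp"]["id"],
        obj["snp"]["position"],
        frozenset(obj["snp"]["alleles"]),
        cut_allele=obj["snp"].get("cut_allele"),
    )
    enzyme = Enzyme(obj["enzyme"]["name"], obj["enzyme"]["site"], obj["enzyme"]["cut_offset"])
    pl = obj["placement"]
    placement = Placement(
        enzyme=enzyme,
        site_span=tuple(pl["site_span"]),
        snp_slot=pl["snp_slot"],
        matching_allele=pl["matching_allele"],
        required_substitutions=tuple(tuple(s) for s in pl["required_substitutions"]),
        side=pl["side"],
        pattern=pl.get("pattern", enzyme.site),
    )
    diag = None
    if obj.get("diagnostics"):
        diag = Diagnostics(
            passed=obj["diagnostics"]["passed"],
            clauses=tuple(tuple(c) for c in obj["diagnostics"]["clauses"]),
        )
    return AssayDesign(
        snp=snp,
        placement=placement,
        fwd=_primer_from_dict(obj["fwd_primer"]),
        rev=_primer_from_dict(obj["rev_primer"]),
        amplicon_length=obj["amplicon_length"],
        predicted_fragments={g: tuple(f) for g, f in obj["predicted_fragments"].items()},
        tm_fwd=obj["tm_fwd"],
        tm_rev=obj["tm_rev"],
        n_engineered_mismatches=obj["n_engineered_mismatches"],
        diagnostics=diag,
        enzyme_name=enzyme.name,
    )


_TSV_HEADER = [
    "snp_id",
    "enzyme",
    "cut_allele",
    "fwd_primer",
    "rev_primer",
    "amplicon_length",
    "fragments_by_genotype",
    "n_engineered_mismatches",
    "valid",
]


def write_design_report(designs, path, format: str = "json") -> None:
    """Persist assay designs; JSON round-trips losslessly via design_from_dict."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps([design_to_dict(d) for d in designs], indent=2) + "\n")
        return
    if format == "tsv":
        lines = ["\t".join(_TSV_HEADER)]
        for d in designs:
            fbg = ";".join(
                f"{g}:{','.join(str(x) for x in frags)}" for g, frags in sorted(d.predicted_fragments.items())
            )
            lines.append(
                "\t".join(
                    [
                        d.snp.id,
                        d.placement.enzyme.name,
                        d.placement.matching_allele,
                        d.fwd.bases.bases,
                        d.rev.bases.bases,
                        str(d.amplicon_length),
                        fbg,
                        str(d.n_engineered_mismatches),
                        str(bool(d.diagnostics.passed)) if d.diagnostics else "NA",
                    ]
                )
            )
        path.write_text("\n".join(lines) + "\n")
        return
    raise ValueError(f"unknown format {format!r}")


def read_design_report(path) -> list[AssayDesign]:
    data = json.loads(Path(path).read_text())
    return [design_from_dict(obj) for obj in data]


def read_design_report_tsv(path) -> list[dict]:
    """TSV report rows with fragment multisets parsed back to tuples."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != _TSV_HEADER:
        raise ValueError(f"{path}: unexpected TSV header")
    rows = []
    for line in lines[1:]:
        vals = dict(zip(_TSV_HEADER, line.split("\t")))
        vals["amplicon_length"] = int(vals["amplicon_length"])
        frags = {}
        for chunk in vals["fragments_by_genotype"].split(";"):
            g, sizes = chunk.split(":")
            frags[g] = tuple(int(x) for x in sizes.split(","))
        vals["predicted_fragments"] = frags
        rows.append(vals)
    return rows


def read_bands_tsv(path) -> list[ObservedBands]:
    """Bands TSV: sample_id, enzyme, fragments (comma-joined ints), uncut_lane (0/1)."""
    out: list[ObservedBands] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("sample_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            sid, enzyme, frag_s, uncut = parts
            try:
                fragments = tuple(int(x) for x in frag_s.split(",")) if frag_s else ()
                out.append(ObservedBands(sid, enzyme, fragments, includes_uncut_lane=bool(int(uncut))))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bands_tsv(bands, path) -> None:
    lines = ["sample_id\tenzyme\tfragments\tuncut_lane"]
    for b in bands:
        lines.append(
            f"{b.sample_id}\t{b.enzyme}\t{','.join(str(f) for f in b.fragments)}\t{int(b.includes_uncut_lane)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_cohort_tsv(cohort: Cohort, path) -> None:
    lines = ["sample_id\trs713598\trs1726866\trs10246939\tca6\tphenotype"]
    for s in cohort.subjects:
        lines.append(
            "\t".join(
                [
                    s.sample_id,
                    s.genotypes.get("rs713598", "NA"),
                    s.genotypes.get("rs1726866", "NA"),
                    s.genotypes.get("rs10246939", "NA"),
                    s.ca6 or "NA",
                    s.phenotype or "NA",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_calls_tsv(rows, path) -> None:
    """rows: dicts with sample_id, the three genotype calls, diplotype, class, ca6, annotation."""
    header = ["sample_id", "rs713598", "rs1726866", "rs10246939", "diplotype", "taster_class", "ca6", "annotation"]
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(row.get(k, "NA") or "NA") for k in header))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ca6_tsv(path) -> dict:
    """CA6 co-genotypes: sample_id <tab> genotype (AA/AG/GG)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("sample_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sid, g = parts
            g = "".join(sorted(g.upper()))
            if g not in ("AA", "AG", "GG"):
                raise ValueError(f"{path}:{lineno}: invalid CA6 genotype {parts[1]!r}")
            out[sid] = g
    return out
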