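# acrskit

Assay design and genotyping for mismatch-primer PCR-RFLP, also known as
amplification-created restriction site (ACRS) or dCAPS genotyping. When a SNP
does not touch any natural restriction site, a primer carrying one or two
deliberate mismatches near its 3′ end can write part of a recognition site
into every PCR product; the site is then completed by exactly one SNP allele,
so a digest tells the alleles apart by fragment length alone.

The package covers the full loop:

- **`seqcore`** — strict A/C/G/T sequences, IUPAC pattern matching,
  recognition-site scanning on both strands, and linear-fragment digestion
  (built-in catalog: HaeIII `GG^CC`, Eco47III `AGC^GCT`, RsaI `GT^AC`, plus a
  TSV loader for user catalogs). Coordinates are 1-based closed intervals
  everywhere.
- **`amplify`** — in-silico PCR with end-to-end, 3′-anchored primer binding
  (bounded mismatches, mandatory 3′-terminal match); amplicons inherit
  primer-encoded substitutions and track SNP offsets.
- **`design`** — the design engine: enumerate enzyme-site placements over a
  SNP that discriminate the two alleles, derive the required primer-embedded
  substitutions, build mutagenic + perfect-match primer pairs under Tm /
  length / fragment-size constraints, validate diagnosability by simulation,
  and rank candidate assays. Tm models: Wallace rule and nearest-neighbor
  (Allawi & SantaLucia 1997 parameters, SantaLucia 1998 salt correction, via
  Biopython).
- **`genotyping`** — call SNP genotypes from observed band patterns (with a
  size tolerance and a sub-floor "fragment ran off the gel" fallback), phase
  the three TAS2R38 SNPs into PAV/AVI diplotypes, map diplotypes to PROP
  taster classes (optionally annotated with a CA6 rs2274333 co-genotype), and
  exact statistics (two-sided Fisher 2×2 and exact Hardy–Weinberg tests in
  exact rational arithmetic).
- **`synth`** — a synthetic TAS2R38-like 1 kb template reconstructed from the
  shipped primer footprints (all assay observables — 203/194 bp products,
  47+156 / 45+149 / 149+45 fragments — are pinned by construction, for every
  seed), plus a cohort simulator with optional band-size jitter and fragment
  dropout.
- **`io` / `cli`** — FASTA, minimal VCF, enzyme/bands/calls TSV, design JSON,
  and the `acrskit` command line.

## CLI

```sh
# generate the synthetic template, a 60-subject cohort, and its band patterns
acrskit simulate --n 60 --ratio 20:20:20 --seed 1 --out-prefix run

# design assays for a SNP (inline or from a minimal VCF)
acrskit design --template run.template.fasta --snp rs713598:145:C:G \
    --tm-max 88 --out designs.json

# in-silico PCR and digestion
acrskit pcr --template run.template.fasta --fwd <seq> --rev <seq> --out amp.fasta
acrskit digest --seq amp.fasta --enzyme HaeIII --out digest.tsv

# genotype a cohort from band patterns
acrskit call --assays run.assays.json --bands run.bands.tsv --out calls.tsv
```

Note on `--tm-max`: mutagenic primers are structurally long (the cut-proximal
fragment spans the amplicon start to the scission point, so a 40 bp
detectability floor forces ~40-nt primers), which pushes their
nearest-neighbor Tm above the conservative 70 °C default ceiling. Widen the
window (e.g. `--tm-max 88`, or `design.FIXTURE_CONSTRAINTS` in code) to let
such designs through; the shipped 46/47-nt reference primers behave the same
way.

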