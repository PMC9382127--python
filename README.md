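# famdup

A gene-family characterization pipeline for plant gene families, built around
the analyses typical of genome-wide family surveys:

- **annotation_io** — family characteristics table I/O (a transcribed 78-gene
  table ships as an in-repo fixture), candidate-hit screening
  (E-value ≤ 1e−5, identity > 50%, keyword hits bypassing the numeric
  filter), exon/intron histograms, and protein physicochemical descriptors
  (average-mass MW, Henderson–Hasselbalch pI with EMBOSS pKa values).
- **duplication** — duplicate-pair detection (global-alignment identity > 0.70
  with the shorter sequence as denominator, length ratio > 0.70) and
  tandem/segmental classification (start-to-start < 200 kb span rule, or a
  100-kb / ≤ 5 intervening-genes window rule; segmental via synteny-block
  tables). Tandem takes precedence, so the classes are disjoint.
- **molevol** — from-scratch Nei–Gojobori (NG86) Ka/Ks with Jukes–Cantor
  correction, stop-codon-excluded site counting and pathway enumeration, and
  divergence dating T = Ks / (2 × 6.1 × 10⁻⁹) × 10⁻⁶ Mya.
- **phylogeny** — Poisson-corrected p-distances, Saitou–Nei neighbour joining
  with deterministic tie-breaking, seeded column-resampling bootstrap, and
  subgroup cutting by longest-internal-edge removal.
- **expression** — FPKM expression-level calls (|log₂ FPKM| ≥ 1 "high" rule,
  literal or positive-only interpretation) and fold-change direction calls
  against a baseline condition with explicit zero handling.
- **phenotype** — internal-browning index ([∑(Sᵢ·Nᵢ)/5N] × 100 over grades
  0–5) and incidence statistics from graded fruit cohorts.
- **synthetic_data** — seeded generators for toy genomes with planted tandem
  clusters and segmental blocks, codon pairs diverged at a chosen ω and
  target Ks, expression matrices with planted fold changes, and graded
  cohorts — so the full pipeline is testable offline with known truth.
- **pipeline_cli** — a YAML-configured `run_all` orchestrator and the
  `famdup` command-line interface.

## CLI

```bash
famdup table --in table.tsv --summary out.json
famdup physchem --fasta proteins.fa --out physchem.tsv
famdup duplication --table table.tsv --fasta proteins.fa --blocks blocks.tsv --rule span_200kb
famdup kaks --pairs pairs.tsv --cds cds.fa --lambda 6.1e-9
famdup tree --aln aln.fa --bootstrap 1000 --seed 42 --subgroups 5
famdup expr --matrix fpkm.tsv --baseline day0
famdup ib --cohorts grades.tsv
famdup simulate --seed 7 --out simdir/
famdup run --config run.yml
```

`famdup run` executes every configured stage (table → physchem → duplication
→ Ka/Ks dating → phylogeny → expression → phenotype) and writes per-stage
TSV/JSON/Newick reports plus a `summary.json` carrying the headline counts,
the seed, and a config hash.

## Layout

```
src/famdup/            package modules (one per pipeline stage)
src/famdup/data/       plain-text fixtures (family table, published pair lists)
tests/                 pytest suite incl. property tests and acceptance gates
scripts/acceptance.py  acceptance report generator
```
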