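# decoytools

A Python library for large-scale analysis of computational protein design
(CPD) decoy populations and related structural bioinformatics tasks — built
for workflows that generate thousands to millions of Rosetta-style decoys
and must distil them into a handful of sequences worth making in the lab.

Heuristic design protocols compensate for imperfect energy functions by
sampling broadly and then filtering hard. That filtering step is where most
ad-hoc scripting happens; `decoytools` replaces it with a small set of
tested, composable operations over pandas-based containers:

- **`DesignTable`** (a `pandas.DataFrame` subclass) — one row per decoy:
  score terms, a `description` identifier, per-chain sequence and
  secondary-structure strings, optional per-chain reference (template)
  sequences. Supports quantile filtering (top *q* by score, strict `<` on
  the linear-interpolation quantile), residue-constrained selection,
  mutation bookkeeping (`P46G`-style tokens), combinatorial variant
  enumeration, wild-type reversion enumeration, Rosetta resfile writing,
  region slicing and experiment merging.
- **`FrequencyMatrix`** — positions × 20 amino acids, the PSSM-like object
  behind enrichment analysis (top fraction minus whole population),
  information content *I(i) = log₂20 − H(i)* for sequence logos, and
  frequency heatmaps.
- **`FragmentSet`** — 9-mer/3-mer fragment libraries with per-residue
  φ/ψ/ω. Fragment quality is measured with no external scoring program:
  each fragment backbone is rebuilt by forward kinematics with ideal bond
  geometry and superposed (Kabsch, SVD) onto the query structure's Cα
  window to give an RMSD profile.
- **`StructureRecord`** — PDB backbones with derived dihedrals,
  four-flavour Ramachandran classification (GENERAL / GLY / PRE-PRO / PRO)
  and chain-break handling.
- **io** — Rosetta silent score tables and score-JSON, FASTA, Clustal,
  fragment files, PDB, CSV reference tables and simple CD/SPR trace
  dialects; everything reads gzip transparently.
- **plotting** — logos, frequency heatmaps, Ramachandran panels,
  fragment-quality profiles, score-distribution grids, population-context
  plots, per-residue BLOSUM62 score tracks, CD and SPR panels (headless).
- **synth** — a deterministic synthetic-data generator (seeded populations
  with planted enrichment, ideal-geometry backbones, fragment libraries,
  CD/SPR traces) so the whole library is testable with no design software
  installed.

## Worked example: mining one design generation to seed the next

```python
import decoytools as dt
from decoytools import seqstats as ss
from decoytools.components import MutationSpec

cfg = dt.FixtureConfig(seed=0)            # 1000 decoys, 60 residues
pop = dt.synth.make_population(cfg)

top = pop.filter_quantile("score", 0.05)  # top 5% by score (strict <)
diff = ss.enrichment_difference(
    ss.sequence_frequencies(top, "A"),
    ss.sequence_frequencies(pop, "A"))
hits = ss.overrepresented(diff, threshold=0.20)
print("overrepresented in top 5%:", hits)

# best-scoring decoy that carries NONE of the enriched residues yet
pick = pop.get_sequence_with("A", hits, confidence=0.25,
                             invert=True).sort_values("score")
template = pick.get_sequence("A", 0)
pick = pick.add_reference_sequence("A", template)

specs = [MutationSpec(p, (template[p - 1], aa)) for p, aa in hits]
variants = pick.generate_mutant_variants("A", specs).identify_mutants("A")
print("variants generated:", len(variants))
print(variants[["description", "mutant_count_A", "mutants_A"]]
      .head(4).to_string(index=False))
```

Output:

```
overrepresented in top 5%: [(34, 'L'), (35, 'E'), (46, 'G'), (47, 'K')]
variants generated: 16
      description  mutant_count_A mutants_A
decoy_00451_v0000               0
decoy_00451_v0001               1      R47K
decoy_00451_v0002               1      R46G
decoy_00451_v0003               2 R46G,R47K
```

Reading this: positions 34, 35, 46 and 47 are enriched by more than 20
percentage points among the best-scoring 5% of decoys, so they are the
positions worth re-designing. The selected template carries none of the
four enriched residues; enumerating every combination of {template residue,
enriched residue} at the four positions yields 2⁴ = 16 second-generation
sequences (the unmodified template included, `mutant_count_A = 0`). Each
variant's mutations are recorded as `<ref><position><new>` tokens, and
`make_resfile` writes the corresponding `PIKAA` resfiles to drive the next
design round.

The same operations run from the shell:

```sh
decoytools fixtures --seed 0 --out-dir corpus
decoytools select  --in corpus/population.silent --quantile 0.05 \
                   --out-csv top.csv --out-fasta top.fasta
decoytools profile --in corpus/population.silent --out-prefix prof
decoytools mutants --in corpus/population.silent --sort-by score \
                   --spec "34:ML,35:ME,46:MG,47:MK" --out-prefix mut
decoytools structure --pdb corpus/backbone.pdb \
                   --fragments corpus/fragments.9mers --out-prefix bb
```

## Scope

`decoytools` writes inputs for and re-imports outputs from design suites;
it never executes Rosetta (or any other design program) itself, implements
no energy function, and its secondary-structure heuristic is a coarse
φ/ψ-box approximation, not a hydrogen-bond based assignment. See
`docs/methods.md` for the models, parameter choices and limitations.
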