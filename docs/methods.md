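# Methods

This note documents the models and procedures behind `npchar`, the defaults
they ship with, and the choices made where more than one reasonable design
exists.

## Curation

Entries pass through a fixed pipeline: parse → structural normalization →
largest-component selection → element/valence filter → neutralize →
reionize → canonical tautomer → canonical SMILES. The audit trail records,
for every entry, the steps completed and the outcome (`kept`,
`removed_element`, `removed_valence`, `removed_parse_error`).

Choices that were genuinely open:

- **Filter placement.** The element/valence filter runs *after*
  largest-component selection, so an organic parent with a metallic
  counterion survives while an organometallic parent is removed. Salts are
  common in registries and the filter's intent is the parent structure.
- **Largest component** = most heavy atoms, ties broken by larger exact
  mass, then lexicographically smallest canonical SMILES — fully
  deterministic.
- **Valence classification.** Any sanitization failure (including
  aromaticity perception failures) counts as `removed_valence`; parser
  failures and empty structures count as `removed_parse_error`.
- **Tautomers.** RDKit's rule-based tautomer canonicalizer with a transform
  cap (1000) guarantees termination; sp3 and double-bond stereo removal is
  disabled so stereochemistry survives curation. Stereo is kept on the
  canonical structure and stripped only in the `achiral_key` used for
  unique-compound, scaffold and ring-system bookkeeping.
- **Duplicates** (shared achiral key) are flagged, never dropped: curated
  size and exclusive-entry count are separate quantities.

## Descriptor panel

HBA/HBD default to Lipinski-style topological counts (HBA = N+O count,
HBD = N–H/O–H hydrogen count); the stricter pharmacophoric HBA is available
via `hba_definition="topological"`. cLogP is Crippen's atomic-contribution
estimate; TPSA is Ertl's fragment sum (Å²). CSP3 is the fraction of carbon
atoms that are sp³. Chiral centers count assigned *plus unassigned potential*
tetrahedral centers, the convention under which NP libraries show their
characteristically high values. Ring classes (carbo/hetero × aliphatic/
aromatic) are counted over the symmetrized smallest ring set, so fused
aromatics count each ring.

Acid/basic atom counts — elsewhere computed by proprietary software without
published definitions — use a transparent SMARTS set: carboxylic, sulfonic/
sulfinic and phosphonic/phosphoric acids (neutral or ionized) for acids;
non-amide aliphatic amines, amidines and guanidines for bases. These are a
documented proxy, not a claim of equivalence with any vendor descriptor.

Rule flags: Lipinski (MW ≤ 500, cLogP ≤ 5, HBD ≤ 5, HBA ≤ 10), Veber
(RB ≤ 10, TPSA ≤ 140 Å²), rule of three (MW < 300 **strict**, cLogP ≤ 3,
HBD ≤ 3, HBA ≤ 3).

## Fingerprints and diversity

MACCS keys (RDKit's 167-bit vector; bit 0 is never set, so Tanimoto values
are identical to the conventional 166-key form), ECFP4/ECFP6 folded to 1024
bits by modulo folding, and a MinHashed atom-pair fingerprint built from
scratch at the shingle level: every unordered heavy-atom pair contributes
shingles (environment of atom i at radius r, topological distance,
environment of atom j at radius r) for r = 1, 2, and the shingle set is
MinHashed with 2048 universal-hash functions (p = 2³¹ − 1; hash parameters
fixed internally so fingerprints are a pure function of structure). The
fraction of equal MinHash components is an unbiased Jaccard estimate; tests
hold its mean absolute error against exact shingle-set Jaccard below 0.05.
Atom environments are canonical rooted fragment SMILES computed per atom —
never deduplicated across symmetric atoms — so fingerprints are invariant
to input atom ordering.

Diversity profiling draws five independent samples of 1000 molecules
without replacement (overlap across samples allowed; a library at or below
the sample size is enumerated exactly once) and pools all pairwise
similarities into one distribution per library, summarized by mean, median
and the empirical cumulative curve. Pooling (rather than per-sample
averaging) is what makes the cumulative curves directly comparable across
libraries; the left-most curve is the most diverse library.

## Scaffolds, SSE and CSR

Bemis–Murcko scaffolds (rings + linkers, exocyclic double-bonded atoms
retained, stereo stripped). Acyclic molecules have an empty scaffold and are
excluded from SSE/CSR denominators and reported as an acyclic fraction.

SSE renormalizes the compound counts over the **top-N scaffolds only**
(default N = 15) before computing entropy and dividing by log₂ N; with
fewer than N scaffolds available, N shrinks to that number, and a
single-scaffold table has SSE 0 by definition. Rank ties at the cutoff are
broken by lexicographic key order for determinism. The CSR curve plots
cumulative compound fraction against scaffold fraction in decreasing
frequency order; its trapezoid area is 0.5 for one-compound-per-scaffold
libraries and grows toward 1 as few scaffolds dominate.

## Ring systems

Extraction: mark ring atoms; protect multiple bonds from ring atoms to
non-ring atoms (the exocyclic partner stays with the ring); cleave every
remaining acyclic single bond — including biaryl-type bonds between ring
atoms of different systems; keep fragments with at least one ring; cap cut
sites with hydrogen; canonicalize, strip stereo, deduplicate. Spiro, fused
and bridged systems stay united because ring bonds are never cut; two rings
joined by an acyclic double bond likewise remain one system (the double
bond is protected). Protection of exocyclic *triple* bonds is an extension
flag, off by default. The test suite proves the implementation equal to an
independent atom-set oracle (connected components of ring bonds plus
non-single bonds) on 52 small molecules, and idempotent on every extracted
key.

Bioactivity classification consumes an external annotation table (report
counts per target class, active/inactive report counts) keyed by achiral
ring SMILES. Thresholds are applied **non-strictly**: active if
active ≥ 10 × inactive, inactive if inactive ≥ 10 × active, else
intermediate; preferred target if the top class ≥ 2 × the runner-up, else
"multiple targets". All-zero annotations classify as intermediate /
"not-known".

## RECAP fragmentation

Eleven bond rules (amide, ester, urea, amine, ether, olefin, quaternary
nitrogen, aromatic N–aliphatic C, lactam N–aliphatic C, biaryl C–C,
sulfonamide), each an individually toggleable SMARTS pattern naming the two
bond atoms; only acyclic bonds are ever cleaved, so rings stay intact. The
leaf set is produced by cleaving **all** rule-matching bonds of the parent
simultaneously — for these bond-local rules this equals the leaves of the
recursive decomposition tree, and it makes heavy-atom conservation exact:
fragments partition the parent's heavy atoms, with cut sites marked by
dummy atoms (`*` in keys, `A` in human-readable output). Ureas are cleaved
at both N–C(=O) bonds with the carbonyl retained as its own fragment (no
atoms are deleted). A `min_fragment_atoms` floor (default 1, i.e. keep
everything) can suppress cuts that would strand very small leaves.

Fragment libraries skip molecules above a MW cap (default 1350 g/mol) and
aggregate leaf counts across the library; rule-of-three descriptors are
computed on the hydrogen-capped fragment so the values describe a
realizable molecule.

## NP-likeness score

For each heavy atom, its circular environment (radius 2 by default) is a
canonical rooted fragment SMILES. Training counts environments in an
NP corpus and a synthetic corpus; environment f contributes
log₁₀[(n_NP(f)+k)/N_NP ÷ (n_SYN(f)+k)/N_SYN] with pseudocount k = 1, where
N are total environment counts. A molecule's raw score is the *mean*
contribution over its heavy atoms (unseen environments contribute 0 —
neutral, so novel chemistry is not penalized unboundedly); per-atom
averaging bounds scores for large molecules. Raw scores are affinely
calibrated so the pooled training scores' 1st/99th percentiles map to
−5/+5, then clamped to [−5, +5]. The calibration is explicit and stored in
the versioned JSON model file, which round-trips bit-identically.

Swapping the corpora negates every contribution and every raw score;
adding occurrences of an environment to the NP corpus never decreases its
contribution (for environments that are not the bulk of the corpus). By
default the model trains on the package's own generated NP-like and
drug-like sets, so the scorer works with no external data; real corpora
can be supplied instead.

## Chemical-multiverse embeddings

Two complementary 2-D views of the pooled multi-library data: (1) PCA over
z-scored HBA, HBD, MW, TPSA, RB, cLogP — standardization and fit on the
pooled matrix so all libraries share one frame; component signs fixed by
making each loading vector's largest element positive; numerically
constant descriptors are dropped with a warning; (2) t-SNE over the
1024-bit ECFP4 vectors (Euclidean metric on 0/1 coordinates; perplexity 30,
5000 iterations, PCA initialization, explicit seed). t-SNE errors out when
the library is not larger than the perplexity. Figure rendering is
deliberately out of scope: both views export coordinates (and PCA loadings/
explained variance) as CSV.

## Synthetic libraries

The generator assembles molecules by decorating curated core pools with
substituent fragments, so every product is valence-correct, parseable and
carries a full recipe (core, substituents, cluster, intended curation
outcome, solvent label):

- `np_like` — oxygen-rich, nitrogen-free polycyclic cores (chromone,
  coumarin, flavanone, pyranose, decalin, terpenoid- and steroid-like) with
  hydroxy/methoxy/acetoxy/hydroxymethyl substituents. Designed contrasts:
  mean CSP3 and oxygen counts above the drug-like set, nitrogen near zero,
  many stereocenters.
- `drug_like` — nitrogen heteroaromatic cores (pyridine, pyrimidine,
  quinoline, benzothiazole, indole, phenylpiperazine) with amine/amide/
  sulfonamide/halogen substituents.
- `cluster` — one core per cluster with light decoration: internally
  homogeneous, mutually distant families that give diversity and embedding
  analyses a known answer.
- `edge_cases` — valid molecules plus exact fractions of salts (default
  0.10; multi-component, must survive curation), disallowed-element
  entries (0.05; a metal atom bonded into the parent, must be removed) and
  pentavalent-carbon entries (0.05; must be removed as valence errors).

Solvent labels emulate NMR-solubility categories with a threshold rule:
TPSA ≥ 75 Å² → DMSO-d6; TPSA < 25 Å² and HBD = 0 → CDCl3; otherwise CD3OD,
with optional label noise. The rule is deliberately simple — the point is a
*recoverable* descriptor signal, not realism.

What the generator does **not** emulate: real NP structural idiosyncrasy
(macrocycles, glycosylation patterns, halogenated marine NPs), realistic MW
or property distributions beyond the designed contrasts, tautomer-rich
chemotypes, or measured solubility. Passing tests therefore demonstrate
that the machinery computes the right quantities and recovers designed
signals — not that any particular real library is diverse or NP-like.

## Pipeline and problem sizes

`run_pipeline` derives every stage seed from one master seed (SHA-256 of
`"{seed}:{stage}"`, truncated below 2³¹), caches artifacts per stage and
hashes the report (floats rounded to 6 decimals) so reruns under one
configuration are bit-identical. The default acceptance/characterization
conditions are two libraries of 300 molecules, diversity sampling at
5 × 1000 on a 1500-molecule set, NP-likeness training at 300 + 300 with
200 + 200 held out, PCA diagnostics at n = 500, and t-SNE at n = 240 —
sizes at which every designed contrast is comfortably detectable.

## Known limitations

- The NP-likeness scorer is a reimplementation of the scoring *scheme*; it
  is not trained on the published reference corpora, so absolute scores are
  comparable only within one trained model.
- RECAP leaves come from single-pass simultaneous cleavage; rule sets with
  context that spans a cut bond could in principle differ from recursive
  decomposition (none of the shipped rules do).
- Ring-system and scaffold keys are constitution-level (stereo-stripped);
  tautomer-insensitive matching of annotation tables is off by default.
- MACCS keys and ECFP bit assignments follow RDKit; similarity values, not
  individual bit identities, are the supported contract.
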