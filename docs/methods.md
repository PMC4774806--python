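# Methods

## Fixed-difference marker model

A diagnostic marker is defined combinatorially, not statistically: a
column is diagnostic for the focal group iff the focal sequences are
fixed for one unambiguous base, the pooled non-focal sequences are fixed
for a single different unambiguous base, and the column survives the
gap/ambiguity policy. No allele-frequency threshold is applied — one
discordant sequence disqualifies the column. This is deliberate: a
forensic marker is only useful if it holds for *every* observed sequence,
and the sample sizes involved (tens of sequences) are too small for
frequency-based diagnosability to add anything but false confidence.

Two policies govern columns containing gaps or IUPAC ambiguity codes:

* `strict` (default): any gap or ambiguity anywhere in the column
  disqualifies it. This is the conservative forensic default.
* `permissive`: sequences contributing a gap or ambiguity code at the
  column are ignored, provided at least one informative sequence remains
  in each group. All ambiguity codes are treated alike (an R is not
  "half an A"); a partially determined base is simply uninformative.
  The permissive marker set always contains the strict set.

Columns where a group is fixed for a gap are never markers (indels are
out of scope), and columns that align to a gap in the reference sequence
are skipped because they have no reference coordinate to report.

### Coordinates

Marker positions are 1-based on the forward strand of a designated
reference (GenBank numbering, e.g. EF375877 for the pig mitogenome),
obtained by counting non-gap reference columns and adding a configurable
offset. The offset is a parameter rather than a constant because the
fragment boundary conventions of published coordinate spans are often
off-by-one ambiguous; internal column indices are 0-based throughout.

### Substitution direction

Markers record the substitution as `background>focal` (the allele carried
by all other sequences, then the allele fixed in the focal taxon). The
published marker tables this package mirrors do not state their polarity;
one convention was chosen and is used consistently everywhere (reports,
truth tables, the bundled panel in `fixmark.assay`). The pairing-class
census is polarity-invariant, so this choice affects labels only.

### Spectrum percentages

Class percentages are round-half-up of 100·count/total, reported as
integers without renormalization to 100 (9/15, 4/15, 2/15 naturally give
60 + 27 + 13 = 100). Round-half-up rather than banker's rounding keeps
12.5% at 13.

## Synthetic data generator

`simulate_alignment` emulates a species-identification study design:

| parameter | default | meaning |
|---|---|---|
| `reference_length` | 735 bp | fragment length (D-loop study fragment) |
| `gc_fraction` | 0.40 | i.i.d. base composition of the reference |
| `group_sizes` | focal 14, other 44 | the 58-sequence study layout |
| `planted_markers` | 4 D-loop markers (149 A>G, 322 A>G, 407 T>A, 675 C>T) | ground-truth fixed differences |
| `within_group_mutation_rate` | 0.01 /site | within-group polymorphism (~99% intra-group identity) |
| `tsv_bias` | 0.9 | probability a within-group mutation is a transition (mtDNA transition bias) |
| `ambiguity_rate` | 0.0 | per-site probability of an N |
| `seed` | 0 | single global seed |

Generation order is fixed (reference, then groups in sorted order, each
sequence site by site, mutations before ambiguities), and all draws come
from one `numpy` generator stream, so identical configs give
byte-identical output. Within-group mutations and N injections are
rejection-sampled away from planted columns, so the returned truth table
is exact by construction; the behavior of discovery on *corrupted* marker
columns is exercised by dedicated fixtures instead. Output is gapless
(column k ≡ reference position k+1); gap handling is tested separately by
injecting gap columns, which keeps coordinate-mapping tests independent
of discovery tests.

What the generator does **not** emulate: phylogenetic correlation between
sequences (every sequence is an independent perturbation of its group
consensus), indels, recombination, and position-dependent mutation rates.
Passing recovery tests therefore demonstrate the correctness of the
fixed-difference logic, not robustness to tree-structured polymorphism —
on real data, shared derived alleles within the background group are
common and are handled by the same fixation test, but no claim about
discovery power on real alignments follows from the simulations.

## In-silico PCR

Primer sites are located on both strands by Hamming distance, with IUPAC
codes in the primer matching their base sets; ambiguity codes in the
*template* never match (conservative). The 3'-terminal
`require_exact_3prime` bases (default 3) must match exactly, modeling the
polymerase's intolerance of 3' mismatches; defaults assume perfect
"universal" primers (`max_mismatches=0`), with tolerance opt-in.

The amplicon runs from the forward primer's 5' footprint edge to the
template position pairing with the reverse primer's 5' end — both primer
footprints included, the standard product-size convention, so the
predicted length matches what a gel shows. Amplification is
orientation-symmetric: the pair is also tried with roles swapped (reverse
primer on the top strand), which is what makes extraction commute with
reverse-complementing the template. Exactly one compatible, non-
overlapping placement must exist; zero placements and multiple placements
are distinct errors, the latter listing every candidate product.

## Restriction digestion

Enzymes are modeled as a recognition word (IUPAC-degenerate, length ≥ 4)
plus top- and bottom-strand cut offsets measured from the recognition
start on the top strand; BsrI is ACTGG(1/-1), i.e. offsets (6, 4), and
the bottom-strand spelling CCAGT is accepted as an alias. Scanning
reports every (possibly overlapping) match on the forward strand and — 
for non-palindromic enzymes — every match of the reverse-complement word,
whose top-strand cut is the mirrored bottom-strand offset
(`start + len − 1 − cut_bottom`). Palindromic recognition is reported
once per locus.

Fragment sizes are computed from top-strand cut positions only: gel
mobility reflects overall length and ±1 nt sticky-end bookkeeping is far
below gel resolution. Cuts that would fall beyond either end of the
molecule are clamped to the boundary — there is no phosphodiester bond to
cleave — which keeps site counts strand-symmetric; boundary cuts produce
zero-length fragments, which are dropped. Linear digests therefore have
exactly (distinct interior cuts + 1) fragments summing to the sequence
length; circular digests have one fragment per cut (one fragment total
when uncut).

Pattern comparison asks whether two fragment multisets would look
different on a gel: fragments are matched greedily in sorted order and
two lengths co-migrate when they differ by at most the resolution. The
default resolution is adaptive — 5% of the larger fragment or 10 bp,
whichever is larger — approximating agarose resolving power; a fixed bp
value can be supplied instead. Enzyme screening requires every focal
pattern to differ from every background pattern *and* each group to be
internally consistent, then ranks discriminating enzymes by fewest total
sites (the cheapest, least fragmented assay) and name.

Templates containing ambiguity codes are rejected by default to avoid
phantom sites; with `allow_ambiguous` the ambiguous positions simply
never match.

## Numerical and degenerate-input choices

* FASTA is parsed with Bio.SeqIO ('>' headers, id = first token); output
  wraps at 70 columns; residues are uppercased on read and validated
  against IUPAC DNA + '-'. Gaps are accepted only in alignment inputs;
  PCR and digestion templates must be gapless.
* Alignments need ≥ 2 records of identical length and unique ids.
* Determinism: every stochastic component takes an explicit integer seed
  and uses `numpy.random.default_rng`; two runs with the same
  configuration produce byte-identical files.
* `plant_recognition_sites` constructs templates whose digest is known by
  design: it scrubs accidental occurrences of the recognition word and
  its reverse complement by redrawing single bases (bounded iteration),
  then writes the word at the requested starts. Constructed stand-ins for
  sequences that are not bundled are always labeled as such.
* Problem sizes in the test-suite simulations (58 × 735 bp alignments,
  100 × 2 kb digest randomizations, 20-seed recovery sweeps) mirror the
  study scale, which is small enough that exhaustive per-column scanning
  is the clearest correct implementation; no indexing or vectorization
  was warranted.

## Known limitations

* Single focal taxon per pass; multi-taxon diagnosis requires one run per
  taxon.
* No thermodynamic primer model (Tm, ΔG, secondary structure) — binding
  is purely sequence-identity based.
* No partial digestion, methylation sensitivity or star activity.
* The bundled 15-marker panel is reference data for the Indian wild pig
  assay; its coordinates are meaningful only on the EF375877 numbering.
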