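# Methods

This note records the scientific model behind `uhpscan`, the parameter
choices and their defaults, what the synthetic data generator does and does
not emulate, the numerical decisions, and the known limitations.

## Biological model

Some genes carry a pair of adjacent exons that arose by tandem
duplication and are spliced mutually exclusively: each coding transcript
includes one exon or the other, so the two protein isoforms are identical
except for the segment encoded by the substituted exon.  We call the two
isoform-specific polypeptide segments the event's **UHP regions** (unique
homologous polypeptide regions): unique to one isoform, homologous to each
other.  `uhpscan` detects such events from gene annotation and
characterises the UHP pairs at the sequence, structure, functional-residue,
and expression levels.

## Event detection (`uhpscan.events`)

A candidate is a pair of distinct CDS of one gene that passes three
predicates:

1. **Consecutive.**  The gene's distinct CDS (unique genomic
   `(start, end)` intervals across its coding transcripts) are ordered
   genomically; a candidate pair is two non-overlapping CDS with no third
   distinct CDS strictly between them.  Adjacency is therefore defined on
   the gene's CDS *loci*, not within any single transcript, so mutually
   exclusive exons — which never co-occur in one transcript — still form
   candidate pairs.
2. **Mutually exclusive.**  Counting the gene's coding transcripts that
   contain exactly one of the pair versus both: the event is accepted only
   when `a_only + b_only > both` (strict majority).  Ties fail.
3. **Homologous.**  The two encoded peptides (each at least
   `min_uhp_len = 7` residues) are aligned locally (BLOSUM62, gap open 11,
   extend 1) and the observed score is compared with scores obtained after
   shuffling one sequence `n_shuffles = 99` times.  The empirical p-value
   is `(1 + #{shuffled >= observed}) / (n_shuffles + 1)`, the standard
   add-one permutation estimator, and the pair is accepted at
   `empirical_p <= 0.01`.  With 99 shuffles the smallest attainable p is
   exactly 0.01, so acceptance requires the observed score to beat every
   shuffle.  The shuffle test is sequence-composition aware: low-complexity
   pairs score high against their own shuffles only if their similarity
   exceeds what composition alone explains — but a repeat aligned to its
   own reversal is genuinely indistinguishable from homology at this level
   (see Limitations).

Each accepted event is assigned a **position class**.  A pair is
N-terminal if one of its CDS is the 5'-most CDS of any transcript,
C-terminal for the 3'-most, internal otherwise, and full-protein when the
isoforms consist of the substituted CDS alone.  When statuses conflict
across transcripts the precedence is full-protein > N-terminal >
C-terminal > internal.  Expected class counts under a uniform
random-position model are proportional to the number of CDS loci of each
class in the annotation, counting only internal CDS of at least 21 nt
(shorter internal CDS cannot encode a testable UHP region); the
observed-vs-expected contrast uses an exact multinomial test up to n = 300
events and a chi-squared test beyond.

## UHP alignment and substitution scoring (`uhpscan.alignment`)

Accepted UHP pairs are realigned globally (Needleman-Wunsch, BLOSUM62,
gap open 10, extend 1); each column is classified conserved (identical
residues), changed (aligned but different), or gapped.  The unknown
residue `X` is never counted conserved.  Changed columns are scored with
the **McLachlan (1972)** amino-acid similarity matrix, shipped as package
data and verified to round-trip against the Biopython distribution of the
same matrix.  Two summaries are reported:

- the pooled mean McLachlan score over all changed columns (column-
  weighted; an event-weighted variant is available), compared against the
  **matrix background**: the unweighted mean over the 190 unordered
  non-identical amino-acid pairs, which is 2.41 (2.4 at one decimal);
- the per-amino-acid **gain profile**: for residues of type *a* in side A
  of changed columns, the mean observed score minus the mean of row *a*
  of the matrix over the other 19 amino acids.  Positive gain means the
  observed substitutions are more conservative than a random replacement.

## Structural features (`uhpscan.structure`)

Models are read from PDB or mmCIF with the per-residue confidence
(pLDDT, 0-100) taken from the CA B-factor column, the convention used by
predicted-structure archives.  Long proteins split across chunked model
files are merged by a manifest of `(path, start_offset)`; on overlap the
earlier file wins.

- **Disorder**: a residue is disordered iff it lies in a run of at least 3
  consecutive residues with pLDDT <= 50 (boundary inclusive).
- **Accessibility**: Shrake-Rupley ASA (probe 1.4 Å, 960 sphere points per
  atom, delegated to Bio.PDB), normalised by the Tien et al. (2013)
  theoretical maximum ASA and clipped to [0, 1]; exposed iff RSA >= 0.2.
- **Secondary structure**: 8-state strings collapse to helix (H, G, I),
  strand (E, B), coil (everything else).  When no 8-state assignment is
  available, a dihedral fallback computes phi/psi from backbone
  coordinates and assigns helix for phi in [-100, -30] and psi in
  [-80, -5], strand for phi in [-180, -90] with psi >= 90 or <= -150,
  coil otherwise (termini are coil).

The display isoform modelled by a structure carries at most one UHP side;
`resolve_uhp_in_model` locates it by exact substring match, then by a
windowed match tolerating up to 2 mismatches.  If both sides match
(overlapping annotation), the side with the lower disordered fraction is
kept; if neither matches the event is excluded with a reason code.  The
exposure analysis removes disordered residues first — their coordinates
are not physically meaningful — then contrasts exposed/buried counts
inside versus outside UHP regions with a chi-squared test (no Yates
correction, Fisher fallback when a margin is zero).

## Binding-residue overlap and conservation (`uhpscan.functional`)

Predicted ligand-binding residues (protein, 1-based position, ligand) are
intersected with the residue annotations.  Two questions are asked: are
binding residues depleted inside UHP regions (Fisher's exact test on the
binding/other × in/out table, restricted to proteins that have
predictions), and are binding residues that do fall inside a UHP region
preferentially conserved between the two sides (Fisher contrast of
conserved fractions over binding versus non-binding UHP columns, with a
gap counting as not maintained)?

## Peptide evidence and tissue specificity (`uhpscan.proteomics`)

Evidence records are (peptide, posterior error probability, experiment,
tissue).  Filters, applied order-independently: PEP <= 0.001; the peptide
is a fully tryptic fragment (cleavage after K/R except before P, at most
one missed cleavage, length >= 7) of an isoform of its mapped gene; the
peptide maps to exactly one gene in the proteome; and it is detected in at
least 2 distinct experiments.  A **discriminating peptide** for a UHP side
is a tryptic peptide of that side's isoforms that overlaps the UHP region
by at least one residue (junction-spanning peptides count), occurs in no
isoform of the other side, and in no other gene.

The **PEC** (peptide experiment count) for an (event, side, tissue) is
the number of distinct (peptide, experiment) detections.  For each event
with at least `MIN_PEC = 3` total PECs on *both* sides, a Fisher's exact
test contrasts side-A versus side-B PECs in each tissue versus all other
tissues, and likewise for each of the 13 configured tissue groups (PECs
pooled over member tissues).  An event is called tissue-specific when any
of these tests has raw two-sided p < 0.05, with the direction given by the
over-represented side.  Benjamini-Hochberg adjusted p-values across all
evaluable tests are attached for transparency but do not drive the call —
this mirrors the screening character of the analysis; see the calibration
note below.

### Calibration of the specificity test

Because each event is subjected to ~39 tests (26 tissues + 13 groups), the
event-level probability that *some* test fires under the null is far above
the per-test alpha; "any tissue anywhere" is not a calibrated family-wise
claim and is not advertised as one.  The quantity we calibrate is the
**directed call rate**: the probability that a given event is called
specific for a *particular pre-specified group with a particular side*.
`simulate.specificity_power` measures exactly this on synthetic evidence:
at effect size theta = 1 (no planted effect) the directed false-call rate
stays below alpha = 0.05 (measured ~0.01 with 500 events), and the rate
rises monotonically with the planted odds ratio theta (about 0.04, 0.13
and 0.40 at theta = 2, 4, 8 under the default detection profile).

## Synthetic data generator (`uhpscan.simulate`)

The generator produces a complete miniature study; its defaults are the
study conditions and are never tuned to make tests pass.

- **Annotation**: each gene gets its own contig.  Event genes carry two
  adjacent duplicated CDS (side B derived from side A by per-residue
  substitution at rate `uhp_divergence = 0.2`) spliced mutually
  exclusively across two transcripts, at an N-terminal / internal /
  C-terminal position drawn from `position_mix = (0.17, 0.50, 0.33)`.
  Decoy classes: duplicated but always co-annotated; duplicated but
  non-adjacent; adjacent but non-homologous; ordinary genes.  Genes are
  placed on the minus strand with probability 0.5 by mirroring the contig.
- **Structures**: backbone models built by internal-coordinate chain
  extension (NeRF; bond lengths N-CA 1.458, CA-C 1.525, C-N 1.329 Å;
  angles 111.2/116.2/121.7 degrees; omega 180), with a helical core
  (phi, psi = -57, -47) and an extended disordered C-terminal tail
  (-139, 135) of 4-12 residues; pLDDT drawn from N(90, 5) in the core and
  N(30, 5) in the tail and written to the B-factor column.
- **Evidence**: 26 tissues in 13 groups of two, 4 experiments per tissue;
  each (peptide, experiment) detection is Bernoulli at baseline rate 0.08;
  a planted specific event multiplies the favoured side's detection odds
  by theta in the target group's experiments.  10% of records draw a PEP
  above the cutoff; passing records draw PEP uniformly below 0.0009 so
  the filter boundary is never probed by generator noise.
- **Binding**: positions drawn uniformly at density 0.05.

What the generator does **not** emulate: splice-site sequence, UTRs and
non-coding transcripts, overlapping genes, sequencing or annotation error,
homology decayed by indels (divergence is substitution-only), real
pLDDT correlation structure, peptide detectability bias (length, charge,
hydrophobicity), or between-experiment batch effects.

## Numerical choices

- **Fisher's exact test** (two-sided, conditional) is computed from
  hypergeometric pmf vectors cached per margin triple, summing the
  probabilities at or below the observed table's probability with a
  relative tolerance of 1e-7 for ties.  This reproduces the standard
  two-sided definition (verified exhaustively against integer-arithmetic
  enumeration on all tables with total <= 60 and against
  `scipy.stats.fisher_exact` spot checks) while being fast enough for
  hundreds of thousands of calls.
- **Exact multinomial** enrichment p-values are computed by full
  enumeration for up to 300 events and 3 classes; larger problems use the
  chi-squared approximation.
- **Alignment** delegates to Biopython's `PairwiseAligner`; the first
  reported optimal alignment is taken, which is deterministic for a fixed
  Biopython version.  Scores are validated against an independent affine
  gap-penalty recursion.
- **Randomness**: every stochastic step takes an explicit seed; derived
  seeds are kept below 2^31.  Re-running any pipeline or script with the
  same seed reproduces outputs byte-for-byte.

## Limitations

- The homology shuffle test cannot reject a low-complexity repeat aligned
  to a rearrangement of itself; with 99 shuffles a truly non-homologous
  adjacent pair still passes with probability about 1/100.  Candidate-level
  curation (and, in the synthetic study, the decoy classes) bounds the
  impact.
- Tissue-specific calls based on raw p-values are a screen, not a
  family-wise claim; only the directed call rate is calibrated.
- The dihedral secondary-structure fallback is a coarse stand-in for DSSP
  and should not be used for fine-grained structural claims.
- Synthetic structures are backbone-only; RSA values are computed without
  side chains and are interpreted only relative to each other.
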