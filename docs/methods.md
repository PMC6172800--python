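# Methods

`debra` is a conservative DeBruijn-graph assembler for short Illumina-style
reads.  Its design goal is base-level correctness and bit-reproducible
output rather than maximal contiguity: every decision that could join two
sequences is taken only when the read evidence supports exactly one
resolution, and every ambiguous decision breaks the contig instead.  This
note records the model, the auto-detected parameters, the numerical and
design choices that were genuinely open, and what the simulated test sets
do and do not demonstrate.

## The assembly model

Reads are decomposed into k-mers packed two bits per base, first base most
significant, so numeric order of the packing equals lexicographic order of
the string; k ≤ 32 fits one 64-bit word and longer k-mers use several
words compared most-significant first.  A k-mer and its reverse complement
are collapsed onto the canonical (lexicographically smaller) form, keeping
separate plus- and minus-strand observation counts; a self-complementary
window counts as plus.  Counting is the sorted-array method: all windows of
all available reads are packed, canonicalized and sorted, and runs are
reduced to `(plus, minus)` counts.  Counting can be partitioned into hash
batches (each k-mer lives wholly in one batch) whose merged result is
provably independent of the partitioning — this is how a `--cores` setting
can never change the output.

Assembly iterates over a ladder of k sizes.  At each k, a graph is built
from the k-mers (count ≥ C_min) of the reads still in play, contigs from
the previous iteration are re-threaded (their k-mers claimed first, making
merging order-independent) and extended at both ends, and new contigs are
seeded from every unused k-mer with count above the per-iteration valley,
in ascending canonical order — the determinism anchor that replaces
thread scheduling.

A one-base extension faces three cases: no candidate (dead end), a single
candidate, or alternates.  Alternates pass three filters:

1. **count** — candidates with total count below `ext_frac` (default 0.1)
   of the best candidate are noise;
2. **strand** — if any candidate is balanced across strands, candidates
   seen predominately on one strand are dropped, targeting the
   strand-specific systematic errors of Illumina chemistry.  "Predominately
   one strand" requires both a minor-strand fraction below `balance_frac`
   (0.25) *and* statistical significance of the skew under fair strand
   sampling (exact binomial tail ≤ 10⁻³; any sub-25% minor strand is
   automatically significant beyond ~40 observations).  Without the
   significance clause, thin coverage at large k occasionally produces a
   chance 1:10 strand split on the *true* base, and the filter would then
   hand the extension to a low-count contaminant candidate;
3. **bounded path exploration** — each remaining choice is walked forward
   up to max(100, k) steps under the same filters; a walk survives by
   reaching the cap or forking again, and dies at a dead end.  Exactly one
   survivor resolves the fork; anything else breaks the contig.

Ownership of k-mers by other contigs is deliberately ignored during these
exploration walks: a claimed path is evidence like any other, and treating
it as dead would steer forks toward unclaimed — typically erroneous —
branches near contig seams.

Every accepted base must additionally pass **bidirectional verification**:
extending backwards from the new k-mer through the same cascade must
uniquely reproduce the previous k-mer.  This check runs before the
ownership logic, so a merge with another contig and a circular self-join
must also survive it; without this, a low-coverage stub could bridge two
contig ends through merges on both sides and smuggle unverified sequence
into the assembly.  Each k-mer joins at most one contig per iteration:
running into another contig's terminal k-mer merges the two, running into
its interior stops extension, and running into the contig's own first
k-mer closes it as circular.

When an end can no longer be extended, its **last k bases are removed**:
the final k-mer of a stopped end (in the worst case the seed k-mer itself)
was never confirmed from the other direction.  An earlier variant trimming
k−1 bases retains exactly one unverified base of a contaminant-seeded stub
and was observed to leak single false bases at contamination seams.  For
contigs carrying prior-iteration sequence the trim is capped at the number
of bases added in the current iteration, so a finished contig is never
eroded by re-threading.  New contigs shorter than k after trimming are
dropped.

Final output keeps only contigs of at least `--min_contig` (default 200)
bases (circular contigs always pass): below that length a free-standing
contig is usually an unverifiable stub — in particular, a cluster of
nearby contaminant variants can build a coherent variant chain just long
enough to survive the end trims, and the length floor is what keeps such
chains out of the assembly.  Output is canonical: each linear contig keeps
the orientation whose first K_min-mer is smaller; each circular contig is rotated to start at the
globally smallest k-mer over both strands; contigs are sorted by sequence
and named `Contig_N_C` (N the 1-based ordinal, C the mean K_min-mer count
to one decimal), circular ones suffixed `_Circ`, 80-column FASTA.

## Read trimming

A 19-mer present in at least `V_f` (default 0.05) of the mates, in either
orientation, is *suspect* (adapter/vector signal); each mate is clipped at
the first suspect 19-mer, removing it and everything after.  The census is
per-read presence, not per-occurrence, matching how adapter contamination
manifests; because it is orientation-symmetric, the suspect set is closed
under reverse complement and a canonical-key scan equals a forward-strand
scan.  Note a practical floor on toy problems: a repeat occupying more
than ~V_f of a (tiny) genome is indistinguishable from an adapter by this
census, so simulated fixtures keep repeats below that fraction, as they
are in real genomes.

## Parameter auto-detection

From the K_min (default 21) spectrum of the trimmed reads:

* **peak/valley/G** — multiplicities are smoothed with a centered moving
  average (window 5, shrinking at the edges to avoid a fake rise at count
  1).  The first strict rise from the running minimum ends the initial
  descent; the main peak is the smoothed argmax beyond it; the valley is
  the largest count achieving the smoothed minimum between the two —
  i.e. the left low end of the genomic distribution, robust both to
  jitter on the peak's flank and to a secondary low-count contaminant
  mode.  G is the number of distinct k-mers above the valley.  A monotone
  spectrum has no peak; then G falls back to 80% of all distinct k-mers
  and the valley is 0.
* **C_min** = max(2, T/(G·50)) and **C_max** = max(10, T/(G·10)), floored,
  with T the total trimmed bases — higher-coverage runs tolerate a higher
  noise floor.
* **K_max** starts at the mean mate length A_read and decreases in steps
  of max(1, round(A_read/25)) until the mean count of k-mers (count ≥
  C_min) reaches C_max; the ladder is S (default 11) odd values spread
  evenly over [K_min, K_max] (nearest-odd rounding, ties down; endpoints
  as given), collapsing to [K_min] unless K_max > 1.5·K_min.
* **I** (paired runs) is the median fragment length over a fixed-seed
  sample of up to 10,000 pairs connected through the K_min graph; fewer
  than 100 connections is an error advising `--insert_size`.  While I is
  unknown the search is capped at 4 mate lengths, a generous prior for
  Illumina libraries.  The maximal insert for all later searches is 3·I.

## Retiring reads and longer-than-mate k-mers

After each iteration a read whose k-mers sit deeper than the buffer zone
M = I + 50 + F inside a contig (F = K_max for input reads, 0 for
pair-assembled fragments; any position of a circular contig counts as
deep) is retired — its information is already consumed, while reads near
contig ends keep feeding later iterations.  A read retires only if it has
at least one contig match and every matching k-mer is deep.

After the mate-length ladder, every still-available pair becomes one
fragment: pairs whose mates both map inside one contig are replaced by the
contig window spanning them; the rest are connected by exhaustive path
enumeration between the last k-mer of mate 1 and the first k-mer of
mate 2, bounded by 3·I total length and 1000 live paths, accepted only
when both directions yield exactly one path and the two agree.  The
fragment store then drives up to three iterations at k sizes
{1.25·K_max, (1.25·K_max+I)/2, I} (odd-rounded, capped at I) — k-mers
longer than any mate, able to span repeats shorter than the insert but
longer than the reads.  These graphs use a count floor of 1 and valley 0:
fragments are already assembled evidence with multiplicity ~1 wherever
contig windows stand in for retired pairs.

Because fragment evidence is thin, the long-k phase is held to stricter
rules than the mate ladder.  First, a connected fragment may not introduce
K_min k-mers with counts at or below the spectrum valley: below-valley
k-mers are untrusted for starting new sequence, and a "unique" gap-filling
path supported only by them is precisely how carryover-contaminant pairs
(whose variant anchors make their path search unambiguous while the
corresponding clean pairs see two paths and fail) would write variant
bases into a junction.  Second, walk-based fork resolution is disabled —
with multiplicity-1 evidence, "whose chain is longer" says nothing about
which branch is real, so any surviving fork breaks.  Third, terminally
stopped long-k extensions are rolled back entirely: the phase exists to
join contigs across repeats, and a dangling fragment-derived extension
that joined nothing is unconfirmable duplication.  Merges and circular
closures keep their gains.

## Simulated study sets and the evaluator

* **substrings set** — every length-K window of a genome, one read per
  position (circular wraparound), reads at even 0-based positions reverse
  complemented.  Error-free; per-base coverage is exactly K; exercises
  both strand counters and the full parameter machinery at 131 possible
  read lengths.
* **contamination set** — clean 2×150 bp pairs with exact 300 bp inserts
  uniformly covering the genome at 60×, plus pairs from a copy of the same
  genome with 0.1% of positions substituted, at 0–15×, emulating low-level
  carryover from a previous sequencing run.  The sweep generator draws the
  contaminant pool once and gives each level a prefix of it, so per-site
  contaminant depth is monotone across levels (a paired-simulation
  variance-reduction design; real carryover sets are independent draws).

Neither set models sequencing errors, quality values, insert-size jitter
or coverage bias; passing them demonstrates the zero-error and
conservatism properties of the algorithm, not performance on real
libraries.  Desk-scale genome length is 50 kb (seeded, uniform random) —
large enough for the full k ladder, small enough that the whole pipeline
runs in tens of seconds per set on one CPU; real microbial genomes are two
orders of magnitude larger.

The evaluator aligns each contig to the reference with edlib, end-gap-free
on the reference, both strands, circular references doubled so rotations
score cleanly.  A contig aligning as one block at ≤5% edit distance
contributes its substitution count; otherwise it is split into 500 bp
chunks whose best placements are grouped into collinear same-strand blocks
(reference gap tolerance 1 kb, the conventional default for extensive
misassemblies), each extra block counting one misassembly; chunks above
30% error are unaligned and count into the total but not the aligned
length.  Reported: N50 (cumulative-half), total length L_A, aligned length
C_RA, substitutions per 100 kb of aligned sequence, misassemblies, and the
length deviation L_R + L_A − 2·C_RA.  This is a simplified scorer, not a
full QUAST: no NGA50, no local/relocation taxonomy, substitutions only
(indels score as edits but are not in the mismatch count).

## Known limitations

* Heuristic thresholds (`ext_frac` 0.1, `balance_frac` 0.25, path cap
  1000, step cap max(100, k)) are exposed but not auto-tuned.
* Sequencing-error robustness is asserted by design (count floor, strand
  filter, path exploration) but the shipped simulations are error-free.
* A repeat copy shorter than the current k survives as a small duplicate
  contig alongside the merged resolution of the repeat (total length can
  slightly exceed the genome; the evaluator's deviation can go negative).
* The contamination trend (contiguity flat to ~6×, degrading from ~9×)
  follows from the 0.1 noise threshold against 60× clean coverage; other
  coverage ratios shift the onset.
* Assembly is single-threaded; `--cores` only batches counting.  The
  determinism contract holds by construction rather than by lock-free
  coordination.
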