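# Methods

This note documents the model, the algorithmic choices and the limits of
what the test suite demonstrates.

## Problem and assumptions

The package assembles a double-stranded DNA target from error-free reads by
overlap–layout: exact suffix–prefix matches (SPMs) of length ≥ ℓ_min are
enumerated between all reads and their reverse complements, transitive
matches are discarded, and contigs are spelled from the resulting string
graph.  The central assumptions are:

* overlaps are **exact** — there is no error tolerance anywhere in the
  matching; sequencing errors fragment the assembly rather than corrupt it
  (the read simulator has a substitution-noise switch precisely to
  demonstrate this degradation);
* the read set after prefiltering is **suffix- and prefix-free**, which the
  overlap machinery exploits (a matching suffix can never start at read
  position 1, and a whole read equal to an interval prefix can only be an
  internal containment);
* reads are short relative to the data set (maximum read length treated as
  a constant in all complexity arguments).

## Prefilter

All 2m strands are sorted under the virtual-sentinel order: end-of-string
sorts after T, and per-strand sentinels are mutually ordered by strand
index.  Sentinels are never stored.  Under this order a proper prefix sorts
*after* all its extensions, and all strings sharing a prefix are
contiguous, so a single scan over consecutive sorted strands finds every
containment: a maximal run of identical strings triggers the duplicate
rule, and a run whose string is a proper prefix of the preceding longer
string marks every read in the run (on the forward strand this means
prefix containment, on the RC strand suffix containment).

Duplicates are resolved run-wise: the read with the smallest input index
among all reads represented in the run is kept.  A pairwise resolution
("mark the later of two equal neighbours") would delete *both* copies of a
duplicated reverse-complement-palindromic read, because the four identical
strands interleave in the run; the run-wise rule is the unique reading that
keeps exactly one copy in every case and coincides with the pairwise rule
otherwise.

## k-mer codes and filters

ϕ_k(s) = Σ_{i=1..k} 4^{k−i} ϕ(s[i]) with ϕ = [A→0, C→1, G→2, T→3] is
order-preserving and fits one 64-bit word for k ≤ 32.  The code of the
k′-prefix is a right shift by 2(k−k′) bits; the code of the initial
k-mer's k″-tail is a mask with 4^{k″}−1.  The membership sets P (all
initial k′-mer codes) and Q (all k″-tail codes) are stored as sorted unique
code arrays with vectorised binary-search membership rather than 4^{k′}-bit
vectors: for the default k′ ≈ log₂ n − 8 the bit vector would dominate
memory on multi-megabase inputs while the sorted array stays proportional
to the number of distinct reads; queries remain exact.

Defaults: k = min(ℓ_min, 32); k′ = clamp(⌈log₂ n⌉ − 8, 8, k);
k″ = max(k′ − 1, 1), where n is the total read length.  The clamps keep the
constraint chain k″ ≤ k′ ≤ k ≤ ℓ_min valid on arbitrarily small inputs.

## SPM-relevant suffix index

Counting and insertion both stream every proper suffix of length ≥ ℓ_min
through the P/Q filters in buffered batches (default capacity
max(1024, d/4) keys; results are provably batching-invariant and tested as
such).  Each batch is sorted and matched against the sorted key table K by
binary search; matches increment counts (counting phase) or are placed at
decrementing per-bucket cursors (insertion phase).  Partial sums follow the
inclusive recurrence π[0] = C[0], π[i] = π[i−1] + C[i], π[d] = π[d−1] = g;
bucket i occupies [π[i−1], π[i]) with π[−1] := 0.  Any mismatch between
counted and inserted occupancy raises a consistency error rather than
producing silent corruption.

Partitioning tiles K into q contiguous code ranges of roughly equal total
bucket size (greedy accumulation towards g/q, closing early when each
remaining part must still receive one bucket).  With a memory limit, q is
the minimal part count under a deliberately simple size model of 16 bytes
per suffix-store entry (two machine words: strand and offset); the
bit-exact packing of a production implementation is out of scope and the
model is documented rather than hidden.  Every part is processed by a full
re-scan of the read set, and the concatenated output is identical to the
single-part run — asserted byte-for-byte on the SPM and contig files.

Bucket sorting compares only the suffix remainders beyond the shared
initial k-mer, with the same sentinel rule as the prefilter; the lcp table
L (all values ≥ k within a bucket) falls out of the comparisons.

## lcp-interval tree traversal

The bottom-up traversal is the classic stack scheme — push an interval on
rising lcp, complete and pop on falling lcp — extended to deliver leaf
edges: the pending singleton between two interval events is attached to
the interval on top of the stack at the moment its position is passed (its
parent is determined by max(L[p], L[p+1])).  Children are always completed
before their parent sees the corresponding branch edge; callback counts
are bounded by 3β − 1 per bucket.  The emitted interval set is checked
against a naive O(β²) enumeration from the interval definition.  A
singleton bucket is delivered as one leaf edge from a degenerate root of
lcp 0 (no lcp evidence exists; downstream logic only requires that the
interval completes below ℓ_min).

## SPM enumeration and transitivity

Terminal edges (suffix ends exactly at interval depth) and whole-read
leaves are collected per the traversal; at each completed interval of
depth ≥ ℓ_min the cartesian product of pending terminal edges with the
interval's whole-read leaves yields SPMs in order of decreasing overlap
per destination.  Because sentinel-labelled edges sort after all
base-labelled edges, one global terminal list suffices, cleared at every
interval completion; the whole-read list is cleared when an interval
shallower than ℓ_min completes.

Transitivity uses the left-context criterion: the first SPM on a
whole-read path is irreducible; a later ⟨r, t, ℓ″⟩ is transitive iff a
stored left context LC(s, ℓ′) of an earlier irreducible ⟨s, t, ℓ′⟩ is a
suffix of LC(r, ℓ″).  The dictionary is a plain list with a linear
`endswith` scan (contract identical to a reversed-string trie; per-path
dictionaries are small at the scales handled here).  Equal-length SPMs to
one destination cannot suppress each other — a suffix relation between
their left contexts would imply one source read is a suffix of the other,
contradicting suffix-freeness — so their processing order is immaterial.

Design choices in this layer:

* **Self-overlaps** ⟨r, r, ℓ⟩ are not emitted; a self-loop has no use in
  the layout.
* **Containment before transitivity**: a first pass flags internally
  contained reads (whole-read leaf attached to an interval as deep as the
  read), a second pass enumerates with those reads' entries absent.  A
  consequence is that a transitive SPM whose middle read is contained is
  *not* suppressed — the clean semantics when the graph is defined over
  non-contained reads only.
* **Mirror filtering after classification**: every SPM appears twice in
  the two-strand enumeration; the non-redundancy conditions (both forward;
  or exactly one RC strand and the forward-strand read earlier in input
  order) are applied only after classification so that every whole-read
  path sees its complete source set.  Classification is mirror-consistent,
  which the oracle tests confirm.

## String graph and contigs

Two vertices per read (r.B, r.E), two complementary edges per
non-redundant irreducible SPM according to the three strand cases; an edge
into x.E carries the forward tail of x, an edge into x.B the
reverse-complement tail, so every walk spells a valid assembly (read
coherence is re-validated edge-by-edge in the tests).  Edges are stored in
a flat array grouped by source vertex via outdegree counting and partial
sums; edge complementing is an involution.

Contigs are maximal chains of *simple* edges — source outdegree 1 and
destination indegree 1.  This is deliberately stricter than "extend while
the next vertex is unbranched": merging an edge into a vertex of indegree
2 would copy the branching read into every walk that reaches it, whereas
under the simple-edge rule every read belongs to exactly one contig and a
branch point (e.g. a repeat boundary) starts a contig of its own.  An edge
and its complement are visited together, so each double-stranded contig is
reported once; reads covered by no chain become single-read contigs unless
internally contained.  The default contig length cutoff is ℓ_min + 1.
Graph cleaning (tips, bubbles) is intentionally absent; the traversal has
no hook for it and error-free inputs do not produce such artifacts.

## Synthetic data

`simdata` generates uniform i.i.d. random templates and samples error-free
reads uniformly in position and strand, with read count
⌈coverage·|template| / mean read length⌉ (defaults: 20× coverage, constant
100 bp, matching the standard benchmarking protocol for exact-overlap
assemblers); `tile_reads` places reads deterministically at a fixed step ≤
L − ℓ_min for coverage-guaranteed reconstruction tests.  What this
emulates — and what it does not: real reads carry errors, quality values,
non-uniform coverage and genomic repeats; random templates are essentially
repeat-free at k = 32.  Passing tests therefore demonstrate the
correctness of the exact-overlap machinery, not robustness to real
sequencing artifacts.  The substitution-noise option exists to demonstrate
degradation, and is off by default.

## Numerical and procedural choices

* All integer k-mer codes use unsigned 64-bit arithmetic (k ≤ 32).
* Ties between identical sequences anywhere are broken by strand index,
  making every output deterministic; SPM files are additionally sorted by
  (source id, strand, destination id, strand, −length).
* Buffered phases use numpy sorting and vectorised binary search; the
  per-batch mechanics differ from a hand-rolled merge scan but the
  counts/placements are identical and batching-invariant.
* Degenerate inputs: empty read sets raise explicit errors at the pipeline
  level; reads shorter than ℓ_min are dropped at ingestion; an all-N FASTA
  yields exit code 2 from the CLI.

## Problem sizes used in the automated checks

Oracle-agreement runs use ~100 simulated sets of 20–200 reads (lengths
30–120, ℓ_min ∈ {15, 25, 45}); partition invariance uses 1 Mb of reads
(20× over a 50 kb template); reconstruction uses 20 templates of 5–20 kb;
the runtime-growth check spans 1–8 Mb of total read length and asserts a
log-log slope below 2.  These sizes were chosen so the whole suite
completes in a few minutes on one core while still exercising every code
path at four orders of magnitude below production scale.

## Known limitations

* No error-tolerant overlaps, no scaffolding, no consensus polishing
  (exact single-strand overlaps make consensus trivial).
* The memory model behind `--memlimit` is a coarse per-entry estimate, not
  a bit-exact accounting.
* Contig extraction reports unitigs only; repeat resolution beyond
  branch-point splitting is out of scope.
* The prefilter's duplicate rule keeps the earliest copy; no coverage or
  quality information is consulted.
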