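# spmgraph

String-graph *de novo* sequence assembly from exact suffix–prefix matches.

`spmgraph` is for people who want a transparent, fully tested implementation
of the overlap–layout approach in which the overlap phase never materialises
the full overlap graph: it enumerates only the **irreducible** suffix–prefix
matches (SPMs) between reads, builds the assembly string graph directly from
them, and spells contigs as maximal unbranched walks.

## The method

Given reads R = (r₁, …, r_m) over {A,C,G,T} and a minimum match length
ℓ_min, an SPM is a triple ⟨r, r′, ℓ⟩ such that the length-ℓ suffix of r
equals the length-ℓ prefix of r′, ℓ ≥ ℓ_min.  An SPM ⟨r, t, ℓ″⟩ is
*transitive* if SPMs ⟨r, s, ℓ⟩ and ⟨s, t, ℓ′⟩ exist with ℓ + ℓ′ = |s| + ℓ″;
otherwise it is *irreducible*.  Only irreducible SPMs become string-graph
edges.  The pipeline:

1. **prefilter** — reads plus their reverse complements are sorted under a
   virtual-sentinel order (A < C < G < T < $₁ < $₂ < …); duplicates and
   reads that are prefixes or suffixes of other reads are removed in one
   scan over lexicographically consecutive strands.
2. **overlap** — every *SPM-relevant suffix* (a whole read, or a proper
   suffix of length ≥ ℓ_min whose initial k-mer equals some read's initial
   k-mer) is located via order-preserving integer k-mer codes
   (ϕ_k(s) = Σᵢ 4^(k−i)·ϕ(s[i]), with prefix/suffix filter codes derived by
   bit shift and mask), counted and inserted into per-k-mer buckets by a
   counting-sort strategy, and each sorted bucket is traversed bottom-up
   through its lcp-interval tree.  Completed intervals of depth ≥ ℓ_min
   yield SPMs as cartesian products of terminal edges and whole-read
   leaves; transitive SPMs are recognised on the fly by left-context
   dictionaries (the left context LC(s, ℓ) = s[1..|s|−ℓ]; an SPM is
   transitive iff a stored irreducible left context for the same
   destination is a suffix of its own), and exactly one of each
   reverse-complement mirror pair is kept.  Internally contained reads are
   detected in a first pass and excluded.
3. **assembly** — two vertices per read (r.B, r.E) and two complementary
   edges per irreducible SPM form the string graph; contigs are maximal
   chains of unambiguous edges (source outdegree 1, destination indegree
   1), each reported once per double-stranded path.

The key/bucket tables can be tiled into q contiguous code-range parts that
are processed independently to bound memory; all outputs are invariant
under q.

## Worked example

```sh
$ printf '>r\nTGGACGT\n>s\nGGACGTAA\n>t\nACGTAACC\n' > trio.fa
$ spmgraph prefilter trio.fa --min-length 4 --out trio.rs
$ spmgraph overlap trio.rs --min-length 4 --kmer 4 --kprime 4 --kdblprime 3 \
    --forward-only --spm-out trio.spm
$ cat trio.spm
1	+	2	+	6
2	+	3	+	6
$ spmgraph assembly trio.rs trio.spm --contig-out trio.contigs.fa --min-contig-length 1
$ cat trio.contigs.fa
>contig_1 length=11 reads=3
TGGACGTAACC
```

Three SPMs exist here: ⟨r, s, 6⟩, ⟨s, t, 6⟩ and ⟨r, t, 4⟩.  The last is
transitive (6 + 6 = 8 + 4, i.e. it is implied by the chain through s) and is
suppressed, so the SPM file holds the two irreducible matches; the string
graph has 6 vertices and 4 edges (two per SPM) and spells the single 11 bp
contig `TGGACGTAACC` laying out r, s, t at offsets 0, 1, 3.

The same pipeline runs in one shot (`spmgraph pipeline reads.fa --contig-out
contigs.fa`), and `spmgraph simreads` generates error-free benchmark read
sets from random templates (e.g. `--length 50000 --coverage 20
--read-length 100`).  `spmgraph verify reads.fa` cross-checks the
enumeration against quadratic brute-force oracles on small inputs.

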