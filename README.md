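# hitcluster

Cluster and annotate the hits of a protein BLAST search.

A similarity search against a modern protein database returns hundreds or
thousands of hits, and reading them linearly hides their structure: a
query's orthologs, its paralogs, distant ancestors and truncated
fragments are interleaved in one bitscore-ordered list. `hitcluster`
post-processes the hit list instead of pre-clustering the database: it
retrieves the hit sequences, groups them on the fly with a greedy
two-pass algorithm, annotates each group (joint taxonomy, domain
architectures, PDB entries, length range), and lets you re-cluster at a
different identity cutoff instantly, without repeating the search.
It is a library plus a small CLI, aimed at anyone who runs `blastp` and
wants the result organized by protein family rather than by score.

## The algorithm

**Pass 1 (length-constrained greedy clustering).** Hit sequences are
sorted by length, descending. The longest remaining sequence becomes a
cluster representative; every remaining sequence joins it if

1. it is *less than* 32 residues shorter than the representative, and
2. its percent identity to the representative reaches the effective
   threshold

   t(L) = max( c , R(L) ),

   where *c* is the user cutoff (default 53 %) and *R(L)* is the
   twilight-zone ("Rost") curve evaluated at the alignment length *L*:

   R(L) = 480 · L^(−0.32·(1 + e^(−L/1000)))   for L ≤ 450,

   constant (≈ 19.5 %) for longer alignments. The curve is a floor:
   lowering *c* below it has no effect, because short alignments need
   high identity before they mean homology.

Absorbed sequences are removed and the procedure repeats until none
remain.

**Pass 2 (singleton rescue).** Clusters left with a single member are
usually fragments or splice variants that failed the length rule. Each
singleton is compared against the representatives of all multi-member
clusters and joins the best-matching one if it reaches t(L) — length
differences ignored. Rescued members are marked `2:` in every output.

Identity is measured on a global (Needleman–Wunsch) alignment with
BLOSUM62 and affine gaps (open 11, extend 1), overhangs free, and the
columns of terminal gap runs excluded from the denominator — so an exact
fragment is 100 % identical to its parent. See `docs/methods.md` for the
numerical details and edge cases.

## Worked example

Generate a synthetic benchmark (three protein families, five members
each, ~85 % identity within a family, background identity between
families) and run the pipeline on it:

```
$ hitcluster synth --out fixture --families 3 --members 5 --seed 4
$ hitcluster run --query fixture/query.fasta --db fixture/db.fasta \
      --hits fixture/hits.tsv --annotations fixture/annotations.tsv \
      --out results
INFO hitcluster: query fam0_r (120 aa)
INFO hitcluster: parsed 15 hits from fixture/hits.tsv
INFO hitcluster: 15 hits -> 3 clusters (0 rescued in pass 2)
```

The hit report (`results/report.tsv`) lists every hit in rank order with
its identity to the query and a cluster color, so family structure is
visible at a glance:

```
rank  accession  label    pident_query  evalue  bitscore  length  cluster  color
1     fam0_r     fam0_r   100.00        1e-30   120       120     1        red
2     fam0_m3    fam0_m3  87.07         1e-30   101       116     1        red
3     fam0_m4    fam0_m4  84.03         1e-30   100       122     1        red
...
```

The cluster summary (`results/clusters.tsv`, with a full JSON alongside)
shows one line per cluster with its joint taxonomy — the deepest lineage
shared by all annotated members — and the domain architectures present:

```
cluster  color  representative  n_members  joint_taxonomy                 architectures      length_range
1        red    fam0_m4         5          Synthetica;Familiales;Family0  Dom0A;Dom0B (x5)   116-122
2        blue   fam1_m4         5          Synthetica;Familiales;Family1  Dom1A;Dom1B (x5)   118-123
3        green  fam2_m1         5          Synthetica;Familiales;Family2  Dom2A;Dom2B (x5)   119-124
```

The three planted families are recovered exactly. Re-clustering reads
the frozen session instead of searching again, so trying another cutoff
is instant; at a stringent 90 % the same 15 hits shatter into 14
clusters because ~85 %-identical family members no longer qualify:

```
$ hitcluster recluster results/state.json --identity-cutoff 90 --out results90
INFO hitcluster: re-clustered 15 hits into 14 clusters at cutoff 90.0 %
```

The same pipeline runs against a real database with
`hitcluster run --query query.fasta --db swissprot.fasta --out results`
(live `blastp`), and `hitcluster fetch-annotations` can build the
annotation table from UniProt when network access is available.

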