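# nifbkit

Curation, domain-architecture classification and distance phylogenetics for
the NifB protein family.

NifB is the radical-SAM maturase that synthesizes NifB-co, the [8Fe-9S-C]
precursor of the active-site cofactors of every known nitrogenase, and it is
the hardest nitrogen-fixation protein to transplant into new hosts. Public
database annotations of NifB are noisy: many entries are actually NifX, a
small carrier protein that shares the C-terminal fold of bacterial NifB but
lacks the catalytic SAM-radical domain. `nifbkit` implements the
computational workflow used to study NifB diversity on such candidate sets:

1. **Fingerprint curation** — a candidate is accepted only if it carries six
   strictly conserved SAM-radical motifs in N-to-C order:
   `HPC`, the AdoMet cysteine triad `Cx3Cx2C`, `ExRP`, `AGPG`, `TxTxN` and
   `Cx2CRxDAxG` (pattern grammar: uppercase = literal residue, `x`/`xN` =
   arbitrary residues). Rejected records are re-scanned for a NifX-like
   domain to explain the false annotation.
2. **Architecture classification** — each accepted protein is assigned one
   of three architectures: a stand-alone SAM-radical domain (`SINGLE`, the
   archaeal form), SAM-radical plus a C-terminal NifX-like domain
   (`TWO_DOMAIN`, the common bacterial form), or an additional NifN-like
   domain (`THREE_DOMAIN`, confined to Firmicutes). Homology domains are
   located by affine-gap local alignment (BLOSUM62, open 11, extend 1)
   against a reference panel; frequencies are tabulated per
   (superkingdom, group).
3. **Domain-split phylogenetics** — progressive multiple alignment (or an
   external MSA), Gblocks-style conserved-block trimming, Poisson-corrected
   p-distances (d = −ln(1−p)), neighbor joining with the rate-corrected
   criterion Q(i,j) = (n−2)·d(i,j) − r_i − r_j, and outgroup rooting at the
   midpoint of the outgroup branch. NJ is exact on additive matrices, which
   is the correctness oracle used throughout the tests.
4. **In-silico bookkeeping** — theoretical average protein mass, in-silico
   PCR (primer annealing, tails, translation of the product) and the
   exponential growth-rate constant ln 2 / t_d.
5. **Synthetic ground truth** — a generator that plants motifs, homology
   domains and NifX-only contaminants with known labels, so every stage of
   the pipeline is testable without downloads.

## Worked example

Generate a labelled synthetic database (200 records, four taxon groups, 20%
NifX-only contaminants), curate it and tabulate architecture frequencies:

```sh
$ nifb simulate --seed 4 --out-dir demo
wrote 200 records to demo/dataset.fasta

$ nifb curate --fasta demo/dataset.fasta --taxonomy demo/taxonomy.tsv --out-dir demo/curated
input=200 retained=160 removed=40 reduction_fraction=0.2
removed records with a NifX-like domain: 40
```

All 40 removed records are the planted contaminants, and every one of them
carries a detectable NifX-like domain — the signature of a mis-annotated
NifX. `demo/curated/frequencies.tsv` shows the per-group architecture mix
recovered from sequence alone (counts, then within-row percentages):

```text
superkingdom  group                SINGLE  TWO_DOMAIN  THREE_DOMAIN  SINGLE_pct  TWO_DOMAIN_pct  THREE_DOMAIN_pct  total
Archaea       Euryarchaeota        40      0           0             100         0               0                 40
Bacteria      Cyanobacteria        8       32          0             20          80              0                 40
Bacteria      Firmicutes           22      13          5             55          33              13                40
Bacteria      Gammaproteobacteria  10      28          2             25          70              5                 40
```

The archaeal group is 100% single-domain, the bacterial groups are dominated
by the two-domain fusion, and only the Firmicutes-like group carries all
three architectures (55/33/13) — the distribution the generator was
configured to emulate. Build a rooted NJ tree from an alignment, using the
archaeal sequence as outgroup:

```sh
$ nifb phylo --msa demo/msa.fasta --outgroup Euryarchaeota_001 --no-trim --out-dir demo/tree
wrote demo/tree/tree.nwk
```

The library surface mirrors the CLI (`nifbkit.curate`,
`classify_architecture`, `architecture_frequencies`, `select_blocks`,
`nj_tree`, `root_tree`, `insilico_pcr`, `generate_dataset`, ...); see the
docstrings and `docs/methods.md` for the underlying models and parameter
choices.

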