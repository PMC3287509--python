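# wolmlva

An MLVA (Multiple Locus VNTR Analysis) toolkit for bacterial
endosymbiont genomes of the *Wolbachia* kind: AT-rich, 1–1.5 Mb
chromosomes dotted with tandem repeats whose copy numbers diverge
between otherwise near-identical strains. Housekeeping-gene typing
(MLST) cannot separate such strains; length-polymorphic tandem repeat
loci can, via a simple PCR sizing readout. This package provides the
in-silico side of that workflow for people designing, validating or
simulating such typing schemes:

* **`trfind`** — genome-wide tandem repeat discovery. Candidate periods
  are seeded from k-mer matches and refined by **wraparound dynamic
  programming**: the locus is aligned against unbounded tandem copies of
  a candidate period, the alignment path wrapping from the period's last
  position back to its first. A reported array scores
  `S = 2·m − 7·x − 7·g` (matches, mismatches, indel bases), with
  defaults: minimum score 50, maximum period 500 bp, minimum 1.8 copies.
* **`vntr`** — VNTR locus structure: decomposition into period
  instances (full copies = 1.0, copies with an internal deletion ≥ 20 bp
  = 0.5, terminal partials = their aligned fraction to one decimal, so a
  seven-copy array with a trailing 42/141 fragment reads **7.3** and is
  written `7+0.3`), plus detection of period-internal direct/inverted
  repeat units and palindromic hairpins (dyads).
* **`mlva`** — in-silico PCR: primer-site location (IUPAC-aware,
  optional mismatches), amplicon extraction and sizing (product length
  includes both primer footprints), per-locus copy-number allele calls,
  multi-locus profiles with a *wsp* amplification control, and
  multiple-infection flagging when one locus yields several product
  lengths. The primer panel for the wMel-derived loci VNTR-141,
  VNTR-105, WD0550 and WD0766 is packaged.
* **`ank`** — ankyrin (ANK) repeat gene architecture: translation with
  premature-stop detection, 33-aa ANK unit detection by a packaged
  log-odds profile, Kyte–Doolittle hydropathy transmembrane prediction,
  average-mass protein weights, large-insertion (IS element) detection
  against a reference ortholog, and a neighbor-joining tree of repeat
  units (p-distance over a center-star alignment) with
  orthologous-position clustering that flags unit duplications and
  shuffling. Because one ANK unit is 33 aa = 99 nt, ortholog size
  differences come in multiples of 99 bp.
* **`synthgen`** — a deterministic, seeded generator of all of the
  above structures with ground-truth annotations, so every analysis can
  be validated against what was actually planted.

## Worked example

Three synthetic strains share one VNTR locus (identical conserved
flanks carrying the primer sites) with 2, 4 and 7 copies of a 141 bp
period; a fourth template set mixes two of them:

```sh
python examples/type_strains.py
```

```
strain strain_low
  VNTR-141: 582 bp
strain strain_mid
  VNTR-141: 864 bp
strain strain_high
  VNTR-141: 1287 bp
strain mixed_host
  VNTR-141: 582 bp | 1287 bp  (multiple infection)

  strain_low VNTR-141 582 bp -> 2 copies
  strain_mid VNTR-141 864 bp -> 4 copies
 strain_high VNTR-141 1287 bp -> 7 copies
  mixed_host VNTR-141 582 bp -> 2 copies
  mixed_host VNTR-141 1287 bp -> 7 copies
```

Amplicon sizes differ by exact multiples of the 141 bp period
(864 − 582 = 2 × 141), which is the whole point of the marker system:
copy number is readable from a gel without sequencing. The mixed host
shows two bands at one locus — the in-silico analogue of a doubly
infected specimen. The other scripts in `examples/` demonstrate the
genome-wide scan, single-locus structure annotation, ANK architecture
comparison and fixture generation, each printing what its numbers mean.

A thin CLI wraps the same library calls:

```sh
wolmlva simulate genome --seed 3 --out g
wolmlva scan --fasta g.fa --out g.gff3
wolmlva summarize --fasta g.fa --repeats g.gff3 --out summary.tsv
wolmlva type --fasta strains.fa --out profiles.tsv --gel report.txt
wolmlva ank --cds genes.fa --out architecture.json --tree units.nwk
```

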