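# naworm

Pseudo-torsion analysis and worm-based motif search for RNA and DNA 3-D
structures.

## The problem

A full description of nucleic-acid backbone conformation needs six backbone
torsions, the glycosidic torsion and the sugar pucker per nucleotide — an
eight-dimensional space that is hard to compare across structures.  A
long-standing simplification assigns each nucleotide *i* just two
pseudo-torsion angles built from backbone atoms of neighbouring residues:

    eta(i)   = torsion( C4'(i-1), P(i),   C4'(i),  P(i+1) )
    theta(i) = torsion( P(i),     C4'(i), P(i+1),  C4'(i+1) )

together with the primed variants eta'/theta' that substitute C1' for C4'
(C1' positions are usually better resolved in experimental density maps).
Plotted against each other, (eta, theta) give a Ramachandran-like 2-D map of
nucleic-acid conformation ("NARama"); read along the sequence, the ordered
list of (position, eta, theta) triples is a *worm* — a linearized,
searchable fingerprint of the 3-D fold.  Because only P and C4' (or P and
C1') atoms are needed, the same machinery works on coarse-grained models.

`naworm` provides, for both RNA and DNA and for PDB or mmCIF input:

* per-nucleotide eta/theta and eta'/theta' calculation, with sugar-pucker
  annotation (C3'-endo vs C2'-endo from the Altona–Sundaralingam
  pseudorotation phase) and a helical/non-helical flag;
* NARama scatter plots, 3-D worm plots (helical segments blue, others red)
  and a per-nucleotide CSV spreadsheet;
* worm-database construction (one CSV per nucleic chain of an input
  directory) and sliding-window motif search: a probe worm of length L is
  scored against every length-L window using the per-position periodic
  Euclidean distance in (eta, theta) space, ranked ascending (0 = exact
  angular match);
* a deterministic generator of idealized synthetic helices, so the whole
  package installs, runs and tests without downloading any structure.

It is intended for structural biologists characterizing motifs, comparing
conformers, or screening new models for unusual backbone geometry.

## Worked example

Generate synthetic fixtures, run the NARama analysis, build a worm database
and search a 6-nucleotide probe against it:

```sh
naworm make-fixtures --out fixtures
naworm narama fixtures/aform12.pdb --out narama_out
naworm build-db fixtures --out wormdb --mode c4
naworm search --db wormdb --probe fixtures/aform12.pdb \
       --chain A --range 3-8 --out hits.txt
```

The spreadsheet (`narama_out/aform12_A_pseudotorsions.csv`) starts:

```
chain,seq_id,insertion_code,residue,eta,theta,eta_prime,theta_prime,pucker,helical
A,1,,A,NA,286.274,NA,138.799,C3'-endo,unknown
A,2,,U,89.419,286.299,233.849,138.773,C3'-endo,helical
A,3,,G,89.419,286.299,233.814,138.803,C3'-endo,helical
```

Residue 1 has no preceding residue, so its eta is undefined (`NA`) and its
helicity unknown; every interior residue of the idealized helix shows the
same (eta, theta) ≈ (89.4°, 286.3°) because the fixture repeats one rigid
helical step, and all sugars classify C3'-endo (North pucker), as built.
Alongside the spreadsheet you get `*_eta_theta.png`,
`*_etaprime_thetaprime.png` and `*_worm.png`, each with a machine-readable
sidecar table of exactly what was plotted.

The database index (`wormdb/index.csv`) accounts for every parsed chain:

```
file,source_id,length,mode
aform12_A.csv,aform12_A,12,c4
bduplex10_A.csv,bduplex10_A,10,c4
bduplex10_B.csv,bduplex10_B,10,c4
```

and the search report (`hits.txt`) ranks all equal-length windows:

```
# naworm motif search results
probe_id: aform12_A:3-8
mode: c4
aggregator: mean
database: wormdb
probe_length: 6
11 hits
rank	source_id	window(seq_ids)	score
1	aform12_A	3-8	0.000
2	aform12_A	5-10	0.043
3	aform12_A	2-7	0.043
```

Rank 1 is the probe's own window at score 0.000 (a perfect angular
self-match); the near-zero scores below it are the neighbouring windows of
the same regular helix, differing only by coordinate-rounding noise.  DNA
windows score far higher and drop off the top of the list.

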