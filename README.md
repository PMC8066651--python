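# f2link

Segregation, two-point linkage and map analysis for F2 intercross
populations, with a meiosis-based synthetic population generator.

The package is written for teaching and small-scale research genetics: the
classical analysis of an F2 progeny derived from two fully homozygous
parents, one carrying the dominant and the other the recessive allele at
every scored locus (the Oregon Wolfe Barley, OWB, design). From a table of
per-individual phenotype classes and molecular-marker calls it computes:

- **Segregation tests** — Pearson χ² goodness-of-fit of observed class
  counts against hypothesised ratios (3:1, 1:2:1, 9:7, 9:3:4, 9:3:3:1, ...),
  with the conventional significance starring (`***`, `**`, `*`, `n.s.`).
- **Epistasis re-classification** — the two awn observations (type:
  hooded/normal; length: long/short, defined only on normal-awned plants)
  are combined into the three classes of a recessive epistasis and tested
  against 9:3:4, optionally dissected into four 9:3:3:1 classes with a
  completely linked dominant marker.
- **Linkage detection** — χ² tests of independence on 2×2, 2×3 and 3×3
  joint classification tables with pairwise-complete deletion of missing
  calls.
- **Recombination fraction** — coupling-phase maximum likelihood from the
  collapsed 2×2 table. Writing a₁ (dominant/dominant), a₂, a₃ (mixed) and
  a₄ (double recessive) for the four joint phenotype counts, N = Σaᵢ, the
  expected F2 class frequencies are (2+x)/4, (1−x)/4, (1−x)/4, x/4 with
  x = (1−r)². The ML estimate of x is the non-negative root of

  ```
  N·x² + (−a₁ + 2a₂ + 2a₃ + a₄)·x − 2a₄ = 0,     r̂ = 1 − √x
  ```

  clamped to [0, 0.5] with a repulsion-phase warning. Codominant markers
  are collapsed to dominant scoring first, so one estimator serves every
  pair.
- **Map assembly** — linkage groups as connected components of the
  significance graph, three-point ordering (central-locus inference),
  coincidence and interference coefficients.
- **Quantitative traits** — descriptive summaries, histogram preparation,
  and the Welch *t* contrast between the two phenotype classes of a major
  locus.
- **Simulation** — F2 populations generated by explicit meiosis along a
  linkage map (uniform starting strand, interval-wise recombination, no
  interference), with dominance, leaky recessive epistasis,
  codominant/dominant marker read-out, major-locus Gaussian-mixture
  quantitative traits, per-locus viability distortion, and
  missing-completely-at-random masking. `owb_default_config()` packages
  the statistical structure of the OWB F2 teaching population (n = 303).

## Worked example

Replication mode replays the segregation layer on the packaged marginal
count tables of the OWB F2 population:

```python
from f2link.datasets import owb_marginal_counts
from f2link.io_cli import report_from_counts

print(report_from_counts(owb_marginal_counts()).to_string(index=False))
```

```
            item      gene             counts   N   ratio  chi2 label
      spike_type       Zeo           229 / 74 303     3:1  0.05  n.s.
      row_number      Vrs1           230 / 73 303     3:1  0.13  n.s.
        awn_type       Kap          169 / 133 302     3:1 58.39   ***
        awn_type       Kap          169 / 133 302     9:7  0.01  n.s.
      awn_length      Lks2            56 / 77 133     3:1 76.75   ***
      grain_type       Nud           237 / 65 302     3:1  1.95  n.s.
leaf_variegation       Wst           237 / 66 303     3:1  1.67  n.s.
 stem_pubescence       Hsh           186 / 70 256     3:1  0.75  n.s.
 awn_three_class  Kap/Lks2      169 / 56 / 77 302   9:3:4  0.04  n.s.
       Bmac 0310 Bmac 0310      57 / 167 / 76 300   1:2:1  6.26     *
       Bmag 0211 Bmag 0211      80 / 130 / 88 298   1:2:1  5.28  n.s.
           HVM40     HVM40      63 / 160 / 78 301   1:2:1  2.69  n.s.
        Knox-dup  Knox-dup           230 / 73 303     3:1  0.13  n.s.
     awn_by_knox  Kap/Lks2 179 / 46 / 50 / 27 302 9:3:3:1  6.76  n.s.
```

Reading the table: five morphological loci and both SSR controls segregate
as expected (n.s. against their Mendelian ratio); awn type fails 3:1
spectacularly (χ² = 58.39) but fits 9:7, the signature of a two-locus
interaction; re-classified into three classes it fits the 9:3:4 recessive
epistasis; Bmac 0310 shows mild segregation distortion (χ² = 6.26, p <
0.05). The `awn_three_class` row is recomputed from its marginal counts —
see `docs/methods.md` for a note on the previously circulated value.

Estimating a recombination fraction from joint counts is one call:

```python
import f2link as fl

est = fl.estimate_r_coupling(104, 42, 47, 109)
print(round(est.x, 4), round(est.r, 4))   # 0.599 0.226
```

A full simulated study, end to end:

```sh
f2link simulate --seed 1 --out-prefix out/pop           # OWB defaults, n=303
f2link report --phenotypes out/pop.phenotypes.csv \
              --genotypes out/pop.genotypes.csv --out out/report
f2link quant --phenotypes out/pop.phenotypes.csv \
             --trait spike_length_mm --by-locus Zeo
```

The genotype CSV uses the common cross-file coding `A`/`H`/`B` for
codominant classes, `D` for dominant-marker dominant phenotype and `-` for
missing (ASCII hyphen), so files convert directly to other cross formats.

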