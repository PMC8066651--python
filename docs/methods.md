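# Methods

## The genetic model

All analyses assume an F2 intercross between two fully homozygous parental
stocks in which one parent contributes the dominant and the other the
recessive allele at every scored locus. Genotypes are encoded as the *dose*
of the dominant-parent allele, an integer in {0, 1, 2}; a single integer
supports both the dominance collapse (dose ≥ 1 → dominant phenotype) and
the codominant 1:2:1 marker classes. Because of the cross design the F1 is
in pure coupling phase: one haplotype carries every dominant allele. This
assumption is load-bearing for the recombination estimator (below) and is
true by construction for OWB-type material; the estimator clamps and flags
estimates that wander above 0.5, which is the symptom of repulsion-phase or
badly distorted data.

Recessive epistasis between an epistatic locus E and a hypostatic locus H
is modelled as: `ee` masks H entirely (one phenotype class regardless of
H); `E_ hh` and `E_ H_` express the two remaining classes, giving the
9:3:4 ratio. A per-individual Bernoulli *leakage* with probability
`leakage_prob` lets a double-dominant individual express the hypostatic
recessive class instead; the default 10/179 reproduces the observed share
of normal-long-awned plants among double-dominant barley. The leaky
individuals are modelled as stochastic; whether they are genotype-linked
(a third modifier locus) cannot be resolved from the available data, and
the stochastic choice is the weakest assumption.

## Statistics

**Goodness of fit.** Pearson χ² with expected counts N·ratioᵢ/Σratio,
df = classes − 1, upper-tail p. No Yates continuity correction anywhere:
back-computation of the published barley statistics (e.g. 58.39 for awn
type against 3:1, 6.26 for the distorted SSR) confirms the uncorrected
form. Reported values are rounded to two decimals in tables; internal
precision is full. A likelihood-ratio G statistic is available as an
internal cross-check only.

One published value is knowingly not reproduced: the three-class awn table
(169, 56, 77) against 9:3:4 gives χ² = 0.0412 ≈ 0.04 by direct
recomputation, not the circulated 0.14. The toolkit reports the recomputed
value.

**Independence.** Pearson χ² on the joint classification table
(scipy's `chi2_contingency`, correction disabled), df = (rows−1)(cols−1).
Pairs involving a codominant marker keep the full 2×3 (or 3×3) table — the
information-preserving default; collapsing to 2×2 is available for parity
with hand calculation. Tables with an empty margin are refused, and inside
the all-pairs scan such degenerate pairs are reported as non-significant
rather than aborting the scan. Missing calls are deleted pairwise, so each
pair uses its own N.

**Recombination fraction.** For the collapsed coupling-phase 2×2 table
with counts a₁ (dom/dom), a₂, a₃ (mixed), a₄ (double recessive) and
N = Σaᵢ, the class probabilities are ((2+x)/4, (1−x)/4, (1−x)/4, x/4) with
x = (1−r)². Setting the score of the multinomial likelihood to zero and
clearing denominators yields

    N x² + (−a₁ + 2a₂ + 2a₃ + a₄) x − 2a₄ = 0.

The product of the roots is −2a₄/N ≤ 0, so at most one root is positive;
the estimator takes x̂ = (−b + √(b² + 8Na₄))/(2N) (which degrades
gracefully to max(0, −b/N) when a₄ = 0) and r̂ = 1 − √x̂, clamped to
[0, 0.5]. Both roots are retained for diagnostics. The estimator is
validated against an independent grid-search maximiser of the same
likelihood (coarse grid of 2·10⁴ points on [0, 1], refined around the
argmax; agreement to 10⁻⁴ in r across random count vectors).

Epistatic phenotype loci are excluded from r estimation — their joint
phenotype frequencies do not follow the two-locus coupling model — but the
epistatic locus itself is scored through its genetic model (dominant class
= hooded + normal-long, which is exactly the `E_` class), and a completely
linked dominant marker proxies the hypostatic locus.

**Three-point analysis.** With three pairwise results: if exactly two are
significant, the locus shared by both significant pairs is central; if all
three are significant, the pair with the largest r̂ flanks the group. The
coincidence coefficient is c = (r_AB + r_BC − r_AC)/(2·r_AB·r_BC) and
interference I = 1 − c; c is undefined when a flanking interval has r = 0.

**Map assembly.** Loci are nodes, pairs significant at α are edges
(annotated with r̂ when estimated), linkage groups are connected
components (networkx), and three-locus components are ordered by the
central-locus rule. The default reporting α is 0.05, mirroring the
published starring convention. For *structure-recovery* analyses over the
45-pair scan the acceptance checks use α = 0.001: with ~50 truly unlinked
pairs, α = 0.05 would contaminate the recovered components with false
edges in roughly a quarter of runs whatever the implementation, so the
stricter edge threshold acts as the multiple-testing guard (it matches the
threshold used for the simulated five-locus chain check).

**Quantitative traits.** Summaries use the n−1 SD and SE = SD/√N. The
major-locus contrast is the Welch unequal-variance t with
Welch–Satterthwaite df: the published degrees of freedom (104 and 98 with
group sizes near 229/74) are inconsistent with the pooled-variance df
(≈ 301) and consistent with Welch, so Welch is inferred — not confirmed —
as the authors' variant. The published summary table and t values are used
to parameterise the simulator, not as replication targets, because the
per-individual data are not public.

## The simulator

Meiosis is simulated directly: per chromosome a gamete starts on a
uniformly chosen parental strand and switches strand between adjacent loci
with the interval's recombination fraction, independently per interval.
There is **no crossover interference** — the data the generator emulates
contain no interference estimate, and the classroom exercise derives
coincidence from data — so simulated c ≈ 1 by construction. Two
independent gametes fuse per individual. The observation model adds, in
order: optional viability thinning (below), the leakage Bernoulli,
quantitative-trait noise, and missingness masks; all randomness flows from
one `numpy` Generator seeded by the single config seed, so identical
seed + config gives a bit-identical population.

**Segregation distortion** is a per-locus triple of viability weights
(dose 0, 1, 2) multiplying the genotype-class sampling probabilities,
implemented by rejection sampling normalised to the maximum attainable
weight; the default OWB weights reproduce the observed mild deficit of
dominant homozygotes at Bmac 0310 ((57, 167, 76) observed against 75/150/75
expected). Distortion at one locus leaks into linked neighbours in
proportion to (1−2r)², which is the biologically expected behaviour.

**Missing data** are missing completely at random, per column, with rates
back-solved from the published observed Ns (e.g. 47/303 for stem
pubescence → expected N ≈ 256). The observed-N variation in the real
tables has no stated mechanism, so MCAR is the weakest assumption. A plant
missing its awn-type record cannot carry an awn-length record.

**Quantitative traits** are single-major-locus Gaussian mixtures: class
mean (dominant vs recessive at the major locus) plus N(0, sd_within). Only
pooled SDs are published, so the within-class SD is back-solved at runtime
from the variance decomposition pooled² = within² + p(1−p)Δ² with p = 3/4:
28.54 mm pooled spike length → 13.72 mm within; 26.57 cm pooled height →
21.30 cm within. The resulting spike-length separation is 4.2 within-class
SDs — strongly bimodal, as in the real population. A single-locus mixture
deliberately omits the polygenic background and the right skew of the real
height distribution; passing tests therefore certify the major-locus
machinery, not polygenic realism.

**The default map** places Vrs1–Zeo–Wst on 2H (r 0.398, 0.251), Lks2–Nud
on 7H (r 0.10), HVM40–Knox-dup–Kap–Bmac 0310–Hsh on 4H (r 0.329, 0.0,
0.375, 0.5) and Bmag 0211 alone on 1H. These adjacent r values are the
published *pairwise estimates*, not additive map positions — no map
function is applied, so implied long-range r values are compositions under
independence. Kap rides at r = 0 from its diagnostic marker (complete
linkage). Hsh is given r = 0.5 to its 4H neighbour because the emulated
population's data show it unlinked to Bmac 0310; the anomalous published
linkages that involve Knox-dup (to Hsh at r = 0.403 and to Lks2) are *not*
emulated — they are attributed by the original analysis to unmodelled
modifier loci and/or the Bmac distortion, and the toolkit's policy is to
report such conflicts, never to build them in.

## Numerical and design choices

- Probabilities, doses and ratios are validated at the boundary; errors
  carry a category (config / input / estimation) that the CLI maps to
  exit codes.
- The quadratic is solved in closed form (no iteration); the discriminant
  b² + 8Na₄ cannot be negative for valid counts.
- Class labels are free strings fixed in config, not enums, so the
  toolkit generalises beyond barley; the missing code is the ASCII
  hyphen "-".
- Problem sizes in the validation suite — 200 populations of n = 300 for
  recovery, 2000 for null calibration, 100 seeds at n = 2000 for structure
  recovery and n = 1000 for epistasis emergence — are chosen so each check
  pins its statistic to well under its tolerance while the whole suite
  stays interactive (~1 minute).

## Known limitations

- Coupling phase is assumed; repulsion-phase estimation is out of scope
  (clamp + warning only).
- No multipoint ML, no EM over missing genotypes, no Haldane/Kosambi map
  functions, no QTL mapping.
- Replication mode covers marginal counts only: published pairwise
  linkage χ² and r values rest on unpublished joint counts and are
  validated indirectly, through simulation-based parameter recovery with
  those values as generating truth.
- The simulator models genotyping error only as missingness; no
  miscalling model.
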