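# Methods

## The model

`genedist` treats a recombination map as a genome-wide grid of fixed-width
bins (default 10 Kb) carrying sex-averaged rates in cM/Mb. Standardization
divides every rate by the genome-wide mean, taken as the unweighted mean
over all bins present in the file — zeros included, missing bins excluded;
since all bins share one width this equals the length-weighted mean. The
standardized rate (SRR) is therefore unitless with mean exactly 1 over
covered bins (enforced to 1e-9), and is invariant under any positive
rescaling of the raw rates, so the map's rate units never matter downstream.

The genetic-distance gene unit is built per side. The walk starts at the bin
containing the first base beyond the gene boundary — bins entirely inside
the gene body are never counted, but the first counted bin is taken in full
even when it partially overlaps the gene — and accumulates SRR outward until
the running sum first reaches the threshold (inclusive; the sum may overshoot).
The unit boundary is that bin's outer edge, which is why a flank can be
shorter than one bin width: a gene ending mid-bin inside a hot bin gets the
remainder of that bin only. A boundary lying exactly on a bin edge starts
counting at the next full bin outward (the half-open convention resolves the
tie). Strand is recorded but ignored; the procedure is symmetric, so sides
are genomic left/right rather than 5′/3′.

### Assumptions

- The map is the authority on genetic distance; no smoothing or
  interpolation is applied across gaps, and rates within a bin are treated
  as homogeneous.
- The gene body is the transcript span (txStart–txEnd after union-collapse
  of same-name transcripts), not the CDS. Distinct overlapping genes are
  left untouched; units may overlap.
- Autosomes only by default; non-autosomal records are skipped with a
  warning unless explicitly permitted.

### Fallback at map edges

Any gap met mid-walk — telomere, centromere, or an interior coverage hole —
flags that side. After all walks on a chromosome finish, every flagged side
is replaced by the median completed flank length of that chromosome, pooling
both sides of all genes; a chromosome with no completed flank at all falls
back to the genome-wide median (logged). Replaced left boundaries are
clipped at coordinate 0. The provisional boundary recorded during the walk
(the last covered edge) never appears in output; the median substitution is
total. Medians are rounded to the nearest bp.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `srr_threshold` | 2 | SRR (unitless) | cumulative stop rule; 2 was chosen as the integer threshold whose median flank (~45 Kb) matches the common ±50 Kb convention |
| `fixed_distance` | 50,000 | bp | the physical-window comparator |
| `bin_width` | 10,000 | bp | the map grid; inferred from the file when not given |
| concordance `tolerance` | 10,000 | bp | boundary-agreement cutoff in the comparison machinery |

Raising `srr_threshold` never shortens a non-fallback flank (monotonicity);
this and scale invariance are enforced by randomized property suites.

## Exact Fisher testing

The definition comparisons are one-tailed Fisher exact tests. With margins
fixed, the top-left cell follows a hypergeometric law; the implementation
sums the tail with integer binomial coefficients through `fractions.Fraction`
and converts to float once, so the result is exact to double precision.
`row1_lower` sums P(X ≤ a), `row1_higher` P(X ≥ a). Degenerate margins (an
empty row or column) return p = 1 with a warning rather than an error. The
test suite checks every table with grand total ≤ 12 against brute-force
enumeration and cross-checks `scipy.stats.fisher_exact` on larger tables.

For the candidate-inclusion comparison, candidates missed by *both*
definitions are removed from both margins before testing, so the 2×2
contrasts only the misses each definition adds on its own. This construction
is an interpretation choice, documented here because other constructions
(keeping shared misses in the margins) give slightly different tables.

## The synthetic generator

`simulate_map` draws per-bin rates from a zero-inflated gamma: mass π₀ at
exactly zero, Gamma(shape, scale) otherwise, with optional Poisson-placed
hotspot bins whose positive rate is multiplied by an intensity factor
(off by default — the gamma tail already carries genome-scale skew).
Defaults are π₀ = 0.426, shape = 0.2951, scale = 5.9030: the scale is forced
so the mixture's population mean is exactly 1 (making the nominal
distribution live on the SRR scale), and the shape is then the least-squares
fit to the two tail landmarks of a real human 10 Kb map, 78.4% of bins below
SRR 1 and 12.9% at SRR ≥ 2. A single-shape gamma cannot pin both tails once
its mean is fixed; the fit achieves 79.0% and 14.2%, which we accept rather
than adding a third shape parameter. The zero mass and the unit mean are
exact by construction.

The default genome is a scaled-down one — 20 chromosomes of 50 Mb — with
1 Mb uncovered telomeres and a 3 Mb centromere gap per chromosome, enough to
exercise the fallback path at realistic frequency. `simulate_genes` places
lognormal gene bodies (median 25 Kb, σ_log = 0.9, floor 1 Kb) uniformly into
covered spans with a minimum inter-gene gap, allotting genes to spans
proportionally to span length.

What the simulator does **not** emulate: spatial autocorrelation of rates
(real hotspots cluster and LD blocks are contiguous; our bins are i.i.d.),
chromosome-length variation, gene clustering, and the correlation between
gene density and recombination. Consequently simulated flank-length
distributions are somewhat narrower and their median (~39 Kb at default
settings) sits below the ~45 Kb seen on a real map, and passing tests
demonstrate the correctness of the algorithms and the statistical shape of
the inputs — not field accuracy of any particular genome statistic that
depends on the map's spatial structure.

The evaluation fixtures (`wtccc-loci`, `rbc-candidates`) are geometric
encodings of published per-locus score rows: expert genes are placed inside
their association regions under both definitions, and "extra"/"missed"
genes are placed so that exactly the recorded definition over- or
under-reaches them. They validate the scorecard, inclusion and Fisher
machinery against printed totals (107 expert genes, +7 vs +26 extras;
4 vs 10 missed candidates of 43) without any external data. The fixture
files are synthetic stand-ins for those studies' gene lists, not the lists
themselves.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere internally; 1-based dialects
  are converted at the parsers. Overlap is strict (`max(l, s) < min(r, e)`),
  so touching intervals do not overlap and a SNP at a unit's right edge is
  outside.
- Quartiles use linear interpolation of order statistics (numpy default);
  flank summaries pool both sides, two per gene.
- The genome mean uses every bin in the file; an all-zero map is an error
  (standardization undefined).
- Bin-width inference takes the modal width, ties broken toward the larger
  value so a short terminal bin never masquerades as the grid.
- The fixed-distance rule clips at 0 on the left and at the chromosome
  length on the right only when a length is supplied; map coverage is not a
  clip because it ends before the physical chromosome end.
- Output files are deterministic (sorted by chromosome, left boundary,
  name) and byte-identical across reruns.

## Known limitations

- A definition file read back from disk carries no gene bodies, so
  extension-length statistics require the gene catalogue to be re-attached
  (`genedist stats --genes ...`).
- The i.i.d. rate model understates long LD deserts; studies of extreme
  flank lengths should use a real map.
- No liftover: maps and gene catalogues must share one assembly, and users
  converting coordinates should do so with dedicated tools before input.
- The structural-variant edge case of strongly inverted, high-LD regions is
  handled only by excluding such loci from evaluation inputs, not modeled.
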