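# Methods

## The HSI model

Habitat quality for one species at one grid cell and month is the unweighted
geometric mean of three partial suitability indices,
HSI = (SI_sal · SI_temp · SI_ADBL)^(1/3), each read off a piecewise-linear
look-up curve. The geometric mean encodes a limiting-factor assumption: a
zero for any variable zeroes the total score regardless of the others. A
weighted arithmetic mean or a minimum rule are plausible alternatives; the
aggregation lives in a single function (`hsi.total_hsi`) precisely so it can
be swapped, but only the geometric mean is supported and tested.

Light availability is average daily bottom light (ADBL): surface
photosynthetically active radiation (PAR, µmol m⁻² s⁻¹) attenuated by the
Beer–Lambert law, ADBL = τ · PAR · exp(−k · depth), with surface
transmission τ = 0.9 and baseline attenuation k = 0.85 m⁻¹. Tape grass
(*V. americana*) carries two ADBL curves because its light-use efficiency
degrades under salt stress; the low-salinity curve applies on
[0, threshold) and the high-salinity curve at and above the threshold
(8 PSU in the shipped fixture). Salinity exactly at the threshold selects
the high-salinity curve — a deterministic convention chosen here; the
boundary case has no documented biological resolution. Curve selection uses
the same (input-perturbed) salinity the salinity curve sees, so one sampled
environment drives the whole evaluation. A reported conditioning of the
curve choice on water depth as well has no stated rule and is deliberately
not guessed at.

Curve evaluation clamps to the nearest endpoint outside the breakpoint
domain rather than erroring, because ±20% input perturbations routinely push
values past the plotted range of the source curves.

### Species curve fixtures

The two shipped YAML files are approximate reconstructions: the source
curves for the Caloosahatchee estuary system exist only as published
figures, with no numeric table. The fixtures reproduce the qualitative
shapes (salt-tolerant vs salt-intolerant salinity response, subtropical
thermal optima, saturating light response) and are labelled as synthetic
approximations in their headers. Conclusions tied to exact breakpoint
values should not be drawn from them; users with authoritative curves
supply their own YAML.

## Uncertain factors

All uncertainty is expressed as dimensionless multiplicative factors with
uniform distributions, default U(0.8, 1.2):

| factor | kind | applies to |
|---|---|---|
| sal, temp, depth, k, par | input | the five environmental drivers |
| f.sal, f.temp, f.adbl (, f.adbl2) | function | each curve's SI output, truncated to [0, 1] |

k = 8 factors for a single-ADBL species, 9 for a dual-ADBL species (the
ninth being the second ADBL curve's multiplier — the factor inventory is a
reconstruction, since no itemized list of the eight/nine factors exists).
One sampled multiplier applies to every cell in a run: each quasi-MC
iteration perturbs the whole map coherently, which is the only reading
consistent with producing one perturbed HSI map per iteration. Temperature
is perturbed multiplicatively in °C like the other inputs for uniformity,
though a multiplier on a Celsius scale is physically arguable.

The proportional ±20% band means low SI values get absolutely narrower
perturbation ranges — uncertainty is smallest where habitat is clearly
unsuitable — and truncation at 1 caps the band for SI > 1/1.2 ≈ 0.83.
An optional discrete factor kind (equiprobable labeled levels, e.g.
alternative curve sets) is provided since variance-based GSA with Sobol
sampling accommodates discrete structural alternatives; it is not part of
the default space.

## Sampling and estimation

Factors are sampled by the unscrambled Sobol low-discrepancy sequence
(Joe–Kuo direction numbers via scipy), skipping the all-zeros first point,
which would map every factor to its lower bound. A 2k-dimensional sequence
of length N supplies base matrices A and B (first/last k columns); the
Saltelli design adds the 2k column-swapped matrices A_B^(i) and B_A^(i) for
M = (2k + 2)·N rows in total. N defaults to 512, hence the 9216 / 10240
runs quoted above.

First-order indices use the Saltelli (2002) correlation estimator averaged
over both available pairings that share only column i,
V_i ≈ ½(⟨y_A·y_{BA(i)}⟩ + ⟨y_B·y_{AB(i)}⟩) − f₀², and total-order indices
the complementary pairings sharing all columns but i. The output mean f₀
and variance V are taken from the pooled A∪B sample (variance with the
2N−1 denominator). Raw estimates may fall slightly outside [0, 1] by
Monte-Carlo error; they are reported raw alongside clamped companions, and
downstream maps use the clamped values. Outputs whose variance is below
10⁻¹² · mean² (or an absolute floor of 10⁻³⁰) are flagged invalid with NaN
indices: a cell where the HSI is ~0 under every perturbation has no
meaningful variance to decompose, and near-zero-variance index estimates
are dominated by numerical error. Second-order indices are available only
from the brute-force oracle, not the MC estimator.

The brute-force oracle (`sobol.brute_force_indices`) enumerates a discrete
factor grid completely and computes every partial variance by Möbius
inversion of the conditional-mean variances; it conserves total variance to
floating tolerance by construction and anchors the estimator tests at
±0.05 alongside the analytic additive (S_i = i²/14) and product
(S₁ = 3/7, S_T1 = 4/7) models.

## Synthetic hydrology

The generator emulates the qualitative structure of estuarine hydrodynamic
model output at monthly, 500 m resolution: a logistic inland→marine
salinity gradient (0 → 35 PSU) whose front makes a dry-season (March-peak)
inland excursion; a seasonal temperature sinusoid (default 18–32 °C,
warmest mid-July); fixed bathymetry (0.3 m inshore to 3 m offshore,
deepening as x^1.5) plus a sea-level-rise increment ramped linearly to
`slr_total` (0.30 m for the future scenario) at the final month, which also
migrates the salt front inland at 0.5 gradient units per metre of SLR; a
12-value PAR climatology sinusoid (700 ± 300 µmol m⁻² s⁻¹, June peak); and
independent per-cell Gaussian noise (1 PSU, 0.5 °C), clipped so salinity
stays non-negative. Default period January 1999 – December 2047.

Monthly means are generated directly rather than aggregated from sub-daily
series, since the HSI model consumes monthly means only. What the generator
does **not** reproduce: real geography and bathymetry, tides, spatial and
temporal autocorrelation of the noise, within-month variance, and
freshwater-pulse events. Passing tests therefore demonstrate the
correctness of the GSA/UA machinery and the qualitative behaviour of the
coupled system (species sorting along the gradient, SLR salinization), not
fidelity to any real estuary.

## Pipeline and numerical choices

One Saltelli design is shared across all cells and months of a run — a
consequence of the spatially shared multipliers; per-month redraws would
require independent factor draws with no basis. The whole run is
deterministic given the config (the seed enters only through the hydrology
generator; the Sobol sequence is deterministic by construction), and reruns
are byte-identical in every artifact except the manifest's timing entries.
SD maps use the M−1 denominator, as sample estimates of propagated
uncertainty. PDF summaries use 25 fixed equal-width bins on [0, 1] so
sites and dates are visually comparable; CDFs are the raw empirical step
functions. Benchmark sites are arbitrary in-grid cell indices supplied in
config. Exceedance probabilities count values strictly greater than the
threshold.

Rasters are ESRI ASCII grids (text); tables are CSV; hydrology persists as
a long-format CSV plus a YAML metadata sidecar, with full-precision float
serialisation so round-trips are exact.

Problem sizes in the shipped tests and the acceptance script are chosen to
keep the demonstration compact: a 12 × 16 synthetic grid, one analysed
month, N = 512 for the pipeline runs (the standard design size), and
N = 2048 for the estimator benchmarks, where the ±0.05 tolerance comfortably
exceeds the Monte-Carlo error.

## Known limitations

Factors are assumed independent (a standard requirement of plain
variance-based GSA); correlated-input variants are out of scope. Only the
uniform distribution is supported. Structural uncertainty is represented
solely as proportional bands around fixed curve shapes. The truncation of
perturbed SI values at 1 slightly compresses uncertainty for baseline
scores above ~0.83.
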