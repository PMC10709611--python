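# Methods

## Index models

All indices operate per pixel on reflectance in [0, 1], at double
precision, with nodata propagated as NaN plus a mask. Ratio indices
return nodata where the denominator is zero: an undefined ratio is
never clamped or zero-filled, because a silent 0 would classify as
"unburned" downstream.

**PRI / sPRI.** PRI = (A − Ve)/(A + Ve) with A the blue-range and Ve the
green-range reflectance. This band choice (rather than the classical
531/570 nm narrow bands) matches the broadband formulation used in the
CO₂-flux literature this model family comes from; with only broad
blue/green bands available it is the formulation the empirical
coefficients below were fitted against. sPRI = (PRI + 1)/2 rescales to
[0, 1] and is affine, hence order-preserving.

**CO₂-flux index.** flux = 13.63 − 66.207·(NDVI·sPRI), in µmol m⁻² s⁻¹.
The two constants are the published empirical regression coefficients;
the model is strictly decreasing in the NDVI·sPRI product and equals the
intercept 13.63 where the product vanishes. Printed forms of this
equation sometimes carry an unbalanced parenthesis; the only reading
consistent with "the multiplication between NDVI and sPRI" is the plain
product term, which is what is implemented.

**NDVI.** (NIR − red)/(NIR + red), the universal definition.

**GPP.** Two entry points: the light-use-efficiency model
GPP = ε·PAR·FPAR with ε = εmax·Tmin_scalar·VPD_scalar (scalars bounded
in [0, 1], all inputs non-negative), and digital-number scaling of 8-day
composite GPP products. The scaling default is 0.001/8 (DN → kg C m⁻²,
then → daily mean over the 8-day composite); product documentation also
circulates a plain 10⁻⁴ factor, so the factor is an explicit argument
(`GPP_SCALE_ALT`) rather than hard-wired — the two readings differ by
25% and the user should know which their product uses.

**NBR / ΔNBR.** NBR = (NIR − SWIR)/(NIR + SWIR); burning lowers NIR
(chlorophyll loss) and raises SWIR (char, dry soil), so NBR drops.
ΔNBR = NBR_pre − NBR_post: positive = burn damage, negative = post-fire
regrowth.

## Severity scheme

The seven-class scheme uses the conventional ΔNBR breaks on the ×10³
scale (ERH −500…−251, ERL −250…−101, UN −100…+99, LS +100…+269, MLS
+270…+439, MHS +440…+659, HS +660…+1300), divided by 1000. Published
tables of these breaks sometimes contain transcription slips in the
unscaled column; the ×10³ column is internally contiguous and matches
the literature's standard breaks, so it is authoritative here.

Boundary convention: half-open intervals, lower bound inclusive, upper
bound of the top class (1.300) closed, so the union covers
[−0.500, 1.300] with no gaps or double assignment. Values outside that
range (and NaN) get an explicit unclassified code (0); the count of
non-finite inputs is logged. Classification is a vectorized
`np.digitize` lookup; tests verify equivalence with an independent
per-class mask oracle on 10⁶ samples including exact boundary values.

## Risk mapping

Per pixel, f = (#years classified MLS/MHS/HS) / (#years with a valid
classification). Using valid years in the denominator avoids penalizing
pixels masked in some epochs; a pixel with no valid year is nodata.
The qualitative levels (low, moderate, elevated, high, very high) have
no canonical numeric definition in the applied literature, so the
default is the transparent equal-width rule [0,0.2), [0.2,0.4),
[0.4,0.6), [0.6,0.8), [0.8,1], with the breaks configurable. f is a
per-pixel mean of indicators, hence invariant to year ordering.

## Trend statistics

**Mann–Kendall.** S = Σ_{i<j} sign(x_j − x_i);
Var(S) = [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18 over tie groups t;
Z = (S ∓ 1)/√Var(S) with the continuity correction, Z = 0 when S = 0;
two-sided normal p. The normal approximation is standard for n ≥ 10 and
the intended use is n ≈ 22 annual values; exact small-n tables are not
implemented. An all-equal series short-circuits to S = 0, Var = 0,
p = 1 (no division by zero). Empirical size at α = 0.05, n = 22, is
verified by simulation to lie in [0.035, 0.065].

**Pettitt.** U_t = Σ_{i≤t} Σ_{j>t} sign(x_j − x_i) for t = 1…n−1;
K = max|U_t|; p ≈ 2·exp(−6K²/(n³+n²)), capped at 1. Ties in the argmax
resolve to the earliest t (deterministic, matching common
implementations). t* is the last index of the first regime; the
reported change year is the *first year of the shifted regime*, so a
step planted at year Y is reported as Y. Monte-Carlo checks bound the
approximation's size (null rejection ≲ 5% at α = 0.05) and verify ≥95%
recovery (±1 year) of a 3·sd mid-series step at n = 22.

**Pearson / PCA.** Series are inner-joined on year before correlation
or PCA (no imputation rule is assumed for missing years). Zero-variance
series give NaN correlations rather than an arbitrary value. PCA is
correlation-based by default because the variables mix units (mm,
counts, kg C m⁻² d⁻¹, µmol m⁻² s⁻¹); the eigendecomposition is
delegated to scikit-learn's full-rank SVD solver, and each component's
sign is fixed so its largest-magnitude loading is positive, making
loadings reproducible across runs. Scores × loadingsᵀ reconstructs the
standardized data to 1e−8.

## Synthetic scenes

The generator emulates the statistical structure of a burned seasonal
wetland, not its physics: no radiative transfer, vegetation growth,
clouds, or spatial autocorrelation beyond the planted scar footprints.

**Reflectance.** Unburned surface means per band: blue 0.05, green
0.10, red 0.06, NIR 0.40, SWIR 0.18 — a generic healthy-canopy
spectrum. Noise has two Gaussian components: a static per-pixel surface
field (sd 0.01, shared between the pre- and post-fire epoch of a year)
and independent epoch noise (sd 0.003). The split matters: the surface
component models real pixel-to-pixel heterogeneity and is large enough
to be visible yet far from the ≥0.17-wide severity-class widths, while
only the epoch component enters ΔNBR off-scar, keeping no-burn |ΔNBR|
noise at ≈0.011 sd so unburned pixels stay decisively inside the UN
class. A single independent draw per epoch at sd 0.01 would instead
push no-burn ΔNBR noise to ≈0.037 sd and produce spurious LS pixels.

**Burn scars.** Each event is a rectangle with a target class and a
target ΔNBR inside that class's interval (validated). Post-fire NIR
moves down and SWIR up symmetrically; since the move preserves
NIR + SWIR = s, the post-fire bands solve in closed form
(NIR′ = s(1+t)/2, SWIR′ = s(1−t)/2 with t = NBR_pre − severity), so the
achieved ΔNBR equals the target exactly unless reflectance clipping at
[0, 1] engages (it does not for the realistic severities ≤ 1.3 on this
spectrum). Same-year footprints must be disjoint. Negative-ΔNBR
regrowth classes (ERH/ERL) are planted the same way — directly as
negative targets — rather than via a regrowth trajectory model.

**Annual series** (defaults chosen as a realistic 22-year analog of a
seasonal wetland record, n = 22 years 2001–2022):

- precipitation: mean 1300 mm, sd 300 mm, built as a deterministic
  wet/dry sinusoid (period 11 yr, amplitude 0.5·sd) plus Gaussian noise
  sd √0.75·sd, so the total spread ≈ the configured sd;
- fire foci: Poisson with log-mean ln(1000) + c·z where z is the
  standardized precipitation anomaly and c = −1.5 by default — the
  simplest count model with a controllable negative coupling (wet years
  burn less);
- GPP: mean 0.018, sd 0.002 kg C m⁻² d⁻¹, loading +0.3 on z (wet years
  fix more carbon), with an optional level shift of `gpp_step` from
  `gpp_change_year` onward;
- CO₂-flux series: mean 10 µmol m⁻² s⁻¹, loading −0.8 on standardized
  GPP plus noise sd 0.6, giving the strong negative GPP–flux
  association expected when sequestration efficiency rises.

Randomness comes from one generator stream keyed by the scene seed with
deterministic substreams per (year, purpose), so a fixed seed is
bit-reproducible and regenerating one year does not disturb others.

**What passing tests show — and don't.** Recovery of planted scars and
couplings shows the chain is self-consistent and correctly implements
the stated models at realistic noise levels. It does not validate
atmospheric correction, compositing-window choices, cloud screening,
spatial autocorrelation effects, or sensor-specific artifacts of real
archives — results on real scenes inherit all of those upstream issues.

## Problem sizes

Default scenes are 16×16 pixels over 22 years; Monte-Carlo checks use
10,000 null replicates for the Mann–Kendall size, 1000 replicates for
Pettitt recovery, 1000 random series for oracle equality and 10⁶
samples for classifier equivalence. These sizes give comfortably tight
binomial error on the verified proportions while keeping the full suite
around ten seconds on one CPU.

## Known limitations

- The Pettitt p-value is the classical closed form, not an exact
  permutation p; its anti-conservatism is bounded by simulation, not
  eliminated.
- Risk-level bins are a documented stand-in for an unstated rule;
  comparisons against maps produced with quantile or expert bins need
  the `breaks` argument set accordingly.
- GeoTIFF support covers pixel-scale/tiepoint georeferencing and a
  nodata tag; CRS metadata (projection keys) is not written.
- The pre/post epoch pairing within a fire season is taken as given
  (explicit per-year stacks); no compositing is performed.
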