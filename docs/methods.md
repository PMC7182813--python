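# Methods

## Acid–base surface-energy decomposition

The solver works in sqrt-space: with unknowns x = √γ_j^LW, y = √γ_j^+,
z = √γ_j^−, each probe liquid contributes the linear equation
(1 + cos θ_i)·γ_i / 2 = x·√γ_i^LW + y·√γ_i^− + z·√γ_i^+. Exactly three
liquids give a direct 3×3 solve; more give ordinary least squares in the
same space. Angles are degrees at every interface and radians internally.

**Negative roots.** On weakly acidic polymers the solved √γ⁺ can be
negative. The components store the squared magnitude and a per-component
flag, and retain the root signs internally; forward-modelling a contact
angle from the solved components uses the signed roots, which makes
solve ∘ forward the identity. Magnitudes are never silently zeroed.

**Conditioning.** Liquid triplets that are nearly collinear in sqrt-space
are a known failure mode of the three-liquid method. The design matrix's
condition number is capped at 1e6 (error) with a warning above 1e3. The
shipped water/formamide/methylene-iodide triplet has condition number ≈ 13.

**Hydrophobicity bands.** The Rijnaarts water-angle bands are open-ended in
their usual statement; we close them on the left: [0, 20) hydrophilic,
[20, 50) intermediately hydrophobic, [50, 180] hydrophobic, so the
classification is a total function with exactly two breakpoints.

**Column-integrity diagnostic.** `apolar_lw_diagnostic` reports, per
measured liquid, the γ^LW implied if that liquid were the sole apolar probe
(γ_j^LW = ((1+cos θ)γ_i)²/(4 γ_i^LW)). Published angle tables sometimes
transpose liquid columns; for three of the four surfaces in the motivating
data set the published γ^LW follows from the formamide-column angle, not the
methylene-iodide column, and their printed γ⁺/γ⁻ are not recoverable from
the printed angles under either assignment. The diagnostic surfaces this;
the package does not guess a correction, and only the PET row is treated as
end-to-end reproducible.

**Display rounding.** CSV outputs carry full-precision columns plus
half-up one-decimal display columns. The display total is the sum of the
*rounded* LW and AB components, matching how printed tables are assembled
(for PET the unrounded total is 50.45, which would round to 50.5, while the
printed value 50.4 = 47.6 + 2.8).

**Uncertainty propagation.** `propagate_uncertainty` resamples each
liquid's angle from an independent normal truncated to [0, 180]°
(truncation rather than rejection keeps the draw count deterministic),
solves each draw, and reports per-component means, sds and the fraction of
draws with negative roots. Note the means of the squared magnitudes exceed
the point solve by approximately the variance of the corresponding root
(E[r²] = r₀² + Var r); the tests check this against the delta-method
prediction rather than pretending the estimator is unbiased. All-zero
angle sds short-circuit to the point solve with zero sds.

## Coverage quantification

Three steps: threshold (Otsu by default — parameter-free and standard for
bimodal bright-field images — or a fixed threshold), cleanup (morphological
opening with a disk of radius 1 px, then removal of 8-connected components
smaller than 25 px), and 8-connected component labelling. Coverage is
foreground pixels / total pixels; border objects are kept, since excluding
them would bias an area fraction downward. Touching cells are not split:
the target statistic is area fraction, for which watershed segmentation is
irrelevant, and object counts are reported only as a convention-dependent
secondary number. An optional rolling-mean background subtraction handles
illumination gradients and is off by default. Replicate statistics use the
sample (n−1) standard deviation; a single image reports sd 0 with a flag.

## Assay bookkeeping

Conditions are material × strain × pH × ionic strength × treatment, with
suspension OD570 (nominally 0.70) and settling time (nominally 24 h) as
metadata. The protease contrast reports after−before difference, the
root-sum-of-squares pooled sd, and the after/before ratio; "strong
reduction" means a *decrease* exceeding twice the pooled sd — a
conservative, assumption-light convention chosen because the underlying
assays report no formal test. No p-values are produced. Ionic strengths
are stored as molar values; the ionic-strength profile flags a drop when
coverage at the highest strength falls below the mean of the lower ones.

## Lipase kinetics

The initial rate is the OLS slope over the full ~100 s trace — more robust
than a two-point difference and adequate because substrate depletion is
negligible over the window; r² < 0.95 triggers a non-linearity warning, and
a constant trace is defined to fit slope 0 with r² = 0. Beer–Lambert
converts A/s to mol L⁻¹ s⁻¹ via a *required* molar extinction coefficient
(p-nitrophenol at pH 7 is of order 10⁴ L mol⁻¹ cm⁻¹; the value is never
hard-coded because it is condition-dependent), then to µmol/min over the
reaction volume. Specific activity divides by the debris mass loaded; for
surface-immobilized debris this is the mass loaded *before* adhesion, so
the retention ratio confounds washed-off debris with genuine activity loss
and is flagged as a lower bound on intrinsic retention.

## Synthetic data: what it emulates, what it does not

`gen_micrograph` places ovoid cells (radius ~ N(6, 1.5²) px clipped ≥ 2,
eccentricity 0.8–1.0) on a 512×512 field until the mask first reaches the
target coverage, then renders background 200 / cells 80 on an 8-bit scale
with additive Gaussian noise (sd 8) and an optional linear illumination
gradient. These defaults were fixed once as a plausible bright-field
rendering of yeast on a coupon — high contrast, salt-level noise — and are
deliberately simple: no realistic cell texture, no out-of-focus halos, no
uneven staining. A green recovery test therefore establishes that the
pipeline measures area fractions correctly on high-contrast images, not
that it would survive arbitrary real-microscope artifacts. Overlap is
allowed by default (settled yeast cluster); `forbid` gives disjoint cells
for unit tests. The exact mask and its realized coverage are returned with
every image, so recovery tests never re-derive truth.

`gen_replicate_micrographs` draws each image's target coverage from
N(mean, 0.05²) clipped to (0.01, 0.99) before rendering: real replicate
micrographs of one coupon differ in local density, with reported replicate
sds of 2–11% of area, and 0.05 sits mid-band. With this stated world the
per-image estimation error (~0.002) is negligible against the between-image
spread, as in the real assay.

`gen_contact_angles` forward-models angles from known components and adds
truncated-normal reading noise; `gen_kinetic_trace` is a line plus Gaussian
noise with the assay's nominal geometry (25.1 mL volume, 1 cm path, 50 mg
debris). Every generator is a pure function of its spec and seed.

## Known limitations

- Only area-fraction coverage is supported; no morphometry, fluorescence or
  time-lapse analysis.
- The solver assumes the probe-liquid constants are exact; errors in the
  liquid table propagate unexamined.
- No interfacial free-energy-of-adhesion (ΔG through water) or DLVO-style
  energy-distance modelling is included.
- Retention of immobilized activity cannot separate detachment losses from
  inactivation; the caveat flag is structural, not fixable downstream.
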