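# relcap

Release limits and expiry time for drug products, from manufacturing
process capability and degradation rate.

## The problem

Specification limits (e.g. 95–105% of the labeled drug concentration) are
what a regulator registers; **release limits** are the manufacturer's
tighter internal bounds applied at batch release, so that a batch that
passes release still meets specification at the end of its shelf life after
degrading. Setting them well requires answering four coupled questions:

1. How uncertain is the assay? (calibration + delta-method propagation)
2. How capable is the manufacturing process? (Cpk under a batch effect)
3. How fast does the product degrade, and may batches be pooled?
   (stability regression + ICH-style poolability testing)
4. Given all that, what expiry time can the process actually support, and
   how should future batches be tested at release? (release-limit
   equation + ASTM E2709-12 acceptance regions)

`relcap` implements the full five-step procedure for users in
pharmaceutical development, QC statistics and stability programs.

## The statistics in brief

- **Capability.** Time-zero assays follow a one-way random-effects model
  `y_ij = μ + a_i + e_ij`, fitted by REML; the capability index
  `Cpk = min((USL−μ)/3σ, (μ−LSL)/3σ)` uses the total SD
  `σ = √(σ²_batch + σ²_within)` and gets a parametric-bootstrap CI.
  Capability (control) limits are `μ ± 3σ`.
- **Stability.** Per-batch straight lines plus a sum-to-zero
  full-interaction fit; type III ANCOVA tests poolability at α = 0.25;
  a Ruberg–Stegeman *critical alpha* (noncentral F) guards against
  accepting poolability from an underpowered test. Shelf life is the
  crossing of a one-sided lower 95% band with the LSL — confidence band
  (the ICH definition) or prediction band for a future individual value.
- **Release.** `LRL(T) = LSL + |b|·T + t₁₋α,ν·√(T²·s_b² + s²)` is strictly
  increasing in the expiry time T, so setting `LRL = LCL` (the lower
  capability limit) and inverting by bisection yields the longest expiry
  the process supports.
- **Batch release.** A Bergum-type ASTM E2709-12 region: release when the
  sample demonstrates, with confidence C, that a proportion ≥ p of the
  batch lies inside [LRL, URL]; equivalently a maximum admissible sample
  SD per sample mean.

See `docs/methods.md` for models, assumptions, numerical choices and
limitations.

## Worked example

`python examples/calibration_uncertainty.py` prints

```
peak area 62.0629 µV·s, dilution factor 0.2
back-calculated concentration: 1.463 µg/mL
delta-method SD:               0.02023 µg/mL  (CV 1.38%)
```

— the concentration behind a measured HPLC area and its propagated
uncertainty. `python examples/release_expiry.py` runs capability and
stability analyses on a simulated three-batch study and inverts the
release-limit equation:

```
release interval [LRL, URL] = [1.4373, 1.4924] µg/mL
pooled slope -8.762e-03 ± 3.218e-04 µg/mL per month
solved expiry time: 4.58 months
```

The release interval is the capability interval `μ ± 3σ`; 4.58 months is
the time at which the rising lower release limit meets the lower capability
limit — the longest expiry this process can support while guaranteeing, at
95% confidence, that released batches still meet the 1.3813 µg/mL LSL. It
is deliberately shorter than the band-crossing shelf life (~8.4 months
here): the difference is the price of controlling the defective fraction at
expiry. The other scripts in `examples/` cover capability analysis,
stability/shelf life, the ASTM acceptance region and the end-to-end
pipeline; each prints a short interpretation of its numbers.

A thin CLI mirrors the library (`relcap capability|stability|release|astm|
simulate|pipeline --help`); exit codes distinguish validation errors (2),
capability failure (3) and design/numerical failure (4).

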