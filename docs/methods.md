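# Methods

This note documents the statistical procedure `medsurvey` implements, the
conventions it fixes where the survey methodology leaves room, the synthetic
data model used to validate it, and the package's known limitations.

## Survey model

A survey observes, for each of ~25 strength- and dosage-form-specific
medicines and each sampled outlet (public or private sector, six regions),
every product in stock on the survey day: its pack price, pack size, origin
(local = manufactured and packaged in the survey country; imported
otherwise) and product type (originator brand, branded generic, INN
generic). Availability is encoded by presence: an (outlet, medicine) pair
with no record was out of stock. The outlet census supplies denominators,
so outlets stocking nothing still count. Government tender records add, per
procured product, a quoted unit price, quantity and INCO term.

## Price analysis

1. **Unit price** = pack price / pack size, carried in exact decimal
   arithmetic (28 significant digits).
2. **Price point**: where an outlet stocks more than one same-origin product
   of a medicine, the outlet contributes the *median* unit price. Counting
   happens after this collapse: 4 products in 2 outlets are 2 price points.
3. **Median price ratio**: `MPR = median(price points) / (IRP_USD × fx)`,
   with `fx` the local-currency-per-USD rate on the first survey day. The
   IQR is the 25th/75th percentile of the outlet-level ratios. Patient-price
   MPRs require ≥ 4 price points per sector; procurement MPRs require ≥ 1.
   Cells failing the threshold are returned as explicit exclusions —
   included + excluded always account for every candidate cell.
4. **Cross-medicine summaries** take the median (and IQR) across the
   per-medicine median MPRs.

Conventions fixed here (the methodology does not specify them): medians use
linear interpolation at even counts; quantiles are linearly interpolated
("type 7"); reported MPRs are rounded to 2 decimals and percentages to
integers with ties away from zero, while all internal computation is
unrounded. Percent differences in report tables are computed from the
2-decimal MPRs as printed, so a reader can reproduce every percentage from
the table itself; the unrounded path is available
(`paired_patient_comparison(..., rounded=False)`).

Two presentations of the patient-price IQR are possible (across medicines of
the per-medicine medians, or the median of the per-medicine IQRs); sector
summaries report the former, the paired patient table also shows the latter
as `median_iqr_low/high`.

## Tender analysis

Imported quotes under terms that exclude delivery costs are scaled to landed
cost by **additive** surcharges: factor = 1 + Σ(component %)/100. Components
add rather than compound because the schedule is a list of charges on the
same base price (15 + 0.5 + 1.5 + 5 → ×1.22 for FOB/FCA; 0.5 + 1.5 + 5 →
×1.07 for CFR; compounding would give ×1.229). Local products and
fully-delivered quotes (`none`) are unchanged; a term with no schedule entry
is a configuration error rather than a silent pass-through.

Per medicine, origins are compared on median landed unit prices. The local
premium, 100 × (local/imported − 1) rounded to the nearest integer percent,
is checked against the local-preference margin; "up to N%" is read
inclusively, so premium = margin is within policy. The substitution
counterfactual reprices the dearer origin's full purchased quantity at the
cheaper origin's median landed unit price (capacity constraints ignored):
savings = q_dearer × (p_dearer − p_cheaper), by default on landed prices
(`use_landed=False` switches to quoted). Quantity shares are conserved
exactly before rounding and reported to one decimal.

The **mark-up ratio** is patient MPR / procurement MPR per medicine and
origin, summarized as the median across medicines with both sides present.

## Synthetic data model

`medsurvey.synthetic` generates countries whose true parameters are known:

* **Structure**: 6 regions; 6 public + 5 private outlets per region by
  default (≈ the pilot samples of 30–34 outlets per sector); the standard
  25-medicine essential-medicines list.
* **Availability**: per (sector, origin, medicine), each outlet stocks ≥ 1
  product with probability `availability_prob`, independently. Defaults:
  0.48/0.19 (public local/imported) and 0.54/0.35 (private).
* **Multiplicity**: the number of same-origin products per stocked cell is
  drawn from {1, 2, 3} with weights (0.7, 0.2, 0.1), exercising the
  median-collapse rule.
* **Prices**: unit prices are log-normal with median
  `target_mpr × IRP × fx` and coefficient of variation `price_cv`. The
  log-normal is used because prices are positive, right-skewed, and the
  median — the estimand — parameterises it directly. Default targets
  (1.44/1.18 public, 1.85/5.42 private) put the generator at the magnitudes
  such surveys report. Default `price_cv` = 0.15: a delta-method power check
  shows the median-of-25-medians then estimates its target with SE ≈ 0.02–
  0.03 in the dearest stratum at 500 outlets/sector, so ground-truth
  recovery to ±0.05 is a meaningful test; much larger CVs (observed IQRs can
  imply CV ≈ 1 in private-sector imports) make that tolerance unattainable
  at any realistic outlet count and can be set per stratum when dispersion
  itself is under study.
* **Reference prices**: drawn once per seed, log-uniform over 0.01–0.50 USD
  per dose unit (the range typical of per-tablet reference prices for
  essential generics), quantized to 4 decimals.
* **Exchange rate**: default 18.73 local units/USD, the ratio implied by a
  published 2013/14 medicines budget of 8.26 billion local units ≈ USD 441
  million.
* **Tenders**: per medicine, local products are tendered with probability
  21/25 (1–5 award lines), imports with probability 12/25 (one line, INCO
  term FOB/FCA/CFR with weights 0.45/0.25/0.30). Tender prices are
  log-normal around `procurement_target_mpr × IRP × fx` with CV 0.05 —
  tenders are single administratively awarded prices, far less dispersed
  than retail. Imported lines are quoted so that the *landed* price hits the
  target. Procurement targets default to patient target / mark-up target
  (mark-up defaults 1.17 local, 1.53 imported), making patient, procurement
  and mark-up recovery mutually consistent. Quantities are log-uniform over
  1e5–5e7 dose units.
* **Determinism**: one `numpy` Generator seeded from the spec seed (separate
  streams for survey, tenders and reference prices, derived as
  `[seed, k]`); identical seeds give byte-identical CSVs.

What the generator does **not** model: between-medicine heterogeneity in
true MPRs under the default spec (every medicine shares its stratum target,
so cross-medicine IQRs are narrower than real surveys; per-medicine
overrides exist), inter-region price or stock correlation, seasonal
stock-outs, unpriced stock, and missing data. Passing recovery tests
therefore show the *estimators* are correct and unbiased at survey scale —
not that real field data meet these independence assumptions.

## Numerical and degenerate-input choices

* Prices are `Decimal` end-to-end in I/O, so write→read round-trips are
  bit-exact; analysis converts to floats.
* Generated pack prices are quantized to 6 decimals; with zero noise and
  target MPR 1 the generated unit price equals IRP × fx exactly, which the
  degenerate-case tests rely on.
* Empty inputs: an outlet with no matching product contributes nothing (not
  a zero); an empty summary list yields an explicit empty sentinel; zero
  surveyed outlets or zero total quantity raise errors rather than NaN.
* Ties: a medicine whose origins tie on landed median price has no cheaper
  origin and contributes no savings.
* Referential integrity is validated eagerly at dataset construction;
  engines never see dangling references.

## Limitations

Availability is a single-day snapshot; the landed-cost schedule covers only
the configured surcharge components (no port-clearance estimation); no
confidence intervals or hypothesis tests are attached to MPRs (medians over
small medicine lists are reported as-is); affordability (days'-wages) and
supply-chain price-component analyses are out of scope.
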