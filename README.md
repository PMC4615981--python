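# discomorb

Physico-chemical signature analysis for disease-associated protein sets —
built for the comparative question behind inverse cancer/CNS-disease
comorbidity: do the proteins up- or down-regulated in neurodegenerative
disorders differ systematically, in structural disorder and related
sequence features, from those deregulated in cancers?

The package is aimed at computational biologists who have gene/protein
membership lists (e.g. up-/down-regulated sets for Alzheimer's,
Parkinson's, Schizophrenia, colorectal, lung and prostate cancer), a
sequence universe in FASTA, and optionally an abundance table and a
mutation/age-of-onset table — and who want a reproducible, testable
version of the classic propensity-scale comparison pipeline instead of a
web service.

## What it computes

**Propensity profiles and scores.** For a protein sequence `s` and a
per-residue propensity scale `b` (disorder, hydrophobicity, α-helix,
β-sheet, burial, aggregation, membrane, or nucleic-acid-binding
propensity; ≥ 3 published scales per class are bundled, more can be
plugged in as TSV), the profile is the sliding-window mean
`P_i = mean(b(s_j), j ∈ window(i))` (window 7, clipped at the termini) and
the protein score is the profile mean. A DisEMBL-style summary — the
fraction of positions above a significance threshold — and the B-value
disorder score — the mean of a [0, 1]-normalised flexibility scale over
residues with values > 0.2 — are also provided.

**Enrichment calls.** Two sets are compared per scale by splitting all
protein scores at the pooled median and testing the resulting 2×2 table
with the two-sided Fisher exact test, computed in exact integer
arithmetic. A comparison is *signal-enriched* / *negative-enriched* only
when `p < 10⁻⁵` (configurable); otherwise non-significant — the
red/green/yellow tri-state of the comparison matrices.

**Signal strength.** A grid of N comparisons with k significant calls in
the majority direction is summarised as `s = ±k/N` (half-up, two
decimals): 17 concordant of 18 gives +0.94; 31 of 36 in the opposite
direction gives −0.86. `agreement_score` applies the same arithmetic
across an up-regulated and a down-regulated matrix.

**Abundance.** Set vs. background log₁₀-abundance distributions are
compared with the two-sample Kolmogorov–Smirnov test (D, asymptotic p,
LOWER/HIGHER/NS call).

**Age of onset.** Per-mutation disorder scores are binned by onset age
(2.5-year windows), the disorder axis is Z-normalised, and the relation is
fitted with a four-parameter logistic `AGE = A + (B−A)/(1+exp(k(z−m)))`
and with linear regression, reporting Pearson correlations and RMSE.

**Synthetic data.** Seeded generators produce composition-biased protein
sets (disorder- vs. order-promoting residues), shifted log-normal
abundance tables, logistic (disorder, onset) samples with known
parameters, and comparison-grid fixtures — so the full pipeline runs and
is tested without any external download.

## Worked example

```python
import discomorb as d

reg = d.default_registry()
cns_up    = d.generate_set(d.composition_preset("disordered"), 200, seed=1, set_name="CNS_UP")
cancer_up = d.generate_set(d.composition_preset("ordered"),    200, seed=2, set_name="CANCER_UP")

mat = d.build_matrix([cns_up], [cancer_up], reg, "disorder")
for o in mat.outcomes():
    print(f"{o.scale_name:18s} p={o.p_value:.3g} {o.direction.value}")
ss = d.signal_strength(mat)
print("signal strength:", ss.value, f"({ss.n_follow}/{ss.n_total})")
```

prints

```
top_idp            p=7.77e-115 A_ENRICHED
bfactor_vihinen    p=7.77e-115 A_ENRICHED
flex_bhaskaran     p=8.13e-104 A_ENRICHED
bvalue             p=7.77e-115 A_ENRICHED
signal strength: 1.0 (4/4)
```

i.e. the disorder-biased set is called enriched on every bundled disorder
scale at `p ≪ 10⁻⁵`, a signal strength of +1.00. The onset stage, on
synthetic logistic ground truth (A=40, B=85, k=3, m=0.5, 428 mutations,
2-year noise, 2.5-year bins):

```python
pairs  = d.generate_onset(d.OnsetGeneratorSpec(), seed=3)
points = d.z_normalize_points(d.bin_by_onset(pairs))
fit = d.fit_onset(points, "SIGMOID")
lin = d.fit_onset(points, "LINEAR")
print(fit.params, fit.pearson_r, fit.rmse)   # {'A': 35.97, 'B': 86.55, 'k': 1.93, 'm': 0.23}, -0.974, 1.20
print(lin.pearson_r, lin.rmse)               # -0.974, 3.41
```

The strongly negative correlation says: the more disordered the mutated
protein, the earlier the onset. The sigmoid's RMSE (1.2 y) vs. the
linear fit's (3.4 y) shows the plateau structure the logistic captures.

The same stages are available from the shell:

```bash
discomorb simulate sets --preset disordered --n 200 --seed 1 --out-prefix cns_up
discomorb simulate sets --preset ordered    --n 200 --seed 2 --out-prefix cancer_up
discomorb multicompare --signal cns_up.fasta --negative cancer_up.fasta \
    --feature-class disorder --out matrix.tsv --summary summary.json
discomorb run --config study.yaml --outdir results/
```

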