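# easilung

Predicting whether a tumor is of lung origin from the spectrum of its
somatic substitutions.

Identifying a tumor's tissue of origin matters for therapy choice, and in
cancers of unknown primary (CUP) it is often not resolvable by histology.
Tobacco carcinogens such as benzo[a]pyrene leave a recognizable imprint on
the lung exome: bulky guanine adducts, preferentially repaired on the
transcribed strand, generate an excess of G>T transversions (and their
complementary C>A changes) on the coding non-transcribed strand.  The
EASILUNG test exploits this: from a whole-exome somatic variant list it
computes the relative frequencies of the 12 strand-resolved substitution
classes (C>A, G>T, C>G, G>C, C>T, G>A, A>C, T>G, A>G, T>C, A>T, T>A) and
combines eight of them into an integer-weighted score

```
score = +175·[%CA > 12] + 62·[%GT > 13]
        − 9·%CT − 6·%GA − 17·%AC − 17·%TG
        − 74·[%AG > 5] − 73·[%TC > 5]
```

where `[·]` is 1 when the condition holds.  The point values are 100× the
coefficients of a logistic regression of lung-vs-other origin, rounded to
the nearest integer.  A logit calibration maps the score to a probability
of lung origin, `P = 1 / (1 + exp(−(A + B·score)))`, and a Youden-optimal
threshold turns it into a call.  Samples with a mutational burden below
1 sub/Mb are called non-lung before scoring (lung tumors in smokers almost
always exceed that burden).

The package is for bioinformaticians and biostatisticians who want to

* **apply** the published score to MAF files or two-column ref/alt lists
  (`easilung score`),
* **recalibrate** it on a new sequencing platform — the score terms
  transfer, the probability mapping and threshold do not
  (`easilung recalibrate`),
* **re-derive** a score of this family from a labelled cohort with the
  full development pipeline — Youden binarization, multivariable logistic
  regression, backward selection at p = 0.2, bootstrap stability
  selection, integer points, AUC / Hosmer–Lemeshow assessment and
  threshold choice (`easilung develop`), or
* **simulate** labelled cohorts with realistic spectrum dispersion and
  burdens straddling the 1 sub/Mb gate (`easilung simulate`).

## Worked example

Score a tumor with 100 somatic substitutions on a 50 Mb capture
(27% C>A, 19% G>T, 8% C>T, 12% G>A, 3% A>G, 5% T>C, remainder in the
unscored classes):

```python
from easilung import build_profile, classify_sample, published_model
from easilung.variant_io import read_pair_list

sv = read_pair_list("sample.tsv", "S1", target_region_mb=50)
call = classify_sample(build_profile(sv), published_model("development"))
print(call.score, round(call.probability, 2), call.label)
```

prints

```
93.0 0.9 lung
```

The score 93 comes from +175 (%CA > 12) +62 (%GT > 13) −9·8 −6·12 with
the remaining terms at zero; 93 exceeds the −303 development threshold, so
the call is `lung`, with probability `expit(1.216 + 0.010·93) = 0.895`.
A C>T/G>A-dominated spectrum (27% / 37%) scores −624 and is called
`non-lung`.  The same call from the shell:

```sh
easilung score --pairs sample.tsv --target-mb 50 --out calls.tsv
```

The bundled model variants are `development-2019` (calibration
1.216 + 0.010·score, threshold −303) and `validation-2019` (the identical
score terms recalibrated for a 50 Mb capture: 2.094 + 0.008·score,
threshold −467); `easilung recalibrate` writes further variants as JSON
files consumable by `--model`.

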