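# lastsight

Extinction-time inference from dated sighting records.

The last fossil of a species is not its last individual: a finite record
of dated occurrences ends, on average, well before the true extinction
time (the Signor–Lipps effect). `lastsight` is a Python package for
palaeobiologists and quantitative ecologists who want to turn a table of
directly dated occurrences — here, the published radiocarbon record of
the late cave bear (*Ursus spelaeus* sensu lato), which ships as a
packaged 23-date reference table — into defensible statements about when
the taxon disappeared.

It provides, as one tested pipeline:

* **Radiocarbon calibration** of ¹⁴C determinations against a gridded
  calibration curve (IntCal `.14c` dialect), producing a posterior
  density over calendar age with mean, SD, median and central 95%
  interval;
* **Record filtering**: an age-range acceptance window and the three
  analysis variants of the reference record (either duplicate date of the
  twice-dated Stajnia Cave specimen, or the conservative
  collagen-vetted subset);
* **Seven last-occurrence estimators** on the sighting series
  t₁ ≤ … ≤ t_n (cal BP, youngest first, r = t_n − t₁):
  Strauss–Sadler `t₁ − r(α^(−1/(n−1)) − 1)`, Solow
  `t₁ − r(α^(−1/n) − 1)`, McInerny `t₁ − ln α / ln(1 − n/r)`,
  Solow–Roberts `t₁ − (t₂ − t₁)(1 − α)/α`, Roberts–Solow optimal linear
  estimation (Weibull extreme-value weights on the k youngest dates), and
  the inverse-weighted McInerny resamplers GRIWM (Gaussian, using each
  date's calibration error) and BRIWM (bootstrap), each reported as a
  median with central 95% resampling interval;
* **Record-density modelling**: ML fits of normal / lognormal / gamma /
  Weibull families with AIC/BIC selection, and the averaged density over
  the two duplicate-date variants;
* **Climate correlation**: Pearson correlation of the density curve with
  a proxy series (e.g. Greenland δ¹⁸O) on an inclusive 20-year grid;
* **Synthetic records with known truth** and a coverage harness that
  validates every estimator's one-sided 95% bound by simulation.

See `docs/methods.md` for the full model descriptions and conventions.

## Worked example

```python
import lastsight as ls

rs = ls.apply_range_filter(ls.load_reference_records())
model = ls.ExtinctionModel.from_records(ls.select_variant(rs, "include_poz"))
res = model.fit(alpha=0.05, iters=10_000, seed=1)
print(res.summary())
```

```
Extinction-time estimates (cal BP; larger = older)
  sightings: n = 22, youngest = 25,251, span r = 4,842 yr
  alpha = 0.05; closed-form methods report the one-sided
  95% bound toward the present; resampling methods report the
  median and central 95% interval; OLE bound uses c = (-ln a/k)^(-v).

  method                 bound95      median          95% interval  note
  strauss_sadler          24,509                                    
  solow93                 24,545                                    
  mcinerny                24,593                                    
  solow_roberts            9,462                                    
  roberts_solow_ole       22,145                                    
  briwm                               24,593       (24,163–26,025)  
  griwm                               24,415       (23,797–25,097)
```

Reading this: with the youngest Stajnia date included, the closed-form
methods place the one-sided 95% boundary around 24,500–24,600 cal BP —
the most recent time still consistent with the 22-date record at
α = 0.05. GRIWM, which down-weights old gaps and propagates each date's
calibration error, puts the median extinction time at ~24,400 cal BP
(interval ~23,800–25,100). The Solow–Roberts two-sighting bound (9,462
cal BP) illustrates why that method is considered over-conservative: it
depends only on the gap between the two youngest dates, and a single
young outlier stretches it enormously — bounds that reach past 0 BP are
flagged "no extinction signal".

The same analysis runs from the shell:

```sh
lastsight estimate --variant include_poz --seed 1
lastsight run --config config.yaml --out report/   # all variants + densities
```

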