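# cefacall

Genotype calling for multiplex-PCR capillary-electrophoresis fragment
analysis (mPCR-CEFA) of alpha- and beta-thalassemia, plus a synthetic
electropherogram simulator that makes the whole pipeline testable without
instrument data.

**Who it is for.** Developers and evaluators of CE fragment-analysis
genotyping panels who need the analysis half of the assay — peak detection,
size-ladder calibration, peak-to-target binding, dosage-ratio copy-number
classification, mutation/wild-type peak interpretation and diploid genotype
assembly — as a reproducible, scriptable library rather than vendor software.

**The model.** Unequal crossover in the alpha-globin cluster yields deletion
and triplication alleles that change the integer copy number of four dosage
amplicons (α1, α2, Y1, Y2).  For a diploid genotype the peak-height ratios

    R_a = h(α1) / h(α2),    R_y = h(Y1) / h(Y2)

equal the ratios of summed per-allele copies: e.g. 2:1 and 1:2 for −α3.7/αα,
1:1 and 1:3 for HKαα/αα.  Classification works in log-ratio space: with
multiplicative height noise of per-peak CV c, each log ratio is Gaussian with
σ = √2·c around the class centroid, and the nearest centroid by combined
z-score is the maximum-likelihood class (gated at z ≤ 4, with a
log-likelihood tie refusal).  Non-deletional variants, breakpoint (gap-PCR
style) deletion markers and NED wild-type control peaks then pin the allele
pair: the caller enumerates every unordered allele pair consistent with the
class and the observed peak pattern, reporting one genotype (OK), several
(AMBIGUOUS, all listed, most parsimonious first) or none (NO_CALL).  Failed
GAPDH/AMEL internal controls make a sample UNINTERPRETABLE, never a genotype.

See `docs/methods.md` for the full model, thresholds and design rationale.

## Worked example

```python
import cefacall as cc

panel = cc.default_panel()            # 16 alpha + 24 beta variant genotypes
sample = cc.simulate_peak_table("aCD74a/-a4.2;bCD17/bN", panel,
                                cc.zero_noise_params(), seed=1)
call = cc.call_sample(sample.peak_table, panel)
print(call.status, call.labels(panel))
print(call.measurement.a_ratio, call.measurement.y_ratio)
```

prints

```
OK ['aCD74a/-a4.2;bCD17/bN']
2.0 2.0
```

the unique compound call: 2:1/2:1 dosage identifies the −α4.2 heterozygote,
the VIC aCD74 peak places Hb Q-Thailand on the other chromosome, and the FAM
βCD17 peak with its NED wild-type control makes the beta side heterozygous.
The mirror case `aWSa/--SEA;bCD37/bN` returns AMBIGUOUS with exactly
`['aWSa/--SEA;bCD37/bN', 'aWSa/--SEA;bCD37/bCD37']`: the SEA deletion hides
behind 1:1 ratios until its breakpoint peak is read, and βCD37 has no
wild-type control so het and hom cannot be told apart.

The `examples/` scripts walk one capability each (copy model, noisy cohort
calling, compound genotypes, raw-trace pipeline, QC failure and recovery),
and a thin CLI wraps the same library:

```sh
cefacall validate-panel
cefacall simulate --genotype "-a3.7/aa;bN/bN" --n 20 --seed 7 --out sim/
cefacall call sim/S*.csv --manifest sim/manifest.tsv --out calls/
cefacall report --calls calls/ --manifest sim/manifest.tsv
```

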