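# isomirseq

Small-RNA sequencing analysis of **isomiRs** — the 5′/3′ end variants of
mature miRNAs — built for experiments that ask whether a stimulus shifts
miRNA *abundance* or miRNA *processing* (isomiR composition), e.g.
neurotrophin-stimulated neurons profiled as 2 conditions × 3 replicate
libraries.

The package covers the full path from raw reads to replicate-level
statistics:

1. **Preprocessing** — 3′ adapter trimming (`AGATCGGAAGAGCACACGTCT` by
   default), FASTX-style quality filtering (≥ 90 % of bases at Phred ≥ 30),
   and exclusion of adapter-only, adapterless, and < 15 nt reads, with
   exact per-fate accounting.
2. **IsomiR calling** — each clean read is explained as a variant of an
   annotated mature miRNA on its precursor hairpin, within a tolerance
   window of one mismatch, ≤ 3 nt trimming at either end, and ≤ 3 nt 3′
   addition. Additions matching the hairpin flank are *templated*
   (consistent with shifted Dicer cleavage); others are *non-templated
   tails*. The canonical read is labelled `0`; 3′ variants are labelled by
   their signed offset (`-2`, `+1`); 5′ variants `5p:±k`; tails `nt:<seq>`.
3. **Quantification** — per-sample count tables at isomiR and miRNA
   resolution; RPM normalisation (reads per million mapped miRNA reads);
   abundance filters (miRNA: mean ≥ 10 RPM in at least one condition;
   isomiR: ≥ 1 RPM); isomiR **proportions** p(label) =
   count(label) / count(miRNA) restricted to templated labels; 5p/3p
   **arm ratios** log₂((RPM₅ₚ+ε)/(RPM₃ₚ+ε)); and an AU-rich (`UAAAU`)
   motif scan.
4. **Differential analysis** — spreadsheet-style two-tailed Student's
   t-tests ("type 2" pooled-variance, "type 3" Welch), paired by
   experiment by default; per-miRNA volcano tables of mean log₂ fold
   change vs p, and per-(miRNA, label) tests on replicate proportions
   with a per-miRNA "any isomiR changed" flag.
5. **Simulation** — a seeded generator of toy hairpin references and
   two-condition libraries with known isomiR mixtures, abundance effects,
   adapter read-through, quality strings and substitution errors, plus
   machine-readable truth tables. Three standard scenarios are bundled:
   null, canonical-proportion shift (0.60 → 0.45, compensated by a
   shorter isoform), and a ×0.5 abundance effect.

The isomiR caller is validated against an independent brute-force oracle
that literally enumerates every variant string in the tolerance window,
and the t-tests against scipy's reference implementations.

## Worked example

Simulate a processing-shift experiment and analyse it:

```python
import isomirseq as iq
from isomirseq.simulate import default_design, null_and_effect_scenarios

ref = iq.make_toy_reference(n_hairpins=3, seed=1)
bundle = null_and_effect_scenarios(default_design(ref, reads_per_sample=200_000))
sim = iq.simulate_libraries(bundle.proportion_shift, ref, seed=42)
result = iq.run_experiment(sim, ref)
analysis = iq.analyze_experiment(result)

pl = analysis.per_label
print(pl[pl["mature_id"] == bundle.target_mature][
    ["label", "mean_control", "mean_treated", "delta", "p_value", "significant"]
].to_string(index=False))
```

```
label  mean_control  mean_treated     delta  p_value  significant
    0      0.619034      0.464852 -0.154182 0.000427         True
   -3      0.102950      0.256829  0.153880 0.000097         True
   -1      0.258151      0.258935  0.000784 0.770946        False
   +1      0.000004      0.000031  0.000027 0.071255        False
 0|m1      0.012888      0.009619 -0.003269 0.008590         True
-3|m1      0.001975      0.004721  0.002746 0.000702         True
```

The designed shift (canonical down 0.15, the 3-nt-shorter isoform up
0.15) is recovered with the correct sign and clear significance, while
the untouched `-1` class is flat. Labels carrying a `|m1` suffix collect
reads with one substitution (sequencing errors); they shadow their parent
classes at ~2 % and echo the same shift. Preprocessing accounting for one
library of this run — all 200 000 reads assigned a single fate:

```
{'input_reads': 200000, 'kept_reads': 195900, 'dropped_quality': 4100,
 'dropped_no_adapter': 0, 'dropped_adapter_only': 0, 'dropped_short': 0}
```

A CLI mirrors the library (`isomir simulate / preprocess / call / quant /
diff`); see `isomir --help`.

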