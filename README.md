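# mirmem

Analysis pipeline linking high-load short-term-memory (STM) performance in
middle-aged mice to differential hippocampal miRNA expression.

In the six-different-object task (6-DOT) a mouse studies six distinct
objects — exploration capped at 210 s (35 s per object) — and at test one
object is replaced by a novel one. A subject that remembers the studied set
explores the novel object preferentially; middle-aged cohorts split into a
memory-preserved and a memory-impaired subgroup. `mirmem` implements the
full computational chain of such a study:

* **behavior** — exploration scoring, the Unimpaired/Impaired criterion
  (`New > mean(Familiar) + 1.5 · SD(Familiar)`), percent novel-object
  exploration, pooled-variance t-test, one-way repeated-measures and
  split-plot (mixed) ANOVA.
* **microarray** — two-channel (Hy3/Hy5) LNA array processing from
  probe-level intensities: flag removal, endogenous-control median
  normalization of log2(Hy3/Hy5) ratios, the strict (8, 14) log2-intensity
  window, technical-replicate averaging, the |log2 FC| > 0.5 / SD 0.4
  retention rule, and up/down/unchanged calling at ±0.7.
* **qpcr** — 2^−ΔΔCt relative quantification against a U6-like reference
  with asymmetric error bars `2^−(ΔΔCt∓SD) − 2^−ΔΔCt`.
* **integration** — Pearson correlation of array vs qPCR log2 fold changes
  and candidate ranking above a +0.5 log2 FC threshold.
* **network** — consensus target selection (≥ 2 of TaPmiR > 0.95,
  TargetScan, miRDB, or validated) and descriptive degree statistics
  (2E/N average degree, hubs) of a target interaction graph.
* **synthetic** — seeded generators for cohorts, replicate slides and Ct
  triplicates with known ground truth, so every stage is testable without
  animal or slide data.

## Worked example

```python
import mirmem as m

# 29-subject cohort with a latent impaired fraction
records, truth = m.simulate_cohort(m.CohortSpec(seed=1))
tests = [r for r in records if r.phase == "test"]
tally = m.classify_cohort(tests)
print(f"{tally.n_unimpaired}/{tally.n_total} Unimpaired "
      f"({tally.pct_unimpaired}%), {tally.n_impaired} Impaired "
      f"({tally.pct_impaired}%)")

# two technical-replicate slides, 179 miRNAs, 38 planted upregulated
slides, planted = m.simulate_array(m.ArraySpec(seed=1))
calls = m.run_pipeline(slides)
s = m.summarize_calls(calls)
print(f"{s.n_total} miRNAs considered: {s.n_up} up, {s.n_down} down, "
      f"{s.n_unchanged} unchanged")

# Ct triplicates -> 2^-ddCt fold changes with asymmetric errors
ct, _ = m.simulate_qpcr(m.QpcrSpec(seed=1))
for e in m.quantify_table(ct):
    if e.assay == "mir-153-3p":
        print(f"{e.assay} {e.sample_id}: FC={e.fold_change:.4f} "
              f"+{e.upper_error:.3f}/-{e.lower_error:.3f}")
```

prints

```
17/29 Unimpaired (58.6%), 12 Impaired (41.4%)
179 miRNAs considered: 38 up, 0 down, 141 unchanged
mir-153-3p IM: FC=2.1863 +0.402/-0.339
mir-153-3p UM: FC=1.0000 +0.106/-0.096
```

The cohort classifier recovers 28/29 latent phenotypes at this effect size;
the array pipeline calls exactly the 38 planted upregulated miRNAs up and
leaves the 141 nulls unchanged; the calibrator pool's fold change is 1 by
construction, and the upper error bar always exceeds the lower one because
the exponential transform of a symmetric ΔΔCt error is asymmetric.

The same stages are available from the shell via the `mirmem` command
(`simulate`, `classify`, `array`, `qpcr`, `integrate`); see
`mirmem --help`.

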