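# ssvep-ratio

Analysis toolkit for **steady-state visual evoked potentials (ssVEP)** and
flicker **electroretinograms (ERG)**: harmonic amplitude extraction at exact
stimulus frequencies, coherent (vector) averaging across repetitions,
amplitude-outlier artifact rejection, Naka–Rushton contrast-response
fitting, and the **sustained/transient frequency-ratio index** with its
group-level statistical battery. A bundled synthetic-cohort generator with
full ground truth makes every stage testable end to end.

## The problem

When a visual stimulus flickers at frequency *f*, phase-locked neural
responses appear at the stimulation frequency (the first harmonic, 1F) and
at its double (2F). The two harmonics index different response dynamics:
1F tracks the *sustained* component, 2F the *transient* component driven by
brightening/darkening of the stimulus. Comparing the two across groups —
e.g. insect genotypes, or clinical and neurotypical human cohorts —
requires a statistic that is insensitive to overall responsiveness. The
normalized ratio

```
ratio = (1F − 2F) / (1F + 2F)          ∈ [−1, 1]
```

serves that purpose: scaling both harmonics by a common factor leaves it
unchanged, while a selective change in the transient component shifts it.
Per subject, the ratio is computed at each *supra-baseline* contrast
(conditions whose 1F amplitude is statistically above the 0%-contrast
response) and averaged into a single index.

Amplitudes come from an exact-frequency projection: the trace is regressed
on a sine/cosine pair at *k·f* (equal to the DFT bin when the window holds
an integer number of cycles, unbiased when it does not, e.g. 5.12 Hz in a
1 s sweep bin). Repetitions are averaged **coherently** (complex mean,
suppressing non-phase-locked noise) within subject; group means are
**scalar** (moduli, phase discarded). Group contrast-response functions are
fit with the hyperbolic (Naka–Rushton) model
`R(C) = baseline + Rmax·Cⁿ/(Cⁿ + C50ⁿ)`.

Three paradigm presets are built in: `fly` (12 Hz flicker ERG, 0–69%
contrast in 7 linear steps, 5×11 s repetitions), `adult` (7 Hz EEG, 0% and
2–64% in octave steps, 8×11 s), and `child_sweep` (5.12 Hz sweep EEG, nine
1 s bins 0–50%, 432 Hz sampling, 10 repetitions).

## Worked example

Simulate and analyse a three-genotype flicker-ERG cohort (12 subjects per
genotype, the two mutant genotypes with transient gain reduced to 60%):

```bash
ssvep-ratio run-all --paradigm fly --seed 7 --out demo_fly --verbose
```

prints the manifest counts (36 subjects, 7 contrasts, 2 harmonics, 6
supra-baseline conditions, 2 repetitions rejected) and writes
`demo_fly/report.txt`:

```
amp_1f_omnibus                   oneway_anova       stat=   0.603 dof=(2x33) p=0.553
amp_1f_contrast_mutant_a         planned_contrast   stat=  -1.089 dof=(33) p=0.284
amp_1f_contrast_mutant_b         planned_contrast   stat=  -0.668 dof=(33) p=0.509
amp_2f_omnibus                   oneway_anova       stat=   9.660 dof=(2x33) p=0.0004982
amp_2f_contrast_mutant_a         planned_contrast   stat=  -3.982 dof=(33) p=0.0003542
amp_2f_contrast_mutant_b         planned_contrast   stat=  -3.603 dof=(33) p=0.001022
ratio_omnibus                    oneway_anova       stat=  19.346 dof=(2x33) p=2.756e-06
ratio_contrast_mutant_a          planned_contrast   stat=   5.544 dof=(33) p=3.701e-06
ratio_contrast_mutant_b          planned_contrast   stat=   5.215 dof=(33) p=9.796e-06
```

Reading the report: first-harmonic amplitudes at the highest contrast do
not differ between genotypes (F₂,₃₃ = 0.60, n.s.), second-harmonic
amplitudes are reduced in both mutants (F₂,₃₃ = 9.66, both planned
contrasts p < 0.01), and consequently the frequency-ratio index is elevated
in both mutants (F₂,₃₃ = 19.35) — a selective transient-pathway deficit
with sustained processing intact. Intermediate tables
(`amplitudes.csv`, `crf_fits.csv`, `conditions.json`, `ratios.csv`) are
written alongside; reruns with the same seed are byte-identical.

The same machinery is available as a library:

```python
from ssvep_ratio import (fly_cohort_config, fly_paradigm, generate_cohort,
                         trial_harmonics_table, reject_artifacts,
                         coherent_average_table, select_supra_baseline,
                         ratio_index)

paradigm = fly_paradigm()
recs, truth = generate_cohort(fly_cohort_config(seed=7), paradigm)
trials = trial_harmonics_table(recs, analysis_window=paradigm.analysis_window)
kept, rejected = reject_artifacts(trials, threshold_sd=4.0)
responses = coherent_average_table(kept)
supra = select_supra_baseline(responses, alpha=0.05)
indices = ratio_index(responses, supra)
```

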