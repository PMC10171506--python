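# Data dictionary

## `behavior.csv` (simulate stage)

One row per subject. Reaction times in ms; corrected hit rates in
percentage points (hit% − false-alarm%), may be negative; recall scores
are item counts. Any battery cell may be missing (empty).

| column | test / variable | construct | direction |
| --- | --- | --- | --- |
| `subject_id` | — | — | — |
| `age_group` | `young` or `older` | — | — |
| `vlmt_learning_sum` | verbal list learning, sum over repetitions of list A | learning ability | higher better |
| `vlmt_distractor` | distractor list B recall | pro-active inhibition | higher better |
| `vlmt_recall_a` | recall of list A after distraction | retro-active inhibition | higher better |
| `vlmt_recall_30min` | 30-min delayed recall of list A | episodic memory | higher better |
| `vlmt_recall_1day` | one-day delayed recall of list A | episodic memory | higher better |
| `wms_immediate` | logical-memory story details, immediate | learning ability | higher better |
| `wms_recall_30min` | logical memory, 30-min delayed | episodic memory | higher better |
| `wms_recall_1day` | logical memory, one-day delayed | episodic memory | higher better |
| `alertness_tone_rt` | RT with cue tone [ms] | tonic alertness | lower better |
| `alertness_no_tone_rt` | RT without cue tone [ms] | phasic alertness | lower better |
| `flexibility_error_rate` | attention-switching error rate | flexibility | lower better |
| `flexibility_rt` | attention-switching RT [ms] | flexibility | lower better |
| `flanker_rt_diff` | incongruent − congruent RT [ms] | interference processing | lower better |
| `nback1_corrected_hit_rate` | 1-back corrected hit rate | working memory | higher better |
| `nback1_rt` | 1-back RT [ms] | working memory | lower better |
| `nback2_corrected_hit_rate` | 2-back corrected hit rate | working memory | higher better |
| `nback2_rt` | 2-back RT [ms] | working memory | lower better |
| `nback3_corrected_hit_rate` | 3-back corrected hit rate | working memory | higher better |
| `nback3_rt` | 3-back RT [ms] | working memory | lower better |
| `a_prime` | recognition-memory ROC area (0.5 chance, 1 perfect) | episodic memory | higher better |

## `scores.csv` (score stage)

One row per subject per contrast. Columns, in order:
`subject_id`, `age_group`, `contrast` (`novelty` | `memory`),
`fade` (deviation score), `same` (similarity score),
`same_act` (activation component, mean standardized deviation over J⁺),
`same_deact` (deactivation component, over J⁻),
`deact_defined` (False when the reference had no significant
deactivations; then `same_deact` is 0 and `same` equals `same_act`).

## `ground_truth.csv` (simulate stage)

`subject_id`, `age_group`, `latent_ability` (drives behavior),
`alpha` (activation attenuation, 0 for young), `delta` (deactivation
reduction, 0 for young).

## Analyze-stage outputs

- `group_comparisons.csv`: per variable — group means/SDs/n after outlier
  exclusion, Levene p, the t form used (`welch` when Levene p < .05, else
  `student`), t, df, two-sided p.
- `outlier_exclusions.csv`: exclusion counts per variable and age group.
- `score_correlations.csv`: pairwise Pearson correlations of the four
  scores, FADE vs SAME-component correlations, and Meng z rows
  (`kind` = `score` | `component` | `meng`), per age group.
- `regressions_memory.csv`, `regressions_cognition.csv`: one row per
  model — dependent, contrast, age group, n, R², F, dfs, model p,
  Holm-corrected significance flag and family size, and per-score
  beta/t/p columns.
- `lda_report.json`: selection order, Wilks' Λ and its p, standardized
  coefficients, overall and per-group classification accuracy.
- `manifest.json`: seed, version, config digest, per-stage timestamps and
  SHA-256 hashes of every output file.
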