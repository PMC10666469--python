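# tonetrace

Analysis pipeline for lexical-tone production accuracy from sampled F0
trajectories. It covers two complementary accuracy notions:

- **Phonetic accuracy** (imitation task): F0 trajectories are normalized to a
  speaker-relative 0–5 T-value scale (log-F0 range mapping), reduced to DCT
  shape coefficients (mean height, slope, curvature) plus a normalized
  duration, and scored by Euclidean *tonal distance* to per-tone centroids of
  the target stimuli. Larger distance = less target-like.
- **Phono-lexical accuracy** (picture-naming task): categorical scoring of
  produced segments + tone against the target word, a 12-type tone-only error
  taxonomy (ordered target→produced tone pairs), 4×4 confusion tables, and
  per-group accuracy summaries. Level-tone labels (mid vs. low) can be
  disambiguated by 2-cluster agglomerative contour clustering and reconciled
  against prior rater labels.

A synthetic-data module generates target stimuli from Chao-numeral tone
specifications (15 rise, 51 fall, 22 mid, 11 low on four segmental frames),
simulated imitations with controlled distortions (slope compression, raised
level tones, white T-space noise), and picture-naming ledgers drawn from
per-speaker tone confusion matrices — so the whole pipeline is testable
end-to-end with no external data.

## Layout

| module | role |
| --- | --- |
| `tonetrace.trajectory_io` | normtime-table + Praat PitchTier readers, contour repair (octave-jump/gap interpolation in log-F0), edge truncation, exclusion ledgers |
| `tonetrace.tone_metrics` | T-value normalization and its inverse, DCT shape coefficients, duration z-scoring, tone centroids, tonal distance |
| `tonetrace.contour_clustering` | Ward-linkage 2-cluster mid/low disambiguation, correspondence rate, label reconciliation |
| `tonetrace.lexical_scoring` | production scoring (correct / tone-only / segment / non-target / excluded), error tables, accuracy summaries |
| `tonetrace.synthetic_data` | tone specs, speaker models, target/imitation/naming generators, planned-design ledgers, full cohort builder |
| `tonetrace.pipeline` / `tonetrace.cli` | config-driven orchestration, bootstrap CIs, run manifests, `tonetrace` CLI |

## CLI

```bash
# synthetic cohort (tables + ground-truth sidecar)
tonetrace simulate --out runs/sim --seed 1

# imitation analysis: features.tsv, distance_summary.tsv, centroids.json
tonetrace imitation --config run.yaml --out runs/imit --seed 1

# picture-naming analysis: outcomes.tsv, error tables, group_summary.csv
tonetrace naming --config run.yaml --out runs/naming --seed 1

# mid/low contour clustering on a normtime table
tonetrace cluster --table runs/sim/imitations.tsv --out runs/clus --k 2
```

A run config (YAML) holds either a `simulate:` block or input paths plus
knobs (`jump_ratio`, `n_drop`, `bootstrap_reps`, `range_source`, `seed`);
see `tonetrace.pipeline.RunConfig`.

## Conventions worth knowing

- T-value transform: `T(x) = 5 (log10 x − log10 xmin) / (log10 xmax − log10 xmin)`
  with speaker ranges pooled over both days by default; out-of-range samples
  are clamped with a warning (strict mode raises).
- DCT: type-II, `c_k = Σ x_n cos(πk(n+½)/N)`, reported as
  `dct1 = c_0/N` (equals the contour mean), `dct2 = c_1·2/N`,
  `dct3 = c_2·2/N`. Rising contours have negative dct2, falling positive;
  U-shaped contours have positive dct3.
- Trajectories carry 20 samples on ingestion; the first and last 2 are
  truncated before analysis (16-point contours).
- All simulation randomness flows from explicit seeds; identical seed +
  config reproduces outputs byte-for-byte.
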