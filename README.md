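# tntdecode

Time-resolved multivariate analysis of EEG from Think/No-Think (TNT)
retrieval-suppression experiments: condition- and item-level decoding,
time-frequency decoding, channel-searchlight mapping, cluster-based
permutation inference, representational similarity analysis (RSA), and
the accompanying behavioral statistics — together with a ground-truth
synthetic data generator so that every stage of the pipeline can be
validated without access to any recording.

## Who this is for

Cognitive-neuroscience groups analyzing epoched EEG from memory-control
paradigms: participants see reminder cues and either retrieve (Think) or
suppress (No-Think) an associated scene, with a no-memory Perceptual
Baseline. The scientific questions the toolkit addresses are *when* the
identity of an individual memory item can be read out from the scalp
pattern, *where* on the scalp that information lives, and *how*
suppression changes it.

## The method in brief

Trials are spatially reduced to the top 15 PCA components. Within each
class, trials are randomly partitioned into bins and averaged into
**sub-ERPs**; a linear SVM (one-vs-one for condition pairs, one-vs-all
with decision-value ties for items) is trained and tested in a
leave-one-bin-out cross-validation at every 20 ms timepoint (features
averaged over ±10 ms), z-scored with training statistics only, and the
whole procedure repeated over random iterations. Per-timepoint accuracy
`a(t)` is compared against the chance level `1/K` — verified empirically
by decoding the pre-stimulus baseline — with cluster-based permutation
tests: pointwise t-values above the `alpha = .05` critical value are
grouped into contiguous clusters, each cluster's summed-t mass is
compared with the maximum-mass distribution over 1,000 permutations of
the retained trial-level classification records. Searchlight maps decode
from each channel's triangulation neighborhood; RSA correlates
(Spearman) the item × item pairwise-decoding matrix at every timepoint
with averaged subjective dissimilarity ratings. Behavioral effects use
repeated-measures ANOVA with Greenhouse–Geisser correction and paired
contrasts with Cohen's `dz = mean(diff)/sd(diff)`.

The synthetic generator plants the structure this analysis is designed
to detect: an early (0–500 ms) occipital theta-band item pattern for the
cue, a late (500–3000 ms) distributed alpha-band item pattern for the
scene (present under Think, scaled by `1 − suppression` under No-Think,
absent in Perceptual Baseline), an early frontocentral theta condition
effect, sustained No-Think alpha reduction, spatially smoothed 1/f
noise, recall scores with a target forgetting effect size, and rater
matrices correlated with the planted item geometry.

## Worked example

```sh
python examples/02_item_decoding.py
```

prints, for one simulated participant (strong signal amplitudes):

```
             Think: early 0.141  late 0.127  (chance 0.083)
           NoThink: early 0.140  late 0.078  (chance 0.083)
PerceptualBaseline: early 0.189  late 0.153  (chance 0.167)
empirical chance from the pre-stimulus baseline: 0.085 (~1/12 = 0.083)
```

Reading: with 12 items, chance is 1/12 ≈ 0.083. All three conditions
decode above chance early (cue perception); only Think stays above
chance late — the signature of scene reinstatement — while No-Think
falls back to chance, the planted effect of full retrieval suppression.
The baseline-period estimate confirms the pipeline's true chance level.
The other examples cover simulation (`01`), cluster permutation
statistics (`03`), searchlight topographies (`04`), RSA (`05`) and
behavioral statistics (`06`); `tntdecode run --out dir` executes the
whole pipeline with a manifest and report.

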