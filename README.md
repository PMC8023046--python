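# lungsound

Analysis of adventitious breath sounds in chest auscultation recordings:
rule-based **crackle** and **wheeze** event detection, **wavelet-packet**
features, a three-class **SVM** recording classifier, the multi-rater
**consensus** procedure used to build gold-standard labels, and the full
**agreement-statistics** suite (per-class sensitivity/precision/
specificity/F1, Cohen's weighted κ with CI, Kendall's W, χ²).

It is written for researchers in respiratory acoustics and biomedical
signal processing who need a reproducible, fully seeded reference
pipeline. Since clinical auscultation corpora are rarely shareable, the
package ships a first-class synthetic simulator that generates
breath-cycle-modulated recordings with exact ground-truth event logs,
so every stage can be validated end to end.

## The method

A 9 s mono recording (two full breathing cycles, 8 kHz) from one of six
chest locations is screened (duration ≥ 9 s, clip fraction ≤ 1%, live
signal), band-passed to 100–2000 Hz, and analysed three ways:

* **Crackle rule.** A crackle is a discontinuous transient with duration
  < 20 ms whose peak magnitude exceeds 2× the signal's average (peak)
  magnitude. The detector extracts maximal runs of the 1 ms peak-hold
  envelope above `2 × reference`, where the reference is the sliding
  1 s mean of the 20 ms short-time peak magnitude.
* **Wheeze rule.** A wheeze is sustained narrowband energy lasting
  ≥ 500 ms. The rectified signal is smoothed with a 200 ms Hamming
  window; a sample is wheeze-active when the envelope peak in the 160 ms
  window centred on it exceeds 2× the envelope mean; active runs closer
  than 50 ms merge, and runs ≥ 500 ms are reported.
* **Classifier.** A depth-4 db6 wavelet-packet tree gives 16 uniform
  subbands; per-subband log-energy `log Σc²` and normalized Shannon
  entropy of `c²` form a 32-value feature vector, standardized and fed
  to a one-vs-rest RBF SVM over {crackle, wheeze, normal} with
  inverse-frequency class weights.

Gold-standard labels come from triples of independent specialist
ratings: unanimous definite triples are accepted, triples without a
definite majority (or with ≥ 2 "indeterminate" ratings) are rejected,
and 2-vs-1 splits go to an expert group for adjudication.

## Worked example

```python
from lungsound.classify import cross_validate
from lungsound.pipeline import PipelineConfig, recording_features, simulate_in_memory

cfg = PipelineConfig(n_per_class=10, snr_db=20.0, seed=7)
recordings, labels, _ = simulate_in_memory(cfg)
features = [recording_features(r, cfg) for r in recordings]
accuracy, predictions = cross_validate(features, labels, n_folds=5, seed=7)
print(f"5-fold cross-validated accuracy on {len(recordings)} recordings: {accuracy:.3f}")
```

prints

```
5-fold cross-validated accuracy on 30 recordings: 1.000
```

i.e. at a 20 dB event-to-background ratio the spectral features recover
the simulator's class labels perfectly under cross-validation. The
scripts in `examples/` walk through each capability the same way —
simulation (`01`), event detection (`02`, detected crackle onsets match
the injected ones to the millisecond), classification (`03`), consensus
(`04`) and agreement statistics (`05`, e.g. the F1 of a sensitivity
81.3% / precision 80.6% operating point prints as 80.9%).

A thin CLI mirrors the library:

```bash
lungsound pipeline --seed 5 --n-per-class 10 --out-dir run/
# -> run/report.json with the confusion matrix and full metric tree
```

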