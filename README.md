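# mesomotif

Detection and statistics of **spontaneous sensory motifs** in mesoscale
cortical imaging movies.

In widefield voltage-sensitive-dye (VSD) imaging of mouse cortex, ongoing
("spontaneous") activity intermittently replays spatiotemporal patterns that
resemble the cortex's own sensory-evoked responses. `mesomotif` implements
the full analysis chain for finding and validating these motifs, and for
asking how they shape trial-to-trial variability of evoked responses:

1. **Preprocessing** — raw fluorescence to percent dF/F₀, zero-phase
   Chebyshev type-I bandpass at 0.5–6 Hz, and blank-trial normalization of
   evoked trials so dye bleaching cancels.
2. **Templates** — the five-frame initial segment of the averaged evoked
   response (forelimb, hindlimb or whisker stimulation), restricted to the
   responding hemisphere and flattened to a vector.
3. **Motif detection** — the Pearson correlation *r*(t) between the template
   and each five-frame window [t, t+5) of spontaneous activity; a motif is a
   run of at least five consecutive frames with *r* above
   **mean + 1.5 SD** of the correlation trace (a threshold at which the
   template/match concordance sweep plateaus). Motif expression is summarized
   as events per 10,000 frames, per animal and modality, with a one-way
   ICC(1,1) quantifying how uniformly modalities are upregulated.
4. **Surrogate nulls** — 2-D Fourier phase randomization of template frames
   or movie frames preserves each frame's amplitude spectrum (mean, variance
   and spatial autocorrelation) while destroying the specific pattern; the
   empirical CI of surrogate match counts is the null against which real
   counts are judged, and two-sample Kolmogorov–Smirnov tests compare real
   vs null correlation distributions.
5. **Variability** — per-trial evoked amplitude (5×5-pixel ROI peak in the
   first ten post-stimulus frames, corrected for the mean signal in the
   three frames preceding response onset), per-subject evoked SD with
   Tukey-fence outlier exclusion, OLS of evoked SD on motif frequency, and
   the linear mixed model

   ```
   amplitude ~ baseline_max_r + (1 | subject)
   ```

   where `baseline_max_r` is the maximal template correlation in the 200 ms
   pre-stimulus baseline.

Because real animal recordings are not distributable, the package ships a
first-class **synthetic-data module**: movies with planted motif events
(localized, spreading, propagating depolarization kernels) over band-limited
background and white noise with exponential bleaching; evoked sessions whose
trial amplitudes follow the mixed model above by construction; and
interval-stimulation sessions with interval-dependent variability. Every
stage of the pipeline is validated against this ground truth.

## Worked example

```python
import numpy as np
from mesomotif import (simulate_spontaneous, template_from_kernel, dff,
                       correlation_trace, detect_events, motif_frequency)

movie, truth = simulate_spontaneous(n_frames=5001, field=(64, 64), seed=7)
d = dff(movie)
template = template_from_kernel("forelimb", (64, 64))
trace = correlation_trace(d, template)
threshold = trace.threshold(1.5)          # mean + 1.5 SD
events = detect_events(trace, threshold)
print(f"trace mean={trace.mu:+.4f}  SD={trace.sigma:.4f}  threshold={threshold:.4f}")
print(f"{len(events)} forelimb motif events "
      f"({motif_frequency(events, d.n_frames):.2f} per 10,000 frames)")
```

prints

```
trace mean=-0.0186  SD=0.0348  threshold=0.0337
6 forelimb motif events (12.01 per 10,000 frames)
```

All six planted forelimb events are recovered; detected onsets
(337, 1778, 2500, …) sit two frames before the planted onsets
(339, 1780, 2502, …) because the sliding five-frame correlation first
crosses threshold while the window partially overlaps the rising event —
within the ±2-frame tolerance the recovery analysis uses.

A full synthetic session (simulate → preprocess → templates → detection →
surrogates → variability) runs from the shell:

```bash
mesomotif run --seed 1 --out results/
```

and writes CSV tables (events, frequencies, trial records, subject
summaries, surrogate CIs, mixed-model fits) plus a JSON manifest with row
counts and the config hash.

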