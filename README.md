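# fasciatrack

Semi-automated muscle tracking and thickness measurement for B-mode
ultrasound video of the lateral abdominal wall, through to the
preferential activation ratio (PAR) and its group statistics.

## The problem

Segmental stabilization exercises train patients to contract the deepest
abdominal muscle, the transversus abdominis (TrA), selectively — without
co-contracting the internal and external obliques (OI, OE) that overlie
it. Whether a patient succeeds can be quantified from B-mode ultrasound:
each muscle appears as a dark band between bright fascia echoes, and its
thickness changes as it contracts. The **preferential activation ratio**

    PAR = TrA_C / (TrA_C + OI_C + OE_C) − TrA_R / (TrA_R + OI_R + OE_R)

compares the TrA's share of the summed three-muscle thickness between
contraction (`_C`) and rest (`_R`): positive PAR means the TrA thickened
preferentially. Measuring the six thicknesses by hand in every recording
is slow; `fasciatrack` automates it on whole video recordings:

1. **Initial frame**: the frame with the highest Sobel edge energy (best
   fascia visibility).
2. **Segmentation**: the four fascia boundaries as brightest left-to-right
   paths by Viterbi dynamic programming, with sub-pixel ridge refinement
   and optional operator corrections from a JSON file.
3. **Tracking**: the segmentation propagated to every frame with dense
   iterative Lucas–Kanade optical flow; three measurement points per
   muscle tracked on its upper fascia. Each frame's flow reference is the
   best-correlated already-segmented frame, not necessarily its
   predecessor.
4. **Thickness traces**: calibrated mm thickness per frame, muscle and
   point; automatic contraction-phase detection on the TrA trace
   (baseline + relative threshold with hysteresis).
5. **PAR and statistics**: per-repetition PAR, summary tables
   (mean/SD/95 % CI per repetition and pooled), mixed-design
   repeated-measures ANOVA with Mauchly's sphericity test and a
   Greenhouse–Geisser branch, paired t-tests with Cohen's d, and
   Mann–Whitney U.

Because clinical recordings cannot be redistributed, the package ships a
synthetic-video generator (`fasciatrack.synth`) that renders a 3-layer
muscle cross-section with bright fasciae, tissue-attached speckle,
scripted contraction profiles and optional drift — with exact ground
truth for every downstream stage. See `docs/methods.md` for the models,
parameter semantics and limitations.

## Worked example

```python
from fasciatrack import ContractionScript, generate_video, process_video

script = ContractionScript()          # cohort-mean ADIM contraction
video, truth = generate_video(script, seed=7)
result = process_video(video)

print(f"contracted interval  : {result['phases'].contracted}")
print(result["summary"].to_string(index=False))
print(f"estimated PAR        : {result['par']:.4f}")
print(f"scripted (true) PAR  : {truth.true_par:.4f}")
```

prints

```
contracted interval  : [(14, 47)]
muscle  rest_mm  contracted_mm  n_rest_frames  n_contracted_frames
    OE 5.228204       5.404763             14                   33
    OI 9.396970      10.358820             14                   33
   TrA 4.659839       5.414317             14                   33
estimated PAR        : 0.0140
scripted (true) PAR  : 0.0136
```

The script contracts the muscles from their rest to their contracted
thickness (TrA 4.61→5.44 mm, OI 9.34→10.57 mm, OE 5.22→5.40 mm) over a
ramp–hold–ramp profile; the pipeline segments, tracks and measures the
rendered video and recovers each phase-mean thickness to within a few
hundredths of a millimetre and the PAR to within a few thousandths. The
detected interval (frames 14–47) is wider than the scripted hold (frames
20–40) because the hysteresis admits the steep ramp portions; since all
three muscles ramp together this barely moves the PAR (a ratio of
shares).

The same chain is available from the shell:

```sh
fasciatrack simulate --out fixture/ --seed 7
fasciatrack run-all --input fixture/frames.tiff --out run/ --seed 7
fasciatrack stats --in cohort_par.csv --out report/
```

`run-all` writes the segmentation, tracks, trace, phase annotation, PAR
and a manifest with a config echo and output hashes to `run/`.

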