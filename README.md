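# laryngotopo

Laryngotopographic analysis of high-speed videolaryngoscopy (HSV)
recordings: per-pixel spectral mapping of vocal-fold vibration and the
**Stiffness Asymmetry Index (SAI)** that quantifies left/right vibratory
asymmetry.

## The problem

Early glottic cancer stiffens the vocal fold it infiltrates: the mucosal
wave disappears and the affected fold stops vibrating where the lesion
sits, while benign masses (polyps, edema) usually keep oscillating.
High-speed laryngoscopy (2000–6000 fps) captures individual vibration
cycles, but turning those videos into an objective, side-resolved
measure of fold pliability requires image analysis. This package is for
voice scientists and laryngology researchers who want that measure from
HSV recordings — and for anyone who needs a fully synthetic, ground-truth
test bed for such pipelines.

## The method

For every pixel inside a user-delineated region of interest, the time
series of its red-channel intensity (the *brightness function*, 0–255)
is Fourier-transformed after DC removal. With one-sided amplitudes
scaled by 2/T, three *laryngotopographic maps* result: each pixel's peak
frequency F0, the amplitude at the global F0 bin (normalized so the
maximum over analyzed pixels is 1), and the phase at that bin (radians,
(−π, π]). Pixels whose normalized amplitude reaches a threshold (default
0.1) form the **vibrating mask**. With the fold region split into left
and right by the glottal axis, the index is

```
SAI = 1 − (AVF_F0 / AVF) / (NAVF_F0 / NAVF)
```

where `AVF`/`NAVF` are the pixel areas of the affected / non-affected
fold and `AVF_F0`/`NAVF_F0` the vibrating areas within them. SAI = 0
means symmetric vibration; values toward 1 mean the affected fold barely
vibrates. An independent kymographic route — the glottal width waveform
(GWW) at a cross-section row — cross-checks the global F0.

Preprocessing before any spectral analysis: blue-channel glare flagging,
integer frame registration by normalized cross-correlation (camera
jitter removal), automatic selection of the maximum-opening frame, and
rotation to a vertical glottal axis from two marked endpoints.

## Worked example

```
python examples/01_single_recording.py
```

builds a noiseless 128×128, 480-frame synthetic scene at 2400 fps in
which the left fold vibrates over a quarter of its area and the right
fold fully, then prints:

```
global F0 (spectral route):   150 Hz
F0 (kymographic cross-check): 150 Hz
SAI = 0.749  (ground truth 0.750; affected side: left)
area terms: AVF_F0/AVF = 864/4054, NAVF_F0/NAVF = 3442/4054
```

The two F0 routes agree exactly at the planted 150 Hz, and the measured
SAI of 0.749 recovers the configured asymmetry (a quarter-vibrating fold
against a fully vibrating one gives 1 − 0.25 = 0.75). The other examples
export the pseudocolor maps (`02_maps_export.py`) and run group-level
Mann-Whitney statistics on a synthetic three-group cohort
(`03_cohort_statistics.py`).

The same workflow is available from the shell:

```
ltg synth --config scene.yaml --out rec/       # synthetic frames + landmarks
ltg run --input rec/ --landmarks rec/landmarks.json --out out/
ltg cohort --manifest cohort.csv --out out/
ltg validate --out out/                        # built-in self-check scenes
```

`ltg run` accepts a PNG/TIFF frame directory (preferred, lossless) or
any video container imageio can decode, plus a JSON/YAML landmark file
with the two glottal-axis endpoints and up to 20 fold-edge nodes.

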