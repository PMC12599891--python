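# mariagait

Classification of alcohol- vs marijuana-impaired gait from smartphone
inertial sensor signals. The pipeline segments triaxial accelerometer
recordings into gait cycles, encodes each cycle as a Gramian Angular
Summation Field (GASF) image, and classifies the images with a tiled
convolutional network using topographic ICA (TICA) pooling, optionally
pretrained unsupervised on sober gait samples.

Because no real impaired-gait dataset ships with the package, a first-class
synthetic generator produces labeled walking bouts with class-dependent
cadence, sway, stride-time variability, and harmonic shape, so the whole
pipeline is testable and benchmarkable end to end.

## Components

| Module | Purpose |
| --- | --- |
| `mariagait.synthetic_gait` | Labeled synthetic triaxial walking bouts (CSV I/O) |
| `mariagait.preprocessing` | Butterworth low-pass, Hampel outliers, SVM¹ magnitude, salient-point cycle segmentation, NCC validation (HDF5 I/O) |
| `mariagait.gaf` | Per-axis rescaling and GASF/GADF encoding to n×n×3 tensors |
| `mariagait.tica_net` | Tiled convolution (mod-k weight tying), pooling topology, TICA objective/gradient, projected line-search pretraining |
| `mariagait.classifier` | Model assembly, subject-/record-wise splits, mini-batch training with backprop through the tiled layer and pooling, metrics |
| `mariagait.cli` / `mariagait.pipeline` | Stage commands and end-to-end orchestration |

Everything is pure NumPy/SciPy; no deep-learning framework is required.

## CLI

Each stage reads its predecessor's artifact:

```sh
mariagait simulate   --config sim.json --out recordings/
mariagait preprocess --in recordings/ --config pre.json --out cycles.h5
mariagait encode     --in cycles.h5 --out gaf.h5 [--png-dir pngs/] [--paa-len 64]
mariagait pretrain   --gaf gaf.h5 --filter-label sober --out w0.h5
mariagait train      --gaf gaf.h5 --init w0.h5 --config train.json --out model.h5
mariagait evaluate   --model model.h5 --gaf gaf.h5 --report report.json
```

or run the whole synthetic pipeline in one shot:

```sh
mariagait run --config experiment.json --seed 1 --report report.json
```

Config files are JSON; every knob has a working default. A single seed
deterministically derives all stage seeds, so identical configs produce
identical reports.

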