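# septodg

Analysis pipeline for septo-hippocampal GABAergic circuit experiments:
fiber-photometry calcium-event analysis, peri-event MS–DG coupling,
novel-place-recognition (NPR) scoring, slice-electrophysiology metrics, and
anatomical-tracing quantification — each paired with a synthetic-data
generator that produces inputs with exact ground truth for validation.

## Modules

| Module | What it does |
| --- | --- |
| `septodg.synthetic_data` | Generators for every input type: dual-channel photometry sessions (Poisson transient trains, shared motion artifacts, ρ-correlated dual-site bout responses), arena behavior tracks with scripted exploration bouts, voltage-clamp sIPSC traces with light-epoch modulation, current-clamp RC/LIF step protocols, and tracing volumes (capsule processes, spherical somata, configurable co-localization). Bit-reproducible given a seed. |
| `septodg.photometry` | ΔF/F = (F − F0)/F0 with median F0; mCherry regression-based motion control; calcium events as suprathreshold (3 SD) excursions with rate/AUC/time-fraction summaries. |
| `septodg.perievent` | Time-locking ΔF/F to exploration bouts (10 Hz / 20 Hz alignment), trial matrices and averages, per-bout response scalars, Pearson MS–DG coupling. |
| `septodg.behavior` | Exploration-bout detection (≤ 2 cm proximity + head-orientation cone, corner-zone analysis clock), recognition score (t_novel − t_familiar)/(t_novel + t_familiar), group comparisons. |
| `septodg.ephys` | Access-resistance QC (> 20% drift excluded), sIPSC detection (local-baseline peak detector, monotone in threshold k), group amplitude/frequency t-tests and pooled KS distribution comparisons, paired pre-vs-light opto contrasts, intrinsic properties (RMP, R, τ, C = τ/R, AP threshold, 16-step F–I) and two-way genotype × current ANOVA. |
| `septodg.tracing` | Channel thresholding (Otsu/fixed/percentile), per-ROI connectivity ratio normalized to starter area, soma counting and GABA co-localization (distance-transform watershed), 3D projection reconstruction (26-connected components, summed voxel volumes, ROI-volume and cell-density normalization). |
| `septodg.stats_report` | Shared two-tailed comparisons at α = 0.05, exclusion bookkeeping, and the `run_pipeline` orchestrator (deterministic given config + seed). |

## CLI

```bash
septodg run --seed 7 --out report/            # all-synthetic demo pipeline
septodg run --config cfg.yaml --seed 7 --out report/
septodg photometry --in sessions/ --out out/ --motion-correct on --min-duration-s 0.2
septodg behavior   --in tracks/   --out out/ --theta 45 --min-bout-s 0.25
septodg ephys      --in sweeps/   --out out/ --detect-k 3.5 --min-iei-ms 5
septodg tracing    --in volume.tif --out out/ --mode retro --threshold otsu
septodg perievent  --session s.csv --track t.csv --out out/ --window -2 4
```

Time series travel as CSV with JSON metadata sidecars; volumes as
multi-channel TIFF plus single-channel ROI mask TIFFs (see `septodg.io`).

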