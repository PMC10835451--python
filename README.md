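# rsomqc

Quality control for raster-scan optoacoustic mesoscopy (RSOM) raw data.

RSOM raster-scans a focused high-frequency ultrasound detector over skin and
records one time-resolved pressure signal (A-line) per laser shot. Image
quality suffers from vertical skin motion (pulsation, breathing, muscular
jitter) and from variations of the system noise level. `rsomqc` implements a
raw-data quality-control scheme around two ideas:

1. **SNR reference gate** — before every scan, a 100 µm suture phantom on the
   coupling membrane is measured; a full scan is allowed only when its SNR
   (peak signal over noise-background standard deviation, in dB) reaches the
   reference value established at the detector focus.
2. **Motion quality index** — the melanin layer produces the strongest signal
   at every scan position, so the per-position envelope-peak depth gives a
   motion-disrupted surface `S_D`; median+Gaussian smoothing gives the
   continuous surface `S_C`; the difference, read out along acquisition time,
   is the vertical motion graph `M = S_D − S_C`. Its standard deviation
   `m_std`, maximum absolute deviation `m_max` and the combined index
   `q_motion = m_std + β·m_max` classify a scan against simulation-calibrated
   thresholds (`β = t_std/t_max`, so `tq_motion = 2·t_std`).

The thresholds are calibrated by a simulation study: a base motion graph is
scaled by a ladder of weights (0.1…3 in steps of 0.3), injected into a clean
scan, retrieved and corrected; each step is scored by the added-vs-retrieved
correlation and by the contrast-to-noise ratio (CNR) of the corrected
delay-and-sum reconstruction. `t_std`/`t_max` sit where the corrected CNR
first drops 1 dB below the zero-motion reference.

Because no public RSOM raw data exists, the package ships a forward simulator
(`rsomqc.synthetic_rsom`) producing full skin-phantom scans, suture reference
lines and fixed-head point measurements with controllable physiological
motion and noise — every stage of the pipeline is testable end to end.

## Modules

| module | contents |
|---|---|
| `rsomqc.data_model` | domain types (`SystemConfig`, `RawScan`, `SurfaceMap`, `MotionGraph`, `MotionMetrics`, `ThresholdSet`, `QCReport`), validation, HDF5/CSV/JSON I/O |
| `rsomqc.synthetic_rsom` | phantom + motion-model specs, base-motion generator, scan/suture/point simulators, cohort generator |
| `rsomqc.snr_gate` | suture SNR measurement, focus-offset search, reference gating |
| `rsomqc.motion` | surface extraction `S_D`, smoothing `S_C`, motion graph, metrics, classification |
| `rsomqc.correction` | vertical motion correction of sinograms, retrieval chain, point-measurement displacement tracking |
| `rsomqc.recon` | zero-phase dual-band filtering, delay-and-sum reconstruction, MIP rendering, CNR |
| `rsomqc.calibration` | weight ladder, corrupt–correct–score study, 1-dB threshold determination |
| `rsomqc.cli` | `rsomqc` command-line interface and batch QC reporting |

## CLI

```sh
rsomqc --seed 1 simulate --preset full --motion-std 3 --out scan.h5
rsomqc simulate --preset suture --out suture.h5
rsomqc gate --scan suture.h5 --r-snr 45            # exit 0 pass / 3 fail
rsomqc --seed 1 calibrate --scan clean.h5 --out thresholds.json
rsomqc qc --scan scan.h5 --thresholds thresholds.json --out report.json
rsomqc correct --scan scan.h5 --out corrected.h5 --motion-csv motion.csv
rsomqc recon --scan scan.h5 --bands 10e6:40e6,40e6:120e6 --mip depth --out mip.tiff
rsomqc report scans/*.h5 --thresholds thresholds.json --out-dir qc_out
```

Exit codes: 0 success, 2 usage error, 3 QC-gate fail, 4 data error.

Scans are single HDF5 containers (`/amplitudes` float32 cube
`[n_fast, n_slow, n_samples]` plus acquisition metadata as root attributes);
motion graphs are `time_s,displacement_um` CSVs; QC reports are JSON.

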