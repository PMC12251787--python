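# gaitdfa

Cycle-wise detrended fluctuation analysis (DFA) of gait recordings. The
package segments strides from force-sensitive-resistor (FSR) foot-pressure
signals, conditions surface EMG, computes a scaling exponent α per gait cycle
per channel, and compares α distributions across participant groups with
one-way ANOVA and Tukey HSD post hoc tests. A synthetic-data module generates
every kind of input the analysis needs (fractional Gaussian noise with known
Hurst exponent, gait records with known heel-strike times), so the whole
pipeline is testable without any downloads.

## Layout

| module | what it does |
|---|---|
| `gaitdfa.signal_io` | read/write records (WFDB format-16 via `gaitdfa.wfdb_lite`, plus a CSV fallback), fixed-length windowing |
| `gaitdfa.preprocess` | 20–450 Hz zero-phase Butterworth bandpass, full-wave rectification, max / min-max normalization |
| `gaitdfa.segmentation` | dynamic-threshold heel-strike detection (0.5 s refractory), gait-cycle slicing |
| `gaitdfa.dfa` | profile integration, windowed linear detrending, F(n), log–log fit for α |
| `gaitdfa.synthetic` | white noise, exact-covariance fGn/fBm (circulant embedding), synthetic gait records |
| `gaitdfa.group_stats` | per-group α summaries, one-way ANOVA, post hoc pairwise comparisons |
| `gaitdfa.pipeline` | orchestration, config, TSV/JSON artifacts |
| `gaitdfa.cli` | `gaitdfa run / dfa / simulate / report` |

## CLI

Generate a labelled synthetic cohort, analyze it, and inspect the outputs:

```sh
gaitdfa simulate --groups 3 --records 2 --cycles 20 --seed 7 -o cohort/
gaitdfa run -i cohort/ -o results/ --window-s 15
cat results/group_summary.tsv
```

`run` emits `alpha_table.tsv` (one row per cycle × channel, exclusions
flagged with a reason), `cycles.tsv`, `group_summary.tsv` (mean ± SD per
group/side/channel), `anova_report.json` (omnibus + post hoc per channel) and
`run_manifest.json` (config echo + seed, sufficient to reproduce the run).
Group labels come from a `manifest.tsv` sidecar (`record_id<TAB>group`).

Ad-hoc DFA of a single trace:

```sh
gaitdfa dfa --input trace.csv          # prints alpha, r^2, scales used
```

Real recordings in WFDB format (`.hea` + format-16 `.dat`) are read directly:
`gaitdfa run -i data_dir/ -o out/`.

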