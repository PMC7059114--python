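# spikemotifs

Microcircuit motif inference from paired spike-train recordings.

`spikemotifs` re-implements, as a tested and reusable pipeline, a
cross-correlogram-based analysis of dual single-unit recordings from
cerebellar molecular-layer interneurons (INs) and Purkinje cells (PCs):

- **Z-scored cross-correlograms** with a block-shuffle surrogate null
  (5 s blocks, 500 surrogates, baseline normalization, |Z| > 3
  significance).
- **Net-spike-change** statistics (baseline-corrected cumulative spike
  counts per trigger event) and a **shuffled-ISI test** for electrically
  triggered spikes (1000 surrogates).
- **Sensory-response analysis**: PSTHs, first-spike latency distributions
  with a 4-SD peak criterion, fast (0–20 ms) / delayed (50–120 ms)
  response decomposition, trial sorting by evoked IN spikes and evoked
  complex spikes.
- **Motif classification**: IN→PC inhibition / co-activation, CF→IN
  excitation / inhibition / combined, IN–IN inhibition with direction,
  gap-junction synchrony (0.5 ms bins, ±1 ms twin peaks), plus soma
  geometry, bootstrap prevalence curves, depth regressions, a two-sided
  Fisher exact test (sum of small p values), and rank-based group tests.
- A **ground-truth generator**: an exact-thinning conditional-intensity
  point-process simulator with multiplicative coupling kernels (box gains
  and alpha kernels), gap-junction coincidences, common-input
  co-modulation, stimulus-locked components, and a depth-graded population
  generator for end-to-end recovery benchmarks.

All analysis parameters live in `AnalysisConfig`
(`spikemotifs.data_model`) with the published procedure's values as
defaults.

## Command line

```bash
# simulate a ground-truth session (YAML/JSON truth config optional)
spikemotifs simulate --out session_dir --seed 1 --duration 600

# correlograms, surrogate nulls, spike-change curves -> TSV/JSON
spikemotifs analyze --session session_dir --out results --seed 1

# motif calls (includes analysis)
spikemotifs classify --session session_dir --out results --seed 1

# human-readable summary
spikemotifs report --results results
```

Exit codes: 0 ok, 1 user error, 2 internal error. Every stage writes a
manifest (seed, config hash, version) so runs are reproducible.

Session format: a directory with one `unit_id.tsv` per unit (single
`time_s` column, seconds, 5 decimals = one sample at 20 kHz) and a
`metadata.json` with unit roles, durations, optional soma coordinates,
stimulus onsets and triggered spike times.

## Library example

```python
import numpy as np
from spikemotifs.ccg import zscored_ccg
from spikemotifs.motifs_geometry import classify_in_pc
from spikemotifs.synthetic import simulate_pair, truth_in_pc

session = simulate_pair(truth_in_pc(gain=0.7), duration=600.0, seed=0)
zs = zscored_ccg(session.trains["in"].times, session.trains["pc_simple"], seed=1)
call = classify_in_pc(zs)
print(call.flags["in_pc_inhibition"], zs.z_at(0.0))
```
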