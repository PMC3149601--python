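# dunbarlim

Does online communication lift the cognitive ceiling on how many
relationships a person can actively maintain, or does Dunbar's number
(~100–200 stable contacts) survive the move to microblogging?  This
package provides the analysis and modelling toolkit for that question:

* **Reply-network construction** — conversation logs (message, author,
  optional parent, optional timestamp) are assembled into reply forests and
  projected onto a directed weighted user network, `w_ij` counting replies
  from user *i* to user *j*.
* **Saturation statistics** — the average interaction strength per
  initiated relationship, `ω_i^out = Σ_j w_ij / k_i^out`, binned against
  out-degree; the reciprocated-contact count `ρ` against in-degree; degree
  distributions; and a peak locator for the degree-binned curves.  The
  signature of a cognitive limit is that `ω^out(k)` rises and then falls:
  beyond a finite number of contacts, attention per contact must drop.
* **A bounded priority-queue agent model** — agents on a scale-free contact
  network hold queues of at most `q_max` pending conversations, answer
  `S_t ~ U{0..q_i}` of them per step with probability proportional to the
  sender's degree, and broadcast weightless status messages with
  probability `p`.  The model reproduces the peaked `ω^out` curve with the
  peak position set linearly by `q_max` — finite attention slots, not
  platform mechanics, fix the number of sustainable relationships.
* **A mean-field single-user reduction** — one focal user with `k/2`
  partners sending at rate `∝ k` (so inflow `⟨R⟩ ∝ k²`) exposes the two
  regimes analytically: below saturation every message is eventually
  answered (`ω ∝ k`), above it replies cap at `q_max/2` per step
  (`ω ∝ 1/k`).
* **A synthetic-data generator** — re-emits instrumented model runs as
  conversation logs (round-trip exact against the simulator's weights) and
  synthesises logs with a planted saturation capacity for known-answer
  testing of the metrics stack.

## Worked example

Plant a saturation capacity of 150 in a synthetic corpus, run the
empirical pipeline, and recover it:

```python
import dunbarlim as dl
from dunbarlim.synthetic_data import GeneratorSpec, parametric_log

spec = GeneratorSpec(n_users=20_000, capacity=150, seed=1)
net = dl.project_to_network(dl.build_forest(list(parametric_log(spec))))
curve = dl.omega_curve(net)          # mean omega per log-spaced degree bin
peak, flag = dl.find_peak(curve)
print(f"users={net.n_users()} total_weight={net.total_weight()}")
print(f"peak at k_out ~ {peak:.1f} ({flag})")
```

```
users=20000 total_weight=182660
peak at k_out ~ 159.3 (interior)
```

The binned curve around the peak (`curve.to_frame()`):

```
 bin_lo  bin_hi      x   center  band_lo  band_hi   n
     90     112  100.0    6.30     6.03     6.58   20
    112     140  124.8    7.64     7.62     7.76    9
    140     175  159.3    8.54     8.41     8.70    6
    175     218  199.1    7.11     6.74     7.46    8
    218     272  246.6    5.85     5.44     6.16    5
```

`ω` rises to ~8.5 replies per relationship near 150 contacts and falls
beyond — the planted capacity, recovered within one bin.  The same
pipeline runs from the shell:

```
dunbarlim generate --mode parametric --spec spec.yaml --out log.tsv
dunbarlim ingest --input log.tsv --dialect tsv --out edges.tsv
dunbarlim metrics --edges edges.tsv --curve omega --binning log --out curve.tsv
```

For the model side, `dunbarlim simulate --n 10000 --qmax 50 --p 0.02
--steps 2000 --replicas 51 --seed 7 --out run/` writes median curves and
the located peak; `dunbarlim single-user --kgrid 2:2000:16 --replicas 200
--seed 7 --out single.tsv` sweeps the mean-field model across degrees.

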