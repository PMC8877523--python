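# polytrans

Monte Carlo and exact first-passage analysis of **polyampholyte translocation
through the asymmetric α-hemolysin pore**.

Polyampholytes (PAs) — polymers carrying both positive and negative unit
charges, the minimal model of intrinsically disordered proteins (IDPs) — are
driven through a nanopore by an electric field. Unlike polyelectrolytes, a PA
sequence contains *antagonistic* charges that the field pushes backwards, so
whether a chain translocates, retracts, or stalls inside the pore is decided
by its charge **sequence**, not just its net charge. `polytrans` implements:

* a ±1 **charge-sequence** model with the descriptors that control the
  outcome: net charge `Q`, head-window charge `Qh`, and the minimum
  pore-window charge `Qmin` (window = 5 monomers = pore length);
* the **energy landscape** `E(x)` of a chain threading α-hemolysin, built
  from tabulated per-ion free energies at seven axial sites (monomer size
  `a = 2 nm`, drive `V = e·150 mV / k_BT = 5.84` per unit charge);
* a **Metropolis engine**: one Monte Carlo time step (MCT) proposes a ±a hop
  of the whole chain, accepted with `min(1, e^(−ΔE))`; a trial ends in
  *translocation* (`x = N+1`), *rejection* (`x = −6`) or *trapping* (still
  engaged at the waiting time `t_w`, default `1.6×10⁵` MCT);
* an **exact solver** treating the same dynamics as a finite absorbing
  birth–death Markov chain: splitting probabilities, full absorption-time
  distributions, trapped mass at `t_w`, and conditional first-passage moments
  — the deterministic oracle for every Monte Carlo estimate;
* **ensemble statistics**: time PDFs with power-law tails `P(t) ~ t^−(1+μ)`,
  the logarithmically decaying trapped population, `Q/Qh/Qmin`-resolved
  outcome matrices and population-percentile times;
* the **drift-vs-disorder theory**: disorder parameter `μ` from
  `⟨e^(−qμU)⟩ = 1` (binary and Gaussian forms), crossover lengths
  `n_d = 1/(σ₁²U²)` and `n_c = 1/⟨q⟩² − 1`, barrier scales, the diblock
  contribution `exp(UN/2 − N ln 2)`, and the minimal charge fraction
  `Q/N > 1 − 2 ln 2 / U` for well-behaved translocation times.

## Worked example

```python
from polytrans import (SimConfig, benchmark_sequence, build_landscape,
                       classify_exact, Direction, run_trials)

seq = benchmark_sequence("a")          # 11-111-111-111-111-111-111 (N=20, Q=8)
print(seq.Q, seq.head_charge(), seq.min_window_charge())
# 8 3 1

cfg = SimConfig(tw=160_000, trials=10_000, seed=2024)
s = run_trials(seq, cfg)
print(f"{s.translocated_pct:.1f}% translocated, "
      f"mean time {s.mean_translocation_time:.0f} ± {s.sd_translocation_time:.0f} MCT")
# 85.8% translocated, mean time 67 ± 18 MCT

exact = classify_exact(build_landscape(seq, Direction.CIS_TO_TRANS), tw=160_000)
print(f"exact: {100*exact.p_translocated:.1f}% by tw, "
      f"mean {exact.mean_translocation_time:.1f} MCT")
# exact: 85.8% by tw, mean 66.9 MCT
```

A regular sequence with every pore window favorable (`Qmin = 1`) translocates
almost ballistically: ~21 net forward hops in ~67 MCT. Moving the same six
antagonistic charges into blocks (`-1-1`, `-1-1-1`) builds barriers of
roughly `(block−1)·V` and stretches the mean time by orders of magnitude —
sequence arrangement, not composition, controls the outcome.

The command line exposes the same pipeline:

```sh
polytrans fixtures --out fixtures/
polytrans simulate --seqs fixtures/benchmark_sequences.txt --trials 10000 --out run/
polytrans stats --events run/events.tsv --results run/results.tsv --out stats/
polytrans theory -Q 12 -N 20 -U 6
```

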