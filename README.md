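# efmentropy

Stoichiometric network analysis (SNA) of entropy production in open-flow
mass-action reaction networks, bundled with a two-replicator chiral
hypercycle model that undergoes spontaneous mirror symmetry breaking (SMSB)
in a continuously stirred tank reactor (CSTR).

## The problem

Biological replication is homochiral: life uses one enantiomer of its
building blocks. A candidate abiotic origin is a pair of chiral replicators
1R and 2R coupled by enantioselective mutual cross-catalysis,

    A + 1R_D + 2R_D  ⇌  2·1R_D + 2R_D        (rate constants ka, k-a)
    A + 2R_D + 1R_D  ⇌  2·2R_D + 1R_D        (rate constants kb, k-b)

with the mirror (L) reactions constrained by chirality to the same rate
constants, all inside a CSTR that feeds the achiral resource A at
concentration [A]in and washes out every species at the dilution rate
f = q/V. Splitting each reversible reaction into forward/reverse halves and
counting the four enantiomer outflows, the A inflow and the A outflow gives
14 unidirectional transformations over 5 species.

For such a network this package computes, exactly where the object is
algebraic and by stiff integration where it is dynamical:

- the stoichiometric matrix ν and the mass-action rate vector
  v_j = k_j Π_i [X_i]^α_ji;
- the **extreme flux modes** (EFMs) — the extreme rays of the stationary
  flux cone {v ≥ 0 : νv = 0}, enumerated by the double description method
  over exact integers, classified (internal closed / open productive /
  flow-through) and paired under the parity operation;
- the convex expansion v_ss = Σ_i j_i E_i of any stationary rate vector in
  nonnegative pathway currents j_i;
- the **entropy production** σ = R Σ_k (v_k,f − v_k,r) ln(v_k,f/v_k,r) ≥ 0,
  the **exchange entropy** σ_e = R Σ_k f (c_k,in − c_k) ln(c_k/c_k,eq)
  carried by the matter flows, and the per-pathway partial entropies σ(E_i)
  obeying the exact balance Σ_i σ(E_i) = σ − σ_e = dS/dt, which vanishes at
  every non-equilibrium stationary state (NESS);
- the **General Evolution Criterion** (GEC) split of the entropy-production
  derivative, dσ/dt = dFσ/dt + dJσ/dt with forces F_k = R ln(v_k,f/v_k,r)
  and flows J_k = v_k,f − v_k,r.

The chiral seed in the reference run is δ = 1e-23 mol/L against racemic
concentrations of 1e-6 mol/L — far below double-precision resolution of the
raw species variables — so the stiff solver integrates chiral
sum/difference coordinates (s = [X_L]+[X_D], χ = [X_L]−[X_D]) whose
right-hand sides are expanded free of catastrophic cancellation.

## Worked example

```python
import efmentropy as ef

network = ef.build_hypercycle_network()          # 5 species, 14 transformations
modes = ef.enumerate_efms(network)               # 9 extreme flux modes
traj = ef.simulate(network, ef.HypercycleParams(), t_end=1e9)
events = ef.event_times(traj)
print(traj.ee[-1], events.smsb_time, events.sigma_peak_time)
```

prints

```
[100. 100.] 187937585.94105092 3868120.546330525
```

the final enantiomeric excesses of both replicators (complete L-handed
homochirality, amplified from the 1e-23 mol/L seed), the time at which the
replicator-1 excess crosses 50% (≈1.9e8 s), and the time of the first
entropy-production peak (the burst of resource conversion, ≈4e6 s).

The same study from the shell:

```
$ efmentropy report -c config.yaml
== efm ==
9 extreme flux modes (4 closed, 4 open productive, 1 flow-through)
== simulate ==
final ee1 = 100 %
final ee2 = 100 %
smsb_time = 1.87938e+08 s
sigma_peak_time = 3.86812e+06 s
NESS: [A]=2.26344e-06, [2RD]=0, [1RD]=0, [1RL]=8.85407e-05, [2RL]=9.19581e-06 (|nu.v| = 4.04e-28)
== entropy ==
balance identity sum sigma(Ei) = sigma - sigma_e: PASS
NESS balance sum sigma(Ei) -> 0: PASS
== gec ==
GEC dF_sigma/dt <= 0: max positive part 2.35e-18 (1.23e-03 of peak magnitude)
dsigma/dt <= 0 after production peak: PASS
|dJ_sigma/dt| <= |dF_sigma/dt| near NESS: PASS
entropy-production minimization: sigma(plateau)=7.83941e-10 -> sigma(NESS)=5.71973e-10 PASS
```

The commands write TSV series (trajectory, rates, entropy ledger, GEC
decomposition) into the configured output directory; re-running a command
with the same config byte-reproduces every file.

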