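# Methods

## Model

The network is a deterministic, non-spatial mass-action ODE system in 25
dynamic species (9 free CaM states, 6 CaM₄–target complexes, the free
phospho-CaMKII subunit pool, cAMP, phospho-PDE4B/D, phospho-I-1, the
I1·PP1 complex, and 4 PKA states). Free pools of targets (AC1, AC8, PDE1,
CaNA, CaMKII subunits, PP1, I-1, PDE4B/D) are eliminated algebraically via
their conservation laws, so every total pool is conserved by construction;
the test suite verifies all eleven pools to 1e-6 relative across every
protocol × knockout combination.

### Ca²⁺–CaM (9 states)

Each CaM lobe is a two-site chain: the first Ca²⁺ binds at the tense-state
rate with a statistical factor of two (two empty sites), the second at the
relaxed-state rate; dissociation mirrors this (factor two on leaving the
doubly occupied state). Lobes fill independently, so the joint model is
the 3×3 tensor product of the two chains and its equilibrium factorizes —
`equilibrate_cam` uses that closed form and asserts a residual against the
kinetic right-hand side. Only CaM₄ binds targets; partially loaded states
have zero target affinity, and Ca²⁺ does not dissociate from target-bound
CaM₄ (complexes decay only via the complex off-rate).

The lobe rates (kon_NT = 770, koff_NT = 1.6e5, kon_NR = 3.2e4,
koff_NR = 2.2e4, kon_CT = 84, koff_CT = 2.6e3, kon_CR = 25,
koff_CR = 6.5; µM⁻¹s⁻¹/s⁻¹) are the standard flash-photolysis calibration
of this scheme and ship in `src/camsignal/data/cam_kinetics.yaml`; the
loader refuses to start if any symbol is missing rather than defaulting
silently.

### Stimulus (synthetic-data generator)

`Ca(t) = Ca_basal + A·Σᵢ exp(−(t−tᵢ)/τ)`: instantaneous amplitude
additions with exponential decay, summating when pulses arrive faster than
τ. Protocols: LFS (1 Hz, A = 0.4 µM, 30 pulses), 10 Hz (A = 1 µM, 10
pulses — a 1 s train; the pulse count is a config default), theta burst
(10 epochs × 4 pulses at 100 Hz, epoch onsets 0.2 s apart; a single train
is the simulation unit), 100 Hz (A = 1 µM, 100 pulses). Every run covers
the train plus 1 s follow-up.

`Ca_basal = 0.1 µM` and `τ = 0.05 s` are configuration defaults, not
measured constants: they were fixed once so that at 1 Hz each transient
decays essentially completely between pulses (e⁻²⁰) while at 100 Hz
pulses summate strongly (fτ = 5, plateau ≈ 5.6 µM). Both are overridable
on every protocol and parameter set; no logic hard-codes them.

### Targets, CaMKII cycle, cAMP, PKA, I-1/PP1

* AC1/AC8/PDE1 bind CaM₄ reversibly (kc1–kc3 pairs).
* PP2B: only Ca-loaded CaNB presents the CaNA subunit for CaM₄ binding; the
  Ca²⁺→CaNB step is a fast pre-equilibrium Hill gate (half-saturation K1 =
  0.5 µM, coefficient 3 — chosen values, as the tables leave K1 undefined).
  The CaM off-rate blends the printed high- and low-Ca limits:
  `koff(Ca) = kc4b1·H(Ca; Kd1, n1) + kc4b2·(1 − H(Ca; Kd2, n2))`, making
  PP2B a deep trap at elevated Ca²⁺ (koff → 0.0012 s⁻¹) and unstable at
  basal Ca²⁺ (→ 2 s⁻¹).
* CaMKII: subunits bind CaM₄ at kc5f; unphosphorylated complexes release at
  kc5b1, phosphorylated at kc5b2 (1000× slower). The T286 flux is
  `kcat14·[CaMCaMKII]·([CaMCaMKII]+[CaMCaMKII^P])/CaMKII_T` — the
  mean-field probability that a neighbouring subunit of the holoenzyme is
  also CaM-bound. Dephosphorylation by PP1 (kcat15, Km15; scaled by
  uninhibited PP1) and PP2A (kcat16, Km16) acts Michaelis–Menten-wise on
  the total phospho pool, split proportionally between CaM-bound and free
  phospho subunits; dephosphorylated CaM-bound subunits keep their CaM.
* cAMP: produced by CaM-bound AC1/AC8 (kcat1/kcat2) and the CaM-independent
  pool AC\* (kcat3); hydrolyzed by PDE1 (basal kcat5 / CaM-stimulated
  kcat6, Km5) and PDE4B/D (basal kcat7/kcat9, PKA-phosphorylated
  kcat8/kcat10 at twice the basal rate; Km7 = 4 µM and Km9 = 2 µM are
  literature PDE4 Michaelis constants, as the printed table omits them).
  The basal/stimulated pairing of kcat5/6, 7/8, 9/10 follows the source
  lineage of the network and is a sourcing decision.
* PKA (full mode): R₂C₂ + 2cAMP ⇌ R₂C₂cAMP₂ (k17), + 2cAMP ⇌ R₂C₂cAMP₄
  (k18), then release of two catalytic subunits. The printed k19 pair has
  mutually inconsistent units, so both orientations are implemented behind
  a flag; a steady-state oracle selects first-order release at 0.0016 s⁻¹
  with termolecular rebinding at 0.25 µM⁻²s⁻¹ (the as-labelled direction
  frees ~2.3 µM of catalytic subunit, an order of magnitude above the
  sub-µM plateau the reduction is built on). The stripped regulatory
  complex is bookkept as PKAc/2.
* Reduced mode computes PKAc algebraically from the Hill constants
  (PKA_max = 0.2170 µM, IC50 = 0.3760 µM, n = 2.569) carried as model
  parameters; it is the default for CaM₄-output work, while cAMP and
  I1PP1 outputs use the full model.
* I-1/PP1: PKAc phosphorylates I-1 (kcat11, Km11); phospho-I-1 binds PP1
  with mass-action kinetics (kon = 10 µM⁻¹s⁻¹, koff = 0.01 s⁻¹, i.e. the
  classic ~1 nM inhibitory constant; explicit kinetics rather than an
  algebraic rapid equilibrium keep the system a plain ODE). PP2A (kcat12,
  Km12) and CaM-bound PP2B (kcat13, Km13) dephosphorylate phospho-I-1
  whether free or PP1-bound; the complexed route releases active PP1.

### A note on the PKA Hill reduction

Fitting follows the constrained procedure: the ceiling is pinned to the
plateau of the computed dose–response, the midpoint is interpolated at
half-ceiling, and only the exponent is fitted. With the shipped constants
the full model's plateau is 0.2398 µM with midpoint 0.202 µM and exponent
≈1.5; the reduced-mode constants above (0.2170/0.3760/2.569) are carried
as transcribed parameters of the reduced model rather than re-derived from
the full model, because no mass-action reading of the printed six rate
constants reproduces them (both release orientations, statistical-factor
conventions, rebinding forms and cAMP-consumption variants were scanned at
true steady state). The discrepancy only affects the full-vs-reduced
comparison, not the CaM₄ analyses.

## Numerics

LSODA with rtol 1e-8, atol 1e-12 µM for experiments (1e-6/1e-9 for GSA
model evaluations); integration proceeds segment-by-segment between pulse
onsets (the input is smooth within a segment and jumps by A at each
pulse), max step half the shortest inter-pulse interval, dense output on a
1 ms grid (10 ms for GSA). The right-hand side exists twice: a readable
pure-Python closure (the reference) and a numba-compiled transliteration
used by the integrator; the test suite asserts bitwise agreement on random
states. States are clipped at −1e-6 µM; anything below that aborts with
the offending species and time. Michaelis terms use the substrate floored
at zero; ties in peak searches break to the earliest time. The Table-2
initial state (complexes and cAMP at zero, CaM equilibrated at basal
Ca²⁺) is deliberately not a network fixed point — cAMP relaxes toward its
basal production/hydrolysis balance over tens of seconds regardless of
stimulation, as in the source model.

## Global sensitivity analysis

Pipeline: per-parameter one-at-a-time sweep (21 points by default) over
baseline×[0.1, 1.9]; the largest contiguous monotone subrange with
Spearman |ρ| ≥ 0.8 is retained (longer limb of unimodal responses, ties to
the lower side; flat or uncorrelated parameters are dropped); Latin
hypercube over the retained ranges (one stratum per sample per parameter,
independent permutations); one model run per sample; PRCC by rank
residualization with p-values from the t-statistic on n − 2 − k degrees of
freedom, significance at p < 10⁻⁴. The KS regionalized screen compares
accepted/rejected marginals at p < 0.01; the acceptance predicate is
explicit configuration (shipped default: output within ±50% of the
baseline run — an artifact choice, as no behavioural criterion is
canonical). The default output summary is the time average of the
observable over the train window; end-of-train and peak are available.
Signed PRCCs are emitted; the acceptance script reports magnitudes to
match the unsigned convention of published sensitivity tables.

Problem sizes: the package default is 5000 LHS samples; the acceptance
script and acceptance tests use 500 and 400 samples respectively with
9-point screens — rank orderings are stable at these sizes, individual
PRCC estimates carry ~±0.05–0.1 sampling noise.

## What the generator does and does not emulate

The stimulus reproduces pulse-train timing, per-pulse amplitude and
summation, which is what the competition mechanism responds to. It does
not model NMDAR gating, Ca²⁺ pumps/buffers, diffusion, or stochastic
vesicle release; passing tests therefore demonstrate properties of the
reaction network under idealized Ca²⁺ drive, not predictions for measured
spine Ca²⁺ traces. Likewise the network omits T305/T306 inhibitory
phosphorylation (no metaplasticity), GluN2B anchoring, and AMPAR
trafficking downstream.

## Known limitations

* Several constants the printed tables omit (lobe rates aside: Km7, Km9,
  K1 and its Hill coefficient, the I1·PP1 kinetics) are sourced or chosen
  as documented above; transient quantities that depend on them (e.g. how
  fast PP2B saturates late in a tetanus) are correspondingly uncertain. In
  this reconstruction PP2B keeps absorbing CaM slowly through a 100 Hz
  train, so bound AC1/PDE1 still decline ~5–8% even with T286A, where the
  source work reports the decline absent.
* At LFS the mean-field T286 flux is quadratic in a very small occupancy,
  so phospho-CaMKII is ~nM-scale and the CaM₄ output is nearly insensitive
  to kcat14/kcat15 — weaker phosphorylation-pathway sensitivities at 1 Hz
  than the source tables report.
* PRCC assumes monotone responses; the screen enforces this per parameter
  but interactions between simultaneously varied parameters can still
  violate it locally.
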