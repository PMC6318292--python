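# wcstmap

Model-based analysis of the Wisconsin Card Sorting Test (WCST), for
researchers who want to go beyond the five classical summary scores and
attribute a participant's performance to interpretable cognitive
parameters — and, when lesion masks are available, to map those parameters
onto the brain.

The WCST asks participants to sort cards varying on three dimensions
(color, form, number) onto four key piles; a hidden sorting rule changes
after 10 consecutive correct sorts. `wcstmap` implements the complete
analysis pipeline around a sequential-attention learning model of this
task:

- **Task simulator** — decks, the deterministic examiner (feedback, silent
  rule switches, discontinuation), and pluggable agents.
- **Attention model** — attention weights `a` on the 3-simplex with
  choice rule `P_k ∝ Σ_i m_ik a_i^d`, feedback signal
  `s ∝ m ∘ a^f` (right) / `(1−m) ∘ a^f` (wrong), and update
  `a' = (1−r)a + r·s` after "right", `a' = (1−p)a + p·s` after "wrong".
  The four free parameters are reward sensitivity `r`, punishment
  sensitivity `p`, decision consistency `d`, and attentional focusing `f`.
- **Scoring** — perseverative/non-perseverative errors (PSV/NPSV),
  categories achieved (NCAT), failures to maintain set (FSET), trials to
  first set (TRSET1).
- **Bayesian inference** — per-participant MCMC with flat priors over the
  bounded supports, MAP point estimates, split-R̂/ESS diagnostics, and
  DIC comparison of the full model (RPDF) against three restricted
  variants (RRDF: `r = p`; RP1F: `d = 1`; RPD0: `f = 0`), reported as
  ΔDIC relative to a uniformly random chooser.
- **Validation studies** — parameter recovery, posterior predictive
  checks, and score landscapes over the parameter grid.
- **Lesion-symptom mapping** — voxelwise Brunner–Munzel tests over binary
  NIfTI lesion masks with overlap masking, Benjamini–Hochberg FDR,
  power flags, density maps, conjunction overlays, and covariate
  residualization.
- **Cluster profiling** — two-step k-means on the fitted parameters with
  silhouette model selection over k = 2..7 and three distances, and
  bootstrap stability validation.
- **Synthetic cohort** — a generator that plants the full statistical
  structure (lesion territories, a punishment-sensitivity deficit in the
  right-prefrontal group, weakly coupled covariates, simulated behavior),
  so the entire pipeline is testable without patient data.

## Worked example

Simulate one participant with known parameters, score the session, and
recover the parameters by MCMC:

```python
from wcstmap import ModelParams, DeckConfig, ExaminerConfig, build_deck, score_administration
from wcstmap.model import simulate_participant
from wcstmap.inference import fit_participant, compute_dic

examiner = ExaminerConfig()                      # 10-sort runs, 6 categories
deck = build_deck(DeckConfig(seed=42))           # 2 x 64-card factorial decks
truth = ModelParams(r=0.2, p=0.65, d=2.0, f=1.0)
session = simulate_participant(truth, deck, examiner, seed=7)
scores = score_administration(session, examiner)
print(f"trials={session.n_trials}  NCAT={scores.ncat}  PSV={scores.psv}  "
      f"NPSV={scores.npsv}  FSET={scores.fset}  TRSET1={scores.trset1}")

fit = fit_participant(session.trials, seed=0)
dic = compute_dic(fit, session.trials)
m = fit.map_params
print(f"MAP: r={m.r:.2f}  p={m.p:.2f}  d={m.d:.2f}  f={m.f:.2f}")
print(f"max R-hat={max(fit.rhat.values()):.3f}  converged={fit.converged}")
print(f"DIC={dic.dic:.1f}  DIC_random={dic.dic_random:.1f}  ΔDIC={dic.delta_dic:.1f}")
```

Output:

```
trials=90  NCAT=6  PSV=12  NPSV=5  FSET=1  TRSET1=13
MAP: r=0.18  p=0.51  d=2.44  f=1.30
max R-hat=1.046  converged=True
DIC=34.0  DIC_random=249.5  ΔDIC=215.6
```

The virtual participant completed all 6 categories in 90 trials with 12
perseverative errors. The fit recovers the generating parameters to
within the posterior's resolution for a single 90-trial session (r 0.18
vs 0.20, p 0.51 vs 0.65, d 2.44 vs 2.00, f 1.30 vs 1.00), and ΔDIC ≈ 216
says the model explains the choices enormously better than a random
4-option chooser (larger ΔDIC = better).

## Command-line pipeline

Every stage is also a subcommand (`wcstmap --help`): `simulate` writes a
synthetic cohort (NIfTI masks + CSV trial logs/scores/covariates), `fit`
runs per-participant MCMC with checkpoint/resume, `compare` ranks the four
model variants by ΔDIC, `recover` / `ppc` / `landscape` run the validation
studies, `vlsm` maps a variable over lesion masks, `cluster` runs the
two-step profiling, and `report` builds correlation and
observed-vs-predicted tables. Each run logs its resolved configuration and
seed next to its outputs.

```bash
wcstmap simulate --out cohort/ --seed 7
wcstmap fit cohort/trials.csv --out fits/
wcstmap vlsm cohort/masks cohort/cohort.csv true_p --out maps/
```

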