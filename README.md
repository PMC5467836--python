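# bayesprog

Bayesian ensemble network analysis of long-term Parkinson's disease (PD)
outcomes: who, at diagnosis, is headed for faster motor and cognitive
decline?

Newly diagnosed PD cohorts collect a wide battery at baseline — UPDRS parts
I–III, the Schwab & England ADL scale, MMSE, dopamine-transporter (DAT)
imaging, genetic risk markers — and then follow participants annually for
years. `bayesprog` implements an open, testable version of the
reverse-engineering / forward-simulation workflow used to mine such cohorts:

1. **Preprocessing** — SNP quality control (minor-allele frequency > 5%,
   missing fraction < 5%, Hardy–Weinberg equilibrium p > 10⁻⁶), genotype and
   clinical k-NN imputation with cross-validated k, additive/dominant/
   recessive codings for key SNPs, PCA collapse of background SNPs, and
   mixed-effects interpolation of imaging onto the annual visit grid.
2. **Network learning** — for every dependent variable (a time-indexed
   outcome such as MoCA at year 5) all small linear-Gaussian local models
   ("fragments") with at most 4 non-SNP parents are enumerated and scored by
   a regularized fit criterion; whole acyclic dynamic Bayesian networks are
   then assembled by Metropolis sampling over per-child fragment swaps,
   yielding an ensemble (1024 networks by default) whose per-edge frequency
   estimates the structural posterior.  Edges at ensemble frequency ≥ 30%
   form the consensus network.
3. **In-silico perturbation** — a putative baseline predictor is clamped
   (do-intervention) at the 5th and the 95th percentile of the training
   data, the signal is propagated forward, and the two simulated endpoint
   posteriors are compared by a permutation test after subsampling each to
   the training-cohort size.  A *disease-state* test compares endpoint
   levels; a *progression* test fits a per-draw least-squares line of
   outcome against year and compares only the slope distributions
   (intercepts discarded), isolating effects on the *rate* of decline.
   P-values below 0.05 are labelled significant, below 0.1 exploratory.

Because the motivating cohort data are access-controlled, the package ships
a first-class synthetic-cohort generator (`bayesprog.synthetic`) that
emulates the study design — annual visits over years 0–7, MoCA observed from
year 4, imaging at months 0 and 22, SNPs at configured allele frequencies —
from a *planted*, fully known linear-Gaussian structural model, so every
stage is testable end to end against ground truth.

## The local model and its score

Each fragment is an ordinary least-squares linear-Gaussian model of a child
on a parent set *S* (|S non-SNP| ≤ 4, at most one coding per SNP), scored

    score(S) = −( n·log(RSS/n) + (|S|+2)·log n )                  (−BIC)
               − |S|·( 2γ·log p + log((1−π)/π) )

where *p* is the number of admissible candidate parents; the EBIC term (γ=1)
and the Bernoulli edge prior (π=0.02 by default) guard against spurious
parents when many candidates compete at cohort-scale n.  The sampler targets
exp(score/T) down a temperature ladder ending at T=1.  On small problems the
sampled edge frequencies are checked against exact enumeration over all
acyclic fragment assignments.

## Worked example

```python
import bayesprog as bp

cfg = bp.default_cohort_config(n_participants=300, seed=17)
frame = bp.frame_from_raw(bp.generate_cohort(cfg, seed=17))

learner = bp.NetworkEnsembleLearner(n_networks=128, random_state=17).fit(frame)
print(learner.consensus(threshold=0.30).to_string(index=False))

res = bp.disease_state_perturbation(learner.ensemble_, frame, "age", "moca@5",
                                    n_permutations=10_000, seed=17)
print(f"age -> MoCA@5: effect {res.effect:+.2f}, p = {res.p_value:.4f} ({res.label})")

slope, _ = bp.progression_perturbation(learner.ensemble_, frame, "bst1", "moca",
                                       n_permutations=10_000, seed=17)
print(f"bst1 -> MoCA slope: effect {slope.effect:+.3f}/yr, p = {slope.p_value:.4f} ({slope.label})")
```

prints

```
       parent    child  frequency  mean_coefficient
          age   moca@4        1.0         -0.231472
          age   moca@5        1.0         -0.237242
          age   moca@6        1.0         -0.246957
          age   moca@7        1.0         -0.222704
bst1_additive   moca@7        1.0         -1.567133
       se_adl   moca@4        1.0          0.362091
       se_adl   moca@5        1.0          0.401438
       se_adl   moca@6        1.0          0.393124
       se_adl   moca@7        1.0          0.398423
       updrs2 updrs3@5        1.0          1.051995
       updrs2 updrs3@6        1.0          1.119519
       updrs2 updrs3@7        1.0          1.001917
age -> MoCA@5: effect -6.65, p = 0.0001 (significant)
bst1 -> MoCA slope: effect -1.059/yr, p = 0.0001 (significant)
```

Every planted level effect (age and baseline S/E ADL on MoCA; baseline
UPDRS II on UPDRS III) is recovered at consensus frequency 1.0 with
coefficients near their planted values (−0.235, +0.385, +1.129), no false
edge enters the consensus, and both perturbation tests flag the planted
effects: clamping age from its 5th to its 95th percentile shifts simulated
year-5 MoCA by −6.65 points, and each planted −0.4 point/year/allele effect
of the key SNP is detected as a −1.06 point/year slope difference between
the 0-copy and 2-copy states.

The same pipeline runs from the shell:

```bash
bayesprog simulate-cohort --n 300 --seed 17 --out cohort/
bayesprog preprocess --clinical cohort/clinical.csv --genotypes cohort/genotypes.tsv \
    --roles cohort/roles.yaml --key-snps bst1 --out frame.csv
bayesprog learn --frame frame.csv --n-networks 1024 --seed 17 --out ens/
bayesprog perturb --ensemble ens/ensemble.json --frame frame.csv \
    --endpoints moca,updrs3 --n-perm 10000 --seed 17 --out results/
bayesprog run --out study/          # end-to-end with a resumable manifest
```

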