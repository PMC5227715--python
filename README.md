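# m6avote

Ensemble support-vector-machine detection of N6-methyladenosine (m6A) sites
in RNA sequence, for computational biologists who need a transparent,
fully reproducible baseline m6A caller and a testbed for ensemble sequence
classifiers.

m6A is the most abundant internal mRNA modification, deposited by the
METTL3/METTL14/WTAP methyltransferase complex. Experimental mapping at
single-base resolution is laborious, so the practical question is: given a
51-nt window centered on an adenosine, is that adenosine methylated?
`m6avote` answers it by majority vote of three SVMs that see the window
through deliberately different representations:

| view | features | kernel |
|---|---|---|
| `psednc` | pseudo dinucleotide composition: 16 dinucleotide frequencies f_k plus lambda tier correlation factors theta_j built from standardized dinucleotide thermodynamics (enthalpy, entropy, free energy) | RBF |
| `motif` | Boolean presence of substrings (length >= 4) occurring in exactly one training class | linear |
| `gkm` | none — gapped k-mer string kernel, K(a,b) = inner product of gapped k-mer count vectors (l = 10, k = 6) | precomputed |

The PseDNC vector is d_k = f_k / (1 + w Σθ) for k ≤ 16 and
d_{16+j} = w θ_j / (1 + w Σθ), with θ_j the mean squared difference of
standardized property triples of dinucleotides j steps apart (defaults
λ = 6, w = 0.9). The final call maximizes the voting score
V_i = Σ_k w_k·[pre(C_k) = class_i]. For three independent voters of equal
accuracy q ∈ (0.5, 1), the majority is right with probability
3q² − 2q³ > q — the reason a trio of ~70% classifiers can beat each of its
members. Evaluation is by jackknife (leave-one-out) or stratified k-fold
cross-validation with the *entire* recipe — motif mining included —
re-fitted inside every training fold, reporting Sn, Sp, Acc and MCC.

See `docs/methods.md` for the model in full, its assumptions and limits.

## Worked example

Train on synthetic benchmark data and evaluate honestly by 10-fold CV
(`examples/train_and_evaluate.py`, a few minutes):

```python
from m6avote import TrainingRecipe, base_classifier_accuracies, kfold
from m6avote.synthetic import SyntheticConfig, generate_dataset

data = generate_dataset(SyntheticConfig(n_pos=100, n_neg=100, seed=1))
cm, metrics, records = kfold(data, k=10, recipe=TrainingRecipe(), seed=1)
```

prints

```
10-fold CV confusion matrix: TP=79 TN=90 FP=10 FN=21
Sn=0.7900  Sp=0.9000  Acc=0.8450  MCC=0.6942

held-out accuracy per base classifier:
  psednc  0.6100
  motif   0.8150
  gkm     0.8750
```

Here 100 positives carry the GGACU consensus context (planting probability
0.9, jitter ±3 around the central A) over a uniform background; 100
negatives are background only. The ensemble's cross-validated accuracy
(0.845) sits at the level of the best single view (the string kernel) and
well above the other two. The theoretical voting gain over the best member
assumes comparably accurate, independent voters; when one view dominates,
the vote tracks it closely instead of beating it.

The same workflows are available from the shell:

```bash
m6avote train pos.fa neg.fa -o model.joblib --seed 1
m6avote predict model.joblib transcripts.fa -o sites.tsv
m6avote evaluate pos.fa neg.fa --mode kfold --k 10 --seed 1 -o eval
m6avote simulate --p1 0.7 --p2 0.7 --p3 0.7     # voting theory check
```

`predict` scans whole transcripts, extracting every 51-nt window whose
center is an adenosine with 25 nt of flank, and writes a tab-delimited
site report (window, call, vote scores, per-classifier labels). Other
short, runnable walkthroughs live in `examples/`.

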