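# mutacyp

Sequence-only prediction of deleterious missense mutations in human
cytochrome P450 enzymes (CYPs).

CYPs metabolize most clinically used drugs, and single amino-acid
substitutions in them cause diseases ranging from congenital adrenal
hyperplasia to rickets. Structures are unavailable for most human CYPs, so
this package scores a substitution `WT<pos>MUT` (e.g. `I462V`) from
sequence-derived inputs alone: a PSI-BLAST position-specific scoring
matrix (PSSM) and a per-residue predicted relative solvent accessibility
(RSA) track.

## Model

Each mutation is summarized by five features:

| Feature | Definition |
|---|---|
| `Abs_dSS` | abs(SS(i, wt) − SS(i, mut)), the PSSM log-odds "similarity score" gap at position i |
| `ss_Abs_dSize` | abs(Δ residue volume) · abs(ΔSS), normalized Zamyatnin volumes |
| `zsEntropy21` | Z-score of the position's Shannon entropy against a 21-residue window |
| `predRSA` | predicted relative solvent accessibility at the position, in [0, 1] |
| `varPredRSA21` | sample variance of predicted RSA over the 21-residue window |

Deleterious mutations concentrate at conserved (negative `zsEntropy21`,
high `Abs_dSS`), buried (low `predRSA`), locally homogeneous (low
`varPredRSA21`) positions.

Candidate features are admitted by F-score

    F = |x̄_n − x̄_d| / (σ_n + σ_d)

(mean/sd over neutral and deleterious classes) with thresholds F ≥ 0.4 and
pairwise |r| < 0.8 (Pearson) against already-admitted features. Two
classifiers consume the vectors: a Fisher linear discriminant (pooled
within-class covariance, midpoint threshold) and a 5-10-5-2 feed-forward
network with logistic activations trained by resilient backpropagation
(Rprop), assessed by stratified 5-fold cross-validation in which 20% of
each training portion is withdrawn as a validation subset for model
selection. Accuracy is reported as Q2, recall, precision, MCC and ROC/AUC.

## Worked example

Evaluating a published benchmark confusion row (true benign called benign
55, benign called deleterious 18, deleterious called benign 13,
deleterious called deleterious 184):

```
$ mutacyp evaluate --confusion 55,18,13,184
{
 "confusion": {"B-B": 55, "B-D": 18, "D-B": 13, "D-D": 184},
 "metrics": {"MCC": 0.7, "Q2": 88.52, "R": 93.4, "P": 91.09}
}
```

i.e. 88.52% of the 270 variants are called correctly, 93.40% of
deleterious variants are recovered, 91.09% of deleterious calls are right,
and the Matthews correlation is 0.70.

A fully synthetic end-to-end run:

```
$ mutacyp simulate --seed 5 --n-benign 30 --n-deleterious 70 --out-dir sim/
$ mutacyp features --pssm sim/synthetic.pssm --rsa sim/synthetic.rsa.tsv \
      --mutations sim/synthetic.mutations.tsv --protein-id synthetic -o f.tsv
$ mutacyp cv --features f.tsv --algo rprop --seed 9 -o cv.json
```

`cv.json` reports per-fold validation/test metrics, their mean ± sd, and
the identifier of the final model (best test MCC, ties broken by the
smallest validation-to-test gap). Other subcommands: `select-features`,
`train`, `score`, `compare` — see `mutacyp --help`.

The package also ships CS30, a 30-variant literature control set
(29 deleterious, 1 benign, across CYP7B1/CYP21A2/CYP11B1/CYP27B1),
loadable with `mutacyp.load_cs30()`.

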