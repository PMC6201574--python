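# strucdiv

Bilinear analysis of how amino-acid substitutions and indels jointly
explain accumulated structural divergence within protein superfamilies.

Structures drift as sequences diverge. Within a superfamily of homologous
protein domains, every pairwise structure alignment yields both structural
divergence measures (superposition RMSD in Å, or the alignment Z-score)
and sequence divergence measures. `strucdiv` splits the sequence signal
into a substitution part and an indel part and fits, per superfamily,

    RMSD    = b0 + b1·PNI + b2·SNG  + u        (Group 1)
    Z-score = b0 + b1·PNS + b2·LSNG + u        (Group 2)

where PNI is the percent sequence non-identity, PNS the percent of
aligned columns scoring ≤ 0 in BLOSUM45, SNG the number of gap runs per
100 aligned residues, and LSNG the same gap count weighted by a fitted
saturating curve a_L = f(L)/f(1), f(L) = c1·e^(−L/c2) + c3, describing how
much an indel of length L shifts the structure of its flanking regions.
A Poisson-corrected variant (PC = −ln(1 − PNI/100)) of Group 1 is also
fitted. |b1| and |b2| are the structural substitution and indel
sensitivities (SSS, SIDS); the product-measure decomposition
C_i = β_i·r_i (with C_sub + C_indel = R²) apportions the explained
variance between the two mutation types. Cross-superfamily aggregation
reports R quartiles, an α/β-class comparison and pooled contribution
shares. The intended users are structural bioinformaticians studying
sequence–structure coevolution; since the original inputs come from
external databases and alignment services, a first-class synthetic-data
module generates every input kind with known ground truth.

## Worked example

Run the full pipeline on a synthetic cohort (4 superfamilies × 80
alignments of 120 residues each, all generated from the default
substitution-dominant ground truth):

```sh
cat > config.yaml <<EOF
out_dir: out
seed: 5
synthetic:
  n_superfamilies: 4
  n_pairs: 80
  n_residues: 120
EOF
strucdiv analyze --config config.yaml
```

prints

```
R[all, group1] median=0.844 IQR=(0.834, 0.851) n=4
R[all, group2] median=0.827 IQR=(0.800, 0.845) n=4
R[pscore, group1] median=0.810 IQR=(0.791, 0.821) n=4
R[pscore, group2] median=0.641 IQR=(0.601, 0.684) n=4
contribution shares: substitutions=0.670 indels=0.330
```

Each line gives the median and interquartile range of the bilinear
multiple correlation coefficient R across superfamilies, for each
variable group and alignment subset ("all" = every alignment with ≥ 50
aligned residues; "pscore" = additionally requiring a strictly positive
P-score). The contribution shares pool the product-measure contributions
C_sub and C_indel over the superfamilies with group-2 R > 0.75: here
two-thirds of the sequence-explained structural variance comes from
substitutions — matching the generating model, in which the substitution
term carries most of the predictor variance. Full per-superfamily fit
statistics (coefficients, SSS/SIDS, adequacies, partial correlations,
VIF, contributions) land in `out/superfamilies.tsv`, the summary in
`out/summary.tsv`, and the fitted indel-weight curve in
`out/weights.yaml`.

The same machinery is available as a library:

```python
from strucdiv import default_truth, gen_alignment_dataset, analyze_superfamily

truth = default_truth(group=2, seed=0)
ds = gen_alignment_dataset(truth, n_pairs=250, group=2, seed=17)
res = analyze_superfamily(ds.records, weights=truth.weight_model)
print(res.fit_group2.r, res.sids_sss_ratio, res.contribution_share_indel)
```

Other subcommands: `strucdiv simulate` writes a synthetic input set to
disk in the package's TSV/FASTA formats, `strucdiv select` lists the
ancient superfamilies of a presence matrix (> 90% of genomes in each
domain of life, ≥ 20 X-ray structures), and `strucdiv aggregate`
re-summarizes a per-superfamily results table.

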